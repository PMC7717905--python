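"""Single-channel trace statistics: filtering, idealization, dwell times, Po, Q10.

The workflow mirrors standard patch-clamp practice: a raw current trace is
digitally low-pass filtered, idealized by half-amplitude threshold crossing
into a sequence of conductance-level events, and the event list is reduced
to open probability (Po / nPo), dwell-time mixture fits, mean dwell times
and temperature coefficients (Q10).  Uncertainty on nPo is estimated by a
moving-block bootstrap over the event sequence, which respects the serial
correlation of gating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "Trace",
    "IdealizedRecord",
    "ExpMixtureFit",
    "ActivitySample",
    "lowpass_filter",
    "idealize",
    "compute_npo",
    "fit_dwell_mixture",
    "mean_closed_time",
    "q10",
    "max_q10",
    "bootstrap_npo_sem",
]

#: Default event-detection dead time, seconds (openings shorter than this
#: are merged into the surrounding level).
MIN_EVENT_DURATION = 4e-5


@dataclass
class Trace:
    """A uniformly sampled current trace.

    ``dt`` is seconds per sample, ``current`` the samples in pA.
    ``metadata`` carries recording conditions (holding potential mV,
    temperature degC, calcium mM, filter cutoff Hz) as plain keys.
    """

    dt: float
    current: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive (got {self.dt})")
        if self.current.size < 2:
            raise ValueError("trace must contain at least 2 samples")

    @property
    def fs(self) -> float:
        """Sampling rate, Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return self.current.size * self.dt


@dataclass
class IdealizedRecord:
    """Sequence of (conductance level, dwell duration) events from one trace."""

    events: list[tuple[int, float]]
    n_channels: int = 1
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        for lvl, dur in self.events:
            if dur <= 0:
                raise ValueError("event durations must be positive")
            if lvl < 0 or lvl > self.n_channels:
                raise ValueError(
                    f"level {lvl} outside 0..n_channels={self.n_channels}"
                )

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.events)

    def level_fractions(self) -> np.ndarray:
        """Time fraction spent at each level 0..n_channels (sums to 1)."""
        frac = np.zeros(self.n_channels + 1)
        for lvl, dur in self.events:
            frac[lvl] += dur
        return frac / frac.sum()

    def dwells(self, level: int) -> np.ndarray:
        """Dwell durations (s) of all events at ``level``."""
        return np.array([d for lvl, d in self.events if lvl == level])


@dataclass(frozen=True)
class ExpMixtureFit:
    """Maximum-likelihood exponential-mixture fit of dwell times.

    ``components`` is a list of (fraction P_i, time constant tau_i seconds)
    with fractions summing to 1 and taus strictly increasing;
    ``n_selected`` is the component count chosen by likelihood-ratio test.
    """

    components: tuple[tuple[float, float], ...]
    log_likelihood: float
    n_selected: int
    warnings: tuple[str, ...] = ()

    @property
    def mean_dwell(self) -> float:
        """Mixture mean sum_i P_i * tau_i, seconds."""
        return sum(p * tau for p, tau in self.components)


@dataclass(frozen=True)
class ActivitySample:
    """Channel activity (Po or nPo) at one temperature (kelvin)."""

    temperature: float
    activity: float

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity must be non-negative")


# ---------------------------------------------------------------------------
# filtering and idealization


def lowpass_filter(trace: Trace, fc: float) -> Trace:
    """Zero-phase Gaussian low-pass filter with -3 dB point at ``fc`` Hz.

    The Gaussian kernel's standard deviation is chosen so its frequency
    response passes 1/sqrt(2) at fc (sigma_t = sqrt(ln 2)/(2*pi*fc)); this
    is the digital analogue of the Gaussian filters conventionally applied
    to single-channel records before event detection.  The trace mean is
    preserved.
    """
    nyquist = 0.5 * trace.fs
    if not 0 < fc < nyquist:
        raise ValueError(f"cutoff fc={fc} Hz must lie in (0, Nyquist={nyquist} Hz)")
    sigma_t = math.sqrt(math.log(2.0)) / (2.0 * math.pi * fc)
    sigma_samples = sigma_t / trace.dt
    # circular boundary: the normalized kernel then preserves the trace mean
    # exactly; wraparound touches only ~4*sigma samples at each end
    filtered = ndimage.gaussian_filter1d(trace.current, sigma_samples, mode="wrap")
    meta = dict(trace.metadata)
    meta["filter_cutoff_Hz"] = fc
    return Trace(dt=trace.dt, current=filtered, metadata=meta)


def _runs(levels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous runs of equal values as (level, start, length)."""
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [levels.size]))
    return [(int(levels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def idealize(
    trace: Trace,
    closed_level: float,
    open_level: float,
    min_duration: float = MIN_EVENT_DURATION,
    n_channels: int = 1,
) -> IdealizedRecord:
    """Half-amplitude threshold idealization of a trace into level events.

    Each sample is assigned to the nearest conductance level on the ladder
    ``closed_level + k*(open_level - closed_level)`` for k = 0..n_channels
    (for one channel this is the classic 50%-threshold rule).  Excursions
    shorter than ``min_duration`` are merged into the enclosing level, then
    adjacent same-level runs are coalesced.  Merging proceeds
    shortest-excursion-first so a brief noise spike cannot split a long
    dwell.

    A warning is attached (not raised) when the open/closed separation is
    less than 3x the baseline noise SD, i.e. when threshold detection is
    unreliable.
    """
    amp = open_level - closed_level
    if amp == 0:
        raise ValueError("open_level must differ from closed_level")
    levels = np.clip(
        np.round((trace.current - closed_level) / amp).astype(int), 0, n_channels
    )

    warnings_: list[str] = []
    closed_samples = trace.current[levels == 0]
    if closed_samples.size >= 10:
        noise_sd = float(np.std(closed_samples))
        if noise_sd > 0 and abs(amp) < 3.0 * noise_sd:
            warnings_.append(
                f"level separation {abs(amp):.3g} pA < 3x noise SD {noise_sd:.3g} pA; "
                "idealization may be unreliable"
            )

    min_samples = max(1, int(round(min_duration / trace.dt)))
    runs = _runs(levels)
    # merge short excursions, shortest first, into the enclosing level
    while len(runs) > 1:
        short = [
            i
            for i in range(len(runs))
            if runs[i][2] < min_samples and 0 < i < len(runs) - 1
        ]
        if not short:
            break
        i = min(short, key=lambda j: runs[j][2])
        lvl_prev = runs[i - 1][0]
        runs[i] = (lvl_prev, runs[i][1], runs[i][2])
        merged: list[tuple[int, int, int]] = []
        for lvl, s, ln in runs:
            if merged and merged[-1][0] == lvl:
                merged[-1] = (lvl, merged[-1][1], merged[-1][2] + ln)
            else:
                merged.append((lvl, s, ln))
        runs = merged

    events = [(lvl, ln * trace.dt) for lvl, s, ln in runs]
    return IdealizedRecord(
        events=events, n_channels=n_channels, warnings=tuple(warnings_)
    )


# ---------------------------------------------------------------------------
# activity statistics


def compute_npo(record: IdealizedRecord) -> tuple[float, float]:
    """(nPo, Po) from an idealized record.

    nPo = sum_i i * P_i over conductance levels i, where P_i is the time
    fraction at level i; Po = nPo / n_channels assumes identical independent
    channels.  The channel count itself must be supplied on the record
    (conventionally the maximum number of simultaneous openings observed at
    high activity).
    """
    frac = record.level_fractions()
    npo = float(np.dot(np.arange(frac.size), frac))
    return npo, npo / record.n_channels


def mean_closed_time(mean_open: float, po: float) -> float:
    """Mean closed dwell implied by the mean open dwell and Po.

    For a binary open/closed alternation, Po = t_open/(t_open + t_closed),
    hence t_closed = mean_open/Po - mean_open.  Po = 0 is rejected (the
    closed time is unbounded).
    """
    if mean_open <= 0:
        raise ValueError(f"mean_open must be positive (got {mean_open})")
    if not 0.0 < po <= 1.0:
        raise ValueError(f"po must lie in (0, 1] (got {po}); po=0 implies infinite closed time")
    return mean_open / po - mean_open


def q10(a: ActivitySample, b: ActivitySample) -> float:
    """Temperature coefficient Q10 = (A2/A1)**(10/(T2-T1)).

    Sample 1 is the lower temperature.  Values > 1 mean heat-activated;
    < 1 cooling-activated.  The 10-degree span in the exponent is a
    difference, so kelvin and Celsius temperatures give identical results.
    """
    lo, hi = (a, b) if a.temperature < b.temperature else (b, a)
    if hi.temperature == lo.temperature:
        raise ValueError("Q10 requires two distinct temperatures")
    if lo.activity <= 0 or hi.activity <= 0:
        raise ValueError("Q10 requires positive activities")
    return (hi.activity / lo.activity) ** (10.0 / (hi.temperature - lo.temperature))


def max_q10(samples: Sequence[ActivitySample]) -> tuple[float, tuple[float, float]]:
    """Largest adjacent-pair Q10 over a temperature series.

    Returns (max Q10, (T_low, T_high) of the pair, kelvin).  Useful when the
    activity rises most steeply over one sub-interval of the scanned range.
    """
    ordered = sorted(samples, key=lambda s: s.temperature)
    if len(ordered) < 2:
        raise ValueError("need at least two activity samples")
    best = None
    for a, b in zip(ordered, ordered[1:]):
        val = q10(a, b)
        if best is None or val > best[0]:
            best = (val, (a.temperature, b.temperature))
    return best


# ---------------------------------------------------------------------------
# dwell-time mixture fitting


def _exp_mixture_loglik(dwells: np.ndarray, p: np.ndarray, tau: np.ndarray) -> float:
    dens = (p / tau) * np.exp(-dwells[:, None] / tau)
    return float(np.sum(np.log(np.maximum(dens.sum(axis=1), 1e-300))))


def _fit_k_components(
    dwells: np.ndarray, k: int, max_iter: int = 2000, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float]:
    """EM fit of a k-component exponential mixture; returns (p, tau, loglik)."""
    if k == 1:
        tau = np.array([dwells.mean()])  # closed-form MLE
        return np.array([1.0]), tau, _exp_mixture_loglik(dwells, np.array([1.0]), tau)
    # spread initial taus across quantiles of the dwell distribution
    qs = np.quantile(dwells, np.linspace(0.15, 0.9, k))
    tau = np.maximum(qs, 1e-12)
    p = np.full(k, 1.0 / k)
    prev = -np.inf
    for _ in range(max_iter):
        dens = (p / tau) * np.exp(-dwells[:, None] / tau)
        total = np.maximum(dens.sum(axis=1), 1e-300)
        resp = dens / total[:, None]
        nk = resp.sum(axis=0)
        p = nk / dwells.size
        tau = np.maximum((resp * dwells[:, None]).sum(axis=0) / np.maximum(nk, 1e-300), 1e-12)
        ll = float(np.sum(np.log(total)))
        if ll - prev < tol * abs(ll):
            break
        prev = ll
    order = np.argsort(tau)
    return p[order], tau[order], _exp_mixture_loglik(dwells, p, tau)


def fit_dwell_mixture(
    dwells: Sequence[float],
    k_max: int = 4,
    confidence: float = 0.95,
) -> ExpMixtureFit:
    """Maximum-likelihood exponential-mixture fit with LRT model selection.

    Components are added one at a time; an extra component is kept only if
    the likelihood-ratio statistic 2*(logL_{k+1} - logL_k) exceeds the
    chi-squared critical value with 2 degrees of freedom at ``confidence``
    (each component adds one fraction and one time constant).  This mirrors
    the automatic term comparison of standard dwell-time fitting software.

    Fitting a mixture of exponentials to raw dwells is equivalent to
    fitting the log-transformed density
    f(ln t) = sum_i P_i exp[(ln t - ln tau_i) - e^(ln t - ln tau_i)]
    to the log-binned dwell histogram; the MLE is identical, so the raw-dwell
    likelihood is maximized directly.
    """
    dwells_arr = np.asarray(dwells, dtype=float)
    if dwells_arr.size < 50:
        raise ValueError(f"need at least 50 dwells (got {dwells_arr.size})")
    if k_max > 4:
        raise ValueError("k_max is capped at 4")
    if (dwells_arr <= 0).any():
        raise ValueError("dwell times must be positive")
    if dwells_arr.size < 2 * k_max:
        raise ValueError("fewer dwells than mixture parameters")

    warnings_: list[str] = []
    crit = stats.chi2.ppf(confidence, df=2)
    p, tau, ll = _fit_k_components(dwells_arr, 1)
    selected = (p, tau, ll, 1)
    for k in range(2, k_max + 1):
        try:
            pk, tauk, llk = _fit_k_components(dwells_arr, k)
        except FloatingPointError:  # pragma: no cover - defensive
            warnings_.append(f"k={k} fit did not converge; skipped")
            continue
        if 2.0 * (llk - selected[2]) > crit:
            selected = (pk, tauk, llk, k)
        else:
            break
    p, tau, ll, k_sel = selected
    # collapse numerically duplicated components (tau within 1%)
    comps = [(float(pi), float(ti)) for pi, ti in zip(p, tau) if pi > 1e-12]
    return ExpMixtureFit(
        components=tuple(comps),
        log_likelihood=ll,
        n_selected=k_sel,
        warnings=tuple(warnings_),
    )


# ---------------------------------------------------------------------------
# bootstrap uncertainty


def bootstrap_npo_sem(
    record: IdealizedRecord,
    n_boot: int = 1000,
    seed: int = 0,
    block_fraction: float = 0.01,
    min_block_events: int = 10,
) -> float:
    """Moving-block bootstrap SEM of nPo over the event sequence.

    The event list is cut into contiguous blocks spanning ~``block_fraction``
    of the total recording (at least ``min_block_events`` events each);
    blocks are resampled with replacement up to the original duration and
    nPo recomputed per replicate.  Blocks preserve local open/closed
    correlation, so the SEM reflects the effective number of independent
    gating epochs rather than the raw event count.  Deterministic for a
    fixed seed.
    """
    if not record.events:
        raise ValueError("record has no events")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} < 100 gives a noisy SEM estimate", stacklevel=2)

    events = record.events
    total = record.total_duration
    target_span = block_fraction * total

    blocks: list[list[tuple[int, float]]] = []
    cur: list[tuple[int, float]] = []
    span = 0.0
    for ev in events:
        cur.append(ev)
        span += ev[1]
        if span >= target_span and len(cur) >= min_block_events:
            blocks.append(cur)
            cur, span = [], 0.0
    if cur:
        if blocks:
            blocks[-1] = blocks[-1] + cur
        else:
            blocks = [cur]
    if len(blocks) < 2:
        return 0.0  # a single block: no between-block variability resolvable

    block_durs = np.array([sum(d for _, d in b) for b in blocks])
    block_open = np.array(
        [sum(lvl * d for lvl, d in b) for b in blocks]
    )  # level-weighted open time

    rng = np.random.default_rng(seed)
    n_blocks = len(blocks)
    reps = np.empty(n_boot)
    for r in range(n_boot):
        open_t = 0.0
        tot_t = 0.0
        while tot_t < total:
            i = rng.integers(0, n_blocks)
            open_t += block_open[i]
            tot_t += block_durs[i]
        reps[r] = open_t / tot_t
    return float(np.std(reps, ddof=1))
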