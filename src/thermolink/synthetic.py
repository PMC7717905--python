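"""Ground-truth-known synthetic data: gating paths, traces, dose–response sets.

The equilibrium allosteric models in :mod:`thermolink.models` say nothing
about kinetics, so simulation requires a kinetic embedding: a continuous-time
Markov chain whose stationary distribution is the model's Boltzmann
distribution.  Forward rates (pore opening, calcium binding) are user
choices; every backward rate is then fixed by detailed balance against the
state weights.  Because the weights derive from state energies, cycle
products close automatically and every embedding reproduces all equilibrium
observables (Po, dwell-time mixtures, dose–response shape) regardless of
the base rates chosen.

Defaults (pore opening 100 /s, calcium on-rate 1e7 /M/s) put dwell times in
the millisecond range typical of large-conductance channel records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .linkage import DoseResponsePoint
from .models import FourStateModel, open_probability
from .single_channel import Trace, lowpass_filter

__all__ = [
    "DEFAULT_BASE_RATES",
    "RateMatrix",
    "GatingPath",
    "build_rate_matrix",
    "simulate_gating",
    "estimate_open_fraction",
    "synthesize_trace",
    "generate_dose_response",
]

DEFAULT_BASE_RATES = {"pore_opening": 100.0, "ca_on": 1e7}

#: state labels of the four-state scheme, pore x sensor occupancy
FOUR_STATE_LABELS = ("UC", "UO", "BC", "BO")
#: conductance class per state (1 = open pore)
OPEN_CLASS = {"UC": 0, "UO": 1, "BC": 0, "BO": 1}


@dataclass(frozen=True)
class RateMatrix:
    """CTMC generator consistent with an equilibrium model.

    ``Q[i, j]`` (i != j) is the transition rate i -> j in 1/s; rows sum to
    zero.  ``weights`` are the (unnormalized) Boltzmann weights of the
    states; detailed balance pi_i q_ij = pi_j q_ji holds by construction.
    """

    states: tuple[str, ...]
    Q: np.ndarray
    weights: np.ndarray

    @property
    def stationary(self) -> np.ndarray:
        """Normalized stationary distribution."""
        return self.weights / self.weights.sum()

    def open_states(self) -> np.ndarray:
        """Boolean mask of open-conductance states."""
        return np.array([OPEN_CLASS[s.rstrip("0123456789")] == 1 for s in self.states])

    def verify_detailed_balance(self, rtol: float = 1e-10) -> bool:
        pi = self.stationary
        n = len(self.states)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                fwd = pi[i] * self.Q[i, j]
                bwd = pi[j] * self.Q[j, i]
                if fwd == 0.0 and bwd == 0.0:
                    continue
                if abs(fwd - bwd) > rtol * max(abs(fwd), abs(bwd)):
                    return False
        return True


@dataclass(frozen=True)
class GatingPath:
    """An exact stochastic gating trajectory: state sequence with sojourn times."""

    states: tuple[str, ...]
    sojourns: np.ndarray  # seconds
    state_sequence: np.ndarray  # indices into `states`
    seed: int

    @property
    def duration(self) -> float:
        return float(self.sojourns.sum())

    def open_fraction(self, open_mask: np.ndarray) -> float:
        """Time fraction spent in open-class states."""
        return float(self.sojourns[open_mask[self.state_sequence]].sum() / self.duration)

    def events(self, open_mask: np.ndarray) -> list[tuple[int, float]]:
        """Aggregate the path into (conductance level, duration) events."""
        levels = open_mask[self.state_sequence].astype(int)
        out: list[tuple[int, float]] = []
        for lvl, dur in zip(levels, self.sojourns):
            if out and out[-1][0] == lvl:
                out[-1] = (lvl, out[-1][1] + float(dur))
            else:
                out.append((int(lvl), float(dur)))
        return out


def build_rate_matrix(
    model: FourStateModel,
    T: float,
    x: float,
    base_rates: Optional[dict] = None,
) -> RateMatrix:
    """Kinetic embedding of a four-state model at temperature ``T`` and calcium ``x``.

    Forward rates: every closed->open pore transition proceeds at
    ``base_rates["pore_opening"]`` (1/s) and every binding transition at
    ``base_rates["ca_on"] * x`` (1/s).  Backward rates are set so each
    edge's equilibrium ratio equals the ratio of Boltzmann weights, which
    enforces detailed balance; the 4-cycle closes exactly because the
    weights come from state energies.

    At ``x = 0`` the bound states carry zero weight and the scheme reduces
    to the two-state unliganded pore (spontaneous openings only).
    """
    rates = dict(DEFAULT_BASE_RATES)
    if base_rates:
        rates.update(base_rates)
    if rates["pore_opening"] <= 0 or rates["ca_on"] <= 0:
        raise ValueError("base rates must be positive")

    w_full = model.state_weights(x, T)  # [UC, UO, BC, BO]
    keep = w_full > 0
    if not keep.any():
        raise ValueError("all state weights are zero")
    labels = tuple(lbl for lbl, k in zip(FOUR_STATE_LABELS, keep) if k)
    w = w_full[keep]
    idx = {lbl: i for i, lbl in enumerate(labels)}

    edges = []  # (from, to, forward_rate) with `from` the closed/unbound side
    if "UC" in idx and "UO" in idx:
        edges.append(("UC", "UO", rates["pore_opening"]))
    if "BC" in idx and "BO" in idx:
        edges.append(("BC", "BO", rates["pore_opening"]))
    if x > 0:
        if "UC" in idx and "BC" in idx:
            edges.append(("UC", "BC", rates["ca_on"] * x))
        if "UO" in idx and "BO" in idx:
            edges.append(("UO", "BO", rates["ca_on"] * x))

    n = len(labels)
    Q = np.zeros((n, n))
    for a, b, kf in edges:
        i, j = idx[a], idx[b]
        Q[i, j] = kf
        Q[j, i] = kf * w[i] / w[j]  # detailed balance
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(states=labels, Q=Q, weights=w)


def simulate_gating(Q: RateMatrix, duration: float, seed: int = 0) -> GatingPath:
    """Exact (Gillespie) CTMC simulation for ``duration`` seconds.

    The initial state is drawn from the stationary distribution so the path
    is stationary from t = 0.  The final sojourn is truncated at
    ``duration``, which leaves time-fraction statistics unbiased.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = len(Q.states)
    exit_rates = -np.diag(Q.Q)
    # embedded jump probabilities
    P = np.zeros_like(Q.Q)
    for i in range(n):
        if exit_rates[i] > 0:
            P[i] = Q.Q[i] / exit_rates[i]
            P[i, i] = 0.0
    cumP = np.cumsum(P, axis=1)

    state = int(rng.choice(n, p=Q.stationary))
    seq: list[int] = []
    soj: list[float] = []
    t = 0.0
    # draw random numbers in chunks to limit Python overhead
    CHUNK = 8192
    u_exp = rng.exponential(size=CHUNK)
    u_jump = rng.random(size=CHUNK)
    k = 0
    while t < duration:
        if k == CHUNK:
            u_exp = rng.exponential(size=CHUNK)
            u_jump = rng.random(size=CHUNK)
            k = 0
        if exit_rates[state] == 0.0:  # absorbing: stay to the end
            seq.append(state)
            soj.append(duration - t)
            t = duration
            break
        dwell = u_exp[k] / exit_rates[state]
        if t + dwell > duration:
            dwell = duration - t
        seq.append(state)
        soj.append(dwell)
        t += dwell
        state = int(np.searchsorted(cumP[state], u_jump[k]))
        k += 1
    return GatingPath(
        states=Q.states,
        sojourns=np.array(soj),
        state_sequence=np.array(seq, dtype=int),
        seed=seed,
    )


def _occupancy_python(
    exit_rates: np.ndarray,
    cumP: np.ndarray,
    cum_pi: np.ndarray,
    open_arr: np.ndarray,
    duration: float,
    seed: int,
) -> float:
    """Open-class occupancy time of a CTMC path; pure-Python reference loop."""
    rng = np.random.default_rng(seed)
    state = int(np.searchsorted(cum_pi, rng.random()))
    t = 0.0
    open_t = 0.0
    while t < duration:
        r = exit_rates[state]
        if r <= 0.0:
            if open_arr[state]:
                open_t += duration - t
            break
        dwell = rng.exponential() / r
        if t + dwell > duration:
            dwell = duration - t
        if open_arr[state]:
            open_t += dwell
        t += dwell
        state = int(np.searchsorted(cumP[state], rng.random()))
    return open_t


try:  # optional numba acceleration for long recordings at high calcium
    from numba import njit

    @njit(cache=False)
    def _occupancy_jit(exit_rates, cumP, cum_pi, open_arr, duration, seed):  # pragma: no cover
        np.random.seed(seed)
        u0 = np.random.random()
        state = 0
        for i in range(cum_pi.size):
            if u0 <= cum_pi[i]:
                state = i
                break
        t = 0.0
        open_t = 0.0
        while t < duration:
            r = exit_rates[state]
            if r <= 0.0:
                if open_arr[state]:
                    open_t += duration - t
                break
            dwell = -math.log(np.random.random()) / r
            if t + dwell > duration:
                dwell = duration - t
            if open_arr[state]:
                open_t += dwell
            t += dwell
            u = np.random.random()
            row = cumP[state]
            nxt = row.size - 1
            for j in range(row.size):
                if u <= row[j]:
                    nxt = j
                    break
            state = nxt
        return open_t

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def estimate_open_fraction(Q: RateMatrix, duration: float, seed: int = 0) -> float:
    """Open-class time fraction of one simulated recording of ``duration`` seconds.

    Runs the same exact CTMC simulation as :func:`simulate_gating` but
    accumulates only the open-class occupancy, so long recordings at high
    calcium (where binding/unbinding events dominate the event count) stay
    cheap.  Uses a compiled inner loop when numba is importable.  Results
    are deterministic per seed within each backend.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = len(Q.states)
    exit_rates = -np.diag(Q.Q).copy()
    P = np.zeros_like(Q.Q)
    for i in range(n):
        if exit_rates[i] > 0:
            P[i] = Q.Q[i] / exit_rates[i]
            P[i, i] = 0.0
    cumP = np.cumsum(P, axis=1)
    cum_pi = np.cumsum(Q.stationary)
    open_arr = Q.open_states()
    if _HAVE_NUMBA:
        open_t = _occupancy_jit(
            exit_rates, cumP, cum_pi, open_arr, float(duration), int(seed) % (2**31)
        )
    else:
        open_t = _occupancy_python(
            exit_rates, cumP, cum_pi, open_arr, float(duration), int(seed) % (2**31)
        )
    return open_t / duration


def synthesize_trace(
    path: GatingPath,
    open_current: float = 10.0,
    noise_sd: float = 1.0,
    fs: float = 25000.0,
    fc: float = 5000.0,
    seed: int = 0,
    open_mask: Optional[np.ndarray] = None,
    metadata: Optional[dict] = None,
) -> Trace:
    """Render a gating path as a noisy, low-pass-filtered current trace.

    Open-class states map to ``open_current`` pA, closed-class to 0 pA;
    Gaussian noise of SD ``noise_sd`` is added sample-wise, then a Gaussian
    low-pass at ``fc`` is applied (``fs`` must exceed 2*fc).  The default
    25 kHz sampling with kHz-range filtering matches common
    single-channel acquisition settings.
    """
    if fs <= 2 * fc:
        raise ValueError(f"fs={fs} Hz must exceed 2*fc={2 * fc} Hz")
    if open_mask is None:
        open_mask = np.array([OPEN_CLASS[s.rstrip("0123456789")] for s in path.states], dtype=bool)

    dt = 1.0 / fs
    n_samples = max(2, int(round(path.duration / dt)))
    # sample the piecewise-constant path on the uniform grid
    edges = np.concatenate(([0.0], np.cumsum(path.sojourns)))
    t_grid = (np.arange(n_samples) + 0.5) * dt
    idx = np.clip(np.searchsorted(edges, t_grid, side="right") - 1, 0, len(path.state_sequence) - 1)
    level = open_mask[path.state_sequence[idx]].astype(float)
    current = level * open_current
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=n_samples)
    meta = dict(metadata or {})
    meta.setdefault("open_current_pA", open_current)
    meta.setdefault("noise_sd_pA", noise_sd)
    trace = Trace(dt=dt, current=current, metadata=meta)
    return lowpass_filter(trace, fc)


def generate_dose_response(
    model: FourStateModel,
    T_list: Sequence[float],
    ca_grid: Sequence[float],
    recording_s: float = 300.0,
    n_patches: int = 3,
    seed: int = 0,
    base_rates: Optional[dict] = None,
) -> list[DoseResponsePoint]:
    """Finite-recording dose–response dataset from a four-state model.

    For every (temperature, calcium) condition, ``n_patches`` independent
    recordings of ``recording_s`` seconds are simulated via the kinetic
    embedding; each patch's Po is its open-class time fraction.  The point
    estimate is the patch mean and the SEM the patch SD / sqrt(n_patches)
    (omitted for a single patch).  As ``recording_s`` grows the estimates
    converge to the analytic open probability.  The 300 s default matches
    the per-condition duration of typical continuous single-channel
    dose–response recordings.

    Patch-level seeds are derived deterministically from ``seed`` by fixed
    offsets, so the full dataset is reproducible.
    """
    if recording_s <= 0:
        raise ValueError("recording_s must be positive")
    points: list[DoseResponsePoint] = []
    counter = 0
    for T in T_list:
        for ca in ca_grid:
            Q = build_rate_matrix(model, T, ca, base_rates)
            po_patches = []
            for _ in range(n_patches):
                po_patches.append(
                    estimate_open_fraction(
                        Q, recording_s, seed=(seed * 100003 + counter) % (2**31)
                    )
                )
                counter += 1
            po_arr = np.array(po_patches)
            sem = (
                float(po_arr.std(ddof=1) / math.sqrt(n_patches))
                if n_patches > 1
                else None
            )
            points.append(
                DoseResponsePoint(
                    temperature=float(T),
                    calcium=float(ca),
                    po=float(po_arr.mean()),
                    sem=sem,
                    n_patches=n_patches,
                )
            )
    return points
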