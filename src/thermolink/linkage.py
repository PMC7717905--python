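"""Hill-plot linkage analysis of dose–response data.

Given open-probability measurements across calcium concentrations at a
fixed temperature, this module fits the four-parameter Hill equation

    Po(x) = A + (B - A) * x**n / (K**n + x**n)

and reads the Hill-plot asymptotes off the fitted plateaus:
chi- = ln(A/(1-A)), chi+ = ln(B/(1-B)).  The asymptote difference
delta_chi = chi+ - chi- is a model-free measure of the net coupling between
the ligand-binding sites and the pore, convertible to a free energy
RT*delta_chi.  Comparing delta_chi across temperatures localizes a
temperature effect: a shift confined to chi- implicates the apo-sensor/pore
interaction, a parallel shift of both asymptotes implicates intrinsic pore
gating, and a pure EC50 shift with invariant asymptotes implicates ligand
binding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .models import ChiValues, R_GAS, R_KCAL

__all__ = [
    "DoseResponsePoint",
    "HillFit",
    "LinkageResult",
    "TemperatureComparison",
    "hill_transform",
    "fit_hill",
    "asymptotes_from_fit",
    "coupling_energy",
    "analyze_dose_response",
    "compare_temperatures",
    "bootstrap_delta_chi",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    """One dose–response observation: Po at a calcium concentration and temperature.

    ``temperature`` in kelvin, ``calcium`` in molar, ``sem`` (optional) the
    standard error of ``po`` across patches, ``n_patches`` the replicate count.
    """

    temperature: float
    calcium: float
    po: float
    sem: Optional[float] = None
    n_patches: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.po <= 1.0:
            raise ValueError(f"po must lie in [0, 1] (got {self.po})")
        if self.calcium < 0:
            raise ValueError(f"calcium must be non-negative (got {self.calcium} M)")
        if self.sem is not None and self.sem < 0:
            raise ValueError(f"sem must be non-negative (got {self.sem})")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill equation parameters.

    A and B are the low- and high-calcium Po plateaus, K the EC50 (molar),
    n the Hill coefficient, ``residual`` the weighted sum of squared
    residuals of the converged fit.
    """

    A: float
    B: float
    K: float
    n: float
    residual: float
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class LinkageResult:
    """Linkage summary at one temperature."""

    temperature: float
    chi_minus: float
    chi_plus: float
    delta_chi: float
    coupling_energy_kcal: float
    coupling_energy_kJ: float
    fit: Optional[HillFit] = None


@dataclass(frozen=True)
class TemperatureComparison:
    """Paired linkage results at two temperatures with their differences."""

    low: LinkageResult
    high: LinkageResult
    d_delta_chi: float
    d_ec50: float
    d_hill_n: float
    dominant_asymptote: str  # "chi_minus", "chi_plus" or "both"
    notes: tuple[str, ...] = ()


class FitError(RuntimeError):
    """Hill fit failed; carries the best parameters found so far, if any."""

    def __init__(self, message: str, best: Optional[HillFit] = None):
        super().__init__(message)
        self.best = best


def hill_transform(po: float) -> float:
    """ln(Po/(1-Po)); the logit of the open probability.

    Undefined at Po = 0 or 1: report the limiting bound from neighbouring
    concentrations instead of transforming a saturated estimate.
    """
    if not 0.0 < po < 1.0:
        raise ValueError(
            f"hill_transform requires 0 < po < 1 (got {po}); for saturated "
            "estimates report a limiting bound instead"
        )
    return math.log(po / (1.0 - po))


def _hill(x: np.ndarray, A: float, B: float, K: float, n: float) -> np.ndarray:
    xn = np.power(x, n)
    return A + (B - A) * xn / (np.power(K, n) + xn)


def fit_hill(
    points: Sequence[DoseResponsePoint],
    weights: Optional[np.ndarray] = None,
) -> HillFit:
    """Weighted least-squares fit of the Hill equation to dose–response points.

    Requires at least 4 points over at least 2 distinct calcium
    concentrations.  Weights default to 1/sem**2 when every point carries a
    SEM, unweighted otherwise.  A deterministic multistart over Hill
    coefficients n in {1, 2, 4, 8} guards against the steep-curve local
    minima typical of cooperative channels; the start with the lowest
    residual wins, ties going to the smallest n.

    Attaches an identifiability warning when a fitted plateau extrapolates
    beyond the observed Po range by more than a factor of two (in logit
    distance from the nearest observation).
    """
    if len(points) < 4:
        raise ValueError(f"need at least 4 dose–response points (got {len(points)})")
    x = np.array([p.calcium for p in points], dtype=float)
    y = np.array([p.po for p in points], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct calcium concentrations")
    if np.ptp(y) == 0:
        raise ValueError("degenerate data: all Po values identical")

    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(w)
    elif all(p.sem is not None and p.sem > 0 for p in points):
        sigma = np.array([p.sem for p in points], dtype=float)

    eps = 1e-6
    lo = [eps, eps, 0.0, 0.1]
    hi = [1.0 - eps, 1.0 - eps, np.inf, 10.0]
    a0 = float(np.clip(y.min(), eps, 1 - eps))
    b0 = float(np.clip(y.max(), eps, 1 - eps))
    xpos = x[x > 0]
    k0 = float(np.exp(np.mean(np.log(xpos)))) if len(xpos) else 1e-3

    best: Optional[tuple[float, float, np.ndarray]] = None  # (residual, n_start, popt)
    for n_start in (1.0, 2.0, 4.0, 8.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _hill,
                    x,
                    y,
                    p0=[a0, b0, k0, n_start],
                    sigma=sigma,
                    absolute_sigma=False,
                    bounds=(lo, hi),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = _hill(x, *popt) - y
        if sigma is not None:
            resid = resid / sigma
        rss = float(np.sum(resid**2))
        if best is None or rss < best[0] - 1e-14:
            best = (rss, n_start, popt)
    if best is None:
        raise FitError("Hill fit failed to converge from every start")

    rss, _, popt = best
    A, B, K, n = (float(v) for v in popt)
    if A > B:  # decreasing response: keep the A<B convention by swapping plateaus
        A, B = B, A

    notes = []
    logit = lambda p: math.log(p / (1 - p))  # noqa: E731
    y_in = np.clip(y, eps, 1 - eps)
    lo_obs, hi_obs = logit(y_in.min()), logit(y_in.max())
    if logit(max(A, eps)) < lo_obs - math.log(2.0) * 2:
        notes.append(
            "lower plateau A extrapolates >2x below the observed Po range; "
            "chi_minus (and delta_chi) may be under-constrained"
        )
    if logit(min(B, 1 - eps)) > hi_obs + math.log(2.0) * 2:
        notes.append(
            "upper plateau B extrapolates >2x above the observed Po range; "
            "chi_plus (and delta_chi) may be under-constrained"
        )
    return HillFit(A=A, B=B, K=K, n=n, residual=rss, warnings=tuple(notes))


def asymptotes_from_fit(fit: HillFit) -> ChiValues:
    """Hill-plot asymptotes from fitted plateaus: chi± = logit of A and B."""
    for name, v in (("A", fit.A), ("B", fit.B)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"plateau {name}={v} is at a bound; asymptote undefined")
    return ChiValues(
        chi_minus=math.log(fit.A / (1.0 - fit.A)),
        chi_plus=math.log(fit.B / (1.0 - fit.B)),
    )


def coupling_energy(delta_chi: float, T: float, units: str = "kcal") -> float:
    """Net coupling free energy R*T*delta_chi.

    ``units`` is ``"kcal"`` (default, R = 1.987e-3 kcal/(mol*K)) or ``"kJ"``
    (R = 8.314e-3 kJ/(mol*K)).
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive (got {T} K)")
    if units == "kcal":
        return R_KCAL * T * delta_chi
    if units == "kJ":
        return R_GAS * 1e-3 * T * delta_chi
    raise ValueError(f"unknown units {units!r}; use 'kcal' or 'kJ'")


def analyze_dose_response(points: Sequence[DoseResponsePoint]) -> LinkageResult:
    """Fit one single-temperature dose–response set and summarize its linkage.

    All points must share one temperature.  Returns the fitted asymptotes,
    delta_chi, and the coupling energy in both kcal/mol and kJ/mol.
    """
    temps = {p.temperature for p in points}
    if len(temps) != 1:
        raise ValueError(f"points span {len(temps)} temperatures; expected exactly 1")
    T = temps.pop()
    fit = fit_hill(points)
    chi = asymptotes_from_fit(fit)
    return LinkageResult(
        temperature=T,
        chi_minus=chi.chi_minus,
        chi_plus=chi.chi_plus,
        delta_chi=chi.delta_chi,
        coupling_energy_kcal=coupling_energy(chi.delta_chi, T, "kcal"),
        coupling_energy_kJ=coupling_energy(chi.delta_chi, T, "kJ"),
        fit=fit,
    )


def compare_temperatures(
    set_low: Sequence[DoseResponsePoint],
    set_high: Sequence[DoseResponsePoint],
) -> TemperatureComparison:
    """Linkage analysis at two temperatures plus their differences.

    Returns per-temperature :class:`LinkageResult` objects and the changes
    in delta_chi, EC50 and Hill n (high minus low).  The
    ``dominant_asymptote`` field flags which asymptote moved more with
    temperature — the diagnostic that separates coupling effects
    (chi_minus-dominated here) from intrinsic pore effects (both asymptotes
    move together).
    """
    low = analyze_dose_response(set_low)
    high = analyze_dose_response(set_high)
    if high.temperature == low.temperature:
        raise ValueError("the two sets must be at distinct temperatures")
    if high.temperature < low.temperature:
        low, high = high, low

    shift_minus = abs(high.chi_minus - low.chi_minus)
    shift_plus = abs(high.chi_plus - low.chi_plus)
    if shift_minus > 2.0 * shift_plus:
        dominant = "chi_minus"
    elif shift_plus > 2.0 * shift_minus:
        dominant = "chi_plus"
    else:
        dominant = "both"

    notes = list(low.fit.warnings) + list(high.fit.warnings)
    notes.append(
        "delta_chi at the lower temperature is a one-sided estimate: if Po at "
        "the lowest attainable calcium is not yet on the chi_minus plateau, "
        "the true low-temperature delta_chi is larger"
    )
    return TemperatureComparison(
        low=low,
        high=high,
        d_delta_chi=high.delta_chi - low.delta_chi,
        d_ec50=high.fit.K - low.fit.K,
        d_hill_n=high.fit.n - low.fit.n,
        dominant_asymptote=dominant,
        notes=tuple(notes),
    )


def bootstrap_delta_chi(
    points: Sequence[DoseResponsePoint],
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap-over-points SE of delta_chi for one dose–response set.

    Resamples points with replacement (keeping >= 4 points over >= 2 calcium
    values), refits, and returns (delta_chi point estimate, bootstrap SD).
    Replicates in which the fit fails are dropped.
    """
    base = analyze_dose_response(points)
    rng = np.random.default_rng(seed)
    reps = []
    pts = list(points)
    for _ in range(n_boot):
        idx = rng.integers(0, len(pts), size=len(pts))
        sample = [pts[i] for i in idx]
        if len({p.calcium for p in sample}) < 2:
            continue
        try:
            reps.append(analyze_dose_response(sample).delta_chi)
        except (ValueError, FitError):
            continue
    sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else float("nan")
    return base.delta_chi, sd
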