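"""Equilibrium allosteric models of ligand- and temperature-dependent channel gating.

The central object is a binary-elements description of a calcium-gated
channel: the pore is closed (C) or open (O), and each calcium-binding site
is unbound (U) or bound (B).  Every pore/site state pair carries a
state-dependent coupling constant ``theta_XY`` (a Boltzmann factor for the
interaction free energy between a site in state X and the pore in state Y).
Temperature enters through van't Hoff parameterization of any equilibrium or
coupling constant, ``K(T) = exp(-(dH - T*dS) / (R*T))``.

Three model families are provided:

* :class:`FourStateModel` — one pore, one (composite) calcium sensor, four
  couplings.  This is the minimal model in which the Hill-plot asymptotes
  ``chi_minus``/``chi_plus`` separate sensor–pore coupling from intrinsic
  pore bias and binding affinity.
* :class:`SensorModel` — pore + ligand site + a discrete thermosensor with
  activation constant M0 and allosteric factors C (thermosensor–pore),
  E (thermosensor–site) and D (pore–site).  Closed-form temperature
  derivatives of the chi values are available.
* :class:`GeneralizedModel` — N binding sites with per-site couplings and
  pairwise site–site interaction factors, evaluated by explicit enumeration
  of all 2**(N+1) channel conformations.

All chi values are carried in natural-log units (dimensionless); conversion
to energies is the job of :mod:`thermolink.linkage`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "R_GAS",
    "R_KCAL",
    "VantHoffCoupling",
    "Coupling",
    "ChiValues",
    "FourStateModel",
    "NormalizedModel",
    "SensorModel",
    "GeneralizedModel",
    "coupling_at_temperature",
    "evaluate_coupling",
    "open_probability",
    "chi_values",
    "normalize",
    "sensor_chi",
    "sensor_chi_derivatives",
    "generalized_evaluate",
    "simulate_hill_plot",
    "celsius_to_kelvin",
]

#: Gas constant, J/(mol*K), used in all van't Hoff exponents.
R_GAS = 8.314
#: Gas constant, kcal/(mol*K), used when reporting coupling energies.
R_KCAL = 1.987e-3


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from degrees Celsius to kelvin."""
    return t_celsius + 273.15


@dataclass(frozen=True)
class VantHoffCoupling:
    """Temperature-dependent equilibrium constant, van't Hoff parameterized.

    Parameters
    ----------
    dH : float
        Enthalpy change, J/mol.
    dS : float
        Entropy change, J/(mol*K).

    The constant at absolute temperature ``T`` is
    ``exp(-(dH - T*dS) / (R*T))`` with R = 8.314 J/(mol*K); it is finite and
    strictly positive for every T > 0.
    """

    dH: float
    dS: float

    def value(self, T: float) -> float:
        """Evaluate the equilibrium constant at temperature ``T`` (kelvin)."""
        if T <= 0:
            raise ValueError(f"temperature must be positive (got {T} K)")
        return math.exp(-(self.dH - T * self.dS) / (R_GAS * T))

    def ddT(self, T: float) -> float:
        """Analytic temperature derivative dK/dT = K * dH / (R*T**2)."""
        return self.value(T) * self.dH / (R_GAS * T * T)


#: A coupling/equilibrium constant: either a fixed positive number or a
#: van't Hoff temperature dependence.
Coupling = Union[float, VantHoffCoupling]


def coupling_at_temperature(vh: VantHoffCoupling, T: float) -> float:
    """Value of a van't Hoff coupling at temperature ``T`` (kelvin)."""
    return vh.value(T)


def evaluate_coupling(c: Coupling, T: float) -> float:
    """Collapse a :data:`Coupling` to a positive number at temperature ``T``."""
    if isinstance(c, VantHoffCoupling):
        return c.value(T)
    v = float(c)
    if not math.isfinite(v) or v <= 0:
        raise ValueError(f"coupling constants must be positive and finite (got {c})")
    return v


@dataclass(frozen=True)
class ChiValues:
    """Limiting Hill-plot asymptotes, in natural-log units.

    ``chi_minus`` is the zero-ligand limit of ln(Po/(1-Po)), ``chi_plus``
    the saturating-ligand limit, and ``delta_chi = chi_plus - chi_minus``
    measures the net sensor–pore coupling.
    """

    chi_minus: float
    chi_plus: float

    @property
    def delta_chi(self) -> float:
        return self.chi_plus - self.chi_minus


@dataclass(frozen=True)
class FourStateModel:
    """Binary-elements model: pore (C/O) x one calcium sensor (U/B).

    Parameters
    ----------
    L0 : Coupling
        Intrinsic pore-opening equilibrium constant (dimensionless).
    K_Ca : Coupling
        Calcium association constant, M**-1.
    theta_UC, theta_UO, theta_BC, theta_BO : Coupling
        State-dependent sensor–pore coupling constants (dimensionless);
        subscripts: sensor Unbound/Bound x pore Closed/Open.

    With the closed-pore/apo-sensor state as energy reference, the partition
    function is

        Z = theta_UC + L0*theta_UO + K*x*theta_BC + L0*K*x*theta_BO
    """

    L0: Coupling
    K_Ca: Coupling
    theta_UC: Coupling = 1.0
    theta_UO: Coupling = 1.0
    theta_BC: Coupling = 1.0
    theta_BO: Coupling = 1.0

    def at_temperature(self, T: float) -> "FourStateModel":
        """Return a copy with every coupling collapsed to a number at ``T``."""
        return FourStateModel(
            L0=evaluate_coupling(self.L0, T),
            K_Ca=evaluate_coupling(self.K_Ca, T),
            theta_UC=evaluate_coupling(self.theta_UC, T),
            theta_UO=evaluate_coupling(self.theta_UO, T),
            theta_BC=evaluate_coupling(self.theta_BC, T),
            theta_BO=evaluate_coupling(self.theta_BO, T),
        )

    def state_weights(self, x: float, T: float) -> np.ndarray:
        """Boltzmann weights of the four states [UC, UO, BC, BO] at (x, T)."""
        if x < 0:
            raise ValueError(f"calcium concentration must be non-negative (got {x} M)")
        m = self.at_temperature(T)
        return np.array(
            [
                m.theta_UC,
                m.L0 * m.theta_UO,
                m.K_Ca * x * m.theta_BC,
                m.L0 * m.K_Ca * x * m.theta_BO,
            ]
        )


@dataclass(frozen=True)
class NormalizedModel:
    """Classical-form reduction of a :class:`FourStateModel`.

    Dividing the partition function by theta_UC and regrouping gives

        Z' = 1 + L0' + K'*x + L0'*K'*x*theta

    with L0' = L0*theta_UO/theta_UC, K' = K*theta_BC/theta_UC and the net
    cooperativity theta = theta_UC*theta_BO/(theta_UO*theta_BC).  Po is
    identical to the source model's at every (x); the state-dependent
    couplings are merely folded into the apparent constants.
    """

    L0_prime: float
    K_prime: float
    theta: float

    def open_probability(self, x: float) -> float:
        if x < 0:
            raise ValueError(f"calcium concentration must be non-negative (got {x} M)")
        num = self.L0_prime * (1.0 + self.K_prime * x * self.theta)
        den = 1.0 + self.L0_prime + self.K_prime * x + self.L0_prime * self.K_prime * x * self.theta
        return num / den


@dataclass(frozen=True)
class SensorModel:
    """Pore + ligand site + discrete thermosensor.

    The thermosensor has activation constant ``M0`` (usually van't Hoff
    temperature-dependent) and interacts with the pore via allosteric factor
    ``C`` and with the ligand-binding site via ``E``; the pore–site coupling
    is the single factor ``D``.  ``K`` is the ligand association constant,
    needed only for full dose–response/Hill-plot evaluation (the chi values
    themselves are independent of it).
    """

    L0: float
    D: float
    C: float
    E: float
    M0: Coupling
    K: Coupling = 20000.0

    def m0_at(self, T: float) -> float:
        return evaluate_coupling(self.M0, T)


@dataclass(frozen=True)
class GeneralizedModel:
    """N-site allosteric channel with per-site couplings and pairwise site–site terms.

    Parameters
    ----------
    L0 : float
        Intrinsic pore-opening equilibrium constant.
    K : sequence of float
        Per-site ligand association constants, M**-1 (length N).
    theta_UC, theta_UO, theta_BC, theta_BO : sequence of float
        Per-site site–pore coupling constants (length N each).
    alpha : ndarray of shape (N, N, 2, 2), optional
        Pairwise site–site coupling factors; ``alpha[i, j, a, b]`` couples
        site i in state a and site j in state b (0 = unbound, 1 = bound).
        Must satisfy ``alpha[i, j, a, b] == alpha[j, i, b, a]``; defaults to
        all ones (no direct site–site interaction).

    Evaluation enumerates all 2**N occupancy patterns per pore state, so N
    is capped at 12.
    """

    L0: float
    K: Sequence[float]
    theta_UC: Sequence[float]
    theta_UO: Sequence[float]
    theta_BC: Sequence[float]
    theta_BO: Sequence[float]
    alpha: np.ndarray | None = None

    MAX_SITES = 12

    @property
    def n_sites(self) -> int:
        return len(self.K)

    def __post_init__(self) -> None:
        n = self.n_sites
        if n < 1:
            raise ValueError("need at least one binding site")
        if n > self.MAX_SITES:
            raise ValueError(
                f"N={n} sites would enumerate 2**{n + 1} states; capped at {self.MAX_SITES}"
            )
        for name in ("theta_UC", "theta_UO", "theta_BC", "theta_BO"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length {n}")
        arrays = {name: np.asarray(getattr(self, name), dtype=float)
                  for name in ("K", "theta_UC", "theta_UO", "theta_BC", "theta_BO")}
        if any((a <= 0).any() for a in arrays.values()) or self.L0 <= 0:
            raise ValueError("all equilibrium and coupling constants must be positive")
        if self.alpha is not None:
            a = np.asarray(self.alpha, dtype=float)
            if a.shape != (n, n, 2, 2):
                raise ValueError(f"alpha must have shape ({n}, {n}, 2, 2)")
            if (a <= 0).any():
                raise ValueError("alpha factors must be positive")
            if not np.allclose(a, np.transpose(a, (1, 0, 3, 2))):
                raise ValueError("alpha must be symmetric: alpha[i,j,a,b] == alpha[j,i,b,a]")
            object.__setattr__(self, "alpha", a)


# ---------------------------------------------------------------------------
# operations on the four-state model


def open_probability(model: FourStateModel, x: float, T: float = 298.15) -> float:
    """Open probability of a :class:`FourStateModel` at calcium ``x`` (M), temperature ``T`` (K).

    Po = (L0*thUO + L0*K*x*thBO) / (thUC + L0*thUO + K*x*thBC + L0*K*x*thBO).
    """
    w = model.state_weights(x, T)
    return (w[1] + w[3]) / w.sum()


def chi_values(model: FourStateModel, T: float = 298.15) -> ChiValues:
    """Hill-plot asymptotes of a four-state model.

    chi- = ln(L0*thUO/thUC) is the zero-calcium limit of ln(Po/(1-Po));
    chi+ = ln(L0*thBO/thBC) the saturating limit.  Their difference
    delta_chi = ln(thBO*thUC/(thBC*thUO)) depends only on the couplings.
    """
    m = model.at_temperature(T)
    return ChiValues(
        chi_minus=math.log(m.L0 * m.theta_UO / m.theta_UC),
        chi_plus=math.log(m.L0 * m.theta_BO / m.theta_BC),
    )


def normalize(model: FourStateModel, T: float = 298.15) -> NormalizedModel:
    """Collapse the four state-dependent couplings into classical apparent constants."""
    m = model.at_temperature(T)
    return NormalizedModel(
        L0_prime=m.L0 * m.theta_UO / m.theta_UC,
        K_prime=m.K_Ca * m.theta_BC / m.theta_UC,
        theta=m.theta_UC * m.theta_BO / (m.theta_UO * m.theta_BC),
    )


# ---------------------------------------------------------------------------
# thermosensor model


def sensor_chi(model: SensorModel, T: float = 298.15) -> ChiValues:
    """Hill-plot asymptotes of the discrete-thermosensor model.

    chi- = ln[L0(1+M0*C)/(1+M0)] and chi+ = ln[L0*D(1+M0*C*E)/(1+M0*E)],
    where M0 is evaluated at ``T``.  When C = 1 the thermosensor is
    uncoupled from the pore and both asymptotes lose their M0 (hence
    temperature) dependence.
    """
    m0 = model.m0_at(T)
    chi_m = math.log(model.L0 * (1.0 + m0 * model.C) / (1.0 + m0))
    chi_p = math.log(
        model.L0 * model.D * (1.0 + m0 * model.C * model.E) / (1.0 + m0 * model.E)
    )
    return ChiValues(chi_minus=chi_m, chi_plus=chi_p)


def sensor_chi_derivatives(
    model: SensorModel, T: float = 298.15
) -> tuple[float, float, float]:
    """Closed-form temperature derivatives (dchi-/dT, dchi+/dT, dDeltachi/dT).

    With m = M0(T), m' = dM0/dT (from the van't Hoff form):

        dchi-/dT = m' (C-1) / [(1+m)(1+mC)]
        dchi+/dT = m' E(C-1) / [(1+mE)(1+mCE)]
        dDchi/dT = m' (E-1)(C-1)(1-m^2 CE) / [(1+m)(1+mC)(1+mE)(1+mCE)]

    If ``M0`` is a plain number the derivative is undefined within the model
    and (0, 0, 0) is returned with a warning.
    """
    if not isinstance(model.M0, VantHoffCoupling):
        import warnings

        warnings.warn(
            "M0 is a fixed constant; temperature derivatives are returned as zero",
            stacklevel=2,
        )
        return (0.0, 0.0, 0.0)
    m = model.M0.value(T)
    dm = model.M0.ddT(T)
    C, E = model.C, model.E
    d_minus = dm * (C - 1.0) / ((1.0 + m) * (1.0 + m * C))
    d_plus = dm * E * (C - 1.0) / ((1.0 + m * E) * (1.0 + m * C * E))
    d_delta = (
        dm
        * (E - 1.0)
        * (C - 1.0)
        * (1.0 - m * m * C * E)
        / ((1.0 + m) * (1.0 + m * C) * (1.0 + m * E) * (1.0 + m * C * E))
    )
    return (d_minus, d_plus, d_delta)


def _sensor_open_probability(model: SensorModel, x: float, T: float) -> float:
    # states: pore {C,O} x sensor {rest, active} x site {U,B}
    #   weight factors: L0 (open), M0 (active), K*x (bound),
    #   C (open & active), D (open & bound), E (active & bound)
    if x < 0:
        raise ValueError(f"ligand concentration must be non-negative (got {x} M)")
    m0 = model.m0_at(T)
    kx = evaluate_coupling(model.K, T) * x
    z_c = 1.0 + m0 + kx + m0 * model.E * kx
    z_o = model.L0 * (
        1.0 + m0 * model.C + model.D * kx + m0 * model.C * model.E * model.D * kx
    )
    return z_o / (z_c + z_o)


# ---------------------------------------------------------------------------
# generalized N-site model


def _occupancy_patterns(n: int) -> np.ndarray:
    """All 2**n occupancy patterns as a (2**n, n) array of 0/1, ordered by count."""
    patterns = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1).astype(int)
    return patterns


def generalized_evaluate(
    model: GeneralizedModel, x: float, T: float = 298.15
) -> tuple[float, float, float, ChiValues]:
    """Contracted partition functions, Po and chi values of an N-site model.

    Returns ``(Z_C, Z_O, Po, ChiValues)``.  Z_C and Z_O are the sums of
    Boltzmann weights over all 2**N site-occupancy patterns with the pore
    closed or open; each weight is the product of L0 (open states only),
    ``K_i * x`` for every occupied site, the per-site site–pore coupling for
    the pattern, and every pairwise alpha factor.  The asymptotes are the
    closed forms

        chi- = ln(L0 * prod thUO_i / prod thUC_i)
        chi+ = ln(L0 * prod thBO_i / prod thBC_i)

    and delta_chi = sum_i ln(thBO_i*thUC_i/(thBC_i*thUO_i)) is independent
    of the affinities K_i, of L0, and of the alpha terms.
    """
    if x < 0:
        raise ValueError(f"ligand concentration must be non-negative (got {x} M)")
    n = model.n_sites
    K = np.asarray(model.K, dtype=float)
    th = {
        (0, 0): np.asarray(model.theta_UC, dtype=float),
        (0, 1): np.asarray(model.theta_UO, dtype=float),
        (1, 0): np.asarray(model.theta_BC, dtype=float),
        (1, 1): np.asarray(model.theta_BO, dtype=float),
    }
    patterns = _occupancy_patterns(n)  # (P, n)

    # pairwise alpha product per pattern (pore-independent)
    if model.alpha is None:
        alpha_prod = np.ones(len(patterns))
    else:
        alpha_prod = np.ones(len(patterns))
        for i in range(n):
            for j in range(i + 1, n):
                alpha_prod *= model.alpha[i, j, patterns[:, i], patterns[:, j]]

    # ligand factor per pattern
    with np.errstate(divide="ignore"):
        kx = K * x
    lig = np.prod(np.where(patterns == 1, kx[None, :], 1.0), axis=1)

    z = {}
    for pore in (0, 1):  # 0 = closed, 1 = open
        coup = np.prod(
            np.where(patterns == 1, th[(1, pore)][None, :], th[(0, pore)][None, :]),
            axis=1,
        )
        w = lig * coup * alpha_prod
        if pore == 1:
            w = model.L0 * w
        z[pore] = float(w.sum())

    z_c, z_o = z[0], z[1]
    po = z_o / (z_c + z_o)
    chi = ChiValues(
        chi_minus=math.log(model.L0) + float(np.log(th[(0, 1)]).sum() - np.log(th[(0, 0)]).sum()),
        chi_plus=math.log(model.L0) + float(np.log(th[(1, 1)]).sum() - np.log(th[(1, 0)]).sum()),
    )
    return z_c, z_o, po, chi


# ---------------------------------------------------------------------------
# Hill-plot simulation


AnyModel = Union[FourStateModel, GeneralizedModel, SensorModel]


def model_open_probability(model: AnyModel, x: float, T: float) -> float:
    """Po of any supported model at calcium ``x`` (M) and temperature ``T`` (K)."""
    if isinstance(model, FourStateModel):
        return open_probability(model, x, T)
    if isinstance(model, SensorModel):
        return _sensor_open_probability(model, x, T)
    if isinstance(model, GeneralizedModel):
        return generalized_evaluate(model, x, T)[2]
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def simulate_hill_plot(
    model: AnyModel,
    T_list: Sequence[float],
    x_grid: Sequence[float],
) -> pd.DataFrame:
    """Hill-transformed dose–response surface over temperatures and calcium.

    For every temperature in ``T_list`` (kelvin) and calcium concentration
    in ``x_grid`` (molar), evaluates Po and its Hill transform
    ln(Po/(1-Po)).  Returns a tidy DataFrame with columns
    ``temperature_K, calcium_M, po, hill_transform``.

    With every parameter temperature-independent the rows repeat across
    temperatures; a temperature-dependent binding constant K shifts the
    curves laterally but leaves both asymptotes (and hence delta_chi)
    unchanged, whereas a temperature-dependent coupling moves the asymptotes
    themselves.
    """
    rows = []
    for T in T_list:
        for x in x_grid:
            po = model_open_probability(model, float(x), float(T))
            rows.append(
                {
                    "temperature_K": float(T),
                    "calcium_M": float(x),
                    "po": po,
                    "hill_transform": math.log(po / (1.0 - po)),
                }
            )
    return pd.DataFrame(rows)
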