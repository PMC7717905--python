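"""Unit and property tests for the equilibrium allosteric models."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermolink.models import (
    FourStateModel,
    GeneralizedModel,
    SensorModel,
    VantHoffCoupling,
    chi_values,
    coupling_at_temperature,
    generalized_evaluate,
    normalize,
    open_probability,
    sensor_chi,
    sensor_chi_derivatives,
    simulate_hill_plot,
)

from conftest import random_four_state

positive = st.floats(min_value=1e-3, max_value=1e3)


# ---------------------------------------------------------------------------
# van't Hoff couplings


@pytest.mark.parametrize(
    "dH, dS, T, expected, rel",
    [
        (0.0, 0.0, 300.0, 1.0, 1e-12),          # zero free energy
        (-71000.0, -220.0, 294.15, 13.076, 1e-3),
        (80000.0, 300.0, 310.15, 157.43, 1e-3),
    ],
)
def test_vant_hoff_value(dH, dS, T, expected, rel):
    assert coupling_at_temperature(VantHoffCoupling(dH, dS), T) == pytest.approx(
        expected, rel=rel
    )


def test_vant_hoff_rejects_nonpositive_temperature():
    vh = VantHoffCoupling(1000.0, 1.0)
    for T in (0.0, -10.0):
        with pytest.raises(ValueError):
            vh.value(T)


@given(dH=st.floats(-2e5, 2e5), dS=st.floats(-500, 500), T=st.floats(200, 400))
@settings(derandomize=True, max_examples=50)
def test_vant_hoff_always_positive_finite(dH, dS, T):
    v = VantHoffCoupling(dH, dS).value(T)
    assert math.isfinite(v) and v > 0


# ---------------------------------------------------------------------------
# four-state model


def test_open_probability_reduces_to_two_state_without_couplings():
    m = FourStateModel(L0=0.1, K_Ca=1e4)
    assert open_probability(m, 0.0) == pytest.approx(0.1 / 1.1, rel=1e-12)


def test_open_probability_at_one_millimolar(mthk_model):
    # four Boltzmann weights: 150 + 1.8 + 160 + 16 -> Po = 17.8/327.8
    assert open_probability(mthk_model, 1e-3) == pytest.approx(17.8 / 327.8, rel=1e-12)


def test_open_probability_saturating_limit(mthk_model):
    # x -> inf: Po -> L0*thBO/(thBC + L0*thBO) = 0.8/8.8
    assert open_probability(mthk_model, 1e3) == pytest.approx(0.8 / 8.8, rel=1e-4)


def test_open_probability_rejects_negative_calcium(mthk_model):
    with pytest.raises(ValueError):
        open_probability(mthk_model, -1e-3)


def test_chi_values_collapse_when_couplings_equal():
    m = FourStateModel(L0=0.25, K_Ca=1e4, theta_UC=3, theta_UO=3, theta_BC=3, theta_BO=3)
    chi = chi_values(m)
    assert chi.delta_chi == pytest.approx(0.0, abs=1e-12)
    assert chi.chi_minus == pytest.approx(math.log(0.25), rel=1e-12)
    assert chi.chi_plus == pytest.approx(math.log(0.25), rel=1e-12)


def test_chi_values_of_mthk_parameters(mthk_model):
    chi = chi_values(mthk_model)
    assert chi.chi_minus == pytest.approx(math.log(1.8 / 150), rel=1e-9)  # ~ -4.423
    assert chi.delta_chi == pytest.approx(math.log(1200 / 144), rel=1e-9)  # ~ 2.120


def test_normalize_identity_when_couplings_trivial():
    m = FourStateModel(L0=0.1, K_Ca=2e4)
    nm = normalize(m)
    assert (nm.L0_prime, nm.K_prime, nm.theta) == pytest.approx((0.1, 2e4, 1.0))


def test_normalize_mthk_parameters(mthk_model):
    nm = normalize(mthk_model)
    assert nm.L0_prime == pytest.approx(0.012, rel=1e-12)
    assert nm.K_prime == pytest.approx(1066.6667, rel=1e-6)
    assert nm.theta == pytest.approx(8.3333333, rel=1e-6)


def test_normalization_preserves_po_pointwise(rng):
    """Apparent-constant reduction is exact: max |Po_full - Po_normalized| < 1e-12."""
    x_grid = np.logspace(-8, -1, 40)
    worst = 0.0
    for _ in range(100):
        m = random_four_state(rng)
        nm = normalize(m)
        for x in x_grid:
            worst = max(worst, abs(open_probability(m, x) - nm.open_probability(x)))
    assert worst < 1e-12


def test_asymptote_convergence(rng):
    """ln(Po/(1-Po)) reaches chi- and chi+ at extreme calcium concentrations."""
    for _ in range(25):
        m = random_four_state(rng)
        nm = normalize(m)
        chi = chi_values(m)
        x_lo = 1e-8 / (nm.K_prime * max(nm.theta, 1.0))
        x_hi = 1e8 / (nm.K_prime * min(nm.theta, 1.0))
        for x, target in ((x_lo, chi.chi_minus), (x_hi, chi.chi_plus)):
            po = open_probability(m, x)
            assert abs(math.log(po / (1 - po)) - target) < 1e-6


def test_po_monotonic_iff_delta_chi_positive(rng):
    """dPo/dx has the sign of theta_BO*theta_UC - theta_UO*theta_BC."""
    x_grid = np.logspace(-7, -1, 30)
    for _ in range(50):
        m = random_four_state(rng)
        sign = np.sign(
            m.theta_BO * m.theta_UC - m.theta_UO * m.theta_BC  # type: ignore[operator]
        )
        po = np.array([open_probability(m, x) for x in x_grid])
        diffs = np.diff(po)
        if sign > 0:
            assert (diffs > 0).all()
        elif sign < 0:
            assert (diffs < 0).all()
        else:
            assert np.allclose(diffs, 0.0, atol=1e-15)


# ---------------------------------------------------------------------------
# thermosensor model


def test_sensor_chi_uncoupled_thermosensor():
    m = SensorModel(L0=0.05, D=50.0, C=1.0, E=0.7, M0=3.0)
    chi = sensor_chi(m)
    assert chi.chi_minus == pytest.approx(math.log(0.05), rel=1e-12)
    assert chi.delta_chi == pytest.approx(math.log(50.0), rel=1e-12)


def test_sensor_chi_resting_sensor():
    m = SensorModel(L0=0.05, D=50.0, C=4.0, E=0.5, M0=1e-300)
    chi = sensor_chi(m)
    assert chi.chi_minus == pytest.approx(math.log(0.05), rel=1e-9)
    assert chi.chi_plus == pytest.approx(math.log(0.05 * 50.0), rel=1e-9)


def test_sensor_chi_worked_example():
    m = SensorModel(L0=0.05, D=50.0, C=4.0, E=0.5, M0=2.0)
    chi = sensor_chi(m)
    assert chi.chi_minus == pytest.approx(math.log(0.15), rel=1e-9)   # ~ -1.897
    assert chi.chi_plus == pytest.approx(math.log(6.25), rel=1e-9)    # ~ 1.833
    assert chi.delta_chi == pytest.approx(3.7297, rel=1e-4)


def _fd_sensor_derivatives(m: SensorModel, T: float, h: float = 1e-3):
    lo, hi = sensor_chi(m, T - h), sensor_chi(m, T + h)
    return (
        (hi.chi_minus - lo.chi_minus) / (2 * h),
        (hi.chi_plus - lo.chi_plus) / (2 * h),
        (hi.delta_chi - lo.delta_chi) / (2 * h),
    )


def test_sensor_derivatives_vanish_when_pore_uncoupled():
    m = SensorModel(L0=0.05, D=50.0, C=1.0, E=0.5,
                    M0=VantHoffCoupling(1e5, 320.0))
    assert sensor_chi_derivatives(m, 300.0) == (0.0, 0.0, 0.0)


def test_sensor_derivatives_equal_when_site_uncoupled():
    m = SensorModel(L0=0.05, D=50.0, C=4.0, E=1.0,
                    M0=VantHoffCoupling(1e5, 320.0))
    d_minus, d_plus, d_delta = sensor_chi_derivatives(m, 300.0)
    assert d_delta == 0.0
    assert d_minus == pytest.approx(d_plus, rel=1e-12)
    assert d_minus != 0.0


def test_sensor_derivatives_match_finite_differences(rng):
    models = [
        SensorModel(L0=0.05, D=50.0, C=4.0, E=0.5, M0=VantHoffCoupling(1e5, 320.0))
    ]
    for _ in range(20):
        models.append(
            SensorModel(
                L0=float(np.exp(rng.uniform(-4, 1))),
                D=float(np.exp(rng.uniform(-2, 4))),
                C=float(np.exp(rng.uniform(-2, 2))),
                E=float(np.exp(rng.uniform(-2, 2))),
                M0=VantHoffCoupling(float(rng.uniform(-1e5, 1e5)), float(rng.uniform(-300, 300))),
            )
        )
    for m in models:
        analytic = sensor_chi_derivatives(m, 300.0)
        fd = _fd_sensor_derivatives(m, 300.0)
        for a, f in zip(analytic, fd):
            assert a == pytest.approx(f, rel=1e-6, abs=1e-12)


def test_sensor_derivatives_warn_for_constant_m0():
    m = SensorModel(L0=0.05, D=50.0, C=4.0, E=0.5, M0=2.0)
    with pytest.warns(UserWarning):
        assert sensor_chi_derivatives(m, 300.0) == (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# generalized N-site model


def _brute_force_partition(model: GeneralizedModel, x: float):
    """Independent enumeration with itertools, used as oracle."""
    n = model.n_sites
    th = {
        (0, 0): model.theta_UC, (0, 1): model.theta_UO,
        (1, 0): model.theta_BC, (1, 1): model.theta_BO,
    }
    z = {0: 0.0, 1: 0.0}
    for occ in itertools.product((0, 1), repeat=n):
        for pore in (0, 1):
            w = model.L0 if pore else 1.0
            for i, oi in enumerate(occ):
                if oi:
                    w *= model.K[i] * x
                w *= th[(oi, pore)][i]
            if model.alpha is not None:
                for i in range(n):
                    for j in range(i + 1, n):
                        w *= model.alpha[i, j, occ[i], occ[j]]
            z[pore] += w
    return z[0], z[1]


def _random_generalized(rng, n, with_alpha=True) -> GeneralizedModel:
    lo = lambda a, b, size=None: np.exp(rng.uniform(np.log(a), np.log(b), size))  # noqa: E731
    alpha = None
    if with_alpha:
        alpha = lo(0.2, 5.0, (n, n, 2, 2))
        alpha = np.sqrt(alpha * np.transpose(alpha, (1, 0, 3, 2)))  # symmetrize
    return GeneralizedModel(
        L0=float(lo(1e-3, 10)),
        K=lo(1e2, 1e6, n),
        theta_UC=lo(0.2, 5, n),
        theta_UO=lo(0.2, 5, n),
        theta_BC=lo(0.2, 5, n),
        theta_BO=lo(0.2, 5, n),
        alpha=alpha,
    )


def test_single_site_reduces_to_four_state(mthk_model):
    g = GeneralizedModel(
        L0=0.1, K=[20000.0], theta_UC=[150.0], theta_UO=[18.0],
        theta_BC=[8.0], theta_BO=[8.0],
    )
    for x in (0.0, 1e-4, 1e-3, 1e-2):
        _, _, po, chi = generalized_evaluate(g, x)
        assert po == pytest.approx(open_probability(mthk_model, x), rel=1e-12)
    chi4 = chi_values(mthk_model)
    _, _, _, chi = generalized_evaluate(g, 1e-3)
    assert chi.chi_minus == pytest.approx(chi4.chi_minus, rel=1e-12)
    assert chi.chi_plus == pytest.approx(chi4.chi_plus, rel=1e-12)


@pytest.mark.parametrize("n", [1, 2, 3, 4])
def test_generalized_matches_independent_enumeration(rng, n):
    for _ in range(10):
        g = _random_generalized(rng, n)
        x = float(np.exp(rng.uniform(np.log(1e-7), np.log(1e-2))))
        zc, zo, po, _ = generalized_evaluate(g, x)
        zc_ref, zo_ref = _brute_force_partition(g, x)
        assert zc > 0 and zo > 0
        assert zc == pytest.approx(zc_ref, rel=1e-10)
        assert zo == pytest.approx(zo_ref, rel=1e-10)
        assert po == pytest.approx(zo_ref / (zc_ref + zo_ref), rel=1e-10)


def test_delta_chi_independent_of_affinity_and_site_interactions(rng):
    """delta_chi depends only on the site-pore couplings."""
    base_theta = dict(theta_UC=[2.0, 0.5], theta_UO=[1.5, 3.0],
                      theta_BC=[0.8, 1.2], theta_BO=[4.0, 0.3])
    ref = None
    for _ in range(50):
        g = _random_generalized(rng, 2)
        g = GeneralizedModel(L0=g.L0, K=g.K, alpha=g.alpha, **base_theta)
        _, _, _, chi = generalized_evaluate(g, 1e-4)
        if ref is None:
            ref = chi.delta_chi
        assert chi.delta_chi == pytest.approx(ref, rel=1e-12)


def test_generalized_chi_formulas_match_numeric_limits(rng):
    """Closed-form chi-/chi+ equal ln(Z_O/Z_C) limits at extreme ligand."""
    for _ in range(10):
        g = _random_generalized(rng, 3)
        _, _, _, chi = generalized_evaluate(g, 1e-4)
        x_lo = 1e-12 * float(np.min(1.0 / np.asarray(g.K)))
        x_hi = 1e12 * float(np.max(1.0 / np.asarray(g.K)))
        for x, target in ((x_lo, chi.chi_minus), (x_hi, chi.chi_plus)):
            zc, zo, _, _ = generalized_evaluate(g, x)
            assert math.log(zo / zc) == pytest.approx(target, rel=1e-6, abs=1e-6)


def test_generalized_site_cap():
    n = 13
    with pytest.raises(ValueError, match="capped"):
        GeneralizedModel(
            L0=0.1, K=[1e4] * n, theta_UC=[1.0] * n, theta_UO=[1.0] * n,
            theta_BC=[1.0] * n, theta_BO=[1.0] * n,
        )


# ---------------------------------------------------------------------------
# Hill-plot simulation


def _delta_chi_from_table(df, T):
    sub = df[df.temperature_K == T].sort_values("calcium_M")
    return sub.hill_transform.iloc[-1] - sub.hill_transform.iloc[0]


def test_hill_plot_identical_rows_without_temperature_dependence(mthk_model):
    df = simulate_hill_plot(mthk_model, [294.15, 310.15], np.logspace(-5, -1, 9))
    lo = df[df.temperature_K == 294.15].reset_index(drop=True)
    hi = df[df.temperature_K == 310.15].reset_index(drop=True)
    assert np.allclose(lo.po, hi.po)


def test_hill_plot_temperature_dependent_affinity_leaves_delta_chi_invariant():
    m = FourStateModel(
        L0=0.1, K_Ca=VantHoffCoupling(-50000.0, -85.0),
        theta_UC=150.0, theta_UO=18.0, theta_BC=8.0, theta_BO=8.0,
    )
    x_grid = np.concatenate(([1e-14], np.logspace(-5, -1, 7), [1e8]))
    df = simulate_hill_plot(m, [294.15, 304.15, 310.15], x_grid)
    dchis = [_delta_chi_from_table(df, T) for T in (294.15, 304.15, 310.15)]
    assert max(dchis) - min(dchis) < 1e-10


def test_hill_plot_temperature_dependent_apo_coupling_moves_only_chi_minus():
    m = FourStateModel(
        L0=0.1, K_Ca=20000.0,
        theta_UC=VantHoffCoupling(-71000.0, -220.0),
        theta_UO=18.0, theta_BC=8.0, theta_BO=8.0,
    )
    x_grid = [1e-14, 1e6]
    df = simulate_hill_plot(m, [294.15, 310.15], x_grid)
    lo = df[df.temperature_K == 294.15].set_index("calcium_M").hill_transform
    hi = df[df.temperature_K == 310.15].set_index("calcium_M").hill_transform
    assert lo[1e6] == pytest.approx(hi[1e6], abs=1e-9)       # chi+ invariant
    assert abs(lo[1e-14] - hi[1e-14]) > 0.5                  # chi- moves


def test_hill_plot_supports_all_model_families(mthk_model):
    sensor = SensorModel(L0=0.05, D=50.0, C=4.0, E=0.5,
                         M0=VantHoffCoupling(1e5, 320.0))
    gen = GeneralizedModel(
        L0=0.1, K=[2e4, 2e4], theta_UC=[12.0, 12.5], theta_UO=[4.0, 4.5],
        theta_BC=[3.0, 2.5], theta_BO=[3.0, 3.2],
    )
    for model in (mthk_model, sensor, gen):
        df = simulate_hill_plot(model, [294.15], [1e-4, 1e-3])
        assert len(df) == 2
        assert ((df.po > 0) & (df.po < 1)).all()
        assert np.allclose(
            df.hill_transform, np.log(df.po / (1 - df.po))
        )
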