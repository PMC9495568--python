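"""Release-model fitting, mechanism calls, Damkohler and equilibrium point."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probead import kinetics as kin
from probead import synthetic as syn
from probead.kinetics import (
    InsufficientWindowError,
    MODEL_ORDER,
    ModelFit,
    ReleaseCurve,
)


def make_curve(t, f, **kw):
    return ReleaseCurve(np.asarray(t, float), np.asarray(f, float), **kw)


# ---------------------------------------------------------------------------
# r_squared


def test_r_squared_identity_mean_and_hand_case():
    obs = np.array([1.0, 2.0, 3.0])
    assert kin.r_squared(obs, obs) == 1.0
    assert kin.r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)
    # SSE = 1, SST = 2 -> 0.5
    assert kin.r_squared(obs, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)


def test_r_squared_zero_variance_rejected():
    with pytest.raises(ValueError):
        kin.r_squared([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])


# ---------------------------------------------------------------------------
# individual fits


def test_zero_order_exact_recovery(paper_timepoints):
    c = make_curve(paper_timepoints, 0.004 * paper_timepoints)
    fit = kin.fit_zero_order(c)
    assert fit.params["k"] == pytest.approx(0.004, rel=1e-12)
    assert fit.r2 == pytest.approx(1.0)


def test_zero_order_degenerate_constant_reports_poor_r2(paper_timepoints):
    f = np.where(paper_timepoints > 0, 0.5, 0.0)
    fit = kin.fit_zero_order(make_curve(paper_timepoints, f))
    assert fit.r2 <= 0.0  # honest: a line through the origin cannot track a constant


def test_zero_order_noisy_mean_unbiased(paper_timepoints):
    ks = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        f = np.clip(0.004 * paper_timepoints + rng.normal(0, 0.01, paper_timepoints.size), 0, 1.05)
        ks.append(kin.fit_zero_order(make_curve(paper_timepoints, f)).params["k"])
    assert abs(np.mean(ks) - 0.004) < 0.0005


def test_higuchi_exact_on_restricted_window(paper_timepoints):
    c = make_curve(paper_timepoints, 0.05 * np.sqrt(paper_timepoints))
    fit = kin.fit_higuchi(c)
    assert fit.params["k"] == pytest.approx(0.05, rel=1e-12)
    assert fit.r2 == pytest.approx(1.0)
    f_used = c.fraction_released[fit.window]
    assert np.all((f_used > 0.1) & (f_used < 0.6))


def test_higuchi_insufficient_window_is_explicit():
    t = np.array([1.0, 10.0, 50.0, 100.0])
    with pytest.raises(InsufficientWindowError, match="0.1"):
        kin.fit_higuchi(make_curve(t, np.array([0.7, 0.8, 0.9, 0.95])))


def test_higuchi_recovers_ps_diffusion_coefficient(paper_timepoints):
    # Peppas-Sahlin with k2 = 0 and m = 0.5 is exactly Higuchi
    truth = syn.KineticTruth("peppas_sahlin", {"k1": 0.04, "k2": 0.0, "m": 0.5}, noise_sd=0)
    fit = kin.fit_higuchi(syn.simulate_release_curve(truth))
    assert fit.params["k"] == pytest.approx(0.04, rel=1e-9)


def test_korsmeyer_peppas_exact_recovery(paper_timepoints):
    c = make_curve(paper_timepoints, 0.0757 * paper_timepoints**0.4060)
    for method in ("log_linear", "nonlinear"):
        fit = kin.fit_korsmeyer_peppas(c, method=method)
        assert fit.params["n"] == pytest.approx(0.4060, rel=1e-8)
        assert fit.params["k"] == pytest.approx(0.0757, rel=1e-8)
        assert fit.r2 == pytest.approx(1.0)


def test_korsmeyer_peppas_nests_zero_order(paper_timepoints):
    fit = kin.fit_korsmeyer_peppas(make_curve(paper_timepoints, 0.003 * paper_timepoints))
    assert fit.params["n"] == pytest.approx(1.0, abs=1e-9)


def test_korsmeyer_peppas_needs_three_usable_points():
    with pytest.raises(InsufficientWindowError):
        kin.fit_korsmeyer_peppas(make_curve([0.0, 1.0, 2.0], [0.0, 0.1, 0.2]))


def test_peppas_sahlin_exact_and_negative_coefficients(paper_timepoints):
    # positive pair
    truth = syn.KineticTruth("peppas_sahlin", {"k1": 0.01, "k2": 0.002, "m": 0.43}, noise_sd=0)
    fit = kin.fit_peppas_sahlin(syn.simulate_release_curve(truth), m=0.43)
    assert fit.params["k1"] == pytest.approx(0.01, rel=1e-9)
    assert fit.params["k2"] == pytest.approx(0.002, rel=1e-9)
    assert fit.r2 == pytest.approx(1.0)
    # diffusion-dominant sign pattern (k1 > 0 > k2): signs recovered exactly
    truth = syn.KineticTruth("peppas_sahlin", syn.DIFFUSION_DOMINANT_PAIR, noise_sd=0)
    fit = kin.fit_peppas_sahlin(syn.simulate_release_curve(truth), m=0.43)
    assert fit.params["k1"] > 0 > fit.params["k2"]


def test_peppas_sahlin_reduces_to_korsmeyer_peppas(paper_timepoints):
    c = make_curve(paper_timepoints, 0.05 * paper_timepoints**0.43)
    fit = kin.fit_peppas_sahlin(c, m=0.43)
    assert fit.params["k2"] == pytest.approx(0.0, abs=1e-10)
    assert fit.params["k1"] == pytest.approx(0.05, rel=1e-9)


def test_peppas_sahlin_free_m_roundtrip(paper_timepoints):
    truth = syn.KineticTruth("peppas_sahlin", {"k1": 0.01, "k2": 0.002, "m": 0.5}, noise_sd=0)
    fit = kin.fit_peppas_sahlin(syn.simulate_release_curve(truth), m="free")
    for name, val in truth.params.items():
        assert fit.params[name] == pytest.approx(val, rel=1e-6)


def test_peppas_sahlin_singular_design_rejected():
    # a single distinct positive time makes the two-term design rank 1
    t = np.full(5, 5.0)
    f = np.full(5, 0.2)
    with pytest.raises(np.linalg.LinAlgError, match="singular"):
        kin._ps_linear_solve(t, f, 0.43)
    # and too few positive timepoints is an explicit window error
    with pytest.raises(kin.InsufficientWindowError):
        kin.fit_peppas_sahlin(make_curve([0.0, 1.0, 2.0, 5.0], [0, 0.1, 0.15, 0.2]), m=0.43)


@pytest.mark.parametrize("model_id,params", [
    ("zero_order", {"k": 0.004}),
    ("higuchi", {"k": 0.05}),
    ("korsmeyer_peppas", {"k": 0.0757, "n": 0.4060}),
    ("peppas_sahlin", {"k1": 0.01, "k2": 0.002, "m": 0.43}),
])
def test_roundtrip_property(model_id, params):
    """Noiseless generate -> fit recovers parameters and attains R^2 = 1."""
    curve = syn.simulate_release_curve(syn.KineticTruth(model_id, params, noise_sd=0))
    fits = kin.fit_all_models(curve)
    fit = fits[model_id]
    for name, val in params.items():
        if val != 0:
            assert fit.params[name] == pytest.approx(val, rel=1e-6)
    assert fit.r2 > 1 - 1e-9


def test_nesting_kp_higuchi_same_window(paper_timepoints):
    c = make_curve(paper_timepoints, 0.05 * np.sqrt(paper_timepoints))
    hig = kin.fit_higuchi(c)
    lo, hi = int(hig.window[0]), int(hig.window[-1]) + 1
    kp = kin.fit_korsmeyer_peppas(c, window=(lo, hi))
    assert kp.params["n"] == pytest.approx(0.5, abs=1e-9)
    assert kp.params["k"] == pytest.approx(hig.params["k"], abs=1e-9)


# ---------------------------------------------------------------------------
# model selection


def test_select_model_prefers_highest_r2():
    fits = [
        ModelFit("zero_order", {"k": 1}, 0.50, np.arange(5), 5),
        ModelFit("higuchi", {"k": 1}, 0.61, np.arange(5), 5),
        ModelFit("peppas_sahlin", {"k1": 1, "k2": 0, "m": 0.43}, 0.89, np.arange(5), 5),
    ]
    assert kin.select_model(fits).r2 == 0.89


def test_select_model_tie_goes_to_fewer_parameters():
    fits = [
        ModelFit("peppas_sahlin", {"k1": 1, "k2": 0, "m": 0.43}, 0.95, np.arange(5), 5),
        ModelFit("higuchi", {"k": 1}, 0.95, np.arange(5), 5),
    ]
    assert kin.select_model(fits).model_id == "higuchi"


def test_select_model_empty_rejected():
    with pytest.raises(ValueError):
        kin.select_model([])


def test_selected_model_dominates_candidates_on_generating_data():
    truth = syn.KineticTruth("korsmeyer_peppas", {"k": 0.02, "n": 0.64}, noise_sd=0)
    fits = kin.fit_all_models(syn.simulate_release_curve(truth))
    best = kin.select_model(fits)
    assert best.r2 > 1 - 1e-9
    assert all(best.r2 >= f.r2 - kin.R2_TIE_TOL for f in fits.values())


# ---------------------------------------------------------------------------
# mechanism classification


@pytest.mark.parametrize("n,category", [
    (0.4060, "fickian"),       # a printed Fickian exponent
    (0.43, "fickian"),         # boundary belongs to the outer category
    (0.6389, "non_fickian"),
    (0.85, "case_II"),
    (1.0, "case_II"),
    (1.2, "super_case_II"),
    (-0.1, "fickian"),
])
def test_classify_kp_exponent(n, category):
    assert kin.classify_kp_exponent(n).category == category


@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=-5, max_value=5, allow_nan=False))
def test_classify_kp_exponent_total(n):
    """Every finite exponent maps to exactly one category."""
    call = kin.classify_kp_exponent(n)
    assert call.category in {"fickian", "non_fickian", "case_II", "super_case_II"}


def test_ps_contributions_single_term_and_sign_patterns():
    win = (1.0, 250.0)
    only_diff = ModelFit("peppas_sahlin", {"k1": 0.01, "k2": 0.0, "m": 0.43}, 1.0, np.arange(5), 5)
    assert kin.ps_contributions(only_diff, win).category == "mainly_diffusion"
    relax = ModelFit("peppas_sahlin", syn.RELAXATION_DOMINANT_PAIR, 1.0, np.arange(5), 5)
    assert kin.ps_contributions(relax, win).category == "mainly_relaxation"
    diff = ModelFit("peppas_sahlin", syn.DIFFUSION_DOMINANT_PAIR, 1.0, np.arange(5), 5)
    assert kin.ps_contributions(diff, win).category == "mainly_diffusion"
    with pytest.raises(ValueError):
        kin.ps_contributions(
            ModelFit("peppas_sahlin", {"k1": 0.0, "k2": 0.0, "m": 0.43}, 1.0, np.arange(5), 5), win
        )


# ---------------------------------------------------------------------------
# rates, Damkohler, equilibrium


def test_estimate_rates_matched_exponentials():
    t = np.linspace(0.0, 100.0, 21)
    growth = kin.GrowthCurve(t, np.exp(0.01 * t), time_unit="min")
    release = make_curve(t, 1.0 - np.exp(-0.01 * t))
    g, r = kin.estimate_rates(growth, release, (0.0, 100.0))
    assert g == pytest.approx(0.01, rel=1e-9)
    assert r == pytest.approx(0.01, rel=1e-9)
    assert kin.damkohler(g, r).da == pytest.approx(1.0)


def test_estimate_rates_flat_growth_gives_da_zero():
    t = np.linspace(0.0, 100.0, 11)
    growth = kin.GrowthCurve(t, np.full(t.size, 2.0), time_unit="min")
    release = make_curve(t, 1.0 - np.exp(-0.01 * t))
    g, r = kin.estimate_rates(growth, release, (0.0, 100.0))
    assert g == pytest.approx(0.0, abs=1e-12)
    assert kin.damkohler(g, r).da == pytest.approx(0.0, abs=1e-9)


def test_constructed_da_ratio():
    t = np.linspace(0.0, 120.0, 25)
    growth = kin.GrowthCurve(t, 5.0 * np.exp(0.012 * t), time_unit="min")
    release = make_curve(t, 1.0 - np.exp(-0.010 * t))
    g, r = kin.estimate_rates(growth, release, (0.0, 120.0))
    res = kin.damkohler(g, r)
    assert res.da == pytest.approx(1.2, abs=1e-6)
    assert res.regime == "reaction_governed"


def test_damkohler_regimes_and_errors():
    assert kin.damkohler(0.01, 0.01).regime == "boundary"
    assert kin.damkohler(0.008, 0.010).regime == "transport_governed"
    with pytest.raises(ValueError):
        kin.damkohler(0.01, 0.0)


@settings(max_examples=100, deadline=None)
@given(
    st.floats(min_value=1e-6, max_value=1e3),
    st.floats(min_value=1e-6, max_value=1e3),
    st.floats(min_value=1e-6, max_value=1e6),
)
def test_damkohler_scale_invariance(g, r, a):
    assert kin.damkohler(a * g, a * r).da == pytest.approx(kin.damkohler(g, r).da, rel=1e-12)


def test_equilibrium_symmetric_crossing():
    t = np.array([0.0, 100.0])
    assert kin.find_equilibrium_time([0.0, 100.0], [100.0, 0.0], t) == pytest.approx(50.0)


def test_equilibrium_none_when_no_intersection():
    t = np.arange(5, dtype=float)
    assert kin.find_equilibrium_time([1, 2, 3, 4, 5], [10, 11, 12, 13, 14], t) is None


def test_equilibrium_exact_sample_equality():
    t = np.array([0.0, 10.0, 20.0])
    assert kin.find_equilibrium_time([0.0, 5.0, 9.0], [8.0, 5.0, 1.0], t) == 10.0


def test_equilibrium_length_mismatch():
    with pytest.raises(ValueError):
        kin.find_equilibrium_time([1.0, 2.0], [1.0], [0.0, 1.0])


def test_equilibrium_invariant_under_common_rescaling():
    rng = np.random.default_rng(1)
    t = np.sort(rng.uniform(0, 250, 12))
    med = np.cumsum(rng.uniform(0, 10, 12))
    inb = med[::-1].copy()
    base = kin.find_equilibrium_time(med, inb, t)
    scaled = kin.find_equilibrium_time(1e6 * med, 1e6 * inb, t)
    assert scaled == pytest.approx(base, rel=1e-12)
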