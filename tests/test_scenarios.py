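"""Dose-response scans, the goodness metric, knockout/compensation,
linear fits, and the wild-type discrepancy report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spornet as sn


# -- goodness-of-agreement metric ---------------------------------------

def test_goodness_identity_is_zero():
    assert sn.goodness_of_agreement([3.0, 5.0, 7.0], [3.0, 5.0, 7.0]) == 0.0


def test_goodness_hand_value():
    assert sn.goodness_of_agreement([1.0, 2.0], [1.1, 1.8]) == pytest.approx(0.10)


def test_goodness_single_point_total_miss():
    assert sn.goodness_of_agreement([2.0], [0.0]) == pytest.approx(1.0)


def test_goodness_rejects_nonpositive_observed():
    with pytest.raises(ValueError):
        sn.goodness_of_agreement([1.0, 0.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        sn.goodness_of_agreement([1.0], [1.0, 2.0])


@given(
    st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=1, max_size=30),
    st.floats(min_value=0.1, max_value=10.0),
)
@settings(max_examples=50, deadline=None)
def test_goodness_scale_invariance(obs, c):
    """Rescaling both series leaves the relative metric unchanged."""
    o = np.array(obs)
    m = o * 1.07
    assert sn.goodness_of_agreement(c * o, c * m) == pytest.approx(
        sn.goodness_of_agreement(o, m), rel=1e-9
    )


# -- dose response -------------------------------------------------------

def test_single_point_grid_equals_steady_state(model, basal):
    dr = sn.dose_response(model, "IPTG", [10.0])
    st_ = sn.steady_state(model, iptg=10.0, guess=basal.as_array())
    assert np.allclose(dr.states.iloc[0].to_numpy(), st_.as_array(), rtol=1e-8)


def test_iptg_dose_response_monotonicity(ref_dose):
    """KinA2~P, Spo0F~P and Spo0A~P rise with induction; Spo0B~P does not
    rise monotonically."""
    for f in ("KinA2P", "Spo0FP", "Spo0AP"):
        assert np.all(np.diff(ref_dose.series(f)) >= -1e-9), f
    bp = ref_dose.series("Spo0BP")
    assert np.any(np.diff(bp) < 0) and np.any(np.diff(bp) > 0)


def test_ss_dose_response_increases(model):
    dr = sn.dose_response(model, "SS", np.linspace(0.0, 2.0, 11))
    for f in ("KinA2P", "Spo0FP", "Spo0AP"):
        assert np.all(np.diff(dr.series(f)) >= -1e-9), f
    # totals never fall below their phospho component
    assert np.all(dr.series("total_Spo0A") >= dr.series("Spo0AP") - 1e-9)


def test_warm_start_matches_cold_start(model, ref_dose):
    """Warm-starting the scan does not bias the solutions (no hysteresis)."""
    sub = [0.0, 6.0, 12.0, 20.0]
    warm = ref_dose.states.iloc[[0, 6, 12, 20]].to_numpy()
    cold = sn.dose_response(model, "IPTG", sub, warm_start=False).states.to_numpy()
    rel = np.abs(warm - cold) / np.maximum(np.abs(warm), 1e-9)
    assert rel.max() < 1e-4


def test_grid_must_increase(model):
    with pytest.raises(ValueError):
        sn.dose_response(model, "IPTG", [0.0, 2.0, 1.0])


# -- steady-state panel --------------------------------------------------

def test_panel_basal_effectors_nonzero(model):
    tables = sn.steady_state_panel(model)
    assert (tables["effectors"][0.0] > 0).all()   # weak basal activation
    assert (tables["phospho"][0.0] > 0).all()


def test_panel_effector_saturation_order(model):
    """Early effectors (AA..IIE) saturate by IPTG=10; GA/GB keep growing."""
    tables = sn.steady_state_panel(model)
    eff = tables["effectors"]
    assert (eff[10.0] >= eff[0.0]).all()
    early = (eff.loc[["AA", "AB", "AC", "IIE"], 20.0]
             / eff.loc[["AA", "AB", "AC", "IIE"], 10.0])
    late = eff.loc[["GA", "GB"], 20.0] / eff.loc[["GA", "GB"], 10.0]
    assert early.max() < late.min()


# -- feedback knockout and compensation ---------------------------------

def test_knockout_reduces_kina_activation(model, ref_dose):
    ko = sn.feedback_knockout(model)
    assert ko.params["tr2.k3"] == 0.0
    dr = sn.dose_response(ko, "IPTG")
    assert np.all(dr.series("KinA2P") <= ref_dose.series("KinA2P") + 1e-9)
    # qualitatively similar: still a rising, sigmoidal response
    k2p = dr.series("KinA2P")
    assert np.all(np.diff(k2p) >= -1e-9)
    assert k2p[-1] / k2p[0] > 5.0


def test_knockout_idempotent(model):
    once = sn.feedback_knockout(model)
    twice = sn.feedback_knockout(once)
    assert once.params.values == twice.params.values


def test_self_fit_recovers_nominal(model, ref_dose):
    """Refitting the intact model against itself returns (k2, KL)."""
    fit = sn.compensate_repression_params(ref_dose, model)
    assert fit.distance < 1e-3
    assert fit.k2 == pytest.approx(model.params["tr2.k2"], rel=0.05)
    assert fit.KL == pytest.approx(model.params["tr2.KL"], rel=0.05)


# -- linear fits ---------------------------------------------------------

def test_linear_fit_collinear():
    t = np.arange(10.0)
    fit = sn.linear_fit(t, 3.0 + 0.5 * t)
    assert fit.slope == pytest.approx(0.5)
    assert fit.intercept == pytest.approx(3.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_linear_fit_pure_noise_r2_near_zero():
    rng = np.random.default_rng(42)
    t = np.linspace(0, 100, 100)
    fit = sn.linear_fit(t, 5.0 + rng.standard_normal(100))
    assert fit.r_squared < 0.05
    assert abs(fit.slope) < 3 * fit.slope_se


def test_linear_fit_zero_variance_flagged():
    fit = sn.linear_fit(np.arange(5.0), np.full(5, 2.0))
    assert fit.flag is not None and np.isnan(fit.r_squared)


def test_linear_fit_needs_three_points():
    with pytest.raises(ValueError):
        sn.linear_fit([0.0, 1.0], [0.0, 1.0])


# -- wild-type discrepancy ----------------------------------------------

@pytest.fixture(scope="module")
def wt_report(model):
    return sn.wildtype_discrepancy_report(
        model, iptg_grid=np.linspace(0, 20, 6), ss_grid=np.linspace(0, 2, 6)
    )


def test_wildtype_model_far_below_benchmark(wt_report):
    """The model's Spo0A ceiling sits ~an order below the wild-type data."""
    assert wt_report.max_total_spo0a_uM <= 4.5
    assert wt_report.ratio >= 8.0


def test_wildtype_corner_below_max(wt_report):
    tab = wt_report.table
    corner = tab[(tab.iptg == 0.0) & (tab.ss == 0.0)]["total_Spo0A"].iloc[0]
    assert corner <= wt_report.max_total_spo0a_internal


def test_scenarios_deterministic(model):
    a = sn.dose_response(model, "IPTG", [0.0, 10.0]).states.to_numpy()
    b = sn.dose_response(model, "IPTG", [0.0, 10.0]).states.to_numpy()
    assert np.array_equal(a, b)
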