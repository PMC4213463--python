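"""Transient integration and steady-state solution."""

import numpy as np
import pytest

import spornet as sn
from spornet.params import BOUNDARY_FORMS, FORMS

IDX = {f: i for i, f in enumerate(FORMS)}

ALL_RATES_OFF = {
    **{k: 0.0 for k in sn.ParameterSet().values
       if k.endswith((".k", ".k1", ".k2", ".k3")) and not k.startswith("deg.")},
    "d_mRNA": 0.0, "d_prot": 0.0,
    **{f"deg.{f}.k": 0.0 for f in FORMS if f not in BOUNDARY_FORMS},
}


def test_zero_network_is_constant(model):
    m = model.with_overrides(ALL_RATES_OFF)
    init = sn.FormState(KinA=7.0, Spo0AP=3.0)
    traj = sn.simulate(m, init, iptg=5.0, ss=1.0, duration=1e4, n_points=11)
    assert np.allclose(traj.y, traj.y[0][None, :], rtol=0, atol=1e-12)
    assert traj.y[-1][IDX["KinA"]] == pytest.approx(7.0)


def test_constitutive_transcription_accumulates_linearly(model):
    """With only tr1 active and no turnover, lacI_t(t) = k * t exactly."""
    m = model.with_overrides({**ALL_RATES_OFF, "tr1.k": 0.1})
    traj = sn.simulate(m, None, iptg=0.0, ss=0.0, duration=1000.0, n_points=11)
    assert np.allclose(traj.series("lacI_t"), 0.1 * traj.t, rtol=1e-8)


def test_clamps_held_fixed(model, basal):
    traj = sn.simulate(model, basal, iptg=3.0, ss=0.5, duration=1e4, n_points=21)
    scale = model.params["stimulus_scale"]
    assert np.all(traj.series("IPTG") == 3.0 * scale)
    assert np.all(traj.series("SS") == 0.5 * scale)


@pytest.mark.parametrize("iptg", [0.0, 5.0, 10.0, 20.0])
def test_long_integration_agrees_with_root_solve(model, basal, iptg):
    """Long-time simulate and steady_state agree to 0.1% on every form."""
    st = sn.steady_state(model, iptg=iptg, guess=basal.as_array())
    traj = sn.simulate(model, basal, iptg, model.params["SS_in"], 2e6, n_points=3)
    final = traj.y[-1]
    target = st.as_array()
    scale = np.maximum(np.abs(target), 1e-6)
    assert np.max(np.abs(final - target) / scale) < 1e-3


def test_steady_state_postcondition(model, basal):
    st = sn.steady_state(model, iptg=10.0, guess=basal.as_array())
    resid = np.max(np.abs(sn.time_derivatives(model, st.state)))
    assert resid <= 1e-9
    assert st.residual <= 1e-9
    assert min(st.state.values()) >= 0.0


def test_zero_synthesis_steady_state_is_zero(model):
    m = model.with_overrides({"tr1.k": 0.0, "tr2.k1": 0.0, "tr2.k2": 0.0,
                              "tr3.k1": 0.0, "tr3.k2": 0.0, "tr4.k": 0.0,
                              "tr5.k1": 0.0, "tr5.k2": 0.0, "tr6.k1": 0.0,
                              "tr6.k2": 0.0, "tr7.k1": 0.0, "tr7.k2": 0.0,
                              "tr8.k1": 0.0, "tr8.k2": 0.0})
    st = sn.steady_state(m, iptg=0.0, guess=np.zeros(len(FORMS)))
    free = [i for i, f in enumerate(FORMS) if f not in BOUNDARY_FORMS]
    assert np.allclose(st.as_array()[free], 0.0, atol=1e-9)


def test_induced_state_has_more_spo0ap(model, basal):
    hi = sn.steady_state(model, iptg=20.0, guess=basal.as_array())
    assert hi["Spo0AP"] > basal["Spo0AP"]


def test_pre_equilibrate_basal_activation(model, basal):
    """Nonzero SS clamp sustains a small basal phosphorelay activation."""
    assert basal["Spo0AP"] > 0.0
    assert basal["KinA2P"] > 0.0


def test_pre_equilibrate_without_signal_has_no_phosphorylation(model):
    quiet = sn.steady_state(model, iptg=0.0, ss=0.0)
    assert quiet["KinA2P"] == pytest.approx(0.0, abs=1e-9)
    assert quiet["Spo0AP"] == pytest.approx(0.0, abs=1e-9)


def test_pre_equilibrate_idempotent(model, basal):
    again = sn.steady_state(model, iptg=0.0, guess=basal.as_array())
    rel = np.abs(again.as_array() - basal.as_array()) / np.maximum(basal.as_array(), 1e-9)
    assert np.max(rel) < 1e-6


def test_trajectory_invariant_under_tolerance_halving(model, basal):
    kw = dict(iptg=8.0, ss=model.params["SS_in"], duration=5e4, n_points=21)
    a = sn.simulate(model, basal, rtol=1e-8, **kw)
    b = sn.simulate(model, basal, rtol=5e-9, **kw)
    scale = np.maximum(np.abs(a.y), 1e-3)
    assert np.max(np.abs(a.y - b.y) / scale) < 1e-6


def test_nonnegativity_of_reported_points(model):
    """Starting far from equilibrium, no form is reported below zero."""
    spike = sn.FormState(KinA=1e4, Spo0FP=1e3, LacI=5.0)
    traj = sn.simulate(model, spike, iptg=0.0, ss=0.1, duration=1e5, n_points=101)
    assert traj.y.min() >= 0.0


def test_duration_must_be_positive(model, basal):
    with pytest.raises(ValueError):
        sn.simulate(model, basal, 0.0, 0.1, duration=0.0)


def test_trajectory_tidy_export(tmp_path, model, basal):
    traj = sn.simulate(model, basal, 0.0, model.params["SS_in"], 100.0, n_points=5)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert list(df.columns) == ["time", "form", "concentration"]
    assert len(df) == 5 * 27
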