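"""Structure and rate laws of the reference network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spornet as sn
from spornet.params import BOUNDARY_FORMS, FORMS, ParameterError
from table1_oracle import TABLE1_RATES, oracle_params

IDX = {f: i for i, f in enumerate(FORMS)}


def test_inventory_counts(model):
    assert len(model.forms) == 27
    assert len(model.reactions) == 55
    by_kind = {}
    for r in model.reactions:
        by_kind[r.rate_law.kind] = by_kind.get(r.rate_law.kind, 0) + 1
    # 29 published reactions + Spo0B~P dephosphorylation + 25 degradations
    assert sum(1 for r in model.reactions if r.id.startswith("deg.")) == 25
    assert {r.id for r in model.reactions} >= {"tr2", "k5", "k8", "kBdeph"}


def test_modifier_wiring(model):
    assert model.reaction("k5").modifiers == ("SS",)
    assert model.reaction("k1").modifiers == ("IPTG",)
    assert "IPTG" not in model.reaction("k1").consumed  # inducer is not depleted
    assert set(model.reaction("tr2").modifiers) == {"LacI", "Spo0AP"}
    assert model.reaction("k3").consumed == {"KinA": 2}
    assert model.reaction("k4").produced == {"KinA": 2}


@pytest.mark.parametrize(
    "rid,state,expected",
    [
        ("tr2", {}, 0.2675),                    # zero repressor, zero feedback
        ("tr3", {"Spo0AP": 50.0}, 0.07),        # feedback at half saturation
        ("tr5", {}, 0.01388),                   # basal term only
        ("k5", {"SS": 3.0}, 0.0),               # no dimer, no flux
    ],
)
def test_rate_law_hand_values(model, rid, state, expected):
    flux = sn.evaluate_rate(model.reaction(rid), sn.FormState(state), model.params)
    assert flux == pytest.approx(expected, rel=1e-12)


def test_zero_state_derivatives(model):
    d = sn.time_derivatives(model, sn.FormState())
    assert d[IDX["lacI_t"]] == pytest.approx(0.1, rel=1e-12)
    assert d[IDX["kinA_t"]] == pytest.approx(0.2675, rel=1e-12)
    assert d[IDX["Spo0FP"]] == 0.0
    assert d[IDX["IPTG"]] == 0.0 and d[IDX["SS"]] == 0.0


def test_rate_laws_match_brute_force_oracle(model, random_states):
    """Every compiled rate law equals the direct formula transcription."""
    flat = oracle_params(model.params)
    for y in random_states[:100]:
        state = dict(zip(FORMS, y))
        fs = sn.FormState(state)
        for rxn in model.reactions:
            expected = TABLE1_RATES[rxn.id](state, flat)
            got = sn.evaluate_rate(rxn, fs, model.params)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-300), rxn.id
            assert got >= 0.0


def test_derivatives_match_oracle_sum(model, random_states):
    """time_derivatives equals stoichiometry x brute-force fluxes."""
    flat = oracle_params(model.params)
    for y in random_states[:20]:
        state = dict(zip(FORMS, y))
        expected = np.zeros(len(FORMS))
        for rxn in model.reactions:
            flux = TABLE1_RATES[rxn.id](state, flat)
            for form, net in rxn.stoichiometry().items():
                expected[IDX[form]] += net * flux
        for b in BOUNDARY_FORMS:
            expected[IDX[b]] = 0.0
        got = sn.time_derivatives(model, sn.FormState(state))
        assert np.allclose(got, expected, rtol=1e-9, atol=1e-12)


TURNOVER_OFF = {
    **{k: 0.0 for k in ("tr1.k", "tr4.k", "tr2.k1", "tr2.k2", "tr3.k1", "tr3.k2",
                         "tr5.k1", "tr5.k2", "tr6.k1", "tr6.k2", "tr7.k1", "tr7.k2",
                         "tr8.k1", "tr8.k2")},
    **{f"tl{s}.k": 0.0 for s in ("1", "2", "3", "4", "5", "6A", "6B", "6C", "7", "8A", "8B")},
    "d_mRNA": 0.0, "d_prot": 0.0,
    **{f"deg.{f}.k": 0.0 for f in FORMS if f not in BOUNDARY_FORMS},
}


def test_phosphoryl_conservation(model, random_states):
    """With synthesis, translation and degradation off, each protein's
    phospho+free total (and KinA monomer equivalents) is exactly conserved."""
    m = model.with_overrides(TURNOVER_OFF)
    totals = {
        "Spo0F": ("Spo0F", "Spo0FP"),
        "Spo0B": ("Spo0B", "Spo0BP"),
        "Spo0A": ("Spo0A", "Spo0AP"),
    }
    for y in random_states[:25]:
        d = sn.time_derivatives(m, sn.FormState(dict(zip(FORMS, y))))
        for name, (free, phos) in totals.items():
            assert d[IDX[free]] + d[IDX[phos]] == pytest.approx(0.0, abs=1e-9), name
        kina = d[IDX["KinA"]] + 2 * d[IDX["KinA2"]] + 2 * d[IDX["KinA2P"]]
        assert kina == pytest.approx(0.0, abs=1e-9)


def test_knockout_leaves_structure(model):
    ko = model.with_overrides({"tr2.k3": 0.0})
    assert len(ko.reactions) == 55
    assert [r.id for r in ko.reactions] == [r.id for r in model.reactions]
    # the feedback term now evaluates to zero: Spo0AP no longer enters tr2
    lo = sn.evaluate_rate(ko.reaction("tr2"), sn.FormState(), ko.params)
    hi = sn.evaluate_rate(ko.reaction("tr2"), sn.FormState(Spo0AP=1e6), ko.params)
    assert lo == pytest.approx(hi, rel=1e-12) == pytest.approx(0.2675, rel=1e-12)


def test_parameter_validation_names_offender():
    with pytest.raises(ParameterError, match="tr2.KL"):
        sn.build_reference_network(sn.ParameterSet({"tr2.KL": 0.0}))
    with pytest.raises(ParameterError, match="k5.k"):
        sn.ParameterSet({"k5.k": -1.0})


def test_config_round_trip(tmp_path, model):
    cfg = tmp_path / "overrides.cfg"
    cfg.write_text("tr2.k3 = 0  # feedback off\n\nd_prot=2e-3\n")
    p = sn.ParameterSet.from_config(cfg)
    assert p["tr2.k3"] == 0.0
    assert p["d_prot"] == 2e-3
    with pytest.raises(ParameterError, match="line 1"):
        sn.parse_config("tr2.k3: 0")


@given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
@settings(max_examples=25, deadline=None)
def test_tr2_flux_nonnegative_and_bounded(lacI):
    """The KinA transcription law stays within its algebraic envelope."""
    m = sn.build_reference_network()
    f = sn.evaluate_rate(m.reaction("tr2"), sn.FormState(LacI=lacI), m.params)
    assert 0.0 < 0.0275 * (1 - 1e-12) <= f <= 0.2675 * (1 + 1e-12)


def test_negative_state_rejected(model):
    with pytest.raises(ValueError):
        sn.FormState(KinA=-1.0)
    y = np.zeros(len(FORMS)); y[IDX["KinA"]] = -0.5
    with pytest.raises(ValueError):
        sn.time_derivatives(model, y)
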