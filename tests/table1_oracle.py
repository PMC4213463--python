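"""Independent brute-force evaluator of the published rate-law formulas.

Each entry is a direct transcription of the "Mathematical form" column of
the model's reaction table into a plain Python lambda over a state dict and
a parameter mapping.  Deliberately kept free of any spornet machinery so it
can serve as an oracle for the compiled rate laws.
"""


def _deg(form):
    return lambda s, p: p[f"deg.{form}.k"] * s[form]


TABLE1_RATES = {
    "tr1": lambda s, p: p["tr1.k"],
    "tl1": lambda s, p: p["tl1.k"] * s["lacI_t"],
    "k1": lambda s, p: p["k1.k"] * s["LacI"] * s["IPTG"],
    "k2": lambda s, p: p["k2.k"] * s["LacI_d"],
    "tr2": lambda s, p: (
        p["tr2.k1"]
        + p["tr2.k2"] * p["tr2.KL"] ** 2 / (p["tr2.KL"] ** 2 + s["LacI"] ** 2)
    ) * (
        1.0
        + p["tr2.k3"] * s["Spo0AP"] ** 2 / (p["tr2.KS"] ** 2 + s["Spo0AP"] ** 2)
    ),
    "tl2": lambda s, p: p["tl2.k"] * s["kinA_t"],
    "k3": lambda s, p: p["k3.k"] * s["KinA"] ** 2,
    "k4": lambda s, p: p["k4.k"] * s["KinA2"],
    "k5": lambda s, p: p["k5.k"] * s["KinA2"] * s["SS"],
    "tr3": lambda s, p: p["tr3.k1"]
    + p["tr3.k2"] * s["Spo0AP"] ** 2 / (p["tr3.KS"] ** 2 + s["Spo0AP"] ** 2),
    "tl3": lambda s, p: p["tl3.k"] * s["spo0F_t"],
    "k6": lambda s, p: p["k6.k"] * s["Spo0F"] * s["KinA2P"],
    "k7": lambda s, p: p["k7.k"] * s["Spo0FP"],
    "tr4": lambda s, p: p["tr4.k"],
    "tl4": lambda s, p: p["tl4.k"] * s["spo0B_t"],
    "k8": lambda s, p: p["k8.k"] * s["Spo0B"] * s["Spo0FP"],
    "tr5": lambda s, p: p["tr5.k1"] * p["tr5.Kk1"] / (p["tr5.Kk1"] + s["Spo0AP"])
    + p["tr5.k2"] * s["Spo0AP"] ** 2 / (p["tr5.Kk2"] ** 2 + s["Spo0AP"] ** 2),
    "tl5": lambda s, p: p["tl5.k"] * s["spo0A_t"],
    "k9": lambda s, p: p["k9.k"] * s["Spo0A"] * s["Spo0BP"],
    "k10": lambda s, p: p["k10.k"] * s["Spo0AP"],
    "kBdeph": lambda s, p: p["kBdeph.k"] * s["Spo0BP"],
    "tr6": lambda s, p: p["tr6.k1"]
    + p["tr6.k2"] * s["Spo0AP"] ** 4 / (p["tr6.Kk"] ** 4 + s["Spo0AP"] ** 4),
    "tl6A": lambda s, p: p["tl6A.k"] * s["spoIIA_t"],
    "tl6B": lambda s, p: p["tl6B.k"] * s["spoIIA_t"],
    "tl6C": lambda s, p: p["tl6C.k"] * s["spoIIA_t"],
    "tr7": lambda s, p: p["tr7.k1"]
    + p["tr7.k2"] * s["Spo0AP"] ** 4 / (p["tr7.Kk"] ** 4 + s["Spo0AP"] ** 4),
    "tl7": lambda s, p: p["tl7.k"] * s["spoIIE_t"],
    "tr8": lambda s, p: p["tr8.k1"]
    + p["tr8.k2"] * s["Spo0AP"] ** 4 / (p["tr8.Kk"] ** 4 + s["Spo0AP"] ** 4),
    "tl8A": lambda s, p: p["tl8A.k"] * s["spoIIG_t"],
    "tl8B": lambda s, p: p["tl8B.k"] * s["spoIIG_t"],
}


def oracle_params(params):
    """Flat mapping with every degradation rate resolved, for the lambdas."""
    from spornet.params import BOUNDARY_FORMS, FORMS

    flat = dict(params.values)
    for form in FORMS:
        if form not in BOUNDARY_FORMS:
            flat[f"deg.{form}.k"] = params.degradation_rate(form)
            TABLE1_RATES.setdefault(f"deg.{form}", _deg(form))
    return flat
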