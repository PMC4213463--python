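"""Reaction network of sporulation initiation and its ODE compilation.

The network couples an IPTG/LacI induction module, sporulation-signal (SS)
driven KinA dimer autophosphorylation, the Spo0F -> Spo0B -> Spo0A
phosphorelay with Spo0A~P transcriptional feedback, and the spoIIA/E/G
effector operons.  13 species give rise to 27 molecular forms and, with one
first-order degradation per non-clamped form plus free Spo0B~P
dephosphorylation, 55 unidirectional reactions.

Rate laws are held as sympy expressions over species and parameter symbols;
a model compiles once into a lambdified right-hand side and Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

from .params import (
    BOUNDARY_FORMS,
    FORMS,
    N_FB,
    N_REP,
    N_SPOII,
    ParameterSet,
    TRANSCRIPTS,
)

__all__ = [
    "FormState", "RateLaw", "Reaction", "NetworkModel",
    "build_reference_network", "evaluate_rate", "time_derivatives",
]

_SPECIES_SYMBOLS: dict[str, sp.Symbol] = {f: sp.Symbol(f, nonnegative=True) for f in FORMS}


def param_symbol(key: str) -> sp.Symbol:
    """Sympy symbol for a parameter key ('tr2.k1' -> p_tr2_k1)."""
    return sp.Symbol("p_" + key.replace(".", "_"), positive=False)


class FormState(dict):
    """Named nonnegative concentrations of the 27 molecular forms."""

    def __init__(self, data: Mapping[str, float] | None = None, **kw):
        base = dict.fromkeys(FORMS, 0.0)
        base.update(data or {})
        base.update(kw)
        unknown = set(base) - set(FORMS)
        if unknown:
            raise KeyError(f"unknown forms: {sorted(unknown)}")
        negative = [f for f, v in base.items() if v < 0]
        if negative:
            raise ValueError(f"negative concentrations for {negative}")
        super().__init__({f: float(base[f]) for f in FORMS})

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FormState":
        return cls(dict(zip(FORMS, np.asarray(y, dtype=float))))

    def as_array(self) -> np.ndarray:
        return np.array([self[f] for f in FORMS], dtype=float)


@dataclass(frozen=True)
class RateLaw:
    """A flux law: sympy expression over species and parameter symbols."""

    kind: str                       # constant | mass_action | kinA_transcription |
                                    # hill_activation_basal | spo0A_transcription |
                                    # spoII_transcription
    expr: sp.Expr
    param_keys: tuple[str, ...]
    modifiers: tuple[str, ...] = ()


@dataclass(frozen=True)
class Reaction:
    id: str
    consumed: dict[str, int] = field(default_factory=dict)
    produced: dict[str, int] = field(default_factory=dict)
    modifiers: tuple[str, ...] = ()
    rate_law: RateLaw = None  # type: ignore[assignment]

    def stoichiometry(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for f, n in self.consumed.items():
            net[f] = net.get(f, 0) - n
        for f, n in self.produced.items():
            net[f] = net.get(f, 0) + n
        return net


def _S(form: str) -> sp.Symbol:
    return _SPECIES_SYMBOLS[form]


def _constant(rid: str) -> RateLaw:
    key = f"{rid}.k"
    return RateLaw("constant", param_symbol(key), (key,))


def _mass_action(rid: str, *forms: str, key: str | None = None) -> RateLaw:
    key = key or f"{rid}.k"
    expr = param_symbol(key)
    for f in forms:
        expr = expr * _S(f)
    return RateLaw("mass_action", expr, (key,), tuple(forms))


def _tr2_law() -> RateLaw:
    k1, k2, k3 = (param_symbol(f"tr2.{s}") for s in ("k1", "k2", "k3"))
    KL, KS = param_symbol("tr2.KL"), param_symbol("tr2.KS")
    L, A = _S("LacI"), _S("Spo0AP")
    expr = (k1 + k2 * KL**N_REP / (KL**N_REP + L**N_REP)) * (
        1 + k3 * A**N_FB / (KS**N_FB + A**N_FB)
    )
    return RateLaw(
        "kinA_transcription", expr,
        ("tr2.k1", "tr2.k2", "tr2.k3", "tr2.KL", "tr2.KS"),
        ("LacI", "Spo0AP"),
    )


def _tr3_law() -> RateLaw:
    k1, k2, KS = (param_symbol(f"tr3.{s}") for s in ("k1", "k2", "KS"))
    A = _S("Spo0AP")
    expr = k1 + k2 * A**N_FB / (KS**N_FB + A**N_FB)
    return RateLaw("hill_activation_basal", expr, ("tr3.k1", "tr3.k2", "tr3.KS"), ("Spo0AP",))


def _tr5_law() -> RateLaw:
    k1, k2 = param_symbol("tr5.k1"), param_symbol("tr5.k2")
    Kk1, Kk2 = param_symbol("tr5.Kk1"), param_symbol("tr5.Kk2")
    A = _S("Spo0AP")
    expr = k1 * Kk1 / (Kk1 + A) + k2 * A**N_FB / (Kk2**N_FB + A**N_FB)
    return RateLaw(
        "spo0A_transcription", expr,
        ("tr5.k1", "tr5.k2", "tr5.Kk1", "tr5.Kk2"), ("Spo0AP",),
    )


def _spoII_law(rid: str) -> RateLaw:
    k1, k2, Kk = (param_symbol(f"{rid}.{s}") for s in ("k1", "k2", "Kk"))
    A = _S("Spo0AP")
    expr = k1 + k2 * A**N_SPOII / (Kk**N_SPOII + A**N_SPOII)
    return RateLaw(
        "spoII_transcription", expr,
        (f"{rid}.k1", f"{rid}.k2", f"{rid}.Kk"), ("Spo0AP",),
    )


def _reactions() -> list[Reaction]:
    R = Reaction
    rxns = [
        # LacI induction module
        R("tr1", {}, {"lacI_t": 1}, (), _constant("tr1")),
        R("tl1", {}, {"LacI": 1}, ("lacI_t",), _mass_action("tl1", "lacI_t")),
        R("k1", {"LacI": 1}, {"LacI_d": 1}, ("IPTG",), _mass_action("k1", "LacI", "IPTG")),
        R("k2", {"LacI_d": 1}, {"LacI": 1}, (), _mass_action("k2", "LacI_d")),
        # KinA expression and activation
        R("tr2", {}, {"kinA_t": 1}, ("LacI", "Spo0AP"), _tr2_law()),
        R("tl2", {}, {"KinA": 1}, ("kinA_t",), _mass_action("tl2", "kinA_t")),
        R("k3", {"KinA": 2}, {"KinA2": 1},
          (), RateLaw("mass_action", param_symbol("k3.k") * _S("KinA") ** 2, ("k3.k",), ("KinA",))),
        R("k4", {"KinA2": 1}, {"KinA": 2}, (), _mass_action("k4", "KinA2")),
        R("k5", {"KinA2": 1}, {"KinA2P": 1}, ("SS",), _mass_action("k5", "KinA2", "SS")),
        # Spo0F arm and phosphotransfer from KinA~P
        R("tr3", {}, {"spo0F_t": 1}, ("Spo0AP",), _tr3_law()),
        R("tl3", {}, {"Spo0F": 1}, ("spo0F_t",), _mass_action("tl3", "spo0F_t")),
        R("k6", {"Spo0F": 1, "KinA2P": 1}, {"Spo0FP": 1, "KinA2": 1}, (),
          _mass_action("k6", "Spo0F", "KinA2P")),
        R("k7", {"Spo0FP": 1}, {"Spo0F": 1}, (), _mass_action("k7", "Spo0FP")),
        # Spo0B arm (constitutive) and phosphotransfer
        R("tr4", {}, {"spo0B_t": 1}, (), _constant("tr4")),
        R("tl4", {}, {"Spo0B": 1}, ("spo0B_t",), _mass_action("tl4", "spo0B_t")),
        R("k8", {"Spo0B": 1, "Spo0FP": 1}, {"Spo0BP": 1, "Spo0F": 1}, (),
          _mass_action("k8", "Spo0B", "Spo0FP")),
        # Spo0A arm and terminal phosphotransfer
        R("tr5", {}, {"spo0A_t": 1}, ("Spo0AP",), _tr5_law()),
        R("tl5", {}, {"Spo0A": 1}, ("spo0A_t",), _mass_action("tl5", "spo0A_t")),
        R("k9", {"Spo0A": 1, "Spo0BP": 1}, {"Spo0AP": 1, "Spo0B": 1}, (),
          _mass_action("k9", "Spo0A", "Spo0BP")),
        R("k10", {"Spo0AP": 1}, {"Spo0A": 1}, (), _mass_action("k10", "Spo0AP")),
        # Free Spo0B~P dephosphorylation (toggleable via kBdeph.k = 0)
        R("kBdeph", {"Spo0BP": 1}, {"Spo0B": 1}, (),
          _mass_action("kBdeph", "Spo0BP", key="kBdeph.k")),
        # spoII effector operons
        R("tr6", {}, {"spoIIA_t": 1}, ("Spo0AP",), _spoII_law("tr6")),
        R("tl6A", {}, {"AA": 1}, ("spoIIA_t",), _mass_action("tl6A", "spoIIA_t")),
        R("tl6B", {}, {"AB": 1}, ("spoIIA_t",), _mass_action("tl6B", "spoIIA_t")),
        R("tl6C", {}, {"AC": 1}, ("spoIIA_t",), _mass_action("tl6C", "spoIIA_t")),
        R("tr7", {}, {"spoIIE_t": 1}, ("Spo0AP",), _spoII_law("tr7")),
        R("tl7", {}, {"IIE": 1}, ("spoIIE_t",), _mass_action("tl7", "spoIIE_t")),
        R("tr8", {}, {"spoIIG_t": 1}, ("Spo0AP",), _spoII_law("tr8")),
        R("tl8A", {}, {"GA": 1}, ("spoIIG_t",), _mass_action("tl8A", "spoIIG_t")),
        R("tl8B", {}, {"GB": 1}, ("spoIIG_t",), _mass_action("tl8B", "spoIIG_t")),
    ]
    # One first-order degradation per form except the clamped inputs.
    for form in FORMS:
        if form in BOUNDARY_FORMS:
            continue
        key = f"deg.{form}.k"
        rxns.append(
            R(f"deg.{form}", {form: 1}, {}, (),
              RateLaw("mass_action", param_symbol(key) * _S(form), (key,), (form,)))
        )
    return rxns


#: Reaction ids whose fluxes synthesize or remove protein/mRNA mass
#: (used by the phosphoryl-conservation oracle).
TURNOVER_IDS: tuple[str, ...] = tuple(
    [f"tr{i}" for i in range(1, 9)]
    + ["tl1", "tl2", "tl3", "tl4", "tl5", "tl6A", "tl6B", "tl6C", "tl7", "tl8A", "tl8B"]
    + [f"deg.{f}" for f in FORMS if f not in BOUNDARY_FORMS]
)


class NetworkModel:
    """Forms + reactions + parameters, compilable to an ODE system."""

    def __init__(self, reactions: Sequence[Reaction], params: ParameterSet):
        self.forms: tuple[str, ...] = FORMS
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.params = params
        self._index = {f: i for i, f in enumerate(FORMS)}
        # Ordered parameter keys actually referenced by rate laws.
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            for key in rxn.rate_law.param_keys:
                seen.setdefault(key)
        self.param_keys: tuple[str, ...] = tuple(seen)
        self._compiled: tuple[Callable, Callable] | None = None
        self._cache: dict = {}

    # -- construction helpers -------------------------------------------
    def with_params(self, params: ParameterSet) -> "NetworkModel":
        model = NetworkModel(self.reactions, params)
        model._compiled = self._compiled  # structure unchanged; reuse code
        return model

    def with_overrides(self, overrides: Mapping[str, float]) -> "NetworkModel":
        return self.with_params(self.params.with_overrides(overrides))

    # -- numeric interface ----------------------------------------------
    def param_vector(self, params: ParameterSet | None = None) -> np.ndarray:
        p = params or self.params
        out = np.empty(len(self.param_keys))
        for i, key in enumerate(self.param_keys):
            if key.startswith("deg."):
                out[i] = p.degradation_rate(key.split(".")[1])
            else:
                out[i] = p[key]
        return out

    def compile(self) -> tuple[Callable, Callable]:
        """Lambdified ``rates(y, p)`` -> per-reaction fluxes and stoichiometry.

        Returns ``(rhs, jac)`` with signatures ``rhs(y, p) -> dy`` and
        ``jac(y, p) -> d(dy)/dy``; clamped inputs have identically zero rows.
        """
        if self._compiled is not None:
            return self._compiled
        y_syms = [_SPECIES_SYMBOLS[f] for f in FORMS]
        p_syms = [param_symbol(k) for k in self.param_keys]
        dydt = [sp.Integer(0)] * len(FORMS)
        for rxn in self.reactions:
            for form, net in rxn.stoichiometry().items():
                dydt[self._index[form]] = dydt[self._index[form]] + net * rxn.rate_law.expr
        for form in BOUNDARY_FORMS:
            dydt[self._index[form]] = sp.Integer(0)
        dvec = sp.Matrix(dydt)
        jmat = dvec.jacobian(y_syms)
        f = sp.lambdify((y_syms, p_syms), dydt, modules="numpy", cse=True)
        j = sp.lambdify((y_syms, p_syms), jmat, modules="numpy", cse=True)

        def rhs(y: np.ndarray, p: np.ndarray) -> np.ndarray:
            return np.asarray(f(y, p), dtype=float)

        def jac(y: np.ndarray, p: np.ndarray) -> np.ndarray:
            return np.asarray(j(y, p), dtype=float)

        self._compiled = (rhs, jac)
        return self._compiled

    def reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)


def build_reference_network(params: ParameterSet | None = None) -> NetworkModel:
    """Assemble the full 27-form, 55-reaction network.

    Raises :class:`spornet.params.ParameterError` (naming the offending
    constant) if *params* violates the constraints.
    """
    params = params or ParameterSet()
    params.validate()
    return NetworkModel(_reactions(), params)


def evaluate_rate(
    reaction: Reaction,
    state: FormState | Mapping[str, float] | np.ndarray,
    params: ParameterSet,
) -> float:
    """Flux (concentration/s) of one reaction at *state*; always >= 0."""
    if isinstance(state, np.ndarray):
        state = FormState.from_array(state)
    elif not isinstance(state, FormState):
        state = FormState(state)  # validates nonnegativity
    subs = {_SPECIES_SYMBOLS[f]: state[f] for f in FORMS}
    for key in reaction.rate_law.param_keys:
        if key.startswith("deg."):
            value = params.degradation_rate(key.split(".")[1])
        else:
            value = params[key]
        subs[param_symbol(key)] = value
    return float(reaction.rate_law.expr.evalf(subs=subs))


def time_derivatives(
    model: NetworkModel,
    state: FormState | Mapping[str, float] | np.ndarray,
) -> np.ndarray:
    """d[form]/dt for all 27 forms; clamped inputs are identically zero."""
    if isinstance(state, np.ndarray):
        y = np.asarray(state, dtype=float)
        if y.shape != (len(FORMS),):
            raise ValueError(f"state must have {len(FORMS)} entries")
        if (y < 0).any():
            raise ValueError("negative concentration in state")
    else:
        if not isinstance(state, FormState):
            state = FormState(state)
        y = state.as_array()
    rhs, _ = model.compile()
    return rhs(y, model.param_vector())
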