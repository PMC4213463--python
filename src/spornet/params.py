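"""Kinetic constants of the sporulation-initiation network.

All rate constants live in a single internal concentration unit (nM) and
time unit (s).  The published stimulus axes (IPTG, SS) are expressed in uM;
``stimulus_scale`` converts one stimulus-axis unit into internal units at the
point where a clamp is applied (see :mod:`spornet.dynamics`).

Parameters are keyed by the rate id and symbol of the reaction table,
e.g. ``"tr2.k1"`` or ``"k5.k"``.  Degradation is first order for every form
except the two clamped inputs; each degradation reaction owns a rate
``"deg.<form>.k"`` which defaults to the shared ``d_mRNA`` (transcripts) or
``d_prot`` (protein forms) unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

#: The 27 molecular forms, in canonical order.
FORMS: tuple[str, ...] = (
    "lacI_t", "LacI", "LacI_d", "IPTG", "SS",
    "kinA_t", "KinA", "KinA2", "KinA2P",
    "spo0F_t", "Spo0F", "Spo0FP",
    "spo0B_t", "Spo0B", "Spo0BP",
    "spo0A_t", "Spo0A", "Spo0AP",
    "spoIIA_t", "AA", "AB", "AC",
    "spoIIE_t", "IIE",
    "spoIIG_t", "GA", "GB",
)

#: Clamped boundary inputs: held constant during integration.
BOUNDARY_FORMS: tuple[str, str] = ("IPTG", "SS")

#: mRNA species (shared default turnover d_mRNA).
TRANSCRIPTS: tuple[str, ...] = (
    "lacI_t", "kinA_t", "spo0F_t", "spo0B_t", "spo0A_t",
    "spoIIA_t", "spoIIE_t", "spoIIG_t",
)

#: Protein forms (shared default turnover d_prot); 17 forms.
PROTEIN_FORMS: tuple[str, ...] = tuple(
    f for f in FORMS if f not in TRANSCRIPTS and f not in BOUNDARY_FORMS
)

#: Fixed Hill exponents (cooperativities) of the regulated promoters.
N_REP = 2      # LacI repression of kinA transcription
N_FB = 2       # Spo0A~P feedback on tr2 / tr3 / tr5
N_SPOII = 4    # Spo0A~P activation of the spoII promoters

# Published kinetic constants (reaction table of the model).
TABLE_DEFAULTS: dict[str, float] = {
    "tr1.k": 0.1,
    "tl1.k": 0.2,
    "k1.k": 0.000175,
    "k2.k": 0.016,
    "tr2.k1": 0.0275, "tr2.k2": 0.24, "tr2.k3": 1.95, "tr2.KL": 50.0, "tr2.KS": 2100.0,
    "tl2.k": 0.0659,
    "k3.k": 0.001,
    "k4.k": 0.25,
    "k5.k": 0.001,
    "tr3.k1": 0.02, "tr3.k2": 0.1, "tr3.KS": 50.0,
    "tl3.k": 0.0723,
    "k6.k": 0.00039,
    "k7.k": 0.05,
    "tr4.k": 0.2384,
    "tl4.k": 0.1076,
    "k8.k": 0.00001,
    "tr5.k1": 0.01388, "tr5.k2": 0.1388, "tr5.Kk1": 100.0, "tr5.Kk2": 150.0,
    "tl5.k": 0.2143,
    "k9.k": 0.0008,
    "k10.k": 0.05,
    "tr6.k1": 0.0277, "tr6.k2": 0.4166, "tr6.Kk": 140.0,
    "tl6A.k": 0.1250, "tl6B.k": 0.0555, "tl6C.k": 0.0138,
    "tr7.k1": 0.0208, "tr7.k2": 0.3125, "tr7.Kk": 230.0,
    "tl7.k": 0.0138,
    "tr8.k1": 0.0222, "tr8.k2": 0.7290, "tr8.Kk": 1700.0,
    "tl8A.k": 0.0034, "tl8B.k": 0.0138,
}

# Turnover and input constants the reaction table leaves implicit.  The
# shared degradation defaults and the nominal SS clamp are calibrated once
# against the published steady-state anchors of the inducible system (total
# KinA of 200 at IPTG=0, ~100% rise between induction levels 4 and 10, and
# the high-induction endpoint); the slow Spo0B turnover reflects its
# constitutive, unregulated synthesis and large cellular pool.  See
# docs/methods.md for the calibration account.
IMPLICIT_DEFAULTS: dict[str, float] = {
    "d_mRNA": 2.2778e-3,        # 1/s, shared transcript turnover
    "d_prot": 4.0e-3,           # 1/s, shared protein turnover
    "deg.spo0B_t.k": 5.0e-3,    # Spo0B arm runs on its own slow turnover:
    "deg.Spo0B.k": 2.5e-5,      #   constitutive synthesis, large stable pool
    "deg.Spo0BP.k": 2.5e-5,
    "kBdeph.k": 1.0e-4,         # free Spo0B~P dephosphorylation (toggleable)
    "IPTG_in": 0.0,             # nominal inducer clamp, stimulus-axis units (uM)
    "SS_in": 0.07,              # nominal sporulation-signal clamp (uM)
    "stimulus_scale": 1000.0,   # internal (nM) units per stimulus-axis unit
}

#: Half-saturation constants: must be strictly positive.
_SATURATION_KEYS = frozenset(
    k for k in TABLE_DEFAULTS if k.split(".")[1].startswith("K")
)

#: Table entries marked "Fitted" whose values were estimated, not measured.
FITTED_KEYS: tuple[str, ...] = (
    "tr1.k", "tl1.k", "tl2.k", "k3.k", "k4.k", "k5.k",
    "tr4.k", "tl4.k", "tl5.k",
    "tl6A.k", "tl6B.k", "tl6C.k",
)


class ParameterError(ValueError):
    """Raised when a parameter value violates its constraints."""


def _degradation_default(form: str, values: Mapping[str, float]) -> float:
    shared = "d_mRNA" if form in TRANSCRIPTS else "d_prot"
    return values[shared]


@dataclass(frozen=True)
class ParameterSet:
    """Immutable bag of kinetic constants keyed by rate id and symbol.

    Unknown keys are tolerated (and inert) so that configuration files may
    carry commentary values; constraints are enforced on the known keys.
    """

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        merged = {**TABLE_DEFAULTS, **IMPLICIT_DEFAULTS}
        merged.update({k: float(v) for k, v in self.values.items()})
        object.__setattr__(self, "values", merged)
        self.validate()

    def validate(self) -> None:
        for key, value in self.values.items():
            if value < 0:
                raise ParameterError(f"{key} must be nonnegative, got {value}")
            if key in _SATURATION_KEYS and value <= 0:
                raise ParameterError(
                    f"half-saturation constant {key} must be > 0, got {value}"
                )
        if self.values["stimulus_scale"] <= 0:
            raise ParameterError("stimulus_scale must be > 0")

    # -- access ---------------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def get(self, key: str, default: float | None = None) -> float | None:
        return self.values.get(key, default)

    def degradation_rate(self, form: str) -> float:
        """First-order turnover of *form* (override or shared default)."""
        if form in BOUNDARY_FORMS:
            raise KeyError(f"{form} is a clamped input and is not degraded")
        return self.values.get(f"deg.{form}.k", _degradation_default(form, self.values))

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        return ParameterSet({**self.values, **overrides})

    def signature(self) -> tuple:
        return tuple(sorted(self.values.items()))

    # -- config files ---------------------------------------------------
    @classmethod
    def from_config(cls, path: str | Path, base: "ParameterSet | None" = None) -> "ParameterSet":
        """Load flat ``key=value`` overrides (``#`` starts a comment)."""
        overrides = parse_config(Path(path).read_text())
        return (base or cls()).with_overrides(overrides)

    def to_config(self, path: str | Path, keys: Iterable[str] | None = None) -> None:
        keys = sorted(keys or self.values)
        Path(path).write_text(
            "".join(f"{k}={self.values[k]!r}\n" for k in keys)
        )


def parse_config(text: str) -> dict[str, float]:
    overrides: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"line {lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        try:
            overrides[key.strip()] = float(value)
        except ValueError as exc:
            raise ParameterError(f"line {lineno}: bad number {value!r}") from exc
    return overrides
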