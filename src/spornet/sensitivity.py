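"""Local relative sensitivity coefficients and one-parameter global scans.

The local coefficient for steady-state concentration c and parameter p is
the dimensionless S = (p/c) * dc/dp, estimated by central finite differences
with the steady state re-solved at each perturbed parameter value.  The
default relative step is 1e-3; when the two one-sided estimates disagree by
more than 10% the step is halved (self-checking scheme).  Coefficients are
computed on steady-state concentrations, not fluxes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import SteadyStateError, pre_equilibrate, steady_state
from .network import FORMS, NetworkModel

_IDX = {f: i for i, f in enumerate(FORMS)}

#: Coefficients within this relative margin of the column maximum are
#: reported together by ``top_coefficients`` (near-tie convention).
TIE_MARGIN = 0.01

#: Concentrations below the steady-state residual tolerance are numerically
#: zero; their relative coefficients are defined as 0 rather than amplified.
ZERO_CONC = 1e-9


def _nominal_value(model: NetworkModel, key: str) -> float:
    if key.startswith("deg."):
        return model.params.degradation_rate(key.split(".")[1])
    value = model.params.get(key)
    if value is None:
        raise KeyError(f"unknown parameter {key!r}")
    return value


@dataclass
class SensitivityMatrix:
    """Relative sensitivity coefficients, target forms x parameters."""

    table: pd.DataFrame            # rows: forms, columns: parameter keys
    rel_step: float
    steps_used: dict[str, float]   # per-parameter final step
    flags: dict[str, str] = field(default_factory=dict)
    nominal: dict[str, float] = field(default_factory=dict)
    state0: pd.Series | None = None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        form, param = pair
        return float(self.table.loc[form, param])

    def max_abs(self) -> tuple[float, str, str]:
        """(value, form, parameter) of the largest |S| entry."""
        arr = self.table.abs().to_numpy()
        i, j = np.unravel_index(np.nanargmax(arr), arr.shape)
        return float(arr[i, j]), str(self.table.index[i]), str(self.table.columns[j])

    def top_coefficients(self) -> pd.DataFrame:
        """All entries within ``TIE_MARGIN`` of the global max |S|."""
        best = self.max_abs()[0]
        stacked = self.table.stack()
        keep = stacked[stacked.abs() >= best * (1 - TIE_MARGIN)]
        keep.index = keep.index.set_names(["form", "parameter"])
        return keep.rename("S").reset_index()

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write(f"# relative sensitivity coefficients S=(p/c) dc/dp\n")
        buf.write(f"# rel_step={self.rel_step}\n")
        for key, step in self.steps_used.items():
            buf.write(f"# step {key}={step}\n")
        for key, val in self.nominal.items():
            buf.write(f"# nominal {key}={val}\n")
        for key, msg in self.flags.items():
            buf.write(f"# flag {key}={msg}\n")
        self.table.to_csv(buf)
        Path(path).write_text(buf.getvalue())


@dataclass
class ScanResult:
    """Steady states along a one-parameter scan (global sensitivity)."""

    parameter: str
    scale_factors: np.ndarray
    raw: pd.DataFrame          # rows: forms, columns: scale factors
    normalized: pd.DataFrame   # raw divided by the factor-1.0 column
    nominal_value: float
    flags: dict[float, str] = field(default_factory=dict)

    def series(self, form: str, normalized: bool = True) -> pd.Series:
        return (self.normalized if normalized else self.raw).loc[form]

    def to_csv(self, path: str | Path, normalized: bool = True) -> None:
        buf = io.StringIO()
        buf.write(f"# parameter scan of {self.parameter}\n")
        buf.write(f"# nominal {self.parameter}={self.nominal_value}\n")
        for fac, msg in self.flags.items():
            buf.write(f"# flag factor={fac}: {msg}\n")
        (self.normalized if normalized else self.raw).to_csv(buf)
        Path(path).write_text(buf.getvalue())


def _solve_perturbed(model, key, value, guess, iptg, ss):
    return steady_state(model.with_overrides({key: value}), iptg=iptg, ss=ss, guess=guess)


def local_sensitivities(
    model: NetworkModel,
    parameters: Sequence[str],
    targets: Sequence[str] | None = None,
    rel_step: float = 1e-3,
    iptg: float = 0.0,
    ss: float | None = None,
    max_halvings: int = 3,
) -> SensitivityMatrix:
    """Relative sensitivities of steady-state concentrations to parameters.

    The nominal steady state (basal by default) seeds every perturbed solve.
    A perturbed solve that fails is flagged and yields a NaN column rather
    than a silent zero.
    """
    targets = list(targets or FORMS)
    if ss is None:
        ss = model.params["SS_in"]
    if iptg == 0.0 and ss == model.params["SS_in"]:
        y0 = pre_equilibrate(model).as_array()
    else:
        y0 = steady_state(model, iptg=iptg, ss=ss).as_array()
    t_idx = [_IDX[f] for f in targets]
    c0 = y0[t_idx]

    columns: dict[str, np.ndarray] = {}
    steps_used: dict[str, float] = {}
    flags: dict[str, str] = {}
    nominal: dict[str, float] = {}
    for key in parameters:
        p0 = _nominal_value(model, key)
        nominal[key] = p0
        if p0 == 0.0:
            # relative coefficient w.r.t. a zero nominal is identically zero
            columns[key] = np.zeros(len(targets))
            steps_used[key] = 0.0
            flags[key] = "nominal value is zero; S defined as 0"
            continue
        h = rel_step
        col = None
        for _ in range(max_halvings + 1):
            try:
                up = _solve_perturbed(model, key, p0 * (1 + h), y0, iptg, ss).as_array()[t_idx]
                dn = _solve_perturbed(model, key, p0 * (1 - h), y0, iptg, ss).as_array()[t_idx]
            except SteadyStateError as exc:
                flags[key] = f"steady state failed at step {h}: {exc}"
                col = np.full(len(targets), np.nan)
                break
            tiny = np.abs(c0) < ZERO_CONC
            with np.errstate(divide="ignore", invalid="ignore"):
                denom = np.where(tiny, np.nan, c0)
                fwd = (up - c0) / (h * denom)
                bwd = (c0 - dn) / (h * denom)
                central = (up - dn) / (2 * h * denom)
            central = np.where(tiny, 0.0, central)
            fwd, bwd = np.where(tiny, 0.0, fwd), np.where(tiny, 0.0, bwd)
            scale = np.maximum(np.nanmax(np.abs(central)), 1e-12)
            if np.nanmax(np.abs(fwd - bwd)) <= 0.1 * scale:
                col = central
                break
            h /= 2.0
            col = central  # keep the best estimate so far
        columns[key] = col
        steps_used[key] = h
    table = pd.DataFrame(columns, index=targets)
    return SensitivityMatrix(
        table=table,
        rel_step=rel_step,
        steps_used=steps_used,
        flags=flags,
        nominal=nominal,
        state0=pd.Series(y0, index=list(FORMS)),
    )


def parameter_scan(
    model: NetworkModel,
    parameter: str,
    scale_factors: Sequence[float],
    iptg: float = 0.0,
    ss: float | None = None,
) -> ScanResult:
    """Steady states with *parameter* at each multiple of its nominal value.

    Results are returned raw and normalized to the factor-1.0 column (which
    is solved even if 1.0 is absent from *scale_factors*).  Successive
    points warm-start from their neighbour.
    """
    factors = np.asarray(sorted(float(f) for f in scale_factors))
    if (factors <= 0).any():
        raise ValueError("scale factors must be > 0")
    if ss is None:
        ss = model.params["SS_in"]
    p0 = _nominal_value(model, parameter)
    guess = pre_equilibrate(model).as_array() if (
        iptg == 0.0 and ss == model.params["SS_in"]
    ) else steady_state(model, iptg=iptg, ss=ss).as_array()

    solve_at = np.unique(np.append(factors, 1.0))
    states: dict[float, np.ndarray] = {}
    flags: dict[float, str] = {}
    for fac in solve_at:
        try:
            st = _solve_perturbed(model, parameter, p0 * fac, guess, iptg, ss)
            states[fac] = st.as_array()
            guess = states[fac]
        except SteadyStateError as exc:
            flags[fac] = str(exc)
            states[fac] = np.full(len(FORMS), np.nan)
    raw = pd.DataFrame(
        {fac: states[fac] for fac in factors}, index=list(FORMS)
    )
    ref = pd.Series(states[1.0], index=list(FORMS))
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = raw.divide(ref, axis=0)
    both_zero = raw.eq(0.0).to_numpy() & ref.eq(0.0).to_numpy()[:, None]
    normalized = normalized.mask(both_zero, 1.0)  # clamped-at-zero inputs
    if any(fac == 1.0 for fac in factors):
        normalized[1.0] = np.where(np.isnan(ref.to_numpy()), np.nan, 1.0)
    return ScanResult(
        parameter=parameter,
        scale_factors=factors,
        raw=raw,
        normalized=normalized,
        nominal_value=p0,
        flags=flags,
    )
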