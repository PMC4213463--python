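"""End-to-end analyses of the sporulation-initiation model.

Dose-response scans over the induction inputs, steady-state panels,
the feedback-knockout/compensation experiment, the mean-relative-distance
goodness metric used to compare curves, ordinary least-squares fits for the
wild-type linear-accumulation comparison, and the wild-type discrepancy
report.

Stimulus grids are on the published axis unit (uM).  Phosphorelay protein
outputs are reported both in internal units (the scale on which the
published KinA numbers 200-2800 are quoted) and, for the Spo0A wild-type
comparison, in uM (internal / 1000), the scale on which the published
benchmarks 4.5 and 37.5 uM are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dynamics import SteadyStateError, pre_equilibrate, steady_state
from .network import FORMS, NetworkModel

#: internal concentration units per uM on the published Spo0A scale
NM_PER_UM = 1000.0

#: published wild-type benchmark: total Spo0A accumulates to 37.5 uM
WILDTYPE_SPO0A_UM = 37.5

#: the model's published ceiling for total Spo0A, uM
MODEL_SPO0A_CEILING_UM = 4.5

PHOSPHO_FORMS = ("KinA2P", "Spo0FP", "Spo0BP", "Spo0AP")
EFFECTOR_FORMS = ("AA", "AB", "AC", "IIE", "GA", "GB")

_IDX = {f: i for i, f in enumerate(FORMS)}


def total_kina(state) -> float:
    """Total KinA in monomer equivalents: KinA + 2 KinA2 + 2 KinA2~P."""
    return state["KinA"] + 2.0 * state["KinA2"] + 2.0 * state["KinA2P"]


def total_of(state, protein: str) -> float:
    """Free + phosphorylated total of Spo0F / Spo0B / Spo0A, or total KinA."""
    if protein == "KinA":
        return total_kina(state)
    return state[protein] + state[protein + "P"]


@dataclass
class DoseResponse:
    """Steady-state response along a stimulus grid."""

    stimulus: str                  # "IPTG" or "SS"
    grid: np.ndarray               # stimulus-axis units, strictly increasing
    states: pd.DataFrame           # rows: grid points, columns: 27 forms
    derived: pd.DataFrame          # totals, phospho-forms, effectors
    flags: dict[float, str] = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        if name in self.derived.columns:
            return self.derived[name].to_numpy()
        return self.states[name].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        out = self.states.copy()
        out.insert(0, self.stimulus.lower() + "_level", self.grid)
        extra = [c for c in self.derived.columns if c not in out.columns]
        out = out.join(self.derived[extra])
        out.to_csv(path, index=False)


def _derived_frame(states: pd.DataFrame) -> pd.DataFrame:
    d = pd.DataFrame(index=states.index)
    d["total_KinA"] = states["KinA"] + 2 * states["KinA2"] + 2 * states["KinA2P"]
    for p in ("Spo0F", "Spo0B", "Spo0A"):
        d[f"total_{p}"] = states[p] + states[p + "P"]
    for f in PHOSPHO_FORMS + EFFECTOR_FORMS:
        d[f] = states[f]
    return d


def dose_response(
    model: NetworkModel,
    stimulus: str,
    grid: Sequence[float] | None = None,
    warm_start: bool = True,
) -> DoseResponse:
    """Steady states along an IPTG grid (SS nominal) or an SS grid (IPTG 0).

    Each point starts from the previous point's solution (warm start); the
    first point starts from the basal pre-equilibrated state.
    """
    if stimulus not in ("IPTG", "SS"):
        raise ValueError("stimulus must be 'IPTG' or 'SS'")
    if grid is None:
        grid = np.linspace(0.0, 20.0, 21) if stimulus == "IPTG" else np.linspace(0.0, 2.0, 21)
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")

    guess = pre_equilibrate(model).as_array()
    rows, flags = [], {}
    for g in grid:
        iptg, ss = (g, model.params["SS_in"]) if stimulus == "IPTG" else (0.0, g)
        try:
            st = steady_state(model, iptg=iptg, ss=ss, guess=guess)
            rows.append(st.as_array())
            if warm_start:
                guess = rows[-1]
        except SteadyStateError as exc:
            flags[float(g)] = str(exc)
            rows.append(np.full(len(FORMS), np.nan))
    states = pd.DataFrame(rows, columns=list(FORMS))
    return DoseResponse(stimulus, grid, states, _derived_frame(states), flags)


def steady_state_panel(
    model: NetworkModel, iptg_levels: Sequence[float] = (0.0, 10.0, 20.0)
) -> dict[str, pd.DataFrame]:
    """Steady-state phospho-form and effector concentrations per IPTG level."""
    guess = pre_equilibrate(model).as_array()
    cols = {}
    for level in iptg_levels:
        st = steady_state(model, iptg=level, guess=guess)
        guess = st.as_array()
        cols[level] = st
    phospho = pd.DataFrame(
        {lvl: [cols[lvl][f] for f in PHOSPHO_FORMS] for lvl in iptg_levels},
        index=list(PHOSPHO_FORMS),
    )
    effectors = pd.DataFrame(
        {lvl: [cols[lvl][f] for f in EFFECTOR_FORMS] for lvl in iptg_levels},
        index=list(EFFECTOR_FORMS),
    )
    return {"phospho": phospho, "effectors": effectors}


def goodness_of_agreement(observed, predicted) -> float:
    """Mean relative distance (1/n) sum |o_i - m_i| / o_i.

    The curve-comparison metric: 0 for identical series; reported as a
    percentage elsewhere by multiplying by 100.
    """
    o = np.asarray(observed, dtype=float)
    m = np.asarray(predicted, dtype=float)
    if o.ndim != 1 or o.shape != m.shape or len(o) < 1:
        raise ValueError("observed and predicted must be 1-d of equal length >= 1")
    if np.any(o <= 0):
        raise ValueError("all observed values must be > 0 (metric divides by o_i)")
    return float(np.mean(np.abs(o - m) / o))


def feedback_knockout(model: NetworkModel) -> NetworkModel:
    """Copy of the model with the Spo0A~P feedback on KinA transcription off."""
    return model.with_overrides({"tr2.k3": 0.0})


@dataclass
class CompensationResult:
    k2: float
    KL: float
    distance: float                # final mean relative distance (fraction)
    model: NetworkModel            # knockout model with refitted parameters
    nfev: int
    converged: bool
    history: list = field(default_factory=list)


def compensate_repression_params(
    reference: DoseResponse,
    knockout_model: NetworkModel,
    bounds_scale: tuple[float, float] = (10.0, 20.0),
    maxfev: int = 400,
) -> CompensationResult:
    """Refit only the LacI-repression constants of KinA transcription.

    Minimizes the mean relative distance between the knockout model's
    steady-state KinA2~P dose-response and *reference* over (tr2.k2, tr2.KL),
    with k2 in [0, 10 x nominal] and KL in [1, 20 x nominal].  Nelder-Mead
    on the metric itself, seeded from the nominal values.
    """
    from scipy.optimize import minimize

    ref_curve = reference.series("KinA2P")
    mask = ref_curve > 0
    if not mask.any():
        raise ValueError("reference KinA2P curve is identically zero")
    grid = reference.grid
    k2n = knockout_model.params["tr2.k2"]
    KLn = knockout_model.params["tr2.KL"]
    k2_hi, KL_hi = bounds_scale[0] * k2n, bounds_scale[1] * KLn
    history: list = []

    def objective(x):
        k2, KL = x
        if not (0.0 <= k2 <= k2_hi and 1.0 <= KL <= KL_hi):
            return 10.0 + abs(k2) + abs(KL)   # soft wall outside the box
        trial = knockout_model.with_overrides({"tr2.k2": k2, "tr2.KL": KL})
        curve = dose_response(trial, reference.stimulus, grid).series("KinA2P")
        d = goodness_of_agreement(ref_curve[mask], curve[mask])
        history.append((k2, KL, d))
        return d

    best = None
    for start in ((k2n, KLn), (k2n * 1.5, KLn * 0.7)):
        res = minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxfev": maxfev},
        )
        if best is None or res.fun < best.fun:
            best = res
    fitted = knockout_model.with_overrides({"tr2.k2": best.x[0], "tr2.KL": best.x[1]})
    result = CompensationResult(
        k2=float(best.x[0]), KL=float(best.x[1]), distance=float(best.fun),
        model=fitted, nfev=int(best.nfev), converged=bool(best.success),
        history=history,
    )
    if not best.success and best.fun > 0.05:
        raise RuntimeError(
            f"compensation refit did not converge (best distance {best.fun:.4f})",
        )
    return result


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    flag: str | None = None


def linear_fit(times, values) -> LinearFit:
    """Ordinary least squares of values on times; R^2 = 1 - SS_res/SS_tot."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(v, v[0]):
        return LinearFit(0.0, float(v[0]), float("nan"), 0.0,
                         flag="zero variance in values; R^2 undefined")
    fit = sm.OLS(v, sm.add_constant(t)).fit()
    return LinearFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_se=float(fit.bse[1]),
    )


@dataclass
class WildtypeReport:
    """Model ceiling for total Spo0A against the wild-type benchmark."""

    max_total_spo0a_internal: float
    max_total_spo0a_uM: float
    argmax: tuple[float, float]          # (iptg, ss) attaining the max
    benchmark_uM: float
    ratio: float                         # benchmark / model max
    envelope: dict[str, tuple[float, float]]
    table: pd.DataFrame                  # iptg, ss, total Spo0A (internal)

    def summary(self) -> dict:
        return {
            "max_total_spo0a_uM": self.max_total_spo0a_uM,
            "benchmark_uM": self.benchmark_uM,
            "ratio_benchmark_over_model": self.ratio,
            "argmax_iptg": self.argmax[0],
            "argmax_ss": self.argmax[1],
        }


def wildtype_discrepancy_report(
    model: NetworkModel,
    iptg_grid: Sequence[float] | None = None,
    ss_grid: Sequence[float] | None = None,
    benchmark_uM: float = WILDTYPE_SPO0A_UM,
) -> WildtypeReport:
    """Maximum steady-state total Spo0A over the joint stimulus envelope.

    The default envelope covers IPTG 0-20 and SS 0-2 (21 x 21 points).  The
    maximum is reported in uM against the wild-type accumulation benchmark;
    the model's inability to approach the benchmark is the finding, so this
    is a discrepancy report rather than a fit.
    """
    iptg_grid = np.asarray(
        np.linspace(0.0, 20.0, 21) if iptg_grid is None else iptg_grid, dtype=float
    )
    ss_grid = np.asarray(
        np.linspace(0.0, 2.0, 21) if ss_grid is None else ss_grid, dtype=float
    )
    rows = []
    col_guess = pre_equilibrate(model).as_array()
    for ssv in ss_grid:
        guess = col_guess
        for i, ig in enumerate(iptg_grid):
            st = steady_state(model, iptg=ig, ss=ssv, guess=guess)
            guess = st.as_array()
            if i == 0:
                col_guess = guess      # warm-start the next SS row
            rows.append((float(ig), float(ssv), total_of(st, "Spo0A")))
    table = pd.DataFrame(rows, columns=["iptg", "ss", "total_Spo0A"])
    imax = int(table["total_Spo0A"].idxmax())
    mx = float(table.loc[imax, "total_Spo0A"])
    return WildtypeReport(
        max_total_spo0a_internal=mx,
        max_total_spo0a_uM=mx / NM_PER_UM,
        argmax=(float(table.loc[imax, "iptg"]), float(table.loc[imax, "ss"])),
        benchmark_uM=benchmark_uM,
        ratio=benchmark_uM / (mx / NM_PER_UM),
        envelope={
            "iptg": (float(iptg_grid.min()), float(iptg_grid.max())),
            "ss": (float(ss_grid.min()), float(ss_grid.max())),
        },
        table=table,
    )
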