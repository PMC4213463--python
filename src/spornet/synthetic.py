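"""Synthetic observations with the statistical structure the analyses assume.

Two generators emulate the two kinds of experimental data the model is
compared against: noisy steady-state dose-response readouts of an inducible
system (multiplicative noise — concentrations span orders of magnitude and
the curve-comparison metric is relative), and linearly accumulating
wild-type time courses with additive noise (roughly constant scatter).  A
parameter-recovery study exercises the fitting machinery used for the
"Fitted" kinetic constants.  All generators are pure functions of their
arguments and a seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import NetworkModel
from .params import FITTED_KEYS
from .scenarios import DoseResponse, dose_response, goodness_of_agreement, linear_fit

#: multiplicative noise is truncated so observations stay positive
NOISE_FLOOR = -0.9


@dataclass
class SyntheticDoseResponseSet:
    stimulus: str
    grid: np.ndarray
    truth: np.ndarray          # deterministic model curve
    observed: np.ndarray       # truth x (1 + cv * N(0,1)), truncated at -90%
    cv: float
    seed: int
    observable: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.stimulus: self.grid, "truth": self.truth, "observed": self.observed}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SyntheticWildtypeTimecourse:
    t_min: np.ndarray                       # minutes
    values: pd.DataFrame                    # one column per species
    slopes: dict[str, float]
    intercepts: dict[str, float]
    sigma: float
    seed: int

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "time_min", self.t_min)
        out.to_csv(path, index=False)


def make_dose_response_observations(
    model: NetworkModel,
    stimulus: str = "IPTG",
    grid: Sequence[float] | None = None,
    cv: float = 0.05,
    seed: int = 0,
    observable: str = "total_KinA",
    truth: DoseResponse | None = None,
) -> SyntheticDoseResponseSet:
    """Noisy steady-state dose-response observations of *observable*.

    The truth column is exactly the deterministic dose-response output; the
    observed column multiplies it by (1 + cv*z) with z ~ N(0,1) truncated at
    -90% so observations stay positive.  Pass *truth* to reuse an already
    computed curve (the generator never recomputes noise from it).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    dr = truth if truth is not None else dose_response(model, stimulus, grid)
    curve = dr.series(observable)
    rng = np.random.default_rng(seed)
    noise = np.maximum(cv * rng.standard_normal(len(curve)), NOISE_FLOOR)
    return SyntheticDoseResponseSet(
        stimulus=dr.stimulus,
        grid=dr.grid,
        truth=curve.copy(),
        observed=curve * (1.0 + noise),
        cv=cv,
        seed=seed,
        observable=observable,
    )


def make_wildtype_timecourse(
    slopes: Mapping[str, float],
    intercepts: Mapping[str, float],
    sigma: float,
    t_grid: Sequence[float],
    seed: int = 0,
) -> SyntheticWildtypeTimecourse:
    """Linear accumulation per species plus additive Gaussian noise.

    *slopes* and *intercepts* are keyed by species label (units per minute
    and units); *t_grid* is in minutes, matching the single-cell wild-type
    time courses the model is compared against.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    t = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    cols = {}
    for species, slope in slopes.items():
        truth = intercepts[species] + slope * t
        cols[species] = truth + sigma * rng.standard_normal(len(t))
    return SyntheticWildtypeTimecourse(
        t_min=t,
        values=pd.DataFrame(cols),
        slopes=dict(slopes),
        intercepts=dict(intercepts),
        sigma=sigma,
        seed=seed,
    )


@dataclass
class RecoveryRecord:
    parameter: str
    true_value: float
    start_value: float
    fitted_value: float
    rel_error: float
    distance: float
    seed: int
    converged: bool


def _refit_single(model, key, observed, grid, stimulus, start, bounds, maxfev=80):
    """1-d refit of one rate constant against a noisy curve (log scale)."""
    from scipy.optimize import minimize_scalar

    lo, hi = bounds

    def objective(logv):
        trial = model.with_overrides({key: float(np.exp(logv))})
        curve = dose_response(trial, stimulus, grid).series("total_KinA")
        return goodness_of_agreement(observed, curve)

    res = minimize_scalar(
        objective,
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-5, "maxiter": maxfev},
    )
    return float(np.exp(res.x)), float(res.fun), bool(res.success)


def parameter_recovery_study(
    true_model: NetworkModel,
    perturb_ids: Sequence[str],
    cv: float = 0.05,
    n_seeds: int = 20,
    seed: int = 0,
    grid: Sequence[float] | None = None,
    perturb_factor: float = 2.0,
) -> pd.DataFrame:
    """Simulate noisy dose-response data and refit perturbed fitted rates.

    For each replicate: draw a noisy total-KinA IPTG dose-response from the
    true model, start each parameter in *perturb_ids* at
    ``perturb_factor x`` its true value, and refit it (alone) by minimizing
    the mean relative distance.  Returns one row per (parameter, seed) with
    the relative recovery error.
    """
    bad = [p for p in perturb_ids if p not in FITTED_KEYS]
    if bad:
        raise ValueError(f"not 'Fitted' table entries: {bad}")
    grid = np.asarray(
        np.linspace(0.0, 20.0, 11) if grid is None else grid, dtype=float
    )
    truth = dose_response(true_model, "IPTG", grid)
    records = []
    for key in perturb_ids:
        true_val = true_model.params[key]
        start = perturb_factor * true_val
        bounds = (true_val / 20.0, true_val * 20.0)
        for rep in range(n_seeds):
            rep_seed = int(np.random.default_rng((seed, rep)).integers(2**31 - 1))
            obs = make_dose_response_observations(
                true_model, "IPTG", grid, cv=cv, seed=rep_seed, truth=truth
            )
            try:
                fitted, dist, ok = _refit_single(
                    true_model, key, obs.observed, grid, "IPTG", start, bounds
                )
            except Exception as exc:  # noqa: BLE001 - flagged per replicate
                records.append(RecoveryRecord(key, true_val, start, np.nan,
                                              np.nan, np.nan, rep_seed, False))
                continue
            records.append(
                RecoveryRecord(
                    parameter=key, true_value=true_val, start_value=start,
                    fitted_value=fitted,
                    rel_error=abs(fitted - true_val) / true_val,
                    distance=dist, seed=rep_seed, converged=ok,
                )
            )
    return pd.DataFrame([r.__dict__ for r in records])
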