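"""Transient integration and steady-state solution of the network.

The stimulus levels (``iptg``, ``ss``) are given on the published axis unit
(uM) and converted by ``params["stimulus_scale"]`` into the internal
concentration unit before being written into the clamped IPTG / SS entries
of the state vector.

Steady states are found by a damped Newton root solve (analytic Jacobian)
warm-started from the basal pre-equilibrated state, with an integrate-then-
polish fallback for hard starting points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import FORMS, FormState, NetworkModel
from .params import BOUNDARY_FORMS

_IDX = {f: i for i, f in enumerate(FORMS)}
_I_IPTG, _I_SS = _IDX["IPTG"], _IDX["SS"]
_FREE = np.array([i for i, f in enumerate(FORMS) if f not in BOUNDARY_FORMS])

#: Default steady-state residual tolerance (model units / s, max-norm).
STEADY_TOL = 1e-9


class IntegrationError(RuntimeError):
    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


class SteadyStateError(RuntimeError):
    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class Trajectory:
    """Time grid x state matrix from a transient simulation."""

    t: np.ndarray              # seconds, strictly increasing
    y: np.ndarray              # shape (len(t), 27)
    iptg: float                # stimulus-axis units
    ss: float

    def state(self, i: int = -1) -> FormState:
        return FormState.from_array(self.y[i])

    def series(self, form: str) -> np.ndarray:
        return self.y[:, _IDX[form]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time, form, concentration."""
        frames = pd.DataFrame(self.y, columns=list(FORMS))
        frames.insert(0, "time", self.t)
        return frames.melt(id_vars="time", var_name="form", value_name="concentration")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SteadyState:
    state: FormState
    residual: float            # max-norm of time derivatives
    method: str                # "newton" | "integrate+newton" | "integrate"
    iterations: int
    iptg: float
    ss: float

    def __getitem__(self, form: str) -> float:
        return self.state[form]

    def as_array(self) -> np.ndarray:
        return self.state.as_array()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"form": list(FORMS), "concentration": self.as_array()}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _apply_clamps(model: NetworkModel, y: np.ndarray, iptg: float, ss: float) -> np.ndarray:
    scale = model.params["stimulus_scale"]
    y = np.array(y, dtype=float, copy=True)
    y[_I_IPTG] = scale * iptg
    y[_I_SS] = scale * ss
    return y


def simulate(
    model: NetworkModel,
    initial: FormState | np.ndarray | None,
    iptg: float,
    ss: float,
    duration: float,
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the ODE system with clamped inputs held fixed.

    Uses LSODA (stiffness-switching).  Concentrations are clipped at zero in
    the returned trajectory; excursions below -1e-9 raise.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if initial is None:
        y0 = np.zeros(len(FORMS))
    elif isinstance(initial, FormState):
        y0 = initial.as_array()
    else:
        y0 = np.asarray(initial, dtype=float)
    y0 = _apply_clamps(model, y0, iptg, ss)
    rhs, jac = model.compile()
    p = model.param_vector()
    t_eval = np.linspace(0.0, duration, n_points)
    sol = solve_ivp(
        lambda t, y: rhs(y, p),
        (0.0, duration),
        y0,
        method="LSODA",
        jac=lambda t, y: jac(y, p),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    got = sol.y.T
    if not sol.success:
        n_ok = len(sol.t)
        partial = Trajectory(sol.t, np.clip(got, 0.0, None), iptg, ss) if n_ok else None
        raise IntegrationError(
            f"integrator failed at t={sol.t[-1] if n_ok else 0.0:g}s: {sol.message}",
            partial=partial,
        )
    if got.min() < -1e-9:
        raise IntegrationError(
            f"negative concentration {got.min():.3e} exceeds tolerance", None
        )
    return Trajectory(sol.t, np.clip(got, 0.0, None), iptg, ss)


def _newton_polish(model, y0, iptg, ss, tol):
    rhs, jac = model.compile()
    p = model.param_vector()

    def fun(x):
        y = _apply_clamps(model, _embed(x, y0), iptg, ss)
        return rhs(y, p)[_FREE]

    def dfun(x):
        y = _apply_clamps(model, _embed(x, y0), iptg, ss)
        return jac(y, p)[np.ix_(_FREE, _FREE)]

    sol = root(fun, y0[_FREE], jac=dfun, method="hybr", tol=1e-13)
    y = _apply_clamps(model, _embed(sol.x, y0), iptg, ss)
    res = float(np.max(np.abs(rhs(y, p))))
    ok = sol.success and res <= tol and y[_FREE].min() >= -1e-9
    nit = int(sol.nfev)
    return ok, np.clip(y, 0.0, None), res, nit


def _embed(x_free: np.ndarray, template: np.ndarray) -> np.ndarray:
    y = np.array(template, copy=True)
    y[_FREE] = x_free
    return y


def steady_state(
    model: NetworkModel,
    iptg: float,
    ss: float | None = None,
    guess: FormState | np.ndarray | None = None,
    tol: float = STEADY_TOL,
    max_horizon: float = 1e9,
) -> SteadyState:
    """Solve d[form]/dt = 0 at the given clamped inputs.

    Newton from *guess* (default: the basal pre-equilibrated state); on
    failure, integrate toward equilibrium and re-polish.  Steady-state
    uniqueness is not assumed: the state reached from the guess is reported.
    """
    if ss is None:
        ss = model.params["SS_in"]
    if guess is None:
        if iptg == 0.0 and ss == model.params["SS_in"]:
            guess_arr = np.zeros(len(FORMS))  # basal solve bootstraps from zero
        else:
            guess_arr = pre_equilibrate(model).as_array()
    elif isinstance(guess, FormState):
        guess_arr = guess.as_array()
    else:
        guess_arr = np.asarray(guess, dtype=float)
    guess_arr = _apply_clamps(model, guess_arr, iptg, ss)

    ok, y, res, nit = _newton_polish(model, guess_arr, iptg, ss, tol)
    if ok:
        return SteadyState(FormState.from_array(y), res, "newton", nit, iptg, ss)

    # Fallback: relax by integration, polishing after each horizon.
    rhs, _ = model.compile()
    p = model.param_vector()
    y = guess_arr
    horizon, total_nit = 1e5, nit
    while horizon <= max_horizon:
        try:
            traj = simulate(model, y, iptg, ss, horizon, n_points=2, rtol=1e-10, atol=1e-12)
            y = _apply_clamps(model, traj.y[-1], iptg, ss)
        except IntegrationError as exc:
            if exc.partial is None:
                raise SteadyStateError(f"integration fallback failed: {exc}") from exc
            y = _apply_clamps(model, exc.partial.y[-1], iptg, ss)
        ok, y2, res, nit = _newton_polish(model, y, iptg, ss, tol)
        total_nit += nit
        if ok:
            return SteadyState(
                FormState.from_array(y2), res, "integrate+newton", total_nit, iptg, ss
            )
        res_int = float(np.max(np.abs(rhs(y, p))))
        if res_int <= tol:
            return SteadyState(
                FormState.from_array(np.clip(y, 0.0, None)),
                res_int, "integrate", total_nit, iptg, ss,
            )
        horizon *= 10.0
    raise SteadyStateError(
        "no convergence within budget",
        {"iptg": iptg, "ss": ss, "residual": res, "last_state": y},
    )


def pre_equilibrate(model: NetworkModel, ss: float | None = None) -> FormState:
    """Basal steady state (IPTG = 0, SS at its nominal clamp).

    Used as the default initial condition for all stimulated scenarios: the
    cell senses unfavourable conditions but is not yet committed.  Cached on
    the model instance (models are treated as immutable).
    """
    if ss is None:
        ss = model.params["SS_in"]
    key = ("basal", ss)
    if key not in model._cache:
        st = steady_state(model, iptg=0.0, ss=ss, guess=np.zeros(len(FORMS)))
        model._cache[key] = st.state
    return model._cache[key]
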