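"""Numerical machinery: integration, summaries, stability, equilibria, scans.

The monolayer system is linear, so in addition to the generic adaptive
integrator an exact matrix-exponential propagator is provided; it is the
fast path used by the treatment-parameter grid search.  Spheroid equilibria
are found by a squared-variable least-squares root solve (which enforces
nonnegativity without constraints) seeded from a long forward integration,
and the bifurcation scan continues that solution along an apoptosis-rate
grid for each treatment intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import least_squares

from .model_core import (
    ModelDomainError,
    MonolayerParams,
    MonolayerState,
    SpheroidParams,
    SpheroidState,
    f_fraction,
    monolayer_matrix,
    monolayer_odes,
    spheroid_odes,
)

__all__ = [
    "IntegrationError",
    "Trajectory",
    "StabilityReport",
    "EquilibriumResult",
    "BifurcationCurve",
    "integrate",
    "monolayer_propagator",
    "propagate_monolayer",
    "monolayer_summary",
    "summarize_monolayer_state",
    "classify_monolayer_stability",
    "solve_equilibrium",
    "equilibrium_by_integration",
    "check_equilibrium_relation",
    "bifurcation_scan",
    "MORTALITY_CONVENTIONS",
    "DEFAULT_SPHEROID_SEED",
    "DEFAULT_C2_SCALES",
]

#: How "computed mortality" is read off the monolayer run at a given time.
#: ``dead_over_live`` (default) expresses the cumulative dead volume D as a
#: percentage of the live total, the convention that reproduces the printed
#: treated-monolayer mortalities; ``dead_over_total`` uses D/(D + live) (a
#: dead fraction of all cells, as in a flow-cytometry gate), and
#: ``dead_over_initial`` uses the initial total as denominator.
MORTALITY_CONVENTIONS = ("dead_over_live", "dead_over_total", "dead_over_initial")

_NONNEG_TOL = 1e-9

#: Standard spheroid seed state: the first observed volume (3.59e6 um^3 at
#: data day 2), all cells cycling, split by the limiting phase proportions.
DEFAULT_SPHEROID_SEED = SpheroidState(2.26, 0.969, 0.359, 0.0, 0.0)


class IntegrationError(RuntimeError):
    """Solver failure; carries the last good state and time."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass
class Trajectory:
    """A solved time course: ``states[i]`` is the state at ``times[i]``.

    ``states`` has one row per time point; columns are (G1, S, G2, D) for
    the monolayer or (G1, S, G2, Q, N) for the spheroid.
    """

    times: np.ndarray
    states: np.ndarray
    model_tag: str

    _COLUMNS = {"monolayer": ["G1", "S", "G2", "D"], "spheroid": ["G1", "S", "G2", "Q", "N"]}

    def state_at(self, t: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise ModelDomainError(f"time {t} is not among the trajectory output points")
        return self.states[idx[0]]

    def totals(self) -> np.ndarray:
        """Live total (monolayer) or total volume T (spheroid) at each time."""
        if self.model_tag == "monolayer":
            return self.states[:, :3].sum(axis=1)
        return self.states.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self._COLUMNS[self.model_tag])
        df.insert(0, "time_days", self.times)
        return df


@dataclass(frozen=True)
class StabilityReport:
    """Routh-Hurwitz analysis of the monolayer characteristic polynomial.

    lam^3 + a2 lam^2 + a1 lam + a0 with a0 = c1 cS (da - c2),
    a1 = c1 cS + c1 (c2 + da) + cS (c2 + da), a2 = c1 + cS + c2 + da.
    All roots have negative real part iff a0 > 0 (the other Routh-Hurwitz
    conditions hold automatically for positive rates), i.e. the culture
    dies out iff c2 < da; c2 = da is the extinction threshold.
    """

    a0: float
    a1: float
    a2: float
    verdict: str  # "persists" | "dies_out" | "critical"
    dominant_eigenvalue: float


@dataclass(frozen=True)
class EquilibriumResult:
    """A steady state of the spheroid system."""

    state: SpheroidState
    residual_norm: float
    converged: bool


@dataclass
class BifurcationCurve:
    """Equilibria along an apoptosis-rate grid at one treatment intensity."""

    c2_scale: float
    da_values: np.ndarray
    equilibria: List[EquilibriumResult]
    critical_da: float  # the monolayer extinction threshold c2,new

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for da, eq in zip(self.da_values, self.equilibria):
            s = eq.state
            rows.append(
                {
                    "c2_scale": self.c2_scale,
                    "da": da,
                    "G1": s.G1,
                    "S": s.S,
                    "G2": s.G2,
                    "Q": s.Q,
                    "N": s.N,
                    "P": s.P,
                    "T": s.T,
                    "converged": eq.converged,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _as_init(model: str, init) -> np.ndarray:
    if isinstance(init, MonolayerState):
        y0 = init.as_array()
    elif isinstance(init, SpheroidState):
        y0 = init.as_array()
    else:
        y0 = np.asarray(init, dtype=float)
        if model == "monolayer" and y0.size == 3:
            y0 = np.append(y0, 0.0)
    expected = 4 if model == "monolayer" else 5
    if y0.size != expected:
        raise ModelDomainError(f"{model} initial state needs {expected} components")
    if y0.min() < 0:
        raise ModelDomainError("initial state must be nonnegative")
    return y0


def integrate(
    model: str,
    params: Union[MonolayerParams, SpheroidParams],
    init,
    t_span: Sequence[float],
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate either model over ``t_span`` (days), sampling at ``t_eval``.

    Adaptive, stiff-capable (LSODA by default; Radau accepted).  Output
    states are checked for nonnegativity to within 1e-9 and clipped at zero.
    """
    if model not in ("monolayer", "spheroid"):
        raise ModelDomainError(f"unknown model tag {model!r}")
    t0, t1 = float(t_span[0]), float(t_span[-1])
    if not t1 > t0:
        raise ModelDomainError("t_span must have positive length")
    y0 = _as_init(model, init)
    rhs = monolayer_odes(params) if model == "monolayer" else spheroid_odes(params)
    sol = solve_ivp(
        rhs, (t0, t1), y0, t_eval=t_eval, rtol=rtol, atol=atol, method=method
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}", sol.t[-1] if sol.t.size else t0,
            sol.y[:, -1] if sol.t.size else y0,
        )
    states = sol.y.T
    if states.min() < -_NONNEG_TOL:
        raise IntegrationError(
            f"negative compartment beyond tolerance: min={states.min():.3e}",
            sol.t[-1], states[-1],
        )
    return Trajectory(times=sol.t, states=np.maximum(states, 0.0), model_tag=model)


def monolayer_propagator(params: MonolayerParams, t: float) -> np.ndarray:
    """Exact 4x4 propagator e^(At) for (G1, S, G2, D) of the linear model."""
    A = np.zeros((4, 4))
    A[:3, :3] = monolayer_matrix(params)
    A[3, 2] = params.da
    return expm(A * t)


def propagate_monolayer(
    params: MonolayerParams, init: MonolayerState, t: float
) -> MonolayerState:
    """Closed-form monolayer solution at time ``t`` (days) via expm."""
    y = monolayer_propagator(params, t) @ init.as_array()
    return MonolayerState.from_array(y)


# ---------------------------------------------------------------------------
# Monolayer summaries and stability
# ---------------------------------------------------------------------------


def summarize_monolayer_state(
    state: MonolayerState,
    mortality_convention: str = "dead_over_live",
    initial_total: Optional[float] = None,
) -> dict:
    """Live total, phase percentages of live cells, and mortality percent."""
    if mortality_convention not in MORTALITY_CONVENTIONS:
        raise ModelDomainError(
            f"unknown mortality convention {mortality_convention!r}; "
            f"choose one of {MORTALITY_CONVENTIONS}"
        )
    live = state.live_total
    if live <= 0:
        raise ModelDomainError("live total must be positive for a phase breakdown")
    if mortality_convention == "dead_over_live":
        mortality = 100.0 * state.D / live
    elif mortality_convention == "dead_over_total":
        mortality = 100.0 * state.D / (state.D + live)
    else:  # dead_over_initial
        if initial_total is None:
            raise ModelDomainError("dead_over_initial requires initial_total")
        mortality = 100.0 * state.D / initial_total
    return {
        "live_total": live,
        "pct_g1": 100.0 * state.G1 / live,
        "pct_s": 100.0 * state.S / live,
        "pct_g2": 100.0 * state.G2 / live,
        "mortality": mortality,
    }


def monolayer_summary(
    traj: Trajectory, at: float, mortality_convention: str = "dead_over_live"
) -> dict:
    """Summary statistics of a monolayer trajectory at output time ``at``."""
    if traj.model_tag != "monolayer":
        raise ModelDomainError("monolayer_summary needs a monolayer trajectory")
    state = MonolayerState.from_array(traj.state_at(at))
    return summarize_monolayer_state(
        state, mortality_convention, initial_total=traj.states[0, :3].sum()
    )


def classify_monolayer_stability(params: MonolayerParams) -> StabilityReport:
    """Routh-Hurwitz persistence verdict plus the dominant eigenvalue.

    The verdict is decided algebraically from the sign of
    a0 = c1 cS (da - c2); the dominant eigenvalue of the rate matrix is
    computed independently as a cross-check (their signs agree for any
    positive rates -- asserted by the property tests, not here).
    """
    c1, cS, c2, da = params.c1, params.cS, params.c2, params.da
    a0 = c1 * cS * (da - c2)
    a1 = c1 * cS + c1 * (c2 + da) + cS * (c2 + da)
    a2 = c1 + cS + c2 + da
    if abs(c2 - da) <= 1e-9 * max(1.0, c2, da):
        verdict = "critical"
    elif c2 > da:
        verdict = "persists"
    else:
        verdict = "dies_out"
    eigs = np.linalg.eigvals(monolayer_matrix(params))
    dominant = float(np.max(eigs.real))
    return StabilityReport(a0=a0, a1=a1, a2=a2, verdict=verdict, dominant_eigenvalue=dominant)


# ---------------------------------------------------------------------------
# Spheroid equilibria
# ---------------------------------------------------------------------------


def equilibrium_by_integration(
    params: SpheroidParams, init: SpheroidState, t_final: float = 2000.0
) -> SpheroidState:
    """Endpoint of a long forward integration (an attractor estimate)."""
    traj = integrate("spheroid", params, init, (0.0, t_final), t_eval=[t_final],
                     rtol=1e-10, atol=1e-12)
    return SpheroidState.from_array(traj.states[-1])


def solve_equilibrium(
    params: SpheroidParams,
    guess: Optional[SpheroidState] = None,
    residual_tol: float = 1e-8,
) -> EquilibriumResult:
    """Root-solve the spheroid RHS with nonnegativity built in.

    The solve is performed in square-root variables (y = z^2), which keeps
    every compartment nonnegative without explicit constraints.  ``guess``
    seeds the solver; a guess at the origin stays at the origin (which is
    always an equilibrium).  Without a guess, the endpoint of a 2000-day
    integration from the standard day-2 seed state is polished instead.
    """
    if guess is None:
        guess = equilibrium_by_integration(params, DEFAULT_SPHEROID_SEED)
    rhs = spheroid_odes(params)
    y_guess = guess.as_array()
    if y_guess.min() < 0:
        raise ModelDomainError("guess must be nonnegative")
    if np.all(y_guess == 0.0):
        return EquilibriumResult(SpheroidState(0, 0, 0, 0, 0), 0.0, True)
    z0 = np.sqrt(y_guess)
    res = least_squares(
        lambda z: rhs(0.0, z * z), z0, xtol=3e-16, ftol=3e-16, gtol=3e-16,
        max_nfev=2000,
    )
    y = res.x * res.x
    residual = float(np.max(np.abs(rhs(0.0, y))))
    return EquilibriumResult(
        state=SpheroidState.from_array(y),
        residual_norm=residual,
        converged=bool(residual < residual_tol),
    )


def check_equilibrium_relation(eq: EquilibriumResult, params: SpheroidParams) -> float:
    """Residual of the steady-state mass balance (c2 (1-2F*) - da) G2* = m N*.

    For da = 0 this is algebraically equivalent to the closed-form relation
    G2* = (m/c2) N* (sn + N*)/(sn - N*), which requires sn > N* for a live
    equilibrium to exist.
    """
    s = eq.state
    if abs(params.sn - s.N) < 1e-12 * params.sn:
        raise ModelDomainError("sn equals N*: the closed-form relation is singular")
    cyc = params.cycle
    F = f_fraction(s.N, params.sn)
    return abs((cyc.c2 * (1.0 - 2.0 * F) - cyc.da) * s.G2 - params.m * s.N)


# ---------------------------------------------------------------------------
# Bifurcation scan
# ---------------------------------------------------------------------------

DEFAULT_C2_SCALES = (1.0, 0.47, 0.29, 0.19, 0.001)


def bifurcation_scan(
    params: SpheroidParams,
    c2_scales: Sequence[float] = DEFAULT_C2_SCALES,
    da_step: float = 0.005,
    da_grids: Optional[dict] = None,
    init: Optional[SpheroidState] = None,
) -> List[BifurcationCurve]:
    """Track the spheroid equilibrium along a da grid per treatment intensity.

    For each ``c2`` scaling the grid runs from 0 to 1.5x the monolayer
    extinction threshold c2,new (step ``da_step``, so the fitted treatment
    da values land on-grid; very small thresholds fall back to a 25-point
    linear grid).  Continuation: the first point is seeded from a long
    integration of the control system, each subsequent point from the
    previous equilibrium.  Non-converged points are flagged, never dropped.
    """
    if len(c2_scales) == 0:
        raise ModelDomainError("c2_scales must be non-empty")
    if init is None:
        init = DEFAULT_SPHEROID_SEED
    control_eq = equilibrium_by_integration(params, init)
    curves: List[BifurcationCurve] = []
    for scale in c2_scales:
        c2_new = params.cycle.c2 * scale
        if da_grids is not None and scale in da_grids:
            grid = np.asarray(da_grids[scale], dtype=float)
        elif 1.5 * c2_new > 10 * da_step:
            grid = np.arange(0.0, 1.5 * c2_new + 0.5 * da_step, da_step)
        else:
            grid = np.linspace(0.0, 1.5 * c2_new, 25)
        if grid.size == 0:
            raise ModelDomainError("empty da grid")
        seed = control_eq
        equilibria: List[EquilibriumResult] = []
        for da in grid:
            p = params.with_treatment(scale, float(da))
            eq = solve_equilibrium(p, guess=seed)
            equilibria.append(eq)
            if eq.converged:
                seed = eq.state
        curves.append(
            BifurcationCurve(
                c2_scale=float(scale),
                da_values=grid,
                equilibria=equilibria,
                critical_da=c2_new,
            )
        )
    return curves
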