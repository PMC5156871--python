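"""Parameter derivation from printed data.

Covers four distinct jobs:

* closed-form calibration of the cell-cycle rates from doubling time, phase
  proportions and death rate (the eigenvector relations of the linear
  model solved for c2, c1, cS in that order);
* geometry: converting spheroid diameters (mm) to volumes (1e6 um^3) and
  splitting a spheroid into live-rim and necrotic-core shells;
* fitting the two drug-action parameters (a multiplier on the division
  rate c2 and a new apoptosis rate da) to a 24 h flow-cytometry row by
  grid search plus Nelder-Mead refinement of the total percent error;
* fitting the spheroid quiescence parameters (cq, e) to a total-volume
  time series by nonlinear least squares, and tuning (m, sn) against a
  final-volume target with live/necrotic range constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .model_core import (
    CalibrationInput,
    CalibrationResult,
    ModelDomainError,
    MonolayerParams,
    MonolayerState,
    SpheroidParams,
    SpheroidState,
)
from . import simulate
from .simulate import DEFAULT_SPHEROID_SEED

__all__ = [
    "FitError",
    "GrowthObservation",
    "TreatmentObservation",
    "TreatmentFit",
    "growth_rate_from_doubling",
    "calibrate_cell_cycle",
    "volume_from_diameter",
    "shell_volumes",
    "fit_treatment_params",
    "fit_spheroid_cq_e",
    "tune_m_sn",
    "load_growth_observations",
    "load_treatment_observations",
]


class FitError(RuntimeError):
    """An optimiser failed to converge; the message carries diagnostics."""


# ---------------------------------------------------------------------------
# Observation records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthObservation:
    """One spheroid measurement: day, diameter (mm), optional viable-rim
    thickness (mm, recorded by light microscopy at the end of a trial)."""

    day: float
    diameter: float
    rim: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ModelDomainError("diameter must be positive")
        if self.rim is not None and not 0 < self.rim <= self.diameter / 2:
            raise ModelDomainError("rim must lie in (0, diameter/2]")

    @property
    def volume(self) -> float:
        return volume_from_diameter(self.diameter)


@dataclass(frozen=True)
class TreatmentObservation:
    """A 24 h flow-cytometry row: live-phase percentages and percent dead."""

    label: str
    pct_g1: float
    pct_s: float
    pct_g2: float
    pct_dead: float

    def __post_init__(self) -> None:
        for name in ("pct_g1", "pct_s", "pct_g2", "pct_dead"):
            if getattr(self, name) < 0:
                raise ModelDomainError(f"{name} must be >= 0")
        total = self.pct_g1 + self.pct_s + self.pct_g2
        if not 99.0 <= total <= 101.0:
            raise ModelDomainError(f"live-phase percents sum to {total}, expected ~100")


@dataclass(frozen=True)
class TreatmentFit:
    """Fitted drug action: ``c2_scale`` (multiplier on c2, in (0, 1]),
    ``da_new`` (per day), and the total-percent-error objective achieved."""

    c2_scale: float
    da_new: float
    objective: float

    def __post_init__(self) -> None:
        if not 0 < self.c2_scale <= 1.0:
            raise ModelDomainError("c2_scale must lie in (0, 1]")
        if self.da_new < 0:
            raise ModelDomainError("da_new must be >= 0")


# ---------------------------------------------------------------------------
# Closed-form cell-cycle calibration
# ---------------------------------------------------------------------------


def growth_rate_from_doubling(D_double: float) -> float:
    """Dominant growth rate lam = ln(2)/D of a culture doubling every D days."""
    if D_double <= 0:
        raise ModelDomainError("doubling time must be positive")
    return math.log(2.0) / D_double


def calibrate_cell_cycle(inp: CalibrationInput) -> CalibrationResult:
    """Solve the eigenvector relations for the cycle rates in closed form.

    With lam = ln(2)/D and the limiting phase proportions (g1*, s*, g2*):

        c2 = (lam + da g2*) / g2*
        c1 = (2 c2 g2* - lam g1*) / g1*
        cS = (c1 g1* - lam s*) / s*

    The resulting rate matrix has dominant eigenvalue lam with eigenvector
    proportional to the proportions (the round-trip property).
    """
    lam = growth_rate_from_doubling(inp.D_double)
    g1, s, g2, da = inp.g1_star, inp.s_star, inp.g2_star, inp.da
    c2 = (lam + da * g2) / g2
    c1 = (2.0 * c2 * g2 - lam * g1) / g1
    cS = (c1 * g1 - lam * s) / s
    if min(c1, cS, c2) < 0:
        raise ModelDomainError(
            f"calibration infeasible: negative rate among c1={c1}, cS={cS}, c2={c2}"
        )
    return CalibrationResult(lam=lam, params=MonolayerParams(c1=c1, cS=cS, c2=c2, da=da))


# ---------------------------------------------------------------------------
# Spheroid geometry
# ---------------------------------------------------------------------------

#: mm^3 expressed in units of 1e6 um^3.
_MM3_TO_1E6_UM3 = 1000.0


def volume_from_diameter(diameter: float) -> float:
    """Sphere volume (pi/6) d^3, converted from mm to 1e6 um^3."""
    if diameter < 0:
        raise ModelDomainError("diameter must be >= 0")
    return math.pi / 6.0 * diameter**3 * _MM3_TO_1E6_UM3


def shell_volumes(diameter: float, rim: float) -> Tuple[float, float]:
    """Split a spheroid into (live, necrotic) volumes from its viable rim.

    The necrotic core is the inner sphere of diameter ``diameter - 2 rim``;
    the live shell is the remainder, so live + necrotic equals the total
    exactly.  A rim of half the diameter means no core.
    """
    if not 0 < rim <= diameter / 2:
        raise ModelDomainError("rim must lie in (0, diameter/2]")
    total = volume_from_diameter(diameter)
    necrotic = volume_from_diameter(diameter - 2.0 * rim)
    return total - necrotic, necrotic


# ---------------------------------------------------------------------------
# Treatment-parameter fitting (monolayer, 24 h)
# ---------------------------------------------------------------------------

#: Default search grids: c2 multiplier log-spaced over (0.001, 1], da on a
#: fine linear grid -- wide enough to bracket every fitted intensity.
DEFAULT_C2_SCALE_GRID = np.logspace(-3, 0, 200)
DEFAULT_DA_GRID = np.arange(0.0, 2.0 + 1e-12, 0.01)

_DEFAULT_T2_INITIAL = MonolayerState(62.87, 26.93, 10.30)


def _treatment_objective(
    c2_scale: float,
    da: float,
    obs: TreatmentObservation,
    base: MonolayerParams,
    init: MonolayerState,
    mortality_convention: str,
    hours: float = 24.0,
) -> float:
    params = base.with_treatment(c2_scale, da)
    end = simulate.propagate_monolayer(params, init, hours / 24.0)
    summ = simulate.summarize_monolayer_state(
        end, mortality_convention, initial_total=init.live_total
    )
    return (
        abs(summ["pct_g1"] - obs.pct_g1)
        + abs(summ["pct_s"] - obs.pct_s)
        + abs(summ["pct_g2"] - obs.pct_g2)
        + abs(summ["mortality"] - obs.pct_dead)
    )


def fit_treatment_params(
    obs: TreatmentObservation,
    base: MonolayerParams,
    c2_scale_grid: Optional[Sequence[float]] = None,
    da_grid: Optional[Sequence[float]] = None,
    init: MonolayerState = _DEFAULT_T2_INITIAL,
    mortality_convention: str = "dead_over_live",
    refine: bool = True,
) -> TreatmentFit:
    """Fit (c2_scale, da) to one observed treatment row.

    Scores each grid candidate by the total percent error -- the sum of
    absolute percentage-point deviations in %G1, %S, %G2 and mortality
    after a 24 h run (solved exactly by the matrix exponential) -- then
    polishes the best grid point with Nelder-Mead, clipped to the grid's
    bounding box.  Deterministic throughout.
    """
    scales = DEFAULT_C2_SCALE_GRID if c2_scale_grid is None else np.asarray(c2_scale_grid, float)
    das = DEFAULT_DA_GRID if da_grid is None else np.asarray(da_grid, float)
    if scales.size == 0 or das.size == 0:
        raise FitError("empty search grid")

    best = (math.inf, math.nan, math.nan)
    for sc in scales:
        for da in das:
            val = _treatment_objective(sc, da, obs, base, init, mortality_convention)
            if val < best[0]:
                best = (val, float(sc), float(da))
    obj, sc_best, da_best = best

    if refine:
        lo_s, hi_s = float(scales.min()), float(scales.max())
        lo_d, hi_d = float(das.min()), float(das.max())

        def clipped(z):
            sc = min(max(z[0], lo_s), hi_s)
            da = min(max(z[1], lo_d), hi_d)
            return _treatment_objective(sc, da, obs, base, init, mortality_convention)

        res = minimize(clipped, [sc_best, da_best], method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-8})
        if res.fun < obj:
            obj = float(res.fun)
            sc_best = float(min(max(res.x[0], lo_s), hi_s))
            da_best = float(min(max(res.x[1], lo_d), hi_d))

    return TreatmentFit(c2_scale=sc_best, da_new=da_best, objective=obj)


# ---------------------------------------------------------------------------
# Spheroid fitting
# ---------------------------------------------------------------------------


def _series_to_arrays(series: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    """Accepts GrowthObservation records or (day, volume) pairs.

    Data days are converted to model time (t = day - first_day; the first
    observation defines t = 0)."""
    days, vols = [], []
    for rec in series:
        if isinstance(rec, GrowthObservation):
            days.append(rec.day)
            vols.append(rec.volume)
        else:
            d, v = rec
            days.append(float(d))
            vols.append(float(v))
    days = np.asarray(days, float)
    vols = np.asarray(vols, float)
    order = np.argsort(days)
    days, vols = days[order], vols[order]
    return days - days[0], vols


def _total_volume_curve(params: SpheroidParams, init: SpheroidState,
                        t_eval: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    traj = simulate.integrate(
        "spheroid", params, init, (0.0, float(t_eval[-1]) if t_eval[-1] > 0 else 1.0),
        t_eval=t_eval, rtol=rtol, atol=rtol * 1e-2,
    )
    return traj.totals()


def fit_spheroid_cq_e(
    series: Sequence,
    fixed: SpheroidParams,
    init: SpheroidState = DEFAULT_SPHEROID_SEED,
    start: Tuple[float, float] = (0.1, 0.5),
    bounds: Tuple[float, float] = (0.0, 10.0),
    rtol: float = 1e-8,
) -> Tuple[float, float, float]:
    """Least-squares fit of (cq, e) to a total-volume time series.

    All other parameters are held at ``fixed``; residuals are the raw
    differences between the simulated total volume T and the observed
    volumes at the observation days.  Deterministic given the fixed start
    point (no stochastic restarts).  Returns (cq, e, sum of squared
    residuals).
    """
    t_eval, vols = _series_to_arrays(series)
    if t_eval.size < 4:
        raise ModelDomainError("need at least 4 observations to fit (cq, e)")

    def residuals(z: np.ndarray) -> np.ndarray:
        p = SpheroidParams(
            cycle=fixed.cycle, cq=float(z[0]), sn=fixed.sn, e=float(z[1]),
            m=fixed.m, s1=fixed.s1, sq=fixed.sq,
        )
        return _total_volume_curve(p, init, t_eval, rtol=rtol) - vols

    res = least_squares(residuals, np.asarray(start, float),
                        bounds=([bounds[0]] * 2, [bounds[1]] * 2))
    if not res.success:
        raise FitError(f"least squares did not converge: status={res.status}, "
                       f"message={res.message!r}, x={res.x}")
    ssr = float(2.0 * res.cost)
    return float(res.x[0]), float(res.x[1]), ssr


def tune_m_sn(
    series: Sequence,
    fixed: SpheroidParams,
    target_final_T: float = 36.0,
    live_range: Tuple[float, float] = (20.5, 31.25),
    necrotic_range: Tuple[float, float] = (4.85, 15.6),
    m_grid: Optional[Sequence[float]] = None,
    sn_grid: Optional[Sequence[float]] = None,
    init: SpheroidState = DEFAULT_SPHEROID_SEED,
    horizon: float = 29.0,
) -> Tuple[float, float]:
    """Prioritised tuning of the necrosis parameters (m, sn).

    Primary objective: final total volume T(horizon) close to the target;
    secondary: live (T - N) and necrotic (N) end volumes inside the
    reported ranges (penalty = distance outside the range).  Candidates
    within 0.1 volume units of the best primary objective are re-ranked by
    the secondary penalty.  The sn grid starts near twice the largest
    observed volume.  The returned pair is verified to admit a live
    equilibrium (sn > N*); violating candidates are discarded.
    """
    _, vols = _series_to_arrays(series)
    v_max = float(vols.max())
    if m_grid is None:
        m_grid = np.linspace(0.02, 0.12, 21)
    if sn_grid is None:
        # centred on ~2x the largest observed volume, per the tuning recipe
        sn_grid = np.linspace(0.75 * 2 * v_max, 1.5 * 2 * v_max, 28)
    if live_range[0] > live_range[1] or necrotic_range[0] > necrotic_range[1]:
        raise ModelDomainError("infeasible (inverted) target ranges")

    scored = []
    for m in m_grid:
        for sn in sn_grid:
            p = SpheroidParams(cycle=fixed.cycle, cq=fixed.cq, sn=float(sn),
                               e=fixed.e, m=float(m), s1=fixed.s1, sq=fixed.sq)
            traj = simulate.integrate("spheroid", p, init, (0.0, horizon),
                                      t_eval=[horizon], rtol=1e-7, atol=1e-9)
            end = traj.states[-1]
            T_end = float(end.sum())
            N_end = float(end[4])
            live_end = T_end - N_end
            penalty = (
                max(0.0, live_range[0] - live_end)
                + max(0.0, live_end - live_range[1])
                + max(0.0, necrotic_range[0] - N_end)
                + max(0.0, N_end - necrotic_range[1])
            )
            scored.append((abs(T_end - target_final_T), penalty, float(m), float(sn)))

    scored.sort()
    best_primary = scored[0][0]
    candidates = sorted(
        (s for s in scored if s[0] <= best_primary + 0.1), key=lambda s: (s[1], s[0])
    )
    for _, _, m, sn in candidates:
        p = SpheroidParams(cycle=fixed.cycle, cq=fixed.cq, sn=sn, e=fixed.e,
                           m=m, s1=fixed.s1, sq=fixed.sq)
        eq = simulate.solve_equilibrium(
            p, guess=simulate.equilibrium_by_integration(p, init, t_final=500.0)
        )
        if eq.converged and p.sn > eq.state.N:
            return m, sn
    raise FitError(
        "no (m, sn) candidate satisfies the live-equilibrium condition sn > N*"
    )


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------


def load_growth_observations(path) -> list:
    """Read a growth CSV with headers day,diameter_mm[,rim_mm]."""
    df = pd.read_csv(path)
    recs = []
    for _, row in df.iterrows():
        rim = row.get("rim_mm")
        rim = None if rim is None or pd.isna(rim) else float(rim)
        recs.append(GrowthObservation(day=float(row["day"]),
                                      diameter=float(row["diameter_mm"]), rim=rim))
    return recs


def load_treatment_observations(path) -> list:
    """Read a treatment CSV with headers label,pct_g1,pct_s,pct_g2,pct_dead."""
    df = pd.read_csv(path)
    return [
        TreatmentObservation(
            label=str(row["label"]), pct_g1=float(row["pct_g1"]),
            pct_s=float(row["pct_s"]), pct_g2=float(row["pct_g2"]),
            pct_dead=float(row["pct_dead"]),
        )
        for _, row in df.iterrows()
    ]
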