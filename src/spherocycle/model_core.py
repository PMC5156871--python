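"""State and parameter types plus the exact right-hand sides of both growth models.

Two coupled compartment models of tumor growth are defined here:

* a **linear monolayer model** of the cell cycle, with compartments G1, S and
  G2 (G2 and M pooled, matching flow-cytometry readouts), in which cells
  transition G1 -> S -> G2 at first-order rates and divide (G2 -> 2 G1) at
  rate ``c2``, with an optional apoptosis rate ``da`` acting at G2/M; and
* a **nonlinear spheroid model** that extends the cell cycle with a quiescent
  compartment Q and a necrotic core N.  Three saturating functional responses
  couple the compartments: ``B`` (fraction of G1 cells that stay in cycle
  rather than going quiescent, controlled by surface area ~ T^(2/3)),
  ``C`` (rate of quiescent cells re-entering S when nutrient is unblocked)
  and ``F`` (fraction of divisions ending in apoptosis, driven by necrosis
  via tumor necrosis factor).

All spheroid volumes are expressed in units of 1e6 um^3; monolayer amounts
are an arbitrary index (conventionally normalised so the initial total is
100); time is in days and every rate is per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelDomainError",
    "MonolayerParams",
    "MonolayerState",
    "CalibrationInput",
    "CalibrationResult",
    "SpheroidParams",
    "SpheroidState",
    "b_fraction",
    "c_rate",
    "f_fraction",
    "monolayer_rhs",
    "spheroid_rhs",
    "monolayer_matrix",
    "monolayer_odes",
    "spheroid_odes",
]


class ModelDomainError(ValueError):
    """An input lies outside the mathematical domain of the model."""


# ---------------------------------------------------------------------------
# Parameter and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonolayerParams:
    """The four first-order rates of the linear cell-cycle model (per day).

    ``c1``: G1 -> S transition; ``cS``: S -> G2; ``c2``: G2/M exit
    (division); ``da``: apoptosis at G2/M (0 for an untreated culture).
    All rates must be nonnegative; c1, cS, c2 strictly positive for a
    nondegenerate cycle (zero values are permitted so that degenerate
    calibrations, e.g. a non-growing culture, remain representable).
    """

    c1: float
    cS: float
    c2: float
    da: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c1", "cS", "c2", "da"):
            if getattr(self, name) < 0:
                raise ModelDomainError(f"rate {name} must be >= 0")

    def with_treatment(self, c2_scale: float, da_new: float) -> "MonolayerParams":
        """Return rates with ``c2`` scaled and ``da`` replaced (drug action)."""
        return replace(self, c2=self.c2 * c2_scale, da=da_new)


@dataclass(frozen=True)
class MonolayerState:
    """Monolayer compartment amounts, plus a cumulative-dead accumulator.

    ``D`` integrates the apoptosis flux ``da*G2``; it is bookkeeping for
    mortality readouts, not part of the dynamical system itself.
    """

    G1: float
    S: float
    G2: float
    D: float = 0.0

    @property
    def live_total(self) -> float:
        return self.G1 + self.S + self.G2

    def as_array(self, include_dead: bool = True) -> np.ndarray:
        if include_dead:
            return np.array([self.G1, self.S, self.G2, self.D], dtype=float)
        return np.array([self.G1, self.S, self.G2], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "MonolayerState":
        y = np.asarray(y, dtype=float)
        return cls(*y) if y.size == 4 else cls(y[0], y[1], y[2])


@dataclass(frozen=True)
class CalibrationInput:
    """Observables that determine the monolayer rates in closed form.

    ``g1_star, s_star, g2_star`` are the limiting (equals initial, for an
    unsynchronised culture) proportions of live cells in each phase; they
    must sum to 1.  ``D_double`` is the doubling time in days and ``da``
    the death rate (per day) observed for the culture.
    """

    g1_star: float
    s_star: float
    g2_star: float
    D_double: float
    da: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g1_star", "s_star", "g2_star"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ModelDomainError(f"proportion {name}={p} must lie in (0, 1)")
        total = self.g1_star + self.s_star + self.g2_star
        if abs(total - 1.0) > 1e-9:
            raise ModelDomainError(f"phase proportions sum to {total}, expected 1")
        if self.D_double <= 0:
            raise ModelDomainError("doubling time must be positive")
        if self.da < 0:
            raise ModelDomainError("death rate must be >= 0")

    @classmethod
    def from_percent(
        cls, g1: float, s: float, g2: float, D_double: float, da: float = 0.0
    ) -> "CalibrationInput":
        """Build from phase percentages (as printed in flow-cytometry tables)."""
        return cls(g1 / 100.0, s / 100.0, g2 / 100.0, D_double, da)


@dataclass(frozen=True)
class CalibrationResult:
    """Dominant growth rate ``lam = ln(2)/D`` and the calibrated rates."""

    lam: float
    params: MonolayerParams


@dataclass(frozen=True)
class SpheroidParams:
    """Spheroid model parameters: the cycle rates plus the coupling constants.

    ``cq``: maximum Q -> S return rate (per day); ``s1``/``sq``: offsets in
    the saturating responses B and C (on the T^(2/3) scale; near zero they
    make B and C behave almost like direct proportions); ``sn``: necrosis
    half-saturation volume for F (1e6 um^3) -- it must exceed the necrotic
    equilibrium volume for a live equilibrium to exist; ``e``: Q -> N death
    rate (per day); ``m``: necrotic dissolution rate (per day).
    """

    cycle: MonolayerParams
    cq: float
    sn: float
    e: float
    m: float
    s1: float = 0.0001
    sq: float = 0.0001

    def __post_init__(self) -> None:
        for name in ("cq", "sn", "e", "m", "s1", "sq"):
            if getattr(self, name) < 0:
                raise ModelDomainError(f"parameter {name} must be >= 0")
        if self.sn <= 0:
            raise ModelDomainError("sn must be > 0")

    def with_treatment(self, c2_scale: float, da_new: float) -> "SpheroidParams":
        return replace(self, cycle=self.cycle.with_treatment(c2_scale, da_new))


@dataclass(frozen=True)
class SpheroidState:
    """Spheroid compartment volumes (1e6 um^3)."""

    G1: float
    S: float
    G2: float
    Q: float
    N: float

    @property
    def P(self) -> float:
        """Live, non-quiescent (cycling) volume."""
        return self.G1 + self.S + self.G2

    @property
    def T(self) -> float:
        """Total spheroid volume, the sum of all compartments."""
        return self.P + self.Q + self.N

    def as_array(self) -> np.ndarray:
        return np.array([self.G1, self.S, self.G2, self.Q, self.N], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpheroidState":
        return cls(*np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# Functional responses
# ---------------------------------------------------------------------------


def b_fraction(G1: float, T: float, s1: float) -> float:
    """Fraction of G1 cells remaining in cycle: B = T^(2/3) / (s1 + G1 + T^(2/3)).

    Surface area scales as T^(2/3); when it is large relative to the G1
    pool, nutrient reaches the cycling cells and B -> 1.  When G1 dominates,
    B -> 0 and the excess is routed to quiescence.  Value lies in [0, 1);
    B = 0 exactly at T = 0 (an empty spheroid recruits nobody).
    """
    if T < 0 or G1 < 0:
        raise ModelDomainError("volumes must be >= 0")
    if s1 <= 0:
        raise ModelDomainError("s1 must be > 0")
    if T == 0.0:
        return 0.0
    a = T ** (2.0 / 3.0)
    return a / (s1 + G1 + a)


def c_rate(P: float, T: float, cq: float, sq: float) -> float:
    """Q -> S return rate: C = cq * T^(2/3) / (sq + P + T^(2/3)).

    Saturates at ``cq`` when surface area dwarfs the cycling volume P and
    vanishes when P blocks nutrient access.  Value lies in [0, cq).
    """
    if P < 0 or T < 0:
        raise ModelDomainError("volumes must be >= 0")
    if cq < 0:
        raise ModelDomainError("cq must be >= 0")
    if sq <= 0:
        raise ModelDomainError("sq must be > 0")
    if T == 0.0:
        return 0.0
    a = T ** (2.0 / 3.0)
    return cq * a / (sq + P + a)


def f_fraction(N: float, sn: float) -> float:
    """Fraction of divisions ending in apoptosis: F = N / (sn + N).

    Phenomenological action of tumor necrosis factor, assumed proportional
    to the necrotic volume.  Value in [0, 1), increasing in N, F(sn) = 1/2.
    """
    if N < 0:
        raise ModelDomainError("N must be >= 0")
    if sn <= 0:
        raise ModelDomainError("sn must be > 0")
    return N / (sn + N)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------


def monolayer_matrix(params: MonolayerParams) -> np.ndarray:
    """The 3x3 rate matrix A of the linear system (G1, S, G2)' = A (G1, S, G2)."""
    c1, cS, c2, da = params.c1, params.cS, params.c2, params.da
    return np.array(
        [
            [-c1, 0.0, 2.0 * c2],
            [c1, -cS, 0.0],
            [0.0, cS, -(c2 + da)],
        ]
    )


def monolayer_rhs(state: MonolayerState, params: MonolayerParams) -> MonolayerState:
    """Time derivative of the monolayer state.

    G1' = 2 c2 G2 - c1 G1;  S' = c1 G1 - cS S;  G2' = cS S - (c2 + da) G2.
    The dead accumulator evolves as D' = da * G2.  The live mass balance
    (G1 + S + G2)' = (c2 - da) G2 holds identically.
    """
    if min(state.G1, state.S, state.G2, state.D) < 0:
        raise ModelDomainError("state components must be >= 0")
    c1, cS, c2, da = params.c1, params.cS, params.c2, params.da
    return MonolayerState(
        G1=2.0 * c2 * state.G2 - c1 * state.G1,
        S=c1 * state.G1 - cS * state.S,
        G2=cS * state.S - (c2 + da) * state.G2,
        D=da * state.G2,
    )


def spheroid_rhs(
    state: SpheroidState,
    params: SpheroidParams,
    force_B: Optional[float] = None,
    force_C: Optional[float] = None,
    force_F: Optional[float] = None,
) -> SpheroidState:
    """Time derivative of the spheroid state.

    G1' = 2 c2 (1-F) G2 - c1 G1
    S'  = c1 B G1 + C Q - cS S
    G2' = cS S - (c2 + da) G2
    Q'  = c1 (1-B) G1 - C Q - e Q
    N'  = e Q - m N

    with B, C, F from :func:`b_fraction`, :func:`c_rate`, :func:`f_fraction`.
    The total mass balance T' = c2 (1 - 2F) G2 - da G2 - m N holds exactly.
    Division-apoptosis (c2 F G2) and treatment-death (da G2) volume leaves
    the system entirely; only quiescent death (e Q) feeds the necrotic core.

    ``force_B``/``force_C``/``force_F`` override the functional responses
    with constants; with B=1, C=F=0 the (G1, S, G2) block reduces exactly to
    the monolayer model.
    """
    y = state.as_array()
    if y.min() < 0:
        raise ModelDomainError("state components must be >= 0")
    cyc = params.cycle
    P, T = state.P, state.T
    B = b_fraction(state.G1, T, params.s1) if force_B is None else force_B
    C = c_rate(P, T, params.cq, params.sq) if force_C is None else force_C
    F = f_fraction(state.N, params.sn) if force_F is None else force_F
    return SpheroidState(
        G1=2.0 * cyc.c2 * (1.0 - F) * state.G2 - cyc.c1 * state.G1,
        S=cyc.c1 * B * state.G1 + C * state.Q - cyc.cS * state.S,
        G2=cyc.cS * state.S - (cyc.c2 + cyc.da) * state.G2,
        Q=cyc.c1 * (1.0 - B) * state.G1 - C * state.Q - params.e * state.Q,
        N=params.e * state.Q - params.m * state.N,
    )


# ---------------------------------------------------------------------------
# Array-valued RHS factories for the integrator (no per-call validation)
# ---------------------------------------------------------------------------


def monolayer_odes(params: MonolayerParams):
    """Return f(t, y) for y = (G1, S, G2, D), suitable for solve_ivp."""
    c1, cS, c2, da = params.c1, params.cS, params.c2, params.da

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        G1, S, G2 = y[0], y[1], y[2]
        return np.array(
            [
                2.0 * c2 * G2 - c1 * G1,
                c1 * G1 - cS * S,
                cS * S - (c2 + da) * G2,
                da * G2,
            ]
        )

    return rhs


def spheroid_odes(params: SpheroidParams):
    """Return f(t, y) for y = (G1, S, G2, Q, N), suitable for solve_ivp.

    The integrator may probe slightly negative states; responses are
    evaluated on the nonnegative part so the vector field stays defined.
    """
    c1, cS, c2, da = (
        params.cycle.c1,
        params.cycle.cS,
        params.cycle.c2,
        params.cycle.da,
    )
    cq, s1, sq, sn, e, m = params.cq, params.s1, params.sq, params.sn, params.e, params.m

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        G1, S, G2, Q, N = np.maximum(y, 0.0)
        P = G1 + S + G2
        T = P + Q + N
        if T > 0.0:
            a = T ** (2.0 / 3.0)
            B = a / (s1 + G1 + a)
            C = cq * a / (sq + P + a)
        else:
            B = 0.0
            C = 0.0
        F = N / (sn + N)
        return np.array(
            [
                2.0 * c2 * (1.0 - F) * G2 - c1 * G1,
                c1 * B * G1 + C * Q - cS * S,
                cS * S - (c2 + da) * G2,
                c1 * (1.0 - B) * G1 - C * Q - e * Q,
                e * Q - m * N,
            ]
        )

    return rhs
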