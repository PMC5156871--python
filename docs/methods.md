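# Methods

## The two models

**Monolayer.** Cells in a 2-D culture have uniform nutrient access and cycle
freely, so the population is modelled by a linear system over the cell-cycle
phases G1, S and G2 (G2 and M pooled, because flow cytometry reports them
together):

    G1' = 2 c2 G2 - c1 G1
    S'  = c1 G1 - cS S
    G2' = cS S - (c2 + da) G2

`c1`, `cS`, `c2` are per-day transition rates; division (G2 -> 2 G1) doubles
the exiting volume; `da` is an apoptosis rate acting at G2/M (zero for an
untreated culture). The live total obeys T' = (c2 - da) G2, so the culture
grows exponentially with dominant rate λ = ln 2 / D for doubling time D. A
cumulative accumulator D' = da·G2 tracks killed volume for mortality
readouts; it does not feed back into the dynamics.

**Spheroid.** A 3-D aggregate develops a proliferating rim, a quiescent
interior and a necrotic core, and stops growing on its own. The cycle block
is extended with quiescent (Q) and necrotic (N) compartments (volumes in
10^6 µm³):

    G1' = 2 c2 (1-F) G2 - c1 G1
    S'  = c1 B G1 + C Q - cS S
    G2' = cS S - (c2 + da) G2
    Q'  = c1 (1-B) G1 - C Q - e Q
    N'  = e Q - m N

with three saturating responses: `B = T^(2/3) / (s1 + G1 + T^(2/3))` (the
fraction of cells leaving G1 that stay in cycle; surface area ~ T^(2/3)
proxies nutrient supply), `C = cq T^(2/3) / (sq + P + T^(2/3))` (the Q -> S
return rate, throttled by the cycling volume P = G1+S+G2 that blocks
nutrient), and `F = N / (sn + N)` (the fraction of divisions ending in
apoptosis, a phenomenological account of tumor necrosis factor produced in
proportion to the necrotic volume). With B = 1 and C = F = 0 the cycling
block reduces exactly to the monolayer model — a property the test suite
asserts on random states.

Growth saturation needs no artificial ceiling: as N accumulates, F rises and
division-apoptosis balances birth. Summing the equations at steady state
gives (c2 (1-2F*) - da) G2* = m N*, which for da = 0 rearranges to
G2* = (m/c2) N* (sn + N*)/(sn - N*); a live equilibrium therefore requires
sn > N*. This identity is used both as a convergence check on solved
equilibria and to reject infeasible (m, sn) candidates during tuning.

**Where killed volume goes.** The fluxes c2·F·G2 and da·G2 leave the system
entirely rather than joining N; that is what the equations state, and the
package follows them. (Physically one might argue treatment-killed cells
should feed the necrotic core; the source equations do not do this, and the
end-state reproductions confirm they were run as written.) Note also an
internal inconsistency in the source prose: the text under the G1 equation
says fraction B of departing G1 cells enters Q, but the equations route
c1·B·G1 into S and c1·(1-B)·G1 into Q, and only that routing matches the
stated monotonicity of B. The equations are implemented.

## Parameters

| symbol | meaning | default | origin |
|---|---|---|---|
| c1, cS, c2 | cycle transition rates (/day) | 0.85, 1.59, 3.85 | closed-form calibration, printed at 2 dp |
| da | G2/M apoptosis (/day) | 0 (control) | observed control death rate |
| cq | max Q->S return (/day) | 0.1212 | fitted to growth record |
| e | Q->N death (/day) | 0.4898 | fitted to growth record |
| m | necrotic dissolution (/day) | 0.0528 | tuned to final volume |
| sn | necrosis half-saturation (1e6 µm³) | 61.0520 | tuned (must exceed N*) |
| s1, sq | response offsets | 0.0001 | chosen: nearly proportional response without a 0/0 at T=0 |

Treatment with the prostaglandin studied here blocks the G2/M -> G1
transition and induces apoptosis at that stage, so each concentration is a
pair (multiplier on c2, new da): (0.47, 0.60), (0.29, 0.59), (0.19, 0.87),
(0.001, 1.3) for 2/4/8/12 µM.

**Calibration.** The eigen relation A x* = λ x* with x* the limiting phase
proportions solves in closed form: c2 = (λ + da g2*)/g2*, then
c1 = (2 c2 g2* - λ g1*)/g1*, then cS = (c1 g1* - λ s*)/s*. For any valid
proportions all three rates are automatically positive (c1 g1* = λ(2-g1*) +
2 da g2* > 0, etc.). The exact recomputation from the printed observables
(proportions 62.87/26.93/10.20 %, D = 1.77 d, da = 0) gives (0.8542,
1.6025, 3.8393); the printed set (0.85, 1.59, 3.85) carries rounding slop
of up to one unit in its last digit (its printed λ = 0.40 likewise differs
from ln 2 / 1.77 = 0.3916). Simulations reproducing printed rows use the
2-dp printed rates, which an exact-propagator check shows is what produced
the printed control total (147.93 with those rates vs 148.16 with the
unrounded ones, printed 147.83).

**Mortality readout.** The printed tables never define "computed
mortality". Three conventions are implemented; an exact-solution comparison
against the printed treated rows identifies `100·D/live` as the one that
reproduces them (10.09 and 17.03 match to the printed precision), so it is
the default. The 12 µM printed value (26.25) instead equals `100·D/T(0)` —
the source is internally inconsistent at that dose; the convention is
configurable.

**Treatment fitting** minimises the total percent error — the sum of
absolute percentage-point deviations in %G1, %S, %G2 and mortality at 24 h —
over a log-spaced 200-point c2-multiplier grid on (0.001, 1] crossed with a
da grid 0–2 (step 0.01), then polishes with Nelder–Mead clipped to the
grid box. The 24 h endpoint is computed with the exact matrix exponential
of the (linear) augmented system, which makes the 40 000-candidate sweep
cheap and exact. On the observed 2 µM row the fit returns (0.460, 0.593),
consistent with the printed local best match (0.47, 0.60); the 4 µM row
returns (0.294, 0.588) against the printed (0.29, 0.59). At 8 µM the global
optimum (0.13, 0.77) improves on the printed pair, and the 12 µM objective
is far larger than the low-dose ones — the documented failure of the
two-parameter drug action at high dose.

**Spheroid fitting.** (cq, e) are fitted by bounded nonlinear least squares
(start (0.1, 0.5), bounds [0, 10]², no restarts) of simulated total volume
against the observed series. On data generated by the model itself the fit
recovers the generating pair exactly; that self-consistency, not the real
growth record, is what identifies the procedure, because on the real record
(with the other parameters fixed at their defaults) the unweighted optimum
drifts to cq ≈ 0 with a lower SSR than the printed pair — the original
fitting protocol evidently weighted the data differently (its optimiser and
settings are unstated). The printed pair remains the package default. The
(m, sn) tuning searches a grid (sn centred near twice the largest observed
volume), primarily minimising the final-volume mismatch, secondarily
penalising live/necrotic end volumes outside their reported ranges, and
discards candidates whose equilibrium violates sn > N*. Similarly, the
model with printed parameters matches both endpoints of the growth record
closely (T(29 d) = 35.94) while overshooting the intermediate days — the
cost of prioritising the endpoint fit.

## Numerics

- Integration: `scipy.integrate.solve_ivp`, LSODA, rtol 1e-8 / atol 1e-10.
  Results are invariant (< 0.01 %) under tolerance halving and under
  switching to Radau; output states are checked nonnegative to 1e-9 and
  clipped at zero. The linear monolayer model is additionally solved
  exactly via `expm`.
- Equilibria: least squares on the RHS in square-root variables (y = z²),
  which enforces nonnegativity without constraints, seeded by the endpoint
  of a 2000-day integration; `converged` requires max|RHS| < 1e-8. The
  origin is always an equilibrium and an origin seed stays there.
- Bifurcation scan: for each c2 intensity {1, 0.47, 0.29, 0.19, 0.001} the
  da grid runs 0 to 1.5× the monolayer extinction threshold c2,new in steps
  of 0.005 (so every fitted da is on-grid; a 25-point linear grid for the
  0.001 intensity, whose threshold is below the step size), with each solve
  seeded by the previous equilibrium (continuation from the control
  branch). Uniqueness is not assumed; the scan reports the branch the
  continuation follows. Non-converged points are flagged, never dropped.
- Stability: the verdict comes from the characteristic-polynomial
  coefficient a0 = c1 cS (da - c2) (the only Routh–Hurwitz condition not
  automatic for positive rates), with |c2 - da| ≤ 1e-9 (relative) classed
  critical; the dominant eigenvalue of the rate matrix is reported
  alongside and property-tested to agree in sign on 1000 random draws.
- Geometry: volumes from diameters via the sphere formula (π/6)d³ (mm³ →
  10^6 µm³); rim/core split by subtracting the inner sphere of diameter
  d - 2·rim, conserving total volume exactly. At the recorded rim range
  (50–150 µm, day 31) this gives a necrotic core of 15.6 down to 0.70 ×10^6
  µm³; the printed lower endpoint 4.85 corresponds to a ~100 µm rim, not
  150 µm, and cannot be reproduced by shell geometry — the formula is
  implemented, the discrepancy flagged here.
- Time alignment: data day d maps to model time t = d - 2; "end of run"
  means 29 model days (data day 31).

## In-silico experiment conventions

- The treatment-response comparison runs the monolayer 24 h and the
  spheroid 72 h, reporting treated/control × 100. The spheroid is treated
  from a **grown** state (the end of the 29-day control run) by default:
  an established spheroid is what the emulated wet-lab comparison treats,
  and a just-seeded day-2 aggregate — available via `start="day2"` — has
  no quiescent/necrotic bulk and responds even more than the monolayer.
  Under the total-volume readout the grown spheroid responds less than the
  monolayer at every dose (e.g. 90 % vs 81 % of control at 2 µM, 73 % vs
  50 % at 12 µM). Under the proliferating- or S-phase readouts it does
  **not**: the rim is hit harder than the monolayer, and the apparent
  resilience is entirely a bulk-volume effect of the quiescent and necrotic
  compartments. All three metrics are computed and reported.
- Long-term treatment sweeps da across ±10 % of each monolayer extinction
  threshold over 100 days from the day-2 volume (monolayer
  phase-proportioned to the same total). The monolayer flips between
  exponential growth and decay (end volumes spanning orders of magnitude);
  the spheroid — whose equilibrium collapses well below the monolayer
  threshold — decays gently toward near zero either way, its end volume
  moving by far less than the untreated equilibrium volume. At the 0.001
  intensity the near-threshold dynamics are too slow (|eigenvalue| ~1e-3 /
  day) for the contrast to develop in 100 days; it is reported but not
  asserted.

## Synthetic data

`generate_synthetic_growth` integrates the spheroid model at the
observation days and applies multiplicative lognormal noise, exp(ε) with
ε ~ N(0, σ²), per point from a seeded generator. It emulates the sampling
structure of the real record (seven sparse observation days, relative
measurement error on volumes); it does not emulate diameter-measurement
discretisation, between-spheroid biological variation, or model
misspecification — so parameter-recovery results certify the fitting
machinery, not the model's adequacy for real spheroids. Defaults: the seven
observed days, σ = 0.01 (about the relative precision of the reported
volumes); the recovery study refits 200 seeded replicates and checks the
median against the generating pair.

## Known limitations

- No spatial resolution (no PDE/agent-based geometry, no explicit oxygen or
  TNF-α fields); quiescence and necrosis act through aggregate volumes.
- The two-parameter drug action (scale c2, set da) demonstrably fails to
  capture the 12 µM cytometry row; conclusions at high dose rest on a poor
  fit.
- The printed (cq, e) cannot be re-derived from the printed growth record
  by plain least squares (above); the package treats them as given.
- Equilibrium continuation follows a single branch; disconnected branches,
  if any, would be missed.
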