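# Methods

This note records the models implemented in `smorepars`, the conventions
and numerical choices behind them, and what the synthetic-data experiments
do and do not demonstrate.

## Lattice ABM

The agent-based model is a 2D on-lattice birth–death–migration simulator.
The microenvironment for carrying capacity `K_A` is an `l × w` lattice with
`l = ceil(sqrt(K_A))`, `w = ceil(K_A / l)`, closed boundaries, and von
Neumann (4-site) neighborhoods. Simulations are initialized with `n0 = 100`
agents at distinct uniformly sampled sites, matching count data normalized
to 100 cells at t = 0; agents map 1:1 to measured cells.

Dynamics per time step of `dt` hours (default 0.25 h):

* Agents update in a fresh uniform random permutation each step; moves and
  divisions take effect immediately (sequential update). Each agent
  attempts at most one action per step, with phase advance taking priority
  over migration.
* A continuous rate ρ (per hour) becomes a per-step probability
  `1 − exp(−ρ·dt)` — exact for exponential waiting times and bounded in
  [0, 1) for any rate.
* On a successful G1→S or G2→M advance under drug concentration `C`, the
  agent instead arrests with probability `r_i·C^a/(γ₁^a + C^a)`. Arrested
  agents are absorbing: they neither cycle nor move, and die at rate
  `δ_p·C^b/(γ₂^b + C^b)`; flagged deaths are removed after all other
  updates in the step. The arrest bookkeeping records the bucket (G1/S vs
  G2/M) at arrest time so ABM output aligns with the surrogate's arrested
  compartments.
* On M→G1 the agent divides into a uniformly chosen open neighbor iff its
  open-neighbor count is at least `T_con` **and** at least 1 (a daughter
  needs a site; with `T_con = 0` and no open neighbor the cell re-enters G1
  alone). Both daughters enter G1.
* Non-advancing agents migrate at rate `s` to a uniformly chosen open
  neighbor, staying put if none is open.

Initial phases are sampled from the dwell-time-weighted stationary
distribution of the cycle (∝ 1/ρ per phase) to avoid synchronization
transients; `init_phases="g1"` is available. The reported G2/M fraction is
(cycling G2 + cycling M + arrested-in-G2/M) / alive total, mirroring the
surrogate's (N2M + A2M)/N.

The per-agent loop is numba-compiled; replicate seeds are spawned from a
`numpy.random.SeedSequence`, so outputs are bitwise reproducible for a
given seed (single-threaded).

## Surrogate ODE models

The control model tracks cycling G1/S and G2/M compartments with transition
rate λ, division rate α and carrying capacity K; division yield falls from
2 daughters on an empty dish to 1 at N = K (crowded cells re-enter G1/S
without dividing), which makes N = K the unique positive equilibrium. The
treatment model adds absorbing arrested compartments fed by Hill-saturating
arrest fluxes (maxima β₁S, β₂M, shared EC50 κ_β and Hill coefficient m) and
drained by a saturating apoptosis flux (maximum δ, EC50 κ_δ, unit Hill
coefficient). All rates are per hour, EC50s in µM, K in cells.

Conventions:

* The Hill factor is pinned to 0 at C = 0 for every exponent (the m → 0
  limit would otherwise give 1/2 at zero dose); the fit bound on m starts
  at 0.1.
* Only the total N(0) = 100 is known at t = 0. The split
  `q = N1S(0)/N(0)` is a free nuisance parameter when compartment-count
  arms are fitted (they pin it down) and is otherwise tied to the
  exponential-growth split implied by the current (λ, α) — the dominant
  eigenvector of the uncrowded linear system. Arrested compartments start
  at 0 (drug exposure begins at t = 0 after drug-free culture).

The public solver is adaptive Runge–Kutta (`scipy.integrate.solve_ivp`,
RK45, rtol 1e−6 / atol 1e−9, evaluation only on the requested grid).
Calibration and profiling inner loops use a numba fixed-step RK4 fast path
(default step 0.05 h) because the adaptive solver's per-call overhead
(~2.6 ms measured) dominates grid × profile sweeps on one CPU; the fast
path agrees with the adaptive solver to better than 1e−6 relative in the
test suite, and a tolerance-tightening convergence check (rtol 1e−6 vs
1e−9, < 1e−4 relative change) is also asserted.

## Weighted least squares

The objective is `RSS = Σ ((sim − mean)/w)²` over every arm (dose ×
observable) and time point. Weights are the replicate SDs, floored
point-wise at 5% of the data mean at that time point; an early design used
an arm-level floor (5% of the arm's mean scale), but for five-fold growth
curves that floor (~16 cells) swamps the true early-time SD (~7 cells),
distorts the likelihood, and measurably degrades profile-CI coverage, so
the floor is per-point. Arms without SDs weight each point by its own mean
(relative error). Count and fraction arms enter with equal weight; per-arm
multipliers are exposed for users who want dataset-specific weighting,
since the right weighting of heterogeneous arms is application-dependent.

Fitting is multi-start (Latin hypercube over the bounds, default 20
starts) bound-constrained L-BFGS-B in a unit-scaled parameterization
(log-scaled for K and the EC50s), deterministic given the seed. Default
bounds: rates in [1e−3, 2] /h, arrest/death maxima in [0, 2] /h, EC50s in
[0.01, 50] µM, m in [0.1, 4], K in [100, 10,000] cells; the K ceiling of
10,000 is the one hard modelling choice, the rest bracket plausible assay
scales and are overridable.

## Profile likelihood

Each parameter is profiled by fixing it on a grid and re-optimizing the
rest, warm-started from the neighboring grid point. With SD-weighted
residuals the RSS behaves as a chi-square up to a constant, so the 95%
threshold is `RSS_min + χ²₀.₉₅,₁ = RSS_min + 3.8415` (configurable level);
CI endpoints interpolate the threshold crossing, and endpoints that reach
the parameter bound first are flagged `at_bound_unbounded` and mapped to
infinite hyperrectangle faces.

Two numerical choices matter in practice:

* **Grid spacing.** Profile grids are log-spaced for any positive
  parameter whose bounds span more than two decades (all rates and scale
  parameters here, e.g. λ ∈ [1e−3, 2]). A linear grid leaves the low
  decades without support: in a coverage experiment the interpolated lower
  CI bound landed ~5× too high purely because the nearest grid point was
  0.17 when the true crossing was near 0.03.
* **Crossing refinement.** Each detected crossing is refined by ~6
  bisections of the bracketing interval (geometric midpoints on log
  grids), re-optimizing at every midpoint, before the final linear
  interpolation. With both choices, profile CIs on a linear-Gaussian toy
  match the closed-form Wald interval within 2%, and coverage of the true
  λ over 100 synthetic noisy control datasets is 100/100 (nominal 95%,
  acceptance bar ≥ 88).

The co-fitted values of the remaining parameters along a profile form a
path in full SM space; paths truncated at the threshold constitute the
practically identifiable combination. The default profile resolution is 20
points per side (41 per parameter) with adaptive early stopping three
points past the crossing; the pipeline uses 12 per side for grid sweeps.

## Acceptance geometry

Per ABM vector the SM-parameter CIs form a closed axis-aligned
hyperrectangle (infinite faces for unbounded endpoints). The data-informed
set S is either Φ — the box of data-derived CIs — or Ψ — the union of
data-derived profile paths, the canonical default. Intersection tests are
closed-set (boundary contact accepts): boxes intersect iff their intervals
overlap in every dimension; a path meets a box iff some vertex lies inside
or some segment crosses it, the latter decided by an exact slab
segment–box test, so a path cannot tunnel through a thin box between two
outside vertices. The ε-subdivision sometimes used for this purpose is
subsumed: subdividing a polyline adds no information beyond its segments.
Because every Ψ vertex projects into each data CI, Ψ-acceptance implies
Φ-acceptance; this superset property is asserted on every end-to-end run.
Vectors whose profiling fails are reported as indeterminate, never
silently rejected.

## Direct baseline and evaluation statistics

The rejection-sampling baseline scores each ABM vector's replicate-mean
trajectory against the data with the identical weighted RSS and accepts
the k lowest, with k set to the SMoRe-ParS-accepted count when the two
methods are compared; RSS ties at rank k break deterministically by vector
id and are logged. Evaluation tables report z-scores
`(simulated − data mean)/data SD` per (vector, arm, time), both per
replicate (default in reports) and for the mean trajectory, and
accepted-vs-rejected RSS summaries (median, quartiles, 95th percentile)
total and per arm; per-arm contributions sum exactly to each vector's
total.

## Synthetic data generator

`synthdata` emulates the structure of a growth-inhibition assay on a
cultured cancer cell line: counts normalized to 100 cells at t = 0,
five time points {10, 24, 36, 48, 72} h, doses {0, 0.75, 7.55} µM, count
arms for every dose, and G2/M-fraction arms only for the treated doses
(control arms carry no cycle data). Replicates (default 3) are the
generating curve times mean-one multiplicative lognormal noise at 10% CV by
default; the generating model is either the surrogate or the ABM
(replicate-averaged). The factorial grids use three levels (low, medium,
high) per varied parameter — 3⁷ control vectors, 3⁵ treatment vectors × 3
doses — with six ABM replicates per condition and JSON disk caching so
interrupted sweeps resume.

The default level values are artifact defaults, not literature values: the
cycle-rate levels put phase dwell times at roughly half to double a ~24 h
cycle (G1 11 h, S 8 h, G2 4 h, M 1 h at the medium level), K_A ∈ {1600,
2500, 3600}, s ∈ {0, 1, 4} /h, T_con ∈ {1, 2, 3}, arrest maxima ∈
{0.2, 0.5, 0.8}, EC50 levels {0.5, 2, 8} µM bracketing the assay doses, and
δ_p ∈ {0.01, 0.03, 0.09} /h. All are overridable in the grid config.

What the generator does not emulate: measurement-system artifacts
(counting bias, gating error in cycle fractions), inter-passage
variability, drug pharmacokinetics (concentration is constant in time and
space), and any spatial readout. Passing recovery tests therefore
demonstrates the machinery is self-consistent under the stated noise
model, not that it would calibrate any particular laboratory dataset.

## End-to-end recovery experiment (problem sizes)

The recovery study used in the test suite and the acceptance script
generates pseudo-data from the ABM at a known vector (K_A = 2500,
ρ_G1→S = 1/11, s = 1, all else at defaults), then runs the full pipeline on
the surrounding 3³ grid (27 vectors × 6 replicates), with 12 multi-starts
for the data fit, 4 per grid vector, and 12 profile points per side. ABM
grid fits include the compartment-count arms (which resolve the λ–α–K
combination that total counts alone leave open); the data fit uses total
counts only, as in the emulated assay. At these sizes the study accepts a
handful of vectors under Ψ, including the generating vector, accepted
vectors have far lower data RSS than rejected ones, and the pseudo-data
lie within one SD of the accepted ensemble's trajectories — the band is
the SD across accepted-vector mean trajectories, which is the comparison
the acceptance step is designed to support. A full-scale 3⁷ study is a
straightforward (if long) application of the same functions.

## Known limitations

* The surrogate's two cycling compartments coarse-grain the ABM's four
  phases: G1/S residence in the ABM is hypoexponential, in the surrogate
  exponential. Compartment-informed fits therefore recover *effective*
  (λ, α) that differ systematically from naive 1/dwell-time values.
* Ψ is a union of one-dimensional conditional-argmin paths. When the
  95% region is effectively higher-dimensional (weak data), Ψ is a
  measure-zero slice of it and acceptance through Ψ is conservative;
  Φ-accepts/Ψ-rejects outcomes are expected, and both record sets are
  always computed.
* Profile thresholds use the asymptotic χ² df = 1 quantile; with five
  points per arm this is an approximation, partially compensated by the
  SD-floored weighting. The F-based alternative can be had by passing a
  custom level/threshold.
* The direct baseline is only feasible because this ABM is cheap; it
  evaluates only sampled vectors and cannot interpolate between them, and
  no interpolation of acceptance between grid vectors is attempted here.
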