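# Methods

This note documents the model equations `remf` implements, the numerical
choices behind them, what the synthetic scenarios emulate, and the design
decisions taken where the formulation was genuinely open.

## Coupled indicator–activity–intervention dynamics

The state is (**E**, **A**, **I**) ∈ ℝ^{n_E} × ℝ^{n_A}_{≥0} × ℝ^{n_I}_{≥0}.
The rate law is

- dE/dt = C·A + C′:(A ⊗ A) − M·I + N(t)
- dA/dt = −K·A + D_fb·E
- dI/dt = N_resp·E − L_decay·I

C′:(A ⊗ A) is the contraction `einsum('kij,i,j->k', C', A, A)` of a rank-3
tensor with the activity outer product; it captures pairwise activity
synergies (e.g. traffic × industry). N(t) is an arbitrary callable forcing
(serialized configs support constant forcing only). The matrices use
distinct names (`D_fb`, `N_resp`, `L_decay`) because the conventional
symbols D and N are heavily overloaded across the sub-models.

**Integrator.** Fixed-step classical RK4, default step 0.01 model-time
units. Fixed stepping was chosen over adaptive/stiff solvers because the
systems of interest are non-stiff by construction (the generator bounds the
linear part's spectral radius below 1) and a fixed grid makes convergence
order directly testable: halving the step must shrink the endpoint error by
≈2⁴, and the test band [12, 20] brackets that. A and I are clipped at 0
after each step — intensities and efforts are physically non-negative, and
clipping (rather than rejection or reflection) keeps the scheme explicit.
E is deliberately not clipped: indicators may be anomalies around a
baseline. On instances whose trajectories stay in the interior (all oracle
instances do), clipping is inactive and the integrator is exactly RK4.

**Stress.** Cumulative stress S_E(t) = ∫₀ᵗ (α‖A‖₁ + β‖E‖₁) dt′, trapezoid
rule on the trajectory grid. The L1 norm is used for the vector arguments:
stress reads as a sum of per-component burdens, and L1 is the only additive
choice. Both weights default to 1.

## Pollutant transport

∂P/∂t + v·∇P = D∇²P + S − R on a 2-D cell-centered grid (x along the first
array axis), with zero-flux (default, closed domain) or periodic boundary
conditions.

**Scheme.** Flux-form first-order upwind advection (face velocities are
means of adjacent cell velocities) plus second-order central diffusion in
conservative form, explicit Euler in time. The flux form makes the interior
divergence telescope, so with S = R = 0 total mass is conserved to
round-off under both boundary conditions — measured drift over 500 steps on
a 64×64 grid is ~1e−16 relative. Under the combined stability bound

dt ≤ 1 / max_cells(|vx|/dx + |vy|/dy + 2D(1/dx² + 1/dy²))

the update is positivity-preserving; `transport_step` refuses larger steps,
naming the admissible bound. Concentrations are additionally floored at 0
so that prescribed removal cannot overdraw a cell (the only mechanism that
could break positivity).

Removal supports a prescribed field R(x, y) or a first-order mode R = k·P
(`removal_rate`), since "removal by natural or artificial processes" admits
both readings. Diffusivity is a scalar constant; spatially varying D and
3-D transport are out of scope.

**Controls.** An intervention is (S_red, R_enh): S ← max(S − S_red, 0),
R ← R + R_enh. The rate constraint check compares max|ΔP|/Δt against a
permissible ε.

The discrete second moment of the central-difference diffusion operator
grows at exactly 2D per unit time on a periodic grid, which is why the
point-release variance test matches the heat-kernel value 2Dt to machine
precision rather than merely the 5% tolerance.

## Ecological rate laws

- Resources: dR/dt = rR(1 − R/K) − E_ext(t) − D_deg(t), optionally
  + (G_enh − D_mit) when a management intervention is active. With no
  extraction/degradation the integrated trajectory reproduces the logistic
  sigmoid to < 1e−6.
- Habitat: static Q_h = Q_h0 − α_L·L + β_C·C_h (floored at 0) and dynamic
  dQ_h/dt = α_HR·H_R − β_S·S.
- Species: basic competition dN_i/dt = N_i(r_i − Σ_j c_ij N_j) − h_i, or the
  extended logistic form r_iN_i(1 − N_i/K_i) − c_i·S + ρ_i·S_P. A stable
  two-species pair converges to the equilibrium of c·N* = r, which the
  tests solve independently as a 2×2 linear system.
- Biodiversity: dB/dt = γ·Q_h·N_tot − δ·S + I_B with I_B = H_R + S_P + E_M.
  I_B adds an effort directly to a rate; its units are declared
  "biodiversity-rate equivalents" because no conversion constant exists in
  the formulation. N_tot aggregates species populations by summation
  (caller-overridable weighting).
- Carbon/water/uncertainty: dC = E_C − A_C − D_C;
  dW = −I_P + P_W − M_W; dU = −λ·E_M + ξ·‖ΔE‖₂. The water mitigation term
  M_W is *subtracted* as the formulation prints it, which means mitigation
  lowers water quality; because the intent is ambiguous the sign is a
  config flag (`water_mitigation_sign: as_printed | flipped`) rather than a
  silent correction. The uncertainty law needs a scalar from the feedback
  vector ΔE; the L2 norm is the only norm-like reduction that yields a
  scalar rate.
- Forecasting: B(t + Δt) = B(t) + ∫ rate dτ by the trapezoid rule on the
  integration grid.

All ecological state variables are floored at 0 after each step; the
underlying formulation never addresses negativity and negative populations
or resource stocks are meaningless.

## Feedback control

Loss L = ‖E − E\*‖². Under the local linear response E(I) = E_base − M·I,
∇_I L = −2Mᵀ(E − E\*), and the controller applies the projected descent
step

I′ = clip(I + 2η·Mᵀ(E − E\*), I_min, I_max).

The update recurrence is conventionally written I ← I + η∇L; taken
literally that *ascends* the loss, so the descent direction — the only
reading under which deviations from target shrink — is implemented, and
stated here prominently. For η < 1/ρ(MᵀM) the linear-model loss is
non-increasing and the unconstrained scalar iteration contracts
geometrically: with M = 1, E_base = 2, target 0 and η = 0.25 the iterates
are 0, 1, 1.5, 1.75, … and the loss falls by exactly 1/4 per step — the
worked example frozen in the tests. Several variants of the update appear
with different rate symbols (η, α, ξ); they are one mechanism with one
configurable rate.

The controller is discrete, firing every `control_interval` (default 0.5)
while the continuous system integrates between firings. Two intervention
laws are config-selectable: `ode` (effort also follows its
responsiveness/decay dynamics between firings) and `controller` (effort
held piecewise-constant; default for scenario runs). M adaptation
M′ = max(M + λ·∇E, 0) takes the observed impact matrix from the caller; a
finite-difference helper (`estimate_impact_matrix`) is provided because the
gradient is otherwise unspecified.

**Scenarios.** `bau` pins I ≡ 0; `moderate` and `aggressive` run the
controller with effort ceilings I_max/2 and I_max. The 50%/100% split is a
declared convention, not inferred from anything. The comparison diagnostic
is the integrated burden ∫‖E(t)‖₁dt.

## Optimization

max F(I) = Σ_k w_k O_k(I) subject to Σ_i C_i I_i ≤ B and box bounds.
Objectives are arbitrary callables (optionally simulator-backed); weights
are normalized to a probability vector (an all-zero weight vector is a
permitted degenerate case where any feasible point is optimal and the
lower-bound corner is returned).

**Projection.** The Euclidean projection onto {box ∩ budget half-space} has
the exact KKT form clip(I − μc, lo, hi) with a single non-negative
multiplier μ; μ = 0 when the clipped point is affordable, otherwise the
unique root of the continuous non-increasing spend function, found by
bisection to 1e−15 relative. This replaces iterative alternating
projections with their exact limit.

**Solver.** Multi-start projected gradient ascent: central-difference
gradients, normalized steps with halving on failure to improve, projection
each iterate, deterministic seeded starts (the lower-bound corner plus
random feasible points), lexicographic tie-break among equal-F finishers.
Projected gradient was chosen because objectives may be non-convex
simulator functionals, yet on linear instances the method provably
terminates at an optimum — the tests compare against
`scipy.optimize.linprog` as an exact independent oracle on seeded 2–3
component instances (observed gap ≲ 1e−8, tolerance 1e−3). Tiny
2-component cases are additionally cross-checked against a literal dense
grid search.

**Weight adaptation.** w ← renormalize(max(w + η_k·∇S, 0)); renormalization
keeps weighted objectives comparable across adaptation steps and raising it
to a hard error when all weights clip to zero avoids silently optimizing a
constant.

## Stakeholder layer

φ(C_eng) = 1 + α·C_eng ≥ 1 scales total intervention
Ĩ = φ·(I_gov + γ_com·P_com), the scalar community term broadcast uniformly
across components. Channel vectors (pollution, resource, biodiversity)
combine by element-wise addition in a common intervention space; mapping
channel-specific units into that space is the config's responsibility.

Allocation: R_s = B·β_sP_sN_s / Σ_j β_jP_jN_j. As conventionally printed
the share formula omits both the budget factor and the fairness weights in
the denominator, which breaks the budget identity Σ R_s ≤ B for general
β; the normalized form used here is the unique proportional rule that
satisfies the identity with equality for arbitrary fairness factors. The
deviation is intentional and this is its record.

## Synthetic scenarios

The generator emulates a stylized urban management problem; it is the sole
source of test inputs, and all of its randomness flows from an explicit
seed.

- `minimal` — 1/1/1 linear system (C = 1, K = 0.5, M = 0.5, no feedback):
  activity decays exponentially and the indicator saturates at
  E₀ + CA₀/K, giving a closed-form anchor for integration tests.
- `urban-small` — 3/3/3 system. Couplings are non-negative draws (|N(0, σ)|
  with σ = 0.3 for C, 0.02 for C′, 0.05 for feedback, 0.1 for
  responsiveness; decay diagonals 0.3–0.5); the linear block matrix is
  rescaled to spectral radius < 1 so trajectories neither blow up nor
  stiffen. Two structural choices make the preset a *monotone* instance:
  mitigation rows of M are capped at total capacity 0.35 per indicator,
  and a constant background forcing of 0.4 per indicator exceeds that
  capacity. Indicators therefore always stay above the zero target no
  matter the intervention level — more intervention can only lower the
  trajectory — so the business-as-usual ≥ moderate ≥ aggressive burden
  ordering is a structural property rather than a sampling accident. This
  mirrors a city whose background emission pressure exceeds what feasible
  interventions can fully offset.
- `urban-grid` — `urban-small` plus a 32×32 pollutant grid (dx = 0.5, wind
  (0.2, 0.1), D = 0.05, two seeded unit point sources, first-order removal
  0.05, zero-flux boundary).

What the generator does **not** emulate: real spatial heterogeneity,
measurement noise, seasonal forcing, regime shifts, or any empirical
parameter magnitudes. Passing tests demonstrate the numerics and the
contracts of the method — order of convergence, conservation, descent,
feasibility, ordering — not predictive skill on real ecosystems.

## Problem sizes and tolerances

Oracle comparisons use 2+2+2-dimensional linear instances (20 seeds, step
1e−3, unit horizon, tolerance 1e−6 max state error); convergence-order
checks use the nonlinear 3/3/3 preset over a unit horizon against a step
1e−4 reference; transport checks use 64×64 (conservation, 500 steps) and
96×96 (kernel variance, 5%) grids; scenario comparisons run 10 seeds over
a 10-unit horizon at step 0.01. These sizes make every invariant
measurable well above round-off while keeping the full suite and the
acceptance script fast on a single CPU.

## Serialization and determinism

YAML is the primary config dialect (JSON accepted — YAML is a superset);
matrices are row-major nested lists. Trajectories are tidy CSV
(time, variable, index, value) written with 17-significant-digit floats
and read back with round-trip parsing, so serialization is exact. Grid
snapshots are per-snapshot CSV. Reports are JSON with sorted keys carrying
the SHA-256 config hash, the seed and the code version; no timestamps enter
any output file, so identical configs yield byte-identical outputs. Logs
go to stderr only.

## Known limitations

- First-order upwind advection is diffusive; plume fronts smear over long
  horizons. A higher-order limiter scheme was deliberately not added — the
  provable conservation/positivity of the simple scheme is worth more here
  than sharpness.
- The controller's linear response model uses the current M; if the true
  impact is strongly nonlinear the descent guarantee is only local.
- The optimizer scalarizes objectives; it does not enumerate Pareto fronts,
  and with non-convex simulator-backed objectives multi-start is a
  heuristic.
- Continuous intervention dynamics and the discrete controller are
  alternative laws, not a unified hybrid model; mixing them within one run
  beyond the provided piecewise scheme is unsupported.
- No stochastic dynamics anywhere: all randomness lives in scenario
  generation, never in integration.
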