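# Methods

## Model

The package integrates a mass-action chemostat model of two conjugative
plasmids. State variables are the densities (cells/mL) of plasmid-free
cells Ø, single carriers X and Y, double carriers XY, and the
concentration R (µg/mL) of one limiting resource. Cells divide at
ψ·ω·R/(R+Q) (Monod kinetics weighted by the carrier's relative fitness),
wash out at Ω, lose plasmids segregationally at δ (δ_XY per plasmid in
double carriers, which therefore leave the XY compartment at 2·δ_XY;
simultaneous loss of both plasmids is not modelled), and conjugate at
mass-action rates γ·D·R between donor and recipient densities. Matings
of XY donors with Ø recipients produce three transconjugant classes:
both plasmids at the co-transfer rate γ_XY = min(γ_X(Y), γ_Y(X)), and
each single plasmid at the residual rates γ_X(Y)−γ_XY and γ_Y(X)−γ_XY.
The resource balance subtracts Π per division.

Assumptions: the culture is well mixed; hosts are isogenic and neither
hosts nor plasmids evolve; both plasmids share one loss rate δ (the
double-carrier loss rate δ_XY = δ·σ is defined only for that case, and
`derive_rates` rejects unequal values); at most two plasmid types
coexist; chemostat parameters are constant in time.

Interaction parameters and defaults (neutral values in parentheses):
epistasis ε (0) acts additively on the double-carrier fitness,
ω_XY = ω_X·ω_Y + ε, uncapped in both directions; intracellular effects
α_X, α_Y (1) multiply transfer out of XY donors; intercellular effects
ξ_X, ξ_Y (1) multiply transfer into carriers of the other plasmid;
loss interference σ (1) multiplies δ in double carriers. Transfer from
XY donors into single carriers uses γ_X(Y) while α_X ≤ 1 but reverts to
the bare γ_X when α_X > 1: entry exclusion by the resident copy in the
recipient outweighs the facilitation. The tie α = 1 takes the
intracellular branch, which is numerically identical to the bare rate.

Chemostat constants: Ω = 0.05 h⁻¹, Q = 5 µg/mL, Π = 10⁻⁶ µg,
ψ = 3·ln 2 h⁻¹ (three doublings per hour, an *E. coli*-like maximum),
R₀ = 100 µg/mL. These values put the plasmid-free carrying capacity at
Ø̂ = (R₀−R̂)/Π ≈ 10⁸ cells/mL with R̂ = QΩ/(ψ−Ω) ≈ 0.123 µg/mL, the
closed form used as an integration oracle in the tests.

## Study design (grids)

The experiment layer enumerates the comparative designs as scenario
grids: single plasmid alone (36 trait combinations of
ω ∈ {0.85, 0.9, 0.95, 0.975}, γ ∈ {10⁻¹³, 10⁻¹², 10⁻¹¹},
δ ∈ {10⁻⁸, 10⁻⁶, 10⁻⁴}), all 432 non-interacting pairings, and one
grid per interaction parameter (ε ∈ {−0.05, 0, 0.05, 0.1};
α ∈ {10⁻³, 1, 10} and ξ ∈ {10⁻², 1, 10} with either X or Y as the
target, never both; σ ∈ {1, 10}), plus a 23 328-case sweep crossing all
six interaction parameters against a fixed competitor (ω_Y = 0.9,
γ_Y = 10⁻¹²). Auxiliary single-plasmid grids cover the doubled
inoculum control (X(0) = 10⁶), the cost-free/beneficial control
(ω_X ∈ {1, 1.05}) and the de-repressed-conjugation probe
(γ_X = 10⁻¹⁰). Initial conditions everywhere else: X(0) = Y(0) =
5×10⁵ cells/mL (Y(0) = 0 in single-plasmid runs), Ø(0) = XY(0) = 0,
R(0) = R₀.

Extinction of the focal plasmid means X < 1 and XY < 1 cells/mL — less
than one plasmid copy per volume unit — at the stable steady state;
survival is the complement, with a density of exactly 1 counting as
survival. The time of extinction is the first integer hour at which
the extinction condition holds on the dense trajectory. Comparative
analyses divide a model's integer ToE by the matching reference value
(same focal traits for the single-plasmid reference; same trait pairing
for the non-interacting reference) and categorize ratios as increase
(> 1), decrease (< 1) or null (exact integer tie — meaningful because
ToE is integer-valued). Benefit proportions in the pooled
single-interaction analysis are computed among the extinct cases of
each interaction stratum; normalization against the single-plasmid
model always uses the primary X(0) = 5×10⁵ run, not the doubled-
inoculum control.

## Numerics

Stiff integration uses scipy's LSODA with the model's analytic
Jacobian, relative tolerance 10⁻⁸ and absolute tolerances 10⁻⁶ cells/mL
(10⁻¹⁰ µg/mL for R) — the 1 cell/mL decision threshold sits ~14 orders
of magnitude below peak densities, so the absolute tolerance must sit
well below 1. Long-horizon runs are driven step by step in a single
continuous integration (no restarts): after every accepted step the
driver (i) scans the integer hours covered by the step's dense output
for extinction crossings of the tracked plasmids, and (ii) evaluates
the steady-state criterion |dy_i/dt| ≤ 10⁻⁷ + 10⁻⁹·|y_i| per component,
declaring convergence after three consecutive satisfying steps. Cold
solver restarts were deliberately removed: LSODA's step-size heuristics
can stall essentially permanently when restarted on the slow
near-neutral manifolds this model produces (e.g. ω_X = 1, where loss
and conjugational recapture almost cancel); as a second guard the
driver switches to BDF from the current state if LSODA exceeds 10⁵
steps. The simulated-time budget is 10⁸ h — the slowest grid case, the
cost-free plasmid with γ_X = 10⁻¹², δ = 10⁻⁴, only crosses the
extinction threshold near t ≈ 9.5×10⁷ h, and with step-based
monitoring the long horizon costs only a few hundred extra steps.
A run that exhausts the budget with neither extinction nor convergence
raises an explicit undetermined-outcome error; it is never reported as
survival.

Converged states are polished by Newton root-finding on the right-hand
side (hybrid Powell, analytic Jacobian); the polish is rejected if it
fails, worsens the residual, moves any component by more than 5% of its
scale, or produces significantly negative densities. Components more
negative than 10× the absolute tolerance abort the run as solver
failure; smaller negatives are clamped to zero. Local stability
requires all Jacobian eigenvalues to have real part below 10⁻⁹; for
single-plasmid scenarios the check is restricted to the active
subspace (Ø, X, R), because the full Jacobian contains invasion modes
of the absent competitor, which are not part of the single-plasmid
question. Survival classification refuses non-converged reports and
treats an unstable equilibrium as non-survival.

Determinism: there is no randomness anywhere in the pipeline; the
worker count of the parallel grid runner does not change any output
bit, and scenario identifiers are content hashes of the full
parameterization.

## Statistics

Extinction-time ratios across interaction levels are compared with the
Kruskal–Wallis test followed by Dunn's pairwise z-tests on joint ranks
with Bonferroni adjustment (implemented here with the tie-corrected
normal approximation); paired designs use the Wilcoxon signed-rank
test with continuity correction. Outcome tables use the chi-squared
test with Yates continuity correction plus pairwise exact conditional
tests between strata (a margin-constrained enumeration implementation
of the r×c Fisher test, cross-checked against scipy's 2×2 version;
enumeration beyond the configured table budget falls back to
chi-squared). The benefit outcome is modelled by maximum-likelihood
logistic regression on the six interaction parameters as continuous
covariates, reporting per-covariate Wald significance, deviance
explained, and both McFadden and Nagelkerke pseudo-R² (two conventions
are reported because the variants differ substantially and no single
one is canonical). Perfect separation is detected and flagged rather
than reported as a clean fit. The single-plasmid extinction-time ANOVA
fits the full continuous factorial ω × log₁₀γ × log₁₀δ (7 model df) on
log₁₀ ToE and reports partial η² per term; the log response was chosen
because ToE spans two orders of magnitude across the grid.

## Scale choices in the default test suite

The default suite runs every comparative design in full except the
multi-interaction sweep: models 1–3 complete (36 + 432 + 1728 cases
plus the controls), the non-neutral strata of models 4–6 (8 strata ×
432 + 432 cases), and the pooled 5184-case benefit analysis. For the
multi-interaction sweep the suite runs the 486-case subset satisfying
the survival preconditions (ε = 0.1, α_X = 10, γ_X = 10⁻¹¹,
ω_X > 0.85) in full plus a deterministic 54-case boundary slice just
outside them; the complete 23 328-case grid remains available through
`build_grid("multi")` or `plasmidyn sweep multi` (roughly an hour on
one CPU). Scenarios whose equilibrium composition is not needed are
run through the extinction-time-only driver, which stops as soon as the
integer crossings are resolved.

## Known limitations

No spatial structure, at most two plasmid types, no host or plasmid
evolution (so no compensatory mutations or co-integrate formation), no
transitory derepression of conjugation, and no demographic noise — in
small effective volumes a density below one cell per mL is already a
stochastic regime that the deterministic threshold only approximates.
Near-boundary survival classifications depend in principle on solver
tolerances; the suite's tolerance-robustness and oracle tests bound
this risk but cannot remove it for cases sitting exactly on a
bifurcation.
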