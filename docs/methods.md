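# Methods

## Model

The population is asexual, haploid and age-structured. Each individual
carries a heritable trait (x_b, x_d) ∈ ℝ²: it reproduces at intensity i_b
while its age lies in the half-open fertility window [0, x_b), and dies at
intensity i_d once its age reaches the mortality onset x_d. A negative x_d
means the hazard runs from birth (the onset is clamped at 0); a
non-positive x_b means sterility. The window convention at the boundary has
measure zero and is fixed only for reproducibility. All individuals,
whatever their lineage, share one additive competition term c·(N−1) in
their death rate, N being the total number currently alive — a logistic
carrying capacity with no trait-specific adaptive value.

At each birth the offspring copies the parental trait; each gene then
mutates independently with probability p by a Gaussian increment of mean 0
and standard deviation σ (no reflection or clamping — the trait space is
unbounded). If the lineage carries the Lansing effect and the parent
reproduces past its own mortality onset (parent age > x_d, possible only
when x_d < x_b), the offspring's post-mutation x_d is scaled by
(1 − magnitude); at magnitude 1 it is exactly 0. The magnitude interpolates
linearly between the two documented endpoints (0 = no effect, 1 = offspring
x_d pinned to 0); the literature defines only the endpoints, the linear
interpolation is this package's choice. Lansing capability itself is a
fixed lineage label, inherited and never mutated, because the reference
experiments compete two fixed sub-populations. One corner is worth noting:
an offspring pinned to x_d = 0 reproduces only at ages > 0 = x_d, so at
full magnitude the rule re-applies to all of its own descendants and
mutations on their x_d are masked.

## Fitness

For a fixed trait, population growth is exponential at the Malthusian
parameter λ, the unique real root of the Euler–Lotka equation
i_b ∫₀^{x_b} S(a) e^{−λa} da = 1 with survivorship S(a) = 1 before
max(x_d, 0) and exponential decay at rate i_d after. The integral has a
closed piecewise-exponential form built from φ(z) = (1 − e^{−z})/z; φ and
its derivative switch to 4-term Taylor series for |z| < 1e−5 (resp. 1e−4),
so the λ = 0 and λ = −i_d singularities are handled analytically, never by
numerical perturbation. The solver is a Newton iteration started at
max(0, i_b(1 − 1/R₀)) inside a maintained sign bracket, falling back to
bisection whenever a step leaves the bracket; tolerance |residual| < 1e−12,
at most 100 iterations (5–8 are typical). F(λ) is strictly decreasing with
F(i_b) < 0, so the bracket always exists; a sterile trait (x_b ≤ 0) has no
root and is reported as λ = −∞.

A Lansing lineage below the diagonal is a two-type system: "normal"
individuals beget normal offspring only while younger than x_d (later
births are pinned to x_d = 0), and the x_d = 0 individuals feed only
themselves. The x_d = 0 subtree is autonomous, so the lineage growth rate
is max(λ_N, λ_L), where λ_N solves the renewal equation with fertile window
truncated at x_d and no intrinsic hazard inside it, and λ_L is the ordinary
root of the trait (x_b, 0). Both branches reuse the same closed-form kernel
(window end w, hazard onset m): (w, m) = (x_b, clamp(x_d, 0, x_b)) for the
one-type case, (min(x_d, x_b), itself) for the normal branch, (x_b, 0) for
the subtree. Above the diagonal the rule never fires and the lineages
coincide; they also coincide for x_d ≤ 0, where the hazard clamp makes the
pinned offspring dynamically identical to the parent.

Selection gradients come from implicit differentiation of the active
branch's renewal equation: dλ/dθ = −(∂F/∂θ)/(∂F/∂λ), with all partials in
closed form. Both components are nonnegative, and their norm decays
exponentially along the diagonal — the selection shadow.

## Adaptive dynamics

On the evolutionary time scale the resident trait follows
d(x_b, x_d)/dt = k·∇λ with equal mutational variance on both genes. The
prefactor k (collecting p, σ² and the resident population size) only
rescales time, so it defaults to 1; passing a mutation kernel sets
k = pσ²/2. Integration uses scipy's RK45 with rtol 1e−8, sampled on a
geometric time grid because the dynamics slow down exponentially; the
default horizon 1e6 (unit-rate time) takes the reference start (1.2, 1.6)
to x_b ≈ 13, where the gap's tail variation is below 1e−7.

The limiting gap solves the gradient-equality condition ∂λ/∂x_b = ∂λ/∂x_d
in the joint large-trait limit λ → i_b, giving
γ* = log((2 i_d + i_b)/i_d)/(i_b + i_d). Because this closed form was
re-derived rather than copied, it is cross-validated in the test suite
against direct canonical-equation integration (two distant starts, two
intensity pairs, agreement ≤ 1e−2) and against its two published anchors
(log(3)/2 at unit intensities; ≈ log 2 at i_b = 0.01). On the grid
[0.01, 1]² the gap's sensitivity to i_d exceeds its sensitivity to i_b
pointwise, with a mean ratio ≈ 4.6 (exactly (2/3 + log 3)/(log 3 − 2/3)
≈ 4.08 along the diagonal); claims of a much larger dominance are not
supported by this formula.

## Stochastic engine

The exact age-structured process is simulated by thinning: every living
individual's total rate is bounded by b = i_b + i_d + c(N−1), which is
refreshed whenever N changes. A candidate event time is drawn at rate N·b,
a candidate individual uniformly, and the candidate becomes a birth or
death with probability equal to its true age-dependent rate over b —
exact sampling with no discretization bias at the x_b/x_d steps. The suite
verifies this against a dt = 1e−3 time-stepping oracle, against the
analytic lifespan law x_d + Exp(i_d), against the mean-field logistic
equilibrium (i_b − i_d)/c, and against the Euler–Lotka growth rate of both
lineage types. Growth-rate checks measure the late-window slope
log(N(T)/N(T/2))/(T/2) because an age-0 founder cohort inflates early
growth until the age distribution stabilizes.

Randomness is a single stdlib `random.Random` stream per run, seeded
explicitly; identical seeds give bit-identical event logs. The event budget
counts accepted births plus deaths. Event logs and snapshots are written as
CSV with shortest-roundtrip float formatting so replay is exact (note that
`pandas.read_csv` must be given `float_precision="round_trip"` to preserve
this on the way back in).

## Reference experiments and problem sizes

*Competition cell*: 500 age-0 founders per lineage, traits (1.5, 1.3)
Lansing and (1.5, 0.83) non-Lansing (their growth rates match to 0.0065,
within the 0.01 audit tolerance; the residue is the 2-decimal rounding of
the published trait values — the exactly matched Lansing onset would be
x_d ≈ 1.3067), i_b = i_d = 1, σ = 0.05, a 2×10⁵ event budget per
replicate, 100 replicates by default. A lineage "collapses" when its live
count reaches 0 before the budget is exhausted; collapse and progeny
indexes are pooled over replicates, the final Lansing share is averaged
over replicates with survivors. These statistics are heavy-tailed — most
replicates end in the fixation of one lineage — so even 100-replicate
estimates of the collapse-count ratio carry a spread of roughly ±0.15, and
the pooled progeny ratio of roughly ±0.5. The headline estimates therefore
raise the replication with per-replicate conditions unchanged — 300
replicates in the test suite and 500 in the reproduction script — which
brings the collapse-ratio standard error down to ≈ 0.04–0.06.

*Trait convergence*: 1000 founders at (1.2, 1.6), c = 9e−4, p = 0.1,
σ = 0.05, horizon 800. The reported statistic is the population-mean gap
time-averaged over t ∈ [500, 800] and then averaged over replicate seeds.
The window starts where the ensemble-mean gap stops rising: a 16-replicate
trace to t = 1200 shows the mean climbing until the mean x_b passes ≈ 2.8
(t ≈ 500 under these parameters) and fluctuating around a plateau of
≈ 0.51–0.52 thereafter, a few hundredths below the deterministic limit
log(3)/2 ≈ 0.549 — the finite-population mean lags the moving optimum
under mutation-selection-drift balance. Replicate averaging is essential:
past convergence the selection gradient is ~e^{−x_b}, drift dominates, and
a single run's windowed gap still carries a standard deviation near 0.15;
48 replicates bring the standard error of the mean to ≈ 0.02.

*Uniform start*: both genes of every founder drawn independently uniform on
[−10, 10], both lineages present, global competition, horizon with a
terminal 10-time-unit reporting window. The scaled default (500 founders
per lineage, horizon 200) shows the early counter-selection of extreme
positive gaps (> 4) clearly. It does not reproduce final gap modes at the
theoretical limits: under this initial condition the region with x_b near
the upper bound and x_d ≥ x_b is a fitness plateau (λ ≈ i_b with gradients
~e^{−x_b}), the population concentrates there after the initial
competition crash, and no horizon reachable by selection moves it to the
positive-gap limits. This is a structural property of the
independent-uniform initial condition, not of the scaled problem size.

## Synthetic data and scope

All inputs are generated by the model itself; no external data exist. The
generator therefore emulates exactly the study conditions (founder counts,
traits, intensities, mutation kernel, competition, budgets) and nothing
else: there is no environmental fluctuation, spatial structure, sexual
reproduction, ploidy, maturation delay or resource-allocation trade-off.
Passing tests show internal consistency of the model's stochastic and
deterministic routes and agreement with its published anchors; they say
nothing about organismal data. Known limitations: the competition summary
statistics are near-bimodal across replicates, so their pooled ratios are
intrinsically noisy at any affordable replication; and the uniform-start
experiment's published final-state anchors are unreachable under the
independent-uniform reading of its initial condition (see above).
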