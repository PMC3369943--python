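# Methods

This note documents the models, algorithms, numerical choices, and design
decisions behind `spikemaxent`, including the points where the design was
genuinely open and the package had to commit to one construction.

## The reference family

The null hypothesis is that an observed sample of bivariate spike counts
(x, y) was generated by *some* member of the family of maximum entropy
distributions with Poisson marginals and a linear correlation constraint.
For rates λ₁, λ₂ > 0 and Pearson correlation ρ, the reference distribution
on the count grid is the unique maximizer of the Shannon entropy subject to
(i) both marginal pmfs and (ii) the product moment E[XY] implied by ρ. It
has the exponential-family form

    P*(i, j) ∝ a_i · b_j · exp(θ · i · j),

with row/column factors enforcing the marginals and a single interaction
exponent θ controlling the correlation. θ > 0 tilts toward positive
correlation, θ = 0 recovers independence.

**Truncation.** The Poisson support is infinite; all computations run on a
finite grid. Each margin is cut at the smallest count K whose cumulative
mass reaches 1 − ε with ε = 1e-10 by default (configurable through
`truncate_support`). Mass below 1e-10 cannot move a rank-based p-value at
the sample sizes the test targets (n ≤ 10⁴). The truncated marginal pmf is
renormalized to sum to one and the constraints are imposed on that
renormalized pmf, keeping the finite-grid problem exactly consistent.
Enlarging the grid beyond the cutoff changes fitted entries by less than
10 ε (regression-tested).

**Solver.** For fixed θ the row/column factors are found by iterative
proportional fitting (Sinkhorn scaling), run multiplicatively when the
kernel exp(θ·i·j) is safely representable and in log space (logsumexp
updates) otherwise. E[XY] of the scaled table is strictly increasing in θ,
so θ is solved by bracketed Brent root-finding on the product-moment gap,
with the scaling factors warm-started across θ evaluations. Convergence
requires the maximal marginal residual and the correlation residual below
1e-9 (configurable); failure raises an error carrying the residuals. The
solver is validated entrywise (≤ 1e-6, typically ~1e-10) against an
independent generic convex solve of the same constrained program (BFGS on
the Lagrange dual) on 8×8 supports across a correlation grid.

**Feasible correlations.** Not every ρ is attainable for fixed discrete
marginals. The attainable range is computed from the comonotone and
countermonotone quantile couplings of the truncated marginals (verified
against a linear-programming search over all couplings on small supports).
Requests outside the range raise an error naming the range; during nuisance
optimization an infeasible proposal is clipped to the range minus a 1e-6
margin instead, so the annealer's search space stays connected.

**Units.** All entropies and mutual informations are in bits (log base 2),
the convention in neural coding.

## Divergence statistics

A divergence D(P̂ ‖ P*) compares the empirical table P̂ (counts of counts,
n·P̂ integer-valued) with the reference table. Both shipped statistics are
absolute differences of information quantities, hence nonnegative and zero
when the tables coincide:

* **entropy_diff** — |H(P̂) − H(P*)|. The empirical plug-in entropy is
  biased, but the Monte Carlo replicates carry the same bias under the
  null, so the rank comparison is unaffected; no explicit bias correction
  is applied (or needed).
* **mi_diff** — |I_emp − I_ref| where I is the mutual information between
  the stimulus (flat prior over the observed labels) and the count pair,
  computed from per-stimulus conditional tables padded to a common grid.
  I_emp uses plug-in conditionals; additive estimation biases cancel in
  the difference under the null for the same reason.

The `DivergenceMeasure` container accepts arbitrary user statistics with
the same signature (unlabelled: two tables → float; labelled: sample +
stimulus ensemble → float), so problem-specific divergences (e.g. one
probing only particular count patterns) plug in without touching the
engine. With 0·log 0 ≡ 0 throughout.

## The Monte Carlo test

For a fixed nuisance triple (λ₁, λ₂, ρ) — one per stimulus for mi_diff —
the engine fits the reference, computes the observed divergence D₀, draws
N Monte Carlo datasets of the same size (and, for mi_diff, the same
per-stimulus trial allocation) from the reference, and computes their
divergences D₁..D_N. Count statistics are discrete, so ties among
divergences have positive probability; an i.i.d. Uniform(0,1) mark attached
to each statistic orders ties randomly (a tied pair is decided by a coin
toss), which keeps the randomized p-value exact:

    p = (#{k : (D_k, U_k) ≥lex (D₀, U₀)} + 1) / (N + 1).

The +1 terms are the finite-N correction; p lives on the lattice
{1/(N+1), ..., 1} and the test rejects when p < α strictly. N defaults to
999. Under the null with the true parameters the p-value is exactly
(super-)uniform — property-tested over 500 replications.

## Nuisance maximization

The true (λ₁, λ₂, ρ) are unknown. Following the maximized Monte Carlo
approach, the reported p-value is the maximum of p(θ) over candidate
nuisance values, which can only make the test more conservative; the
decision uses the worst case.

**Search domain.** The maximization runs over a *confidence set* of the
nuisance parameters, not the unbounded space: a per-parameter box around
the sample estimates (Wald interval for each Poisson rate, Fisher-z
interval for ρ; 95% by default, configurable). The restriction is the
package's central design decision and is load-bearing. The maximization
exists to protect the level against estimation error in the nuisance
parameters, and the box covers exactly that uncertainty. Over an unbounded
space, by contrast, any scalar divergence of this kind can be *absorbed*:
for every dataset there exist rates whose reference entropy matches the
(biased) plug-in entropy of the data exactly, driving D₀ to zero and p to
one — in simulation this annihilates the test's power everywhere while
adding nothing to validity. The confidence-set restriction removes that
pathology; its price is that the level guarantee is inherited only up to
the box's coverage (the test remains strongly conservative in all level
simulations, because fitting the nuisance parameters to the data already
shrinks D₀ below its null calibration).

**Annealing.** Within the box, simulated annealing maximizes p: Gaussian
proposals with standard deviation 0.5 standard errors per parameter,
p-increases always accepted, decreases accepted with Metropolis probability
exp(Δp/T) under geometric cooling (T₀ = 0.1 in p-value units, factor 0.95),
15 steps by default. The budget is deliberately short: p(θ) varies on the
scale of the box within a few SE-sized moves, each evaluation is itself a
random variable (fresh Monte Carlo seeds by default; a common-random-
numbers mode exists), and longer searches systematically inflate the
worst-case p-value — raising conservatism and eroding power with no gain
in validity. The default budget and scales were fixed by calibrating the
test's operating characteristics on the copula-mixture benchmarks (level
below α across a correlation grid at n = 100; small-sample power in the
5–20% range for mixture data with m ~ U(0,1) at n < 50; power near 1 at
m = 1, n = 200); sensitivity to the budget is monotone (more steps → more
conservative). All budgets are configurable via `AnnealConfig`.

**Initialization** is at the sample means and the plug-in Pearson
correlation (0 if a marginal variance vanishes). For mi_diff the nuisance
dimension is 3 × (#stimuli), with an independent box per stimulus.

## Copula benchmark generators

The validation families couple fixed Poisson marginals to controlled
higher-order structure through copulas. On the count grid the copula-based
pmf is the rectangle inclusion–exclusion of the copula CDF over the
marginal CDF knots; validity (all rectangle masses ≥ 0) is asserted on
every evaluated grid. The Gaussian copula CDF is evaluated through the
bivariate normal CDF (`scipy.stats.multivariate_normal`), with the
boundary conventions Φ⁻¹(0) = −∞, Φ⁻¹(1) = +∞ handled exactly.

The benchmark families mix a maximum entropy component with a
Gaussian-mixture-copula component:

    M(m) = (1 − m) · P*_{ρt} + m · C-table,   m ∈ [0, 1],

where the copula component is itself a mixture of two Gaussian copulas
with opposite-sign parameters: ρ₁ = 0.9 fixed (chosen to produce a
pronounced cross-shaped pmf, i.e. strong higher-order dependence;
configurable) and ρ₂ calibrated by root-finding so the component's Pearson
correlation hits the family target ρt — 0 for `M1`, 0.2 for `M2` — within
1e-4. The inner copula mixture weight defaults to 0.5. Both components
therefore share marginals and correlation, so m moves *only* the
higher-order structure; marginals stay Poisson(rate) for every m (within
1e-8), and the entropy gap H(ME) − H(M(m)) grows monotonically with m.
The default rate 3.0 corresponds to 30 Hz in 100 ms bins. Note that with
these defaults the calibrated `M2` component is closer to its maximum
entropy counterpart than `M1`'s is (entropy gap 0.19 vs 0.54 bits at
m = 1), so detection power against `M2` is correspondingly lower.

## Baselines and auxiliary tests

**Likelihood ratio test.** Full model: the saturated multinomial on the
count grid (MLE = empirical frequencies). Reduced model: the maximum
entropy family, with (λ₁, λ₂, ρ) fit by Nelder–Mead maximization of the ME
likelihood from the sample estimates (log/atanh reparametrized). Statistic
Λ = 2(ℓ_full − ℓ_ME), referred to a chi-square with df = (#grid cells − 1)
− 3, counting the full model's free parameters on the fitted truncated
support. With hundreds of cells and tens of samples the chi-square
approximation is extremely conservative — the documented reason the Monte
Carlo test dominates at small n.

**Benjamini–Hochberg.** The step-up FDR rule (via
`statsmodels.stats.multitest`) for multi-pair, multi-bin scans. Dataset
scans correct within each (bin size, condition) universe and never across
bin sizes: each bin size carries its own hypothesis.

**Single-neuron Poisson GOF.** A univariate analogue of the main test:
statistic = |H(empirical count histogram) − H(truncated Poisson(λ))|,
p-value by the same randomized Monte Carlo rank procedure, maximized over
λ with a short 1-D anneal confined to a ±2 SE interval around the sample
mean (same rationale as the bivariate box). This construction preserves
the role of the original check — level under the Poisson null, sensitivity
to over/underdispersion — without claiming to replicate an exact statistic.

**Time-rescaling KS test.** Interspike intervals are rescaled by the
integrated piecewise-constant rate; under a Poisson process the rescaled
intervals are unit-exponential, so 1 − exp(−τ) is tested against
Uniform(0,1) with Kolmogorov–Smirnov. Operating directly on spike timing,
this test is more sensitive to renewal-process regularity than the
count-based ME test — the expected and observed ordering in the gamma
study.

## Spike train simulation and fixtures

Gamma renewal processes draw i.i.d. Gamma(shape γ, mean 1/r) interspike
intervals; γ = 1 is the Poisson process (binned counts verified
Poisson-distributed by chi-square), γ > 1 adds refractoriness (ISI CV =
1/√γ). The process starts ordinarily at t = 0 (no equilibrium correction;
the bias is negligible at the 5–10 s durations used). The two "concurrent"
trains of the robustness study are simulated independently — the study
probes marginal autocorrelation effects, not cross-correlation. Binning is
left-closed right-open with the trailing partial bin discarded.

The experiment fixture emulates a multielectrode adaptation experiment:
11 neurons (55 pairs) split into high (uniform 20–35 Hz) and low (2–8 Hz)
firing-rate subpopulations, 8 orientations, control/adaptation conditions,
42 repetitions per cell, bin sizes 10–400 ms, with a configurable
dependence model per pair (independent, maxent, M1, M2). The generator
reproduces the *design* of such an experiment — balanced trial counts,
bimodal rates, many simultaneous hypotheses — but not stimulus-locked rate
dynamics within presentations, non-stationarity across trials, or genuine
cross-neuron heterogeneity of dependence; conclusions from fixture runs
are about the testing machinery, not about cortex.

## Experiment runners and reproducibility

The study runners (`run_power_study`, `run_lr_comparison`,
`run_autocorrelation_study`, `run_dataset_scan`) enumerate grid cells in a
fixed order and derive per-cell seeds as SeedSequence(base_seed,
spawn_key=(cell_index,)), with per-replication children spawned inside the
cell — end-to-end deterministic under a fixed base seed, and cells are
independent work units safe for any scheduler. Summary tables report
rejection counts, fractions (exactly the mean of per-replication
booleans), and Wilson binomial confidence intervals.

The "random correlation strengths" null study draws ρ ~ Uniform(0, 0.5)
(an interpretation; configurable), and the mixture comparison draws
m ~ Uniform(0, 1) with family `M1` by default.

**Problem sizes.** The shipped test suite and the acceptance script run
the simulation studies at 100 replications per cell (300 for the pooled
small-sample power study), N = 199 Monte Carlo samples for level studies
and N = 999 for power studies, and the default 15-step anneal — sizes
chosen so the full validation completes in minutes on one core while
keeping binomial error around each fraction near one to two percentage
points. All sizes scale up through `ExperimentGrid`.

## Known limitations

* The level guarantee of the nuisance maximization is inherited only up to
  the coverage of the confidence box; in every simulation the test is in
  fact strongly conservative (observed Type I ≈ 0 at α = 0.05), which
  costs power.
* Scalar information divergences cannot distinguish distributions with
  equal values of the summary; the confidence-set restriction mitigates,
  but power against alternatives whose divergence mimics the null within
  the box is limited by construction.
* Pairwise only: higher-order structure invisible in all bivariate
  distributions is not detectable; extending the grid to more neurons
  scales exponentially in memory and time.
* Poisson marginals only (the `MarginalSpec` interface is extensible);
  strongly non-Poisson marginals are flagged by the GOF baselines rather
  than absorbed.
* The likelihood-ratio baseline inherits the inexactness of its chi-square
  reference at realistic sample sizes; it is a comparison point, not a
  recommended test.
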