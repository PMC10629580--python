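# Methods

`chronodiv` asks whether lineage diversification tracked a changing
environment or simply the passage of time.  It fits environment- and
time-dependent birth–death models to an ultrametric phylogeny, compares
them with small-sample information criteria, correlates posterior
rate-through-time curves with paleoclimate proxies by detrended
cross-correlation, and tests tip-rate/covariate associations with
permutation schemes that respect phylogenetic pseudoreplication.  A
synthetic-data module generates all inputs with the statistical
structure these analyses assume, so every stage is testable offline.

## Time trees

A `TimeTree` is a rooted, binary, ultrametric phylogeny with node ages
in My before present (tips at 0, ages increasing into the past) and a
global sampling fraction `f` ∈ (0, 1] — the probability that an extant
species appears in the tree.  Validation is strict: polytomies are
rejected rather than randomly resolved (the likelihood assumes a binary
reconstructed tree), branch lengths must be positive, and a root-to-tip
spread above `1e-6 ×` crown age rejects the tree rather than silently
stretching it, because silent repair biases branching times.  A single
stem unifurcation at the root is tolerated; the likelihood operates on
the crown tree while per-tip path statistics (equal splits) include the
stem edge.

## Proxy preprocessing

Every proxy series passes through the same two steps before touching a
likelihood or a correlation: Tukey's 3RS3R compound running-median
smoother (medians of 3 repeated to convergence, splitting of two-point
flat extrema by the median end-value rule, re-smoothing, the cycle
iterated to a fixed point; endpoints copied), then linear interpolation
onto the consumer's age grid, clamped to the nearest knot outside the
proxy's coverage.  Iterating to a fixed point makes the smoother
idempotent; median end rules keep the output inside the input range.
The smoother's span and end rules are not dictated by any single
convention in the literature, so the classic compound variant was chosen
and is documented here.  Proxies are used on their native scale (δ18O is
not converted to °C).

## The birth–death likelihood

Rates are `constant`, `exp_time` (`r0·e^{βt}`), or `exp_env`
(`r0·e^{αT(t)}`).  With `r(t) = ∫₀ᵗ(λ−μ)du` and
`g(t) = 1/f + ∫₀ᵗ λe^{r}`:

- `Φ(t) = 1 − e^{r(t)}/g(t)` — probability that a lineage alive at age
  `t` leaves no sampled descendant;
- `Ψ(s,t) = e^{r(t)−r(s)}·(g(s)/g(t))²` — the kernel of an edge from
  age `s` (young) to `t` (old).

The log-likelihood sums `log λ(tᵢ)` over the n−1 internal nodes,
`log Ψ` over the 2n−2 crown-tree edges, and `n log f`.  Under the
default crown-survival conditioning the likelihood is divided by
`λ(t_c)·(1−Φ(t_c))²`: the crown event is conditioned upon, not
observed.  This matters.  Keeping the crown rate factor rewards any
model whose λ explodes at the crown age; with 4-parameter exponential
extinction models this manifests as a high-turnover parameter ridge
(λ, μ both growing into the past with λ ≈ μ) that spuriously gains
several log-units even on constant-rate data.  With the division, the
likelihood reduces exactly to the classic constant-rate
reconstructed-tree density (verified against an independent closed-form
implementation to ~3e-10), and the ridge's advantage collapses to the
ordinary overfitting expected of two extra parameters.
`conditioning="none"` keeps the raw product for oracle tests.

Numerics: `r` and `∫λe^{r}` are accumulated by cumulative Simpson
quadrature on a dense grid (default 2,000 points) into which the tree's
node ages are merged, so values at node ages are read off grid nodes
exactly — re-interpolating them is the error that would otherwise
dominate.  A net-diversification integral exceeding 500 raises an
explicit numerical error instead of propagating overflow.

## Fitting and model comparison

Each model is fitted by multi-start Nelder–Mead (default 5 starts,
deterministic given a seed).  Base rates are optimized on the log scale;
slopes are box-constrained to ±10.  The first start anchors λ0 at the
Yule-like estimate (n−1)/total branch length.  Models with extinction
additionally get a high-turnover start (μ0 = 0.8·λ0, mild positive
slopes), because slope-zero starts routinely miss that region of the
surface, and within each family the richer models are warm-started from
the simpler fits (no-extinction → constant → exponential), treating both
families symmetrically.

The working set is six models: exponential speciation driven by the
environment or by time × {no, constant, exponential} extinction.
Constant-speciation and linear-rate models are excluded: linear rate
functions are notoriously pathological over realistic covariate ranges
and bias family comparisons.  Extinction is a nuisance component only;
its estimates are never interpreted as historical extinction rates.
Comparison uses AICc with n = number of tips (the convention of the
standard R implementations; n = branching times would change little at
these sizes), Akaike weights computed jointly over all six fits, and the
family evidence ratio `Σω(env)/Σω(time)`.

Pure-birth check: with `f = 1` and crown conditioning, the analytic MLE
is `(n−2)/L` (total branch length L) — the conditioning removes one
speciation factor from the classic `(n−1)/L`.

## DCCA

Both series are integrated into profiles, partitioned into overlapping
boxes (default length ⌊N/4⌋, minimum 4), each box detrended by an OLS
line, and `ρ = F²xy/(Fx·Fy)` averages the residual moments over boxes.
ρ ∈ [−1, 1] (Cauchy–Schwarz), equals ±1 for (anti)identical series, and
is invariant under positive affine maps of either series.  A single
mid-range box scale with linear detrending is the default because the
method's scale parameter is genuinely a free choice; it is exposed as a
flag.  For an ensemble of posterior rate curves the proxy is smoothed
and interpolated onto the ensemble's own grid and one coefficient is
computed per draw; a one-sample Wilcoxon signed-rank test compares the
coefficient distribution with zero (a two-sample rank-sum variant
against a zero vector is available behind a flag).  Posterior draws are
strongly correlated, so this p-value is descriptive, not a calibrated
error rate — the mean coefficient is the headline quantity.  Burn-in
removal is a reader option (`burnin_frac`).

## Tip-rate tests

Equal splits: `ES_i = Σ_j l_j·2^{−(j−1)}` along the tip-to-root path
(j = 1 at the tip edge); DR = 1/ES is the tip-rate proxy.

Es-Sim: observed Pearson correlation of a continuous trait with
log(DR); the null re-simulates the trait as Brownian motion on the tree
with σ² estimated by ML (GLS root state profiled out) and recomputes the
statistic; two-tailed p by rank of |observed| among |null|.

STRAPP: tip rates are constant within rate regimes; the null permutes
which rate value each regime carries while regimes keep their tip sets,
nulling phylogenetic pseudoreplication without refitting rate models.
This is a structure-preserving simplification of resampling a Bayesian
posterior of shift configurations — the permutation unit is the regime,
not the tip — and regimes come from the tip table (here, the
simulator).  Statistics: Spearman (continuous), Mann–Whitney U distance
from its null mean (binary), Kruskal–Wallis H (categorical); a single
regime returns p = 1 by invariance.

D statistic: `D = (d_obs − mean d_BM)/(mean d_random − mean d_BM)`,
where `d` sums the absolute sister-clade differences of recursively
averaged tip states, `d_random` comes from shuffling tip states and
`d_BM` from Brownian simulations thresholded at the observed prevalence.
D ≈ 1 for a phylogenetically random trait, ≈ 0 for Brownian clumping,
negative for stronger clumping.

All permutation p-values use `(1 + #exceedances)/(1 + n)` so p is never
zero.  Tropical classification is a strict majority rule: more than half
the localities within ±23.5° latitude (boundary counts as inside), or
more than half exceeding 18 °C in temperature mode; exactly half is
nontropical.

## Bioregions

Membership is an input table over the seven classic orchid bioregions
(or any labels); endemics are species in exactly one region.  Grid maps
use equal-angle lon/lat bins sized to a target equatorial cell area
(default 200 km²) — richness is distinct species per cell and the cell
rate is the unweighted mean of those species' tip rates.  Cross-region
rate-through-time curves are compared with Pearson correlations
(constant curves are flagged undefined), and per-region exponential
rate-vs-temperature fits (`rate = a·e^{bT}`, nonlinear least squares
initialized from the log-linear regression) are restricted to a recent
window (default 10 My).

## Synthetic data

`simulate_climate` — monotone cooling trend with curvature (change
concentrated near the present: `s(u) = (1−e^{−ku})/(1−e^{−k})`),
sinusoidal oscillation whose amplitude can fade with age, and white
noise.  Defaults emulate a benthic-δ18O-like record: ~60% of the total
change in the most recent quarter of the span corresponds to k ≈ 3.5,
and My-scale oscillations are largest near the present.  A linear trend
(k = 0) is a degenerate choice for method evaluation: `e^{αT(t)}` then
equals `e^{βt}` almost exactly and the environment/time families become
statistically congruent.

`simulate_bd_tree` — forward birth–death from two crown lineages with
time-varying rates via thinning (the bound is 1.1× the windowed maximum
of λ+μ over 1-My windows, widened one grid node so linear interpolation
never exceeds it), extinct lineages pruned, extant tips binomially
subsampled with `f`, and replicates rejected until the sampled count
falls in the configured window with both crown lineages surviving —
matching the likelihood's crown conditioning.  The raw forward pass is
exposed separately so branching-process expectations
(`E[N] = 2e^{∫(λ−μ)}`, f-thinning) can be checked without the
conditioning.  Lineage counts above 100,000 abort a replicate; more
than 1,000 rejections abort the study.

`simulate_rtt_ensemble` — posterior-like rate curves: the true curve
times elementwise mean-one lognormal noise.  `simulate_traits` —
Brownian traits (Cholesky of the tree covariance), threshold-binary
traits at a target prevalence, and clade-painted rate regimes.
`simulate_occurrences` — Gaussian scatter around region centers.

The generator emulates the structure the analyses assume — smooth
parametric rates, uniform sampling, regime-constant tip rates,
independent lognormal posterior noise.  It does not emulate clade-biased
sampling, dating error, posterior autocorrelation between rate draws,
spatially realistic range shapes, or rate-shift processes, so passing
tests demonstrate correctness and calibration of the machinery under
its own assumptions, not robustness of the method to real-data
violations of them.

## Study sizes and frozen scenarios

The recovery study uses a frozen cooling curve (5 → 0 proxy units over
90 My, curvature 3.5, oscillation amplitude 1.0 / period 8 My fading
with age, noise 0.15), truth `λ(t) = 0.1·e^{−0.15 T(t)}`, crown age
76 My and f = 0.75, chosen so the branching-process expectation is
~150 sampled tips; the constant-rate null arm uses λ = ln(100)/76 so
tree sizes match.  Replicate studies run at 50 trees per arm with
5-start fits on a 1,000-point grid; calibration suites run 200 null
replicates (Es-Sim, STRAPP) and 100 (D statistic).  The acceptance
script reduces the recovery study to 20 replicates.  At these sizes the
environment/time families are separated by only a few log-units per
tree, so family selection rates carry binomial noise of ±6 percentage
points; the model-selection probability under the frozen conditions sits
near 0.75–0.80.

## Known limitations

- The reconstructed-process likelihood has near-congruent parameter
  sets (high-turnover ridges); estimates of extinction parameters are
  not interpretable and are treated as nuisance values.
- DCCA ensemble p-values ignore posterior correlation between draws and
  are anticonservative; they are reported for comparability, with the
  mean coefficient as the quantity of record.
- The AICc sample-size convention (tips) and the DCCA scale are
  documented choices, not uniquely determined by the method definitions.
- Equal-angle grid cells shrink in physical area toward the poles; cell
  geometry is configurable but no equal-area projection is attempted.
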