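# Methods

## Data model and preprocessing

The package consumes a genes × samples expression matrix (linear or log2
scale) and a sample annotation table (sex ∈ {M, F}, age in months,
replicate).  Gene and sample identifiers are opaque strings matched by
exact, case-sensitive equality; probe-set collapsing and symbol aliasing are
upstream concerns.

For temporal analysis, replicates are collapsed by the arithmetic mean
within each (sex, age) group, producing one profile per gene per sex on the
shared age grid.  Ages are mapped linearly onto [−1, 1] before any
polynomial basis is built; cubic powers of raw months (up to 18³) are
numerically hostile and the mapping changes nothing statistically.

Profiles are then standardized.  Two variants are provided:

* **per-profile** (default): each (gene, sex) row is centered by its own
  mean and divided by its own sample SD (ddof = 1).  Clustering becomes
  purely shape-based; level and amplitude are discarded.  Rows with SD
  below 1e−8 are removed and reported.
* **per-gene pooled** (`per="gene"`): the gene's male and female rows share
  the pooled mean/SD, so between-sex level and amplitude differences
  survive.

The per-profile variant imposes two exact constraints on every row (mean 0,
SD 1).  Because the mixture's residual variance σ² is shared across
clusters, those zero-variance directions subsidize ever-sharper components:
on low-noise synthetic data the penalized fit can profitably split each
true cluster in two.  This is a genuine property of the per-profile
variant, documented here rather than patched over; the concordance
experiments in the test suite therefore use the pooled variant, which does
not constrain individual rows.  On noisy real data the effect is expected
to be much weaker, but users clustering very clean data should prefer
`per="gene"`.

## The temporal mixture model

Each standardized profile `y_i ∈ R^T` follows, given cluster `c_i = k`,

    y_i ~ N( X β_k , Z D_k Zᵀ + σ² I_T )

* `X` (T×4): cubic fixed-effect basis `[1, s, s², s³]`; `β_k` is the
  cluster's mean trajectory.
* `Z` (T×3): quadratic random-effect basis; `D_k` (3×3 PSD) captures
  within-cluster heterogeneity of trajectory shape.
* `σ²`: residual variance, shared across clusters.  Five time points cannot
  identify a per-cluster residual variance alongside a full 3×3 `D_k`;
  heterogeneity belongs in `D_k` by construction.

## Entropy-penalized EM

The fit maximizes

    J = Σ_i log Σ_k π_k f_k(y_i) + λ N Σ_k π_k log π_k

The negative-entropy reward drains mixing weight from superfluous
components; components whose expected membership `π_k · N` falls below
`prune_threshold` (default 1.0) are annihilated, so the cluster count is
selected automatically starting from `K_max`.

One iteration comprises:

1. **E-step**: responsibilities `r_ik ∝ π_k f_k(y_i)` (log-sum-exp).
2. **π update**: the closed-form mass-reallocation fixed point
   `π_k ← n_k/N + λ π_k (log π_k − Σ_j π_j log π_j)` (which sums to one by
   construction), clamped at zero and safeguarded by backtracking toward
   the incumbent weights so the penalized M-step objective never decreases.
3. **β update**: responsibility-weighted generalized least squares per
   cluster, an exact conditional maximization.
4. **(D_k, σ²) update**: one EM step over the random effects — posterior
   means/covariance of `b_i` at the current parameters, then the standard
   closed-form updates — a generalized-EM ascent step.  σ² and the
   eigenvalues of each `D_k` are floored at `variance_floor` (1e−6) to
   prevent likelihood blow-up on noise-free inputs.

Together these make every iteration an ascent step of J for fixed λ; the
test suite asserts the monotonicity (tolerance 1e−8) on seeded random data.
When a component is pruned the objective is not comparable across the
dimension change, so `objective_trace` restarts at each prune; the full
history is kept in `objective_history`.

**Penalty weight.**  λ defaults to 0.5 and is annealed linearly to zero over
the first half of `max_iter`: penalize early to prune, finish with pure
maximum likelihood.  Weaker penalties (λ ≈ 0.1) leave redundant components
alive on well-separated data — the drift they induce scales with
`π_k (log π_k − mean)`, which is too small to beat the likelihood's mild
preference for splitting; λ = 0.5 reliably collapses a K_max = 10 start
onto 4 true clusters in the recovery experiments.  Because annealing only
lowers λ and the penalty term is non-positive, the recorded objective
remains monotone through the anneal.

**Other algorithmic choices.**

* Initialization: seeded k-means on the standardized profiles into `K_max`
  groups, then per-cluster OLS curves; `n_restarts` (default 10)
  independent starts, best final J kept.
* Convergence: relative change `|ΔJ| < tol · (1 + |J|)` (default tol 1e−6),
  checked only after λ has reached its final value.  Non-convergence at
  `max_iter` (default 200) is flagged, never silent.
* Canonical order: clusters are relabeled 1..K by descending membership,
  ties broken by the first mean-curve coefficient, so reported labels are
  deterministic.
* Components whose `(β, D)` coincide within 1e−6 are pooled at
  finalization.  Identical components are unidentifiable (any weight split
  yields the same mixture density); they arise only on degenerate inputs
  such as a set of identical profiles, which collapse to a single cluster
  with σ² at the floor.  On non-degenerate data the merge never triggers.
* Ties in the hard assignment go to the lowest cluster index.

## Differential-expression screen

Per gene: pooled-variance two-sample t (male vs female) across **all** time
points on the unlogged scale (log2 input is exponentiated first), df =
n_M + n_F − 2, two-sided p, Benjamini–Hochberg q over all genes in the
matrix (the full universe is the reproducible default; no pre-filter is
applied).  Genes with zero variance in both sexes and equal means get
t = 0, p = 1.  Male/female ratios are reported on unlogged means; a
non-positive female mean flags the ratio undefined rather than erroring.
The signature at threshold q keeps genes with q below it, signed +1/−1 by
the direction of the mean difference; equal means carry no direction and
are excluded.

## Concordance and overrepresentation

Cross-tabulation counts genes by (male label, female label); only genes
labeled in both sexes enter, and one-sided genes are excluded with a
report.  Concordant = on-diagonal.  Gene-set summaries report counts per
side with percentages rounded to integers for display (exact fractions
retained).  Overrepresentation is the one-sided upper-tail hypergeometric
test — the direction conventionally meant by "modified Fisher exact" in
enrichment tools — with BH q across sets; each set is intersected with the
user-supplied background before testing.

## Signature-association scan

Within each dataset, every signature gene present is z-scored across
samples (ddof = 1; flat genes dropped; duplicate gene rows: first
occurrence wins).  A sample's SA score is the unweighted mean of
sign · z over scored genes — unweighted so scores are comparable across
signatures of different sizes, and mean-zero per dataset by construction.
Datasets covering less than `min_coverage` (default 0.5) of the signature
are skipped with a warning.  "Strong" samples are those whose |SA| reaches
the pooled `strong_quantile` (default 0.90) quantile across all passing
datasets — a pooled threshold makes every dataset's 2×2 table well defined
against the rest of the compendium.  Each dataset is tested with the
two-sided Fisher exact test on (strong / not) × (this dataset / rest),
with BH q across datasets.  Being an exact conditional test on discrete
tables, the scan runs slightly conservative under the null (measured
false-positive rates a little below the nominal 5%).

## Synthetic data

`simulate_timecourse_study` draws, per gene, a male cluster from π, flips
the female cluster (uniformly among the other labels) with probability
`discordant_fraction`, draws an independent random effect per sex — each
gene × sex profile is a distinct object — and emits
`y = Xβ_k + Zb + ε` replicated `n_replicates` times per age with
ε ~ N(0, σ²).  Values are mapped to expression scale by a per-gene affine
transform with lognormal baselines (medians 100 and 15), giving the
unlogged t-test path a realistic mean–variance spread.  The default
conditions mirror the study design: 2 sexes × ages {3, 6, 9, 12, 18} × 4
replicates, 4 clusters, σ² = 0.05.

The canonical cluster shapes are standardized cubics chosen to remain
distinct after per-profile standardization; exactly-linear curves are
deliberately absent because a linear family collapses to a single point
under standardization (a degenerate atom no Gaussian mixture models
sensibly).  `simulate_profile_mixture` bypasses the replicate/expression
machinery and draws fit-ready profiles straight from the mixture, for
model-faithful parameter-recovery experiments.

`simulate_compendium` builds unit-variance noise datasets containing all
signature genes plus decoys; the first `n_embedded` datasets shift the
signature genes of half their samples by `effect_delta · sign`.

**What the generator does not emulate**: probe-level microarray noise,
batch effects, array QC failures, correlated genes within pathways, or
heavy-tailed expression distributions.  Passing recovery tests therefore
demonstrates correctness of the algorithms under their own assumptions,
not performance on real microarray data.

## Problem sizes used in the recovery experiments

Cluster recovery: 2,000 profiles from K = 4, fit at K_max = 10 with 3
restarts, 5 seeds.  Concordance: a 2,000-gene study at 30% discordance,
pooled standardization.  Scan calibration: 200 scans × 12 datasets × 40
samples.  t-test calibration: 10,000 null genes.  These sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the whole suite fast on a single CPU.

## Known limitations

* The entropy penalty cannot separate exactly equal-weight duplicate
  components by itself; symmetry is broken by the data, the k-means starts,
  and the final duplicate merge.
* Shared σ² plus per-profile standardization can over-split clean synthetic
  data (see above).
* The t-test screen ignores time entirely, as specified; a time-stratified
  or moderated (empirical-Bayes) variant is out of scope.
* The scan's "strong" threshold and 2×2 orientation are one reasonable
  convention; both are configurable, and rankings — not absolute p-values —
  are the robust output.
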