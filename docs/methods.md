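# Methods

## Model

For n individuals with phenotype vector y (trait records, or sire-level
pseudo-phenotypes such as EBV/DRP) and a panel of m biallelic markers with
dosages x_ij ∈ {0,1,2}, the marker matrix is centred and scaled per marker,

    W_ij = (x_ij − 2 p_j) / sqrt(2 p_j (1 − p_j)),

with p_j the alternate-allele frequency observed in the analysed sample
(never an external reference panel).  A marker set S with m_S members
defines G_S = W_S W_S′ / m_S, and the partitioned model is

    y = 1μ + g_S + g_¬S + e,
    Var(g_S) = G_S σ²_S,  Var(g_¬S) = G_¬S σ²_¬S,  Var(e) = D σ²_e,

with D diagonal and fixed: the identity when no reliabilities are given,
otherwise D_ii = 1 / w_i with w_i = r_i²/(1 − r_i²) from the record's
deregressed-proof reliability r_i (weights below a configurable
reliability floor, default 0.01, are rejected rather than clipped, so
weights stay positive and finite).  The one-component model replaces the
two genetic terms with g ~ N(0, G σ²_g), G = W W′/m.

The per-marker 2p(1−p) scaling is what makes the decomposition

    G = (m_S G_S + m_¬S G_¬S) / m

an algebraic identity for every partition, so the one-component model is
the two-component model constrained to σ²_S/m_S = σ²_¬S/m_¬S — the
infinitesimal null hypothesis.  A global-denominator scaling
(Σ 2p(1−p)) would break this identity and was rejected.  The complement
GRM is recovered from the identity (m G − m_S G_S)/m_¬S rather than a
second matrix product; both routes agree to floating-point noise and the
identity route guarantees exact nesting.

Individual alignment is genotype-order canonical; individuals missing
either genotype or the analysed trait are dropped (minimum 3).  Dosage is
the count of the alternate allele (VCF ALT; PLINK A1); the GRM is
invariant to global allele flips after centring, so this is a
documentation choice, not a numerical one.  Coordinates are 1-based
closed intervals throughout; strand is ignored; marker-in-gene membership
is purely positional with an optional symmetric flank (default 0 bp).
Markers with min(p, 1−p) ≤ 0.01 are removed before scaling (strict
inequality; the boundary itself is excluded, configurable).

## Estimation

Variance components are estimated by restricted maximum likelihood with
intercept-only fixed effects; REML (not ML) log-likelihoods are used for
both models, which share the fixed-effects structure, so their difference
is a valid likelihood ratio.  The restricted log-likelihood includes the
−(n−1)/2·log 2π constant so closed-form Gaussian values match exactly.

The optimizer is average-information (AI) REML:

- gradient ∂ℓ/∂θ_i = −½(tr(P M_i) − y′P M_i P y) and AI matrix
  ½ (M_i P y)′ P (M_j P y), computed from an explicit V⁻¹ (Cholesky +
  LAPACK `dpotri`), which makes every trace an O(n²) Hadamard sum;
- the AI step is solved with an active set: components an unconstrained
  step would drive negative are pinned at the boundary ε = 1e−10·Var(y)
  and the system is re-solved for the free components (without this, a
  single boundary component stalls the whole fit in slow EM updates);
- the step is halved up to six times if it fails to improve the
  likelihood, then an EM-REML step (monotone, admissible) is taken;
- convergence: relative restricted-log-likelihood change < 1e−8 or
  projected-gradient norm < 1e−6, at most 100 iterations; starting values
  sit at the null hypothesis (σ²_e = 0.5·Var(y), genetic half split
  proportionally to marker counts).

Likelihood ratios LR = 2(ℓ_partitioned − ℓ_simple) are truncated to 0 when
in (−1e−4, 0); larger negative values are flagged `negative_lr`.  Fit QC
additionally flags `variance_inflation` (total estimated variance > 4 ×
sample phenotypic variance) and `near_zero_component` (any component
< 1e−6 × sample variance).  Only `negative_lr`, `variance_inflation` and
non-convergence mark a fit as unusable: a genetic component estimated *at*
the zero boundary is a legitimate REML solution, common for small random
groups under the null, and excluding such fits would censor the lower half
of the null distribution and bias the median-H²_set diagnostics; the
near-zero flag is therefore advisory.  In calibration runs at the default
study size, well under 2 % of random-group fits are excluded.

## Competitive null and thresholds

Random gene groups generate data under the competitive null "all markers
contribute alike".  Per group: a target marker count is drawn uniformly
from {1, …, max_target}; genes with ≥ 1 mapped marker are sampled
uniformly without replacement until the unique-marker union first reaches
the target (the union may overshoot by part of the last gene; if the gene
universe is exhausted first the full union is returned and flagged).  The
reference ceiling max_target = 50 000 corresponds to a 637 951-marker
panel with ~39 % of markers mapped, i.e. about one fifth of the mapped
markers; simulation-scale runs default to max_target = 0.2 × mapped
markers to preserve that ratio.  The one-component fit does not depend on
S and is computed once per trait and reused for every group and pathway.
Per-group RNG streams are spawned deterministically from the master seed;
a batch is bit-for-bit reproducible.

Threshold curves LR95/H²95 (and the medians LR50/H²50) are monotone
quantile regressions of the statistic on group size: piecewise-linear in
size over ~12 quantile-spaced knots, minimizing the pinball loss at
τ ∈ {0.5, 0.95} subject to a non-decreasing shape, with a total-variation
penalty λ on the slope, solved exactly as a linear program (HiGHS).  The
monotone constraint is the substantive content; λ is chosen by 5-fold
cross-validated pinball loss over a dimensionless grid by default, because
any fixed λ value is specific to one tool's parameterization.  Curves are
clamped outside the fitted size range.  When a focal gene is configured,
curves are additionally stratified into focal/non-focal groups (each
stratum needs ≥ 50 usable samples, otherwise a single "all" stratum is
used).  A pathway is *interesting* when LR ≥ LR95(m_S) **and**
H²_set ≥ H²95(m_S), both inclusive, evaluated at its own size and stratum.

For p-values, the empirical null LR distribution (negatives truncated at
0) is compared by Kolmogorov–Smirnov distance to χ²(1), χ²(2), and an
equal-weight mixture of the two (the mixture weight is configurable; equal
weights are the symmetric default since no canonical weighting exists for
this comparison).  Ties break toward the lowest df.  Pathway p-values are
the upper-tail probability of the selected reference (LR = 0 maps to
p = 1), adjusted by Benjamini–Hochberg, significant at q ≤ 0.10 by
default.

## Focal region

A known large-effect gene (the *DGAT1* case in dairy cattle) violates the
infinitesimal null through long-range LD around it.  `focal_region_genes`
returns every gene whose interval overlaps the focal gene's interval
padded by 500 kbp on each side — interval-gap distance, not midpoint
distance, which is the conservative reading of "within 500 kbp".  Random
groups and pathways touching this list carry a focal flag used for curve
stratification and reporting.

## Synthetic data

The generator emulates the statistical structure of a dense sire-panel
study at desk scale; its defaults are the package's study conditions:

- genotypes: n = 500 individuals × m = 5000 markers on 5 chromosomes,
  marker spacing 4 kbp (HD-panel density; a chromosome is 4 Mbp, so the
  500-kbp focal window is a small fraction of it).  Dosages are sums of
  two latent-Gaussian gametes thresholded at the allele-frequency quantile
  (frequencies uniform on [0.05, 0.95]); gametes within an LD block of 25
  markers share a factor with loading sqrt(ρ_LD), ρ_LD = 0.6, blocks are
  independent — Hardy–Weinberg margins with block LD;
- annotation: non-overlapping gene intervals with log-normal lengths
  (median 40 kbp ⇒ ~10–16 markers per gene, matching a ~14-SNP/gene
  regime) placed uniformly until 40 % of markers fall inside genes;
  20 pathways with log-normal gene counts (median 10), each resampled to
  span ≥ 2 chromosomes, so pathway marker sets are genome-scattered;
- phenotypes: y = W a + e on a unit-variance scale with total genomic
  heritability h² = 0.5 by default (pseudo-phenotypes of progeny-tested
  sires carry most of the genetic signal; the null-calibration study uses
  h² = 0.3).  Effects a are i.i.d. within stratum: equal variance
  everywhere (infinitesimal null); a share ρ_S concentrated on a target
  set (enriched); or one marker inside the focal gene carrying 25 % of the
  genetic variance over an infinitesimal background (focal).  Because
  effects are independent across markers, Var(Wa) equals the configured
  σ²_g in expectation even under LD, and the fitted covariance
  σ²_S G_S + σ²_¬S G_¬S is exactly the simulation's — recovery tests probe
  estimator behaviour, not model misspecification.  Optional reliabilities
  from a Beta distribution (clipped to [0.05, 0.99]) induce
  heteroskedastic residuals σ²_e/w_i through the same r²/(1−r²) weights
  the estimator uses.

What the generator does not emulate: pedigree/family structure beyond what
the all-marker GRM induces, selection, allele-frequency–effect coupling,
long-range LD between blocks, and realistic gene-length/pathway ontologies.
Passing tests therefore certify the estimator and the resampling
machinery under a correctly specified covariance with block LD — not
robustness to population structure misspecification, which real sire data
would stress harder.

## Problem sizes and numerics

Calibration runs fit 800 random-group models at n = 500, m = 5000 (about
a minute on one core: each AI iteration is one n³/3 Cholesky + n³/3
inversion); recovery studies use 25 replicates × 3 enrichment levels;
brute-force oracle comparisons use n ≤ 40 panels, where a coarse
variance-fraction grid plus Nelder–Mead polish independently maximizes the
same restricted likelihood.  Dense GRMs are held in memory — n is the
limiting dimension, not m.  Degenerate inputs are errors, not silent
fixes: monomorphic markers must be filtered before scaling, empty marker
sets and full-panel "subsets" are rejected, and an all-zero LR sample
cannot select a χ² reference.

## Known limitations

- Single trait, intercept-only fixed effects; multi-trait extensions and
  additional covariates are out of scope.
- No BLUP/prediction output; the package quantifies variance, it does not
  predict breeding values.
- The LP quantile fit is exact but dense; null tables beyond ~10⁴ groups
  would warrant a sparse formulation.
- A fitted 95th-percentile curve's out-of-sample coverage has sampling
  noise of roughly ±1.5–2 percentage points at 400 training groups; that
  is a property of estimating an extreme quantile from finite resamples,
  not of the optimizer.
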