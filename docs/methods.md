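# Methods

This note records the model, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Model and null distributions

**Global statistic.** For a ligand/receptor pair the inputs are per-spot
composite expression vectors: library-size-normalized (`scale` counts per
spot, default 1e4), log1p-transformed, and averaged over subunits
(arithmetic mean by default; geometric mean available as a stringent
option that zeroes the composite wherever any subunit is absent). The
global bivariate Moran's R (README) measures spatial cross-correlation of
ligand against receptor through the weight matrix W. R is invariant to
affine rescaling of either input and symmetric in its arguments for
symmetric W.

**Weights.** RBF weights `exp(-d²/2l²)` with a hard cutoff applied to the
*unnormalized* kernel value (entries `< cutoff` are zeroed, limiting
support to `d ≤ l·sqrt(-2 ln cutoff)`), an optional zeroed diagonal for
single-cell-resolution data, and a final global rescaling to total mass n.
The order is cutoff → diagonal → normalization, so the sum-to-n invariant
holds for the matrix actually used. The directed KNN alternative (default
6 neighbours, intended for contact/ECM signalling) has exactly k unit
entries per row before normalization; distance ties are broken by spot
index through a stable sort, and a `symmetrize` flag takes the elementwise
maximum with the transpose. Matrices are dense up to 5000 spots and sparse
beyond.

**Null.** Both tests target the exchangeability null: the spot labels of
one variable are re-paired uniformly at random. The permutation mode does
this literally (one shared, seeded permutation set reused across pairs;
p floored at 1/(n_perm+1) so downstream −log and FDR transforms stay
finite). The analytic mode uses the exact first two permutation moments.
The variance formula in the README is derived by averaging the exact
conditional permutation variance over the label assignment of the second
variable; it is valid for arbitrary, including asymmetric, W, and reduces
to the familiar symmetric-W expression. The same derivation at spot level
gives

    Var(R_i) = σ₁²σ₂² [ 2(n·S2_i − r_i²)/(n−1) + 2((n·w_ii − r_i)/(n−1))² ]

with S2_i the row sum of squared weights. Both formulas match exhaustive
enumeration of all label permutations at n = 7 to 1e-10 (the test suite
performs this enumeration) and 200k-draw Monte Carlo at n = 200 to well
under 2%. Large-n limits recover the commonly quoted approximations
(e.g. 2σ₁²σ₂²(S2_i + w_ii²) locally); the exact forms are kept because the
finite-n correction terms are free and the permutation oracle is the
ground truth. Testing is one-sided (upper tail) throughout: negative
spatial association is visible in R's sign but never selected.

**Selection.** Benjamini–Hochberg across all tested pairs; `selected`
means adjusted p below the threshold (default 0.1). Pairs with constant
composite ligand or receptor are reported untested rather than silently
dropped. An optional fine-tuned ranking statistic `w_l·I_l + w_r·I_r + R`
adds univariate auto-correlation terms; both weights default to 0, in
which case it is exactly R.

**Local analysis.** Inputs are gene-wise standardized with the population
(divide-by-n) convention — chosen so σ₁ = σ₂ = 1 plugs directly into the
permutation moments — and clipped to ±10 so a handful of extreme spots
cannot dominate; clipping happens after standardization. Standardization
can be turned off (centered-only inputs retain expression magnitude); only
the permutation test is offered then, because the analytic variance
assumes a common scale. The quadrant filter sets p_i = 1 wherever both
centered ligand and centered receptor are ≤ 0, so "low-low"
neighbourhoods never become hits; since clipping is symmetric around the
mean it cannot change these signs. Hits are thresholded at raw local
p < 0.1 — deliberately no per-spot FDR, as the hit maps are exploratory
and feed the pattern clustering.

## Downstream components

**Patterns.** Each selected pair's binary hit vector is smoothed with a
row-normalized RBF kernel at a user-stated length scale and the smoothed
profiles are clustered by k-means (fixed seed, n_init 10). This is a
deliberate, documented substitution for Gaussian-process expression-
histology mixtures: it preserves the operational behaviour (pairs hitting
the same region share a pattern; planted disjoint blocks are recovered
with adjusted Rand index 1) at a fraction of the machinery. Pairs with
fewer than 10 hit spots are excluded as unplaceable.

**Enrichment.** One-sided Fisher's exact test per pathway on the 2×2
table (selected vs not) × (in pathway vs not) over the filtered database;
pathways with fewer than 2 selected pairs are flagged. The implementation
is scipy's; the tests verify it equals direct hypergeometric tail
summation on every small table.

**Chord edge weights.** `n_AB = Σ_ij w_ij · sender_i · A_i · receiver_j · B_j`
for cell-type weight vectors A (senders) and B (receivers); bilinear in
the type weights, so edges over all type combinations sum to the total
directed flow. The per-pair variant uses each pair's own sender/receiver
vectors.

**Cell-type regression.** OLS (with intercept) from the spots × pairs
matrix of local p-values to spots × types weights, fitted and evaluated on
all spots; reported as the Pearson correlation between flattened predicted
and observed weights. Rank-deficient designs fall back to the least-norm
solution with a warning.

**Differential test.** Pairs × samples z-scores (undetected pairs enter
as 0) are modelled per pair by a Gaussian linear model with and without
the condition covariate. The default estimates the error variance *pooled
across pairs*: z-scores share a unit null scale by construction, and with
the typical 2–4 replicates per condition a per-pair variance on n−2
degrees of freedom is too unstable to be useful — at 3+3 samples the
per-pair chi-squared LRT has a 13% false-positive rate at nominal 5%,
while the per-pair exact F test is calibrated but recovers only ~20% of
3-sd effects. Pooling restores both: the scaled statistic
(RSS_reduced − RSS_full)/σ̂²_pooled is essentially exactly chi-squared(1)
under the null (pooled error df are large) and recovers ~85% of 3-sd
effects at FDR < 0.1. `var_method="per_pair"` provides the classical
alternatives (`p_method="fstat"` exact, `"chi2"` asymptotic). Direction
labels use the 30%/70% quantiles of the cross-condition z difference;
only FDR-significant pairs outside the quantile cutoffs are labelled
condition-specific. A numeric covariate with >2 levels is treated as
continuous (the label is the slope sign). The pooled default assumes
pairs share an error scale; with strong per-pair variance heterogeneity
(e.g. mixing wildly different platforms) prefer `per_pair`.

## Synthetic data

Each gene is a latent unit-variance Gaussian field over the spots, mixed
from four standardized components with variance fractions summing to 1 —
intrinsic (linear in the paired receptor field), environment (GP with RBF
covariance, length scale 2.0 grid units), interaction (W·receptor with the
same RBF weights the analysis uses, l = 1.2, cutoff 0.2 on the unit
lattice), and white noise. Fields become counts through a lognormal-
Poisson read-out (dispersion 0.7, mean depth 1 count/gene/spot — spot
platforms spread a few thousand UMIs over >15k genes, so a typical LR
transcript is seen at zero-to-few copies per spot). Receptors and null
ligands carry the zero-interaction profile; interacting ligands whose
realized correlation with their receptor is negative are sign-flipped.
Defaults: 300-spot unit lattice, 500 pairs, zero-interaction profile
env 0.02 / noise 0.98; when interaction is simulated at fraction f the
remaining mass keeps that ratio (env 0.02(1−f), noise 0.98(1−f)).

Two conditions informed the zero-interaction profile. First, most genes
in spot-level data show no detectable spatial variability, so a couple of
percent of environmental variance is the realistic default for a *null*
gene. Second — a genuine limitation worth stating — Moran-type tests
target an exchangeability null, and when **both** members of a pair carry
substantial autocorrelation at the analysis scale, permutation and
analytic tests alike become anti-conservative (the Clifford–Richardson
phenomenon; at env 0.3 the null z-scores here have sd ≈ 2.2 and the
false-positive rate at nominal 5% exceeds 20%). Passing calibration
benchmarks on this generator therefore demonstrates correctness *within*
the exchangeability regime; on tissues where both ligand and receptor are
strongly and smoothly patterned for reasons unrelated to signalling, the
test measures spatial co-occurrence, not causal communication, and its
p-values should be read accordingly.

At these settings the pipeline operates in the regime familiar from
spot-level benchmarks of this statistic: AUROC ≈ 0.92–0.94 at 25%
interaction rising to ≈ 0.99 at 99%, power ≈ 0.7 at p < 0.05 and 25%
interaction, Spearman ≈ 0.99 between permutation and analytic p-values —
all recomputed, never hard-coded, by `scripts/acceptance.py` and the
acceptance tests.

**Variance-component fit.** The generative model is inverted by maximum
likelihood: the standardized composite ligand is modelled as a zero-mean
multivariate normal whose covariance is a non-negative mix of the linear
kernel on receptor subunits, an RBF kernel on coordinates, the linear
kernel on W·receptor, and the identity; kernels are trace-normalized so
the fitted σ² shares are directly the variance fractions. Optimization is
L-BFGS-B over log-variances (bounds e⁻¹² to e⁶, ftol 1e-6) from 3 seeded
restarts; Cholesky factorizations get an escalating jitter (1e-10 × 100
per retry) so duplicated spots do not crash the fit. The dense fit is
limited to 2000 spots. Fitted components can be rescaled to any
interaction fraction to regenerate data from a fitted pair. On noise-free
latent fields the interaction fraction is recovered to within a few
percent; on counts, read-out noise is (correctly) absorbed into the noise
component, so recovered non-noise fractions shrink proportionally.

## What the synthetic benchmarks do not show

The generator draws smooth Gaussian fields with stationary covariance on
a lattice; real tissue has anisotropic, non-stationary structure, cell-
type mosaics, segmentation artefacts and gene-gene correlation beyond the
single planted partner. The count model is lognormal-Poisson with a
common depth; real spots differ in size and quality. Calibration and
power results here therefore validate the statistics and their nulls, not
the biological fidelity of any particular dataset analysis. Parameter
presets for real data (l = 1.2/cutoff 0.2 for ~200 μm-pitch unit-grid
slides; l = 75 for 100 μm-pitch coordinates in platform units; KNN-6 for
contact signalling) follow common practice for those platforms and should
be reviewed per dataset — coordinates are treated as planar Euclidean in
platform units, with no unit conversion.
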