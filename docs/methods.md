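# Methods

This note documents the statistical model behind each stage of `mdgpipe`,
the defaults and why they were chosen, what the synthetic cohorts emulate,
and the numerical conventions that matter for reproducing results.

## Data model

The pipeline consumes four coupled tables: a CpG × sample beta matrix
(β = M/(M+U) ∈ [0,1], from methylated/unmethylated array intensities), a
gene × sample nonnegative integer count matrix, a BED-like CpG → gene map
with region labels (each CpG kept at its first occurrence only), and a
sample table with phenotype ∈ {NT, I, II, III, IV}, follow-up time and an
event indicator. All analysis contrasts are *progression vs baseline*:
each tumor stage against non-tumor tissue. The sequential scheme
(I vs NT, II vs I, …) is retained behind `sequential_contrasts` because it
is the natural alternative, but baseline contrasts are the default: with
staged tumors the dominant methylation differences separate tumor from
normal, and consecutive stages differ too little for stable calling.

## Preprocessing

Genes are removed if (in this order) they are absent from the annotation,
have zero counts in more than 50% of samples, or have mean count below 10.
Both boundaries are strict in the directions stated: a gene with exactly
half zeros, or mean exactly 10, is retained. The order matters only
through the annotation step, since the other two filters commute. CpGs
with any missing beta value are dropped outright; no imputation, because a
median-based gene classifier is sensitive to imputed mass near the 0.4/0.6
thresholds.

`within_bin_quantile_normalize` offers a simplified covariate-bias
correction: genes are split into equal-frequency bins of a per-gene
covariate (GC content, length), and within each sample every bin's counts
are full-quantile mapped onto the sample's pooled count distribution.
Output is rounded half-even back to integers because the downstream test
models counts. Batch correction is deliberately out of scope; an
externally corrected matrix can be supplied in place of the raw counts.

## Differential expression

Size factors are median-of-ratios: for genes positive in every sample,
factor_j = median_g (c_gj / geometric mean_g). The test is a Wald test on
Δ = log2(m_t + ½) − log2(m_b + ½), with group means on the normalized
scale and the delta-method variance (m + α m²)/(n (m + ½)² ln²2) per
group. The dispersion α is pooled method-of-moments,
α = (s² − m̄)/m̄², floored at 1e-8 so Poisson-like genes do not produce
negative variances. The pseudocount ½ bounds fold changes for zero-mean
groups and is configurable. P-values are BH-adjusted; `up` requires
LogFC > 2.0 *and* FDR < 0.05, both strict; `down` is the mirrored rule —
the underexpression threshold is assumed symmetric. No dispersion
shrinkage across genes is attempted: the cohort sizes this pipeline
targets (≥ 24 per group) make per-gene moments adequate, and numerical
equivalence with any particular NB-GLM package is a non-goal.

## Differential methylation

Per CpG: mean difference Δβ (target − baseline) and a two-sided Wilcoxon
rank-sum p-value — exact (via the null permutation distribution) when both
groups have ≤ 8 samples, otherwise the normal approximation with tie and
continuity correction, vectorized across CpGs. A call requires
|Δβ| ≥ 0.15 and p < 0.05 on the *raw* p-value; no multiplicity correction
by default (a BH option exists) because the mean-difference effect filter,
not the p-value, is the operative screen at these sample sizes. The
0.4/0.6 band applies to the tumor-group mean of the CpG: `hyper` needs
tumor β > 0.6, `hypo` needs < 0.4. The band references the tumor side, so
the strict group-swap antisymmetry of the test holds exactly only with the
band disabled (`apply_band=False`, also the switch for band-free DM
counting).

Bootstrap DM counting redraws `group_size` samples per phenotype (default:
the smallest group, without replacement when the group is larger) and
reports the mean and percentile interval of hyper/hypo counts over
replicates — this removes the mechanical dependence of DM counts on group
size when phenotypes are unbalanced. Sample clustering uses Euclidean
distance on beta profiles with average linkage, cut at k = 2; NT purity is
the fraction of NT samples in the NT-majority cluster. These settings are
conventions, chosen once; methylation separates tumor from normal strongly
enough that the qualitative result does not hinge on the linkage.

## MDG calling

A gene is a candidate for a contrast when ≥ 1 of its *promoter* CpGs is DM
and its DE status is not `none`, both from the same contrast. The
classifier is the median β over all (promoter CpG, sample) cells in the
tumor group: < 0.4 with `up` → hypo-MDG, > 0.6 with `down` → hyper-MDG,
strict at both thresholds (a median exactly at a threshold is not
classified). The two classes are disjoint by construction. NT-side medians
are reported for transparency but play no role in classification. Stage
sets intersect gene ids across contrasts; a gene may carry different
medians per contrast. Role annotation joins an oncogene list and a
tumor-suppressor list; genes present in both are labeled `both`.

## Mutual-information networks

Expression input is size-factor-normalized counts; the estimator is
rank-based, so any monotone transform (log, CPM scaling) leaves it
unchanged. Each profile is discretized into B = max(2, ⌊n^(1/3)⌋)
equal-frequency bins and MI is the plug-in sum Σ p(a,b) ln[p(a,b)/(p(a)p(b))]
with the Miller–Madow correction
[(m_x − 1) + (m_y − 1) − (m_xy − 1)]/(2n) added (m = occupied cells),
clamped at zero. The cube-root bin rule keeps the estimator's bias an
order of magnitude below the MI of a moderately correlated Gaussian pair
at every n the pipeline meets (verified against the closed form
−½ ln(1 − ρ²): within a few percent at ρ = 0.8, n = 10⁴, and ≈ 0 under
permutation); a √n rule would leave a bias of several tenths of a nat at
n = 10⁴, larger than most true signals. Networks pair every MDG with every
gene in the matrix (the MDG-only mode is a flag), exclude self-pairs,
canonicalize edges as gene_a < gene_b and deduplicate. Top-k filtering
keeps the k largest-MI edges with ties broken lexicographically, making
the result independent of input order. ARACNe-style DPI pruning (drop the
weakest edge of a triangle when below (1 − tol)·min of the other two,
tol = 0.15) is implemented but off by default: the analysis is defined by
MI + top-k.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines; the module adds the split rule — samples strictly above the
gene's median expression are `high`, ties go `low` (deterministic) — and
pools all tumor stages by default (a stage filter exists). Times are used
in the unit supplied (days), with no administrative horizon. Hand-computed
product-limit values and a brute-force Σ(O − E)²/V expansion serve as
independent oracles in the tests.

## Enrichment

Over-representation is the upper-tail hypergeometric probability
P(X ≥ overlap) with universe = genes surviving preprocessing (configurable).
Sets are restricted to the universe first; results are filtered strictly
at raw p < 0.01 (α = 1 disables filtering), with BH values reported
alongside for reference.

## Synthetic cohorts

`simulate_cohort` emulates the structure the pipeline targets: five
phenotype groups with unbalanced sizes (default 24/158/31/72/57), beta
values drawn from Beta(μφ, (1−μ)φ) with a bimodal baseline (per-CpG means
at 0.2 or 0.8 with equal probability, precision φ = 50), and counts from a
negative binomial (dispersion 0.1) with log-normal gene means
(ln mean ~ N(6, 1), so virtually all genes clear the mean-count filter).
Planted hypo genes have promoter means 0.8 in NT shifted down by 0.45 in
tumor groups with counts scaled by 2³; hyper genes mirror this. The shift
of 0.45 from the 0.2/0.8 anchors is chosen so planted tumor medians cross
the 0.4/0.6 thresholds essentially always at 5 CpGs per gene, i.e. the
planted truth is recoverable in principle and failures indict the method,
not the generator. Effects apply to all tumor stages by default
(`planted_stages` restricts them); missing values are injected completely
at random only on request. Survival times are exponential with baseline
hazard 1/1000 per day, the hazard multiplied by `hazard_ratio` for samples
above the link gene's median expression, and independent censoring: with
probability `censor_rate` a sample is censored at a uniform fraction of
its event time. `simulate_block_cohort` adds what mean-shift planting
cannot: a gene block sharing a per-sample latent log-normal factor
(σ = 1), hence genuinely co-expressed *within* a phenotype, for network
recovery and neighbor-concordance experiments.

What the generator does *not* emulate: probe-level artifacts and batch
structure, realistic genomic CpG geography (every simulated CpG is
promoter-labeled), correlated null genes, stage-dependent effect sizes, or
competing risks in survival. Passing tests therefore demonstrate that the
implementation recovers the signals it defines under its own noise model —
calibration and correctness, not performance guarantees on array data.

## Numerical conventions and degenerate inputs

Strict inequalities at every published threshold (LogFC 2.0, FDR 0.05,
Δβ 0.15, p 0.05, β 0.4/0.6). Constant CpGs get p = 1 and no call; genes
with all-zero counts in both groups are excluded from DE with missing
statistics; constant expression vectors give MI = 0 and an all-`low`
median split with a warning. Ties: average ranks in the Wilcoxon and in MI
binning; round-half-even when normalized counts are re-integerized;
lexicographic tie-breaks in top-k edges. All randomness flows through
`numpy.random.default_rng` seeds recorded in the run manifest; identical
seeds give byte-identical outputs (checksummed in `manifest.json`).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on cohorts of 150–2,000
genes (5 promoter CpGs each), 24–342 samples, 20-replicate null batches,
200-replicate log-rank size/power simulations, and a 210-gene network
(≈ 22k pairs) — sizes chosen so the full battery of recovery, calibration
and oracle checks runs on a laptop-class single core in a couple of
minutes while keeping every Monte-Carlo interval tight enough to be
decisive.

## Known limitations

The DE test is a moments-based NB Wald test: adequate at n ≥ 24 per group,
anticonservative for very small groups, and not numerically concordant
with shrinkage-based packages. Raw-p DM filtering controls nothing
family-wise; it reproduces the analysis definition, not a discovery
guarantee. The MI estimator's discretization loses information for very
small n (B = 2 bins below n = 27). CpG-to-gene assignment trusts the
supplied first-occurrence map; enhancer and gene-body methylation are out
of scope.
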