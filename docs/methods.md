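# Methods

This note documents the statistical models, the defaults and why they
are what they are, what the synthetic data does and does not emulate,
and the numerical conventions used throughout `dipkit`.

## Coordinates and input conventions

All coordinates are 0-based half-open (BED-native) in every module;
refFlat gene models are assumed to use the same convention for
txStart/txEnd, as UCSC dumps do. Tags are stored as 5′ positions (the
interval start for plus/unstranded tags, `end − 1` for minus-strand
tags); no fragment extension is applied by default — an extension, if
wanted, belongs to windowing, not I/O. Duplicate gene records collapse
to the longest transcript.

## Enrichment segmentation

Tags are counted in sliding windows of `window_bp` = 1000 stepped by
`window_step_bp` = 500 (half-overlap balances resolution against cost;
a tag contributes to every window containing it). The null is built by
Monte-Carlo permutation: in each of `n_permutations` rounds every tag
position is redrawn uniformly within its chromosome, preserving the
per-chromosome tag count, and the window counts of all rounds are
pooled into one empirical distribution. A window's empirical p is the
pooled upper-tail probability of its count with the (1 + k)/(1 + N)
convention, so p ∈ (0, 1]. Windows with p ≤ α are merged into regions
when they overlap or lie within `merge_gap_bp` (default: one window);
region p = min window p, extent = union of merged windows. Trailing
partial windows are kept; their counts are rescaled to full-window
equivalents (identically for observed and permuted data) before any
tail lookup.

Two α's matter and they are different things. The *calibration* α
(default 0.001) is a per-window type-I level: on background-only data
the fraction of windows called tracks α up to the discreteness of
integer counts (the achievable tail at the integer cutoff is ≤ α, which
is why calibration ratios of ~0.7–0.8 at λ = 5 are expected rather than
alarming). For *region discovery* over tens of thousands of windows a
stricter α is the right choice — we use α = 1e−5 at desk scale so the
expected number of false windows (α × #windows) stays below one; the
permutation depth (B × #windows null samples) comfortably supports that
resolution. Both are exposed as configuration, honoring the original
"parameter-optimized" description without re-running any optimization.

The null model redraw is uniform-per-chromosome rather than a shuffle
of inter-tag gaps; the upstream segmentation algorithm this emulates is
not reproducible from its description, so this is a documented
reimplementation choice.

## Differential region testing

Per-library enriched regions (per mark) are merged into one
non-overlapping test universe and tags re-counted per region per
library. Size factors are DESeq-style median-of-ratios, rescaled to
geometric mean 1, with a total-count fallback (and warning) when no
region is positive in all libraries.

Dispersion is estimated per region by method of moments on the
within-condition variance of normalized counts
(`α̂ = (s² − μ·mean(1/s_j)) / μ²`, pooled over conditions), then a trend
`α(μ) = a₀ + a₁/μ` is fitted across regions by least squares. With two
pools per condition the per-region estimate is nearly information-free,
so the *trend value* is used for testing (`shrinkage="trend"`); the
conservative `max(trend, per-region)` rule is available as
`shrinkage="maximum"` but deflates type-I error well below nominal at
this replicate count.

The test itself is an exact conditional NB test. Group sums of NB
counts with common dispersion α and equal means are NB with dispersion
α/n, so conditional on the region total T the irradiated-group sum x_B
follows f(x) ∝ NB(x; T·p_B, α/n_B) · NB(T − x; T·(1 − p_B), α/n_A),
with p_B = S_B/(S_A + S_B) from the size-factor sums. The two-sided p
sums f over outcomes no more likely than the observed one (minlike), so
at α → 0 it *is* the exact conditional binomial test. A Wald test on
the log ratio of normalized condition means (variance from the NB
observed information) is provided as `method="wald"`; it was not made
the default because its normal approximation is off by up to ~0.2 in
p at the small counts this design produces, while the exact
formulation is both accurate and cheap at desk scale (enumeration over
0..T per region). Fold changes are log2 of the normalized condition
means with a 0.5 pseudocount; direction "up" means higher in the
irradiated condition. Regions with all-zero counts are dropped with a
warning. BH adjustment is the statsmodels step-up procedure; Storey
q-values use the smoothed (cubic) π₀(λ) estimate read off at the
largest λ of the grid, clipped to [0, 1] with a warning, and reduce
exactly to BH when π₀ = 1.

## Annotation

The anchor for all distance rules is the region midpoint. A region is
annotated to the gene whose TSS is nearest the midpoint if that
distance is ≤ 50 kb (one gene per region; gene lists are deduplicated
downstream). Signed distances run along the gene strand (negative =
upstream of the TSS). Context labels use the precedence TSS-proximal
(25 kb) > intragenic > boundary (region straddles a gene edge) >
intergenic; non-exclusive membership flags are also reported since the
classes genuinely overlap. All tie-breaks (equidistant TSSs, rank ties
in top-N selection) resolve by ascending (chrom, start, gene_id) so
results are reproducible. Class enrichment re-places each region
uniformly on its chromosome (lengths preserved) and compares the
base-pair overlap fraction two-sidedly with the +1 permutation
convention.

## Bidirectional analysis

"Bidirectional" genes are those associated with both an up- and a
down-regulated DHR; the up/down overlap is tested with the upper-tail
hypergeometric probability (observed overlap 0 ⇒ p = 1). For density,
genes shorter than 200 kb are removed and DHR midpoints are counted in
four 50 kb bins laid from the TSS along the direction of transcription
("distal to the gene start" is read as downstream body bins; upstream
flanks are excluded). Counts per fixed-width bin are reported rather
than per-kb rates — equivalent up to a constant. Density contrasts
between gene classes permute class labels; the per-bin statistic is the
difference of class means, the global statistic their sum over bins,
two-sided p-values use (1 + hits)/(B + 1), and when the number of
distinct label splits is ≤ B the test switches to exhaustive
enumeration (then the p is the exact proportion, identity split
included). Per-bin p-values are BH-adjusted across bins. The
significance correlation is Spearman's ρ between row-sum density per
gene length and −log10 of the gene's best DHR p; zero-variance inputs
return ρ = 0 with a degeneracy flag. The comparison class is
configurable: unidirectional (up-only/down-only) genes are the default
control, and long genes without DHRs are available as a calibration
class.

## Integration

Gene-set overlaps use the two-sided Fisher exact test on the 2×2 table
implied by the declared universe, with a Haldane 0.5 correction for the
odds ratio when a cell is zero, and BH adjustment across each declared
family of tests. The default universe choice (all genes vs only
annotated genes) is the caller's, exposed explicitly, because no
principled universe can be inferred from data. Pooled-sample
comparisons (in-silico union of replicates, then per-region Fisher
tests of tag proportions) are a documented stand-in for an earlier
pooled-analysis procedure that is not reproducible from its
description; results from this path should be read as rank
information, not calibrated inference. K-means runs on per-dimension
standardized features, best of `n_starts` initializations, labels
canonicalized by descending cluster size; k defaults to 4 with a
silhouette scan over k ∈ 2..8 available. Metagene matrices use 10 kb
flanks in 50 fixed bins per side and 100 body bins (genes shorter than
the bin count are skipped with a warning); densities are divided by bin
width and by the genome-wide median 1 kb window density, rows sorted by
descending expression, minus-strand genes flipped. Heatmaps z-score
rows (population SD; zero-variance rows → 0) and cap the color map at
the 80% quantile of the scaled values.

## Synthetic data: what it emulates and what it does not

The generator plants, on a 2 × 10 Mb genome with 160 non-overlapping
genes (20% ≥ 200 kb — sized so placement succeeds for essentially any
seed), three kinds of structure per mark: enriched-only regions
(5× background), unidirectional differential regions (4× between
conditions, half up / half down), and bidirectional genes (≥ 200 kb
bodies carrying 2 up + 2 down 5hmC regions in distinct 50 kb bins;
random regions are kept out of these bodies so the planted bin
structure stays clean). Expression coupling adds the published
qualitative geography: 5mC depleted (×0.3) within ±2 kb of active-gene
TSSs and mildly elevated in low-expression bodies, 5hmC enriched up to
3× in active bodies. Replicate noise enters as per-region gamma
multipliers with variance `nb_dispersion` (0.05 default), making region
counts gamma-Poisson (NB) — deliberately the same family the
differential model assumes, so parameter recovery is a fair test of the
estimator rather than of model misspecification. Matched RNA-Seq counts
are NB with half of the 5hmC-up genes co-up-regulated 2-fold.

Deliberate non-realisms: tag positions are independent draws (no
fragment-length autocorrelation, no mappability or GC structure, no
CpG landscape, no input/IgG background), depth is ~10³× below a real
library, and effect sizes are single fixed folds rather than a
distribution (none is published to estimate one from). Passing tests
therefore demonstrate the *statistical machinery* — calibration,
recovery, exactness, determinism — not robustness to the biases of
real immunoprecipitation data.

Recovery checks use the study conditions stated with each property:
segmentation recovery uses exact 5× planted folds (noise-free), since
with replicate noise a "5× region" whose library multiplier drew low is
not a 5× region in that library; differential recovery keeps the 0.05
dispersion. Problem sizes (2 × 10 Mb, ~10⁵ tags/library, 50–100
permutations, 2000–2500 regions for calibration) were chosen as the
smallest at which the Monte-Carlo standard errors are comfortably
inside the property tolerances.

## Known limitations

- No GLM covariates, paired designs, or independent filtering in the
  differential module.
- The segmentation null ignores local chromatin/mappability structure;
  on real data a matched input library would be needed.
- Fisher-based pooled comparisons ignore overdispersion between pooled
  replicates and are anti-conservative on real data; they exist for
  cross-study concordance ranking.
- GO/KEGG-style term lookup is out of scope; only the generic
  interval-class and gene-set overlap machinery is provided.
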