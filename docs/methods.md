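# Methods

`glioprofile` re-implements, as a tested library, the analysis chain used in
retrospective genomic/transcriptomic studies of treatment response in
glioblastoma (GBM): BAC array-CGH copy-number calling with tumor-purity-aware
thresholds, minimal-common-region (MCR) aggregation, differential-genomics
testing, centroid-based transcriptomic subtyping, empirical-Bayes moderated-t
differential expression with hypergeometric gene-set analysis, and
contingency/survival statistics. A synthetic-cohort generator provides data
with the same statistical structure, so the full chain is testable without
any external download.

## Copy-number model and calling

**Mixture model.** A tumor sample is modelled as a fraction R (the *tumor
cell rate*, purity) of tumor cells with integer copy number `cn` at a locus,
mixed with diploid normal cells. The noiseless log2 ratio against a diploid
control is

    log2((R * cn + 2 * (1 - R)) / 2)

Key consequences used throughout: a single-copy loss sits at `log2(1 - R/2)`,
a single-copy gain at `log2(1 + R/2)`, a homozygous deletion (cn = 0) at
`log2(1 - R)`, and the level `log2(1 + 1.5 R)` is exactly the cn = 5 value —
so "amplicon" thresholded there means tumor copy number above 5 at *any*
purity.

**Segmentation.** Smoothed log2 ratios are the exact least-squares
piecewise-constant fit per chromosome: minimize `SSE + lambda * (number of
segments)` by an O(n^2) dynamic program. The default penalty is
`2 * sigma^2 * ln(n)` with `sigma = 1.4826 * median|first differences| /
sqrt(2)` (a robust per-clone noise estimate) and n the number of informative
clones in the profile. Missing clones are dropped from the fit and stay
missing; they are never imputed.

**Center and spread.** The profile's neutral level is the mode of the
smoothed values (Gaussian KDE, Silverman bandwidth, 512-point grid, snapped
to the nearest observed value so recentering is exact on piecewise-constant
data). The spread is robust: `1.4826 * MAD` about the mode, so large
aberrant genome fractions do not inflate the gain/loss thresholds.

**Purity estimation.** R is estimated by inverting the single-copy-loss
displacement: with m the length-weighted median of loss-segment means,
`R = 2 (1 - 2^(m - mode))`. Two guards matter in practice:

- only segments displaced at least `|log2(1 - lo/2)|` (the shallowest
  single-copy displacement at the clamp floor lo) count as losses/gains —
  otherwise near-zero neutral segments corrupt the weighted median;
- a loss cluster deeper than any single-copy loss at the clamp ceiling
  (`m - mode < log2(1 - hi/2)`) can only be homozygous and is inverted with
  `R = 1 - 2^(m - mode)` instead. Without this, a sample whose only losses
  are homozygous would estimate R ~ 2R and miss its own deletions.

Fallbacks: gain-based inversion `R = 2 (2^(m - mode) - 1)` when no loss
segments exist (only if the lift is inside the single-copy band; an amplicon
of unknown copy number cannot be inverted), then a configurable default
(0.7). Estimates are clamped to [0.1, 0.95].

**Five-state calls.** On recentered smoothed values v: homozygous deletion
iff `v <= log2(1 - R) + allowance`; amplicon iff `v > log2(1 + 1.5 R) -
allowance`; else loss/gain iff v beyond -/+ one robust SD; else neutral.
The homdel boundary is inclusive (cn = 0 sits exactly at the threshold in
the noiseless model); the amp boundary is strict (the threshold is exactly
the cn = 5 level and amplicons are copy number *above* 5).

**The standard-error allowance.** Because the noiseless homozygous-deletion
level coincides exactly with its threshold, a segment-mean comparison
against the bare threshold would have ~50% sensitivity under any noise.
The decision boundary therefore includes an allowance of
`z * sigma / sqrt(segment length)` (z = `se_multiplier`, default 3.0),
the standard error of the segment mean. z = 3 recovers a 3-clone two-copy
loss with ~99% probability at the default noise (SD 0.15) while keeping the
chance that a single-copy loss segment crosses the homdel boundary below
1e-4 even at the least favorable purity (0.5). The allowance vanishes on
noiseless data, so all closed-form threshold identities hold exactly.

## Minimal common regions

For one event type, all samples' aberrant intervals (maximal clone runs) on
a chromosome define a breakpoint grid; over each atomic interval the
supporting-sample set is computed, and an MCR is a maximal run of adjacent
atoms with identical support and recurrence >= `min_recurrence` (default 2;
the construction is the standard one, reconstructed from the field's usage).
Adjacent regions with different support stay distinct — they are different
events. Every MCR is contained in the intersection of its supporters'
intervals, and the output is invariant to sample order.

## Differential genomics

Per MCR (or clone), samples are cross-tabulated as group x event-present and
tested with the two-sided Fisher exact test (probability-mass criterion,
1e-7 relative tolerance on the tail comparison). Benjamini-Hochberg
adjustment is applied across the regions of one event type within one
contrast. A region with a zero margin in both groups gets p = 1 by
convention. Two-sided tests are used throughout: they reproduce the
published 0.02/0.03/0.04 contingency values.

## Expression analysis

**Clustering.** Ward agglomeration applied directly to the `1 - Pearson`
sample dissimilarity via the Lance-Williams update — the Ward.D convention
(validated against R `hclust(..., "ward.D")`), chosen over Ward.D2 because
it is the convention of the toolchains this pipeline emulates. Ties break
on the smallest pair of cluster indices, making merges deterministic.

**Centroid subtyping.** A classifier is built from labelled reference
expression by per-probe z-scoring across the reference and averaging z
per class (>= 2 samples per class). New cohorts are z-scored across
themselves; each sample gets the class of the centroid it best correlates
with (ties to the first class in model order, with a warning; >= 50% of
model probes must be present). The probe list is the caller's choice — the
published GBM classifiers use curated lists of under a hundred probe sets.

**Moderated t.** Per gene, the pooled two-group variance `s_g^2` with
`d_g = n1 + n2 - 2` residual df is shrunk toward a prior `(d0, s0^2)`
fitted by moment matching on `log s_g^2` using digamma/trigamma inversion
(Newton iterations for the trigamma inverse), the standard empirical-Bayes
construction (validated against Bioconductor limma to 1e-4 relative).
The moderated statistic uses `s~_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)`
on `d0 + d_g` df. One deliberate departure in the degenerate branch: when
the observed log-variances are underdispersed (evar <= 0, prior df
infinite), the common variance is the *arithmetic mean* of `s_g^2` — the
unbiased estimate under the equal-variance model — so that with identical
gene variances the moderated t reduces exactly to the ordinary pooled t.

**Selection and filtering.** "Top genes" are the n smallest-p probes per
direction (default 500 per side, ties broken by probe id). The published
counting filter keeps genes with raw p < 0.05 and direction-symmetric fold
change `max(fc, 1/fc) > 1.5`; raw p is used because the published counts
precede any stated adjustment. `fc = 2^delta` with delta = first contrast
group minus second.

**Gene-set over-representation.** Probes collapse to genes by keeping the
highest-variance probe per gene; the universe is all collapsed genes on the
array (collapsed genes, not probes — the choice is documented because the
alternative is defensible). Each set's overlap k with the gene list is
scored by the exact hypergeometric upper tail P(X >= k), BH-adjusted across
sets.

## Contingency and survival statistics

2x2 Fisher tests are computed by direct hypergeometric enumeration; r x c
tables use the Freeman-Halton generalization by exhaustive enumeration of
all margin-consistent tables (grand totals capped at 200 — cohort-scale
tables are tiny, and a Monte Carlo fallback is deliberately out of scope).
Kaplan-Meier curves and the log-rank test delegate to lifelines; the median
convention is the smallest observed time with S <= 0.5, and subjects
censored at an event time count as at risk there. Log-rank ties use the
standard hypergeometric-variance formula without continuity correction.

## The synthetic cohort

The generator emulates the structure of a two-arm GBM treatment-response
study: 21/18 radiotherapy (RT) responders/non-responders and 11/17
first-line chemotherapy (CT) responders/non-responders with CGH profiles,
19/15/12/10 with expression — patients per cell are the maximum of the two,
with per-sample assay flags. Defaults:

- 4,434 clones spaced 670 kb, apportioned to hg-like chromosome-length
  proportions (largest-remainder rounding); clone length 150 kb.
- Copy-number events: chr7 gain and chr10 loss at 0.8 in every cell
  (the GBM-typical backbone); a 7p11 EGFR amplicon (cn 20) at 9/11 vs 6/17
  in the CT arm; a 9p21 homozygous deletion (2 Mb, the p16/CDKN2A locus) at
  9/11 vs 0/17 in the CT arm; plus a panel of lower-frequency arm events
  (9p22-24 loss, 5p15 loss, 17q24-25 gain, 11q13 and 20p13 gains) at the
  frequencies the corresponding published contrasts imply.
- Frequencies are realized as exact counts (`round(p * n)` samples chosen by
  a seeded draw), not binomial draws, so the planted small-cohort contrasts
  are exact — e.g. the 9/11 vs 0/17 deletion contrast reproduces its Fisher
  p of 7.96e-6 deterministically.
- Purity uniform on [0.5, 0.9] per sample (no purities are published;
  the range brackets realistic tumor content); per-clone Gaussian noise
  SD 0.15 log2 units.
- Expression: baseline 7.0 log2 units, four subtype centroids (classical /
  mesenchymal / proneural / neural, proportions 0.3/0.3/0.2/0.2) with 50
  marker probes each at +1 log2; planted gene-set contrasts (+1 log2 on 50
  probes each): immune up in RT responders, hypoxia up in RT non-responders,
  normal-brain up in CT responders, stem-cell up in CT non-responders;
  residual SD 0.5 log2 — all values chosen as typical microarray effect and
  noise scales.
- Survival: exponential progression-free survival (PFS) per cell with
  medians 13/3.5/9/3 months; RT-arm PFS is drawn conditioned on the
  response-defining window (responders > 10 months, non-responders < 5, by
  rejection), so labels re-derived from simulated PFS reproduce the planted
  labels exactly. Overall survival adds an exponential increment (mean 8
  months); 20% of OS observations are censored. PFS is left uncensored to
  keep the label-consistency invariant clean.
- A single seed fixes everything via `numpy.random.SeedSequence` fan-out.

**What the generator does not emulate** — and hence what passing tests do
not establish about real arrays: probe-level spatial artifacts and dye bias,
segmental noise correlation, subclonal (non-integer) copy number, probe
cross-hybridization, batch effects in expression, and non-exponential
hazards. The generator's copy-number model is deliberately the same mixture
the caller inverts; tests of the caller on simulated data therefore verify
internal consistency and algebra, not robustness to model misspecification.

## Numerical choices

- All coordinates are 0-based half-open internally and in every output;
  1-based clone maps convert at parse time only.
- Thresholds are compared with a 1e-9 absolute tolerance (calling) and
  1e-7 relative tolerance (Fisher tail inclusion) to avoid float-order
  artifacts at exact boundary cases.
- Ties everywhere break lexicographically (probe ids, clone order, class
  order) for byte-reproducible outputs.
- Problem sizes in the test suite are scaled to the desk: cohort-level
  checks run on the chemotherapy arm (28 profiles), calibration suites use
  2,000 genes / 2,000 replicates, and oracle enumerations cap at the sizes
  where exhaustive computation is exact (totals <= 60, N <= 30, 12-point
  segmentation signals).

## Known limitations

- The r x c exact test enumerates exhaustively and refuses totals above 200.
- The purity estimator assumes at least one single-copy (or homozygous)
  aberration; a flat genome falls back to a default rate with a warning.
- MCR construction does not bridge small gaps and implements no
  significance model of recurrence (GISTIC-style scoring is out of scope).
- Survival machinery covers KM and two-group log-rank only; no Cox
  regression or multivariable adjustment.
- The centroid classifier reproduces the published *machinery*; actual
  published centroid values are user-supplied inputs, not part of the
  package.
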