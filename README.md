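# glioprofile

Genomic and transcriptomic treatment-response profiling for glioblastoma
(GBM) cohorts. The package implements, as a tested reusable library, the
analysis chain of a two-arm retrospective response study — patients treated
with radiotherapy alone versus first-line alkylating chemotherapy — and a
synthetic-cohort generator that makes every stage testable at desk scale.

**Who it is for:** computational biologists analyzing BAC array-CGH
copy-number profiles and microarray expression of tumor cohorts, who need
purity-aware aberration calls, recurrent-region statistics, subtype
classification and response-association tests in one place, with exact and
reproducible statistics.

## What it computes

*Copy number.* Per-clone log2 ratios are smoothed by an exact least-squares
piecewise-constant fit (dynamic program, penalty `2σ²ln n`). With mode m and
robust SD s of the smoothed values and a sample-level estimate of the tumor
cell rate R (inverted from the single-copy-loss displacement
`log2(1 − R/2)`), clones are called in five states on the recentered value
v = smoothed − m:

- homozygous deletion: v ≤ log2(1 − R)
- loss: v < −s   /   gain: v > +s
- amplicon (tumor copy number > 5 at any purity): v > log2(1 + 1.5 R)

Recurrent **minimal common regions** (MCRs) are maximal intervals with a
constant supporting-sample set; responder/non-responder contrasts use the
two-sided Fisher exact test with Benjamini–Hochberg adjustment.

*Expression.* Ward clustering on 1 − Pearson dissimilarity; nearest-centroid
subtype classification (classical / mesenchymal / proneural / neural);
empirical-Bayes moderated t (variance shrinkage `s̃² = (d₀s₀² + d·s²)/(d₀+d)`
with the prior fitted by digamma/trigamma moment matching); top-gene
selection and exact hypergeometric gene-set over-representation.

*Clinical statistics.* Exact 2×2 and r×c (Freeman–Halton) Fisher tests,
BH adjustment, Kaplan–Meier curves and the log-rank test.

See `docs/methods.md` for the model, defaults, and numerical choices.

## Worked example

Simulate the default cohort (21/18 radiotherapy and 11/17 chemotherapy
responders/non-responders on the CGH side, GBM-typical chr7 gain / chr10
loss, a 9p21 deletion planted at 9/11 vs 0/17 in the chemotherapy arm),
call copy number, and test which recurrent deletions separate responders:

```python
from glioprofile import (SimulationConfig, simulate_cohort, call_profile,
                         derive_mcrs, differential_regions, fisher_exact_2x2)

cohort = simulate_cohort(SimulationConfig(seed=1))
meta = cohort.metadata.table
ct = meta[(meta.treatment == "CT") & meta.has_cgh]

calls = {}
for sid in ct.sample_id:
    c, _seg, st = call_profile(cohort.profiles[sid].log2_ratio, cohort.clone_map)
    calls[sid] = c

groups = ct.set_index("sample_id")["response"]
mcrs = derive_mcrs(calls, "homdel", 2, cohort.clone_map)
table = differential_regions(mcrs, calls, groups, cohort.clone_map)
top = table.iloc[0]
print(f"top homdel MCR: {top.chrom}:{top.start}-{top.end}")
print(f"freq responders={top.freq_responder:.2f} "
      f"nonresponders={top.freq_nonresponder:.2f}")
print(f"Fisher p={top.p_value:.3g}  BH q={top.q_value:.3g}")

p, _ = fisher_exact_2x2([[7, 1], [3, 8]])
print(f"classical-subtype response contrast: p={p:.3f}")
```

Output:

```
top homdel MCR: chr9:21440000-22930000
freq responders=0.82 nonresponders=0.00
Fisher p=7.96e-06  BH q=7.96e-06
classical-subtype response contrast: p=0.020
```

The caller recovers the planted p16/CDKN2A-locus deletion as the top-ranked
differential region: present in 82% of chemotherapy responders and no
non-responder, Fisher p ≈ 8×10⁻⁶. The last line is the exact test behind a
subtype-by-treatment response table (7/8 responders under chemotherapy vs
3/11 under radiotherapy).

More narrative scripts live in `examples/` (one per capability), and the
same stages are available from the shell:

```sh
glioprofile run --seed 17 --outdir results/        # full pipeline + report.json
glioprofile simulate --seed 17 --outdir sim/
glioprofile call-cgh --profiles sim/profiles.tsv --clone-map sim/clone_map.tsv \
    --out calls.bed
```

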