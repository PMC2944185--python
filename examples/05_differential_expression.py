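"""Moderated-t differential expression and gene-set over-representation.

Contrasts radiotherapy responders vs non-responders, applies the published
counting filter (raw p < 0.05, fold change > 1.5), and scores the planted
gene sets on the top genes per direction.
"""

import warnings

from glioprofile import (SimulationConfig, collapse_to_genes, filter_de,
                         hypergeometric_enrichment, moderated_t_test,
                         select_top_genes, simulate_cohort)

warnings.filterwarnings("ignore")

cohort = simulate_cohort(SimulationConfig(seed=17))
meta = cohort.metadata.table
rt = meta[(meta.treatment == "RT") & meta.has_expr]
groups = rt.set_index("sample_id")["response"]
expr = cohort.expression[list(groups.index)]

de, fit = moderated_t_test(expr, groups, contrast=("responder",
                                                   "nonresponder"))
print(f"variance prior: d0={fit.d0:.1f}, s0^2={fit.s0_sq:.3f} "
      f"(shrinkage target fitted from {len(de)} probes)")

counts = filter_de(de)["counts"]
print(f"genes at p<0.05 and FC>1.5: {counts}")

up_resp, up_nonresp = select_top_genes(de, n_per_side=100)
gene_probe = collapse_to_genes(expr, cohort.probe_genes)
representative = set(gene_probe.to_numpy())
universe = frozenset(gene_probe.index)
for side, probes in (("responders", up_resp), ("non-responders", up_nonresp)):
    genes = sorted({cohort.probe_genes[p] for p in probes
                    if p in representative})
    enr = hypergeometric_enrichment(genes, cohort.gene_sets, universe)
    top = enr.iloc[0]
    print(f"top set up in {side:15s}: {top['set']:16s} "
          f"(overlap {top['overlap']}/{top['set_size']}, q={top['q_value']:.2g})")
print("-> the planted immune (responder) and hypoxia (non-responder) "
      "programs are the top-ranked enrichments.")
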