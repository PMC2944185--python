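"""Minimal common regions and responder-vs-nonresponder Fisher tests.

Runs the chemotherapy arm of the default cohort through calling, aggregates
homozygous deletions and amplicons into MCRs, and tests each region's
association with response — the machinery behind a "regions differentiating
responders from non-responders" table.
"""

import warnings

from glioprofile import (SimulationConfig, call_profile, derive_mcrs,
                         differential_regions, simulate_cohort)

warnings.filterwarnings("ignore")

cohort = simulate_cohort(SimulationConfig(seed=17))
meta = cohort.metadata.table
ct = meta[(meta.treatment == "CT") & meta.has_cgh]

calls = {sid: call_profile(cohort.profiles[sid].log2_ratio,
                           cohort.clone_map)[0]
         for sid in ct.sample_id}
groups = ct.set_index("sample_id")["response"]

for event in ("homdel", "amp"):
    mcrs = derive_mcrs(calls, event, min_recurrence=2,
                       clone_map=cohort.clone_map)
    table = differential_regions(mcrs, calls, groups, cohort.clone_map)
    top = table.iloc[0]
    print(f"{event:6s} top MCR {top.chrom}:{top.start}-{top.end}  "
          f"R={top.freq_responder:.2f} NR={top.freq_nonresponder:.2f}  "
          f"p={top.p_value:.3g} q={top.q_value:.3g}")
print("-> the 9p21 deletion (planted 9/11 vs 0/17) and the 7p11 amplicon "
      "(9/11 vs 6/17) are recovered with their exact Fisher p-values.")
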