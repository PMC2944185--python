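"""Kaplan-Meier curves and the log-rank test on cohort metadata.

Compares progression-free survival between responders and non-responders in
each treatment arm of the default synthetic cohort.
"""

import warnings

from glioprofile import (SimulationConfig, SurvivalData, km_estimator,
                         logrank_test, simulate_cohort)

warnings.filterwarnings("ignore")

cohort = simulate_cohort(SimulationConfig(seed=17))
meta = cohort.metadata.table

for arm in ("RT", "CT"):
    t = meta[meta.treatment == arm]
    data = SurvivalData(t.pfs_months.to_numpy(), t.pfs_event.to_numpy(),
                        t.response.to_numpy())
    medians = {g: km_estimator(data, g).median
               for g in ("responder", "nonresponder")}
    chi2, p = logrank_test(data)
    print(f"{arm}: median PFS responders {medians['responder']:.1f} mo vs "
          f"non-responders {medians['nonresponder']:.1f} mo; "
          f"log-rank chi2={chi2:.1f}, p={p:.2g}")
print("-> radiotherapy responders are defined by PFS > 10 months and "
      "non-responders by PFS < 5, so that arm separates by construction; "
      "the chemotherapy arm separates through its planted hazards.")
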