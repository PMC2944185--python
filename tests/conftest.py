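"""Shared fixtures: small clone maps and a seeded default cohort with calls.

The cohort-scale fixtures are session-scoped because simulating and calling
~30 BAC profiles dominates the suite's runtime; every test that uses them
treats them as read-only.
"""

import numpy as np
import pandas as pd
import pytest

from glioprofile.io_formats import CloneMap
from glioprofile.simulate import (SimulationConfig, CopyNumberEvent,
                                  simulate_cohort)
from glioprofile.pipeline import call_cohort

TEST_SEED = 7


def make_clone_map(n_per_chrom: dict[str, int], spacing: int = 1_000_000,
                   length: int = 150_000) -> CloneMap:
    rows = []
    for chrom, n in n_per_chrom.items():
        for i in range(n):
            rows.append((f"{chrom}_c{i:03d}", chrom, i * spacing,
                         i * spacing + length))
    return CloneMap(pd.DataFrame(
        rows, columns=["clone_id", "chrom", "start", "end"]))


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (study-sized cells, default noise)."""
    return simulate_cohort(SimulationConfig(seed=TEST_SEED))


@pytest.fixture(scope="session")
def ct_calls(default_cohort):
    """Aberration calls for the chemotherapy-arm CGH samples."""
    meta = default_cohort.metadata.table
    ct_ids = set(meta.loc[(meta["treatment"] == "CT") & meta["has_cgh"],
                          "sample_id"])
    sub = default_cohort
    profiles = {sid: p for sid, p in sub.profiles.items() if sid in ct_ids}
    cohort_view = type(sub)(
        clone_map=sub.clone_map, chrom_lengths=sub.chrom_lengths,
        profiles=profiles, expression=sub.expression,
        probe_genes=sub.probe_genes, gene_sets=sub.gene_sets,
        metadata=sub.metadata, truth=sub.truth)
    calls, stats = call_cohort(cohort_view)
    return calls, stats


def small_pipeline_config(seed: int = TEST_SEED) -> SimulationConfig:
    """A fast, mostly-neutral genome for pipeline-level tests."""
    cells = {"RT:responder": 4, "RT:nonresponder": 4,
             "CT:responder": 5, "CT:nonresponder": 6}
    return SimulationConfig(
        n_clones=400,
        chrom_mb={f"chr{i}": 100 for i in range(1, 9)},
        events=[
            CopyNumberEvent("gain_chr1", "chr1", 0, None, 3,
                            {c: 0.6 for c in cells}),
            CopyNumberEvent("loss_chr2", "chr2", 0, None, 1,
                            {c: 0.6 for c in cells}),
            CopyNumberEvent("homdel_chr3", "chr3", 10_000_000, 14_010_000, 0,
                            {"CT:responder": 0.8}),
            CopyNumberEvent("amp_chr4", "chr4", 20_000_000, 24_010_000, 20,
                            {"CT:responder": 0.8, "CT:nonresponder": 0.2}),
        ],
        n_cgh=cells, n_expr=cells,
        n_probes=300, markers_per_class=20, genes_per_set=20, seed=seed)
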