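"""End-to-end orchestration: simulate (or load) a cohort, call copy number,
derive MCRs, test differential regions, classify subtypes, run differential
expression with gene-set analysis, and compute survival contrasts.

Every stage writes its outputs under the run directory and the whole run is
summarized in a machine-readable ``report.json``.  A single global seed is
fanned out to per-stage child seeds through ``numpy.random.SeedSequence``,
so identical config + seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (CloneMap, SampleMetadata, write_clone_map,
                         write_matrix_tsv, write_metadata, write_segments_bed,
                         write_gmt)
from .simulate import SimulationConfig, simulate_cohort, Cohort
from .calling import CallingParameters, call_profile
from .mcr import derive_mcrs, mcrs_to_frame, EVENT_TYPES
from .association import differential_regions
from .transcriptomics import (build_centroid_classifier, classify_by_centroid,
                              collapse_to_genes, hypergeometric_enrichment,
                              moderated_t_test, select_top_genes, filter_de,
                              ward_pearson_cluster)
from .stats import SurvivalData, km_estimator, logrank_test

log = logging.getLogger("glioprofile")

__all__ = ["run_pipeline", "call_cohort", "differential_genomics",
           "expression_analysis", "survival_analysis"]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("call-cgh")
def call_cohort(cohort: Cohort, params: CallingParameters | None = None):
    """Call aberrations for every CGH sample; returns (calls, stats frame)."""
    params = params or CallingParameters()
    calls, stats_rows = {}, []
    for sid in sorted(cohort.profiles):
        c, _seg, st = call_profile(cohort.profiles[sid].log2_ratio,
                                   cohort.clone_map, params)
        calls[sid] = c
        stats_rows.append({"sample_id": sid, "mode": st.mode, "sd": st.sd,
                           "r_tc_hat": st.r_tc_hat,
                           "source": st.estimation_source})
    return calls, pd.DataFrame(stats_rows)


@_stage("diff-genome")
def differential_genomics(calls, metadata: SampleMetadata,
                          clone_map: CloneMap, treatment: str,
                          min_recurrence: int = 2):
    """Per-arm MCR derivation and responder-vs-nonresponder Fisher tests."""
    t = metadata.table
    arm = t[(t["treatment"] == treatment) & t["sample_id"].isin(calls)]
    arm_calls = {sid: calls[sid] for sid in arm["sample_id"]}
    groups = arm.set_index("sample_id")["response"]
    mcrs, tables = {}, {}
    for event in EVENT_TYPES:
        recs = derive_mcrs(arm_calls, event, min_recurrence, clone_map)
        mcrs[event] = recs
        tables[event] = differential_regions(recs, arm_calls, groups,
                                             clone_map)
    return mcrs, tables


@_stage("expression")
def expression_analysis(cohort: Cohort, treatment: str,
                        n_per_side: int = 500):
    """Moderated-t DE (responder vs nonresponder) plus enrichment per side."""
    t = cohort.metadata.table
    arm = t[(t["treatment"] == treatment) & t["has_expr"]]
    ids = [s for s in arm["sample_id"] if s in cohort.expression.columns]
    groups = arm.set_index("sample_id").loc[ids, "response"]
    expr = cohort.expression[ids]
    de, fit = moderated_t_test(expr, groups,
                               contrast=("responder", "nonresponder"))
    up_resp, up_nonresp = select_top_genes(de, n_per_side)
    gene_probe = collapse_to_genes(expr, cohort.probe_genes)
    probe_to_gene = cohort.probe_genes
    representative = set(gene_probe.to_numpy())
    universe = frozenset(gene_probe.index)

    def probes_to_genes(probes):
        return sorted({probe_to_gene[p] for p in probes
                       if p in representative})

    enrich = {
        "responder": hypergeometric_enrichment(
            probes_to_genes(up_resp), cohort.gene_sets, universe),
        "nonresponder": hypergeometric_enrichment(
            probes_to_genes(up_nonresp), cohort.gene_sets, universe),
    }
    filtered = filter_de(de)
    return de, fit, enrich, filtered


@_stage("survival")
def survival_analysis(metadata: SampleMetadata, treatment: str,
                      time_col: str = "pfs_months",
                      event_col: str = "pfs_event"):
    """KM curves and the responder-vs-nonresponder log-rank test in one arm."""
    t = metadata.table
    arm = t[t["treatment"] == treatment]
    data = SurvivalData(arm[time_col].to_numpy(),
                        arm[event_col].to_numpy(),
                        arm["response"].to_numpy())
    curves = {g: km_estimator(data, g) for g in np.unique(data.group)}
    chi2, p = logrank_test(data)
    return curves, chi2, p


def _fingerprint(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: SimulationConfig | dict, outdir,
                 calling_params: CallingParameters | None = None) -> dict:
    """Run the full synthetic-cohort analysis; returns the report dict.

    ``config`` is a SimulationConfig (or a dict of overrides for one).  All
    stage outputs and ``report.json`` are written under ``outdir``.
    """
    if isinstance(config, dict):
        config = SimulationConfig(**config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "version": __version__,
        "config_fingerprint": _fingerprint(
            {k: v for k, v in asdict(config).items()
             if not isinstance(v, (list,))}),
        "outputs": {}, "summary": {},
    }

    def save(name, writer, *args):
        path = outdir / name
        writer(*args, path)
        report["outputs"][name.split(".")[0]] = str(path)
        return path

    log.info("simulating cohort (seed %d)", config.seed)
    cohort = simulate_cohort(config)
    save("clone_map.tsv", write_clone_map, cohort.clone_map)
    profiles = pd.DataFrame(
        {sid: p.log2_ratio for sid, p in sorted(cohort.profiles.items())},
        index=cohort.clone_map.clone_ids)
    save("profiles.tsv", write_matrix_tsv, profiles)
    save("expression.tsv", write_matrix_tsv, cohort.expression)
    save("metadata.tsv", write_metadata, cohort.metadata)
    save("gene_sets.gmt", write_gmt, cohort.gene_sets)
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.truth, fh, indent=1, default=str)
    report["outputs"]["truth"] = str(outdir / "truth.json")

    calls, stats = call_cohort(cohort, calling_params)
    save("sample_stats.tsv",
         lambda df, p: df.to_csv(p, sep="\t", index=False,
                                 float_format="%.6g"), stats)
    save("calls.bed",
         lambda c, p: write_segments_bed(c, cohort.clone_map, p), calls)
    report["summary"]["n_cgh_samples"] = len(calls)
    counts = {}
    for ev in EVENT_TYPES:
        counts[ev] = int(sum((np.asarray(c.status, dtype=object) == ev).sum()
                             for c in calls.values()))
    report["summary"]["clone_calls"] = counts

    sig_regions = {}
    for arm in ("RT", "CT"):
        mcrs, tables = differential_genomics(calls, cohort.metadata,
                                             cohort.clone_map, arm)
        for ev, recs in mcrs.items():
            if recs:
                save(f"mcrs_{arm}_{ev}.tsv",
                     lambda df, p: df.to_csv(p, sep="\t", index=False),
                     mcrs_to_frame(recs))
        for ev, tab in tables.items():
            if len(tab):
                save(f"diff_{arm}_{ev}.tsv",
                     lambda df, p: df.to_csv(p, sep="\t", index=False,
                                             float_format="%.6g"), tab)
        sig_regions[arm] = {
            ev: int(tab["significant"].sum()) if len(tab) else 0
            for ev, tab in tables.items()}
        report["summary"][f"n_mcrs_{arm}"] = {ev: len(r)
                                              for ev, r in mcrs.items()}
    report["summary"]["significant_regions"] = sig_regions

    # subtype classification: centroids from the planted labels, then
    # self-reclassification of the cohort
    expr_meta = cohort.metadata.table[cohort.metadata.table["has_expr"]]
    labels = expr_meta.set_index("sample_id")["subtype"]
    labels = labels[labels.index.isin(cohort.expression.columns)]
    model = build_centroid_classifier(cohort.expression[list(labels.index)],
                                      labels)
    assigned = classify_by_centroid(model, cohort.expression)
    save("classification.tsv",
         lambda df, p: df.to_csv(p, sep="\t", float_format="%.6g"), assigned)
    agree = (assigned.loc[labels.index, "class"] == labels).mean()
    report["summary"]["centroid_self_agreement"] = float(agree)
    clusters, _tree = ward_pearson_cluster(cohort.expression,
                                           k=len(config.class_names))
    save("clusters.tsv",
         lambda s, p: s.to_csv(p, sep="\t"), clusters)

    de_summary = {}
    for arm in ("RT", "CT"):
        de, fit, enrich, filtered = expression_analysis(cohort, arm)
        save(f"de_{arm}.tsv",
             lambda df, p: df.to_csv(p, sep="\t", float_format="%.6g"), de)
        for side, tab in enrich.items():
            save(f"enrichment_{arm}_{side}.tsv",
                 lambda df, p: df.to_csv(p, sep="\t", index=False,
                                         float_format="%.6g"), tab)
        de_summary[arm] = {
            "d0": fit.d0 if np.isfinite(fit.d0) else "inf",
            "filtered_counts": filtered["counts"],
            "top_set_responder": (enrich["responder"].iloc[0]["set"]
                                  if len(enrich["responder"]) else None),
            "top_set_nonresponder": (enrich["nonresponder"].iloc[0]["set"]
                                     if len(enrich["nonresponder"]) else None),
        }
    report["summary"]["differential_expression"] = de_summary

    surv_summary = {}
    for arm in ("RT", "CT"):
        curves, chi2, p = survival_analysis(cohort.metadata, arm)
        surv_summary[arm] = {
            "logrank_chi2": chi2, "logrank_p": p,
            "median_pfs": {g: c.median for g, c in curves.items()},
        }
    report["summary"]["survival"] = surv_summary

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
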