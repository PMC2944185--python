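"""Synthetic glioblastoma cohort generator.

Produces BAC-array copy-number profiles, a log2 expression matrix, clinical
metadata and survival times with the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without any download.

The copy-number model is a two-population mixture: a tumor fraction
(the tumor cell rate R, drawn per sample) carrying integer copy number
``cn`` mixed with diploid normal cells, giving a noiseless log2 ratio of

    log2((R * cn + 2 * (1 - R)) / 2)

plus Gaussian measurement noise.  This is deliberately the same mixture the
caller's purity-aware thresholds invert, keeping generator and caller
consistent.  Recurrent events (chr7 gain, chr10 loss, 9p21 homozygous
deletion, 7p11 EGFR amplicon, and a panel of lower-frequency arm events)
are planted per treatment-by-response cell at configured frequencies; the
frequencies are realized as exact counts (round(p*n) samples chosen by a
seeded draw) so that small-cohort contrasts are exact rather than binomial.

Expression is baseline + subtype-centroid effect + planted gene-set group
effects + Gaussian noise; survival is exponential per group with independent
censoring.  Radiotherapy-arm progression-free survival is drawn conditioned
on the response-defining window (>10 months for responders, <5 for
non-responders), so response labels re-derived from simulated PFS reproduce
the planted labels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CloneMap, GeneSetCollection, SampleMetadata
from .stats import SurvivalData

__all__ = [
    "CopyNumberEvent",
    "GeneSetEffect",
    "SimulationConfig",
    "GenomicProfile",
    "Cohort",
    "make_clone_map",
    "simulate_acgh_profile",
    "simulate_expression",
    "simulate_survival",
    "simulate_cohort",
]

# rounded hg-like chromosome lengths (Mb), used only as proportions
_CHROM_MB = {
    "chr1": 249, "chr2": 243, "chr3": 198, "chr4": 191, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 146, "chr9": 141, "chr10": 136,
    "chr11": 135, "chr12": 134, "chr13": 115, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 81, "chr18": 78, "chr19": 59, "chr20": 63,
    "chr21": 48, "chr22": 51, "chrX": 155,
}

CELLS = ("RT:responder", "RT:nonresponder", "CT:responder", "CT:nonresponder")


@dataclass
class CopyNumberEvent:
    """A planted aberration: interval, tumor copy number, frequency per cell.

    ``end=None`` means "to the end of the chromosome".  ``prob`` maps
    treatment:response cells (e.g. ``"CT:responder"``) to the planting
    frequency; missing cells default to 0.
    """

    name: str
    chrom: str
    start: int
    end: int | None
    copy_number: int
    prob: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.copy_number < 0 or int(self.copy_number) != self.copy_number:
            raise ValueError(f"event {self.name!r}: copy_number must be a "
                             "nonnegative integer")
        for cell, p in self.prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"event {self.name!r}: probability {p} for "
                                 f"{cell!r} outside [0, 1]")


@dataclass
class GeneSetEffect:
    """A planted expression contrast: +effect on one set in one cohort cell."""

    set_name: str
    treatment: str
    up_in: str          # response label whose samples carry the effect
    log2_effect: float


def _default_events() -> list[CopyNumberEvent]:
    return [
        CopyNumberEvent("chr7_gain", "chr7", 0, None, 3,
                        {c: 0.8 for c in CELLS}),
        CopyNumberEvent("chr10_loss", "chr10", 0, None, 1,
                        {c: 0.8 for c in CELLS}),
        CopyNumberEvent("egfr_amp_7p11", "chr7", 54_000_000, 56_010_000, 20,
                        {"CT:responder": 9 / 11, "CT:nonresponder": 6 / 17,
                         "RT:responder": 0.43, "RT:nonresponder": 0.44}),
        CopyNumberEvent("p16_homdel_9p21", "chr9", 21_000_000, 23_010_000, 0,
                        {"CT:responder": 9 / 11, "CT:nonresponder": 0.0,
                         "RT:responder": 0.4, "RT:nonresponder": 0.4}),
        CopyNumberEvent("loss_9p22_24", "chr9", 0, 19_000_000, 1,
                        {"CT:responder": 7 / 11, "CT:nonresponder": 2 / 17,
                         "RT:responder": 0.3, "RT:nonresponder": 0.3}),
        CopyNumberEvent("loss_5p15", "chr5", 0, 7_030_000, 1,
                        {"RT:responder": 6 / 21}),
        CopyNumberEvent("gain_17q24_25", "chr17", 62_000_000, 75_000_000, 3,
                        {"RT:nonresponder": 4 / 18}),
        CopyNumberEvent("gain_11q13", "chr11", 65_000_000, 70_020_000, 3,
                        {"CT:responder": 10 / 11, "CT:nonresponder": 3 / 17}),
        CopyNumberEvent("gain_20p13", "chr20", 0, 4_020_000, 3,
                        {"CT:responder": 9 / 11, "CT:nonresponder": 2 / 17}),
    ]


def _default_set_effects() -> list[GeneSetEffect]:
    return [
        GeneSetEffect("immune_response", "RT", "responder", 1.0),
        GeneSetEffect("hypoxia_induced", "RT", "nonresponder", 1.0),
        GeneSetEffect("normal_brain", "CT", "responder", 1.0),
        GeneSetEffect("stem_cell", "CT", "nonresponder", 1.0),
    ]


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort.

    Cohort cell sizes default to the study design this generator emulates:
    21/18 radiotherapy responders/non-responders and 11/17 chemotherapy
    responders/non-responders on the CGH array, 19/15/12/10 on the
    expression array.  ``seed`` fixes all randomness.
    """

    n_clones: int = 4434
    clone_spacing_bp: int = 670_000
    clone_length_bp: int = 150_000
    chrom_mb: dict[str, int] = field(default_factory=lambda: dict(_CHROM_MB))
    events: list[CopyNumberEvent] = field(default_factory=_default_events)
    purity_range: tuple[float, float] = (0.5, 0.9)
    noise_sd: float = 0.15
    n_cgh: dict[str, int] = field(default_factory=lambda: {
        "RT:responder": 21, "RT:nonresponder": 18,
        "CT:responder": 11, "CT:nonresponder": 17})
    n_expr: dict[str, int] = field(default_factory=lambda: {
        "RT:responder": 19, "RT:nonresponder": 15,
        "CT:responder": 12, "CT:nonresponder": 10})
    # expression
    n_probes: int = 2000
    class_names: tuple[str, ...] = ("classical", "mesenchymal",
                                    "proneural", "neural")
    class_proportions: tuple[float, ...] = (0.3, 0.3, 0.2, 0.2)
    markers_per_class: int = 50
    centroid_effect: float = 1.0
    genes_per_set: int = 50
    set_effects: list[GeneSetEffect] = field(default_factory=_default_set_effects)
    expr_baseline: float = 7.0
    expr_noise_sd: float = 0.5
    # survival (hazards in 1/month)
    pfs_hazard: dict[str, float] = field(default_factory=lambda: {
        "RT:responder": np.log(2) / 13.0, "RT:nonresponder": np.log(2) / 3.5,
        "CT:responder": np.log(2) / 9.0, "CT:nonresponder": np.log(2) / 3.0})
    os_extra_hazard: float = 0.125
    censoring_rate: float = 0.2
    pfs_cutoffs: tuple[float, float] = (5.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce plain mappings (e.g. parsed YAML) into the event dataclasses
        self.events = [ev if isinstance(ev, CopyNumberEvent)
                       else CopyNumberEvent(**ev) for ev in self.events]
        self.set_effects = [e if isinstance(e, GeneSetEffect)
                            else GeneSetEffect(**e) for e in self.set_effects]
        self.purity_range = tuple(self.purity_range)
        self.class_names = tuple(self.class_names)
        self.class_proportions = tuple(self.class_proportions)
        self.pfs_cutoffs = tuple(self.pfs_cutoffs)
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("purity_range must lie strictly inside (0, 1)")
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        for h in self.pfs_hazard.values():
            if h <= 0:
                raise ValueError("hazards must be positive")


@dataclass
class GenomicProfile:
    """One sample's per-clone log2 ratios plus simulation ground truth."""

    sample_id: str
    log2_ratio: np.ndarray
    true_state: np.ndarray | None = None   # integer copy number per clone
    true_purity: float | None = None


@dataclass
class Cohort:
    clone_map: CloneMap
    chrom_lengths: dict[str, int]
    profiles: dict[str, GenomicProfile]
    expression: pd.DataFrame                 # probes x samples, log2
    probe_genes: pd.Series                   # probe -> gene symbol
    gene_sets: GeneSetCollection
    metadata: SampleMetadata
    truth: dict


def make_clone_map(config: SimulationConfig) -> tuple[CloneMap, dict[str, int]]:
    """Build the tiling clone map: clones per chromosome are apportioned to
    hg-like length proportions (largest-remainder rounding to hit ``n_clones``
    exactly) and spaced ``clone_spacing_bp`` apart."""
    mb = config.chrom_mb
    total = sum(mb.values())
    quotas = {c: config.n_clones * v / total for c, v in mb.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = config.n_clones - sum(counts.values())
    for c in sorted(mb, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    rows = []
    lengths = {}
    for chrom in mb:
        n = counts[chrom]
        lengths[chrom] = n * config.clone_spacing_bp
        for i in range(n):
            start = i * config.clone_spacing_bp
            rows.append((f"{chrom}_c{i:04d}", chrom, start,
                         start + config.clone_length_bp))
    cm = CloneMap(pd.DataFrame(rows, columns=["clone_id", "chrom", "start", "end"]))
    return cm, lengths


def _resolve_events(events, chrom_lengths):
    resolved = []
    for ev in events:
        if ev.chrom not in chrom_lengths:
            raise ValueError(f"event {ev.name!r}: unknown chromosome {ev.chrom!r}")
        end = chrom_lengths[ev.chrom] if ev.end is None else ev.end
        if ev.start < 0 or end > chrom_lengths[ev.chrom] or end <= ev.start:
            raise ValueError(
                f"event {ev.name!r} outside chromosome bounds "
                f"({ev.chrom}:{ev.start}-{end}, length "
                f"{chrom_lengths[ev.chrom]})")
        resolved.append((ev.name, ev.chrom, ev.start, end, ev.copy_number))
    return resolved


def simulate_acgh_profile(clone_map: CloneMap, events, purity: float,
                          noise_sd: float, seed,
                          sample_id: str = "sample",
                          chrom_lengths: dict[str, int] | None = None,
                          ) -> GenomicProfile:
    """Simulate one aCGH profile under the tumor/normal mixture model.

    ``events`` is a list of ``(name, chrom, start, end, copy_number)`` (or
    CopyNumberEvent objects, resolved against ``chrom_lengths``); later
    events override earlier ones where they overlap.  Copy number is 2
    outside all events.
    """
    if not 0.0 < purity < 1.0:
        raise ValueError("purity must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    t = clone_map.table
    starts = t["start"].to_numpy()
    ends = t["end"].to_numpy()
    chroms = t["chrom"].to_numpy()
    cn = np.full(len(clone_map), 2, dtype=np.int64)
    if events and isinstance(events[0], CopyNumberEvent):
        if chrom_lengths is None:
            raise ValueError("chrom_lengths required to resolve event objects")
        events = _resolve_events(events, chrom_lengths)
    for _name, chrom, ev_start, ev_end, ev_cn in events:
        hit = (chroms == chrom) & (starts < ev_end) & (ends > ev_start)
        cn[hit] = ev_cn
    ratio = np.log2((purity * cn + (1.0 - purity) * 2.0) / 2.0)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, size=len(ratio))
    return GenomicProfile(sample_id, ratio, cn, purity)


def simulate_expression(config: SimulationConfig, class_labels, group_labels,
                        seed) -> tuple[pd.DataFrame, pd.Series,
                                       GeneSetCollection, dict]:
    """Simulate a log2 expression matrix with subtype and gene-set structure.

    ``class_labels`` assigns each sample a subtype; ``group_labels`` assigns
    each sample a treatment:response cell.  Returns (matrix, probe->gene map,
    planted gene sets, truth dict).  Each probe belongs to at most one
    planted block (class marker or gene set).
    """
    class_labels = pd.Series(class_labels)
    group_labels = pd.Series(group_labels, index=class_labels.index)
    unknown = set(class_labels) - set(config.class_names)
    if unknown:
        raise ValueError(f"unknown class label(s) {sorted(unknown)!r}")
    rng = np.random.default_rng(seed)

    n_probes = config.n_probes
    probes = [f"P{i:05d}" for i in range(n_probes)]
    # probe -> gene: 1:1 except a sprinkle of duplicate probes per gene to
    # exercise probe collapse downstream
    genes = []
    g = 0
    for i in range(n_probes):
        if i % 37 == 36:
            genes.append(genes[-1])
        else:
            genes.append(f"G{g:05d}")
            g += 1
    probe_genes = pd.Series(genes, index=pd.Index(probes, name="probe"))

    needed = len(config.class_names) * config.markers_per_class + \
        len(config.set_effects) * config.genes_per_set
    if needed > n_probes:
        raise ValueError("not enough probes for the planted structure")

    pos = 0
    marker_probes: dict[str, list[str]] = {}
    for cls in config.class_names:
        marker_probes[cls] = probes[pos:pos + config.markers_per_class]
        pos += config.markers_per_class
    set_probes: dict[str, list[str]] = {}
    for eff in config.set_effects:
        set_probes[eff.set_name] = probes[pos:pos + config.genes_per_set]
        pos += config.genes_per_set

    samples = list(class_labels.index)
    mat = np.full((n_probes, len(samples)), config.expr_baseline, dtype=float)
    probe_pos = {p: i for i, p in enumerate(probes)}
    for j, s in enumerate(samples):
        cls = class_labels[s]
        for p in marker_probes[cls]:
            mat[probe_pos[p], j] += config.centroid_effect
    for eff in config.set_effects:
        cell = f"{eff.treatment}:{eff.up_in}"
        cols = [j for j, s in enumerate(samples) if group_labels[s] == cell]
        rows = [probe_pos[p] for p in set_probes[eff.set_name]]
        for j in cols:
            mat[rows, j] += eff.log2_effect
    if config.expr_noise_sd > 0:
        mat = mat + rng.normal(0.0, config.expr_noise_sd, size=mat.shape)

    expr = pd.DataFrame(mat, index=pd.Index(probes, name="probe"),
                        columns=samples)
    gene_sets = GeneSetCollection(
        {name: frozenset(probe_genes[p] for p in plist)
         for name, plist in set_probes.items()},
        universe=frozenset(probe_genes),
    )
    truth = {
        "marker_probes": marker_probes,
        "set_probes": set_probes,
        "class_labels": class_labels.to_dict(),
    }
    return expr, probe_genes, gene_sets, truth


def simulate_survival(group_labels, hazards: dict, censoring_rate: float,
                      seed) -> SurvivalData:
    """Exponential survival per group with independent exponential censoring.

    The censoring hazard is chosen so that a fraction ``censoring_rate`` of
    subjects is censored in expectation (competing exponentials).
    """
    group_labels = np.asarray(group_labels)
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must lie in [0, 1)")
    for g in np.unique(group_labels):
        if g not in hazards:
            raise ValueError(f"no hazard for group {g!r}")
        if hazards[g] <= 0:
            raise ValueError(f"non-positive hazard for group {g!r}")
    rng = np.random.default_rng(seed)
    h = np.array([hazards[g] for g in group_labels], dtype=float)
    t_event = rng.exponential(1.0 / h)
    if censoring_rate > 0:
        h_cens = h * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / h_cens)
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SurvivalData(time, event, group_labels)


def _conditioned_pfs(rng, hazard, responder: bool, cutoffs):
    """Exponential PFS conditioned on the response-defining window."""
    low_cut, high_cut = cutoffs
    for _ in range(100_000):
        t = rng.exponential(1.0 / hazard)
        if responder and t > high_cut:
            return t
        if not responder and t < low_cut:
            return t
    raise RuntimeError("rejection sampling failed; hazard incompatible "
                       "with PFS window")


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort (profiles, expression, metadata).

    Deterministic under ``config.seed``.  Per-cell patient counts are the
    maximum of the CGH and expression cell sizes; per-sample flags record
    which assay exists for each patient.
    """
    root = np.random.SeedSequence(config.seed)
    ss_assign, ss_cgh, ss_expr, ss_surv = root.spawn(4)
    rng_assign = np.random.default_rng(ss_assign)

    clone_map, chrom_lengths = make_clone_map(config)
    events = _resolve_events(config.events, chrom_lengths)

    # --- patients per cell -------------------------------------------------
    sample_rows = []
    for cell in CELLS:
        n_cgh = config.n_cgh.get(cell, 0)
        n_expr = config.n_expr.get(cell, 0)
        n = max(n_cgh, n_expr)
        if n == 0:
            warnings.warn(f"cohort cell {cell!r} is empty; downstream "
                          "contrasts involving it will be unavailable")
            continue
        treatment, response = cell.split(":")
        tag = "R" if response == "responder" else "N"
        for i in range(n):
            sample_rows.append({
                "sample_id": f"{treatment}_{tag}{i + 1:02d}",
                "treatment": treatment, "response": response, "cell": cell,
                "has_cgh": i < n_cgh, "has_expr": i < n_expr,
            })
    samples = pd.DataFrame(sample_rows)

    # --- event planting: exact counts per cell -----------------------------
    event_samples: dict[str, list[str]] = {name: [] for name, *_ in events}
    for cell in samples["cell"].unique():
        in_cell = (samples["cell"] == cell) & samples["has_cgh"]
        ids = samples.loc[in_cell, "sample_id"].to_numpy()
        for ev in config.events:
            p = ev.prob.get(cell, 0.0)
            k = int(round(p * len(ids)))
            if k > 0:
                chosen = rng_assign.choice(ids, size=k, replace=False)
                event_samples[ev.name].extend(sorted(chosen))

    # --- aCGH profiles -----------------------------------------------------
    lo, hi = config.purity_range
    profiles: dict[str, GenomicProfile] = {}
    purities: dict[str, float] = {}
    cgh_ids = samples.loc[samples["has_cgh"], "sample_id"].tolist()
    child_seeds = ss_cgh.spawn(len(cgh_ids))
    for sid, child in zip(cgh_ids, child_seeds):
        purity = float(rng_assign.uniform(lo, hi))
        purities[sid] = purity
        own = [ev for ev in events if sid in event_samples[ev[0]]]
        profiles[sid] = simulate_acgh_profile(
            clone_map, own, purity, config.noise_sd, child, sample_id=sid)

    # --- subtype labels and expression -------------------------------------
    classes = rng_assign.choice(config.class_names, size=len(samples),
                                p=config.class_proportions)
    samples["subtype"] = classes
    expr_mask = samples["has_expr"]
    class_labels = pd.Series(samples.loc[expr_mask, "subtype"].to_numpy(),
                             index=samples.loc[expr_mask, "sample_id"])
    group_labels = pd.Series(samples.loc[expr_mask, "cell"].to_numpy(),
                             index=samples.loc[expr_mask, "sample_id"])
    expression, probe_genes, gene_sets, expr_truth = simulate_expression(
        config, class_labels, group_labels, ss_expr)

    # --- survival ----------------------------------------------------------
    rng_surv = np.random.default_rng(ss_surv)
    pfs = np.empty(len(samples))
    for i, row in samples.iterrows():
        hazard = config.pfs_hazard[row["cell"]]
        if row["treatment"] == "RT":
            pfs[i] = _conditioned_pfs(rng_surv, hazard,
                                      responder=row["response"] == "responder",
                                      cutoffs=config.pfs_cutoffs)
        else:
            pfs[i] = rng_surv.exponential(1.0 / hazard)
    os_extra = rng_surv.exponential(1.0 / config.os_extra_hazard,
                                    size=len(samples))
    censored = rng_surv.uniform(size=len(samples)) < config.censoring_rate
    os_months = pfs + np.where(
        censored, rng_surv.uniform(size=len(samples)) * os_extra, os_extra)
    metadata = SampleMetadata(pd.DataFrame({
        "sample_id": samples["sample_id"],
        "treatment": samples["treatment"],
        "response": samples["response"],
        "pfs_months": pfs,
        "os_months": os_months,
        "pfs_event": 1,
        "os_event": (~censored).astype(int),
        "subtype": samples["subtype"],
        "has_cgh": samples["has_cgh"],
        "has_expr": samples["has_expr"],
    }))

    # consistency: RT response labels re-derived from PFS match the plant
    rt = metadata.table[metadata.table["treatment"] == "RT"]
    low_cut, high_cut = config.pfs_cutoffs
    derived = np.where(rt["pfs_months"] > high_cut, "responder",
                       np.where(rt["pfs_months"] < low_cut, "nonresponder",
                                "unassigned"))
    if not (derived == rt["response"].to_numpy()).all():
        raise AssertionError("derived RT response labels disagree with "
                             "planted labels")

    truth = {
        "seed": config.seed,
        "events": {name: {"chrom": chrom, "start": int(start),
                          "end": int(end), "copy_number": int(cn),
                          "samples": event_samples[name]}
                   for name, chrom, start, end, cn in events},
        "purity": purities,
        **expr_truth,
    }
    return Cohort(clone_map, chrom_lengths, profiles, expression,
                  probe_genes, gene_sets, metadata, truth)
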