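"""Readers and writers for the pipeline's external formats.

All genomic coordinates are 0-based half-open internally and in every file
this module writes.  Clone maps supplied with 1-based inclusive coordinates
are converted at parse time (``one_based=True``); nothing downstream ever
sees a 1-based coordinate.  Missing values are written and read as ``NA``
and propagated as NaN, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CloneMap",
    "GeneSetCollection",
    "SampleMetadata",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_clone_map",
    "write_clone_map",
    "read_gmt",
    "write_gmt",
    "read_metadata",
    "write_metadata",
    "write_segments_bed",
    "read_config",
    "write_config",
]

TREATMENTS = ("RT", "CT")
RESPONSES = ("responder", "nonresponder", "unassigned")


@dataclass
class CloneMap:
    """Ordered BAC-clone map: (clone_id, chrom, start, end), 0-based half-open.

    The canonical order — lexicographic chromosome, then start — is applied
    on construction and defines the genome order used by segmentation and
    calling.  Overlapping clones are permitted (BAC tiling paths overlap).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["clone_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"clone map missing columns: {missing}")
        t = self.table[required].copy()
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        if (t["end"] <= t["start"]).any():
            bad = t.loc[t["end"] <= t["start"], "clone_id"].iloc[0]
            raise ValueError(f"clone {bad!r} has end <= start")
        dup = t["clone_id"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate clone_id {t.loc[dup, 'clone_id'].iloc[0]!r}")
        t = t.sort_values(["chrom", "start", "end", "clone_id"], kind="mergesort")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def clone_ids(self) -> pd.Index:
        return pd.Index(self.table["clone_id"])

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Positional indices (canonical order) of the clones on one chromosome."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of annotatable gene symbols."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        if not self.universe:
            u: set[str] = set()
            for s in self.sets.values():
                u |= s
            self.universe = frozenset(u)
        else:
            self.universe = frozenset(self.universe)

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with a new universe, dropping emptied sets."""
        u = frozenset(universe)
        kept = {k: s & u for k, s in self.sets.items()}
        return GeneSetCollection({k: s for k, s in kept.items() if s}, u)


@dataclass
class SampleMetadata:
    """Per-sample clinical annotations (treatment arm, response, outcomes)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "treatment", "response",
                    "pfs_months", "os_months", "pfs_event", "os_event"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        t = self.table.copy()
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        bad_t = ~t["treatment"].isin(TREATMENTS)
        if bad_t.any():
            raise ValueError(
                f"unknown treatment {t.loc[bad_t, 'treatment'].iloc[0]!r}")
        bad_r = ~t["response"].isin(RESPONSES)
        if bad_r.any():
            raise ValueError(f"unknown response {t.loc[bad_r, 'response'].iloc[0]!r}")
        both = t["pfs_months"].notna() & t["os_months"].notna()
        if (t.loc[both, "pfs_months"] > t.loc[both, "os_months"] + 1e-9).any():
            raise ValueError("pfs_months exceeds os_months for some sample")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def group_labels(self, by: str = "response") -> pd.Series:
        return self.table.set_index("sample_id")[by]


def read_matrix_tsv(path, orientation: str = "rows_are_features") -> pd.DataFrame:
    """Read a numeric TSV matrix (first row = column ids, first column = row ids).

    Missing values must be encoded ``NA`` and come back as NaN.  Duplicated
    ids and non-numeric cells raise with the offending location.
    """
    if orientation not in ("rows_are_features", "rows_are_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=[])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated row id {dup!r} in {path}")
    if pd.Index(df.columns).duplicated().any():
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"duplicated column id {dup!r} in {path}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        numeric = pd.to_numeric(raw.where(raw != "NA"), errors="coerce")
        bad = numeric.isna() & (raw != "NA")
        if bad.any():
            row = raw.index[bad][0]
            raise ValueError(
                f"non-numeric value {raw[bad].iloc[0]!r} at row {row!r}, "
                f"column {col!r} in {path}")
        out[col] = numeric
    if orientation == "rows_are_samples":
        out = out.T
    return out


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a numeric matrix as TSV with ``NA`` for missing, 0-padding-free."""
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_clone_map(path, one_based: bool = False) -> CloneMap:
    """Read a clone map TSV (clone_id, chrom, start, end).

    ``one_based=True`` converts 1-based inclusive coordinates to the internal
    0-based half-open convention at parse time.
    """
    t = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "chrom": str})
    if one_based:
        t["start"] = t["start"] - 1
    return CloneMap(t)


def write_clone_map(clone_map: CloneMap, path) -> None:
    clone_map.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read GMT gene sets (name, description, members...; tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_metadata(path) -> SampleMetadata:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleMetadata(t)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_segments_bed(calls, clone_map: CloneMap, path,
                       include_neutral: bool = False) -> None:
    """Write per-sample aberration calls as BED5 (chrom, start, end, status, sample).

    ``calls`` maps sample_id -> per-clone status aligned to the clone map
    (an AberrationCalls or any object with a ``status`` Series/array).  One
    line is emitted per maximal run of clones with identical status on a
    chromosome; coordinates are clone-bounded, 0-based half-open.
    """
    t = clone_map.table
    lines: list[tuple[str, int, int, str, str]] = []
    for sample_id in sorted(calls):
        status = getattr(calls[sample_id], "status", calls[sample_id])
        status = np.asarray(status, dtype=object)
        if len(status) != len(clone_map):
            raise ValueError(
                f"sample {sample_id!r}: {len(status)} calls for "
                f"{len(clone_map)} clones")
        for chrom in clone_map.chroms:
            idx = clone_map.chrom_indices(chrom)
            run_start = 0
            st = status[idx]
            for i in range(1, len(idx) + 1):
                if i == len(idx) or st[i] != st[run_start]:
                    val = st[run_start]
                    if pd.notna(val) and (include_neutral or val != "neutral"):
                        lines.append((
                            chrom,
                            int(t["start"].iloc[idx[run_start]]),
                            int(t["end"].iloc[idx[i - 1]]),
                            str(val),
                            sample_id,
                        ))
                    run_start = i
    lines.sort(key=lambda r: (r[0], r[1], r[2], r[4]))
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, status_, sample_id in lines:
            fh.write(f"{chrom}\t{start}\t{end}\t{status_}\t{sample_id}\n")


def read_config(path) -> dict:
    """Load a YAML (or JSON; JSON is a YAML subset) configuration mapping."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
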