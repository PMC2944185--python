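"""Minimal common regions (MCRs) of recurrent copy-number aberrations.

An MCR of one event type is a maximal genomic interval over which the set of
samples carrying that event is constant and at least ``min_recurrence``
large.  The construction is a breakpoint sweep: collect the endpoints of all
samples' aberrant intervals on a chromosome, evaluate the supporting-sample
set over every atomic interval between consecutive breakpoints, and merge
maximal runs of adjacent atomic intervals with identical support.  Adjacent
regions with different supporting sets stay distinct (they are different
events), and every MCR is contained in the intersection of its supporting
samples' aberrant intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CloneMap

__all__ = ["McrRecord", "calls_to_intervals", "derive_mcrs"]

EVENT_TYPES = ("gain", "loss", "amp", "homdel")


@dataclass
class McrRecord:
    event_type: str
    chrom: str
    start: int
    end: int
    supporting_samples: frozenset[str]

    @property
    def recurrence(self) -> int:
        return len(self.supporting_samples)


def calls_to_intervals(status, clone_map: CloneMap, event_type: str,
                       ) -> list[tuple[str, int, int]]:
    """Clone-bounded aberrant intervals of one event type for one sample.

    Maximal runs of clones with the given status become (chrom, start, end)
    intervals, 0-based half-open, bounded by the first/last clone of the run.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    status = np.asarray(status, dtype=object)
    if len(status) != len(clone_map):
        raise ValueError("status length does not match clone map")
    t = clone_map.table
    intervals = []
    for chrom in clone_map.chroms:
        idx = clone_map.chrom_indices(chrom)
        hit = status[idx] == event_type
        run_start = None
        for i in range(len(idx) + 1):
            if i < len(idx) and hit[i]:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                intervals.append((chrom,
                                  int(t["start"].iloc[idx[run_start]]),
                                  int(t["end"].iloc[idx[i - 1]])))
                run_start = None
    return intervals


def derive_mcrs(calls_by_sample: dict, event_type: str,
                min_recurrence: int = 2,
                clone_map: CloneMap | None = None) -> list[McrRecord]:
    """Derive MCRs of one event type across samples.

    ``calls_by_sample`` maps sample_id to either an AberrationCalls-like
    object (requires ``clone_map``) or a pre-computed list of
    (chrom, start, end) aberrant intervals.  Output is sorted by
    (chrom, start) and independent of sample order.
    """
    if min_recurrence < 1:
        raise ValueError("min_recurrence must be >= 1")
    intervals_by_sample: dict[str, list[tuple[str, int, int]]] = {}
    for sid, calls in calls_by_sample.items():
        if hasattr(calls, "status") or (
                isinstance(calls, np.ndarray) and calls.dtype == object):
            if clone_map is None:
                raise ValueError("clone_map required when passing call arrays")
            status = getattr(calls, "status", calls)
            intervals_by_sample[sid] = calls_to_intervals(
                status, clone_map, event_type)
        else:
            intervals_by_sample[sid] = [(c, int(s), int(e))
                                        for c, s, e in calls]

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for sid, ivals in intervals_by_sample.items():
        for chrom, start, end in ivals:
            by_chrom.setdefault(chrom, []).append((start, end, sid))

    records: list[McrRecord] = []
    for chrom in sorted(by_chrom):
        ivals = by_chrom[chrom]
        points = sorted({p for s, e, _ in ivals for p in (s, e)})
        atoms = []  # (start, end, frozenset supporting)
        for a, b in zip(points[:-1], points[1:]):
            support = frozenset(sid for s, e, sid in ivals if s <= a and e >= b)
            atoms.append((a, b, support))
        # merge maximal runs of adjacent atoms with identical support
        i = 0
        while i < len(atoms):
            a, b, support = atoms[i]
            j = i + 1
            while (j < len(atoms) and atoms[j][2] == support
                   and atoms[j][0] == atoms[j - 1][1]):
                b = atoms[j][1]
                j += 1
            if len(support) >= min_recurrence:
                records.append(McrRecord(event_type, chrom, a, b, support))
            i = j
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def mcrs_to_frame(records: list[McrRecord]) -> pd.DataFrame:
    """Tabular view of MCRs (samples joined by comma, sorted)."""
    return pd.DataFrame([{
        "event_type": r.event_type, "chrom": r.chrom,
        "start": r.start, "end": r.end, "recurrence": r.recurrence,
        "samples": ",".join(sorted(r.supporting_samples)),
    } for r in records])
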