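"""Indel quantification at guide target windows from barcode-tagged alignments.

Editing at each gRNA target site is validated straight from the
single-cell alignments: for every assignment group (each assigned guide,
plus the doublet and not-assigned pools) and every target window, reads
whose aligned span fully contains the window are counted, and the
fraction carrying an insertion or deletion touching the window is the
indel ratio.  The numerator is a per-read boolean by default, which
bounds the ratio in [0, 1]; ``events`` mode counts every I/D event
instead, matching the alternative event-count reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import GenomicInterval

__all__ = [
    "AlignedRead",
    "IndelResult",
    "read_spans_window",
    "read_has_indel_in_window",
    "count_indel_events_in_window",
    "indel_ratios",
    "enrichment_matrix",
]

# CIGAR ops that consume reference positions
_REF_CONSUMING = {"M", "D", "N", "=", "X"}


@dataclass(frozen=True)
class AlignedRead:
    """A single alignment: 0-based leftmost position plus CIGAR ops."""

    read_id: str
    ref_name: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    cell_barcode: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "cigar", tuple(self.cigar))
        if any(n <= 0 for _, n in self.cigar):
            raise ValueError(f"read {self.read_id}: non-positive CIGAR length")

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_span


@dataclass
class IndelResult:
    """Indel tally for one (assignment group, target window) cell."""

    group: str
    target: str
    target_window: GenomicInterval
    n_spanning: int
    n_with_indel: int

    @property
    def ratio(self) -> float:
        if self.n_spanning == 0:
            return math.nan
        return self.n_with_indel / self.n_spanning

    @property
    def flagged_empty(self) -> bool:
        return self.n_spanning == 0


def read_spans_window(read: AlignedRead, window: GenomicInterval) -> bool:
    """True iff the aligned reference span fully contains the window."""
    if read.ref_name != window.chrom:
        return False
    return read.pos <= window.start and window.end <= read.reference_end


def _indel_events(read: AlignedRead, window: GenomicInterval):
    """Yield I/D events whose reference locus intersects the window.

    A deletion occupies the deleted reference interval.  An insertion
    sits between two reference bases; it intersects the window only when
    that junction is strictly interior (start < point < end), so an
    insertion flush against the window edge does not count.  N (splice)
    consumes reference but is never an indel; soft/hard clips consume
    nothing.
    """
    ref = read.pos
    for op, n in read.cigar:
        if op == "D":
            if ref < window.end and window.start < ref + n:
                yield ("D", ref, n)
        elif op == "I":
            if window.start < ref < window.end:
                yield ("I", ref, n)
        if op in _REF_CONSUMING:
            ref += n


def read_has_indel_in_window(read: AlignedRead, window: GenomicInterval) -> bool:
    """True iff >= 1 insertion or deletion intersects the window.

    Must be called on a read that fully spans the window.
    """
    if not read_spans_window(read, window):
        raise ValueError(
            f"read {read.read_id} does not span {window.to_peak_id()}"
        )
    return next(_indel_events(read, window), None) is not None


def count_indel_events_in_window(
    read: AlignedRead, window: GenomicInterval
) -> int:
    """Number of distinct I/D events intersecting the window."""
    if not read_spans_window(read, window):
        raise ValueError(
            f"read {read.read_id} does not span {window.to_peak_id()}"
        )
    return sum(1 for _ in _indel_events(read, window))


def indel_ratios(
    reads: Iterable[AlignedRead],
    windows: Mapping[str, GenomicInterval],
    cell_groups: Mapping[str, str],
    events: bool = False,
) -> tuple[list[IndelResult], int]:
    """Tally spanning reads and indels per (assignment group, target).

    ``cell_groups`` maps cell barcode to its assignment group (assigned
    guide id, ``Doublet`` or ``Not assigned``); reads whose barcode is
    absent are dropped and counted.  ``windows`` maps target name
    (typically guide id) to its genomic window.  Returns the result grid
    (every observed group x every target, zero-spanning combinations
    flagged) and the number of dropped reads.
    """
    groups = sorted(set(cell_groups.values()))
    tallies: dict[tuple[str, str], list[int]] = {
        (g, t): [0, 0] for g in groups for t in windows
    }
    dropped = 0
    for read in reads:
        group = cell_groups.get(read.cell_barcode)
        if group is None:
            dropped += 1
            continue
        for target, window in windows.items():
            if not read_spans_window(read, window):
                continue
            tally = tallies[(group, target)]
            tally[0] += 1
            if events:
                tally[1] += count_indel_events_in_window(read, window)
            elif read_has_indel_in_window(read, window):
                tally[1] += 1
    results = [
        IndelResult(g, t, windows[t], n_span, n_indel)
        for (g, t), (n_span, n_indel) in tallies.items()
    ]
    return results, dropped


def enrichment_matrix(results: Iterable[IndelResult]) -> pd.DataFrame:
    """Groups x targets ratio matrix scaled by each row's maximum.

    All-zero rows are left as zeros (no 0/0); NaN ratios (groups with no
    spanning reads at a target) propagate.
    """
    rows: dict[str, dict[str, float]] = {}
    for res in results:
        rows.setdefault(res.group, {})[res.target] = res.ratio
    mat = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    mat = mat[sorted(mat.columns)]
    scaled = mat.copy()
    for group, row in mat.iterrows():
        row_max = row.max(skipna=True)
        if pd.notna(row_max) and row_max > 0:
            scaled.loc[group] = row / row_max
    return scaled


def results_table(results: Iterable[IndelResult]) -> pd.DataFrame:
    """Flat TSV-ready table of indel results."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "target": r.target,
                "window": r.target_window.to_peak_id(),
                "n_spanning": r.n_spanning,
                "n_with_indel": r.n_with_indel,
                "ratio": r.ratio,
                "flag": "no_spanning_reads" if r.flagged_empty else "",
            }
            for r in results
        ]
    )
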