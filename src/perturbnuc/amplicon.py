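"""Dual-guide amplicon classification and viral-pool representation QC.

Long amplicon reads of the gRNA cassette are classified against the
designed library: each of the two spacer slots is searched for its best
Levenshtein match among all library spacers inside an offset window, a
guide is detected only when that match is within ``max_edit`` and
uniquely best, and a read is an on-target pair only when both detected
guides belong to the same designed pair.  Both slots detected but from
different pairs marks a chimera (template switching during pooled
amplification).  The pool report checks the mean per-guide depth
against the sequencing-depth requirement and adds uniformity metrics
(CV, Gini) over per-pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import numpy as np
from Bio import SeqIO

from .types import GuideLibrary

__all__ = [
    "CassetteLayout",
    "PairCall",
    "DistributionReport",
    "classify_amplicon_read",
    "classify_fastq",
    "summarize_pool",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_CHARS = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CassetteLayout:
    """Where the two spacers sit in the amplicon.

    ``g1_offset``/``g2_offset`` are the designed 0-based positions of
    each 20-nt spacer; ``slop`` widens the search window on both sides
    to absorb indel drift in long reads.
    """

    g1_offset: int
    g2_offset: int
    spacer_length: int = 20
    slop: int = 12

    def window(self, seq: str, slot: str) -> str:
        offset = self.g1_offset if slot == "g1" else self.g2_offset
        lo = max(0, offset - self.slop)
        hi = min(len(seq), offset + self.spacer_length + self.slop)
        return seq[lo:hi]


@dataclass
class PairCall:
    """Classification of one amplicon read."""

    read_id: str
    g1_hit: Optional[str]
    g2_hit: Optional[str]
    status: str  # on_target_pair | chimeric | unassigned
    edit_distances: tuple[Optional[int], Optional[int]] = (None, None)
    pair_id: Optional[str] = None


@dataclass
class DistributionReport:
    """Pool representation summary over classified reads."""

    per_pair_counts: dict[str, int]
    per_guide_counts: dict[str, int]
    n_reads: int
    n_on_target: int
    n_chimeric: int
    n_unassigned: int
    on_target_fraction: float
    mean_reads_per_guide: float
    cv: float
    gini: float
    depth_ok: bool

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_on_target": self.n_on_target,
            "n_chimeric": self.n_chimeric,
            "n_unassigned": self.n_unassigned,
            "on_target_fraction": self.on_target_fraction,
            "mean_reads_per_guide": self.mean_reads_per_guide,
            "cv": self.cv,
            "gini": self.gini,
            "depth_ok": self.depth_ok,
            "per_pair_counts": self.per_pair_counts,
            "per_guide_counts": self.per_guide_counts,
        }


def _detect_in_window(
    window: str, library: GuideLibrary, max_edit: int
) -> tuple[Optional[str], Optional[int]]:
    """Best unique spacer match in a window, or (None, None).

    A guide is detected iff its spacer aligns within ``max_edit``
    (Levenshtein, infix alignment) and no other spacer attains the same
    best distance.
    """
    best_id: Optional[str] = None
    best_dist: Optional[int] = None
    tied = False
    for g in library.guides:
        res = edlib.align(g.spacer, window, mode="HW", task="distance", k=max_edit)
        dist = res["editDistance"]
        if dist < 0:
            continue
        if best_dist is None or dist < best_dist:
            best_id, best_dist, tied = g.guide_id, dist, False
        elif dist == best_dist:
            tied = True
    if best_dist is None or tied:
        return None, None
    return best_id, best_dist


def classify_amplicon_read(
    seq: str,
    library: GuideLibrary,
    layout: CassetteLayout,
    max_edit: int = 3,
    read_id: str = "",
) -> PairCall:
    """Classify one amplicon read against the designed library.

    Both the given orientation and its reverse complement are scanned;
    the orientation detecting more guides (ties broken by lower total
    edit distance) wins, and a dead-heat between orientations with at
    least one detection is conservatively unassigned.  Sequences with
    characters outside ACGTN are unassigned without scanning.
    """
    seq = seq.upper()
    if not set(seq) <= _VALID_CHARS:
        return PairCall(read_id, None, None, "unassigned")
    if len(library) == 0:
        raise ValueError("empty guide library")

    candidates = []
    for oriented in (seq, reverse_complement(seq)):
        g1_hit, d1 = _detect_in_window(
            layout.window(oriented, "g1"), library, max_edit
        )
        g2_hit, d2 = _detect_in_window(
            layout.window(oriented, "g2"), library, max_edit
        )
        n_det = (g1_hit is not None) + (g2_hit is not None)
        total = (d1 or 0) + (d2 or 0)
        candidates.append((n_det, -total, g1_hit, g2_hit, d1, d2))

    fwd, rev = candidates
    if fwd[:2] == rev[:2] and fwd[0] > 0 and (fwd[2:4] != rev[2:4]):
        # orientations disagree at identical score: refuse to guess
        return PairCall(read_id, None, None, "unassigned")
    n_det, _, g1_hit, g2_hit, d1, d2 = max(fwd, rev, key=lambda c: c[:2])
    if g1_hit is None or g2_hit is None:
        return PairCall(read_id, g1_hit, g2_hit, "unassigned", (d1, d2))
    pair1 = library.guide(g1_hit).pair_id
    pair2 = library.guide(g2_hit).pair_id
    if pair1 == pair2:
        return PairCall(read_id, g1_hit, g2_hit, "on_target_pair", (d1, d2), pair1)
    return PairCall(read_id, g1_hit, g2_hit, "chimeric", (d1, d2))


def classify_fastq(
    fastq_path,
    library: GuideLibrary,
    layout: CassetteLayout,
    max_edit: int = 3,
) -> tuple[list[PairCall], int]:
    """Classify every read of a FASTQ file (qualities ignored).

    Returns the calls plus a warning counter of reads rejected for
    malformed sequence characters.
    """
    calls: list[PairCall] = []
    n_malformed = 0
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        seq = str(rec.seq).upper()
        if not set(seq) <= _VALID_CHARS:
            n_malformed += 1
            calls.append(PairCall(rec.id, None, None, "unassigned"))
            continue
        calls.append(
            classify_amplicon_read(seq, library, layout, max_edit, read_id=rec.id)
        )
    return calls, n_malformed


def _gini(counts: np.ndarray) -> float:
    """Gini coefficient of a nonnegative count vector (0 = uniform)."""
    x = np.sort(counts.astype(float))
    n = x.size
    total = x.sum()
    if n == 0 or total == 0:
        return 0.0
    ranks = np.arange(1, n + 1)
    return float((2 * (ranks * x).sum() - (n + 1) * total) / (n * total))


def summarize_pool(
    calls: Iterable[PairCall],
    library: GuideLibrary,
    min_mean_depth: int = 100,
) -> DistributionReport:
    """Pool representation report over classified reads.

    Per-pair counts tally on-target reads only (including zeros for
    unseen pairs); per-guide counts tally every individual detection in
    on-target and chimeric reads.  ``depth_ok`` requires the mean reads
    per guide to exceed ``min_mean_depth``, the stated sequencing-depth
    requirement for pool QC.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no amplicon calls to summarize")
    per_pair = {pid: 0 for pid in library.pair_ids}
    per_guide = {gid: 0 for gid in library.guide_ids}
    n_on, n_chi, n_un = 0, 0, 0
    for call in calls:
        if call.status == "on_target_pair":
            n_on += 1
            per_pair[call.pair_id] += 1
        elif call.status == "chimeric":
            n_chi += 1
        else:
            n_un += 1
        if call.status in ("on_target_pair", "chimeric"):
            per_guide[call.g1_hit] += 1
            per_guide[call.g2_hit] += 1
    pair_counts = np.array(list(per_pair.values()), dtype=float)
    guide_counts = np.array(list(per_guide.values()), dtype=float)
    mean_guide = float(guide_counts.mean())
    mean_pair = pair_counts.mean()
    cv = float(pair_counts.std() / mean_pair) if mean_pair > 0 else float("nan")
    return DistributionReport(
        per_pair_counts=per_pair,
        per_guide_counts=per_guide,
        n_reads=len(calls),
        n_on_target=n_on,
        n_chimeric=n_chi,
        n_unassigned=n_un,
        on_target_fraction=n_on / len(calls),
        mean_reads_per_guide=mean_guide,
        cv=cv,
        gini=_gini(pair_counts),
        depth_ok=mean_guide > min_mean_depth,
    )
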