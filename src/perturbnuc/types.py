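"""Core domain types shared by every pipeline stage.

Conventions
-----------
* All genomic intervals are 0-based, half-open ``[start, end)``.  SAM
  positions (1-based) are converted on read; BED is consumed natively.
* Count matrices are sparse CSR with cells as rows and features as
  columns; entries are nonnegative integers.
* Strand is carried on intervals but ignored by every computation here:
  guide-count, window and peak logic in this toolkit is strandless.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "GenomicInterval",
    "GuideRecord",
    "GuideLibrary",
    "CellByFeatureCounts",
    "CELL_META_RNA_COLUMNS",
    "CELL_META_ATAC_COLUMNS",
    "validate_cell_meta",
]

_SPACER_RE = re.compile(r"^[ACGT]+$")
_PEAK_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")

Modality = Literal["guide", "gene", "peak"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, 0-based.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded); it is
    retained for provenance but no computation in this package depends
    on it.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @classmethod
    def from_peak_id(cls, peak_id: str) -> "GenomicInterval":
        """Parse a ``chrom:start-end`` peak identifier."""
        m = _PEAK_ID_RE.match(peak_id)
        if m is None:
            raise ValueError(f"malformed peak id {peak_id!r}; expected chrom:start-end")
        return cls(m["chrom"], int(m["start"]), int(m["end"]))

    def to_peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GuideRecord:
    """One gRNA of a dual-guide cassette.

    ``position_in_cassette`` is ``g1`` or ``g2``; every designed pair
    contributes exactly one of each.  ``control_class`` distinguishes
    gene-targeting guides from non-target (NT, no genomic site) and
    safe-target (ST, non-genic site) controls.
    """

    guide_id: str
    spacer: str
    pair_id: str
    position_in_cassette: str
    target_gene: Optional[str] = None
    control_class: str = "targeting"
    target_window: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if not _SPACER_RE.match(self.spacer):
            raise ValueError(
                f"guide {self.guide_id}: non-ACGT spacer {self.spacer!r}"
            )
        if self.position_in_cassette not in ("g1", "g2"):
            raise ValueError(
                f"guide {self.guide_id}: position_in_cassette must be g1 or g2"
            )
        if self.control_class not in ("targeting", "non_target", "safe_target"):
            raise ValueError(
                f"guide {self.guide_id}: unknown control_class {self.control_class!r}"
            )
        if self.control_class == "targeting" and self.target_window is None:
            raise ValueError(
                f"guide {self.guide_id}: targeting guide needs a target_window"
            )


@dataclass
class GuideLibrary:
    """A validated dual-guide library.

    Invariants enforced at construction: unique guide ids, every
    ``pair_id`` maps to exactly one g1 and one g2, spacers are uppercase
    ACGT, targeting guides carry a target window.
    """

    guides: list[GuideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.guide_id for g in self.guides]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate guide_id(s): {dup}")
        by_pair: dict[str, dict[str, GuideRecord]] = {}
        for g in self.guides:
            slot = by_pair.setdefault(g.pair_id, {})
            if g.position_in_cassette in slot:
                raise ValueError(
                    f"pair {g.pair_id}: duplicate {g.position_in_cassette}"
                )
            slot[g.position_in_cassette] = g
        for pid, slot in by_pair.items():
            if set(slot) != {"g1", "g2"}:
                missing = {"g1", "g2"} - set(slot)
                raise ValueError(
                    f"incomplete pair {pid}: missing {sorted(missing)}"
                )
        self._by_pair = by_pair
        self._by_id = {g.guide_id: g for g in self.guides}

    def __len__(self) -> int:
        return len(self.guides)

    @property
    def pair_ids(self) -> list[str]:
        seen: list[str] = []
        for g in self.guides:
            if g.pair_id not in seen:
                seen.append(g.pair_id)
        return seen

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    def guide(self, guide_id: str) -> GuideRecord:
        return self._by_id[guide_id]

    def pair(self, pair_id: str) -> tuple[GuideRecord, GuideRecord]:
        slot = self._by_pair[pair_id]
        return slot["g1"], slot["g2"]

    def targeting_guides(self) -> list[GuideRecord]:
        return [g for g in self.guides if g.control_class == "targeting"]

    def control_guides(self) -> list[GuideRecord]:
        return [g for g in self.guides if g.control_class != "targeting"]


class CellByFeatureCounts:
    """Sparse cell x feature nonnegative integer count matrix.

    One container serves all three modalities (guide UMIs, gene UMIs,
    peak fragment counts); rows are cell barcodes, columns features.
    """

    def __init__(
        self,
        counts: sparse.spmatrix | np.ndarray,
        cell_barcodes: Iterable[str],
        feature_ids: Iterable[str],
        modality: Modality,
    ) -> None:
        mat = sparse.csr_matrix(counts)
        barcodes = list(cell_barcodes)
        features = list(feature_ids)
        if mat.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(barcodes)} barcodes x {len(features)} features"
            )
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("cell barcodes are not unique")
        if len(set(features)) != len(features):
            raise ValueError("feature ids are not unique")
        if modality not in ("guide", "gene", "peak"):
            raise ValueError(f"unknown modality {modality!r}")
        data = mat.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be nonnegative integers")
        mat.data = data.astype(np.int64)
        self.counts = mat
        self.cell_barcodes = barcodes
        self.feature_ids = features
        self.modality: Modality = modality
        self._bc_index = {b: i for i, b in enumerate(barcodes)}
        self._ft_index = {f: i for i, f in enumerate(features)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def barcode_index(self, barcode: str) -> int:
        return self._bc_index[barcode]

    def feature_index(self, feature_id: str) -> int:
        return self._ft_index[feature_id]

    def total(self) -> int:
        return int(self.counts.sum())

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, barcodes: Iterable[str]) -> "CellByFeatureCounts":
        keep = [self._bc_index[b] for b in barcodes]
        return CellByFeatureCounts(
            self.counts[keep, :],
            [self.cell_barcodes[i] for i in keep],
            self.feature_ids,
            self.modality,
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellByFeatureCounts):
            return NotImplemented
        return (
            self.cell_barcodes == other.cell_barcodes
            and self.feature_ids == other.feature_ids
            and self.modality == other.modality
            and (self.counts != other.counts).nnz == 0
        )


# Per-cell metadata is a plain DataFrame indexed by barcode; these are the
# metric columns each QC stage requires.  The doublet score and intronic
# fraction are consumed as supplied -- their computation is upstream.
CELL_META_RNA_COLUMNS = [
    "n_genes",
    "n_umi",
    "pct_mito",
    "frac_intronic",
    "doublet_score",
]
CELL_META_ATAC_COLUMNS = [
    "n_count_peaks",
    "frac_reads_in_peaks",
    "tss_enrichment",
    "frac_blacklist",
    "nucleosome_signal",
]


def validate_cell_meta(meta: pd.DataFrame, require: Iterable[str]) -> None:
    """Check that metadata carries the required metric columns.

    Raises ``KeyError`` naming every missing column, and ``ValueError``
    for out-of-range fractions or negative counts.
    """
    missing = [c for c in require if c not in meta.columns]
    if missing:
        raise KeyError(f"cell metadata missing column(s): {missing}")
    for col in ("frac_intronic", "frac_reads_in_peaks", "frac_blacklist"):
        if col in meta.columns:
            vals = meta[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"{col} outside [0, 1]")
    for col in ("n_genes", "n_umi", "n_count_peaks"):
        if col in meta.columns and np.any(meta[col].to_numpy(dtype=float) < 0):
            raise ValueError(f"{col} contains negative values")
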