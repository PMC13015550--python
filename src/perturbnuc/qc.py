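"""Cell-level and cluster-level QC filters for RNA and ATAC modalities.

Boundary semantics follow the quoted rules literally and strictly: a
cell is dropped for *fewer than* 500 genes (exactly 500 is kept), for
UMIs *below* 1,000 or *above* 15,000 (exactly 15,000 is kept), for a
doublet score *above* 1.5, and on the ATAC side for peak counts outside
[200, 10,000], FRiP below 0.10, TSS enrichment below 1, blacklist
fraction above 7.5% or nucleosome signal above 0.3 (exactly 0.3 is
kept).  Cluster-level RNA rules act on cluster medians: gene count,
percent-mitochondrial (percent scale) and intronic fraction (fraction
scale) -- the two scales are deliberately kept as quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    CELL_META_ATAC_COLUMNS,
    CELL_META_RNA_COLUMNS,
    validate_cell_meta,
)

__all__ = [
    "RnaThresholds",
    "AtacThresholds",
    "QcThresholds",
    "QcDecision",
    "rna_cell_qc",
    "atac_cell_qc",
    "intersect_modalities",
    "decisions_frame",
]


@dataclass(frozen=True)
class RnaThresholds:
    min_genes: int = 500
    min_umi: int = 1000
    max_umi: int = 15000
    max_doublet_score: float = 1.5
    cluster_median_genes_min: float = 1000.0
    cluster_median_mito_max: float = 8.0  # percent
    cluster_median_intronic_max: float = 0.55  # fraction

    def __post_init__(self) -> None:
        if self.min_umi >= self.max_umi:
            raise ValueError("min_umi must be < max_umi")


@dataclass(frozen=True)
class AtacThresholds:
    min_count: int = 200
    max_count: int = 10000
    min_frip: float = 0.10
    min_tss: float = 1.0
    max_blacklist: float = 0.075
    max_nucleosome: float = 0.3

    def __post_init__(self) -> None:
        if self.min_count >= self.max_count:
            raise ValueError("min_count must be < max_count")
        for frac in (self.min_frip, self.max_blacklist):
            if not 0 <= frac <= 1:
                raise ValueError("fraction thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class QcThresholds:
    rna: RnaThresholds = field(default_factory=RnaThresholds)
    atac: AtacThresholds = field(default_factory=AtacThresholds)


@dataclass
class QcDecision:
    cell_barcode: str
    kept: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must equal 'no failed rules'")


def _decide(barcode: str, reasons: list[str]) -> QcDecision:
    return QcDecision(barcode, kept=not reasons, reasons=reasons)


def rna_cell_qc(
    meta: pd.DataFrame,
    clusters: Optional[Mapping[str, str]] = None,
    thresholds: Optional[RnaThresholds] = None,
) -> list[QcDecision]:
    """Apply RNA cell- and cluster-level filters.

    ``meta`` is indexed by barcode with the RNA metric columns; optional
    ``clusters`` maps barcode to cluster label, enabling the
    cluster-median rules (cells in failing clusters are dropped with a
    ``cluster_*`` reason).  ``sample_tag_confident``, when present as a
    boolean column, gates cells whose sample tag was not confidently
    demultiplexed.
    """
    thresholds = thresholds or RnaThresholds()
    validate_cell_meta(meta, CELL_META_RNA_COLUMNS)

    bad_clusters: dict[str, list[str]] = {}
    if clusters is not None:
        cl = pd.Series({bc: clusters[bc] for bc in meta.index if bc in clusters})
        for label, members in cl.groupby(cl).groups.items():
            sub = meta.loc[list(members)]
            reasons = []
            if sub["n_genes"].median() < thresholds.cluster_median_genes_min:
                reasons.append("cluster_genes")
            if sub["pct_mito"].median() > thresholds.cluster_median_mito_max:
                reasons.append("cluster_mito")
            if sub["frac_intronic"].median() > thresholds.cluster_median_intronic_max:
                reasons.append("cluster_intronic")
            if reasons:
                bad_clusters[str(label)] = reasons

    decisions = []
    for bc, row in meta.iterrows():
        reasons = []
        if row["n_genes"] < thresholds.min_genes:
            reasons.append("min_genes")
        if row["n_umi"] < thresholds.min_umi:
            reasons.append("min_umi")
        if row["n_umi"] > thresholds.max_umi:
            reasons.append("max_umi")
        if row["doublet_score"] > thresholds.max_doublet_score:
            reasons.append("doublet_score")
        if clusters is not None and bc in clusters:
            reasons.extend(bad_clusters.get(str(clusters[bc]), []))
        if "sample_tag_confident" in meta.columns and not bool(
            row["sample_tag_confident"]
        ):
            reasons.append("sample_tag")
        decisions.append(_decide(str(bc), reasons))
    return decisions


def atac_cell_qc(
    meta: pd.DataFrame,
    thresholds: Optional[AtacThresholds] = None,
) -> list[QcDecision]:
    """Apply ATAC cell-level filters to metadata indexed by barcode."""
    thresholds = thresholds or AtacThresholds()
    validate_cell_meta(meta, CELL_META_ATAC_COLUMNS)
    decisions = []
    for bc, row in meta.iterrows():
        reasons = []
        if row["n_count_peaks"] < thresholds.min_count:
            reasons.append("atac_min_count")
        if row["n_count_peaks"] > thresholds.max_count:
            reasons.append("atac_max_count")
        if row["frac_reads_in_peaks"] < thresholds.min_frip:
            reasons.append("atac_frip")
        if row["tss_enrichment"] < thresholds.min_tss:
            reasons.append("atac_tss")
        if row["frac_blacklist"] > thresholds.max_blacklist:
            reasons.append("atac_blacklist")
        if row["nucleosome_signal"] > thresholds.max_nucleosome:
            reasons.append("atac_nucleosome")
        decisions.append(_decide(str(bc), reasons))
    return decisions


def intersect_modalities(
    rna_decisions: Iterable[QcDecision],
    atac_decisions: Iterable[QcDecision],
) -> tuple[set[str], dict[str, int]]:
    """Barcodes kept by both modalities, plus per-modality counts.

    Only nuclei passing RNA and ATAC QC jointly enter downstream
    analysis.  A disjoint intersection raises a warning but is returned.
    """
    import warnings

    rna_keep = {d.cell_barcode for d in rna_decisions if d.kept}
    atac_keep = {d.cell_barcode for d in atac_decisions if d.kept}
    joint = rna_keep & atac_keep
    if not joint and (rna_keep or atac_keep):
        warnings.warn("no cells pass QC in both modalities")
    counts = {
        "rna_kept": len(rna_keep),
        "atac_kept": len(atac_keep),
        "joint_kept": len(joint),
    }
    return joint, counts


def decisions_frame(decisions: Iterable[QcDecision]) -> pd.DataFrame:
    """TSV-ready table with semicolon-joined failure reasons."""
    return pd.DataFrame(
        [
            {
                "cell_barcode": d.cell_barcode,
                "kept": d.kept,
                "reasons": ";".join(d.reasons),
            }
            for d in decisions
        ]
    )
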