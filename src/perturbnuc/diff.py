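"""Pseudobulk differential expression / accessibility testing.

For each cell type, counts of cells carrying a single guide assignment
are summed into pseudobulk columns per (guide, sample tag) group.  Each
perturbation is compared with the designated non-target control guide
by a negative-binomial GLM likelihood-ratio test with guide and sample
tag as covariates, TMM normalization factors, and Cox-Reid estimated
dispersions; BH correction is applied within each contrast.  Genes are
prefiltered (``> 10`` UMIs in at least two columns) for RNA; the peak
matrix keeps everything except all-zero rows by default, mirroring the
DAR variant of the workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import glm
from .assign import AssignmentTable
from .stats import bh_adjust
from .types import CellByFeatureCounts, GuideLibrary

__all__ = [
    "PseudobulkMatrix",
    "make_pseudobulk",
    "prefilter_genes",
    "norm_factors",
    "estimate_dispersion",
    "build_design",
    "nb_glm_lrt",
    "run_screen",
    "concordance",
]

_LN2 = np.log(2.0)


@dataclass
class PseudobulkMatrix:
    """Features x (guide, sample) pseudobulk counts for one cell type."""

    counts: np.ndarray  # (G, n) int
    feature_ids: list[str]
    columns: pd.DataFrame  # per column: guide, sample, n_cells
    modality: str
    cell_type: str = ""
    norm_factors_: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.columns)):
            raise ValueError("pseudobulk dimensions inconsistent")

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def subset_features(self, keep: np.ndarray) -> "PseudobulkMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return PseudobulkMatrix(
            self.counts[idx],
            [self.feature_ids[i] for i in idx],
            self.columns,
            self.modality,
            self.cell_type,
            self.norm_factors_,
        )


def make_pseudobulk(
    counts: CellByFeatureCounts,
    meta: pd.DataFrame,
    assignments: AssignmentTable,
    cell_type: str,
) -> PseudobulkMatrix:
    """Sum single-assignment cells of one cell type into pseudobulk.

    ``meta`` is indexed by barcode with ``cell_type`` and ``sample_tag``
    columns.  Doublet and not-assigned cells are excluded; (guide,
    sample) groups with no cells are simply absent.  Column sums
    conserve the contributing single-cell totals exactly.
    """
    if cell_type not in set(meta["cell_type"]):
        raise ValueError(f"cell type {cell_type!r} absent from metadata")
    singles = assignments.single_cells()
    barcodes_ct = set(meta.index[meta["cell_type"] == cell_type])
    in_matrix = set(counts.cell_barcodes)
    members: dict[tuple[str, str], list[str]] = {}
    for bc, gid in singles.items():
        if bc in barcodes_ct and bc in in_matrix:
            tag = str(meta.loc[bc, "sample_tag"])
            members.setdefault((gid, tag), []).append(bc)
    keys = sorted(members)
    cols = []
    data = np.zeros((counts.n_features, len(keys)), dtype=np.int64)
    for j, key in enumerate(keys):
        idx = [counts.barcode_index(bc) for bc in members[key]]
        data[:, j] = np.asarray(counts.counts[idx, :].sum(axis=0)).ravel()
        cols.append(
            {"guide": key[0], "sample": key[1], "n_cells": len(members[key])}
        )
    return PseudobulkMatrix(
        data,
        list(counts.feature_ids),
        pd.DataFrame(cols),
        counts.modality,
        cell_type,
    )


def prefilter_genes(
    pb: PseudobulkMatrix, min_umi: int = 10, min_samples: int = 2
) -> np.ndarray:
    """Boolean keep-mask: strictly more than ``min_umi`` counts in at
    least ``min_samples`` pseudobulk columns."""
    return (pb.counts > min_umi).sum(axis=1) >= min_samples


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed mean of M-values factor of one column against the reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o, r = obs[ok].astype(float), ref[ok].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # asymptotic (delta-method) inverse variances as weights
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = m.size
    if np.allclose(m, m[0]):
        return float(2 ** m[0])
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = sp_stats.rankdata(m)
    rank_a = sp_stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep]
    f = np.sum(m[keep] * inv_w) / np.sum(inv_w)
    return float(2**f)


def norm_factors(pb: PseudobulkMatrix) -> np.ndarray:
    """TMM normalization factors with geometric mean one.

    The reference column is the one whose 75th percentile of
    library-scaled counts is closest to the mean across columns.
    """
    if pb.n_columns < 2:
        raise ValueError("need at least 2 pseudobulk columns")
    libs = pb.lib_sizes
    if np.any(libs == 0):
        bad = int(np.flatnonzero(libs == 0)[0])
        raise ValueError(f"pseudobulk column {bad} has zero total count")
    scaled = pb.counts / libs[None, :]
    uq = np.quantile(scaled, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair(pb.counts[:, j], pb.counts[:, ref], libs[j], libs[ref])
            for j in range(pb.n_columns)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    pb.norm_factors_ = factors
    return factors


def estimate_dispersion(
    pb: PseudobulkMatrix, design: pd.DataFrame, prior_weight: float = 10.0
) -> glm.DispersionEstimate:
    """Common + tagwise dispersions on the pseudobulk with offsets."""
    offset = _offsets(pb)
    return glm.estimate_dispersion(
        pb.counts, design.to_numpy(dtype=float), offset, prior_weight=prior_weight
    )


def _offsets(pb: PseudobulkMatrix) -> np.ndarray:
    factors = (
        pb.norm_factors_ if pb.norm_factors_ is not None else np.ones(pb.n_columns)
    )
    return np.log(pb.lib_sizes * factors)


def build_design(
    columns: pd.DataFrame, control_guide: str
) -> pd.DataFrame:
    """Design matrix with guide and sample covariates.

    The control guide and the first sample tag are the reference
    levels, so each ``guide_<id>`` coefficient is that perturbation's
    log-scale effect relative to control and is the coefficient the LRT
    drops.
    """
    guides = [g for g in pd.unique(columns["guide"]) if g != control_guide]
    if control_guide not in set(columns["guide"]):
        raise ValueError(f"control guide {control_guide!r} absent from pseudobulk")
    samples = list(pd.unique(columns["sample"]))[1:]
    design = pd.DataFrame({"intercept": np.ones(len(columns))})
    for g in guides:
        design[f"guide_{g}"] = (columns["guide"] == g).astype(float).to_numpy()
    for s in samples:
        design[f"sample_{s}"] = (columns["sample"] == s).astype(float).to_numpy()
    return design


def nb_glm_lrt(
    pb: PseudobulkMatrix,
    design: pd.DataFrame,
    coef: str,
    dispersion,
) -> pd.DataFrame:
    """Likelihood-ratio test dropping one design coefficient.

    Returns one row per feature: log2 fold change, LR statistic,
    chi-square (df=1) p-value and BH-adjusted p.  Features with zero
    counts in every column entering the contrast get logFC 0 and p 1
    with a ``separation`` flag; when either group is entirely zero the
    reported (never tested) logFC uses a +0.125 pseudocount on group
    sums to stay finite.
    """
    if coef not in design.columns:
        raise ValueError(f"unknown design coefficient {coef!r}")
    X_full = design.to_numpy(dtype=float)
    X_red = design.drop(columns=[coef]).to_numpy(dtype=float)
    offset = _offsets(pb)
    phi = np.broadcast_to(
        np.asarray(dispersion, dtype=float), (pb.counts.shape[0],)
    )
    full = glm.fit_nb_glm(pb.counts, X_full, offset, phi)
    red = glm.fit_nb_glm(pb.counts, X_red, offset, phi)
    lr = np.maximum(2.0 * (full.loglik - red.loglik), 0.0)
    p = sp_stats.chi2.sf(lr, df=1)
    coef_idx = list(design.columns).index(coef)
    logfc = full.beta[:, coef_idx] / _LN2

    pert_cols = design[coef].to_numpy(dtype=float) > 0
    ctrl_cols = ~pert_cols
    y_pert = pb.counts[:, pert_cols].sum(axis=1)
    y_ctrl = pb.counts[:, ctrl_cols].sum(axis=1)
    all_zero = (y_pert == 0) & (y_ctrl == 0)
    lr[all_zero] = 0.0
    p[all_zero] = 1.0
    logfc[all_zero] = 0.0
    zero_group = ((y_pert == 0) | (y_ctrl == 0)) & ~all_zero
    if zero_group.any():
        lib_p = pb.lib_sizes[pert_cols].sum()
        lib_c = pb.lib_sizes[ctrl_cols].sum()
        shrunk = np.log2(
            ((y_pert[zero_group] + 0.125) / lib_p)
            / ((y_ctrl[zero_group] + 0.125) / lib_c)
        )
        logfc[zero_group] = shrunk
    flags = np.where(all_zero, "separation", "")
    return pd.DataFrame(
        {
            "feature": pb.feature_ids,
            "logFC": logfc,
            "LR": lr,
            "p": p,
            "padj": bh_adjust(p),
            "flag": flags,
        }
    )


def run_screen(
    counts_rna: CellByFeatureCounts,
    counts_atac: Optional[CellByFeatureCounts],
    meta: pd.DataFrame,
    assignments: AssignmentTable,
    library: GuideLibrary,
    control: str,
    alpha: float = 0.05,
    min_cells_per_group: int = 1,
    dar_prefilter: bool = False,
) -> tuple[dict[tuple[str, str, str], pd.DataFrame], pd.DataFrame]:
    """Full DEG/DAR screen over every (cell type, perturbation) pair.

    Every assigned guide other than the control is contrasted against
    the control within each cell type (control-vs-control contrasts
    therefore come out of the same machinery when control-class guides
    are present).  RNA applies the UMI prefilter; ATAC drops only
    all-zero rows unless ``dar_prefilter`` is set.  Returns the per
    contrast tables keyed by (cell_type, perturbation, modality) and a
    summary grid of significant-feature counts at ``padj < alpha``.
    """
    tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    summary_rows = []
    modalities = [("rna", counts_rna)]
    if counts_atac is not None:
        modalities.append(("atac", counts_atac))
    for cell_type in sorted(pd.unique(meta["cell_type"])):
        for modality, counts in modalities:
            pb = make_pseudobulk(counts, meta, assignments, cell_type)
            keep_cols = pb.columns["n_cells"] >= min_cells_per_group
            if not keep_cols.all():
                pb = PseudobulkMatrix(
                    pb.counts[:, keep_cols.to_numpy()],
                    pb.feature_ids,
                    pb.columns[keep_cols].reset_index(drop=True),
                    pb.modality,
                    pb.cell_type,
                )
            if control not in set(pb.columns["guide"]):
                warnings.warn(
                    f"cell type {cell_type!r}: control {control!r} absent; skipped"
                )
                continue
            if modality == "rna" or dar_prefilter:
                keep = prefilter_genes(pb)
            else:
                keep = pb.counts.sum(axis=1) > 0
            pb = pb.subset_features(keep)
            if pb.counts.shape[0] == 0 or pb.n_columns < 3:
                continue
            norm_factors(pb)
            design = build_design(pb.columns, control)
            if design.shape[1] >= pb.n_columns:
                warnings.warn(
                    f"cell type {cell_type!r} ({modality}): design saturated; skipped"
                )
                continue
            disp = estimate_dispersion(pb, design)
            for g in pd.unique(pb.columns["guide"]):
                if g == control:
                    continue
                table = nb_glm_lrt(pb, design, f"guide_{g}", disp.tagwise)
                tables[(cell_type, g, modality)] = table
                n_cells = int(
                    pb.columns.loc[pb.columns["guide"] == g, "n_cells"].sum()
                )
                summary_rows.append(
                    {
                        "cell_type": cell_type,
                        "perturbation": g,
                        "modality": modality,
                        "n_cells": n_cells,
                        "n_features_tested": len(table),
                        "n_significant": int((table["padj"] < alpha).sum()),
                    }
                )
    return tables, pd.DataFrame(summary_rows)


def concordance(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Cross-cell-type effect concordance between two contrasts.

    Pearson correlation of log2 fold changes over features significant
    (``padj < alpha``) in either table, plus the shared significant set
    and the per-feature pairs for plotting.
    """
    merged = table_a.merge(
        table_b, on="feature", suffixes=("_a", "_b"), how="inner"
    )
    if merged.empty:
        raise ValueError("no overlapping features between tables")
    sig = (merged["padj_a"] < alpha) | (merged["padj_b"] < alpha)
    sub = merged[sig]
    if len(sub) < 2:
        raise ValueError("fewer than 2 features in the union-of-significant set")
    r = float(np.corrcoef(sub["logFC_a"], sub["logFC_b"])[0, 1])
    shared = set(
        merged.loc[(merged["padj_a"] < alpha) & (merged["padj_b"] < alpha), "feature"]
    )
    return {
        "r": r,
        "n_union": int(sig.sum()),
        "shared_significant": shared,
        "pairs": sub[["feature", "logFC_a", "logFC_b", "padj_a", "padj_b"]],
    }
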