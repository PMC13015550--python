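"""Guide-to-nucleus assignment from the cell-by-guide UMI matrix.

Each guide's UMI counts across cells are modelled with a two-component
Gaussian mixture on log2-transformed positive counts: the low-mean
component captures ambient background (free-floating cassette
transcripts caught in the wrong nucleus), the high-mean component true
guide capture.  A cell receives a guide when its UMI count clears a hard
minimum (default 3) and its posterior probability under the signal
component clears a cutoff.  Cells end up with exactly one guide
(``single``), several (``Doublet``), or none (``Not assigned``).

Guides with too few positive cells for an identifiable mixture fall
back to threshold-only assignment and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .stats import bh_adjust, log_normalize
from .types import CellByFeatureCounts, GuideLibrary

__all__ = [
    "MixtureFit",
    "AssignmentTable",
    "fit_guide_mixture",
    "assign_guides",
    "assignment_metrics",
    "cross_guide_correlation",
    "knockdown_check",
    "LABEL_SINGLE",
    "LABEL_DOUBLET",
    "LABEL_NOT_ASSIGNED",
]

LABEL_SINGLE = "single"
LABEL_DOUBLET = "Doublet"
LABEL_NOT_ASSIGNED = "Not assigned"

_MIN_POSITIVE_CELLS = 10


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fitted on log2 positive counts."""

    guide_id: str
    means: tuple[float, float]  # (background, signal), ascending
    variances: tuple[float, float]
    weights: tuple[float, float]
    converged: bool
    n_cells_used: int
    fallback: bool = False

    def signal_posterior(self, counts: np.ndarray) -> np.ndarray:
        """Posterior of the higher-mean component at log2(count).

        In fallback mode every positive count gets posterior 1 (the
        min-UMI threshold alone decides).
        """
        counts = np.asarray(counts, dtype=float)
        post = np.zeros_like(counts)
        pos = counts > 0
        if self.fallback:
            post[pos] = 1.0
            return post
        x = np.log2(counts[pos])
        log_dens = np.stack(
            [
                np.log(w) + sp_stats.norm.logpdf(x, m, np.sqrt(v))
                for w, m, v in zip(self.weights, self.means, self.variances)
            ]
        )
        log_dens -= log_dens.max(axis=0, keepdims=True)
        dens = np.exp(log_dens)
        post[pos] = dens[1] / dens.sum(axis=0)
        return post


def fit_guide_mixture(
    counts: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureFit:
    """Fit the per-guide mixture on log2 of positive counts.

    Cells with zero count are excluded from fitting (they can only be
    non-assignments).  With fewer than 10 positive cells, or when the
    fit degenerates (zero spread, coincident components), the guide
    falls back to threshold-only mode.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need counts for at least 2 cells")
    positives = counts[counts > 0]
    n_pos = positives.size
    if n_pos < _MIN_POSITIVE_CELLS or np.ptp(positives) == 0:
        return MixtureFit(
            guide_id="",
            means=(0.0, 0.0),
            variances=(1.0, 1.0),
            weights=(0.5, 0.5),
            converged=False,
            n_cells_used=n_pos,
            fallback=True,
        )
    x = np.log2(positives).reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gmm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            tol=tol,
            max_iter=max_iter,
            n_init=1,
            init_params="k-means++",
            random_state=seed,
        ).fit(x)
    means = gmm.means_.ravel()
    variances = gmm.covariances_.ravel()
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    if not np.isfinite(variances).all() or np.isclose(means[0], means[1]):
        return MixtureFit(
            guide_id="",
            means=(float(means[0]), float(means[1])),
            variances=(1.0, 1.0),
            weights=(0.5, 0.5),
            converged=False,
            n_cells_used=n_pos,
            fallback=True,
        )
    return MixtureFit(
        guide_id="",
        means=(float(means[0]), float(means[1])),
        variances=(float(variances[0]), float(variances[1])),
        weights=(float(weights[0]), float(weights[1])),
        converged=bool(gmm.converged_),
        n_cells_used=n_pos,
    )


class AssignmentTable:
    """Per-cell guide calls with single/Doublet/Not-assigned labels."""

    def __init__(
        self,
        cell_barcodes: list[str],
        assignments: list[list[str]],
        posteriors: list[list[float]],
        umis: list[list[int]],
        min_umi: int,
    ) -> None:
        labels = []
        for guides in assignments:
            if len(guides) == 0:
                labels.append(LABEL_NOT_ASSIGNED)
            elif len(guides) == 1:
                labels.append(LABEL_SINGLE)
            else:
                labels.append(LABEL_DOUBLET)
        self.cell_barcodes = cell_barcodes
        self.assignments = assignments
        self.posteriors = posteriors
        self.umis = umis
        self.labels = labels
        self.min_umi = min_umi

    def __len__(self) -> int:
        return len(self.cell_barcodes)

    def label_counts(self) -> dict[str, int]:
        out = {LABEL_SINGLE: 0, LABEL_DOUBLET: 0, LABEL_NOT_ASSIGNED: 0}
        for lab in self.labels:
            out[lab] += 1
        return out

    def per_cell_groups(self) -> dict[str, str]:
        """Barcode -> assignment group (guide id for singles)."""
        out = {}
        for bc, guides, lab in zip(self.cell_barcodes, self.assignments, self.labels):
            out[bc] = guides[0] if lab == LABEL_SINGLE else lab
        return out

    def single_cells(self) -> dict[str, str]:
        """Barcode -> guide id, singles only."""
        return {
            bc: guides[0]
            for bc, guides, lab in zip(
                self.cell_barcodes, self.assignments, self.labels
            )
            if lab == LABEL_SINGLE
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_barcode": self.cell_barcodes,
                "guides": [";".join(g) for g in self.assignments],
                "label": self.labels,
                "posteriors": [
                    ";".join(f"{p:.6g}" for p in ps) for ps in self.posteriors
                ],
                "umis": [";".join(str(u) for u in us) for us in self.umis],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_umi: int = 3) -> "AssignmentTable":
        def cells(col):
            # columns round-trip through TSV: single-entry rows may come
            # back as numerics, empty rows as NaN
            out = []
            for v in df[col]:
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    out.append([])
                else:
                    s = str(v)
                    out.append(s.split(";") if s else [])
            return out

        assignments = cells("guides")
        posteriors = [[float(x) for x in row] for row in cells("posteriors")]
        umis = [[int(float(x)) for x in row] for row in cells("umis")]
        return cls(list(df["cell_barcode"]), assignments, posteriors, umis, min_umi)


def assign_guides(
    guide_counts: CellByFeatureCounts,
    min_umi: int = 3,
    posterior_cut: float = 0.5,
    seed: int = 0,
) -> tuple[AssignmentTable, dict[str, MixtureFit]]:
    """Assign guides to every cell of a guide-modality count matrix.

    A cell gets guide ``g`` iff its UMI count for ``g`` is at least
    ``min_umi`` and the signal-component posterior is at least
    ``posterior_cut``.  Returns the assignment table plus the per-guide
    mixture fits.
    """
    if guide_counts.modality != "guide":
        raise ValueError("assign_guides requires a guide-modality matrix")
    dense = guide_counts.to_dense()
    fits: dict[str, MixtureFit] = {}
    assigned_mask = np.zeros(dense.shape, dtype=bool)
    posterior_mat = np.zeros(dense.shape, dtype=float)
    for j, gid in enumerate(guide_counts.feature_ids):
        col = dense[:, j]
        fit = fit_guide_mixture(col, seed=seed)
        fit.guide_id = gid
        fits[gid] = fit
        post = fit.signal_posterior(col)
        posterior_mat[:, j] = post
        assigned_mask[:, j] = (col >= min_umi) & (post >= posterior_cut)
    assignments, posteriors, umis = [], [], []
    for i in range(dense.shape[0]):
        idx = np.flatnonzero(assigned_mask[i])
        assignments.append([guide_counts.feature_ids[j] for j in idx])
        posteriors.append([float(posterior_mat[i, j]) for j in idx])
        umis.append([int(dense[i, j]) for j in idx])
    table = AssignmentTable(
        list(guide_counts.cell_barcodes), assignments, posteriors, umis, min_umi
    )
    return table, fits


def assignment_metrics(
    table: AssignmentTable,
    meta: Optional[pd.DataFrame] = None,
    group_by: Optional[str] = None,
) -> pd.DataFrame:
    """Assignment and single-assignment rates, overall and per group.

    ``assigned_pct`` counts singles plus doublets; ``single_pct``
    singles only.  With ``group_by`` (a metadata column such as the
    sample tag or cell type), one row per group is added; groups with no
    cells after matching barcodes are omitted with a warning.
    """
    if len(table) == 0:
        raise ValueError("empty assignment table")
    df = pd.DataFrame(
        {"cell_barcode": table.cell_barcodes, "label": table.labels}
    )
    rows = [_rate_row("all", df)]
    if group_by is not None:
        if meta is None:
            raise ValueError("group_by requires cell metadata")
        if group_by not in meta.columns:
            raise KeyError(f"unknown group key {group_by!r}")
        merged = df.merge(
            meta[[group_by]].reset_index(names="cell_barcode"),
            on="cell_barcode",
            how="left",
        )
        for group, sub in merged.groupby(group_by, dropna=True, sort=True):
            if len(sub) == 0:
                warnings.warn(f"group {group!r} empty after filtering; omitted")
                continue
            rows.append(_rate_row(str(group), sub))
    return pd.DataFrame(rows)


def _rate_row(name: str, df: pd.DataFrame) -> dict:
    n = len(df)
    n_single = int((df["label"] == LABEL_SINGLE).sum())
    n_doublet = int((df["label"] == LABEL_DOUBLET).sum())
    n_none = n - n_single - n_doublet
    return {
        "group": name,
        "n_cells": n,
        "n_single": n_single,
        "n_doublet": n_doublet,
        "n_not_assigned": n_none,
        "assigned_pct": 100.0 * (n_single + n_doublet) / n,
        "single_pct": 100.0 * n_single / n,
    }


def cross_guide_correlation(guide_counts: CellByFeatureCounts) -> pd.DataFrame:
    """Pearson correlation between guide UMI profiles across cells.

    Symmetric with unit diagonal; zero-variance guides yield NaN rows
    and columns (flagged by the NaN itself).  Low off-diagonal values
    indicate specific capture under low-MOI delivery.
    """
    if guide_counts.n_features < 2:
        raise ValueError("need at least 2 guides")
    if guide_counts.n_cells < 3:
        raise ValueError("need at least 3 cells")
    dense = guide_counts.to_dense().astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(dense, rowvar=False)
    # unit diagonal even for zero-variance guides, matching convention
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(
        corr, index=guide_counts.feature_ids, columns=guide_counts.feature_ids
    )


def knockdown_check(
    expr_counts: CellByFeatureCounts,
    table: AssignmentTable,
    library: GuideLibrary,
    control_class: str = "safe_target",
) -> pd.DataFrame:
    """On-target knockdown sanity check per targeting guide.

    Compares mean log-normalized expression of each guide's target gene
    in cells singly assigned to that guide against cells singly assigned
    to control guides of ``control_class``, with a two-sided rank-sum
    test and BH correction across targets.  Targets whose gene is absent
    from the expression matrix are kept as flagged rows.

    Assignment labels may be either guide ids (per-guide capture) or
    pair ids (cassette-level capture); both are matched.
    """
    singles = table.single_cells()
    control_ids = {
        g.guide_id for g in library.guides if g.control_class == control_class
    } | {g.pair_id for g in library.guides if g.control_class == control_class}
    control_cells = [bc for bc, gid in singles.items() if gid in control_ids]
    if not control_cells:
        raise ValueError(f"no cells singly assigned to {control_class} controls")
    in_matrix = set(expr_counts.cell_barcodes)
    control_cells = [bc for bc in control_cells if bc in in_matrix]
    totals = expr_counts.cell_totals()
    nonzero = {
        expr_counts.cell_barcodes[i] for i in np.flatnonzero(totals > 0)
    }
    control_cells = [bc for bc in control_cells if bc in nonzero]
    # zero-total cells cannot be normalized and are excluded up front
    ordered = [bc for bc in expr_counts.cell_barcodes if bc in nonzero]
    lognorm = log_normalize(expr_counts.subset_cells(ordered))
    norm_index = {bc: i for i, bc in enumerate(ordered)}

    rows = []
    for guide in library.targeting_guides():
        gene = guide.target_gene
        target_cells = [
            bc
            for bc, gid in singles.items()
            if gid in (guide.guide_id, guide.pair_id) and bc in norm_index
        ]
        if gene is None or gene not in expr_counts._ft_index:
            rows.append(
                {
                    "guide_id": guide.guide_id,
                    "target_gene": gene,
                    "n_target_cells": len(target_cells),
                    "n_control_cells": len(control_cells),
                    "mean_target": np.nan,
                    "mean_control": np.nan,
                    "difference": np.nan,
                    "p": np.nan,
                    "flag": "gene_missing",
                }
            )
            continue
        j = expr_counts.feature_index(gene)
        col = np.asarray(lognorm[:, j].todense()).ravel()
        tgt = col[[norm_index[bc] for bc in target_cells]]
        ctl = col[[norm_index[bc] for bc in control_cells]]
        if tgt.size == 0 or ctl.size == 0:
            p = np.nan
            flag = "no_cells"
        else:
            p = float(sp_stats.ranksums(tgt, ctl).pvalue)
            flag = ""
        rows.append(
            {
                "guide_id": guide.guide_id,
                "target_gene": gene,
                "n_target_cells": tgt.size,
                "n_control_cells": ctl.size,
                "mean_target": float(tgt.mean()) if tgt.size else np.nan,
                "mean_control": float(ctl.mean()) if ctl.size else np.nan,
                "difference": float(tgt.mean() - ctl.mean()) if tgt.size else np.nan,
                "p": p,
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["padj"] = np.nan
    if ok.any():
        out.loc[ok, "padj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
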