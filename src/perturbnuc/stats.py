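"""Shared numerics: library-size log-normalization and BH correction."""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .types import CellByFeatureCounts

__all__ = ["log_normalize", "bh_adjust"]


def log_normalize(
    counts: CellByFeatureCounts, scale: float = 1e4
) -> sparse.csr_matrix:
    """Log-normalize counts per cell: ``ln(1 + scale * c / total)``.

    With the default ``scale=1e4`` this is log1p of counts-per-10k
    (CP10K), the conventional single-cell normalization.  Zero entries
    stay exactly zero, so the sparse structure is preserved.

    Raises ``ValueError`` naming the first barcode whose total is zero.
    """
    totals = counts.cell_totals().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell {counts.cell_barcodes[zero[0]]!r} has zero total count; "
            "cannot normalize"
        )
    mat = counts.counts.tocsr().astype(float)
    # scale each row by scale/total, then log1p on stored entries only
    row_scale = scale / totals
    mat = sparse.diags(row_scale) @ mat
    mat.data = np.log1p(mat.data)
    return mat.tocsr()


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns ``min_{j >= rank(i)} m * p_(j) / j`` clipped to [0, 1]; the
    output is monotone in the input ranks and always >= the raw p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out
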