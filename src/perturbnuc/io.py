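"""Readers and writers for the on-disk formats used across the pipeline.

Formats: guide library TSV, MatrixMarket count bundles (``.mtx`` plus
barcode/feature TSVs), BED3+ target windows and peaks, FASTQ amplicons,
SAM text alignments with ``CB:Z`` cell-barcode tags, and gene coordinate
TSVs.  MatrixMarket files round-trip integer matrices losslessly.
"""

from __future__ import annotations

import io as _io
import os
import re
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam
from scipy import io as scipy_io
from scipy import sparse

from .types import CellByFeatureCounts, GenomicInterval, GuideLibrary, GuideRecord

__all__ = [
    "read_guide_library",
    "write_guide_library",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_bed_windows",
    "write_bed_windows",
    "read_gene_coords",
    "write_gene_coords",
    "read_sam_reads",
    "parse_cigar",
]

GUIDE_LIBRARY_COLUMNS = [
    "guide_id",
    "spacer",
    "pair_id",
    "position_in_cassette",
    "target_gene",
    "control_class",
    "target_chrom",
    "target_start",
    "target_end",
]


def read_guide_library(path: str | os.PathLike) -> GuideLibrary:
    """Read a guide library TSV into a validated :class:`GuideLibrary`.

    The table needs the documented header (see
    ``GUIDE_LIBRARY_COLUMNS``); target coordinates may be blank for
    control guides.  Pair completeness and spacer alphabet are enforced
    by the library constructor.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GUIDE_LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"guide library missing column(s): {missing}")
    guides = []
    for row in df.itertuples(index=False):
        window = None
        if row.target_chrom:
            start, end = int(row.target_start), int(row.target_end)
            if start < 0:
                raise ValueError(
                    f"guide {row.guide_id}: negative target coordinate"
                )
            window = GenomicInterval(row.target_chrom, start, end)
        guides.append(
            GuideRecord(
                guide_id=row.guide_id,
                spacer=row.spacer,
                pair_id=row.pair_id,
                position_in_cassette=row.position_in_cassette,
                target_gene=row.target_gene or None,
                control_class=row.control_class,
                target_window=window,
            )
        )
    return GuideLibrary(guides)


def write_guide_library(library: GuideLibrary, path: str | os.PathLike) -> None:
    rows = []
    for g in library.guides:
        rows.append(
            {
                "guide_id": g.guide_id,
                "spacer": g.spacer,
                "pair_id": g.pair_id,
                "position_in_cassette": g.position_in_cassette,
                "target_gene": g.target_gene or "",
                "control_class": g.control_class,
                "target_chrom": g.target_window.chrom if g.target_window else "",
                "target_start": g.target_window.start if g.target_window else "",
                "target_end": g.target_window.end if g.target_window else "",
            }
        )
    pd.DataFrame(rows, columns=GUIDE_LIBRARY_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_counts_mtx(
    matrix_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    features_path: str | os.PathLike,
    modality: str,
) -> CellByFeatureCounts:
    """Read a MatrixMarket bundle (cells x features) into counts.

    The ``.mtx`` stores cells as rows.  Barcode and feature files are
    one id per line; their lengths must match the matrix dimensions.
    """
    mat = scipy_io.mmread(os.fspath(matrix_path))
    barcodes = _read_lines(barcodes_path)
    features = _read_lines(features_path)
    mat = sparse.csr_matrix(mat)
    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"{len(barcodes)} barcodes for a matrix with {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(features):
        raise ValueError(
            f"{len(features)} features for a matrix with {mat.shape[1]} columns"
        )
    return CellByFeatureCounts(mat, barcodes, features, modality)  # type: ignore[arg-type]


def write_counts_mtx(
    counts: CellByFeatureCounts,
    matrix_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    features_path: str | os.PathLike,
) -> None:
    coo = counts.counts.tocoo()
    coo.data = coo.data.astype(np.int64)
    scipy_io.mmwrite(os.fspath(matrix_path), coo, field="integer")
    _write_lines(barcodes_path, counts.cell_barcodes)
    _write_lines(features_path, counts.feature_ids)


def _read_lines(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path: str | os.PathLike, lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"{line}\n")


def read_bed_windows(path: str | os.PathLike) -> dict[str, GenomicInterval]:
    """Read BED3+ intervals; column 4 (name) keys the result.

    Unnamed intervals are keyed by their ``chrom:start-end`` id.
    """
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            name = fields[3] if len(fields) > 3 and fields[3] else iv.to_peak_id()
            if name in out:
                raise ValueError(f"{path}:{ln}: duplicate interval name {name!r}")
            out[name] = iv
    return out


def write_bed_windows(
    windows: dict[str, GenomicInterval], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for name, iv in windows.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_gene_coords(path: str | os.PathLike) -> pd.DataFrame:
    """Gene coordinate TSV: gene_id, chrom, start, end, strand.

    Start/end are 0-based half-open; the TSS is ``start`` on ``+`` and
    ``end - 1`` on ``-`` strand.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene coordinate table missing column(s): {missing}")
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(
            f"gene(s) with start >= end: {df.loc[bad, 'gene_id'].tolist()}"
        )
    return df.set_index("gene_id", drop=False)


def write_gene_coords(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- SAM -------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# pysam numeric op codes -> CIGAR characters
_PYSAM_OPS = "MIDNSHP=XB"


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into ``(op, length)`` tuples."""
    if cigar == "*" or not cigar:
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    if any(n <= 0 for _, n in ops):
        raise ValueError(f"non-positive CIGAR length in {cigar!r}")
    return ops


def read_sam_reads(path: str | os.PathLike):
    """Iterate alignments from a text SAM file as :class:`AlignedRead`.

    Files with a header go through pysam; headerless files (the text
    dialect allows omitting it) fall back to a plain column parser.
    Unmapped reads and reads without a ``CB:Z`` tag are skipped.
    Positions are converted to 0-based.
    """
    from .indel import AlignedRead  # local import avoids a cycle

    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = first.startswith("@")
    reads: list[AlignedRead] = []
    if has_header:
        with pysam.AlignmentFile(path, "r") as sam:
            for aln in sam:
                if aln.is_unmapped or aln.reference_id < 0:
                    continue
                try:
                    barcode = aln.get_tag("CB")
                except KeyError:
                    continue
                cigar = [
                    (_PYSAM_OPS[op], length) for op, length in aln.cigartuples or []
                ]
                reads.append(
                    AlignedRead(
                        read_id=aln.query_name,
                        ref_name=aln.reference_name,
                        pos=aln.reference_start,
                        cigar=cigar,
                        cell_barcode=str(barcode),
                    )
                )
        return reads
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{ln}: fewer than 11 SAM columns")
            flag = int(fields[1])
            if flag & 0x4 or fields[2] == "*":
                continue
            barcode = None
            for tag in fields[11:]:
                if tag.startswith("CB:Z:"):
                    barcode = tag[5:]
                    break
            if barcode is None:
                continue
            reads.append(
                AlignedRead(
                    read_id=fields[0],
                    ref_name=fields[2],
                    pos=int(fields[3]) - 1,
                    cigar=parse_cigar(fields[5]),
                    cell_barcode=barcode,
                )
            )
    return reads
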