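"""Synthetic single-nucleus multiome Perturb-seq experiments.

Generates a complete experiment with ground truth so every downstream
stage is testable without sequencing data: a dual-guide library with
designed pairs and NT/ST controls, low-MOI cassette integration per
nucleus, guide UMI counts as ambient Poisson background plus
negative-binomial signal, gene and peak counts with cell-type baselines
shifted by a perturbation effect table, per-cell QC metadata,
error-bearing long amplicon reads of the cassette (including chimeras),
and barcode-tagged alignments carrying indels at target windows for
edited cells.

Guide capture model
-------------------
The cassette expresses one polyadenylated transcript per vector, so the
default capture mode (``cassette``) emits one count feature per
designed pair -- a nucleus with a single integrated vector then shows a
single-feature signal, matching how assignment labels are interpreted.
``per_guide`` mode instead gives both guides of an integrated pair
independent signal counts (two features per vector), useful for
stressing the assignment logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import sparse

from .amplicon import CassetteLayout, reverse_complement
from .indel import AlignedRead
from .io import (
    write_bed_windows,
    write_counts_mtx,
    write_gene_coords,
    write_guide_library,
)
from .types import CellByFeatureCounts, GenomicInterval, GuideLibrary, GuideRecord

__all__ = ["SimConfig", "SimTruth", "SimExperiment", "simulate_experiment", "make_fixture"]

_BASES = np.array(list("ACGT"))
_CHROM = "chr_sim"
_ANCHOR5 = "TTGTGGAAAGGACGAAACAC"  # invariant cassette flank upstream of g1
_LINKER = "GTTTAAGAGCTATGCTGGAA"  # scaffold stub between the two spacers
_ANCHOR3 = "ACTCGGTGCCACTTTTTCAA"  # invariant flank downstream of g2

CASSETTE_LAYOUT = CassetteLayout(
    g1_offset=len(_ANCHOR5), g2_offset=len(_ANCHOR5) + 20 + len(_LINKER)
)


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment.

    Defaults emulate the stated study conditions: low-MOI AAV delivery
    (about one integrated vector per nucleus, truncated at 3), ambient
    guide background far below true-capture signal, five biological
    replicates, and majority-edited assigned nuclei.
    """

    n_cells: int = 2000
    n_cell_types: int = 3
    n_targeting_pairs: int = 8
    n_nt_pairs: int = 2
    n_st_pairs: int = 2
    guide_capture: str = "cassette"  # or "per_guide"
    moi_mean: float = 1.0
    moi_max: int = 3
    fixed_pairs_per_cell: Optional[int] = None
    signal_count_mean: float = 40.0
    signal_dispersion: float = 0.3
    ambient_rate: float = 0.05
    n_genes: int = 150
    n_peaks: int = 150
    gene_mean_range: tuple[float, float] = (0.5, 20.0)
    peak_mean_range: tuple[float, float] = (0.2, 5.0)
    gene_dispersion: float = 0.15
    peak_dispersion: float = 0.2
    effect_table: Optional[pd.DataFrame] = None  # None -> default effects
    n_effect_genes_per_pair: int = 10
    n_effect_peaks_per_pair: int = 5
    coupled_links: list[tuple[str, str, float]] = field(default_factory=list)
    edit_rate: float = 0.8
    deletion_length: int = 4
    reads_per_cell_window: int = 2
    n_amplicon_reads: int = 5000
    amplicon_error_rate: float = 0.02
    chimera_fraction: float = 0.05
    n_samples: int = 5
    qc_fail_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moi_mean < 0 or self.ambient_rate < 0 or self.edit_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.signal_dispersion <= 0:
            raise ValueError("signal_dispersion must be positive")
        for p in (self.edit_rate, self.chimera_fraction, self.qc_fail_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.guide_capture not in ("cassette", "per_guide"):
            raise ValueError(f"unknown guide_capture {self.guide_capture!r}")


@dataclass
class SimTruth:
    """Ground truth emitted next to the synthetic data."""

    cells: pd.DataFrame  # barcode, cell_type, sample_tag, pairs, edited
    effects: pd.DataFrame  # pair_id, cell_type, modality, feature_id, log2fc
    amplicons: pd.DataFrame  # read_id, kind, g1_pair, g2_pair

    def pair_sets(self) -> dict[str, set[str]]:
        return {
            row.cell_barcode: set(row.pairs.split(";")) if row.pairs else set()
            for row in self.cells.itertuples()
        }


@dataclass
class SimExperiment:
    config: SimConfig
    library: GuideLibrary
    guide_counts: CellByFeatureCounts
    gene_counts: CellByFeatureCounts
    peak_counts: CellByFeatureCounts
    cell_meta: pd.DataFrame
    amplicon_reads: list[tuple[str, str]]
    sam_reads: list[AlignedRead]
    target_windows: dict[str, GenomicInterval]
    gene_coords: pd.DataFrame
    truth: SimTruth

    def write(self, outdir) -> None:
        """Write every artifact in its documented on-disk format."""
        import os

        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        write_guide_library(self.library, f"{outdir}/guide_library.tsv")
        for name, counts in (
            ("guide", self.guide_counts),
            ("gene", self.gene_counts),
            ("peak", self.peak_counts),
        ):
            write_counts_mtx(
                counts,
                f"{outdir}/{name}_counts.mtx",
                f"{outdir}/{name}_barcodes.tsv",
                f"{outdir}/{name}_features.tsv",
            )
        self.cell_meta.to_csv(f"{outdir}/cell_meta.tsv", sep="\t")
        write_bed_windows(self.target_windows, f"{outdir}/target_windows.bed")
        write_gene_coords(self.gene_coords, f"{outdir}/gene_coords.tsv")
        records = [
            SeqRecord(
                Seq(seq),
                id=read_id,
                description="",
                letter_annotations={"phred_quality": [40] * len(seq)},
            )
            for read_id, seq in self.amplicon_reads
        ]
        with open(f"{outdir}/amplicons.fastq", "w") as fh:
            SeqIO.write(records, fh, "fastq")
        self._write_sam(f"{outdir}/reads.sam")
        self.truth.cells.to_csv(f"{outdir}/truth_cells.tsv", sep="\t", index=False)
        self.truth.effects.to_csv(
            f"{outdir}/truth_effects.tsv", sep="\t", index=False
        )
        self.truth.amplicons.to_csv(
            f"{outdir}/truth_amplicons.tsv", sep="\t", index=False
        )

    def _write_sam(self, path) -> None:
        ref_len = max(
            (w.end for w in self.target_windows.values()), default=1000
        ) + 1000
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unknown"},
                "SQ": [{"SN": _CHROM, "LN": int(ref_len)}],
            }
        )
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for read in self.sam_reads:
                a = pysam.AlignedSegment(header)
                a.query_name = read.read_id
                a.flag = 0
                a.reference_id = 0
                a.reference_start = read.pos
                a.mapping_quality = 60
                a.cigarstring = "".join(f"{n}{op}" for op, n in read.cigar)
                a.set_tag("CB", read.cell_barcode, "Z")
                out.write(a)


def _random_spacers(rng: np.random.Generator, n: int, min_dist: int = 9) -> list[str]:
    """Distinct 20-nt spacers with pairwise edit distance >= min_dist."""
    import edlib

    spacers: list[str] = []
    while len(spacers) < n:
        cand = "".join(rng.choice(_BASES, size=20))
        if all(
            edlib.align(cand, s, task="distance")["editDistance"] >= min_dist
            for s in spacers
        ):
            spacers.append(cand)
    return spacers


def _build_library(config: SimConfig, rng: np.random.Generator) -> tuple[
    GuideLibrary, dict[str, GenomicInterval], list[str]
]:
    n_pairs = config.n_targeting_pairs + config.n_nt_pairs + config.n_st_pairs
    spacers = _random_spacers(rng, 2 * n_pairs)
    guides = []
    windows: dict[str, GenomicInterval] = {}
    gene_ids = [f"gene{i:03d}" for i in range(config.n_genes)]
    classes = (
        ["targeting"] * config.n_targeting_pairs
        + ["non_target"] * config.n_nt_pairs
        + ["safe_target"] * config.n_st_pairs
    )
    for i, cls in enumerate(classes):
        if cls == "targeting":
            pid = f"T{i}"
            target_gene = gene_ids[i % config.n_genes]
        else:
            prefix = "NT" if cls == "non_target" else "ST"
            pid = f"{prefix}{i}"
            target_gene = None
        base = 1000 * i + 500
        for k, slot in enumerate(("g1", "g2")):
            gid = f"{pid}-{slot}"
            window = None
            if cls == "targeting":
                # the two cut sites of a pair sit >100 bp apart
                start = base + 200 * k
                window = GenomicInterval(_CHROM, start, start + 30)
                windows[gid] = window
            guides.append(
                GuideRecord(
                    guide_id=gid,
                    spacer=spacers[2 * i + k],
                    pair_id=pid,
                    position_in_cassette=slot,
                    target_gene=target_gene,
                    control_class=cls,
                    target_window=window,
                )
            )
    return GuideLibrary(guides), windows, gene_ids


def default_effect_table(
    library: GuideLibrary,
    cell_types: list[str],
    gene_ids: list[str],
    peak_ids: list[str],
    rng: np.random.Generator,
    n_genes_per_pair: int = 10,
    n_peaks_per_pair: int = 5,
) -> pd.DataFrame:
    """Cell-type-restricted perturbation effects plus on-target knockdown.

    Each targeting pair perturbs a random gene/peak set in one cell
    type (|log2FC| in 1-2, random sign) and halves its own target gene
    in every cell type, so knockdown checks have signal everywhere.
    """
    rows = []
    targeting_pairs = sorted(
        {g.pair_id for g in library.targeting_guides()}
    )
    for i, pid in enumerate(targeting_pairs):
        ct = cell_types[i % len(cell_types)]
        genes = rng.choice(gene_ids, size=min(n_genes_per_pair, len(gene_ids)), replace=False)
        for gene in genes:
            lfc = float(rng.uniform(1.0, 2.0) * rng.choice([-1, 1]))
            rows.append((pid, ct, "gene", gene, lfc))
        peaks = rng.choice(peak_ids, size=min(n_peaks_per_pair, len(peak_ids)), replace=False)
        for peak in peaks:
            lfc = float(rng.uniform(1.0, 2.0) * rng.choice([-1, 1]))
            rows.append((pid, ct, "peak", peak, lfc))
        g1, _ = library.pair(pid)
        if g1.target_gene is not None:
            for ct_all in cell_types:
                rows.append((pid, ct_all, "gene", g1.target_gene, -1.0))
    return pd.DataFrame(
        rows, columns=["pair_id", "cell_type", "modality", "feature_id", "log2fc"]
    )


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    """Per-base substitutions plus occasional 1-bp indels."""
    if error_rate <= 0:
        return seq
    out = []
    for ch in seq:
        u = rng.random()
        if u < error_rate * 0.7:
            out.append(str(rng.choice(_BASES)))
        elif u < error_rate * 0.85:
            out.append(ch + str(rng.choice(_BASES)))  # insertion after base
        elif u < error_rate:
            continue  # deletion
        else:
            out.append(ch)
    return "".join(out)


def simulate_experiment(config: SimConfig) -> SimExperiment:
    """Run the full generator; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    library, windows, gene_ids = _build_library(config, rng)
    cell_types = [f"CT{i}" for i in range(config.n_cell_types)]
    sample_tags = [f"S{i}" for i in range(config.n_samples)]
    barcodes = [f"BC{i:05d}" for i in range(config.n_cells)]
    pair_ids = library.pair_ids

    # peaks tiled along a dedicated chromosome shared with gene bodies
    peak_ids = []
    peaks: dict[str, GenomicInterval] = {}
    for j in range(config.n_peaks):
        iv = GenomicInterval("chr_reg", 5000 * j + 100, 5000 * j + 500)
        peak_ids.append(iv.to_peak_id())
        peaks[iv.to_peak_id()] = iv
    gene_coords = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chr_reg",
            "start": [10_000 * i for i in range(config.n_genes)],
            "end": [10_000 * i + 2_000 for i in range(config.n_genes)],
            "strand": ["+"] * config.n_genes,
        }
    ).set_index("gene_id", drop=False)

    effects = config.effect_table
    if effects is None:
        effects = default_effect_table(
            library,
            cell_types,
            gene_ids,
            peak_ids,
            rng,
            config.n_effect_genes_per_pair,
            config.n_effect_peaks_per_pair,
        )
    _validate_effects(effects, pair_ids, cell_types, gene_ids, peak_ids)

    # --- per-cell truth ----------------------------------------------------
    ct_of = rng.choice(cell_types, size=config.n_cells)
    tag_of = rng.choice(sample_tags, size=config.n_cells)
    pair_sets: list[list[str]] = []
    for _ in range(config.n_cells):
        if config.fixed_pairs_per_cell is not None:
            k = config.fixed_pairs_per_cell
        else:
            k = min(int(rng.poisson(config.moi_mean)), config.moi_max)
        k = min(k, len(pair_ids))
        chosen = sorted(rng.choice(pair_ids, size=k, replace=False)) if k else []
        pair_sets.append(list(chosen))
    targeting = {g.pair_id for g in library.targeting_guides()}
    edited = np.array(
        [
            bool(set(ps) & targeting) and rng.random() < config.edit_rate
            for ps in pair_sets
        ]
    )

    # --- guide counts ------------------------------------------------------
    if config.guide_capture == "cassette":
        guide_features = pair_ids
        present = [set(ps) for ps in pair_sets]
    else:
        guide_features = library.guide_ids
        present = [
            {gid for pid in ps for gid in (f"{pid}-g1", f"{pid}-g2")}
            for ps in pair_sets
        ]
    gmat = rng.poisson(
        config.ambient_rate, size=(config.n_cells, len(guide_features))
    ).astype(np.int64)
    feat_index = {f: j for j, f in enumerate(guide_features)}
    for i, feats in enumerate(present):
        for f in feats:
            gmat[i, feat_index[f]] += int(
                _nb_draw(rng, config.signal_count_mean, config.signal_dispersion)
            )
    guide_counts = CellByFeatureCounts(
        sparse.csr_matrix(gmat), barcodes, guide_features, "guide"
    )

    # --- gene / peak counts ------------------------------------------------
    gene_counts_mat = _expression_matrix(
        rng,
        config,
        gene_ids,
        cell_types,
        ct_of,
        pair_sets,
        effects,
        "gene",
        config.gene_mean_range,
        config.gene_dispersion,
    )
    peak_base_mu = _baseline_means(
        rng, config.n_peaks, len(cell_types), config.peak_mean_range
    )
    peak_counts_mat = _shifted_counts(
        rng,
        peak_base_mu,
        peak_ids,
        cell_types,
        ct_of,
        pair_sets,
        effects,
        "peak",
        config.peak_dispersion,
        coupled=config.coupled_links,
        gene_counts=gene_counts_mat,
        gene_ids=gene_ids,
    )
    gene_counts = CellByFeatureCounts(
        sparse.csr_matrix(gene_counts_mat), barcodes, gene_ids, "gene"
    )
    peak_counts = CellByFeatureCounts(
        sparse.csr_matrix(peak_counts_mat), barcodes, peak_ids, "peak"
    )

    cell_meta = _make_meta(rng, config, barcodes, ct_of, tag_of)

    amplicon_reads, amplicon_truth = _make_amplicons(rng, config, library)
    sam_reads = _make_alignments(
        rng, config, barcodes, pair_sets, edited, windows, library
    )

    truth = SimTruth(
        cells=pd.DataFrame(
            {
                "cell_barcode": barcodes,
                "cell_type": ct_of,
                "sample_tag": tag_of,
                "pairs": [";".join(ps) for ps in pair_sets],
                "edited": edited,
            }
        ),
        effects=effects,
        amplicons=amplicon_truth,
    )
    return SimExperiment(
        config=config,
        library=library,
        guide_counts=guide_counts,
        gene_counts=gene_counts,
        peak_counts=peak_counts,
        cell_meta=cell_meta,
        amplicon_reads=amplicon_reads,
        sam_reads=sam_reads,
        target_windows=windows,
        gene_coords=gene_coords,
        truth=truth,
    )


def _validate_effects(effects, pair_ids, cell_types, gene_ids, peak_ids) -> None:
    known = {"gene": set(gene_ids), "peak": set(peak_ids)}
    for row in effects.itertuples():
        if row.pair_id not in pair_ids:
            raise ValueError(f"effect table references unknown pair {row.pair_id!r}")
        if row.cell_type not in cell_types:
            raise ValueError(
                f"effect table references unknown cell type {row.cell_type!r}"
            )
        if row.feature_id not in known.get(row.modality, set()):
            raise ValueError(
                f"effect table references unknown {row.modality} {row.feature_id!r}"
            )


def _baseline_means(rng, n_features, n_cell_types, mean_range) -> np.ndarray:
    lo, hi = mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_features))
    ct_factor = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=(n_features, n_cell_types)))
    return base[:, None] * ct_factor  # (features, cell types)


def _effect_lfc_matrix(effects, modality, feature_ids, cell_types):
    """(pair, cell_type) -> per-feature log2fc vectors as a nested dict."""
    idx = {f: i for i, f in enumerate(feature_ids)}
    out: dict[tuple[str, str], np.ndarray] = {}
    sub = effects[effects["modality"] == modality]
    for row in sub.itertuples():
        key = (row.pair_id, row.cell_type)
        vec = out.setdefault(key, np.zeros(len(feature_ids)))
        vec[idx[row.feature_id]] += row.log2fc
    return out


def _expression_matrix(
    rng, config, feature_ids, cell_types, ct_of, pair_sets, effects,
    modality, mean_range, dispersion,
):
    base_mu = _baseline_means(rng, len(feature_ids), len(cell_types), mean_range)
    return _shifted_counts(
        rng, base_mu, feature_ids, cell_types, ct_of, pair_sets, effects,
        modality, dispersion,
    )


def _shifted_counts(
    rng, base_mu, feature_ids, cell_types, ct_of, pair_sets, effects,
    modality, dispersion, coupled=(), gene_counts=None, gene_ids=None,
):
    ct_index = {ct: i for i, ct in enumerate(cell_types)}
    lfc = _effect_lfc_matrix(effects, modality, feature_ids, cell_types)
    n_cells = len(ct_of)
    mu = np.empty((n_cells, len(feature_ids)))
    for i in range(n_cells):
        m = base_mu[:, ct_index[ct_of[i]]].copy()
        for pid in pair_sets[i]:
            vec = lfc.get((pid, ct_of[i]))
            if vec is not None:
                m = m * np.exp2(vec)
        mu[i] = m
    if coupled and gene_counts is not None:
        fidx = {f: j for j, f in enumerate(feature_ids)}
        gidx = {g: j for j, g in enumerate(gene_ids)}
        for gene, peak, strength in coupled:
            gvec = gene_counts[:, gidx[gene]].astype(float)
            scale = ((gvec + 1.0) / (gvec.mean() + 1.0)) ** strength
            mu[:, fidx[peak]] *= scale
    return _nb_draw(rng, mu, dispersion).astype(np.int64)


def _make_meta(rng, config, barcodes, ct_of, tag_of) -> pd.DataFrame:
    n = len(barcodes)
    meta = pd.DataFrame(
        {
            "cell_type": ct_of,
            "sample_tag": tag_of,
            "n_genes": rng.integers(800, 6000, size=n),
            "n_umi": rng.integers(1500, 12000, size=n),
            "pct_mito": rng.uniform(0.0, 6.0, size=n),
            "frac_intronic": rng.uniform(0.2, 0.5, size=n),
            "doublet_score": rng.uniform(0.0, 1.0, size=n),
            "n_count_peaks": rng.integers(500, 8000, size=n),
            "frac_reads_in_peaks": rng.uniform(0.2, 0.8, size=n),
            "tss_enrichment": rng.uniform(2.0, 10.0, size=n),
            "frac_blacklist": rng.uniform(0.0, 0.05, size=n),
            "nucleosome_signal": rng.uniform(0.05, 0.25, size=n),
            "sample_tag_confident": True,
        },
        index=pd.Index(barcodes, name="cell_barcode"),
    )
    n_fail = int(round(config.qc_fail_fraction * n))
    if n_fail:
        fail_idx = rng.choice(n, size=n_fail, replace=False)
        modes = rng.integers(0, 4, size=n_fail)
        for i, mode in zip(fail_idx, modes):
            bc = barcodes[i]
            if mode == 0:
                meta.loc[bc, "n_genes"] = int(rng.integers(50, 500))
            elif mode == 1:
                meta.loc[bc, "n_umi"] = int(rng.integers(15_001, 40_000))
            elif mode == 2:
                meta.loc[bc, "doublet_score"] = float(rng.uniform(1.51, 3.0))
            else:
                meta.loc[bc, "nucleosome_signal"] = float(rng.uniform(0.31, 1.0))
    return meta


def _make_amplicons(rng, config, library) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    pair_ids = library.pair_ids
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(config.n_amplicon_reads):
        read_id = f"amp{i:06d}"
        if len(pair_ids) > 1 and rng.random() < config.chimera_fraction:
            a, b = rng.choice(len(pair_ids), size=2, replace=False)
            g1 = library.pair(pair_ids[a])[0]
            g2 = library.pair(pair_ids[b])[1]
            kind = "chimeric"
            p1, p2 = pair_ids[a], pair_ids[b]
        else:
            pid = pair_ids[int(rng.integers(len(pair_ids)))]
            g1, g2 = library.pair(pid)
            kind = "on_target"
            p1 = p2 = pid
        seq = _ANCHOR5 + g1.spacer + _LINKER + g2.spacer + _ANCHOR3
        seq = _mutate(seq, rng, config.amplicon_error_rate)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append((read_id, seq))
        truth_rows.append((read_id, kind, p1, p2))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "kind", "g1_pair", "g2_pair"]
    )
    return reads, truth


def _make_alignments(
    rng, config, barcodes, pair_sets, edited, windows, library
) -> list[AlignedRead]:
    """Reads spanning every target window for every cell.

    A read carries a single deletion of ``deletion_length`` placed
    uniformly inside the window iff its cell is edited and actually
    carries the window's pair; all other reads align cleanly (pure M).
    """
    reads: list[AlignedRead] = []
    read_len = 120
    counter = 0
    for i, bc in enumerate(barcodes):
        carried = set(pair_sets[i])
        for gid, window in windows.items():
            pair = library.guide(gid).pair_id
            with_indel = bool(edited[i]) and pair in carried
            for _ in range(config.reads_per_cell_window):
                lead = int(rng.integers(10, 41))
                pos = window.start - lead
                if with_indel:
                    del_len = config.deletion_length
                    d = int(rng.integers(window.start, window.end - del_len + 1))
                    m1 = d - pos
                    cigar = (("M", m1), ("D", del_len), ("M", read_len - m1))
                else:
                    cigar = (("M", read_len),)
                reads.append(
                    AlignedRead(
                        read_id=f"sam{counter:07d}",
                        ref_name=_CHROM,
                        pos=pos,
                        cigar=cigar,
                        cell_barcode=bc,
                    )
                )
                counter += 1
    return reads


_FIXTURES = {
    "well_separated_assignment": dict(
        n_cells=1000,
        n_targeting_pairs=8,
        n_nt_pairs=1,
        n_st_pairs=1,
        fixed_pairs_per_cell=1,
        ambient_rate=0.05,
        signal_count_mean=40.0,
        n_genes=50,
        n_peaks=20,
        n_amplicon_reads=200,
        reads_per_cell_window=1,
        n_samples=2,
        seed=7,
    ),
    "null_differential": dict(
        n_cells=1500,
        n_targeting_pairs=4,
        n_nt_pairs=2,
        n_st_pairs=2,
        n_cell_types=1,
        effect_table=pd.DataFrame(
            columns=["pair_id", "cell_type", "modality", "feature_id", "log2fc"]
        ),
        n_genes=200,
        n_peaks=50,
        n_amplicon_reads=100,
        reads_per_cell_window=1,
        n_samples=4,
        seed=11,
    ),
    "chimera_stress": dict(
        n_cells=100,
        n_targeting_pairs=4,
        n_nt_pairs=1,
        n_st_pairs=1,
        chimera_fraction=0.2,
        n_amplicon_reads=2000,
        n_genes=30,
        n_peaks=10,
        reads_per_cell_window=1,
        n_samples=2,
        seed=13,
    ),
    "edited_all": dict(
        n_cells=200,
        n_targeting_pairs=4,
        n_nt_pairs=1,
        n_st_pairs=1,
        fixed_pairs_per_cell=1,
        edit_rate=1.0,
        n_genes=30,
        n_peaks=10,
        n_amplicon_reads=100,
        reads_per_cell_window=2,
        n_samples=2,
        seed=17,
    ),
}


def make_fixture(name: str, **overrides) -> SimExperiment:
    """Generate one of the small named test bundles.

    ``well_separated_assignment``: one vector per cell, signal mean 800x
    the ambient rate.  ``null_differential``: empty effect table.
    ``chimera_stress``: 20% chimeric amplicons.  ``edited_all``: every
    assigned cell edited (edit rate 1).  Keyword overrides adjust the
    underlying config.
    """
    if name not in _FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
        )
    params = dict(_FIXTURES[name])
    params.update(overrides)
    return simulate_experiment(SimConfig(**params))
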