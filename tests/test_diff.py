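import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from perturbnuc.assign import AssignmentTable, assign_guides
from perturbnuc.diff import (
    PseudobulkMatrix,
    build_design,
    concordance,
    estimate_dispersion,
    make_pseudobulk,
    nb_glm_lrt,
    norm_factors,
    prefilter_genes,
    run_screen,
)
from perturbnuc.types import CellByFeatureCounts


def pb_from(counts, guides, samples, feature_ids=None):
    counts = np.asarray(counts)
    cols = pd.DataFrame(
        {"guide": guides, "sample": samples, "n_cells": [10] * len(guides)}
    )
    fids = feature_ids or [f"f{i}" for i in range(counts.shape[0])]
    return PseudobulkMatrix(counts, fids, cols, "gene", "ct0")


@pytest.fixture(scope="module")
def screen_sim():
    from perturbnuc.simulate import SimConfig, simulate_experiment

    return simulate_experiment(
        SimConfig(
            n_cells=3000,
            n_cell_types=2,
            n_targeting_pairs=3,
            n_nt_pairs=1,
            n_st_pairs=1,
            fixed_pairs_per_cell=1,
            n_genes=120,
            n_peaks=60,
            n_samples=4,
            qc_fail_fraction=0.0,
            reads_per_cell_window=0,
            n_amplicon_reads=10,
            seed=23,
        )
    )


class TestPseudobulk:
    def test_column_sums_conserve_single_cell_totals(self, screen_sim):
        table, _ = assign_guides(screen_sim.guide_counts, seed=0)
        meta = screen_sim.cell_meta
        ct = sorted(meta["cell_type"].unique())[0]
        pb = make_pseudobulk(screen_sim.gene_counts, meta, table, ct)
        singles = table.single_cells()
        expected_cells = [
            bc for bc in singles if meta.loc[bc, "cell_type"] == ct
        ]
        idx = [screen_sim.gene_counts.barcode_index(bc) for bc in expected_cells]
        total_cells = int(
            np.asarray(screen_sim.gene_counts.counts[idx, :].sum())
        )
        assert pb.counts.sum() == total_cells
        assert pb.columns["n_cells"].sum() == len(expected_cells)

    def test_doublets_excluded(self):
        mat = np.array([[4, 1], [6, 2], [8, 3]])
        counts = CellByFeatureCounts(mat, ["a", "b", "c"], ["g1", "g2"], "gene")
        meta = pd.DataFrame(
            {"cell_type": ["ct"] * 3, "sample_tag": ["s1"] * 3},
            index=["a", "b", "c"],
        )
        table = AssignmentTable(
            ["a", "b", "c"],
            [["gA"], ["gA", "gB"], ["gA"]],
            [[1.0], [0.9, 0.9], [1.0]],
            [[5], [4, 4], [9]],
            min_umi=3,
        )
        pb = make_pseudobulk(counts, meta, table, "ct")
        assert pb.counts[:, 0].tolist() == [4 + 8, 1 + 3]
        assert pb.columns["n_cells"].tolist() == [2]

    def test_unknown_cell_type_rejected(self, screen_sim):
        table, _ = assign_guides(screen_sim.guide_counts, seed=0)
        with pytest.raises(ValueError, match="absent"):
            make_pseudobulk(
                screen_sim.gene_counts, screen_sim.cell_meta, table, "no_such_ct"
            )


class TestPrefilter:
    def test_strict_umi_floor_and_column_count(self):
        pb = pb_from(
            [[11, 12, 0, 0],   # 2 columns above 10 -> kept
             [11, 9, 0, 0],    # only 1 column above 10 -> dropped
             [10, 10, 10, 10]],  # never strictly above 10 -> dropped
            ["c", "c", "t", "t"], ["s1", "s2", "s1", "s2"],
        )
        assert prefilter_genes(pb).tolist() == [True, False, False]


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(30, size=200)
        pb = pb_from(np.column_stack([col, col, col]),
                     ["c", "t", "t"], ["s1", "s1", "s2"])
        assert np.allclose(norm_factors(pb), 1.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        pb = pb_from(rng.poisson(20, size=(300, 6)),
                     list("cctttt"), ["s1", "s2"] * 3)
        f = norm_factors(pb)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_depth_change_alone_leaves_factors_near_unity(self):
        # factors correct for composition, not depth: doubling a column is
        # absorbed entirely by its library size (M-values are computed on
        # library-scaled counts), so factors stay close to those of the
        # unscaled pool; only the precision weights shift slightly
        rng = np.random.default_rng(2)
        base = rng.poisson(40, size=(400, 4))
        f1 = norm_factors(pb_from(base, list("cctt"), ["s1", "s2"] * 2))
        scaled = base.copy()
        scaled[:, 0] *= 2
        f2 = norm_factors(pb_from(scaled, list("cctt"), ["s1", "s2"] * 2))
        assert np.allclose(f1, f2, rtol=0.02)

    def test_composition_bias_shrinks_effective_library(self):
        # a handful of hugely expressed features inflate one column's raw
        # library size; TMM trims them out, sees the majority of features
        # deflated, and compensates with a factor below the other column's
        rng = np.random.default_rng(3)
        base = rng.poisson(50, size=(500, 2))
        biased = base.copy()
        biased[:10, 1] += 20_000
        f = norm_factors(pb_from(biased, ["c", "t"], ["s1", "s1"]))
        assert f[1] < 0.9 * f[0]

    def test_zero_library_rejected(self):
        pb = pb_from([[0, 3], [0, 4]], ["c", "t"], ["s1", "s1"])
        with pytest.raises(ValueError, match="zero total"):
            norm_factors(pb)

    def test_matches_edger_calc_norm_factors(self, tmp_path):
        """edgeR's calcNormFactors is the reference implementation."""
        if shutil.which("Rscript") is None:
            raise RuntimeError("Rscript unavailable; cannot run reference")
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(5, 5 / (5 + 60.0), size=(800, 6))
        counts[:20, 3] += 5000  # composition bias in one column
        mat_file = tmp_path / "counts.tsv"
        np.savetxt(mat_file, counts, fmt="%d", delimiter="\t")
        out_file = tmp_path / "factors.tsv"
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- as.matrix(read.table('{mat_file}'))\n"
            "f <- calcNormFactors(x, method='TMM')\n"
            f"write.table(f, '{out_file}', row.names=FALSE, col.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = np.loadtxt(out_file)
        pb = pb_from(counts, list("cttttt"), ["s1"] * 6)
        ours = norm_factors(pb)
        assert np.allclose(ours, ref, rtol=0.02)


class TestDesign:
    def test_reference_levels_dropped(self):
        cols = pd.DataFrame(
            {
                "guide": ["ctrl", "ctrl", "gA", "gA", "gB", "gB"],
                "sample": ["s1", "s2", "s1", "s2", "s1", "s2"],
                "n_cells": [5] * 6,
            }
        )
        design = build_design(cols, "ctrl")
        assert list(design.columns) == [
            "intercept", "guide_gA", "guide_gB", "sample_s2"
        ]
        assert design["guide_gA"].tolist() == [0, 0, 1, 1, 0, 0]
        assert design["sample_s2"].tolist() == [0, 1, 0, 1, 0, 1]

    def test_missing_control_rejected(self):
        cols = pd.DataFrame(
            {"guide": ["gA", "gB"], "sample": ["s1", "s1"], "n_cells": [5, 5]}
        )
        with pytest.raises(ValueError, match="control guide"):
            build_design(cols, "ctrl")


class TestLrt:
    def _null_pb(self, rng, n_features=2000, phi=0.1):
        r = 1 / phi
        mu = 50.0
        counts = rng.negative_binomial(r, r / (r + mu), size=(n_features, 16))
        return pb_from(counts, ["c"] * 8 + ["t"] * 8, ["s1"] * 16)

    def test_null_type_one_error_calibrated(self):
        """Under the null, p-values at level alpha reject at rate alpha
        (binomial band for 2000 features)."""
        rng = np.random.default_rng(10)
        pb = self._null_pb(rng)
        norm_factors(pb)
        design = build_design(pb.columns, "c")
        disp = estimate_dispersion(pb, design)
        out = nb_glm_lrt(pb, design, "guide_t", disp.tagwise)
        rate = (out["p"] < 0.05).mean()
        # central binomial band: 0.05 +- 3*sqrt(0.05*0.95/2000)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        pb = self._null_pb(rng)
        norm_factors(pb)
        design = build_design(pb.columns, "c")
        disp = estimate_dispersion(pb, design)
        out = nb_glm_lrt(pb, design, "guide_t", disp.tagwise)
        from scipy import stats as sp_stats

        ks = sp_stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 1e-3

    def test_known_effect_detected_with_correct_sign(self):
        rng = np.random.default_rng(12)
        phi, r = 0.1, 10
        mu = np.full((500, 8), 50.0)
        mu[:25, 4:] *= 4.0  # injected 2-fold-log2 up-shift in treatment
        counts = rng.negative_binomial(r, r / (r + mu))
        pb = pb_from(counts, list("cccctttt"), ["s1", "s2", "s3", "s4"] * 2)
        norm_factors(pb)
        design = build_design(pb.columns, "c")
        disp = estimate_dispersion(pb, design)
        out = nb_glm_lrt(pb, design, "guide_t", disp.tagwise)
        hits = set(out.index[out["padj"] < 0.05])
        true_hits = hits & set(range(25))
        false_hits = hits - set(range(25))
        assert len(true_hits) >= 20  # nearly all injected effects found
        # BH at 5% FDR permits only a handful of false discoveries
        assert len(false_hits) <= 5
        assert (out.loc[sorted(true_hits), "logFC"] > 1).all()

    def test_all_zero_feature_flagged(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(30, size=(50, 6))
        counts[7] = 0
        pb = pb_from(counts, list("cctttt"), ["s1", "s2", "s3"] * 2)
        design = build_design(pb.columns, "c")
        out = nb_glm_lrt(pb, design, "guide_t", 0.1)
        assert out.loc[7, "flag"] == "separation"
        assert out.loc[7, "p"] == 1.0 and out.loc[7, "logFC"] == 0.0

    def test_zero_group_logfc_finite(self):
        rng = np.random.default_rng(14)
        counts = rng.poisson(30, size=(50, 6))
        counts[3, 2:] = 0  # expressed in control only
        pb = pb_from(counts, list("cctttt"), ["s1", "s2", "s3"] * 2)
        design = build_design(pb.columns, "c")
        out = nb_glm_lrt(pb, design, "guide_t", 0.1)
        assert np.isfinite(out.loc[3, "logFC"])
        assert out.loc[3, "logFC"] < 0

    def test_unknown_coefficient_rejected(self):
        pb = pb_from(np.ones((5, 4), dtype=int), list("cctt"), ["s1", "s2"] * 2)
        design = build_design(pb.columns, "c")
        with pytest.raises(ValueError, match="unknown design coefficient"):
            nb_glm_lrt(pb, design, "guide_x", 0.1)


class TestRunScreen:
    def test_significant_features_localized_to_injected_effects(self, screen_sim):
        """Calls concentrate in the simulated (pair, cell type) effect
        combinations; contrasts without injected effects stay clean."""
        table, _ = assign_guides(screen_sim.guide_counts, seed=0)
        tables, summary = run_screen(
            screen_sim.gene_counts,
            screen_sim.peak_counts,
            screen_sim.cell_meta,
            table,
            screen_sim.library,
            control="NT3",
        )
        effects = screen_sim.truth.effects
        effect_keys = set(
            zip(effects["cell_type"], effects["pair_id"],
                effects["modality"].map({"gene": "rna", "peak": "atac"}))
        )
        hot = summary[
            summary.apply(
                lambda r: (r["cell_type"], r["perturbation"], r["modality"])
                in effect_keys,
                axis=1,
            )
        ]
        cold = summary[
            ~summary.apply(
                lambda r: (r["cell_type"], r["perturbation"], r["modality"])
                in effect_keys,
                axis=1,
            )
        ]
        assert hot["n_significant"].sum() > 10
        # contrasts with no injected effect yield at most a stray call each
        assert cold["n_significant"].median() <= 1
        assert hot["n_significant"].sum() > 5 * max(cold["n_significant"].sum(), 1)

    def test_true_effect_recovery_and_direction(self, screen_sim):
        table, _ = assign_guides(screen_sim.guide_counts, seed=0)
        tables, _ = run_screen(
            screen_sim.gene_counts,
            None,
            screen_sim.cell_meta,
            table,
            screen_sim.library,
            control="NT3",
        )
        effects = screen_sim.truth.effects
        gene_fx = effects[effects["modality"] == "gene"]
        n_checked = n_signed = 0
        for (ct, pid), grp in gene_fx.groupby(["cell_type", "pair_id"]):
            key = (ct, pid, "rna")
            if key not in tables:
                continue
            tab = tables[key].set_index("feature")
            for _, row in grp.iterrows():
                if row["feature_id"] not in tab.index:
                    continue
                est = tab.loc[row["feature_id"], "logFC"]
                n_checked += 1
                if np.sign(est) == np.sign(row["log2fc"]):
                    n_signed += 1
        assert n_checked >= 20
        assert n_signed / n_checked >= 0.9


class TestConcordance:
    def test_identical_tables_fully_concordant(self):
        rng = np.random.default_rng(15)
        tab = pd.DataFrame(
            {
                "feature": [f"f{i}" for i in range(50)],
                "logFC": rng.normal(size=50),
                "padj": rng.uniform(size=50) * 0.2,
            }
        )
        out = concordance(tab, tab)
        assert out["r"] == pytest.approx(1.0)
        assert out["shared_significant"] == set(
            tab.loc[tab["padj"] < 0.05, "feature"]
        )

    def test_disjoint_features_rejected(self):
        a = pd.DataFrame({"feature": ["x"], "logFC": [1.0], "padj": [0.01]})
        b = pd.DataFrame({"feature": ["y"], "logFC": [1.0], "padj": [0.01]})
        with pytest.raises(ValueError, match="no overlapping"):
            concordance(a, b)
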