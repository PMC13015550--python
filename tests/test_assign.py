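import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from perturbnuc.assign import (
    AssignmentTable,
    assign_guides,
    assignment_metrics,
    cross_guide_correlation,
    fit_guide_mixture,
    knockdown_check,
)
from perturbnuc.types import CellByFeatureCounts


def mixture_sample(rng, n_bg=400, n_sig=100, bg_mean=0.5, sig_mean=6.0):
    """Counts from ambient Poisson plus a high log-normal signal mode."""
    bg = rng.poisson(bg_mean, size=n_bg)
    sig = np.round(2 ** rng.normal(sig_mean, 0.5, size=n_sig)).astype(int)
    return np.concatenate([bg, np.maximum(sig, 1)])


class TestMixtureFit:
    def test_recovers_separated_component_means(self):
        rng = np.random.default_rng(0)
        counts = mixture_sample(rng)
        fit = fit_guide_mixture(counts, seed=0)
        assert not fit.fallback
        assert fit.means[0] < fit.means[1]
        assert abs(fit.means[1] - 6.0) < 0.5
        assert fit.n_cells_used == int((counts > 0).sum())

    def test_posterior_monotone_in_count(self):
        rng = np.random.default_rng(1)
        fit = fit_guide_mixture(mixture_sample(rng), seed=0)
        grid = np.arange(1, 200)
        post = fit.signal_posterior(grid)
        # the signal component has the larger mean, so the posterior must
        # cross from near 0 to near 1 and never decrease appreciably
        assert post[0] < 0.01 and post[-1] > 0.99
        assert np.all(np.diff(post) > -1e-9)

    def test_zero_count_has_zero_posterior(self):
        rng = np.random.default_rng(2)
        fit = fit_guide_mixture(mixture_sample(rng), seed=0)
        assert fit.signal_posterior(np.array([0]))[0] == 0.0

    def test_few_positive_cells_fall_back(self):
        counts = np.array([0] * 50 + [5, 7, 9])
        fit = fit_guide_mixture(counts)
        assert fit.fallback
        post = fit.signal_posterior(np.array([0, 1, 5]))
        assert list(post) == [0.0, 1.0, 1.0]

    def test_constant_positive_counts_fall_back(self):
        counts = np.array([0] * 30 + [4] * 30)
        assert fit_guide_mixture(counts).fallback

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_guide_mixture(np.array([3]))


class TestAssignGuides:
    def test_min_umi_floor_is_inclusive(self):
        # fallback guides assign on count alone, isolating the UMI floor:
        # 2 is below, 3 at, 4 above the default threshold of 3
        mat = np.zeros((40, 1), dtype=int)
        mat[:3, 0] = [2, 3, 4]
        counts = CellByFeatureCounts(
            mat, [f"c{i}" for i in range(40)], ["gX"], "guide"
        )
        table, fits = assign_guides(counts)
        assert fits["gX"].fallback
        assert table.labels[0] == "Not assigned"
        assert table.labels[1] == "single" and table.assignments[1] == ["gX"]
        assert table.labels[2] == "single"

    def test_modality_checked(self):
        counts = CellByFeatureCounts(
            np.ones((5, 2), dtype=int), list("abcde"), ["x", "y"], "gene"
        )
        with pytest.raises(ValueError, match="guide-modality"):
            assign_guides(counts)

    def test_well_separated_cells_recover_true_vector(self, well_separated):
        table, fits = assign_guides(well_separated.guide_counts, seed=0)
        truth = well_separated.truth.pair_sets()
        correct = 0
        for bc, guides, label in zip(
            table.cell_barcodes, table.assignments, table.labels
        ):
            if label == "single" and set(guides) == truth[bc]:
                correct += 1
        assert correct / len(table) >= 0.99

    def test_frame_round_trip_preserves_labels(self, well_separated):
        table, _ = assign_guides(well_separated.guide_counts, seed=0)
        back = AssignmentTable.from_frame(table.to_frame())
        assert back.labels == table.labels
        assert back.assignments == table.assignments
        assert back.umis == table.umis


class TestAssignmentTable:
    def _table(self):
        return AssignmentTable(
            ["c0", "c1", "c2", "c3"],
            [["gA"], [], ["gA", "gB"], ["gB"]],
            [[0.99], [], [0.8, 0.7], [1.0]],
            [[12], [], [5, 6], [30]],
            min_umi=3,
        )

    def test_labels_follow_guide_count(self):
        t = self._table()
        assert t.labels == ["single", "Not assigned", "Doublet", "single"]
        assert t.label_counts() == {"single": 2, "Doublet": 1, "Not assigned": 1}

    def test_per_cell_groups_use_guide_for_singles(self):
        groups = self._table().per_cell_groups()
        assert groups == {
            "c0": "gA", "c1": "Not assigned", "c2": "Doublet", "c3": "gB"
        }

    def test_single_cells_excludes_doublets(self):
        assert self._table().single_cells() == {"c0": "gA", "c3": "gB"}


class TestMetrics:
    def test_hand_computed_rates(self):
        table = AssignmentTable(
            ["a", "b", "c", "d"],
            [["g"], ["g", "h"], [], ["h"]],
            [[1.0], [0.9, 0.9], [], [1.0]],
            [[5], [4, 4], [], [9]],
            min_umi=3,
        )
        row = assignment_metrics(table).iloc[0]
        assert row["assigned_pct"] == pytest.approx(75.0)
        assert row["single_pct"] == pytest.approx(50.0)
        assert row["n_doublet"] == 1

    def test_grouped_rates(self, well_separated):
        table, _ = assign_guides(well_separated.guide_counts, seed=0)
        meta = well_separated.cell_meta
        out = assignment_metrics(table, meta, group_by="sample_tag")
        groups = set(out["group"])
        assert "all" in groups and len(groups) > 1
        assert out["n_cells"].iloc[0] == out["n_cells"].iloc[1:].sum()

    def test_unknown_group_key(self, well_separated):
        table, _ = assign_guides(well_separated.guide_counts, seed=0)
        with pytest.raises(KeyError, match="no_such_column"):
            assignment_metrics(table, well_separated.cell_meta, "no_such_column")

    def test_empty_table_rejected(self):
        table = AssignmentTable([], [], [], [], min_umi=3)
        with pytest.raises(ValueError, match="empty"):
            assignment_metrics(table)


class TestCrossGuideCorrelation:
    def test_symmetric_unit_diagonal(self, well_separated):
        corr = cross_guide_correlation(well_separated.guide_counts)
        arr = corr.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.allclose(np.diag(arr), 1.0)

    def test_low_moi_gives_low_off_diagonal(self, well_separated):
        arr = cross_guide_correlation(well_separated.guide_counts).to_numpy()
        off = arr[~np.eye(arr.shape[0], dtype=bool)]
        # one vector per cell: different guides are anti- or un-correlated
        assert np.nanmax(off) < 0.3

    def test_zero_variance_guide_is_nan(self):
        mat = np.array([[1, 0, 2], [3, 0, 1], [5, 0, 4], [2, 0, 2]])
        counts = CellByFeatureCounts(
            mat, list("abcd"), ["g1", "gdead", "g2"], "guide"
        )
        corr = cross_guide_correlation(counts)
        assert np.isnan(corr.loc["gdead", "g1"])
        assert corr.loc["gdead", "gdead"] == 1.0
        assert not np.isnan(corr.loc["g1", "g2"])

    def test_shape_requirements(self):
        one_guide = CellByFeatureCounts(
            np.ones((5, 1), dtype=int), list("abcde"), ["g"], "guide"
        )
        with pytest.raises(ValueError, match="2 guides"):
            cross_guide_correlation(one_guide)


class TestKnockdown:
    def test_target_genes_lower_in_assigned_cells(self, well_separated):
        """Simulated on-target knockdown (half expression) shows up as a
        negative difference for every targeting pair."""
        table, _ = assign_guides(well_separated.guide_counts, seed=0)
        out = knockdown_check(
            well_separated.gene_counts,
            table,
            well_separated.library,
            control_class="safe_target",
        )
        clean = out[out["flag"] == ""]
        assert len(clean) > 0
        assert (clean["difference"] < 0).mean() >= 0.9
        assert (clean.loc[clean["padj"].notna(), "padj"] < 0.05).mean() >= 0.75

    def test_missing_gene_flagged_not_dropped(self, two_pair_library):
        rng = np.random.default_rng(3)
        counts = CellByFeatureCounts(
            rng.poisson(5, size=(6, 2)),
            [f"c{i}" for i in range(6)],
            ["other1", "other2"],  # target genes geneA/geneB absent
            "gene",
        )
        table = AssignmentTable(
            [f"c{i}" for i in range(6)],
            [["A-g1"], ["A-g1"], ["B-g1"], ["B-g1"], ["B-g2"], ["A-g2"]],
            [[1.0]] * 6,
            [[10]] * 6,
            min_umi=3,
        )
        with pytest.raises(ValueError, match="no cells singly assigned"):
            knockdown_check(counts, table, two_pair_library)

    def test_missing_gene_flag_with_controls(self, two_pair_library):
        from perturbnuc.types import GuideLibrary, GuideRecord

        lib = GuideLibrary(
            list(two_pair_library.guides)
            + [
                GuideRecord("S-g1", "AATTAATTAATTAATTAATT", "S", "g1", None, "safe_target"),
                GuideRecord("S-g2", "TTGGTTGGTTGGTTGGTTGG", "S", "g2", None, "safe_target"),
            ]
        )
        rng = np.random.default_rng(4)
        counts = CellByFeatureCounts(
            rng.poisson(5, size=(6, 2)) + 1,
            [f"c{i}" for i in range(6)],
            ["other1", "other2"],
            "gene",
        )
        table = AssignmentTable(
            [f"c{i}" for i in range(6)],
            [["A-g1"], ["A-g1"], ["B-g1"], ["S-g1"], ["S-g1"], ["S-g2"]],
            [[1.0]] * 6,
            [[10]] * 6,
            min_umi=3,
        )
        out = knockdown_check(counts, table, lib)
        assert set(out["flag"]) == {"gene_missing"}
        assert len(out) == 4  # one row per targeting guide, all kept
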