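"""Labelling engine: Otsu thresholding, mode aggregation, filters, aE/sNE."""

import numpy as np
import pandas as pd
import pytest

from helpess import (
    binarise_cell_line,
    filter_crispr,
    label_common,
    label_context,
    label_three_class,
    otsu_threshold,
    ucs_genes,
)
from helpess.io import ContextMap, ScoreMatrix
from helpess.labelling import AE, E, NE, OTSU_BINS, SNE, LabelAssignment

from conftest import brute_force_otsu


def _random_sample(rng):
    """Random bimodal or unimodal array, the mix the threshold faces in screens."""
    kind = rng.integers(3)
    n = int(rng.integers(20, 1000))
    if kind == 0:  # bimodal, well separated
        n1 = int(rng.integers(2, n - 1))
        return np.concatenate(
            [rng.normal(-2.0, 0.3, n1), rng.normal(0.0, 0.2, n - n1)]
        )
    if kind == 1:  # bimodal, overlapping
        n1 = int(rng.integers(2, n - 1))
        return np.concatenate(
            [rng.normal(-1.0, 0.4, n1), rng.normal(0.0, 0.4, n - n1)]
        )
    return rng.normal(0.0, 1.0, n)  # unimodal


class TestOtsu:
    def test_threshold_falls_in_the_gap(self):
        vals = np.array([-3.0, -2.9, -2.8, 0.0, 0.1, 0.2])
        t = otsu_threshold(vals)
        assert -2.8 < t < 0.0

    def test_matches_midpoint_scan_on_stated_example(self):
        vals = np.array([-3.0, -2.8, -2.9, 0.1, 0.2, 0.0, 0.15, 0.05])
        t = otsu_threshold(vals)
        oracle = brute_force_otsu(vals)
        bin_width = (vals.max() - vals.min()) / OTSU_BINS
        assert abs(t - oracle) <= bin_width or np.array_equal(vals < t, vals < oracle)

    def test_two_point_forced_separation(self):
        t = otsu_threshold([-1.0, 0.0])
        assert -1.0 < t <= 0.0

    def test_degenerate_constant_input_error(self):
        with pytest.raises(ValueError):
            otsu_threshold([1.0, 1.0, 1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_agrees_with_exhaustive_oracle(self, seed):
        """Histogram Otsu classifies like the exact scan, up to one bin width."""
        rng = np.random.default_rng(seed)
        for _ in range(20):
            vals = _random_sample(rng)
            t = otsu_threshold(vals)
            oracle = brute_force_otsu(vals)
            bin_width = (vals.max() - vals.min()) / OTSU_BINS
            disagree = vals[(vals < t) != (vals < oracle)]
            near = np.minimum(np.abs(disagree - oracle), np.abs(disagree - t))
            assert np.all(near <= bin_width)

    def test_cross_check_against_reference_implementation(self):
        """Independent route: the image-processing reference threshold."""
        skimage_filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(-1.5, 0.3, 70), rng.normal(0, 0.2, 930)])
        ours = otsu_threshold(vals)
        ref = skimage_filters.threshold_otsu(vals, nbins=OTSU_BINS)
        bin_width = (vals.max() - vals.min()) / OTSU_BINS
        assert abs(ours - ref) <= bin_width


class TestBinarise:
    def test_below_threshold_is_essential(self):
        col = pd.Series([-2.5, -2.4, 0.0, 0.1, 0.2], index=list("ABCDE"))
        labels, thr = binarise_cell_line(col, "c1")
        assert labels["A"] == E and labels["C"] == NE
        assert -2.4 < thr.threshold < 0.0
        assert thr.n_used == 5

    def test_boundary_score_is_not_essential(self):
        """Label is E iff score is strictly below the threshold."""
        col = pd.Series([-2.0, -2.0, 0.0, 0.0, 0.1], index=list("ABCDE"))
        labels, thr = binarise_cell_line(col, "c1")
        np.testing.assert_array_equal(
            (labels == E).to_numpy(), (col < thr.threshold).to_numpy()
        )
        np.testing.assert_array_equal(
            (labels == NE).to_numpy(), (col >= thr.threshold).to_numpy()
        )

    def test_missing_scores_yield_missing_labels(self):
        col = pd.Series([-2.0, np.nan, 0.0, 0.1], index=list("ABCD"))
        labels, _ = binarise_cell_line(col, "c1")
        assert labels["B"] is None

    def test_constant_column_all_not_essential(self, caplog):
        col = pd.Series([0.5, 0.5, 0.5], index=list("ABC"))
        labels, thr = binarise_cell_line(col, "c1")
        assert set(labels) == {NE}
        assert np.isnan(thr.threshold)


class TestFilters:
    def _screen(self, n_small=9, n_big=12, missing_gene_frac=None):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(40)]
        cells = [f"s{i}" for i in range(n_small)] + [f"b{i}" for i in range(n_big)]
        data = pd.DataFrame(rng.normal(size=(40, len(cells))), index=genes, columns=cells)
        if missing_gene_frac is not None:
            n_missing = int(round(missing_gene_frac * len(cells)))
            data.iloc[0, :n_missing] = np.nan
        ctx = {c: ("small" if c.startswith("s") else "big") for c in cells}
        return ScoreMatrix(data), ContextMap(pd.Series(ctx))

    def test_small_context_removed(self):
        scores, contexts = self._screen()
        fs, fc = filter_crispr(scores, contexts, min_cell_lines=10)
        assert fc.contexts == ["big"]
        assert all(c.startswith("b") for c in fs.cell_ids)

    def test_gene_above_missing_limit_removed(self):
        # 25 cell lines so that 24/25 = 96% missing exceeds the 95% limit
        scores, contexts = self._screen(n_small=0, n_big=25, missing_gene_frac=0.96)
        fs, _ = filter_crispr(scores, contexts)
        assert "G0" not in fs.gene_ids

    def test_gene_at_exact_missing_limit_kept(self):
        scores, contexts = self._screen(n_small=0, n_big=20, missing_gene_frac=0.95)
        assert (scores.data.loc["G0"].isna().mean()) == 0.95
        fs, _ = filter_crispr(scores, contexts)
        assert "G0" in fs.gene_ids

    def test_everything_filtered_is_an_error(self):
        scores, contexts = self._screen(n_small=9, n_big=9)
        with pytest.raises(ValueError):
            filter_crispr(scores, contexts, min_cell_lines=10)


def _matrix_from_columns(cols: dict) -> tuple[ScoreMatrix, ContextMap]:
    data = pd.DataFrame(cols)
    ctx = ContextMap(pd.Series({c: "T" for c in data.columns}))
    return ScoreMatrix(data), ctx


class TestModeAggregation:
    def test_even_split_resolves_to_not_essential(self):
        # gene X: E,E,NE,NE across 4 cell lines -> NE
        rng = np.random.default_rng(0)
        base = {f"c{i}": rng.normal(0, 0.05, 10) for i in range(4)}
        data = pd.DataFrame(base, index=[f"G{i}" for i in range(10)])
        data.loc["G0", ["c0", "c1"]] = -3.0  # essential in half the lines
        data.loc["G1"] = -3.0  # essential everywhere, anchors the low mode
        sm, cm = _matrix_from_columns(data)
        labels = label_context(sm, cm, "T").labels
        assert labels["G0"] == NE
        assert labels["G1"] == E

    def test_strict_majority_wins(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {f"c{i}": rng.normal(0, 0.05, 10) for i in range(4)},
            index=[f"G{i}" for i in range(10)],
        )
        data.loc["G0", ["c0", "c1", "c2"]] = -3.0
        data.loc["G1"] = -3.0
        sm, cm = _matrix_from_columns(data)
        assert label_context(sm, cm, "T").labels["G0"] == E

    def test_single_cell_line_mode_of_one(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"c0": rng.normal(0, 0.05, 10)}, index=[f"G{i}" for i in range(10)])
        data.loc["G0"] = -3.0
        sm, cm = _matrix_from_columns(data)
        assert label_context(sm, cm, "T").labels["G0"] == E

    def test_unknown_context_error(self, tiny_scores, tiny_contexts):
        with pytest.raises(ValueError, match="nope"):
            label_context(tiny_scores, tiny_contexts, "nope")

    def test_gene_with_no_usable_scores_omitted(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {f"c{i}": rng.normal(0, 0.05, 10) for i in range(2)},
            index=[f"G{i}" for i in range(10)],
        )
        data.loc["G3"] = -3.0
        data.loc["G9"] = np.nan
        sm, cm = _matrix_from_columns(data)
        labels = label_context(sm, cm, "T").labels
        assert "G9" not in labels and "G3" in labels


class TestCommonAndSubtraction:
    def _two_level_screen(self, dup_column=False):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(30)]
        cols, ctx = {}, {}
        for t, n_cells in (("T1", 4), ("T2", 6), ("T3", 3)):
            for i in range(n_cells):
                cid = f"{t}_c{i}"
                cols[cid] = rng.normal(0, 0.1, len(genes))
                ctx[cid] = t
        data = pd.DataFrame(cols, index=genes)
        data.loc["G0"] = -3.0  # common essential (all tissues)
        data.loc["G1", [c for c in data.columns if c.startswith(("T1", "T2"))]] = -3.0
        data.loc["G2", [c for c in data.columns if c.startswith("T1")]] = -3.0
        if dup_column:
            data["T2_dup"] = data["T2_c0"]
            ctx["T2_dup"] = "T2"
        return ScoreMatrix(data), ContextMap(pd.Series(ctx))

    def test_mode_over_tissues(self):
        sm, cm = self._two_level_screen()
        common = label_common(sm, cm).labels
        assert common["G0"] == E  # essential in 3/3 tissues
        assert common["G1"] == E  # 2/3 strict majority
        assert common["G2"] == NE  # 1/3

    def test_even_tissue_split_resolves_to_not_essential(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(20)]
        cols, ctx = {}, {}
        for t in ("T1", "T2"):
            for i in range(3):
                cid = f"{t}_c{i}"
                cols[cid] = rng.normal(0, 0.1, len(genes))
                ctx[cid] = t
        data = pd.DataFrame(cols, index=genes)
        data.loc["G0"] = -3.0
        data.loc["G1", [c for c in data.columns if c.startswith("T1")]] = -3.0
        sm, cm = ScoreMatrix(data), ContextMap(pd.Series(ctx))
        common = label_common(sm, cm).labels
        assert common["G0"] == E
        assert common["G1"] == NE  # E in T1, NE in T2: tie -> NE

    def test_duplicating_a_cell_line_leaves_common_labels_unchanged(self):
        sm1, cm1 = self._two_level_screen(dup_column=False)
        sm2, cm2 = self._two_level_screen(dup_column=True)
        assert label_common(sm1, cm1).labels == label_common(sm2, cm2).labels

    def test_ucs_is_set_difference(self):
        cs = LabelAssignment({"A": E, "B": E, "C": NE}, pd.DataFrame(), "T1")
        common = LabelAssignment({"A": NE, "B": E, "C": NE}, pd.DataFrame(), "common")
        assert ucs_genes(cs, common) == {"A"}

    def test_ucs_empty_when_all_common(self):
        cs = LabelAssignment({"A": E}, pd.DataFrame(), "T1")
        common = LabelAssignment({"A": E, "B": E}, pd.DataFrame(), "common")
        assert ucs_genes(cs, common) == set()

    def test_ucs_equals_cs_when_no_common(self):
        cs = LabelAssignment({"A": E, "B": E}, pd.DataFrame(), "T1")
        common = LabelAssignment({"A": NE, "B": NE}, pd.DataFrame(), "common")
        assert ucs_genes(cs, common) == {"A", "B"}


class TestThreeClass:
    def _screen_with_intermediate(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(60)]
        cols = {f"c{i}": rng.normal(0, 0.05, len(genes)) for i in range(5)}
        data = pd.DataFrame(cols, index=genes)
        data.iloc[:5] = rng.normal(-3.0, 0.05, size=(5, 5))  # essential
        data.iloc[5:15] = rng.normal(-0.8, 0.05, size=(10, 5))  # intermediate mode
        return _matrix_from_columns(data)

    def test_partition_of_the_universe(self):
        sm, cm = self._screen_with_intermediate()
        three = label_three_class(sm, cm, "T")
        two = label_context(sm, cm, "T")
        values = pd.Series(three.labels)
        assert set(values.unique()) <= {E, AE, SNE}
        assert set(three.labels) == set(two.labels)

    def test_essential_set_is_preserved(self):
        sm, cm = self._screen_with_intermediate()
        three = label_three_class(sm, cm, "T")
        two = label_context(sm, cm, "T")
        assert three.genes_with(E) == two.genes_with(E)

    def test_ae_and_sne_partition_the_ne_set(self):
        sm, cm = self._screen_with_intermediate()
        three = label_three_class(sm, cm, "T")
        two = label_context(sm, cm, "T")
        assert three.genes_with(AE) | three.genes_with(SNE) == two.genes_with(NE)
        assert not (three.genes_with(AE) & three.genes_with(SNE))

    def test_intermediate_mode_becomes_almost_essential(self):
        sm, cm = self._screen_with_intermediate()
        three = label_three_class(sm, cm, "T")
        intermediates = {f"G{i}" for i in range(5, 15)}
        assert intermediates <= three.genes_with(AE)
        # second threshold separates the -0.8 mode from the 0 mode
        second_pass = [t for t in three.thresholds[5:] if not np.isnan(t.threshold)]
        assert all(-0.8 < t.threshold < 0.0 for t in second_pass)


class TestPlantedRecovery:
    def test_context_labelling_recovers_planted_truth(self, default_screen):
        scores, contexts, planted = default_screen
        fs, fc = filter_crispr(scores, contexts)
        for ctx in fc.contexts:
            assignment = label_context(fs, fc, ctx)
            pred = pd.Series(assignment.labels)
            truth = planted[ctx].loc[pred.index]
            assert (pred == truth).mean() >= 0.99
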