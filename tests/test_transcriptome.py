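"""Expression aggregation, fold changes and percentile selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphogrowth.transcriptome import (RegionSetConfig, aggregate_expression,
                                        contrast_report, fold_change, n_top,
                                        select_top_percentile)

CFG = RegionSetConfig(target_structures=("op_a", "op_b"), contrast_structures=("ins",))


def _row(gene, spec, region, layer, value):
    return {"gene_id": gene, "specimen_id": spec, "region": region,
            "layer": layer, "value": value}


class TestAggregate:
    def test_single_sample_pair(self):
        t = pd.DataFrame([_row("g1", "s1", "op_a", "SG", 10.0),
                          _row("g1", "s1", "ins", "SG", 2.0)])
        out = aggregate_expression(t, CFG, "SG")
        assert out.loc[0, "target_mean"] == 10.0
        assert out.loc[0, "contrast_mean"] == 2.0

    def test_mean_across_specimens(self):
        t = pd.DataFrame([_row("g1", "s1", "op_a", "SG", 8.0),
                          _row("g1", "s2", "op_a", "SG", 12.0),
                          _row("g1", "s1", "ins", "SG", 1.0)])
        out = aggregate_expression(t, CFG, "SG")
        assert out.loc[0, "target_mean"] == 10.0

    def test_structure_present_in_one_specimen_only(self):
        # hand-computed on a 6-row toy table: op_b measured in s1 only
        t = pd.DataFrame([
            _row("g1", "s1", "op_a", "SG", 4.0),
            _row("g1", "s2", "op_a", "SG", 6.0),
            _row("g1", "s1", "op_b", "SG", 11.0),
            _row("g1", "s1", "ins", "SG", 1.0),
            _row("g1", "s2", "ins", "SG", 3.0),
            _row("g2", "s1", "ins", "SG", 5.0),   # g2 has no target sample
        ])
        out = aggregate_expression(t, CFG, "SG")
        g1 = out[out["gene_id"] == "g1"].iloc[0]
        assert g1["target_mean"] == pytest.approx((4 + 6 + 11) / 3)
        assert g1["contrast_mean"] == pytest.approx(2.0)
        # g2 is dropped from the inner join: expected - observed = 1
        assert len(out) == 1

    def test_empty_side_raises(self):
        t = pd.DataFrame([_row("g1", "s1", "op_a", "SG", 1.0)])
        with pytest.raises(ValueError):
            aggregate_expression(t, CFG, "SG")


class TestFoldChange:
    def test_plain_ratio_without_pseudocount(self):
        assert fold_change(20.0, 10.0, pseudocount=0.0) == 2.0
        assert fold_change(10.5, 0.5, pseudocount=0.0) == 21.0

    def test_double_zero_is_symmetric_null(self):
        assert fold_change(0.0, 0.0, pseudocount=0.5) == 1.0

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4), st.floats(1.01, 100.0))
    def test_scale_invariance(self, t, c, scale):
        # multiplying all values by c (with the pseudocount scaled too)
        # leaves the fold unchanged
        base = fold_change(t, c, pseudocount=0.5)
        scaled = fold_change(t * scale, c * scale, pseudocount=0.5 * scale)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestSelection:
    def _folds(self, values, genes=None):
        genes = genes or [f"g{i:03d}" for i in range(len(values))]
        return pd.DataFrame({"gene_id": genes, "fold_change": values})

    def test_percentile_rank_rule(self):
        assert n_top(35_000, 99.9) == 35
        assert n_top(1_000, 99.9) == 1
        assert n_top(100, 90.0) == 10

    def test_single_selection_is_argmax(self, rng):
        vals = rng.lognormal(0, 1, 1000)
        lc = select_top_percentile(self._folds(vals), 99.9)
        sel = lc.table[lc.table["selected"]]
        assert len(sel) == 1
        assert sel["fold_change"].iloc[0] == vals.max()

    def test_planted_block_recovered_exactly(self, rng):
        vals = np.concatenate([rng.uniform(0.5, 2.0, 90), rng.uniform(50, 60, 10)])
        genes = [f"g{i:03d}" for i in range(100)]
        lc = select_top_percentile(self._folds(vals, genes), 90.0)
        assert set(lc.table.loc[lc.table["selected"], "gene_id"]) == set(genes[90:])

    def test_selection_equals_brute_force_sort(self, rng):
        vals = rng.lognormal(0, 1.5, 500)
        df = self._folds(vals)
        lc = select_top_percentile(df, 99.0)
        oracle = df.sort_values(["fold_change", "gene_id"], ascending=[False, True])
        expected = set(oracle.head(lc.n_selected)["gene_id"])
        assert set(lc.table.loc[lc.table["selected"], "gene_id"]) == expected
        assert lc.cutoff_fold == oracle["fold_change"].iloc[lc.n_selected - 1]

    def test_boundary_ties_broken_lexicographically(self):
        df = self._folds([5.0, 5.0, 5.0, 1.0], ["gd", "gb", "gc", "ga"])
        lc = select_top_percentile(df, 50.0)  # select 2 of 4
        assert list(lc.table.loc[lc.table["selected"], "gene_id"]) == ["gb", "gc"]

    def test_cutoff_non_increasing_in_selection_size(self, rng):
        df = self._folds(rng.lognormal(0, 1, 400))
        cutoffs = [select_top_percentile(df, p).cutoff_fold for p in (99.5, 99.0, 95.0, 90.0)]
        assert all(a >= b for a, b in zip(cutoffs, cutoffs[1:]))


class TestContrastReport:
    def test_planted_genes_dominate_selection(self, expression_small):
        spec, table, truth = expression_small
        cfg = RegionSetConfig(target_structures=spec.target_regions,
                              contrast_structures=spec.contrast_regions)
        result = contrast_report(table, cfg)
        for layer, lc in result.layers.items():
            planted = set(truth.loc[truth["layer"] == layer, "gene_id"])
            selected = set(lc.table.loc[lc.table["selected"], "gene_id"])
            # n_sel = 3 of 3000 genes; all should be planted (folds 15-25)
            assert selected <= planted

    def test_single_layer_table(self):
        t = pd.DataFrame([_row("g1", "s1", "op_a", "CP", 5.0),
                          _row("g1", "s1", "ins", "CP", 1.0),
                          _row("g2", "s1", "op_a", "CP", 1.0),
                          _row("g2", "s1", "ins", "CP", 1.0)])
        result = contrast_report(t, CFG)
        assert list(result.layers) == ["CP"]
        assert len(result.warnings) == 3  # SG, MZ, SP skipped explicitly

    def test_no_signal_cutoff_near_unity(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:04d}" for i in range(2000)]
        rows = []
        for g in genes:
            for region in ("op_a", "ins"):
                rows.append(_row(g, "s1", region, "SG", 7.0))
        result = contrast_report(pd.DataFrame(rows), CFG)
        lc = result.layers["SG"]
        assert 0.8 <= lc.cutoff_fold <= 1.3
        # all-equal folds: deterministic lexicographic head is selected
        sel = list(lc.table.loc[lc.table["selected"], "gene_id"])
        assert sel == sorted(genes)[: lc.n_selected]

    def test_report_csv_sorted_by_layer_then_fold(self, tmp_path, expression_small):
        from morphogrowth import io as mio

        spec, table, _ = expression_small
        cfg = RegionSetConfig(target_structures=spec.target_regions,
                              contrast_structures=spec.contrast_regions)
        result = contrast_report(table, cfg)
        path = tmp_path / "report.csv"
        mio.write_contrast_report(result, path)
        out = pd.read_csv(path)
        layer_order = [l for l in ["SG", "MZ", "CP", "SP"] if l in set(out["layer"])]
        assert list(out["layer"].unique()) == layer_order
        for layer in layer_order:
            folds = out.loc[out["layer"] == layer, "fold_change"].to_numpy()
            assert (np.diff(folds) <= 0).all()
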