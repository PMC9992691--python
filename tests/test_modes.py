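import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hichipnet.modes import (
    MODE_MAP,
    assign_modes,
    assign_tf_targets,
    boundary_crossing_report,
    crosses_boundary,
    fisher_enrichment_p,
    mode_expression_test,
    region_set_enrichment,
)
from hichipnet.annotation import RegulatoryElements
from hichipnet.validation import hypergeom_oracle_p


def _annotations():
    return pd.DataFrame(
        {"chrom": ["chr1"] * 4,
         "bin": [100, 110, 120, 130],
         "label": ["promoter", "enhancer", "promoter", "enhancer"],
         "gene_ids": ["gA", "", "gB;gC", ""],
         "se_flag": [False, False, False, True]}
    )


def _anchor_classes(cls110="inducible", cls130="repressed"):
    return pd.DataFrame(
        {"chrom": ["chr1"] * 4, "bin": [100, 110, 120, 130],
         "diff_class": ["unclassified", cls110, "unclassified", cls130]}
    )


class TestAssignModes:
    @pytest.mark.parametrize(
        "loop_class,enh_class,mode",
        [("gained", "inducible", "i"), ("constant", "inducible", "ii"),
         ("gained", "constitutive", "iii"), ("lost", "constitutive", "iv"),
         ("constant", "repressed", "v"), ("lost", "repressed", "vi"),
         ("constant", "constitutive", "control")],
    )
    def test_mode_map(self, loop_class, enh_class, mode):
        loops = pd.DataFrame({"loop_id": ["L1"], "chrom": ["chr1"], "bin1": [100],
                              "bin2": [110], "diff_class": [loop_class]})
        out = assign_modes(loops, _annotations(), _anchor_classes(cls110=enh_class))
        assert list(out["mode"]) == [mode]
        assert list(out["gene_id"]) == ["gA"]

    def test_unmapped_combination_skipped(self):
        loops = pd.DataFrame({"loop_id": ["L1"], "chrom": ["chr1"], "bin1": [100],
                              "bin2": [110], "diff_class": ["gained"]})
        out = assign_modes(loops, _annotations(), _anchor_classes(cls110="repressed"))
        assert len(out) == 0

    def test_loop_without_promoter_anchor_skipped(self):
        loops = pd.DataFrame({"loop_id": ["L1"], "chrom": ["chr1"], "bin1": [110],
                              "bin2": [130], "diff_class": ["gained"]})
        out = assign_modes(loops, _annotations(), _anchor_classes(cls130="inducible"))
        assert len(out) == 0

    def test_multi_gene_promoter_anchor_fans_out(self):
        loops = pd.DataFrame({"loop_id": ["L1"], "chrom": ["chr1"], "bin1": [120],
                              "bin2": [130], "diff_class": ["lost"]})
        out = assign_modes(loops, _annotations(), _anchor_classes(cls130="repressed"))
        assert sorted(out["gene_id"]) == ["gB", "gC"]
        assert set(out["mode"]) == {"vi"}

    def test_order_invariance(self):
        loops = pd.DataFrame({"loop_id": ["L1", "L2"], "chrom": ["chr1"] * 2,
                              "bin1": [100, 120], "bin2": [110, 130],
                              "diff_class": ["gained", "lost"]})
        a = assign_modes(loops, _annotations(), _anchor_classes())
        b = assign_modes(loops.iloc[::-1].reset_index(drop=True), _annotations(),
                         _anchor_classes())
        pd.testing.assert_frame_equal(
            a.sort_values("loop_id").reset_index(drop=True),
            b.sort_values("loop_id").reset_index(drop=True),
        )


class TestModeExpression:
    def _assignments(self, genes_by_mode):
        rows = []
        for mode, genes in genes_by_mode.items():
            for k, g in enumerate(genes):
                rows.append((g, f"L_{mode}_{k}", "chr1", 0, "x", "y", mode))
        return pd.DataFrame(rows, columns=["gene_id", "loop_id", "chrom", "distal_bin",
                                           "loop_diff_class", "enhancer_diff_class", "mode"])

    def test_mode_equal_to_control_gives_p_one(self):
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        de = pd.DataFrame({"log2fc": rng.normal(0, 1, 12)}, index=genes)
        out = mode_expression_test(self._assignments({"i": genes, "control": genes}), de)
        row = out.set_index("mode").loc["i"]
        assert row["p_vs_control"] == pytest.approx(1.0)

    def test_planted_shift_detected_and_matches_welch_oracle(self):
        rng = np.random.default_rng(1)
        mode_genes = [f"m{i}" for i in range(30)]
        ctrl_genes = [f"c{i}" for i in range(30)]
        lfc = pd.concat([
            pd.Series(rng.normal(1.0, 0.3, 30), index=mode_genes),
            pd.Series(rng.normal(0.0, 0.3, 30), index=ctrl_genes),
        ])
        de = pd.DataFrame({"log2fc": lfc})
        out = mode_expression_test(
            self._assignments({"i": mode_genes, "control": ctrl_genes}), de
        ).set_index("mode")
        t_oracle, p_oracle = stats.ttest_ind(
            lfc[mode_genes], lfc[ctrl_genes], equal_var=False
        )
        assert out.loc["i", "t"] == pytest.approx(t_oracle)
        assert out.loc["i", "p_vs_control"] == pytest.approx(p_oracle)
        assert out.loc["i", "t"] > 0 and out.loc["i", "p_vs_control"] < 0.01

    def test_genes_deduplicated_within_mode(self):
        genes = ["g1", "g1", "g2"]
        de = pd.DataFrame({"log2fc": [1.0, 2.0]}, index=["g1", "g2"])
        out = mode_expression_test(
            self._assignments({"ii": genes, "control": ["g1", "g2"]}), de
        ).set_index("mode")
        assert out.loc["ii", "n"] == 2


class TestCrossesBoundary:
    def test_strictly_between_is_true(self):
        assert crosses_boundary([10], [20], [15])[0]

    def test_boundary_at_anchor_bin_is_false(self):
        assert not crosses_boundary([10], [20], [10])[0]
        assert not crosses_boundary([10], [20], [20])[0]

    def test_no_boundaries(self):
        assert not crosses_boundary([10], [20], [])[0]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(1, 100), st.lists(st.integers(0, 600), max_size=8))
    def test_matches_exhaustive_containment(self, b1, d, bounds):
        b2 = b1 + d
        fast = bool(crosses_boundary([b1], [b2], bounds)[0])
        assert fast == any(b1 < b < b2 for b in bounds)


class TestBoundaryCrossingReport:
    def test_no_boundaries_fraction_zero_and_sums_to_one(self):
        loops = pd.DataFrame({"loop_id": ["L1", "L2"], "chrom": ["chr1"] * 2,
                              "bin1": [100, 120], "bin2": [110, 130]})
        table, summary = boundary_crossing_report(
            loops, pd.DataFrame({"chrom": [], "bin": []}), None, _annotations()
        )
        assert summary["fraction_across"] == 0.0
        assert summary["fraction_across"] + summary["fraction_within"] == 1.0

    def test_crossing_flag_and_de_classes(self):
        loops = pd.DataFrame({"loop_id": ["L1", "L2"], "chrom": ["chr1"] * 2,
                              "bin1": [100, 120], "bin2": [110, 130]})
        boundaries = pd.DataFrame({"chrom": ["chr1"], "bin": [105]})
        de = pd.DataFrame({"de_class": ["up", "down", "unchanged"]},
                          index=["gA", "gB", "gC"])
        table, summary = boundary_crossing_report(loops, boundaries, de, _annotations())
        assert summary["n_across"] == 1 and summary["n_within"] == 1
        assert summary["genes_across_up"] == 1
        assert summary["genes_within_down"] == 1


class TestTfTargets:
    def _elements(self):
        promoters = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                  "start": [997_500, 1_997_500],
                                  "end": [1_002_500, 2_002_500],
                                  "gene_id": ["gP", "gD"]})
        enhancers = pd.DataFrame({"chrom": ["chr1"], "start": [2_105_000],
                                  "end": [2_106_000], "name": ["e"], "signal": [5.0]})
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        stitched = enhancers.assign(is_se=False)[["chrom", "start", "end", "signal", "is_se"]]
        return RegulatoryElements(promoters, enhancers, stitched, empty)

    def _annotations(self):
        return pd.DataFrame({"chrom": ["chr1"] * 3, "bin": [100, 200, 210],
                             "label": ["promoter", "promoter", "enhancer"],
                             "gene_ids": ["gP", "gD", ""], "se_flag": False})

    def test_three_classes(self):
        tf = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [1_000_000, 2_105_200],
                           "end": [1_000_400, 2_105_600], "name": ["t1", "t2"],
                           "signal": [9.0, 9.0]})
        loops = pd.DataFrame({"chrom": ["chr1"], "bin1": [200], "bin2": [210]})
        out = assign_tf_targets(tf, self._elements(), loops, self._annotations())
        classes = out.set_index("gene_id")["tf_class"]
        assert classes["gP"] == "promoter_only"
        assert classes["gD"] == "distal_only"

    def test_promoter_and_distal(self):
        tf = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [2_000_000, 2_105_200],
                           "end": [2_000_400, 2_105_600], "name": ["t1", "t2"],
                           "signal": [9.0, 9.0]})
        loops = pd.DataFrame({"chrom": ["chr1"], "bin1": [200], "bin2": [210]})
        out = assign_tf_targets(tf, self._elements(), loops, self._annotations())
        assert out.set_index("gene_id")["tf_class"]["gD"] == "promoter_and_distal"

    def test_unlooped_enhancer_binding_is_not_distal(self):
        tf = pd.DataFrame({"chrom": ["chr1"], "start": [2_105_200], "end": [2_105_600],
                           "name": ["t2"], "signal": [9.0]})
        loops = pd.DataFrame({"chrom": [], "bin1": [], "bin2": []})
        out = assign_tf_targets(tf, self._elements(), loops, self._annotations())
        assert len(out) == 0


def intervals(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestRegionSetEnrichment:
    def test_query_equals_universe_p_one(self):
        universe = intervals([("chr1", i * 1000, i * 1000 + 500) for i in range(30)])
        reference = intervals([("chr1", i * 1000, i * 1000 + 500) for i in range(10)])
        odds, p, table = region_set_enrichment(universe, reference, universe)
        assert p == pytest.approx(1.0)

    def test_spec_table_matches_hypergeometric_tail(self):
        # table (a, b, c, d) = (20, 10, 5, 65)
        p = fisher_enrichment_p(20, 10, 5, 65)
        assert p == pytest.approx(hypergeom_oracle_p(20, 10, 5, 65), abs=1e-14)
        _, p_scipy = stats.fisher_exact([[20, 10], [5, 65]], alternative="greater")
        assert p == pytest.approx(p_scipy, rel=1e-9)

    def test_disjoint_query_is_depleted(self):
        universe = intervals([("chr1", i * 1000, i * 1000 + 500) for i in range(40)])
        reference = intervals([("chr1", i * 1000, i * 1000 + 500) for i in range(30)])
        query = intervals([("chr1", i * 1000, i * 1000 + 500) for i in range(30, 40)])
        odds, p, table = region_set_enrichment(query, reference, universe)
        assert odds < 1.0
        assert p > 0.5

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_fisher_p_matches_oracle_property(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_enrichment_p(a, b, c, d) == pytest.approx(
            hypergeom_oracle_p(a, b, c, d), abs=1e-12
        )
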