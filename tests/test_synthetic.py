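import numpy as np
import pandas as pd
import pytest

from hichipnet.synthetic import (
    TruthTable,
    generate_genome,
    generate_hic,
    generate_hichip,
    generate_peaks,
    generate_rna_counts,
    nb_sample,
    plant_truth,
)

from conftest import make_truth_frames


class TestGenerateGenome:
    def test_spacing_and_uniqueness(self):
        g = generate_genome(1, 30_000_000, 100, seed=1)
        tss = np.sort(g.genes["tss"].to_numpy())
        assert len(g.genes) == 100
        assert g.genes["gene_id"].is_unique
        assert np.diff(tss).min() >= 30_000

    def test_deterministic(self):
        a = generate_genome(1, 30_000_000, 100, seed=1)
        b = generate_genome(1, 30_000_000, 100, seed=1)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_infeasible_spacing_raises(self):
        with pytest.raises(ValueError):
            generate_genome(1, 5_000_000, 10_000, seed=1)

    def test_short_chromosome_raises(self):
        with pytest.raises(ValueError):
            generate_genome(1, 1_000_000, 10, seed=1)


class TestGenerateHic:
    def test_pure_decay_decreasing(self, genome):
        m = generate_hic(genome, [], noise="none", tad_enrichment=3.0)
        row = m.counts[0, 1:200]
        assert (np.diff(row) < 0).all()

    def test_tad_block_ratio(self, genome):
        n = genome.n_bins(genome.chrom_names[0])
        b = n // 2
        m = generate_hic(genome, [b], tad_enrichment=3.0, seed=3)
        base = generate_hic(genome, [b], tad_enrichment=3.0, noise="none")
        within = (base.counts[:b, :b].sum() + base.counts[b:, b:].sum())
        # compare empirical within/between means against the planted 3x ratio
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        decay = np.maximum(d, 1) ** -1.0
        same = np.zeros((n, n), dtype=bool)
        same[:b, :b] = same[b:, b:] = True
        far = (d >= 5) & (d <= 50)
        ratio = (m.counts[same & far].mean() / decay[same & far].mean()) / (
            m.counts[~same & far].mean() / decay[~same & far].mean()
        )
        assert ratio == pytest.approx(3.0, rel=0.1)
        assert within > 0  # planted enrichment present in the expectation

    def test_symmetry_and_integer_counts(self, genome):
        m = generate_hic(genome, [100], seed=4)
        assert np.array_equal(m.counts, m.counts.T)
        assert (m.counts >= 0).all()
        assert np.array_equal(m.counts, np.round(m.counts))

    def test_boundary_out_of_range(self, genome):
        with pytest.raises(ValueError):
            generate_hic(genome, [10**6], seed=0)

    @pytest.mark.parametrize("kw", [dict(decay_exponent=0.5), dict(tad_enrichment=0.5)])
    def test_invalid_parameters(self, genome, kw):
        with pytest.raises(ValueError):
            generate_hic(genome, [], **kw)


class TestGenerateHichip:
    def _truth_with_loops(self, loops):
        return TruthTable(**make_truth_frames(loops=loops))

    def test_deterministic(self, genome, truth):
        t1 = generate_hichip(genome, truth, seed=9)
        t2 = generate_hichip(genome, truth, seed=9)
        for cond in ("A", "B"):
            pd.testing.assert_frame_equal(t1[cond], t2[cond])

    def test_null_multiplier_equal_conditions(self, genome):
        loops = pd.DataFrame(
            {"loop_id": ["L1"], "chrom": [genome.chrom_names[0]], "bin1": [500],
             "bin2": [510], "base_strength": [20.0], "mult_a": [1.0], "mult_b": [1.0],
             "loop_class": ["constant"], "dispersion": [0.05], "gene_id": [""],
             "crosses_boundary": [False]}
        )
        tables = generate_hichip(genome, self._truth_with_loops(loops), n_replicates=6, seed=5)
        means = {}
        for cond in ("A", "B"):
            row = tables[cond].set_index(["bin1", "bin2"]).loc[(500, 510)]
            means[cond] = row[[c for c in row.index if c.startswith("count")]].mean()
        assert means["A"] == pytest.approx(means["B"], rel=0.35)

    def test_planted_multiplier_vs_matched_distance_background(self, genome):
        # a 4x loop should sit ~4x above the mean of same-distance background pairs
        loops = pd.DataFrame(
            {"loop_id": ["L1"], "chrom": [genome.chrom_names[0]], "bin1": [500],
             "bin2": [510], "base_strength": [4.0], "mult_a": [1.0], "mult_b": [1.0],
             "loop_class": ["constant"], "dispersion": [0.01], "gene_id": [""],
             "crosses_boundary": [False]}
        )
        tables = generate_hichip(genome, self._truth_with_loops(loops), n_replicates=4,
                                 library_size=2_000_000, seed=6)
        df = tables["A"]
        cols = [c for c in df.columns if c.startswith("count")]
        pooled = df[cols].sum(axis=1)
        loop_idx = df.index[(df.bin1 == 500) & (df.bin2 == 510)][0]
        same_d_idx = df.index[(df.bin2 - df.bin1) == 10].drop(loop_idx)
        background = pooled.loc[same_d_idx].mean()
        assert pooled.loc[loop_idx] / background == pytest.approx(4.0, rel=0.5)

    def test_span_validation(self, genome):
        loops = pd.DataFrame(
            {"loop_id": ["L1"], "chrom": [genome.chrom_names[0]], "bin1": [500],
             "bin2": [501], "base_strength": [4.0], "mult_a": [1.0], "mult_b": [1.0],
             "loop_class": ["constant"], "dispersion": [0.0], "gene_id": [""],
             "crosses_boundary": [False]}
        )
        with pytest.raises(ValueError):
            TruthTable(**make_truth_frames(loops=loops))

    def test_counts_are_nonnegative_integers(self, genome, truth):
        tables = generate_hichip(genome, truth, seed=2)
        for df in tables.values():
            cols = [c for c in df.columns if c.startswith("count")]
            assert (df[cols].to_numpy() >= 0).all()
            assert np.array_equal(df[cols].to_numpy(), np.round(df[cols].to_numpy()))


class TestGeneratePeaks:
    def test_constitutive_ratio_within_constant_band(self, genome, truth):
        pa = generate_peaks(genome, truth, "A", seed=1).set_index("name")["signal"]
        pb = generate_peaks(genome, truth, "B", seed=2).set_index("name")["signal"]
        const = truth.enhancers[truth.enhancers["enh_class"] == "constitutive"]["enh_id"]
        ratio = np.log2(pb.loc[const].to_numpy() / pa.loc[const].to_numpy())
        assert (np.abs(ratio) < 0.378512).all()

    def test_inducible_ratio_near_planted(self, genome, truth):
        pa = generate_peaks(genome, truth, "A", seed=1).set_index("name")["signal"]
        pb = generate_peaks(genome, truth, "B", seed=2).set_index("name")["signal"]
        ind = truth.enhancers[truth.enhancers["enh_class"] == "inducible"]
        planted = np.log2(ind["signal_b"].to_numpy() / ind["signal_a"].to_numpy())
        observed = np.log2(pb.loc[ind["enh_id"]].to_numpy() / pa.loc[ind["enh_id"]].to_numpy())
        assert observed == pytest.approx(planted, abs=0.3)

    @pytest.mark.parametrize("kind", ["h3k27ac", "ctcf", "tf"])
    def test_intervals_within_bounds_and_sorted(self, genome, truth, kind):
        p = generate_peaks(genome, truth, "A", seed=0, kind=kind)
        for chrom, sub in p.groupby("chrom"):
            assert (sub["start"] >= 0).all()
            assert (sub["end"] <= genome.chrom_lengths[chrom]).all()
            assert sub["start"].is_monotonic_increasing
        assert (p["signal"] >= 0).all()

    def test_unknown_kind_raises(self, genome, truth):
        with pytest.raises(ValueError):
            generate_peaks(genome, truth, "A", seed=0, kind="nope")


class TestGenerateRna:
    def test_control_genes_near_zero_lfc(self, genome, truth):
        counts = generate_rna_counts(genome, truth, n_replicates=6, seed=3)
        controls = truth.gene_modes[truth.gene_modes["mode"] == "control"]["gene_id"]
        a = counts.loc[controls, [c for c in counts if c.startswith("A_")]].mean(axis=1)
        b = counts.loc[controls, [c for c in counts if c.startswith("B_")]].mean(axis=1)
        assert np.log2(b / a).mean() == pytest.approx(0.0, abs=0.15)

    def test_planted_lfc_recovered_at_large_n(self, genome):
        gm = pd.DataFrame({"gene_id": [genome.genes["gene_id"].iloc[0]],
                           "mode": ["iii"], "log2fc": [1.0]})
        truth = TruthTable(**make_truth_frames(gene_modes=gm))
        counts = generate_rna_counts(genome, truth, n_replicates=60, seed=4)
        row = counts.iloc[0]
        a = row[[c for c in counts if c.startswith("A_")]].mean()
        b = row[[c for c in counts if c.startswith("B_")]].mean()
        assert np.log2(b / a) == pytest.approx(1.0, abs=0.2)

    def test_deterministic(self, genome, truth):
        c1 = generate_rna_counts(genome, truth, seed=7)
        c2 = generate_rna_counts(genome, truth, seed=7)
        pd.testing.assert_frame_equal(c1, c2)


class TestTruthTable:
    def test_round_trip(self, truth, tmp_path):
        truth.to_dir(tmp_path / "t")
        back = TruthTable.from_dir(tmp_path / "t")
        for attr in ("boundaries", "loops", "enhancers", "gene_modes", "ctcf_sites",
                     "tf_sites", "tf_targets"):
            a, b = getattr(truth, attr), getattr(back, attr)
            pd.testing.assert_frame_equal(
                a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False
            )

    def test_mode_wiring_consistency(self, truth):
        # a mode-i gene must be wired to a gained loop and an inducible enhancer
        loops = truth.loops.set_index("gene_id")
        enh = truth.enhancers.set_index("gene_id")
        for g in truth.gene_modes[truth.gene_modes["mode"] == "i"]["gene_id"]:
            assert loops.loc[g, "mult_b"] > loops.loc[g, "mult_a"]
            assert enh.loc[g, "signal_b"] > 1.3 * enh.loc[g, "signal_a"]

    def test_plant_truth_needs_enough_genes(self, genome):
        with pytest.raises(ValueError):
            plant_truth(genome, genes_per_mode=100)


def test_nb_sample_moments():
    rng = np.random.default_rng(0)
    x = nb_sample(rng, np.full(200_000, 50.0), 0.1)
    assert x.mean() == pytest.approx(50.0, rel=0.02)
    assert x.var() == pytest.approx(50 + 0.1 * 2500, rel=0.05)
    y = nb_sample(rng, np.full(100_000, 50.0), 0.0)  # Poisson limit
    assert y.var() == pytest.approx(50.0, rel=0.05)
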