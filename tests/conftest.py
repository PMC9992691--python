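import numpy as np
import pandas as pd
import pytest

from hichipnet.matrix import ContactMatrix
from hichipnet.pipeline import PipelineConfig, run_all
from hichipnet.synthetic import GenomeModel, generate_genome, plant_truth


@pytest.fixture(scope="session")
def genome():
    return generate_genome(n_chroms=1, chrom_length=20_000_000, n_genes=120, seed=11)


@pytest.fixture(scope="session")
def truth(genome):
    return plant_truth(genome, n_boundaries=4, genes_per_mode=10, seed=12)


@pytest.fixture
def two_block_matrix():
    """Noise-free two-block contact matrix: contacts 10 within blocks, 1 across."""
    n = 200
    counts = np.ones((n, n))
    counts[:100, :100] = 10.0
    counts[100:, 100:] = 10.0
    return ContactMatrix("chr1", 10_000, counts)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on a reduced configuration, shared across tests."""
    outdir = tmp_path_factory.mktemp("demo_pipeline")
    cfg = PipelineConfig(
        seed=5, chrom_length=12_000_000, n_genes=90, n_boundaries=3,
        genes_per_mode=5, n_filler_loops=80, n_cross_loops=4, n_tf_per_class=4,
        hichip_library_size=250_000,
    )
    report = run_all(cfg, outdir)
    return cfg, outdir, report


def make_truth_frames(**overrides):
    """Empty truth-table frames, overridable per test."""
    frames = {
        "boundaries": pd.DataFrame(columns=["chrom", "bin"]),
        "loops": pd.DataFrame(columns=["loop_id", "chrom", "bin1", "bin2", "base_strength",
                                       "mult_a", "mult_b", "loop_class", "dispersion",
                                       "gene_id", "crosses_boundary"]),
        "enhancers": pd.DataFrame(columns=["enh_id", "chrom", "start", "end", "signal_a",
                                           "signal_b", "enh_class", "dispersion", "gene_id"]),
        "gene_modes": pd.DataFrame(columns=["gene_id", "mode", "log2fc"]),
    }
    frames.update(overrides)
    return frames
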