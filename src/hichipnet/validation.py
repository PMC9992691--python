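"""Recovery and calibration experiments on planted-truth synthetic data.

Each experiment regenerates its inputs from a seed, runs the relevant part
of the package and measures how well the planted truth is recovered (or how
well a null is controlled).  They are used both by the test suite and by the
acceptance script.
"""

from __future__ import annotations

import math
import tempfile

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import synthetic as syn
from .differential import nb_wald
from .loops import call_loops
from .matrix import call_boundaries, insulation_score
from .modes import crosses_boundary, fisher_enrichment_p
from .network import build_clique_graph, clique_connectivity, louvain_communities


def boundary_recovery_experiment(
    seed: int = 0,
    chrom_length: int = 30_000_000,
    n_boundaries: int = 5,
    tad_enrichment: float = 3.0,
    margin: int = 3,
) -> dict:
    """Plant evenly spaced boundaries, call them back from a noisy matrix."""
    genome = syn.generate_genome(1, chrom_length, n_genes=1, seed=seed)
    n = genome.n_bins(genome.chrom_names[0])
    planted = [int(round(j * n / (n_boundaries + 1))) for j in range(1, n_boundaries + 1)]
    m = syn.generate_hic(genome, planted, tad_enrichment=tad_enrichment, seed=seed + 1)
    prof = insulation_score(m)
    calls = call_boundaries(prof)
    called = calls["bin"].to_numpy()
    recovered = sum(any(abs(b - c) <= margin for c in called) for b in planted)
    spurious = sum(all(abs(c - b) > margin for b in planted) for c in called)
    max_offset = max(
        (min(abs(b - c) for c in called) for b in planted), default=np.inf
    ) if len(called) else np.inf
    return {
        "recall": recovered / n_boundaries,
        "n_spurious": int(spurious),
        "n_called": int(len(called)),
        "max_offset_bins": float(max_offset),
    }


def null_calibration_experiment(
    seed: int = 0,
    n_features: int = 2000,
    mean: float = 200.0,
    dispersion: float = 0.1,
    n_reps: int = 2,
) -> dict:
    """Fraction of null NB features with p < 0.05 (should sit near 0.05)."""
    rng = np.random.default_rng(seed)
    mu = np.full(n_features, mean)
    A = np.column_stack([syn.nb_sample(rng, mu, dispersion) for _ in range(n_reps)])
    B = np.column_stack([syn.nb_sample(rng, mu, dispersion) for _ in range(n_reps)])
    res = nb_wald(A, B, size_factors=np.ones(2 * n_reps))
    return {"fraction_p_below_0.05": float((res["p"] < 0.05).mean()), "n": n_features}


def de_power_experiment(
    seed: int = 0,
    n_features: int = 2000,
    mean: float = 200.0,
    fold: float = 2.0,
    dispersion: float = 0.1,
    n_reps: int = 3,
) -> dict:
    """Fraction of planted ``fold``-change features recovered at BH FDR 0.05."""
    rng = np.random.default_rng(seed)
    mu = np.full(n_features, mean)
    A = np.column_stack([syn.nb_sample(rng, mu, dispersion) for _ in range(n_reps)])
    B = np.column_stack([syn.nb_sample(rng, mu * fold, dispersion) for _ in range(n_reps)])
    res = nb_wald(A, B, size_factors=np.ones(2 * n_reps))
    padj = multipletests(res["p"], method="fdr_bh")[1]
    return {"power": float((padj < 0.05).mean()), "n": n_features}


def _loop_recovery_once(seed: int, n_loops: int, strength: float, library_size: int,
                        chrom_length: int, fdr: float) -> tuple:
    genome = syn.generate_genome(1, chrom_length, n_genes=1, seed=seed)
    chrom = genome.chrom_names[0]
    n = genome.n_bins(chrom)
    rng = np.random.default_rng(seed + 7)
    pairs = set()
    while len(pairs) < n_loops:
        b1 = int(rng.integers(10, n - 20))
        d = int(rng.integers(3, 16))  # 30-150 kb spans
        pairs.add((b1, b1 + d))
    pairs = sorted(pairs)
    loops = pd.DataFrame(
        {
            "loop_id": [f"T{k}" for k in range(len(pairs))],
            "chrom": chrom,
            "bin1": [p[0] for p in pairs],
            "bin2": [p[1] for p in pairs],
            "base_strength": strength,
            "mult_a": 1.0,
            "mult_b": 1.0,
            "loop_class": "constant",
            "dispersion": 0.1,
            "gene_id": "",
            "crosses_boundary": False,
        }
    )
    truth = syn.TruthTable(
        boundaries=pd.DataFrame(columns=["chrom", "bin"]),
        loops=loops,
        enhancers=pd.DataFrame(columns=["enh_id", "chrom", "start", "end", "signal_a",
                                        "signal_b", "enh_class", "dispersion", "gene_id"]),
        gene_modes=pd.DataFrame(columns=["gene_id", "mode", "log2fc"]),
    )
    tables = syn.generate_hichip(genome, truth, n_replicates=2,
                                 library_size=library_size, seed=seed + 13)
    calls = call_loops(tables["A"], fdr=fdr)
    called = set(map(tuple, calls[["bin1", "bin2"]].to_numpy()))
    planted = set(pairs)
    tp = len(called & planted)
    fp = len(called - planted)
    return tp, fp, len(planted)


def loop_recovery_experiment(
    seed: int = 0,
    n_seeds: int = 5,
    n_loops: int = 200,
    strength: float = 10.0,
    library_size: int = 300_000,
    chrom_length: int = 20_000_000,
    fdr: float = 1e-5,
) -> dict:
    """Recall and empirical FDR of the loop caller on 10x planted loops.

    Pooled over ``n_seeds`` independent simulations.
    """
    tp = fp = total = 0
    for k in range(n_seeds):
        t, f, n = _loop_recovery_once(seed + 1000 * k, n_loops, strength,
                                      library_size, chrom_length, fdr)
        tp += t
        fp += f
        total += n
    return {
        "recall": tp / total,
        "empirical_fdr": fp / max(tp + fp, 1),
        "n_called": tp + fp,
        "n_planted": total,
    }


def null_loop_experiment(
    seed: int = 0,
    n_seeds: int = 20,
    library_size: int = 60_000,
    chrom_length: int = 10_000_000,
    fdr: float = 1e-5,
) -> dict:
    """Fraction of background-only simulations yielding zero loop calls."""
    zero = 0
    for k in range(n_seeds):
        genome = syn.generate_genome(1, chrom_length, n_genes=1, seed=seed + k)
        truth = syn.TruthTable(
            boundaries=pd.DataFrame(columns=["chrom", "bin"]),
            loops=pd.DataFrame(columns=["loop_id", "chrom", "bin1", "bin2", "base_strength",
                                        "mult_a", "mult_b", "loop_class", "dispersion",
                                        "gene_id", "crosses_boundary"]),
            enhancers=pd.DataFrame(columns=["enh_id", "chrom", "start", "end", "signal_a",
                                            "signal_b", "enh_class", "dispersion", "gene_id"]),
            gene_modes=pd.DataFrame(columns=["gene_id", "mode", "log2fc"]),
        )
        tables = syn.generate_hichip(genome, truth, n_replicates=2,
                                     library_size=library_size, seed=seed + 31 * k + 5)
        calls = call_loops(tables["A"], fdr=fdr)
        zero += int(len(calls) == 0)
    return {"fraction_zero_call_runs": zero / n_seeds, "n_seeds": n_seeds}


def mode_recovery_experiment(seed: int = 1) -> dict:
    """Full pipeline on the default demo configuration; per-mode metrics."""
    from .pipeline import PipelineConfig, run_all

    with tempfile.TemporaryDirectory() as tmp:
        report = run_all(PipelineConfig(seed=seed), tmp)
    mm = report["mode_metrics"]
    p_vs_control = {d["mode"]: d["p_vs_control"] for d in report["mode_expression"]}
    mean_lfc = {d["mode"]: d["mean_log2fc"] for d in report["mode_expression"]}
    return {
        "min_precision": min(d["precision"] for d in mm.values()),
        "min_recall": min(d["recall"] for d in mm.values()),
        "per_mode": mm,
        "mean_lfc": mean_lfc,
        "p_vs_control": p_vs_control,
        "fraction_gained_across_boundary": report["fraction_gained_across_boundary"],
        "boundary_recall": report["boundary_recall"],
        "loop_recovery": report["loop_recovery"],
        "tf_class_agreement": report["tf_class_agreement"],
    }


def crossing_oracle_experiment(seed: int = 0, n_configs: int = 10_000) -> dict:
    """Agreement of the vectorised crossing test with exhaustive containment."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_configs):
        b1 = int(rng.integers(0, 990))
        b2 = b1 + int(rng.integers(2, min(200, 1000 - b1)))
        n_b = int(rng.integers(0, 6))
        bounds = sorted(rng.integers(0, 1000, size=n_b).tolist())
        fast = bool(crosses_boundary([b1], [b2], bounds)[0])
        slow = any(b1 < b < b2 for b in bounds)
        agree += int(fast == slow)
    return {"agreement": agree / n_configs, "n": n_configs}


def hypergeom_oracle_p(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive one-sided tail sum of the hypergeometric pmf (math.comb)."""
    n_total, k_succ, n_draw = a + b + c + d, a + c, a + b
    denom = math.comb(n_total, n_draw)
    hi = min(k_succ, n_draw)
    return sum(
        math.comb(k_succ, x) * math.comb(n_total - k_succ, n_draw - x) for x in range(a, hi + 1)
    ) / denom


def fisher_oracle_experiment(max_total: int = 50) -> dict:
    """Max |Fisher p - exhaustive hypergeometric tail| over all small tables."""
    tables = []
    for n in range(1, max_total + 1):
        for ab in range(n + 1):
            for a in range(ab + 1):
                for c in range(n - ab + 1):
                    tables.append((a, ab - a, c, n - ab - c))
    arr = np.array(tables)
    p_fast = fisher_enrichment_p(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
    max_diff = 0.0
    for (a, b, c, d), pf in zip(tables, p_fast):
        max_diff = max(max_diff, abs(pf - hypergeom_oracle_p(a, b, c, d)))
    return {"max_abs_diff": float(max_diff), "n_tables": len(tables)}


def _all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(graph: nx.Graph) -> float:
    """Maximum modularity over every partition of the nodes (<= 10 nodes)."""
    nodes = list(graph.nodes)
    if len(nodes) > 10:
        raise ValueError("exhaustive enumeration is limited to 10 nodes")
    best = -np.inf
    for part in _all_partitions(nodes):
        q = nx.community.modularity(graph, [set(p) for p in part])
        best = max(best, q)
    return float(best)


def louvain_test_graphs(seed: int = 0) -> dict:
    g1 = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])  # two triangles
    g2 = nx.path_graph(7)
    g3 = nx.complete_bipartite_graph(3, 3)
    g4 = nx.cycle_graph(8)
    g5 = nx.barbell_graph(3, 1)
    graphs = {"two_triangles": g1, "path7": g2, "k33": g3, "cycle8": g4, "barbell": g5}
    rng = np.random.default_rng(seed)
    for k in range(3):
        g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
        if g.number_of_edges():
            graphs[f"random{k}"] = g
    return graphs


def louvain_oracle_experiment(seed: int = 0) -> dict:
    """Louvain modularity vs the exhaustive optimum on small graphs, plus a
    brute-force recount of intra-community edges."""
    results = {}
    worst_ratio = 1.0
    connectivity_ok = True
    for name, g in louvain_test_graphs(seed).items():
        assignment, q = louvain_communities(g, seed=seed)
        best = exhaustive_best_modularity(g)
        ratio = 1.0 if best <= 1e-12 and q >= -1e-12 else q / best
        worst_ratio = min(worst_ratio, ratio)
        conn = clique_connectivity(g, assignment)
        brute = {}
        for u, v in g.edges:
            if assignment[u] == assignment[v]:
                brute[assignment[u]] = brute.get(assignment[u], 0) + 1
        for cid in conn:
            if conn[cid] != brute.get(cid, 0):
                connectivity_ok = False
        results[name] = {"louvain": q, "optimum": best, "ratio": ratio}
    return {"min_ratio": worst_ratio, "connectivity_exact": connectivity_ok,
            "per_graph": results}


def rose_worked_example() -> dict:
    """Nine unit-signal enhancers plus one outlier: exactly one super-enhancer."""
    from .annotation import stitch_super_enhancers

    enh = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(10) * 100_000,
            "end": np.arange(10) * 100_000 + 1000,
            "name": [f"e{k}" for k in range(10)],
            "signal": [1.0] * 9 + [100.0],
        }
    )
    stitched = stitch_super_enhancers(enh)
    se = stitched[stitched["is_se"]]
    return {"n_super_enhancers": int(len(se)),
            "se_signal": float(se["signal"].iloc[0]) if len(se) else np.nan}
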