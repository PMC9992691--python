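"""Virtual-4C track extraction and 3D-clique graph analysis.

A virtual-4C track projects genome-wide loop calls onto one viewpoint bin:
each bin in the window carries the -log10(Q) (or normalised contact count)
of the loop joining it to the viewpoint, 0 where no loop touches the
viewpoint.  The 3D-clique graph has loop anchors as vertices and significant
loops (-log10 Q >= 5 by default) as edges; cliques are Louvain communities
and a clique's connectivity is the number of edges connecting vertices
within it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class V4CTrack:
    chrom: str
    viewpoint_bin: int
    bin_size: int
    bins: np.ndarray
    values: np.ndarray
    mode: str


def virtual_4c(
    loops: pd.DataFrame,
    viewpoint: tuple,
    window: int = 1_000_000,
    mode: str = "neglog10q",
    bin_size: int = 10_000,
    chrom_length: int | None = None,
    library_sizes: np.ndarray | None = None,
) -> V4CTrack:
    """Extract a one-viewpoint track from a loop table.

    ``viewpoint`` is (chrom, position in bp); only loops with one anchor in
    the viewpoint's bin contribute, symmetrically in anchor order.  In
    ``counts`` mode the pooled replicate count is scaled to the mean
    replicate library size when ``library_sizes`` is given.
    """
    chrom, pos = viewpoint
    if pos < 0 or (chrom_length is not None and pos >= chrom_length):
        raise ValueError(f"viewpoint {pos} outside chromosome {chrom}")
    if mode not in ("neglog10q", "normalized_counts"):
        raise ValueError(f"unknown mode {mode!r}")
    vp_bin = int(pos) // bin_size
    w = window // bin_size
    bins = np.arange(max(0, vp_bin - w), vp_bin + w + 1)
    values = np.zeros(len(bins))
    sub = loops[(loops["chrom"] == chrom)]
    touching = sub[(sub["bin1"] == vp_bin) | (sub["bin2"] == vp_bin)]
    for L in touching.itertuples():
        other = L.bin2 if L.bin1 == vp_bin else L.bin1
        k = other - bins[0]
        if not 0 <= k < len(bins):
            continue
        if mode == "neglog10q":
            values[k] = L.neglog10q
        else:
            v = float(L.count)
            if library_sizes is not None:
                v *= np.mean(library_sizes) / np.sum(library_sizes)
            values[k] = v
    return V4CTrack(chrom, vp_bin, bin_size, bins, values, mode)


def build_clique_graph(
    loops: pd.DataFrame,
    neglog10q_min: float = 5.0,
    anchor_signal: dict | None = None,
) -> nx.Graph:
    """Anchor-loop graph with -log10 q edge weights above a threshold.

    Nodes are (chrom, bin) anchors of retained loops (isolated anchors are
    excluded by construction); node attribute ``signal`` carries the summed
    H3K27ac level of the anchor when provided.
    """
    g = nx.Graph()
    kept = loops[loops["neglog10q"] >= neglog10q_min]
    for L in kept.itertuples():
        u, v = (L.chrom, int(L.bin1)), (L.chrom, int(L.bin2))
        g.add_edge(u, v, weight=float(L.neglog10q))
    if anchor_signal:
        for n in g.nodes:
            g.nodes[n]["signal"] = float(anchor_signal.get(n, 0.0))
    return g


def louvain_communities(graph: nx.Graph, seed: int = 0, n_restarts: int = 8) -> tuple[dict, float]:
    """Louvain partition and its (weighted) modularity; seeded, reproducible.

    The greedy heuristic can land in poor local optima on small graphs, so
    the partition is taken from ``n_restarts`` runs with seeds derived from
    ``seed``, keeping the highest modularity (first winner on ties).
    """
    if graph.number_of_nodes() == 0:
        return {}, 0.0
    best_parts, best_q = None, -np.inf
    for k in range(max(n_restarts, 1)):
        parts = nx.community.louvain_communities(graph, weight="weight", seed=seed + k)
        q = nx.community.modularity(graph, parts, weight="weight")
        if q > best_q + 1e-12:
            best_parts, best_q = parts, q
    assignment = {}
    for cid, nodes in enumerate(sorted(best_parts, key=lambda s: sorted(s)[0])):
        for n in nodes:
            assignment[n] = cid
    return assignment, float(best_q)


def clique_connectivity(graph: nx.Graph, assignment: dict) -> dict:
    """Number of intra-community edges per community (cross edges excluded)."""
    conn: dict = {cid: 0 for cid in set(assignment.values())}
    for u, v in graph.edges:
        if assignment.get(u) == assignment.get(v) and assignment.get(u) is not None:
            conn[assignment[u]] += 1
    return conn
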