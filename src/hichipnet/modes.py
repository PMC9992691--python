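"""Regulatory-mode assignment and downstream integrative analyses.

A gene is wired to a distal enhancer through a loop between its promoter
anchor and an enhancer anchor; the joint dynamic of the loop
(gained/lost/constant) and the distal enhancer (inducible/repressed/
constitutive) defines six regulatory modes:

    (gained,   inducible)    -> i      gain of loop to activation-inducible enhancer
    (constant, inducible)    -> ii     preformed loop with activation-inducible enhancer
    (gained,   constitutive) -> iii    gain of loop to constitutive enhancer
    (lost,     constitutive) -> iv     loss of loop from constitutive enhancer
    (constant, repressed)    -> v      preformed loop with activation-repressed enhancer
    (lost,     repressed)    -> vi     loss of loop from activation-repressed enhancer
    (constant, constitutive) -> control

Other combinations stay unassigned.  The module also detects gained loops
that cross condition-A TAD boundaries, maps transcription-factor target
genes through loops, and performs Fisher region-set enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import RegulatoryElements, _build_trees, _overlaps

MODE_MAP = {
    ("gained", "inducible"): "i",
    ("constant", "inducible"): "ii",
    ("gained", "constitutive"): "iii",
    ("lost", "constitutive"): "iv",
    ("constant", "repressed"): "v",
    ("lost", "repressed"): "vi",
    ("constant", "constitutive"): "control",
}


def assign_modes(
    loops: pd.DataFrame,
    annotations: pd.DataFrame,
    anchor_enh_class: pd.DataFrame,
) -> pd.DataFrame:
    """Assign (gene, loop, distal enhancer) triplets to regulatory modes.

    ``loops`` needs loop_id, chrom, bin1, bin2 and diff_class; ``annotations``
    maps (chrom, bin) to label and gene_ids; ``anchor_enh_class`` maps
    (chrom, bin) to the enhancer-activity class.  Loops without exactly one
    promoter anchor and one enhancer anchor are skipped; a gene may carry one
    assignment per qualifying loop.
    """
    lab = annotations.set_index(["chrom", "bin"])
    ecl = anchor_enh_class.set_index(["chrom", "bin"])["diff_class"]
    rows = []
    for L in loops.itertuples():
        try:
            a1 = lab.loc[(L.chrom, L.bin1)]
            a2 = lab.loc[(L.chrom, L.bin2)]
        except KeyError:
            continue
        if a1["label"] == "promoter" and a2["label"] == "enhancer":
            prom, distal_bin = a1, L.bin2
        elif a2["label"] == "promoter" and a1["label"] == "enhancer":
            prom, distal_bin = a2, L.bin1
        else:
            continue
        enh_class = ecl.get((L.chrom, distal_bin), "unclassified")
        mode = MODE_MAP.get((L.diff_class, enh_class))
        if mode is None:
            continue
        for gene in str(prom["gene_ids"]).split(";"):
            if gene:
                rows.append((gene, L.loop_id, L.chrom, distal_bin, L.diff_class, enh_class, mode))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "loop_id", "chrom", "distal_bin", "loop_diff_class",
                 "enhancer_diff_class", "mode"],
    )


def mode_expression_test(assignments: pd.DataFrame, de_records: pd.DataFrame) -> pd.DataFrame:
    """Welch t-test of each mode's gene expression log2FC against control genes.

    Genes are deduplicated within each mode (a gene wired through several
    loops counts once per mode).  Returns one row per mode i..vi plus
    control with n, mean log2FC, t and the two-sided p versus control.
    """
    lfc = de_records["log2fc"]
    gene_sets = {
        m: sorted(set(assignments.loc[assignments["mode"] == m, "gene_id"]))
        for m in ["i", "ii", "iii", "iv", "v", "vi", "control"]
    }
    control_vals = lfc.reindex(gene_sets["control"]).dropna().to_numpy()
    rows = []
    for m in ["i", "ii", "iii", "iv", "v", "vi", "control"]:
        vals = lfc.reindex(gene_sets[m]).dropna().to_numpy()
        if m == "control":
            t_stat, p = np.nan, np.nan
        elif len(vals) >= 2 and len(control_vals) >= 2:
            t_stat, p = stats.ttest_ind(vals, control_vals, equal_var=False)
        else:
            t_stat, p = np.nan, np.nan
        rows.append((m, len(vals), float(vals.mean()) if len(vals) else np.nan, t_stat, p))
    return pd.DataFrame(rows, columns=["mode", "n", "mean_log2fc", "t", "p_vs_control"])


def crosses_boundary(bin1, bin2, boundary_bins) -> np.ndarray:
    """True where some boundary bin b satisfies bin1 < b < bin2 (strict).

    Vectorised over loops; a boundary falling inside an anchor bin does not
    separate the anchors.
    """
    b = np.sort(np.asarray(list(boundary_bins), dtype=int))
    b1 = np.atleast_1d(np.asarray(bin1, dtype=int))
    b2 = np.atleast_1d(np.asarray(bin2, dtype=int))
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    if len(b) == 0:
        return np.zeros(len(b1), dtype=bool)
    # count boundaries strictly inside (lo, hi)
    n_inside = np.searchsorted(b, hi - 1, side="right") - np.searchsorted(b, lo, side="right")
    return n_inside > 0


def boundary_crossing_report(
    gained_loops: pd.DataFrame,
    boundaries: pd.DataFrame,
    de_records: pd.DataFrame | None,
    annotations: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Fraction of gained enhancer-promoter loops crossing condition-A boundaries.

    Only loops connecting a promoter anchor to an enhancer anchor are
    counted.  All genes at the promoter anchor are tallied; their expression
    class (up/down/unchanged) comes from ``de_records`` when provided.
    """
    lab = annotations.set_index(["chrom", "bin"])
    rows = []
    for L in gained_loops.itertuples():
        try:
            a1 = lab.loc[(L.chrom, L.bin1)]
            a2 = lab.loc[(L.chrom, L.bin2)]
        except KeyError:
            continue
        labels = {a1["label"], a2["label"]}
        if labels != {"promoter", "enhancer"}:
            continue
        prom = a1 if a1["label"] == "promoter" else a2
        bb = boundaries.loc[boundaries["chrom"] == L.chrom, "bin"]
        crossing = bool(crosses_boundary([L.bin1], [L.bin2], bb)[0])
        for gene in str(prom["gene_ids"]).split(";"):
            if not gene:
                continue
            de_class = "unknown"
            if de_records is not None and gene in de_records.index:
                de_class = de_records.loc[gene, "de_class"]
            rows.append((L.loop_id, L.chrom, L.bin1, L.bin2, crossing, gene, de_class))
    df = pd.DataFrame(
        rows, columns=["loop_id", "chrom", "bin1", "bin2", "crosses_boundary", "gene_id", "de_class"]
    )
    loops_u = df.drop_duplicates("loop_id")
    n_across = int(loops_u["crosses_boundary"].sum())
    n_within = int((~loops_u["crosses_boundary"]).sum())
    total = n_across + n_within
    summary = {
        "n_across": n_across,
        "n_within": n_within,
        "fraction_across": n_across / total if total else 0.0,
        "fraction_within": n_within / total if total else 0.0,
    }
    for crossing, tag in ((True, "across"), (False, "within")):
        sub = df[df["crosses_boundary"] == crossing].drop_duplicates("gene_id")
        for cls in ("up", "down", "unchanged"):
            summary[f"genes_{tag}_{cls}"] = int((sub["de_class"] == cls).sum())
    return df, summary


def assign_tf_targets(
    tf_peaks: pd.DataFrame,
    elements: RegulatoryElements,
    loops: pd.DataFrame,
    annotations: pd.DataFrame,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Classify direct TF target genes by promoter vs looped distal binding.

    promoter_only: a TF peak at the gene promoter, no loop to a TF-bound
    enhancer anchor; promoter_and_distal: both; distal_only: no promoter
    peak but at least one loop connecting the gene's promoter anchor to a
    TF-bound enhancer anchor.
    """
    ttrees = _build_trees(tf_peaks)
    # promoter-bound genes
    promoter_bound = set()
    for p in elements.promoters.itertuples():
        if _overlaps(ttrees, p.chrom, p.start, p.end):
            promoter_bound.add(p.gene_id)
    # TF-bound enhancer anchors among loop anchors
    lab = annotations.set_index(["chrom", "bin"])
    distal_bound = set()
    for L in loops.itertuples():
        try:
            a1 = lab.loc[(L.chrom, L.bin1)]
            a2 = lab.loc[(L.chrom, L.bin2)]
        except KeyError:
            continue
        for prom, other, other_bin in ((a1, a2, L.bin2), (a2, a1, L.bin1)):
            if prom["label"] != "promoter" or other["label"] != "enhancer":
                continue
            start, end = int(other_bin) * bin_size, (int(other_bin) + 1) * bin_size
            if not _overlaps(ttrees, L.chrom, start, end):
                continue
            for gene in str(prom["gene_ids"]).split(";"):
                if gene:
                    distal_bound.add(gene)
    rows = []
    for gene in sorted(promoter_bound | distal_bound):
        if gene in promoter_bound and gene in distal_bound:
            cls = "promoter_and_distal"
        elif gene in promoter_bound:
            cls = "promoter_only"
        else:
            cls = "distal_only"
        rows.append((gene, cls))
    return pd.DataFrame(rows, columns=["gene_id", "tf_class"])


def fisher_enrichment_p(a, b, c, d):
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Equals the hypergeometric upper tail P(X >= a) with population a+b+c+d,
    a+c successes and a+b draws.  Vectorised over table cells.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    c = np.asarray(c, dtype=int)
    d = np.asarray(d, dtype=int)
    n_total = a + b + c + d
    p = stats.hypergeom.sf(a - 1, n_total, a + c, a + b)
    return float(p) if p.ndim == 0 else p


def region_set_enrichment(
    query_regions: pd.DataFrame,
    reference_set: pd.DataFrame,
    universe_regions: pd.DataFrame,
) -> tuple[float, float, tuple]:
    """One-sided Fisher enrichment of a reference region set within a query.

    Each universe region is scored for membership in the query (>= 1 bp
    overlap with any query region) and for overlap with the reference set;
    the resulting 2x2 table is tested with a one-sided (greater) Fisher
    exact test.  The odds ratio uses a Haldane 0.5 correction when any cell
    is zero.  Returns (odds_ratio, p, (a, b, c, d)).
    """
    qtrees = _build_trees(query_regions)
    rtrees = _build_trees(reference_set)
    in_q = np.array(
        [bool(_overlaps(qtrees, u.chrom, u.start, u.end)) for u in universe_regions.itertuples()]
    )
    in_r = np.array(
        [bool(_overlaps(rtrees, u.chrom, u.start, u.end)) for u in universe_regions.itertuples()]
    )
    a = int((in_q & in_r).sum())
    b = int((in_q & ~in_r).sum())
    c = int((~in_q & in_r).sum())
    d = int((~in_q & ~in_r).sum())
    p = fisher_enrichment_p(a, b, c, d)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p), (a, b, c, d)
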