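"""End-to-end pipeline: simulate -> matrices/peaks/counts -> loops ->
annotation -> differential -> modes/boundaries/targets -> v4c/cliques ->
summary, with a manifest of outputs and a recovery report against the
planted truth.

Stages communicate through plain-text files in the output directory so any
stage can be rerun in isolation; reruns with unchanged inputs reproduce
identical outputs for fixed seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import differential as diff
from . import io as hio
from . import loops as lp
from . import matrix as mx
from . import modes as md
from . import network as net
from . import synthetic as syn

log = logging.getLogger("hichipnet")

CONDITIONS = ("A", "B")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults mirror the analysis constants
    (10 kb bins, 20 kb-2 Mb spans, loop FDR 1e-5, log2FC bands 0.378512 /
    0.584963, promoters +/-2.5 kb, 12.5 kb stitching, insulation
    500 kb / 200 kb / 0.1 / 3)."""

    seed: int = 1
    # genome / truth
    n_chroms: int = 1
    chrom_length: int = 20_000_000
    bin_size: int = 10_000
    n_genes: int = 120
    n_boundaries: int = 4
    genes_per_mode: int = 10
    n_filler_loops: int = 150
    n_cross_loops: int = 6
    n_tf_per_class: int = 8
    base_strength: float = 25.0
    planted_dispersion: float = 0.0
    filler_dispersion: float = 0.1
    # Hi-C
    hic_diag_scale: float = 300.0
    tad_enrichment: float = 3.0
    decay_exponent: float = -1.0
    # HiChIP
    hichip_library_size: int = 400_000
    hichip_replicates: int = 2
    nb_dispersion: float = 0.1
    # peaks / RNA
    peak_replicates: int = 2
    rna_replicates: int = 3
    rna_base_mean: float = 200.0
    # loop calling
    loop_fdr: float = 1e-5
    min_loop_span: int = 20_000
    max_loop_span: int = 2_000_000
    # insulation
    insulation_window: int = 500_000
    insulation_delta_span: int = 200_000
    insulation_nt: float = 0.1
    insulation_bmoe: int = 3
    # compartments
    compartment_bin_size: int = 100_000
    # annotation
    promoter_halfwidth: int = 2500
    stitch_distance: int = 12_500
    # thresholds
    p_change: float = 0.1
    p_constant: float = 0.5
    lfc_constant_band: float = 0.378512
    lfc_loop_change: float = 0.584963
    lfc_enhancer_change: float = 0.378512
    rna_fdr: float = 0.05
    rna_fc_expression: float = 2.0
    rna_fc_crossing: float = 1.3
    # network
    v4c_window: int = 1_000_000
    clique_min_neglog10q: float = 5.0

    def __post_init__(self):
        if not 0 < self.loop_fdr < 1:
            raise PipelineError(f"loop_fdr must be in (0, 1), got {self.loop_fdr}")
        if not 0 < self.rna_fdr < 1:
            raise PipelineError(f"rna_fdr must be in (0, 1), got {self.rna_fdr}")
        if self.nb_dispersion < 0 or self.planted_dispersion < 0:
            raise PipelineError("dispersions must be non-negative")
        if self.min_loop_span >= self.max_loop_span:
            raise PipelineError("min_loop_span must be below max_loop_span")

    @property
    def thresholds(self) -> diff.ThresholdSet:
        return diff.ThresholdSet(
            p_change=self.p_change,
            p_constant=self.p_constant,
            lfc_constant_band=self.lfc_constant_band,
            lfc_loop_change=self.lfc_loop_change,
            lfc_enhancer_change=self.lfc_enhancer_change,
            rna_fdr=self.rna_fdr,
            rna_fc={"expression": self.rna_fc_expression, "crossing": self.rna_fc_crossing},
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, offset: int) -> int:
        return (self.seed * 1_000_003 + offset) % (2**31)


STAGES = [
    "simulate", "insulation", "compartments", "call-loops", "annotate",
    "diff-loops", "diff-anchors", "diff-expression", "modes", "boundaries",
    "tf-targets", "enrich", "v4c", "cliques", "summary",
]

#: files each stage requires before it can run, and the stage that makes them
PREREQS = {
    "insulation": [("hic_A.matrix.tsv", "simulate")],
    "compartments": [("hic_A.matrix.tsv", "simulate")],
    "call-loops": [("hichip_A.tsv", "simulate")],
    "annotate": [("loops_A.tsv", "call-loops")],
    "diff-loops": [("loops_A.tsv", "call-loops")],
    "diff-anchors": [("anchors.tsv", "annotate")],
    "diff-expression": [("rna_counts.tsv", "simulate")],
    "modes": [("diff_loops.tsv", "diff-loops"), ("diff_anchors.tsv", "diff-anchors"),
              ("diff_expression.tsv", "diff-expression")],
    "boundaries": [("diff_loops.tsv", "diff-loops"), ("boundaries_A.bed", "insulation")],
    "tf-targets": [("anchors.tsv", "annotate")],
    "enrich": [("diff_loops.tsv", "diff-loops"), ("anchors.tsv", "annotate")],
    "v4c": [("loops_A.tsv", "call-loops")],
    "cliques": [("loops_A.tsv", "call-loops"), ("anchors.tsv", "annotate")],
    "summary": [("mode_assignments.tsv", "modes"), ("boundary_crossing.json", "boundaries")],
}


def _check_prereqs(stage: str, outdir: Path) -> None:
    for fname, producer in PREREQS.get(stage, []):
        if not (outdir / fname).exists():
            raise PipelineError(
                f"stage '{stage}' needs {fname}; run stage '{producer}' first"
            )


def _load_genome(outdir: Path) -> syn.GenomeModel:
    return syn.GenomeModel.from_dir(outdir / "genome")


def _load_truth(outdir: Path) -> syn.TruthTable:
    return syn.TruthTable.from_dir(outdir / "truth")


def _load_matrix(outdir: Path, cond: str, genome: syn.GenomeModel) -> mx.ContactMatrix:
    counts = hio.read_dense_matrix(outdir / f"hic_{cond}.matrix.tsv")
    return mx.ContactMatrix(genome.chrom_names[0], genome.bin_size, counts)


def _peak_files(outdir: Path, cond: str, n_reps: int):
    return [outdir / f"peaks_h3k27ac_{cond}_rep{r + 1}.bed" for r in range(n_reps)]


def stage_simulate(config: PipelineConfig, outdir: Path) -> list:
    genome = syn.generate_genome(
        n_chroms=config.n_chroms, chrom_length=config.chrom_length,
        n_genes=config.n_genes, seed=config.stage_seed(1), bin_size=config.bin_size,
    )
    truth = syn.plant_truth(
        genome, n_boundaries=config.n_boundaries, genes_per_mode=config.genes_per_mode,
        n_filler_loops=config.n_filler_loops, n_cross_loops=config.n_cross_loops,
        n_tf_per_class=config.n_tf_per_class, base_strength=config.base_strength,
        planted_dispersion=config.planted_dispersion,
        filler_dispersion=config.filler_dispersion, seed=config.stage_seed(2),
    )
    genome.to_dir(outdir / "genome")
    truth.to_dir(outdir / "truth")
    outputs = []
    for k, cond in enumerate(CONDITIONS):
        m = syn.generate_hic(
            genome, truth.boundaries, decay_exponent=config.decay_exponent,
            tad_enrichment=config.tad_enrichment, seed=config.stage_seed(3 + k),
            diag_scale=config.hic_diag_scale,
        )
        path = outdir / f"hic_{cond}.matrix.tsv"
        hio.write_dense_matrix(m.counts, path)
        outputs.append(path)
    tables = syn.generate_hichip(
        genome, truth, n_replicates=config.hichip_replicates,
        library_size=config.hichip_library_size, dispersion=config.nb_dispersion,
        decay_exponent=config.decay_exponent, seed=config.stage_seed(5),
    )
    for cond in CONDITIONS:
        path = outdir / f"hichip_{cond}.tsv"
        hio.write_tsv(tables[cond], path)
        outputs.append(path)
    for k, cond in enumerate(CONDITIONS):
        for r in range(config.peak_replicates):
            peaks = syn.generate_peaks(
                genome, truth, condition=cond, seed=config.stage_seed(10 + 10 * k + r),
                kind="h3k27ac",
            )
            path = _peak_files(outdir, cond, config.peak_replicates)[r]
            hio.write_bed(peaks, path)
            outputs.append(path)
    for kind in ("ctcf", "tf"):
        peaks = syn.generate_peaks(genome, truth, condition="A",
                                   seed=config.stage_seed(30), kind=kind)
        path = outdir / f"peaks_{kind}.bed"
        hio.write_bed(peaks, path)
        outputs.append(path)
    rna = syn.generate_rna_counts(
        genome, truth, n_replicates=config.rna_replicates, seed=config.stage_seed(40),
        base_mean=config.rna_base_mean, dispersion=config.nb_dispersion,
    )
    path = outdir / "rna_counts.tsv"
    rna.to_csv(path, sep="\t")
    outputs.append(path)
    log.info("simulate: %d genes, %d planted loops, %d enhancers",
             len(genome.genes), len(truth.loops), len(truth.enhancers))
    return outputs


def stage_insulation(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    outputs = []
    calls = {}
    for cond in CONDITIONS:
        m = _load_matrix(outdir, cond, genome)
        prof = mx.insulation_score(m, window_b=config.insulation_window)
        bg = outdir / f"insulation_{cond}.bedgraph"
        hio.write_bedgraph(m.chrom, m.bin_size, prof.score, bg)
        b = mx.call_boundaries(
            prof, delta_span_ids=config.insulation_delta_span,
            nt=config.insulation_nt, bmoe=config.insulation_bmoe,
        )
        calls[cond] = b
        bed = outdir / f"boundaries_{cond}.bed"
        hio.write_bed(
            pd.DataFrame({
                "chrom": b["chrom"], "start": b["bin"] * m.bin_size,
                "end": (b["bin"] + 1) * m.bin_size,
                "name": [f"boundary_{cond}_{k + 1}" for k in range(len(b))],
                "signal": b["strength"],
            }),
            bed,
        )
        log.info("insulation %s: %d boundaries", cond, len(b))
        outputs += [bg, bed]
    _, summary = mx.boundary_strength_compare(calls["A"], calls["B"],
                                              match_margin=config.insulation_bmoe)
    path = outdir / "boundary_compare.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs.append(path)
    return outputs


def stage_compartments(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    outputs = []
    # orientation track: H3K27ac peak coverage per 100-kb bin (condition A, rep 1)
    peaks = hio.read_bed(_peak_files(outdir, "A", config.peak_replicates)[0])
    for cond in CONDITIONS:
        m = _load_matrix(outdir, cond, genome)
        n100 = -(-genome.chrom_lengths[m.chrom] // config.compartment_bin_size)
        track = np.zeros(n100)
        for p in peaks[peaks["chrom"] == m.chrom].itertuples():
            track[p.start // config.compartment_bin_size] += p.signal
        prof = mx.compartment_eigenvector(
            m, bin_size=config.compartment_bin_size, orient_track=track
        )
        path = outdir / f"eigenvector_{cond}.bedgraph"
        hio.write_bedgraph(m.chrom, config.compartment_bin_size, prof.eigenvector, path)
        outputs.append(path)
    return outputs


def stage_call_loops(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    outputs = []
    calls_by_cond = {}
    for cond in CONDITIONS:
        pairs = hio.read_tsv(outdir / f"hichip_{cond}.tsv")
        calls = lp.call_loops(
            pairs, fdr=config.loop_fdr, min_span=config.min_loop_span,
            max_span=config.max_loop_span, bin_size=genome.bin_size,
        )
        calls_by_cond[cond] = calls
        path = outdir / f"loops_{cond}.tsv"
        hio.write_tsv(calls, path)
        bedpe = outdir / f"loops_{cond}.bedpe"
        calls.attrs["bin_size"] = genome.bin_size
        hio.write_bedpe(calls, bedpe, extra_cols=["count", "expected", "p", "q", "neglog10q"])
        log.info("call-loops %s: %d significant of %d planted", cond, len(calls),
                 len(_load_truth(outdir).loops))
        outputs += [path, bedpe]
    qc = lp.loop_qc_summary(calls_by_cond)
    path = outdir / "loop_qc.tsv"
    hio.write_tsv(qc, path)
    outputs.append(path)
    return outputs


def _pooled_peaks(outdir: Path, config: PipelineConfig) -> pd.DataFrame:
    """Union of H3K27ac peak intervals with mean signal across replicates and
    conditions (element definitions are condition-independent here)."""
    frames = []
    for cond in CONDITIONS:
        for f in _peak_files(outdir, cond, config.peak_replicates):
            frames.append(hio.read_bed(f))
    allp = pd.concat(frames, ignore_index=True)
    return (
        allp.groupby(["chrom", "start", "end", "name"], as_index=False)["signal"]
        .mean()
        .sort_values(["chrom", "start", "end"])
        .reset_index(drop=True)
    )


def stage_annotate(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    peaks = _pooled_peaks(outdir, config)
    ctcf = hio.read_bed(outdir / "peaks_ctcf.bed")
    elements = ann.build_elements(
        genome.genes, peaks, ctcf, promoter_halfwidth=config.promoter_halfwidth,
        stitch=config.stitch_distance,
    )
    outputs = []
    for name, df in (("promoters", elements.promoters), ("enhancers", elements.enhancers),
                     ("ctcf_sites", elements.ctcf_sites)):
        path = outdir / f"elements_{name}.tsv"
        hio.write_tsv(df, path)
        outputs.append(path)
    path = outdir / "elements_stitched.tsv"
    hio.write_tsv(elements.stitched, path)
    outputs.append(path)

    frames = [hio.read_tsv(outdir / f"loops_{c}.tsv") for c in CONDITIONS]
    anchors = pd.concat(
        [f[["chrom", "bin1"]].rename(columns={"bin1": "bin"}) for f in frames]
        + [f[["chrom", "bin2"]].rename(columns={"bin2": "bin"}) for f in frames],
        ignore_index=True,
    ).drop_duplicates().sort_values(["chrom", "bin"]).reset_index(drop=True)
    annotated = ann.annotate_anchors(anchors, elements, bin_size=genome.bin_size)
    path = outdir / "anchors.tsv"
    hio.write_tsv(annotated, path)
    outputs.append(path)
    for cond, frame in zip(CONDITIONS, frames):
        classed = ann.classify_loops_by_elements(frame, annotated)
        path = outdir / f"loop_classes_{cond}.tsv"
        hio.write_tsv(classed, path)
        outputs.append(path)
        log.info("annotate %s: %s", cond, classed["loop_class"].value_counts().to_dict())
    return outputs


def _loop_universe(outdir: Path, config: PipelineConfig) -> pd.DataFrame:
    """Loops significant in at least one of the two conditions, with
    per-replicate counts from both conditions."""
    called = [hio.read_tsv(outdir / f"loops_{c}.tsv") for c in CONDITIONS]
    key = ["chrom", "bin1", "bin2"]
    universe = pd.concat([c[key] for c in called], ignore_index=True).drop_duplicates()
    counts = {c: hio.read_tsv(outdir / f"hichip_{c}.tsv") for c in CONDITIONS}
    out = universe
    for cond in CONDITIONS:
        cols = [c for c in counts[cond].columns if c.startswith("count_")]
        renamed = counts[cond].rename(columns={c: f"{cond}_{c}" for c in cols})
        out = out.merge(renamed, on=key, how="left")
    out = out.fillna(0).sort_values(key).reset_index(drop=True)
    out.insert(0, "loop_id", [f"U{k + 1:05d}" for k in range(len(out))])
    return out


def stage_diff_loops(config: PipelineConfig, outdir: Path) -> list:
    universe = _loop_universe(outdir, config)
    a_cols = [c for c in universe.columns if c.startswith("A_count")]
    b_cols = [c for c in universe.columns if c.startswith("B_count")]
    res = diff.nb_wald(universe[a_cols].to_numpy(), universe[b_cols].to_numpy())
    res["diff_class"] = diff.classify_loops(res, config.thresholds)
    out = pd.concat([universe, res], axis=1)
    path = outdir / "diff_loops.tsv"
    hio.write_tsv(out, path)
    log.info("diff-loops: %s", out["diff_class"].value_counts().to_dict())
    return [path]


def stage_diff_anchors(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    diff_loops = hio.read_tsv(outdir / "diff_loops.tsv")
    anchors = pd.concat(
        [diff_loops[["chrom", "bin1"]].rename(columns={"bin1": "bin"}),
         diff_loops[["chrom", "bin2"]].rename(columns={"bin2": "bin"})],
        ignore_index=True,
    ).drop_duplicates().sort_values(["chrom", "bin"]).reset_index(drop=True)
    mat = {}
    for cond in CONDITIONS:
        for r, f in enumerate(_peak_files(outdir, cond, config.peak_replicates)):
            peaks = hio.read_bed(f)
            mat[f"{cond}_{r + 1}"] = diff.anchor_h3k27ac_signal(anchors, peaks,
                                                               bin_size=genome.bin_size)
    a_cols = [k for k in mat if k.startswith("A_")]
    b_cols = [k for k in mat if k.startswith("B_")]
    A = np.column_stack([mat[k] for k in a_cols])
    B = np.column_stack([mat[k] for k in b_cols])
    res = diff.nb_wald(np.round(A), np.round(B))
    res["diff_class"] = diff.classify_enhancer_anchors(res, config.thresholds)
    out = pd.concat([anchors.reset_index(drop=True), res], axis=1)
    path = outdir / "diff_anchors.tsv"
    hio.write_tsv(out, path)
    log.info("diff-anchors: %s", out["diff_class"].value_counts().to_dict())
    return [path]


def stage_diff_expression(config: PipelineConfig, outdir: Path) -> list:
    rna = hio.read_tsv(outdir / "rna_counts.tsv", index_col=0)
    n_a = sum(c.startswith("A_") for c in rna.columns)
    n_b = sum(c.startswith("B_") for c in rna.columns)
    res = diff.differential_expression(
        rna, n_a, n_b, thresholds=config.thresholds, fc_threshold=config.rna_fc_expression
    )
    path = outdir / "diff_expression.tsv"
    res.to_csv(path, sep="\t")
    log.info("diff-expression: %d DE of %d genes", int(res["is_de"].sum()), len(res))
    return [path]


def stage_modes(config: PipelineConfig, outdir: Path) -> list:
    diff_loops = hio.read_tsv(outdir / "diff_loops.tsv")
    anchors = hio.read_tsv(outdir / "anchors.tsv").fillna({"gene_ids": ""})
    anchor_cls = hio.read_tsv(outdir / "diff_anchors.tsv")
    de = hio.read_tsv(outdir / "diff_expression.tsv", index_col=0)
    assignments = md.assign_modes(diff_loops, anchors, anchor_cls)
    summary = md.mode_expression_test(assignments, de)
    p1 = outdir / "mode_assignments.tsv"
    p2 = outdir / "mode_summary.tsv"
    hio.write_tsv(assignments, p1)
    hio.write_tsv(summary, p2)
    p3 = outdir / "mode_summary.json"
    p3.write_text(summary.to_json(orient="records", indent=2))
    log.info("modes: %s", assignments["mode"].value_counts().to_dict())
    return [p1, p2, p3]


def stage_boundaries(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    diff_loops = hio.read_tsv(outdir / "diff_loops.tsv")
    gained = diff_loops[diff_loops["diff_class"] == "gained"]
    bed = hio.read_bed(outdir / "boundaries_A.bed")
    boundaries = pd.DataFrame({"chrom": bed["chrom"], "bin": bed["start"] // genome.bin_size})
    anchors = hio.read_tsv(outdir / "anchors.tsv").fillna({"gene_ids": ""})
    rna = hio.read_tsv(outdir / "rna_counts.tsv", index_col=0)
    n_a = sum(c.startswith("A_") for c in rna.columns)
    n_b = sum(c.startswith("B_") for c in rna.columns)
    de = diff.differential_expression(
        rna, n_a, n_b, thresholds=config.thresholds, fc_threshold=config.rna_fc_crossing
    )
    table, summary = md.boundary_crossing_report(gained, boundaries, de, anchors)
    p1 = outdir / "boundary_crossing.tsv"
    p2 = outdir / "boundary_crossing.json"
    hio.write_tsv(table, p1)
    p2.write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("boundaries: %.0f%% of gained loops across", 100 * summary["fraction_across"])
    return [p1, p2]


def _elements_from_outputs(outdir: Path) -> ann.RegulatoryElements:
    return ann.RegulatoryElements(
        promoters=hio.read_tsv(outdir / "elements_promoters.tsv"),
        enhancers=hio.read_tsv(outdir / "elements_enhancers.tsv"),
        stitched=hio.read_tsv(outdir / "elements_stitched.tsv"),
        ctcf_sites=hio.read_tsv(outdir / "elements_ctcf_sites.tsv"),
    )


def stage_tf_targets(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    tf = hio.read_bed(outdir / "peaks_tf.bed")
    elements = _elements_from_outputs(outdir)
    loops_b = hio.read_tsv(outdir / "loops_B.tsv")
    anchors = hio.read_tsv(outdir / "anchors.tsv").fillna({"gene_ids": ""})
    targets = md.assign_tf_targets(tf, elements, loops_b, anchors, bin_size=genome.bin_size)
    path = outdir / "tf_targets.tsv"
    hio.write_tsv(targets, path)
    log.info("tf-targets: %s", targets["tf_class"].value_counts().to_dict())
    return [path]


def stage_enrich(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    bs = genome.bin_size
    diff_loops = hio.read_tsv(outdir / "diff_loops.tsv")
    tf = hio.read_bed(outdir / "peaks_tf.bed")

    def anchor_intervals(sub):
        bins = pd.concat(
            [sub[["chrom", "bin1"]].rename(columns={"bin1": "bin"}),
             sub[["chrom", "bin2"]].rename(columns={"bin2": "bin"})]
        ).drop_duplicates()
        return pd.DataFrame({"chrom": bins["chrom"], "start": bins["bin"] * bs,
                             "end": (bins["bin"] + 1) * bs})

    universe = anchor_intervals(diff_loops)
    query = anchor_intervals(diff_loops[diff_loops["diff_class"] == "gained"])
    odds, p, table = md.region_set_enrichment(query, tf, universe)
    path = outdir / "enrichment.json"
    path.write_text(json.dumps(
        {"query": "gained-loop anchors", "reference": "TF peaks",
         "odds_ratio": odds, "p": p, "table": table}, indent=2, sort_keys=True))
    log.info("enrich: OR=%.2f p=%.3g", odds, p)
    return [path]


def stage_v4c(config: PipelineConfig, outdir: Path) -> list:
    genome = _load_genome(outdir)
    truth = _load_truth(outdir)
    gi = genome.genes.set_index("gene_id")
    outputs = []
    picks = []
    for mode in ("i", "vi"):
        sub = truth.gene_modes[truth.gene_modes["mode"] == mode]
        if len(sub):
            picks.append(sub["gene_id"].iloc[0])
    for gene in picks:
        tss = int(gi.loc[gene, "tss"])
        chrom = gi.loc[gene, "chrom"]
        for cond in CONDITIONS:
            calls = hio.read_tsv(outdir / f"loops_{cond}.tsv")
            track = net.virtual_4c(
                calls, (chrom, tss), window=config.v4c_window,
                bin_size=genome.bin_size, chrom_length=genome.chrom_lengths[chrom],
            )
            path = outdir / f"v4c_{gene}_{cond}.bedgraph"
            with open(path, "w") as fh:
                for b, v in zip(track.bins, track.values):
                    fh.write(f"{chrom}\t{b * genome.bin_size}\t{(b + 1) * genome.bin_size}\t{v:.6g}\n")
            outputs.append(path)
    return outputs


def stage_cliques(config: PipelineConfig, outdir: Path) -> list:
    anchors = hio.read_tsv(outdir / "anchors.tsv")
    peaks = _pooled_peaks(outdir, config)
    genome = _load_genome(outdir)
    signal = diff.anchor_h3k27ac_signal(anchors, peaks, bin_size=genome.bin_size)
    sig_map = {(a.chrom, int(a.bin)): s for a, s in zip(anchors.itertuples(), signal)}
    outputs = []
    stats = {}
    for cond in CONDITIONS:
        calls = hio.read_tsv(outdir / f"loops_{cond}.tsv")
        g = net.build_clique_graph(calls, neglog10q_min=config.clique_min_neglog10q,
                                   anchor_signal=sig_map)
        assignment, q = net.louvain_communities(g, seed=config.stage_seed(50))
        conn = net.clique_connectivity(g, assignment)
        nodes = pd.DataFrame(
            [(c, b, assignment[(c, b)], g.nodes[(c, b)].get("signal", 0.0))
             for (c, b) in sorted(g.nodes)],
            columns=["chrom", "bin", "community", "signal"],
        )
        edges = pd.DataFrame(
            [(u[0], u[1], v[1], d["weight"]) for u, v, d in
             sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))],
            columns=["chrom", "bin1", "bin2", "neglog10q"],
        )
        p1 = outdir / f"clique_nodes_{cond}.tsv"
        p2 = outdir / f"clique_edges_{cond}.tsv"
        hio.write_tsv(nodes, p1)
        hio.write_tsv(edges, p2)
        outputs += [p1, p2]
        stats[cond] = {
            "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges(),
            "n_communities": len(set(assignment.values())), "modularity": q,
            "max_connectivity": max(conn.values()) if conn else 0,
        }
    path = outdir / "clique_stats.json"
    path.write_text(json.dumps(stats, indent=2, sort_keys=True))
    outputs.append(path)
    return outputs


def _recovery_report(config: PipelineConfig, outdir: Path) -> dict:
    genome = _load_genome(outdir)
    truth = _load_truth(outdir)
    report: dict = {}

    # boundary recovery (condition A)
    bed = hio.read_bed(outdir / "boundaries_A.bed")
    called = bed["start"].to_numpy() // genome.bin_size
    planted = truth.boundaries["bin"].to_numpy()
    margin = config.insulation_bmoe
    recovered = sum(any(abs(b - c) <= margin for c in called) for b in planted)
    spurious = sum(all(abs(c - b) > margin for b in planted) for c in called)
    report["boundary_recall"] = recovered / len(planted) if len(planted) else np.nan
    report["boundary_spurious"] = int(spurious)

    # planted-loop recovery in the condition where each loop is strong
    cond_of = {"gained": "B", "lost": "A"}
    called_sets = {
        c: set(map(tuple, hio.read_tsv(outdir / f"loops_{c}.tsv")[["bin1", "bin2"]].to_numpy()))
        for c in CONDITIONS
    }
    hits = 0
    for L in truth.loops.itertuples():
        conds = [cond_of.get(L.loop_class)] if L.loop_class in cond_of else list(CONDITIONS)
        if any((L.bin1, L.bin2) in called_sets[c] for c in conds):
            hits += 1
    report["loop_recovery"] = hits / len(truth.loops)

    # mode precision / recall per mode
    assignments = hio.read_tsv(outdir / "mode_assignments.tsv")
    truth_mode = truth.gene_modes.set_index("gene_id")["mode"].to_dict()
    per_mode = {}
    for m in ["i", "ii", "iii", "iv", "v", "vi", "control"]:
        assigned = set(assignments.loc[assignments["mode"] == m, "gene_id"])
        true_set = {g for g, mm in truth_mode.items() if mm == m}
        tp = len(assigned & true_set)
        per_mode[m] = {
            "n_true": len(true_set), "n_assigned": len(assigned), "tp": tp,
            "precision": tp / len(assigned) if assigned else np.nan,
            "recall": tp / len(true_set) if true_set else np.nan,
        }
    report["mode_metrics"] = per_mode

    crossing = json.loads((outdir / "boundary_crossing.json").read_text())
    report["fraction_gained_across_boundary"] = crossing["fraction_across"]
    truth_cross = truth.loops[truth.loops["loop_class"] == "gained"]
    report["planted_fraction_across"] = (
        float(truth_cross["crosses_boundary"].mean()) if len(truth_cross) else np.nan
    )

    tf = hio.read_tsv(outdir / "tf_targets.tsv")
    merged = tf.merge(truth.tf_targets, on="gene_id", suffixes=("_called", "_true"))
    report["tf_class_agreement"] = (
        float((merged["tf_class_called"] == merged["tf_class_true"]).mean())
        if len(merged) else np.nan
    )
    report["mode_expression"] = json.loads((outdir / "mode_summary.json").read_text())
    report["clique_stats"] = json.loads((outdir / "clique_stats.json").read_text())
    return report


def stage_summary(config: PipelineConfig, outdir: Path) -> list:
    report = _recovery_report(config, outdir)
    p1 = outdir / "summary.json"
    p1.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    rows = []
    for m, d in report["mode_metrics"].items():
        rows.append((m, d["n_true"], d["n_assigned"], d["precision"], d["recall"]))
    p2 = outdir / "recovery_report.tsv"
    hio.write_tsv(pd.DataFrame(rows, columns=["mode", "n_true", "n_assigned",
                                              "precision", "recall"]), p2)
    return [p1, p2]


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "insulation": stage_insulation,
    "compartments": stage_compartments,
    "call-loops": stage_call_loops,
    "annotate": stage_annotate,
    "diff-loops": stage_diff_loops,
    "diff-anchors": stage_diff_anchors,
    "diff-expression": stage_diff_expression,
    "modes": stage_modes,
    "boundaries": stage_boundaries,
    "tf-targets": stage_tf_targets,
    "enrich": stage_enrich,
    "v4c": stage_v4c,
    "cliques": stage_cliques,
    "summary": stage_summary,
}


def run_stage(stage: str, config: PipelineConfig, outdir) -> list:
    """Run one stage; validates config and prerequisites, updates the manifest."""
    if stage not in STAGE_FUNCS:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_prereqs(stage, outdir)
    outputs = STAGE_FUNCS[stage](config, outdir)
    hio.update_manifest(outdir, stage, config.to_dict(), outputs, config.seed)
    return outputs


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order and return the summary report."""
    for stage in STAGES:
        log.info("=== stage %s ===", stage)
        run_stage(stage, config, outdir)
    return json.loads((Path(outdir) / "summary.json").read_text())
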