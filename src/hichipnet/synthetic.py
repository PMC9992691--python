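"""Synthetic genomes, contact maps, HiChIP counts, peaks and expression.

Every generator takes an explicit seed and writes its planted truth into a
:class:`TruthTable`, so that each downstream caller (boundary detection, loop
significance, differential classification, regulatory-mode assignment) can be
scored against known answers.

The emulated design is two conditions (A = resting, B = stimulated) with at
least two replicates each: a power-law distance-decay contact background with
planted TAD blocks, loops planted on top of the background with
condition-specific strength multipliers, enhancer peaks with
condition-specific activity, and negative-binomial gene counts whose planted
log2 fold-changes follow the regulatory mode each gene is wired into.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio

DEFAULT_BIN_SIZE = 10_000
MIN_LOOP_SPAN = 20_000
MAX_LOOP_SPAN = 2_000_000

#: regulatory mode -> (loop dynamic, distal-enhancer dynamic, planted RNA log2FC)
MODE_WIRING = {
    "i": ("gained", "inducible", 2.0),
    "ii": ("constant", "inducible", 1.5),
    "iii": ("gained", "constitutive", 1.0),
    "iv": ("lost", "constitutive", -1.0),
    "v": ("constant", "repressed", -1.5),
    "vi": ("lost", "repressed", -2.0),
    "control": ("constant", "constitutive", 0.0),
}
MODES = list(MODE_WIRING)

#: loop dynamic -> per-condition strength multipliers (A, B)
LOOP_MULT = {"gained": (1.0, 3.0), "lost": (3.0, 1.0), "constant": (2.0, 2.0)}

#: enhancer dynamic -> per-condition mean peak signal (A, B)
ENHANCER_SIGNAL = {
    "inducible": (400.0, 1000.0),
    "repressed": (1000.0, 400.0),
    "constitutive": (700.0, 700.0),
}


@dataclass
class GenomeModel:
    """Chromosome sizes, fixed bin size and a unique-TSS gene table."""

    chrom_names: list
    chrom_lengths: dict
    genes: pd.DataFrame  # gene_id, chrom, strand, tss
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self):
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        for _, g in self.genes.iterrows():
            if g.tss >= self.chrom_lengths[g.chrom]:
                raise ValueError(f"TSS of {g.gene_id} beyond chromosome end")

    def n_bins(self, chrom: str) -> int:
        # last partial bin is kept
        return -(-self.chrom_lengths[chrom] // self.bin_size)

    def tss_bin(self, gene_id: str) -> int:
        tss = int(self.genes.set_index("gene_id").loc[gene_id, "tss"])
        return tss // self.bin_size

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"chrom": self.chrom_names, "length": [self.chrom_lengths[c] for c in self.chrom_names]}
        ).to_csv(path / "chrom_sizes.tsv", sep="\t", index=False)
        self.genes.to_csv(path / "genes.tsv", sep="\t", index=False)
        (path / "bin_size.txt").write_text(str(self.bin_size))

    @classmethod
    def from_dir(cls, path) -> "GenomeModel":
        path = Path(path)
        sizes = pd.read_csv(path / "chrom_sizes.tsv", sep="\t")
        genes = pd.read_csv(path / "genes.tsv", sep="\t")
        return cls(
            chrom_names=list(sizes["chrom"]),
            chrom_lengths=dict(zip(sizes["chrom"], sizes["length"])),
            genes=genes,
            bin_size=int((path / "bin_size.txt").read_text()),
        )


@dataclass
class TruthTable:
    """Machine-readable planted truth for every downstream stage."""

    boundaries: pd.DataFrame  # chrom, bin
    loops: pd.DataFrame  # loop_id, chrom, bin1, bin2, base_strength, mult_a, mult_b,
    #                      loop_class, dispersion, gene_id, crosses_boundary
    enhancers: pd.DataFrame  # enh_id, chrom, start, end, signal_a, signal_b, enh_class,
    #                          dispersion, gene_id
    gene_modes: pd.DataFrame  # gene_id, mode, log2fc
    ctcf_sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))
    tf_sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "gene_id"]))
    tf_targets: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene_id", "tf_class"]))

    _FILES = {
        "boundaries": "boundaries.tsv",
        "loops": "loops.tsv",
        "enhancers": "enhancers.tsv",
        "gene_modes": "gene_modes.tsv",
        "ctcf_sites": "ctcf_sites.tsv",
        "tf_sites": "tf_sites.tsv",
        "tf_targets": "tf_targets.tsv",
    }

    def __post_init__(self):
        if len(self.loops):
            span = (self.loops["bin2"] - self.loops["bin1"]) * DEFAULT_BIN_SIZE
            bad = (span < MIN_LOOP_SPAN) | (span > MAX_LOOP_SPAN)
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} planted loops have spans outside "
                    f"[{MIN_LOOP_SPAN}, {MAX_LOOP_SPAN}] bp"
                )

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            getattr(self, attr).to_csv(path / fname, sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "TruthTable":
        path = Path(path)
        kw = {}
        for attr, fname in cls._FILES.items():
            kw[attr] = pd.read_csv(path / fname, sep="\t").fillna({"gene_id": ""})
            if "gene_id" in kw[attr].columns:
                kw[attr]["gene_id"] = kw[attr]["gene_id"].astype(str).replace("nan", "")
        return cls(**kw)


def nb_sample(rng: np.random.Generator, mean, dispersion) -> np.ndarray:
    """Negative binomial draw parameterised by mean and dispersion alpha.

    Var = mu + alpha * mu^2; alpha == 0 degenerates to Poisson.  Vectorised
    over ``mean``; ``dispersion`` may be scalar or per-element.
    """
    mean = np.asarray(mean, dtype=float)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape).copy()
    out = np.empty(mean.shape, dtype=np.int64)
    pois = disp < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        a = disp[~pois]
        lam = rng.gamma(shape=1.0 / a, scale=mean[~pois] * a)
        out[~pois] = rng.poisson(lam)
    return out


def generate_genome(
    n_chroms: int = 1,
    chrom_length: int = 30_000_000,
    n_genes: int = 100,
    seed: int = 0,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_spacing: int = 30_000,
    edge_margin: int = 200_000,
) -> GenomeModel:
    """Place ``n_genes`` unique TSSs uniformly with a minimum spacing.

    Spacing is guaranteed by construction: sorted uniform draws over the
    slack are offset by multiples of ``min_spacing``.
    """
    if chrom_length < 5_000_000:
        raise ValueError("chrom_length must be at least 5 Mb")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    lengths = {c: int(chrom_length) for c in chroms}
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    rows = []
    gid = 0
    for c, k in zip(chroms, per_chrom):
        slack = chrom_length - 2 * edge_margin - (k - 1) * min_spacing
        if slack <= 0:
            raise ValueError(
                f"cannot place {k} genes with {min_spacing} bp spacing on a "
                f"{chrom_length} bp chromosome"
            )
        offs = np.sort(rng.uniform(0, slack, size=k))
        tss = (edge_margin + offs + np.arange(k) * min_spacing).astype(int)
        strands = rng.choice(["+", "-"], size=k)
        for t, s in zip(tss, strands):
            gid += 1
            rows.append((f"g{gid:04d}", c, s, int(t)))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])
    return GenomeModel(chrom_names=chroms, chrom_lengths=lengths, genes=genes, bin_size=bin_size)


def _promoter_bins(genome: GenomeModel, halfwidth: int = 2500) -> dict:
    """Set of bins per chromosome touched by any promoter interval."""
    bins = {c: set() for c in genome.chrom_names}
    bs = genome.bin_size
    for _, g in genome.genes.iterrows():
        lo = max(0, g.tss - halfwidth)
        hi = min(genome.chrom_lengths[g.chrom], g.tss + halfwidth)
        bins[g.chrom].update(range(lo // bs, (hi - 1) // bs + 1))
    return bins


def plant_truth(
    genome: GenomeModel,
    n_boundaries: int = 5,
    genes_per_mode: int = 10,
    n_filler_loops: int = 150,
    n_cross_loops: int = 6,
    n_tf_per_class: int = 8,
    base_strength: float = 25.0,
    planted_dispersion: float = 0.0,
    filler_dispersion: float = 0.1,
    seed: int = 0,
) -> TruthTable:
    """Wire genes into the six regulatory modes plus controls.

    Each wired gene gets one loop from its promoter bin to a distal enhancer
    bin (40-150 kb away) and one enhancer peak in that distal bin; loop
    multipliers and enhancer signals follow :data:`MODE_WIRING`.
    ``n_cross_loops`` of the gained-loop genes have their enhancer placed on
    the far side of the nearest planted TAD boundary, so that the
    gained-loop-across-boundary analysis has planted positives.  Filler loops
    (noisy strength and noisy anchor enhancer signal, not attached to genes)
    make the differential universe realistically heterogeneous.
    """
    rng = np.random.default_rng(seed)
    bs = genome.bin_size
    prom_bins = _promoter_bins(genome)

    boundaries = []
    for c in genome.chrom_names:
        nb = genome.n_bins(c)
        for j in range(1, n_boundaries + 1):
            boundaries.append((c, int(round(j * nb / (n_boundaries + 1)))))
    boundaries = pd.DataFrame(boundaries, columns=["chrom", "bin"])

    need = genes_per_mode * len(MODES)
    if need > len(genome.genes):
        raise ValueError(f"need at least {need} genes to wire {genes_per_mode} per mode")
    order = rng.permutation(len(genome.genes))
    wired = genome.genes.iloc[order[:need]].reset_index(drop=True)
    mode_of = {}
    for i, (_, g) in enumerate(wired.iterrows()):
        mode_of[g.gene_id] = MODES[i // genes_per_mode]

    used_bins = {c: set(prom_bins[c]) for c in genome.chrom_names}
    bdict = {c: sorted(boundaries[boundaries.chrom == c]["bin"]) for c in genome.chrom_names}

    # choose which gained-loop genes cross a boundary
    gained_genes = [g for g, m in mode_of.items() if MODE_WIRING[m][0] == "gained"]
    cross_set = set(gained_genes[:n_cross_loops])

    loops, enhancers, gene_rows = [], [], []
    enh_id = 0
    for _, g in wired.iterrows():
        mode = mode_of[g.gene_id]
        loop_class, enh_class, lfc = MODE_WIRING[mode]
        nb = genome.n_bins(g.chrom)
        pb = int(g.tss) // bs
        target = None
        crosses = False
        if g.gene_id in cross_set:
            # enhancer strictly beyond the nearest boundary, span <= 2 Mb
            for b in sorted(bdict[g.chrom], key=lambda b: abs(b - pb)):
                step = 1 if b > pb else -1
                for d in rng.permutation(np.arange(3, 40)):
                    cand = b + step * int(d)
                    if (
                        0 <= cand < nb
                        and cand not in used_bins[g.chrom]
                        and MIN_LOOP_SPAN <= abs(cand - pb) * bs <= MAX_LOOP_SPAN
                        and min(pb, cand) < b < max(pb, cand)
                    ):
                        target, crosses = cand, True
                        break
                if target is not None:
                    break
        if target is None:
            crosses = False
            for _try in range(200):
                d = int(rng.integers(4, 16))
                step = rng.choice([-1, 1])
                cand = pb + step * d
                if 0 <= cand < nb and cand not in used_bins[g.chrom]:
                    # keep within-TAD unless this gene was chosen to cross
                    if any(min(pb, cand) < b < max(pb, cand) for b in bdict[g.chrom]):
                        continue
                    target = cand
                    break
            if target is None:
                raise RuntimeError(f"could not place a distal enhancer for {g.gene_id}")
        used_bins[g.chrom].add(target)
        b1, b2 = sorted((pb, target))
        ma, mb = LOOP_MULT[loop_class]
        loops.append(
            (f"L{len(loops) + 1:04d}", g.chrom, b1, b2, base_strength, ma, mb,
             loop_class, planted_dispersion, g.gene_id, crosses)
        )
        sa, sb = ENHANCER_SIGNAL[enh_class]
        center = target * bs + bs // 2
        enh_id += 1
        enhancers.append(
            (f"E{enh_id:04d}", g.chrom, center - 1000, center + 1000, sa, sb,
             enh_class, planted_dispersion, g.gene_id)
        )
        gene_rows.append((g.gene_id, mode, lfc, crosses))

    # filler loops with noisy strengths and noisy anchor enhancers
    for _ in range(n_filler_loops):
        for _try in range(500):
            c = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
            nb = genome.n_bins(c)
            b1 = int(rng.integers(20, nb - 60))
            d = int(rng.integers(4, 51))
            b2 = b1 + d
            if b1 in used_bins[c] or b2 in used_bins[c]:
                continue
            used_bins[c].update((b1, b2))
            ma = 2.0 * 2 ** rng.normal(0, 0.15)
            mb = 2.0 * 2 ** rng.normal(0, 0.15)
            loops.append(
                (f"L{len(loops) + 1:04d}", c, b1, b2, base_strength, ma, mb,
                 "filler", filler_dispersion, "", False)
            )
            for b in (b1, b2):
                s = 300.0 * 2 ** rng.normal(0, 0.3)
                center = b * bs + bs // 2
                enh_id += 1
                enhancers.append(
                    (f"E{enh_id:04d}", c, center - 1000, center + 1000, s, s,
                     "filler", filler_dispersion, "")
                )
            break

    loops = pd.DataFrame(
        loops,
        columns=["loop_id", "chrom", "bin1", "bin2", "base_strength", "mult_a",
                 "mult_b", "loop_class", "dispersion", "gene_id", "crosses_boundary"],
    )
    enhancers = pd.DataFrame(
        enhancers,
        columns=["enh_id", "chrom", "start", "end", "signal_a", "signal_b",
                 "enh_class", "dispersion", "gene_id"],
    )
    gene_modes = pd.DataFrame(gene_rows, columns=["gene_id", "mode", "log2fc", "crosses_boundary"])

    ctcf = pd.DataFrame(
        {
            "chrom": boundaries["chrom"],
            "start": boundaries["bin"] * bs + bs // 2 - 500,
            "end": boundaries["bin"] * bs + bs // 2 + 500,
        }
    )

    # TF wiring: genes whose loop is present in condition B (gained/constant)
    candidates = gene_modes[gene_modes["mode"].isin(["i", "ii", "iii", "control"])]["gene_id"].tolist()
    tf_rows, tf_sites = [], []
    classes = ["promoter_only", "promoter_and_distal", "distal_only"]
    gi = genome.genes.set_index("gene_id")
    edict = enhancers.set_index("gene_id")
    for k, cls in enumerate(classes):
        take = candidates[k * n_tf_per_class:(k + 1) * n_tf_per_class]
        for gene in take:
            tss = int(gi.loc[gene, "tss"])
            chrom = gi.loc[gene, "chrom"]
            if cls in ("promoter_only", "promoter_and_distal"):
                tf_sites.append((chrom, tss - 200, tss + 200, gene))
            if cls in ("promoter_and_distal", "distal_only"):
                e = edict.loc[gene]
                tf_sites.append((chrom, int(e.start), int(e.end), gene))
            tf_rows.append((gene, cls))
    tf_sites = pd.DataFrame(tf_sites, columns=["chrom", "start", "end", "gene_id"])
    tf_targets = pd.DataFrame(tf_rows, columns=["gene_id", "tf_class"])

    return TruthTable(
        boundaries=boundaries,
        loops=loops,
        enhancers=enhancers,
        gene_modes=gene_modes,
        ctcf_sites=ctcf,
        tf_sites=tf_sites,
        tf_targets=tf_targets,
    )


def generate_hic(
    genome: GenomeModel,
    boundaries,
    decay_exponent: float = -1.0,
    tad_enrichment: float = 3.0,
    noise: str = "poisson",
    seed: int = 0,
    diag_scale: float = 300.0,
    chrom: str | None = None,
):
    """Contact matrix with power-law decay and planted TAD blocks.

    Expected count at bin distance d is ``diag_scale * max(d, 1)**exponent``,
    multiplied by ``tad_enrichment`` for bin pairs inside the same planted
    block (blocks are the segments between consecutive boundaries).  With
    ``noise='poisson'`` counts are Poisson-sampled; ``noise='none'`` returns
    the expectation.
    """
    from .matrix import ContactMatrix

    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    if tad_enrichment <= 1:
        raise ValueError("tad_enrichment must be > 1")
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    chrom = chrom or genome.chrom_names[0]
    if isinstance(boundaries, pd.DataFrame):
        bounds = sorted(boundaries.loc[boundaries["chrom"] == chrom, "bin"].astype(int))
    else:
        bounds = sorted(int(b) for b in boundaries)
    n = genome.n_bins(chrom)
    for b in bounds:
        if not 0 <= b < n:
            raise ValueError(f"boundary bin {b} outside [0, {n})")
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    expected = diag_scale * np.maximum(d, 1).astype(float) ** decay_exponent
    block = np.searchsorted(bounds, idx, side="right")
    same = block[:, None] == block[None, :]
    expected = np.where(same, expected * tad_enrichment, expected)
    if noise == "none":
        counts = expected
    else:
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(n)
        sampled = rng.poisson(expected[iu, ju])
        counts = np.zeros((n, n))
        counts[iu, ju] = sampled
        counts[ju, iu] = sampled
    return ContactMatrix(chrom=chrom, bin_size=genome.bin_size, counts=counts)


def _pair_grid(n: int, min_d: int, max_d: int):
    i_all, j_all = [], []
    for d in range(min_d, min(max_d, n - 1) + 1):
        i = np.arange(0, n - d)
        i_all.append(i)
        j_all.append(i + d)
    return np.concatenate(i_all), np.concatenate(j_all)


def generate_hichip(
    genome: GenomeModel,
    truth: TruthTable,
    n_replicates: int = 2,
    library_size: int = 400_000,
    dispersion: float = 0.1,
    decay_exponent: float = -1.0,
    bias_sigma: float = 0.25,
    seed: int = 0,
    min_pair_bins: int = 2,
    max_pair_bins: int = 200,
) -> dict:
    """Per-condition, per-replicate counted bin pairs.

    Background mean is distance decay times a multiplicative log-normal
    coverage bias per anchor, scaled so each replicate totals
    ``library_size`` expected pairs.  Planted loops multiply the background
    by ``base_strength * condition multiplier``.  Counts are NB-sampled with
    the background dispersion (planted rows use their own dispersion from the
    truth table).  Returns ``{"A": DataFrame, "B": DataFrame}`` with one
    count column per replicate.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    span = (truth.loops["bin2"] - truth.loops["bin1"]) * genome.bin_size
    if ((span < MIN_LOOP_SPAN) | (span > MAX_LOOP_SPAN)).any():
        raise ValueError("planted loop span outside the allowed range")
    rng = np.random.default_rng(seed)
    frames = {"A": [], "B": []}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        i, j = _pair_grid(n, min_pair_bins, max_pair_bins)
        d = (j - i).astype(float)
        bias = np.exp(rng.normal(0.0, bias_sigma, size=n))
        mu0 = d ** decay_exponent * bias[i] * bias[j]
        mu0 *= library_size / mu0.sum()
        disp = np.full(i.shape, dispersion)
        factor = {"A": np.ones_like(mu0), "B": np.ones_like(mu0)}
        sub = truth.loops[truth.loops["chrom"] == chrom]
        if len(sub):
            pos = {(b1, b2): k for k, (b1, b2) in enumerate(zip(i, j))}
            for _, L in sub.iterrows():
                k = pos.get((int(L.bin1), int(L.bin2)))
                if k is None:
                    continue
                factor["A"][k] = L.base_strength * L.mult_a
                factor["B"][k] = L.base_strength * L.mult_b
                disp[k] = L.dispersion
        for cond in ("A", "B"):
            df = pd.DataFrame({"chrom": chrom, "bin1": i, "bin2": j})
            mu = mu0 * factor[cond]
            for r in range(n_replicates):
                df[f"count_{r + 1}"] = nb_sample(rng, mu, disp)
            frames[cond].append(df)
    out = {}
    for cond in ("A", "B"):
        df = pd.concat(frames[cond], ignore_index=True)
        df.attrs["bin_size"] = genome.bin_size
        out[cond] = df
    return out


def generate_peaks(
    genome: GenomeModel,
    truth: TruthTable,
    condition: str = "A",
    seed: int = 0,
    kind: str = "h3k27ac",
) -> pd.DataFrame:
    """One replicate of a sorted BED peak track with integer signal.

    ``kind='h3k27ac'`` samples each planted enhancer's per-condition mean
    signal with its own dispersion; ``'ctcf'`` and ``'tf'`` emit the planted
    binding sites with Poisson signal around a constant mean.
    """
    if condition not in ("A", "B"):
        raise ValueError("condition must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    if kind == "h3k27ac":
        e = truth.enhancers
        mean = e["signal_a" if condition == "A" else "signal_b"].to_numpy(float)
        sig = nb_sample(rng, mean, e["dispersion"].to_numpy(float))
        df = pd.DataFrame(
            {"chrom": e["chrom"], "start": e["start"], "end": e["end"],
             "name": e["enh_id"], "signal": sig}
        )
    elif kind == "ctcf":
        s = truth.ctcf_sites
        df = pd.DataFrame(
            {"chrom": s["chrom"], "start": s["start"], "end": s["end"],
             "name": [f"ctcf{k + 1}" for k in range(len(s))],
             "signal": rng.poisson(100.0, size=len(s))}
        )
    elif kind == "tf":
        s = truth.tf_sites
        df = pd.DataFrame(
            {"chrom": s["chrom"], "start": s["start"], "end": s["end"],
             "name": [f"tf{k + 1}" for k in range(len(s))],
             "signal": rng.poisson(100.0, size=len(s))}
        )
    else:
        raise ValueError(f"unknown peak kind {kind!r}")
    for c in genome.chrom_names:
        m = df["chrom"] == c
        df.loc[m, "end"] = df.loc[m, "end"].clip(upper=genome.chrom_lengths[c])
        df.loc[m, "start"] = df.loc[m, "start"].clip(lower=0)
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def generate_rna_counts(
    genome: GenomeModel,
    truth: TruthTable,
    n_replicates: int = 3,
    seed: int = 0,
    base_mean: float = 200.0,
    mean_log2_sd: float = 0.5,
    dispersion: float = 0.1,
) -> pd.DataFrame:
    """NB gene-count matrix (genes x samples, columns A_1..A_n, B_1..B_n).

    Condition-B means are the condition-A means scaled by 2**log2fc for the
    planted mode of each gene (0 for unwired genes).
    """
    rng = np.random.default_rng(seed)
    genes = genome.genes["gene_id"].tolist()
    lfc = truth.gene_modes.set_index("gene_id")["log2fc"].reindex(genes).fillna(0.0).to_numpy()
    mean_a = base_mean * 2 ** rng.normal(0, mean_log2_sd, size=len(genes))
    mean_b = mean_a * 2.0 ** lfc
    data = {}
    for r in range(n_replicates):
        data[f"A_{r + 1}"] = nb_sample(rng, mean_a, dispersion)
    for r in range(n_replicates):
        data[f"B_{r + 1}"] = nb_sample(rng, mean_b, dispersion)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
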