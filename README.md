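# hichipnet

Enhancer-centric 3D genome analysis on synthetic data with planted truth.

Chromatin folds into compartments, topologically associating domains (TADs)
and loops; CTCF-anchored boundaries insulate TADs while enhancer–promoter
loops inside them drive condition-specific transcription.  `hichipnet`
implements the full analysis chain used to dissect such systems —
insulation-score TAD boundary calling, FitHiChIP-style significance calling
of 10-kb HiChIP bin pairs, regulatory-element anchor annotation with ROSE
super-enhancer stitching, a negative-binomial differential engine with exact
threshold classification, the six-regulatory-mode taxonomy linking loop and
enhancer dynamics to expression, cross-boundary gained-loop analysis,
virtual 4C, loop-mediated TF target assignment, Fisher region-set
enrichment, and Louvain 3D-clique graphs — and ships a synthetic-data
generator that plants every effect (boundaries, loops, enhancer dynamics,
expression changes) so each stage can be scored against known answers.

It is aimed at computational genomicists who want a compact, fully tested
reference implementation of these methods, or a planted-truth benchmark for
their own callers.

## The core models

**Insulation and boundaries.**  For a binned symmetric contact matrix, the
raw insulation at bin *i* is the mean count in the *w*×*w* square flanking
*i* (500 kb window at 10 kb bins); the score is log2(raw / chromosomal
mean).  With Δ(i) = mean score over the 200 kb left of *i* minus the 200 kb
right of *i*, boundaries are +→− zero crossings of Δ at local score minima;
boundary strength is the Δ swing around the crossing, thresholded at 0.1.

**Loop significance.**  Expected(pair) = stratum mean(distance) × bias₁ ×
bias₂, with logarithmic distance strata and per-anchor coverage bias;
p = Poisson upper tail of the pooled count, q = Benjamini–Hochberg across
all pairs spanning 20 kb–2 Mb; loops satisfy q < 10⁻⁵ (H3K27ac) or 10⁻²
(TF-directed).

**Differential classification.**  One NB Wald engine (median-of-ratios size
factors, trend-floored moment dispersions) tests loops, anchor H3K27ac and
genes.  Classes use the exact bands: constant/constitutive = P > 0.5 and
|log2FC| < 0.378512 (= log2 1.3); gained/lost = P < 0.1 and |log2FC| >
0.584963 (= log2 1.5); inducible/repressed = P < 0.1 and |log2FC| >
0.378512.  The joint (loop, distal-enhancer) dynamic maps each gene to a
regulatory mode:

| mode | loop | distal enhancer |
|------|----------|--------------|
| i    | gained   | inducible    |
| ii   | constant | inducible    |
| iii  | gained   | constitutive |
| iv   | lost     | constitutive |
| v    | constant | repressed    |
| vi   | lost     | repressed    |
| control | constant | constitutive |

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Run the whole pipeline on the default demo configuration (20 Mb chromosome,
120 genes of which 10 per mode are wired, 4 TAD boundaries, 2 conditions × 2
HiChIP replicates):

```bash
hichipnet run-all --seed 1 --outdir out/
```

which finishes in seconds and prints

```
boundary recall: 1.00
loop recovery: 1.00
gained loops across boundary: 21.05%
```

meaning: all 4 planted boundaries were re-called within ±3 bins from the
noisy Hi-C matrix, every planted loop was recovered at q < 10⁻⁵ in the
condition where it is strong, and 21% (4/19) of the loops classified
*gained* and connecting a promoter to an enhancer cross a condition-A TAD
boundary — the truth table wired 5 of its 20 gained loops across boundaries
(25%).  The per-mode expression comparison lands in `out/mode_summary.tsv`:

```
mode  n   mean_log2fc  t       p_vs_control
i      9   2.012       10.47   1.45e-08
ii    10   1.477        7.47   9.21e-07
iii   10   1.037        6.82   1.32e-05
iv    10  -0.823       -3.48   2.85e-03
v     10  -1.584       -9.29   7.19e-07
vi    10  -2.075       -9.52   3.18e-08
control 9 -0.085       —       —
```

Genes that gain a loop to an activation-inducible enhancer (mode i) are
strongly up-regulated relative to control genes on preformed constant loops
to constitutive enhancers, genes losing a loop from a repressed enhancer
(mode vi) are down-regulated, and the intermediate modes order between them
— recovering the planted +2 … −2 log2 fold-changes.  `out/summary.json`
holds the full recovery report (per-mode precision/recall, TF-target class
agreement, clique statistics), and every stage writes its parameters, seed
and output hashes to `out/manifest.json`.

Individual stages are available as subcommands (`simulate`, `insulation`,
`compartments`, `call-loops`, `annotate`, `diff-loops`, `diff-anchors`,
`diff-expression`, `modes`, `boundaries`, `tf-targets`, `enrich`, `v4c`,
`cliques`) or as library functions (`hichipnet.call_boundaries`,
`hichipnet.call_loops`, `hichipnet.nb_wald`, `hichipnet.assign_modes`, …).

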