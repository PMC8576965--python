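# ap2erf

A desk-scale survey toolkit for the **AP2/ERF transcription-factor
superfamily** — the large plant TF family defined by the ~60-residue AP2
DNA-binding domain (Pfam PF00847) whose members regulate shoot and leaf
development, hormone responses and stress tolerance.  The package grew out
of a genome-wide survey of the family in *Liriodendron chinense* (104
members, `LcERF1`–`LcERF104`) and packages every computational stage of such
a survey as a tested, reusable library with a thin CLI.

## What it does

* **Domain scanning** — locates AP2 and B3 domains with log-odds
  position-specific scoring matrices
  (`score[p][a] = log2((c_pa + λ)/(R + 20λ)/q_a)`), or ingests HMMER3
  `domtblout` tables filtered at `E ≤ 10⁻³`.
* **Classification** — domain-architecture rules: two AP2 domains → AP2
  subfamily; AP2 + B3 → RAV; single AP2 homologous to the Arabidopsis
  Soloist gene (At4g13040) → Soloist; remaining single-domain proteins split
  into the **DREB** branch (diagnostic residues V14/E19 in the domain frame)
  and the **ERF** branch (A14/D19), with Nakano-style groups (I–IV; V–X,
  VI-L) assigned by k-nearest-reference identity vote.
* **Phylogeny** — Poisson-corrected distances `d = −ln(1 − p)`,
  Saitou–Nei neighbor joining, column-resampling bootstrap supports,
  newick output (dendropy trees).
* **Gene structure** — exon/intron statistics from GFF3 on spliced-CDS
  coordinates, plus scanning for the family's conserved elements
  (WLG, YLG, RAYD, TGR, AA).
* **Expression / STC** — FPKM = `C·10⁹/(N·L)`, `log2(x+1)` + row Z-scores,
  hierarchical heatmap ordering, and the series-test-of-cluster chain:
  K-means (K = 10, 20 random starts) followed by hypergeometric
  over-representation tests with Bonferroni correction (α = 0.05) and a
  centroid rule naming tissue-specific clusters.
* **RT-qPCR statistics** — 2^(−ΔΔCT) relative quantification with
  technical/biological replicate handling, one-way ANOVA and Duncan's
  multiple range test letter groupings.
* **Synthetic data** — seeded generators for protein families with planted
  domains, gene models with subfamily-typical intron counts, expression
  matrices with planted tissue-specific clusters and qPCR plates with known
  fold changes, each with a machine-readable ground-truth sidecar.

## Worked example

The packaged family table (104 genes with lengths, intron counts and group
labels) reproduces the survey's headline statistics:

```python
from ap2erf.registry import packaged_registry, registry_stats

s = registry_stats(packaged_registry())
```

which prints, formatted:

```text
family size        : 104
protein length (aa): min 100  max 758  mean 315.8
subfamily counts   : {'DREB': 41, 'ERF': 43, 'AP2': 14, 'RAV': 5, 'Soloist': 1}
AP2 intron range   : (6, 12)
```

The shortest protein (100 aa) is LcERF29 and the longest (758 aa) LcERF42;
the 84 single-domain genes split into 41 DREB and 43 ERF members.

A full synthetic survey — generate a family, scan, classify, build the
bootstrapped tree, profile gene structure, run the STC chain and the qPCR
stage — is one command:

```console
$ ap2erf run --seed 1 --out demo --bootstrap 100
stages completed: simulate, scan, classify, tree, structure, stc, qpcr
report -> demo/
```

`demo/specificity.tsv` then flags exactly one shoot-specific expression
cluster (the planted one), and `demo/qpcr_rq.tsv` shows the recovered fold
changes with Duncan letters — a plate simulated with true fold changes
1 / 8 / 2 comes back as:

```text
sample	mean_rq	sd_rq	duncan
leaf	1.0006	0.0405	c
shoot	7.9068	0.1254	a
stem	1.9214	0.0318	b
```

i.e. shoot expression is ~8-fold the leaf calibrator and all three samples
differ significantly at α = 0.05.

## Layout

```
src/ap2erf/
  registry.py     family table I/O, MW/pI statistics
  references.py   synthetic domain cores, seed alignments, group panel
  domains.py      PSSM construction and scanning, domtblout ingestion
  classify.py     subfamily rules, DREB/ERF diagnostics, group kNN
  phylo.py        alignment, Poisson distances, NJ, bootstrap, newick
  structure.py    GFF3 intron profiles, conserved-element scan
  expression.py   FPKM, normalization, K-means STC, enrichment
  qpcr.py         2^-ddCt, ANOVA, Duncan letters
  simulate.py     seeded generators with ground truth
  pipeline.py     end-to-end orchestration, run manifest
  cli.py          `ap2erf` command group
```

The reference domain set shipped with the package is synthetic: constructed
sequences that reproduce the family's diagnostic geometry (frame positions,
WLG/YLG elements, a divergent Soloist lineage) without redistributing any
database content. See `docs/methods.md` for the modelling details and
limitations.
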