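# Methods

This note records the models, parameter choices and numerical conventions
behind `ap2erf`, and what the synthetic-data experiments do and do not
demonstrate about real survey data.

## Protein statistics

Molecular weight uses Expasy average residue masses; a chain of *n*
residues weighs the sum of residue masses plus one water (18.015 Da), the
condensation identity.  The isoelectric point solves net charge = 0 for
the Henderson–Hasselbalch sum with the Bjellqvist/Expasy pKa set: side
chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; C-terminus
3.55; per-residue N-terminal pKa (A 7.59, M 7.0, S 6.93, P 8.36, T 6.82,
V 7.44, E 7.7, default 7.5).  The charge function is strictly decreasing
in pH, so 50 bisection steps on [0, 14] give ~4×10⁻¹⁵ pH resolution; tests
cross-check against a 10⁻⁴-step grid scan.  Different web tools use
slightly different pKa sets, so absolute pI values are comparable only
within one convention.

## Synthetic reference set

The package ships no third-party database content.  Instead,
`references.py` constructs a 58-column AP2-domain frame whose geometry
mirrors the real family: diagnostic columns 14/19 (V/E in the DREB branch,
A/D in the ERF branch), the WLG tripeptide at columns 28–30 (YLG in the
AP2-subfamily core, which also carries TGR and the RAYD element), and a
Soloist lineage produced by a fixed alphabet shift at all but eight anchor
columns (~14% identity to the ERF branch — strongly divergent yet never
saturating a Poisson distance).  Eleven group templates (I–IV from the
DREB core, V–X and VI-L from the ERF core, six frozen substitutions each)
define the group panel, with two extra close variants per group so the
3-nearest-neighbour vote has a real majority.  All of this is generated by
seeded PCG64 draws frozen in the source; the sequences are synthetic
stand-ins, and results on them validate the *machinery*, not any
biological claim about particular genes.

## Domain scanning

PSSMs are log2-odds matrices with pseudocount 0.5 against a uniform
background (q = 0.05).  The default scan threshold is 0.35 × the
consensus self-score.  This fraction was calibrated once against two
fixed requirements: pure-random decoy windows must never fire (their best
scores sit tens of bits below zero because unmatched letters cost
~−1.3 bits per column), and the divergent Soloist domain — represented by
three rows of the seed alignment — must clear the threshold (it scores
roughly half the consensus self-score).  A higher fraction (e.g. 0.6)
would silently drop the Soloist lineage; a much lower one buys nothing
because decoys are already rejected by ~70 bits of margin.  Overlapping
windows are resolved greedily by descending score with leftmost
tie-breaking, so hit lists are deterministic.

## Classification

Architecture rules apply in priority order: ≥2 AP2 hits → AP2; 1 AP2 + B3
→ RAV; single AP2 with ≥40% global identity to the Soloist reference →
Soloist; otherwise ERF superfamily.  The 40% floor is permissive because
Soloist is defined by homology to a single divergent gene; ERF-branch
domains score far below it (~19% against the synthetic reference), so the
rule has a wide margin on both sides.  The DREB/ERF split reads the
diagnostic frame columns after projecting the domain into the reference
frame by global alignment; any non-canonical combination (or a gap at a
diagnostic column) falls back to the nearest-reference vote, and the group
vote is then restricted to the branch chosen, which guarantees the
invariant that DREB calls carry groups I–IV and ERF calls V–X/VI-L.
k = 3 is the smallest odd neighbourhood robust to one mislabelled
reference.

## Phylogeny

Pairwise alignment is Needleman–Wunsch with a linear gap model and
deterministic traceback (diagonal > up > left).  Distances use the Poisson
correction d = −ln(1 − p) over comparable (gap-free) columns; pairwise
deletion is the default and complete deletion is available behind a flag
(complete deletion discards more signal on sparse alignments but makes all
pairs share one column set).  Saturated pairs (p = 1) are errors, not
infinities.  Neighbor joining follows Saitou–Nei with the standard Q
criterion; ties break on the smallest active index pair and negative
branch lengths clamp to zero, making trees bit-reproducible.  Bootstrap
replicates resample columns with replacement from one seeded PCG64 stream
(replicate r consumes the r-th pre-drawn block, so results are independent
of evaluation order); replicates whose resampled columns saturate a pair
are skipped with a warning, and more than 50% skipped is an error.
Support values are percentages of replicate trees containing each
non-trivial bipartition of the full-data tree.

## Gene structure

Intron positions are measured on spliced-CDS coordinates, not genomic
span, and classed by thirds: r < 1/3 N-terminal, r > 2/3 C-terminal, else
middle.  The thirds boundary is a convention fixed here; the qualitative
observation it encodes is that single-intron ERF-branch genes consist of
one long and one very short exon, putting the intron near a terminus.
The two-letter AA element is only reported inside detected AP2 domains;
as a bare dipeptide it would match by chance roughly every 400 residues.

## Expression and STC

FPKM = C·10⁹/(N·L).  Normalization is log2(x+1) followed by per-row
Z-scores; constant rows become all-zero rather than NaN.  Genes whose
maximum FPKM stays below 1 or whose profile is flat are dropped before
clustering — the same kind of detected-gene reduction expression-profiling
pipelines apply (in the motivating survey, 104 annotated family members
reduced to 86 detected ones).  Clustering is K-means (Lloyd, Euclidean,
random-point initialization, best of 20 starts, K = 10), delegated to
scikit-learn with a fixed seed.  Enrichment of a subfamily in a cluster is
the hypergeometric upper tail P(X ≥ k) for the observed overlap, Bonferroni
corrected over (#subfamilies × #clusters) tests at α = 0.05 — exactly
enumerable, which the tests exploit for populations up to n = 30.  A
cluster is called specific to a tissue when its centroid is ≥ 1 Z there
and ≤ 0 everywhere else.

The synthetic expression generator plants a one-tissue-high cluster
(default: 12 of 120 genes, +4 log2-fold in shoot) on top of background
genes organized into five broadly expressed co-expression modules
(module profiles N(0, 0.75²) per tissue in log2, gene-level jitter
N(0, 0.3²), Poisson counts around a log-normal abundance).  Module
profiles are redrawn if they would themselves look single-tissue-specific
on the Z scale — the generator's ground truth is that *only* planted genes
are tissue-specific, so the background must honour that by construction.
What passing tests show: the chain separates a 16-fold planted signal from
correlated background and names the right tissue, and finds nothing under
the null.  What they do not show: performance under replicate-level
biological noise, batch effects, or subtler fold changes; occasionally
(a few percent of seeds) K-means splits the planted cluster into two
valid shoot-specific clusters rather than one.

## qPCR statistics

Technical replicates are averaged to one Ct per biological replicate
before ΔCT = Ct_target − Ct_reference; ΔΔCT subtracts the calibrator
sample's mean ΔCT and RQ = 2^(−ΔΔCT).  RQ is invariant to any constant
machine offset applied to a whole plate.  Primer-efficiency correction is
deliberately not implemented (pure ΔΔCT assumes ~100% efficiency).
Duncan's multiple range test sorts means descending and compares each span
of p means against R_p = q(α_p, p, df_error)·√(MSE/n) with protection
level α_p = 1 − (1 − α)^(p−1); studentized-range quantiles come from
scipy's distribution (memoized — the ppf is expensive) rather than shipped
tables.  Letters are assigned from the maximal non-significant spans of
the ordered means, which makes them monotone by construction.  Unequal
group sizes use the harmonic-mean n with a warning; zero error variance
with distinct means yields all-distinct letters.

## Problem sizes and determinism

Every stochastic experiment is seeded (numpy PCG64 via
`default_rng`; changing the RNG would be a breaking change).  The default
experiment sizes — 5 seeds × 200 proteins for classification recovery,
10 seeds × 120 genes for the STC chain, 50 random 4–6-taxon matrices for
the NJ/least-squares comparison, 2000 null datasets for the ANOVA
calibration, 100–1000 bootstrap replicates — were chosen so each
experiment carries enough repetitions to make its pass/fail criterion
statistically meaningful while the whole suite stays comfortably
interactive.

## Known limitations

* The reference panel and seed alignments are synthetic; applying the
  classifier to real proteomes requires swapping in a curated panel FASTA
  (`|group=` headers) and re-checking the scan threshold.
* No profile-HMM scoring (forward/Viterbi) and no E-value calibration for
  the PSSM path; HMMER output can be ingested instead.
* Multiple alignment of full-length proteins is out of scope; trees are
  built from fixed-width domain windows or externally aligned FASTA.
* De-novo motif discovery is out of scope (externally produced motif
  tables can be joined onto reports).
* FPKM is computed from provided counts/lengths/totals; read mapping and
  transcript assembly are upstream of this package.
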