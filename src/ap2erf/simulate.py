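"""Seeded generators for every pipeline input, with recorded ground truth.

Each generator is a pure function of its arguments plus a seed (numpy
PCG64 via ``numpy.random.default_rng``; changing this RNG would be a
breaking change) and returns a Truth object sufficient to score the
downstream stage without peeking at generator internals.

What is emulated: protein families with planted AP2/B3 domains and the
subfamily-defining architectures (two AP2 copies for AP2, AP2+B3 for
RAV, a divergent Soloist lineage, single-domain DREB/ERF members with
the diagnostic V14/E19 or A14/D19 residues); gene models with
subfamily-typical intron counts (AP2 6-12, DREB/ERF mostly 0-1, RAV
1-4, Soloist exactly 5); tissue expression with planted one-tissue-high
clusters; and qPCR plates with known fold changes, three biological by
three technical replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .references import (
    AMINO_ACIDS,
    AP2_CORE,
    B3_CORE,
    DREB_GROUPS,
    ERF_GROUPS,
    SOLOIST_CORE,
    group_templates,
)

__all__ = [
    "FamilyTruth",
    "ExpressionTruth",
    "QpcrTruth",
    "gen_family",
    "gen_gene_models",
    "gen_expression",
    "gen_qpcr",
    "write_fasta",
    "DEFAULT_TISSUES",
]

DEFAULT_TISSUES = ("bract", "sepal", "petal", "stamen", "pistil",
                   "leaf", "shoot", "BSPSP")


@dataclass
class FamilyTruth:
    """Planted labels of a synthetic protein family."""

    seed: int
    substitution_rate: float
    subfamily: dict[str, str] = field(default_factory=dict)
    group: dict[str, str] = field(default_factory=dict)
    domains: dict[str, list] = field(default_factory=dict)  # (start, end, label)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class ExpressionTruth:
    seed: int
    specific_tissue: str
    planted_genes: list[str]
    log2_effect: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class QpcrTruth:
    seed: int
    sigma_ct: float
    rq_true: dict[str, float]
    calibrator: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _mutate_seq(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for pos in hits:
        choices = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _linker(rng: np.random.Generator, lo: int = 15, hi: int = 35) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def gen_family(n_per_subfamily: dict[str, int],
               substitution_rate: float = 0.05,
               seed: int = 0) -> tuple[dict[str, str], FamilyTruth]:
    """Synthetic protein family with planted domain architectures.

    AP2 members carry two AP2-subfamily domain copies, RAV one
    ERF-branch AP2 domain plus a B3 domain, Soloist a mutated copy of
    the Soloist reference, and each DREB/ERF member a single copy of a
    uniformly drawn group template.  Random uniform linkers surround the
    domains; substitutions hit domain copies at substitution_rate.
    """
    if not 0.0 <= substitution_rate <= 0.3:
        raise ValueError("substitution_rate must be in [0, 0.3]")
    if all(n <= 0 for n in n_per_subfamily.values()):
        raise ValueError("need a positive count for at least one subfamily")
    rng = np.random.default_rng(seed)
    templates = group_templates()
    seqs: dict[str, str] = {}
    truth = FamilyTruth(seed=seed, substitution_rate=substitution_rate)
    idx = 0
    for subfamily in ("AP2", "RAV", "DREB", "ERF", "Soloist"):
        for _ in range(n_per_subfamily.get(subfamily, 0)):
            idx += 1
            name = f"syn{idx:04d}"
            # parts: alternating (linker, None) and (domain, label)
            if subfamily == "AP2":
                group = "AP2"
                parts = [
                    (_linker(rng), None),
                    (_mutate_seq(AP2_CORE, substitution_rate, rng), "AP2"),
                    (_linker(rng), None),
                    (_mutate_seq(AP2_CORE, substitution_rate, rng), "AP2"),
                    (_linker(rng), None),
                ]
            elif subfamily == "RAV":
                group = "RAV"
                parts = [
                    (_linker(rng), None),
                    (_mutate_seq(templates["RAV"], substitution_rate, rng), "AP2"),
                    (_linker(rng), None),
                    (_mutate_seq(B3_CORE, substitution_rate, rng), "B3"),
                    (_linker(rng), None),
                ]
            elif subfamily == "Soloist":
                group = "Soloist"
                parts = [
                    (_linker(rng), None),
                    (_mutate_seq(SOLOIST_CORE, substitution_rate, rng), "AP2"),
                    (_linker(rng), None),
                ]
            else:
                pool = DREB_GROUPS if subfamily == "DREB" else ERF_GROUPS
                group = pool[rng.integers(len(pool))]
                parts = [
                    (_linker(rng), None),
                    (_mutate_seq(templates[group], substitution_rate, rng), "AP2"),
                    (_linker(rng), None),
                ]
            seq = ""
            domains: list[list] = []
            for part, label in parts:
                if label is not None:
                    domains.append([len(seq), len(seq) + len(part), label])
                seq += part
            seqs[name] = seq
            truth.subfamily[name] = subfamily
            truth.group[name] = group
            truth.domains[name] = domains
    return seqs, truth


def gen_gene_models(truth: FamilyTruth, seed: int = 0) -> str:
    """GFF3 text with subfamily-typical intron counts per truth entry.

    AP2: uniform 6-12 introns; DREB/ERF: 0-1 with a 10% chance of 2-7
    (outlier mimic); RAV: 1-4; Soloist: exactly 5.  Genes are laid out
    sequentially on one synthetic scaffold; strands alternate.
    """
    rng = np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    cursor = 1000
    for i, (name, subfamily) in enumerate(sorted(truth.subfamily.items())):
        if subfamily == "AP2":
            n_introns = int(rng.integers(6, 13))
        elif subfamily in ("DREB", "ERF"):
            if rng.random() < 0.10:
                n_introns = int(rng.integers(2, 8))
            else:
                n_introns = int(rng.integers(0, 2))
        elif subfamily == "RAV":
            n_introns = int(rng.integers(1, 5))
        else:  # Soloist
            n_introns = 5
        strand = "+" if i % 2 == 0 else "-"
        exon_lens = rng.integers(100, 301, size=n_introns + 1)
        intron_lens = rng.integers(80, 501, size=n_introns)
        start = cursor
        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el) - 1))  # 1-based inclusive
            pos += int(el)
            if j < n_introns:
                pos += int(intron_lens[j])
        end = exons[-1][1]
        lines.append(f"scaffold_sim1\tap2erf_sim\tgene\t{start}\t{end}\t.\t"
                     f"{strand}\t.\tID={name}")
        lines.append(f"scaffold_sim1\tap2erf_sim\tmRNA\t{start}\t{end}\t.\t"
                     f"{strand}\t.\tID={name}.t1;Parent={name}")
        for s, e in exons:
            lines.append(f"scaffold_sim1\tap2erf_sim\texon\t{s}\t{e}\t.\t"
                         f"{strand}\t.\tParent={name}.t1")
        cursor = end + 2000
    return "\n".join(lines) + "\n"


def _broad_module_profiles(n_modules: int, n_tissues: int,
                           rng: np.random.Generator,
                           sigma_log2: float = 0.75) -> np.ndarray:
    """Log2 tissue profiles of broadly expressed background modules.

    Profiles are redrawn until none of them looks single-tissue-specific
    on the Z scale (one component above 0.8 with all others below 0.2):
    the generator's ground truth is that only planted genes are
    tissue-specific, so the background must honour it by construction.
    """
    profiles = np.empty((n_modules, n_tissues))
    for m in range(n_modules):
        for _ in range(1000):
            prof = rng.normal(0.0, sigma_log2, size=n_tissues)
            z = (prof - prof.mean()) / prof.std()
            top = z.argmax()
            rest = np.delete(z, top)
            if not (z[top] >= 0.8 and (rest <= 0.2).all()):
                profiles[m] = prof
                break
        else:  # pragma: no cover - rejection nearly always succeeds
            raise RuntimeError("could not draw a broad module profile")
    return profiles


def gen_expression(n_genes: int = 120, tissues=DEFAULT_TISSUES,
                   specific_cluster_size: int = 12, log2_effect: float = 4.0,
                   seed: int = 0, specific_tissue: str = "shoot",
                   n_modules: int = 5,
                   ) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Fragment-count matrix with one planted tissue-high gene cluster.

    Background genes are co-expressed: each belongs to one of a few
    broadly expressed modules whose log2 tissue profile is shared by its
    members up to N(0, 0.3) gene-level jitter, on top of a log-normal
    per-gene abundance; counts are Poisson draws around the resulting
    rate.  Planted genes are flat across tissues except for a
    2^log2_effect multiplier in the target tissue.
    """
    if specific_cluster_size >= n_genes:
        raise ValueError("specific_cluster_size must be < n_genes")
    if specific_tissue not in tissues:
        raise ValueError(f"{specific_tissue!r} not among tissues")
    rng = np.random.default_rng(seed)
    n_tissues = len(tissues)
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_genes)
    modules = _broad_module_profiles(n_modules, n_tissues, rng)
    membership = rng.integers(0, n_modules, size=n_genes)
    jitter = rng.normal(0.0, 0.3, size=(n_genes, n_tissues))
    log2_profile = modules[membership] + jitter
    planted = list(rng.choice(genes, size=specific_cluster_size, replace=False))
    t_idx = list(tissues).index(specific_tissue)
    for g in planted:
        i = genes.index(g)
        log2_profile[i] = jitter[i]  # flat background for planted genes
        log2_profile[i, t_idx] += log2_effect
    lam = base[:, None] * np.exp2(log2_profile)
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=genes, columns=list(tissues))
    truth = ExpressionTruth(seed=seed, specific_tissue=specific_tissue,
                            planted_genes=sorted(planted),
                            log2_effect=log2_effect)
    return df, truth


def gen_qpcr(rq_true: dict[str, float], sigma_ct: float = 0.1, seed: int = 0,
             calibrator: str | None = None, target: str = "LcERF94",
             reference: str = "LcActin97", n_bio: int = 3, n_tech: int = 3,
             base_target_ct: float = 24.0, base_reference_ct: float = 18.0,
             ) -> tuple[pd.DataFrame, QpcrTruth]:
    """Synthetic Ct plate realizing the given per-sample fold changes.

    Ct_target = base - log2(RQ_true) + noise and Ct_reference = base_ref
    + noise, with N(0, sigma_ct) noise per technical replicate; the
    calibrator defaults to the first sample and should have RQ_true = 1.
    """
    if sigma_ct < 0:
        raise ValueError("sigma_ct must be >= 0")
    rng = np.random.default_rng(seed)
    samples = list(rq_true)
    if calibrator is None:
        calibrator = samples[0]
    rows = []
    for sample in samples:
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                ct_t = (base_target_ct - np.log2(rq_true[sample])
                        + rng.normal(0.0, sigma_ct))
                ct_r = base_reference_ct + rng.normal(0.0, sigma_ct)
                rows.append((sample, target, bio, tech, float(ct_t)))
                rows.append((sample, reference, bio, tech, float(ct_r)))
    df = pd.DataFrame(rows, columns=["sample", "gene", "bio_rep",
                                     "tech_rep", "ct"])
    truth = QpcrTruth(seed=seed, sigma_ct=sigma_ct,
                      rq_true={s: float(v) for s, v in rq_true.items()},
                      calibrator=calibrator)
    return df, truth


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write protein FASTA, wrapped at `width` columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
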