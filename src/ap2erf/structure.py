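"""Exon/intron structure statistics and conserved-element scanning.

Gene models come from GFF3; intron positions are measured on spliced CDS
coordinates and classed into N-terminal / middle / C-terminal thirds,
matching the long-exon + short-exon geometry typical of single-intron
ERF-branch genes.  Conserved elements (WLG, YLG, RAYD, TGR, AA) are
literal amino-acid words scanned exactly; the two-letter AA element is
only reported inside detected AP2 domains to keep chance hits out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils

from .domains import DomainArchitecture

__all__ = [
    "GeneModel",
    "IntronProfile",
    "read_gene_models",
    "intron_profile",
    "scan_conserved_elements",
    "element_report",
    "write_profiles_tsv",
    "DEFAULT_ELEMENTS",
]

DEFAULT_ELEMENTS = ("WLG", "YLG", "RAYD", "TGR")
#: Short elements scanned only inside detected AP2 domains.
DOMAIN_ONLY_ELEMENTS = ("AA",)


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon intervals of one gene, 0-based half-open, genomic."""

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for s, e in exons:
            if not 0 <= s < e:
                raise ValueError(f"{self.gene_id}: bad exon interval")


@dataclass(frozen=True)
class IntronProfile:
    """Intron count and per-intron position class on spliced coordinates."""

    gene_id: str
    intron_count: int
    position_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.position_classes) != self.intron_count:
            raise ValueError("one position class per intron required")


def read_gene_models(path: str | Path,
                     exon_featuretype: str = "exon") -> list[GeneModel]:
    """Parse gene models (gene -> exon features) from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open.  Exons are collected across all transcripts of a gene and
    deduplicated.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = sorted({(f.start - 1, f.end)
                        for f in db.children(gene, featuretype=exon_featuretype)})
        if not exons:
            continue
        models.append(GeneModel(gene_id=gene.id, strand=gene.strand,
                                exons=tuple(exons)))
    return models


def intron_profile(model: GeneModel) -> IntronProfile:
    """Intron count and thirds-based position classes of one gene model.

    The relative position of an intron is the spliced-CDS fraction 5' of
    it: r < 1/3 -> N-terminal, r > 2/3 -> C-terminal, else middle.
    Minus-strand models are flipped into transcription order first.
    """
    exons = sorted(model.exons)
    if model.strand == "-":
        exons = exons[::-1]
    lengths = [e - s for s, e in exons]
    total = sum(lengths)
    classes: list[str] = []
    cum = 0
    for length in lengths[:-1]:
        cum += length
        r = cum / total
        if r < 1 / 3:
            classes.append("N-terminal")
        elif r > 2 / 3:
            classes.append("C-terminal")
        else:
            classes.append("middle")
    return IntronProfile(gene_id=model.gene_id,
                         intron_count=len(exons) - 1,
                         position_classes=tuple(classes))


def scan_conserved_elements(seq: str, element_set=DEFAULT_ELEMENTS,
                            ) -> list[tuple[str, int]]:
    """All exact occurrences of each element word, 0-based, left to right."""
    hits: list[tuple[str, int]] = []
    for element in element_set:
        start = 0
        while True:
            pos = seq.find(element, start)
            if pos < 0:
                break
            hits.append((element, pos))
            start = pos + 1
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def element_report(seq: str, arch: DomainArchitecture | None = None,
                   ) -> list[tuple[str, int]]:
    """Element hits for one protein; AA restricted to AP2 domain spans."""
    hits = scan_conserved_elements(seq, DEFAULT_ELEMENTS)
    if arch is not None:
        spans = [(h.start, h.end) for h in arch.hits if h.label == "AP2"]
        for element, pos in scan_conserved_elements(seq, DOMAIN_ONLY_ELEMENTS):
            if any(s <= pos and pos + len(element) <= e for s, e in spans):
                hits.append((element, pos))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def write_profiles_tsv(profiles: list[IntronProfile], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tintron_count\tposition_classes\n")
        for p in profiles:
            fh.write(f"{p.gene_id}\t{p.intron_count}\t"
                     f"{','.join(p.position_classes)}\n")
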