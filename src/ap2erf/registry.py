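"""Gene registry I/O and per-protein physicochemical statistics.

The registry is the family ledger of an AP2/ERF survey: one row per gene
with its identifier, genomic location, protein length, intron count and
Nakano-style group label (DREB groups I-IV, ERF groups V-X and VI-L, plus
AP2, RAV and Soloist).  A transcription of the Liriodendron chinense
family table ships with the package and serves as the worked example.

Molecular weight uses average (isotope-abundance weighted) residue masses
and the condensation identity MW = sum(residue masses) + one water.  The
isoelectric point is solved by bisection of the Henderson-Hasselbalch net
charge with per-residue N-terminal pKa values (Bjellqvist/Expasy set).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "GROUPS",
    "GROUP_TO_SUBFAMILY",
    "SUBFAMILIES",
    "GeneRecord",
    "GeneRegistry",
    "ProteinStats",
    "parse_registry",
    "write_registry",
    "packaged_registry",
    "registry_stats",
    "compute_mw_pi",
]

#: Closed set of group labels.
GROUPS = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "VI-L", "AP2", "RAV", "Soloist",
)

#: DREB branch = groups I-IV; ERF branch = V-X plus VI-L.
GROUP_TO_SUBFAMILY = {
    "I": "DREB", "II": "DREB", "III": "DREB", "IV": "DREB",
    "V": "ERF", "VI": "ERF", "VII": "ERF", "VIII": "ERF",
    "IX": "ERF", "X": "ERF", "VI-L": "ERF",
    "AP2": "AP2", "RAV": "RAV", "Soloist": "Soloist",
}

SUBFAMILIES = ("AP2", "DREB", "ERF", "RAV", "Soloist")

_COLUMNS = ("name", "gene_id", "scaffold", "protein_length", "intron_count", "group")


@dataclass(frozen=True)
class GeneRecord:
    """One gene of the family: identity, location, structure, group."""

    name: str
    gene_id: str
    scaffold: str
    protein_length: int
    intron_count: int
    group: str

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError(f"{self.name}: protein_length must be >= 1")
        if self.intron_count < 0:
            raise ValueError(f"{self.name}: intron_count must be >= 0")
        if self.group not in GROUPS:
            raise ValueError(f"{self.name}: unknown group label {self.group!r}")

    @property
    def subfamily(self) -> str:
        return GROUP_TO_SUBFAMILY[self.group]


@dataclass
class GeneRegistry:
    """Ordered collection of GeneRecords with unique names."""

    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.name in seen:
                raise ValueError(f"duplicate gene name: {rec.name}")
            seen.add(rec.name)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> GeneRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)


@dataclass(frozen=True)
class ProteinStats:
    """Molecular weight (Da) and isoelectric point (pH units)."""

    mw: float
    pi: float


def parse_registry(path: str | Path) -> GeneRegistry:
    """Read a registry TSV (UTF-8, '#' comment lines ignored).

    The header row must contain at least the six registry columns;
    extra columns (e.g. provenance notes) are ignored.
    """
    records: list[GeneRecord] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"missing registry columns: {missing}")
                continue
            row = dict(zip(header, fields))
            try:
                length = int(row["protein_length"])
                introns = int(row["intron_count"])
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"line {lineno}: non-integer length/introns ({exc})"
                ) from None
            rec = GeneRecord(
                name=row["name"],
                gene_id=row["gene_id"],
                scaffold=row["scaffold"],
                protein_length=length,
                intron_count=introns,
                group=row["group"],
            )
            if any(r.name == rec.name for r in records):
                raise ValueError(f"duplicate gene name: {rec.name}")
            records.append(rec)
    return GeneRegistry(records)


def write_registry(reg: GeneRegistry, path: str | Path) -> None:
    """Write a registry TSV that :func:`parse_registry` round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for rec in reg:
            fh.write(
                f"{rec.name}\t{rec.gene_id}\t{rec.scaffold}\t"
                f"{rec.protein_length}\t{rec.intron_count}\t{rec.group}\n"
            )


def packaged_registry() -> GeneRegistry:
    """The packaged Liriodendron chinense AP2/ERF family table (104 genes)."""
    ref = resources.files("ap2erf.data") / "liriodendron_ap2erf_registry.tsv"
    with resources.as_file(ref) as path:
        return parse_registry(path)


def registry_stats(reg: GeneRegistry) -> dict:
    """Summary statistics of a registry.

    Returns a dict with length min/max/mean, per-subfamily and per-group
    member counts, and per-subfamily intron min/max.
    """
    if len(reg) == 0:
        raise ValueError("registry is empty")
    lengths = [r.protein_length for r in reg]
    by_group: dict[str, int] = {}
    by_subfamily: dict[str, int] = {}
    introns: dict[str, list[int]] = {}
    for rec in reg:
        by_group[rec.group] = by_group.get(rec.group, 0) + 1
        sf = rec.subfamily
        by_subfamily[sf] = by_subfamily.get(sf, 0) + 1
        introns.setdefault(sf, []).append(rec.intron_count)
    return {
        "n": len(reg),
        "length_min": min(lengths),
        "length_max": max(lengths),
        "length_mean": statistics.mean(lengths),
        "group_counts": by_group,
        "subfamily_counts": by_subfamily,
        "intron_range": {sf: (min(v), max(v)) for sf, v in introns.items()},
    }


# Average residue masses (Da), Expasy table; free amino acid = residue + water.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Side-chain pKa values (Bjellqvist/Expasy).  Acidic groups contribute
# -1/(1+10^(pKa-pH)); basic groups +1/(1+10^(pH-pKa)).
_PKA_SIDECHAIN_ACID = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PKA_SIDECHAIN_BASE = {"H": 5.98, "K": 10.0, "R": 12.0}
_PKA_CTERM = 3.55
# Per-residue N-terminal pKa; residues not listed use the default.
_PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
              "V": 7.44, "E": 7.7}
_PKA_NTERM_DEFAULT = 7.5


def _net_charge(seq: str, ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM.get(seq[0], _PKA_NTERM_DEFAULT)))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    for aa in seq:
        if aa in _PKA_SIDECHAIN_BASE:
            charge += 1.0 / (1.0 + 10 ** (ph - _PKA_SIDECHAIN_BASE[aa]))
        elif aa in _PKA_SIDECHAIN_ACID:
            charge -= 1.0 / (1.0 + 10 ** (_PKA_SIDECHAIN_ACID[aa] - ph))
    return charge


def compute_mw_pi(seq: str) -> ProteinStats:
    """Average molecular weight and isoelectric point of a protein.

    MW sums average residue masses plus one water (peptide-bond
    condensation removes n-1 waters from the free amino-acid masses).
    pI is the pH at which the Henderson-Hasselbalch net charge vanishes,
    found by bisection on [0, 14] to 1e-6 pH units.
    """
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted({aa for aa in seq if aa not in _RESIDUE_MASS})
    if bad:
        raise ValueError(f"unknown amino-acid letter(s): {''.join(bad)}")
    mw = sum(_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
    lo, hi = 0.0, 14.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return ProteinStats(mw=mw, pi=0.5 * (lo + hi))
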