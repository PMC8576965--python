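"""Subfamily and group assignment from domain architecture.

The AP2/ERF superfamily partitions on domain counts alone: two AP2
domains -> AP2 subfamily; one AP2 plus a B3 domain -> RAV; a single AP2
domain homologous to the Arabidopsis Soloist reference -> Soloist; any
other single-AP2 protein belongs to the ERF superfamily, which splits
into the DREB branch (diagnostic residues V14/E19 in the domain frame)
and the ERF branch (A14/D19).  Within the two branches, Nakano-style
groups (I-IV for DREB; V-X and VI-L for ERF) are assigned by majority
vote among the k nearest group-labelled reference domains by global-
alignment percent identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .domains import DomainArchitecture, scan_architecture
from .phylo import global_align, percent_identity
from .references import (
    AP2_FRAME_WIDTH,
    DREB_CORE,
    DREB_GROUPS,
    ERF_GROUPS,
    synthetic_reference_panel,
)
from .registry import GROUP_TO_SUBFAMILY

__all__ = [
    "SubfamilyCall",
    "ReferencePanel",
    "classify_architecture",
    "split_dreb_erf",
    "assign_group",
    "map_to_frame",
    "classify_protein",
    "classify_proteins",
    "write_calls_tsv",
    "DEFAULT_SOLOIST_MIN_IDENTITY",
]

#: Minimum global percent identity to the Soloist reference domain for a
#: single-AP2 protein to be called Soloist.  Permissive because the
#: lineage is defined by homology to one divergent gene, strict enough
#: to reject ERF-branch domains (which sit far below 40% here).
DEFAULT_SOLOIST_MIN_IDENTITY = 40.0

# 0-based frame positions of the diagnostic residues (columns 14 and 19).
_DIAG_POS = (13, 18)


@dataclass(frozen=True)
class SubfamilyCall:
    """Subfamily + group + the evidence rules that fired."""

    protein: str
    subfamily: str
    group: str
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.subfamily == "DREB" and self.group not in DREB_GROUPS:
            raise ValueError(f"{self.protein}: DREB call needs group I-IV")
        if self.subfamily == "ERF" and self.group not in ERF_GROUPS:
            raise ValueError(f"{self.protein}: ERF call needs group V-X/VI-L")
        if GROUP_TO_SUBFAMILY.get(self.group) is None:
            raise ValueError(f"{self.protein}: unknown group {self.group!r}")


@dataclass
class ReferencePanel:
    """Group-labelled reference domains plus the Soloist reference."""

    entries: list[tuple[str, str]]
    soloist_ref: str

    def __post_init__(self) -> None:
        labels = {g for _, g in self.entries}
        required = set(DREB_GROUPS) | set(ERF_GROUPS) | {"AP2", "RAV", "Soloist"}
        missing = required - labels
        if missing:
            raise ValueError(f"panel missing groups: {sorted(missing)}")


def map_to_frame(domain_seq: str, frame_ref: str = DREB_CORE) -> str:
    """Project a domain sequence onto the 58-column reference frame.

    Global alignment against the frame reference; insertion columns
    (gaps in the reference) are dropped, deletions appear as '-'.
    """
    ra, rb, _ = global_align(domain_seq, frame_ref)
    frame = [q for q, r in zip(ra, rb) if r != "-"]
    assert len(frame) == len(frame_ref)
    return "".join(frame)


def split_dreb_erf(frame_seq: str) -> str | None:
    """DREB/ERF branch call from the diagnostic frame columns 14 and 19.

    Returns "DREB" for V14+E19, "ERF" for A14+D19, and None for any
    other combination or a gap at a diagnostic column (callers fall back
    to the nearest-reference vote).
    """
    if len(frame_seq) < AP2_FRAME_WIDTH:
        return None
    c14, c19 = frame_seq[_DIAG_POS[0]], frame_seq[_DIAG_POS[1]]
    if c14 == "V" and c19 == "E":
        return "DREB"
    if c14 == "A" and c19 == "D":
        return "ERF"
    return None


def assign_group(domain_seq: str, panel: ReferencePanel, k: int = 3,
                 restrict: tuple[str, ...] | None = None) -> str:
    """Majority group among the k nearest panel references by identity.

    Ties go to the group of the single best-identity neighbour, and
    neighbour order itself is deterministic (identity, then panel
    index).  restrict limits the vote to a subset of group labels.
    """
    entries = [(s, g) for s, g in panel.entries
               if restrict is None or g in restrict]
    if not entries:
        raise ValueError("empty reference panel")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd number")
    if k > len(entries):
        raise ValueError(f"k={k} exceeds panel size {len(entries)}")
    scored = sorted(
        ((percent_identity(domain_seq, s), idx, g)
         for idx, (s, g) in enumerate(entries)),
        key=lambda t: (-t[0], t[1]))
    top = scored[:k]
    votes: dict[str, int] = {}
    for _, _, g in top:
        votes[g] = votes.get(g, 0) + 1
    best_count = max(votes.values())
    winners = [g for g, c in votes.items() if c == best_count]
    if len(winners) == 1:
        return winners[0]
    return top[0][2]


def classify_architecture(arch: DomainArchitecture, panel: ReferencePanel,
                          seq: str,
                          soloist_min_identity: float = DEFAULT_SOLOIST_MIN_IDENTITY,
                          ) -> tuple[str, tuple[str, ...]]:
    """Subfamily-level call from domain counts and Soloist homology.

    Returns (subfamily, evidence); "ERF-superfamily" is returned for
    single-AP2 proteins pending the DREB/ERF split.
    """
    n_ap2 = arch.count("AP2")
    if n_ap2 == 0:
        raise ValueError(f"{arch.protein}: not an AP2/ERF gene (no AP2 domain)")
    if n_ap2 >= 2:
        return "AP2", ("double-AP2-domain",)
    if arch.count("B3") >= 1:
        return "RAV", ("single-AP2+B3-domain",)
    hit = next(h for h in arch.hits if h.label == "AP2")
    domain = seq[hit.start:hit.end]
    pid = percent_identity(domain, panel.soloist_ref)
    if pid >= soloist_min_identity:
        return "Soloist", (f"soloist-identity-{pid:.0f}pct",)
    return "ERF-superfamily", ("single-AP2-domain",)


def classify_protein(name: str, seq: str,
                     panel: ReferencePanel | None = None,
                     arch: DomainArchitecture | None = None,
                     k: int = 3,
                     soloist_min_identity: float = DEFAULT_SOLOIST_MIN_IDENTITY,
                     ) -> SubfamilyCall:
    """Full classification of one protein.

    Scans for domains unless an architecture is supplied, applies the
    architecture rules, then resolves the DREB/ERF branch (diagnostic
    residues first, nearest-reference vote as fallback) and the group.
    """
    if panel is None:
        panel = synthetic_reference_panel()
    if arch is None:
        arch = scan_architecture(name, seq)
    subfamily, evidence = classify_architecture(
        arch, panel, seq, soloist_min_identity=soloist_min_identity)
    if subfamily != "ERF-superfamily":
        return SubfamilyCall(protein=name, subfamily=subfamily,
                             group=subfamily, evidence=evidence)
    hit = next(h for h in arch.hits if h.label == "AP2")
    domain = seq[hit.start:hit.end]
    frame = map_to_frame(domain)
    branch = split_dreb_erf(frame)
    if branch is not None:
        c14, c19 = frame[_DIAG_POS[0]], frame[_DIAG_POS[1]]
        evidence = evidence + (f"diagnostic-{c14}14{c19}19",)
        groups = DREB_GROUPS if branch == "DREB" else ERF_GROUPS
        group = assign_group(domain, panel, k=k, restrict=groups)
    else:
        evidence = evidence + ("diagnostic-fallback-knn",)
        group = assign_group(domain, panel, k=k,
                             restrict=DREB_GROUPS + ERF_GROUPS)
        branch = GROUP_TO_SUBFAMILY[group]
    evidence = evidence + (f"knn-group-{group}",)
    return SubfamilyCall(protein=name, subfamily=branch, group=group,
                         evidence=evidence)


def classify_proteins(seqs: dict[str, str],
                      panel: ReferencePanel | None = None,
                      k: int = 3,
                      soloist_min_identity: float = DEFAULT_SOLOIST_MIN_IDENTITY,
                      skip_unscannable: bool = True) -> list[SubfamilyCall]:
    """Classify a whole FASTA worth of proteins, preserving input order.

    Proteins in which no AP2 domain is found are skipped (they are not
    family members) unless skip_unscannable is False, in which case they
    raise.
    """
    if panel is None:
        panel = synthetic_reference_panel()
    calls: list[SubfamilyCall] = []
    for name, seq in seqs.items():
        arch = scan_architecture(name, seq)
        if arch.count("AP2") == 0:
            if skip_unscannable:
                continue
            raise ValueError(f"{name}: not an AP2/ERF gene (no AP2 domain)")
        calls.append(classify_protein(name, seq, panel=panel, arch=arch,
                                      k=k,
                                      soloist_min_identity=soloist_min_identity))
    return calls


def write_calls_tsv(calls: list[SubfamilyCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tsubfamily\tgroup\tevidence\n")
        for c in calls:
            fh.write(f"{c.protein}\t{c.subfamily}\t{c.group}\t"
                     f"{';'.join(c.evidence)}\n")
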