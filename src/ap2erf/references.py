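"""Synthetic AP2/B3 reference frame, seed alignments and group panel.

Everything in this module is SYNTHETIC: the domain cores are constructed
sequences that reproduce the diagnostic geometry of the real AP2 domain
family — a fixed 58-column frame with the DREB/ERF diagnostic residues at
frame columns 14 and 19 (V/E in DREB, A/D in ERF), the WLG tripeptide at
columns 28-30 in the ERF branch (converted to YLG in the AP2-subfamily
core, which also carries TGR and RAYD), and a strongly diverged Soloist
lineage — without shipping any third-party database content.  They are
the stand-in for a curated Arabidopsis reference set.

The panel maps group labels (I-X, VI-L, AP2, RAV, Soloist) to frame-width
domain sequences; each of the eleven DREB/ERF-branch groups gets a
deterministic template plus two close variants so that nearest-neighbour
group assignment has a proper majority to vote with.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "AP2_FRAME_WIDTH",
    "DIAGNOSTIC_COLUMNS",
    "DREB_CORE",
    "ERF_CORE",
    "AP2_CORE",
    "SOLOIST_CORE",
    "B3_CORE",
    "DREB_GROUPS",
    "ERF_GROUPS",
    "group_templates",
    "ap2_seed_alignment",
    "b3_seed_alignment",
    "synthetic_reference_panel",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Width of the AP2-domain reference frame (columns, 1-based in docs).
AP2_FRAME_WIDTH = 58

#: 1-based frame columns carrying the DREB/ERF diagnostic residues.
DIAGNOSTIC_COLUMNS = (14, 19)

# ERF-branch core with V14/E19 (DREB diagnostic) and WLG at 28-30,
# AA at 38-39 and RAYD at 40-43.
DREB_CORE = "RHYRGVRQRPWGKVAEIREPKKSARVQWLGTFDTAEEAARAYDRAALKFRGPRAKTNF"
# Same frame with the ERF diagnostic pair A14/D19.
ERF_CORE = DREB_CORE[:13] + "A" + DREB_CORE[14:18] + "D" + DREB_CORE[19:]
# AP2-subfamily core: YLG instead of WLG, TGR element, RAYD retained,
# plus scattered divergence from the ERF branch.
AP2_CORE = "RSYRGKRQRAWGKGAEIRDPKESARVQYLGTGRTSEEAARAYDKAALKYRGPRASTNF"
# Soloist core: a single strongly diverged lineage, detectable only
# because it is represented in the scoring model, exactly like the
# divergent Soloist clade inside the real family.  Derived from the
# DREB core by a fixed alphabet shift everywhere except eight anchor
# columns (including WLG), leaving ~14% identity to the ERF branch —
# divergent, but never saturating a pairwise Poisson distance.
_SOLOIST_ANCHORS = frozenset({0, 4, 27, 28, 29, 39, 44, 57})


def _fixed_divergence(seq: str, anchors: frozenset, shift: int = 7) -> str:
    return "".join(
        c if i in anchors else AMINO_ACIDS[(AMINO_ACIDS.index(c) + shift) % 20]
        for i, c in enumerate(seq))


SOLOIST_CORE = _fixed_divergence(DREB_CORE, _SOLOIST_ANCHORS)

# B3 DNA-binding domain core (RAV subfamily second domain), 40 columns.
B3_CORE = "FEKVLTPSDVGKLNRLVIPKQHAERYFPLDSSNNQKGVLL"

DREB_GROUPS = ("I", "II", "III", "IV")
ERF_GROUPS = ("V", "VI", "VII", "VIII", "IX", "X", "VI-L")

# Frame positions (0-based) that group variants must not touch:
# diagnostics at 13/18 and the WLG/YLG tripeptide at 27-29.
_ANCHORED = frozenset({13, 18, 27, 28, 29})


def _check_lengths() -> None:
    for core in (DREB_CORE, ERF_CORE, AP2_CORE, SOLOIST_CORE):
        assert len(core) == AP2_FRAME_WIDTH


_check_lengths()


def _mutate(seq: str, n_subs: int, rng: np.random.Generator,
            protect: frozenset = _ANCHORED) -> str:
    """Substitute n_subs non-anchored positions with different letters."""
    free = [i for i in range(len(seq)) if i not in protect]
    positions = rng.choice(len(free), size=n_subs, replace=False)
    chars = list(seq)
    for idx in positions:
        pos = free[idx]
        choices = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def group_templates() -> dict[str, str]:
    """Frozen per-group domain templates on the 58-column frame.

    DREB groups I-IV derive from the DREB core (V14/E19 preserved), ERF
    groups V-X and VI-L from the ERF core (A14/D19 preserved); each group
    template carries six fixed substitutions elsewhere in the frame.
    """
    rng = np.random.default_rng(758104)  # frozen: templates are reference data
    templates: dict[str, str] = {}
    for group in DREB_GROUPS:
        templates[group] = _mutate(DREB_CORE, 6, rng)
    for group in ERF_GROUPS:
        templates[group] = _mutate(ERF_CORE, 6, rng)
    templates["AP2"] = AP2_CORE
    templates["RAV"] = _mutate(DREB_CORE, 6, rng)
    templates["Soloist"] = SOLOIST_CORE
    return templates


def ap2_seed_alignment() -> list[str]:
    """Gapless seed alignment used to train the AP2-domain scoring matrix.

    Contains every branch template, the AP2-subfamily core and variant,
    and three Soloist rows; without the Soloist representation the
    scoring model would never recover that divergent lineage.
    """
    rng = np.random.default_rng(758105)
    templates = group_templates()
    rows = [templates[g] for g in DREB_GROUPS + ERF_GROUPS]
    rows.append(AP2_CORE)
    rows.append(_mutate(AP2_CORE, 3, rng))
    rows.append(SOLOIST_CORE)
    rows.append(_mutate(SOLOIST_CORE, 2, rng))
    rows.append(_mutate(SOLOIST_CORE, 2, rng))
    return rows


def b3_seed_alignment() -> list[str]:
    """Seed alignment for the B3-domain scoring matrix (RAV subfamily)."""
    rng = np.random.default_rng(758106)
    return [B3_CORE] + [_mutate(B3_CORE, 3, rng, protect=frozenset())
                        for _ in range(4)]


def synthetic_reference_panel():
    """Group-labelled reference panel for nearest-neighbour placement.

    Returns a :class:`ap2erf.classify.ReferencePanel` with three entries
    per DREB/ERF-branch group (template + two two-substitution variants),
    two AP2 entries, one RAV and the Soloist reference.
    """
    from .classify import ReferencePanel

    rng = np.random.default_rng(758107)
    templates = group_templates()
    entries: list[tuple[str, str]] = []
    for group in DREB_GROUPS + ERF_GROUPS:
        base = templates[group]
        entries.append((base, group))
        entries.append((_mutate(base, 2, rng), group))
        entries.append((_mutate(base, 2, rng), group))
    entries.append((AP2_CORE, "AP2"))
    entries.append((_mutate(AP2_CORE, 2, rng), "AP2"))
    entries.append((templates["RAV"], "RAV"))
    entries.append((SOLOIST_CORE, "Soloist"))
    return ReferencePanel(entries=entries, soloist_ref=SOLOIST_CORE)
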