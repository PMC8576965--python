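"""Poisson-corrected neighbor-joining phylogeny with bootstrap supports.

Distances between aligned domain sequences use the Poisson correction
d = -ln(1 - p) for the proportion p of differing comparable sites; trees
are built with the Saitou-Nei neighbor-joining agglomeration and supports
come from column-resampling bootstrap over the alignment.  Trees are
dendropy objects, so newick I/O and tree comparison come for free.

All tie-breaks (alignment traceback, Q-matrix minima) are index-based and
documented, making every tree bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "MSA",
    "DistanceMatrix",
    "global_align",
    "percent_identity",
    "poisson_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "write_newick",
    "parse_newick",
]


@dataclass
class MSA:
    """Equal-length aligned sequences ('-' = gap) with unique names."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, cols: np.ndarray) -> "MSA":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return MSA(names=list(self.names), rows=rows)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site)."""

    names: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.names)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match names")
        if not np.isfinite(self.d).all():
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if (np.diag(self.d) != 0).any() or (self.d < 0).any():
            raise ValueError("need zero diagonal and non-negative entries")


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                 gap: float = -2.0) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment under a linear gap model.

    Traceback ties prefer diagonal over up (gap in b) over left (gap in
    a), so the reported alignment is deterministic.  An empty input
    aligns as all gaps against the other sequence.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[1:, 0] = gap * np.arange(1, n + 1)
    score[0, 1:] = gap * np.arange(1, m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row_prev = score[i - 1]
        row = score[i]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            row[j] = max(diag, row_prev[j] + gap, row[j - 1] + gap)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            if score[i, j] == diag:
                out_a.append(a[i - 1]); out_b.append(b[j - 1])
                i -= 1; j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append("-")
            i -= 1
            continue
        out_a.append("-"); out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])


def percent_identity(a: str, b: str, **align_kwargs) -> float:
    """Global-alignment percent identity (matches / alignment columns)."""
    ra, rb, _ = global_align(a, b, **align_kwargs)
    if not ra:
        return 0.0
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return 100.0 * matches / len(ra)


def poisson_distance(row_a: str, row_b: str) -> float:
    """Poisson-corrected distance d = -ln(1-p) over gap-free columns.

    Only columns where neither row has a gap are comparable.  A pair with
    p = 1 is saturated and raises, as does a pair with no comparable
    sites.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    comparable = 0
    diff = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise ValueError("zero comparable sites")
    p = diff / comparable
    if p >= 1.0:
        raise ValueError("saturated pair (p = 1)")
    return -math.log(1.0 - p)


def distance_matrix(msa: MSA, deletion: str = "pairwise") -> DistanceMatrix:
    """Poisson distance matrix from an MSA.

    deletion="pairwise" drops, per pair, columns gapped in either row;
    deletion="complete" first drops every column gapped in any row.
    """
    rows = msa.rows
    if deletion == "complete":
        keep = [c for c in range(msa.n_sites)
                if all(r[c] != "-" for r in rows)]
        rows = ["".join(r[c] for c in keep) for r in rows]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(rows[i], rows[j])
    return DistanceMatrix(names=list(msa.names), d=d)


def _new_tree(taxon_names: list[str]) -> tuple[dendropy.Tree, list[dendropy.Node]]:
    ns = dendropy.TaxonNamespace(taxon_names)
    tree = dendropy.Tree(taxon_namespace=ns)
    leaves = []
    for name in taxon_names:
        node = dendropy.Node(taxon=ns.get_taxon(name))
        leaves.append(node)
    return tree, leaves


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; ties in Q broken by smallest (i, j).

    Negative branch lengths are clamped to zero.  The returned dendropy
    tree is flagged unrooted; with three or more taxa its seed node is
    the final trifurcation.
    """
    names = list(dm.names)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    tree, nodes = _new_tree(names)
    if n == 2:
        root = dendropy.Node()
        half = max(dm.d[0, 1] / 2.0, 0.0)
        for node in nodes:
            root.add_child(node)
            node.edge.length = half
        tree.seed_node = root
        tree.is_rooted = False
        return tree

    active = list(range(n))
    d = {(i, j): dm.d[i, j] for i in range(n) for j in range(n)}
    next_id = n
    node_of = dict(enumerate(nodes))

    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(d[min(i, k), max(i, k)] for k in active if k != i)
                   for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - row_sum[i] - row_sum[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (row_sum[i] - row_sum[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(node_of[i]); node_of[i].edge.length = max(li, 0.0)
        parent.add_child(node_of[j]); node_of[j].edge.length = max(lj, 0.0)
        node_of[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[min(i, k), max(i, k)] + d[min(j, k), max(j, k)] - d[i, j])
            d[(k, next_id)] = d[(next_id, k)] = dk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    dij = d[min(i, j), max(i, j)]
    dik = d[min(i, k), max(i, k)]
    djk = d[min(j, k), max(j, k)]
    center = dendropy.Node()
    for idx, length in ((i, (dij + dik - djk) / 2.0),
                        (j, (dij + djk - dik) / 2.0),
                        (k, (dik + djk - dij) / 2.0)):
        center.add_child(node_of[idx])
        node_of[idx].edge.length = max(length, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits as canonical frozensets of leaf names.

    Each internal edge induces a split; the side not containing the
    lexicographically first taxon is kept, and splits with fewer than two
    names on either side are dropped.
    """
    leaf_names = sorted(t.label for t in tree.taxon_namespace)
    all_names = frozenset(leaf_names)
    anchor = leaf_names[0]
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_names - side
        if 2 <= len(side) <= len(all_names) - 2:
            splits.add(side)
    return splits


def bootstrap_support(msa: MSA, n_reps: int = 1000, seed: int = 0,
                      deletion: str = "pairwise") -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports in [0, 100].

    Columns are resampled with replacement per replicate; replicate r
    uses the r-th block of pre-drawn indices from a single seeded PCG64
    generator, so results do not depend on evaluation order.  Replicates
    with saturated pairs are skipped with a warning; more than 50%
    skipped is an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = nj_tree(distance_matrix(msa, deletion=deletion))
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, msa.n_sites, size=(n_reps, msa.n_sites))
    counts: dict[frozenset, int] = {}
    skipped = 0
    for r in range(n_reps):
        rep = msa.resample_columns(draws[r])
        try:
            rep_tree = nj_tree(distance_matrix(rep, deletion=deletion))
        except ValueError:
            skipped += 1
            warnings.warn(f"bootstrap replicate {r} skipped (saturated pair)")
            continue
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    valid = n_reps - skipped
    if valid < n_reps / 2.0:
        raise ValueError(f"more than half of bootstrap replicates skipped "
                         f"({skipped}/{n_reps})")
    leaf_names = sorted(t.label for t in full.taxon_namespace)
    all_names = frozenset(leaf_names)
    anchor = leaf_names[0]
    for node in full.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_names - side
        if not (2 <= len(side) <= len(all_names) - 2):
            continue
        support = 100.0 * counts.get(side, 0) / valid
        node.support = support
        node.label = f"{support:.0f}"
    return full


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Newick string with supports as internal-node labels."""
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True).strip() + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s)
    return s


def parse_newick(source: str) -> dendropy.Tree:
    """Parse a newick string (internal labels read back as supports)."""
    tree = dendropy.Tree.get(data=source, schema="newick",
                             suppress_internal_node_taxa=True)
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree
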