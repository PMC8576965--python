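"""Alignment, Poisson distances, NJ reconstruction and bootstrap."""

import itertools
import math

import numpy as np
import pytest

from ap2erf.phylo import (
    MSA,
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    global_align,
    nj_tree,
    parse_newick,
    poisson_distance,
    write_newick,
)

# ---------------------------------------------------------------- oracles


def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies as edge lists, by leaf insertion."""
    assert len(taxa) >= 3
    first = [("internal0", t) for t in taxa[:3]]
    trees = [(first, 1)]
    for taxon in taxa[3:]:
        nxt = []
        for edges, n_int in trees:
            for i in range(len(edges)):
                u, v = edges[i]
                mid = f"internal{n_int}"
                new_edges = edges[:i] + edges[i + 1:]
                new_edges += [(u, mid), (mid, v), (mid, taxon)]
                nxt.append((new_edges, n_int + 1))
        trees = nxt
    return [e for e, _ in trees]


def tree_paths(edges, taxa):
    """Leaf-pair -> list of edge indices, via DFS on the edge list."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = {}
    for a, b in itertools.combinations(taxa, 2):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, path = stack.pop()
            if node == b:
                paths[(a, b)] = path
                break
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, path + [eidx]))
    return paths


def least_squares_fit(edges, taxa, dmat):
    """Least-squares branch lengths for a fixed topology; returns residual."""
    paths = tree_paths(edges, taxa)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for eidx in paths[(taxa[i], taxa[j])]:
            A[row, eidx] = 1.0
        y[row] = dmat[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


def splits_of_edges(edges, taxa):
    """Non-trivial splits of a topology, canonicalized like bipartitions()."""
    taxa_sorted = sorted(taxa)
    anchor = taxa_sorted[0]
    allset = frozenset(taxa)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    splits = set()
    for u, v in edges:
        # leaves reachable from v without crossing u
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node in taxa:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        fs = frozenset(side)
        if anchor in fs:
            fs = allset - fs
        if 2 <= len(fs) <= len(taxa) - 2:
            splits.add(fs)
    return splits


def random_additive_matrix(taxa, rng):
    """Distances generated by a random topology with random edge lengths."""
    topos = enumerate_unrooted_topologies(taxa)
    edges = topos[rng.integers(len(topos))]
    lengths = rng.uniform(0.05, 1.0, size=len(edges))
    paths = tree_paths(edges, taxa)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = sum(lengths[e] for e in paths[(taxa[i], taxa[j])])
    return d, edges


def tree_path_lengths(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


# ----------------------------------------------------------------- tests


class TestGlobalAlign:
    def test_identical_sequences_align_gapless(self):
        ra, rb, score = global_align("WLGTF", "WLGTF", match=1, mismatch=-1,
                                     gap=-1)
        assert (ra, rb) == ("WLGTF", "WLGTF")
        assert score == 5

    def test_leading_gap_case_matches_enumeration(self):
        # alignments of "AC" vs "C": best is gap + match = 0
        ra, rb, score = global_align("AC", "C", match=1, mismatch=-1, gap=-1)
        assert score == 0
        assert (ra, rb) == ("AC", "-C")

    def test_empty_sequence_forces_all_gaps(self):
        ra, rb, score = global_align("", "AAA", match=1, mismatch=-1, gap=-1)
        assert (ra, rb) == ("---", "AAA")
        assert score == -3


class TestPoissonDistance:
    def test_identical_rows_have_zero_distance(self):
        assert poisson_distance("WLGTF", "WLGTF") == 0.0

    def test_half_different_gives_ln2(self):
        assert poisson_distance("AAAA", "AACC") == pytest.approx(math.log(2))

    def test_gapped_columns_match_hand_count(self):
        a = "AW-LD-G"
        b = "AWK-DCG"
        # comparable columns: 0,1,4,5,6 -> wait 3 has gap in a? count by hand:
        # col0 A/A ok match; col1 W/W match; col2 -/K skip; col3 L/- skip;
        # col4 D/D match; col5 -/C skip; col6 G/G match -> p = 0/4
        assert poisson_distance(a, b) == 0.0
        c = "AWQD"
        d_ = "AW-C"
        # comparable: cols 0,1,3 -> one difference
        assert poisson_distance(c, d_) == pytest.approx(-math.log(1 - 1 / 3))

    def test_saturated_pair_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            poisson_distance("AAAA", "CCCC")

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            poisson_distance("A-", "-A")

    def test_complete_vs_pairwise_deletion(self):
        msa = MSA(names=["a", "b", "c"],
                  rows=["AAWW", "AC-W", "ACWW"])
        pw = distance_matrix(msa, deletion="pairwise")
        # a-b comparable over cols 0,1,3 (col2 gapped in b)
        assert pw.d[0, 1] == pytest.approx(-math.log(1 - 1 / 3))
        comp = distance_matrix(msa, deletion="complete")
        # col2 dropped for everyone: a-c differ at col1 only, over 3 cols
        assert comp.d[0, 2] == pytest.approx(-math.log(1 - 1 / 3))


class TestNJ:
    def test_two_taxa_split_edge_equally(self):
        t = nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]])))
        dist = tree_path_lengths(t)
        assert dist("A", "B") == pytest.approx(0.4)
        for leaf in t.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.2)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        x = (0.3 + 0.5 - 0.6) / 2  # edge to A
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(x)
        assert lengths["B"] == pytest.approx(0.3 - x)
        assert lengths["C"] == pytest.approx(0.5 - x)

    def test_additive_four_taxon_recovers_generating_tree(self):
        d = np.array([[0, 3, 8, 9], [3, 0, 9, 10],
                      [8, 9, 0, 9], [9, 10, 9, 0]], float)
        taxa = ["A", "B", "C", "D"]
        t = nj_tree(DistanceMatrix(taxa, d))
        dist = tree_path_lengths(t)
        for i, j in itertools.combinations(range(4), 2):
            assert dist(taxa[i], taxa[j]) == pytest.approx(d[i, j], abs=1e-9)
        # among all 3 unrooted topologies, the NJ one minimizes least squares
        topos = enumerate_unrooted_topologies(taxa)
        residuals = [least_squares_fit(e, taxa, d) for e in topos]
        best = topos[int(np.argmin(residuals))]
        assert splits_of_edges(best, taxa) == bipartitions(t)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, np.inf], [np.inf, 0]]))

    def test_matches_scikit_bio_on_random_matrix(self):
        """Independent cross-check: identical topology to skbio's NJ."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        taxa = [f"t{i}" for i in range(7)]
        d, _ = random_additive_matrix(taxa, rng)
        d += rng.uniform(0, 0.01, size=d.shape)  # mild noise, keep symmetric
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ours = nj_tree(DistanceMatrix(taxa, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
        theirs_dp = parse_newick(str(theirs))
        assert bipartitions(theirs_dp) == bipartitions(ours)


class TestBootstrap:
    def test_tree_consistent_signal_gives_full_support(self):
        # constant block + a perfectly tree-consistent signal block
        rows = {"A": "GGGGG" + "AAAAA" + "CC",
                "B": "GGGGG" + "AAAAA" + "CC",
                "C": "GGGGG" + "CCCCC" + "CC",
                "D": "GGGGG" + "CCCCC" + "CG"}
        msa = MSA(names=list(rows), rows=list(rows.values()))
        t = bootstrap_support(msa, n_reps=100, seed=3)
        supports = [n.support for n in t.preorder_node_iter()
                    if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(9)
        names = ["A", "B", "C", "D", "E"]
        rows = ["".join("ACDEF"[rng.integers(5)] for _ in range(40))
                for _ in names]
        msa = MSA(names=names, rows=rows)
        s1 = write_newick(bootstrap_support(msa, n_reps=50, seed=7))
        s2 = write_newick(bootstrap_support(msa, n_reps=50, seed=7))
        assert s1 == s2

    def test_conflicting_sites_match_multinomial_oracle(self):
        """70/30 conflicting site patterns: the majority split's support
        tracks the resampling probability that its pattern stays in the
        majority, estimated by direct multinomial simulation."""
        p1 = {"A": "A", "B": "A", "C": "C", "D": "C"}   # AB|CD
        p2 = {"A": "A", "B": "C", "C": "A", "D": "C"}   # AC|BD
        n1, n2, nc = 70, 30, 20  # plus constant columns to avoid saturation
        rows = {t: p1[t] * n1 + p2[t] * n2 + "G" * nc for t in "ABCD"}
        msa = MSA(names=list(rows), rows=list(rows.values()))
        t = bootstrap_support(msa, n_reps=200, seed=11)
        # canonicalization keeps the side lacking the first taxon 'A'
        supports = {tuple(sorted(s)): c for s, c in
                    _support_map(t).items()}
        got = supports[("C", "D")]
        rng = np.random.default_rng(99)
        n_sites = n1 + n2 + nc
        draws = rng.multinomial(n_sites, [n1 / n_sites, n2 / n_sites,
                                          nc / n_sites], size=5000)
        wins = (draws[:, 0] > draws[:, 1]).mean()
        assert got == pytest.approx(100 * wins, abs=10)

    def test_saturated_replicates_skipped_with_warning(self):
        # one matching + one differing column: a replicate drawing only
        # the differing column saturates every pair and must be skipped
        msa = MSA(names=["A", "B", "C"], rows=["AG", "AC", "AT"])
        with pytest.warns(UserWarning, match="skipped"):
            bootstrap_support(msa, n_reps=40, seed=1)

    def test_fully_saturated_alignment_is_an_error(self):
        msa = MSA(names=["A", "B", "C"], rows=["AAAA", "CCCC", "GGGG"])
        with pytest.raises(ValueError, match="saturated"):
            bootstrap_support(msa, n_reps=10, seed=1)


def _support_map(tree):
    out = {}
    leaf_names = sorted(t.label for t in tree.taxon_namespace)
    allset = frozenset(leaf_names)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if not hasattr(node, "support"):
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leaf_names[0] in side:
            side = allset - side
        out[side] = node.support
    return out


class TestNewickRoundTrip:
    def test_topology_lengths_and_supports_survive(self):
        rows = {"A": "GGGGG" + "AAAAACCCCC", "B": "GGGGG" + "AAAAACCCCG",
                "C": "GGGGG" + "CCCCCAAAAA", "D": "GGGGG" + "CCCCGAAAAA",
                "E": "GGGGG" + "CCCGGAAAAA"}
        msa = MSA(names=list(rows), rows=list(rows.values()))
        t = bootstrap_support(msa, n_reps=50, seed=2)
        s = write_newick(t)
        back = parse_newick(s)
        assert bipartitions(back) == bipartitions(t)
        d1, d2 = tree_path_lengths(t), tree_path_lengths(back)
        for a, b in itertools.combinations(rows, 2):
            assert d1(a, b) == pytest.approx(d2(a, b), abs=1e-9)
        assert _support_map(back).keys() == _support_map(t).keys()
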