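"""Neighbor joining (against additive-tree and scikit-bio oracles), Newick
round-trips via dendropy, and non-metric MDS behaviour."""

import io

import dendropy
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ystrkit import (
    DistanceMatrix,
    ValidationError,
    clamp_distances,
    neighbor_joining,
    nmds,
    patristic_distances,
    sum_branch_lengths,
    to_newick,
)


def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """Distances generated from a random tree; oracle independent of NJ.

    Builds a random binary topology by sequentially attaching leaves with
    positive branch lengths and accumulates leaf-to-leaf path lengths
    directly.
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    # adjacency: node -> list of (node, length); leaves are labels,
    # internal nodes are ints
    adj = {labels[0]: [], labels[1]: []}
    length = lambda: float(rng.uniform(0.1, 2.0))
    l01 = length()
    adj[labels[0]].append((labels[1], l01))
    adj[labels[1]].append((labels[0], l01))
    edges = [(labels[0], labels[1])]
    next_internal = 0
    for leaf in labels[2:]:
        a, b = edges[rng.integers(len(edges))]
        w = next((l for nb, l in adj[a] if nb == b))
        mid = next_internal
        next_internal += 1
        # split edge (a, b) at `mid`, hang the new leaf off it
        adj[a] = [(nb, l) for nb, l in adj[a] if nb != b]
        adj[b] = [(nb, l) for nb, l in adj[b] if nb != a]
        cut = float(rng.uniform(0.05, 0.95)) * w
        adj[mid] = [(a, cut), (b, w - cut)]
        adj[a].append((mid, cut))
        adj[b].append((mid, w - cut))
        l_leaf = length()
        adj[leaf] = [(mid, l_leaf)]
        adj[mid].append((leaf, l_leaf))
        edges = [e for e in edges if e != (a, b)] + [(a, mid), (mid, b), (mid, leaf)]
    # BFS path lengths between leaves
    d = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, l in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + l
                    stack.append(nb)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(labels), d=d)


def dendropy_patristic(newick: str):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


class TestClamp:
    def test_nonnegative_unchanged(self):
        dm = DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, 0.3], [0.3, 0.0]]))
        out = clamp_distances(dm)
        assert np.array_equal(out.d, dm.d) and out.n_clamped == 0

    def test_negative_entry_zeroed(self):
        dm = DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, -0.0017], [-0.0017, 0.0]]))
        out = clamp_distances(dm)
        assert out.d[0, 1] == 0.0 and out.n_clamped == 2

    def test_idempotent(self):
        dm = DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, -0.5], [-0.5, 0.0]]))
        once = clamp_distances(dm)
        twice = clamp_distances(once)
        assert np.array_equal(once.d, twice.d)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError, match="asymmetric"):
            DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxon_worked_example(self):
        dm = DistanceMatrix(
            labels=("A", "B", "C"),
            d=np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float),
        )
        tree = neighbor_joining(dm)
        lengths = sorted(leaf.length for leaf in tree.leaves())
        assert lengths == [1.0, 1.0, 2.0]
        assert sum_branch_lengths(tree) == 4.0

    def test_four_taxon_additive_recovery(self):
        d = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], dtype=float
        )
        dm = DistanceMatrix(labels=("a", "b", "c", "d"), d=d)
        tree = neighbor_joining(dm)
        pat = patristic_distances(tree)
        assert np.allclose(pat.d, d, atol=1e-12)

    @pytest.mark.parametrize("n_leaves", [4, 6, 8])
    def test_random_additive_matrices_recovered(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(20):
            dm = random_additive_matrix(n_leaves, rng)
            tree = neighbor_joining(dm)
            pat = patristic_distances(tree)
            assert np.max(np.abs(pat.d - dm.d)) < 1e-9

    def test_patristic_via_dendropy_round_trip(self):
        rng = np.random.default_rng(5)
        dm = random_additive_matrix(6, rng)
        tree = neighbor_joining(dm)
        dist = dendropy_patristic(to_newick(tree))
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert dist(a, b) == pytest.approx(dm.d[i, j], abs=1e-9)

    def test_matches_scikit_bio_on_random_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(77)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = tuple("abcdef")
        ours = neighbor_joining(DistanceMatrix(labels=labels, d=m))
        ours_pat = patristic_distances(ours)
        theirs = skbio_nj(SkbioDM(m, ids=labels))
        theirs_pat = theirs.tip_tip_distances(endpoints=list(labels))
        assert np.allclose(ours_pat.d, theirs_pat.data, atol=1e-9)

    def test_star_like_matrix_near_zero_internal_branch(self):
        # ultrametric equidistant taxa: any resolution is arbitrary, and the
        # internal branch collapses to ~0
        n = 4
        d = np.ones((n, n)) * 2.0
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix(labels=tuple("abcd"), d=d))
        internal = [c for c in tree.root.children if not c.is_leaf]
        assert all(abs(node.length) < 1e-12 for node in internal)

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(labels=("a", "b"), d=np.zeros((2, 2))))


class TestSblAndNewick:
    def test_sbl_sums_all_branches(self):
        dm = random_additive_matrix(5, np.random.default_rng(1))
        tree = neighbor_joining(dm)
        lengths = []

        def walk(node):
            for c in node.children:
                lengths.append(c.length)
                walk(c)

        walk(tree.root)
        assert sum_branch_lengths(tree) == pytest.approx(sum(lengths), abs=1e-15)

    def test_sbl_invariant_to_relabeling(self):
        rng = np.random.default_rng(2)
        dm = random_additive_matrix(6, rng)
        tree1 = neighbor_joining(dm)
        renamed = DistanceMatrix(labels=tuple(f"X{l}" for l in dm.labels), d=dm.d)
        tree2 = neighbor_joining(renamed)
        assert sum_branch_lengths(tree1) == pytest.approx(sum_branch_lengths(tree2))

    def test_newick_round_trip_preserves_lengths(self):
        dm = random_additive_matrix(7, np.random.default_rng(3))
        tree = neighbor_joining(dm)
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        total = sum(
            e.length for e in parsed.edges() if e.length is not None and e.head_node != parsed.seed_node
        )
        assert total == pytest.approx(sum_branch_lengths(tree), abs=1e-12)

    def test_labels_with_spaces_quoted(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        dm = DistanceMatrix(labels=("Jiangsu Han", "Beijing Han", "Dai"), d=d)
        newick = to_newick(neighbor_joining(dm))
        assert "'Jiangsu Han'" in newick
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == {
            "Jiangsu Han", "Beijing Han", "Dai"
        }


class TestNmds:
    def test_collinear_points_perfectly_embedded(self):
        pts = np.array([[0.0], [1.0], [2.5], [4.0]])
        d = squareform(pdist(pts))
        res = nmds(DistanceMatrix(labels=tuple("abcd"), d=d), seed=0)
        assert res.stress <= 1e-4

    def test_stress_history_non_increasing(self):
        rng = np.random.default_rng(6)
        m = rng.random((9, 9))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        res = nmds(DistanceMatrix(labels=tuple("abcdefghi"), d=m), seed=1)
        assert all(b <= a + 1e-15 for a, b in zip(res.stress_history, res.stress_history[1:]))

    def test_scale_invariance_of_stress(self):
        rng = np.random.default_rng(7)
        m = rng.random((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        res1 = nmds(DistanceMatrix(labels=tuple("abcdefg"), d=m), seed=2)
        res2 = nmds(DistanceMatrix(labels=tuple("abcdefg"), d=10.0 * m), seed=2)
        assert res1.stress == pytest.approx(res2.stress, abs=1e-8)

    def test_optimization_dominates_classical_init(self):
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            m = rng.random((8, 8))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            res = nmds(DistanceMatrix(labels=tuple("abcdefgh"), d=m), seed=seed)
            assert res.stress <= res.stress_initial + 1e-15

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            nmds(DistanceMatrix(labels=tuple("abc"), d=np.zeros((3, 3))))
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValidationError):
            nmds(DistanceMatrix(labels=("a", "b"), d=d))
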