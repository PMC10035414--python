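import itertools

import numpy as np
import pytest

from famscan import phylogeny as ph
from famscan.errors import InputError

# ---------------------------------------------------------------------------
# independent oracle: exhaustive topology enumeration with least-squares fit
# ---------------------------------------------------------------------------


def _enumerate_topologies(n_taxa):
    """All unrooted binary topologies on taxa 0..n-1 as edge lists.

    Nodes >= n_taxa are internal.  Built by inserting each taxon into every
    edge of every smaller topology (3 -> 15 -> 105 trees for 4..6 taxa).
    """
    base = [(0, 1000), (1, 1000), (2, 1000)]  # internal node ids start at 1000
    trees = [(base, 1001)]
    for taxon in range(3, n_taxa):
        new_trees = []
        for edges, next_node in trees:
            for i, (a, b) in enumerate(edges):
                new_internal = next_node
                new_edges = edges[:i] + edges[i + 1 :]
                new_edges += [(a, new_internal), (b, new_internal), (taxon, new_internal)]
                new_trees.append((new_edges, next_node + 1))
        trees = new_trees
    return [edges for edges, _ in trees]


def _tree_paths(edges, n_taxa):
    """Leaf-pair -> set of edge indices on the connecting path."""
    adj = {}
    for idx, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))
    paths = {}
    for leaf in range(n_taxa):
        stack = [(leaf, None, [])]
        seen = {leaf}
        while stack:
            node, _, used = stack.pop()
            if node < n_taxa and node != leaf:
                paths[frozenset((leaf, node))] = used
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, used + [eidx]))
    return paths


def _splits_of_edges(edges, n_taxa):
    """Non-trivial bipartitions induced by the internal edges."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    splits = set()
    for a, b in edges:
        # leaves on the 'a' side when edge (a, b) is removed
        stack, seen = [a], {a, b}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_taxa:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 1 < len(side) < n_taxa - 1:
            anchor_side = side if 0 not in side else set(range(n_taxa)) - side
            splits.add(frozenset(anchor_side))
    return splits


def lsq_best_topology(D):
    """Exhaustive least-squares topology search (oracle for NJ)."""
    n = D.shape[0]
    best = None
    for edges in _enumerate_topologies(n):
        paths = _tree_paths(edges, n)
        pairs = sorted(paths, key=sorted)
        A = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, pair in enumerate(pairs):
            i, j = sorted(pair)
            y[r] = D[i, j]
            for eidx in paths[pair]:
                A[r, eidx] = 1.0
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ x - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, edges)
    return best[1], best[0]


def random_additive_matrix(rng, n_taxa):
    """Distance matrix generated from a random tree with known splits."""
    edges = _enumerate_topologies(n_taxa)[
        int(rng.integers(0, len(_enumerate_topologies(n_taxa))))
    ]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    paths = _tree_paths(edges, n_taxa)
    D = np.zeros((n_taxa, n_taxa))
    for pair, eidxs in paths.items():
        i, j = sorted(pair)
        D[i, j] = D[j, i] = sum(lengths[e] for e in eidxs)
    return D, _splits_of_edges(edges, n_taxa)


def _names(n):
    return tuple(f"t{i:02d}" for i in range(n))


def _nj_splits_as_indices(tree, names):
    index = {name: i for i, name in enumerate(names)}
    out = set()
    for bp in tree.bipartitions():
        side = frozenset(index[n] for n in bp)
        if 0 in side:
            side = frozenset(range(len(names))) - side
        out.add(side)
    return out


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


class TestPairwisePdistance:
    def test_identical_rows_zero(self):
        dm = ph.pairwise_pdistance({"a": "ACDE", "b": "ACDE"})
        assert dm.get("a", "b") == 0.0

    def test_quarter_mismatch(self):
        dm = ph.pairwise_pdistance({"a": "ACDE", "b": "ACDW"})
        assert dm.get("a", "b") == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        dm = ph.pairwise_pdistance({"a": "AC-E", "b": "ACD-"})
        assert dm.get("a", "b") == 0.0  # only 2 comparable, both equal

    def test_zero_comparable_columns_error(self):
        with pytest.raises(InputError, match="no comparable columns"):
            ph.pairwise_pdistance({"a": "A---", "b": "-CDE"})

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(0)
        residues = "ACDEFGHIKL-"
        rows = {
            f"r{i:02d}": "".join(
                residues[j] for j in rng.integers(0, len(residues), 30)
            )
            for i in range(20)
        }
        dm = ph.pairwise_pdistance(rows)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_fewer_than_three_taxa_rejected(self):
        dm = ph.DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(InputError):
            ph.neighbor_joining(dm)

    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 0.4, 0.6, 0.8
        dm = ph.DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]]),
        )
        tree = ph.neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx((d12 + d13 - d23) / 2)
        assert lengths["b"] == pytest.approx((d12 + d23 - d13) / 2)
        assert lengths["c"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(1)
        D, splits = random_additive_matrix(rng, 4)
        names = _names(4)
        tree = ph.neighbor_joining(ph.DistanceMatrix(names, D))
        assert _nj_splits_as_indices(tree, names) == splits
        recovered = tree.leaf_distances()
        assert np.allclose(recovered.matrix, D, atol=1e-9)

    def test_six_taxon_path_metric(self):
        rng = np.random.default_rng(2)
        D, _ = random_additive_matrix(rng, 6)
        names = _names(6)
        tree = ph.neighbor_joining(ph.DistanceMatrix(names, D))
        assert np.allclose(tree.leaf_distances().matrix, D, atol=1e-9)

    def test_additive_recovery_against_lsq_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 7))
            D, splits = random_additive_matrix(rng, n)
            names = _names(n)
            tree = ph.neighbor_joining(ph.DistanceMatrix(names, D))
            assert _nj_splits_as_indices(tree, names) == splits
            oracle_edges, rss = lsq_best_topology(D)
            assert rss < 1e-16
            assert _splits_of_edges(oracle_edges, n) == splits

    def test_leaf_permutation_invariance(self):
        rng = np.random.default_rng(4)
        D, _ = random_additive_matrix(rng, 6)
        names = _names(6)
        tree1 = ph.neighbor_joining(ph.DistanceMatrix(names, D))
        perm = rng.permutation(6)
        names2 = tuple(names[i] for i in perm)
        D2 = D[np.ix_(perm, perm)]
        tree2 = ph.neighbor_joining(ph.DistanceMatrix(names2, D2))
        assert tree1.bipartitions() == tree2.bipartitions()

    def test_negative_branches_clamped(self):
        # triangle-inequality violation forces a negative estimate at 'a'
        D = np.array(
            [
                [0.0, 1.0, 1.0],
                [1.0, 0.0, 10.0],
                [1.0, 10.0, 0.0],
            ]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = ph.neighbor_joining(ph.DistanceMatrix(_names(3), D))
        assert tree.negative_branches_clamped
        for node in tree.root.walk():
            assert node.length >= 0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _two_clade_alignment():
    """Two 4-leaf clades separated by 30 invariant signal columns, plus one
    private column per taxon so all pairwise distances are distinct."""
    taxa = ["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"]
    out = {}
    for k, name in enumerate(taxa):
        signal = ("A" if name.startswith("a") else "T") * 30
        private = ["C"] * 8
        private[k] = "G"
        out[name] = signal + "".join(private)
    return out


class TestBootstrap:
    def test_saturated_split_full_support(self):
        tree = ph.bootstrap_support(_two_clade_alignment(), 100, seed=0)
        supports = [
            n.support
            for n in tree.root.walk()
            if n.support is not None
        ]
        central = frozenset({"b1", "b2", "b3", "b4"})
        for node in tree.root.walk():
            if node.is_leaf or node.support is None:
                continue
            side = frozenset(l.name for l in node.leaves())
            if side in (central, frozenset({"a1", "a2", "a3", "a4"})):
                assert node.support == 100.0
        assert all(0 <= s <= 100 for s in supports)

    def test_single_rep_support_binary(self):
        tree = ph.bootstrap_support(_two_clade_alignment(), 1, seed=3)
        for node in tree.root.walk():
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_same_seed_identical(self):
        t1 = ph.bootstrap_support(_two_clade_alignment(), 25, seed=7)
        t2 = ph.bootstrap_support(_two_clade_alignment(), 25, seed=7)
        assert t1.newick() == t2.newick()

    def test_nreps_zero_rejected(self):
        with pytest.raises(InputError):
            ph.bootstrap_support(_two_clade_alignment(), 0, seed=0)


# ---------------------------------------------------------------------------
# subfamily assignment
# ---------------------------------------------------------------------------


class TestAssignSubfamily:
    def test_identical_to_reference(self):
        alignment = {"m": "ACDEACDE", "refA": "ACDEACDE", "refB": "WWWWWWWW"}
        labels = {"refA": "VIIIb", "refB": "XII"}
        assert ph.assign_subfamily(alignment, labels)["m"] == "VIIIb"

    def test_equidistant_unplaced(self):
        alignment = {"m": "AAAA", "refA": "AAAC", "refB": "AAAG"}
        labels = {"refA": "L1", "refB": "L2"}
        assert ph.assign_subfamily(alignment, labels)["m"] == ph.UNPLACED

    def test_requires_reference(self):
        with pytest.raises(InputError):
            ph.assign_subfamily({"m": "AAAA"}, {})

    def test_noise_free_truth_recovery(self, noisefree_bundle):
        b = noisefree_bundle
        alignment = dict(b.seed_alignment) | b.reference_alignment
        assignment = ph.assign_subfamily(alignment, b.reference_labels)
        for gid, row in b.seed_alignment.items():
            assert assignment[gid] == b.truth[gid].subfamily

    def test_cp159_truth_recovery(self, cp159_bundle):
        b = cp159_bundle
        alignment = dict(b.seed_alignment) | b.reference_alignment
        assignment = ph.assign_subfamily(alignment, b.reference_labels)
        correct = sum(
            assignment[gid] == b.truth[gid].subfamily
            for gid in b.seed_alignment
        )
        assert correct == len(b.seed_alignment)

    def test_clade_majority_method(self):
        # two well-separated clades each anchored by one labeled reference
        clade_a = "A" * 20 + "CCCC"
        clade_b = "T" * 20 + "CCCC"
        alignment = {
            "m1": clade_a[:23] + "G",
            "m2": clade_a[:22] + "GC",
            "refA": clade_a,
            "m3": clade_b[:23] + "G",
            "m4": clade_b[:22] + "GC",
            "refB": clade_b,
        }
        labels = {"refA": "L1", "refB": "L2"}
        assignment = ph.assign_subfamily(alignment, labels, method="clade-majority")
        assert assignment == {"m1": "L1", "m2": "L1", "m3": "L2", "m4": "L2"}
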