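"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap
support and reference-based subfamily assignment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InputError

UNPLACED = "unplaced"


@dataclass(frozen=True)
class DistanceMatrix:
    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.names), len(self.names)):
            raise InputError("matrix shape does not match taxon count")
        if not np.allclose(m, m.T):
            raise InputError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise InputError("diagonal must be zero")
        if np.any(m < 0):
            raise InputError("distances must be nonnegative")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.index(a), self.index(b)])


class Node:
    """Tree node; ``length`` is the branch to the parent."""

    __slots__ = ("name", "children", "parent", "length", "support")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length
        self.support: Optional[float] = None

    def add(self, child: "Node", length: float):
        child.parent = self
        child.length = length
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    """Unrooted tree stored with a degree-3 root (the final NJ join)."""

    root: Node
    names: tuple[str, ...]
    negative_branches_clamped: bool = False

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.root.leaves()}

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, each canonicalized to the side
        not containing the alphabetically first taxon."""
        all_names = frozenset(self.names)
        anchor = min(self.names)
        out = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(n.name for n in node.leaves())
            if len(side) <= 1 or len(side) >= len(all_names) - 1:
                continue
            if anchor in side:
                side = all_names - side
            out.add(side)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length metric between all leaf pairs."""
        names = tuple(sorted(self.names))
        idx = {n: i for i, n in enumerate(names)}
        m = np.zeros((len(names), len(names)))

        # d(a, b) = depth(a) + depth(b) - 2 * depth(lca) in the root frame
        depth: dict[str, float] = {}
        parent_chain: dict[str, list[tuple[Node, float]]] = {}

        def collect(node: Node, acc: float, chain):
            chain = chain + [(node, acc)]
            if node.is_leaf:
                depth[node.name] = acc
                parent_chain[node.name] = chain
            for c in node.children:
                collect(c, acc + c.length, chain)

        collect(self.root, 0.0, [])
        for i, a in enumerate(names):
            nodes_a = {id(n): d for n, d in parent_chain[a]}
            for b in names[i + 1 :]:
                lca_depth = 0.0
                for n, d in parent_chain[b]:
                    if id(n) in nodes_a:
                        lca_depth = d
                d = depth[a] + depth[b] - 2 * lca_depth
                m[idx[a], idx[b]] = m[idx[b], idx[a]] = d
        return DistanceMatrix(names=names, matrix=m)

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_pdistance(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Proportion of mismatching columns with pairwise gap deletion."""
    names = tuple(sorted(alignment))
    if len(names) < 2:
        raise InputError("need at least two rows")
    rows = [alignment[n] for n in names]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputError("alignment rows differ in length")
    arr = np.array([list(r) for r in rows])
    gap = arr == "-"
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                raise InputError(
                    f"no comparable columns between {names[i]!r} and {names[j]!r}"
                )
            mism = int((arr[i, ok] != arr[j, ok]).sum())
            m[i, j] = m[j, i] = mism / total
    return DistanceMatrix(names=names, matrix=m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration on the Q-criterion.

    Ties in Q break by the smallest (name_i, name_j) pair, where internal
    nodes carry the smallest leaf name of their clade.  Negative branch
    length estimates are clamped to zero and flagged.
    """
    n0 = len(dm.names)
    if n0 < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, Node] = {name: Node(name) for name in dm.names}
    labels = list(dm.names)
    D = dm.matrix.astype(float).copy()
    clamped = False

    def join_pair(i, j, li, lj):
        nonlocal clamped
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        parent.add(nodes[labels[i]], li)
        parent.add(nodes[labels[j]], lj)
        return parent

    while len(labels) > 3:
        n = len(labels)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        best_q = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                pair = tuple(sorted((labels[i], labels[j])))
                if Q[i, j] < best_q - 1e-12 or (
                    abs(Q[i, j] - best_q) <= 1e-12 and (best is None or pair < best[2])
                ):
                    best_q = Q[i, j]
                    best = (i, j, pair)
        i, j, _ = best
        d_ij = D[i, j]
        li = d_ij / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d_ij - li
        parent = join_pair(i, j, li, lj)
        new_label = min(labels[i], labels[j])
        d_new = (D[i] + D[j] - d_ij) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = {labels[k]: nodes[labels[k]] for k in keep} | {new_label: parent}
        labels = [labels[k] for k in keep] + [new_label]

    # final 3-way join: closed-form branch lengths
    a, b, c = 0, 1, 2
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = D[a, b] - la
    lc = D[a, c] - la
    root = Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        if lk < 0:
            clamped = True
            lk = 0.0
        root.add(nodes[labels[k]], lk)
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to zero")
    return PhyloTree(root=root, names=dm.names, negative_branches_clamped=clamped)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int,
    seed: int,
    *,
    distance_fn=pairwise_pdistance,
) -> PhyloTree:
    """NJ tree on the full alignment with per-edge bootstrap support.

    Columns are resampled with replacement; support is the percentage of
    replicate trees containing each internal bipartition of the full tree.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    names = sorted(alignment)
    width = len(alignment[names[0]])
    tree = neighbor_joining(distance_fn(alignment))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        resampled = {n: "".join(alignment[n][c] for c in cols) for n in names}
        try:
            rep_tree = neighbor_joining(distance_fn(resampled))
        except InputError:
            continue  # replicate with an incomparable pair contributes no support
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_names = frozenset(tree.names)
    anchor = min(tree.names)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(n.name for n in node.leaves())
        if len(side) <= 1 or len(side) >= len(all_names) - 1:
            continue
        key = (all_names - side) if anchor in side else side
        node.support = 100.0 * counts.get(key, 0) / n_reps
    return tree


# ---------------------------------------------------------------------------
# subfamily assignment
# ---------------------------------------------------------------------------

def assign_subfamily(
    alignment: Mapping[str, str],
    reference_labels: Mapping[str, str],
    *,
    method: str = "nearest",
    tree: Optional[PhyloTree] = None,
) -> dict[str, str]:
    """Label members by reference taxa.

    "nearest": each member takes the label of the reference at minimal
    p-distance (distinct labels tied at the minimum -> "unplaced").
    "clade-majority": smallest NJ clade containing >= 1 reference; majority
    label, ties -> "unplaced".
    """
    if not reference_labels:
        raise InputError("need at least one labeled reference taxon")
    members = [n for n in alignment if n not in reference_labels]
    if method == "nearest":
        dm = pairwise_pdistance(alignment)
        refs = sorted(reference_labels)
        out = {}
        for m in members:
            dists = [(dm.get(m, r), r) for r in refs]
            dmin = min(d for d, _ in dists)
            labels = {reference_labels[r] for d, r in dists if d <= dmin + 1e-12}
            out[m] = labels.pop() if len(labels) == 1 else UNPLACED
        return out
    if method == "clade-majority":
        if tree is None:
            tree = neighbor_joining(pairwise_pdistance(alignment))
        all_leaves = frozenset(n.name for n in tree.root.leaves())
        ref_names = set(reference_labels) & all_leaves
        # every edge of the unrooted tree splits the leaves in two; the
        # clades containing a member are the member-side halves
        sides = []
        for node in tree.root.walk():
            if node is tree.root:
                continue
            sides.append(frozenset(n.name for n in node.leaves()))
        out = {}
        for m in members:
            best: Optional[tuple[int, frozenset]] = None
            candidates = []
            for side in sides:
                clade = side if m in side else all_leaves - side
                refs_in = ref_names & clade
                if not refs_in:
                    continue
                if best is None or len(clade) < best[0]:
                    best = (len(clade), clade)
                    candidates = [refs_in]
                elif len(clade) == best[0]:
                    candidates.append(refs_in)
            if best is None:
                out[m] = UNPLACED
                continue
            winners = set()
            for refs_in in candidates:
                tally: dict[str, int] = {}
                for r in refs_in:
                    lab = reference_labels[r]
                    tally[lab] = tally.get(lab, 0) + 1
                top = max(tally.values())
                winners.update(k for k, v in tally.items() if v == top)
            out[m] = winners.pop() if len(winners) == 1 else UNPLACED
        return out
    raise InputError(f"unknown method {method!r}")
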