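"""Distance computation, UPGMA clustering, bootstrap supports and the
labelled-subset clade test.

Distances are counted in numbers of differing residues under pairwise gap
deletion: for a pair of rows only the columns where both carry a residue are
compared.  UPGMA merges the closest pair of clusters at height d/2 with
size-weighted (arithmetic-mean) linkage; ties are broken on the
lexicographically smallest pair of cluster labels, where a cluster's label is
its smallest leaf name.  The result is a rooted ultrametric binary tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .seqio import GAP, Alignment


@dataclass
class Node:
    height: float
    name: Optional[str] = None
    children: tuple["Node", ...] = ()
    support: Optional[float] = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_set(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    root: Node

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.walk() if not n.is_leaf()]

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        return {n.leaf_set() for n in self.internal_nodes()}

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths: list[float] = []

        def leaf_depth(node: Node, below: float) -> None:
            if node.is_leaf():
                depths.append(below)
            for c in node.children:
                leaf_depth(c, below + node.height - c.height)

        leaf_depth(self.root, 0.0)
        for n in self.root.walk():
            for c in n.children:
                if n.height < c.height - tol:
                    return False
        return max(depths) - min(depths) <= tol


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


def _encode(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    codes = np.frombuffer(
        "".join(r.residues for r in alignment.rows).encode("ascii"),
        dtype=np.uint8).reshape(alignment.n_rows, alignment.n_cols)
    return codes, codes == ord(GAP)


def count_differences(alignment: Alignment,
                      deletion: str = "pairwise") -> DistanceMatrix:
    """Number of differing residues per sequence pair.

    ``deletion='pairwise'`` compares, per pair, columns where both rows carry
    a residue; ``'complete'`` first drops every column containing any gap.
    """
    codes, gap = _encode(alignment)
    if deletion == "complete":
        keep = ~gap.any(axis=0)
        codes, gap = codes[:, keep], gap[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = codes.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        both = ~gap[i] & ~gap[i + 1:]
        diff = (codes[i] != codes[i + 1:]) & both
        d[i, i + 1:] = diff.sum(axis=1)
    d += d.T
    return DistanceMatrix(ids=list(alignment.ids), d=d)


def upgma(dm: DistanceMatrix) -> Tree:
    """Average-linkage agglomeration into a rooted ultrametric binary tree."""
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 ids")
    nodes: dict[int, Node] = {
        i: Node(height=0.0, name=name) for i, name in enumerate(dm.ids)}
    labels: dict[int, str] = {i: name for i, name in enumerate(dm.ids)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    d = dm.d.copy()
    active = list(range(n))
    next_id = n
    big = np.inf

    work = np.full((2 * n, 2 * n), big)
    work[:n, :n] = d
    np.fill_diagonal(work, big)

    while len(active) > 1:
        idx = np.array(active)
        sub = work[np.ix_(idx, idx)]
        m = sub.min()
        cand = []
        for a, b in zip(*np.where(sub == m)):
            if a < b:
                i, j = idx[a], idx[b]
                cand.append((tuple(sorted((labels[i], labels[j]))), i, j))
        cand.sort()
        _, i, j = cand[0]
        h = m / 2.0
        node = Node(height=h, children=(nodes[i], nodes[j]))
        nodes[next_id] = node
        labels[next_id] = min(labels[i], labels[j])
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)]
        for k in active:
            work[next_id, k] = work[k, next_id] = (
                sizes[i] * work[i, k] + sizes[j] * work[j, k]
            ) / (sizes[i] + sizes[j])
        active.append(next_id)
        next_id += 1

    return Tree(root=nodes[active[0]])


def bootstrap_support(alignment: Alignment, n_reps: int, seed: int,
                      deletion: str = "pairwise") -> Tree:
    """UPGMA tree with column-bootstrap supports on its internal nodes.

    Each replicate resamples alignment columns with replacement; the support
    of an internal node is the fraction of replicate trees containing the
    same leaf set as a cluster.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = upgma(count_differences(alignment, deletion))
    counts: dict[frozenset[str], int] = {c: 0 for c in tree.clades()}
    rng = np.random.default_rng(seed)
    n_cols = alignment.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = Alignment(
            rows=[type(r)(id=r.id,
                          residues="".join(r.residues[c] for c in cols))
                  for r in alignment.rows],
            alphabet=alignment.alphabet)
        rep_clades = upgma(count_differences(rep, deletion)).clades()
        for c in counts:
            if c in rep_clades:
                counts[c] += 1
    for node in tree.internal_nodes():
        node.support = counts[node.leaf_set()] / n_reps
    return tree


class CladeResult(NamedTuple):
    found: bool
    node: Node
    jaccard: float


def is_clade(tree: Tree, labels: set[str]) -> CladeResult:
    """Test whether ``labels`` is exactly the leaf set of some internal node.

    Always reports the internal node with the best Jaccard overlap, to
    quantify near-clades when the test fails.
    """
    leaf_names = set(tree.leaf_names())
    unknown = set(labels) - leaf_names
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)[:5]}")
    target = frozenset(labels)
    for node in tree.internal_nodes():
        if node.leaf_set() == target:
            return CladeResult(found=True, node=node, jaccard=1.0)
    # near-clade search skips the trivial all-leaves root
    candidates = [n for n in tree.internal_nodes() if n is not tree.root]
    best, best_j = tree.root, -1.0
    for node in candidates:
        ls = node.leaf_set()
        j = len(ls & target) / len(ls | target)
        if j > best_j:
            best, best_j = node, j
    if best_j < 0:
        best_j = len(target) / len(set(tree.leaf_names()) | target)
    return CladeResult(found=False, node=best, jaccard=best_j)


def distance_matrix_from_tree(tree: Tree) -> DistanceMatrix:
    """Ultrametric distances implied by a tree: d(a,b) = 2 × MRCA height."""
    names = tree.leaf_names()
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    d = np.zeros((n, n))

    def descend(node: Node) -> list[str]:
        if node.is_leaf():
            return [node.name]
        sets = [descend(c) for c in node.children]
        for a_i in range(len(sets)):
            for b_i in range(a_i + 1, len(sets)):
                for a in sets[a_i]:
                    for b in sets[b_i]:
                        d[index[a], index[b]] = d[index[b], index[a]] = 2 * node.height
        return [x for s in sets for x in s]

    descend(tree.root)
    return DistanceMatrix(ids=names, d=d)
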