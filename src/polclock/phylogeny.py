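"""Per-patient crypt phylogenies from binary mutation sharing.

Each microdissected crypt reads out the somatic mutation set of one recent
ancestral stem cell, so presence/absence of shared mutations across crypts of
a patient defines binary irreversible characters (a somatic mutation arises
once and is not lost).  Topologies are scored by Camin-Sokal parsimony: the
cost of a character is the minimal number of independent origins, i.e. the
number of maximal clades whose leaves all carry the variant.  Small patients
(<= `exhaustive_max` leaves) are solved by exhaustive enumeration of rooted
topologies; larger ones by NNI hill-climbing from an agglomerative start with
random restarts.  Bootstrap support comes from column resampling.

Mutations are then mapped onto branches by a per-mutation binomial read-count
likelihood: leaves below the branch are expected at VAF 0.5 x purity, all
other leaves at the sequencing-error VAF.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import binom


@dataclass
class Node:
    """Rooted tree node; the branch it subtends is the edge to its parent.

    The root node's branch is the trunk (fertilised egg to the most recent
    common ancestor of the sampled crypts).  ``time`` is the age (years) at
    which the node's split occurs (leaves: sampling age).
    """

    name: str | None = None
    children: list["Node"] = field(default_factory=list)
    time: float = 0.0
    branch_id: str = ""
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def postorder(self) -> list["Node"]:
        out = []
        for c in self.children:
            out.extend(c.postorder())
        out.append(self)
        return out

    def copy(self) -> "Node":
        n = Node(self.name, [c.copy() for c in self.children], self.time,
                 self.branch_id, self.support)
        return n

    def newick(self, lengths: dict[str, float] | None = None) -> str:
        def rec(node):
            if node.is_leaf():
                label = node.name
            else:
                label = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.support is not None:
                    label += f"{node.support:.0f}"
            if lengths is not None:
                label += f":{lengths.get(node.branch_id, 0)}"
            return label

        return rec(self) + ";"


@dataclass
class CryptPhylogeny:
    tree: Node
    samples: list[str]
    branch_mutations: dict[str, list] = field(default_factory=dict)
    branch_counts: pd.DataFrame | None = None
    supports: dict[frozenset, float] = field(default_factory=dict)
    parsimony_score: int = 0
    unassigned: list = field(default_factory=list)

    def branches(self) -> list[Node]:
        return self.tree.postorder()


def _assign_branch_ids(root: Node) -> None:
    for i, node in enumerate(root.postorder()):
        if not node.branch_id:
            node.branch_id = "trunk" if node is root else (
                node.name if node.is_leaf() else f"b{i}"
            )
    root.branch_id = "trunk"


def parsimony_score(root: Node, matrix: np.ndarray, samples: list[str],
                    weights: np.ndarray | None = None) -> float:
    """Camin-Sokal parsimony score: total number of origins over characters.

    ``matrix`` is samples x variants, binary.  A node is 'pure' for a
    character when every leaf below carries it; the character's cost is the
    number of maximal pure nodes.
    """
    if weights is None:
        weights = np.ones(matrix.shape[1])
    sidx = {s: i for i, s in enumerate(samples)}
    total = np.zeros(matrix.shape[1])
    ones_below: dict[int, np.ndarray] = {}
    size_below: dict[int, int] = {}
    for node in root.postorder():
        if node.is_leaf():
            ones = matrix[sidx[node.name]].astype(np.int64)
            size = 1
        else:
            ones = sum(ones_below[id(c)] for c in node.children)
            size = sum(size_below[id(c)] for c in node.children)
        ones_below[id(node)] = ones
        size_below[id(node)] = size
        pure = ones == size
        if node.is_leaf():
            child_pure_sum = np.zeros(matrix.shape[1])
        else:
            child_pure_sum = sum(
                ((ones_below[id(c)] == size_below[id(c)]) & (ones_below[id(c)] > 0)).astype(int)
                for c in node.children
            )
        # a maximal pure node contributes 1; its pure children no longer count
        total += np.where(pure & (ones > 0), 1 - 0, 0)
        total -= np.where(pure & (ones > 0), child_pure_sum, 0)
    return float((total * weights).sum())


def _all_topologies(names: list[str]):
    """Yield every rooted binary leaf-labelled topology (nested tuples)."""

    def insert_everywhere(tree, leaf):
        # replace any subtree t by (t, leaf)
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for sub in insert_everywhere(left, leaf):
                yield (sub, right)
            for sub in insert_everywhere(right, leaf):
                yield (left, sub)

    def rec(i):
        if i == 2:
            yield (names[0], names[1])
            return
        for t in rec(i - 1):
            yield from insert_everywhere(t, names[i - 1])

    if len(names) == 1:
        yield names[0]
    else:
        yield from rec(len(names))


def _tuple_to_node(t) -> Node:
    if isinstance(t, str):
        return Node(name=t)
    return Node(children=[_tuple_to_node(t[0]), _tuple_to_node(t[1])])


def _linkage_start(matrix: np.ndarray, samples: list[str]) -> Node:
    if matrix.shape[1] == 0:
        d = np.zeros(len(samples) * (len(samples) - 1) // 2)
    else:
        d = pdist(matrix, metric="hamming")
    Z = linkage(d, method="average")
    def conv(cl):
        if cl.is_leaf():
            return Node(name=samples[cl.id])
        return Node(children=[conv(cl.left), conv(cl.right)])
    return conv(to_tree(Z))


def _random_topology(samples: list[str], rng: np.random.Generator) -> Node:
    nodes = [Node(name=s) for s in samples]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _nni_neighbours(root: Node):
    """Yield copies of the tree with one nearest-neighbour interchange."""
    # index nodes by path for copy-and-modify
    def paths(node, path=()):
        yield path, node
        for i, c in enumerate(node.children):
            yield from paths(c, path + (i,))

    for path, node in list(paths(root)):
        if node.is_leaf() or len(node.children) != 2:
            continue
        for ci, child in enumerate(node.children):
            if child.is_leaf():
                continue
            for gi in range(len(child.children)):
                new = root.copy()
                # walk to node in the copy
                tgt = new
                for p in path:
                    tgt = tgt.children[p]
                other = tgt.children[1 - ci]
                ch = tgt.children[ci]
                g = ch.children[gi]
                ch.children[gi] = other
                tgt.children[1 - ci] = g
                yield new


def _search(matrix, samples, rng, n_restarts=10, exhaustive_max=7):
    uniq, inv = np.unique(matrix.T, axis=0, return_inverse=True)
    weights = np.bincount(inv, minlength=uniq.shape[0]).astype(float)
    umat = uniq.T  # samples x unique variants

    if len(samples) <= exhaustive_max:
        best, best_score = None, np.inf
        for t in _all_topologies(samples):
            node = _tuple_to_node(t)
            s = parsimony_score(node, umat, samples, weights)
            if s < best_score:
                best, best_score = node, s
        return best, best_score

    def hill_climb(start):
        cur, cur_s = start, parsimony_score(start, umat, samples, weights)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbours(cur):
                s = parsimony_score(nb, umat, samples, weights)
                if s < cur_s:
                    cur, cur_s, improved = nb, s, True
                    break
        return cur, cur_s

    best, best_score = hill_climb(_linkage_start(matrix, samples))
    for _ in range(n_restarts):
        cand, s = hill_climb(_random_topology(samples, rng))
        if s < best_score:
            best, best_score = cand, s
    return best, best_score


def build_tree(
    genotypes: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
    n_restarts: int = 10,
    exhaustive_max: int = 7,
) -> CryptPhylogeny:
    """Maximum-parsimony crypt tree from a samples x variants binary matrix.

    Bootstrap support (percent of column resamples recovering each clade) is
    attached to internal nodes.  Deterministic for a fixed seed.
    """
    if genotypes.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    samples = list(genotypes.index)
    matrix = genotypes.to_numpy().astype(np.int8)
    rng = np.random.default_rng(seed)

    if matrix.shape[1] and (matrix == matrix[0]).all():
        warnings.warn("all genotypes identical; returning star-like tree")
    best, score = _search(matrix, samples, rng, n_restarts, exhaustive_max)
    _assign_branch_ids(best)

    supports: dict[frozenset, float] = {}
    if n_bootstrap > 0 and matrix.shape[1] > 0:
        clade_hits = {n.leaf_names(): 0 for n in best.postorder() if not n.is_leaf()}
        for _ in range(n_bootstrap):
            cols = rng.integers(0, matrix.shape[1], size=matrix.shape[1])
            bt, _s = _search(matrix[:, cols], samples, rng, n_restarts=0,
                             exhaustive_max=exhaustive_max)
            bt_clades = {n.leaf_names() for n in bt.postorder() if not n.is_leaf()}
            for cl in clade_hits:
                if cl in bt_clades:
                    clade_hits[cl] += 1
        supports = {cl: 100.0 * k / n_bootstrap for cl, k in clade_hits.items()}
        for node in best.postorder():
            if not node.is_leaf():
                node.support = supports[node.leaf_names()]

    return CryptPhylogeny(tree=best, samples=samples, supports=supports,
                          parsimony_score=int(score))


def assign_mutations(
    phylo: CryptPhylogeny,
    variants: pd.DataFrame,
    error_rate: float = 0.01,
    purity: float = 1.0,
) -> CryptPhylogeny:
    """Maximum-likelihood mapping of mutations onto branches.

    For each mutation and each branch, the log-likelihood sums binomial terms
    over leaves: leaves below the branch at expected VAF ``0.5 * purity``,
    leaves elsewhere at ``error_rate``.  Ties break toward the most terminal
    branch (fewest leaves below).  Mutations with zero depth everywhere are
    reported unassigned.
    """
    samples = phylo.samples
    nv = variants[[f"NV_{s}" for s in samples]].to_numpy()
    nr = variants[[f"NR_{s}" for s in samples]].to_numpy()

    nodes = phylo.tree.postorder()
    below = []
    for node in nodes:
        names = node.leaf_names()
        below.append(np.array([s in names for s in samples]))
    below = np.array(below)  # branches x samples

    p_present = 0.5 * purity
    with np.errstate(divide="ignore"):
        ll_present = binom.logpmf(nv, nr, p_present)   # muts x samples
        ll_absent = binom.logpmf(nv, nr, error_rate)
    ll_present = np.where(nr > 0, ll_present, 0.0)
    ll_absent = np.where(nr > 0, ll_absent, 0.0)

    # muts x branches
    ll = ll_present @ below.T.astype(float) + ll_absent @ (~below).T.astype(float)
    n_below = below.sum(axis=1)
    assigned = []
    for m in range(ll.shape[0]):
        best = np.max(ll[m])
        cand = np.nonzero(ll[m] >= best - 1e-9)[0]
        b = cand[np.argmin(n_below[cand])]
        assigned.append(nodes[b].branch_id)

    zero_depth = (nr == 0).all(axis=1)
    branch_mutations: dict[str, list] = {n.branch_id: [] for n in nodes}
    unassigned = []
    ids = variants.index.tolist()
    classes = variants["vclass"].tolist() if "vclass" in variants else ["SBS"] * len(ids)
    cls_of = dict(zip(ids, classes))
    for mid, b, zd in zip(ids, assigned, zero_depth):
        if zd:
            unassigned.append(mid)
        else:
            branch_mutations[b].append(mid)

    counts = pd.DataFrame(
        {
            "SBS": [sum(1 for m in branch_mutations[n.branch_id]
                        if cls_of[m] == "SBS") for n in nodes],
            "ID": [sum(1 for m in branch_mutations[n.branch_id]
                       if cls_of[m] == "ID") for n in nodes],
        },
        index=[n.branch_id for n in nodes],
    )
    phylo.branch_mutations = branch_mutations
    phylo.branch_counts = counts
    phylo.unassigned = unassigned
    return phylo


def robinson_foulds(a: Node, b: Node) -> int:
    """Symmetric clade-set difference between two rooted trees."""
    ca = {n.leaf_names() for n in a.postorder() if not n.is_leaf()}
    cb = {n.leaf_names() for n in b.postorder() if not n.is_leaf()}
    return len(ca ^ cb)
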