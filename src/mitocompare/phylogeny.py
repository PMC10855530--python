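"""K2P distance matrices, neighbor-joining trees, bootstrap and newick.

The neighbor-joining implementation follows Saitou & Nei's Q-criterion
agglomeration.  Ties in Q are broken deterministically by the
lexicographically smallest (cluster-label, cluster-label) pair, where a
cluster is labelled by its smallest leaf name, so repeated runs on equal
input give identical trees.  Negative branch length estimates are clamped
to zero with the deficit transferred to the sister branch of the join, the
usual practical convention.  Trees are unrooted, represented with a
trifurcating root node; bootstrap supports live on internal edges as
percentages of replicate trees containing the same leaf bipartition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .divergence import SaturatedPairError, k2p_from_counts


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def postorder(self) -> Iterable["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self


@dataclass
class PhyloTree:
    root: TreeNode  # trifurcating (unrooted convention) unless 2 taxa

    @property
    def taxa(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, one per internal edge, each
        canonicalized to the smaller side (ties by sorted tuple)."""
        all_taxa = frozenset(self.root.leaves())
        out: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaves())
            other = all_taxa - side
            if len(side) < 2 or len(other) < 2:
                continue
            canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            out.add(canon)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.postorder()
                if not n.is_leaf and n is not self.root]


def _sort_children(node: TreeNode) -> None:
    for c in node.children:
        _sort_children(c)
    node.children.sort(key=lambda c: min(c.leaves()))


def write_newick(tree: PhyloTree, path: str | None = None,
                 decimals: int = 6) -> str:
    """Serialize to newick with branch lengths; bootstrap supports appear
    as internal node labels.  Children are ordered by smallest leaf name so
    the representation is canonical (round-trip stable)."""
    _sort_children(tree.root)

    def fmt(x: float) -> str:
        s = f"{x:.{decimals}f}".rstrip("0").rstrip(".")
        return s if s and s != "-0" else "0"

    def rec(node: TreeNode, top: bool = False) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(rec(c) for c in node.children)
            label = "" if node.support is None else fmt(node.support)
            body = f"({inner}){label}"
        return body if top else f"{body}:{fmt(node.length)}"

    text = rec(tree.root, top=True) + ";"
    if path:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def read_newick(text: str) -> PhyloTree:
    """Parse newick (via dendropy) into a :class:`PhyloTree`; internal node
    labels are interpreted as bootstrap supports when numeric."""
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def conv(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label if dnode.taxon else None,
            length=dnode.edge.length or 0.0,
        )
        label = getattr(dnode, "label", None)
        if label and not dnode.taxon:
            try:
                node.support = float(label)
            except ValueError:
                node.name = label
        node.children = [conv(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(conv(dtree.seed_node))


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def mean_distance(self) -> float:
        n = len(self.taxa)
        iu = np.triu_indices(n, 1)
        return float(self.d[iu].mean())

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _ENC[ord(_b)] = _i
_IS_PURINE = np.array([False, True, False, True, False])  # index by code


def _encode_alignment(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    names = list(seqs)
    L = len(next(iter(seqs.values())))
    if any(len(s) != L for s in seqs.values()):
        raise ValueError("sequences must be aligned to equal length")
    arr = np.frombuffer("".join(seqs[n].upper() for n in names).encode(),
                        dtype=np.uint8).reshape(len(names), L)
    return names, _ENC[arr]


def _pair_class_matrix(mat: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Classify every column for every pair: 0 invalid, 1 identical,
    2 transition, 3 transversion."""
    n = mat.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    cls = np.zeros((len(pairs), mat.shape[1]), dtype=np.uint8)
    pur = _IS_PURINE[mat]
    for k, (i, j) in enumerate(pairs):
        valid = (mat[i] > 0) & (mat[j] > 0)
        same = mat[i] == mat[j]
        ts = valid & ~same & (pur[i] == pur[j])
        tv = valid & ~same & (pur[i] != pur[j])
        cls[k][valid & same] = 1
        cls[k][ts] = 2
        cls[k][tv] = 3
    return cls, pairs


def _k2p_matrix_from_classes(cls: np.ndarray, pairs: list[tuple[int, int]],
                             n: int, cols: np.ndarray | None = None,
                             taxa: Sequence[str] | None = None) -> np.ndarray:
    sub = cls if cols is None else cls[:, cols]
    sites = (sub > 0).sum(axis=1)
    ts = (sub == 2).sum(axis=1)
    tv = (sub == 3).sum(axis=1)
    d = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        if sites[k] == 0:
            raise ValueError("no comparable sites for a pair")
        try:
            dij = k2p_from_counts(int(sites[k]), int(ts[k]), int(tv[k]))
        except SaturatedPairError:
            pair = (taxa[i], taxa[j]) if taxa else (i, j)
            raise SaturatedPairError(f"saturated pair {pair}") from None
        d[i, j] = d[j, i] = dij
    return d


def distance_matrix(seqs: dict[str, str], model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix over an alignment (K2P or uncorrected p).

    A saturated pair under K2P raises :class:`SaturatedPairError` naming the
    pair; nothing is imputed.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 taxa")
    names, mat = _encode_alignment(seqs)
    cls, pairs = _pair_class_matrix(mat)
    if model == "k2p":
        d = _k2p_matrix_from_classes(cls, pairs, len(names), taxa=names)
    elif model == "p":
        sites = (cls > 0).sum(axis=1)
        diff = (cls >= 2).sum(axis=1)
        d = np.zeros((len(names), len(names)))
        for k, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = diff[k] / sites[k]
    else:
        raise ValueError(f"unknown model {model!r}")
    return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Returns an unrooted tree (trifurcating root).  For 3 taxa the unique
    star resolution with three-point branch lengths is returned.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    labels: list[str] = list(dm.taxa)  # tie-break key: min leaf name
    active = list(range(n))

    def clamp(u: float, v: float) -> tuple[float, float]:
        if u < 0:
            v += u
            u = 0.0
        if v < 0:
            u += v
            v = 0.0
        return u, max(v, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best  # type: ignore[misc]
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # reduce the matrix: new node replaces i
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = dk
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = active
    # three-point formulas
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    tree = PhyloTree(root)
    _sort_children(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    tree: PhyloTree                 # NJ tree on the full alignment
    replicates: int
    completed: int
    skipped_saturated: int
    no_variation: bool = False      # alignment had zero variable columns


def bootstrap_support(seqs: dict[str, str], replicates: int = 1000,
                      seed: int | None = None) -> BootstrapResult:
    """NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement per replicate; the
    support of an internal edge is the percentage of completed replicate
    trees containing the same bipartition.  Replicates hitting a saturated
    pair are skipped and counted.  With zero variable columns supports are
    meaningless: they are left at 0 and the result is flagged.
    """
    names, mat = _encode_alignment(seqs)
    n, L = mat.shape
    cls, pairs = _pair_class_matrix(mat)
    d_full = _k2p_matrix_from_classes(cls, pairs, n, taxa=names)
    tree = nj_tree(DistanceMatrix(names, d_full))

    varying = bool((cls >= 2).any())
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    completed = skipped = 0
    if varying:
        for _ in range(replicates):
            cols = rng.integers(0, L, size=L)
            try:
                d = _k2p_matrix_from_classes(cls, pairs, n, cols, names)
            except (SaturatedPairError, ValueError):
                skipped += 1
                continue
            rep = nj_tree(DistanceMatrix(names, d))
            completed += 1
            for bp in rep.bipartitions():
                if bp in counts:
                    counts[bp] += 1
    all_taxa = frozenset(names)
    for node in tree.root.postorder():
        if node.is_leaf or node is tree.root:
            continue
        side = frozenset(node.leaves())
        canon = min(side, all_taxa - side,
                    key=lambda s: (len(s), tuple(sorted(s))))
        if varying and completed:
            node.support = 100.0 * counts.get(canon, 0) / completed
        else:
            node.support = 0.0
    return BootstrapResult(tree, replicates, completed, skipped,
                           no_variation=not varying)


# ---------------------------------------------------------------------------
# Supermatrix export
# ---------------------------------------------------------------------------

def write_phylip(seqs: dict[str, str], path: str) -> None:
    """Relaxed PHYLIP (full names, space-separated)."""
    L = len(next(iter(seqs.values())))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(seqs)} {L}\n")
        for name, seq in seqs.items():
            fh.write(f"{name}  {seq}\n")


def write_charsets(charsets: list[tuple[str, int, int]], path: str) -> None:
    """Per-gene coordinate map of a concatenation (1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene, start, stop in charsets:
            fh.write(f"charset {gene} = {start}-{stop};\n")
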