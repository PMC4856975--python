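"""Kernel distances, neighbour joining, Newick I/O, spectral clustering and
motif/clade (synapomorphy vs homoplasy) annotation.

The sequence kernel is the mean column-wise substitution score between two
aligned rows (BLOSUM62 by default for proteins, an identity match/mismatch
matrix otherwise), with explicit gap scoring so that indel structure affects
the distances. Distances follow the kernel-induced squared-norm form
``d(x, y) = s(x,x) + s(y,y) - 2 s(x,y)`` clamped at zero, and trees are built
with canonical Saitou-Nei neighbour joining with lexicographic tie-breaking.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .alignment import MSA, GroupAssignment, default_palette
from .errors import (
    BoundsError,
    ConfigurationError,
    InputError,
    NewickParseError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kernel and distances


def _substitution_lookup(msa: MSA, matrix_name: str) -> np.ndarray:
    """Score lookup over alphabet symbols + gap (last index).

    Falls back to identity scoring when the named matrix does not cover the
    MSA's alphabet (e.g. nucleotide data under the BLOSUM62 default).
    """
    syms = msa.alphabet.symbols
    n = len(syms)
    table = np.zeros((n + 1, n + 1))
    if matrix_name.lower() == "identity":
        table[:n, :n] = np.eye(n)
        return table
    if msa.alphabet.name in ("dna", "rna"):
        # amino-acid matrices are meaningless on nucleotides even where the
        # letters coincide; score match/mismatch instead
        logger.info(
            "nucleotide alphabet: using identity scores instead of %s",
            matrix_name,
        )
        table[:n, :n] = np.eye(n)
        return table
    from Bio.Align import substitution_matrices

    try:
        sub = substitution_matrices.load(matrix_name)
    except FileNotFoundError:
        raise ConfigurationError(
            f"unknown substitution matrix {matrix_name!r} "
            f"(available: {substitution_matrices.load()} or 'identity')"
        ) from None
    if not set(syms) <= set(sub.alphabet):
        logger.warning(
            "matrix %s does not cover alphabet %r; falling back to identity",
            matrix_name, msa.alphabet.name,
        )
        table[:n, :n] = np.eye(n)
        return table
    for i, a in enumerate(syms):
        for j, b in enumerate(syms):
            table[i, j] = sub[a, b]
    return table


def kernel_matrix(
    msa: MSA,
    matrix_name: str = "BLOSUM62",
    gap_score: float = -4.0,
    gap_gap_score: float = 0.0,
) -> np.ndarray:
    """Mean column-wise substitution-score similarity between all row pairs.

    Gap-vs-residue columns score ``gap_score``; gap-vs-gap columns score
    ``gap_gap_score``. Symmetric by construction.
    """
    table = _substitution_lookup(msa, matrix_name)
    n_sym = len(msa.alphabet.symbols)
    table[n_sym, :n_sym] = gap_score
    table[:n_sym, n_sym] = gap_score
    table[n_sym, n_sym] = gap_gap_score

    index = {s: i for i, s in enumerate(msa.alphabet.symbols)}
    index[msa.alphabet.gap_symbol] = n_sym
    enc = np.array([[index[ch] for ch in row] for row in msa.rows])
    n = msa.n_seq
    sim = np.empty((n, n))
    for i in range(n):
        sim[i] = table[enc[i][None, :], enc].mean(axis=1)
    return (sim + sim.T) / 2


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise InputError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise InputError("distance matrix diagonal must be exactly zero")
        if np.any(d < 0):
            raise InputError("distance matrix has negative entries")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.labels)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.data):
                fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def kernel_to_distance(sim: np.ndarray, labels: list[str]) -> DistanceMatrix:
    """d(x, y) = max(0, s(x,x) + s(y,y) - 2 s(x,y)); clamping is logged."""
    sim = np.asarray(sim, dtype=float)
    diag = np.diag(sim)
    d = diag[:, None] + diag[None, :] - 2 * sim
    negatives = int((d < -1e-12).sum() // 2)
    if negatives:
        logger.info("clamped %d negative kernel distances to 0", negatives)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, (d + d.T) / 2)


def triangle_violations(d: DistanceMatrix) -> int:
    """Count of (i, j, k) triples violating d(i,k) <= d(i,j) + d(j,k)."""
    m = d.data
    n = d.n
    count = 0
    for i in range(n):
        for k in range(i + 1, n):
            if np.any(m[i, k] > m[i] + m[:, k] + 1e-12):
                count += 1
    return count


# ---------------------------------------------------------------------------
# Trees


class TreeNode:
    """A node of a (possibly trifurcating-rooted) phylogenetic tree."""

    __slots__ = ("label", "branch_length", "children", "parent")

    def __init__(self, label: str | None = None,
                 branch_length: float | None = None):
        self.label = label
        self.branch_length = branch_length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, node: "TreeNode") -> None:
        node.parent = self
        self.children.append(node)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Preorder traversal."""
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.walk() if n.is_leaf)


@dataclass
class PhyloTree:
    """Rooted representation of an (unrooted) tree; NJ output has a
    trifurcating root."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths (sorted labels); used for additivity checks."""
        leaves = sorted(self.leaves(), key=lambda n: n.label)
        labels = [n.label for n in leaves]

        def ancestors(node: TreeNode) -> dict[int, float]:
            acc, dist, cur = {}, 0.0, node
            while cur is not None:
                acc[id(cur)] = dist
                dist += cur.branch_length or 0.0
                cur = cur.parent
            return acc
        n = len(leaves)
        mat = np.zeros((n, n))
        anc = [ancestors(l) for l in leaves]
        for i in range(n):
            for j in range(i + 1, n):
                common = None
                cur = leaves[j]
                dist_j = 0.0
                while cur is not None:
                    if id(cur) in anc[i]:
                        common = cur
                        break
                    dist_j += cur.branch_length or 0.0
                    cur = cur.parent
                mat[i, j] = mat[j, i] = anc[i][id(common)] + dist_j
        return labels, mat


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbour joining.

    Iteratively joins the pair minimizing Q(i,j) = (n-2) d(i,j) - R_i - R_j;
    ties break by the lexicographically smallest (label_i, label_j) pair,
    where an internal node carries the smallest leaf label beneath it.
    Negative branch-length estimates are clamped to 0 with a log notice.
    n = 2 yields a single edge; the final join leaves a trifurcating root.
    """
    n = d.n
    if n < 2:
        raise InputError("neighbour joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(l) for l in d.labels]
    keys: list[str] = list(d.labels)  # deterministic tie-break keys
    mat = d.data.copy()
    active = list(range(n))
    clamped = 0

    def set_bl(node: TreeNode, bl: float):
        nonlocal clamped
        if bl < 0:
            clamped += 1
            bl = 0.0
        node.branch_length = bl

    while len(active) > 3:
        m = len(active)
        sub = mat[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        iu = np.triu_indices(m, 1)
        qmin = Q[iu].min()
        cand = [
            (a, b) for a, b in zip(*iu) if Q[a, b] <= qmin + 1e-12
        ]
        a, b = min(
            cand,
            key=lambda ab: tuple(sorted((keys[active[ab[0]]], keys[active[ab[1]]]))),
        )
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (R[a] - R[b]) / (2 * (m - 2))
        lj = dij - li
        new = TreeNode()
        set_bl(nodes[i], li)
        set_bl(nodes[j], lj)
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        # distances to the new node
        newrow = np.zeros(mat.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (mat[i, k] + mat[j, k] - dij)
        mat = np.pad(mat, ((0, 1), (0, 1)))
        mat[-1, :-1] = newrow[:-1]
        mat[:-1, -1] = newrow[:-1]
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [mat.shape[0] - 1]

    root = TreeNode()
    if len(active) == 2:
        i, j = active
        total = mat[i, j]
        # single edge of total length `total`, represented as two half-branches
        set_bl(nodes[i], total / 2)
        set_bl(nodes[j], total / 2)
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    else:
        i, j, k = active
        dij, dik, djk = mat[i, j], mat[i, k], mat[j, k]
        set_bl(nodes[i], (dij + dik - djk) / 2)
        set_bl(nodes[j], (dij + djk - dik) / 2)
        set_bl(nodes[k], (dik + djk - dij) / 2)
        for node in (nodes[i], nodes[j], nodes[k]):
            root.add_child(node)
    if clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", clamped)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Newick I/O


def _fmt_bl(bl: float | None) -> str:
    return "" if bl is None else f":{bl:.12g}"


def _node_newick(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{node.label or ''}{_fmt_bl(node.branch_length)}"
    inner = ",".join(_node_newick(c) for c in node.children)
    return f"({inner}){node.label or ''}{_fmt_bl(node.branch_length)}"


def tree_to_newick(tree: PhyloTree) -> str:
    return _node_newick(tree.root) + ";"


def write_newick(tree: PhyloTree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


class _NewickParser:
    _LABEL_STOP = set("(),:;")

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def _peek(self) -> str:
        self._skip_ws()
        if self.pos >= len(self.text):
            raise NewickParseError("unexpected end of Newick text", self.pos)
        return self.text[self.pos]

    def _label(self) -> str:
        self._skip_ws()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in self._LABEL_STOP \
                and not self.text[self.pos].isspace():
            self.pos += 1
        return self.text[start:self.pos]

    def _branch_length(self) -> float | None:
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == ":":
            self.pos += 1
            start = self.pos
            while self.pos < len(self.text) and (
                self.text[self.pos] in "+-.eE" or self.text[self.pos].isdigit()
            ):
                self.pos += 1
            raw = self.text[start:self.pos]
            try:
                return float(raw)
            except ValueError:
                raise NewickParseError(
                    f"invalid branch length {raw!r}", start
                ) from None
        return None

    def _node(self) -> TreeNode:
        node = TreeNode()
        if self._peek() == "(":
            open_pos = self.pos
            self.pos += 1
            while True:
                node.add_child(self._node())
                ch = self._peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise NewickParseError("unclosed '(' in Newick", open_pos)
            label = self._label()
            node.label = label or None
        else:
            label = self._label()
            if not label:
                raise NewickParseError("expected a leaf label", self.pos)
            node.label = label
        node.branch_length = self._branch_length()
        return node

    def parse(self) -> PhyloTree:
        root = self._node()
        if self._peek() != ";":
            raise NewickParseError("expected ';' at end of tree", self.pos)
        self.pos += 1
        return PhyloTree(root)


def parse_newick(text: str) -> PhyloTree:
    """Parse Newick text; raises NewickParseError with a character position."""
    return _NewickParser(text).parse()


def read_newick(path: str | os.PathLike) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Spectral clustering


def spectral_clustering(
    d: DistanceMatrix, k: int, sigma: float | None = None, seed: int = 0
) -> GroupAssignment:
    """Normalized-Laplacian spectral clustering of a distance matrix.

    Affinity A = exp(-d^2 / (2 sigma^2)) with zero diagonal (sigma defaults
    to the median off-diagonal distance); the rows of the k bottom
    eigenvectors of L = I - D^{-1/2} A D^{-1/2} are unit-normalized and
    clustered by k-means (10 restarts, seeded). Groups are named
    ``cluster1..k`` in order of first appearance along the sequence order.
    """
    n = d.n
    if not 1 <= k <= n:
        raise InputError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        names = ["cluster1"]
        return GroupAssignment(
            names, {"cluster1": default_palette(1)[0]},
            {i: "cluster1" for i in range(1, n + 1)},
        )
    if sigma is None:
        off = d.data[np.triu_indices(n, 1)]
        sigma = float(np.median(off))
    if sigma <= 0:
        sigma = 1.0
    A = np.exp(-(d.data ** 2) / (2 * sigma ** 2))
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
    from scipy.linalg import eigh

    _, vecs = eigh(L, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    embedding = vecs / norms[:, None]

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(embedding)
    # stable naming: clusters numbered by first appearance
    relabel: dict[int, int] = {}
    for lbl in raw:
        if lbl not in relabel:
            relabel[lbl] = len(relabel) + 1
    names = [f"cluster{i}" for i in range(1, k + 1)]
    palette = default_palette(k)
    colors = dict(zip(names, palette))
    membership = {
        i + 1: f"cluster{relabel[lbl]}" for i, lbl in enumerate(raw)
    }
    return GroupAssignment(names, colors, membership)


# ---------------------------------------------------------------------------
# Synapomorphy / homoplasy annotation


class CladeStatus(Enum):
    SYNAPOMORPHY = "synapomorphy"
    HOMOPLASY = "homoplasy"
    ABSENT = "absent"
    UNIVERSAL = "universal"


def motif_carriers(msa: MSA, motif: set[tuple[int, str]]) -> frozenset[str]:
    """Labels of sequences carrying every (column, symbol) of the motif."""
    if not motif:
        raise InputError("motif is empty")
    for col, _ in motif:
        msa.check_col(col)
    carriers = []
    for label, row in zip(msa.labels, msa.rows):
        if all(row[col - 1] == sym.upper() for col, sym in motif):
            carriers.append(label)
    return frozenset(carriers)


def motif_clade_status(
    tree: PhyloTree, msa: MSA, motif: set[tuple[int, str]]
) -> tuple[CladeStatus, frozenset[str], TreeNode | None]:
    """Classify a motif against the tree's (unrooted) bipartitions.

    Carriers are the tree leaves whose sequence matches every (column, symbol)
    pair. SYNAPOMORPHY means the carriers form one side of some edge
    bipartition (a clade of the unrooted tree); HOMOPLASY means the motif is
    scattered. Also returns the smallest rooted clade containing all carriers.
    """
    leaves = tree.leaf_labels()
    missing = leaves - set(msa.labels)
    if missing:
        raise BoundsError(f"tree leaves not in MSA: {sorted(missing)}")
    carriers = motif_carriers(msa, motif) & leaves
    if not carriers:
        return CladeStatus.ABSENT, carriers, None
    if carriers == leaves:
        return CladeStatus.UNIVERSAL, carriers, tree.root

    # bipartition test on the unrooted tree: each non-root node's leaf set is
    # one side of the edge above it
    is_clade = False
    for node in tree.root.walk():
        if node is tree.root:
            continue
        side = node.leaf_labels()
        if carriers == side or carriers == leaves - side:
            is_clade = True
            break
    status = CladeStatus.SYNAPOMORPHY if is_clade else CladeStatus.HOMOPLASY

    # minimal rooted clade spanning all carriers
    best = tree.root
    for node in tree.root.walk():
        side = node.leaf_labels()
        if carriers <= side and len(side) < len(best.leaf_labels()):
            best = node
    return status, carriers, best
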