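"""Rooted-tree container, Newick I/O and the phylogenetic covariance machinery.

The central objects are :class:`Phylogeny` — a rooted tree with branch
lengths in time units (Myr for a dated tree) and genus names on the tips —
and :class:`PhyloCovariance`, the among-tip covariance matrix implied by
shared evolutionary history: entry (i, j) is the path length from the root
to the most recent common ancestor of tips i and j.  Every comparative
method in the package (Brownian-motion likelihoods, Pagel's λ, contrasts,
ancestral reconstruction) traverses one of these two structures.

Newick reading and writing are delegated to :mod:`dendropy`; this module
only converts between dendropy's tree and the lightweight node structure
used internally.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, TreeValidationError

__all__ = [
    "Node",
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "write_newick",
    "resolve_polytomies",
    "prune_to_taxa",
    "vcv_matrix",
    "lambda_transform",
    "is_ultrametric",
]


class Node:
    """A single tree node with a parent link and a branch length to it."""

    __slots__ = ("children", "parent", "length", "label", "id")

    def __init__(self, length: float = 0.0, label: str | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length          # branch length to the parent; 0.0 at the root
        self.label = label            # tip label (genus) or optional internal label
        self.id: int = -1             # stable preorder index, set by Phylogeny

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Node ids are assigned in preorder at construction and are stable across
    copies, so reports can refer to internal nodes unambiguously.  Tip order
    (used to align trait vectors and covariance matrices) is the left-to-right
    leaf order of the tree.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._index()
        if validate:
            self.validate()

    def _index(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.id = i

    # -- traversals ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    # -- basic views --------------------------------------------------------

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def node_depths(self) -> dict[Node, float]:
        """Distance from the root to every node (root = 0)."""
        depths: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                depths[node] = depths[node.parent] + node.length
        return depths

    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        depths = self.node_depths()
        return max(depths[t] for t in self.tips)

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes)

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.length, node.label)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root), validate=False)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_tips < 2:
            raise TreeValidationError("a phylogeny needs at least 2 tips")
        labels = self.tip_labels
        if any(not lab for lab in labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise TreeValidationError(
                    f"missing branch length above node {node.label or node.id}"
                )
            if node.length < 0:
                raise TreeValidationError(
                    f"negative branch length ({node.length}) above node "
                    f"{node.label or node.id}"
                )

    # -- interop ------------------------------------------------------------

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def build(node: Node, dnode: dendropy.Node) -> None:
            dnode.edge.length = node.length if node.parent is not None else None
            if node.is_tip:
                dnode.taxon = taxa.require_taxon(label=node.label)
            else:
                if node.label:
                    dnode.label = node.label
                for child in node.children:
                    build(child, dnode.new_child())

        build(self.root, dtree.seed_node)
        return dtree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, validate: bool = True) -> "Phylogeny":
        def build(dnode: dendropy.Node) -> Node:
            length = dnode.edge.length
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(0.0 if length is None else float(length), label)
            node.length = length if length is not None else (
                None if dnode.parent_node is not None else 0.0
            )
            for dchild in dnode.child_nodes():
                node.add_child(build(dchild))
            return node

        return cls(build(dtree.seed_node), validate=validate)


@dataclass
class PhyloCovariance:
    """Among-tip covariance implied by shared root-to-MRCA path lengths."""

    matrix: np.ndarray
    tip_order: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, labels: Sequence[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(l) for l in labels]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(labels))


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree string into a validated :class:`Phylogeny`.

    Labels may be quoted; bracketed comments are stripped; internal labels
    are preserved when present.  Duplicate tip labels and missing branch
    lengths are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer subclasses
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(f"malformed Newick: {exc}", offset=offset) from exc
    return Phylogeny.from_dendropy(dtree)


def write_newick(tree: Phylogeny, annotate_internal_labels: bool = True) -> str:
    """Serialize to a single-line Newick string with round-trip precision."""
    dtree = tree.to_dendropy()
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
        unquoted_underscores=True,
        suppress_internal_node_labels=not annotate_internal_labels,
    )
    return text.strip() + "\n"


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Structural operations


def resolve_polytomies(tree: Phylogeny, seed: int = 0) -> Phylogeny:
    """Return a strictly binary copy; inserted branches have length zero.

    Multifurcations are resolved by repeatedly pairing two adjacent children
    (the pair chosen by a generator seeded with ``seed``) under a new
    zero-length node, so every tip-to-tip path length — and hence the induced
    covariance — is unchanged, and the left-to-right leaf order is preserved.
    An already-binary tree is returned as an unmodified copy.
    """
    out = tree.copy()
    rng = random.Random(seed)
    for node in list(out.postorder()):
        while len(node.children) > 2:
            # pair two children under a zero-length node, keeping the merged
            # node at the first child's position so leaf order is preserved
            i = rng.randrange(len(node.children) - 1)
            a = node.children[i]
            b = node.children[i + 1]
            j = i + 1
            merged = Node(0.0)
            merged.parent = node
            merged.add_child(a)
            merged.add_child(b)
            node.children[i] = merged
            del node.children[j]
    return Phylogeny(out.root, validate=False)


def prune_to_taxa(tree: Phylogeny, keep: Sequence[str]) -> Phylogeny:
    """Prune to the given tip set, merging pass-through internal branches.

    The root node is always retained (possibly with a single child) so that
    root-to-MRCA path lengths — and therefore the covariance matrix of the
    retained tips — are exactly the corresponding submatrix of the original.
    """
    keep_set = set(keep)
    missing = keep_set - set(tree.tip_labels)
    if missing:
        raise TreeValidationError(f"tips not in tree: {sorted(missing)}")
    out = tree.copy()

    # drop unwanted tips bottom-up
    for node in list(out.postorder()):
        if node.is_tip and node.label not in keep_set and node.parent is not None:
            node.parent.children.remove(node)
    # remove now-empty internal nodes and merge unary ones (except the root)
    changed = True
    while changed:
        changed = False
        for node in list(out.postorder()):
            if node is out.root or node.label in keep_set and node.is_tip:
                continue
            if node.is_tip:  # internal node that lost all children
                node.parent.children.remove(node)
                changed = True
            elif len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                child.parent = node.parent
                node.parent.children[node.parent.children.index(node)] = child
                changed = True
    return Phylogeny(out.root, validate=False)


# ---------------------------------------------------------------------------
# Covariance construction


def vcv_matrix(tree: Phylogeny) -> PhyloCovariance:
    """Phylogenetic covariance: C[i, j] = root-to-MRCA(i, j) path length.

    Diagonal entries are the root-to-tip distances; for an ultrametric tree
    they are all equal to the tree depth.  Accepts multifurcating trees.
    """
    tips = tree.tips
    labels = [t.label for t in tips]
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    depths = tree.node_depths()
    C = np.zeros((n, n))

    # postorder: collect tip indices below each node; tips in different child
    # subtrees of a node share exactly that node's depth
    below: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            i = index[node]
            C[i, i] = depths[node]
            below[node] = np.array([i])
        else:
            kids = [below.pop(c) for c in node.children]
            d = depths[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    C[np.ix_(kids[a], kids[b])] = d
                    C[np.ix_(kids[b], kids[a])] = d
            below[node] = np.concatenate(kids)
    return PhyloCovariance(C, labels)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's λ rescaling: off-diagonal entries multiplied by λ.

    λ = 1 leaves the Brownian covariance untouched; λ = 0 removes all shared
    history (a star phylogeny).  Values outside [0, 1] are rejected: for an
    ultrametric tree, 1 is the natural upper bound of the model set compared
    here, and λ > 1 can leave the matrix indefinite.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(M, list(C.tip_order))


def is_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> bool:
    """True when all root-to-tip distances agree within ``rel_tol`` × depth."""
    depths = tree.node_depths()
    d = np.array([depths[t] for t in tree.tips])
    dmax = d.max()
    if dmax == 0:
        return True
    return (dmax - d.min()) < rel_tol * dmax
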