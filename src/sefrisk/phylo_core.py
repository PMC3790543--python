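"""Rooted phylogenies, phylogenetic covariance, and phylogenetic-diversity arithmetic.

The tree is the backbone of every downstream computation: the
variance-covariance matrix V of shared root-to-MRCA path lengths drives
Pagel's-lambda likelihoods and PGLS, and Faith-style branch-length sums
quantify how much evolutionary history a surviving species set retains.
Newick parsing and node bookkeeping are delegated to :mod:`dendropy`;
everything numerical is built here on top of plain numpy arrays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "VCVMatrix",
    "NewickFormatError",
    "PhylogenyError",
    "read_newick",
    "vcv_matrix",
    "lambda_transform",
    "pd_total",
]


class PhylogenyError(ValueError):
    """Invalid tree structure or tree/data mismatch."""


class NewickFormatError(PhylogenyError):
    """Malformed Newick input."""


class Phylogeny:
    """A rooted tree with branch lengths over a local species pool.

    Tips are the species; branch lengths are in arbitrary time or
    divergence units. Polytomies are allowed. Tip labels must be unique
    and are exposed in a stable (postorder leaf) ordering that every
    vector-valued quantity in the package aligns to.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._leaves = list(tree.leaf_node_iter())
        self._labels = [lf.taxon.label.strip() for lf in self._leaves]
        self._index = {lab: i for i, lab in enumerate(self._labels)}
        self._depths: np.ndarray | None = None

    # -- construction ------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return read_newick(text)

    def _validate(self) -> None:
        tree = self._tree
        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 2:
            raise PhylogenyError("a phylogeny needs at least 2 tips")
        labels = [lf.taxon.label.strip() if lf.taxon else "" for lf in leaves]
        if any(not lab for lab in labels):
            raise PhylogenyError("every tip must carry a label")
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise PhylogenyError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        total = 0.0
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            bl = node.edge.length
            if bl is None:
                raise PhylogenyError(
                    f"missing branch length on edge above {_node_name(node)}"
                )
            if bl < 0:
                raise PhylogenyError(
                    f"negative branch length {bl} above {_node_name(node)}"
                )
            total += bl
        if total <= 0:
            raise PhylogenyError("tree has zero total branch length")

    # -- basic queries -----------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_internal_node_iter()
        )

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path length for each tip, in tip order."""
        if self._depths is None:
            depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
            for node in self._tree.preorder_node_iter():
                if node is self._tree.seed_node:
                    continue
                depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
            self._depths = np.array(
                [depth[id(lf)] for lf in self._leaves], dtype=float
            )
        return self._depths

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        d = self.tip_depths()
        dmax = d.max()
        return dmax > 0 and (dmax - d.min()) <= rtol * dmax

    def total_branch_length(self) -> float:
        return sum(
            nd.edge.length
            for nd in self._tree.preorder_node_iter()
            if nd is not self._tree.seed_node
        )

    # -- structure-changing helpers ----------------------------------

    def resolve_polytomies(self) -> "Phylogeny":
        """Return a binary tree, breaking polytomies with zero-length edges.

        Resolution is sequential (deterministic). Needed only by the D
        statistic, which is defined on fully bifurcating trees.
        """
        clone = self._tree.clone(depth=1)
        clone.resolve_polytomies()
        for node in clone.preorder_node_iter():
            if node is not clone.seed_node and node.edge.length is None:
                node.edge.length = 0.0
        return Phylogeny(clone)

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        keep = set(keep)
        missing = keep - set(self._labels)
        if missing:
            raise PhylogenyError(f"unknown tip labels: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label.strip() in keep]
        clone.retain_taxa(taxa)
        return Phylogeny(clone)

    def to_newick(self) -> str:
        return (
            self._tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Phylogeny(n_tips={self.n_tips})"


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return "<internal node>"


@dataclass
class VCVMatrix:
    """Phylogenetic variance-covariance matrix.

    ``matrix[i, j]`` is the branch length shared by the root-to-tip paths
    of tips i and j (the depth of their MRCA); diagonals are root-to-tip
    distances. Under Brownian motion trait covariances are proportional
    to these entries.
    """

    labels: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("VCV matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("label/matrix size mismatch")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("VCV matrix must be symmetric")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.labels)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    if not isinstance(text, str) or not text.strip():
        raise NewickFormatError("empty Newick input")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        pos = _error_position(text)
        raise NewickFormatError(
            f"could not parse Newick (near character {pos}): {exc}"
        ) from exc
    phy = Phylogeny(tree)
    if not phy.is_ultrametric(rtol=0.01):
        logger.warning(
            "tree is not ultrametric (tip depths differ by >1%%); "
            "Pagel's lambda has its standard interpretation on ultrametric trees"
        )
    return phy


def _error_position(text: str) -> int:
    """Best-effort character position of a Newick syntax problem."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
    if depth != 0 or ";" not in text:
        return len(text)
    return 0


def vcv_matrix(tree: Phylogeny) -> VCVMatrix:
    """Shared-path-length (Brownian) covariance matrix of the tips.

    Computed in one postorder pass: each internal node at depth *t*
    contributes covariance *t* to every tip pair split between two of
    its child subtrees.
    """
    n = tree.n_tips
    V = np.zeros((n, n))
    index = tree._index
    depth: dict[int, float] = {id(tree._tree.seed_node): 0.0}
    for node in tree._tree.preorder_node_iter():
        if node is not tree._tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    tips_below: dict[int, np.ndarray] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            idx = np.array([index[node.taxon.label.strip()]])
        else:
            groups = [tips_below.pop(id(c)) for c in node.child_nodes()]
            t = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    V[np.ix_(groups[a], groups[b])] = t
                    V[np.ix_(groups[b], groups[a])] = t
            idx = np.concatenate(groups)
        tips_below[id(node)] = idx
    np.fill_diagonal(V, tree.tip_depths())
    return VCVMatrix(tree.tip_labels, V)


def lambda_transform(V: VCVMatrix | np.ndarray, lam: float, *, max_lambda: float = 1.0) -> VCVMatrix | np.ndarray:
    """Pagel's lambda rescaling: multiply off-diagonal covariances by lam.

    lambda = 1 leaves the Brownian structure intact; lambda = 0 erases all
    phylogenetic covariance, leaving independent tips. Values above
    ``max_lambda`` (default 1.0, matching the conventional range) are
    rejected.
    """
    if not (0.0 <= lam <= max_lambda):
        raise ValueError(f"lambda must be in [0, {max_lambda}], got {lam}")
    arr = V.matrix if isinstance(V, VCVMatrix) else np.asarray(V, dtype=float)
    out = arr * lam
    np.fill_diagonal(out, np.diag(arr))
    if isinstance(V, VCVMatrix):
        return VCVMatrix(list(V.labels), out)
    return out


def pd_total(tree: Phylogeny, subset: Sequence[str] | set[str]) -> float:
    """Faith-style phylogenetic diversity of a species subset.

    Sum of branch lengths of the minimal subtree connecting the subset
    tips to the root: the amount of evolutionary history the subset
    spans. Monotone under subset inclusion; the full tip set gives the
    total branch length.
    """
    members = {s.strip() for s in subset}
    if not members:
        raise ValueError("subset must be non-empty")
    unknown = members - set(tree.tip_labels)
    if unknown:
        raise PhylogenyError(f"unknown species in subset: {sorted(unknown)}")

    total = 0.0
    has_member: dict[int, bool] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            hit = node.taxon.label.strip() in members
        else:
            hit = any(has_member[id(c)] for c in node.child_nodes())
        has_member[id(node)] = hit
        if hit and node is not tree._tree.seed_node:
            total += node.edge.length
    return total
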