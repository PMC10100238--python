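"""Phylogeny input/output, pruning, and Brownian covariance construction.

Trees are rooted dendropy trees wrapped in a thin :class:`Phylogeny`
container that fixes a tip order and exposes the quantities PGLS needs:
root-to-tip depths and the phylogenetic variance-covariance matrix V,
where ``V[i, j]`` is the depth of the most recent common ancestor of tips
i and j (the expected shared Brownian history) and ``V[i, i]`` is the
root-to-tip depth of tip i.

Tip labels are normalised to the dominant convention of avian phylogeny
files: surrounding whitespace is trimmed and internal spaces are replaced
by underscores, so labels in tree files and trait tables compare as exact
strings.

A root edge length, when present, counts towards every depth: it records
shared history above the first split, which matters after pruning (see
:func:`prune_to`).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCov",
    "TreeParseError",
    "TreeValidationError",
    "read_trees",
    "prune_to",
    "vcv",
    "max_clade_cred",
    "mcc_tree",
    "write_newick",
    "normalize_label",
]


class TreeParseError(ValueError):
    """A tree file could not be parsed."""


class TreeValidationError(ValueError):
    """A parsed tree violates a structural requirement."""


def normalize_label(label: str) -> str:
    """Trim whitespace and replace internal spaces with underscores."""
    return label.strip().replace(" ", "_")


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, plus a fixed tip order.

    ``tips`` is the leaf-traversal order of the underlying dendropy tree
    after label normalisation; all matrix-valued quantities derived from
    the tree use this order.
    """

    tree: dendropy.Tree
    tips: tuple[str, ...]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, index: int | None = None) -> "Phylogeny":
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise TreeValidationError(
                    f"tree {index if index is not None else ''}: unlabeled tip"
                )
            leaf.taxon.label = normalize_label(leaf.taxon.label)
            labels.append(leaf.taxon.label)
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            where = f" in tree {index}" if index is not None else ""
            raise TreeValidationError(f"duplicate tip labels{where}: {dupes}")
        return cls(tree=tree, tips=tuple(labels))

    @classmethod
    def from_newick(cls, newick: str, index: int | None = None) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises a zoo of error types
            idx = f" {index}" if index is not None else ""
            if "duplicate" in str(exc).lower():
                raise TreeValidationError(
                    f"duplicate tip labels in tree{idx}: {exc}"
                ) from exc
            raise TreeParseError(f"failed to parse tree{idx}: {exc}") from exc
        return cls.from_dendropy(tree, index=index)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Depth of every node from the (virtual) origin.

        The seed node's own edge length, if set, is included, so depths are
        comparable before and after pruning.
        """
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            e = node.edge.length
            e = 0.0 if e is None else float(e)
            if e < 0:
                raise TreeValidationError(f"negative branch length {e}")
            parent = node.parent_node
            depths[node] = e + (depths[parent] if parent is not None else 0.0)
        return depths

    def tip_depths(self) -> np.ndarray:
        depths = self.node_depths()
        by_label = {
            leaf.taxon.label: depths[leaf] for leaf in self.tree.leaf_node_iter()
        }
        return np.array([by_label[t] for t in self.tips])

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        scale = max(d.max(), 1e-300)
        return bool((d.max() - d.min()) <= rel_tol * scale)

    def to_newick(self, sig_digits: int = 17) -> str:
        return _build_newick(self, sig_digits=sig_digits)


@dataclass
class PhyloCov:
    """Phylogenetic variance-covariance matrix in a fixed taxon order.

    ``V[i, j]`` is the depth of the MRCA of taxa i and j; the diagonal
    holds root-to-tip depths. Symmetric and positive semi-definite for any
    valid rooted tree.
    """

    taxa: tuple[str, ...]
    V: np.ndarray
    _eig_cache: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        if self.V.shape != (len(self.taxa), len(self.taxa)):
            raise TreeValidationError("covariance shape does not match taxa")

    @property
    def diag(self) -> np.ndarray:
        return np.diag(self.V).copy()

    def submatrix(self, taxa) -> "PhyloCov":
        taxa = list(taxa)
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise TreeValidationError(f"taxa not in covariance: {missing}")
        idx = np.array([index[t] for t in taxa])
        return PhyloCov(taxa=tuple(taxa), V=self.V[np.ix_(idx, idx)])


def read_trees(path: str, format: str = "newick") -> list[Phylogeny]:
    """Read a file of trees, preserving file order and tip labels.

    Newick files are split into individual statements so a malformed tree
    is reported by its (0-based) index. Nexus files go through dendropy's
    TreeList reader.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format: {format!r}")
    out: list[Phylogeny] = []
    if format == "newick":
        with open(path) as fh:
            text = fh.read()
        statements = [s.strip() for s in text.split(";") if s.strip()]
        if not statements:
            raise TreeParseError(f"no trees found in {path}")
        for i, stmt in enumerate(statements):
            phy = Phylogeny.from_newick(stmt + ";", index=i)
            _warn_if_not_ultrametric(phy, i)
            out.append(phy)
    else:
        try:
            tl = dendropy.TreeList.get(
                path=path, schema="nexus", preserve_underscores=True
            )
        except Exception as exc:
            raise TreeParseError(f"failed to parse nexus file {path}: {exc}") from exc
        if len(tl) == 0:
            raise TreeParseError(f"no trees found in {path}")
        for i, t in enumerate(tl):
            phy = Phylogeny.from_dendropy(t, index=i)
            _warn_if_not_ultrametric(phy, i)
            out.append(phy)
    return out


def _warn_if_not_ultrametric(phy: Phylogeny, index: int) -> None:
    if not phy.is_ultrametric():
        warnings.warn(
            f"tree {index} is not ultrametric; the lambda transform is still "
            "defined but depths differ across tips",
            stacklevel=3,
        )


def _fmt_len(x: float, sig_digits: int) -> str:
    return f"{x:.{sig_digits}g}"


def _build_newick(
    phy: Phylogeny,
    sig_digits: int = 17,
    keep: set[str] | None = None,
) -> str:
    """Serialise (optionally pruning to ``keep``) with unifurcations collapsed.

    Collapsed degree-2 nodes have their branch lengths summed; if pruning
    strips everything off the root side, the removed path is kept as a root
    edge length so depths are conserved.
    """
    frag: dict[dendropy.Node, tuple[str | None, float]] = {}
    for node in phy.tree.postorder_node_iter():
        e = node.edge.length
        e = 0.0 if e is None else float(e)
        if node.is_leaf():
            label = node.taxon.label
            if keep is not None and label not in keep:
                frag[node] = (None, 0.0)
            else:
                frag[node] = (label, e)
        else:
            kids = [frag[c] for c in node.child_nodes() if frag[c][0] is not None]
            if not kids:
                frag[node] = (None, 0.0)
            elif len(kids) == 1:
                s, ce = kids[0]
                frag[node] = (s, ce + e)
            else:
                inner = ",".join(
                    f"{s}:{_fmt_len(ce, sig_digits)}" for s, ce in kids
                )
                frag[node] = (f"({inner})", e)
    s, root_edge = frag[phy.tree.seed_node]
    if s is None:
        raise TreeValidationError("pruning removed every tip")
    if root_edge > 0:
        return f"{s}:{_fmt_len(root_edge, sig_digits)};"
    return f"{s};"


def prune_to(phy: Phylogeny, taxa) -> Phylogeny:
    """Prune a tree to a taxon subset, conserving depths and MRCA depths.

    Degree-2 internal nodes left behind are suppressed with their branch
    lengths summed; shared history above the first surviving split is
    retained as a root edge length, so the pruned tree's `vcv` equals the
    corresponding submatrix of the original tree's `vcv`.
    """
    keep = {normalize_label(t) for t in taxa}
    missing = sorted(keep - set(phy.tips))
    if missing:
        raise TreeValidationError(f"taxa absent from tree: {missing}")
    newick = _build_newick(phy, keep=keep)
    pruned = Phylogeny.from_newick(newick)
    # order tips as in the original tree for determinism
    return pruned


def vcv(phy: Phylogeny) -> PhyloCov:
    """Phylogenetic covariance: V[i, j] = depth of MRCA(i, j)."""
    depths = phy.node_depths()  # validates branch lengths >= 0
    index = {t: i for i, t in enumerate(phy.tips)}
    n = phy.n_tips
    V = np.zeros((n, n))
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depths[node]
            tipsets[node] = [i]
        else:
            d = depths[node]
            child_sets = [tipsets.pop(c) for c in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = np.asarray(child_sets[a])
                    ib = np.asarray(child_sets[b])
                    V[np.ix_(ia, ib)] = d
                    V[np.ix_(ib, ia)] = d
            merged: list[int] = []
            for cs in child_sets:
                merged.extend(cs)
            tipsets[node] = merged
    return PhyloCov(taxa=phy.tips, V=V)


def _clades(phy: Phylogeny) -> set[frozenset]:
    out = set()
    tipsets: dict[dendropy.Node, frozenset] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(tipsets.pop(c) for c in node.child_nodes()))
            tipsets[node] = s
            out.add(s)
    return out


def max_clade_cred(trees: list[Phylogeny]) -> tuple[int, list[float]]:
    """Index and log clade-credibility score of every tree in a sample.

    Each tree is scored by the sum over its internal clades of the log of
    that clade's frequency in the sample; the maximum clade credibility
    tree maximises this score (ties broken towards the lowest index).
    """
    if not trees:
        raise TreeValidationError("empty tree list")
    tipset0 = set(trees[0].tips)
    for i, t in enumerate(trees):
        if set(t.tips) != tipset0:
            raise TreeValidationError(f"tree {i} has a different tip set")
    per_tree = [_clades(t) for t in trees]
    counts: Counter = Counter()
    for clades in per_tree:
        counts.update(clades)
    n = len(trees)
    scores = [
        float(sum(math.log(counts[c] / n) for c in clades)) for clades in per_tree
    ]
    best = int(np.argmax(scores))
    return best, scores


def mcc_tree(trees: list[Phylogeny]) -> Phylogeny:
    """The maximum clade credibility tree of a posterior sample."""
    best, _ = max_clade_cred(trees)
    return trees[best]


def write_newick(phy: Phylogeny, path: str | None = None, sig_digits: int = 6) -> str:
    """Serialise to Newick with branch lengths at 6 significant digits."""
    s = _build_newick(phy, sig_digits=sig_digits)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s
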