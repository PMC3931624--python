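"""Rooted phylogeny container, Newick/NEXUS I/O and patristic distances.

The :class:`PhyloTree` wraps a :class:`dendropy.Tree` and adds the
validation and flat index arrays the rest of the package needs: a fixed
postorder over nodes, stable node identifiers, per-node branch lengths
and children lists.  Tip labels are canonicalised on input (whitespace
trimmed, underscores treated as spaces, per the Newick convention) so
that names match across the tree, the trait matrix and the predictor
table.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import NewickFormatError, ValidationError

__all__ = [
    "PhyloTree",
    "canonical_label",
    "read_newick",
    "read_tree",
    "patristic_matrix",
    "write_annotated_tree",
]


def canonical_label(label) -> str:
    """Normalise a species label: trim, collapse whitespace, ``_`` == `` ``."""
    return " ".join(str(label).replace("_", " ").split())


class PhyloTree:
    """A rooted phylogeny with branch lengths.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``.  Ownership passes to this object; the
        dendropy tree must not be mutated afterwards.
    missing_length:
        Policy for edges without a branch length: ``"error"`` (default)
        raises :class:`ValidationError`; ``"zero"`` substitutes 0.0 and
        emits a warning.  The downstream analyses are meaningless
        without branch lengths, hence the hard default.

    Attributes
    ----------
    n_nodes, n_tips : int
    postorder : list[int]
        Node indices in postorder; the root is last.  All flat arrays
        below are indexed by these node indices.
    branch_lengths : ndarray
        Length of the edge above each node (0.0 for the root).
    children : list[list[int]]
    is_tip : ndarray of bool
    node_ids : list[str]
        Tips carry their canonical label; internal nodes are named
        ``nodeK`` with K counting internal nodes in postorder (the root
        therefore has the highest K).
    tip_labels : list[str]
        Canonical tip labels in the tree's leaf order.
    """

    def __init__(self, tree: dendropy.Tree, missing_length: str = "error"):
        if missing_length not in ("error", "zero"):
            raise ValueError("missing_length must be 'error' or 'zero'")
        self._tree = tree
        self._index(missing_length)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, missing_length: str = "error") -> "PhyloTree":
        """Parse a Newick string.  Comments in ``[...]`` are ignored."""
        try:
            t = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "duplicate taxon label" in str(exc).lower():
                raise ValidationError(f"duplicate tip labels: {exc}") from exc
            raise NewickFormatError(_parse_error_message(exc)) from exc
        return cls(t, missing_length=missing_length)

    @classmethod
    def from_string(cls, text: str, schema: str = "newick",
                    missing_length: str = "error") -> "PhyloTree":
        if schema == "newick":
            return cls.from_newick(text, missing_length=missing_length)
        try:
            t = dendropy.Tree.get(
                data=text, schema=schema, preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise NewickFormatError(_parse_error_message(exc)) from exc
        return cls(t, missing_length=missing_length)

    @classmethod
    def from_file(cls, path, schema: str = "newick",
                  missing_length: str = "error") -> "PhyloTree":
        with open(path) as fh:
            return cls.from_string(fh.read(), schema=schema,
                                   missing_length=missing_length)

    # -- indexing & validation ------------------------------------------

    def _index(self, missing_length: str) -> None:
        nodes = list(self._tree.postorder_node_iter())
        if not nodes:
            raise ValidationError("empty tree")
        self._nodes = nodes
        index_of = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.n_nodes = n
        self.postorder = list(range(n))
        self.is_tip = np.zeros(n, dtype=bool)
        self.branch_lengths = np.zeros(n, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.parent = np.full(n, -1, dtype=int)
        self.node_ids: list[str] = [""] * n

        root = self._tree.seed_node
        n_internal = 0
        tip_labels: list[str] = []
        for i, nd in enumerate(nodes):
            if nd is not root:
                length = nd.edge.length
                if length is None:
                    if missing_length == "error":
                        raise ValidationError(
                            "edge without a branch length; pass "
                            "missing_length='zero' to substitute 0")
                    warnings.warn("missing branch length substituted with 0.0",
                                  stacklevel=3)
                    length = 0.0
                if length < 0:
                    raise ValidationError(f"negative branch length {length}")
                self.branch_lengths[i] = float(length)
                self.parent[i] = index_of[id(nd.parent_node)]
            for ch in nd.child_nodes():
                self.children[i].append(index_of[id(ch)])
            if nd.is_leaf():
                raw = nd.taxon.label if nd.taxon is not None else nd.label
                if raw is None or not str(raw).strip():
                    raise ValidationError("tip with empty label")
                lab = canonical_label(raw)
                self.is_tip[i] = True
                self.node_ids[i] = lab
            else:
                self.node_ids[i] = f"node{n_internal}"
                n_internal += 1

        # leaf order as written in the source (preorder of leaves)
        for nd in self._tree.leaf_node_iter():
            raw = nd.taxon.label if nd.taxon is not None else nd.label
            tip_labels.append(canonical_label(raw))
        self.tip_labels = tip_labels
        self.n_tips = len(tip_labels)
        if self.n_tips < 2:
            raise ValidationError("a tree needs at least 2 tips")
        if len(set(tip_labels)) != self.n_tips:
            dupes = sorted({x for x in tip_labels if tip_labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {', '.join(dupes)}")
        self.tip_index = {self.node_ids[i]: i
                          for i in range(n) if self.is_tip[i]}
        self.root_index = index_of[id(root)]
        self.internal_ids = [self.node_ids[i] for i in self.postorder
                             if not self.is_tip[i]]
        self._id_to_index = {self.node_ids[i]: i for i in range(n)}

    # -- basic queries ---------------------------------------------------

    def node_index(self, node_id: str) -> int:
        try:
            return self._id_to_index[node_id]
        except KeyError:
            raise ValidationError(f"unknown node id: {node_id!r}") from None

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (preorder accumulation)."""
        d = np.zeros(self.n_nodes)
        for i in reversed(self.postorder):  # reversed postorder = preorder
            if self.parent[i] >= 0:
                d[i] = d[self.parent[i]] + self.branch_lengths[i]
        return d

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        d = self.depths()
        return float(d[self.is_tip].max())

    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def rescale(self, factor: float) -> "PhyloTree":
        """Return a copy with all branch lengths multiplied by ``factor``."""
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return PhyloTree(clone)

    # -- distances -------------------------------------------------------

    def patristic_matrix(self) -> pd.DataFrame:
        """Pairwise path-length distances between tips.

        Delegates to dendropy's phylogenetic distance matrix and returns
        a symmetric :class:`pandas.DataFrame` indexed by canonical tip
        label, in the tree's leaf order.
        """
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {canonical_label(t.label): t for t in self._tree.taxon_namespace
                if t.label is not None}
        labels = self.tip_labels
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]])
        return pd.DataFrame(d, index=labels, columns=labels)

    # -- serialisation ---------------------------------------------------

    def to_newick(self, annotations: Mapping[str, object] | None = None) -> str:
        """Serialise to Newick, optionally with ``[&...]`` node comments.

        ``annotations`` maps node ids (see :attr:`node_ids`) to either a
        scalar or a mapping of key/value pairs; they are embedded as
        comments directly after the node and survive a round trip as
        ignorable metadata.
        """
        ann = dict(annotations or {})
        for key in ann:
            if key not in self._id_to_index:
                raise ValidationError(f"unknown node id in annotations: {key!r}")
        out = self._subtree_newick(self.root_index, ann)
        return out + ";"

    def _subtree_newick(self, i: int, ann: Mapping[str, object]) -> str:
        if self.is_tip[i]:
            s = self.node_ids[i].replace(" ", "_")
        else:
            s = "(" + ",".join(self._subtree_newick(c, ann)
                               for c in self.children[i]) + ")"
        node_id = self.node_ids[i]
        if node_id in ann:
            s += _format_comment(ann[node_id])
        if self.parent[i] >= 0:
            s += f":{self.branch_lengths[i]:.17g}"
        return s

    def to_nexus(self, annotations: Mapping[str, object] | None = None,
                 tree_name: str = "tree1") -> str:
        """Serialise as a minimal NEXUS document with one TREES block."""
        return nexus_document({tree_name: (self, annotations)})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips}, n_nodes={self.n_nodes})"


def _format_comment(value) -> str:
    if isinstance(value, Mapping):
        inner = ",".join(f"{k}={_fmt_scalar(v)}" for k, v in value.items())
    else:
        inner = _fmt_scalar(value)
    return f"[&{inner}]"


def _fmt_scalar(v) -> str:
    if isinstance(v, float):
        return f"{v:.17g}"
    return str(v)


def _parse_error_message(exc: Exception) -> str:
    msg = str(exc)
    col = getattr(exc, "col_num", None)
    line = getattr(exc, "line_num", None)
    if col is not None:
        loc = f" (line {line}, column {col})" if line is not None else \
              f" (column {col})"
        if "column" not in msg:
            msg += loc
    return f"failed to parse tree: {msg}"


def nexus_document(trees: Mapping[str, tuple]) -> str:
    """Build a NEXUS document from ``{name: (PhyloTree, annotations)}``.

    All trees must share the same taxon set; a single TAXA block is
    emitted followed by one TREE statement per entry.
    """
    first = next(iter(trees.values()))[0]
    labels = [lab.replace(" ", "_") for lab in sorted(first.tip_labels)]
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(labels)};",
        "    TAXLABELS " + " ".join(labels) + ";",
        "END;",
        "BEGIN TREES;",
    ]
    for name, (tree, ann) in trees.items():
        safe = name.replace(" ", "_")
        lines.append(f"    TREE {safe} = [&R] {tree.to_newick(ann)}")
    lines.append("END;")
    return "\n".join(lines) + "\n"


# -- module-level convenience wrappers ----------------------------------

def read_newick(text: str, missing_length: str = "error") -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text, missing_length=missing_length)


def read_tree(path, schema: str = "newick",
              missing_length: str = "error") -> PhyloTree:
    return PhyloTree.from_file(path, schema=schema,
                               missing_length=missing_length)


def patristic_matrix(tree: PhyloTree) -> pd.DataFrame:
    return tree.patristic_matrix()


def write_annotated_tree(tree: PhyloTree,
                         node_annotations: Mapping[str, object] | None,
                         path=None, schema: str = "nexus",
                         tree_name: str = "tree1") -> str:
    """Serialise a tree with per-node comment annotations.

    Returns the document text; if ``path`` is given it is also written
    there.
    """
    if schema == "nexus":
        text = tree.to_nexus(node_annotations, tree_name=tree_name)
    elif schema == "newick":
        text = tree.to_newick(node_annotations) + "\n"
    else:
        raise ValueError("schema must be 'nexus' or 'newick'")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
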