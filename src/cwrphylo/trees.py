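"""Rooted phylogenetic trees and patristic distances.

This module is the measurement substrate for the crop-wild-relative screen:
trees are read from Newick, transformed to ultrametric, scaled so every
root-to-tip path has length 1.0, and converted to pairwise patristic distance
matrices.  Distances on such a normalized tree are dimensionless and bounded
by 2.0, which makes per-crop compatibility thresholds comparable across
markers and studies.

Tree storage and Newick parsing are delegated to :mod:`dendropy`; the
ultrametric transformations (mean-path-length smoothing and a least-squares
height projection) are implemented here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.utility import error as _dp_error

from .errors import (
    DataError,
    DegenerateHeightError,
    DegenerateTreeError,
    DuplicateTaxonError,
    InsufficientOverlapError,
    MalformedInputError,
    NotUltrametricError,
    ConfigurationError,
)

logger = logging.getLogger("cwrphylo")

#: relative tolerance of the ultrametricity (equal root-to-tip depth) check
ULTRAMETRIC_RTOL = 1e-6
#: heights at or below this are treated as degenerate (zero-height star trees)
MIN_HEIGHT = 1e-12

_WS_RUN = re.compile(r"[\s_]+")


def canonical_name(name: str) -> str:
    """Canonical taxon name: outer whitespace trimmed, internal runs of
    whitespace/underscores collapsed to single underscores.

    Matching between tree tips and knowledge-base tables is exact on this
    canonical form; no fuzzy taxonomy is attempted.
    """
    return _WS_RUN.sub("_", name.strip())


class PhyloTree:
    """A rooted tree with uniquely labelled tips and non-negative branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the package's
    invariants (label uniqueness after canonicalization, clamped branch
    lengths) and carries provenance metadata such as the ultrametricization
    method and the height factor applied during normalization.
    """

    def __init__(self, dtree: dendropy.Tree, metadata: dict | None = None):
        self.dtree = dtree
        self.metadata = dict(metadata or {})

    # -- basic accessors ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        return {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in self.dtree.leaf_node_iter()
        }

    @property
    def height(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = list(self.tip_depths().values())
        h = max(depths)
        return (h - min(depths)) <= rtol * max(h, 1.0)

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.dtree.clone(depth=1), dict(self.metadata))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_tips={self.n_tips} height={self.height:.6g}>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Negative branch lengths are clamped to zero and missing lengths treated
    as zero, both with a logged warning (maximum-likelihood outputs
    occasionally contain either).  The input's root is trusted; a basal
    trifurcation is accepted as a rooted polytomy with a logged notice.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except _dp_error.DataParseError as exc:
        offset = getattr(exc, "col_num", None)
        name = type(exc).__name__
        if "Duplicate" in name:
            raise DuplicateTaxonError(str(exc)) from exc
        raise MalformedInputError(f"malformed Newick: {exc}", offset) from exc

    labels: set[str] = set()
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not (leaf.taxon.label or "").strip():
            raise MalformedInputError("Newick contains a tip with an empty label")
        label = canonical_name(leaf.taxon.label)
        if label in labels:
            raise DuplicateTaxonError(f"duplicate tip label after canonicalization: {label!r}")
        labels.add(label)
        leaf.taxon.label = label

    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge
            continue
        if edge.length is None:
            logger.warning("missing branch length treated as 0")
            edge.length = 0.0
        elif edge.length < 0:
            logger.warning("negative branch length %g clamped to 0", edge.length)
            edge.length = 0.0

    if len(dtree.seed_node.child_nodes()) > 2:
        logger.info(
            "input root is a polytomy (%d children); treating it as the root",
            len(dtree.seed_node.child_nodes()),
        )
    return PhyloTree(dtree)


def read_newick_file(path) -> PhyloTree:
    with open(path, "r", encoding="utf-8") as fh:
        return read_newick(fh.read())


def write_newick(tree: PhyloTree) -> str:
    """Serialize with mandatory branch lengths at 10 significant digits."""
    out = tree.clone()
    for edge in out.dtree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            edge.length = 0.0
    out.dtree.seed_node.edge.length = None
    return out.dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )


def write_newick_file(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree))


# ---------------------------------------------------------------------------
# Patristic distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric taxon x taxon patristic distance matrix.

    ``labels`` follow the source tree's tip order.  On a height-1 ultrametric
    tree every entry lies in [0, 2].
    """

    labels: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataError(
                f"distance matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if (self.values < 0).any():
            raise DataError("distance matrix has negative entries")
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)
        self._index = {canonical_name(l): i for i, l in enumerate(self.labels)}
        if len(self._index) != n:
            raise DuplicateTaxonError("duplicate labels in distance matrix")

    def __contains__(self, label: str) -> bool:
        return canonical_name(label) in self._index

    def distance(self, a: str, b: str) -> float:
        from .errors import MissingTaxonError

        try:
            ia = self._index[canonical_name(a)]
            ib = self._index[canonical_name(b)]
        except KeyError as exc:
            raise MissingTaxonError(f"taxon {exc.args[0]!r} not in distance matrix") from exc
        return float(self.values[ia, ib])

    def row(self, label: str) -> dict[str, float]:
        from .errors import MissingTaxonError

        key = canonical_name(label)
        if key not in self._index:
            raise MissingTaxonError(f"taxon {label!r} not in distance matrix")
        i = self._index[key]
        return {l: float(self.values[i, j]) for j, l in enumerate(self.labels)}

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self._index[canonical_name(l)] for l in labels]
        return DistanceMatrix([self.labels[i] for i in idx], self.values[np.ix_(idx, idx)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    # -- writers -----------------------------------------------------------

    def write_phylip(self, path) -> None:
        """PHYLIP-style square matrix: taxon-count header, then label + row."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                vals = "\t".join(format(v, ".10g") for v in row)
                fh.write(f"{label}\t{vals}\n")

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.10g")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_crop_star(cls, crop: str, distances: dict[str, float]) -> "DistanceMatrix":
        """Build a valid (star-additive) matrix from one crop's distance row.

        Used in matrix-bypass mode when only crop-to-relative distances are
        known (e.g. distances digitized from a published table).  Pairs not
        involving the crop are assigned the star-metric sum d(i,crop) +
        d(crop,j), which preserves every crop-relative distance and keeps the
        matrix a proper additive tree metric.
        """
        labels = [crop] + [t for t in distances if canonical_name(t) != canonical_name(crop)]
        d = np.array([0.0] + [float(distances[t]) for t in labels[1:]])
        values = d[:, None] + d[None, :]
        values[0, :] = d
        values[:, 0] = d
        np.fill_diagonal(values, 0.0)
        return cls(labels, values)


def patristic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """All-pairs path-length (patristic) distances, in tree tip order."""
    if tree.n_tips < 2:
        raise DegenerateTreeError("patristic distances require at least 2 tips")
    pdm = tree.dtree.phylogenetic_distance_matrix()
    leaves = list(tree.dtree.leaf_node_iter())
    taxa = [leaf.taxon for leaf in leaves]
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix([t.label for t in taxa], values)


# ---------------------------------------------------------------------------
# Ultrametric transformation and height normalization
# ---------------------------------------------------------------------------

def _mpl_heights(dtree: dendropy.Tree) -> dict:
    """Mean-path-length node heights: height(v) = mean over descendant tips of
    the v-to-tip path length (each tip weighted equally)."""
    heights: dict = {}
    ntips: dict = {}
    for node in dtree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            heights[node] = 0.0
            ntips[node] = 1
        else:
            total = sum(
                ntips[c] * ((c.edge.length or 0.0) + heights[c]) for c in children
            )
            ntips[node] = sum(ntips[c] for c in children)
            heights[node] = total / ntips[node]
    return heights


def _ls_heights(dtree: dendropy.Tree) -> dict:
    """Least-squares node heights: minimize sum over edges of
    ((h(parent) - h(child)) - b)^2 with tips fixed at height 0."""
    internal = [n for n in dtree.preorder_node_iter() if n.child_nodes()]
    index = {n: i for i, n in enumerate(internal)}
    rows, rhs = [], []
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        row = np.zeros(len(internal))
        row[index[node.parent_node]] = 1.0
        if node in index:
            row[index[node]] = -1.0
        rows.append(row)
        rhs.append(node.edge.length or 0.0)
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    heights = {n: float(sol[i]) for n, i in index.items()}
    for node in dtree.leaf_node_iter():
        heights[node] = 0.0
    return heights


_ULTRAMETRIC_METHODS = {
    "mean_path_length": _mpl_heights,
    "mpl": _mpl_heights,
    "least_squares": _ls_heights,
    "ls": _ls_heights,
}


def make_ultrametric(tree: PhyloTree, method: str = "mean_path_length") -> PhyloTree:
    """Return a topology-preserving ultrametric version of ``tree``.

    ``mean_path_length`` sets each node's height to the mean of its
    node-to-tip path lengths; ``least_squares`` projects branch lengths onto
    the closest set consistent with fixed node heights.  Either way heights
    are then clamped top-down so no child sits above its parent, and branch
    lengths are rebuilt as height differences, which makes every root-to-tip
    path exactly equal to the root height.
    """
    key = method.lower()
    if key not in _ULTRAMETRIC_METHODS:
        raise ConfigurationError(
            f"unknown ultrametric method {method!r}; "
            f"expected one of {sorted(set(_ULTRAMETRIC_METHODS))}"
        )
    if tree.n_tips < 2:
        raise DegenerateTreeError("ultrametric transform requires at least 2 tips")
    for edge in tree.dtree.preorder_edge_iter():
        if edge.tail_node is not None and not np.isfinite(edge.length or 0.0):
            raise DataError("non-finite branch length")

    out = tree.clone()
    heights = _ULTRAMETRIC_METHODS[key](out.dtree)
    clamped: dict = {}
    for node in out.dtree.preorder_node_iter():
        h = max(heights[node], 0.0)
        if node.parent_node is not None:
            h = min(h, clamped[node.parent_node])
        if not node.child_nodes():
            h = 0.0
        clamped[node] = h
        if node.parent_node is not None:
            node.edge.length = clamped[node.parent_node] - h
    out.metadata["ultrametric_method"] = (
        "mean_path_length" if _ULTRAMETRIC_METHODS[key] is _mpl_heights else "least_squares"
    )
    return out


def normalize_height(tree: PhyloTree) -> PhyloTree:
    """Rescale an ultrametric tree so the root-to-tip height is exactly 1.0.

    All pairwise patristic distances scale by the same factor, so distances
    on the result are dimensionless fractions of total tree depth.
    """
    if not tree.is_ultrametric():
        raise NotUltrametricError(
            "normalize_height requires an ultrametric tree; run make_ultrametric first"
        )
    h = tree.height
    if h <= MIN_HEIGHT:
        raise DegenerateHeightError(f"tree height {h:g} is zero or near zero")
    out = tree.clone()
    factor = 1.0 / h
    for edge in out.dtree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is not None:
            edge.length = edge.length * factor
    out.metadata["height_factor"] = factor
    out.metadata["original_height"] = h
    return out


# ---------------------------------------------------------------------------
# Shared-taxon pruning
# ---------------------------------------------------------------------------

def prune_to_shared(tree_a: PhyloTree, tree_b: PhyloTree) -> tuple[PhyloTree, PhyloTree]:
    """Prune both trees to their common tip set (exact canonical-name match).

    Path lengths among retained tips are preserved: suppressed unifurcations
    have their branch lengths summed.
    """
    shared = set(tree_a.tip_labels) & set(tree_b.tip_labels)
    if len(shared) < 2:
        raise InsufficientOverlapError(
            f"trees share only {len(shared)} tip(s); need at least 2"
        )
    out = []
    for tree in (tree_a, tree_b):
        t = tree.clone()
        t.dtree.retain_taxa_with_labels(sorted(shared))
        out.append(t)
    return out[0], out[1]
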