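"""Species-by-species dissimilarity matrices for the three diversity facets.

Taxonomic distances are the trivial 0/1 matrix (reducing Rao's quadratic
entropy to the Gini-Simpson index); functional distances are Euclidean
distances between min-max scaled trait vectors, rescaled by the maximum
observed pair; phylogenetic distances are patristic (tip-to-tip branch-length
sums) on a majority-rule consensus tree, likewise rescaled to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from betascape.io import TraitTable, TreeSet

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise species dissimilarities in [0, 1] for one facet."""

    species_ids: list[str]
    d: np.ndarray
    facet: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.species_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if d.min() < 0 or d.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.species_ids, columns=self.species_ids)

    def to_csv(self, path, *, tab: bool = False) -> None:
        self.to_frame().to_csv(path, sep="\t" if tab else ",", index_label="species_id")

    @classmethod
    def from_csv(cls, path, facet: str, *, tab: bool = False) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t" if tab else ",").set_index("species_id")
        return cls(list(df.index), df.to_numpy(dtype=float), facet)


def taxonomic_distance(species_ids: list[str]) -> DistanceMatrix:
    """All inter-species distances 1: Rao's Q becomes the Gini-Simpson index."""
    n = len(species_ids)
    if n < 2:
        raise ValueError("need at least 2 species for a distance matrix")
    d = np.ones((n, n)) - np.eye(n)
    return DistanceMatrix(list(species_ids), d, "taxonomic")


def scale_traits(traits: TraitTable) -> pd.DataFrame:
    """Min-max scale every trait column to [0, 1] so all traits weigh equally.

    A constant column carries no dissimilarity information and maps to all
    zeros (with a warning) rather than raising.
    """
    tr = traits.traits
    if len(tr) < 2:
        raise ValueError("need at least 2 species to scale traits")
    lo, hi = tr.min(axis=0), tr.max(axis=0)
    span = hi - lo
    const = span.index[span == 0].tolist()
    if const:
        logger.warning("constant trait columns scaled to all zeros: %s", const)
    span = span.replace(0, 1.0)
    return (tr - lo) / span


def functional_distance(scaled: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean trait distances divided by the maximum pair."""
    raw = pdist(scaled.to_numpy(dtype=float), metric="euclidean")
    dmax = raw.max() if raw.size else 0.0
    if dmax == 0:
        raise ValueError("all species have identical traits; maximum distance is zero")
    return DistanceMatrix(list(scaled.index), squareform(raw / dmax), "functional")


# ---------------------------------------------------------------------------
# consensus tree and patristic distances
# ---------------------------------------------------------------------------

def _tree_splits(tree: dendropy.Tree, labels: list[str]) -> dict[frozenset, float]:
    """Nontrivial unrooted bipartitions of one tree, keyed by the side not
    containing the first label, mapped to branch length.

    A rooted bifurcation at the root yields the same bipartition from both
    root-child edges; their lengths are summed, matching the unrooted branch.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    full = frozenset(range(len(labels)))
    splits: dict[frozenset, float] = {}

    def leafset(node) -> frozenset:
        return frozenset(idx[leaf.taxon.label] for leaf in node.leaf_iter())

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = leafset(node)
        if len(side) <= 1 or len(side) >= len(full) - 1:
            continue  # trivial split (leaf edge or its complement)
        if 0 in side:
            side = full - side
        length = node.edge.length or 0.0
        splits[side] = splits.get(side, 0.0) + length
    return splits


def _leaf_lengths(tree: dendropy.Tree) -> dict[str, float]:
    out = {}
    for leaf in tree.leaf_node_iter():
        length = leaf.edge.length or 0.0
        # a leaf hanging off a rooted bifurcating 2-tip root also absorbs the
        # sibling-free root edge; irrelevant for >=3-tip trees
        out[leaf.taxon.label] = out.get(leaf.taxon.label, 0.0) + length
    return out


def majority_consensus(treeset: TreeSet, threshold: float = 0.5) -> dendropy.Tree:
    """Unrooted majority-rule consensus of a tree set.

    A bipartition enters the consensus iff it occurs in strictly more than
    ``threshold`` of the trees (ties at the threshold are excluded).  Each
    consensus branch receives the mean length of that bipartition across the
    input trees that contain it; leaf branches receive the mean leaf branch
    length over all trees.
    """
    trees = treeset.trees
    n_trees = len(trees)
    labels = sorted(treeset.tip_labels(0))
    n_taxa = len(labels)

    counts: dict[frozenset, int] = {}
    length_sums: dict[frozenset, float] = {}
    leaf_sums = {lab: 0.0 for lab in labels}
    for tree in trees:
        for split, length in _tree_splits(tree, labels).items():
            counts[split] = counts.get(split, 0) + 1
            length_sums[split] = length_sums.get(split, 0.0) + length
        for lab, length in _leaf_lengths(tree).items():
            leaf_sums[lab] += length

    majority = [s for s, c in counts.items() if c > threshold * n_trees]
    # majority splits (> 1/2) are pairwise compatible, so they form a laminar
    # family of clusters on the side away from taxon 0
    majority.sort(key=len, reverse=True)

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node

    # build nesting: parent of a cluster is the smallest strictly-containing one
    nodes: dict[frozenset, dendropy.Node] = {}
    for clade in majority:
        parent = root
        best: frozenset | None = None
        for other in majority:
            if other is not clade and clade < other and (best is None or len(other) < len(best)):
                best = other
        if best is not None:
            parent = nodes[best]
        node = dendropy.Node()
        node.edge.length = length_sums[clade] / counts[clade]
        parent.add_child(node)
        nodes[clade] = node

    for i, lab in enumerate(labels):
        parent = root
        best = None
        for clade in majority:
            if i in clade and (best is None or len(clade) < len(best)):
                best = clade
        if best is not None:
            parent = nodes[best]
        leaf = dendropy.Node(taxon=taxa.get_taxon(lab))
        leaf.edge.length = leaf_sums[lab] / n_trees
        parent.add_child(leaf)

    tree.is_rooted = False
    if n_taxa == 0:
        raise ValueError("empty tree set")
    return tree


def phylo_distance(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip patristic distances divided by the maximum pairwise value."""
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("need a tree with at least 2 tips")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    labels = sorted(leaf.taxon.label for leaf in leaves)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    dmax = d.max()
    if dmax == 0:
        raise ValueError("all patristic distances are zero")
    return DistanceMatrix(labels, d / dmax, "phylogenetic")
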