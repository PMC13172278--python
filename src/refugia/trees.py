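"""Tree utilities shared by phylogenetic and functional diversity.

Both Faith's PD and dendrogram-based FD reduce to the same primitive: the sum
of branch lengths of the rooted subtree spanning a set of tips *and the root*
(root-inclusive convention, so a single-species assemblage scores its full
root-to-tip path rather than zero).  The primitive is expressed as an
edge x species incidence matrix so that whole rasters of assemblages are a
single matrix product.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

__all__ = ["edge_matrix", "branch_sums", "total_length", "tip_depths", "path_distance_matrix"]


def _edge_len(node: dendropy.Node) -> float:
    return float(node.edge.length or 0.0)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def edge_matrix(tree: dendropy.Tree, species: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Edge lengths and edge x species incidence for a rooted tree.

    Returns ``(lengths, incidence)`` where ``lengths`` has one entry per
    non-root edge and ``incidence[e, s]`` is True when species ``s`` is a
    descendant of edge ``e``.  Species absent from the tree get all-False
    columns (the caller decides how to warn).  Polytomies are handled
    naturally — every edge is scored independently.
    """
    index = {s: i for i, s in enumerate(species)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    below: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(len(species), dtype=bool)
            lbl = node.taxon.label if node.taxon is not None else None
            if lbl in index:
                vec[index[lbl]] = True
        else:
            vec = np.zeros(len(species), dtype=bool)
            for child in node.child_nodes():
                vec |= below[child]
        below[node] = vec
        if node.parent_node is not None:
            lengths.append(_edge_len(node))
            rows.append(vec)
    return np.asarray(lengths, dtype=float), np.asarray(rows, dtype=bool)


def branch_sums(lengths: np.ndarray, incidence: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """Root-inclusive spanning-subtree branch sums for many assemblages.

    ``presence`` is (n_species, n_assemblages) boolean; returns one sum per
    assemblage.  An edge contributes its length whenever at least one of its
    descendant species is present, which is exactly the set of edges on the
    paths from the root to every present tip.
    """
    touched = incidence.astype(float) @ presence.astype(float) > 0
    return lengths @ touched


def total_length(tree: dendropy.Tree) -> float:
    return sum(_edge_len(n) for n in tree.preorder_node_iter() if n.parent_node is not None)


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + _edge_len(node)
        if node.is_leaf():
            out[node.taxon.label] = depth[node]
    return out


def path_distance_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Patristic (sum of branch lengths) distances between all tip pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            out[i, j] = out[j, i] = d
    return labels, out


def match_species(tree: dendropy.Tree, species: list[str], context: str) -> list[str]:
    """Species from ``species`` that have a tip; warns once about the rest."""
    tips = set(tip_labels(tree))
    missing = [s for s in species if s not in tips]
    if missing:
        warnings.warn(
            f"{context}: {len(missing)} species absent from the tree are excluded: "
            + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else ""),
            stacklevel=2,
        )
    return [s for s in species if s in tips]
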