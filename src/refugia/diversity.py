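"""Per-cell taxonomic, phylogenetic, and functional diversity.

TD is species richness from the binary range stack.  PD is Faith's
phylogenetic diversity with the basal branches included (root-inclusive), so
a single-species cell scores its root-to-tip path length rather than zero.
FD follows the functional-dendrogram recipe: mixed-type traits are imputed
from phylogenetic neighbors, converted to a Gower distance matrix, clustered
by UPGMA, and the same root-inclusive branch-sum routine is applied to the
resulting dendrogram — one implementation serves both PD and FD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import trees
from .grids import GridSpec
from .sdm import RangeAtlas
from .synthetic import TraitMatrix

__all__ = [
    "DiversityMap",
    "richness_map",
    "faith_pd_map",
    "fdend_map",
    "impute_traits",
    "gower_matrix",
    "upgma_dendrogram",
]


@dataclass
class DiversityMap:
    metric: str  # "TD" | "PD" | "FD"
    values: np.ndarray
    scenario_tag: str
    grid: GridSpec


def richness_map(atlas: RangeAtlas, scenario: str) -> DiversityMap:
    """Species richness (SR): per-cell count of present species."""
    sr = atlas.stack(scenario).sum(axis=0).astype(float)
    sr[~atlas.grid.analysis_mask] = 0.0
    return DiversityMap("TD", sr, scenario, atlas.grid)


def _tree_diversity_map(
    atlas: RangeAtlas, tree: dendropy.Tree, scenario: str, metric: str
) -> DiversityMap:
    matched = trees.match_species(tree, atlas.species, context=f"{metric} [{scenario}]")
    grid = atlas.grid
    out = grid.zeros()
    if matched:
        lengths, incidence = trees.edge_matrix(tree, matched)
        stack = atlas.stack(scenario, matched)
        mask = grid.analysis_mask
        presence = stack[:, mask]  # (n_species, n_cells)
        out[mask] = trees.branch_sums(lengths, incidence, presence)
    return DiversityMap(metric, out, scenario, grid)


def faith_pd_map(atlas: RangeAtlas, tree: dendropy.Tree, scenario: str) -> DiversityMap:
    """Faith's PD per cell, root-inclusive (basal branches count, so
    single-species cells have PD > 0)."""
    return _tree_diversity_map(atlas, tree, scenario, "PD")


def fdend_map(atlas: RangeAtlas, dendrogram: dendropy.Tree, scenario: str) -> DiversityMap:
    """Functional-dendrogram diversity per cell — the PD routine applied to
    the UPGMA trait dendrogram."""
    return _tree_diversity_map(atlas, dendrogram, scenario, "FD")


# --------------------------------------------------------------------------
# trait imputation


def impute_traits(traits: TraitMatrix, tree: dendropy.Tree, k: int = 5) -> TraitMatrix:
    """Fill missing trait values from the k phylogenetically nearest species.

    Continuous/ordinal traits take the inverse-path-distance weighted mean of
    the k nearest species with observed values; categorical/binary traits
    take the plurality state among them (ties resolved by the single nearest
    neighbor).  Imputed entries are flagged in the result.
    """
    data = traits.data.copy()
    imputed = pd.DataFrame(False, index=data.index, columns=data.columns)
    if traits.is_complete():
        return TraitMatrix(data, dict(traits.kinds), imputed)
    labels, dist = trees.path_distance_matrix(tree)
    pos = {s: i for i, s in enumerate(labels)}
    missing_species = [s for s in data.index[data.isna().any(axis=1)] if s not in pos]
    if missing_species:
        raise ValueError(f"species with missing traits absent from the tree: {missing_species}")
    for trait in data.columns:
        col = data[trait]
        observed = col.dropna()
        if observed.empty:
            raise ValueError(f"trait {trait!r} has no observed values")
        donors = [s for s in observed.index if s in pos]
        kind = traits.kinds[trait]
        for sp in col.index[col.isna()]:
            d = np.array([dist[pos[sp], pos[s]] for s in donors])
            order = np.argsort(d, kind="stable")[:k]
            dd = np.maximum(d[order], 1e-12)
            vals = observed.loc[[donors[i] for i in order]]
            if kind in ("continuous", "ordinal"):
                w = 1.0 / dd
                est = float(np.average(vals.astype(float), weights=w))
                if kind == "ordinal":
                    est = float(np.round(est))
            else:
                counts = vals.value_counts()
                top = counts[counts == counts.max()].index
                est = vals.iloc[0] if len(top) > 1 else top[0]
            data.loc[sp, trait] = est
            imputed.loc[sp, trait] = True
    return TraitMatrix(data, dict(traits.kinds), imputed)


# --------------------------------------------------------------------------
# Gower distance


def gower_matrix(traits: TraitMatrix) -> pd.DataFrame:
    """Gower dissimilarity over mixed trait types with pairwise deletion.

    d_ij = sum_t delta_ijt * s_ijt / sum_t delta_ijt, where s_ijt is the
    range-normalized absolute difference for continuous/ordinal traits and a
    mismatch indicator for categorical/binary ones; delta_ijt = 1 when both
    values are observed.  Zero-range traits are skipped.  A species pair with
    no comparable trait raises an error naming the pair.
    """
    data = traits.data
    species = list(data.index)
    n = len(species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for trait, kind in traits.kinds.items():
        col = data[trait]
        obs = col.notna().to_numpy()
        both = np.outer(obs, obs)
        if kind in ("continuous", "ordinal"):
            v = col.to_numpy(dtype=float)
            observed = v[obs]
            rng = observed.max() - observed.min() if observed.size else 0.0
            if rng == 0:
                continue  # no discriminating power for any pair
            s = np.abs(v[:, None] - v[None, :]) / rng
            s = np.where(both, s, 0.0)
        else:
            v = col.to_numpy(dtype=object)
            s = np.where(both, (v[:, None] != v[None, :]).astype(float), 0.0)
        num += np.where(both, s, 0.0)
        den += both.astype(float)
    off = ~np.eye(n, dtype=bool)
    bad = np.argwhere((den == 0) & off)
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"species pair ({species[i]!r}, {species[j]!r}) shares no comparable trait")
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=species, columns=species)


# --------------------------------------------------------------------------
# UPGMA


def upgma_dendrogram(dist: pd.DataFrame) -> dendropy.Tree:
    """UPGMA (size-weighted average linkage) dendrogram of a distance matrix.

    Merge heights are half the merge distance; ties on the closest pair are
    broken by the lexicographically smallest pair of cluster labels (a
    cluster is labelled by its alphabetically first member).  The result is
    an ultrametric rooted dendropy tree.
    """
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    species = list(dist.index)
    taxa = dendropy.TaxonNamespace()
    # cluster state: label -> (node, size, height)
    nodes: dict[str, tuple[dendropy.Node, int, float]] = {}
    for s in species:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(s)
        nodes[s] = (node, 1, 0.0)
    dmat: dict[frozenset[str], float] = {}
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            dmat[frozenset((species[i], species[j]))] = d[i, j]

    while len(nodes) > 1:
        labels = sorted(nodes)
        best = None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                key = (dmat[frozenset((labels[i], labels[j]))], labels[i], labels[j])
                if best is None or key < best:
                    best = key
        merge_d, la, lb = best
        (na, sa, ha), (nb, sb, hb) = nodes.pop(la), nodes.pop(lb)
        height = merge_d / 2.0
        parent = dendropy.Node()
        na.edge.length = height - ha
        nb.edge.length = height - hb
        parent.add_child(na)
        parent.add_child(nb)
        new_label = min(la, lb)
        for other in list(nodes):
            key_a, key_b = frozenset((la, other)), frozenset((lb, other))
            merged = (sa * dmat.pop(key_a) + sb * dmat.pop(key_b)) / (sa + sb)
            dmat[frozenset((new_label, other))] = merged
        dmat.pop(frozenset((la, lb)))
        nodes[new_label] = (parent, sa + sb, height)

    root = next(iter(nodes.values()))[0]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return tree
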