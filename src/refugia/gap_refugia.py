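"""Congruence, protected-area gap, and climate-refugia analyses.

Quantifies how the three diversity dimensions agree (Kendall tau over cell
values and priority ranks, directional overlap of top-fraction masks), how
well protected areas cover hotspots and priority areas, and which cells stay
in the multidimensional top-priority area under the current climate and
every future scenario (refugia), enumerated as connected regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import GridSpec, PAMask

__all__ = [
    "kendall_tau",
    "hotspot_mask",
    "coverage",
    "overlap_table",
    "OverlapReport",
    "refugia_mask",
    "RefugiaResult",
    "label_regions",
]


def kendall_tau(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray) -> float:
    """Tie-corrected Kendall tau-b between two rasters over masked cells.

    Returns NaN (with a warning) when either map is constant on the mask.
    """
    a, b = np.asarray(map_a)[mask], np.asarray(map_b)[mask]
    if a.size < 2:
        raise ValueError("need at least 2 masked cells")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant map: Kendall tau undefined")
        return float("nan")
    return float(stats.kendalltau(a, b).statistic)


def hotspot_mask(values: np.ndarray, mask: np.ndarray, top_pct: float) -> tuple[np.ndarray, float]:
    """Value-threshold hotspot mask for the top ``top_pct`` of analysis cells.

    The threshold v* is the smallest positive value such that the cells with
    value >= v* number at most ceil(top_pct * N); all tied cells at v* are
    included, so with coarse (e.g. integer richness) values the mask may
    undershoot the nominal percentage, and when no positive value satisfies
    the bound the most exclusive one is used (and may overshoot).
    Returns (mask, v*).
    """
    if not 0 < top_pct < 1:
        raise ValueError("top_pct must be in (0, 1)")
    vals = np.asarray(values, dtype=float)
    v = vals[mask]
    target = int(np.ceil(top_pct * v.size))
    positive = np.unique(v[v > 0])
    if positive.size == 0:
        warnings.warn("all-zero map: empty hotspot mask")
        return np.zeros_like(mask, dtype=bool), float("nan")
    counts = v.size - np.searchsorted(np.sort(v), positive, side="left")
    ok = counts <= target
    vstar = float(positive[ok][0]) if ok.any() else float(positive[-1])
    return (vals >= vstar) & mask, vstar


def coverage(mask: np.ndarray, pa: PAMask | np.ndarray) -> float:
    """Fraction of masked cells inside protected areas; NaN for empty masks."""
    pa_mask = pa.mask if isinstance(pa, PAMask) else np.asarray(pa, dtype=bool)
    m = np.asarray(mask, dtype=bool)
    total = m.sum()
    if total == 0:
        warnings.warn("empty mask: coverage undefined")
        return float("nan")
    return float((m & pa_mask).sum() / total)


@dataclass
class OverlapReport:
    """Directional pairwise overlaps and k-way agreement of named masks."""

    pairwise: dict[tuple[str, str], float]  # (base, other) -> |base & other| / |base|
    kway_jaccard: float  # |intersection| / |union|
    kway_of_analysis: float  # |intersection| / |analysis mask|
    pa_coverage: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "pairwise": {f"{a}|{b}": v for (a, b), v in self.pairwise.items()},
            "kway_jaccard": self.kway_jaccard,
            "kway_of_analysis": self.kway_of_analysis,
            "pa_coverage": dict(self.pa_coverage),
        }


def overlap_table(
    masks: dict[str, np.ndarray], analysis_mask: np.ndarray, pa: PAMask | None = None
) -> OverlapReport:
    """Pairwise (both directions) and k-way overlap of named boolean masks."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    names = list(masks)
    pairwise = {}
    for a, b in combinations(names, 2):
        inter = (masks[a] & masks[b]).sum()
        pairwise[(a, b)] = float(inter / masks[a].sum()) if masks[a].sum() else float("nan")
        pairwise[(b, a)] = float(inter / masks[b].sum()) if masks[b].sum() else float("nan")
    inter_all = np.logical_and.reduce([masks[n] for n in names])
    union_all = np.logical_or.reduce([masks[n] for n in names])
    kway = float(inter_all.sum() / union_all.sum()) if union_all.sum() else float("nan")
    kway_analysis = float(inter_all.sum() / analysis_mask.sum())
    pa_cov = {}
    if pa is not None:
        for n in names:
            pa_cov[n] = coverage(masks[n], pa)
        pa_cov["all"] = coverage(inter_all, pa) if inter_all.any() else float("nan")
    return OverlapReport(pairwise, kway, kway_analysis, pa_cov)


@dataclass
class RefugiaResult:
    """Cross-scenario refugia: the intersection of per-scenario optimal areas."""

    mask: np.ndarray
    scenarios: list[str]
    labels: np.ndarray
    regions: pd.DataFrame
    pa_coverage: float = float("nan")


def refugia_mask(
    optimal_masks: dict[str, np.ndarray],
    pa: PAMask | None = None,
    connectivity: int = 8,
    min_area: int = 5,
) -> RefugiaResult:
    """Intersect per-scenario optimal priority areas into refugia.

    ``optimal_masks`` maps each scenario (current plus every future
    scenario) to its optimal priority area — typically the intersection of
    the TD, PD and FD top-fraction masks.  Refugia are the cells present in
    every scenario's optimal area; connected regions below ``min_area``
    cells are dropped from the region table.
    """
    if not optimal_masks:
        raise ValueError("no scenario masks given")
    scenarios = list(optimal_masks)
    refugia = np.logical_and.reduce([np.asarray(optimal_masks[s], bool) for s in scenarios])
    labels, regions = label_regions(refugia, connectivity=connectivity, min_area=min_area)
    cov = coverage(refugia, pa) if (pa is not None and refugia.any()) else float("nan")
    return RefugiaResult(refugia, scenarios, labels, regions, cov)


def label_regions(
    mask: np.ndarray, connectivity: int = 8, min_area: int = 1
) -> tuple[np.ndarray, pd.DataFrame]:
    """Connected-component labeling with small-region suppression.

    Regions with fewer than ``min_area`` cells are removed from the label
    grid; the survivors are re-labelled 1..k by decreasing area (ties keep
    first-encounter order) and tabulated with their centroids.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    raw_labels, n = ndimage.label(np.asarray(mask, bool), structure=structure)
    if n == 0:
        return np.zeros_like(raw_labels), pd.DataFrame(
            columns=["region_id", "area", "centroid_row", "centroid_col"]
        )
    areas = ndimage.sum_labels(np.ones_like(raw_labels), raw_labels, index=np.arange(1, n + 1))
    keep = np.nonzero(areas >= min_area)[0] + 1
    order = keep[np.argsort(-areas[keep - 1], kind="stable")]
    out = np.zeros_like(raw_labels)
    rows = []
    for new_id, old_id in enumerate(order, start=1):
        sel = raw_labels == old_id
        out[sel] = new_id
        rr, cc = np.nonzero(sel)
        rows.append(
            {
                "region_id": new_id,
                "area": int(sel.sum()),
                "centroid_row": float(rr.mean()),
                "centroid_col": float(cc.mean()),
            }
        )
    return out, pd.DataFrame(rows)
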