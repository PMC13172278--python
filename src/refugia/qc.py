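"""Occurrence cleaning and environmental-variable collinearity filtering.

The cleaning rule set is deliberately small and fully tallied: invalid
coordinates, records outside the analysis extent, exact duplicates, and
per-species grid-cell thinning (one record per species per cell, first in
stable input order wins).  Gazetteer-based heuristics (centroids,
institutions, urban areas) are out of scope; the QC report makes the reduced
rule set visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec

__all__ = ["QCReport", "clean_occurrences", "select_variables"]


@dataclass
class QCReport:
    """Per-rule removal tallies; removed + retained equals the input count."""

    input_count: int = 0
    invalid_coordinate: int = 0
    out_of_extent: int = 0
    exact_duplicate: int = 0
    cell_duplicate: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input_count": self.input_count,
            "invalid_coordinate": self.invalid_coordinate,
            "out_of_extent": self.out_of_extent,
            "exact_duplicate": self.exact_duplicate,
            "cell_duplicate": self.cell_duplicate,
            "retained": self.retained,
        }


def clean_occurrences(occ: pd.DataFrame, grid: GridSpec) -> tuple[pd.DataFrame, QCReport]:
    """Apply the four-rule cleaning cascade in a fixed order.

    Returns the retained records (stable input order, with ``row``/``col``
    cell indices attached) and the per-rule report.
    """
    report = QCReport(input_count=len(occ))
    if len(occ) == 0:
        out = occ.copy()
        out["row"] = pd.Series(dtype=int)
        out["col"] = pd.Series(dtype=int)
        return out, report
    df = occ.reset_index(drop=True).copy()

    finite = np.isfinite(df["x"].to_numpy(float)) & np.isfinite(df["y"].to_numpy(float))
    report.invalid_coordinate = int((~finite).sum())
    df = df[finite]

    cells = [grid.point_to_cell(x, y) for x, y in zip(df["x"], df["y"])]
    inside = np.array(
        [c is not None and bool(grid.analysis_mask[c]) for c in cells], dtype=bool
    )
    report.out_of_extent = int((~inside).sum())
    df = df[inside]
    kept_cells = [c for c, ok in zip(cells, inside) if ok]
    df = df.assign(
        row=[c[0] for c in kept_cells], col=[c[1] for c in kept_cells]
    )

    before = len(df)
    df = df.drop_duplicates(subset=["species", "x", "y"], keep="first")
    report.exact_duplicate = before - len(df)

    before = len(df)
    df = df.drop_duplicates(subset=["species", "row", "col"], keep="first")
    report.cell_duplicate = before - len(df)

    report.retained = len(df)
    return df.reset_index(drop=True), report


def select_variables(
    env: EnvStack, threshold: float = 0.8, priority_order: list[str] | None = None
) -> list[str]:
    """Greedy collinearity filter: keep a layer iff |r| < threshold against
    every already-kept layer (Pearson over analysis-mask cells), scanning in
    priority order.  Constant layers are dropped with a warning."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = env.layer_names if priority_order is None else list(priority_order)
    missing = set(env.layer_names) - set(order)
    if missing:
        raise ValueError(f"priority_order does not cover layers: {sorted(missing)}")
    mask = env.grid.analysis_mask
    vals = {name: env.layers[name][mask] for name in order if name in env.layers}
    retained: list[str] = []
    for name in order:
        if name not in vals:
            continue
        v = vals[name]
        if v.std() == 0:
            warnings.warn(f"layer {name!r} is constant over the mask; dropped")
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(v, vals[kept])[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained
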