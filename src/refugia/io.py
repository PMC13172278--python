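"""Plain-text raster and table I/O.

Rasters travel as ESRI ASCII grids (.asc): a six-line header followed by
whitespace-separated cell values, rows north to south.  Trees travel as
Newick via dendropy; tables as CSV via pandas.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .grids import GridSpec

NODATA = -9999.0


def write_ascii_grid(path: str | os.PathLike, values: np.ndarray, grid: GridSpec) -> None:
    """Write a single-band raster as an ESRI ASCII grid.

    Cells outside the analysis mask are written as the nodata value.
    Boolean rasters are written as 0/1 integers.
    """
    arr = np.asarray(values)
    if arr.shape != grid.shape:
        raise ValueError(f"raster shape {arr.shape} != grid shape {grid.shape}")
    out = arr.astype(float).copy()
    out[~grid.analysis_mask] = NODATA
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1]}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    fmt = "%d" if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer) else "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | os.PathLike) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns (array with NaN at nodata, GridSpec).

    The returned GridSpec's analysis mask marks the non-nodata cells.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", NODATA)
    mask = data != nodata
    data = data.astype(float)
    data[~mask] = np.nan
    grid = GridSpec(
        n_rows,
        n_cols,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        analysis_mask=mask if mask.any() else None,
    )
    return data, grid


def write_occurrences(path: str | os.PathLike, occ: pd.DataFrame) -> None:
    occ.to_csv(path, index=False)


def read_occurrences(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"occurrence CSV must have columns {sorted(required)}")
    return df


def write_newick(path: str | os.PathLike, tree) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | os.PathLike):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")
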