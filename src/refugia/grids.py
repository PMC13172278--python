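"""Grid containers shared by every pipeline stage.

All rasters are dense 2-D numpy arrays in row-major order with row 0 at the
northern edge (standard raster convention).  A :class:`GridSpec` fixes the
geometry — shape, cell size in abstract km, origin of the lower-left corner —
and carries the boolean analysis mask that delimits the study region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "EnvStack", "PAMask"]


class GridError(ValueError):
    """Invalid grid geometry or misaligned layers."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; both must be >= 1.
    cell_size : float
        Edge length of a square cell, in abstract km.
    origin : tuple of float
        (x, y) of the lower-left corner of the grid.
    analysis_mask : ndarray of bool, optional
        Cells inside the study region.  Defaults to the full grid.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    analysis_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError(f"grid shape must be positive, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")
        mask = self.analysis_mask
        if mask is None:
            mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise GridError(
                    f"analysis_mask shape {mask.shape} != grid shape "
                    f"({self.n_rows}, {self.n_cols})"
                )
            if not mask.any():
                raise GridError("analysis_mask has no true cells")
        object.__setattr__(self, "analysis_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_analysis_cells(self) -> int:
        return int(self.analysis_mask.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped like the grid."""
        ox, oy = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = ox + (cols + 0.5) * self.cell_size
        # row 0 is the northern edge
        y = oy + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a point to its (row, col) cell, or None if off-grid."""
        ox, oy = self.origin
        col = int(np.floor((x - ox) / self.cell_size))
        row_from_bottom = int(np.floor((y - oy) / self.cell_size))
        row = self.n_rows - 1 - row_from_bottom
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def zeros(self, dtype=float) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)


@dataclass
class EnvStack:
    """A named stack of environmental layers on a shared grid.

    ``scenario_tag`` is "current" or a scenario label such as
    "mild-2050s"; layer order is meaningful and preserved.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    scenario_tag: str = "current"

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise GridError("EnvStack needs at least one layer")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise GridError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            if not np.isfinite(arr[self.grid.analysis_mask]).all():
                raise GridError(f"layer {name!r} has non-finite values inside the analysis mask")
            self.layers[name] = arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def values_at(self, rows: np.ndarray, cols: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Environment matrix (n_points, n_layers) at the given cells."""
        names = self.layer_names if names is None else names
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Environment matrix over the analysis mask, (n_cells, n_layers)."""
        mask = self.grid.analysis_mask
        names = self.layer_names if names is None else names
        return np.column_stack([self.layers[n][mask] for n in names])

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise GridError(f"layers not in stack: {missing}")
        return EnvStack(self.grid, {n: self.layers[n] for n in names}, self.scenario_tag)


@dataclass
class PAMask:
    """Protected-area mask aligned to the analysis grid."""

    grid: GridSpec
    mask: np.ndarray
    achieved_coverage: float = 0.0
    coverage_warning: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise GridError("PA mask shape does not match grid")
        if (self.mask & ~self.grid.analysis_mask).any():
            raise GridError("PA mask extends outside the analysis mask")
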