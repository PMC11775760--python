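"""Shared raster-grid geometry.

One convention everywhere: row/col grid with origin at the top-left corner,
x increasing with column, y increasing with row (i.e. downward), all
distances in metres, half-open pixel ownership
``pixel (r, c) owns [c*px, (c+1)*px) x [r*px, (r+1)*px)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid."""

    rows: int
    cols: int
    pixel_size: float = 15.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def width_m(self) -> float:
        return self.cols * self.pixel_size

    @property
    def height_m(self) -> float:
        return self.rows * self.pixel_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids of every pixel center, each ``rows x cols``."""
        x = self.x0 + (np.arange(self.cols) + 0.5) * self.pixel_size
        y = self.y0 + (np.arange(self.rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def center_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        return (
            self.x0 + (col + 0.5) * self.pixel_size,
            self.y0 + (row + 0.5) * self.pixel_size,
        )

    def point_to_rc(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the pixel owning each point (half-open ownership)."""
        col = np.floor((np.asarray(x) - self.x0) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.pixel_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.point_to_rc(x, y)
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)
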