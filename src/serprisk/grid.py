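"""Lightweight geo-referenced raster grid.

All layers in a pipeline run share one grid frame: same shape, cell size
and origin. Row 0 is the northern edge; the y axis points south in array
space. Text I/O uses the ESRI ASCII grid format so every artifact the
pipeline writes stays plain text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class GridLayer:
    """A single-band raster on a square-cell grid."""

    data: np.ndarray
    cell_size: float = 500.0
    x0: float = 0.0
    y0: float = 0.0
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("GridLayer data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def same_grid(self, other: "GridLayer") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.x0 == other.x0
            and self.y0 == other.y0
        )

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return self.data != self.nodata

    def copy_with(self, data: np.ndarray) -> "GridLayer":
        return GridLayer(
            data=data, cell_size=self.cell_size, x0=self.x0, y0=self.y0,
            nodata=self.nodata,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell center; y decreases with row index."""
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def write_ascii(self, path) -> None:
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x0}\n"
            f"yllcorner {self.y0}\n"
            f"cellsize {self.cell_size}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path) -> "GridLayer":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                meta[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError(f"grid shape mismatch reading {path}")
        return cls(
            data=data,
            cell_size=meta["cellsize"],
            x0=meta["xllcorner"],
            y0=meta["yllcorner"],
            nodata=meta.get("nodata_value", NODATA_DEFAULT),
        )


def require_same_grid(*layers: GridLayer) -> None:
    ref = layers[0]
    for layer in layers[1:]:
        if not ref.same_grid(layer):
            raise ValueError("all layers must share one grid frame")
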