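"""Minimal single-band raster container with ESRI ASCII grid text I/O.

The landscape covariates need only regular, north-up, square-cell grids at
~2 m resolution, so the container is deliberately small: a 2-D float array
(row 0 = northernmost) plus the lower-left corner and cell size.
Coordinates refer to pixel centers; cell bounds are half-open.  On disk the
format is the ESRI ASCII grid (.asc), a widely supported plain-text raster
interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from feedernet.errors import ValidationError


@dataclass
class Raster:
    data: np.ndarray  # shape (nrows, ncols); row 0 is the top (north)
    x_ll: float  # x of the lower-left *corner* of the grid
    y_ll: float
    cellsize: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("raster data must be 2-D")
        if not self.cellsize > 0:
            raise ValidationError("raster cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer cell edges."""
        return (
            self.x_ll,
            self.y_ll,
            self.x_ll + self.ncols * self.cellsize,
            self.y_ll + self.nrows * self.cellsize,
        )

    def x_centers(self) -> np.ndarray:
        return self.x_ll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Per-row center y, row 0 first (north → south)."""
        return self.y_ll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.x_ll, other.x_ll)
            and np.isclose(self.y_ll, other.y_ll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def write_ascii(self, path, nodata: float = -9999.0) -> None:
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x_ll!r}\n"
            f"yllcorner {self.y_ll!r}\n"
            f"cellsize {self.cellsize!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                meta[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValidationError(
                f"{path}: grid shape {data.shape} does not match header"
            )
        return cls(
            data=data,
            x_ll=meta["xllcorner"],
            y_ll=meta["yllcorner"],
            cellsize=meta["cellsize"],
        )
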