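"""Grid geometry and raster-stack containers.

All rasters in this package live on a simple axis-aligned, equal-area
projected grid (nominal 1-km pixels) with pixel-center registration and
(row, col) 0-based indexing; no geodesy.  An 8-day composite year always
has 46 layers starting at day-of-year 1, 9, ..., 361.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Start day-of-year of the 46 fixed 8-day composites in a calendar year.
COMPOSITE_DOYS: tuple[int, ...] = tuple(range(1, 362, 8))

#: Sentinel used for missing pixels in float rasters.  Chosen far outside
#: any physically meaningful indicator or yield value.
NODATA: float = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned projected grid: pixel (r, c) has its center at
    ``(origin_x + (c + 0.5) * pixel_size, origin_y - (r + 0.5) * pixel_size)``
    (row axis points south, as in north-up imagery)."""

    rows: int
    cols: int
    pixel_size: float = 1000.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def pixel_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """Projected (x, y) coordinates of one or more pixel centers."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def nearest_pixel(self, x, y):
        """(row, col) of the pixel whose center is nearest to (x, y)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.pixel_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def contains(self, row, col) -> bool:
        return bool(np.all((np.asarray(row) >= 0) & (np.asarray(row) < self.rows)
                           & (np.asarray(col) >= 0) & (np.asarray(col) < self.cols)))

    def to_dict(self) -> dict:
        return {"rows": self.rows, "cols": self.cols, "pixel_size": self.pixel_size,
                "origin_x": self.origin_x, "origin_y": self.origin_y}

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(**d)


@dataclass
class CompositeStack:
    """One year of 8-day composite rasters for a single indicator.

    ``data`` has shape ``(len(doys), rows, cols)``; layer k starts on
    day-of-year ``doys[k]``.  Missing pixels hold ``nodata``.
    """

    indicator: str
    year: int
    data: np.ndarray
    geometry: GridGeometry
    doys: tuple[int, ...] = COMPOSITE_DOYS
    nodata: float = NODATA
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (len(self.doys), self.geometry.rows, self.geometry.cols):
            raise ValueError(
                f"stack shape {self.data.shape} does not match "
                f"{len(self.doys)} layers on {self.geometry.shape}")
        steps = np.diff(self.doys)
        if len(self.doys) > 1 and not np.all(steps == 8):
            raise ValueError("composite start DOYs must step by 8")

    @property
    def n_layers(self) -> int:
        return len(self.doys)

    def layer(self, doy: int) -> np.ndarray:
        """Raster of the composite starting at the given day-of-year."""
        try:
            k = self.doys.index(doy)
        except ValueError:
            raise KeyError(f"no composite starts at DOY {doy}") from None
        return self.data[k]

    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    def copy(self) -> "CompositeStack":
        return CompositeStack(self.indicator, self.year, self.data.copy(),
                              self.geometry, self.doys, self.nodata, self.units)


@dataclass
class PhenologyMap:
    """Per-pixel growing-window bounds (day-of-year) for one crop-year.

    The window runs from an early vegetative stage (maize V3; wheat
    emergence / green-up) to maturity and never wraps the calendar year.
    """

    year: int
    crop: str
    start_doy: np.ndarray
    end_doy: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.start_doy = np.asarray(self.start_doy)
        self.end_doy = np.asarray(self.end_doy)
        for name, arr in (("start_doy", self.start_doy), ("end_doy", self.end_doy)):
            if arr.shape != self.geometry.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.geometry.shape}")

    def validate(self, mask: np.ndarray | None = None) -> None:
        """Check 1 <= start < end <= 365 on the given (or full) mask."""
        sel = np.ones(self.geometry.shape, bool) if mask is None else mask.astype(bool)
        s, e = self.start_doy[sel], self.end_doy[sel]
        if sel.any() and not (np.all(s >= 1) and np.all(s < e) and np.all(e <= 365)):
            raise ValueError("phenology windows must satisfy 1 <= start < end <= 365")
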