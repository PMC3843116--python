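"""Georeferenced 2D scalar rasters (mineral volume fraction, fibril angle).

A :class:`ScalarField` is a plain 2D array of dimensionless fractions or
degrees on a regular grid, with a physical pixel size in micrometres, an
origin, and a boolean validity mask. Pixel centres sit at
``origin + (index + 0.5) * pixel_size``; porosity and background are
represented by the mask (never by sentinel values), so spatial averages stay
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import InvalidParameterError

__all__ = ["ScalarField"]


@dataclass
class ScalarField:
    values: np.ndarray
    pixel_size: float = 0.5  # um / pixel
    origin: tuple[float, float] = (0.0, 0.0)  # um, physical coords of pixel (0,0) *corner*
    mask: np.ndarray | None = None  # True = valid pixel
    quantity: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("ScalarField values must be 2D")
        if not self.pixel_size > 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise InvalidParameterError("mask shape must match values shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise InvalidParameterError("masked-in pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centres in um.

        Row index maps to y, column index to x (image convention).
        """
        ny, nx = self.values.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        return x, y

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the raster in um."""
        ny, nx = self.values.shape
        return (
            self.origin[0],
            self.origin[0] + nx * self.pixel_size,
            self.origin[1],
            self.origin[1] + ny * self.pixel_size,
        )

    def copy(self) -> "ScalarField":
        return ScalarField(
            self.values.copy(), self.pixel_size, tuple(self.origin),
            self.mask.copy(), self.quantity, self.units,
        )

    # ------------------------------------------------------------------ I/O
    def to_tiff(self, path) -> None:
        """Write a float32 TIFF plus a YAML sidecar with grid metadata.

        Masked-out pixels are stored as NaN.
        """
        path = Path(path)
        arr = self.values.astype(np.float32).copy()
        arr[~self.mask] = np.nan
        tifffile.imwrite(path, arr)
        meta = {
            "pixel_size_um": float(self.pixel_size),
            "origin_um": [float(self.origin[0]), float(self.origin[1])],
            "quantity": self.quantity,
            "units": self.units,
        }
        path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_tiff(cls, path) -> "ScalarField":
        path = Path(path)
        arr = np.asarray(tifffile.imread(path), dtype=float)
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
        mask = np.isfinite(arr)
        values = np.where(mask, arr, 0.0)
        return cls(
            values,
            pixel_size=float(meta.get("pixel_size_um", 0.5)),
            origin=tuple(meta.get("origin_um", (0.0, 0.0))),
            mask=mask,
            quantity=meta.get("quantity", ""),
            units=meta.get("units", ""),
        )

    def to_csv(self, path) -> None:
        """Export masked-in pixels as a (x_um, y_um, value) table."""
        import pandas as pd

        x, y = self.pixel_centers()
        X, Y = np.meshgrid(x, y)
        df = {"x_um": X[self.mask], "y_um": Y[self.mask], "value": self.values[self.mask]}
        pd.DataFrame(df).to_csv(path, index=False)
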