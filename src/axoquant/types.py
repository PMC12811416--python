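"""Calibrated containers shared by every analysis module.

Coordinate convention used throughout the package: ``x`` is the column
index, ``y`` the row index, origin at the top-left corner, ``y``
increasing downward.  All physical quantities are expressed in
micrometers (distances, areas) and seconds (time), converted from pixel
and frame units exclusively through :class:`Calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Calibration",
    "Image2D",
    "Movie",
    "BinaryMask",
    "PolylineROI",
]


@dataclass(frozen=True)
class Calibration:
    """Physical pixel/frame scaling.

    Parameters
    ----------
    pixel_size_x_um, pixel_size_y_um
        Length of one pixel along x (columns) and y (rows), in micrometers.
        Anisotropic calibrations are allowed; operations that require a
        single isotropic pixel size (arc rasterization, skeleton geodesics)
        raise if the two differ.
    frame_interval_s
        Time between consecutive movie frames, in seconds.  ``None`` for
        still images; any movie-time conversion requires it.
    """

    pixel_size_x_um: float = 1.0
    pixel_size_y_um: float = 1.0
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        if not (self.pixel_size_x_um > 0 and self.pixel_size_y_um > 0):
            raise ValueError("pixel sizes must be strictly positive")
        if self.frame_interval_s is not None and not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be strictly positive")

    @property
    def isotropic(self) -> bool:
        return np.isclose(self.pixel_size_x_um, self.pixel_size_y_um)

    @property
    def pixel_size_um(self) -> float:
        """Isotropic pixel size; raises for anisotropic calibrations."""
        if not self.isotropic:
            raise ValueError(
                "operation requires isotropic pixels; calibration has "
                f"x={self.pixel_size_x_um} um, y={self.pixel_size_y_um} um"
            )
        return float(self.pixel_size_x_um)

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_x_um * self.pixel_size_y_um)

    def require_time(self) -> float:
        if self.frame_interval_s is None:
            raise ValueError("calibration has no frame_interval_s; cannot convert movie time")
        return float(self.frame_interval_s)


def _check_2d(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"{name} must be a 2-D array of at least 2x2, got shape {arr.shape}")
    return arr


@dataclass
class Image2D:
    """A single-channel 2-D intensity image with physical calibration.

    Values are stored as float64.  Finite values are required; negative
    values are permitted because background-subtracted and
    difference-filtered images legitimately contain them.
    """

    values: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        arr = _check_2d(self.values, "Image2D.values").astype(np.float64, copy=False)
        if not np.all(np.isfinite(arr)):
            raise ValueError("Image2D values must be finite")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """A 2-D boolean mask with the same calibration contract as Image2D."""

    values: np.ndarray
    calibration: Calibration
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _check_2d(self.values, "BinaryMask.values").astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area_um2(self) -> float:
        return float(self.values.sum()) * self.calibration.pixel_area_um2


@dataclass
class Movie:
    """An ordered stack of identically shaped, identically calibrated frames.

    Stored internally as a (n_frames, rows, cols) float array.  Total
    acquisition time follows the convention T = n_frames * frame_interval_s
    (a 360-frame movie at 0.5 s spans 180 s).
    """

    frames: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"Movie frames must be a 3-D (t, y, x) array, got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("Movie needs at least 2 frames")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Movie values must be finite")
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def total_time_s(self) -> float:
        return self.n_frames * self.calibration.require_time()

    def frame(self, i: int) -> Image2D:
        return Image2D(self.frames[i], self.calibration)


@dataclass
class PolylineROI:
    """An ordered polyline in pixel coordinates with a sampling width.

    ``vertices`` is an (n, 2) array of (x, y) points; intensity sampling
    averages across ``width_um`` perpendicular to the path.
    """

    vertices: np.ndarray
    width_um: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("PolylineROI needs an (n>=2, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("PolylineROI vertices must be finite")
        seg = np.diff(v, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive PolylineROI vertices must be distinct")
        if not self.width_um > 0:
            raise ValueError("width_um must be strictly positive")
        self.vertices = v

    def path_length_px(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def reversed(self) -> "PolylineROI":
        return PolylineROI(self.vertices[::-1].copy(), self.width_um)


def as_xy(points: Sequence[Sequence[float]]) -> np.ndarray:
    """Coerce a sequence of (x, y) pairs into a float array."""
    return np.asarray(points, dtype=np.float64).reshape(-1, 2)
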