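"""Arc-length sampling of polyline paths with perpendicular width averaging.

Shared by the profile extractor and the kymograph builder: both sample a
1-um-wide (by default) segmented line at 1-px steps along its path and
average the intensity across the width.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import Calibration, PolylineROI

__all__ = ["PathSampler"]


def _resample_polyline(vertices: np.ndarray, step_px: float, max_len_px: float | None):
    """Points and unit tangents at uniform arc-length steps along a polyline."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    stop = total if max_len_px is None else min(total, max_len_px)
    s = np.arange(0.0, stop + 0.5 * step_px, step_px)
    s = s[s <= total + 1e-9]
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    pts = vertices[idx] + frac[:, None] * seg[idx]
    tan = seg[idx] / seg_len[idx, None]
    return s, pts, tan


class PathSampler:
    """Precomputed sampling geometry for one ROI on one image grid.

    Samples at 1-px arc-length steps.  At each step the intensity is the
    mean over perpendicular offsets spanning the ROI width: 3 evenly
    spaced offsets per micrometer of width (minimum 1).  Requires an
    isotropic pixel size so distances along the path are well defined.
    """

    def __init__(self, roi: PolylineROI, calibration: Calibration,
                 length_um: float | None = None, step_px: float = 1.0):
        px = calibration.pixel_size_um
        max_len_px = None if length_um is None else length_um / px
        s_px, pts, tan = _resample_polyline(roi.vertices, step_px, max_len_px)
        if length_um is not None and s_px[-1] * px < length_um - 1e-6:
            raise ValueError(
                f"ROI path is {s_px[-1] * px:.2f} um long; {length_um} um requested")
        normals = np.stack([-tan[:, 1], tan[:, 0]], axis=1)
        width_px = roi.width_um / px
        n_off = max(1, int(round(3 * roi.width_um)))
        if n_off % 2 == 0:      # keep the path center among the offsets
            n_off += 1
        offsets = (np.linspace(-width_px / 2, width_px / 2, n_off)
                   if n_off > 1 else np.zeros(1))
        # sample coordinates: (n_points, n_offsets, 2) in (x, y)
        coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
        self.distances_um = s_px * px
        self._coords = coords
        self.n_points = len(s_px)

    def check_bounds(self, shape: tuple[int, int]) -> None:
        x = self._coords[..., 0]
        y = self._coords[..., 1]
        if (x.min() < -0.5 or y.min() < -0.5
                or x.max() > shape[1] - 0.5 or y.max() > shape[0] - 0.5):
            raise ValueError("ROI (with its sampling width) leaves the image bounds")

    def sample(self, values: np.ndarray) -> np.ndarray:
        """Mean intensity across the width at each step (bilinear interpolation)."""
        rows = self._coords[..., 1].ravel()
        cols = self._coords[..., 0].ravel()
        sampled = ndimage.map_coordinates(values, [rows, cols], order=1, mode="nearest")
        return sampled.reshape(self._coords.shape[:2]).mean(axis=1)
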