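"""Sholl quantification of axonal outgrowth.

Outgrowth of axons exiting microgrooves is measured as the number of
intersections of a binarized axon field with concentric semicircles of
increasing radius, centered where the axons exit, and summed within
distance bins.  An "intersection" is one connected run of foreground
pixels on the discretized arc (a crossing process), not a raw pixel
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .types import BinaryMask, Image2D

__all__ = ["ShollParams", "ShollProfile", "BinSums", "binarize",
           "sholl_intersections", "bin_sums"]


@dataclass(frozen=True)
class ShollParams:
    """Sampling geometry for semicircular Sholl analysis.

    ``direction`` is the unit vector of the sampled half-plane
    ``{p : (p - center) . direction >= 0}``; the default +x matches
    axons growing away from microgrooves toward increasing x.  Radii are
    ``step, 2*step, ... <= r_max`` in micrometers (2-um steps out to
    1500 um by default).
    """

    center: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float] = (1.0, 0.0)
    radius_step_um: float = 2.0
    r_max_um: float = 1500.0
    bin_edges_um: tuple[float, ...] = (0.0, 500.0, 1000.0, 1500.0)

    def __post_init__(self) -> None:
        if not self.radius_step_um > 0:
            raise ValueError("radius_step_um must be positive")
        if self.r_max_um < self.radius_step_um:
            raise ValueError("r_max_um must be >= radius_step_um")
        edges = np.asarray(self.bin_edges_um, dtype=float)
        if len(edges) >= 2 and np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(edges) and edges[-1] > self.r_max_um + 1e-9:
            raise ValueError("last bin edge exceeds r_max_um")
        n = math.hypot(*self.direction)
        if n == 0:
            raise ValueError("direction must be a nonzero vector")
        object.__setattr__(self, "direction",
                           (self.direction[0] / n, self.direction[1] / n))

    @property
    def radii_um(self) -> np.ndarray:
        n = int(math.floor(self.r_max_um / self.radius_step_um + 1e-9))
        return self.radius_step_um * np.arange(1, n + 1)


@dataclass
class ShollProfile:
    radii_um: np.ndarray
    counts: np.ndarray
    params: ShollParams

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.radii_um) != len(self.counts):
            raise ValueError("radii and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinSums:
    bins: list[tuple[float, float]]
    sums: np.ndarray

    def __post_init__(self) -> None:
        self.sums = np.asarray(self.sums, dtype=int)


def binarize(image: Image2D, threshold: float | None = None,
             method: str = "otsu") -> BinaryMask:
    """Threshold an image into a binary mask (``mask = image > threshold``).

    A fixed ``threshold`` overrides the automatic method, mirroring
    identical thresholding across experimental conditions; otherwise
    Otsu's criterion picks the value.  The value used is recorded in
    ``mask.meta["threshold"]``.
    """
    if threshold is None:
        if method != "otsu":
            raise ValueError(f"unknown automatic threshold method {method!r}")
        vals = image.values
        if np.ptp(vals) == 0:
            raise ValueError(
                "automatic threshold undefined on a constant image; "
                "pass a fixed threshold instead")
        threshold = float(threshold_otsu(vals))
    mask = BinaryMask(image.values > threshold, image.calibration)
    mask.meta["threshold"] = float(threshold)
    return mask


def _arc_pixels(cx: float, cy: float, r_px: float, phi0: float) -> np.ndarray:
    """Ordered 1-px chain of the semicircular arc around direction phi0.

    Midpoint-style rasterization by dense angular sampling followed by
    consecutive deduplication; successive chain pixels are 8-adjacent.
    """
    dtheta = 0.25 / max(r_px, 1.0)
    theta = np.arange(phi0 - math.pi / 2, phi0 + math.pi / 2 + dtheta, dtheta)
    xs = np.rint(cx + r_px * np.cos(theta)).astype(int)
    ys = np.rint(cy + r_px * np.sin(theta)).astype(int)
    keep = np.ones(len(xs), dtype=bool)
    keep[1:] = (np.diff(xs) != 0) | (np.diff(ys) != 0)
    return np.stack([xs[keep], ys[keep]], axis=1)


def _count_runs(fg: np.ndarray, adjacent: np.ndarray) -> int:
    """Connected foreground runs along an ordered arc chain.

    A run breaks at a background pixel or wherever the chain itself is
    interrupted (out-of-image gap).
    """
    if not len(fg):
        return 0
    linked = np.zeros(len(fg), dtype=bool)
    linked[1:] = fg[:-1] & adjacent
    return int((fg & ~linked).sum())


def sholl_intersections(mask: BinaryMask, params: ShollParams) -> ShollProfile:
    """Count foreground runs on each semicircular arc of the sampling set."""
    px = mask.calibration.pixel_size_um   # raises for anisotropic calibration
    h, w = mask.shape
    cx, cy = params.center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"center {params.center} lies outside the {w}x{h} image")
    phi0 = math.atan2(params.direction[1], params.direction[0])
    radii = params.radii_um
    counts = np.zeros(len(radii), dtype=int)
    vals = mask.values
    for i, r_um in enumerate(radii):
        chain = _arc_pixels(cx, cy, r_um / px, phi0)
        inb = ((chain[:, 0] >= 0) & (chain[:, 0] < w)
               & (chain[:, 1] >= 0) & (chain[:, 1] < h))
        fg = np.zeros(len(chain), dtype=bool)
        fg[inb] = vals[chain[inb, 1], chain[inb, 0]]
        steps = np.abs(np.diff(chain, axis=0)).max(axis=1) <= 1
        adjacent = steps & inb[:-1] & inb[1:]
        counts[i] = _count_runs(fg, adjacent)
    return ShollProfile(radii, counts, params)


def bin_sums(profile: ShollProfile, bin_edges_um=None) -> BinSums:
    """Total intersections per distance bin, half-open ``(lo, hi]``.

    Half-open membership puts a radius equal to an edge in the
    lower-labeled bin exactly once, so contiguous bins conserve the
    profile total.
    """
    edges = np.asarray(profile.params.bin_edges_um if bin_edges_um is None
                       else bin_edges_um, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    bins = [(float(lo), float(hi)) for lo, hi in zip(edges[:-1], edges[1:])]
    r = profile.radii_um
    sums = [int(profile.counts[(r > lo) & (r <= hi)].sum()) for lo, hi in bins]
    return BinSums(bins=bins, sums=np.asarray(sums))
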