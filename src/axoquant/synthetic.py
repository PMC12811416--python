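"""Synthetic fluorescence-microscopy generators with exact ground truth.

Every generator emulates one acquisition type used by the downstream
analyses and returns, next to the rendered image/movie/mask, a truth
record holding the exact geometry or kinematics it rendered.  The truth
records are consumed by tests and by nothing else in the package.

Generated scenes:

* axon arbors emanating from a microgroove edge (for Sholl counting),
* growth-cone masks: an elliptical actin body plus filopodia,
* EB3-comet movies: moving Gaussian spots over static structures,
* two-channel spot images with a controlled overlap fraction,
* puncta fields inside/outside a mask,
* straight axons with a prescribed axial intensity profile.

All randomness flows through ``numpy.random.default_rng(seed)``;
identical parameters and seed reproduce every output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .types import BinaryMask, Calibration, Image2D, Movie, PolylineROI

__all__ = [
    "Ray",
    "Branch",
    "AxonFieldTruth",
    "make_axon_field",
    "random_rays",
    "analytic_crossing_counts",
    "Filopodium",
    "GCTruth",
    "make_growth_cone",
    "Comet",
    "StaticSpot",
    "CometMovieTruth",
    "make_comet_movie",
    "ColocTruth",
    "make_coloc_pair",
    "PunctaTruth",
    "make_puncta_field",
    "ProfileTruth",
    "make_profile_image",
]


# --------------------------------------------------------------------------
# shared rendering helpers

def _add_gaussian(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    """Accumulate an isotropic Gaussian spot onto ``img`` in place."""
    h, w = img.shape
    r = int(math.ceil(4 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    img[y0:y1, x0:x1] += amp * np.exp(
        -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma**2))


def _draw_segment(canvas: np.ndarray, a_xy: np.ndarray, b_xy: np.ndarray,
                  trim_px: float = 0.0) -> None:
    """Rasterize segment a->b (x, y float px), optionally trimmed at the tip."""
    d = b_xy - a_xy
    n = float(np.hypot(*d))
    if trim_px > 0 and n > trim_px:
        b_xy = a_xy + d * (n - trim_px) / n
    rr, cc = skdraw.line(int(round(a_xy[1])), int(round(a_xy[0])),
                         int(round(b_xy[1])), int(round(b_xy[0])))
    ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[ok], cc[ok]] = True


def _place_points(rng: np.random.Generator, n: int, shape: tuple[int, int],
                  margin: float, min_sep: float,
                  existing: list[np.ndarray] | None = None,
                  inside: np.ndarray | None = None,
                  max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample n points with a minimum pairwise separation.

    ``inside`` optionally restricts centers to pixels where it is True
    (or, if inverted beforehand, False).  Raises when packing fails.
    """
    pts: list[np.ndarray] = list(existing) if existing else []
    placed: list[np.ndarray] = []
    h, w = shape
    tries = 0
    while len(placed) < n:
        if tries > max_tries:
            raise ValueError(
                f"cannot place {n} points with min separation {min_sep}px "
                f"in a {w}x{h} image (packed {len(placed)})")
        tries += 1
        p = np.array([rng.uniform(margin, w - 1 - margin),
                      rng.uniform(margin, h - 1 - margin)])
        if inside is not None and not inside[int(round(p[1])), int(round(p[0]))]:
            continue
        if all(np.hypot(*(p - q)) > min_sep for q in pts):
            pts.append(p)
            placed.append(p)
    return np.asarray(placed).reshape(n, 2)


# --------------------------------------------------------------------------
# axon fields (Sholl ground truth)

@dataclass(frozen=True)
class Branch:
    """A straight branch forking off a parent ray."""
    fork_um: float          # distance from the field center along the parent
    angle_rad: float        # absolute direction of the branch
    length_um: float        # length beyond the fork


@dataclass(frozen=True)
class Ray:
    """A straight axon trace from the field center."""
    angle_rad: float
    length_um: float
    branches: tuple[Branch, ...] = ()


@dataclass
class AxonFieldTruth:
    center: tuple[float, float]               # (x, y) px
    rays: tuple[Ray, ...]
    radii_um: np.ndarray
    expected_counts: np.ndarray               # analytic crossing counts
    direction: tuple[float, float] = (1.0, 0.0)
    stroke_halfwidth_um: float = 0.0


def _ray_segments(rays: Sequence[Ray]) -> list[tuple[np.ndarray, np.ndarray]]:
    """All straight segments (in um, relative to the center) of an arbor."""
    segs = []
    for ray in rays:
        u = np.array([math.cos(ray.angle_rad), math.sin(ray.angle_rad)])
        segs.append((np.zeros(2), u * ray.length_um))
        for br in ray.branches:
            a = u * br.fork_um
            v = np.array([math.cos(br.angle_rad), math.sin(br.angle_rad)])
            segs.append((a, a + v * br.length_um))
    return segs


def analytic_crossing_counts(rays: Sequence[Ray], radii_um: np.ndarray,
                             halfwidth_um: float = 0.0,
                             merge_gap_um: float = 0.0,
                             direction: tuple[float, float] = (1.0, 0.0)) -> np.ndarray:
    """Closed-form crossing counts of an arbor with semicircular arcs.

    For each radius, every straight segment's circle crossings are solved
    exactly; each crossing covers an angular interval given by the stroke
    half-width, and intervals closer than ``merge_gap_um`` of arc are
    merged into one crossing, mirroring how finite-width strokes fuse
    into a single foreground run on a rasterized arc.  With zero widths
    this is the pure geometric crossing count, which for unbranched
    straight rays from the center reduces to "number of rays with length
    >= r".
    """
    segs = _ray_segments(rays)
    phi0 = math.atan2(direction[1], direction[0])
    counts = np.zeros(len(radii_um), dtype=int)
    for i, r in enumerate(radii_um):
        intervals: list[tuple[float, float]] = []
        alpha = math.asin(min(1.0, halfwidth_um / r)) if halfwidth_um > 0 else 0.0
        for a, b in segs:
            d = b - a
            # |a + t d|^2 = r^2
            A = float(d @ d)
            B = 2 * float(a @ d)
            C = float(a @ a) - r * r
            disc = B * B - 4 * A * C
            if disc < 0:
                continue
            sq = math.sqrt(disc)
            for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
                # tolerate float error at exact-tip crossings (r == segment end)
                if not (-1e-9 <= t <= 1.0 + 1e-9):
                    continue
                p = a + t * d
                th = math.atan2(p[1], p[0])
                # fold into the half-plane window around phi0
                dth = (th - phi0 + math.pi) % (2 * math.pi) - math.pi
                if abs(dth) > math.pi / 2:
                    continue
                intervals.append((dth - alpha, dth + alpha))
        if not intervals:
            continue
        gap = merge_gap_um / r
        intervals.sort()
        merged = 1
        cur_hi = intervals[0][1]
        for lo, hi in intervals[1:]:
            if lo - cur_hi >= gap:
                merged += 1
            cur_hi = max(cur_hi, hi)
        counts[i] = merged
    return counts


def random_rays(rng: np.random.Generator, n_rays: int,
                length_range_um: tuple[float, float] = (100.0, 1400.0),
                angle_max_rad: float = math.radians(80.0),
                min_sep_rad: float = 0.23) -> tuple[Ray, ...]:
    """Random arbor of straight rays with a minimum angular separation.

    Angles are drawn on a jittered grid over ``[-angle_max, angle_max]``
    so that any two rays stay at least ``min_sep_rad`` apart; the
    separation guarantees that rendered strokes never fuse on any
    sampled arc of the default oracle geometry.
    """
    span = 2 * angle_max_rad
    if (n_rays - 1) * min_sep_rad > span:
        raise ValueError("too many rays for the requested minimum separation")
    slot = span / n_rays
    jitter = max(0.0, (slot - min_sep_rad) / 2)
    angles = (-angle_max_rad + slot * (np.arange(n_rays) + 0.5)
              + rng.uniform(-jitter, jitter, size=n_rays))
    lengths = rng.uniform(*length_range_um, size=n_rays)
    return tuple(Ray(float(a), float(l)) for a, l in zip(angles, lengths))


def make_axon_field(rays: Sequence[Ray], shape: tuple[int, int],
                    calibration: Calibration,
                    center: tuple[float, float] | None = None,
                    radii_um: np.ndarray | None = None,
                    dilate: int = 1) -> tuple[BinaryMask, AxonFieldTruth]:
    """Render an axon arbor as a binarized field with analytic Sholl truth.

    Rays are drawn as 1-px Bresenham lines (trimmed by the dilation reach
    so rendered tips sit at the stated lengths) and dilated ``dilate``
    iterations with a cross structuring element, emulating binarized
    axon traces a few pixels wide.
    """
    px = calibration.pixel_size_um
    h, w = shape
    if center is None:
        center = (0.0, (h - 1) / 2.0)
    cx, cy = center
    canvas = np.zeros(shape, dtype=bool)
    for a_um, b_um in _ray_segments(rays):
        a_px = np.array([cx, cy]) + a_um / px
        b_px = np.array([cx, cy]) + b_um / px
        if not (0 <= b_px[0] <= w - 1 and 0 <= b_px[1] <= h - 1):
            raise ValueError(f"ray endpoint {tuple(b_px)} exits the {w}x{h} image")
        _draw_segment(canvas, a_px, b_px, trim_px=float(dilate))
    if dilate:
        canvas = ndimage.binary_dilation(canvas, iterations=dilate)
    if radii_um is None:
        rmax = max((r.length_um for r in rays), default=0.0)
        radii_um = np.arange(2.0, rmax + 2.0, 2.0)
    radii_um = np.asarray(radii_um, dtype=float)
    halfwidth = (dilate + 0.5) * px
    expected = analytic_crossing_counts(rays, radii_um, halfwidth_um=halfwidth,
                                        merge_gap_um=1.0 * px)
    truth = AxonFieldTruth(center=center, rays=tuple(rays), radii_um=radii_um,
                           expected_counts=expected,
                           stroke_halfwidth_um=halfwidth)
    return BinaryMask(canvas, calibration), truth


# --------------------------------------------------------------------------
# growth cones

@dataclass(frozen=True)
class Filopodium:
    """A straight protrusion anchored on the body's boundary.

    ``base_t`` is the ellipse parameter of the anchor; the protrusion
    points along the outward normal unless ``direction_rad`` overrides it.
    """
    base_t: float
    length_um: float
    width_px: int = 1
    direction_rad: float | None = None


@dataclass
class GCTruth:
    center: tuple[float, float]       # (x, y) px
    a_um: float
    b_um: float
    orientation_rad: float
    filopodia: tuple[Filopodium, ...]
    bases_px: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))


def _ellipse_point(truth_center, a_px, b_px, orient, t):
    ct, st = math.cos(t), math.sin(t)
    co, so = math.cos(orient), math.sin(orient)
    x = a_px * ct * co - b_px * st * so + truth_center[0]
    y = a_px * ct * so + b_px * st * co + truth_center[1]
    return np.array([x, y])


def _ellipse_normal(a_px, b_px, orient, t):
    ct, st = math.cos(t), math.sin(t)
    co, so = math.cos(orient), math.sin(orient)
    nx = b_px * ct * co - a_px * st * so
    ny = b_px * ct * so + a_px * st * co
    n = np.array([nx, ny])
    return n / np.hypot(*n)


def make_growth_cone(center: tuple[float, float], a_um: float, b_um: float,
                     orientation_rad: float,
                     filopodia: Sequence[Filopodium],
                     shape: tuple[int, int],
                     calibration: Calibration) -> tuple[BinaryMask, GCTruth]:
    """Render a growth-cone mask: filled ellipse body plus filopodia.

    The body is the best-fit-ellipse model of the actin boundary
    (semi-axes in um, a >= b); filopodia are line segments of the stated
    lengths anchored on the boundary, rasterized at their stated widths.
    """
    if not (a_um >= b_um > 0):
        raise ValueError("ellipse needs a >= b > 0")
    px = calibration.pixel_size_um
    a_px, b_px = a_um / px, b_um / px
    cx, cy = center
    canvas = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.ellipse(cy, cx, b_px, a_px, shape=shape,
                            rotation=-orientation_rad)
    canvas[rr, cc] = True
    bases = []
    for fil in filopodia:
        if not fil.length_um > 0:
            raise ValueError("filopodium length must be positive")
        base = _ellipse_point((cx, cy), a_px, b_px, orientation_rad, fil.base_t)
        if fil.direction_rad is None:
            u = _ellipse_normal(a_px, b_px, orientation_rad, fil.base_t)
        else:
            u = np.array([math.cos(fil.direction_rad), math.sin(fil.direction_rad)])
        tip = base + u * fil.length_um / px
        if not (0 <= tip[0] <= shape[1] - 1 and 0 <= tip[1] <= shape[0] - 1):
            raise ValueError("filopodium does not fit inside the image")
        fcanvas = np.zeros(shape, dtype=bool)
        _draw_segment(fcanvas, base, tip)
        if fil.width_px > 1:
            fcanvas = ndimage.binary_dilation(fcanvas,
                                              iterations=(fil.width_px - 1) // 2 or 1)
        canvas |= fcanvas
        bases.append(base)
    truth = GCTruth(center=center, a_um=a_um, b_um=b_um,
                    orientation_rad=orientation_rad, filopodia=tuple(filopodia),
                    bases_px=np.asarray(bases).reshape(-1, 2))
    return BinaryMask(canvas, calibration), truth


def validate_filopodium_base(truth: GCTruth, base_px: np.ndarray,
                             calibration: Calibration, tol_px: float = 1.5) -> None:
    """Check that an explicit base point lies on the body boundary."""
    px = calibration.pixel_size_um
    a_px, b_px = truth.a_um / px, truth.b_um / px
    co, so = math.cos(truth.orientation_rad), math.sin(truth.orientation_rad)
    d = np.asarray(base_px, float) - np.asarray(truth.center, float)
    u = d[0] * co + d[1] * so
    v = -d[0] * so + d[1] * co
    val = (u / a_px) ** 2 + (v / b_px) ** 2
    # tolerance expressed as a radial band around the boundary
    if abs(math.sqrt(val) - 1.0) * min(a_px, b_px) > tol_px:
        raise ValueError("filopodium base is not on the ellipse boundary")


# --------------------------------------------------------------------------
# EB3 comet movies

@dataclass(frozen=True)
class Comet:
    start_time_s: float
    start_pos_um: float          # arc-length position along the axis
    velocity_um_s: float
    lifetime_s: float
    amplitude: float = 100.0
    sigma_px: float = 1.5


@dataclass(frozen=True)
class StaticSpot:
    x: float
    y: float
    amplitude: float = 100.0
    sigma_px: float = 1.5


@dataclass
class CometMovieTruth:
    axis: PolylineROI
    comets: tuple[Comet, ...]
    static_spots: tuple[StaticSpot, ...]
    noise_sd: float
    seed: int
    n_frames: int
    calibration: Calibration

    @property
    def mean_velocity(self) -> float:
        return float(np.mean([c.velocity_um_s for c in self.comets]))

    @property
    def mean_lifetime(self) -> float:
        return float(np.mean([c.lifetime_s for c in self.comets]))


def _axis_interpolator(axis: PolylineROI, calibration: Calibration):
    px = calibration.pixel_size_um
    v = axis.vertices
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1]) * px
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    def point_at(s_um: float) -> np.ndarray:
        if s_um < -1e-9 or s_um > cum[-1] + 1e-9:
            raise ValueError(f"position {s_um} um is off the {cum[-1]:.2f} um axis")
        i = int(np.clip(np.searchsorted(cum, s_um, side="right") - 1, 0, len(seg_len) - 1))
        frac = (s_um - cum[i]) / seg_len[i]
        return v[i] + frac * seg[i]

    return point_at, float(cum[-1])


def make_comet_movie(axis: PolylineROI, comets: Sequence[Comet],
                     static_spots: Sequence[StaticSpot],
                     shape: tuple[int, int], n_frames: int,
                     calibration: Calibration,
                     noise_sd: float = 0.0, poisson: bool = False,
                     seed: int = 0) -> tuple[Movie, CometMovieTruth]:
    """Render a time-lapse of Gaussian comets moving along an axis.

    Frame ``t`` (acquired at time ``t * frame_interval_s``) is the sum of
    the static spots, every comet active at that time placed at
    ``start_pos + v * (t - t_start)`` along the axis, and optional
    additive Gaussian noise (with optional Poisson resampling).  Defaults
    emulate a 3-min acquisition at 2 fps.
    """
    dt = calibration.require_time()
    total = n_frames * dt
    point_at, axis_len = _axis_interpolator(axis, calibration)
    for c in comets:
        if c.velocity_um_s <= 0 or c.lifetime_s <= 0:
            raise ValueError("comet velocity and lifetime must be positive")
        if c.start_time_s < 0 or c.start_time_s + c.lifetime_s > total + 1e-9:
            raise ValueError("comet active outside the movie duration")
        point_at(c.start_pos_um)
        point_at(c.start_pos_um + c.velocity_um_s * c.lifetime_s)  # stays on axis
    rng = np.random.default_rng(seed)
    base = np.zeros(shape)
    for sp in static_spots:
        _add_gaussian(base, sp.x, sp.y, sp.amplitude, sp.sigma_px)
    frames = np.empty((n_frames,) + tuple(shape))
    for f in range(n_frames):
        t = f * dt
        frame = base.copy()
        for c in comets:
            if c.start_time_s - 1e-9 <= t < c.start_time_s + c.lifetime_s - 1e-9:
                p = point_at(c.start_pos_um + c.velocity_um_s * (t - c.start_time_s))
                _add_gaussian(frame, p[0], p[1], c.amplitude, c.sigma_px)
        if poisson:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=shape)
        frames[f] = frame
    truth = CometMovieTruth(axis=axis, comets=tuple(comets),
                            static_spots=tuple(static_spots),
                            noise_sd=noise_sd, seed=seed, n_frames=n_frames,
                            calibration=calibration)
    return Movie(frames, calibration), truth


# --------------------------------------------------------------------------
# two-channel colocalization pairs

def random_comets(rng: np.random.Generator, n: int, axis_length_um: float,
                  total_time_s: float,
                  velocity_range: tuple[float, float] = (0.05, 0.15),
                  lifetime_range: tuple[float, float] = (10.0, 30.0),
                  amplitude: float = 100.0, sigma_px: float = 1.5,
                  margin_um: float = 0.8, gap_s: float = 3.5,
                  max_tries: int = 200000) -> tuple[Comet, ...]:
    """Random comets with distinguishable kymograph dashes.

    Velocities and lifetimes are drawn uniformly from the stated ranges;
    start positions and times are rejection-sampled so that the
    space-time footprints of any two comets (track extent padded by
    ``margin_um``, active window padded by ``gap_s``) never overlap --
    emulating kymographs in which individual growth events are
    distinguishable enough to trace.
    """
    # kinematics are drawn once per comet, so the realized velocity and
    # lifetime distributions stay uniform; placement then proceeds from
    # the largest space-time footprint down (large rectangles pack far
    # better when placed into an empty domain first)
    kin = [(rng.uniform(*velocity_range), rng.uniform(*lifetime_range))
           for _ in range(n)]
    order = sorted(range(n), key=lambda i: -(kin[i][0] * kin[i][1] + 2 * margin_um)
                   * (kin[i][1] + 2 * gap_s))
    boxes: list[tuple[float, float, float, float]] = []   # x0, x1, t0, t1
    placed: dict[int, Comet] = {}
    for i in order:
        v, life = kin[i]
        track = v * life
        if track + 2 * margin_um > axis_length_um or life > total_time_s:
            raise ValueError("comet kinematics do not fit the domain")
        for _ in range(max_tries):
            x0 = rng.uniform(margin_um, axis_length_um - track - margin_um)
            t0 = rng.uniform(0.0, total_time_s - life)
            box = (x0 - margin_um, x0 + track + margin_um,
                   t0 - gap_s, t0 + life + gap_s)
            if not any(box[0] < b[1] and b[0] < box[1]
                       and box[2] < b[3] and b[2] < box[3] for b in boxes):
                break
        else:
            raise ValueError(
                f"cannot pack {n} comets on a {axis_length_um} um x "
                f"{total_time_s} s domain (placed {len(placed)})")
        boxes.append(box)
        placed[i] = Comet(start_time_s=t0, start_pos_um=x0, velocity_um_s=v,
                          lifetime_s=life, amplitude=amplitude, sigma_px=sigma_px)
    return tuple(placed[i] for i in range(n))


@dataclass
class ColocTruth:
    n_spots_ch1: int
    n_spots_ch2: int
    overlap_fraction: float
    amplitude: float
    sigma_px: float
    seed: int
    centers_ch1: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    centers_ch2: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    shared: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))


def make_coloc_pair(n_spots_ch1: int, n_spots_ch2: int, overlap_fraction: float,
                    shape: tuple[int, int], calibration: Calibration,
                    amplitude: float = 100.0, sigma_px: float = 1.5,
                    noise_sd: float = 0.0, seed: int = 0
                    ) -> tuple[Image2D, Image2D, ColocTruth]:
    """Two spot channels sharing an exact fraction of ch1 centers.

    ``round(overlap_fraction * n_spots_ch1)`` spots sit at identical
    centers in both channels; every other center keeps > 4 sigma
    separation from all spots of the opposite channel.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    n_shared = int(round(overlap_fraction * n_spots_ch1))
    if n_shared > n_spots_ch2:
        raise ValueError("channel 2 has fewer spots than the requested overlap")
    rng = np.random.default_rng(seed)
    sep = 4.0 * sigma_px
    margin = 4.0 * sigma_px + 1
    c1 = _place_points(rng, n_spots_ch1, shape, margin, sep)
    shared = c1[rng.choice(n_spots_ch1, size=n_shared, replace=False)] if n_shared else np.zeros((0, 2))
    extra2 = _place_points(rng, n_spots_ch2 - n_shared, shape, margin, sep,
                           existing=list(c1) + list(shared))
    c2 = np.vstack([shared, extra2]) if len(shared) or len(extra2) else np.zeros((0, 2))
    ch1 = np.zeros(shape)
    ch2 = np.zeros(shape)
    for x, y in c1:
        _add_gaussian(ch1, x, y, amplitude, sigma_px)
    for x, y in c2:
        _add_gaussian(ch2, x, y, amplitude, sigma_px)
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0, noise_sd, shape)
        ch2 = ch2 + rng.normal(0, noise_sd, shape)
    truth = ColocTruth(n_spots_ch1, n_spots_ch2, overlap_fraction, amplitude,
                       sigma_px, seed, c1, c2, shared)
    return Image2D(ch1, calibration), Image2D(ch2, calibration), truth


# --------------------------------------------------------------------------
# puncta fields

@dataclass
class PunctaTruth:
    n_inside: int
    n_outside: int
    min_sep_px: float
    amplitude: float
    sigma_px: float
    seed: int
    centers_inside: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    centers_outside: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))


def make_puncta_field(mask: BinaryMask, n_inside: int, n_outside: int,
                      amplitude: float = 100.0, sigma_px: float = 1.5,
                      min_sep_px: float | None = None, noise_sd: float = 0.0,
                      boundary_margin_px: float = 2.0,
                      seed: int = 0) -> tuple[Image2D, PunctaTruth]:
    """Gaussian puncta with known counts inside and outside a mask.

    Inside/outside classification is by the mask value at the punctum
    center; packing respects ``min_sep_px`` (default 4 sigma) between
    all puncta.  Centers keep ``boundary_margin_px`` away from the mask
    boundary so the classification is unambiguous: a punctum straddling
    the boundary has no well-defined side, and noise could push its
    detected centroid across it.
    """
    if not mask.values.any():
        raise ValueError("mask is empty")
    sep = 4.0 * sigma_px if min_sep_px is None else float(min_sep_px)
    rng = np.random.default_rng(seed)
    margin = 4.0 * sigma_px + 1
    interior = ndimage.distance_transform_edt(mask.values) > boundary_margin_px
    exterior = ndimage.distance_transform_edt(~mask.values) > boundary_margin_px
    inside = _place_points(rng, n_inside, mask.shape, margin, sep, inside=interior)
    outside = _place_points(rng, n_outside, mask.shape, margin, sep,
                            existing=list(inside), inside=exterior)
    img = np.zeros(mask.shape)
    for x, y in np.vstack([inside, outside]) if n_inside + n_outside else []:
        _add_gaussian(img, x, y, amplitude, sigma_px)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, mask.shape)
    truth = PunctaTruth(n_inside, n_outside, sep, amplitude, sigma_px, seed,
                        inside, outside)
    return Image2D(img, mask.calibration), truth


# --------------------------------------------------------------------------
# axial intensity profile phantoms

@dataclass
class ProfileTruth:
    distances_um: np.ndarray
    values: np.ndarray            # f sampled at pixel centers, baseline excluded
    baseline: float
    tip_px: tuple[float, float]   # (x, y) of the axon tip
    width_px: int


def make_profile_image(f: Callable[[np.ndarray], np.ndarray],
                       length_um: float, width_px: int, baseline: float,
                       calibration: Calibration,
                       shape: tuple[int, int] | None = None,
                       ) -> tuple[Image2D, ProfileTruth]:
    """A straight horizontal axon whose axial intensity follows ``f``.

    Intensity at distance ``d`` from the tip (leftmost axon column) is
    ``f(d) + baseline``; everywhere else the image equals the baseline.
    The truth holds ``f`` sampled at pixel centers.
    """
    px = calibration.pixel_size_um
    n_cols = int(round(length_um / px)) + 1
    margin = 10
    if shape is None:
        shape = (width_px + 2 * margin, n_cols + 2 * margin)
    h, w = shape
    if n_cols + 2 * margin > w or width_px + 2 > h:
        raise ValueError("axon does not fit inside the image")
    d = np.arange(n_cols) * px
    vals = np.asarray(f(d), dtype=float)
    if np.any(vals < 0):
        raise ValueError("axial intensity function must be nonnegative")
    img = np.full(shape, float(baseline))
    row0 = (h - width_px) // 2
    img[row0:row0 + width_px, margin:margin + n_cols] += vals[None, :]
    tip = (float(margin), row0 + (width_px - 1) / 2.0)
    truth = ProfileTruth(distances_um=d, values=vals, baseline=baseline,
                         tip_px=tip, width_px=width_px)
    return Image2D(img, calibration), truth


def profile_roi(truth: ProfileTruth, length_um: float, width_um: float = 1.0,
                calibration: Calibration | None = None) -> PolylineROI:
    """The tip-anchored sampling line matching a rendered profile phantom."""
    px = 1.0 if calibration is None else calibration.pixel_size_um
    x0, y0 = truth.tip_px
    return PolylineROI(np.array([[x0, y0], [x0 + length_um / px, y0]]), width_um)
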