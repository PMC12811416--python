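"""TIFF / CSV / JSON input-output for images, movies, ROIs and tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .types import BinaryMask, Calibration, Image2D, Movie, PolylineROI

__all__ = [
    "read_image",
    "write_image",
    "read_movie",
    "write_movie",
    "read_mask",
    "write_mask",
    "load_roi",
    "save_roi",
    "write_table",
    "read_table",
]


def _load_page(path: Path, channel: int | None) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path} has {arr.shape[-1] if arr.shape[-1] <= 4 else arr.shape[0]} "
                "channels/pages; pass an explicit channel selector"
            )
        arr = arr[..., channel] if arr.shape[-1] <= 4 else arr[channel]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D page, got shape {arr.shape}")
    return arr


def read_image(path: str | Path, calibration: Calibration, channel: int | None = None) -> Image2D:
    """Read a single-page grayscale TIFF into a calibrated Image2D.

    Integer pages are cast to float without rescaling.  Multi-channel
    pages require an explicit ``channel``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return Image2D(_load_page(path, channel).astype(np.float64), calibration)


def write_image(image: Image2D, path: str | Path) -> None:
    tifffile.imwrite(Path(path), image.values.astype(np.float32),
                     photometric="minisblack")


def read_movie(path: str | Path, calibration: Calibration) -> Movie:
    """Read a multi-page TIFF as an ordered frame stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path} is a single page; a movie needs >= 2 frames")
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected (t, y, x) pages, got shape {arr.shape}")
    return Movie(arr.astype(np.float64), calibration)


def write_movie(movie: Movie, path: str | Path) -> None:
    tifffile.imwrite(Path(path), movie.frames.astype(np.float32),
                     photometric="minisblack")


def read_mask(path: str | Path, calibration: Calibration) -> BinaryMask:
    arr = _load_page(Path(path), None)
    return BinaryMask(arr > 0, calibration)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.values.astype(np.uint8) * 255,
                     photometric="minisblack")


def load_roi(path: str | Path) -> PolylineROI:
    """Load a polyline ROI from CSV (columns x,y in pixels) or JSON.

    JSON files carry ``{"vertices": [[x, y], ...], "width_um": w}``; CSV
    files default the sampling width to 1.0 um.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return PolylineROI(np.asarray(payload["vertices"], dtype=float),
                           float(payload.get("width_um", 1.0)))
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        # headerless two-column form
        df = pd.read_csv(path, header=None, names=["x", "y"])
        cols = {"x": "x", "y": "y"}
    verts = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    return PolylineROI(verts, 1.0)


def save_roi(roi: PolylineROI, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            {"vertices": roi.vertices.tolist(), "width_um": roi.width_um}, indent=2))
    else:
        pd.DataFrame(roi.vertices, columns=["x", "y"]).to_csv(path, index=False)


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                columns: Iterable[str] | None = None) -> None:
    """Write flat records to CSV with a deterministic column order.

    Floats are rendered with ``repr`` precision so a round trip restores
    them bit-for-bit.  Heterogeneous field names raise.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            keys = list(records[0].keys())
            for r in records[1:]:
                if list(r.keys()) != keys:
                    raise ValueError("heterogeneous records: all rows need identical fields")
            df = pd.DataFrame.from_records(records, columns=keys)
        else:
            df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
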