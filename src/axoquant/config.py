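"""Analysis configuration: per-module parameter blocks with strict keys.

Defaults follow the published acquisition/analysis settings: 2-um Sholl
steps out to 1500 um with 0/500/1000/1500 um bins, 1.0-um filopodium
threshold, 50-um profiles with the 45-50 um distal baseline window,
4/50-frame separation sigmas, and 2 fps / 0.5 s frame intervals for
simulated movies.  Unknown keys anywhere in the tree are rejected.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["DEFAULTS", "AnalysisConfig", "load_config"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "axoquant_out",
    "log_level": "INFO",
    "calibration": {
        "pixel_size_x_um": 1.0,
        "pixel_size_y_um": 1.0,
        "frame_interval_s": 0.5,
    },
    "sholl": {
        "threshold": None,
        "threshold_method": "otsu",
        "center": None,
        "direction": [1.0, 0.0],
        "radius_step_um": 2.0,
        "r_max_um": 1500.0,
        "bin_edges_um": [0.0, 500.0, 1000.0, 1500.0],
    },
    "gc": {
        "min_filopodium_len_um": 1.0,
        "prune_len_um": 0.5,
        "connectivity": 8,
    },
    "profile": {
        "length_um": 50.0,
        "background": 0.0,
        "baseline_mode": "none",      # none | tip_anchor | distal_window
        "distal_window_um": [45.0, 50.0],
        "terminal_window_um": 10.0,
    },
    "kymo": {
        "sigma_mobile": 4.0,
        "sigma_static": 50.0,
        "threshold": None,
        "min_dash_len_px": 5.0,
    },
    "coloc": {
        "thr1": 0.0,
        "thr2": 0.0,
    },
    "puncta": {
        "threshold": 0.0,
        "min_area_px": 2,
        "max_area_px": 200,
    },
    "stages": [],
}


def _merge(defaults: Any, user: Any, path: str) -> Any:
    if isinstance(defaults, dict):
        if not isinstance(user, dict):
            raise ValueError(f"config block {path or '<root>'} must be a mapping")
        unknown = set(user) - set(defaults)
        # stage blocks are free-form apart from the required 'stage' key
        if unknown and path != "stages[]":
            raise ValueError(f"unknown config keys at {path or '<root>'}: {sorted(unknown)}")
        merged = copy.deepcopy(defaults)
        for k, v in user.items():
            merged[k] = _merge(defaults[k], v, f"{path}.{k}" if path else k) \
                if isinstance(defaults.get(k), dict) else copy.deepcopy(v)
        return merged
    return copy.deepcopy(user)


@dataclass
class AnalysisConfig:
    """A validated configuration tree (defaults merged with user values)."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_dict(cls, user: dict[str, Any]) -> "AnalysisConfig":
        return cls(_merge(DEFAULTS, user, ""))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)


def load_config(path: str | Path) -> AnalysisConfig:
    return AnalysisConfig.from_dict(json.loads(Path(path).read_text()))
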