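"""Shared fixtures: calibrations and small synthetic scenes."""

import numpy as np
import pytest

from axoquant.types import Calibration


@pytest.fixture
def unit_cal() -> Calibration:
    """1 um/px, 1 s/frame: physical outputs equal pixel/frame outputs."""
    return Calibration(1.0, 1.0, 1.0)


@pytest.fixture
def gc_cal() -> Calibration:
    """High-magnification still-image calibration (0.1 um/px)."""
    return Calibration(0.1, 0.1)


@pytest.fixture
def movie_cal() -> Calibration:
    """Live-imaging calibration: 0.1 um/px at 2 fps."""
    return Calibration(0.1, 0.1, 0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
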