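import numpy as np
import pytest

from octmoco import synth
from octmoco.datamodel import ScanProtocol
from octmoco.preprocess import PreprocessConfig


@pytest.fixture
def small_protocol() -> ScanProtocol:
    """Tiny but non-degenerate acquisition for fast end-to-end tests."""
    return ScanProtocol(
        n_depth=160, n_fast=96, n_slow=48,
        axial_pitch_um=3.6,
        fast_pitch_um=10000.0 / 96,
        slow_pitch_um=11000.0 / 48,
        bscan_rate_hz=100.0,
        n_refs=3, alpha=0.33,
    )


@pytest.fixture
def small_surface(small_protocol):
    return synth.make_quartic_cap(small_protocol.n_fast, small_protocol.n_slow,
                                  apex_px=60.0, sag_px=20.0)


@pytest.fixture
def small_cfg() -> PreprocessConfig:
    """Preprocess config scaled to the small fixture frames."""
    return PreprocessConfig(threshold_window=32, border_crop=8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260904)
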