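"""Standard scaled-down simulation experiments.

The full acquisition (512 fast B-scans of 1024×1024 px) is scaled to
128 fast B-scans of 512 (depth) × 256 (lateral) px covering the same
physical field, so a complete simulate → compensate → evaluate cycle runs
in seconds on one CPU while preserving the axial pixel pitch (3.6 μm/px)
and frame rate (100 Hz) the error figures are quoted in.  The 50-px border
crop scales proportionally to 12 px.
"""

from __future__ import annotations

import numpy as np

from octmoco import metrics, synth
from octmoco.axial import compensate_volume
from octmoco.datamodel import ScanProtocol
from octmoco.preprocess import PreprocessConfig, preprocess_bscan

__all__ = [
    "scaled_protocol",
    "scaled_surface",
    "run_compensation_experiment",
    "axial_sinusoid_experiment",
    "freehand_experiment",
    "FREEHAND_PARAMS",
]

SCALED_CROP_PX = 12  # 50 px scaled by 256/1024

#: Free-hand motion defaults: target mean inter-frame steps of 14.18 μm
#: axial / 165 μm lateral; per-axis frequency bands keep the excursions
#: inside the scaled imaging window (amplitude ~ step·rate/(4f)) while
#: staying band-limited below 5 Hz.
FREEHAND_PARAMS = {
    "axial_step_um": 14.18,
    "lateral_step_um": 165.0,
    "axial_f_min": 1.0,
    "axial_f_max": 3.0,
    "lateral_f_min": 3.0,
    "lateral_f_max": 5.0,
}


def scaled_protocol(n_refs: int = 3, alpha: float = 0.33) -> ScanProtocol:
    return ScanProtocol(
        n_depth=512, n_fast=256, n_slow=128,
        axial_pitch_um=3.6,
        fast_pitch_um=10000.0 / 256,
        slow_pitch_um=11000.0 / 128,
        bscan_rate_hz=100.0,
        n_refs=n_refs, alpha=alpha,
    )


def scaled_surface(protocol: ScanProtocol) -> synth.PhantomSurface:
    """Quartic corneal cap leaving headroom for ±700 μm axial motion."""
    return synth.make_quartic_cap(protocol.n_fast, protocol.n_slow,
                                  apex_px=200.0, sag_px=40.0)


def run_compensation_experiment(protocol: ScanProtocol,
                                motion: synth.MotionTrace,
                                seed: int,
                                search_px: int,
                                noise: synth.NoiseConfig = synth.NoiseConfig(),
                                ) -> dict:
    """Simulate, compensate and score one volume against its ground truth.

    The error is the mean absolute difference between the compensated
    per-frame surface fits f(x) and the motion-free true surface, over the
    border-cropped columns, in micrometers.  Frames the pipeline failed on
    contribute their uncompensated surface fit (honest accounting), and are
    counted in ``n_failed``.
    """
    surface = scaled_surface(protocol)
    volume, truth = synth.simulate_acquisition(
        protocol, surface, motion, noise=noise, seed=seed,
        include_motion_free=False)
    pre = PreprocessConfig(border_crop=SCALED_CROP_PX)
    comp, estimates, report = compensate_volume(
        volume, pre_cfg=pre, search_px=search_px, crop_px=SCALED_CROP_PX)
    cols = np.arange(SCALED_CROP_PX, protocol.n_fast - SCALED_CROP_PX)
    fits = []
    for est, bscan in zip(estimates, volume.bscans):
        if est.surface is not None:
            fits.append(est.surface)
        else:  # failed frame: score its uncompensated surface
            fits.append(preprocess_bscan(bscan, pre)[1])
    grid = metrics.surfaces_to_grid(fits, cols)
    rep = metrics.surface_error(grid, truth.z_true[:, cols],
                                axial_pitch_um=protocol.axial_pitch_um)
    return {
        "mae_um": rep.mae_um,
        "rmse_um": rep.rmse_um,
        "n_failed": report["n_failed"],
        "n_frames": report["n_frames"],
    }


def axial_sinusoid_experiment(freq_hz: float, seed: int,
                              n_refs: int = 3,
                              amplitude_um: float = 700.0) -> dict:
    """Sinusoidal axial motion at ``freq_hz`` (~700 μm amplitude, 100 Hz rate)."""
    protocol = scaled_protocol(n_refs=n_refs)
    motion = synth.make_motion(
        "sinusoid",
        {"axial_amplitude_um": amplitude_um, "axial_freq_hz": freq_hz},
        frames=protocol.n_refs + protocol.n_slow,
        rate=protocol.bscan_rate_hz, seed=seed)
    return run_compensation_experiment(protocol, motion, seed, search_px=20)


def freehand_experiment(seed: int, n_refs: int = 3) -> dict:
    """Band-limited 3D free-hand motion (≈14 μm axial / 165 μm lateral steps)."""
    protocol = scaled_protocol(n_refs=n_refs)
    motion = synth.make_motion(
        "freehand", dict(FREEHAND_PARAMS),
        frames=protocol.n_refs + protocol.n_slow,
        rate=protocol.bscan_rate_hz, seed=seed)
    return run_compensation_experiment(protocol, motion, seed, search_px=100)
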