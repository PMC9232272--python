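"""Synthetic OCT acquisition simulator with ground truth.

Provides corneal phantom surfaces, axial/lateral motion traces (sinusoidal
and band-limited "free-hand"), speckled B-scan rendering with an optional
bright-stripe saturation artifact, and a full protocol simulation that
acquires the slow-axis reference B-scans first and then the fast-axis
C-scan, exactly as the compensation pipeline expects.

Determinism: every random quantity is drawn from ``numpy`` generators
seeded from the caller's seed; the same (protocol, surface, motion, noise,
seed) tuple produces bit-identical volumes.  Each frame uses a child seed
derived from (seed, global frame index), so the motion-free ground-truth
volume shares its per-frame speckle with the moving volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from octmoco.datamodel import BScan, CScanVolume, ReferenceSet, ScanProtocol
from octmoco.errors import FormatError, MotionRangeError

__all__ = [
    "PhantomSurface",
    "MotionTrace",
    "NoiseConfig",
    "make_quartic_cap",
    "make_spherical_cap",
    "make_keratoconus",
    "make_motion",
    "render_bscan",
    "simulate_acquisition",
    "GroundTruth",
]


@dataclass
class PhantomSurface:
    """Smooth phantom surface z_true(x, y), all coordinates in pixels."""

    kind: str
    params: dict
    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def z(self, x, y) -> np.ndarray:
        return np.asarray(self.fn(np.asarray(x, dtype=float),
                                  np.asarray(y, dtype=float)), dtype=float)

    def validate(self, n_fast: int, n_slow: int, n_depth: int, margin: int = 0) -> None:
        xs, ys = np.meshgrid(np.arange(n_fast), np.arange(n_slow))
        z = self.z(xs, ys)
        if not np.all(np.isfinite(z)):
            raise FormatError("phantom surface is non-finite over the field")
        if z.min() < margin or z.max() > n_depth - 1 - margin:
            raise FormatError(
                f"phantom surface range [{z.min():.1f}, {z.max():.1f}] px exceeds "
                f"depth margin [{margin}, {n_depth - 1 - margin}]"
            )


def make_quartic_cap(n_fast: int, n_slow: int, apex_px: float, sag_px: float,
                     a4_frac: float = 0.3) -> PhantomSurface:
    """Rotationally-symmetric quartic cap, apex (shallowest) at field center.

    z = apex + sag * [(1 - a4_frac) u + a4_frac u²] with
    u = ((x-cx)/hx)² + ((y-cy)/hy)², so any fixed-y cross-section is an
    exact quartic in x (an order-4 fit has zero model error).
    """
    cx, cy = (n_fast - 1) / 2.0, (n_slow - 1) / 2.0
    hx, hy = max(cx, 1.0), max(cy, 1.0)

    def fn(x, y):
        u = ((x - cx) / hx) ** 2 + ((y - cy) / hy) ** 2
        return apex_px + sag_px * ((1.0 - a4_frac) * u + a4_frac * u**2)

    return PhantomSurface(kind="quartic",
                          params=dict(apex_px=apex_px, sag_px=sag_px,
                                      a4_frac=a4_frac, n_fast=n_fast, n_slow=n_slow),
                          fn=fn)


def make_spherical_cap(n_fast: int, n_slow: int, apex_px: float,
                       radius_px: float, lateral_scale: float = 1.0) -> PhantomSurface:
    """Spherical cap z = apex + R - sqrt(R² - r²), r scaled by lateral_scale.

    ``lateral_scale`` converts lateral pixel distance into axial pixel units
    (ratio of lateral to axial pitch).
    """

    cx, cy = (n_fast - 1) / 2.0, (n_slow - 1) / 2.0

    def fn(x, y):
        r2 = (lateral_scale * (x - cx)) ** 2 + (lateral_scale * (y - cy)) ** 2
        r2 = np.minimum(r2, radius_px**2)  # clamp outside the cap
        return apex_px + radius_px - np.sqrt(radius_px**2 - r2)

    return PhantomSurface(kind="spherical_cap",
                          params=dict(apex_px=apex_px, radius_px=radius_px,
                                      lateral_scale=lateral_scale),
                          fn=fn)


def make_keratoconus(n_fast: int, n_slow: int, apex_px: float, sag_px: float,
                     bump_center_frac: tuple[float, float] = (0.6, 0.5),
                     bump_width_frac: float = 0.08,
                     bump_height_px: float = 8.0) -> PhantomSurface:
    """Quartic cap with a local Gaussian steepening bump (cone protrudes
    toward the instrument, i.e. locally shallower)."""
    base = make_quartic_cap(n_fast, n_slow, apex_px, sag_px)
    bx = bump_center_frac[0] * (n_fast - 1)
    by = bump_center_frac[1] * (n_slow - 1)
    wx = max(bump_width_frac * n_fast, 1.0)
    wy = max(bump_width_frac * n_slow, 1.0)

    def fn(x, y):
        bump = bump_height_px * np.exp(
            -(((x - bx) / wx) ** 2 + ((y - by) / wy) ** 2) / 2.0
        )
        return base.fn(x, y) - bump

    return PhantomSurface(kind="keratoconus",
                          params=dict(apex_px=apex_px, sag_px=sag_px,
                                      bump_center_frac=bump_center_frac,
                                      bump_width_frac=bump_width_frac,
                                      bump_height_px=bump_height_px),
                          fn=fn)


@dataclass
class MotionTrace:
    """Axial/lateral sample displacement sampled at frame start times.

    The trace also keeps its sinusoidal components so displacement can be
    evaluated at arbitrary (e.g. per-A-line) times; each component is a
    triple (amplitude_um, freq_hz, phase_rad).
    """

    times: np.ndarray
    axial_um: np.ndarray
    lateral_um: np.ndarray
    kind: str
    seed: Optional[int] = None
    axial_components: tuple = ()
    lateral_components: tuple = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.axial_um = np.asarray(self.axial_um, dtype=float)
        self.lateral_um = np.asarray(self.lateral_um, dtype=float)
        if not (len(self.times) == len(self.axial_um) == len(self.lateral_um)):
            raise FormatError("trace arrays must have equal length")

    @staticmethod
    def _eval(components, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for amp, freq, phase in components:
            out = out + amp * np.sin(2.0 * math.pi * freq * t + phase)
        return out

    def axial_at(self, t) -> np.ndarray:
        return self._eval(self.axial_components, t)

    def lateral_at(self, t) -> np.ndarray:
        return self._eval(self.lateral_components, t)

    def __len__(self) -> int:
        return len(self.times)


def _freehand_components(rng: np.random.Generator, n_components: int,
                         f_min: float, f_max: float) -> list[tuple[float, float, float]]:
    freqs = rng.uniform(f_min, f_max, n_components)
    amps = rng.uniform(0.5, 1.0, n_components) / np.sqrt(freqs)  # red-ish spectrum
    phases = rng.uniform(0.0, 2.0 * math.pi, n_components)
    return list(zip(amps, freqs, phases))


def _rescale_to_step(components, times, target_step_um: float):
    vals = MotionTrace._eval(components, times)
    step = float(np.mean(np.abs(np.diff(vals))))
    if step == 0 or target_step_um == 0:
        scale = 0.0
    else:
        scale = target_step_um / step
    return [(a * scale, f, p) for a, f, p in components]


def make_motion(kind: str, params: dict, frames: int, rate: float,
                seed: int = 0) -> MotionTrace:
    """Build a motion trace of ``frames`` samples at ``rate`` Hz.

    kind="sinusoid": params axial_amplitude_um, axial_freq_hz, axial_phase
    (and the lateral_* counterparts, all defaulting to zero motion).

    kind="freehand": params axial_step_um / lateral_step_um (target mean
    absolute inter-frame displacement), f_max (default 5 Hz), f_min
    (default 0.2 Hz), n_components (default 8).  Per-axis frequency bands
    may override the shared ones via axial_f_min/axial_f_max and
    lateral_f_min/lateral_f_max (a sum of sinusoids rescaled to a fixed
    mean step puts amplitude ~ step·rate/(4f) into a component at
    frequency f, so the band also bounds the excursion).  Independent
    random-phase sinusoid sums per axis, rescaled to the target mean step.
    """
    if frames < 1:
        raise ValueError("frames must be >= 1")
    times = np.arange(frames) / rate
    rng = np.random.default_rng(seed)
    if kind == "sinusoid":
        ax = []
        lat = []
        for prefix, out in (("axial", ax), ("lateral", lat)):
            amp = float(params.get(f"{prefix}_amplitude_um", 0.0))
            freq = float(params.get(f"{prefix}_freq_hz", 0.0))
            phase = float(params.get(f"{prefix}_phase", 0.0))
            if amp != 0.0:
                if freq >= rate / 2.0:
                    raise ValueError(
                        f"{prefix} frequency {freq} Hz aliases at rate {rate} Hz"
                    )
                out.append((amp, freq, phase))
        axial_components, lateral_components = tuple(ax), tuple(lat)
    elif kind == "freehand":
        f_max = float(params.get("f_max", 5.0))
        f_min = float(params.get("f_min", 0.2))
        n_comp = int(params.get("n_components", 8))
        if n_comp < 8:
            raise ValueError("freehand motion needs at least 8 components")
        bands = {}
        for prefix in ("axial", "lateral"):
            lo = float(params.get(f"{prefix}_f_min", f_min))
            hi = float(params.get(f"{prefix}_f_max", f_max))
            if hi >= rate / 2.0:
                raise ValueError(f"{prefix} f_max {hi} Hz aliases at rate {rate} Hz")
            if not 0 < lo < hi:
                raise ValueError(f"invalid {prefix} frequency band [{lo}, {hi}]")
            bands[prefix] = (lo, hi)
        axial_components = tuple(_rescale_to_step(
            _freehand_components(rng, n_comp, *bands["axial"]), times,
            float(params.get("axial_step_um", 14.18))))
        lateral_components = tuple(_rescale_to_step(
            _freehand_components(rng, n_comp, *bands["lateral"]), times,
            float(params.get("lateral_step_um", 165.0))))
    else:
        raise ValueError(f"unknown motion kind {kind!r}")
    trace = MotionTrace(times=times,
                        axial_um=MotionTrace._eval(axial_components, times),
                        lateral_um=MotionTrace._eval(lateral_components, times),
                        kind=kind, seed=seed,
                        axial_components=axial_components,
                        lateral_components=lateral_components)
    return trace


@dataclass(frozen=True)
class NoiseConfig:
    """Speckle / background / saturation model of a rendered B-scan."""

    speckle: bool = True
    speckle_scale: float = 0.6  # 0 = none, 1 = fully developed exponential
    band_thickness_px: float = 2.0
    psf_sigma_px: float = 1.5
    background_level: float = 0.03
    tissue_decay_px: float = 12.0  # attenuation length of tissue below the band
    saturation_stripes: int = 0
    saturation_intensity: float = 4.0

    def __post_init__(self):
        for name in ("speckle_scale", "band_thickness_px", "psf_sigma_px",
                     "background_level", "tissue_decay_px",
                     "saturation_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.saturation_stripes < 0:
            raise ValueError("saturation_stripes must be >= 0")


def render_bscan(surface: PhantomSurface, axis_role: str, position: int,
                 n_cols: int, n_depth: int,
                 offsets: tuple = (0.0, 0.0),
                 noise: NoiseConfig = NoiseConfig(),
                 seed=0, index: int = 0) -> BScan:
    """Render one B-scan of the phantom.

    ``axis_role`` "fast" scans x at y=position; "slow" scans y at
    x=position.  ``offsets`` is (axial_px, lateral_px), each a scalar or a
    per-column array (per-column values model motion during the frame).
    The lateral offset shifts the sampled surface coordinate along x.
    The bright band spans [z_true + axial_px, .. + band_thickness_px]
    axially (top edge at the surface) and is then blurred by the PSF.
    """
    axial_px = np.broadcast_to(np.asarray(offsets[0], dtype=float), (n_cols,))
    lateral_px = np.broadcast_to(np.asarray(offsets[1], dtype=float), (n_cols,))
    cols = np.arange(n_cols, dtype=float)
    if axis_role == "fast":
        x = cols - lateral_px
        y = np.full(n_cols, float(position))
    elif axis_role == "slow":
        x = np.full(n_cols, float(position)) - lateral_px
        y = cols
    else:
        raise ValueError(f"axis_role must be 'fast' or 'slow', got {axis_role!r}")
    top = surface.z(x, y) + axial_px
    if np.any(top < 0) or np.any(top + noise.band_thickness_px > n_depth - 1):
        raise MotionRangeError(
            f"shifted surface range [{top.min():.1f}, {top.max():.1f}] px "
            f"leaves the imaging depth [0, {n_depth - 1}]"
        )
    rows = np.arange(n_depth, dtype=float)[:, None]
    # tissue starts at z_true (+ offset): a full-brightness surface band of
    # band_thickness_px, then exponentially attenuating stroma below — the
    # TOP edge is the surface and carries the dominant axial gradient
    depth_below = rows - top[None, :]
    band = np.where(
        depth_below < -1e-9, 0.0,
        np.where(depth_below <= noise.band_thickness_px, 1.0,
                 np.exp(-(depth_below - noise.band_thickness_px)
                        / max(noise.tissue_decay_px, 1e-9))
                 if noise.tissue_decay_px > 0 else 0.0))
    rng = np.random.default_rng(seed)
    img = band
    if noise.speckle and noise.speckle_scale > 0:
        # multiplicative unit-mean speckle, applied before the PSF blur so
        # the grain is resolution-limited like real coherent speckle
        speckle = 1.0 + noise.speckle_scale * (
            rng.exponential(1.0, size=(n_depth, n_cols)) - 1.0
        )
        img = img * speckle
    if noise.psf_sigma_px > 0:
        img = ndimage.gaussian_filter1d(img, noise.psf_sigma_px, axis=0,
                                        mode="nearest")
    if noise.saturation_stripes > 0:
        stripe_cols = rng.choice(n_cols, size=noise.saturation_stripes,
                                 replace=False)
        img = img.copy()
        img[:, stripe_cols] += noise.saturation_intensity
    img = img + noise.background_level
    return BScan(np.maximum(img, 0.0), axis_role=axis_role, index=index,
                 slow_position=position)


@dataclass
class GroundTruth:
    """Everything needed to score a simulated acquisition.

    ``z_true[y, x]`` is the motion-free surface; ``axial_px``/``lateral_px``
    are the per-frame, per-column injected offsets actually applied to the
    fast B-scans (after the lateral origin convention below);
    ``motion_free`` is a paired-noise rendering of the static sample.
    """

    protocol: ScanProtocol
    z_true: np.ndarray
    axial_px: np.ndarray
    lateral_px: np.ndarray
    motion: MotionTrace
    motion_free: Optional[CScanVolume] = None


def simulate_acquisition(protocol: ScanProtocol, surface: PhantomSurface,
                         motion: MotionTrace, noise: NoiseConfig = NoiseConfig(),
                         seed: int = 0,
                         freeze_references: bool = True,
                         intra_frame_motion: bool = True,
                         include_motion_free: bool = True,
                         ) -> tuple[CScanVolume, GroundTruth]:
    """Simulate the full protocol: references first, then the raster C-scan.

    Frames 0..n_refs-1 are slow-axis reference B-scans at
    ``protocol.ref_positions`` (motion-free by default, matching the
    method's assumption; ``freeze_references=False`` lets motion corrupt
    them).  The remaining n_slow frames are fast-axis B-scans at successive
    y positions with the trace's displacements converted to pixels.  With
    ``intra_frame_motion`` each A-line samples the motion at its own
    acquisition time, so displacement varies across a frame.

    Lateral origin convention: the lateral displacement at the first fast
    frame's start time is subtracted from the whole lateral trace — the
    first B-scan defines the lateral coordinate origin the compensation
    aligns to (it has no absolute lateral anchor).
    """
    p = protocol
    total = p.n_refs + p.n_slow
    if len(motion) < total:
        raise FormatError(
            f"motion trace has {len(motion)} frames, protocol needs {total}"
        )
    surface.validate(p.n_fast, p.n_slow, p.n_depth, margin=0)
    rate = p.bscan_rate_hz
    lat0 = float(motion.lateral_at(p.n_refs / rate))

    def frame_offsets(global_index: int, n_cols: int):
        t0 = global_index / rate
        if intra_frame_motion:
            times = t0 + np.arange(n_cols) / (n_cols * rate)
        else:
            times = np.full(n_cols, t0)
        ax_px = motion.axial_at(times) / p.axial_pitch_um
        lat_px = (motion.lateral_at(times) - lat0) / p.fast_pitch_um
        return ax_px, lat_px

    ref_bscans = []
    for i, x_r in enumerate(p.ref_positions):
        if freeze_references:
            offs = (0.0, 0.0)
        else:
            offs = frame_offsets(i, p.n_slow)
        ref_bscans.append(
            render_bscan(surface, "slow", x_r, p.n_slow, p.n_depth,
                         offsets=offs, noise=noise, seed=[seed, i], index=i)
        )
    references = ReferenceSet(ref_bscans=ref_bscans, ref_x=p.ref_positions)

    bscans = []
    still_bscans = [] if include_motion_free else None
    axial_px = np.zeros((p.n_slow, p.n_fast))
    lateral_px = np.zeros((p.n_slow, p.n_fast))
    for t in range(p.n_slow):
        g = p.n_refs + t
        ax_px, lat_px = frame_offsets(g, p.n_fast)
        axial_px[t] = ax_px
        lateral_px[t] = lat_px
        bscans.append(
            render_bscan(surface, "fast", t, p.n_fast, p.n_depth,
                         offsets=(ax_px, lat_px), noise=noise,
                         seed=[seed, g], index=t)
        )
        if still_bscans is not None:
            still_bscans.append(
                render_bscan(surface, "fast", t, p.n_fast, p.n_depth,
                             offsets=(0.0, 0.0), noise=noise,
                             seed=[seed, g], index=t)
            )
    volume = CScanVolume(protocol=p, bscans=bscans, references=references)
    motion_free = None
    if still_bscans is not None:
        motion_free = CScanVolume(protocol=p, bscans=still_bscans,
                                  references=references)
    xs, ys = np.meshgrid(np.arange(p.n_fast), np.arange(p.n_slow))
    truth = GroundTruth(protocol=p, z_true=surface.z(xs, ys),
                        axial_px=axial_px, lateral_px=lateral_px,
                        motion=motion, motion_free=motion_free)
    return volume, truth
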