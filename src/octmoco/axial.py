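"""Axial motion estimation against slow-axis reference planes, and the
full per-volume compensation driver.

For B-scan t at slow position y_t, the surface fit z_t is sampled at the
reference columns x_i^r and compared with each reference plane's surface at
y_t; the offsets a(x_i^r) = z_t(x_i^r) - z_i^r are interpolated by a
polynomial a(x) (quadratic for three references) and subtracted:
f(x) = z_t(x) - a(x).  Image columns shift by the rounded offset; surface
bookkeeping stays at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from octmoco.datamodel import (
    BScan,
    CScanVolume,
    PolynomialSurface,
    ReferenceSet,
    SurfaceTrace,
)
from octmoco.errors import FormatError, MotionRangeError, OctMocoError
from octmoco.lateral import LateralShift, apply_lateral_shift, crop_borders, estimate_lateral_shift
from octmoco.preprocess import PreprocessConfig, preprocess_bscan

__all__ = [
    "AxialMotionModel",
    "MotionEstimate",
    "reference_depths_at",
    "axial_offsets",
    "fit_axial_motion",
    "compensate_axial",
    "fit_reference_surfaces",
    "compensate_volume",
]

_INTERP_TOL = 1e-9


@dataclass(frozen=True)
class AxialMotionModel:
    """Per-B-scan axial motion a(x) = a2 x² + a1 x + a0, in pixels."""

    bscan_index: int
    coeffs: tuple[float, float, float]  # (a0, a1, a2)
    ref_offsets: tuple[float, ...]
    ref_x: tuple[float, ...] = ()

    def __call__(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(x, dtype=float), np.asarray(self.coeffs)
        )

    def as_surface(self, domain: tuple[float, float]) -> PolynomialSurface:
        co = np.asarray(self.coeffs)
        return PolynomialSurface(order=co.size - 1, coeffs=co, domain=domain)


@dataclass
class MotionEstimate:
    """Combined per-B-scan motion estimate and compensation outcome."""

    bscan_index: int
    lateral: Optional[LateralShift] = None
    axial: Optional[AxialMotionModel] = None
    surface: Optional[PolynomialSurface] = None  # compensated fit f(x)
    error: Optional[str] = None


def reference_depths_at(refset: ReferenceSet, y_t: float,
                        extrapolate: bool = False) -> tuple[float, ...]:
    """Evaluate each reference plane's surface fit at slow coordinate y_t."""
    if refset.ref_fits is None:
        raise FormatError("reference set has no surface fits; preprocess it first")
    out = []
    for i, fit in enumerate(refset.ref_fits):
        if not extrapolate and not fit.in_domain(y_t):
            raise FormatError(
                f"slow position {y_t} outside reference {i} fit domain {fit.domain}"
            )
        out.append(float(fit(y_t)))
    return tuple(out)


def axial_offsets(z_t: PolynomialSurface, refset: ReferenceSet, y_t: float,
                  extrapolate: bool = False) -> tuple[float, ...]:
    """a(x_i) = z_t(x_i^r) - z_i^r; positive = surface deeper than reference.

    With ``extrapolate`` the global polynomials are evaluated at the
    reference columns even outside their fitted domains; the pipeline needs
    this when lateral motion pushes a reference column out of the imaged
    window (the fitted quartic extrapolates smoothly a few tens of pixels).
    """
    ref_depths = reference_depths_at(refset, y_t, extrapolate=extrapolate)
    offs = []
    for x_r, z_r in zip(refset.ref_x, ref_depths):
        if not extrapolate and not z_t.in_domain(x_r):
            raise FormatError(
                f"reference column {x_r} outside surface fit domain {z_t.domain}"
            )
        offs.append(float(z_t(x_r)) - z_r)
    return tuple(offs)


def fit_axial_motion(points, bscan_index: int = 0) -> AxialMotionModel:
    """Exact interpolating polynomial through the reference offsets.

    ``points`` is a sequence of (x_i^r, a_i); three points yield the unique
    quadratic, two points the unique line (a2 = 0).  Duplicate x positions
    are rejected.
    """
    pts = [(float(x), float(a)) for x, a in points]
    if len(pts) < 2:
        raise ValueError("need at least two reference points")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size != xs.size:
        raise ValueError(f"duplicate reference x positions: {xs.tolist()}")
    deg = len(pts) - 1
    co = np.polynomial.polynomial.polyfit(xs, ys, deg)
    coeffs = np.zeros(max(3, deg + 1))
    coeffs[: co.size] = co
    model = AxialMotionModel(
        bscan_index=bscan_index,
        coeffs=tuple(coeffs[:3]) if deg <= 2 else tuple(coeffs),
        ref_offsets=tuple(ys),
        ref_x=tuple(xs),
    )
    resid = float(np.max(np.abs(model(xs) - ys)))
    if resid > 1e-6:
        raise ValueError(f"interpolation residual {resid:.3g} too large")
    return model


def compensate_axial(bscan: BScan, z_t: PolynomialSurface, model: AxialMotionModel
                     ) -> tuple[BScan, PolynomialSurface]:
    """Shift every A-line by -round(a(x)); return compensated image and f(x).

    f(x) = z_t(x) - a(x) is kept at full (unrounded) precision.
    """
    n_rows, n_cols = bscan.pixels.shape
    a = model(np.arange(n_cols))
    if not np.all(np.isfinite(a)):
        raise MotionRangeError("axial motion model is non-finite over the frame")
    if np.any(np.abs(a) >= n_rows):
        raise MotionRangeError(
            f"axial motion {np.max(np.abs(a)):.1f} px exceeds imaging depth {n_rows}"
        )
    shifts = np.rint(a).astype(int)
    out = np.zeros_like(bscan.pixels)
    rows = np.arange(n_rows)
    for col in range(n_cols):
        src = rows + shifts[col]
        ok = (src >= 0) & (src < n_rows)
        out[rows[ok], col] = bscan.pixels[src[ok], col]
    f = z_t.minus(model.as_surface(domain=z_t.domain))
    comp = BScan(out, axis_role=bscan.axis_role, index=bscan.index,
                 slow_position=bscan.slow_position)
    return comp, f


def fit_reference_surfaces(refset: ReferenceSet, cfg: PreprocessConfig) -> ReferenceSet:
    """Segment and fit each reference B-scan's surface (as a function of y)."""
    fits = []
    for b in refset.ref_bscans:
        _, fit = preprocess_bscan(b, cfg)
        fits.append(fit)
    return ReferenceSet(ref_bscans=refset.ref_bscans, ref_x=refset.ref_x,
                        ref_fits=fits)


def compensate_volume(volume: CScanVolume,
                      pre_cfg: PreprocessConfig = PreprocessConfig(),
                      search_px: int = 50,
                      crop_px: Optional[int] = None,
                      ) -> tuple[CScanVolume, list[MotionEstimate], dict]:
    """Full pipeline: per B-scan preprocess → lateral → axial, then crop.

    Frames that fail at any stage are passed through uncompensated, recorded
    in their :class:`MotionEstimate` and counted in the report.  The first
    successfully preprocessed B-scan serves as the lateral alignment target.
    """
    if volume.references is None:
        raise FormatError("volume has no reference set; cannot compensate")
    crop = pre_cfg.border_crop if crop_px is None else crop_px
    refset = volume.references
    if refset.ref_fits is None:
        refset = fit_reference_surfaces(refset, pre_cfg)

    target_fit: Optional[PolynomialSurface] = None
    estimates: list[MotionEstimate] = []
    out_bscans: list[BScan] = []
    n_failed = 0
    for b in volume.bscans:
        est = MotionEstimate(bscan_index=b.index)
        try:
            _, fit = preprocess_bscan(b, pre_cfg)
            if target_fit is None:
                target_fit = fit
            shift = estimate_lateral_shift(fit, target_fit, search_px=search_px,
                                           bscan_index=b.index)
            est.lateral = shift
            shifted_img = apply_lateral_shift(b, shift)
            shifted_fit = fit.shifted_arg(shift.shift_px)
            offs = axial_offsets(shifted_fit, refset, y_t=b.slow_position,
                                 extrapolate=True)
            model = fit_axial_motion(list(zip(refset.ref_x, offs)),
                                     bscan_index=b.index)
            est.axial = model
            comp, f = compensate_axial(shifted_img, shifted_fit, model)
            est.surface = f
            out_bscans.append(comp)
        except OctMocoError as exc:
            est.error = str(exc)
            n_failed += 1
            out_bscans.append(b)
        estimates.append(est)

    out = CScanVolume(protocol=volume.protocol, bscans=out_bscans, references=refset)
    out = crop_borders(out, crop)
    report = {
        "n_frames": len(volume.bscans),
        "n_failed": n_failed,
        "failures": [
            {"bscan_index": e.bscan_index, "error": e.error}
            for e in estimates if e.error is not None
        ],
        "crop_px": crop,
        "search_px": search_px,
    }
    return out, estimates, report
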