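"""Per-B-scan segmentation of the anterior corneal surface.

Stages, in order: Gaussian speckle smoothing, mean-line saturation removal,
local-mean adaptive thresholding, largest-connected-component selection,
initial (shallowest-pixel) surface extraction, gradient-image refinement and
higher-order polynomial fitting.

All convolutions use replicate (edge) padding and are defined as
cross-correlations; every kernel used here is either symmetric or squared,
so orientation conventions do not leak into results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from octmoco.datamodel import BScan, PolynomialSurface, SurfaceTrace
from octmoco.errors import FormatError, NoSurfaceError, StageError

__all__ = [
    "PreprocessConfig",
    "GradientImage",
    "gaussian_smooth",
    "remove_saturation",
    "adaptive_threshold",
    "largest_component",
    "initial_surface",
    "gradient_image",
    "refine_surface",
    "fit_surface",
    "preprocess_bscan",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the segmentation pipeline.

    ``min_contrast`` is a surface sanity check not part of the core
    algorithm: the selected component's mean raw intensity must exceed
    ``min_contrast`` times the image mean, otherwise "no surface found" is
    raised (guards against pure-noise frames, where thresholding plus
    connected components would otherwise select an arbitrary noise blob).
    """

    gauss_size: int = 10
    gauss_sigma: float = 4.0
    mean_filter_len: int = 40
    refine_window: int = 15
    fit_order: int = 4
    threshold_window: int = 64
    threshold_offset: float = 0.0
    threshold_floor: float = 0.02
    border_crop: int = 50
    gradient_sqrt: bool = False
    gradient_kernels: str = "axial"  # or "printed" (transposed) kernels
    min_contrast: float = 2.0

    def __post_init__(self):
        for name in ("gauss_size", "mean_filter_len", "threshold_window", "border_crop"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0) and not (name == "border_crop" and v == 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not 2 <= self.fit_order <= 6:
            raise ValueError(f"fit_order must be in [2, 6], got {self.fit_order}")
        if self.refine_window < 1:
            raise ValueError(f"refine_window must be >= 1, got {self.refine_window}")
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be > 0")


@dataclass
class GradientImage:
    """Squared-gradient magnitude image (Sobel² + Prewitt²)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("gradient image must be 2D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise FormatError("gradient values must be finite and non-negative")


def _as_2d(image) -> np.ndarray:
    if isinstance(image, BScan):
        image = image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise FormatError("image contains non-finite values")
    return arr


def correlate2d_replicate(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dense 2D cross-correlation with replicate padding, same-size output.

    For a kernel of size (kh, kw) the anchor is (floor((kh-1)/2),
    floor((kw-1)/2)); even sizes therefore extend one tap further toward
    larger indices.  This exact definition is what the brute-force oracle
    tests pin down.
    """
    kh, kw = kernel.shape
    ah, aw = (kh - 1) // 2, (kw - 1) // 2
    padded = np.pad(image, ((ah, kh - 1 - ah), (aw, kw - 1 - aw)), mode="edge")
    windows = sliding_window_view(padded, (kh, kw))
    return np.tensordot(windows, kernel, axes=([2, 3], [0, 1]))


def _correlate1d_replicate(arr: np.ndarray, weights: np.ndarray, axis: int
                           ) -> np.ndarray:
    """1D correlation along ``axis`` matching :func:`correlate2d_replicate`'s
    anchor convention ((len-1)//2, i.e. one tap earlier than ndimage's
    default for even lengths)."""
    weights = np.asarray(weights, dtype=float)
    origin = -1 if weights.size % 2 == 0 else 0
    return ndimage.correlate1d(arr, weights, axis=axis, mode="nearest",
                               origin=origin)


def gaussian_kernel2d(size: int, sigma: float) -> np.ndarray:
    """size×size sampled Gaussian, unit sum, symmetric around the grid center.

    For even sizes samples sit at half-integer offsets (±0.5, ±1.5, ...).
    """
    offs = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(offs**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def gaussian_smooth(image, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Smooth speckle with the cfg.gauss_size² Gaussian (σ = cfg.gauss_sigma).

    The outer-product kernel is applied as two separable 1D passes; with
    replicate padding this equals the dense 2D correlation exactly (index
    clamping acts per axis), which the brute-force oracle test pins down.
    """
    arr = _as_2d(image)
    offs = np.arange(cfg.gauss_size) - (cfg.gauss_size - 1) / 2.0
    g = np.exp(-(offs**2) / (2.0 * cfg.gauss_sigma**2))
    g = g / g.sum()
    return _correlate1d_replicate(_correlate1d_replicate(arr, g, axis=0), g, axis=1)


def remove_saturation(smoothed, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Mean-line subtraction: I = Ig - Ig * A, A = axial averaging filter.

    A has ``cfg.mean_filter_len`` taps of 1/len along the depth (row) axis;
    a depth-constant saturation stripe in a column is therefore removed
    exactly.  Output may be negative (kept as-is for thresholding).
    """
    arr = _as_2d(smoothed)
    n = cfg.mean_filter_len
    if arr.shape[0] < n:
        raise FormatError(
            f"image depth {arr.shape[0]} shorter than mean filter length {n}"
        )
    return arr - _axis_local_mean(arr, n, axis=0)


def _axis_local_mean(arr: np.ndarray, size: int, axis: int) -> np.ndarray:
    return _correlate1d_replicate(arr, np.full(size, 1.0 / size), axis)


def adaptive_threshold(image, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Local-mean (Bradley-style) binarization.

    A pixel is foreground iff its value strictly exceeds
    ``max(local_mean, 0) * (1 + threshold_offset) + threshold_floor * range``
    where ``local_mean`` is the mean over the pixel's replicate-padded
    ``threshold_window``² neighborhood and ``range`` is the image dynamic
    range.  The mean-line subtraction stage hands this stage a zero-mean
    background with a negative shadow under the surface band; the clamp at
    zero and the small floor keep that shadow's surroundings (and noise
    percolation) out of the foreground so the surface band is the largest
    bright component.  With ``threshold_floor=0`` the comparison reduces to
    the plain scaled local mean.  The square-window local mean is computed
    separably (exact, since replicate padding clamps indices per axis).
    """
    arr = _as_2d(image)
    w = cfg.threshold_window
    if w > min(arr.shape):
        raise FormatError(
            f"threshold window {w} larger than image {arr.shape}"
        )
    local_mean = _axis_local_mean(_axis_local_mean(arr, w, axis=0), w, axis=1)
    span = float(arr.max() - arr.min())
    # scale-relative tolerance: regions constant up to floating-point dust
    # must stay background (their values equal the local mean)
    tol = max(cfg.threshold_floor * span, 1e-9 * span)
    thresh = np.maximum(local_mean, 0.0) * (1.0 + cfg.threshold_offset) + tol
    return arr > thresh


_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def largest_component(mask: np.ndarray, source: np.ndarray | None = None) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties on pixel count are broken by the component containing the brightest
    ``source`` pixel (when given), then by smallest top-left coordinate.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        raise NoSurfaceError("no surface found: empty foreground mask")
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best = np.flatnonzero(counts == counts.max()) + 1
    if best.size > 1 and source is not None:
        src = np.asarray(source, dtype=float)
        peak = [src[labels == lab].max() for lab in best]
        best = best[np.flatnonzero(peak == np.max(peak))]
    if best.size > 1:
        # smallest top-left coordinate in row-major scan order
        flat = labels.ravel()
        firsts = [np.argmax(flat == lab) for lab in best]
        best = best[[int(np.argmin(firsts))]]
    return labels == best[0]


def initial_surface(component: np.ndarray) -> SurfaceTrace:
    """Shallowest foreground row per column; gaps linearly interpolated.

    Columns without any foreground pixel are flagged invalid and filled by
    linear interpolation between valid neighbors (edge columns take the
    nearest valid value).
    """
    component = np.asarray(component, dtype=bool)
    any_fg = component.any(axis=0)
    if not any_fg.any():
        raise NoSurfaceError("no surface found: component has no valid column")
    depths = np.where(any_fg, component.argmax(axis=0), np.nan).astype(float)
    cols = np.arange(component.shape[1])
    valid = any_fg.copy()
    if not valid.all():
        depths[~valid] = np.interp(cols[~valid], cols[valid], depths[valid])
    return SurfaceTrace(depths=depths, valid=valid)


_SOBEL = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)
_PREWITT = np.array([[1, 1, 1], [0, 0, 0], [-1, -1, -1]], dtype=float)


def gradient_image(raw, cfg: PreprocessConfig = PreprocessConfig()) -> GradientImage:
    """F = (S * I0)² + (P * I0)² with Sobel and Prewitt kernels.

    ``cfg.gradient_kernels`` selects the kernel orientation: "axial"
    (default) differentiates along depth, so F peaks on the tissue
    boundary and the refinement stage can snap the trace onto it;
    "printed" applies the transposed kernels instead, which respond only
    to lateral intensity changes (refinement then mostly keeps the initial
    trace via its tie rule).  No square root by default
    (``cfg.gradient_sqrt`` switches it on); refinement only ranks pixels,
    so either convention selects the same rows.
    """
    arr = _as_2d(raw)
    s_k, p_k = _SOBEL, _PREWITT
    if cfg.gradient_kernels == "printed":
        s_k, p_k = _SOBEL.T, _PREWITT.T
    elif cfg.gradient_kernels != "axial":
        raise ValueError(
            f"gradient_kernels must be 'axial' or 'printed', got "
            f"{cfg.gradient_kernels!r}"
        )
    s = correlate2d_replicate(arr, s_k)
    p = correlate2d_replicate(arr, p_k)
    f = s * s + p * p
    if cfg.gradient_sqrt:
        f = np.sqrt(f)
    return GradientImage(values=f)


def refine_surface(trace: SurfaceTrace, grad: GradientImage,
                   cfg: PreprocessConfig = PreprocessConfig()) -> SurfaceTrace:
    """Snap each column's depth to the strongest gradient within ±refine_window.

    The search window is clipped to image bounds.  Ties pick the row closest
    to the initial depth, then the shallower row.
    """
    F = grad.values
    n_rows, n_cols = F.shape
    if len(trace) != n_cols:
        raise FormatError(
            f"trace has {len(trace)} columns, gradient image has {n_cols}"
        )
    w = cfg.refine_window
    out = np.empty(n_cols)
    for col in range(n_cols):
        z0 = int(round(trace.depths[col]))
        lo = max(0, z0 - w)
        hi = min(n_rows, z0 + w + 1)
        window = F[lo:hi, col]
        best_val = window.max()
        rows = lo + np.flatnonzero(window == best_val)
        # tie-break: nearest to initial depth, then shallowest
        dist = np.abs(rows - z0)
        rows = rows[dist == dist.min()]
        out[col] = rows.min()
    return SurfaceTrace(depths=out, valid=trace.valid.copy())


def fit_surface(trace: SurfaceTrace, order: int = 4) -> PolynomialSurface:
    """Least-squares polynomial fit of the valid trace columns.

    Solves the Vandermonde system V P = Z in the least-squares sense.
    Columns are rescaled to [-1, 1] internally for conditioning; reported
    coefficients are in original pixel-column coordinates.
    """
    x = np.flatnonzero(trace.valid).astype(float)
    z = trace.depths[trace.valid]
    if np.unique(x).size < order + 1:
        raise FormatError(
            f"need at least {order + 1} distinct valid columns for order {order}, "
            f"have {np.unique(x).size}"
        )
    fit = np.polynomial.Polynomial.fit(x, z, deg=order)
    co = fit.convert().coef
    coeffs = np.zeros(order + 1)
    coeffs[: co.size] = co
    return PolynomialSurface(order=order, coeffs=coeffs,
                             domain=(float(x.min()), float(x.max())))


def preprocess_bscan(bscan, cfg: PreprocessConfig = PreprocessConfig()
                     ) -> tuple[SurfaceTrace, PolynomialSurface]:
    """Run the full segmentation chain on one B-scan.

    Returns the gradient-refined surface trace and its order-``cfg.fit_order``
    polynomial fit.  Stage failures are re-raised as :class:`StageError`
    naming the stage; a frame with no detectable surface raises
    :class:`NoSurfaceError`.
    """
    raw = _as_2d(bscan)
    stage = "gaussian_smooth"
    try:
        smoothed = gaussian_smooth(raw, cfg)
        stage = "remove_saturation"
        satfree = remove_saturation(smoothed, cfg)
        stage = "adaptive_threshold"
        mask = adaptive_threshold(satfree, cfg)
        stage = "largest_component"
        component = largest_component(mask, source=satfree)
        # sanity: the selected blob must be brighter than the typical
        # (median) pixel, otherwise we are looking at structureless noise;
        # the median is robust to the band itself and to saturation stripes
        comp_mean = raw[component].mean()
        background = float(np.median(raw))
        if background > 0 and comp_mean < cfg.min_contrast * background:
            raise NoSurfaceError(
                "no surface found: selected component is not brighter than "
                f"background (contrast {comp_mean / background:.2f} < "
                f"{cfg.min_contrast})"
            )
        stage = "initial_surface"
        trace = initial_surface(component)
        stage = "gradient_image"
        grad = gradient_image(raw, cfg)
        stage = "refine_surface"
        refined = refine_surface(trace, grad, cfg)
        stage = "fit_surface"
        fit = fit_surface(refined, order=cfg.fit_order)
    except NoSurfaceError:
        raise
    except (FormatError, ValueError) as exc:
        raise StageError(stage, str(exc)) from exc
    return refined, fit
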