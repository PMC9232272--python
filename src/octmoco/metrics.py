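"""Evaluation: surface error, motion amplitude/spectrum, polynomial-order sweeps.

Note on naming: the headline error metric is the mean absolute per-A-scan
surface difference (MAE).  The true root-mean-square error is computed
alongside; reports state which definition each number uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from octmoco.datamodel import PolynomialSurface, SurfaceTrace
from octmoco.errors import FormatError
from octmoco.preprocess import fit_surface

__all__ = [
    "EvalReport",
    "surface_error",
    "surfaces_to_grid",
    "motion_spectrum",
    "energy_fraction_below",
    "order_sweep",
]


@dataclass
class EvalReport:
    mae_um: float
    rmse_um: float
    per_frame: list  # [{"frame": i, "mae_um": ..., "rmse_um": ...}, ...]
    n_frames: int
    n_columns: int
    metric_note: str = (
        "mae_um is the mean absolute per-A-scan surface difference "
        "(the headline metric); rmse_um is the true root-mean-square."
    )

    def __post_init__(self):
        if self.mae_um < 0 or self.rmse_um < 0:
            raise ValueError("error metrics must be >= 0")
        if self.mae_um > self.rmse_um + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")

    def to_dict(self) -> dict:
        return {
            "mae_um": self.mae_um,
            "rmse_um": self.rmse_um,
            "n_frames": self.n_frames,
            "n_columns": self.n_columns,
            "per_frame": self.per_frame,
            "metric_note": self.metric_note,
        }


def surfaces_to_grid(surfaces, columns) -> np.ndarray:
    """Evaluate a list of per-frame surfaces at the given columns.

    Accepts :class:`PolynomialSurface` (evaluated), :class:`SurfaceTrace`
    (indexed) or plain per-column arrays.
    """
    columns = np.asarray(columns)
    rows = []
    for s in surfaces:
        if isinstance(s, PolynomialSurface):
            rows.append(s(columns))
        elif isinstance(s, SurfaceTrace):
            rows.append(s.depths[columns])
        else:
            rows.append(np.asarray(s, dtype=float)[columns])
    return np.vstack(rows)


def surface_error(test: np.ndarray, reference: np.ndarray,
                  axial_pitch_um: float = 3.6) -> EvalReport:
    """Per-A-scan surface error between two (n_frames, n_cols) depth grids.

    Depths are in pixels; errors are reported in micrometers.  Symmetric in
    its two arguments.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape or test.ndim != 2:
        raise FormatError(
            f"surface grids must share a 2D shape, got {test.shape} vs "
            f"{reference.shape}"
        )
    diff_um = np.abs(test - reference) * axial_pitch_um
    per_frame = [
        {"frame": i,
         "mae_um": float(np.mean(d)),
         "rmse_um": float(np.sqrt(np.mean(d**2)))}
        for i, d in enumerate(diff_um)
    ]
    return EvalReport(
        mae_um=float(np.mean(diff_um)),
        rmse_um=float(np.sqrt(np.mean(diff_um**2))),
        per_frame=per_frame,
        n_frames=test.shape[0],
        n_columns=test.shape[1],
    )


def motion_spectrum(axial_um, lateral_um=None, rate_hz: float = None) -> dict:
    """Mean inter-frame steps and one-sided DFT amplitude spectra.

    Accepts either (MotionTrace, rate_hz=...) or two per-frame displacement
    arrays plus the frame rate.  The mean of each trace is removed before
    the transform, so the reported energy is AC-only.  Frequencies in Hz.
    """
    if hasattr(axial_um, "axial_um"):  # a MotionTrace-like object
        trace = axial_um
        if rate_hz is None:
            dt = np.diff(np.asarray(trace.times))
            rate_hz = 1.0 / float(dt[0])
        lateral_um = trace.lateral_um
        axial_um = trace.axial_um
    if rate_hz is None:
        raise ValueError("rate_hz is required with plain arrays")
    axial = np.asarray(axial_um, dtype=float)
    lateral = np.asarray(lateral_um, dtype=float)
    if axial.size < 8 or lateral.size < 8:
        raise FormatError("need at least 8 frames for a spectrum")
    if axial.size != lateral.size:
        raise FormatError("axial and lateral traces must have equal length")
    n = axial.size
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    out = {
        "freqs_hz": freqs,
        "mean_step_axial_um": float(np.mean(np.abs(np.diff(axial)))),
        "mean_step_lateral_um": float(np.mean(np.abs(np.diff(lateral)))),
        "n_frames": n,
        "rate_hz": rate_hz,
    }
    for name, trace in (("axial", axial), ("lateral", lateral)):
        spec = np.abs(np.fft.rfft(trace - trace.mean())) / n
        out[f"{name}_amplitude"] = spec
    return out


def energy_fraction_below(spectrum: dict, cutoff_hz: float, which: str = "axial"
                          ) -> float:
    """Fraction of AC spectral energy strictly below ``cutoff_hz``."""
    amp = np.asarray(spectrum[f"{which}_amplitude"], dtype=float)
    freqs = np.asarray(spectrum["freqs_hz"], dtype=float)
    energy = amp**2
    total = energy.sum()
    if total == 0:
        return 1.0
    return float(energy[freqs < cutoff_hz].sum() / total)


def order_sweep(traces_with_truth, orders=range(2, 7),
                axial_pitch_um: float = 3.6) -> dict:
    """Fit each trace at every order and score RMSE against ground truth.

    ``traces_with_truth`` is a sequence of (SurfaceTrace, truth_depths_px)
    pairs; truth is evaluated over the trace's valid columns.  Returns
    {order: rmse_um averaged over traces}.
    """
    out = {}
    for order in orders:
        errs = []
        for trace, truth in traces_with_truth:
            truth = np.asarray(truth, dtype=float)
            if truth.size != len(trace):
                raise FormatError("truth length does not match trace")
            fit = fit_surface(trace, order=order)
            cols = np.flatnonzero(trace.valid)
            d = (fit(cols) - truth[cols]) * axial_pitch_um
            errs.append(np.sqrt(np.mean(d**2)))
        out[int(order)] = float(np.mean(errs))
    return out
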