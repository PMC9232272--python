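"""Core types, coordinate conventions and file I/O shared by all stages.

Coordinate conventions (global, enforced by the readers):

- B-scan pixel grids are depth-major: row 0 is the shallowest depth (z
  increases downward), columns run along the lateral scan direction
  (x for fast-axis B-scans, y for slow-axis reference B-scans).
- All indices are 0-based and intervals half-open.  Depths are stored in
  pixels everywhere; conversion to micrometers happens only in reports.
- Volumes are multi-page TIFF files, one page per B-scan, reference pages
  first, with a JSON/YAML sidecar describing the scan protocol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from octmoco.errors import FormatError

__all__ = [
    "ScanProtocol",
    "BScan",
    "CScanVolume",
    "SurfaceTrace",
    "PolynomialSurface",
    "ReferenceSet",
    "default_ref_positions",
    "read_volume",
    "write_volume",
    "read_protocol",
    "write_protocol",
    "write_surface_csv",
    "read_surface_csv",
    "write_report_json",
    "read_report_json",
]

#: Keys of the protocol sidecar file, in canonical order.
PROTOCOL_KEYS = (
    "n_depth",
    "n_fast",
    "n_slow",
    "axial_pitch_um",
    "fast_pitch_um",
    "slow_pitch_um",
    "bscan_rate_hz",
    "n_refs",
    "alpha",
    "ref_positions",
)


def default_ref_positions(n_fast: int, n_refs: int, alpha: float) -> tuple[int, ...]:
    """Default fast-axis column indices for ``n_refs`` reference planes.

    For three planes the outer planes sit at ``(1/2 ∓ alpha) * m`` around the
    central column (``m = n_fast - 1``).  For any other count the planes are
    evenly distributed at ``(2i - 1) * n_fast / (2 t)``, the spacing rule that
    minimizes the placement error (see :mod:`octmoco.refplan`).
    """
    m = n_fast - 1
    if n_refs == 3:
        xs = [(0.5 - alpha) * m, 0.5 * m, (0.5 + alpha) * m]
    else:
        xs = [(2 * i - 1) * n_fast / (2 * n_refs) for i in range(1, n_refs + 1)]
    pos = tuple(int(round(x)) for x in xs)
    if len(set(pos)) != len(pos):
        raise ValueError(f"degenerate reference positions {pos} for n_fast={n_fast}")
    return pos


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition geometry of one motion-compensated C-scan.

    ``n_refs`` slow-axis reference B-scans are acquired first, then
    ``n_slow`` fast-axis B-scans of ``n_fast`` A-lines each, ``n_depth``
    pixels deep.  ``alpha`` is the ratio d/L between adjacent-reference
    spacing and B-scan width.
    """

    n_depth: int = 1024
    n_fast: int = 1024
    n_slow: int = 512
    axial_pitch_um: float = 3.6
    fast_pitch_um: float = 10000.0 / 1024
    slow_pitch_um: float = 11000.0 / 512
    bscan_rate_hz: float = 100.0
    n_refs: int = 3
    alpha: float = 0.33
    ref_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_refs < 2:
            raise ValueError(f"n_refs must be >= 2, got {self.n_refs}")
        if not 0.0 < self.alpha <= 0.5:
            raise ValueError(f"alpha must be in (0, 0.5], got {self.alpha}")
        for name in ("axial_pitch_um", "fast_pitch_um", "slow_pitch_um", "bscan_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.ref_positions:
            object.__setattr__(
                self,
                "ref_positions",
                default_ref_positions(self.n_fast, self.n_refs, self.alpha),
            )
        pos = tuple(int(p) for p in self.ref_positions)
        object.__setattr__(self, "ref_positions", pos)
        if len(pos) != self.n_refs:
            raise ValueError(
                f"ref_positions has {len(pos)} entries, expected n_refs={self.n_refs}"
            )
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"ref_positions must be strictly increasing, got {pos}")
        if pos[0] < 0 or pos[-1] > self.n_fast - 1:
            raise ValueError(f"ref_positions {pos} outside [0, {self.n_fast - 1}]")
        if self.n_refs % 2 == 1:
            mid = pos[self.n_refs // 2]
            if abs(mid - (self.n_fast - 1) / 2) > 1.0:
                raise ValueError(
                    f"middle reference at {mid}, expected center column "
                    f"{(self.n_fast - 1) / 2:.1f} (±1 px)"
                )

    @property
    def width_um(self) -> float:
        """Physical fast-axis B-scan width L in micrometers."""
        return self.n_fast * self.fast_pitch_um

    def frame_times(self, n_frames: int) -> np.ndarray:
        """Acquisition start times (s) of ``n_frames`` consecutive B-scans."""
        return np.arange(n_frames) / self.bscan_rate_hz

    def to_dict(self) -> dict:
        return {
            "n_depth": self.n_depth,
            "n_fast": self.n_fast,
            "n_slow": self.n_slow,
            "axial_pitch_um": self.axial_pitch_um,
            "fast_pitch_um": self.fast_pitch_um,
            "slow_pitch_um": self.slow_pitch_um,
            "bscan_rate_hz": self.bscan_rate_hz,
            "n_refs": self.n_refs,
            "alpha": self.alpha,
            "ref_positions": list(self.ref_positions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        unknown = set(d) - set(PROTOCOL_KEYS)
        if unknown:
            raise FormatError(f"unknown protocol keys: {sorted(unknown)}")
        kw = dict(d)
        if "ref_positions" in kw and kw["ref_positions"] is not None:
            kw["ref_positions"] = tuple(int(p) for p in kw["ref_positions"])
        return cls(**kw)


@dataclass
class BScan:
    """One 2D OCT frame: rows = depth (z, downward), columns = lateral."""

    pixels: np.ndarray
    axis_role: str = "fast"  # "fast" (sweeps x) or "slow" (sweeps y, reference)
    index: int = 0
    slow_position: int = 0  # y index of a fast B-scan; x column of a reference

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"B-scan pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("B-scan contains non-finite intensities")
        if self.axis_role not in ("fast", "slow"):
            raise ValueError(f"axis_role must be 'fast' or 'slow', got {self.axis_role!r}")
        if self.index < 0:
            raise ValueError(f"B-scan index must be >= 0, got {self.index}")

    @property
    def n_depth(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SurfaceTrace:
    """Per-column detected surface depth (fractional pixels) with validity mask."""

    depths: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depths.shape != self.valid.shape or self.depths.ndim != 1:
            raise FormatError("depths and valid must be 1D arrays of equal length")
        if not np.all(np.isfinite(self.depths[self.valid])):
            raise FormatError("valid surface depths must be finite")

    def __len__(self) -> int:
        return self.depths.size


@dataclass
class PolynomialSurface:
    """Order-n polynomial surface z(x) = p_{n+1} x^n + ... + p_2 x + p_1.

    ``coeffs`` are stored in ascending order (p_1 first, constant term),
    in original pixel-column coordinates over the half-open ``domain``.
    """

    order: int
    coeffs: np.ndarray  # ascending: coeffs[k] multiplies x**k
    domain: tuple[float, float]

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != self.order + 1:
            raise FormatError(
                f"expected {self.order + 1} coefficients for order {self.order}, "
                f"got {self.coeffs.size}"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise FormatError("polynomial coefficients must be finite")

    def __call__(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coeffs)

    def in_domain(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.domain[0]) & (x <= self.domain[1])

    def shifted_arg(self, dx: float) -> "PolynomialSurface":
        """Return q with q(x) = self(x + dx); domain translated accordingly."""
        # compose with x + dx via numpy polynomial arithmetic
        base = np.polynomial.Polynomial(self.coeffs)
        shifted = base(np.polynomial.Polynomial([dx, 1.0]))
        co = np.zeros(self.order + 1)
        co[: shifted.coef.size] = shifted.coef
        return PolynomialSurface(
            order=self.order,
            coeffs=co,
            domain=(self.domain[0] - dx, self.domain[1] - dx),
        )

    def minus(self, other: "PolynomialSurface") -> "PolynomialSurface":
        """Pointwise difference self - other as a polynomial surface."""
        n = max(self.order, other.order)
        a = np.zeros(n + 1)
        b = np.zeros(n + 1)
        a[: self.coeffs.size] = self.coeffs
        b[: other.coeffs.size] = other.coeffs
        lo = max(self.domain[0], other.domain[0])
        hi = min(self.domain[1], other.domain[1])
        return PolynomialSurface(order=n, coeffs=a - b, domain=(lo, hi))


@dataclass
class ReferenceSet:
    """The slow-axis reference B-scans with their surface fits.

    ``ref_fits`` are polynomials in the slow-axis coordinate y (None until
    computed by preprocessing); ``ref_x`` are the fast-axis column indices
    the reference planes intersect.
    """

    ref_bscans: list
    ref_x: tuple[int, ...]
    ref_fits: Optional[list] = None

    def __post_init__(self):
        self.ref_x = tuple(int(x) for x in self.ref_x)
        if len(self.ref_bscans) != len(self.ref_x):
            raise FormatError("ref_bscans and ref_x counts differ")
        if self.ref_fits is not None and len(self.ref_fits) != len(self.ref_x):
            raise FormatError("ref_fits count does not match ref_x")

    @property
    def n_refs(self) -> int:
        return len(self.ref_x)


@dataclass
class CScanVolume:
    """Ordered stack of fast-axis B-scans plus optional reference set."""

    protocol: ScanProtocol
    bscans: list
    references: Optional[ReferenceSet] = None

    def __post_init__(self):
        if len(self.bscans) != self.protocol.n_slow:
            raise FormatError(
                f"volume has {len(self.bscans)} B-scans, protocol expects "
                f"n_slow={self.protocol.n_slow}"
            )
        shape = (self.protocol.n_depth, self.protocol.n_fast)
        for b in self.bscans:
            if b.pixels.shape != shape:
                raise FormatError(
                    f"B-scan {b.index} shape {b.pixels.shape} != protocol {shape}"
                )
        if self.references is not None:
            if self.references.n_refs != self.protocol.n_refs:
                raise FormatError("reference count does not match protocol n_refs")
            if tuple(self.references.ref_x) != tuple(self.protocol.ref_positions):
                raise FormatError("reference ref_x does not match protocol.ref_positions")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_protocol(protocol: ScanProtocol, path) -> None:
    path = Path(path)
    d = protocol.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def read_protocol(path) -> ScanProtocol:
    text = Path(path).read_text()
    return ScanProtocol.from_dict(yaml.safe_load(text))


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_volume(volume: CScanVolume, path, include_references: bool = True) -> None:
    """Write a volume as a multi-page TIFF plus a JSON protocol sidecar.

    Reference pages (when present) come first, then fast-axis B-scans in
    acquisition order.  Integer input arrays round-trip bit-exactly; float
    input is stored as float32.
    """
    path = Path(path)
    refs = volume.references if include_references else None
    pages = (list(refs.ref_bscans) if refs is not None else []) + list(volume.bscans)
    with tifffile.TiffWriter(path) as tw:
        for b in pages:
            px = b.pixels
            if px.dtype.kind == "f":
                px = px.astype(np.float32)
            tw.write(px, contiguous=False)
    sidecar = {
        "protocol": volume.protocol.to_dict(),
        "has_references": refs is not None,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_volume(path, protocol: Optional[ScanProtocol] = None) -> CScanVolume:
    """Read a multi-page TIFF volume written by :func:`write_volume`.

    If ``protocol`` is None the JSON sidecar next to the TIFF is required.
    The first ``n_refs`` pages are split into a :class:`ReferenceSet` when
    the sidecar flags them (or when the page count is n_slow + n_refs).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    has_refs = None
    if protocol is None:
        sc = _sidecar_path(path)
        if not sc.exists():
            raise FormatError(f"no protocol given and no sidecar at {sc}")
        meta = json.loads(sc.read_text())
        protocol = ScanProtocol.from_dict(meta["protocol"])
        has_refs = bool(meta.get("has_references", False))
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
    except Exception as exc:  # pragma: no cover - tifffile internal failures
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if has_refs is None:
        has_refs = len(pages) == protocol.n_slow + protocol.n_refs
    n_ref_pages = protocol.n_refs if has_refs else 0
    if len(pages) != protocol.n_slow + n_ref_pages:
        raise FormatError(
            f"{path} has {len(pages)} pages, protocol expects "
            f"{protocol.n_slow + n_ref_pages}"
        )
    references = None
    if has_refs:
        ref_bscans = []
        for i in range(protocol.n_refs):
            px = pages[i]
            if px.shape[0] != protocol.n_depth:
                raise FormatError(
                    f"reference page {i} depth {px.shape[0]} != n_depth={protocol.n_depth}"
                )
            ref_bscans.append(
                BScan(px, axis_role="slow", index=i,
                      slow_position=protocol.ref_positions[i])
            )
        references = ReferenceSet(ref_bscans, protocol.ref_positions)
    bscans = []
    for t, px in enumerate(pages[n_ref_pages:]):
        if px.shape != (protocol.n_depth, protocol.n_fast):
            raise FormatError(
                f"fast page {t} shape {px.shape} != "
                f"({protocol.n_depth}, {protocol.n_fast})"
            )
        bscans.append(BScan(px, axis_role="fast", index=t, slow_position=t))
    return CScanVolume(protocol=protocol, bscans=bscans, references=references)


SURFACE_CSV_COLUMNS = ["bscan_index", "column", "depth_px", "depth_um", "valid"]


def write_surface_csv(traces: Sequence[tuple[int, SurfaceTrace]], path,
                      axial_pitch_um: float = 3.6) -> None:
    """Write (bscan_index, SurfaceTrace) pairs as one long-format CSV."""
    rows = []
    for idx, trace in traces:
        for col in range(len(trace)):
            rows.append(
                (idx, col, trace.depths[col],
                 trace.depths[col] * axial_pitch_um, bool(trace.valid[col]))
            )
    df = pd.DataFrame(rows, columns=SURFACE_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_surface_csv(path) -> list[tuple[int, SurfaceTrace]]:
    df = pd.read_csv(path)
    missing = set(SURFACE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"surface CSV missing columns: {sorted(missing)}")
    out = []
    for idx, grp in df.groupby("bscan_index", sort=True):
        grp = grp.sort_values("column")
        out.append(
            (int(idx), SurfaceTrace(grp["depth_px"].to_numpy(),
                                    grp["valid"].to_numpy(dtype=bool)))
        )
    return out


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, cls=_NumpyJSONEncoder))


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())
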