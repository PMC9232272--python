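"""Lateral (fast-axis) motion estimation and removal.

Each B-scan's fitted surface polynomial is compared with the first B-scan's
surface; the integer shift minimizing the variance of the absolute surface
difference over the overlapping columns is the estimated lateral motion.

Sign convention: positive ``shift_px`` means the sample moved toward +x
between frame 1 and frame t, i.e. z_t(x + shift) re-aligns with z_1(x);
compensation translates the frame's columns by -shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from octmoco.datamodel import BScan, CScanVolume, PolynomialSurface, ScanProtocol
from octmoco.errors import FormatError, MotionRangeError

__all__ = [
    "LateralShift",
    "estimate_lateral_shift",
    "apply_lateral_shift",
    "crop_borders",
]

MIN_OVERLAP_COLUMNS = 10


@dataclass(frozen=True)
class LateralShift:
    bscan_index: int
    shift_px: int
    cost: float

    def __post_init__(self):
        if self.cost < 0:
            raise ValueError("cost must be >= 0")


def estimate_lateral_shift(z_t: PolynomialSurface, z_1: PolynomialSurface,
                           search_px: int = 50, bscan_index: int = 0) -> LateralShift:
    """Exhaustive integer-shift variance minimization.

    For every candidate shift dl in [-search_px, +search_px] the cost
    var(|z_t(x + dl) - z_1(x)|) is evaluated at all integer x where both
    polynomial arguments lie inside their fitted domains.  Shifts whose
    overlap is below ``MIN_OVERLAP_COLUMNS`` are skipped; ties prefer the
    smallest |dl|, then the negative one.
    """
    if search_px < 0:
        raise ValueError("search_px must be >= 0")
    x_all = np.arange(int(np.floor(min(z_1.domain[0], z_t.domain[0]) - search_px)),
                      int(np.ceil(max(z_1.domain[1], z_t.domain[1]) + search_px)) + 1)
    # visit shifts in tie-break preference order: 0, -1, +1, -2, +2, ...
    order = [0]
    for k in range(1, search_px + 1):
        order.extend([-k, k])
    found = False
    best_cost = np.inf
    best_shift = 0
    for dl in order:
        xs = x_all[z_1.in_domain(x_all) & z_t.in_domain(x_all + dl)]
        if xs.size < MIN_OVERLAP_COLUMNS:
            continue
        diff = np.abs(z_t(xs + dl) - z_1(xs))
        cost = float(np.var(diff))
        # strict < keeps the first-visited shift on ties, i.e. the
        # tie-break preference encoded in the visit order
        if not found or cost < best_cost:
            best_cost = cost
            best_shift = dl
            found = True
    if not found:
        raise MotionRangeError(
            f"no candidate shift in ±{search_px} px has at least "
            f"{MIN_OVERLAP_COLUMNS} overlapping columns"
        )
    return LateralShift(bscan_index=bscan_index, shift_px=int(best_shift),
                        cost=max(best_cost, 0.0))


def apply_lateral_shift(bscan: BScan, shift: LateralShift) -> BScan:
    """Translate columns by -shift_px; vacated columns are zero-filled."""
    dl = shift.shift_px
    n_cols = bscan.n_cols
    if abs(dl) >= n_cols:
        raise MotionRangeError(f"|shift| {abs(dl)} >= column count {n_cols}")
    out = np.zeros_like(bscan.pixels)
    if dl >= 0:
        # sample moved +x; image content moves -x
        out[:, : n_cols - dl] = bscan.pixels[:, dl:]
    else:
        out[:, -dl:] = bscan.pixels[:, : n_cols + dl]
    return BScan(out, axis_role=bscan.axis_role, index=bscan.index,
                 slow_position=bscan.slow_position)


def crop_borders(volume: CScanVolume, crop: int) -> CScanVolume:
    """Remove ``crop`` columns from both lateral borders of every B-scan.

    The protocol's n_fast and ref_positions are updated consistently.
    Reference B-scans (columns = y) are left untouched.
    """
    if crop == 0:
        return volume
    if crop < 0:
        raise ValueError("crop must be >= 0")
    p = volume.protocol
    if 2 * crop >= p.n_fast:
        raise FormatError(f"crop {crop} too large for {p.n_fast} columns")
    new_positions = tuple(x - crop for x in p.ref_positions)
    if new_positions[0] < 0 or new_positions[-1] > p.n_fast - 2 * crop - 1:
        raise FormatError(
            f"crop {crop} would push reference positions {p.ref_positions} "
            "outside the image"
        )
    new_protocol = ScanProtocol(**{**p.to_dict(),
                                   "n_fast": p.n_fast - 2 * crop,
                                   "ref_positions": new_positions})
    new_bscans = [
        BScan(b.pixels[:, crop: p.n_fast - crop], axis_role=b.axis_role,
              index=b.index, slow_position=b.slow_position)
        for b in volume.bscans
    ]
    refs = volume.references
    if refs is not None:
        refs = replace(refs, ref_x=new_positions)
    return CScanVolume(protocol=new_protocol, bscans=new_bscans, references=refs)
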