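"""Ring-phase analysis: one angle for a ring's perceived motion.

On a ring stimulus, pure expansion moves every point outward along the
local radial direction, and pure rotation moves every point along the
local tangent. The *ring phase* expresses a decoded flow field as a single
angle relative to the outward radial direction: 0 deg is pure expansion,
+90 deg pure clockwise rotation (on screen), -90 deg counter-clockwise,
and intermediate values (e.g. +-45 deg) a vector mixture of expansion and
rotation. This is the quantity that exposes illusory rotation: a looming
ring of obliquely oriented micropatterns is physically at phase 0 but
decodes away from it.

Phases are aggregated over annulus pixels with magnitude-weighted
*circular* statistics (arithmetic means are meaningless on a circle); the
resultant length in [0, 1] reports how concentrated the per-pixel phases
are around the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decode import FlowField
from .geometry import wrap_deg
from .stimuli import ParameterError

__all__ = ["PhaseMeasurement", "measure_ring_phase", "phase_timecourse", "combine_phases"]


@dataclass(frozen=True)
class PhaseMeasurement:
    """Circular-mean motion phase of an annulus, clockwise positive.

    ``phase_deg`` in (-180, 180]; ``resultant_length`` in [0, 1] (1 =
    perfectly aligned per-pixel phases); ``n_pixels`` the count that
    entered the mean; ``total_weight`` the summed magnitude weight.
    """

    phase_deg: float
    resultant_length: float
    n_pixels: int
    total_weight: float = 0.0


def measure_ring_phase(
    flow: FlowField,
    center: tuple[float, float],
    r_min: float,
    r_max: float,
    magnitude_floor_frac: float = 0.1,
) -> PhaseMeasurement | None:
    """Magnitude-weighted circular mean of (decoded - radial) angle.

    Pixels of the annulus ``r_min <= rho <= r_max`` whose magnitude is at
    least ``magnitude_floor_frac`` times the annulus maximum contribute,
    weighted by magnitude, the signed angular difference between their
    decoded direction and the local outward radial direction (clockwise
    positive on screen). Returns ``None`` — the undefined-phase signal —
    when the annulus is empty or no pixel passes the floor.
    """
    if not 0.0 <= magnitude_floor_frac < 1.0:
        raise ParameterError("magnitude_floor_frac must be in [0, 1)")
    if r_min < 0 or r_max <= r_min:
        raise ParameterError("need 0 <= r_min < r_max")
    cx, cy = center
    h, w = flow.magnitude.shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = x - cx, y - cy
    rho = np.hypot(dx, dy)
    annulus = (rho >= r_min) & (rho <= r_max) & flow.defined
    if not annulus.any():
        return None
    mags = flow.magnitude[annulus]
    floor = magnitude_floor_frac * mags.max()
    keep = mags >= floor
    if not keep.any() or mags.max() == 0:
        return None
    # outward radial direction in the screen convention (cw positive, y down)
    radial = np.rad2deg(np.arctan2(dy, dx))[annulus][keep]
    decoded = flow.angle[annulus][keep]
    weights = mags[keep]
    diff = np.deg2rad(wrap_deg(decoded - radial))
    z = np.sum(weights * np.exp(1j * diff))
    total = weights.sum()
    return PhaseMeasurement(
        phase_deg=float(wrap_deg(np.rad2deg(np.angle(z)))),
        resultant_length=float(np.abs(z) / total),
        n_pixels=int(keep.sum()),
        total_weight=float(total),
    )


def phase_timecourse(
    flows: Sequence[FlowField],
    center: tuple[float, float],
    r_min: float | Sequence[float],
    r_max: float | Sequence[float],
    magnitude_floor_frac: float = 0.1,
) -> list[PhaseMeasurement | None]:
    """Per-frame ring phase; ``None`` marks frames with undefined phase.

    ``r_min``/``r_max`` may be sequences (one per frame) to track an
    expanding ring with a moving annulus window.
    """
    n = len(flows)
    r_mins = np.broadcast_to(np.asarray(r_min, float), (n,))
    r_maxs = np.broadcast_to(np.asarray(r_max, float), (n,))
    return [
        measure_ring_phase(f, center, r_mins[i], r_maxs[i], magnitude_floor_frac)
        for i, f in enumerate(flows)
    ]


def combine_phases(measurements: Sequence[PhaseMeasurement | None]) -> PhaseMeasurement | None:
    """Pool per-frame phase measurements into one circular mean.

    Each defined frame contributes its resultant vector scaled by its
    total magnitude weight, so strong, concentrated frames dominate.
    Returns ``None`` if no frame has a defined phase.
    """
    z = 0.0j
    total = 0.0
    n_pixels = 0
    for m in measurements:
        if m is None:
            continue
        w = m.total_weight if m.total_weight > 0 else m.n_pixels
        z += w * m.resultant_length * np.exp(1j * np.deg2rad(m.phase_deg))
        total += w
        n_pixels += m.n_pixels
    if total == 0:
        return None
    return PhaseMeasurement(
        phase_deg=float(wrap_deg(np.rad2deg(np.angle(z)))),
        resultant_length=float(np.abs(z) / total),
        n_pixels=n_pixels,
        total_weight=float(total),
    )
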