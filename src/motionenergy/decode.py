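"""Direction decoding and color-wheel rendering.

The population of K opponent channels is collapsed to a per-pixel velocity
direction by a rectified vector sum: each channel with positive opponent
evidence votes for its preferred direction with weight equal to that
evidence,

    v = sum_k max(O_k, 0) * (cos theta_k, sin theta_k).

The decoded angle is atan2 of the resultant (screen convention, clockwise
positive) and the magnitude is its norm. Where the resultant vanishes
(static input, perfectly balanced motion) the direction is undefined and
is flagged, never replaced by a fake angle.

Rendering maps angle to hue around a color wheel and magnitude to
brightness, scaled either by a per-frame robust maximum (percentile) for
display or by a caller-fixed absolute scale for quantitative comparison
across conditions. Undefined pixels render neutral (black).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .filterbank import FilterBank
from .geometry import math_from_screen, screen_from_math, wrap_deg
from .stimuli import ParameterError

__all__ = ["FlowField", "ColorWheelConfig", "decode_flow", "flow_to_rgb", "render_legend"]


@dataclass
class FlowField:
    """Per-pixel decoded motion direction and strength.

    ``angle`` is in degrees, screen convention, in (-180, 180], and NaN
    where undefined; ``magnitude`` is nonnegative and zero exactly where
    the angle is undefined.
    """

    angle: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        if self.angle.shape != self.magnitude.shape:
            raise ParameterError("angle and magnitude must share a shape")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of pixels with a defined direction."""
        return self.magnitude > 0


@dataclass(frozen=True)
class ColorWheelConfig:
    """Hue anchoring and brightness scaling of the direction wheel.

    ``hue_at_zero_deg`` is the hue (0-1) shown for rightward motion;
    ``direction_of_increase`` sets whether hue advances clockwise or
    counter-clockwise around the screen. ``magnitude_percentile`` is the
    robust per-frame maximum used for display scaling; ``fixed_scale``
    (absolute magnitude units) overrides it for cross-condition
    comparisons. ``gamma`` < 1 lifts faint motion.
    """

    hue_at_zero_deg: float = 0.0
    direction_of_increase: Literal["cw", "ccw"] = "cw"
    magnitude_percentile: float = 99.0
    gamma: float = 1.0
    fixed_scale: float | None = None

    def __post_init__(self):
        if not 50.0 < self.magnitude_percentile <= 100.0:
            raise ParameterError("magnitude_percentile must be in (50, 100]")
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")
        if self.direction_of_increase not in ("cw", "ccw"):
            raise ParameterError("direction_of_increase must be 'cw' or 'ccw'")
        if self.fixed_scale is not None and self.fixed_scale <= 0:
            raise ParameterError("fixed_scale must be > 0")


def decode_flow(O: np.ndarray, bank: FilterBank | np.ndarray) -> FlowField:
    """Rectified vector-sum readout of an (H, W, K) opponent map.

    ``bank`` may be a FilterBank or a plain array of K channel directions
    (degrees, screen convention). Opposite channels carry exactly opposite
    opponent values, so rectification keeps each direction's positive
    evidence once.
    """
    directions = bank.directions if isinstance(bank, FilterBank) else np.asarray(bank, float)
    O = np.asarray(O, dtype=np.float64)
    if O.shape[-1] != len(directions):
        raise ParameterError(
            f"opponent map has {O.shape[-1]} channels, bank has {len(directions)}"
        )
    if not np.all(np.isfinite(O)):
        raise ParameterError("opponent map must be finite")
    w = np.maximum(O, 0.0)
    # vector sum in the y-up math frame, converted once at the boundary
    th_math = np.deg2rad(math_from_screen(directions))
    vx = w @ np.cos(th_math)
    vy_up = w @ np.sin(th_math)
    magnitude = np.hypot(vx, vy_up)
    # symmetric populations cancel only to round-off; snap those to zero
    cancelled = magnitude <= 1e-12 * w.sum(axis=-1)
    magnitude[cancelled] = 0.0
    angle_math = np.rad2deg(np.arctan2(vy_up, vx))
    angle = np.asarray(screen_from_math(angle_math), dtype=np.float64)
    angle[magnitude == 0] = np.nan
    return FlowField(angle=angle, magnitude=magnitude)


def _hue_of(angle_deg: np.ndarray, cfg: ColorWheelConfig) -> np.ndarray:
    sign = 1.0 if cfg.direction_of_increase == "cw" else -1.0
    return np.mod(cfg.hue_at_zero_deg + sign * np.asarray(angle_deg, float) / 360.0, 1.0)


def flow_to_rgb(flow: FlowField, cfg: ColorWheelConfig = ColorWheelConfig()) -> np.ndarray:
    """Render a flow field to an (H, W, 3) uint8 color-wheel image.

    Hue encodes the decoded angle; value encodes magnitude relative to the
    per-frame robust maximum (or ``cfg.fixed_scale``), gamma-corrected.
    Undefined-direction pixels are neutral black.
    """
    mag = flow.magnitude
    defined = flow.defined
    if cfg.fixed_scale is not None:
        scale = cfg.fixed_scale
    else:
        scale = np.percentile(mag[defined], cfg.magnitude_percentile) if defined.any() else 1.0
        if scale <= 0:
            scale = 1.0
    value = np.clip(mag / scale, 0.0, 1.0) ** cfg.gamma
    value[~defined] = 0.0
    hue = _hue_of(np.nan_to_num(flow.angle), cfg)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return (hsv_to_rgb(hsv) * 255).round().astype(np.uint8)


def render_legend(cfg: ColorWheelConfig = ColorWheelConfig(), size: int = 129) -> np.ndarray:
    """Square RGBA color-wheel legend with direction tick marks.

    Every pixel inside the disc shows the exact hue/brightness the
    rendering assigns to motion at that screen angle (brightness ramps
    radially from centre to rim); corners outside the disc are fully
    transparent. Tick marks darken the four cardinal directions.
    """
    c = (size - 1) / 2
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = x - c, y - c
    rho = np.hypot(dx, dy)
    angle = wrap_deg(np.rad2deg(np.arctan2(dy, dx)))
    inside = rho <= c
    # reuse the flow rendering so legend and output share one mapping
    mag = np.where(inside, rho / max(c, 1.0), 0.0)
    flow = FlowField(angle=np.where(inside, angle, np.nan), magnitude=mag)
    rgb = flow_to_rgb(flow, ColorWheelConfig(
        hue_at_zero_deg=cfg.hue_at_zero_deg,
        direction_of_increase=cfg.direction_of_increase,
        magnitude_percentile=cfg.magnitude_percentile,
        gamma=cfg.gamma,
        fixed_scale=1.0,
    ))
    # cardinal tick marks
    tick = (rho > 0.85 * c) & inside & (
        (np.abs(dy) < 1.0) | (np.abs(dx) < 1.0)
    )
    rgb[tick] = (rgb[tick] * 0.3).astype(np.uint8)
    alpha = np.where(inside, 255, 0).astype(np.uint8)
    return np.dstack([rgb, alpha])
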