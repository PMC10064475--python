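"""Synthetic stimulus generators for the motion-energy model.

Everything the model is tested and demonstrated with is generated here:
drifting and counterphase sinusoidal gratings (the canonical probes of a
linear motion detector), the stepping-feet configuration (two equal-speed
bars on a high-contrast striped background), expanding/rotating textured
rings, rings of oriented Gabor micropatterns (the looming configuration
that elicits illusory rotation), and a fixational-eye-movement emulation
implemented as a global random-walk image jitter.

All stimuli are rendered by evaluating the analytic pattern at continuous
coordinates per frame — never by shifting a rasterised template — so
sub-pixel speeds carry no interpolation artifacts. Luminance is in [0, 1];
colour is out of scope (a first-order motion detector is luminance-driven),
so e.g. the classically yellow/blue stepping feet become bright/dark bars.

Angles follow the screen convention of :mod:`motionenergy.geometry`:
clockwise-positive as displayed, 0 deg pointing right.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import ndimage

from .geometry import unit_vector_screen

__all__ = [
    "ParameterError",
    "FrameSequence",
    "RingStimulusSpec",
    "SteppingFeetSpec",
    "gen_drifting_grating",
    "gen_counterphase_grating",
    "gen_stepping_feet",
    "gen_ring_stimulus",
    "jitter_path",
    "apply_camera_jitter",
]


class ParameterError(ValueError):
    """A stimulus or filter parameter violates its stated precondition."""


def _as_size(size) -> tuple[int, int]:
    if np.isscalar(size):
        size = (int(size), int(size))
    h, w = int(size[0]), int(size[1])
    if h < 1 or w < 1:
        raise ParameterError(f"frame size must be positive, got {(h, w)}")
    return h, w


@dataclass
class FrameSequence:
    """An ordered stack of luminance frames plus nominal frame rate.

    ``frames`` is a (T, H, W) float array with values in [0, 1] (clipped on
    construction); ``frame_rate`` is metadata only — the model works in
    units of frames.
    """

    frames: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=np.float64)
        if f.ndim != 3 or f.shape[0] < 1:
            raise ParameterError(
                f"frames must be a (T, H, W) stack with T >= 1, got shape {f.shape}"
            )
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        self.frames = np.clip(f, 0.0, 1.0)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class RingStimulusSpec:
    """Geometry and appearance of an expanding/rotating ring stimulus.

    ``expansion_rate`` is px/frame (positive = expanding), ``rotation_rate``
    deg/frame (positive = clockwise on screen). ``element_orientation_offset``
    tilts each Gabor element's carrier wave vector away from the local
    outward radial direction, clockwise-positive; 0 keeps the carrier
    radial (stripes tangential), +-90 makes it tangential.
    """

    center: tuple[float, float]  # (x, y) px, image coordinates
    base_radius: float
    expansion_rate: float = 0.0
    rotation_rate: float = 0.0
    element_kind: Literal["solid_texture", "gabor_elements"] = "solid_texture"
    n_elements: int = 12
    element_orientation_offset: float = 0.0
    element_wavelength: float = 8.0
    element_sigma: float = 4.0
    contrast: float = 0.9

    def __post_init__(self):
        if self.base_radius <= 0:
            raise ParameterError("base_radius must be > 0")
        if not 0.0 <= self.contrast <= 1.0:
            raise ParameterError("contrast must be in [0, 1]")
        if self.element_kind not in ("solid_texture", "gabor_elements"):
            raise ParameterError(f"unknown element_kind {self.element_kind!r}")
        if self.element_kind == "gabor_elements" and self.n_elements < 4:
            raise ParameterError("gabor_elements requires n_elements >= 4")
        if self.n_elements < 1:
            raise ParameterError("n_elements must be >= 1")
        if self.element_wavelength < 2 or self.element_sigma <= 0:
            raise ParameterError("element_wavelength >= 2 and element_sigma > 0 required")


@dataclass(frozen=True)
class SteppingFeetSpec:
    """Two equal-speed bars ("feet") of opposite polarity over stripes.

    The background is a vertical square-wave grating of spatial period
    ``grating_period`` px and Michelson contrast ``background_contrast``
    about mid-gray. Both feet translate rightward at ``speed`` px/frame.
    """

    grating_period: float = 16.0
    foot_luminances: tuple[float, float] = (0.9, 0.1)
    foot_size: tuple[float, float] = (20.0, 8.0)  # (w, h) px
    speed: float = 1.0
    background_contrast: float = 1.0
    vertical_gap: float = 4.0

    def __post_init__(self):
        if self.grating_period < 2:
            raise ParameterError("grating_period must be >= 2 px")
        if self.speed <= 0:
            raise ParameterError("speed must be > 0")
        b, d = self.foot_luminances
        if b == d:
            raise ParameterError("foot luminances must be distinct")
        if not (0 <= b <= 1 and 0 <= d <= 1):
            raise ParameterError("foot luminances must be in [0, 1]")
        if not 0.0 <= self.background_contrast <= 1.0:
            raise ParameterError("background_contrast must be in [0, 1]")
        if self.foot_size[0] <= 0 or self.foot_size[1] <= 0:
            raise ParameterError("foot_size must be positive")
        if self.vertical_gap < 0:
            raise ParameterError("vertical_gap must be >= 0")


def _check_grating_params(wavelength_px, contrast, mean_luminance):
    if wavelength_px < 2:
        raise ParameterError("wavelength must be >= 2 px")
    if not 0.0 <= contrast <= 1.0:
        raise ParameterError("contrast must be in [0, 1]")
    lo, hi = mean_luminance - contrast / 2, mean_luminance + contrast / 2
    if lo < -1e-12 or hi > 1 + 1e-12:
        raise ParameterError(
            f"mean_luminance +- contrast/2 must stay in [0, 1], got [{lo}, {hi}]"
        )


def _along_coordinate(size, orientation_deg):
    """Signed coordinate of each pixel along a screen-frame direction."""
    h, w = size
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = unit_vector_screen(orientation_deg)
    return x * dx + y * dy


def gen_drifting_grating(
    size,
    wavelength_px: float,
    orientation_deg: float,
    speed_px_per_frame: float,
    contrast: float,
    n_frames: int,
    mean_luminance: float = 0.5,
    frame_rate: float = 30.0,
    phase_deg: float = 0.0,
) -> FrameSequence:
    """Sinusoidal grating translating rigidly in direction ``orientation_deg``.

    The stripes are perpendicular to the drift direction; ``speed`` is the
    component of the pattern velocity along that direction (px/frame).
    """
    size = _as_size(size)
    _check_grating_params(wavelength_px, contrast, mean_luminance)
    u = _along_coordinate(size, orientation_deg)
    frames = np.empty((n_frames, *size))
    ph0 = np.deg2rad(phase_deg)
    for t in range(n_frames):
        frames[t] = mean_luminance + (contrast / 2) * np.cos(
            2 * np.pi * (u - speed_px_per_frame * t) / wavelength_px + ph0
        )
    return FrameSequence(frames, frame_rate)


def gen_counterphase_grating(
    size,
    wavelength_px: float,
    orientation_deg: float,
    temporal_freq: float,
    contrast: float,
    n_frames: int,
    mean_luminance: float = 0.5,
    frame_rate: float = 30.0,
) -> FrameSequence:
    """Standing grating whose contrast reverses sinusoidally in time.

    ``temporal_freq`` is in cycles/frame. Pixelwise this equals the sum of
    two opposite-direction drifting gratings at half contrast — the
    classic balanced-motion probe for which opponent energy vanishes.
    """
    size = _as_size(size)
    _check_grating_params(wavelength_px, contrast, mean_luminance)
    u = _along_coordinate(size, orientation_deg)
    t = np.arange(n_frames)[:, None, None]
    frames = mean_luminance + (contrast / 2) * np.cos(2 * np.pi * u / wavelength_px) * np.cos(
        2 * np.pi * temporal_freq * t
    )
    return FrameSequence(frames, frame_rate)


def _box_coverage(coord: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fraction of each unit pixel cell [c, c+1) covered by [lo, hi)."""
    return np.clip(np.minimum(coord + 1.0, hi) - np.maximum(coord, lo), 0.0, 1.0)


def stepping_feet_positions(spec: SteppingFeetSpec, size, n_frames: int):
    """Per-frame (left-x, top-y) of the bright and dark foot, plus geometry.

    Returns ``(xs, (y_top_bright, y_top_dark), (w, h))`` where ``xs[t]`` is
    the left edge of both feet at frame ``t``. Used by the renderer and by
    analyses that need foot regions of interest.
    """
    h, w = _as_size(size)
    fw, fh = spec.foot_size
    x0 = 2.0
    xs = x0 + spec.speed * np.arange(n_frames)
    if xs[-1] + fw > w:
        raise ParameterError(
            f"feet leave the frame: final right edge {xs[-1] + fw:.1f} > width {w}"
        )
    total_h = 2 * fh + spec.vertical_gap
    if total_h > h:
        raise ParameterError("feet do not fit vertically in the frame")
    y_top = (h - total_h) / 2
    return xs, (y_top, y_top + fh + spec.vertical_gap), (fw, fh)


def gen_stepping_feet(spec: SteppingFeetSpec, size, n_frames: int,
                      frame_rate: float = 30.0) -> FrameSequence:
    """Two vertically aligned opposite-polarity bars over a striped background.

    Both bars move rightward at exactly ``spec.speed`` px/frame (continuous
    coordinates; edges are anti-aliased by pixel coverage). The stripes are
    static; reducing ``background_contrast`` fades them toward mid-gray.
    """
    h, w = _as_size(size)
    xs, (yb, yd), (fw, fh) = stepping_feet_positions(spec, (h, w), n_frames)
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    # square-wave vertical stripes about mid-gray (half-period each polarity)
    stripe = 1.0 - 2.0 * (np.floor(2 * x[0] / spec.grating_period) % 2)
    background = 0.5 + (spec.background_contrast / 2) * stripe
    lum_b, lum_d = spec.foot_luminances
    cov_yb = _box_coverage(y[:, 0], yb, yb + fh)
    cov_yd = _box_coverage(y[:, 0], yd, yd + fh)
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        frame = np.broadcast_to(background, (h, w)).copy()
        cov_x = _box_coverage(x[0], xs[t], xs[t] + fw)
        for cov_y, lum in ((cov_yb, lum_b), (cov_yd, lum_d)):
            cov = cov_y[:, None] * cov_x[None, :]
            frame = frame * (1 - cov) + lum * cov
        frames[t] = frame
    return FrameSequence(frames, frame_rate)


def _ring_radius_at(spec: RingStimulusSpec, t: int) -> float:
    return spec.base_radius + spec.expansion_rate * t


def _check_ring_fits(spec: RingStimulusSpec, size, n_frames: int):
    h, w = size
    cx, cy = spec.center
    margin = 3.0 * spec.element_sigma
    for t in (0, n_frames - 1):
        r = _ring_radius_at(spec, t)
        if r <= 0:
            raise ParameterError(f"ring radius becomes non-positive at frame {t}")
        if (
            cx - r - margin < 0
            or cy - r - margin < 0
            or cx + r + margin > w
            or cy + r + margin > h
        ):
            raise ParameterError(
                f"ring (radius {r:.1f} + 3 sigma margin) exits the {h}x{w} frame at frame {t}"
            )


def _render_solid_ring(spec: RingStimulusSpec, size, t: int) -> np.ndarray:
    h, w = size
    cx, cy = spec.center
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = x - cx, y - cy
    rho = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)  # screen-convention polar angle (cw positive)
    r = _ring_radius_at(spec, t)
    rot = np.deg2rad(spec.rotation_rate * t)
    radial = np.cos(2 * np.pi * (rho - r) / spec.element_wavelength)
    angular = np.cos(spec.n_elements * (phi - rot))
    envelope = np.exp(-((rho - r) ** 2) / (2 * spec.element_sigma**2))
    return 0.5 + (spec.contrast / 2) * angular * radial * envelope


def _render_gabor_ring(spec: RingStimulusSpec, size, t: int) -> np.ndarray:
    h, w = size
    cx, cy = spec.center
    r = _ring_radius_at(spec, t)
    rot = spec.rotation_rate * t
    frame = np.full((h, w), 0.5)
    half = int(np.ceil(3 * spec.element_sigma)) + 1
    for i in range(spec.n_elements):
        ang = 360.0 * i / spec.n_elements + rot  # screen angle of element
        ex, ey = unit_vector_screen(ang)
        ccx, ccy = cx + r * ex, cy + r * ey
        x0, x1 = int(np.floor(ccx)) - half, int(np.floor(ccx)) + half + 1
        y0, y1 = int(np.floor(ccy)) - half, int(np.floor(ccy)) + half + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        px, py = xx - ccx, yy - ccy
        gx, gy = unit_vector_screen(ang + spec.element_orientation_offset)
        u = px * gx + py * gy  # along the carrier wave vector
        patch = (
            (spec.contrast / 2)
            * np.exp(-(px**2 + py**2) / (2 * spec.element_sigma**2))
            * np.cos(2 * np.pi * u / spec.element_wavelength)
        )
        frame[y0:y1, x0:x1] += patch
    return frame


def gen_ring_stimulus(spec: RingStimulusSpec, size, n_frames: int,
                      frame_rate: float = 30.0) -> FrameSequence:
    """Expanding and/or rotating ring stimulus.

    ``solid_texture`` renders an annulus carrying the product of an
    ``n_elements``-fold angular luminance modulation and a radial carrier of
    wavelength ``element_wavelength``, under a Gaussian radial envelope; the
    whole pattern rotates by ``rotation_rate`` deg/frame (clockwise
    positive) and its radius grows by ``expansion_rate`` px/frame, so pure
    rotation moves only the angular phase and pure expansion only the
    radial one.

    ``gabor_elements`` places ``n_elements`` Gabor micropatterns on the
    circle, each carrier tilted ``element_orientation_offset`` degrees
    (clockwise positive) from its local outward radial direction — the
    configuration whose looming version elicits illusory rotation. Elements
    are rendered additively on mid-gray and clipped to [0, 1].
    """
    size = _as_size(size)
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    _check_ring_fits(spec, size, n_frames)
    render = _render_solid_ring if spec.element_kind == "solid_texture" else _render_gabor_ring
    frames = np.stack([render(spec, size, t) for t in range(n_frames)])
    return FrameSequence(frames, frame_rate)


def jitter_path(n_frames: int, rms_amplitude_px: float, seed: int) -> np.ndarray:
    """Random-walk displacement path (T, 2) in (dx, dy) image px.

    Increments are i.i.d. zero-mean Gaussian with standard deviation
    ``rms_amplitude_px`` per axis; the path is their cumulative sum, so it
    emulates slow fixational drift rather than frame-to-frame flicker.
    Deterministic given (n_frames, rms_amplitude_px, seed).
    """
    if rms_amplitude_px < 0:
        raise ParameterError("rms_amplitude_px must be >= 0")
    rng = np.random.default_rng(seed)
    increments = rng.normal(0.0, rms_amplitude_px, size=(n_frames, 2))
    return np.cumsum(increments, axis=0)


def apply_camera_jitter(seq: FrameSequence, rms_amplitude_px: float, seed: int) -> FrameSequence:
    """Globally translate each frame along a seeded random walk.

    Emulates fixational eye movements (or a slightly moving camera) as a
    rigid global image motion. Frames keep their size; borders are filled
    by reflection so no spurious dark-edge motion energy is introduced.
    ``rms_amplitude_px = 0`` returns the input unchanged.
    """
    if rms_amplitude_px < 0:
        raise ParameterError("rms_amplitude_px must be >= 0")
    if rms_amplitude_px == 0:
        return FrameSequence(seq.frames.copy(), seq.frame_rate)
    path = jitter_path(len(seq), rms_amplitude_px, seed)
    out = np.empty_like(seq.frames)
    for t, frame in enumerate(seq):
        dx, dy = path[t]
        # ndimage.shift displaces content by +shift along each axis (y, x)
        out[t] = ndimage.shift(frame, (dy, dx), order=1, mode="reflect")
    return FrameSequence(np.clip(out, 0.0, 1.0), seq.frame_rate)
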