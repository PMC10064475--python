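"""Named stimulus presets: the demonstration conditions of the tool.

Each preset is a callable ``(size, n_frames, seed=0, **params)`` returning
a :class:`~motionenergy.stimuli.FrameSequence`. The defaults are the
conditions used throughout the demos, tests and the reproduction script:
128x128 frames, stimulus spatial wavelength 8 px matched to the default
bank, and speeds near the bank's preferred ~1 px/frame.

Ring geometry is sized so the ring plus its 3-sigma envelope stays inside
the frame for the whole sequence (a generator precondition); expanding
rings therefore start small enough to finish within the 64 px half-width.
"""

from __future__ import annotations

from .stimuli import (
    FrameSequence,
    RingStimulusSpec,
    SteppingFeetSpec,
    apply_camera_jitter,
    gen_counterphase_grating,
    gen_drifting_grating,
    gen_ring_stimulus,
    gen_stepping_feet,
)

__all__ = ["PRESETS", "make_preset", "ring_spec", "pinna_spec", "feet_spec"]


def _grating(size=(128, 128), n_frames=48, seed=0, *, wavelength_px=8.0,
             orientation_deg=0.0, speed=1.0, contrast=1.0, mean_luminance=0.5):
    return gen_drifting_grating(size, wavelength_px, orientation_deg, speed,
                                contrast, n_frames, mean_luminance)


def _counterphase(size=(128, 128), n_frames=48, seed=0, *, wavelength_px=8.0,
                  orientation_deg=0.0, temporal_freq=0.125, contrast=1.0):
    return gen_counterphase_grating(size, wavelength_px, orientation_deg,
                                    temporal_freq, contrast, n_frames)


def feet_spec(**params) -> SteppingFeetSpec:
    """Stepping-feet condition: opposite-polarity bars over unit-contrast
    stripes of period 16 px, moving at 1 px/frame."""
    defaults = dict(grating_period=16.0, foot_luminances=(0.9, 0.1),
                    foot_size=(20.0, 8.0), speed=1.0,
                    background_contrast=1.0, vertical_gap=4.0)
    defaults.update(params)
    return SteppingFeetSpec(**defaults)


def _stepping_feet(size=(64, 128), n_frames=48, seed=0, **params):
    return gen_stepping_feet(feet_spec(**params), size, n_frames)


def ring_spec(**params) -> RingStimulusSpec:
    """Solid textured annulus: 12-fold angular modulation on a radial
    carrier of wavelength 8 px, radius 24 px, rotating clockwise at
    3 deg/frame by default (set ``rotation_rate``/``expansion_rate`` to
    taste)."""
    defaults = dict(center=(64.0, 64.0), base_radius=24.0, expansion_rate=0.0,
                    rotation_rate=3.0, element_kind="solid_texture",
                    n_elements=12, element_wavelength=8.0, element_sigma=4.0,
                    contrast=0.9)
    defaults.update(params)
    return RingStimulusSpec(**defaults)


def _ring(size=(128, 128), n_frames=48, seed=0, **params):
    return gen_ring_stimulus(ring_spec(**params), size, n_frames)


def pinna_spec(**params) -> RingStimulusSpec:
    """Looming ring of 16 Gabor micropatterns (wavelength 8, sigma 4 px),
    carriers tilted +45 deg (clockwise) from radial, expanding at
    1 px/frame from radius 28 px — physically pure expansion."""
    defaults = dict(center=(64.0, 64.0), base_radius=28.0, expansion_rate=1.0,
                    rotation_rate=0.0, element_kind="gabor_elements",
                    n_elements=16, element_orientation_offset=45.0,
                    element_wavelength=8.0, element_sigma=4.0, contrast=0.9)
    defaults.update(params)
    return RingStimulusSpec(**defaults)


def _pinna(size=(128, 128), n_frames=24, seed=0, **params):
    return gen_ring_stimulus(pinna_spec(**params), size, n_frames)


def _jittered_ring(size=(128, 128), n_frames=48, seed=0, *, rms_amplitude_px=0.5, **params):
    """Static ring viewed through fixational-eye-movement jitter."""
    static = _ring(size, n_frames, seed, rotation_rate=0.0, expansion_rate=0.0, **params)
    return apply_camera_jitter(static, rms_amplitude_px, seed)


PRESETS = {
    "grating": _grating,
    "counterphase": _counterphase,
    "stepping_feet": _stepping_feet,
    "ring": _ring,
    "pinna": _pinna,
    "jittered_ring": _jittered_ring,
}


def make_preset(name: str, size=None, n_frames=None, seed=0, **params) -> FrameSequence:
    """Instantiate a preset by name with optional overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    fn = PRESETS[name]
    kwargs = dict(params)
    args = {}
    if size is not None:
        args["size"] = size
    if n_frames is not None:
        args["n_frames"] = n_frames
    return fn(seed=seed, **args, **kwargs)
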