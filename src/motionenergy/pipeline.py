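"""End-to-end pipelines: sequence in, flow fields / renderings / phases out.

Thin composition layer over the stimuli, energy, decode and ring modules,
shared by the CLI, the demos and the reproduction script. All outputs are
aligned with the *warmed-up* frames: the first ``bank.n_taps - 1`` input
frames only fill the temporal buffer and produce no output.
"""

from __future__ import annotations

import logging
import time
from typing import Sequence

import numpy as np

from .decode import ColorWheelConfig, FlowField, decode_flow, flow_to_rgb
from .energy import MotionEnergyEngine
from .filterbank import FilterBank
from .rings import PhaseMeasurement, combine_phases, phase_timecourse
from .stimuli import FrameSequence

logger = logging.getLogger("motionenergy")

__all__ = ["decode_sequence", "render_sequence", "analyze_ring_sequence"]


def decode_sequence(
    seq: FrameSequence, bank: FilterBank, normalize: bool = False
) -> list[FlowField]:
    """Stream a sequence through the bank and decode per-frame flow fields.

    Returns one FlowField per warmed-up frame (input frame indices
    ``bank.n_taps - 1 ..``).
    """
    t0 = time.perf_counter()
    engine = MotionEnergyEngine(bank, normalize=normalize)
    flows = []
    for frame in seq:
        O = engine.push(frame)
        if O is not None:
            flows.append(decode_flow(O, bank))
    logger.info(
        "decode_sequence: %d frames -> %d flows in %.2fs",
        len(seq), len(flows), time.perf_counter() - t0,
    )
    return flows


def render_sequence(
    flows: Sequence[FlowField], cfg: ColorWheelConfig = ColorWheelConfig()
) -> np.ndarray:
    """Render flow fields to a (T, H, W, 3) uint8 color-wheel stack."""
    return np.stack([flow_to_rgb(f, cfg) for f in flows])


def analyze_ring_sequence(
    seq: FrameSequence,
    bank: FilterBank,
    center: tuple[float, float],
    r_min,
    r_max,
    magnitude_floor_frac: float = 0.1,
    normalize: bool = False,
) -> tuple[list[PhaseMeasurement | None], PhaseMeasurement | None]:
    """Full pipeline: frames -> opponent energy -> flow -> ring phase.

    ``r_min``/``r_max`` may be scalars or per-output-frame sequences (to
    track an expanding ring). Returns the per-frame time course and the
    pooled circular-mean measurement.
    """
    flows = decode_sequence(seq, bank, normalize=normalize)
    course = phase_timecourse(flows, center, r_min, r_max, magnitude_floor_frac)
    return course, combine_phases(course)
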