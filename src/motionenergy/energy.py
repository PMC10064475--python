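"""Streaming motion-energy computation.

Frames are pushed into a rolling spatiotemporal buffer and filtered by the
bank's separable components: each incoming frame is convolved once with
every spatial quadrature pair (reflect boundary, same-size output), the
per-frame spatial responses are buffered, and the causal temporal filters
are applied as a dot product over the buffer at the latest time sample.
This is algebraically identical to correlating the full x-y-t volume with
each channel's 3-D kernel (the brute-force oracle used in the tests) but
costs one spatial pass per frame.

Outputs per warmed-up frame:

* **energy map** ``E`` (H, W, K): per channel, squared even response plus
  squared odd response — phase-invariant, nonnegative, quadratic in
  contrast. Multi-scale banks sum energies over scales per direction.
* **opponent map** ``O`` (H, W, K): ``O_k = E_k - E_{k + K/2}`` — signed
  directional evidence that vanishes for static frames and for balanced
  counterphase motion.

Divisive contrast normalisation (``O / (eps + local mean E)``) is
available but off by default: contrast-dependent phenomena such as the
stepping-feet illusion require output strength to track stimulus contrast.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .filterbank import FilterBank
from .stimuli import FrameSequence, ParameterError

__all__ = [
    "EngineNotReady",
    "FrameVolume",
    "MotionEnergyEngine",
    "push_frame",
    "compute_energy",
    "compute_opponent",
    "process_stream",
]

_SQRT2 = np.sqrt(2.0)


class EngineNotReady(RuntimeError):
    """The temporal buffer holds fewer frames than the kernel needs."""


class FrameVolume:
    """Rolling FIFO buffer of the T most recent grayscale frames.

    ``depth`` is the temporal kernel length; the volume is *warm* once it
    holds exactly ``depth`` frames (oldest first). Pushing onto a full
    volume drops the oldest frame.
    """

    def __init__(self, depth: int, frame_shape: tuple[int, int] | None = None):
        if depth < 1:
            raise ParameterError("depth must be >= 1")
        self.depth = int(depth)
        self.frame_shape = tuple(frame_shape) if frame_shape is not None else None
        self._buf: deque[np.ndarray] = deque(maxlen=self.depth)

    def push(self, frame: np.ndarray) -> "FrameVolume":
        frame = np.asarray(frame, dtype=np.float64)
        if frame.ndim != 2:
            raise ParameterError(f"frame must be 2-D, got shape {frame.shape}")
        if self.frame_shape is None:
            self.frame_shape = frame.shape
        elif frame.shape != self.frame_shape:
            raise ParameterError(
                f"frame shape {frame.shape} does not match buffer shape {self.frame_shape}"
            )
        self._buf.append(frame)
        return self

    def __len__(self) -> int:
        return len(self._buf)

    def __getitem__(self, i) -> np.ndarray:
        return list(self._buf)[i] if isinstance(i, slice) else self._buf[i]

    @property
    def is_warm(self) -> bool:
        return len(self._buf) == self.depth

    @property
    def frames(self) -> np.ndarray:
        """(T, H, W) copy of the buffer contents, oldest first."""
        return np.stack(self._buf)


def push_frame(vol: FrameVolume, frame: np.ndarray) -> FrameVolume:
    """FIFO push; drops the oldest frame once the volume is full."""
    return vol.push(frame)


def _spatial_responses(frame: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Even/odd spatial responses, shape (n_scales, K/2, 2, H, W).

    Only the first K/2 directions are filtered: the opposite direction
    shares the even kernel and negates the odd one, which the combination
    stage exploits.
    """
    half = bank.K // 2
    out = np.empty((bank.n_scales, half, 2, *frame.shape))
    for s in range(bank.n_scales):
        for k in range(half):
            sp = bank.spatial_pairs[s * bank.K + k]
            out[s, k, 0] = ndimage.correlate(frame, sp.even, mode="reflect")
            out[s, k, 1] = ndimage.correlate(frame, sp.odd, mode="reflect")
    return out


def _energy_from_buffer(resp_lag: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Combine buffered spatial responses into an (H, W, K) energy map.

    ``resp_lag`` has shape (n_taps, n_scales, K/2, 2, H, W) ordered by
    temporal lag (index 0 = most recent frame).
    """
    ff, fs = bank.temporal_pair.fast, bank.temporal_pair.slow
    A_f = np.tensordot(ff, resp_lag, axes=(0, 0))  # (n_scales, K/2, 2, H, W)
    A_s = np.tensordot(fs, resp_lag, axes=(0, 0))
    half = bank.K // 2
    H, W = resp_lag.shape[-2:]
    E = np.zeros((H, W, bank.K))
    for s in range(bank.n_scales):
        for k in range(half):
            Aef, Aof = A_f[s, k, 0], A_f[s, k, 1]
            Aes, Aos = A_s[s, k, 0], A_s[s, k, 1]
            a = (Aef - Aos) / _SQRT2
            b = (Aof + Aes) / _SQRT2
            E[:, :, k] += a**2 + b**2
            # opposite direction: same even kernel, negated odd kernel
            a2 = (Aef + Aos) / _SQRT2
            b2 = (-Aof + Aes) / _SQRT2
            E[:, :, k + half] += a2**2 + b2**2
    return E


def compute_energy(vol: FrameVolume, bank: FilterBank) -> np.ndarray:
    """Per-pixel, per-direction motion energy at the latest time sample.

    Spatial filtering uses reflect ("same") boundary handling; temporal
    filtering is causal and valid — the volume must be warm, i.e. hold
    ``bank.n_taps`` frames. Returns a nonnegative (H, W, K) array.
    """
    if vol.depth != bank.n_taps:
        raise ParameterError(
            f"volume depth {vol.depth} does not match bank n_taps {bank.n_taps}"
        )
    if not vol.is_warm:
        raise EngineNotReady(
            f"volume holds {len(vol)}/{vol.depth} frames; push more before computing"
        )
    resp = np.stack([_spatial_responses(vol[-1 - lag], bank) for lag in range(vol.depth)])
    return _energy_from_buffer(resp, bank)


def compute_opponent(E: np.ndarray, bank: FilterBank | None = None) -> np.ndarray:
    """Opponent map ``O_k = E_k - E_{k + K/2}`` (exact antisymmetry)."""
    K = E.shape[-1]
    if K % 2:
        raise ParameterError("opponent stage requires an even number of channels")
    half = K // 2
    O = np.empty_like(E)
    O[..., :half] = E[..., :half] - E[..., half:]
    O[..., half:] = -O[..., :half]
    return O


def _normalize_opponent(O: np.ndarray, E: np.ndarray, sigma_px: float, eps: float) -> np.ndarray:
    pool = ndimage.gaussian_filter(E.mean(axis=-1), sigma=2.0 * sigma_px, mode="reflect")
    return O / (eps + pool)[..., None]


class MotionEnergyEngine:
    """Streaming front end: push frames, receive opponent maps when warm.

    Spatial responses are cached per frame so each frame is filtered
    exactly once regardless of the temporal kernel length; results are
    identical (to float64 round-off) to batch 3-D correlation over the
    full volume.
    """

    def __init__(self, bank: FilterBank, normalize: bool = False, eps: float = 1e-3):
        self.bank = bank
        self.normalize = normalize
        self.eps = eps
        self._resp: deque[np.ndarray] = deque(maxlen=bank.n_taps)
        self._shape: tuple[int, int] | None = None

    def reset(self) -> None:
        self._resp.clear()
        self._shape = None

    @property
    def is_warm(self) -> bool:
        return len(self._resp) == self.bank.n_taps

    def push(self, frame: np.ndarray) -> np.ndarray | None:
        """Push one frame; return the (H, W, K) opponent map once warm."""
        frame = np.asarray(frame, dtype=np.float64)
        if frame.ndim != 2:
            raise ParameterError(f"frame must be 2-D, got shape {frame.shape}")
        if self._shape is None:
            self._shape = frame.shape
        elif frame.shape != self._shape:
            raise ParameterError(
                f"frame shape {frame.shape} does not match stream shape {self._shape}"
            )
        self._resp.append(_spatial_responses(frame, self.bank))
        if not self.is_warm:
            return None
        resp_lag = np.stack([self._resp[-1 - lag] for lag in range(self.bank.n_taps)])
        E = _energy_from_buffer(resp_lag, self.bank)
        O = compute_opponent(E)
        if self.normalize:
            O = _normalize_opponent(O, E, self.bank.sigma_px, self.eps)
        return O

    def energy(self) -> np.ndarray:
        """Energy map for the current buffer (must be warm)."""
        if not self.is_warm:
            raise EngineNotReady(
                f"engine holds {len(self._resp)}/{self.bank.n_taps} frames"
            )
        resp_lag = np.stack([self._resp[-1 - lag] for lag in range(self.bank.n_taps)])
        return _energy_from_buffer(resp_lag, self.bank)


def process_stream(
    frames: FrameSequence | Iterable[np.ndarray] | Sequence[np.ndarray],
    bank: FilterBank,
    normalize: bool = False,
) -> list[np.ndarray]:
    """Opponent maps for every warmed-up frame of a sequence.

    Output length is ``len(frames) - bank.n_taps + 1``; a sequence shorter
    than the temporal kernel is an error. Identical to batch computation
    on the full volume.
    """
    engine = MotionEnergyEngine(bank, normalize=normalize)
    out = [O for O in map(engine.push, frames) if O is not None]
    if not out:
        raise ParameterError(
            f"sequence too short: need at least {bank.n_taps} frames"
        )
    return out
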