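"""Direction-selective spatiotemporal quadrature filter bank.

The linear front end of the motion-energy model: K direction channels at
uniformly spaced preferred directions, each an oriented space-time
quadrature pair built from separable components,

* a spatial Gabor quadrature pair (cosine/sine carrier under an isotropic
  Gaussian), carrier wave vector along the preferred direction;
* a fast/slow pair of causal biphasic temporal filters

      f_n(t) = (t/tau)^n exp(-t/tau) [1/n! - (t/tau)^2/(n+2)!]

  with n = 3 (fast) and n = 5 (slow), sampled at integer frame lags.

Direction selectivity arises from the oriented combinations
``even*fast - odd*slow`` and ``odd*fast + even*slow``: their squared sum
(the energy) is large for patterns drifting toward the channel's preferred
direction and small for the opposite direction. Channel k and k + K/2 are
mirror/time-reversed counterparts, which is what the opponent stage
subtracts.

All kernels are zero-DC and unit L2 norm so channel responses are
comparable. Temporal kernels are indexed by *lag*: tap 0 weights the most
recent frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import math_from_screen
from .stimuli import ParameterError

__all__ = [
    "SpatialQuadPair",
    "TemporalFilterPair",
    "DirectionChannel",
    "FilterBank",
    "make_spatial_quadrature",
    "make_temporal_pair",
    "build_filterbank",
]

#: Bank defaults: 8 directions, spatial wavelength 8 px with sigma 3 px in a
#: 15-tap kernel (carrier ~1 octave bandwidth, Gaussian truncated beyond
#: 2.3 sigma), temporal time constant 0.75 frames over 16 causal taps (both
#: biphasic lobes contained; tail < 1% of peak). Preferred speed for the
#: default bank is ~1 px/frame at wavelength 8.
DEFAULTS = dict(K=8, wavelength_px=8.0, sigma_px=3.0, tau_frames=0.75,
                kernel_size=15, n_taps=16)


@dataclass(frozen=True)
class SpatialQuadPair:
    """Even (cosine-phase) and odd (sine-phase) spatial Gabor kernels."""

    even: np.ndarray
    odd: np.ndarray
    orientation_deg: float
    wavelength_px: float
    sigma_px: float


@dataclass(frozen=True)
class TemporalFilterPair:
    """Fast (n=3) and slow (n=5) biphasic temporal kernels, lag-indexed."""

    fast: np.ndarray
    slow: np.ndarray
    tau_frames: float

    @property
    def n_taps(self) -> int:
        return len(self.fast)


@dataclass(frozen=True)
class DirectionChannel:
    """One direction's spatiotemporal quadrature pair.

    Kernels have shape (n_taps, kernel_size, kernel_size); axis 0 is
    temporal lag (0 = most recent frame).
    """

    theta_deg: float
    kernel_even: np.ndarray
    kernel_odd: np.ndarray
    wavelength_px: float


def make_spatial_quadrature(
    wavelength_px: float, sigma_px: float, orientation_deg: float, kernel_size: int
) -> SpatialQuadPair:
    """Oriented spatial Gabor quadrature pair, DC-corrected and unit-normed.

    ``orientation_deg`` is the carrier wave-vector direction in the screen
    convention (the direction of motion the channel will prefer). The even
    kernel is symmetric and the odd antisymmetric under 180-degree rotation
    about the kernel centre.
    """
    if kernel_size % 2 == 0:
        raise ParameterError("kernel_size must be odd")
    if sigma_px <= 0:
        raise ParameterError("sigma_px must be > 0")
    if wavelength_px < 2:
        raise ParameterError("wavelength_px must be >= 2")
    c = kernel_size // 2
    y, x = np.mgrid[-c : c + 1, -c : c + 1].astype(np.float64)
    # trig in the y-up math frame; y-down image rows enter with flipped sign
    th = np.deg2rad(math_from_screen(orientation_deg))
    u = x * np.cos(th) + (-y) * np.sin(th)
    g = np.exp(-(x**2 + y**2) / (2 * sigma_px**2))
    even = g * np.cos(2 * np.pi * u / wavelength_px)
    odd = g * np.sin(2 * np.pi * u / wavelength_px)
    # remove DC by projecting out the Gaussian (keeps the kernel local)
    even -= g * (even.sum() / g.sum())
    even /= np.linalg.norm(even)
    odd /= np.linalg.norm(odd)
    return SpatialQuadPair(even, odd, float(orientation_deg), wavelength_px, sigma_px)


def _sampled_biphasic(n: int, tau: float, n_taps: int) -> np.ndarray:
    s = np.arange(n_taps, dtype=np.float64) / tau
    return (s**n) * np.exp(-s) * (1.0 / factorial(n) - s**2 / factorial(n + 2))


def make_temporal_pair(tau_frames: float, n_taps: int) -> TemporalFilterPair:
    """Sample the fast (n=3) and slow (n=5) biphasic impulse responses.

    The support must contain both lobes of each filter (exactly one sign
    change) and be long enough that the last tap is below 1% of the peak;
    otherwise the truncated filter would ring at the buffer boundary.
    """
    if n_taps < 5:
        raise ParameterError("n_taps must be >= 5")
    if tau_frames <= 0:
        raise ParameterError("tau_frames must be > 0")
    kernels = []
    for n in (3, 5):
        f = _sampled_biphasic(n, tau_frames, n_taps)
        signs = np.sign(f[np.abs(f) > 1e-12 * np.max(np.abs(f))])
        n_changes = int(np.sum(signs[1:] != signs[:-1]))
        if n_changes != 1:
            raise ParameterError(
                f"temporal support too short for the biphasic lobe "
                f"(n={n}, tau={tau_frames}, n_taps={n_taps}: {n_changes} sign changes)"
            )
        if np.abs(f[-1]) >= 0.01 * np.max(np.abs(f)):
            raise ParameterError(
                f"temporal support too short: last tap is "
                f"{np.abs(f[-1]) / np.max(np.abs(f)):.1%} of peak (need < 1%)"
            )
        kernels.append(f / np.linalg.norm(f))
    return TemporalFilterPair(kernels[0], kernels[1], tau_frames)


def _direction_channel(
    sp: SpatialQuadPair, tp: TemporalFilterPair, theta_deg: float
) -> DirectionChannel:
    ff, fs = tp.fast[:, None, None], tp.slow[:, None, None]
    k_even = sp.even[None] * ff - sp.odd[None] * fs
    k_odd = sp.odd[None] * ff + sp.even[None] * fs
    k_even = k_even / np.linalg.norm(k_even)
    k_odd = k_odd / np.linalg.norm(k_odd)
    return DirectionChannel(theta_deg, k_even, k_odd, sp.wavelength_px)


@dataclass(frozen=True)
class FilterBank:
    """K direction channels (optionally replicated over spatial scales).

    ``channels`` is scale-major: entry ``s * K + k`` is direction
    ``directions[k]`` at ``wavelengths[s]``. Energies are summed over
    scales per direction, so downstream maps are always H x W x K.
    """

    channels: tuple[DirectionChannel, ...]
    directions: np.ndarray  # (K,) screen-convention degrees
    wavelengths: tuple[float, ...]
    sigma_px: float
    tau_frames: float
    kernel_size: int
    n_taps: int
    spatial_pairs: tuple[SpatialQuadPair, ...]  # scale-major, like channels
    temporal_pair: TemporalFilterPair

    @property
    def K(self) -> int:
        return len(self.directions)

    @property
    def n_scales(self) -> int:
        return len(self.wavelengths)

    def opposite(self, k: int) -> int:
        """Index of the channel preferring the opposite direction."""
        return (k + self.K // 2) % self.K

    def direction_channels(self, k: int) -> list[DirectionChannel]:
        """All scales of direction k."""
        return [self.channels[s * self.K + k] for s in range(self.n_scales)]

    def describe(self) -> str:
        lines = [
            f"FilterBank: K={self.K} directions, wavelengths={list(self.wavelengths)} px, "
            f"sigma={self.sigma_px} px, tau={self.tau_frames} frames, "
            f"spatial {self.kernel_size}x{self.kernel_size}, {self.n_taps} temporal taps"
        ]
        for k, th in enumerate(self.directions):
            lines.append(f"  channel {k}: preferred direction {th:6.1f} deg (screen, cw+)")
        return "\n".join(lines)

    def save(self, path) -> Path:
        """Serialise all kernels and parameters to a .npz container."""
        path = Path(path)
        arrays = {
            "directions": self.directions,
            "wavelengths": np.array(self.wavelengths),
            "params": np.array([self.sigma_px, self.tau_frames, self.kernel_size, self.n_taps]),
            "temporal_fast": self.temporal_pair.fast,
            "temporal_slow": self.temporal_pair.slow,
        }
        for i, ch in enumerate(self.channels):
            arrays[f"even_{i}"] = ch.kernel_even
            arrays[f"odd_{i}"] = ch.kernel_odd
        np.savez(path, **arrays)
        return path


def build_filterbank(
    K: int = DEFAULTS["K"],
    wavelength_px: float | Sequence[float] = DEFAULTS["wavelength_px"],
    sigma_px: float = DEFAULTS["sigma_px"],
    tau_frames: float = DEFAULTS["tau_frames"],
    kernel_size: int = DEFAULTS["kernel_size"],
    n_taps: int = DEFAULTS["n_taps"],
) -> FilterBank:
    """Construct the K-direction spatiotemporal energy filter bank.

    K must be even (the opponent stage pairs each channel with its
    opposite) and at least 4. ``wavelength_px`` may be a sequence to build
    a multi-scale bank whose energies are summed per direction.
    """
    if K < 4 or K % 2:
        raise ParameterError("K must be even and >= 4")
    wavelengths = (
        (float(wavelength_px),) if np.isscalar(wavelength_px) else tuple(float(w) for w in wavelength_px)
    )
    tp = make_temporal_pair(tau_frames, n_taps)
    directions = np.array([360.0 * k / K for k in range(K)])
    spatial_pairs, channels = [], []
    for wl in wavelengths:
        for theta in directions:
            sp = make_spatial_quadrature(wl, sigma_px, theta, kernel_size)
            spatial_pairs.append(sp)
            channels.append(_direction_channel(sp, tp, theta))
    return FilterBank(
        channels=tuple(channels),
        directions=directions,
        wavelengths=wavelengths,
        sigma_px=sigma_px,
        tau_frames=tau_frames,
        kernel_size=kernel_size,
        n_taps=n_taps,
        spatial_pairs=tuple(spatial_pairs),
        temporal_pair=tp,
    )
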