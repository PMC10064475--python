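import numpy as np
import pytest

from motionenergy import build_filterbank
from motionenergy.filterbank import FilterBank


@pytest.fixture(scope="session")
def bank() -> FilterBank:
    """Default 8-direction filter bank shared across tests."""
    return build_filterbank()


def batch_opponent_oracle(frames: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Brute-force batch reference: full 3-D correlation over the volume.

    Pads the volume spatially (symmetric mirror, matching the engine's
    boundary rule), slides each channel's complete x-y-t kernel over it
    with a plain tensor contraction, squares and sums the quadrature pair,
    and subtracts opposite directions. Shares no code with the streaming
    separable engine. float64 throughout.
    """
    frames = np.asarray(frames, dtype=np.float64)
    T = bank.n_taps
    c = bank.kernel_size // 2
    padded = np.pad(frames, ((0, 0), (c, c), (c, c)), mode="symmetric")
    win = np.lib.stride_tricks.sliding_window_view(
        padded, (T, bank.kernel_size, bank.kernel_size)
    )
    E = np.zeros((*win.shape[:3], bank.K))
    for i, ch in enumerate(bank.channels):
        # kernels are lag-ordered (0 = newest); windows are oldest-first
        re = np.tensordot(win, ch.kernel_even[::-1], axes=([3, 4, 5], [0, 1, 2]))
        ro = np.tensordot(win, ch.kernel_odd[::-1], axes=([3, 4, 5], [0, 1, 2]))
        E[..., i % bank.K] += re**2 + ro**2
    half = bank.K // 2
    return np.concatenate(
        [E[..., :half] - E[..., half:], E[..., half:] - E[..., :half]], axis=-1
    )


def energy_series(frames, bank: FilterBank):
    """(energies, opponents) per warmed-up frame via the streaming engine."""
    from motionenergy.energy import MotionEnergyEngine

    eng = MotionEnergyEngine(bank)
    Es, Os = [], []
    for f in frames:
        O = eng.push(f)
        if O is not None:
            Os.append(O)
            Es.append(eng.energy())
    return Es, Os
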