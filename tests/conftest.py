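import numpy as np
import pytest

from pfmap.pf_core import FrequencyGrid
from pfmap.synthgen import DEFAULT_COORDS, CliqueRecording

FS = 2000.0


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    return FrequencyGrid.log_spaced()


@pytest.fixture(scope="session")
def coords() -> np.ndarray:
    return DEFAULT_COORDS.copy()


def tone(freq: float, n: int = 1000, amp: float = 1.0, fs: float = FS) -> np.ndarray:
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def burst(
    freq: float,
    t0_s: float = 0.25,
    width_s: float = 0.003,
    n: int = 1000,
    amp: float = 1.0,
    fs: float = FS,
) -> np.ndarray:
    t = np.arange(n) / fs
    return amp * np.exp(-((t - t0_s) ** 2) / (2 * width_s**2)) * np.sin(
        2 * np.pi * freq * (t - t0_s)
    )


def clique(signals: np.ndarray, fs: float = FS) -> CliqueRecording:
    return CliqueRecording(signals=np.asarray(signals, float), coords=DEFAULT_COORDS.copy(), fs=fs)


def bins_apart(grid: FrequencyGrid, f_a: float, f_b: float) -> int:
    """Distance in grid bins between two frequencies (grid members or not)."""
    fa = int(np.searchsorted(grid.freqs, f_a))
    fb = int(np.searchsorted(grid.freqs, f_b))
    return abs(fa - fb)
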