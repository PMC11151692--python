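"""Wavelet scalogram and peak-frequency trace: eigenfunction behaviour,
ridge extraction, thresholding properties, and cross-checks against
independent spectral estimators."""

import numpy as np
import pytest
from scipy.signal import periodogram, spectrogram

from pfmap.pf_core import (
    FrequencyGrid,
    ThresholdPolicy,
    annotate_pf,
    annotate_voltage,
    cwt_scalogram,
    peak_frequency_trace,
)

from .conftest import FS, bins_apart, burst, tone


def test_zero_signal_gives_zero_scalogram_and_zero_trace(grid):
    scal = cwt_scalogram(np.zeros(1000), FS, grid)
    assert scal.magnitudes.shape == (len(grid), 1000)
    np.testing.assert_array_equal(scal.magnitudes, 0.0)
    np.testing.assert_array_equal(peak_frequency_trace(scal).pf_t, 0.0)


def test_sinusoid_ridge_at_its_frequency_on_interior_samples(grid):
    scal = cwt_scalogram(tone(200.0), FS, grid)
    ridge_rows = scal.magnitudes[:, scal.interior()].argmax(axis=0)
    ridge_freqs = grid.freqs[ridge_rows]
    assert all(bins_apart(grid, f, 200.0) <= 1 for f in np.unique(ridge_freqs))


def test_l1_normalisation_equal_ridge_magnitude_across_frequency(grid):
    # unit-amplitude tones at different frequencies: ridge magnitude ~ 0.5
    # (the analytic half) independent of frequency
    mags = []
    for f in (60.0, 150.0, 300.0, 450.0):
        scal = cwt_scalogram(tone(f), FS, grid)
        mags.append(scal.magnitudes[:, scal.interior()].max())
    assert np.allclose(mags, 0.5, rtol=0.02)


def test_burst_localised_in_time_and_frequency_vs_stft_oracle(grid):
    x = burst(300.0, t0_s=0.25)
    scal = cwt_scalogram(x, FS, grid)
    i, j = np.unravel_index(np.argmax(scal.magnitudes), scal.magnitudes.shape)
    assert abs(j / FS - 0.25) <= 0.005
    assert bins_apart(grid, grid.freqs[i], 300.0) <= 1
    # independent short-time FFT oracle agrees on the dominant frequency
    f_s, t_s, sxx = spectrogram(x, fs=FS, nperseg=128, noverlap=96)
    fi, ti = np.unravel_index(np.argmax(sxx), sxx.shape)
    assert bins_apart(grid, grid.freqs[i], f_s[fi]) <= 1


def test_trace_of_pure_tone_stays_within_one_bin(grid):
    scal = cwt_scalogram(tone(200.0), FS, grid)
    trace = peak_frequency_trace(scal)
    interior = trace.pf_t[scal.interior()]
    assert (interior > 0).all()
    assert all(bins_apart(grid, f, 200.0) <= 1 for f in np.unique(interior))


def test_weak_high_frequency_component_dominates_trace(grid):
    # 20x smaller 300 Hz burst on a 60 Hz carrier: PF reports the sharp
    # component, not the large-amplitude one
    x = tone(60.0) + burst(300.0, amp=0.05)
    scal = cwt_scalogram(x, FS, grid)
    trace = peak_frequency_trace(scal, ThresholdPolicy(rel_frac=0.01))
    at_burst = trace.pf_t[int(0.25 * FS)]
    assert bins_apart(grid, at_burst, 300.0) <= 1
    # FFT oracle confirms the 300 Hz component is present but sub-dominant
    f, p = periodogram(x, fs=FS)
    assert p[np.argmin(np.abs(f - 300))] < p[np.argmin(np.abs(f - 60))]


def test_single_tone_ridge_matches_dense_fft_oracle_on_random_signals(grid):
    rng = np.random.default_rng(1234)
    for _ in range(50):
        f0 = rng.uniform(40.0, 450.0)
        amp = rng.uniform(0.05, 2.0)
        x = tone(f0, amp=amp)
        scal = cwt_scalogram(x, FS, grid)
        ridge = grid.freqs[scal.magnitudes[:, scal.interior()].max(axis=1).argmax()]
        freqs, p = periodogram(x, fs=FS, nfft=8192)
        f_fft = freqs[np.argmax(p)]
        assert bins_apart(grid, ridge, f_fft) <= 1


def test_ridge_frequency_cross_checked_against_pywavelets(grid):
    pywt = pytest.importorskip("pywt")
    x = tone(250.0)
    scal = cwt_scalogram(x, FS, grid)
    mine = grid.freqs[scal.magnitudes[:, scal.interior()].max(axis=1).argmax()]
    scales = pywt.frequency2scale("cmor1.5-1.0", grid.freqs / FS)
    coef, freqs = pywt.cwt(x, scales, "cmor1.5-1.0", sampling_period=1 / FS)
    theirs = freqs[np.abs(coef[:, 300:700]).max(axis=1).argmax()]
    assert bins_apart(grid, mine, theirs) <= 1


def test_amplitude_invariance_of_pf_annotation(grid):
    # relative thresholding with zero floor: scaling the signal never moves PF
    rng = np.random.default_rng(7)
    for _ in range(20):
        x = tone(rng.uniform(50, 120)) + burst(rng.uniform(200, 400), amp=rng.uniform(0.02, 0.5))
        policy = ThresholdPolicy(rel_frac=0.1, abs_floor=0.0)
        ref = annotate_pf(x, FS, grid, policy)
        for c in (0.01, 0.1, 10.0):
            assert annotate_pf(c * x, FS, grid, policy) == ref


def test_raising_rel_frac_never_raises_the_trace(grid):
    rng = np.random.default_rng(42)
    for _ in range(10):
        x = rng.normal(0, 0.1, 1000) + burst(rng.uniform(200, 400))
        scal = cwt_scalogram(x, FS, grid)
        lo = peak_frequency_trace(scal, ThresholdPolicy(rel_frac=0.05)).pf_t
        hi = peak_frequency_trace(scal, ThresholdPolicy(rel_frac=0.4)).pf_t
        assert (hi <= lo).all()


def test_every_nonzero_trace_value_is_a_grid_member(grid):
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.05, 1000) + burst(333.0, amp=0.4)
    trace = peak_frequency_trace(cwt_scalogram(x, FS, grid))
    nz = trace.pf_t[trace.pf_t > 0]
    assert np.isin(nz, grid.freqs).all()


def test_window_of_pre_activation_quiet_returns_zero(grid):
    x = burst(300.0, t0_s=0.35, amp=0.5)
    policy = ThresholdPolicy(rel_frac=0.1, abs_floor=0.01)
    assert annotate_pf(x, FS, grid, policy, window=(100.0, 200.0)) == 0.0
    assert annotate_pf(x, FS, grid, policy, window=(300.0, 400.0)) > 0.0


def test_annotate_voltage_closed_forms_and_windows():
    assert annotate_voltage(np.full(100, 0.7)) == 0.0
    x = tone(10.0, n=200)  # one full cycle at fs=2000
    assert annotate_voltage(x) == pytest.approx(2.0, abs=1e-3)
    assert annotate_voltage(x, FS, window=(0.0, 100.0)) == pytest.approx(2.0, abs=1e-3)
    with pytest.raises(ValueError):
        annotate_voltage(x, FS, window=(50.0, 50.0))


@pytest.mark.parametrize(
    "bad",
    [
        lambda g: cwt_scalogram(np.zeros(10), FS, g),  # too short
        lambda g: cwt_scalogram(np.full(1000, np.nan), FS, g),
        lambda g: cwt_scalogram(np.zeros(1000), 800.0, g),  # grid beyond Nyquist
    ],
)
def test_scalogram_input_validation(grid, bad):
    with pytest.raises(ValueError):
        bad(grid)


def test_grid_and_policy_validation():
    with pytest.raises(ValueError):
        FrequencyGrid(np.array([100.0, 50.0]))
    with pytest.raises(ValueError):
        FrequencyGrid(np.array([-10.0, 50.0]))
    with pytest.raises(ValueError):
        ThresholdPolicy(rel_frac=0.0)
    with pytest.raises(ValueError):
        ThresholdPolicy(rel_frac=0.1, abs_floor=-1.0)
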