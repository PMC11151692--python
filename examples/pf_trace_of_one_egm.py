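"""Compute a peak-frequency trace for a hand-built electrogram.

The signal is a large 60 Hz far-field wave with a 20x smaller 300 Hz burst
riding on it.  The PF trace ignores amplitude and reports the highest
frequency component present at each instant: ~60 Hz on the wave, ~300 Hz
during the burst.
"""

import numpy as np

from pfmap import ThresholdPolicy, cwt_scalogram, peak_frequency_trace

fs = 2000.0
t = np.arange(1000) / fs
farfield = 1.0 * np.sin(2 * np.pi * 60 * t)
burst = 0.05 * np.exp(-((t - 0.25) ** 2) / (2 * 0.003**2)) * np.sin(2 * np.pi * 300 * (t - 0.25))
egm = farfield + burst

scal = cwt_scalogram(egm, fs)
trace = peak_frequency_trace(scal, ThresholdPolicy(rel_frac=0.01))

at_wave = trace.pf_t[int(0.15 * fs)]
at_burst = trace.pf_t[int(0.25 * fs)]
print(f"PF at 150 ms (far-field only): {at_wave:6.1f} Hz")
print(f"PF at 250 ms (burst present):  {at_burst:6.1f} Hz")
print("the 0.05 mV burst dominates the trace despite the 1.0 mV carrier —")
print("PF tracks sharpness, not amplitude")
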