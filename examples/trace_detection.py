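"""Trace-tier spike detection against ground truth.

Renders a light-modulated Poisson spike train as biphasic waveforms (8x the
noise SD) in white Gaussian noise at 25 kHz, band-pass filters 400-5000 Hz,
detects threshold crossings at 5x SD with a 1.5 ms pause, and scores the
detected spikes against the generator's ground-truth timestamps.
"""

import numpy as np

from retinakit import mea, synth

protocol = synth.make_protocol(intensities=[1e14], reps=5, flash_dur=0.35, dark_gap=0.7)
model = synth.RateModel.flat([1e14], on_rate=30.0, spont_rate=8.0)
template = synth.biphasic_template(25000.0, amplitude_sd=8.0)

rec, truth = synth.simulate_trace(protocol, model, template, noise_sd=1e-5, seed=0)
filtered = mea.bandpass_filter(rec)
train = mea.detect_spikes(filtered)

detected = train.times[0]
true_t = np.sort(truth["t_s"].to_numpy())
matched = sum(np.min(np.abs(detected - t)) < 5e-4 for t in true_t) if len(detected) else 0
print(f"ground-truth spikes : {len(true_t)}")
print(f"detected events     : {len(detected)}")
print(f"matched within 0.5ms: {matched}")
print(
    "\nAt 8x noise amplitude the detector recovers essentially every spike "
    "with sub-millisecond timing; misses would indicate threshold or "
    "dead-time misconfiguration."
)
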