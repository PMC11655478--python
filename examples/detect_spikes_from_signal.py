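"""Threshold spike detection on a rendered voltage trace.

Renders a short simulated recording (biphasic spike waveforms on
Gaussian noise), estimates baseline noise from the two quietest 200-ms
segments and detects spikes at +-5 SD, then reports recall against the
simulator's ground-truth spike times.
"""

import numpy as np

from meaburst.pipeline import extract_spikes
from meaburst.simulate import SimConfig, generate_well, render_signal
from meaburst.spikes import estimate_baseline

config = SimConfig(seed=4, duration_s=30.0, n_channels=3)
trains, _ = generate_well(config)
recording = render_signal(trains, config)

baseline = estimate_baseline(recording.signal[0],
                             recording.sampling_rate_hz)
print(f"channel ch00 baseline: mean {baseline.mean_uv:+.3f} uV, "
      f"sd {baseline.sd_uv:.3f} uV "
      f"(quiet segments at {baseline.segment_starts_s[0]:.2f} s and "
      f"{baseline.segment_starts_s[1]:.2f} s)")

detected = extract_spikes(recording)
for ch, truth in trains.trains.items():
    got = detected.trains[ch]
    recall = np.mean([np.any(np.abs(got - t) <= 2e-3) for t in truth])
    print(f"{ch}: {got.size} detected / {truth.size} true spikes, "
          f"recall {recall:.3f} (+-2 ms matching)")
print("\nRecall near 1.0 shows the +-5 SD threshold on the estimated "
      "baseline recovers the simulated spikes; detected counts can sit "
      "below truth because sub-millisecond spike pairs fall inside the "
      "1 ms refractory window.")
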