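"""Compare two burst detections with the timestamp-overlap score.

Detects reverberations on one spike train twice — with the hippocampal
default MaxInterval parameters and with the cortical ISI-100 variant —
and quantifies how much the resulting burst rasters differ using the
normalized overlap error A = sum |b_p - b_t| / sum b_t.
"""

import numpy as np

from meaburst.maxinterval import MaxIntervalParams, detect_reverberations
from meaburst.model import burst_occupancy, burst_overlap_error
from meaburst.simulate import generate_training_dataset

(window,) = generate_training_dataset(1, seed=3)
times = np.flatnonzero(window.spikes) / 1e4

default = detect_reverberations(times, MaxIntervalParams())
cortical = detect_reverberations(
    times, MaxIntervalParams.preset("cortical_isi100"))
print(f"default parameters (15/20/25 ms): {len(default)} reverberations")
print(f"cortical ISI100 (100/100/200 ms): {len(cortical)} reverberations")

err = burst_overlap_error(burst_occupancy(cortical),
                          burst_occupancy(default))
print(f"overlap error of cortical vs default rasters: {err:.3f}")
print("The cortical variant tolerates 100-ms inter-spike intervals, so "
      "it fuses reverberations (and absorbs noise spikes) that the "
      "hippocampal defaults keep separate; the overlap error counts the "
      "extra burst-state timestamps relative to the default raster.")
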