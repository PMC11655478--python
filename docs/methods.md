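# Methods

This note records the scientific and numerical choices behind
`meaburst`: what each stage computes, which knobs matter, what the
simulator does and does not emulate, and where the design was genuinely
open.

## Event model and units

All timestamps are seconds; MaxInterval parameters are exchanged in
milliseconds (the units the burst-detection literature prints) and
converted exactly once at module boundaries. An event interval is
half-open `[start, end)` spanning first to last member spike; a spike
whose time equals an event's `end` belongs to the event (it *is* the
last spike). Half-open semantics make gap and overlap arithmetic
unambiguous: a gap is `next.start − prev.end`, two intervals overlap iff
each starts strictly before the other ends, and touching endpoints
neither overlap nor merge.

## Spike detection

Baseline noise per channel is estimated from two non-overlapping 200-ms
segments "without activity" near the start of the recording. Absence of
activity is operationalized as minimal root-mean-square amplitude: all
200-ms windows on a half-window grid within the first 10 s (config
`search_span_s`) are ranked by RMS and the two lowest non-overlapping
ones are taken; mean and SD are computed over their concatenation. This
is deterministic and matches the intent of picking visually quiet
stretches. A flat signal (SD = 0) is a degenerate-baseline error rather
than silently producing zero spikes everywhere.

Detection emits a spike where `|x − mean|` first exceeds
`threshold_sd × SD` (default 5 — the conventional ±5 SD rule),
timestamps it at the extremum of the absolute deviation within 2 ms
after the crossing, and suppresses further crossings for
`refractory_ms` (default 1 ms). The refractory period and extremum
alignment are not dictated by the detection rule itself; they are
conventional defaults and both are exposed in `SpikeDetectConfig`.
Detection is polarity-symmetric by construction. Recordings are assumed
already band-limited by the acquisition chain; an optional 100 Hz
high-pass / 3.5 kHz low-pass stage (`apply_bandpass`) mirrors a typical
chain for simulator-rendered raw signal, and is off by default.

## MaxInterval detection

The three phases are described in the README. Two conventions are worth
stating because different implementations disagree:

- **Phase order** — merging before duration/count filtering is the
  default (the NeuroExplorer-style convention); `filter_first=True`
  gives the other order. The orders genuinely differ when a short
  fragment sits within *min between* of a valid event.
- **Strictness** — merging (both the *min between* phase and the 300-ms
  burst/network-burst rule) uses strict `<`; the *min duration* and
  *min spikes* filters use `≥`. The opening inter-spike interval counts
  toward the event, i.e. the opening pair is inside it.

`merge_events` always wraps each run of events in a parent (a lone
network reverberation still receives a network-burst parent), keeping
the burst-composition count and the event-table hierarchy well defined;
re-merging changes no span or count because surviving gaps are at least
the threshold.

## Network events

"Active" channels are those with mean firing rate ≥ 0.1 Hz (inclusive).
Candidate network events are connected components of temporal overlap
among active channels' reverberations — no time bins, so results do not
depend on an arbitrary bin phase. A candidate passes when

1. participating distinct channels ≥ ⌈2/3 × n_active⌉, and
2. the sweep-line maximum of simultaneously open reverberations ≥
   ⌈1/2 × required cohort⌉.

Reading "at least half" as referring to the required two-thirds cohort
is a choice; the alternative base (half of the *actual* participants,
which is stricter when more channels join) is available via
`simultaneity_base="actual"`. All fractional channel counts use
ceilings, with ties at exact equality accepted.

## Outcome measures

- MFR averages per-channel rates over **active** channels (dead
  electrodes would otherwise dilute it); `mfr_over_active_only=False`
  averages over all channels. A well with no active channel has MFR 0.
- %RS counts spikes from **all** recorded channels that fall outside
  every network-burst span — a well-level statement, not per-channel.
  With zero spikes it is undefined; with spikes but no network bursts
  it is 100.
- NIBI measures the quiescence (previous end → next start), matching
  the visual meaning of an inter-burst gap; start→start is a config
  flag. CoV-NIBI uses the sample (n−1) standard deviation.
- Definedness: NIBI needs ≥ 2 network bursts; CoV-NIBI needs ≥ 3
  (two intervals — a single interval has no sample SD); NBD, network
  reverberation duration and NBC need ≥ 1 event. Undefined values are
  NaN in memory and empty cells in the metric CSV, never 0.

## Parameter-prediction models

Three variants share one architecture family: `spikes30` (binary spike
raster binned by 30; a bin is 1 if any spike falls in it — mean-binning
is a flag), `signal30` and `signal100` (per-window min-max-normalized
signal, mean-binned). Binning 50 000 samples by 30 yields 1667 bins
with the last bin averaging the remaining 20 samples; by 100, exactly
500 bins. Windows shorter than 5 s are right-padded with zeros before
binning.

The default network is deliberately small for few-hundred-sample
training sets: two conv blocks (16 then 32 filters, kernel 7, max-pool
4), a 64-unit dense layer, and a 3-unit linear head (~213 k parameters
for signal30), trained with Adam (lr 1e-3, batch 32, 40 epochs) on MSE
over the three targets in ms. Targets share a scale so they are not
standardized by default (`standardize_targets` exists). Predictions are
clipped to (2–200, 2–200, 2–500) ms; the two fixed parameters
(min duration 20 ms, min spikes 5) come from config. The network runs
on an in-package numpy implementation (`meaburst.nn`) with analytic
gradients verified against finite differences in the test suite; all
initialization and shuffling flow from the config seed, so training is
bit-reproducible.

Two scores are reported side by side because they answer different
questions: the overlap error `A = Σ|b_p − b_t| / Σ b_t` is a
discrepancy (0 = perfect, can exceed 1 when the prediction
over-detects), normalized by the target's active timestamps so an
all-zero prediction cannot look good; the learning-curve "custom
accuracy" is `max(0, 1 − A)` and rises toward 1. Per-epoch accuracy
tracking re-runs the detector per window and can be disabled
(`track_accuracy=False`) for speed.

Applying a model to a full recording cuts each channel into
consecutive non-overlapping 5-s windows, predicts parameters per
window, detects within windows, and merges events across a boundary
when their gap is below the mean of the two windows' predicted *min
between*. Per-channel-per-window prediction is one defensible scheme
among several (per-well prediction would enforce cross-channel
consistency at the cost of ignoring channel heterogeneity); it is
isolated in `predict_reverberations`, so the policy can be swapped
without touching detection.

## Simulator

The defaults describe one reference condition — a mature, strongly
rhythmic hippocampal culture on a 12-electrode well at 10 kHz:
network-burst quiescence ~ Gamma(shape 16, mean 5 s) (CoV ≈ 0.25,
i.e. clearly rhythmic), 1 + Poisson(2) reverberations per burst,
intra-reverberation ISIs exponential with 4 ms mean, inter-reverberation
gaps 40–150 ms, 90 % channel participation with 5 ms onset jitter,
0.1 Hz background spikes, 0.2 Hz isolated noise spikes, 40 ± 8 µV spike
amplitudes on 3 µV noise. All spikes sit on the sample grid so binary
rasters, rendered signal and spike-time lists are mutually consistent.

The central construction guarantee: intra-reverberation ISIs are
truncated at 80 % of min(max start, max end); inter-reverberation gaps
and noise-spike clearances are at least 110 % of the relevant
thresholds; durations and counts exceed the minima. The generating
parameters are therefore *comfortably* optimal — the MaxInterval method
run with them reproduces the ground-truth reverberations exactly, which
is what lets generated training windows carry objective parameter
labels (the synthetic analogue of an expert's choice) and makes
`detect_reverberations(spikes, own params)` reproduce every window's
bursts block with overlap error 0. Parameters for training windows are
drawn as whole milliseconds (containers store integer ms), from
(8–30, 10–40, 15–60) by default; the margins absorb the integer
rounding.

Full-well background spikes are *not* clearance-protected — they land
anywhere, and can attach to or bridge reverberations. This perturbs
event boundaries by milliseconds but leaves well-level network-burst
counts and seconds-scale rhythmicity intact, which is why end-to-end
recovery is exact at the count level while %RS and durations agree only
to a fraction of a percent. Burst- and network-level ground truth is
recomputed from the per-channel ground truth with the package's own
merge/network rules (single source of truth) rather than stored
independently.

What the simulator does **not** emulate: electrode geometry and spatial
correlation structure, waveform diversity and spike sorting ambiguity,
slow drifts and artifacts, development over days in vitro, and the
statistics of any particular real dataset. Passing tests therefore
demonstrate algorithmic correctness and recoverability under the stated
generative model, not performance on real recordings; models intended
for real data should be retrained on windows labelled for that data.

## Problem sizes

The shipped tests and the acceptance script use sizes chosen to
exercise every claim at desk scale: 1000 random trains for the
detector-oracle comparison, 500 windows for self-consistency, one
600-s/12-channel well (~115 network bursts) for end-to-end recovery,
and 400 windows (20 % held out) for CNN training. Accuracy on the
held-out split saturates near 0.99 within ~15 epochs under the default
conditions; 40 epochs is kept as a comfortable default.

## Known limitations

- The windowed model-driven path guarantees equivalence with whole-train
  detection only when no event straddles a window boundary; straddling
  events are re-joined by the boundary-merge rule, which can differ from
  whole-train detection when a fragment alone fails the duration/count
  filter.
- `burst_overlap_error` is undefined for an all-zero target window by
  design; windows without bursts are excluded from accuracy averages.
- The delimited-text recording reader exists for interoperability and
  loads the whole file eagerly; the HDF5 layout is the canonical input.
  Vendor-proprietary acquisition formats are out of scope.
- CoV-NIBI at exactly two network bursts is reported as missing (one
  interval has no sample SD) even though NIBI itself is defined.
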