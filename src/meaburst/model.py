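"""Learned prediction of MaxInterval parameters from 5-s MEA windows.

Three input variants feed a small 1-D CNN that regresses the three
learnable detector parameters (max interval to start, max interval to
end, min interval between, all in ms):

``spikes30``
    binary spike train binned by 30 samples -> length 1667;
``signal30``
    min-max-normalized signal, mean-binned by 30 -> length 1667;
``signal100``
    min-max-normalized signal, mean-binned by 100 -> length 500.

Training minimizes mean squared error against the target parameters and
additionally tracks a burst-overlap score: bursts detected with the
predicted parameters are compared timestamp-wise with bursts detected
with the target parameters, normalized by the target's active
timestamps (``burst_overlap_error``); the learning-curve "custom
accuracy" is ``max(0, 1 - error)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import TrainingSample, WINDOW_LEN
from .maxinterval import EventInterval, MaxIntervalParams, detect_reverberations
from .nn import Adam, Conv1D, Dense, Flatten, MaxPool1D, Network, ReLU, mse_loss

log = logging.getLogger(__name__)

VARIANTS = ("spikes30", "signal30", "signal100")
VARIANT_FACTOR = {"spikes30": 30, "signal30": 30, "signal100": 100}
VARIANT_LENGTH = {"spikes30": 1667, "signal30": 1667, "signal100": 500}

#: clipping bounds for predicted parameters, ms
DEFAULT_CLIP_BOUNDS = ((2.0, 200.0), (2.0, 200.0), (2.0, 500.0))


@dataclass(frozen=True)
class ModelInput:
    values: np.ndarray
    variant: str

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        expect = VARIANT_LENGTH[self.variant]
        if self.values.shape != (expect,):
            raise ValueError(
                f"{self.variant} input must have length {expect}, "
                f"got {self.values.shape}")


@dataclass(frozen=True)
class ParamPrediction:
    """Three predicted parameters plus the two fixed ones from config."""

    params_ms: tuple[float, float, float]
    min_duration_ms: float = 20.0
    min_spikes: int = 5

    def as_maxinterval(self) -> MaxIntervalParams:
        s, e, b = self.params_ms
        return MaxIntervalParams(s, e, b, self.min_duration_ms,
                                 self.min_spikes)


@dataclass(frozen=True)
class ArchitectureSpec:
    """(filters, kernel, pool) conv blocks, one hidden dense layer, and a
    3-unit linear output head."""

    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 7, 4), (32, 7, 4))
    dense_width: int = 64
    output_width: int = 3

    def to_dict(self) -> dict:
        return {"conv_blocks": [list(b) for b in self.conv_blocks],
                "dense_width": self.dense_width,
                "output_width": self.output_width}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(conv_blocks=tuple(tuple(b) for b in d["conv_blocks"]),
                   dense_width=int(d["dense_width"]),
                   output_width=int(d.get("output_width", 3)))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    clip_bounds: tuple = DEFAULT_CLIP_BOUNDS
    min_duration_ms: float = 20.0
    min_spikes: int = 5
    spikes_binarize: bool = True         # any-spike-in-bin indicator
    standardize_targets: bool = False    # z-score the 3 targets
    track_accuracy: bool = True          # burst-overlap score per epoch

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


# ---------------------------------------------------------------------------
# preprocessing


def _bin_means(x: np.ndarray, factor: int) -> np.ndarray:
    """Mean over consecutive bins of ``factor`` samples; the final short
    bin averages the remaining samples."""
    edges = np.arange(0, x.size, factor)
    sums = np.add.reduceat(x, edges)
    counts = np.diff(np.append(edges, x.size))
    return sums / counts


def preprocess_window(window, variant: str,
                      spikes_binarize: bool = True) -> ModelInput:
    """Turn one 5-s window into a model input.

    ``window`` is a `TrainingSample` or a raw array (signal for the
    signal variants, binary spikes for ``spikes30``). Shorter windows are
    right-padded with zeros to 50,000 samples before binning. Signal is
    min-max normalized to [0, 1] per window; a zero-dynamic-range window
    yields an all-zero input with a warning.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if isinstance(window, TrainingSample):
        x = window.spikes if variant == "spikes30" else window.signal
    else:
        x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size > WINDOW_LEN:
        raise ValueError(f"window must be 1-D with <= {WINDOW_LEN} samples")
    if x.size < WINDOW_LEN:
        x = np.pad(x, (0, WINDOW_LEN - x.size))
    factor = VARIANT_FACTOR[variant]
    if variant == "spikes30":
        if not np.isin(x, (0, 1)).all():
            raise ValueError("spikes30 input must be binary")
        binned = _bin_means(x, factor)
        if spikes_binarize:
            binned = (binned > 0).astype(float)
    else:
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            warnings.warn("window has zero dynamic range; "
                          "emitting all-zero model input")
            binned = np.zeros(VARIANT_LENGTH[variant])
        else:
            binned = _bin_means((x - lo) / (hi - lo), factor)
    return ModelInput(values=binned, variant=variant)


# ---------------------------------------------------------------------------
# Eq.-1 style burst-overlap scoring


def burst_occupancy(events: list[EventInterval], n: int = WINDOW_LEN,
                    sampling_rate_hz: float = 10_000.0,
                    t0_s: float = 0.0) -> np.ndarray:
    """Binary occupancy array: 1 from each event's first to last spike
    timestamp inclusive."""
    out = np.zeros(n, dtype=np.uint8)
    for ev in events:
        a = int(round((ev.start_s - t0_s) * sampling_rate_hz))
        b = int(round((ev.end_s - t0_s) * sampling_rate_hz))
        out[max(a, 0):min(b, n - 1) + 1] = 1
    return out


def burst_overlap_error(predicted: np.ndarray, target: np.ndarray) -> float:
    """Timestamp-wise discrepancy between two binary burst arrays,
    normalized by the target's active timestamps:
    ``sum |b_p - b_t| / sum b_t``. 0 means identical; an all-zero
    prediction against any non-empty target scores exactly 1."""
    predicted = np.asarray(predicted)
    target = np.asarray(target)
    if predicted.shape != target.shape:
        raise ValueError("arrays must have equal length")
    active = int(target.sum())
    if active == 0:
        raise ValueError("target burst array has no active timestamps; "
                         "the normalization is undefined")
    return float(np.abs(predicted.astype(int) - target.astype(int)).sum()
                 / active)


def custom_accuracy(predicted: np.ndarray, target: np.ndarray) -> float:
    """``max(0, 1 - burst_overlap_error)``: the rising learning-curve
    counterpart of the overlap error."""
    return max(0.0, 1.0 - burst_overlap_error(predicted, target))


# ---------------------------------------------------------------------------
# the model handle


class ParamModel:
    """A trained (or fresh) parameter-prediction network."""

    def __init__(self, net: Network, variant: str, config: TrainConfig,
                 target_mean: np.ndarray | None = None,
                 target_sd: np.ndarray | None = None) -> None:
        self.net = net
        self.variant = variant
        self.config = config
        self.target_mean = target_mean
        self.target_sd = target_sd

    @property
    def n_params(self) -> int:
        return self.net.n_params

    # -- persistence -------------------------------------------------------

    def config_hash(self) -> str:
        blob = json.dumps({"variant": self.variant,
                           "architecture": self.config.architecture.to_dict(),
                           "clip_bounds": self.config.clip_bounds,
                           "min_duration_ms": self.config.min_duration_ms,
                           "min_spikes": self.config.min_spikes},
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["architecture"] = self.config.architecture.to_dict()
        meta = {"variant": self.variant, "config": cfg,
                "config_hash": self.config_hash()}
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        arrays = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        if self.target_mean is not None:
            arrays["target_mean"] = self.target_mean
            arrays["target_sd"] = self.target_sd
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path,
             expect_variant: str | None = None) -> "ParamModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        variant = meta["variant"]
        if expect_variant is not None and variant != expect_variant:
            raise ValueError(
                f"checkpoint variant {variant!r} != expected {expect_variant!r}")
        cfg = dict(meta["config"])
        cfg["architecture"] = ArchitectureSpec.from_dict(cfg["architecture"])
        cfg["split"] = tuple(cfg["split"])
        cfg["clip_bounds"] = tuple(tuple(b) for b in cfg["clip_bounds"])
        config = TrainConfig(**cfg)
        model = build_model(config, variant)
        with np.load(directory / "weights.npz") as z:
            weights = [z[f"w{i}"] for i in range(len(model.net.get_weights()))]
            model.net.set_weights(weights)
            if "target_mean" in z:
                model.target_mean = z["target_mean"]
                model.target_sd = z["target_sd"]
        return model

    # -- inference ---------------------------------------------------------

    def predict_raw(self, inputs: np.ndarray) -> np.ndarray:
        """Network output (n, 3) in ms for a (n, length) input batch."""
        out = self.net.forward(inputs[..., None])
        if self.target_mean is not None:
            out = out * self.target_sd + self.target_mean
        return out

    def predict_params(self, window) -> ParamPrediction:
        """Predict the three parameters for one window and attach the two
        fixed ones; predictions are clipped to the configured bounds."""
        if isinstance(window, ModelInput):
            if window.variant != self.variant:
                raise ValueError(
                    f"input variant {window.variant!r} != model "
                    f"variant {self.variant!r}")
            mi = window
        else:
            mi = preprocess_window(window, self.variant,
                                   self.config.spikes_binarize)
        raw = self.predict_raw(mi.values[None, :])[0]
        lo = np.array([b[0] for b in self.config.clip_bounds])
        hi = np.array([b[1] for b in self.config.clip_bounds])
        clipped = np.clip(raw, lo, hi)
        return ParamPrediction(params_ms=tuple(float(v) for v in clipped),
                               min_duration_ms=self.config.min_duration_ms,
                               min_spikes=self.config.min_spikes)


def build_model(config: TrainConfig, variant: str) -> ParamModel:
    """Construct the (untrained) 1-D CNN for a variant; the same seed
    always yields identical initial weights."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    arch = config.architecture
    if arch.output_width != 3:
        raise ValueError("output layer width must be exactly 3 "
                         "(the three learnable MaxInterval parameters)")
    rng = np.random.default_rng(config.seed)
    shape = (VARIANT_LENGTH[variant], 1)
    layers: list = []
    for filters, kernel, pool in arch.conv_blocks:
        conv = Conv1D(shape[1], filters, kernel, rng)
        shape = conv.out_shape(shape)
        if shape[0] <= 0:
            raise ValueError("architecture incompatible with input length "
                             f"{VARIANT_LENGTH[variant]}")
        mp = MaxPool1D(pool)
        layers += [conv, ReLU(), mp]
        shape = mp.out_shape(shape)
        if shape[0] <= 0:
            raise ValueError("architecture incompatible with input length")
    flat = Flatten()
    layers.append(flat)
    n_in = flat.out_shape(shape)[0]
    layers += [Dense(n_in, arch.dense_width, rng), ReLU(),
               Dense(arch.dense_width, arch.output_width, rng)]
    return ParamModel(Network(layers), variant, config)


# ---------------------------------------------------------------------------
# training


def _accuracy_of_params(sample: TrainingSample, params_ms,
                        config: TrainConfig) -> float:
    """Custom accuracy of one parameter triple on one window: detect with
    the (clipped) parameters on the window's spikes and compare occupancy
    with the stored target bursts."""
    if sample.bursts.sum() == 0:
        return float("nan")
    lo = np.array([b[0] for b in config.clip_bounds])
    hi = np.array([b[1] for b in config.clip_bounds])
    s, e, b = np.clip(np.asarray(params_ms, dtype=float), lo, hi)
    mi = MaxIntervalParams(s, e, b, config.min_duration_ms, config.min_spikes)
    times = np.flatnonzero(sample.spikes) / 1e4
    events = detect_reverberations(times, mi)
    return custom_accuracy(burst_occupancy(events), sample.bursts)


@dataclass
class LearningCurves:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        rows = []
        for i in range(len(self.train_mse)):
            for split, mse, acc in (
                    ("train", self.train_mse, self.train_accuracy),
                    ("validation", self.val_mse, self.val_accuracy)):
                rows.append({
                    "epoch": i + 1, "split": split, "mse": mse[i],
                    "custom_accuracy": acc[i] if i < len(acc) else float("nan"),
                })
        return rows


def split_dataset(n: int, split: tuple[float, float, float],
                  seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled train/validation/test index split."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def train_model(samples: list[TrainingSample], config: TrainConfig,
                variant: str = "signal30"
                ) -> tuple[ParamModel, LearningCurves]:
    """Train the parameter-regression CNN on a training dataset.

    Weights are updated from the training split only (MSE on the three
    parameters in ms); the curves record per-epoch MSE for both splits
    and, when ``track_accuracy``, the mean burst-overlap custom accuracy.
    Deterministic for a given seed. ``epochs=0`` returns the
    initialization with empty curves.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to train")
    X = np.stack([preprocess_window(s, variant, config.spikes_binarize).values
                  for s in samples])
    y = np.stack([s.params_ms for s in samples])
    tr, va, _ = split_dataset(len(samples), config.split, config.seed)
    if not (len(tr) and len(va)):
        raise ValueError("train and validation splits must be non-empty")

    model = build_model(config, variant)
    y_fit = y
    if config.standardize_targets:
        model.target_mean = y[tr].mean(axis=0)
        model.target_sd = y[tr].std(axis=0) + 1e-12
        y_fit = (y - model.target_mean) / model.target_sd

    opt = Adam(model.net, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    curves = LearningCurves()
    Xt = X[..., None]

    def epoch_metrics(idx):
        pred_fit = model.net.forward(Xt[idx])
        mse = float(np.mean((pred_fit - y_fit[idx]) ** 2))
        acc = float("nan")
        if config.track_accuracy:
            pred_ms = pred_fit
            if config.standardize_targets:
                pred_ms = pred_fit * model.target_sd + model.target_mean
            accs = [_accuracy_of_params(samples[i], pred_ms[k], config)
                    for k, i in enumerate(idx)]
            accs = [a for a in accs if not np.isnan(a)]
            acc = float(np.mean(accs)) if accs else float("nan")
        return mse, acc

    for epoch in range(config.epochs):
        order = rng.permutation(tr)
        for lo_i in range(0, len(order), config.batch_size):
            batch = order[lo_i:lo_i + config.batch_size]
            pred = model.net.forward(Xt[batch])
            loss, dpred = mse_loss(pred, y_fit[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch "
                    f"{epoch + 1}; lower the learning rate")
            model.net.backward(dpred)
            opt.step()
        tr_mse, tr_acc = epoch_metrics(tr)
        va_mse, va_acc = epoch_metrics(va)
        curves.train_mse.append(tr_mse)
        curves.val_mse.append(va_mse)
        curves.train_accuracy.append(tr_acc)
        curves.val_accuracy.append(va_acc)
        log.info("epoch %d/%d train mse %.3f val mse %.3f val acc %.3f",
                 epoch + 1, config.epochs, tr_mse, va_mse, va_acc)
    return model, curves


def evaluate_model(model: ParamModel, samples: list[TrainingSample],
                   indices=None) -> dict:
    """Mean squared error, mean burst-overlap error and mean custom
    accuracy of a model on (a subset of) a dataset."""
    if indices is None:
        indices = range(len(samples))
    indices = list(indices)
    errs, accs, sqs = [], [], []
    for i in indices:
        s = samples[i]
        pred = model.predict_params(s)
        sqs.append(np.mean((np.array(pred.params_ms) - s.params_ms) ** 2))
        if s.bursts.sum():
            err = burst_overlap_error(
                _occupancy_for(s, pred, model.config), s.bursts)
            errs.append(err)
            accs.append(max(0.0, 1.0 - err))
    return {"n": len(indices),
            "mse": float(np.mean(sqs)) if sqs else float("nan"),
            "mean_overlap_error": float(np.mean(errs)) if errs else float("nan"),
            "mean_custom_accuracy": float(np.mean(accs)) if accs else float("nan")}


def _occupancy_for(sample: TrainingSample, pred: ParamPrediction,
                   config: TrainConfig) -> np.ndarray:
    times = np.flatnonzero(sample.spikes) / 1e4
    return burst_occupancy(detect_reverberations(times, pred.as_maxinterval()))


# ---------------------------------------------------------------------------
# applying a model to whole recordings / spike trains


def predict_reverberations(spike_trains, model: ParamModel,
                           duration_s: float,
                           recording=None,
                           window_s: float = 5.0
                           ) -> dict[str, list[EventInterval]]:
    """Detect reverberations channel by channel with per-window predicted
    parameters.

    Each channel is cut into consecutive non-overlapping ``window_s``
    windows; the model predicts parameters per window (signal variants
    need ``recording``; ``spikes30`` builds its input from the spike
    train) and the MaxInterval method runs inside each window. Events
    abutting a window boundary are merged across it when their gap is
    under the mean of the two windows' predicted min-between. Empty
    windows are skipped without a prediction call.
    """
    if model.variant != "spikes30" and recording is None:
        raise ValueError(f"{model.variant} model needs the raw recording")
    t0 = getattr(spike_trains, "t0_s", 0.0)
    n_windows = max(1, int(np.ceil(duration_s / window_s)))
    if duration_s < window_s:
        warnings.warn("recording shorter than one window; "
                      "processing as a single zero-padded window")
    out: dict[str, list[EventInterval]] = {}
    rate = recording.sampling_rate_hz if recording is not None else 10_000.0
    for ci, (ch, times) in enumerate(spike_trains.trains.items()):
        events: list[EventInterval] = []
        boundary_between: list[float] = []  # predicted min_between per window
        for w in range(n_windows):
            a, b = t0 + w * window_s, t0 + (w + 1) * window_s
            in_win = times[(times >= a) & (times < b)]
            if in_win.size == 0:
                boundary_between.append(np.nan)
                continue
            if model.variant == "spikes30":
                occ = np.zeros(int(round(window_s * 1e4)), dtype=np.uint8)
                occ[np.round((in_win - a) * 1e4).astype(int)] = 1
                window = occ
            else:
                i0 = int(round((a - t0) * rate))
                i1 = min(int(round((b - t0) * rate)),
                         recording.signal.shape[1])
                window = recording.signal[ci, i0:i1]
            pred = model.predict_params(window)
            params = pred.as_maxinterval()
            boundary_between.append(params.min_between_ms)
            new = detect_reverberations(in_win, params, channel=ch)
            # merge across the window boundary when the gap is under the
            # mean of the two windows' predicted min-between
            if (events and new
                    and len(boundary_between) >= 2):
                prev_between = next(
                    (v for v in reversed(boundary_between[:-1])
                     if not np.isnan(v)), np.nan)
                if not np.isnan(prev_between):
                    gap_ms = (new[0].start_s - events[-1].end_s) * 1e3
                    if gap_ms < (prev_between + params.min_between_ms) / 2:
                        prev = events.pop()
                        first = new.pop(0)
                        events.append(EventInterval(
                            start_s=prev.start_s, end_s=first.end_s,
                            spike_count=prev.spike_count + first.spike_count,
                            channel=ch))
            events.extend(new)
        out[ch] = events
    return out
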