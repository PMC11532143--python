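"""Soft-sensing pipeline: estimate hard-to-measure state from easy signals.

Offline biomass assays arrive every few hours; the fused frame carries a
per-minute feature vector (stirring speed, DO, feed rate, pH, temperature,
broth weight, airflow, pump speeds, plus derived CER/OUR).  The pipeline

1. assembles one sample per fused grid point (features + interpolated
   biomass target), optionally excluding spans flagged by a fault report;
2. splits samples 8:2 into training and validation (random over samples
   by default, batch-blocked mode available);
3. fits a pluggable regressor on z-scored features (training statistics
   only) and records a loss curve;
4. predicts the target along a fused frame in original units, point by
   point, exactly as a streaming deployment would.

The reference regressor is a small multilayer perceptron (default four
hidden layers, i.e. six layers counting input and output); a linear model
is provided as a transparent baseline.  Models serialize with their
feature statistics embedded so a reloaded model predicts bitwise
identically.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor

from .faults import FaultReport
from .model import FusedFrame, RangeError, SourceClass, TimeSeries

__all__ = [
    "DEFAULT_FEATURES",
    "FeatureSpec",
    "SampleSet",
    "SoftSensor",
    "make_regressor",
    "assemble_samples",
    "split_train_val",
    "fit_soft_sensor",
    "predict_stream",
    "save_model",
    "load_model",
]

DEFAULT_FEATURES = [
    "agitation", "do", "feed_rate", "ph", "temperature", "weight",
    "air_flow", "acid_pump", "inspection_pump", "CER", "OUR",
]


@dataclass
class FeatureSpec:
    """Which fused columns feed the model and which offline variable it predicts."""

    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))
    target: str = "biomass"

    def __post_init__(self) -> None:
        if self.target in self.features:
            raise RangeError(f"target {self.target!r} listed among features")


@dataclass
class SampleSet:
    """Aligned (features, target) samples with their times and batch labels."""

    X: np.ndarray
    y: np.ndarray
    times: np.ndarray
    batch_labels: np.ndarray
    feature_names: list[str]
    target_name: str
    dropped: int = 0  # rows discarded for missing features/target

    def __len__(self) -> int:
        return self.y.size

    def subset(self, idx: np.ndarray) -> "SampleSet":
        return SampleSet(X=self.X[idx], y=self.y[idx], times=self.times[idx],
                         batch_labels=self.batch_labels[idx],
                         feature_names=list(self.feature_names),
                         target_name=self.target_name)


def assemble_samples(
    frames: list[FusedFrame] | FusedFrame,
    spec: FeatureSpec,
    fault_reports: dict[str, FaultReport] | None = None,
) -> SampleSet:
    """One sample per fused grid point where features and target are finite.

    Rows with any missing value are dropped and counted.  If a fault
    report is supplied for a batch, samples inside anomalous intervals
    are excluded as well.
    """
    if isinstance(frames, FusedFrame):
        frames = [frames]
    X_parts, y_parts, t_parts, b_parts = [], [], [], []
    dropped = 0
    for frame in frames:
        missing_cols = [c for c in [*spec.features, spec.target] if c not in frame.data.columns]
        if missing_cols:
            raise RangeError(f"fused frame lacks column(s) {missing_cols}")
        bid = frame.meta.batch_id if frame.meta else "batch"
        X = frame.data[spec.features].to_numpy(dtype=float)
        y = frame.data[spec.target].to_numpy(dtype=float)
        keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
        if fault_reports and bid in fault_reports:
            for iv in fault_reports[bid].intervals:
                keep &= ~((frame.times >= iv.start) & (frame.times <= iv.end))
        dropped += int((~keep).sum())
        X_parts.append(X[keep])
        y_parts.append(y[keep])
        t_parts.append(frame.times[keep])
        b_parts.append(np.full(int(keep.sum()), bid, dtype=object))
    X = np.vstack(X_parts)
    if X.shape[0] == 0:
        raise RangeError("no usable samples after dropping missing rows")
    return SampleSet(X=X, y=np.concatenate(y_parts), times=np.concatenate(t_parts),
                     batch_labels=np.concatenate(b_parts),
                     feature_names=list(spec.features), target_name=spec.target,
                     dropped=dropped)


def split_train_val(
    s: SampleSet, ratio: float = 0.8, seed: int = 0, *, by_batch: bool = False
) -> tuple[SampleSet, SampleSet]:
    """Random 8:2 partition: |train| = round(ratio*n), disjoint, exhaustive.

    ``by_batch=True`` assigns whole batches to one side (methodologically
    safer when batches are strongly autocorrelated), still targeting the
    sample-count ratio as closely as whole batches allow.
    """
    n = len(s)
    if n < 5:
        raise RangeError(f"need >= 5 samples to split, have {n}")
    rng = np.random.default_rng(seed)
    if by_batch:
        ids = list(dict.fromkeys(s.batch_labels.tolist()))
        rng.shuffle(ids)
        target = round(ratio * n)
        train_ids, count = [], 0
        for bid in ids:
            if count < target:
                train_ids.append(bid)
                count += int((s.batch_labels == bid).sum())
        train_mask = np.isin(s.batch_labels, train_ids)
    else:
        perm = rng.permutation(n)
        k = round(ratio * n)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[perm[:k]] = True
    return s.subset(np.flatnonzero(train_mask)), s.subset(np.flatnonzero(~train_mask))


# ---------------------------------------------------------------------------
# Regressors

def make_regressor(kind: str = "mlp", seed: int = 0, **kwargs):
    """Reference regressors satisfying the fit/predict contract.

    ``mlp``: multilayer perceptron, hidden layers (64, 64, 32, 16) by
    default (six layers counting input and output).  ``linear``: ordinary
    least squares, used as the transparent baseline in tests.
    """
    if kind == "linear":
        return LinearRegression(**kwargs)
    if kind == "mlp":
        opts = dict(
            hidden_layer_sizes=(64, 64, 32, 16),
            activation="relu",
            solver="adam",
            learning_rate_init=3e-3,
            max_iter=400,
            tol=1e-6,
            random_state=seed,
        )
        opts.update(kwargs)
        return MLPRegressor(**opts)
    raise RangeError(f"unknown regressor kind {kind!r}")


@dataclass
class SoftSensor:
    """A fitted regressor plus the standardization statistics it was trained with."""

    model: object
    feature_names: list[str]
    target_name: str
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.model.predict(Z) * self.y_scale + self.y_mean


def fit_soft_sensor(
    train: SampleSet,
    model=None,
    val: SampleSet | None = None,
) -> SoftSensor:
    """Standardize with training statistics only, fit, and record losses.

    The loss curve is the regressor's own iteration history where it keeps
    one (MLP); for one-shot fits a single final MSE is recorded.  A
    non-finite loss aborts with a diagnostic.
    """
    x_mean = train.X.mean(axis=0)
    x_scale = train.X.std(axis=0, ddof=0)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    y_mean = float(train.y.mean())
    y_scale = float(train.y.std(ddof=0)) or 1.0
    Z = (train.X - x_mean) / x_scale
    yz = (train.y - y_mean) / y_scale
    model = model if model is not None else make_regressor("mlp")
    model.fit(Z, yz)
    sensor = SoftSensor(model=model, feature_names=list(train.feature_names),
                        target_name=train.target_name, x_mean=x_mean, x_scale=x_scale,
                        y_mean=y_mean, y_scale=y_scale)
    history = list(getattr(model, "loss_curve_", []))
    if history and not np.isfinite(history).all():
        raise RangeError("training diverged: non-finite loss in the loss curve")
    train_mse = float(np.mean((sensor.predict(train.X) - train.y) ** 2))
    sensor.train_loss = history or [train_mse]
    if val is not None and len(val):
        sensor.val_loss = [float(np.mean((sensor.predict(val.X) - val.y) ** 2))]
    if not np.isfinite(sensor.train_loss[-1]):
        raise RangeError("training diverged: non-finite final loss")
    return sensor


def predict_stream(sensor: SoftSensor, frame: FusedFrame, spec: FeatureSpec | None = None) -> TimeSeries:
    """Predict the target along a fused frame, in original units.

    The prediction is stateless per grid point, so streaming the points in
    any order gives the same series.
    """
    names = spec.features if spec is not None else sensor.feature_names
    if list(names) != list(sensor.feature_names):
        raise RangeError("feature list does not match the fitted model")
    missing = [c for c in names if c not in frame.data.columns]
    if missing:
        raise RangeError(f"fused frame lacks feature column(s) {missing}")
    X = frame.data[list(names)].to_numpy(dtype=float)
    yhat = sensor.predict(X)
    return TimeSeries(variable=f"{sensor.target_name}_pred", unit="",
                      source=SourceClass.ONLINE, times=frame.times.copy(), values=yhat)


def save_model(sensor: SoftSensor, path) -> None:
    """Serialize the sensor (model + embedded feature statistics)."""
    with open(path, "wb") as fh:
        pickle.dump(sensor, fh)


def load_model(path) -> SoftSensor:
    with open(path, "rb") as fh:
        sensor = pickle.load(fh)
    if not isinstance(sensor, SoftSensor):
        raise RangeError(f"{path}: not a saved soft-sensor model")
    return sensor
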