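"""Data-driven observation model: biomass -> cumulative off-gas signals.

The measurement quantities of the soft sensor are the cumulative oxygen
uptake (cOUR) and cumulative carbon-dioxide production (cCPR).  Simple
linear laws of the Luedeking-Piret type are not accurate enough for these
curves, so the measurement map ``H: X -> (cOUR, cCPR)`` is learned from
data: one epsilon-insensitive support-vector regressor with an RBF kernel
per channel, trained on (X, signal) pairs pooled across cultivation runs
with a seeded 70/30 train/validation holdout.

Fitting uses scikit-learn's libsvm-backed ``SVR``; prediction is a plain
numpy RBF expansion over the extracted support vectors, so a trained model
serializes to JSON and round-trips bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.metrics import r2_score
from sklearn.svm import SVR

from .errors import ConfigurationError, TrainingError

logger = logging.getLogger(__name__)

CHANNELS = ("cOUR", "cCPR")


@dataclass(frozen=True)
class TrainingSet:
    """Pooled (X, cOUR, cCPR) training points with per-point run labels."""

    X_values: np.ndarray
    cOUR_values: np.ndarray
    cCPR_values: np.ndarray
    run_labels: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.X_values, dtype=float)
        o = np.asarray(self.cOUR_values, dtype=float)
        c = np.asarray(self.cCPR_values, dtype=float)
        labels = np.asarray(self.run_labels)
        if not (x.shape == o.shape == c.shape == labels.shape) or x.ndim != 1:
            raise ValueError("training columns must be equal-length 1-d")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(o)) \
                or not np.all(np.isfinite(c)):
            raise ValueError("training set contains non-finite values")
        if np.any(x < 0) or np.any(o < 0) or np.any(c < 0):
            raise ValueError("X and cumulative signals must be non-negative")
        object.__setattr__(self, "X_values", x)
        object.__setattr__(self, "cOUR_values", o)
        object.__setattr__(self, "cCPR_values", c)
        object.__setattr__(self, "run_labels", labels)
        # cumulative signals should be non-decreasing in X within a run;
        # measurement noise may break this, so warn rather than reject
        for run in np.unique(labels):
            m = labels == run
            order = np.argsort(x[m])
            for name, col in (("cOUR", o), ("cCPR", c)):
                if np.any(np.diff(col[m][order]) < 0):
                    logger.warning(
                        "run %r: %s not monotone in X (noisy pairing?)",
                        run, name)
                    break

    def __len__(self) -> int:
        return self.X_values.size


class _Channel:
    """One trained RBF-SVR channel, stored as raw arrays.

    Prediction (on standardized input z):
    ``y_std(z) = sum_i alpha_i exp(-gamma (z - sv_i)^2) + b``,
    de-standardized with the training-partition target moments.
    """

    def __init__(self, support_vectors, dual_coef, intercept, gamma, epsilon,
                 C, x_mean, x_std, y_mean, y_std):
        self.support_vectors = np.asarray(support_vectors, dtype=float).ravel()
        self.dual_coef = np.asarray(dual_coef, dtype=float).ravel()
        self.intercept = float(intercept)
        self.gamma = float(gamma)
        self.epsilon = float(epsilon)
        self.C = float(C)
        self.x_mean = float(x_mean)
        self.x_std = float(x_std)
        self.y_mean = float(y_mean)
        self.y_std = float(y_std)

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        d2 = (z[..., None] - self.support_vectors[None, :]) ** 2
        k = np.exp(-self.gamma * d2)
        # per-row summation keeps batch and single-point reduction order
        # identical, so vectorized prediction is bit-equal to a loop
        acc = np.sum(k * self.dual_coef, axis=-1)
        return (acc + self.intercept) * self.y_std + self.y_mean

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept, "gamma": self.gamma,
            "epsilon": self.epsilon, "C": self.C,
            "x_mean": self.x_mean, "x_std": self.x_std,
            "y_mean": self.y_mean, "y_std": self.y_std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Channel":
        return cls(**d)


class ObservationPrediction(NamedTuple):
    cOUR: np.ndarray | float
    cCPR: np.ndarray | float
    extrapolated: np.ndarray | bool


@dataclass
class ValidationReport:
    """Per-channel holdout scores from training."""

    n_train: int
    n_validation: int
    split_seed: int
    rmse_train: dict = field(default_factory=dict)
    rmse_validation: dict = field(default_factory=dict)
    r2_train: dict = field(default_factory=dict)
    r2_validation: dict = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)


class ObservationModel:
    """Measurement map ``H: X -> (cOUR, cCPR)`` of the state estimator."""

    def __init__(self, channels: dict, x_range: tuple[float, float],
                 metadata: dict | None = None):
        missing = [c for c in CHANNELS if c not in channels]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        self.channels = channels
        self.x_range = (float(x_range[0]), float(x_range[1]))
        self.metadata = metadata or {}

    def predict(self, X) -> ObservationPrediction:
        """Predict both channels; flags queries outside the training range.

        Scalar input returns scalars, array input returns arrays of the
        same shape.  Extrapolation beyond the training X range is permitted
        but indicated through ``extrapolated``.
        """
        scalar = np.isscalar(X) or np.ndim(X) == 0
        x = np.atleast_1d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("prediction input must be finite")
        if np.any(x < 0):
            raise ValueError("biomass concentration must be non-negative")
        cour = self.channels["cOUR"].predict(x)
        ccpr = self.channels["cCPR"].predict(x)
        extrap = (x < self.x_range[0]) | (x > self.x_range[1])
        if scalar:
            return ObservationPrediction(float(cour[0]), float(ccpr[0]),
                                         bool(extrap[0]))
        return ObservationPrediction(cour, ccpr, extrap)

    def observe(self, X) -> np.ndarray:
        """Both channels stacked as a (..., 2) array; filter-facing helper."""
        p = self.predict(X)
        return np.stack([np.atleast_1d(p.cOUR), np.atleast_1d(p.cCPR)],
                        axis=-1).squeeze()

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {"channels": {n: ch.to_dict() for n, ch in self.channels.items()},
                "x_range": list(self.x_range), "metadata": self.metadata}

    @classmethod
    def from_dict(cls, d: dict) -> "ObservationModel":
        channels = {n: _Channel.from_dict(cd)
                    for n, cd in d["channels"].items()}
        return cls(channels, tuple(d["x_range"]), d.get("metadata"))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "ObservationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


DEFAULT_GRID = {
    "C": (1.0, 10.0, 100.0),
    # epsilon as a fraction of the target range; the grid reaches down to
    # 0.1% because cumulative off-gas curves start near zero and a wide
    # epsilon-tube would swallow the whole low-signal region, flattening
    # the fit exactly where the filter needs local slope
    "epsilon_frac": (0.001, 0.002, 0.005, 0.01, 0.02),
    "gamma": (0.1, 1.0, 10.0),
}


def _fit_channel(x_train, y_train, x_val, y_val, grid) -> tuple[_Channel, dict]:
    x_mean, x_std = float(np.mean(x_train)), float(np.std(x_train))
    if x_std == 0.0:
        raise TrainingError("degenerate training data: constant X")
    y_mean, y_std = float(np.mean(y_train)), float(np.std(y_train))
    if y_std == 0.0:
        y_std = 1.0  # constant target: fit in raw offsets
    zt = ((x_train - x_mean) / x_std).reshape(-1, 1)
    zv = ((x_val - x_mean) / x_std).reshape(-1, 1)
    wt = (y_train - y_mean) / y_std
    y_range = float(np.ptp(y_train))
    best = None
    for C in grid["C"]:
        for ef in grid["epsilon_frac"]:
            eps = ef * y_range / y_std
            for gamma in grid["gamma"]:
                svr = SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
                svr.fit(zt, wt)
                pred_val = svr.predict(zv) * y_std + y_mean
                rmse = float(np.sqrt(np.mean((pred_val - y_val) ** 2)))
                key = (rmse, C, ef, gamma)  # deterministic tie-break
                if best is None or key < best[0]:
                    best = (key, svr, {"C": C, "epsilon_frac": ef,
                                       "gamma": gamma, "epsilon": eps})
    _, svr, hyper = best
    channel = _Channel(
        support_vectors=svr.support_vectors_, dual_coef=svr.dual_coef_,
        intercept=svr.intercept_[0], gamma=hyper["gamma"],
        epsilon=hyper["epsilon"], C=hyper["C"],
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std)
    return channel, hyper


def train_observation_model(data: TrainingSet, hyper: dict | None = None,
                            split_fraction: float = 0.7,
                            seed: int = 0) -> tuple[ObservationModel,
                                                    ValidationReport]:
    """Train both SVR channels on a seeded random train/validation split.

    For each channel the hyperparameters (C, epsilon, gamma) minimizing
    validation RMSE are selected from the grid and the winning model (fit
    on the training partition) is kept.  Both channels share the same
    split.  Inputs and targets are standardized to the training partition
    before fitting.
    """
    if hyper is None:
        hyper = DEFAULT_GRID
    for k in ("C", "epsilon_frac", "gamma"):
        if k not in hyper or len(hyper[k]) == 0:
            raise ConfigurationError(f"hyperparameter grid missing/empty {k!r}")
    n = len(data)
    if n < 10:
        raise TrainingError(f"need at least 10 training points, got {n}")
    if not 0.0 < split_fraction < 1.0:
        raise ConfigurationError("split_fraction must be in (0, 1)")
    if np.std(data.X_values) == 0.0:
        raise TrainingError("degenerate training data: constant X")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    idx_train, idx_val = perm[:n_train], perm[n_train:]

    x_train, x_val = data.X_values[idx_train], data.X_values[idx_val]
    report = ValidationReport(n_train=n_train, n_validation=n - n_train,
                              split_seed=int(seed))
    channels = {}
    for name in CHANNELS:
        y = getattr(data, f"{name}_values")
        ch, chosen = _fit_channel(x_train, y[idx_train], x_val, y[idx_val],
                                  hyper)
        channels[name] = ch
        pt, pv = ch.predict(x_train), ch.predict(x_val)
        report.rmse_train[name] = float(np.sqrt(np.mean((pt - y[idx_train]) ** 2)))
        report.rmse_validation[name] = float(np.sqrt(np.mean((pv - y[idx_val]) ** 2)))
        report.r2_train[name] = float(r2_score(y[idx_train], pt)) \
            if np.ptp(y[idx_train]) > 0 else 1.0
        report.r2_validation[name] = float(r2_score(y[idx_val], pv)) \
            if np.ptp(y[idx_val]) > 0 else 1.0
        report.hyperparameters[name] = chosen

    model = ObservationModel(
        channels,
        x_range=(float(np.min(x_train)), float(np.max(x_train))),
        metadata={"split_seed": int(seed), "split_fraction": split_fraction,
                  "n_train": n_train, "n_validation": n - n_train,
                  "rmse_validation": dict(report.rmse_validation),
                  "r2_validation": dict(report.r2_validation)})
    return model, report


def build_training_set(runs: Sequence[tuple]) -> TrainingSet:
    """Pair offline biomass samples with interpolated cumulative signals.

    ``runs`` is a sequence of ``(offline_samples, measurement_series)``
    pairs, optionally ``(offline, measurements, label)``.  For every
    offline X sample inside the measurement-series span, cOUR and cCPR are
    linearly interpolated at the sample's timestamp; samples outside the
    span are excluded with a warning.  Points from all runs are pooled.
    """
    xs, cours, ccprs, labels = [], [], [], []
    for i, run in enumerate(runs):
        if len(run) == 3:
            offline, series, label = run
        else:
            offline, series = run
            label = f"run{i}"
        t0, t1 = float(series.times[0]), float(series.times[-1])
        for j, t in enumerate(offline.times):
            if not np.isfinite(offline.X_obs[j]):
                continue
            if t < t0 or t > t1:
                logger.warning("offline sample at t=%.3f h outside "
                               "measurement span [%.3f, %.3f]; excluded",
                               t, t0, t1)
                continue
            xs.append(float(offline.X_obs[j]))
            cours.append(float(np.interp(t, series.times, series.cOUR)))
            ccprs.append(float(np.interp(t, series.times, series.cCPR)))
            labels.append(label)
    if not xs:
        raise TrainingError("no pairable offline samples found")
    return TrainingSet(np.asarray(xs), np.asarray(cours), np.asarray(ccprs),
                       np.asarray(labels))
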