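"""CSV/JSON/YAML readers and writers plus run-configuration loading.

All CSV artifacts use explicit headers; times are hours.  Schemas:

- feed profile:       ``time_h, feed_rate_L_per_h``
- measurement series: ``time_h, cOUR, cCPR``
- offline samples:    ``time_h, biomass_g_per_L, product_g_per_L``
- training set:       ``X_g_per_L, cOUR, cCPR, run_id``
- estimate trajectory: ``time_h, X_hat, ..., innov_cCPR``
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, FormatError
from .measurements import MeasurementSeries
from .observation_model import TrainingSet
from .process_model import FeedProfile, OfflineSamples, ProcessParameters
from .ukf import EstimateTrajectory, UKFConfig

_FLOAT_FMT = "%.9g"   # >= 6 significant digits for times


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _check_strictly_increasing(t: np.ndarray, path) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        i = int(bad[0]) + 1
        if t[i] == t[i - 1]:
            raise DataError(f"{path}: duplicated timestamp at row {i}", row=i)
        raise DataError(f"{path}: non-monotone time at row {i}", row=i)


def read_measurement_series(path) -> MeasurementSeries:
    df = _read_csv(path, ["time_h", "cOUR", "cCPR"])
    t = df["time_h"].to_numpy(dtype=float)
    _check_strictly_increasing(t, path)
    return MeasurementSeries(times=t, cOUR=df["cOUR"].to_numpy(dtype=float),
                             cCPR=df["cCPR"].to_numpy(dtype=float),
                             source=str(path))


def write_measurement_series(series: MeasurementSeries, path) -> None:
    pd.DataFrame({"time_h": series.times, "cOUR": series.cOUR,
                  "cCPR": series.cCPR}).to_csv(path, index=False,
                                               float_format=_FLOAT_FMT)


def read_feed_profile(path) -> FeedProfile:
    df = _read_csv(path, ["time_h", "feed_rate_L_per_h"])
    t = df["time_h"].to_numpy(dtype=float)
    _check_strictly_increasing(t, path)
    return FeedProfile(t, df["feed_rate_L_per_h"].to_numpy(dtype=float))


def write_feed_profile(feed: FeedProfile, path) -> None:
    pd.DataFrame({"time_h": feed.breakpoints,
                  "feed_rate_L_per_h": feed.rates}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_offline_samples(path) -> OfflineSamples:
    df = _read_csv(path, ["time_h", "biomass_g_per_L", "product_g_per_L"])
    t = df["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        i = int(np.flatnonzero(np.diff(t) < 0)[0]) + 1
        raise DataError(f"{path}: offline times not sorted at row {i}", row=i)
    return OfflineSamples(times=t,
                          X_obs=df["biomass_g_per_L"].to_numpy(dtype=float),
                          P_obs=df["product_g_per_L"].to_numpy(dtype=float))


def write_offline_samples(samples: OfflineSamples, path) -> None:
    pd.DataFrame({"time_h": samples.times,
                  "biomass_g_per_L": samples.X_obs,
                  "product_g_per_L": samples.P_obs}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_training_set(path) -> TrainingSet:
    df = _read_csv(path, ["X_g_per_L", "cOUR", "cCPR", "run_id"])
    return TrainingSet(X_values=df["X_g_per_L"].to_numpy(dtype=float),
                       cOUR_values=df["cOUR"].to_numpy(dtype=float),
                       cCPR_values=df["cCPR"].to_numpy(dtype=float),
                       run_labels=df["run_id"].to_numpy())


def write_training_set(ts: TrainingSet, path) -> None:
    pd.DataFrame({"X_g_per_L": ts.X_values, "cOUR": ts.cOUR_values,
                  "cCPR": ts.cCPR_values, "run_id": ts.run_labels}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)


_TRAJ_COLS = ["time_h", "X_hat", "S_hat", "P_hat", "mu_hat",
              "var_X", "var_S", "var_P", "var_mu",
              "cOUR_pred", "cCPR_pred", "innov_cOUR", "innov_cCPR"]


def write_trajectory(traj: EstimateTrajectory, path) -> None:
    traj.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> pd.DataFrame:
    return _read_csv(path, _TRAJ_COLS)


def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_process_parameters(path) -> ProcessParameters:
    d = _load_structured(path)
    try:
        return ProcessParameters.from_dict(d)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def save_process_parameters(params: ProcessParameters, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))


def load_ukf_config(path) -> UKFConfig:
    d = _load_structured(path)
    try:
        return UKFConfig.from_dict(d)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Validated file-level configuration of an estimation run."""

    measurements: Path
    feed: Path
    model: Path
    params: Path | None = None
    ukf: Path | None = None
    offline: Path | None = None
    output_dir: Path = Path(".")
    log_level: str = "INFO"

    _KEYS = ("measurements", "feed", "model", "params", "ukf", "offline",
             "output_dir", "log_level")


def load_run_config(path) -> RunConfig:
    d = _load_structured(path)
    if not isinstance(d, dict):
        raise ConfigurationError(f"{path}: expected a mapping")
    unknown = set(d) - set(RunConfig._KEYS)
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    for key in ("measurements", "feed", "model"):
        if key not in d:
            raise ConfigurationError(f"{path}: missing required key {key!r}")
    base = Path(path).parent
    kw = {}
    for key in ("measurements", "feed", "model", "params", "ukf", "offline"):
        if d.get(key) is not None:
            p = (base / d[key]).resolve() if not Path(d[key]).is_absolute() \
                else Path(d[key])
            if not p.exists():
                raise ConfigurationError(f"{path}: {key} file not found: {p}")
            kw[key] = p
    kw["output_dir"] = Path(d.get("output_dir", "."))
    kw["log_level"] = str(d.get("log_level", "INFO"))
    return RunConfig(**kw)
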