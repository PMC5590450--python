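"""Unscented Kalman Filter over the fed-batch state [X, S, P, mu].

The filter is the additive-noise (non-augmented) scaled unscented variant
of Wan & van der Merwe.  The stochastic state is the 4-vector
``[X, S, P, mu]``; the working volume W is excluded and advanced
deterministically from the known feed profile (dW/dt = F).  Time
propagation runs each sigma point through the mass-balance ODE of
:mod:`fedbatch_ukf.process_model` with ``mu`` frozen at that point's own
value (random-walk growth rate); the measurement map is the trained
support-vector observation model ``H: X -> (cOUR, cCPR)``.

The correction step is the standard Kalman form

    c(t_k) = c^(t_k) + K (y_measured(t_k) - y_predicted(t_k)),

with the gain K built from the unscented cross- and innovation
covariances, the latter inflated by the diagonal measurement noise
``V_meas``.  The prediction covariance is inflated by the diagonal process
noise ``V_mod``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (FilterError, NumericalError, PropagationError,
                     UpdateError)
from .measurements import MeasurementSeries
from .observation_model import ObservationModel
from .process_model import FeedProfile, ProcessParameters

logger = logging.getLogger(__name__)

#: order of the stochastic state vector
STATE_NAMES = ("X", "S", "P", "mu")


@dataclass(frozen=True)
class UKFConfig:
    """Scaling parameters and noise covariances of the filter.

    ``V_state0`` is the *initial* state covariance diagonal in state order
    (X, S, P, mu); ``V_meas`` the measurement-noise diagonal for
    (cOUR, cCPR); ``V_mod`` the process ("model") noise diagonal,
    defaulting to ``0.01 * V_state0``.

    ``V_mod`` is a continuous-time noise *intensity* (variance per hour):
    every prediction over a step of length dt adds ``diag(V_mod) * dt`` to
    the covariance.  This makes the filter's behaviour invariant to the
    measurement sampling period — halving the filter step does not double
    the diffusion of the random-walk growth rate.
    """

    alpha: float = 1.0
    beta: float = 2.0
    kappa: float = 0.0
    V_state0: tuple = (0.2, 0.2, 0.2, 2.0)
    V_meas: tuple = (0.01, 0.01)
    V_mod: tuple | None = None
    jitter: float = 1e-10

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if any(v < 0 for v in self.V_state0) or any(v < 0 for v in self.V_meas):
            raise ValueError("noise diagonals must be non-negative")
        if self.V_mod is None:
            object.__setattr__(self, "V_mod",
                               tuple(0.01 * v for v in self.V_state0))
        if any(v < 0 for v in self.V_mod):
            raise ValueError("V_mod entries must be non-negative")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "kappa": self.kappa,
                "V_state0": list(self.V_state0), "V_meas": list(self.V_meas),
                "V_mod": list(self.V_mod), "jitter": self.jitter}

    @classmethod
    def from_dict(cls, d: dict) -> "UKFConfig":
        known = {"alpha", "beta", "kappa", "V_state0", "V_meas", "V_mod",
                 "jitter"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown UKF config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("V_state0", "V_meas", "V_mod"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class Belief:
    """Gaussian belief over the stochastic state [X, S, P, mu].

    The covariance is symmetrized on construction; the mean concentrations
    must be non-negative.  W is the deterministically carried working
    volume.
    """

    mean: np.ndarray
    cov: np.ndarray
    t: float
    W: float

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=float).ravel()
        P = np.asarray(self.cov, dtype=float)
        n = m.size
        if P.shape != (n, n):
            raise ValueError(f"cov shape {P.shape} does not match mean size {n}")
        if not np.all(np.isfinite(m)) or not np.all(np.isfinite(P)):
            raise ValueError("belief contains non-finite values")
        asym = float(np.max(np.abs(P - P.T), initial=0.0))
        if asym > 1e-8:
            raise ValueError(f"covariance asymmetric by {asym:.2e}")
        P = 0.5 * (P + P.T)
        w = np.linalg.eigvalsh(P)
        if w.min(initial=0.0) < -1e-8:
            raise ValueError(f"covariance indefinite (min eig {w.min():.2e})")
        if n >= 3 and np.any(m[:3] < 0):
            raise ValueError("mean concentrations must be non-negative")
        if self.W <= 0:
            raise ValueError("working volume must be positive")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", P)

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class SigmaPointSet:
    """2N+1 scaled sigma points with mean and covariance weights."""

    points: np.ndarray        # (2N+1, N)
    mean_weights: np.ndarray  # (2N+1,)
    cov_weights: np.ndarray   # (2N+1,)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        wm = np.asarray(self.mean_weights, dtype=float)
        wc = np.asarray(self.cov_weights, dtype=float)
        n = pts.shape[1]
        if pts.shape[0] != 2 * n + 1 or wm.size != 2 * n + 1 \
                or wc.size != 2 * n + 1:
            raise ValueError("need exactly 2N+1 points and weights")
        if abs(wm.sum() - 1.0) > 1e-12:
            raise ValueError("mean weights must sum to 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "mean_weights", wm)
        object.__setattr__(self, "cov_weights", wc)

    @property
    def n_dim(self) -> int:
        return self.points.shape[1]


def _safe_cholesky(M: np.ndarray, jitter: float) -> np.ndarray:
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        n = M.shape[0]
        bump = max(jitter * np.trace(M) / n, jitter)
        try:
            return np.linalg.cholesky(M + bump * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"covariance square root failed even after jitter {bump:.2e}"
            ) from exc


def generate_sigma_points(mean: np.ndarray, cov: np.ndarray,
                          config: UKFConfig) -> SigmaPointSet:
    """Scaled sigma-point construction.

    With ``lambda = alpha^2 (N + kappa) - N``, the 2N+1 points are the mean
    and the mean +/- the columns of the lower-triangular square root of
    ``(N + lambda) cov``.  Weights follow the standard scaled formulas;
    ``beta`` enters only the central covariance weight (beta = 2 is optimal
    for Gaussian priors).
    """
    m = np.asarray(mean, dtype=float).ravel()
    P = 0.5 * (np.asarray(cov, dtype=float) + np.asarray(cov, dtype=float).T)
    n = m.size
    lam = config.alpha ** 2 * (n + config.kappa) - n
    scale = n + lam
    if scale <= 0:
        raise ValueError(f"alpha^2 (N + kappa) must be positive, got {scale}")
    L = _safe_cholesky(scale * P, config.jitter)
    pts = np.empty((2 * n + 1, n))
    pts[0] = m
    for i in range(n):
        pts[1 + i] = m + L[:, i]
        pts[1 + n + i] = m - L[:, i]
    wm = np.full(2 * n + 1, 1.0 / (2.0 * scale))
    wc = wm.copy()
    wm[0] = lam / scale
    wc[0] = lam / scale + 1.0 - config.alpha ** 2 + config.beta
    return SigmaPointSet(pts, wm, wc)


def unscented_transform(points: SigmaPointSet,
                        f: Callable[[np.ndarray], np.ndarray]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Propagate sigma points through ``f``; return weighted mean and cov.

    ``f`` maps a state vector to a vector of any dimension.  Raises
    :class:`PropagationError` naming the offending sigma point if ``f``
    returns a non-finite value.
    """
    ys = []
    for i, p in enumerate(points.points):
        y = np.atleast_1d(np.asarray(f(p), dtype=float))
        if not np.all(np.isfinite(y)):
            raise PropagationError(
                f"mapping returned non-finite value at sigma point {i}: {y}")
        ys.append(y)
    Y = np.asarray(ys)
    mean = points.mean_weights @ Y
    dev = Y - mean
    cov = (points.cov_weights[:, None] * dev).T @ dev
    return mean, 0.5 * (cov + cov.T)


def _propagate_points(points: np.ndarray, t0: float, t1: float, W0: float,
                      feed: FeedProfile, params: ProcessParameters,
                      tol: float) -> tuple[np.ndarray, float]:
    """Propagate all sigma points jointly through the mass-balance ODE.

    Each point's mu is held constant during the step (random-walk model).
    The points share the deterministic volume, so the whole set is
    integrated as one stacked system for speed.
    """
    n_pts = points.shape[0]
    mus = points[:, 3].copy()
    cF = np.array([0.0, params.cF_S, 0.0])
    y = np.concatenate([points[:, :3].ravel(), [W0]])

    def rhs(t, y):
        c = y[:-1].reshape(n_pts, 3)
        W = y[-1]
        X = np.maximum(c[:, 0], 0.0)
        R = np.column_stack([
            mus * X,
            -(mus / params.Yxs + params.Ypx * mus / params.Yps + params.ms) * X,
            params.Ypx * mus * X])
        dc = R + (F / W) * (cF[None, :] - c)
        return np.concatenate([dc.ravel(), [F]])

    for a, b, F in feed.iter_segments(t0, t1):
        sol = solve_ivp(rhs, (a, b), y, method="RK45", rtol=tol, atol=1e-10)
        if not sol.success:
            raise PropagationError(
                f"sigma-point propagation failed in [{a}, {b}]: {sol.message}",
                last_valid_time=a)
        y = sol.y[:, -1]
    out = np.empty_like(points)
    out[:, :3] = y[:-1].reshape(n_pts, 3)
    out[:, 3] = mus
    return out, float(y[-1])


def predict_step(belief: Belief, t1: float, feed: FeedProfile,
                 params: ProcessParameters, config: UKFConfig,
                 tol: float = 1e-8) -> Belief:
    """Time update: propagate the belief through the process model to t1.

    Sigma points are propagated *unclipped*: the mass-balance right-hand
    side is well defined for transient negative excursions (reaction rates
    use max(X, 0); S and P enter only linearly; a negative mu is ordinary
    decay).  Zero-clipping sigma points would systematically bias the mean
    of any state whose uncertainty straddles zero — most damagingly the
    random-walk growth rate and an initially zero product concentration —
    so physicality is enforced only on the returned mean concentrations.
    Negative excursions are counted and logged at debug level.

    The unscented covariance of the propagated points is inflated by
    ``diag(V_mod) * (t1 - belief.t)`` (V_mod is a per-hour intensity); W
    advances deterministically by the fed volume.
    """
    if not t1 > belief.t:
        raise ValueError(f"t1={t1} must exceed belief time {belief.t}")
    sigma = generate_sigma_points(belief.mean, belief.cov, config)
    pts = sigma.points
    n_negative = int(np.sum(pts < 0))
    if n_negative:
        logger.debug("%d negative sigma-point components at t=%.4f h",
                     n_negative, belief.t)
    prop, W1 = _propagate_points(pts, belief.t, t1, belief.W, feed, params,
                                 tol)
    mean = sigma.mean_weights @ prop
    dev = prop - mean
    cov = (sigma.cov_weights[:, None] * dev).T @ dev
    cov = 0.5 * (cov + cov.T) + np.diag(config.V_mod) * (t1 - belief.t)
    mean[:3] = np.maximum(mean[:3], 0.0)
    return Belief(mean=mean, cov=cov, t=float(t1), W=W1)


def update_step(predicted: Belief, y_measured,
                obs_model: ObservationModel | Callable,
                config: UKFConfig
                ) -> tuple[Belief, np.ndarray, np.ndarray]:
    """Measurement update (correction) at the predicted belief's time.

    Sigma points of the predicted belief are mapped through the
    observation model; the innovation covariance is the unscented
    observation covariance plus ``diag(V_meas)``.  Returns the corrected
    belief, the innovation ``y_measured - y_predicted`` and the predicted
    observation.

    ``obs_model`` is either a trained :class:`ObservationModel` (mapping
    the biomass component) or any callable taking the full state vector
    and returning the observation vector (used e.g. for linear-system
    cross-checks).
    """
    y_meas = np.atleast_1d(np.asarray(y_measured, dtype=float))
    if not np.all(np.isfinite(y_meas)):
        raise ValueError("measured observation must be finite")
    if isinstance(obs_model, ObservationModel):
        def h(x):
            return obs_model.observe(max(float(x[0]), 0.0))
    elif callable(obs_model):
        h = obs_model
    else:
        raise TypeError("obs_model must be an ObservationModel or callable")

    sigma = generate_sigma_points(predicted.mean, predicted.cov, config)
    Y = []
    for i, p in enumerate(sigma.points):
        yi = np.atleast_1d(np.asarray(h(p), dtype=float))
        if not np.all(np.isfinite(yi)):
            raise PropagationError(
                f"observation map non-finite at sigma point {i}")
        Y.append(yi)
    Y = np.asarray(Y)
    m_obs = Y.shape[1]
    if y_meas.size != m_obs:
        raise ValueError(f"measurement has size {y_meas.size}, "
                         f"observation model produces {m_obs}")
    V_meas = np.asarray(config.V_meas, dtype=float)
    if V_meas.size != m_obs:
        raise ValueError(f"V_meas has {V_meas.size} entries for "
                         f"{m_obs}-dim observation")

    y_pred = sigma.mean_weights @ Y
    dY = Y - y_pred
    dX = sigma.points - predicted.mean
    S = (sigma.cov_weights[:, None] * dY).T @ dY + np.diag(V_meas)
    S = 0.5 * (S + S.T)
    Pxy = (sigma.cov_weights[:, None] * dX).T @ dY
    try:
        K = np.linalg.solve(S, Pxy.T).T
    except np.linalg.LinAlgError as exc:
        raise UpdateError(
            "singular innovation covariance; increase V_meas or jitter"
        ) from exc
    innovation = y_meas - y_pred
    mean = predicted.mean + K @ innovation
    cov = predicted.cov - K @ S @ K.T
    cov = 0.5 * (cov + cov.T)
    # floor tiny negative eigenvalues arising from subtraction
    w, V = np.linalg.eigh(cov)
    if w.min() < 0:
        if w.min() < -1e-6 * max(w.max(), 1.0):
            raise UpdateError(
                f"update produced indefinite covariance (min eig {w.min():.2e})")
        cov = (V * np.maximum(w, 0.0)) @ V.T
        cov = 0.5 * (cov + cov.T)
    if mean.size >= 3:
        mean[:3] = np.maximum(mean[:3], 0.0)
    corrected = Belief(mean=mean, cov=cov, t=predicted.t, W=predicted.W)
    return corrected, innovation, y_pred


@dataclass
class EstimateTrajectory:
    """Filter output: one record per processed measurement."""

    times: np.ndarray
    means: np.ndarray           # (n, 4) state means
    cov_diagonals: np.ndarray   # (n, 4) posterior variances
    predicted_obs: np.ndarray   # (n, 2) H(predicted state)
    innovations: np.ndarray     # (n, 2) measured - predicted
    volumes: np.ndarray = field(default=None)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_h": self.times,
            "X_hat": self.means[:, 0], "S_hat": self.means[:, 1],
            "P_hat": self.means[:, 2], "mu_hat": self.means[:, 3],
            "var_X": self.cov_diagonals[:, 0],
            "var_S": self.cov_diagonals[:, 1],
            "var_P": self.cov_diagonals[:, 2],
            "var_mu": self.cov_diagonals[:, 3],
            "cOUR_pred": self.predicted_obs[:, 0],
            "cCPR_pred": self.predicted_obs[:, 1],
            "innov_cOUR": self.innovations[:, 0],
            "innov_cCPR": self.innovations[:, 1],
        })
        return df

    def __len__(self) -> int:
        return self.times.size


def run_filter(measurements: MeasurementSeries, feed: FeedProfile,
               params: ProcessParameters, obs_model: ObservationModel,
               init: Belief, config: UKFConfig,
               tol: float = 1e-8) -> EstimateTrajectory:
    """Run the full predict/update recursion over a measurement series.

    Measurements must have strictly increasing timestamps not earlier than
    the initial belief's time; the feed profile must cover their span.
    Offline laboratory samples are never consumed here — they serve only
    for observation-model training and validation.

    On an internal failure a :class:`FilterError` is raised with the
    partial trajectory attached.
    """
    if len(measurements) and measurements.times[0] < init.t:
        raise ValueError("first measurement precedes the initial belief")
    belief = init
    times, means, covd, preds, innovs, vols = [], [], [], [], [], []
    try:
        for k in range(len(measurements)):
            t_k = float(measurements.times[k])
            if t_k > belief.t + 1e-12:
                belief = predict_step(belief, t_k, feed, params, config,
                                      tol=tol)
            y_k = np.array([measurements.cOUR[k], measurements.cCPR[k]])
            belief, innovation, y_pred = update_step(belief, y_k, obs_model,
                                                     config)
            times.append(t_k)
            means.append(belief.mean.copy())
            covd.append(np.diag(belief.cov).copy())
            preds.append(y_pred)
            innovs.append(innovation)
            vols.append(belief.W)
    except (PropagationError, NumericalError, UpdateError) as exc:
        partial = _trajectory_from_lists(times, means, covd, preds, innovs,
                                         vols)
        raise FilterError(f"filter aborted at step {len(times)}: {exc}",
                          partial_trajectory=partial) from exc
    if not times:
        return EstimateTrajectory(
            times=np.array([init.t]),
            means=init.mean[None, :].copy(),
            cov_diagonals=np.diag(init.cov)[None, :].copy(),
            predicted_obs=np.full((1, 2), np.nan),
            innovations=np.full((1, 2), np.nan),
            volumes=np.array([init.W]))
    return _trajectory_from_lists(times, means, covd, preds, innovs, vols)


def _trajectory_from_lists(times, means, covd, preds, innovs, vols):
    return EstimateTrajectory(
        times=np.asarray(times), means=np.asarray(means),
        cov_diagonals=np.asarray(covd), predicted_obs=np.asarray(preds),
        innovations=np.asarray(innovs), volumes=np.asarray(vols))
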