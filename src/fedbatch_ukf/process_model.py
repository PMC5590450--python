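"""Mass-balance process model for fed-batch cultivations.

The reactor state is the concentration vector ``c = (X, S, P)`` (biomass,
substrate, product, all in g/L), the specific growth rate ``mu`` (1/h) and
the working volume ``W`` (L).  Feeding at rate ``F(t)`` (L/h) with a feed
whose only non-zero component is the substrate concentration ``cF_S``
dilutes the broth and adds substrate:

.. math::

    \\frac{dc}{dt} = R + \\frac{F}{W}\\,(c_F - c), \\qquad
    \\frac{d\\mu}{dt} = 0, \\qquad
    \\frac{dW}{dt} = F,

with the volumetric conversion rates

.. math::

    R = \\begin{pmatrix} \\mu X \\\\
        -\\left(\\mu/Y_{xs} + \\pi/Y_{ps} + m_s\\right) X \\\\
        Y_{px}\\,\\mu\\,X \\end{pmatrix},
    \\qquad \\pi = Y_{px}\\,\\mu .

Product formation is purely growth-associated (the specific production rate
``pi`` is proportional to ``mu``).  ``mu`` is carried as an extended state
with zero deterministic dynamics — the random-walk assumption the state
estimator exploits; for simulation and parameter fitting an explicit growth
law (e.g. Monod) can be supplied instead.

Units are fixed package-wide: hours, g/L, L, L/h.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import ConfigurationError, FitError, PropagationError

logger = logging.getLogger(__name__)

#: growth law signature: (time h, raw state vector [X, S, P, mu, W]) -> mu (1/h)
GrowthLaw = Callable[[float, np.ndarray], float]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} contains non-finite value {v!r}")


@dataclass(frozen=True)
class ProcessState:
    """Physical state of the cultivation at one time point.

    Parameters
    ----------
    X, S, P : float
        Biomass, substrate and product concentrations (g/L); non-negative.
    mu : float
        Specific growth rate (1/h).  May be any finite number: the filter
        treats it as an estimated quantity.
    W : float
        Working volume (L); strictly positive.
    t : float
        Time (h); finite and non-negative.
    """

    X: float
    S: float
    P: float
    mu: float
    W: float
    t: float = 0.0

    def __post_init__(self):
        _require_finite("ProcessState", self.X, self.S, self.P, self.mu,
                        self.W, self.t)
        if self.X < 0 or self.S < 0 or self.P < 0:
            raise ValueError(
                f"concentrations must be non-negative, got "
                f"X={self.X}, S={self.S}, P={self.P}")
        if self.W <= 0:
            raise ValueError(f"working volume must be positive, got W={self.W}")
        if self.t < 0:
            raise ValueError(f"time must be non-negative, got t={self.t}")

    def as_vector(self) -> np.ndarray:
        """Raw state vector ``[X, S, P, mu, W]`` used by the integrator."""
        return np.array([self.X, self.S, self.P, self.mu, self.W], dtype=float)


@dataclass(frozen=True)
class ProcessParameters:
    """Yield and maintenance parameters of the conversion model.

    Attributes
    ----------
    Yxs : float
        Biomass-on-substrate yield (g/g).
    Yps : float
        Product-on-substrate yield (g/g).
    Ypx : float
        Product-on-biomass yield (g/g).
    ms : float
        Maintenance coefficient (g substrate / (g biomass * h)).
    cF_S : float
        Substrate concentration of the feed solution (g/L); default 600.
    """

    Yxs: float
    Yps: float
    Ypx: float
    ms: float
    cF_S: float = 600.0

    def __post_init__(self):
        _require_finite("ProcessParameters", self.Yxs, self.Yps, self.Ypx,
                        self.ms, self.cF_S)
        if self.Yxs <= 0 or self.Yps <= 0 or self.cF_S <= 0:
            raise ValueError("Yxs, Yps and cF_S must be positive")
        if self.Ypx < 0 or self.ms < 0:
            raise ValueError("Ypx and ms must be non-negative")

    def to_dict(self) -> dict:
        return {"Yxs": self.Yxs, "Yps": self.Yps, "Ypx": self.Ypx,
                "ms": self.ms, "cF_S": self.cF_S}

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessParameters":
        unknown = set(d) - {"Yxs", "Yps", "Ypx", "ms", "cF_S"}
        if unknown:
            raise ConfigurationError(
                f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


class FeedProfile:
    """Piecewise-constant (zero-order-hold) feed-rate profile.

    The rate at time ``t`` is the rate of the last breakpoint at or before
    ``t`` (left-continuous hold), 0 outside ``[t_start, t_end]``.  Pump
    setpoints are step signals, so ZOH is the natural interpolation.
    """

    def __init__(self, breakpoints: Sequence[float], rates: Sequence[float],
                 t_start: float | None = None, t_end: float | None = None):
        bp = np.asarray(breakpoints, dtype=float)
        r = np.asarray(rates, dtype=float)
        if bp.ndim != 1 or bp.size == 0 or bp.shape != r.shape:
            raise ValueError("breakpoints and rates must be equal-length 1-d")
        if not np.all(np.isfinite(bp)) or not np.all(np.isfinite(r)):
            raise ValueError("feed profile contains non-finite values")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("feed rates must be non-negative")
        self.breakpoints = bp
        self.rates = r
        self.t_start = float(bp[0] if t_start is None else t_start)
        self.t_end = float(bp[-1] if t_end is None else t_end)
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")

    def rate(self, t: float) -> float:
        """Feed rate F(t) in L/h (0 outside the validity window)."""
        if t < self.t_start or t > self.t_end:
            return 0.0
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        if i < 0:
            return 0.0
        return float(self.rates[i])

    def iter_segments(self, t0: float, t1: float) -> Iterator[tuple[float, float, float]]:
        """Yield ``(a, b, F)`` sub-intervals of [t0, t1] with constant rate."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        edges = [t0]
        cuts = np.concatenate([self.breakpoints,
                               [self.t_start, self.t_end]])
        for c in np.unique(cuts):
            if t0 < c < t1:
                edges.append(float(c))
        edges.append(t1)
        edges = sorted(set(edges))
        for a, b in zip(edges[:-1], edges[1:]):
            yield a, b, self.rate(0.5 * (a + b))

    def cumulative_volume(self, t0: float, t1: float) -> float:
        """Exact integral of F over [t0, t1] (L)."""
        return sum(F * (b - a) for a, b, F in self.iter_segments(t0, t1))


@dataclass(frozen=True)
class OfflineSamples:
    """Sparse offline measurements of biomass and/or product concentration.

    NaN marks a missing value.  Times must be sorted ascending; every used
    column must carry at least one non-missing value.
    """

    times: np.ndarray
    X_obs: np.ndarray
    P_obs: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.X_obs, dtype=float)
        p = np.asarray(self.P_obs, dtype=float)
        if not (t.shape == x.shape == p.shape) or t.ndim != 1:
            raise ValueError("times, X_obs, P_obs must be equal-length 1-d")
        if t.size == 0:
            raise ValueError("offline sample set is empty")
        if np.any(np.diff(t) < 0):
            raise ValueError("offline times must be sorted ascending")
        if not (np.any(np.isfinite(x)) or np.any(np.isfinite(p))):
            raise ValueError("offline samples carry no usable values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "X_obs", x)
        object.__setattr__(self, "P_obs", p)

    def __len__(self) -> int:
        return self.times.size


def conversion_rates(state: ProcessState,
                     params: ProcessParameters) -> np.ndarray:
    """Volumetric conversion rate vector ``R = (R_X, R_S, R_P)`` in g/(L h).

    ``R_X = mu X``, ``R_P = Ypx mu X`` and
    ``R_S = -(mu/Yxs + pi/Yps + ms) X`` with ``pi = Ypx mu``.
    All rates scale linearly with biomass; substrate is consumed
    (``R_S <= 0``) whenever ``mu >= 0``.
    """
    mu, X = state.mu, state.X
    pi = params.Ypx * mu
    R_X = mu * X
    R_S = -(mu / params.Yxs + pi / params.Yps + params.ms) * X
    R_P = params.Ypx * mu * X
    return np.array([R_X, R_S, R_P])


def state_derivative(state: ProcessState, F: float,
                     params: ProcessParameters) -> np.ndarray:
    """Time derivative ``(dX, dS, dP, dmu, dW)/dt`` of the mass balances.

    ``dc/dt = R + (F/W)(c_F - c)`` with ``c_F = (0, cF_S, 0)``;
    ``dmu/dt = 0`` (random-walk state) and ``dW/dt = F``.
    """
    if not math.isfinite(F):
        raise ValueError(f"feed rate must be finite, got {F}")
    if F < 0:
        raise ValueError(f"feed rate must be non-negative, got F={F}")
    if state.W <= 0:
        raise ValueError(f"working volume must be positive, got W={state.W}")
    R = conversion_rates(state, params)
    c = np.array([state.X, state.S, state.P])
    c_F = np.array([0.0, params.cF_S, 0.0])
    dc = R + (F / state.W) * (c_F - c)
    return np.array([dc[0], dc[1], dc[2], 0.0, F])


def _rhs(t: float, y: np.ndarray, F: float, params: ProcessParameters,
         mu_law: GrowthLaw | None) -> np.ndarray:
    """Integrator right-hand side on the raw vector ``[X, S, P, mu, W]``."""
    X = max(y[0], 0.0)
    mu = mu_law(t, y) if mu_law is not None else y[3]
    pi = params.Ypx * mu
    R = np.array([mu * X,
                  -(mu / params.Yxs + pi / params.Yps + params.ms) * X,
                  params.Ypx * mu * X])
    FW = F / y[4]
    dc = R + FW * (np.array([0.0, params.cF_S, 0.0]) - y[:3])
    return np.array([dc[0], dc[1], dc[2], 0.0, F])


def propagate_state(state: ProcessState, t1: float, feed: FeedProfile,
                    params: ProcessParameters, tol: float = 1e-8,
                    mu_law: GrowthLaw | None = None) -> ProcessState:
    """Integrate the mass balances from ``state.t`` to ``t1``.

    The interval is split at feed-profile breakpoints so the integrator
    never steps across a feed discontinuity; each sub-interval is solved
    with adaptive Runge-Kutta (``rtol=tol``, ``atol=1e-10``).  Negative
    concentration overshoots (possible near S ~ 0) are clipped to zero and
    logged.

    Parameters
    ----------
    mu_law : callable, optional
        Growth law ``mu(t, y)`` overriding the constant-``mu`` assumption;
        used by the simulator (Monod kinetics) and by :func:`fit_yields`.
    """
    if t1 < state.t:
        raise ValueError(f"t1={t1} precedes state.t={state.t}")
    if t1 == state.t:
        return state
    y = state.as_vector()
    t_last = state.t
    for a, b, F in feed.iter_segments(state.t, t1):
        sol = solve_ivp(_rhs, (a, b), y, args=(F, params, mu_law),
                        method="RK45", rtol=tol, atol=1e-10)
        if not sol.success:
            raise PropagationError(
                f"ODE solver failed in [{a}, {b}]: {sol.message}",
                last_valid_time=t_last)
        y = sol.y[:, -1]
        t_last = b
    if np.any(y[:3] < 0):
        worst = float(np.min(y[:3]))
        if worst < -1e-7:
            logger.warning("clipping negative concentration overshoot "
                           "(min %.3e) to 0 at t=%.4f h", worst, t1)
        y[:3] = np.maximum(y[:3], 0.0)
    mu1 = mu_law(t1, y) if mu_law is not None else y[3]
    return ProcessState(X=float(y[0]), S=float(y[1]), P=float(y[2]),
                        mu=float(mu1), W=float(y[4]), t=float(t1))


@dataclass
class FitReport:
    """Residual report from :func:`fit_yields`."""

    objective: float
    residuals: np.ndarray          # stacked relative residuals
    residual_times: np.ndarray     # time of each residual (h)
    residual_channel: list         # 'X' or 'P' per residual
    n_evaluations: int
    converged: bool
    message: str = ""


_FREE_ALL = ("Yxs", "Yps", "Ypx", "ms")


def fit_yields(offline: OfflineSamples, feed: FeedProfile,
               init: ProcessState, params0: ProcessParameters,
               free: Sequence[str] = _FREE_ALL,
               mu_law: GrowthLaw | None = None,
               tol: float = 1e-8) -> tuple[ProcessParameters, FitReport]:
    """Fit yield/maintenance parameters to offline concentration samples.

    Minimizes the sum of squared *relative* residuals between model
    trajectories (propagated from ``init`` under ``mu_law``) sampled at the
    offline times and the observed X/P values, over the parameters listed
    in ``free``.  A bounded trust-region least-squares solver is used;
    parameters stay strictly positive.

    Returns the fitted :class:`ProcessParameters` and a :class:`FitReport`.
    Raises :class:`FitError` (carrying best-so-far parameters) if the
    optimizer reports non-convergence.

    .. note::
       Yxs and Yps enter the dynamics only through the lumped coefficient
       ``1/Yxs + Ypx/Yps`` and cannot be separated by X/P data alone;
       freeing both leaves one direction of the pair unconstrained (a
       warning is logged).  The identifiable set is ``(Yxs, Ypx, ms)``
       with Yps fixed at a nominal value.
    """
    free = tuple(free)
    if not free or any(f not in _FREE_ALL for f in free):
        raise ConfigurationError(f"free must be a non-empty subset of "
                                 f"{_FREE_ALL}, got {free}")
    if "Yxs" in free and "Yps" in free:
        # substrate consumption depends on Yxs and Yps only through the
        # lump 1/Yxs + Ypx/Yps, so the pair is exactly collinear: any
        # X/P data determine the lump, not the individual yields
        logger.warning("Yxs and Yps are structurally collinear (only "
                       "1/Yxs + Ypx/Yps is identifiable from X/P data); "
                       "consider fixing one of them")
    x_mask = np.isfinite(offline.X_obs)
    p_mask = np.isfinite(offline.P_obs)

    def _scales(values, mask):
        # relative-residual scales; floored at 5% of the channel maximum so
        # early, near-zero samples do not dominate the objective
        out = np.full(values.shape, np.nan)
        if mask.any():
            floor = 0.05 * max(float(np.max(np.abs(values[mask]))), 1e-6)
            out[mask] = np.maximum(np.abs(values[mask]), floor)
        return out

    x_scale = _scales(offline.X_obs, x_mask)
    p_scale = _scales(offline.P_obs, p_mask)

    eval_times = np.unique(offline.times)
    n_evals = 0

    def trajectory(params: ProcessParameters) -> dict[float, ProcessState]:
        out = {}
        st = init
        for te in eval_times:
            st = propagate_state(st, float(te), feed, params,
                                 tol=tol, mu_law=mu_law)
            out[float(te)] = st
        return out

    def theta_to_params(theta: np.ndarray) -> ProcessParameters:
        d = params0.to_dict()
        for name, v in zip(free, theta):
            d[name] = float(v)
        return ProcessParameters.from_dict(d)

    def residuals(theta: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        traj = trajectory(theta_to_params(theta))
        res = []
        for i, te in enumerate(offline.times):
            st = traj[float(te)]
            if x_mask[i]:
                res.append((st.X - offline.X_obs[i]) / x_scale[i])
            if p_mask[i]:
                res.append((st.P - offline.P_obs[i]) / p_scale[i])
        return np.asarray(res)

    theta0 = np.array([getattr(params0, f) for f in free])
    lower = np.full(len(free), 1e-6)
    upper = np.array([50.0 if f != "ms" else 5.0 for f in free])
    result = least_squares(residuals, theta0, bounds=(lower, upper),
                           method="trf", x_scale=np.maximum(theta0, 1e-3),
                           xtol=1e-12, ftol=1e-12, gtol=1e-12)
    fitted = theta_to_params(result.x)
    final_res = residuals(result.x)
    times_list, chan_list = [], []
    for i, te in enumerate(offline.times):
        if x_mask[i]:
            times_list.append(float(te)); chan_list.append("X")
        if p_mask[i]:
            times_list.append(float(te)); chan_list.append("P")
    report = FitReport(objective=float(np.sum(final_res ** 2)),
                       residuals=final_res,
                       residual_times=np.asarray(times_list),
                       residual_channel=chan_list,
                       n_evaluations=n_evals,
                       converged=bool(result.success),
                       message=str(result.message))
    if not result.success:
        raise FitError(f"yield fit did not converge: {result.message}",
                       best_params=fitted, report=report)
    return fitted, report


def monod_growth_law(mu_max: float, Ks: float) -> GrowthLaw:
    """Monod kinetics ``mu(S) = mu_max S / (Ks + S)`` as a growth law."""
    if mu_max <= 0 or Ks <= 0:
        raise ConfigurationError("mu_max and Ks must be positive")

    def law(t: float, y: np.ndarray) -> float:
        S = max(y[1], 0.0)
        return mu_max * S / (Ks + S)

    return law
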