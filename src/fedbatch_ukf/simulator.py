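"""Seeded synthetic fed-batch cultivation generator.

Emulates a 30 C fed-batch *E. coli* cultivation: ground-truth
trajectories come from the mass-balance model with Monod growth kinetics
(or a prescribed mu(t) table), cumulative off-gas signals from a declared
nonlinear observation law, and measurements carry multiplicative Gaussian
noise.  Sparse offline samples of biomass and product mimic laboratory
assays.  Everything is reproducible bit-exactly from an integer seed.

The ground-truth observation law for each channel is

    instantaneous rate = (k1 * mu**p + k2) * X * W,

cumulated over time.  With p != 1 this is deliberately *not* of the linear
Luedeking-Piret form, so the learned observation model faces a genuinely
nonlinear target.  Signal units are normalized so that cumulative values
are of order one over the reference run; on that scale the default
filter measurement variance (0.01 per channel) corresponds to a few
percent of the final signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, PropagationError
from .measurements import MeasurementSeries
from .process_model import (FeedProfile, GrowthLaw, OfflineSamples,
                            ProcessParameters, ProcessState,
                            monod_growth_law)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KineticsSpec:
    """True growth-rate law of the simulated organism.

    mode 'monod': mu = mu_max * S / (Ks + S); mode 'prescribed': mu(t)
    interpolated linearly from a table.
    """

    mode: str = "monod"
    mu_max: float = 0.5
    Ks: float = 0.05
    mu_profile: tuple | None = None   # (times, values)

    def __post_init__(self):
        if self.mode not in ("monod", "prescribed"):
            raise ConfigurationError(f"unknown kinetics mode {self.mode!r}")
        if self.mode == "monod" and (self.mu_max <= 0 or self.Ks <= 0):
            raise ConfigurationError("mu_max and Ks must be positive")
        if self.mode == "prescribed":
            if self.mu_profile is None:
                raise ConfigurationError("prescribed mode needs mu_profile")
            t, v = self.mu_profile
            if np.any(np.asarray(v) < 0):
                raise ConfigurationError("prescribed mu must be non-negative")

    def growth_law(self) -> GrowthLaw:
        if self.mode == "monod":
            return monod_growth_law(self.mu_max, self.Ks)
        t_tab = np.asarray(self.mu_profile[0], dtype=float)
        v_tab = np.asarray(self.mu_profile[1], dtype=float)

        def law(t, y):
            return float(np.interp(t, t_tab, v_tab))

        return law

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "mu_max": self.mu_max, "Ks": self.Ks}
        if self.mu_profile is not None:
            d["mu_profile"] = [list(map(float, self.mu_profile[0])),
                               list(map(float, self.mu_profile[1]))]
        return d


@dataclass(frozen=True)
class ChannelLaw:
    """One channel of the ground-truth off-gas law: (k1 mu^p + k2) X W."""

    k1: float
    k2: float
    p: float

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ConfigurationError("k1 and k2 must be non-negative")
        if self.p <= 0:
            raise ConfigurationError("nonlinearity exponent p must be positive")

    def rate(self, mu, X, W):
        return (self.k1 * np.maximum(mu, 0.0) ** self.p + self.k2) * X * W


@dataclass(frozen=True)
class ObservationLaw:
    """Ground-truth cumulative off-gas kinetics for both channels."""

    cOUR: ChannelLaw = field(default_factory=lambda: ChannelLaw(0.08, 0.003, 1.3))
    cCPR: ChannelLaw = field(default_factory=lambda: ChannelLaw(0.07, 0.0035, 1.2))

    def to_dict(self) -> dict:
        return {ch: {"k1": law.k1, "k2": law.k2, "p": law.p}
                for ch, law in (("cOUR", self.cOUR), ("cCPR", self.cCPR))}


@dataclass(frozen=True)
class Scenario:
    """Complete specification of one synthetic cultivation."""

    params: ProcessParameters
    kinetics: KineticsSpec
    observation_law: ObservationLaw
    feed: FeedProfile
    initial_state: ProcessState
    horizon: float = 10.0              # h
    noise_level: float = 0.025         # multiplicative, per measurement
    meas_interval: float = 1.0 / 60.0  # h (1 min grid)
    offline_interval: float = 1.0      # h
    offline_noise: float = 0.0         # optional relative noise on samples
    name: str = "S-emu"

    def __post_init__(self):
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be positive")
        if self.noise_level < 0 or self.offline_noise < 0:
            raise ConfigurationError("noise levels must be non-negative")
        if self.meas_interval <= 0 or self.offline_interval <= 0:
            raise ConfigurationError("sampling intervals must be positive")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params.to_dict(),
            "kinetics": self.kinetics.to_dict(),
            "observation_law": self.observation_law.to_dict(),
            "initial_state": {"X": self.initial_state.X,
                              "S": self.initial_state.S,
                              "P": self.initial_state.P,
                              "mu": self.initial_state.mu,
                              "W": self.initial_state.W,
                              "t": self.initial_state.t},
            "horizon": self.horizon, "noise_level": self.noise_level,
            "meas_interval": self.meas_interval,
            "offline_interval": self.offline_interval,
            "offline_noise": self.offline_noise,
        }


@dataclass(frozen=True)
class TruthTrajectory:
    """Dense noise-free ground truth on the measurement grid."""

    times: np.ndarray
    X: np.ndarray
    S: np.ndarray
    P: np.ndarray
    mu: np.ndarray
    W: np.ndarray
    cOUR: np.ndarray
    cCPR: np.ndarray


@dataclass(frozen=True)
class SyntheticDataset:
    """Ground truth + noisy observations + sparse offline samples."""

    scenario: Scenario
    seed: int
    truth: TruthTrajectory
    measurements: MeasurementSeries
    offline: OfflineSamples

    @property
    def feed(self) -> FeedProfile:
        return self.scenario.feed


def generate_feed_profile(kind: str, horizon: float, F0: float = 0.004,
                          k: float = 0.3, t_switch: float | None = None,
                          dt: float = 1.0 / 60.0) -> FeedProfile:
    """Build a feed profile of a standard fed-batch shape.

    kind 'constant': F = F0; 'exponential': F = F0 exp(k t);
    'exponential_then_constant': exponential until ``t_switch`` (default
    0.7 * horizon), then held at the switch-time rate.  The profile is
    discretized to zero-order-hold breakpoints on a ``dt`` grid (1 min by
    default); queries outside [0, horizon] evaluate to 0.
    """
    if horizon <= 0:
        raise ConfigurationError("horizon must be positive")
    if F0 <= 0:
        raise ConfigurationError("feed rate F0 must be positive")
    times = np.arange(0.0, horizon, dt)
    if kind == "constant":
        rates = np.full(times.shape, F0)
    elif kind == "exponential":
        rates = F0 * np.exp(k * times)
    elif kind == "exponential_then_constant":
        ts = 0.7 * horizon if t_switch is None else t_switch
        if not 0 < ts <= horizon:
            raise ConfigurationError("t_switch must lie inside the horizon")
        rates = F0 * np.exp(k * np.minimum(times, ts))
    else:
        raise ConfigurationError(f"unknown feed profile kind {kind!r}")
    return FeedProfile(times, rates, t_start=0.0, t_end=horizon)


def reference_scenario(noise_level: float = 0.025,
                       horizon: float = 10.0,
                       offline_interval: float = 1.0,
                       offline_noise: float = 0.0,
                       name: str = "S-emu") -> Scenario:
    """The default desk-scale cultivation scenario.

    10 h horizon, X0 = 0.5 g/L, S0 = 2 g/L, P0 = 0, W0 = 5 L, feed with
    600 g/L substrate, Monod kinetics (mu_max 0.5 1/h, Ks 0.05 g/L), an
    exponential feed (F0 = 0.004 L/h, k = 0.3 1/h) held constant from 7 h,
    1-min off-gas sampling with 2.5% multiplicative noise, hourly offline
    samples.  Yields Yxs 0.5, Yps 1.2, Ypx 0.04 g/g, ms 0.03 g/(g h).
    """
    params = ProcessParameters(Yxs=0.5, Yps=1.2, Ypx=0.04, ms=0.03,
                               cF_S=600.0)
    kinetics = KineticsSpec(mode="monod", mu_max=0.5, Ks=0.05)
    feed = generate_feed_profile("exponential_then_constant", horizon,
                                 F0=0.004, k=0.3,
                                 t_switch=min(7.0, 0.7 * horizon))
    init = ProcessState(X=0.5, S=2.0, P=0.0, mu=kinetics.mu_max * 2.0 / 2.05,
                        W=5.0, t=0.0)
    return Scenario(params=params, kinetics=kinetics,
                    observation_law=ObservationLaw(), feed=feed,
                    initial_state=init, horizon=horizon,
                    noise_level=noise_level,
                    offline_interval=offline_interval,
                    offline_noise=offline_noise, name=name)


def add_measurement_noise(series: MeasurementSeries, level: float,
                          seed: int) -> MeasurementSeries:
    """Multiply every sample by (1 + level * z), z iid standard normal."""
    if level < 0:
        raise ConfigurationError("noise level must be non-negative")
    if level == 0:
        return series
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(series), 2))
    return MeasurementSeries(
        times=series.times,
        cOUR=series.cOUR * (1.0 + level * z[:, 0]),
        cCPR=series.cCPR * (1.0 + level * z[:, 1]),
        source=series.source)


def simulate_cultivation(scenario: Scenario, seed: int) -> SyntheticDataset:
    """Integrate the true dynamics and produce a full synthetic dataset.

    The augmented truth state is [X, S, P, W, cOUR, cCPR] with mu supplied
    by the kinetics law; the cumulative channels integrate the observation
    law alongside the mass balances.  Noise streams for measurements and
    offline samples are derived independently from the seed.
    """
    sc = scenario
    law = sc.kinetics.growth_law()
    par = sc.params
    cour_law, ccpr_law = sc.observation_law.cOUR, sc.observation_law.cCPR
    s0 = sc.initial_state
    t_grid = np.round(np.arange(0.0, sc.horizon + 0.5 * sc.meas_interval,
                                sc.meas_interval), 12)

    def rhs(t, y):
        X = max(y[0], 0.0)
        W = y[3]
        mu = law(t, np.array([y[0], y[1], y[2], 0.0, W]))
        pi = par.Ypx * mu
        R = np.array([mu * X,
                      -(mu / par.Yxs + pi / par.Yps + par.ms) * X,
                      par.Ypx * mu * X])
        dc = R + (F / W) * (np.array([0.0, par.cF_S, 0.0]) - y[:3])
        dour = cour_law.rate(mu, X, W)
        dcpr = ccpr_law.rate(mu, X, W)
        return np.array([dc[0], dc[1], dc[2], F, dour, dcpr])

    y = np.array([s0.X, s0.S, s0.P, s0.W, 0.0, 0.0])
    ys = [y.copy()]
    t_prev = 0.0
    for t_next in t_grid[1:]:
        for a, b, F in sc.feed.iter_segments(t_prev, float(t_next)):
            sol = solve_ivp(rhs, (a, b), y, method="RK45",
                            rtol=1e-8, atol=1e-10)
            if not sol.success:
                raise PropagationError(
                    f"truth integration failed in [{a}, {b}]: {sol.message}",
                    last_valid_time=a)
            y = sol.y[:, -1]
        y[:3] = np.maximum(y[:3], 0.0)
        ys.append(y.copy())
        t_prev = float(t_next)
    Y = np.asarray(ys)
    mu_true = np.array([law(t, np.array([Y[i, 0], Y[i, 1], Y[i, 2], 0.0,
                                         Y[i, 3]]))
                        for i, t in enumerate(t_grid)])
    truth = TruthTrajectory(times=t_grid, X=Y[:, 0], S=Y[:, 1], P=Y[:, 2],
                            mu=mu_true, W=Y[:, 3], cOUR=Y[:, 4],
                            cCPR=Y[:, 5])

    clean = MeasurementSeries(times=t_grid, cOUR=Y[:, 4], cCPR=Y[:, 5],
                              source=f"{sc.name}:truth")
    seed = int(seed)
    measurements = add_measurement_noise(clean, sc.noise_level,
                                         seed=_child_seed(seed, 1))

    n_off = int(np.floor(sc.horizon / sc.offline_interval + 1e-9)) + 1
    t_off = np.arange(n_off) * sc.offline_interval
    X_off = np.interp(t_off, t_grid, truth.X)
    P_off = np.interp(t_off, t_grid, truth.P)
    if sc.offline_noise > 0:
        rng = np.random.default_rng(_child_seed(seed, 2))
        X_off = X_off * (1.0 + sc.offline_noise * rng.standard_normal(n_off))
        P_off = P_off * (1.0 + sc.offline_noise * rng.standard_normal(n_off))
        X_off = np.maximum(X_off, 0.0)
        P_off = np.maximum(P_off, 0.0)
    offline = OfflineSamples(times=t_off, X_obs=X_off, P_obs=P_off)
    return SyntheticDataset(scenario=sc, seed=seed, truth=truth,
                            measurements=measurements, offline=offline)


def _child_seed(seed: int, stream: int) -> int:
    """Derive an independent 31-bit child seed for a named stream."""
    return int(np.random.default_rng([seed, stream]).integers(0, 2 ** 31))


def generate_training_runs(seed: int, n_runs: int = 3,
                           scenario: Scenario | None = None
                           ) -> list[SyntheticDataset]:
    """Simulate several replicate cultivations for observation training.

    Emulates training the observation model on a set of sister runs of the
    same process: identical scenario, independent noise realizations.
    """
    if scenario is None:
        scenario = reference_scenario()
    runs = []
    for i in range(n_runs):
        run_sc = replace(scenario, name=f"{scenario.name}-train{i}")
        runs.append(simulate_cultivation(run_sc, seed=_child_seed(seed, 10 + i)))
    return runs
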