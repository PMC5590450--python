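# Methods

## Process model

The reactor is a stirred-tank fed-batch system: substrate solution is fed
at a known rate F(t) (L/h) without broth removal, so the working volume W
grows as dW/dt = F. The concentration states c = (X, S, P) (biomass,
substrate, product, g/L) obey

    dc/dt = R + (F/W) (c_F − c),

where c_F = (0, cF_S, 0) is the feed composition (only substrate is fed;
default cF_S = 600 g/L) and the volumetric conversion rates are

    R_X = µ X
    R_S = −(µ/Y_xs + π/Y_ps + m_s) X
    R_P = Y_px µ X,          π = Y_px µ.

Product formation is purely growth-associated: the specific production
rate π rises monotonically with µ, here proportionally. Units are fixed
package-wide at hours, g/L, L and L/h.

The specific growth rate µ (1/h) is **not** modelled mechanistically
inside the estimator. It is an extended state with dµ/dt = 0 plus model
noise — a random walk — so the filter infers it from data instead of
trusting an uncertain kinetic law. For *simulation* and *parameter
fitting*, where a true growth law is required, `propagate_state` accepts
an explicit law µ(t, state); the built-in options are Monod kinetics
µ = µ_max S/(K_s + S) and a prescribed µ(t) table.

Feed profiles are zero-order-hold step functions (pump setpoints are step
signals). The integrator (adaptive RK45, rtol 1e−8, atol 1e−10) is
restarted at every feed breakpoint so no step straddles a discontinuity;
volume balances then hold to the solver tolerance exactly. Negative
concentration overshoots (possible near S ≈ 0) are clipped to zero with a
logged warning.

### Parameter fitting and identifiability

`fit_yields` estimates yield/maintenance parameters by least squares on
*relative* residuals between propagated trajectories and offline X/P
samples, with positivity bounds (scipy trust-region reflective).

One structural fact dominates the design: Y_xs and Y_ps enter the
dynamics only through the lumped coefficient

    L = 1/Y_xs + Y_px/Y_ps,

so they are exactly collinear — no offline X/P data, under any feed
profile or growth law, can separate them. The identifiable parameter set
is (Y_xs, Y_px, m_s) with Y_ps held at a nominal value (equivalently, one
may report L). `fit_yields` accepts any subset of the four but logs a
warning when both members of the collinear pair are freed. On noiseless
synthetic data the identifiable set is recovered essentially exactly
(< 0.01% error).

The maintenance coefficient is *weakly* identifiable: at the reference
conditions maintenance is only ~1.5–6% of total substrate turnover, and a
Cramér–Rao analysis at the true parameters gives sd(m_s) ≈ 88% of its
value for 11 hourly offline samples with 2% relative noise. Observed
median errors over repeated noisy fits (~20–50%) are consistent with that
bound; m_s from sparse noisy offline data should be treated as an order
of magnitude, not a number.

## Observation model

The measurement quantities are the cumulative oxygen-uptake and
CO₂-production signals (cOUR, cCPR). Cumulation suppresses sensor noise
and matches the cumulative nature of biomass and product. The map
H: X → (cOUR, cCPR) is learned per channel with ε-insensitive RBF-kernel
support-vector regression on (X, signal) pairs built by linearly
interpolating each run's cumulative signals at its offline biomass
timestamps, pooled over all runs.

Hyperparameters (C, ε, γ) are selected on a single seeded 70/30
train/validation split by validation RMSE; inputs and targets are
standardized to the training partition. The ε grid spans 0.1–2% of the
target range: cumulative curves start near zero, and a wide ε-tube would
flatten the fit exactly in the low-X region where the filter extracts
growth-rate information early in a run. Training uses scikit-learn's SVR;
prediction is re-implemented as a plain numpy kernel expansion over the
extracted support vectors so that a model serialized to JSON round-trips
bit-exactly. Queries outside the training X range are allowed but flagged.

H maps biomass alone. Strictly, a cumulative signal is a functional of
the whole trajectory, not a function of X; the approximation is good when
the training and evaluation runs follow similar feeding policies (sister
runs of one process), which is the intended use and the synthetic study
design.

## Unscented Kalman Filter

Additive-noise scaled UKF over the 4-dim state [X, S, P, µ]; W is known
given F(t) and is carried deterministically. Sigma points: λ = α²(N+κ) −
N, points at the mean ± columns of the lower Cholesky factor of (N+λ)Σ
(jitter-regularized retry on failure), standard scaled weights with β in
the central covariance weight. Defaults α = 1, β = 2, κ = 0.

Covariances are diagonal by default: initial state covariance
V_state0 = (0.2, 0.2, 0.2, 2.0), measurement noise V_meas = (0.01, 0.01),
model noise V_mod = 0.01·V_state0. Two conventions deserve emphasis:

- **V_mod is an intensity.** The process model is continuous-time, so
  V_mod is interpreted as covariance growth *per hour*: a prediction over
  dt adds diag(V_mod)·dt. This keeps the filter invariant to the
  measurement period (1-min default). Adding diag(V_mod) per step would
  make the µ random walk diffuse at 1.2 (1/h)² per hour at 1-min
  sampling, drowning the µ estimate in estimation noise.

- **No sigma-point clipping.** The mass-balance right-hand side is well
  defined for transient negative excursions (reaction rates use
  max(X, 0); S and P enter linearly; negative µ is ordinary decay), so
  sigma points are propagated unclipped. Zero-clipping points would
  systematically bias any state whose uncertainty straddles zero: the µ
  random walk would acquire a persistent positive bias, and an initially
  zero product concentration — unobserved, hence with non-shrinking
  variance — would inflate from 0 to ~0.4 g/L within an hour. Physicality
  is enforced only on returned mean concentrations (clipped at 0).

The update maps the predicted sigma points through H, adds diag(V_meas)
to the unscented observation covariance, and applies the standard gain.
Posterior covariances are symmetrized and tiny negative eigenvalues
(from the subtraction) floored at zero. Offline laboratory samples are
never consumed by the filter — they only train and validate H.

## Synthetic cultivation study

The reference scenario emulates a 30 °C fed-batch *E. coli* cultivation
at desk scale: 10 h horizon, X₀ = 0.5 g/L, S₀ = 2 g/L, P₀ = 0, W₀ = 5 L,
Monod kinetics (µ_max = 0.5 1/h, K_s = 0.05 g/L), yields Y_xs = 0.5,
Y_ps = 1.2, Y_px = 0.04 g/g, m_s = 0.03 g/(g·h), feed with 600 g/L
substrate rising exponentially (F₀ = 0.004 L/h, k = 0.3 1/h) and held
constant from 7 h. The run has a short batch phase (µ ≈ µ_max), substrate
exhaustion near 3.8 h, a feed-limited phase tracking the exponential
feed, and a declining-µ tail after the feed plateaus — X reaches
≈ 11.7 g/L. Off-gas is sampled every minute with 2.5% multiplicative
Gaussian noise per sample and channel; offline X/P samples are hourly
(optionally with independent relative noise for fitting studies). All
noise streams derive from one integer seed; identical seeds give
bit-identical datasets.

True off-gas kinetics follow the declared law
rate = (k₁ µ^p + k₂)·X·W per channel, cumulated over time, with
(k₁, k₂, p) = (0.08, 0.003, 1.3) for cOUR and (0.07, 0.0035, 1.2) for
cCPR. The exponent p ≠ 1 makes the target genuinely nonlinear (the
linear Luedeking–Piret form would be too easy a target for the SVR and
unrepresentative of real metabolic data). The coefficients normalize the
cumulative signals to order one over the reference run, the scale on
which the default V_meas = 0.01 is a sensible measurement variance
(2.5% of a final value ≈ 4 has sd ≈ 0.1).

The observation model is trained on three replicate runs (independent
noise realizations of the scenario) and the filter is evaluated on the
first of them — training on the very cultivations that are later
supervised is the normal situation when sister runs of one process are
available. Evaluation compares filter means against the simulator's
ground truth: X and P as RMSE relative to their final values, µ as RMSE
after a 1 h burn-in (the initial belief has a deliberately diffuse µ
prior, variance 2.0).

What the synthetic study does *not* emulate: induction/IPTG expression
dynamics, oxygen-transfer limitation, acetate overflow, temperature/pH
effects, drifting sensor calibration, and model mismatch between the
filter's yields and the organism's true yields (the filter is given the
generating parameters). Passing tests therefore demonstrate the
estimator's correctness and noise behaviour, not robustness to the full
model-mismatch spectrum of a real plant.

## Numerical choices

- ODE: scipy RK45, rtol 1e−8 / atol 1e−10, segment-restarted at feed
  breakpoints; the nine sigma points of a prediction step are integrated
  as one stacked system sharing the deterministic volume.
- Cholesky jitter: 1e−10·trace/N added once on factorization failure.
- SVR standardization: training-partition moments; constant targets fall
  back to unit scale.
- Tie-breaks in hyperparameter search: lexicographic on
  (RMSE, C, ε, γ), so identical data and seed give identical models.
- Serialization: JSON with Python float repr (shortest round-trip), so
  deserialized models predict bit-identically.

## Known limitations

- S and P are unobserved through H (which reads X only); their estimates
  are model propagation corrected only via cross-covariances, and S in
  particular inherits any error in the assumed yields.
- Y_xs/Y_ps collinearity and the weak identifiability of m_s (above).
- The learned H is trajectory-specific; applying a model trained on one
  feeding policy to a very different one extrapolates (flagged, not
  prevented).
- The filter assumes known, constant yields; no adaptive noise tuning,
  smoothing, or square-root covariance implementation is provided.
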