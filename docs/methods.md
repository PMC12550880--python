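# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the `thermotrait` pipeline. It states
nothing the test suite or `scripts/acceptance.py` does not itself compute.

## Study design and the synthetic generator

The pipeline targets batch-culture growth experiments on a full factorial
grid: three separate resource experiments (light in µmol photons m⁻² s⁻¹;
nitrogen and phosphorus in µmol L⁻¹), each with 8 levels

| resource | levels |
|---|---|
| light | 1, 8, 18, 40, 70, 108, 164, 240 |
| nitrogen | 0.5, 1, 2, 5, 20, 80, 400, 800 |
| phosphorus | 0.01, 0.1, 0.5, 1.5, 5, 10, 35, 50 |

crossed with six temperatures (15, 20, 24, 28, 32, 35 °C) and 4 replicates
— 48 treatments per resource, 3,648 wells per experiment, 10,944 wells in
all for the default pool of 19 populations. Non-manipulated conditions are
held replete (light 110 µmol photons m⁻² s⁻¹, N 800 µmol L⁻¹,
P 50 µmol L⁻¹).

The generator's ground truth is the double-exponential thermal performance
curve with its birth term scaled by a Monod factor g(R) = R/(K_s + R).
This coupling is chosen so the simulated surface is *exactly* Monod in R at
fixed T and *exactly* the replete TPC at saturating R — i.e., the
downstream fitted models are correctly specified, which is what makes
parameter recovery a clean test of the inference machinery rather than of
model mismatch. Trait ranges per population (drawn once per seed):
T_opt ~ U(18, 33) °C, b₂ ~ U(0.05, 0.12) °C⁻¹, d₂ − b₂ ~ U(0.08, 0.20) °C⁻¹
(guaranteeing a hump), d₀ ~ U(0.05, 0.30) d⁻¹, replete growth at the
optimum U(0.5, 2.2) d⁻¹ (b₁ solved from these), and log-uniform K_s
spanning roughly each resource gradient's informative range (light 2–40,
nitrogen 0.2–20, phosphorus 0.01–2).

Two noise models: additive Gaussian (sd 0.05 d⁻¹ by default) on growth
rates for the fast path, and multiplicative lognormal noise
(CV 0.05) on fluorescence readings for the time-series path — fluorescence
error scales with signal. Trajectories start at the 20-RFU inoculation
target, stay flat for a per-population lag (0–0.5 d), then grow
exponentially at the true rate, hard-capped at the carrying capacity
(800–3,000 RFU); readings are floored at 0.1 RFU so logs are always
defined. The default plate schedule is two readings ~9 h apart on each of
days 0–4 plus daily readings on days 5–7 (13 points). The cap is a hard
ceiling, not a smooth logistic approach: the growth-rate estimator models
an abrupt exponential-to-stationary transition, and a smooth bend would
contaminate the exponential-segment slope by design rather than by noise
(with a smooth logistic, fast growers' slopes are biased low by up to
~0.26 d⁻¹; with the cap, median recovery error is 0.01–0.04 d⁻¹ across
seeds).

What the generator does *not* emulate: plate-position/edge effects,
bacterial contamination, pigment-channel differences between phyla,
acclimation carry-over, and any model misspecification. Passing tests
therefore demonstrate that the inference machinery is correct and
well-calibrated under its own assumptions, not that those assumptions hold
for any particular real dataset.

## Growth-rate estimation

Each well's ln(RFU) series is fitted under four mean structures — line,
lag+line, line+saturation, lag+line+saturation — with breakpoints profiled
over the observed time points (each candidate reduces to a 2-parameter
least squares given the breakpoints). Selection is by AIC
(n·ln(RSS/n) + 2k, k counting mean parameters, breakpoints and the residual
variance; AICc optional), with ties broken toward fewer parameters, so on
noiseless exponential data the plain line wins. The exponential segment
must contain ≥ 3 observations. RSS is floored at 1e-12·n to keep the
criterion finite on exact fits. Estimates are invariant to rescaling all
RFU by a positive constant (only the intercept shifts).

## Bayesian fits

Both nonlinear models are sampled with an affine-invariant ensemble sampler
using differential-evolution moves (80% DE / 20% DE-snooker), which mix far
better than stretch moves on these correlated posteriors at short chain
lengths. Walkers are partitioned into 4 chain groups; the first half of
each chain is burn-in; retained draws are pooled (20,000 at protocol
settings of 4 x 10,000; tests and the acceptance script use 4 x 2,000
pooling 4,000 — the reduced size keeps a 40-fit recovery study around a
minute while leaving split-R̂ < 1.05). Split-R̂ over the chain groups is
reported per parameter with threshold 1.05; non-convergence flags the fit,
never silently accepts it. Every fit's seed derives from a master seed
hashed with the unit identifiers (population, resource, gradient value), so
any single fit is independently reproducible.

The observation model is Gaussian with a half-normal(1) prior on the
residual sd; replicates enter as independent observations. Monod priors are
truncated normals at zero: μ_max (1, 0.9) and m (0, 0.7) for all resources,
K_s resource-specific — light (2.5, 0.7), nitrogen (2.5, 0.9), phosphorus
(0.001, 0.8). A fit requires data at ≥ 3 distinct resource levels, and the
retention rule keeps a fit only when ≥ 3 levels have mean observed μ above
m_ext = 0.1 d⁻¹.

Because the K_s priors are informative, posterior medians shrink toward the
prior mean; at the study noise level this contributes a few percent of
error for truths far from the prior mean (nonlinear least squares on the
same data achieves ~7% median K_s error; the Bayesian medians land at
~7–13% depending on the seed, while μ_max recovers within ~2%). This is a
property of the protocol's priors, not a sampler defect.

The TPC is sampled in the reparameterisation (w, b₂, d₀, d₂, T_opt) with
w = b₁·e^{b₂·T_opt} — the birth rate at the optimum — which decorrelates
the birth amplitude from T_opt; b₁ is recovered afterwards. Priors
(truncated normals): w (1, 1), b₂ (0.1, 0.1), d₀ (0.1, 0.5), d₂ (0.3, 0.3),
T_opt (27, 8) bounded to [0, 50] °C; the support additionally requires
d₂ > b₂ so the curve has an interior maximum. g is fixed to 1 within a
resource level — level-specific limitation is absorbed into b₁. A fit
requires mean observed μ > m_ext at ≥ 3 temperatures.

Derived thermal traits are computed per retained draw by scanning for a
sign change and polishing with Brent's method (xtol 1e-9): T_max in
(T_opt, T_opt + 100], T_min in [T_opt − 150, T_opt), and the two crossings
of 0.8·μ(T_opt) for T_br. Draws where μ(T_opt) ≤ 0 or a bracket contains no
sign change drop out of that trait's posterior summary only. Posterior
summaries are medians with equal-tailed 95% intervals.

Posterior-median exclusion bounds (inclusive for retention; only medians
strictly beyond a bound are flagged, and fits are flagged, never deleted):
T_opt within the measured 15–35 °C; T_max ≤ 40 °C (5 °C above the warmest
treatment); T_min ≥ 0 °C (15 °C below the coldest); T_br ≤ 20 °C (the
measured range).

## Shape classification

The penalized spline is a cubic B-spline basis of dimension
min(10, g − 1) for g gradient values, with the *integrated squared second
derivative* as the penalty (computed exactly by 3-point Gauss–Legendre
quadrature per knot span). This penalty's null space is exactly the linear
functions, so infinite smoothing recovers a straight line and the influence
trace runs from 2 (λ → ∞) to the basis dimension (λ → 0). The reported EDF
is the smooth-term convention — trace minus one — so a straight line has
EDF 1, matching the ≤ 1.6 linearity threshold. λ is selected per fit by GCV
over a 49-point log grid (1e-8 to 1e8); near-exact GCV ties resolve to the
largest λ so exactly-linear data land on the linear pathway rather than on
an interpolating wiggle. The gamma family uses a log link, under which the
IRLS weights are constant, so the same influence traces apply and GCV is
evaluated on the working residuals; gamma is guarded to strictly positive
responses and is used for the zero-bounded traits (R\*, α) against
temperature. Nitrogen and phosphorus gradients are log10-transformed before
fitting.

Each bootstrap iteration samples one posterior draw independently per
gradient value and fits one curve; the protocol size is 5,000 bootstrap
fits (tests and benchmarks use 100–500). With ≤ 3 gradient values the
pathway is a straight line from the start. Classification evaluates the
spline's analytic first derivative on a 200-point grid; a crossing requires
the sign on each side to persist for ≥ 2 consecutive grid points (noise
guard). Negative→positive crossing = U-shaped, positive→negative =
hump-shaped, no crossing = monotonic. Gates: ≥ 80% of fits linear → refit
lines to the same bootstrap samples and require ≥ 70% slope-sign agreement;
otherwise the modal derivative-based label needs ≥ 60% support; anything
weaker is "uncertain". The mean-species curve is a single unweighted fit to
cross-population means of posterior medians (≥ 2 populations per gradient
value) under the same gates, reported deterministically.

## Trait associations

Summaries per population x resource: R\*_min is the smallest posterior-median
R\* across temperatures among retained fits, natural-log transformed and
z-scored across populations *within each resource type* (the log base only
shifts the mean, which the z-score removes); TR\*_min is the experimental
temperature at which that minimum occurs; net-μ_max_max, T_opt_max,
T_max_max and T_br_max are maxima over the relevant gradient of
non-excluded medians. Populations missing a trait are dropped listwise per
analysis, with counts reported.

PCA runs on centered/scaled columns (scikit-learn); ANOSIM is computed from
ranked Euclidean distances, R = (r̄_between − r̄_within)/(M/2) with
M = n(n−1)/2 and a label-permutation p-value (cross-checked against
scikit-bio in the tests); Welch ANOVA and Games-Howell come from pingouin;
Kendall τ-b from scipy (cross-checked against an O(n²) pair-count oracle).
The interaction test is a partial F-test of y ~ x·resource against
y ~ x + resource; when p > 0.05 the pooled regression is reported. The
constrained null for correlations with T_max_max draws a surrogate trait
uniformly between a lower bound and each population's T_max_max; the lower
bound defaults to the coldest treatment (15 °C) because T_min is rarely
estimable, and is configurable to an estimated T_min where retained. No
multiple-testing correction is applied to the correlation matrix by
default (Benjamini–Hochberg available as an option at the call site).

## Limitations

- Fits are per temperature (Monod) or per resource level (TPC); there is no
  joint temperature x resource surface model, and no random-effect
  structure across replicates.
- The synthetic study is correctly specified by construction; recovery
  results bound the machinery's error, not real-data error.
- K_s medians inherit prior shrinkage (see above); users fitting organisms
  with half-saturation constants far from the default priors should widen
  them.
- Shape calls at 6 gradient values have limited power; the "uncertain"
  label is the honest outcome for weak signals and occurs frequently at
  realistic noise.
- The reduced sampler settings used in tests trade posterior tail accuracy
  for speed; protocol settings (4 x 10,000, 20,000 pooled draws) are the
  defaults in `PipelineConfig`.
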