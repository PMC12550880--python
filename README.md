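# thermotrait

Trait inference for phytoplankton growth under crossed temperature x
resource gradients.

Warming surface waters change light and nutrient availability at the same
time, so whether a phytoplankton population thrives under future conditions
depends jointly on its thermal performance and its resource competitiveness.
This package implements, as a tested and reusable pipeline, the full
inference chain for batch-culture growth experiments in which populations
are grown along a resource gradient (light, nitrogen or phosphorus; 8
levels) crossed with a temperature gradient (15, 20, 24, 28, 32, 35 °C) in
replicate. It is aimed at experimental aquatic ecologists and at anyone who
needs a worked, end-to-end reference implementation of Monod / thermal
performance curve (TPC) trait inference with honest uncertainty propagation.

## The models

**Growth vs resource (Monod).** At a fixed temperature, the specific growth
rate against resource level *R* is

μ(R) = μ_max · R / (K_s + R) − m

with μ_max the gross maximum specific growth rate (d⁻¹), K_s the
half-saturation constant (resource units) and m the intrinsic loss rate
(d⁻¹). Posteriors are sampled per population x temperature with
truncated-normal priors (all parameters bounded below at zero) and the
derived competition traits are computed per posterior draw:

- affinity α = μ_max / K_s (initial slope, competitiveness at low resource);
- R\* = m_tot·K_s / (μ_max − m_tot) with m_tot = m + m_ext, the resource
  level at which net growth balances total losses — the equilibrium
  competitive-ability metric of resource competition theory (lower wins).
  m_ext is an externally imposed loss (dilution/sinking), 0.1 d⁻¹ by
  default;
- net-μ_max = μ_max − m.

**Growth vs temperature (double-exponential TPC).** At a fixed resource
level, growth is birth minus death with both rates exponential in
temperature:

μ(T) = b₁·e^{b₂T}·g(R) − [d₀ + (b₁b₂/d₂)·e^{(b₂−d₂)T_opt}·e^{d₂T}]

parameterised so the curve peaks exactly at T_opt when resource is replete
(g = 1). Derived per draw by root-finding: T_max and T_min (upper/lower
zero crossings) and T_br (thermal breadth, the width of the interval where
μ ≥ 80% of μ(T_opt)).

**Shape classification.** How each trait varies along its gradient (Monod
traits vs temperature; TPC traits vs resource) is classified by a
posterior-bootstrap ensemble of penalized-spline (GAM) fits: one posterior
draw per gradient value per bootstrap, smoothing by GCV, a fit counting as
linear when its smooth-term EDF ≤ 1.6. When ≥ 80% of fits are linear,
straight lines are refitted and a slope-sign call needs ≥ 70% agreement;
otherwise the sign pattern of the spline's first derivative labels each fit
U-shaped / hump-shaped / increasing / decreasing and the modal label needs
≥ 60% support, else "uncertain".

**Trait associations.** Six summary traits per population x resource
(scaled log R\*_min, TR\*_min, net-μ_max_max, T_opt_max, T_max_max,
T_br_max) feed a PCA, ANOSIM group tests, Welch ANOVA + Games-Howell,
a Kendall τ-b correlation matrix, resource-interaction tests, and a
constrained-resampling null model for correlations involving T_max_max
(a trait bounded above by T_max correlates with it even at random; the
null quantifies that artifact).

Everything is exercised end-to-end on synthetic data whose generator
reproduces the experimental design exactly (19 populations x 48 treatments
x 4 replicates per resource = 3,648 wells per experiment, 10,944 wells in
total) from known ground-truth traits, so every stage's accuracy is
measurable.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the synthetic
study and write their tables under `results/`:

```sh
python analysis/01_simulate_experiment.py --seed 1
python analysis/02_estimate_growth_rates.py
python analysis/03_fit_monod.py
python analysis/04_fit_tpc.py
python analysis/05_classify_shapes.py
python analysis/06_trait_associations.py
```

With seed 1 the chain prints, among other things:

```
light: 48 treatments, 3648 wells
total wells: 10944
median |mu_hat - mu_true|: 0.0193 d^-1          # growth-rate stage, 576 wells
fits: 72; retained: 48; converged: 71           # Monod stage, 4 populations
median mu_max recovery error: 4.5%
median |Topt_hat - Topt_true| ...: 0.35 C       # TPC stage
PCA: PC1+PC2 explain 86.7% of variance
tau(Topt_max, Tmax_max) = 0.848; constrained-null mean 0.272,
observed at percentile 1.000
```

Reading this: per-well growth rates come back within ~0.02 d⁻¹ of the
simulated truth; Bayesian Monod and TPC fits recover μ_max within ~5% and
T_opt within ~0.4 °C at the study's noise level; and in the association
stage the observed correlation between the warmest optimum and the thermal
maximum (τ = 0.85) clearly exceeds what the bounded-sampling artifact alone
would produce (null mean 0.27) — the kind of statement the null model
exists to license. The shape stage labels most populations' R\*–temperature
relationships U-shaped, the geometry resource competition theory predicts.

## Layout

- `src/thermotrait/` — the library: `synthetic_data`, `growth_rates`,
  `monod_traits`, `tpc_traits`, `gradient_shapes`, `trait_associations`,
  `pipeline_io` (config, CSV interchange, one-call orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — the model, priors, numerical choices and limitations.
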