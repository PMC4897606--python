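# Methods

## Problem setting

An outdoor aquaculture pond is instrumented with S dissolved-oxygen (DO)
sensors plus a shore weather station recording water temperature (°C), solar
radiation (W/m²), wind speed (m/s), rainfall (mm) and air humidity (%) at a
fixed interval (20 min by default). Field DO sensors fail in three
characteristic ways: dropouts that report an exact 0.00 mg/L, spikes far
above neighbouring values, and persistent calibration bias. The package
first fuses the redundant sensors into one credible DO series, then
forecasts that series one step ahead.

## Synthetic pond generator

No public pond dataset accompanies this method, so the generator emulates
the statistical structure the method assumes. The latent truth is

    DO(t) = m + a·sin(2π(h(t) − φ)/24) + b·(T(t) − T̄) + e(t),

with `h(t)` the hour of day, `T(t)` water temperature and `e(t)` a
stationary AR(1) residual. Defaults: mean m = 6 mg/L, diel amplitude
a = 2 mg/L, phase φ = 10 h (peak at 16:00, after the day's photosynthesis),
temperature coupling b = 0.1 mg/L/°C, AR(1) ρ = 0.9 with innovation SD
0.15 mg/L, floored at 0.05 mg/L (inactive at defaults). Covariates carry
matching diel structure: temperature peaks mid-afternoon (26 ± 3 °C),
solar radiation is a clipped half-sine peaking at noon (800 W/m² max),
humidity moves opposite to temperature, wind is AR(1) around 2 m/s, rain is
sparse exponential events. The value ranges bracket the 0–8.4 mg/L span
typical of summer crab-pond records.

Sensors observe truth + N(0, 0.2 mg/L); per reading, independently, a
dropout (probability 0.02, reading set to exact 0.00) or a spike
(probability 0.01, +3 mg/L) is injected, and one sensor (index 3) carries a
−0.8 mg/L bias throughout; readings are clipped at 0 (physical
non-negativity). Fault sites are recorded in a validity mask used only for
evaluation — the fusion stage never sees it, mirroring deployment. Faults
are i.i.d. per reading; real faults can cluster in bursts, and real weather
is not a stationary sinusoid-plus-AR(1), so passing tests demonstrate the
machinery and its robustness mechanism, not field performance.

## Fusion network

Inputs are the S = 4 raw sensor readings by default; the reference target is
sensor 1's reading. (An optional switch adds the five covariates as fusion
inputs; it is off by default since the sensors alone carry the fused signal
and the mixed-unit covariates would need their own scaling.) Training rows
whose reference reading is an exact 0.00 are dropped from the fit — a zero
target is itself a dropout — but prediction runs on every row.

Centers come from K-means (scikit-learn's Lloyd's algorithm, 10 restarts,
seeded); the shared width is the classical heuristic σ = d_max/√(2K) with
d_max the largest pairwise center distance (fallback σ = 1 for degenerate
geometries). The hidden-to-output map is linear, so the output weights and
bias are the minimum-norm least-squares solution of `[Φ, 1]·[w; b] = y` —
exact, deterministic, and well-defined even for rank-deficient designs;
no iterative error criterion is needed. K defaults to 10 hidden units:
small enough that centers summarize fault-free reading clusters rather than
memorize faults, large enough to track the diel range. Training residual is
non-increasing in K in practice (tested over K ∈ {2,4,8,16}).

## LSSVM

Training solves the (N+1)-dimensional KKT system by a dense symmetric solve
(`scipy.linalg.solve`, minimum-norm fallback, residual checked against
1e−8·‖y‖); N is ~120 here, so no low-rank machinery is warranted. The kernel
convention is fixed as K(x,z) = exp(−‖x−z‖²/2σ²) — conventions differ by
factors of 2 between texts and (γ, σ) optima are convention-dependent, so it
is stated once and used everywhere. Features are z-scored with
training-block statistics (stored in the results object, re-applied at
prediction): an isotropic kernel over °C, W/m², mm and mg/L is meaningless
without it. The baseline selects (γ, σ) by 5-fold cross-validation on a
log-spaced grid (γ ∈ {0.1…1000}, σ ∈ {0.25…4}) with contiguous unshuffled
folds and ties broken toward smaller γ then smaller σ.

## Particle swarm tuning

Particles encode (log₁₀γ, log₁₀σ) in the box [−2, 6] × [−2, 2], so decoded
parameters are always positive and the search spans eight decades of
regularization. Swarm defaults: 50 particles, 200 generations, c1 = c2 = 2,
velocity cap 0.2·(range) per dimension, uniform initialization, strict-
improvement personal/global best updates. The standard variant uses constant
inertia w = 0.9; the improved variant maps each particle's current fitness
linearly from w_min = 0.4 (swarm-best) to w_max = 0.9 (swarm-average and
worse) — the published description of this adaptive rule is qualitative
("close to the optimum ⇒ smaller weight"), so the linear fitness-
proportional form is our concrete interpretation — and, independently,
re-draws each particle's position uniformly with mutation probability
pm = 0.05. The two mechanisms have separate knobs and either can be
disabled. Non-finite objective values are logged and treated as +∞; the
iteration floor for early stopping defaults to 0 (all generations run).
`gbest_history` records the best fitness after initialization and after
each generation (length = generations + 1) and is non-increasing by
construction.

Tuning fitness is the RMSE between predicted and actual values on a
validation portion of the training block: the `tune_lssvm` default is the
last-20% temporal holdout (cheap, respects time order); the pipeline's
roster comparison instead uses 5-fold CV fitness (`pso_folds=5`) so that the
swarm-tuned models and the grid-CV baseline are selected by the same
criterion and the comparison isolates the optimizer rather than the
validation scheme. A 24-row holdout is simply too noisy a selection signal
at this data size.

## Experiment protocol

Rows 0–499 train the fusion network; rows 500–699 are fused out-of-sample
and become the forecasting dataset. The supervised table regresses fused DO
at time t on the five covariates at t plus the fused DO at t−1 (one-step
ahead at the native interval); the lag drops one row, so the 200 fused rows
yield 199 usable ones, split 120 train / 79 test — the closest faithful
accounting of a 120/80 description that ignores the lag row, and
configurable. Splits are contiguous and temporally ordered; nothing is
shuffled. Scaling statistics, K-means centers and tuned (γ, σ) are all
computed on training partitions only, and a test asserts this from the
persisted artifacts. All randomness derives from one experiment seed
(synthetic data and K-means use it directly; the standard and improved
swarms use seed+1 and seed+2), making `metrics.json` byte-reproducible. A
backprop-network baseline is deliberately not reimplemented; any external
model's predictions can be scored through the same metrics via a CSV.

## Metrics

MAE, MSE, RMSE, MAPE (zero observations excluded from the mean, with a
warning), Nash–Sutcliffe efficiency computed against the evaluation block's
own mean (the standard definition; a constant observed block leaves it
undefined/NaN with a warning), and R² as squared Pearson correlation.
Model comparison uses `relative_difference(ref, cand) =
100·(ref − cand)/ref`, rounded to 2 decimals at the reporting layer only.
The comparison report carries both MAE and MAPE so either reading of an
ambiguous published column label is reproducible. Running time is
hardware-dependent and excluded from comparisons.

## Problem sizes and determinism

Default experiment size is 720 simulated rows (10 days at 20 min), of which
700 feed the fusion splits; the test suite runs reduced swarms (10–20
particles, 10–40 generations) where the property under test does not need
the full 50 × 200 budget, and the end-to-end reproducibility check runs the
full default configuration twice. Stochastic claims (fusion beats every
corrupted sensor; tuned fitness reaches a planted model's; sphere
convergence) are asserted over 10 fixed seeds with the margins stated in
the tests.

## Known limitations

* The generator's faults are temporally independent; bursty or drifting
  faults would challenge the fusion network differently.
* Fusion quality is judged against synthetic truth; with real data only the
  reference sensor is available as a target, inheriting its own faults
  (zero-target rows are dropped, spike-target rows are not).
* One-step-ahead only; multi-step forecasting is out of scope.
* The swarm does not guarantee a global optimum; with the 5-fold CV fitness
  it is competitive with grid CV at this data size, but on very small
  holdouts it can overfit the validation slice.
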