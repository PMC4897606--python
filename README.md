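# pondcast

Forecasting dissolved oxygen (DO) in outdoor aquaculture ponds from noisy,
partially faulty multi-sensor records. DO is the variable that decides
whether a crab pond thrives or suffocates, and the raw record from field
sensors is full of dropouts (exact 0.00 mg/L readings), spikes far above
their neighbours, and persistently biased units. `pondcast` implements the
hybrid method this situation calls for, as three composable stages:

1. **RBF-network sensor fusion.** S simultaneous DO readings are fused into
   one credible value by a three-layer radial-basis-function network: hidden
   units `φ_j(x) = exp(−‖x − c_j‖² / 2σ_j²)` with centers `c_j` from K-means
   clustering of the training inputs, and a linear output layer
   `ŷ = Σ_j w_j φ_j(x) + b` fitted by least squares. Faulty reading vectors
   lie far from every center, so their activations vanish and the output
   falls back toward the bias instead of echoing the fault.
2. **LSSVM forecasting.** A least-squares support vector machine regresses
   next-step fused DO on the meteorological covariates and the previous
   fused value. Training is a single symmetric linear solve of the KKT
   system `[[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]` with the RBF kernel
   `K(x,z) = exp(−‖x − z‖²/2σ²)`; prediction is the dual expansion
   `f(x) = Σ_i α_i K(x, x_i) + b`.
3. **Improved particle swarm optimization (IPSO).** The LSSVM's
   regularization γ and kernel width σ are tuned by a particle swarm in
   (log₁₀γ, log₁₀σ) space. The improved variant adds a fitness-proportional
   inertia weight (good particles exploit, bad particles explore) and a
   mutation probability that re-seeds particles uniformly to escape local
   minima.

A synthetic pond generator (diel DO cycle phase-locked to solar radiation,
temperature coupling, AR(1) weather noise, configurable fault injection)
makes every stage runnable and testable without field data.

## Worked example

```python
import numpy as np
import pondcast as pc

frame = pc.simulate(pc.SyntheticConfig(n_samples=700, seed=42))
X = frame.sensor_do                       # (700, 4) faulty DO readings

fusion = pc.RBFNetFusion(X[:500, 0], X[:500], n_centers=10).fit(seed=42)
print(fusion.summary())
fused = fusion.predict(X)

report = pc.run_experiment(pc.ExperimentConfig(seed=42,
                                               pso_particles=20, pso_iters=40))
```

The fusion summary prints

```
RBF fusion network
==================
hidden units (K):      10
input dimension:       4
training rows used:    490 of 500
shared width sigma:    2.504
training RMSE (mg/L):  0.353693
```

(10 of the 500 training rows had a zero-fault reference reading and were
dropped). On the 200 held-out rows the fused series has RMSE 0.254 mg/L
against the true DO, while the four corrupted sensors individually score
0.576, 0.766, 1.348 and 1.084 mg/L — fusion suppresses the injected zeros,
spikes and the biased fourth sensor. The experiment report then compares the
forecasters on the 79-row test block:

```
cv-lssvm   gamma=10        sigma=4       RMSE=0.3864 MAE=0.3015 NSC=0.9484
pso-lssvm  gamma=1.615e+05 sigma=100     RMSE=0.3462 MAE=0.2573 NSC=0.9586
ipso-lssvm gamma=1.608e+05 sigma=100     RMSE=0.3462 MAE=0.2572 NSC=0.9586
```

NSC is the Nash–Sutcliffe efficiency (1 = perfect forecast, 0 = no better
than the observed mean); here the swarm-tuned model improves on the
grid-CV baseline by 14.68 % in MAE, 10.40 % in RMSE and 19.71 % in MSE
(`report["relative_differences_vs_ipso"]`).

## Command line

```bash
pondcast simulate --n 700 --seed 3 --out frame.csv
pondcast fuse     --in frame.csv --train-rows 500 --k 10 --seed 3 --out fused.csv
pondcast tune     --in fused.csv --train-rows 120 --improved --out model.json
pondcast predict  --model model.json --in fused.csv --start-row 120 --out pred.csv
pondcast evaluate --obs pred.csv --out report.json
pondcast run-all  --n 720 --seed 1 --outdir experiment/
```

`run-all` persists every stage artifact (fused frame, supervised table,
model JSON files, predictions, swarm fitness histories and `metrics.json`)
and is byte-reproducible under a fixed seed. An external baseline's
predictions can be scored alongside the roster with `--external pred.csv`.

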