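# numprf

Numerosity population receptive field (pRF) analysis for surface-sampled
fMRI.

Cortical populations in several visual and auditory regions respond
preferentially to particular *numerosities* — the number of items (dots,
tones) in a stimulus — with tuning that is well described as Gaussian in
logarithmic number space. `numprf` estimates that tuning per cortical
vertex from block-design fMRI time series and quantifies how preferred
numerosity is laid out over the cortical surface. It is aimed at
researchers fitting numerosity (or similar parametric-feature) pRF models
to surface-resampled BOLD data, and ships a synthetic-data generator so
the entire pipeline is testable without scanner data.

## The model

Each vertex's neuronal response to numerosity x is

    z(x) = exp( -1/2 ((ln x - ln mu) / sigma_log)^2 ),

with preferred numerosity mu and log-space width sigma_log, reported as
the FWHM in linear units, omega = 2 mu sinh(sqrt(2 ln 2) sigma_log). The
predicted BOLD signal is s_t = z(x(t)) * h(t) (canonical double-gamma
HRF), and the measured percent-signal-change series is modelled as
y_t = beta s_t + beta0 + eps_t with i.i.d. Gaussian noise.

Estimation is exhaustive: all 89 x 60 grid combinations of
(mu in 0.8–5.2, sigma_log in 0.05–3.0, both step 0.05) are evaluated, the
scaling (beta, beta0) fit by OLS, and the likelihood maximizer retained.
Out-of-sample fit is the split-half cross-validated R^2 (odd runs 1,3,5,7
vs even runs 2,4,6,8, averaged over both directions). Vertices are
selected if beta > 0, 1 <= mu <= 5, and cvR^2 exceeds the F-test threshold
at alpha = 0.05 Bonferroni-corrected for the hemisphere's vertex count
(R^2 = 0.1625 at n = 145 volumes and 100 000 vertices). Selected vertices
are clustered on the mesh, cluster areas computed from fully-interior
triangles, clusters assigned to numerotopic maps by proximity to
reference centers, and topography quantified by binned area/FWHM
statistics, an order-5 coordinate polynomial model with 10-fold CV, and
mixed-effects models across subjects.

See `docs/methods.md` for the full model description and the numerical
choices.

## Worked example

Simulate 200 vertices (100 tuned with beta = 1 and per-run noise SD 0.5
in percent signal change, 100 pure noise), fit, and score recovery:

```python
import numpy as np, pandas as pd
from numprf import build_run, fit_vertices, fwhm_log, recovery_report
from numprf.simulate import GroundTruthVertex, simulate_vertices

schedule = build_run("visual")          # 4 cycles, TR 2.1 s, 145 volumes
rng = np.random.default_rng(0)
truths = [GroundTruthVertex(mu_true=float(m), sigma_log_true=0.5,
                            beta_true=1.0, noise_sd=0.5)
          for m in rng.uniform(1, 5, 100)]
truths += [GroundTruthVertex(noise_sd=0.5) for _ in range(100)]
runs = simulate_vertices(schedule, truths, n_runs=8, seed=1)

fits = fit_vertices(list(runs), schedule)
print(fits.loc[:2, ["mu_hat", "omega_hat", "beta_hat", "cv_r2", "selected"]])

truth = pd.DataFrame({
    "mu_true": [t.mu_true for t in truths],
    "omega_true": [None if t.is_null else fwhm_log(t.mu_true, t.sigma_log_true)
                   for t in truths]})
for k, v in recovery_report(fits, truth).items():
    print(f"{k}: {v}")
```

Output:

```
   mu_hat  omega_hat  beta_hat     cv_r2  selected
0    3.55   4.425459  1.006740  0.988213      True
1    2.10   2.617877  0.994662  0.979956      True
2    1.10   1.526348  0.984926  0.970640      True
n_tuned: 100
n_null: 100
sensitivity: 0.97
specificity: 1.0
mu_bias: 0.007978515131132123
mu_rmse: 0.05962474603873867
omega_rmse: 0.24413874295766547
```

The first rows show per-vertex estimates: preferred numerosity `mu_hat`
(grid-quantized to 0.05), linear-space FWHM `omega_hat`, the scaling
factor near its true value 1, and cvR^2 far above the 0.1625 selection
threshold. The report shows 97 of 100 tuned vertices selected, no false
positives among the 100 null vertices, and mu recovered with ~0.06 RMSE.

The same pipeline runs from the shell:

```
numprf schedule --modality visual --cycles 4 --tr 2.1 --volumes 145 --out events.tsv
numprf simulate --n-vertices 900 --map-fraction 0.3 --noise-sd 0.5 --seed 42 --out subj
numprf fit --data subj --out fits.tsv
numprf geometry --fits fits.tsv --mesh subj/mesh.asc --a-min 10 --d-max 60 --out clusters.tsv
```

which prints, for this seed:

```
48 blocks, stimulus ends 302.4 s, run spans 304.5 s -> events.tsv
wrote 8 runs x 900 vertices (visual) to subj/
900 vertices, 253 selected (R2 threshold 0.1625) -> fits.tsv
1 clusters -> clusters.tsv
```

with the planted numerotopic patch recovered as a single 221 mm^2 cluster
whose order-5 coordinate model reaches cv-r = 0.999.

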