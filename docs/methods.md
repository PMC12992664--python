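# Methods

## The model

Each vertex of the cortical surface is assumed to pool a neural population
whose response to a presented numerosity x is Gaussian in logarithmic
stimulus space:

    z(x) = exp( -1/2 ( (ln x - ln mu) / sigma_log )^2 )

with preferred numerosity mu (the stimulus eliciting the maximal response)
and tuning width sigma_log (SD in log-numerosity units). The width reported
to users is the full width at half maximum in *linear* numerosity units,

    omega = exp(ln mu + c sigma_log) - exp(ln mu - c sigma_log)
          = 2 mu sinh(c sigma_log),      c = sqrt(2 ln 2),

implemented through the hyperbolic-sine form (numerically identical to the
exponential difference, and trivially invertible via asinh). A linear-space
Gaussian variant (z Gaussian in x, omega = 2 c sigma_lin) is provided for
model comparison only; on data generated with log-Gaussian tuning it
cross-validates systematically worse, which the acceptance suite checks.

The measured percent-signal-change series of a vertex is modelled as

    y_t = beta * s_t + beta0 + eps_t,     s_t = z(x(t)) * h(t),

where h is the canonical double-gamma HRF, beta a scaling factor (percent
signal change per unit neuronal response), beta0 a baseline, and eps i.i.d.
Gaussian noise. Serial correlations are deliberately not modelled: under
i.i.d. errors, maximizing the Gaussian likelihood over (mu, sigma_log)
equals minimizing the residual sum of squares, which is what the grid
search does.

## Stimulus design

One run presents numerosities 1–5 in ascending order (blocks of 4.2 s, six
stimulus events each), a 16.8 s block of 20 items, the numerosities in
descending order, and a second 20-item block; this 12-block cycle repeats
four times per run (75.6 s/cycle, stimulation ends at 302.4 s of a 304.5 s
run, 145 volumes at TR 2.1 s). Eight runs per session give 384
presentations of each numerosity 1–5. Event timing differs by modality:
visual events are 300 ms stimulus + 400 ms gap; auditory events 500 ms +
200 ms. The 20-item baseline enters x(t) as numerosity 20 — it is a
modelled condition, not rest: it drives responses of broadly tuned
populations and anchors the low end of the tuning curves.

Two timing details are under-determined by the design description and are
fixed here as package choices:

- The default neuronal regressor is a block-level boxcar (the 400/200 ms
  intra-block gaps are far below BOLD temporal resolution); event-level
  boxcars are available via `event_level=True`.
- The auditory 20-item block is modelled as 8 events of 2.1 s (2.0 s tone
  sequence + 0.1 s pause), matching its 16.8 s total.

## Numerics of the forward model

The HRF is the difference of two gamma densities (shape 6 and 16, unit
dispersions, 1:6 peak:undershoot ratio, 32 s support), sampled on the
microtime grid and normalized to unit peak. Peak normalization only
rescales beta; cvR^2 and all selection decisions are invariant to it.

Convolution is causal, zero-padded at the run start, truncated to the run
length, and scaled by the microtime step dt (a Riemann sum of the
continuous convolution), with dt = tr/21 = 0.1 s by default so every event
duration is a grid multiple. Volume samples are taken at k*tr + 1.025 s
(the slice-timing reference); since 1.025 s is not a grid multiple of dt,
the convolved series is linearly interpolated at the exact sample times.

Because x(t) only takes values in {1, 2, 3, 4, 5, 20}, the predicted time
course for any tuning curve factorizes as C @ z(levels), where C holds the
six HRF-convolved per-level indicator boxcars. The grid search uses this
factorization; a test asserts it equals the direct per-parameter
convolution to 1e-10.

## Conditioning

Runs are standardized to percent signal change about their own mean
(100*(v/mean - 1)), then 12 confounds are removed by OLS against
[intercept | confounds]: six motion parameters, white-matter, CSF and
global signals, and three cosine drift terms. The drift basis is the three
lowest non-constant DCT-II terms (periods 609, 304.5 and 203 s for a
304.5 s run — i.e. everything slower than a 128 s high-pass). Residuals
keep zero mean; the model's beta0 absorbs any offset. Conditioned runs are
averaged pointwise (runs, never cycles).

## Estimation, cross-validation and selection

The default grid spans mu in 0.8–5.2 (step 0.05, 89 values) and sigma_log
in 0.05–3.0 (step 0.05, 60 values); these widths correspond to FWHM bounds
0.12–34.17 at mu = 1 and 0.59–170.9 at mu = 5. All 5340 combinations are
evaluated; ties in the maximum (possible only at exact numerical equality)
resolve to the first grid point in (mu ascending, sigma ascending) scan
order and are counted in `n_ties_`.

Split-half cross-validation partitions the 8 runs into odd (1, 3, 5, 7)
and even (2, 4, 6, 8) halves. Tuning parameters are fit on one half's
average; on the other half's average only (beta0, beta) are re-estimated by
OLS and R^2 = 1 - RSS/TSS is computed; cvR^2 is the mean of the two
directions. Because the linear coefficients are re-fit on the test half,
cvR^2 is non-negative by construction; the F-statistic conversion
nevertheless extends monotonically to negative inputs for robustness. With
p = 2 free parameters (beta0, beta — mu and omega come from independent
data), F = (R^2/(p-1)) / ((1-R^2)/(n-p)) with (1, 143) degrees of freedom
at n = 145. The selection threshold inverts the F quantile at
alpha/n_vertices; at alpha = 0.05 corrected for 100 000 vertices this gives
R^2 = 0.1625.

A vertex is selected if beta > 0, 1 <= mu <= 5, and cvR^2 exceeds the
threshold. The reported map values (mu, omega, beta, beta0) come from the
fit to the all-runs average; significance comes from the split-half
procedure. (The alternative — reporting the mean of the two half fits — is
a one-line change via the returned half estimators.)

## Surface geometry

Selected vertices are clustered by direct mesh-edge connectivity
(scipy connected components; a networkx BFS serves as the test oracle).
Cluster area is the summed cross-product area of triangles whose three
corners all belong to the cluster, so boundary triangles drop out —
splitting a cluster strictly loses area, which a test asserts. Clusters
below a minimum area (50 mm^2 visual, 25 mm^2 auditory) are discarded;
the rest are assigned to a numerotopic map if at least one vertex lies
within d_max (25 mm visual, 50 mm auditory) of a reference center, taking
the nearest center with label-order tie-breaking. Reference centers are a
user-supplied table; the packaged `data/synthetic_map_centers.tsv` is a
synthetic stand-in for testing only. Whole clusters get one label; no
splitting across maps is attempted.

Preferred numerosities are binned into eight width-0.5 bins on [1, 5]
(left-closed, last bin closed at 5). Per-bin summed area assigns each
fully supra-threshold triangle to a bin by the mean preferred numerosity
of its three corners; FWHM is averaged per vertex bin with its standard
error. Pearson correlations over bin centers, linear fits, and (for area)
quadratic fits summarize the relationships.

Topography within a cluster is modelled as mu = b0 + sum_k (b_xk x^k +
b_yk y^k + b_zk z^k), k = 1..5, on mean-centered coordinates (16 design
columns, no cross terms), estimated with 10-fold cross-validation over a
seeded random vertex partition; performance is the Pearson correlation of
predicted versus actual mu (cv-r) and the mean absolute error. Clusters
with <= 16 vertices are skipped. Boxplot summaries of per-map numerosity
ranges use linear-interpolation quartiles and the 1.5 IQR whisker rule.

## Group statistics

Participant count maps sum per-subject selection masks in a shared
standard-space vertex indexing. The geometry mixed-effects model regresses
binned area (or FWHM) on a hemisphere factor (L reference) plus
hemisphere-specific mu slopes, with a random intercept per subject,
estimated by REML (statsmodels MixedLM); a singular random-effects fit
falls back to pooled OLS with a warning. The control analysis fits a
categorical GLM with six HRF-convolved condition regressors (numerosities
1–5 and 20) plus confounds and evaluates the contrast
(1/5, 1/5, 1/5, 1/5, 1/5, -1); per-subject contrasts feed a one-sample
t-test with both one-sided p-values reported.

## Synthetic data: what it emulates and what it does not

The generator draws y = beta*s + beta0 + noise under the exact block
design, with i.i.d. Gaussian noise in percent-signal-change units
(optionally AR(1) to probe robustness). Default amplitudes bracket
realistic evoked responses: beta around 1–3 for visual-like and around
0.3–0.75 for auditory-like signal changes; the default recovery setting
(beta = 1, noise SD 0.5 per run, 8 runs) leaves roughly 0.18 noise SD in
the averaged run against a predicted response of order 1–4. Synthetic
subjects carry a planar grid mesh (analytically known triangle areas)
with a contiguous patch in which mu progresses smoothly along one axis and
sigma_log grows with mu, so FWHM increases with preferred numerosity; a
geometric position-to-mu mapping plants the decreasing area-versus-mu
relationship. Null vertices are pure noise.

What passing these simulations does *not* show about real data: the
generator contains no physiological noise spectrum, motion, spatial noise
correlation, HRF variability, or vertex-to-vertex signal leakage, and its
planar mesh is not a folded cortex. Recovery rates measured here
(sensitivity near 1 at the default SNR, specificity at or above 0.999)
therefore characterize the estimator under its own assumptions, not
expected field performance.

## Problem sizes and defaults used in tests

The test and acceptance suites use 500 tuned vertices for recovery, 10 000
null vertices for specificity calibration, 200 vertices for the log-versus-
linear comparison, 1600-vertex meshes for topography, and 8 simulated
subjects × 2 hemispheres × 8 bins for the mixed models; all sizes are
package defaults chosen to make the Monte-Carlo margins comfortable at
desk scale.

## Known limitations

- No gradient-based refinement: estimates are quantized to the grid step
  (0.05 in mu), which bounds recovery accuracy from below.
- Serial correlations are ignored by design; AR(1) simulation exists only
  to probe robustness.
- Whole-cluster map assignment can mislabel clusters spanning several
  reference centers.
- The GIFTI reader handles surface geometry arrays only (pointset +
  triangle), not per-vertex functional files.
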