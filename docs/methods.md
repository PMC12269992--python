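# Methods

## Non-reversibility (arrow of time)

For preprocessed signals the pairwise lagged Pearson correlation
`r_ij(T) = corr(s_i(t), s_j(t+T))` is mapped to the nonnegative dependency
scale `FS[i,j] = -1/2 log(1 - r²)`, computed on the forward series and on
the per-column time-flipped series; the squared element-wise difference is
the non-reversibility pair matrix. The transform keeps the output positive
and interpretable as dependency strength; it carries no Gaussian assumption
about the signals.

Conventions and their consequences:

* **Single maximal window.** Correlations use the one `M - T` overlapping
  window. Under this convention time reversal is *exactly* equivalent to
  transposition of the forward matrix (the reversed estimator pairs the
  same samples), so the pair matrix equals `(FS - FSᵀ)²` to machine
  precision and the measure is precisely the asymmetry of lagged
  dependencies. Finite-sample estimation noise, not window edge effects, is
  what makes it positive for reversible processes; it shrinks as the series
  grows.
* **Diagonal excluded** from every reduction: lagged autocorrelation is
  reversal-symmetric and only adds noise.
* **Global value = off-diagonal mean** (squared-Frobenius norm divided by
  the number of off-diagonal elements), so values are comparable across
  parcellation sizes; node values are row means over `j ≠ i`; a network
  value is the mean over ordered pairs with both regions in the network
  (node-level averaging is available by reducing `node_values` instead).
* **Lag fixed at 1 TR** by default (TR = 2.2 s), configurable in samples.
* `r²` is clamped at `1 - 1e-12` to keep the log finite on degenerate pairs.

## Preprocessing

Linear detrend, then a 2nd-order Butterworth band-pass (0.008–0.08 Hz)
applied forward–backward (zero phase — any phase lag would contaminate the
lag-based asymmetry), then per-column z-scoring. Columns with zero variance
after filtering raise an explicit error listing the offending regions: the
caller must exclude them via `exclude_nodes`, mirroring uniform exclusion
across subjects rather than silent per-subject dropping. Regions are always
matched by id across time series, coupling matrices, and parcellation
tables.

Preprocessing is only approximately idempotent: re-filtering an already
band-limited, z-scored signal reproduces it to about `1e-3` per interior
sample, the residual coming from filter edge transients entering the
z-score normalization. Exact idempotence is not attainable with a real
filter chain.

## The linearized Hopf model

Each node is a Hopf normal form with `a = -0.02` (noise-driven regime),
intrinsic frequency `ω` from the in-band peak of the cohort-averaged Welch
spectrum, noise SD `σ = 0.02` per real component, and diffusive coupling
`Σ_k C_jk (z_k - z_j)`. In `(x, y)` coordinates the Jacobian is
`[[A, -B], [B, A]]` with `A = diag(a - Σ_k C_jk) + C`, `B = diag(ω)`; for
nonnegative coupling the Gershgorin discs sit left of `a < 0`, so the
linearized system is provably stable (the code still verifies the
eigenvalues). Noise convention: `J Σ + Σ Jᵀ = -σ² I`, matching
`dX = J X dt + σ dW`; any fixed convention is absorbed by the fit because
both FC and CSv are correlation-normalized.

`CSv(T)[i,j]` estimates `corr(x_i(t), x_j(t+T))` on both the empirical and
the model side (the lag-0 empirical estimator divides by `M` so it equals
FC exactly on z-scored columns). The coupling entry `C_ij` carries the
influence `j → i`, which drives `corr(x_j(t), x_i(t+T)) = CSv[j,i]`; the
gradient update therefore pairs `C_ij` with the *transposed* CSv misfit.
Pairing it untransposed stalls the fit at a biased fixed point (recovery
correlation ≈ 0.63 instead of ≈ 0.98 on a 10-node benchmark) — the
orientation is load-bearing and is covered by a deliberate transposition
test.

Fitting: updates only on off-diagonal entries where the (binarized) SC mask
is nonzero; clamp to `[0, 0.2]` for stability headroom; model statistics
recomputed analytically each iteration; total error = sum of the two
Frobenius misfits; the best-error iterate is returned; convergence =
improvement below `1e-6` over 100 consecutive iterations (default cap 5000
iterations). An update that destabilizes the model is halved and retried,
up to 10 consecutive times. Cohort fitting pretrains a group-mean coupling
per cohort and initializes each subject at it. Defaults are desk-scale
(N ≲ 100); larger parcellations work but are not part of the test surface.

**Validity of the linear approximation.** The cubic `|z|²` saturation is
*not* negligible at `a = -0.02, σ = 0.02`: it shrinks the stationary
variance ~35% below the Lyapunov value and biases FC by up to ~0.1 per
element on moderately coupled networks. Under weak noise (`σ = 0.01`) the
analytic FC/CSv agree with long nonlinear simulations within 0.02 per
element, which is the regime the validation tests use. The fit itself is
unaffected by this caveat in practice because empirical and model sides are
compared on the same correlation scale. The simulator exposes
`cubic=False` to integrate the exactly-linear system for such validations;
Euler–Maruyama discretization additionally inflates variance when
`ω² dt ≳ 2|a|`, so validation runs use small `dt` or fast-mixing regimes.

## Trophic hierarchy

From edge weights `w_mn` (edge `m → n`; coupling matrices are transposed
into this orientation internally): in/out-weights, total `u`, imbalance
`v = w_in - w_out`, and levels solving `Λ h = v` with
`Λ = diag(u) - W - Wᵀ`. `Λ` is singular along the constant vector, so the
minimum-norm least-squares solution is taken per weakly connected component
and shifted to mean zero — incoherence and dispersion are gauge-invariant,
so any gauge is valid and mean-zero is reproducible. Incoherence
`F0 = Σ w_mn (h_n - h_m - 1)² / Σ w_mn`; coherence `1 - F0`. Self-edges are
allowed (they cancel in `v` and contribute `(0-1)² w` to `F0`); fitted GEC
diagonals are zero by construction. Flatness = SD of levels over ROIs;
cohort comparisons of flatness use Mann–Whitney U by default with
Brown–Forsythe also exposed. Regional aggregation averages levels within
anatomical groups; pairwise regional comparisons use the Wilcoxon
signed-rank test on per-subject group-mean differences, BH-FDR corrected
over pairs (the exact test behind such matrices is a declared choice).
PageRank uses damping 0.85 on the weighted out-degree-normalized walk with
dangling nodes sent uniformly.

## Cohort statistics

* Rank tests: "wilcoxon"/"mannwhitney" both run the rank-sum/Mann–Whitney U
  test (exact for small tie-free samples); "brownforsythe" tests variance
  via absolute deviations from group medians.
* Mixed models: random-intercept LMM `value ~ cohort + age + sex` with
  subject grouping; cohort fixed-effect p from the normal approximation.
  Type-I error calibrates to ~0.04–0.05 at 60 subjects in the null
  simulations; with a single value per subject the model collapses to OLS,
  and singular fits fall back to subject-mean OLS with a warning.
* MMD²: unbiased U-statistic, Gaussian kernel, bandwidth = median pairwise
  distance of the pooled sample (mean fallback); energy distance: Euclidean
  two-sample E-statistic. Both use label permutations with the add-one
  p-value `(1 + #{perm ≥ obs}) / (1 + n_perm)`, kernel/distance matrices
  computed once.
* BH-FDR step-up adjustment; MAD screening flags
  `|x - median| > k·1.4826·MAD` (k = 3); Spearman correlations with
  family-wise BH-FDR for clinical scores.
* Pattern separation: linear SVM (C = 1 — the protocol's purpose is
  separation, not tuning), per-feature standardization fit on training
  folds only. `split_cv` = repeated stratified random 85/15 splits (the
  "1000-fold" protocol read as 1000 random splits); `loocv_permutation` =
  PCA to 20 components fit on training folds, LOOCV accuracy, label-shuffle
  permutation p; a label-swap robustness check is available. GEC features
  are all off-diagonal entries (direction matters); FC/SC use the upper
  triangle. No leakage: scaler and PCA are inside the CV pipeline, verified
  by chance-level accuracy on pure-noise features with n ≪ d.

## Synthetic cohorts

The generator emulates the target study design: two cohorts of 15 subjects,
40 nodes, 200 volumes at TR = 2.2 s, intrinsic frequencies uniform in
0.008–0.08 Hz, a shared sparse symmetric mask (density 0.3). Directionality
is injected by redistributing each reciprocal edge pair's weight toward the
low-to-high-index ("feed-forward") direction: control-like subjects get a
baseline imbalance fraction of 0.4, patient-like subjects twice that, with
the pair total conserved — so the manipulation changes the arrow-of-time
signature without changing mean coupling (and hence barely changes FC).
Per-subject multiplicative jitter (SD 0.1) creates within-cohort
variability; per-subject SC matrices are the shared base weights with
subject jitter and *no* cohort effect, so SC-based separation sits at
chance by construction. `base_coupling = 0.03` puts row sums near 0.4 s⁻¹,
giving lagged correlations at 1 TR around 0.3–0.5 — strong enough to carry
directional information, far from saturation. BOLD is the Hopf
x-component directly (no hemodynamic convolution); clinical columns are
placeholder draws for interface testing only.

What the generator does *not* emulate: realistic anatomy or network
topology, hemodynamics, measurement noise, head motion, or clinically
meaningful score distributions. Passing tests therefore demonstrate that
the pipeline detects directional-imbalance effects of this kind and size
under its own model class — not that real patient data would behave this
way.

## Problem sizes and numerical choices

The shipped study (40 nodes, 15+15 subjects, asymmetry factor 2, seed 0)
runs in about 4–5 minutes on one core; group fits cap at 3000 iterations
and subject fits at 1500, which is past the convergence patience in
practice. Validation simulations use 10⁵–10⁶ Euler–Maruyama steps.
Degenerate inputs are handled explicitly: zero-variance correlation windows
give r = 0 with a warning, empty graphs and empty cohorts raise, dangling
PageRank nodes redistribute uniformly, all-tied rank tests return p = 1
with a warning.

## Known limitations

* The non-reversibility value is an asymmetry proxy, not an entropy
  estimate.
* The GEC fit is a heuristic gradient scheme on two moment matrices; it
  recovers ground truth well on its own model class (r ≥ 0.85 on 10-node
  benchmarks) but identifiability on real data is not established here.
* The LMM p-value uses the normal approximation; small cohorts (≲ 30
  subjects) will be mildly anticonservative.
* Hierarchy flatness comparisons report dispersion and direction only; the
  mapping from dispersion changes to "flatter" organization is an
  interpretive step left to the analyst.
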