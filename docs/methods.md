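# Methods

This note documents the models, conventions and numerical choices behind
`ephyscensus`: what the synthetic-data generator emulates, how each of the
33 variables is defined and extracted, and how the multivariate stages are
computed. It also states what the synthetic tests do and do not establish
about real recordings.

## The synthetic cell model

The generator is deliberately phenomenological rather than
conductance-based. The downstream analysis consumes only trace-level
features, so the model's job is to produce protocol-faithful traces whose
extracted variables have *exact* generative counterparts. Every recovery
test then has a closed-form oracle, which a Hodgkin–Huxley-style model
could not provide without re-deriving the feature definitions from its own
dynamics.

### Voltage-clamp IV traces

Active currents are synthesized directly from the functional forms the
extractor later fits:

- Na⁺ amplitude per step: Boltzmann sigmoid with half-activation `na_act`,
  slope 6 mV, plateau `na_max` (≤ 0);
- transient K⁺ amplitude: Boltzmann sigmoid (`kt_act`, slope 6 mV, plateau
  `kt_max`);
- stable K⁺ amplitude: exponential hinge `max(0, exp((v−a)/b) − e)·c` with
  `b = 25 mV` and `a = ks_act − b`, so the current activates at exactly
  `ks_act` and the curve maximum over the sampled range equals `ks_max`.

Time courses use unit-peak kernels with a 3 ms onset delay for the K⁺
currents, which temporally separates them from the fast Na⁺ transient
(alpha kernel peaking at 0.8 ms). The early-window minimum therefore reads
off the Na⁺ amplitude exactly, the steady-state window the stable-K⁺
amplitude, and their difference the transient-K⁺ amplitude, to well within
the 2% test tolerance. Traces are passive-subtracted by construction; real
data must be leak-subtracted before extraction.

### Spiking

Spikes are triangular waveforms anchored at the threshold potential
(`spike_thresh`), with a linear rise of duration `spike_rise/0.8` (making
the 10–90% rise time exactly `spike_rise`) and a fall chosen so the
half-height width is exactly `spike_width`. Spike counts per step current
follow the difference-of-exponentials tuning with offset 10 pA, slow scale
400 pA, decay `spike_adapt`, and peak scaled to `spike_gain`; intra-train
intervals start at `isi_first` and grow by `isi_accom` over the first
intervals (then saturate so trains fit the 300 ms injection); amplitudes
decay by `amp_accom`. The depolarization plateau of spiking sweeps sits at
threshold and charges with a fixed 3 ms constant, while the post-injection
repolarization decays with the cell's own τ_m = Rm·Cm — the asymmetry is
intentional: it gives the first spike a settled baseline (exact threshold
recovery) while keeping the tail variable tied to the passive parameters.

Cosine sweeps emit spikes per wave according to a period-tuning curve of
the same difference-of-exponentials family: `b = cos_width` and `c` solved
(Brent) so the analytic argmax sits exactly at `cos_resonance`; at 100 Hz
the per-wave means are additionally shaped by a ramp-exponential profile
whose argmax is `wave_buildup` and decay `wave_decay`. Emission is by
deterministic rounding of the cumulative expected count (so the bout total
is the rounded expectation and noiseless sweeps are bit-identical);
per-sweep Gaussian timing jitter (`spike_jitter`) makes the jitter index
informative.

### Synaptic and spontaneous protocols

Each shock leaves a 0.4 ms biphasic artifact, then an EPSC (alpha kernel,
5.2 ms latency, fully inside the 5–14 ms monosynaptic window) whose charge
follows `Q(τ) = 5·syn_amp·(1 + syn_facil·g(τ))` with `g` a unit-peak bump
at `τ = syn_tau`. The projected charge under infinitely slow stimulation
is `5·syn_amp`, so the ground-truth paired-pulse ratio is `1 + syn_facil`.
An optional slow component of mean amplitude `poly_amp` occupies the
15–145 ms polysynaptic window. Spontaneous traces carry Poisson-timed
mEPSC-shaped events (rate `mini_rate`, mean amplitude `mini_amp`, 15%
amplitude scatter) on Gaussian noise.

### Cohorts and missingness

Group parameter distributions (per stage group × naïve/stimulated) are
configuration, with defaults chosen to qualitatively reproduce the study
conditions this pipeline targets: naïve groups of 64 (stages 45–46) and 56
(stages 48–49) cells plus 60 stimulated cells; older naïve cells ~1.4×
more variable in every parameter; stimulated cells spikier on average but
~0.8× as variable. They are statements about the generator, not estimates
of real animals. Missingness is applied completely at random at a default
rate of 0.18 (the typical fraction of absent observations in such
censuses), with guards so no cell or variable is ever fully masked. The
MCAR mechanism is an assumption: real missingness is protocol-structured
(whole protocols drop out when a cell dies), so imputation performance on
real data may be worse than these tests show.

## Extraction conventions

- **IV windows.** The early window is 0–18.5 ms and the steady-state
  window 116.5–136.5 ms after the potential step — window specifications
  given in sample counts at 10 kHz, which places both inside the 150 ms
  step. Both are configurable.
- **Sigmoid canonicalization.** The IV sigmoid is
  `c/(1+exp(−(v−a)/b)) + d`, which has its half-maximum at `v = a`; the
  reported half-activation is `a` and the maximal current is the extremum
  of the fitted curve over the sampled range (read on a 0.1 mV grid).
- **Stable-K⁺ hinge.** In `max(0, exp((v−a)/b) − e)·c + d` the symbol `e`
  is Euler's number (the model has four free parameters a–d); the
  activation potential is the hinge opening, `a + b` in closed form.
- **Kink convention.** The spike threshold is the potential at the maximum
  of the second time derivative in a 4 ms pre-peak window (lightly
  smoothed for the derivative; the potential itself read from the raw
  trace). Amplitude is peak − kink; rise is 10→90% of that excursion;
  width is measured at the potential midway between kink and peak, using
  the half-level crossings nearest the peak (noise-robust). Note a
  consequence of the kink reference: for an ideal Gaussian bump the
  expected width is 2σ·sqrt(2·ln(2/(1+e^{−3/2}))) ≈ 1.98σ, not the
  baseline-referenced FWHM 2.355σ.
- **Spike detector.** Matched-filter Gaussian smoothing (SD 0.6 ms),
  peak-prominence threshold at max(6 mV, 6× the noise SD estimated from
  the MAD of the smoothed trace's first difference), a 2 ms refractory
  spacing, peaks snapped to the raw-trace maximum, and shape-based
  rejection of candidates smaller than 10 mV or with half-widths outside
  [0.2, 10] ms. All thresholds live in `DetectorConfig`. On generator
  spikes at SNR 5 the detector's F1 is ≥ 0.95 (tested); this replaces
  manual curation, which synthetic ground truth makes unnecessary.
- **Train metrics.** "I best" and "N spikes, step" are the argmax and
  maximum of the spikes-vs-current fit (0.1 pA grid). ISI metrics come
  from the sweep with the most spikes that is closest to I best;
  accommodation ratios are oriented second/first (ISI₂/ISI₁ and
  amp₂/amp₁, so values < 1 mean amplitude accommodation); the orientation
  is configurable.
- **Jitter.** δ-trains at 10 kHz, Gaussian smoothing σ = 2 ms, unit
  normalization, mean over all pairwise scalar products, then
  `ln(1 − mean)`. Empty sweeps are excluded from pairing; a mean of 1
  (identical trains) is clamped at 1 − 10⁻¹² before the logarithm, so the
  index is bounded by ln(10⁻¹²) ≈ −27.6.
- **Synaptic charge.** Artifacts are removed by linear interpolation
  across a 4 ms post-shock window (interpolation rather than zeroing, so
  synaptic current spanning the next shock at short ISIs is approximately
  preserved); repeats of each ISI are averaged, the pre-stimulus median
  subtracted, and current integrated from the first shock to 300 ms past
  the last (configurable; the response-window end is not standardized).
- **Monosynapticity.** Mean current 5–14 ms post-shock divided by the mean
  over 15–145 ms, averaged over shocks of the long-ISI (≥ 100 ms)
  conditions, with the late window truncated at the next shock; larger
  values mean a more purely monosynaptic response. Missing when the
  late-window mean is indistinguishable from zero.
- **mEPSC detection.** Threshold detection on a lightly smoothed trace:
  peaks above baseline + max(5 pA, 4.5× MAD noise), ≥ 5 ms apart;
  frequency = events / 60 s, amplitude = mean peak height above baseline.
- **Cosine counts.** "N spikes, cosine" averages per-wave counts across
  the five frequencies (per-wave, not per-bout, so frequencies contribute
  comparably); wave counts use the physical number of waves per bout
  (round(200 ms / T)).

All fits use bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) with a deterministic set of ~5 starts (plus an
informed log-slope start for the stable-K⁺ hinge, whose curve spans orders
of magnitude); the best residual is kept even when the optimizer halts on
a flat plateau. Degenerate inputs (all-zero counts, flat curves) return
non-converged fits whose derived values are missing, except where a value
is defined (zero spikes ⇒ "N spikes" = 0).

## Spike-train similarity

The Victor–Purpura metric is computed by dynamic programming with
insert/delete cost 1 and shift cost q·|Δt| capped at 2 (the
delete-plus-insert bound), q = 0.1/ms. Step-protocol responses are
concatenated in ascending current order before comparison. The embedding
is classical (Torgerson) MDS — double-centered squared distances,
eigendecomposition, top-2 coordinates, negative eigenvalues truncated, a
deterministic sign convention — chosen over nonmetric MDS for determinism
and because the downstream use (neighbor pulls) only needs local geometry;
nonmetric MDS is a reasonable alternative. Similar-spiking groups are the
reference cell plus its k = 5 nearest 2D neighbors, ties broken by id.

## Statistical engine

- **Correlations / FDR.** Pairwise-complete-observation correlations (each
  pair on its own n); Benjamini–Hochberg step-up at α = 0.05, reporting
  the largest passing raw p as the implied threshold.
- **Principal variables.** Share of total variance explained by variable
  i = mean over all p variables (self included) of r²ᵢⱼ — the squared-RM
  criterion for singletons; an uncorrelated variable scores exactly 1/p.
  For variable subsets, the mean over all variables of the R² from
  regressing each on the subset (several equivalent formulations of the
  multi-variable criterion exist; this regression form is the one
  implemented — users comparing against other definitions should check).
- **PCA with missing values.** Probabilistic PCA (y = Wx + μ + ε,
  isotropic noise) estimated by EM in which the E-step uses only each
  cell's observed entries. Initialization is deterministic (SVD of the
  mean-imputed standardized matrix); convergence when the relative change
  in expected observed-entry reconstruction error falls below 10⁻⁶, cap
  5000 iterations, with a non-convergence flag. Variables are standardized
  before fitting. Component shares are λ_c / total observed variance with
  λ_c = ‖w_c‖² + σ², computed on observed entries only — with missing data
  these shares are biased low relative to complete-data PCA, because
  missing values cannot contribute to explained variance even though
  predictions for them exist. On complete data the fit reproduces standard
  PCA (score correlation > 0.99, shares within 0.01; tested).
- **Promax.** Varimax (SVD algorithm) followed by oblique Procrustes
  rotation toward the element-wise power-4 target of the varimax solution
  (the conventional power; column-rescaled as in the standard promax
  recipe). Scores are counter-rotated so scores·loadingsᵀ is unchanged
  (tested to 10⁻⁸).
- **Projection.** New cells are standardized with the training means/SDs
  and scored by the PPCA posterior mean over their observed entries, then
  carried through the training rotation. Self-projection reproduces fit
  scores to machine precision.
- **Multiple imputation.** Gaussian chained equations: each incomplete
  column is regressed (ridge-stabilized) on all others, coefficients and
  residual variance are drawn from their posterior (normal–inverse-χ²),
  and missing entries are filled from the posterior predictive; 5 sweeps
  per imputation, 50 imputations by default, each reproducible from
  (seed, index). Columns with < 3 observations are mean-imputed with a
  warning. Equivalence with any particular imputation package is claimed
  only at the level of downstream statistics on synthetic data.
- **Cloud geometry.** Median of all pairwise distances (Euclidean in
  component space, city-block in the full 33-dimensional space). The
  group-comparison procedure standardizes the *pooled* data (per-variable,
  so between-group spread differences are preserved), imputes each group
  50 times, subsamples 10 sets of 50 cells per imputation (compensating
  unequal group sizes), computes the median city-block distance of each
  subset, and compares the two sets of 500 medians by Welch's t-test.
- **AGNES coefficient.** Average-linkage agglomerative clustering on
  Euclidean distances; for each observation m(i) = first-merge height /
  final-merge height, coefficient = mean(1 − m(i)). Verified against the
  reference R implementation to 10 decimal places on fixtures; coincident
  points contribute zero first-merge heights.
- **Local PCA.** Standard PCA on the standardized (imputed) matrix of one
  group; the reported share is (λ₁+λ₂)/Σλ.
- **Group tests.** Mann–Whitney (two-sided) for two-group contrasts,
  Welch's t, one-way ANOVA across stage groups, η² = SS_between/SS_total,
  and the variance-ratio F-test. The F-test is two-sided by default; the
  variance-inflation *screen* uses the one-sided alternative ("did
  variability increase?"), which is the question such screens ask and
  which at n = 60/group has exact power 0.82 against a 1.4× SD inflation
  at α = 0.05 (the two-sided version has 0.73). BH-FDR or Bonferroni
  masks are attached per test family as configured.
- **Sequential regression.** Type-I (sequential) sums of squares for a
  configured predictor order — activation potentials first, then membrane
  resistance, Na⁺ amplitude, capacitance, matching the narrative order of
  the analysis this reproduces — with pairwise interaction products
  (centered) appended after main effects when requested; shares are
  SS_term/SS_total and each term gets an F-test against the full-model
  residual. Type-I shares are order-dependent by construction, so the
  order is a configuration knob, not a default to trust blindly.
- **Rank renormalization.** Values are rank-transformed (stable ties) and
  mapped back to original units via a least-squares cubic polynomial of
  rank; a monotonicity pass (ε-bumps) guarantees the map is strictly
  order-preserving. Used to de-band activation potentials quantized by the
  10–20 mV command grid.

## Problem sizes in tests and acceptance

The test suite and acceptance script use deliberately small but fully
representative problem sizes: single quiet (noise-free) cells for exact
round trips; 10–30-cell cohorts for the end-to-end pipeline; 100 × 33
matrices for the PCA checks; 64 + 56 cells with 18% MCAR masking, 50
imputations × 10 subsamples of 50 for the cloud-inflation power check; and
500 simulations for the variance-ratio power check. These sizes were
chosen to estimate each property with comfortable margin; all scale knobs
are function arguments.

## Known limitations

- The generator's kinetics are schematic: no channel inactivation
  dynamics, no conductance interactions, no correlated noise. Passing
  round-trip tests demonstrate that the *extraction and statistics* are
  correct, not that the simulator reproduces tectal biophysics.
- The printed command-step range runs to +115 mV, which is unusually
  depolarized for a physiological step series; the simulator follows that
  protocol text as given.
- MCAR missingness and Gaussian imputation understate the difficulty of
  real, protocol-structured missingness.
- Isomap / locally-linear-embedding ordinations are out of scope; only the
  R² ordination-quality metric used to compare embeddings is provided.
- The exhaustive model-search layer sometimes wrapped around the
  sequential regression is out of scope; predictor order is explicit
  configuration here.
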