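# Methods

## Scope and model

The package analyses static functional connectivity of a 48-channel
frontal fNIRS montage in a two-session, within-subject design: each
subject is recorded before and after 24 h of total sleep deprivation,
each session containing a 60-s rest followed by six 10-s finger-tapping
stimuli (left/right alternating, 10-s inter-stimulus intervals) at a
3.9 Hz sampling rate. Connectivity is the Pearson correlation of
preprocessed total-hemoglobin (HbT) signals over 10-s state segments;
networks are summarised by density (weighted `ᵂD` or binary average node
degree), binary clustering coefficient `C`, and binary global efficiency
`E`.

All states enter with the same segment length — floor(10 s × fs) = 39
samples — because correlation estimates at different lengths are not
comparable. The rest segment is the centred 10-s window of the rest
period ([25 s, 35 s)); epochs are half-open sample intervals with start
index floor(onset × fs).

## Montage

The published optode lists (16 sources, 16 detectors on 10-10 positions)
do not include the pairing that defines the 48 channels. The packaged
montage therefore pairs every source with its three nearest detectors on
a flat scalp grid (one 10-10 step ≈ 3 cm), which reproduces the channel
count exactly and keeps a plausible ~3 cm separation; ties are broken by
detector list order and channels are ordered lexicographically by
(source index, detector index) for determinism. The SNIRF reader accepts
whatever montage a file carries — the pairing is input data, not an
algorithmic assumption. "Motor" channels, used for planting lateralised
responses, are those whose midpoint lies over the FC/C/CP rows of one
hemisphere.

## Preprocessing

Fixed order: wavelet despiking → low-pass → Beer–Lambert → (optional)
CBSI.

* **Wavelet despiking.** Discrete wavelet transform per channel and
  wavelength; detail coefficients outside the interquartile fence
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of their level are zeroed. Defaults:
  Daubechies-2, depth 3, linear ("smooth") boundary extension. The depth
  is deliberately shallow: at 3.9 Hz the three detail bands cover
  ≈ 0.24–1.95 Hz, entirely above the hemodynamic and systemic
  low-frequency band, so smooth in-band signal is reconstructed exactly
  (verified to machine precision) while broadband motion spikes lose
  ≥ 90 % of their amplitude. Deeper decompositions put genuine slow
  oscillations into thresholded levels and distort them; the family,
  depth and fence factor remain configurable.
* **Low-pass.** 5th-order Butterworth at 0.4 Hz applied forward and
  backward (zero phase), so the magnitude response is the squared
  single-pass response (amplitude gain 1/2 at the cutoff) and epoch
  timing is preserved.
* **Beer–Lambert.** Per channel and time point the 2×2 system
  ΔOD(λ) = [ε(λ,HbO)·ΔHbO + ε(λ,HbR)·ΔHbR]·d·DPF(λ) is solved for the
  micromolar concentration changes. Literature extinction coefficients
  for 760/850 nm are packaged; DPF defaults to 6.0 at both wavelengths
  and d to 3 cm. All constants are configuration; the synthetic
  generator uses the identical forward model, so forward∘inverse is an
  identity (tested at 1e-9).
* **CBSI.** With α = sd(HbO)/sd(HbR): HbO* = (HbO − α·HbR)/2,
  HbR* = −HbO*/α. Outputs are exactly anticorrelated by construction;
  HbT* = HbO*(1 − 1/α) remains a nonzero scaled copy whenever α ≠ 1.

**Quality control.** Coefficient of variation sd/mean of *raw intensity*
per channel (worst of the two wavelengths; CV of a zero-mean OD series
would be ill-defined). A session is excluded when the fraction of
channels with CV > 7.5 % strictly exceeds 80 %; a subject failing in
either session is dropped from all cells of the design.

## Thresholding

* *absolute*: keep c ≥ τ, grid 0.15–0.75 step 0.05 (the discard rule is
  "less than τ", so equality keeps the edge).
* *cost*: keep the k = round(cost·M) largest positive coefficients,
  M = N(N−1)/2, grid 0.10–0.85 step 0.05; ties broken by (row, column)
  order, which makes edge sets nested across the grid.
* *surrogate*: keep positive c with two-sided p < 0.05 from the exact
  transform t = c·√((n−2)/(1−c²)), df = n−2. Autocorrelation of the
  39-sample segments is ignored (correlations treated as i.i.d.-sample
  correlations) and no multiplicity correction is applied across the
  1128 pairs — both literal modelling choices, noted as fidelity
  limitations. Under channel-independent noise the expected retention is
  α/2 (only the positive tail is kept).

Zero-variance channels yield zero rows rather than being dropped,
keeping N = 48 constant across states. Metrics `C` and `E` are defined
on binarised networks only and, for wiring-cost-matched comparisons, are
*summed* across the cost grid (an ANOVA is invariant to the sum-vs-mean
scale choice).

## Statistics

The ANOVA is a balanced fully within-subject decomposition implemented
directly (sums of squares by the standard balanced-factorial identity;
each effect tested against its subject-interaction stratum), because the
design needs an arbitrary number of crossed within factors — sleep (2) ×
task (7), optionally × threshold — plus per-effect Greenhouse–Geisser
epsilon and Mauchly's test from orthonormally contrast-transformed
subject scores. The two-factor case is cross-validated against
statsmodels' AnovaRM (F, df, p to 1e-8) and pingouin (GG epsilon and
corrected p). The GG-corrected p is reported whenever Mauchly rejects at
0.05; with fewer subjects than effect df the contrast covariance is
singular, Mauchly is undefined (reported as NaN) and the trace-based
epsilon is still applied. Metrics are log(x + ε) transformed first
(ε = 1e-6, handling exact-zero densities).

Dunnett's many-to-one comparisons (each stimulus vs. rest, within sleep
state) use paired contrasts; adjusted p of contrast k is
P(max_j |T_j| ≥ |t_k|) under a multivariate t with the correlation
matrix estimated from the contrast scores (eigenvalue-clipped to PSD),
evaluated by Monte-Carlo with 10⁵ draws and a fixed seed. With one
contrast this reduces to the paired two-sided t-test (verified).

ΔᵂD is, per subject, the after-minus-before difference of (mean over the
six stimuli − rest) global weighted density from surrogate-thresholded
networks; it is correlated (Pearson, uncorrected two-sided p, pairwise
deletion of missing scores) with visit-2-minus-visit-1 changes in PAL,
RTI and RVPA. Channel-wise contrast maps are paired t-tests on local
weighted density (task-average minus rest, per sleep state, and their
between-state difference) with Benjamini–Hochberg FDR over the 48
channels. Kendall's W (tie-corrected) measures between-subject
concordance of the per-channel sleep-deprivation effect — the ranking of
channels by the change of (task − rest) local density — an
interpretation chosen because the concordance statistic's exact input is
otherwise underdetermined.

## Synthetic cohorts

The generator is the package's test bed and defines the conditions under
which every statistical guarantee is demonstrated.

* **Latent connectivity.** Each channel's HbO is a standard-normal
  latent process (sd 1 µM) whose inter-channel correlation matrix is
  imposed exactly by Cholesky factorisation, per sample, switching
  between a rest target and a task target (eigenvalue-clipped nearest
  correlation matrix if a block design is indefinite). Channels belong
  to four scalp-quadrant communities: r = 0.40 within, 0.10 between.
  Finger tapping adds −0.25 to all off-diagonal correlations; after
  sleep deprivation +0.15 is added back in task epochs only, modelling
  the attenuated task response that is the design's headline effect.
  Per-subject Gaussian jitter (sd 0.05) on both modulations provides the
  between-subject variability that brain-behaviour correlations need.
* **Signals.** HbR = −HbO/3 + noise (sd 0.1 µM). Task responses are
  10-s boxcars convolved with a canonical double-gamma HRF (peak 6 s,
  undershoot 16 s, ratio 1/6), scaled to a 1 µM peak on the motor
  channels contralateral to the tapping hand. Systemic physiology is
  sinusoidal — cardiac 1.1 Hz (0.4 µM), respiratory 0.25 Hz (0.3 µM),
  Mayer 0.1 Hz (0.3 µM) — with per-channel random phase and 5 %
  frequency jitter, so it adds realistic spectral content without
  imposing cross-channel correlation. White noise sd 0.2 µM. Motion
  artifacts are Poisson spikes (0.5/min) with exponentially decaying 1-s
  tails at 5–20× the signal's OD sd. Hemoglobin is converted to
  two-wavelength OD (and intensity, baseline 1.0) through the same
  forward Beer–Lambert model the analysis inverts.
* **Cognitive scores.** Per-subject PAL change is slope × (planted
  per-subject attenuation) + noise, slope −40 by default; RTI/RVPA are
  uncoupled. One realisation of each baseline score is drawn from
  plausible score ranges.
* **QC fixture.** Ten subjects generated artifact-free; the last
  subject's intensities receive 15 %-sd multiplicative noise on 90 % of
  channels, so exactly one subject trips the exclusion rule regardless
  of seed.

What the generator does *not* emulate: spatially structured scalp
hemodynamics (shared systemic components across channels), serial
correlation of the latent processes beyond what filtering induces,
optical path and partial-volume heterogeneity across channels, and
subject-specific anatomy. Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes, not that real
recordings satisfy those assumptions.

## Calibration and problem sizes

The self-validation battery (`fnirs_fc.calibration`, exercised by the
acceptance tests and `scripts/acceptance.py`) uses these sizes, chosen
to keep Monte-Carlo error well inside the tested margins: graph-metric
oracle agreement on 200 random 12-node graphs (brute-force edge
counting, triple enumeration and Floyd–Warshall); surrogate null
retention over 200 replicate 48-channel noise segments of 39 samples;
ANOVA type-I error over 300–500 null cohorts of 10 subjects; power over
50–100 cohorts of 20 subjects with a large planted effect
(task −0.30, attenuation +0.25); ΔᵂD sign recovery over 20 cohorts of
50 subjects with low score noise. Cohort-level simulations generate
artifact-free recordings and skip the despiking stage, which is the
identity on artifact-free data — the two choices are made together so
the simulated fast path matches what the full pipeline computes.

## Known limitations

* Surrogate-threshold p-values ignore the autocorrelation that the
  0.4 Hz low-pass induces in 39-sample segments; retention rates on
  filtered data are therefore anticonservative relative to the nominal
  α/2 (the null-retention calibration uses unfiltered noise, where the
  nominal rate is exact).
* Mauchly's p uses the first-order chi-square approximation; reference
  implementations with higher-order terms differ in the second decimal.
* The Dunnett adjustment conditions on the estimated contrast
  correlation matrix; with few subjects that estimate is noisy.
* Cost-thresholding tie-breaks are deterministic but arbitrary; they
  matter only for exactly equal correlation coefficients.
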