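# Methods

`gastrosync` quantifies phase synchrony between the stomach's basal electrical
rhythm, recorded as an electrogastrogram (EGG), and resting-state BOLD fMRI,
and decides voxel by voxel whether that synchrony exceeds what circularly
time-shifted surrogate data would produce.  This note documents the model,
the numerical choices, what the synthetic-data generator does and does not
emulate, and known limitations.

## Signal model and analysis chain

The gastric rhythm is a narrow-band oscillation in the normogastric window
(0.033–0.066 Hz, nominally ~0.05 Hz, one cycle every ~20 s).  The analysis
assumes that coupled brain regions carry a BOLD component phase-locked to the
gastric phase at some fixed but region-specific delay, and that this delay —
not amplitude covariation — is the quantity of interest.

Per participant the chain is:

1. **Peak detection.** Welch power spectra of every EGG channel over the
   scan period (200 s Hann windows, 150 s overlap, per-segment linear
   detrend, `scaling="spectrum"` so a sinusoid's peak reads in μV²).  A
   channel qualifies if its largest in-band local maximum exceeds 15 μV²;
   among qualifying channels the most powerful is chosen unless another is
   more than twice as *sharp* (peak prominence / median in-band power), a
   quantitative stand-in for what is otherwise a visual judgement.  A manual
   override reproduces hand selection.  No qualifying channel is a rejection
   — such a recording cannot anchor the analysis.
2. **Gastric-band filtering.** Zero-phase (forward–backward) Hamming-window
   FIR bandpass, nominal band = peak ± 0.015 Hz.  A literal low-order FIR
   cannot realize a ±0.015 Hz band, so the tap count follows the design rule
   N ≈ 3.3·fs/Δf with transition width Δf = 0.015 Hz and −6 dB cutoffs at
   ±1.5 half-widths: gain is flat (< 1 dB) across the nominal band, a few dB
   down at ±2 half-widths and > 40 dB down beyond ±3 half-widths (per pass).
   The filter is applied to the EGG at 10 Hz with 30 s padding at each end,
   and to every BOLD voxel at 0.5 Hz with identical band parameters.
   Zero-phase application matters: any filter-induced lag would masquerade
   as a physiological phase delay.
3. **BOLD conditioning** (before the gastric filter): quadratic detrend,
   0.01–0.1 Hz 4th-order Butterworth (zero phase, demeaned first), optional
   nuisance regression against supplied series (e.g. a CSF reference).
   The order detrend → bandpass → nuisance → gastric band → trim is enforced
   by `PreprocChain`.
4. **Phases.** Hilbert transform of the full-length filtered series; the
   first and last 15 volumes (30 s) are then discarded from the phase and
   amplitude series, leaving 420 samples (840 s at TR = 2 s).  Computing the
   analytic signal before trimming places its edge artifacts in exactly the
   samples that are dropped.
5. **Coupling.** Phase-locking value per voxel,
   PLV = |(1/T) Σ_t e^{i(φ_x − φ_y)}|, against the EGG phase; chance level =
   median PLV over all circular shifts of the EGG phase by at least 60 s
   (~3 gastric cycles).  With T = 420 and TR = 2 s the half-open enumeration
   s ∈ [30, 389] yields 360 surrogates, each with exactly the empirical
   sample count so the PLV's sample-size dependence cancels.  Coupling
   strength = empirical − chance.
6. **Group inference.** Paired t of empirical vs chance per voxel
   (df = n−1; zero-variance voxels get t = 0), clusters of supra-threshold
   voxels (|t| above the two-sided p < 0.01 Student quantile, 26-connectivity
   by default, positive and negative families separate), cluster mass =
   Σ t.  The null exchanges the empirical/chance labels within participants
   (equivalently, sign-flips the difference maps), keeping per permutation
   only the largest positive and smallest negative cluster mass — the
   max-statistic construction that corrects for multiple comparisons.
   Monte-Carlo p = (1 + #extremes)/(n_perm + 1); a cluster is retained when
   its one-tailed p < α/2 (two-sided accounting at α = 0.05).

Node-level statistics on the significant clusters: the node series is the
voxel-mean time series (equivalently the voxel-mean analytic signal — the
Hilbert transform is linear); the lock angle Φ_k is the argument of the mean
phase-difference vector; network-relative angles subtract the *circular* mean
across nodes (the absolute EGG-to-pacemaker delay is unknowable; an
arithmetic mean of angles would be ill-defined near ±π); phase-delay
consistency is the across-participant resultant length of the relative
angles; differences in mean direction across nodes are tested with a
hand-implemented Watson–Williams circular ANOVA (with the 1 + 3/(8κ̂)
concentration correction, κ̂ from the standard resultant→κ approximation;
flagged when the mean resultant < 0.45).  Shared variance between EGG and a
node is squared coherence at the gastric bin from Hann-windowed spectra
(120 s windows, 20 s overlap; the window count follows from the data length
— a fixed count independent of duration would be arithmetically
inconsistent), nearest-neighbor bin on the Welch grid.  Delayed vs
instantaneous functional connectivity between nodes: squared coherence at
the gastric frequency vs squared Pearson correlation of the gastric-band
series.  Dynamics: PLV in 60 s windows stepped by 10 s (79 windows on 840 s),
correlated with the window-mean Hilbert envelope, Fisher-z group tests with
Bonferroni over nodes/pairs.

## Synthetic-data generator

The generator exists so every stage can be validated against ground truth.

* **EGG**: instantaneous frequency follows a reflected Gaussian random walk
  inside [0.033, 0.066] Hz (diffusion 2×10⁻⁴ Hz·s^−1/2 by default, i.e. a
  few mHz of drift over a 900 s scan — the stomach "goes faster and slower"
  rather than ticking); phase is its integral; four channels at gains
  (1.0, 0.65, 0.45, 0.3) with 15 μV white sensor noise on a 120 μV
  oscillation, 10 Hz sampling, 960 s (900 s scan + 30 s padding per end).
  The amplitude calibration puts the selected channel's Welch peak three
  orders of magnitude above the 15 μV² floor, as a clean recording sits.
* **BOLD**: 450 volumes at TR 2 s on a 20×20×20 default grid.  Coupled
  clusters (three 3³ cubes at well-separated corners by default) carry
  `a · cos(θ_gastric + δ)` with per-cluster delay δ; everything else is 1/f
  spectrally-shaped noise (exponent 1), unit variance.  The coupling
  amplitude is set from a target in-band RMS signal-to-noise ratio
  (default SNR 2.5) computed analytically from the noise-shaping weights.
  An optional slow multiplicative gain (Gaussian-smoothed, ~120 s timescale)
  comodulates coupling strength and BOLD amplitude for the dynamics
  analyses.
* **Cohorts**: per-participant gastric frequencies drawn uniformly from
  0.041–0.053 Hz (the published between-participant spread), shared cluster
  layout, all seeds derived from one master seed (`SeedSequence`), so
  cohorts are bit-reproducible.

What the generator does *not* emulate: hemodynamic convolution, head motion,
physiological confounds (cardiac/respiratory), spatial autocorrelation of
BOLD noise, or vendor EGG formats.  Passing tests therefore demonstrate that
the *estimators and inference* behave as designed under known ground truth —
not that real gastric-BOLD coupling of any particular anatomy would be
recovered from real data.

## Numerical and design choices

* **Chance level bias.** The chance PLV is the *median* of a right-skewed
  surrogate distribution while the empirical PLV is a draw from it, so even
  under the null the coupling strength has a small positive mean
  (≈ +0.003 under default conditions, vs planted effects > 0.3).  This is a
  property of the published estimator, reproduced deliberately; group
  inference remains calibrated (verified by permutation-null and
  time-shift-null tests).
* **Surrogate correlation.** The 360 shift-surrogate PLVs of a narrow-band
  840 s series are serially correlated (≈ 25 independent phase stretches),
  so per-voxel surrogate quantiles are noisier than iid draws; the pipeline
  never relies on per-voxel intervals, only on the median and on group
  permutation tests.
* **Frequency specificity.** Because the gastric filter is flat across
  ± 0.015 Hz by contract, a narrowband oscillator is untouched by filter
  offsets smaller than the half-width; on synthetic data the offset curve
  is flat out to ±0.015 Hz and falls sharply at ±0.02 Hz.  The specificity
  control therefore reads offsets beyond the passband half-width.  (A
  slight positive tilt toward higher-frequency offsets can appear on
  planted cohorts because 1/f noise leaves more in-band SNR there.)
* **Shift enumeration.** Half-open at the wrap boundary, s ∈ [m, T−m−1],
  the convention that reproduces 360 surrogates at T = 420; the closed
  interval would give 361.  A convention, not physics.
* **Two-sidedness.** Positive and negative cluster families are each tested
  against their own one-tailed max-statistic null at α/2.  Small-sample p
  uses the +1 correction and can never be exactly zero; with n participants
  only 2ⁿ sign patterns exist, so no cluster can reach significance below
  n = 6 at α = 0.05.
* **Connectivity** defaults to 26 (configurable 6/18/26) and is recorded in
  every result.
* **Window aggregation.** The BOLD amplitude entering the PLV-amplitude
  correlation is the window-mean Hilbert envelope (RMS would behave
  equivalently for these narrow-band series).  Fisher z clips |r| at
  1 − 10⁻¹².

## Problem sizes in the test suite

The verification suites run at desk scale, chosen once: planted-recovery
cohorts at n = 12 participants on the full 20³ grid with 1000 permutations
and 20 replicates; null-calibration cohorts at n = 8 on 12³ grids with 500
permutations and 20 replicates; specificity and swap controls on 8³–10³
grids with 4–8 participants.  Statistical tolerances are binomial or
Monte-Carlo bands at those sizes.

## Limitations

* PLV is undirected; nothing here speaks to whether the stomach drives the
  brain or vice versa.
* The Watson–Williams test assumes concentrated, von-Mises-like samples;
  results with mean resultant < 0.45 are flagged, not blocked.
* Coherence-based shared variance is upward-biased at small window counts
  (8 windows on 840 s); comparisons are therefore made within identical
  segmentations.
* The pipeline assumes spatially preprocessed BOLD input; slice timing,
  motion correction, normalisation and smoothing are upstream concerns.
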