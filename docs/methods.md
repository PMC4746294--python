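# Methods

This note documents the models, parameter choices, and numerical conventions
behind `flightlearn`, and what the synthetic-data validation does and does not
establish about real recordings.

## Study model

The package assumes the four-group × four-day between/within design: anodal
tDCS over right DLPFC or left M1, each with a sham control (default group
sizes 7, 7, 10, 8 — 32 subjects), with six 20-trial adaptive n-back blocks
and five easy-landing attempts per daily session. EEG is 500 Hz multichannel;
fNIRS is 8 Hz dual-wavelength (760/850 nm) over 20 channels (10 per ROI);
flight telemetry is 10 Hz.

## Flight metrics

- **Coordinates.** Latitude/longitude/altitude are mapped to a local
  tangent-plane East-North-Up frame on a spherical Earth (R = 6,371,000 m)
  with the origin at the runway threshold. At landing-approach scale
  (kilometres) the spherical approximation is sub-meter, far below the noise
  of hand-flown trajectories.
- **Alignment.** Subject and autopilot traces generally differ in length.
  Both are split into `min(len_a, len_b) // window` contiguous chunks over
  their own extent and chunk-averaged (window default 10 samples = 1 s).
  Window 1 on equal-length traces reduces exactly to the naive pointwise
  comparison, which the tests exploit as an oracle. Whether deviations are
  summed over raw samples or window averages is ambiguous in principle;
  both are available via the `window` argument, windowed being the default.
- **g-force.** Central finite difference of vertical speed (converted
  ft/min → m/s) across the touchdown sample, one-sided at the trace edge;
  the absolute value is reported because the training goal is to minimise
  impact magnitude.
- **Vertical-speed deviation** uses absolute differences: signed sums cancel
  and would let a wildly oscillating approach score as perfect.
- **Control inputs** count sign changes of vertical speed; zero samples
  inherit the previous nonzero sign, so a noise-free hold at exactly
  0 ft/min does not count as an input.
- **Missed landings** (no touchdown within the runway extent; the terminal
  sample itself is inclusive) are excluded from metric aggregation and
  reported separately as percentages.
- **Vertical-speed variance** runs from the first recorded sample to
  touchdown (the whole approach is the "landing period").

## Adaptive n-back

Raw percent accuracy pools the position and image decision streams with
equal weight (the pooling rule is a package convention; per-stream
accuracies are also reported). Scaling weights are 0.33/0.66/1.0 for
1/2/3-back; bit-wise and log alternatives sit behind the same interface but
are off by default since they change little. The adaptive rule is strict
(> 80 % up, < 20 % down) and clipped to [1, 3]; 3-back is the cap because
only levels 1–3 are scored. Trials-to-reach-level counts are 1-based block
counts, since the level only changes between blocks. The level is carried
across days rather than reset, modelling trained competence.

## Learning-rate decomposition

Online rates are OLS slopes over block index within a day; the offline rate
is the first-trial-minus-last-trial difference across a day boundary treated
as a slope over unit trial spacing; the meta rate is the OLS slope over the
interleaved sequence [on₁, off₁₂, on₂, …, on₄]. Rates are computed both per
subject (then aggregated) and on group-averaged series; outlier-rejected
trials are dropped with indices preserved. A constant series yields slope 0
with zero standard error (the generic OLS formula degenerates to 0/0 there).

## Variance inference

Trial-wise variance comparisons use the two-sample F-test with the
asymmetric F distribution appropriate to the degrees of freedom; the
two-sided p is 2·min(P(F ≤ f), P(F ≥ f)) capped at 1, which makes the test
invariant to which sample is the numerator. Across days, Bartlett's test is
applied to per-subject day averages so the samples are independent (the
trial-wise F-tests reuse subjects across trials; that caveat is inherited
from the design). Outlier rejection is single-pass at 3 pooled SDs — with
small samples a lone extreme point cannot mathematically exceed 3 SDs
(max z = (n−1)/√n), so the rule only bites at realistic pooled trial counts.

## EEG spectral analysis

A 2nd-order (12 dB/octave) 0.5 Hz Butterworth high-pass is applied
forward-backward: band power is phase-insensitive and zero-phase filtering
avoids group delay across epoch boundaries (the designed single-pass filter
has its analytic −3 dB point at 0.5 Hz; the two-pass application doubles the
attenuation at the edge). Each task segment is cut into non-overlapping 1-s
epochs, so FFT bins land on integer frequencies; a periodic Hann taper with
window-power normalisation makes the one-sided bin sum equal the windowed
signal variance (Parseval, tested to 1e-6). Band power is the mean over the
band's integer bins (4 for theta, 5 for alpha). Epoch rejection is one-sided
high (mean + 2 SD of the channel-average power) because artifacts inflate
power; unusually quiet epochs are kept. Missing subject cells are imputed
with the group/day/channel/band mean and flagged.

## Cluster-based permutation testing

Per-channel Student pooled-variance t (independent) or paired t (day
contrasts) is thresholded at the two-sided data-point α; supra-threshold
channels of the same sign form adjacency-connected clusters (breadth-first
search), discarding clusters below the 2-channel minimum extent. The cluster
mass is the summed |t| — the field-standard default. The null is the maximum
cluster mass over label exchanges (independent) or per-pair sign flips
(paired); the observed assignment counts as one of the `n_perm` draws, so
p ∈ [1/n_perm, 1], and the test switches to exhaustive enumeration whenever
`n_perm` covers all distinct permutations. Clusters are reported with the
signed mean member t (the reporting convention of day-contrast tables) and
corrected p. The cluster-forming α is used as printed (0.05 overall), not
split per tail. Adjacency is built from the 2-D layout: channels within a
configurable quantile (default 0.12) of all pairwise distances are
neighbours; the packaged neutral 31-channel 10-10 layout (with Fz and FC1)
is a schematic head projection, not any specific cap's measured geometry.

## fNIRS

- **MBLL.** ΔOD_λ = Σ_chrom ε_chrom,λ · Δc_chrom · d · DPF_λ is inverted per
  channel by 2×2 solve; concentrations are reported in mM, Hbtot ≡ Hboxy +
  Hbdeoxy at every stage. The published DPF values are bound one per
  chromophore; physically a DPF belongs to a wavelength, so the package maps
  5.98 → 760 nm and 7.15 → 850 nm, with the mapping configurable.
- **Band-pass.** Least-squares linear-phase FIR, odd tap count, order 3× the
  longest passband period (2401 taps at 8 Hz), applied as symmetric
  'same'-mode convolution (zero phase). The high-side stopband reaches
  −40 dB by 1.2× the 0.2 Hz edge (−115 dB at 0.24 Hz; a 1.2 Hz cardiac tone
  is attenuated > 100 dB). The tap count bounds frequency resolution near
  fs/numtaps ≈ 0.0033 Hz, so the low-side transition is widened to end at
  lo/2 = 0.005 Hz (−39 dB there, −52 dB at DC); a narrower 40 dB transition
  at 0.01 Hz is unattainable at this filter order. Records shorter than the
  kernel are rejected rather than silently filtered.
- **Channel exclusion** uses the strict > 0.001 mM baseline max−min rule
  (exactly at threshold is kept). Baseline subtraction removes the
  baseline-window mean after excising inter-trial samples.
- **GLM.** Task boxcars are convolved with a canonical double-gamma HRF
  (peak 6 s, undershoot 16 s, ratio 1/6, unit peak — so a unit-amplitude
  HRF-shaped response returns a unit beta); DCT cosines with periods above
  128 s (the convention of SPM-style temporal filtering) plus an intercept
  complete the design; OLS betas and t per channel, with an explicit
  rank-deficiency error. Day-4 − day-1 contrasts use per-channel paired t at
  the Bonferroni-corrected threshold (family α / 20 channels = 0.0025) and
  report ROI means ± SD with significant-channel counts. The 3.5-SD
  channel-wise rule flags |trial mean| > 3.5 · sd/√n (the SD rule is
  normative; the p-value printed alongside it in the source material does
  not correspond to a 3.5-SD normal tail and is not reproduced).

## Synthetic-data generator

The generator is the package's test bed: it produces data with the exact
statistical structure the analysis assumes, plus the ground truth needed to
check recovery.

- **Autopilot reference.** Constant −600 ft/min descent from 800 ft with
  vertical speed changing only in the final 5 s; a single nose-flare zero
  crossing ~1 s before touchdown yields exactly one control input. Altitude
  integrates vertical speed up to flare onset, then eases linearly to zero
  over the final second — an exactly integrated altitude cannot both
  terminate at zero and carry the flare's positive blip, and 10 Hz telemetry
  of ground-effect settling is the behaviour being emulated.
- **Subject landings** perturb the reference with AR(1) vertical-speed noise
  (φ = 0.92), lateral drift, altitude spread enveloped by height (the glide
  path funnels toward the threshold), and a touchdown-impact kick, all
  scaled by 1/skill; skill → ∞ returns the reference exactly. Missed
  landings are Bernoulli with a rate interpolating 0.10 (day 1) → 0.02
  (day 4); no overrun mechanism is modelled beyond the flag.
- **n-back.** Per-trial correctness is logistic in (N − ability)
  (width 0.5). For cohort generation the block ability is derived by
  inverting the logistic at the current level so that the expected scaled
  accuracy follows a linear target: start ≈ 24 scaled points, online slope
  drawn per subject from N(group mean 1.5, SD 1.0 — SD multiplied by
  √shrink, default shrink 0.25 for DLPFC stim), overnight gains
  N(1.0, 0.5). This makes the generated online rate exactly the regression
  estimand, so recovery is a test of the pipeline rather than of a model
  mismatch. Accuracy saturation (scaled accuracy cannot exceed
  weight(N)·100) censors extreme trajectories, exactly as the real task
  does.
- **EEG.** Pink (1/f) noise (0.5 μV) plus fixed-frequency oscillations:
  6 Hz theta with frontal topography (weight 1 at Fz/FC1) and 10 Hz alpha
  with parietal topography. Oscillation amplitude is set from the requested
  band-mean power via a = √(2·n_bins·P), so the injected number is on the
  analysis's own scale; at the default 4 μV² the oscillation dominates the
  in-band noise and power ratios are recoverable within a few percent. MFT
  power grows linearly by group slope (default +1 μV²/day for DLPFC stim).
- **fNIRS.** True concentrations are HRF-convolved task boxcars (Hboxy
  amplitude per ROI, Hbdeoxy = −0.3×Hboxy), forward-modelled to OD and
  corrupted with white noise (1e-4 OD), slow drift (0.002 Hz sinusoid +
  linear ramp), and a 1.2 Hz cardiac tone — all of which the band-pass stage
  must remove. The injected DLPFC Hboxy day-4 − day-1 change defaults to
  −0.0024 mM for DLPFC stim, the magnitude scale of the day-contrast tables
  the analysis produces.
- **Record sizes.** Neural records are generated lazily from per-record
  seeds derived from the study seed (byte-deterministic), with defaults of
  30 s EEG per task-day and 5 blocks × (30 s task + 30 s rest) fNIRS per
  day. These are deliberate scaled-down session lengths chosen so that a
  32-subject cohort is generated in under a second and whole-pipeline
  recovery studies can run hundreds of replicate cohorts; the statistical
  structure (groups, days, blocks, trials, effects) is at full scale.

### What the synthetic validation does not show

The generator contains no ocular/cardiac EEG artifacts, no motion artifacts
or superficial-physiology contamination in fNIRS, no aerodynamics, and no
model mismatch between the behavioral generator and the regression estimand.
Passing recovery tests therefore demonstrates that the analysis chain is
correct and calibrated under its own assumptions — not that those
assumptions hold for any particular real recording. Artifact rejection
(e.g. ICA) is explicitly out of scope.

## Validation design

- **Family-wise error.** On 500 null band-power studies (two groups of 7,
  30 channels, i.i.d. data), the fraction with any significant cluster at
  the study's settings is compared to the nominal 5% with a one-sided 95%
  binomial margin.
- **Recovery.** Over 200 replicate cohorts, each group's mean online rate
  estimate must lie within 2 sampling standard errors of the injected mean —
  "standard error" being the SD of the estimator across the replicate
  ensemble, the Monte-Carlo measurement of its sampling distribution (a
  literal 2·sd/√7 per-cohort interval has 90.8% nominal coverage at these
  group sizes and cannot meet a 95% criterion) — in at least the nominal
  fraction of cohorts with the same binomial margin. The DLPFC-stim variance
  shrink is recovered from the ratio of pooled noise-corrected
  between-subject variances (per-day slope SE² subtracted), pooled across
  cohorts, within 25% relative; the per-cohort variance ratio at n = 7 is
  an F(6,6)-scale quantity and is individually uninformative.
- **Oracles.** Exhaustive permutation enumeration at n = 3 vs 3, naive
  pointwise path deviation at window 1, exact MBLL round trips, and textbook
  Bartlett/F formulas serve as independent checks of the corresponding
  implementations.

## Known limitations

- The trial-wise F-tests reuse subjects across trials; only the Bartlett
  route preserves independence.
- The tDCS montage type stores the printed total current and current
  density verbatim; the pair is not mutually consistent with the stated
  electrode areas and the package does not reconcile them.
- The adaptive-level carry-over across days and the equal-weight pooling of
  position/image streams are package conventions where the task description
  is silent.
- GLM betas on band-passed data are mildly attenuated relative to the
  injected amplitude because the design regressor is not passed through the
  same filter; contrasts and signs are unaffected.
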