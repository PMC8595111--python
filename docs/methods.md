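# Methods

This note documents the models, measurement rules, numerical choices and
limitations behind `oddballerp`.

## The synthetic oddball model

The generator emulates epidural 3×3-grid recordings of an awake-rodent
auditory oddball session. Its purpose is to provide data whose statistical
structure matches what the analysis assumes, with every nuisance process
(noise colour, inter-animal variability, artifacts) explicit and
controllable — not to be a biophysical cortex model.

**Stimulus trains.** A session presents `n_standard` frequent and
`n_deviant` rare tones at a fixed inter-stimulus interval, with the
constraint that two deviants never occur in succession. Defaults are 1,200
standards + 180 deviants (13% deviants) at 1 s ISI. Placement is
constructive and rejection-free: the standards define `n_standard + 1`
gaps and each deviant occupies a distinct gap drawn uniformly without
replacement, a bijection onto the valid arrangements, so the sequence
distribution is uniform over all legal trains and the constraint holds by
construction. Tone acoustics (frequency, level, rise time) are treated as
metadata; the simulator models evoked neural responses, not sound.

**Evoked responses.** Each stimulus class has an ERP template: a set of
components, each a Gaussian bump with polarity fixed by its name (P* = +1,
N* = −1), a peak latency (ms), width (Gaussian SD, ms) and nonnegative
amplitude (µV). A rendered trial is the polarity-signed sum of bumps.
Gaussians make peak values and window means analytic, which the tests use.
Default latencies (P1 50, N1 93, P2 118, N2 150, P3 300 ms) sit inside the
canonical measurement windows; default amplitudes are a few µV with the
deviant template carrying clearly larger N1 (−6 vs −2 µV) and P3 (+4 vs
+1 µV), the change-detection morphology the analysis targets. All
defaults are overridable.

**Treatments** are per-component multiplicative amplitude gains and
additive latency shifts applied at render time; sham is the identity. The
bundled effect models encode directions only (e.g. high-dose alcohol
suppresses N1 strongly and all components partially; electrical
stimulation enhances P1/N1/N2; naltrexone enhances N1/P2/P3 and shortens
early latencies); their magnitudes are free simulator parameters, chosen
to be plausible, not fitted to any dataset.

**Variability and noise.** Each animal has a global lognormal amplitude
gain (SD 0.2) and a normal latency offset (SD 4 ms) drawn once per animal
and reused across all of its sessions (within-subjects design); each trial
additionally jitters all component latencies (SD 6 ms). Additive noise is
a white + 1/f Gaussian mixture: 1/f noise is produced by shaping white
noise with 1/√k in the rFFT domain (DC zeroed) and rescaling by its
analytically expected variance, keeping the generator linear, Gaussian and
exactly seed-reproducible; `pink_fraction` (default 0.5) sets the share of
variance from the 1/f process. The default total SD of 5 µV puts a single
trial at roughly −10 dB SNR against the deviant template (template RMS
≈ 1.5 µV over the −100..700 ms epoch), computed a priori from the
template. **Artifacts** are squared-cosine transients of 600 µV peak and
50 ms duration injected on a Bernoulli-chosen subset of trials (default
rate 0.02), deliberately far beyond the 400 µV rejection criterion so that
rejection decisions are unambiguous; in continuous sessions they hit all
channels simultaneously, emulating movement. Channel gains fall off from
frontocentral (FC = 1.0) to posterior (0.75), matching where auditory ERP
components peak.

**Seeding.** All randomness derives from the cohort seed through
`numpy.random.SeedSequence` spawn keys: per-animal parameters from
(seed, animal), per-session streams from (seed, animal, treatment-label
CRC), per-channel noise from a further channel-label fork. Subsets of a
cohort therefore regenerate bit-identically in isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: volume-conducted correlation between channels
(noise is independent per channel), line noise, non-stationary drift or
habituation across a session, non-Gaussian artifact families (chewing,
electrode pops), latency–amplitude covariation, and any real
pharmacodynamics. Classifier accuracies on this generator characterize
the pipeline's statistical machinery under controlled conditions, not
expected in-vivo performance.

## Preprocessing

**Band-pass design.** The ERP path uses a Kaiser-window FIR band-pass,
default 0.1–45 Hz at 3 kHz with linear ripple 0.001 (A = 60 dB). β follows
the standard Kaiser formula (0.1102·(A − 8.7) for A > 50, giving 5.65).
The transition width is tied to the low edge as Δf = min(max(0.25·f_low,
2 Hz), 2·f_low) — 0.2 Hz at f_low = 0.1 — and the order is
⌈(A − 8)/(2.285·2πΔf/fs)⌉ rounded up to even: 54,330 at these settings
(54,331 symmetric taps). Because 0 Hz sits exactly at the lower stop-band
edge, the design additionally nulls the DC response outright by
subtracting the tap mean (a symmetric perturbation below the ripple
elsewhere), so constant offsets cannot leak through. Filtering uses
one-pass FFT convolution with the group delay (order/2) removed, keeping
features time-locked; samples within order/2 of the record ends are
flagged unreliable in metadata rather than trimmed.

**Epoching** uses a half-open [−100, 700) ms grid with the stimulus onset
exactly on a sample (index 300 at 3 kHz; 2,400 samples per epoch). Events
whose window would cross a record edge are dropped and counted. Baseline
correction subtracts the per-(trial, channel) mean over [−100, 0) ms and
is idempotent. **Artifact rejection** marks a (trial, channel) as excluded
when its within-epoch peak-to-peak range exceeds the delta criterion
(default 400 µV); the criterion is applied per channel (configurable
interpretation — a whole-trial variant would simply AND the mask across
channels). ERP averaging uses each channel's own retention; classification
uses the frontocentral channel's retention only.

**Downsampling (classification path).** Epochs are low-passed with a
least-squares linear-phase FIR (cut-off 32 Hz, transition ±12.5%, 1,001
taps at 3 kHz, reflect-padded within the epoch) and resampled to 64 Hz.
The output grid is anchored at stimulus onset — samples at t = k·15.625 ms
within the epoch window — so a sample lies at or immediately after each
window boundary, t = 0 is always on the grid, and a −100..700 ms epoch
yields 51 samples. Values are obtained by cubic-spline evaluation of the
filtered signal; at ~47× oversampling of a 32 Hz-limited signal this is
accurate band-limited interpolation (relative error ≪ 1e−3), and the
onset-anchored grid is what makes the 22-point feature layout exact. A
plain polyphase decimator would anchor the grid at the epoch start, where
the onset falls between output samples.

## ERP measurement and statistics

Peak latency is the polarity-consistent extremum (max for P*, min for N*)
within the component's closed window; ties break to the earliest sample.
Amplitude is the mean over the 10 ms window centred on the peak latency;
the P2 amplitude is reported as the N1–P2 peak-to-peak difference. In the
pipeline, peak latencies are determined per channel on the *grand-average*
difference curve of a treatment and then applied to each animal's curve,
so the per-animal amplitudes entering the t-tests are linear functionals
of each animal's data.

One caveat drove an API decision: measuring amplitude at a peak picked on
the *same* data is selection-biased under the null hypothesis (the
extremum of noise is not zero-mean), which would inflate the type-I error
of the one-sample test far beyond α. The API therefore separates peak
finding from amplitude measurement, and the null-calibration study
measures amplitudes in the fixed 10 ms window at the canonical template
latency. With that design the one-sample test's rejection rate under a
pure null sits inside the 99% binomial band of α = 0.05 (verified over
1,000 simulated cohorts).

Tests are two-tailed one-sample and paired t (df = n − 1), with paired
Cohen's d = mean(diff)/SD(diff) (sample SD; all-zero differences give
d = 0, constant nonzero differences raise rather than returning ∞).
Multiple comparisons are corrected with Benjamini–Hochberg step-up within
the nine-channel family of each (treatment, component). A pooled
channel-group paired test (`grouped_paired_t`, averaging per-animal
measures over e.g. the frontal row before testing) is provided as an
interpretation aid and is not part of the per-channel family.

## SWLDA classification

Difference trials double the training material per session: each retained
deviant minus the mean retained standard (kind 1) and the mean retained
deviant minus each retained standard (kind 2); both kinds have the session
difference curve as expectation. Features are the raw 64 Hz voltages in
the N1 (80–105 ms) and P3 (200–500 ms) ranges. The window-to-index rule —
first index round(start·fs/1000), count ⌈(end−start)·fs/1000⌉ on the
onset-anchored grid — is the unique simple convention yielding 2 + 20 = 22
points; floor or inclusive variants give 21 or 23.

Feature selection is classical stepwise regression of the ±1-coded label
on the features: at each step, the partial-F p-value (F = (RSS_reduced −
RSS_full)/(RSS_full/(n − k_full − 1)), p from F(1, n − k_full − 1)) is
computed for adding every excluded feature; the smallest-p entrant is
added if p < 0.05, otherwise the largest-p incumbent is removed if
p > 0.1, otherwise the loop stops. p_enter < p_remove prevents add/remove
cycling, with a step guard as backstop; ties break to the earlier feature
index. If nothing was ever selected, the single feature with the smallest
first-step p-value is used. The implementation evaluates candidate RSS
values from precomputed Gram matrices (O(k³) per candidate, k ≤ 23); the
test suite pins it step-for-step against a naive oracle that refits every
model from scratch with `lstsq`. Affine label recoding leaves partial-F
p-values unchanged, so the ±1 coding is a convention, not an assumption.

The minority class is oversampled (seeded, with replacement, originals
kept) to balance the classes *once, before selection*, and the same
balanced set trains the discriminant — whether selection itself should see
oversampled data is ambiguous in common practice; doing both on the same
balanced set is the simplest self-consistent choice. The classifier is a
Fisher discriminant, w ∝ S_pooled⁻¹(μ_A − μ_B) with the threshold at the
midpoint projection; a singular pooled covariance falls back to a scaled
identity ridge (1e−6·tr(S)/d). Trials on the exact boundary go to class A,
flagged by a zero score. Session-level prediction is a simple majority
vote over all test trials; an exact tie (possible with even trial counts)
goes to the class with the larger mean absolute score margin and is
flagged. Evaluation is leave-one-animal-out: a session's training set
pools difference trials from all *other* animals' sessions of the two
treatments; animals missing one session of a pair still have their
available session tested, with counts logged. Pairs are summarized as 2×2
actual × predicted contingency tables with session accuracy and a Pearson
chi-square without continuity correction (a Yates variant is available;
for the 17-of-18 reference case both stay below p = 0.001).

## Simulation studies (desk scale)

`oddballerp.experiments` fixes the study conditions used by the test suite
and acceptance script. Problem sizes are the package's own choices to keep
a full study in the minutes range on one CPU:

- **Parameter recovery**: 8-animal cohorts, sham vs a treatment
  suppressing N1 and P3 amplitudes by 50%, sessions of 174 + 26 stimuli
  (13% deviants), default −10 dB single-trial SNR; mean leave-one-animal-
  out session accuracy ≥ 90% over 20 cohort seeds, and non-decreasing in
  the suppression fraction.
- **Null classification**: two identical condition models, 200 cohorts of
  4 animals with 52 + 8-stimulus sessions; accuracy stays within the 95%
  binomial band of 50%.
- **ERP calibration**: pure-null cohorts (deviant template ≡ standard) of
  10 animals × (12 + 6) trials at 750 Hz, 1,000 seeds; fixed-window
  one-sample test rejects within the 99% binomial band of α = 0.05. The
  power companion (default templates, 72 + 24 trials, 9 channels) rejects
  N1 and P3 at FDR 5% on every channel in ≥95% of cohorts.
- **End-to-end demo**: 4 animals, sham vs high-dose alcohol, 300-stimulus
  sessions; runs in ~1 minute and regenerates byte-identically under a
  fixed seed.

Simulated accuracies characterize the pipeline under the generator's
assumptions; see the generator's non-goals above for what they do not
claim about real recordings.

## File formats and reproducibility

Continuous recordings are raw little-endian float32 (channel-major) with a
JSON sidecar (rate, channel labels, unit, trial metadata) and a
BIDS-events-style TSV of onsets/labels; epochs are NPZ containers; tables
are TSV; configs are a single YAML document with per-stage sections,
strict key checking and cross-field validation before any computation
(e.g. p_enter < p_remove). Voltages are µV throughout; epoch times are ms
relative to stimulus onset; file-level onsets are seconds. Every artifact
is re-derivable from config + seed; the run record (config hash, version,
per-stage counts) is the only timestamped output.

## Known limitations

- The artifact criterion's per-channel reading and the oversampling
  placement are documented interpretations of under-specified procedure
  points; both are configurable or isolated behind single functions.
- Multi-channel classification exists only insofar as the channel is
  configurable; no feature fusion across channels is implemented.
- No ICA, re-referencing, notch filtering, source localization,
  time-frequency analysis, multiclass classification or online operation.
- EDF export is not implemented; the raw float32 + sidecar layout is the
  only recording format.
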