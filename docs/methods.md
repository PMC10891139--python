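# Methods

This note documents the models, parameter choices and numerical conventions
behind `diplisten`, and what the synthetic data do and do not establish.

## Stimulus model and calibration

The masker is Gaussian noise band-limited to the 2/3-octave geometric band
around 1 kHz (zero-phase 4th-order Butterworth, applied **before**
modulation, the common construction for gated narrowband maskers), then gated
by a 10 Hz rectangular envelope with 50% duty cycle and 10 ms cos² ramps
placed inside each burst. The noise is frozen: the same `noise_seed`
reproduces bit-identical samples.

Absolute sound pressure is irrelevant to every analysis (only SNR matters),
so dB SPL is mapped to linear amplitude through a single software calibration
constant: a full-scale sine corresponds to 94 dB SPL. "Masker level" refers
by default to the RMS of the ON bursts (`masker_level_convention="on"`); the
long-term whole-cycle RMS is ~3 dB lower at 50% duty and can be selected
instead. Targets are specified by their plateau RMS; the 50 ms cos² ramps
make the whole-waveform RMS ~0.3 dB lower than nominal.

Trial timing: cycle phase 0° is defined as the burst onset, and the 45°
scheduling phase is therefore 12.5 ms into each 100 ms cycle. After the
200 ms hold and 50 ms system delay, the target waits for the next 45°
crossing; the residual wait is uniform over [0, 100) ms in poke phase, so the
total delay spans [250, 350) ms with the infimum attained and the supremum
open. Analysis time 0 s is the acoustic target onset (the 45° crossing after
the fixed delays); this is the package-wide convention.

## Behavioral model

Session scheduling draws Go vs NoGo from a configurable base mix (default
108:62, the typical per-session counts) and the Go SNR uniformly from
{−10, 0, +10} dB. Every FALSE ALARM forces the next trial to NoGo, chained
while false alarms continue. The cap of 15 sequential NoGo trials is enforced
*globally*: once a run reaches 15 the next trial is forced Go, so no response
policy can exceed the cap (the unconstrained base draw could otherwise exceed
it by chance). Timeouts are drawn uniformly from [1.0, 1.5] s.

Hit and false-alarm rates are bracketed to [0.05, 0.95] before
d′ = Φ⁻¹(HR) − Φ⁻¹(FAR); unbracketed rates of 0 or 1 are rejected rather
than silently producing ±∞.

The psychometric model is a binomial GLM with logit link fitted by IRLS;
trial counts enter as binomial denominators, which is exactly the
proportional weighting of per-duration hit rates. Durations are in seconds,
so the slope β₁ is "per second of tone duration". `duration_threshold`
inverts the fitted curve against a d′ criterion for an **explicit** assumed
FAR (bisection to 1 ms); thresholds rise monotonically with the assumed FAR,
and we report them as a function of FAR rather than as a single number,
because a criterion d′ alone does not determine the threshold.

A caveat established while validating recovery: at a realistic session scale
(~15 Go trials per duration) single-session maximum-likelihood slopes are
upward-biased by ~25–30% because long durations yield hit rates near 1
(quasi-separation). Parameter-recovery checks therefore use 1000 trials per
duration per simulated session, where the per-session MLE is effectively
unbiased; per-session estimates at behavioral scale should be interpreted
with this bias in mind.

## Generative model of cortical units

Each unit is an inhomogeneous Poisson process with a 1 ms dead time, sampled
by thinning on a 1 ms rate grid over [−1, 2] s. The rate is composed
multiplicatively from

1. **baseline × envelope locking**: a mean-preserving rectangular half-cycle
   modulation, λ ∝ 1 − d + d·g(phase) with g = 2 on the ON half-cycle and 0
   on the OFF half. Fraction `d` (`locking_depth`) of the rate mass is thus
   concentrated in the ON half-cycle, giving the closed form VS = 2d/π
   ((1/π)∫cos θ dθ over (−π/2, π/2) at d = 1), which anchors the estimator
   tests analytically;
2. **nose-poke gain** (active engagement only): a multiplicative factor for
   200 ms (two masker cycles) after poke onset — 1.218 for the
   sound-detecting preset, 0.974 for the non-sound-detecting preset;
3. **target terms** (Go trials): a sustained gain on 0.1–0.95 s (< 1
   suppression, > 1 enhancement), a reduction of the locking depth during the
   target (envelope-locking suppression), and additive exponential
   onset/offset transients (latency 20 ms, decay 30 ms; amplitudes are
   order-of-magnitude choices — the empirical literature reports their
   existence and SNR ordering, not their shape).

Two cohort presets encode the qualitative group differences the analyses must
resolve. The *sound-detecting* preset has sustained gains that reverse sign
across SNR (1.30 at −10 dB, 1.12 at 0 dB, 0.78 at +10 dB), locking
suppression rising with SNR (50/65/80% of depth), and the positive poke
gain. The *non-sound-detecting* preset keeps all sustained gains above 1,
has a locking depth higher by ≈ 0.16 (so measured VS is ≈ 0.1 higher,
via VS = 2d/π), and slightly suppressive poke modulation. Unit-level
parameters are jittered around the preset means (lognormal baseline,
truncated-normal depth and gains) from seeded substreams: per-trial streams
are keyed by (seed, unit, trial) so any single train is reproducible in
isolation.

Default cohort sizes mirror the experimental groups (151 and 56 units), but
all shipped tests and examples run at 20 units to keep the suite fast; the
qualitative contrasts are stable at that size across seeds.

What the generator does **not** emulate: biophysical membrane dynamics,
spike-waveform diversity beyond a single template, electrode drift,
correlated (shared) variability across units, and any dependence of neural
responses on the behavioral outcome within a trial. Passing tests therefore
show that the *analysis chain* recovers the structure it assumes, not that
real cortex behaves this way.

## Spike detection

Raw traces are common-average referenced, band-passed 300–6000 Hz with a
6th-order Butterworth applied forward-backward (`sosfiltfilt`, zero phase),
and thresholded at −4.8σₙ on local negative minima with a 1 ms minimum
separation; events beyond 30σₙ are rejected as artifacts. σₙ is the median
absolute deviation divided by 0.6745 — the standard robust estimator, chosen
because it is insensitive to the few percent of samples occupied by spikes.
Sorting is a deliberately simplified automatic stand-in for interactive
curation: PCA to 3 components, seeded k-means, and automated QC (refractory
violations < 1%, firing-rate stability across session thirds, a
negative-dominant mean waveform, and a centroid-separation statistic with a
default threshold of 1 cluster-SD).

## Neurometric conventions

- **RTH**: 10 ms bins over [−1, 2] s, 50 ms rectangular kernel (half the
  modulation period — the Nyquist window of the 10 Hz envelope). Densities
  are in spikes/s; Pearson ρ and the similarity slope are invariant to this
  common scale, only the similarity intercept depends on it. Convolution
  uses reflected boundaries to avoid rim artifacts in the outer 25 ms; mass
  (mean spikes/trial) is conserved to ~1%.
- **Rate z** (and the PSD/decorrelation z): zero-variance denominators yield
  NaN ("missing"), never ±∞; downstream summaries skip them.
- **Vector strength** is computed on spikes pooled across trials per
  condition (n = total spike count); per-trial VS is available by mapping
  over single-trial trains. The Rayleigh approximation satisfies p = 1
  exactly at VS = 0 since 1 + 4n + 4n² = (1 + 2n)².
- **Multitaper PSD**: the pooled, mean-subtracted binned train (1 ms bins)
  on the 0.85 s sustained segment, DPSS tapers with time-bandwidth 3 and 5
  tapers, zero-padded to a 1 Hz grid so 10 Hz is exactly on-grid; half the
  trials resampled with replacement, 20 repetitions, seeded.
- **Decorrelation z**: ρ between Go and NoGo RTHs in 300 ms windows stepped
  by 10 ms. The onset set comprises windows *starting* within 300 ms after
  target onset (the early target response); the baseline set comprises
  windows *ending* within 300 ms after the nose poke, so no baseline window
  crosses the target onset — the baseline is strictly the masker-only
  response immediately preceding the target. Since poke-to-target delays are
  250–350 ms, a symmetric "windows starting after the poke" definition would
  mix target response into the baseline and can even flip the sign of z.
- **Mutual information**: plug-in two-Poisson model, λ̂ = mean sustained
  count per condition, equiprobable classes, in bits (hence the [0, 1]
  range). Summation is truncated at λmax + 12√λmax + 25 counts, which keeps
  the truncation error below 1e-10 (verified against exhaustive summation to
  machine precision for λ ≤ 50). No small-sample bias correction is applied;
  this is the documented reading of "estimate λ and compute MI".
- **Similarity index**: OLS slope with NoGo density on the abscissa and Go on
  the ordinate (the slope is not orientation-invariant; this orientation
  reads "how much of the masker response survives the target").
- **Sustained interval**: [0.1, 0.95] s, configurable. Note it spans 8.5
  modulation cycles; the non-integer cycle count makes locking-depth changes
  leak very slightly into mean rates.

## Pipeline and reproducibility

`run_experiment` is a pure function of (config, master seed): the seed fans
out via SHA-256 into named substreams (scheduler, cohort, sampler,
resampler, fixtures), all below 2³¹. The passive condition reuses the same
trial sounds in a shuffled presentation order. Outputs are CSV tables
(schema-versioned), a JSON session report with group means ± SEM per SNR ×
engagement, and a manifest of SHA-256 file digests; identical configs
reproduce identical digests.

## Known limitations

- The decorrelation z-score is a descriptive statistic; under the null its
  single-realization distribution is heavy-tailed because the ρ series is
  strongly autocorrelated across overlapping windows. Only its sign and
  ordering across conditions are interpreted.
- The PSD z-scores from resampled ensembles have artificially small
  denominators (resampling variance, not trial variance), so their magnitude
  is not comparable to the rate z magnitude — again only sign and ordering
  are used.
- Onset/offset transient amplitudes per SNR are plausible but not fitted to
  any recording; first-spike-latency summaries depend on them directly.
- Inferential statistics (repeated-measures/mixed ANOVA families) are out of
  scope; the report tables are tidy inputs for external tools.
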