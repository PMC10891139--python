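# diplisten

Simulation and analysis pipeline for **dip-listening** experiments: detecting a
tone target inside a temporally fluctuating background ("listening in the
dips"), and asking whether cortical **rate** or **temporal** spike codes carry
the target across positive and negative signal-to-noise ratios (SNRs).

The package is written for auditory neuroscientists and psychophysicists who
want a fully synthetic, end-to-end testbed for this class of experiment: a
Go/NoGo tone-in-modulated-noise task (as used with Mongolian gerbils), an
inhomogeneous-Poisson model of envelope-locked auditory-cortex units, a spike
detection stage for raw extracellular traces, and the complete neurometric
suite comparing target-present (Go) with target-absent (NoGo) responses.

## What it computes

**Task and behavior.** The masker is continuous 10 Hz rectangularly
amplitude-modulated band-limited noise (50% duty cycle, 10 ms cos² burst
ramps, 2/3-octave band at 1 kHz); the target is a 1 s, 1 kHz tone with 50 ms
cos² ramps at 40/50/60 dB SPL (SNR −10/0/+10 dB against the 50 dB SPL masker).
A trial starts with a 200 ms nose-poke hold plus a 50 ms system delay, then
the target waits for the next 45° masker phase, so the poke-to-target delay
spans 250–350 ms. Responses are scored HIT / MISS / FALSE ALARM / CORRECT
REJECT; each false alarm forces NoGo trials (at most 15 in a row). With hit
rate HR and false-alarm rate FAR bracketed to [0.05, 0.95],

    d' = Φ⁻¹(HR) − Φ⁻¹(FAR).

Psychometric functions of HR vs tone duration are fitted with a binomial GLM,
HR = logit⁻¹(β₀ + β₁·duration), weighted by trial counts.

**Neurometrics.** For each unit, SNR and engagement condition (active task vs
passive listening), aligned to target onset at 0 s on a [−1, 2] s window:

- response time histograms (RTH): 10 ms bins, 50 ms rectangular smoothing
  kernel (half the 10 Hz modulation period);
- rate z-score z = (μ_Go − μ_NoGo) / ½(σ_Go + σ_NoGo) over the sustained
  interval 0.1–0.95 s;
- vector strength VS = (1/n)·|Σ e^{iθ}| with θᵢ = 2π·frac(tᵢ f), and the
  Rayleigh p ≈ exp[√(1 + 4n + 4n²(1 − VS²)) − (1 + 2n)];
- multitaper power spectral density of the pooled spike point process
  (half-trial resampling × 20) and its Go/NoGo z-score at 10 Hz;
- sliding-window (300 ms / 10 ms step) Pearson ρ between Go and NoGo RTHs and
  the target-evoked decorrelation z-score;
- plug-in Poisson mutual information (bits, ≤ 1) between the Go/NoGo variable
  and the sustained spike count;
- similarity index: regression slope of the Go RTH on the NoGo RTH;
- first-spike latency.

The synthetic units reproduce the empirical structure these metrics probe:
envelope locking (rectangular half-cycle concentration, closed-form
VS = 2d/π at depth d), SNR-dependent sustained suppression/enhancement,
envelope-locking suppression during the target, onset/offset transients, and
nose-poke anticipatory rate modulation.

## Worked example

```python
from diplisten import behavior as bh, simulate as sim, pipeline as pl

agent = bh.make_psychometric_agent({-10.0: 0.82, 0.0: 0.88, 10.0: 0.93},
                                   far=0.12, seed=5)
trials = bh.schedule_session(170, agent, rng_seed=7)
s = bh.summarize_session(trials)
print(f"HR={s.hr:.3f} FAR={s.far:.3f} d'={s.dprime:.3f}")

_, trains = sim.generate_cohort(8, trials, "sound-detecting", "active", seed=11)
tbl = pl.analyze_cohort(trains, trials, resample_seed=13)
print(tbl.groupby("snr_db")[["rate_z", "psd10_z", "decorrelation_z",
                             "mi_bits", "similarity_index"]].mean().round(3))
```

prints

```
HR=0.888 FAR=0.069 d'=2.695
        rate_z  psd10_z  decorrelation_z  mi_bits  similarity_index
snr_db
-10.0    0.937   -6.186           -1.457    0.152             0.554
 0.0     0.385   -7.571           -3.991    0.046             0.347
 10.0   -0.797   -7.821           -4.732    0.114             0.098
```

The simulated agent performs well above the d′ = 1.9 criterion. Across the
8-unit cohort the **rate z-score changes sign** with SNR (more spikes on Go
trials at −10 dB, fewer at +10 dB), so a fixed rate-based decision criterion
cannot serve all SNRs. The **temporal measures do not change sign**: the
10 Hz PSD z-score and the decorrelation z-score are negative at every SNR —
adding the target always suppresses envelope locking and always decorrelates
the response from the masker-only pattern. The similarity index stays
positive and falls as SNR rises.

A full run (both engagement modes, CSV tables, JSON report, manifest with
digests) from the shell:

```bash
diplisten run --seed 1 --out results/demo
diplisten report --out results/demo
```

## Layout

- `src/diplisten/stimulus.py` — masker/target synthesis, trial timing, WAV export
- `src/diplisten/behavior.py` — Go/NoGo scheduler, scoring, d′, psychometric GLM
- `src/diplisten/simulate.py` — inhomogeneous-Poisson unit simulator, cohort
  presets, synthetic extracellular traces
- `src/diplisten/detect.py` — referencing, band-pass, 4.8σₙ event detection,
  30σₙ artifact rejection, PCA + k-means sorting with QC
- `src/diplisten/neurometrics.py` — RTH, z-scores, VS/Rayleigh, multitaper PSD,
  decorrelation, mutual information, similarity index, latency
- `src/diplisten/pipeline.py`, `cli.py` — orchestration, seeding, reports, CLI

See `docs/methods.md` for the modeling and numerical choices.
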