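"""Masker/target synthesis and trial-timing rules for the dip-listening task.

The background ("masker") is a continuous 10 Hz rectangularly amplitude-modulated
band-limited noise (50% duty cycle, 10 ms cosine-squared ramps per burst,
2/3-octave band around 1 kHz, frozen noise).  The target is a 1 kHz, 1 s pure
tone with 50 ms cosine-squared rise/fall.  A trial initiated by a nose poke
schedules the target at the next 45-degree phase of the masker cycle after a
200 ms hold plus a 50 ms fixed system delay, so the poke-to-target delay spans
250-350 ms depending on the poke phase.

Levels are expressed in dB SPL relative to a package-wide software calibration
(a full-scale sine corresponds to ``FULL_SCALE_DB_SPL``); only relative levels
(SNR) matter for the analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal as sig
from scipy.io import wavfile

#: dB SPL assigned to a full-scale (amplitude 1.0) sine; software calibration.
FULL_SCALE_DB_SPL = 94.0


def db_spl_to_rms(level_db: float) -> float:
    """Linear RMS corresponding to ``level_db`` under the package calibration."""
    full_scale_rms = 1.0 / np.sqrt(2.0)
    return full_scale_rms * 10.0 ** ((level_db - FULL_SCALE_DB_SPL) / 20.0)


@dataclass(frozen=True)
class StimulusConfig:
    """Acoustic parameters of the masker and target.

    ``masker_level_convention`` selects whether ``masker_level_db`` refers to the
    RMS of the ON bursts (``"on"``, default) or to the long-term RMS over full
    modulation cycles (``"longterm"``); at 50% duty the two differ by ~3 dB.
    """

    masker_level_db: float = 50.0
    mod_rate_hz: float = 10.0
    duty_cycle: float = 0.5
    burst_ramp_s: float = 0.010
    center_freq_hz: float = 1000.0
    bandwidth_oct: float = 2.0 / 3.0
    noise_seed: int = 20240223
    target_freq_hz: float = 1000.0
    target_dur_s: float = 1.0
    target_ramp_s: float = 0.050
    target_levels_db: tuple[float, ...] = (40.0, 50.0, 60.0)
    sample_rate_hz: float = 50_000.0
    masker_level_convention: str = "on"
    hold_dur_s: float = 0.200
    system_delay_s: float = 0.050
    #: masker phase (degrees) at which the target may start; 0 deg = burst onset
    target_phase_deg: float = 45.0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must lie strictly between 0 and 1")
        if self.mod_rate_hz <= 0:
            raise ValueError("mod_rate_hz must be positive")
        if 2 * self.target_ramp_s > self.target_dur_s:
            raise ValueError("target ramps exceed target duration")
        if self.masker_level_convention not in ("on", "longterm"):
            raise ValueError("masker_level_convention must be 'on' or 'longterm'")
        if self.band_edges_hz[1] >= self.sample_rate_hz / 2:
            raise ValueError("upper band edge at or above Nyquist")

    @property
    def mod_period_s(self) -> float:
        return 1.0 / self.mod_rate_hz

    @property
    def band_edges_hz(self) -> tuple[float, float]:
        half = 2.0 ** (self.bandwidth_oct / 2.0)
        return (self.center_freq_hz / half, self.center_freq_hz * half)

    def replace(self, **kwargs) -> "StimulusConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Waveform:
    """Pressure samples in linear units under the package dB SPL calibration."""

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def level_db(self) -> float:
        """Level in dB SPL of the whole waveform under the calibration."""
        return FULL_SCALE_DB_SPL + 20.0 * np.log10(self.rms() * np.sqrt(2.0))

    def to_wav(self, path, dtype: str = "float32") -> None:
        if dtype == "float32":
            wavfile.write(path, int(self.sample_rate_hz), self.samples.astype(np.float32))
        elif dtype == "int16":
            scaled = np.clip(self.samples, -1.0, 1.0)
            wavfile.write(path, int(self.sample_rate_hz), (scaled * 32767).astype(np.int16))
        else:
            raise ValueError("dtype must be 'float32' or 'int16'")


@dataclass(frozen=True)
class TrialTiming:
    """Decomposition of the poke-to-target delay."""

    poke_onset_s: float
    hold_dur_s: float
    system_delay_s: float
    phase_delay_s: float
    target_onset_s: float

    def __post_init__(self) -> None:
        total = self.hold_dur_s + self.system_delay_s + self.phase_delay_s
        if abs((self.target_onset_s - self.poke_onset_s) - total) > 1e-12:
            raise ValueError("target onset inconsistent with delay components")


def modulation_envelope(config: StimulusConfig, t: np.ndarray) -> np.ndarray:
    """Amplitude envelope of the masker: rectangular bursts with cos^2 ramps.

    Cycle phase 0 is the burst onset.  Each burst occupies ``duty_cycle`` of the
    cycle; a 10 ms cosine-squared ramp is applied inside each burst edge.
    """
    period = config.mod_period_s
    on_dur = config.duty_cycle * period
    ramp = config.burst_ramp_s
    tau = np.mod(t, period)  # position within the cycle
    env = np.zeros_like(tau)
    inside = tau < on_dur
    env[inside] = 1.0
    rising = inside & (tau < ramp)
    env[rising] = np.sin(np.pi * tau[rising] / (2.0 * ramp)) ** 2
    falling = inside & (tau > on_dur - ramp)
    env[falling] = np.cos(np.pi * (tau[falling] - (on_dur - ramp)) / (2.0 * ramp)) ** 2
    return env


def synth_masker(config: StimulusConfig, duration_s: float) -> Waveform:
    """Synthesize the frozen amplitude-modulated band-limited noise masker.

    Gaussian noise is band-limited to the 2/3-octave geometric band (zero-phase
    4th-order Butterworth) and then gated by the rectangular 10 Hz envelope.
    The ON-segment RMS (or long-term RMS, per the config convention) is scaled
    to ``masker_level_db``.  The same ``noise_seed`` reproduces identical
    samples.
    """
    if duration_s < config.mod_period_s:
        raise ValueError("duration must cover at least one modulation period")
    fs = config.sample_rate_hz
    lo, hi = config.band_edges_hz
    if fs < 4 * hi:
        raise ValueError("sample rate below 4x the upper band edge")
    n = round(duration_s * fs)
    rng = np.random.default_rng(config.noise_seed)
    noise = rng.standard_normal(n)
    sos = sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    noise = sig.sosfiltfilt(sos, noise)

    t = np.arange(n) / fs
    env = modulation_envelope(config, t)
    samples = noise * env

    on_mask = env > 0.999  # plateau of the bursts
    if config.masker_level_convention == "on":
        ref_rms = float(np.sqrt(np.mean(samples[on_mask] ** 2)))
    else:
        ref_rms = float(np.sqrt(np.mean(samples**2)))
    samples = samples * (db_spl_to_rms(config.masker_level_db) / ref_rms)
    return Waveform(samples=samples, sample_rate_hz=fs)


def synth_target(config: StimulusConfig, level_db: float) -> Waveform:
    """Synthesize the pure-tone target with cosine-squared onset/offset ramps."""
    if not 0.0 <= level_db <= 90.0:
        raise ValueError("target level outside the supported 0-90 dB SPL range")
    fs = config.sample_rate_hz
    n = round(config.target_dur_s * fs)
    t = np.arange(n) / fs
    amp = db_spl_to_rms(level_db) * np.sqrt(2.0)
    tone = amp * np.sin(2.0 * np.pi * config.target_freq_hz * t)
    ramp = config.target_ramp_s
    env = np.ones(n)
    nr = round(ramp * fs)
    edge = np.sin(np.pi * np.arange(nr) / (2.0 * nr)) ** 2
    env[:nr] = edge
    env[n - nr:] = edge[::-1]
    return Waveform(samples=tone * env, sample_rate_hz=fs)


def _phase_crossing_offset_s(config: StimulusConfig) -> float:
    """Time after a cycle start at which the scheduling phase occurs."""
    return (config.target_phase_deg / 360.0) * config.mod_period_s


def schedule_target_onset(poke_onset_s: float, config: StimulusConfig) -> TrialTiming:
    """Resolve target onset: hold + system delay, then wait for the next
    45-degree masker phase.

    The masker runs continuously from session time 0 with cycle phase 0 (burst
    onset) at t = 0.  The residual wait after the fixed delays is the phase
    delay, in [0, cycle period).
    """
    period = config.mod_period_s
    earliest = poke_onset_s + config.hold_dur_s + config.system_delay_s
    crossing = _phase_crossing_offset_s(config)
    phase_delay = (crossing - earliest) % period
    # a poke landing exactly on the crossing waits 0, not a full cycle
    if period - phase_delay < 1e-9:
        phase_delay = 0.0
    return TrialTiming(
        poke_onset_s=poke_onset_s,
        hold_dur_s=config.hold_dur_s,
        system_delay_s=config.system_delay_s,
        phase_delay_s=phase_delay,
        target_onset_s=earliest + phase_delay,
    )


def onset_delay_bounds(
    config: StimulusConfig | None = None, n_grid: int = 10_000
) -> tuple[float, float]:
    """(infimum, supremum) of the poke-to-target delay over all poke phases.

    The delay is a sawtooth of the poke phase with range
    [hold + system, hold + system + period): the infimum is attained, the
    supremum is the open endpoint one period above it.  The grid enumeration
    verifies both: the grid minimum attains the infimum and the grid maximum
    stays strictly below (but approaches) the supremum.
    """
    config = config or StimulusConfig()
    period = config.mod_period_s
    pokes = np.linspace(0.0, period, n_grid, endpoint=False)
    # ensure the phase that attains the minimum is on the grid
    attaining = (_phase_crossing_offset_s(config)
                 - config.hold_dur_s - config.system_delay_s) % period
    pokes = np.append(pokes, attaining)
    delays = np.array(
        [schedule_target_onset(p, config).target_onset_s - p for p in pokes]
    )
    inf = float(delays.min())
    sup = inf + period
    if not (delays.max() < sup <= delays.max() + 2 * period / n_grid):
        raise AssertionError("delay map is not the expected sawtooth")
    return inf, sup
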