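"""Rate and temporal neurometrics comparing Go vs NoGo cortical responses.

All metrics operate on spike times aligned to (virtual) target onset at 0 s,
over the analysis window [-1, 2] s:

* response time histograms (RTHs): 10 ms bins smoothed with a 50 ms
  rectangular kernel (half the 10 Hz modulation period, the Nyquist window
  of the masker envelope);
* incremental firing rates in expanding 50 ms windows from target onset, and
  the Go/NoGo rate z-score z = (mu_Go - mu_NoGo) / (0.5 (sigma_Go + sigma_NoGo));
* vector strength at a base frequency (1-20 Hz grid) with the Rayleigh-test
  p-value approximation p = exp[sqrt(1 + 4n + 4n^2(1 - VS^2)) - (1 + 2n)];
* multitaper power spectral density of the pooled point process, resampling
  half the trials with replacement 20 times, and its Go/NoGo z-score at 10 Hz;
* sliding-window (300 ms, 10 ms steps) Pearson correlation between Go and
  NoGo RTHs, summarized by the decorrelation z-score contrasting the first
  300 ms after target onset with the 300 ms after the nose poke;
* plug-in mutual information (bits) between the binary trial class and the
  sustained-interval (0.1-0.95 s) spike count under fitted Poisson models;
* similarity index: regression slope of the Go RTH on the NoGo RTH over the
  sustained interval;
* first-spike latency after target onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal.windows import dpss

from .simulate import ANALYSIS_WINDOW_S, SUSTAINED_INTERVAL_S, SpikeTrain

RTH_BIN_S = 0.010
RTH_KERNEL_S = 0.050
MOD_RATE_HZ = 10.0


# ---------------------------------------------------------------------------
# Response time histograms


@dataclass(frozen=True)
class RTH:
    """Trial-averaged smoothed spike-rate time course (spikes/s per bin)."""

    bin_centers_s: np.ndarray
    density: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        d = np.diff(self.bin_centers_s)
        if not np.allclose(d, RTH_BIN_S, atol=1e-9):
            raise ValueError("RTH grid spacing must be exactly 10 ms")
        if np.any(self.density < -1e-12):
            raise ValueError("RTH density must be non-negative")


def rth_bin_edges(window: tuple[float, float] = ANALYSIS_WINDOW_S) -> np.ndarray:
    n_bins = round((window[1] - window[0]) / RTH_BIN_S)
    return window[0] + RTH_BIN_S * np.arange(n_bins + 1)


def compute_rth(
    spike_trains: list[SpikeTrain] | list[np.ndarray],
    window: tuple[float, float] = ANALYSIS_WINDOW_S,
    bin_s: float = RTH_BIN_S,
    kernel_s: float = RTH_KERNEL_S,
) -> RTH:
    """Bin spikes into 10 ms windows and convolve with a 50 ms rectangular
    kernel (reflected boundaries), yielding trial-averaged spikes/s.

    The kernel is area-normalized, so the integral of the density over the
    window equals the mean spike count per trial.
    """
    if len(spike_trains) < 1:
        raise ValueError("need at least one trial")
    times = [st.spike_times_s if isinstance(st, SpikeTrain) else np.asarray(st)
             for st in spike_trains]
    edges = window[0] + bin_s * np.arange(round((window[1] - window[0]) / bin_s) + 1)
    counts = np.zeros(len(edges) - 1)
    for t in times:
        counts += np.histogram(t, bins=edges)[0]
    rate = counts / (len(times) * bin_s)  # spikes/s per bin

    k = round(kernel_s / bin_s)
    kernel = np.ones(k) / k
    padded = np.pad(rate, k, mode="reflect")
    smooth = np.convolve(padded, kernel, mode="same")[k:-k]
    centers = (edges[:-1] + edges[1:]) / 2.0
    return RTH(bin_centers_s=centers, density=smooth, n_trials=len(times))


def per_trial_rth(
    spike_trains, window=ANALYSIS_WINDOW_S, bin_s=RTH_BIN_S, kernel_s=RTH_KERNEL_S
) -> np.ndarray:
    """Stack of single-trial smoothed RTH densities, shape (n_trials, n_bins)."""
    return np.stack([compute_rth([st], window, bin_s, kernel_s).density
                     for st in spike_trains])


# ---------------------------------------------------------------------------
# Firing rate and the rate z-score


def incremental_rates(
    spike_trains, t0: float = 0.0, step_s: float = 0.050, n_steps: int = 20
) -> np.ndarray:
    """Firing rate per trial in expanding windows [t0, t0 + k*step], k=1..n.

    Returns shape (n_trials, n_steps), in spikes/s.
    """
    times = [st.spike_times_s if isinstance(st, SpikeTrain) else np.asarray(st)
             for st in spike_trains]
    ends = t0 + step_s * np.arange(1, n_steps + 1)
    out = np.empty((len(times), n_steps))
    for i, t in enumerate(times):
        post = t[t >= t0]
        out[i] = np.searchsorted(post, ends, side="right") / (ends - t0)
    return out


@dataclass(frozen=True)
class GoNogoMoments:
    mu_go: float
    sigma_go: float
    mu_nogo: float
    sigma_nogo: float
    z: float  # nan when both SDs are zero


def rate_zscore(go_rates: np.ndarray, nogo_rates: np.ndarray) -> GoNogoMoments:
    """Go/NoGo separation z = (mu_Go - mu_NoGo) / (0.5 (sigma_Go + sigma_NoGo)).

    Across-trial SDs; a zero denominator yields z = nan (flagged missing).
    """
    go = np.asarray(go_rates, dtype=float)
    nogo = np.asarray(nogo_rates, dtype=float)
    if len(go) < 2 or len(nogo) < 2:
        raise ValueError("need at least two trials per condition")
    mu_g, mu_n = go.mean(), nogo.mean()
    sd_g, sd_n = go.std(ddof=1), nogo.std(ddof=1)
    denom = 0.5 * (sd_g + sd_n)
    z = (mu_g - mu_n) / denom if denom > 0 else np.nan
    return GoNogoMoments(mu_g, sd_g, mu_n, sd_n, float(z))


# ---------------------------------------------------------------------------
# Vector strength and the Rayleigh test


@dataclass(frozen=True)
class PhaseStats:
    f_base_hz: float
    n: int
    vs: float
    p: float


def vector_strength(spike_times_s: np.ndarray, f_base_hz: float = MOD_RATE_HZ) -> PhaseStats:
    """Resultant length of spike phases at ``f_base_hz``.

    ``spike_times_s`` are pooled across trials (per condition/SNR); phases are
    theta_i = 2 pi frac(t_i f).  Raises on an empty spike set.
    """
    t = np.asarray(spike_times_s, dtype=float)
    n = t.size
    if n == 0:
        raise ValueError("vector strength undefined for zero spikes")
    theta = 2.0 * np.pi * np.mod(t * f_base_hz, 1.0)
    vs = float(np.hypot(np.cos(theta).sum(), np.sin(theta).sum()) / n)
    return PhaseStats(f_base_hz=f_base_hz, n=n, vs=vs, p=rayleigh_p(vs, n))


def vector_strength_spectrum(
    spike_times_s: np.ndarray, f_grid_hz: np.ndarray | None = None
) -> list[PhaseStats]:
    """Vector strength on the 1-20 Hz grid (1 Hz steps by default)."""
    if f_grid_hz is None:
        f_grid_hz = np.arange(1.0, 21.0)
    return [vector_strength(spike_times_s, f) for f in f_grid_hz]


def rayleigh_p(vs: float, n: int) -> float:
    """Approximate Rayleigh-test p-value for circular uniformity.

    p = exp[sqrt(1 + 4n + 4 n^2 (1 - VS^2)) - (1 + 2n)]; equals 1 exactly at
    VS = 0 since 1 + 4n + 4n^2 = (1 + 2n)^2.
    """
    if n < 1:
        raise ValueError("need at least one spike")
    if not 0.0 <= vs <= 1.0:
        raise ValueError("VS must lie in [0, 1]")
    return float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * n**2 * (1.0 - vs**2)) - (1.0 + 2.0 * n)))


# ---------------------------------------------------------------------------
# Multitaper PSD of the pooled point process


def mts_psd(
    spike_trains,
    interval_s: tuple[float, float] = SUSTAINED_INTERVAL_S,
    resample_fraction: float = 0.5,
    n_resamples: int = 20,
    seed: int = 0,
    dt: float = 0.001,
    nw: float = 3.0,
    n_tapers: int = 5,
    nfft: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper spectrum of the pooled spike point process, trial-resampled.

    For each of ``n_resamples`` repetitions, ``resample_fraction`` of the
    trials are drawn with replacement, their spikes pooled into a
    mean-subtracted binned train on ``interval_s``, and a DPSS multitaper
    periodogram (time-bandwidth ``nw``, ``n_tapers`` tapers) is computed.
    ``nfft`` is chosen so the frequency grid includes exactly 10 Hz
    (1 Hz resolution by default).  Returns ``(freqs_hz, psd)`` where ``psd``
    has shape (n_resamples, n_freqs).
    """
    trains = [st.spike_times_s if isinstance(st, SpikeTrain) else np.asarray(st)
              for st in spike_trains]
    if len(trains) < 4:
        raise ValueError("need at least 4 trials for resampled MTS")
    n_pick = max(2, round(resample_fraction * len(trains)))
    rng = np.random.default_rng(seed)

    t0, t1 = interval_s
    n_samp = round((t1 - t0) / dt)
    if nfft is None:
        nfft = round(1.0 / dt)  # 1 Hz grid -> includes exactly 10 Hz
    tapers = dpss(n_samp, nw, n_tapers)
    freqs = np.fft.rfftfreq(nfft, d=dt)

    psds = np.empty((n_resamples, len(freqs)))
    for r in range(n_resamples):
        idx = rng.integers(0, len(trains), n_pick)
        binned = np.zeros(n_samp)
        for i in idx:
            t = trains[i]
            sel = t[(t >= t0) & (t < t1)]
            binned += np.histogram(sel, bins=n_samp, range=(t0, t1))[0]
        binned = binned - binned.mean()
        spec = np.abs(np.fft.rfft(tapers * binned, n=nfft, axis=1)) ** 2
        psds[r] = spec.mean(axis=0) * dt / n_samp
    return freqs, psds


def psd10_zscore(
    go_psds: np.ndarray, nogo_psds: np.ndarray, freqs_hz: np.ndarray,
    f_hz: float = MOD_RATE_HZ,
) -> GoNogoMoments:
    """Go/NoGo z-score of the PSD at 10 Hz across resample ensembles."""
    i = int(np.argmin(np.abs(freqs_hz - f_hz)))
    if abs(freqs_hz[i] - f_hz) > 1e-6:
        raise ValueError("frequency grid does not include the requested bin")
    return rate_zscore(go_psds[:, i], nogo_psds[:, i])


# ---------------------------------------------------------------------------
# Target-evoked decorrelation


@dataclass(frozen=True)
class DecorrelationStats:
    window_start_s: np.ndarray
    rho_series: np.ndarray  # nan where undefined (zero variance)
    win_s: float


def sliding_rho(
    go_rth: RTH, nogo_rth: RTH, win_s: float = 0.300, step_s: float = RTH_BIN_S
) -> DecorrelationStats:
    """Pearson correlation between Go and NoGo RTHs in running 300 ms windows.

    Windows slide over the full analysis interval in 10 ms steps; a window
    with zero variance in either series yields nan.
    """
    if not np.allclose(go_rth.bin_centers_s, nogo_rth.bin_centers_s):
        raise ValueError("RTH grids do not match")
    g, n = go_rth.density, nogo_rth.density
    w = round(win_s / RTH_BIN_S)
    step = round(step_s / RTH_BIN_S)
    starts, rhos = [], []
    for i in range(0, len(g) - w + 1, step):
        gs, ns = g[i:i + w], n[i:i + w]
        if gs.std() == 0 or ns.std() == 0:
            rho = np.nan
        else:
            rho = float(np.corrcoef(gs, ns)[0, 1])
        starts.append(go_rth.bin_centers_s[i] - RTH_BIN_S / 2.0)
        rhos.append(rho)
    return DecorrelationStats(np.asarray(starts), np.asarray(rhos), win_s)


def decorrelation_zscore(
    stats_: DecorrelationStats, poke_time_s: float, onset_time_s: float = 0.0
) -> GoNogoMoments:
    """z = (mu_onset - mu_poke) / (0.5 (sigma_onset + sigma_poke)).

    mu/sigma_onset summarize rho over windows *starting* within the first
    300 ms after target onset (the early target response); mu/sigma_poke over
    windows *ending* within 300 ms after the nose poke, so the baseline set
    samples the masker-only response immediately preceding the target and no
    baseline window crosses the target onset.
    """
    s, r, w = stats_.window_start_s, stats_.rho_series, stats_.win_s

    def region(t_from: float) -> np.ndarray:
        m = (s >= t_from - 1e-9) & (s < t_from + w - 1e-9)
        vals = r[m]
        return vals[~np.isnan(vals)]

    onset, poke = region(onset_time_s), region(poke_time_s - w)
    if len(onset) < 2 or len(poke) < 2:
        raise ValueError("too few defined correlation windows in a region")
    denom = 0.5 * (onset.std(ddof=1) + poke.std(ddof=1))
    z = (onset.mean() - poke.mean()) / denom if denom > 0 else np.nan
    return GoNogoMoments(onset.mean(), onset.std(ddof=1),
                         poke.mean(), poke.std(ddof=1), float(z))


# ---------------------------------------------------------------------------
# Poisson mutual information


@dataclass(frozen=True)
class PoissonPair:
    lambda_go: float
    lambda_nogo: float
    sustained_interval_s: tuple[float, float]
    mi_bits: float


def sustained_counts(spike_trains, interval_s=SUSTAINED_INTERVAL_S) -> np.ndarray:
    """Spike count per trial over the sustained response interval."""
    times = [st.spike_times_s if isinstance(st, SpikeTrain) else np.asarray(st)
             for st in spike_trains]
    lo, hi = interval_s
    return np.array([np.count_nonzero((t >= lo) & (t < hi)) for t in times])


def poisson_mutual_information(
    go_counts: np.ndarray,
    nogo_counts: np.ndarray,
    interval_s: tuple[float, float] = SUSTAINED_INTERVAL_S,
) -> PoissonPair:
    """Mutual information (bits) between the equiprobable Go/NoGo variable and
    the sustained spike count under fitted Poisson models.

    lambda per condition is the mean count; MI is computed by summation over
    a truncated count support (0 .. ceil(max lambda + 12 sqrt(max lambda) + 25)),
    which keeps the truncation error below 1e-10 for lambda up to a few
    hundred.  Bounded by 1 bit.
    """
    go = np.asarray(go_counts, dtype=float)
    nogo = np.asarray(nogo_counts, dtype=float)
    if len(go) < 2 or len(nogo) < 2:
        raise ValueError("need at least two trials per condition")
    if np.any(go < 0) or np.any(nogo < 0):
        raise ValueError("counts must be non-negative")
    lam_g, lam_n = float(go.mean()), float(nogo.mean())
    mi = _two_poisson_mi_bits(lam_g, lam_n)
    return PoissonPair(lam_g, lam_n, interval_s, mi)


def _two_poisson_mi_bits(lam_g: float, lam_n: float) -> float:
    lam_max = max(lam_g, lam_n)
    if lam_max == 0.0:
        return 0.0
    support = np.arange(0, int(np.ceil(lam_max + 12.0 * np.sqrt(lam_max) + 25.0)) + 1)
    p_g = stats.poisson.pmf(support, lam_g) if lam_g > 0 else (support == 0).astype(float)
    p_n = stats.poisson.pmf(support, lam_n) if lam_n > 0 else (support == 0).astype(float)
    mix = 0.5 * (p_g + p_n)
    mi = 0.0
    for p in (p_g, p_n):
        nz = p > 0
        mi += 0.5 * np.sum(p[nz] * np.log2(p[nz] / mix[nz]))
    return float(min(max(mi, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Similarity index and first-spike latency


@dataclass(frozen=True)
class SimilaritySlope:
    slope: float
    intercept: float


def similarity_index(
    go_rth: RTH, nogo_rth: RTH, interval_s: tuple[float, float] = SUSTAINED_INTERVAL_S
) -> SimilaritySlope:
    """OLS slope of the Go RTH regressed on the NoGo RTH over the sustained
    interval.  A slope of 1 means the target leaves the masker response
    unchanged; 0 means the target reorganizes the response entirely.
    """
    if not np.allclose(go_rth.bin_centers_s, nogo_rth.bin_centers_s):
        raise ValueError("RTH grids do not match")
    lo, hi = interval_s
    m = (go_rth.bin_centers_s >= lo) & (go_rth.bin_centers_s < hi)
    if m.sum() < 3:
        raise ValueError("too few bins in the sustained interval")
    x, y = nogo_rth.density[m], go_rth.density[m]
    if np.std(x) == 0:
        raise ValueError("NoGo RTH is constant over the interval")
    res = stats.linregress(x, y)
    return SimilaritySlope(slope=float(res.slope), intercept=float(res.intercept))


@dataclass(frozen=True)
class LatencySummary:
    latencies_s: np.ndarray
    mean_s: float
    n_excluded: int  # trials with no post-onset spike


def first_spike_latency(spike_trains, onset_s: float = 0.0) -> LatencySummary:
    """Per-trial time of the first spike after target onset."""
    times = [st.spike_times_s if isinstance(st, SpikeTrain) else np.asarray(st)
             for st in spike_trains]
    lats = []
    excluded = 0
    for t in times:
        post = t[t >= onset_s]
        if len(post):
            lats.append(post[0] - onset_s)
        else:
            excluded += 1
    lats = np.asarray(lats)
    mean = float(lats.mean()) if len(lats) else np.nan
    return LatencySummary(lats, mean, excluded)
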