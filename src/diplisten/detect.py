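"""Spike detection from raw extracellular traces.

Pipeline: common-average referencing across channels, zero-phase band-pass
(Butterworth, 300-6000 Hz), robust noise estimation (MAD / 0.6745), detection
of negative peaks below -4.8 sigma_n with rejection of artifacts exceeding
30 sigma_n, and a simplified PCA + k-means sorting stage with automated
quality control (refractory-violation fraction < 1%, firing-rate stability,
waveform validity).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.signal as sig
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class DetectionParams:
    band_hz: tuple[float, float] = (300.0, 6000.0)
    filter_order: int = 6
    detect_k: float = 4.8
    artifact_k: float = 30.0
    refractory_violation_max: float = 0.01
    min_separation_s: float = 0.001
    snippet_s: float = 0.002

    def __post_init__(self) -> None:
        if not self.artifact_k > self.detect_k > 0:
            raise ValueError("require artifact_k > detect_k > 0")


def common_average_reference(traces: np.ndarray) -> np.ndarray:
    """Subtract the per-sample grand mean across channels from every channel.

    ``traces`` has shape (n_channels, n_samples).  A single channel is
    returned unchanged with a warning.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < 2:
        warnings.warn("common-average reference skipped: single channel")
        return traces.copy()
    return traces - traces.mean(axis=0, keepdims=True)


def bandpass(trace: np.ndarray, fs: float, params: DetectionParams = DetectionParams()) -> np.ndarray:
    """Forward-backward Butterworth band-pass (zero group delay)."""
    lo, hi = params.band_hz
    if hi >= fs / 2:
        raise ValueError("upper band edge at or above Nyquist")
    if fs <= 12_000:
        raise ValueError("sampling rate too low for the 300-6000 Hz band")
    sos = sig.butter(params.filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sig.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def estimate_sigma_n(trace: np.ndarray) -> float:
    """Robust background-noise SD: median absolute deviation / 0.6745.

    The MAD-based estimator is insensitive to the small fraction of samples
    occupied by spikes, unlike the raw standard deviation.
    """
    trace = np.asarray(trace, dtype=float)
    sigma = float(np.median(np.abs(trace - np.median(trace))) / 0.6745)
    if sigma == 0.0:
        warnings.warn("constant trace: sigma_n = 0")
    return sigma


def detect_events(
    trace: np.ndarray,
    fs: float,
    params: DetectionParams = DetectionParams(),
    sigma_n: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect spike events as negative peaks below ``-detect_k * sigma_n``.

    Peaks whose magnitude exceeds ``artifact_k * sigma_n`` are rejected as
    artifacts.  Events closer than ``min_separation_s`` are merged (largest
    peak wins via the distance constraint).  Returns
    ``(peak_sample_indices, snippets)`` with snippets windowed around each
    peak.
    """
    trace = np.asarray(trace, dtype=float)
    if sigma_n is None:
        sigma_n = estimate_sigma_n(trace)
    if sigma_n <= 0:
        raise ValueError("sigma_n must be positive")
    distance = max(1, round(params.min_separation_s * fs))
    peaks, props = sig.find_peaks(-trace, height=params.detect_k * sigma_n, distance=distance)
    amplitudes = props["peak_heights"]
    keep = amplitudes <= params.artifact_k * sigma_n
    peaks = peaks[keep]

    half = round(params.snippet_s * fs / 2)
    valid = (peaks >= half) & (peaks + half < len(trace))
    peaks = peaks[valid]
    snippets = np.stack([trace[p - half:p + half] for p in peaks]) if len(peaks) else \
        np.empty((0, 2 * half))
    return peaks, snippets


@dataclass(frozen=True)
class ClusterQC:
    unit_id: int
    n_events: int
    refractory_violation_frac: float
    rate_stability: float  # max/min firing rate over session thirds
    waveform_valid: bool
    separation_ok: bool
    passed: bool


def sort_and_qc(
    snippets: np.ndarray,
    peak_samples: np.ndarray,
    fs: float,
    k_clusters: int = 2,
    params: DetectionParams = DetectionParams(),
    n_components: int = 3,
    seed: int = 0,
    rate_stability_max: float = 3.0,
    separation_min: float = 1.0,
) -> tuple[np.ndarray, list[ClusterQC]]:
    """Simplified sorting: PCA to 3 components, seeded k-means, automated QC.

    QC per cluster: refractory-violation fraction below 1%, firing-rate
    stability across session thirds (max/min ratio), a waveform-validity check
    (negative-dominant mean waveform), and pairwise cluster separation in PC
    space (distance between centroids relative to cluster spread).
    """
    if len(snippets) < 50:
        raise ValueError("need at least 50 snippets to sort")
    if len(snippets) < k_clusters:
        raise ValueError("fewer snippets than clusters")
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(snippets)
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed).fit(pcs)
    labels = km.labels_

    t_all = np.asarray(peak_samples) / fs
    session_len = t_all.max() - t_all.min() if len(t_all) > 1 else 0.0
    reports = []
    for u in range(k_clusters):
        times = np.sort(t_all[labels == u])
        n = len(times)
        isi = np.diff(times)
        viol = float(np.mean(isi < params.min_separation_s)) if len(isi) else 0.0
        if session_len > 0 and n >= 3:
            edges = t_all.min() + session_len * np.array([0.0, 1 / 3, 2 / 3, 1.0])
            counts = np.histogram(times, bins=edges)[0].astype(float)
            counts = np.maximum(counts, 0.5)  # avoid div-by-zero for empty thirds
            stability = float(counts.max() / counts.min())
        else:
            stability = np.inf
        mean_wave = snippets[labels == u].mean(axis=0) if n else np.zeros(snippets.shape[1])
        waveform_valid = bool(-mean_wave.min() > mean_wave.max()) and mean_wave.min() < 0

        others = pcs[labels != u]
        own = pcs[labels == u]
        if len(others) and len(own) > 1:
            d = np.linalg.norm(own.mean(axis=0) - others.mean(axis=0))
            spread = np.sqrt(own.var(axis=0).sum())
            separation_ok = bool(d / max(spread, 1e-12) >= separation_min)
        else:
            separation_ok = True
        passed = (
            viol < params.refractory_violation_max
            and stability <= rate_stability_max
            and waveform_valid
            and separation_ok
        )
        reports.append(ClusterQC(u, n, viol, stability, waveform_valid,
                                 separation_ok, passed))
    return labels, reports
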