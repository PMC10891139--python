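"""End-to-end orchestration: task simulation -> spike simulation -> neurometrics.

A single :class:`ExperimentConfig` (optionally read from YAML) drives the whole
run.  One master seed is fanned out to named substreams (scheduler, cohort,
sampler, resampler, fixtures) so each stage can be re-run in isolation and the
whole run is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, io as dio, neurometrics as nm, simulate
from .behavior import GO_SNRS_DB, Kind, NOGO_SNR_DB

_SUBSTREAMS = ("scheduler", "cohort", "sampler", "resampler", "fixtures")


def substream_seed(master_seed: int, name: str) -> int:
    """Stable named substream below 2^31, derived by hashing (seed, name)."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}")
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    n_units: int = 20
    n_trials: int = 170
    n_sessions: int = 1
    preset: str = "sound-detecting"
    engagement: str = "both"  # active, passive, or both
    snr_set: tuple[float, ...] = GO_SNRS_DB
    hit_rates: dict = field(default_factory=lambda: {-10.0: 0.82, 0.0: 0.88, 10.0: 0.93})
    far: float = 0.12
    seed: int = 0
    output_dir: str = "diplisten_out"
    sim_dt_s: float = 0.001

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if "hit_rates" in raw:
            cfg.hit_rates = {float(k): float(v) for k, v in raw["hit_rates"].items()}
        if "snr_set" in raw:
            cfg.snr_set = tuple(float(s) for s in raw["snr_set"])
        return cfg


def simulate_session_trials(config: ExperimentConfig, session: int = 0) -> pd.DataFrame:
    agent = behavior.make_psychometric_agent(
        config.hit_rates, config.far,
        seed=substream_seed(config.seed, "scheduler") + 2 * session + 1)
    return behavior.schedule_session(
        config.n_trials, agent, snr_set=config.snr_set,
        rng_seed=substream_seed(config.seed, "scheduler") + 2 * session)


def analyze_unit(
    trains: list[simulate.SpikeTrain],
    trials: pd.DataFrame,
    snr_set=GO_SNRS_DB,
    resample_seed: int = 0,
) -> list[dict]:
    """Per-SNR neurometric summary for one unit (one engagement condition).

    Returns one record per Go SNR with: rate z over the sustained interval,
    vector strength + Rayleigh p (NoGo and Go), 10 Hz multitaper PSD z-score,
    decorrelation z-score, Poisson mutual information, similarity index, and
    mean first-spike latency.
    """
    by_trial = {st.trial_index: st for st in trains}
    kinds = trials.set_index("index")
    nogo_idx = kinds.index[kinds["kind"] == Kind.NOGO.value]
    nogo_trains = [by_trial[i] for i in nogo_idx if i in by_trial]
    if len(nogo_trains) < 4:
        raise ValueError("too few NoGo trials for neurometrics")
    nogo_rth = nm.compute_rth(nogo_trains)
    nogo_counts = nm.sustained_counts(nogo_trains)
    sus_len = nm.SUSTAINED_INTERVAL_S[1] - nm.SUSTAINED_INTERVAL_S[0]
    f_nogo, psd_nogo = nm.mts_psd(nogo_trains, seed=resample_seed)
    nogo_sus = _pooled_sustained_times(nogo_trains)
    mean_poke = -float((kinds["target_onset_s"] - kinds["poke_onset_s"]).mean())

    records = []
    for snr in snr_set:
        go_idx = kinds.index[(kinds["kind"] == Kind.GO.value) & (kinds["snr_db"] == snr)]
        go_trains = [by_trial[i] for i in go_idx if i in by_trial]
        if len(go_trains) < 4:
            raise ValueError(f"too few Go trials at {snr} dB SNR")
        go_rth = nm.compute_rth(go_trains)
        go_counts = nm.sustained_counts(go_trains)
        rate_z = nm.rate_zscore(go_counts / sus_len, nogo_counts / sus_len)
        _, psd_go = nm.mts_psd(go_trains, seed=resample_seed + 1)
        psd_z = nm.psd10_zscore(psd_go, psd_nogo, f_nogo)
        rho = nm.sliding_rho(go_rth, nogo_rth)
        dec_z = nm.decorrelation_zscore(rho, poke_time_s=mean_poke)
        mi = nm.poisson_mutual_information(go_counts, nogo_counts)
        sim = nm.similarity_index(go_rth, nogo_rth)
        vs_go = nm.vector_strength(_pooled_sustained_times(go_trains))
        vs_nogo = nm.vector_strength(nogo_sus)
        lat = nm.first_spike_latency(go_trains)
        records.append(dict(
            unit_id=trains[0].unit_id, snr_db=snr,
            rate_z=rate_z.z, psd10_z=psd_z.z, decorrelation_z=dec_z.z,
            mi_bits=mi.mi_bits, similarity_index=sim.slope,
            vs_go=vs_go.vs, vs_nogo=vs_nogo.vs,
            rayleigh_p_go=vs_go.p, rayleigh_p_nogo=vs_nogo.p,
            first_spike_latency_s=lat.mean_s,
            n_go=len(go_trains), n_nogo=len(nogo_trains),
        ))
    return records


def _pooled_sustained_times(trains) -> np.ndarray:
    lo, hi = nm.SUSTAINED_INTERVAL_S
    pooled = np.concatenate([st.spike_times_s for st in trains]) if trains else np.empty(0)
    return pooled[(pooled >= lo) & (pooled < hi)]


def analyze_cohort(
    trains_by_unit: dict[int, list[simulate.SpikeTrain]],
    trials: pd.DataFrame,
    snr_set=GO_SNRS_DB,
    resample_seed: int = 0,
) -> pd.DataFrame:
    rows = []
    for uid, trains in trains_by_unit.items():
        rows.extend(analyze_unit(trains, trials, snr_set, resample_seed + uid))
    return pd.DataFrame(rows)


def group_summary(unit_table: pd.DataFrame) -> pd.DataFrame:
    """Across-unit mean and SEM of each neurometric, per SNR."""
    metrics = ["rate_z", "psd10_z", "decorrelation_z", "mi_bits",
               "similarity_index", "vs_go", "vs_nogo", "first_spike_latency_s"]
    g = unit_table.groupby("snr_db")[metrics]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem().add_suffix("_sem")
    return mean.join(sem).reset_index()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute all stages and write tables, a JSON report and a run manifest.

    Produces per-engagement unit-level neurometric tables, group summaries
    (the machine-readable analogue of the headline rate-vs-temporal figure),
    a behavioral d'-vs-SNR table, and a manifest with per-file SHA-256
    digests; a re-run with an identical config reproduces identical digests.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    engagements = ("active", "passive") if config.engagement == "both" \
        else (config.engagement,)

    trials = simulate_session_trials(config)
    behavior.trial_table_to_csv(trials, out / "trials.csv")

    behav_rows = [dict(snr_db="all", **asdict(behavior.summarize_session(trials)))]
    for snr in config.snr_set:
        s = behavior.summarize_session(trials, snr_db=snr)
        behav_rows.append(dict(snr_db=snr, **asdict(s)))
    pd.DataFrame(behav_rows).to_csv(out / "behavior_dprime.csv", index=False)

    cfg_dict = {**asdict(config), "snr_set": list(config.snr_set)}
    cfg_dict.pop("output_dir")  # a path, not part of the scientific config
    report = {"config": cfg_dict, "engagements": {}}
    for eng in engagements:
        eng_trials = trials
        if eng == "passive":
            # same sounds, shuffled presentation order
            rng = np.random.default_rng(substream_seed(config.seed, "scheduler") + 999)
            eng_trials = trials.sample(frac=1.0, random_state=rng.integers(2**31)) \
                .reset_index(drop=True)
            eng_trials["index"] = np.arange(len(eng_trials))
        profiles, trains = simulate.generate_cohort(
            config.n_units, eng_trials, preset=config.preset, engagement=eng,
            seed=substream_seed(config.seed, "sampler"), dt=config.sim_dt_s)
        dio.write_spike_table(trains, out / f"spikes_{eng}.csv")
        unit_table = analyze_cohort(
            trains, eng_trials, config.snr_set,
            resample_seed=substream_seed(config.seed, "resampler"))
        unit_table.to_csv(out / f"neurometrics_{eng}.csv", index=False)
        summary = group_summary(unit_table)
        summary.to_csv(out / f"summary_{eng}.csv", index=False)
        report["engagements"][eng] = summary.to_dict(orient="records")

    (out / "session_report.json").write_text(json.dumps(report, indent=2))
    manifest = {
        "schema_version": dio.SCHEMA_VERSION,
        "config_hash": hashlib.sha256(
            json.dumps(report["config"], sort_keys=True).encode()).hexdigest(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {p.name: _digest(p) for p in sorted(out.iterdir())
                  if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_fixtures(seed: int, out_dir) -> dict:
    """Write a tiny deterministic dataset (4 units, 40 trials, one raw-trace
    snippet) used by the test suite and docs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = ExperimentConfig(n_units=4, n_trials=40, engagement="active",
                           seed=substream_seed(seed, "fixtures"),
                           output_dir=str(out))
    manifest = run_experiment(cfg)

    rng = np.random.default_rng(substream_seed(seed, "fixtures"))
    fs = 25_000.0
    spike_times = np.sort(rng.uniform(0.05, 1.95, 40))
    spike_times = spike_times[np.diff(spike_times, prepend=-1) > 0.003]
    trace, truth = simulate.synth_extracellular_trace(
        spike_times, duration_s=2.0, fs=fs, amplitude=10.0,
        seed=substream_seed(seed, "fixtures"))
    dio.write_trace(trace, fs, out / "raw_trace")
    np.savetxt(out / "raw_trace_truth_samples.txt", truth, fmt="%d")
    return manifest
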