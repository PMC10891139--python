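"""Go/NoGo task scheduling, response scoring, d-prime, and the psychometric GLM.

Scoring rules: a lick-spout contact on a Go trial is a HIT; a re-poke or no
response on a Go trial is a MISS; a lick on a NoGo trial is a FALSE ALARM
(followed by a mandatory 1-1.5 s timeout and a forced NoGo trial, chained up to
15 sequential NoGo trials); withheld or re-poke responses on NoGo trials are
CORRECT REJECTs.  Hit and false-alarm rates are bracketed to [0.05, 0.95]
before computing d' = Phi^-1(HR) - Phi^-1(FAR).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
import statsmodels.api as sm

GO_SNRS_DB = (-10.0, 0.0, 10.0)
NOGO_SNR_DB = -np.inf
RESPONSE_WINDOW_S = 4.2
TIMEOUT_RANGE_S = (1.0, 1.5)
BRACKET_LO, BRACKET_HI = 0.05, 0.95
DEFAULT_GO_PER_SESSION = 108
DEFAULT_NOGO_PER_SESSION = 62
FA_CHAIN_CAP = 15


class Kind(str, enum.Enum):
    GO = "Go"
    NOGO = "NoGo"


class Response(str, enum.Enum):
    LICK = "lick"
    REPOKE = "repoke"
    NONE = "none"


class Outcome(str, enum.Enum):
    HIT = "HIT"
    MISS = "MISS"
    CORRECT_REJECT = "CORRECT_REJECT"
    FALSE_ALARM = "FALSE_ALARM"


def score_trial(kind: Kind | str, response: Response | str) -> Outcome:
    """Map (trial kind, animal response) to the signal-detection outcome."""
    kind = Kind(kind)
    response = Response(response)
    if kind is Kind.GO:
        return Outcome.HIT if response is Response.LICK else Outcome.MISS
    return Outcome.FALSE_ALARM if response is Response.LICK else Outcome.CORRECT_REJECT


Agent = Callable[[Kind, float], Response]


def always_lick_agent(kind: Kind, snr_db: float) -> Response:
    return Response.LICK


def never_lick_agent(kind: Kind, snr_db: float) -> Response:
    return Response.NONE


def make_psychometric_agent(
    hit_rates: dict[float, float], far: float, seed: int
) -> Agent:
    """Stochastic agent licking with P(hit | SNR) on Go and P(FA) on NoGo."""
    rng = np.random.default_rng(seed)

    def agent(kind: Kind, snr_db: float) -> Response:
        p = far if kind is Kind.NOGO else hit_rates[snr_db]
        return Response.LICK if rng.random() < p else Response.NONE

    return agent


def schedule_session(
    n_trials: int,
    agent: Agent,
    snr_set: Sequence[float] = GO_SNRS_DB,
    go_nogo_mix: tuple[int, int] = (DEFAULT_GO_PER_SESSION, DEFAULT_NOGO_PER_SESSION),
    fa_chain_cap: int = FA_CHAIN_CAP,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Run a simulated Go/NoGo session against a response agent.

    Base trials draw Go vs NoGo from ``go_nogo_mix`` and an SNR uniformly from
    ``snr_set``.  Every FALSE ALARM forces the next trial to NoGo, chained
    while false alarms continue; a run of ``fa_chain_cap`` consecutive NoGo
    trials forces the next trial to Go, so no agent can produce a longer run.

    Returns one row per trial: index, kind, snr_db, poke/target times,
    response, outcome, timeout_s.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(rng_seed)
    p_go = go_nogo_mix[0] / sum(go_nogo_mix)

    rows = []
    session_t = 0.0
    forced_nogo = False
    nogo_run = 0
    for i in range(n_trials):
        if nogo_run >= fa_chain_cap:
            kind = Kind.GO
        elif forced_nogo:
            kind = Kind.NOGO
        else:
            kind = Kind.GO if rng.random() < p_go else Kind.NOGO
        snr = float(rng.choice(snr_set)) if kind is Kind.GO else NOGO_SNR_DB

        poke = session_t + rng.uniform(1.0, 5.0)  # inter-trial interval
        phase_delay = rng.uniform(0.0, 0.100)
        target = poke + 0.200 + 0.050 + phase_delay
        response = agent(kind, snr)
        outcome = score_trial(kind, response)

        timeout = 0.0
        if outcome is Outcome.FALSE_ALARM:
            timeout = rng.uniform(*TIMEOUT_RANGE_S)
        forced_nogo = outcome is Outcome.FALSE_ALARM
        nogo_run = nogo_run + 1 if kind is Kind.NOGO else 0

        session_t = target + RESPONSE_WINDOW_S + timeout
        rows.append(
            dict(index=i, kind=kind.value, snr_db=snr, poke_onset_s=poke,
                 target_onset_s=target, response=response.value,
                 outcome=outcome.value, timeout_s=timeout)
        )
    return pd.DataFrame(rows)


def bracket_rate(rate: float) -> float:
    """Clamp an observed proportion to [0.05, 0.95] (anti-infinite-d' rule)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    return min(max(rate, BRACKET_LO), BRACKET_HI)


def dprime(hr: float, far: float) -> float:
    """Signal-detection sensitivity d' = Phi^-1(HR) - Phi^-1(FAR).

    Expects already-bracketed rates strictly inside (0, 1).
    """
    if not (0.0 < hr < 1.0 and 0.0 < far < 1.0):
        raise ValueError("rates must be bracketed strictly inside (0, 1)")
    return float(norm.ppf(hr) - norm.ppf(far))


@dataclass(frozen=True)
class BehavioralSummary:
    hr: float
    far: float
    dprime: float
    n_go: int
    n_nogo: int


def summarize_session(trials: pd.DataFrame, snr_db: float | None = None) -> BehavioralSummary:
    """HR, FAR and bracketed d' for one session (optionally one Go SNR)."""
    go = trials[trials["kind"] == Kind.GO.value]
    if snr_db is not None:
        go = go[go["snr_db"] == snr_db]
    nogo = trials[trials["kind"] == Kind.NOGO.value]
    if len(go) == 0 or len(nogo) == 0:
        raise ValueError("need at least one Go and one NoGo trial")
    hr = bracket_rate((go["outcome"] == Outcome.HIT.value).mean())
    far = bracket_rate((nogo["outcome"] == Outcome.FALSE_ALARM.value).mean())
    return BehavioralSummary(hr=hr, far=far, dprime=dprime(hr, far),
                             n_go=len(go), n_nogo=len(nogo))


@dataclass(frozen=True)
class PsychometricFit:
    """Binomial GLM of hit rate vs tone duration, HR = logit^-1(b0 + b1*dur)."""

    beta0: float
    beta1: float
    std_errors: tuple[float, float]
    z_values: tuple[float, float]
    dof: int
    converged: bool
    separation_warning: bool = False

    def predict_hr(self, duration_s):
        eta = self.beta0 + self.beta1 * np.asarray(duration_s, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_psychometric(
    durations_s: Sequence[float],
    hit_counts: Sequence[int],
    trial_counts: Sequence[int],
) -> PsychometricFit:
    """Fit the psychometric function by a binomial GLM with logit link.

    Trial counts enter as binomial denominators, which weighs each duration's
    hit rate proportionally to its trial count.  Durations are in seconds, so
    the slope is per second of tone duration.
    """
    durations_s = np.asarray(durations_s, dtype=float)
    hits = np.asarray(hit_counts, dtype=float)
    n = np.asarray(trial_counts, dtype=float)
    if len(np.unique(durations_s)) < 2:
        raise ValueError("need at least two distinct durations")
    if np.any(n < 1) or np.any(hits < 0) or np.any(hits > n):
        raise ValueError("invalid hit/trial counts")

    endog = np.column_stack([hits, n - hits])
    exog = sm.add_constant(durations_s)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        warned = any("PerfectSeparation" in type(w.message).__name__ for w in caught)
    # statsmodels also warns on zero-deviance fits; only flag genuine
    # separation, i.e. observed rates pinned at 0 or 1
    separation = warned and bool(np.any(hits == 0) or np.any(hits == n))
    if separation:
        warnings.warn("possible complete separation in psychometric fit")
    return PsychometricFit(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        std_errors=(float(res.bse[0]), float(res.bse[1])),
        z_values=(float(res.params[0] / res.bse[0]), float(res.params[1] / res.bse[1])),
        dof=int(res.df_resid),
        converged=bool(res.converged),
        separation_warning=separation,
    )


def duration_threshold(
    fit: PsychometricFit,
    criterion_dprime: float = 1.9,
    assumed_far: float = BRACKET_LO,
    max_dur_s: float = 1.0,
    tol_s: float = 0.001,
) -> float:
    """Shortest tone duration whose predicted HR reaches the d' criterion.

    The model HR at a candidate duration is bracketed and combined with
    ``assumed_far`` via the d' formula; the root is found by bisection to
    ``tol_s``.  Raises if the criterion is not reachable within (0, max_dur].
    """
    far = bracket_rate(assumed_far)

    def excess(dur: float) -> float:
        hr = bracket_rate(float(fit.predict_hr(dur)))
        return dprime(hr, far) - criterion_dprime

    lo, hi = 1e-6, max_dur_s
    if excess(hi) < 0:
        raise ValueError("criterion d' not reachable within the duration range")
    if excess(lo) >= 0:
        return lo
    return float(brentq(excess, lo, hi, xtol=tol_s))


def trial_table_to_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def trial_table_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
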