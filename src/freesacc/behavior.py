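"""EOG saccade detection, trial exclusion, RT statistics, trial history.

Saccade onsets are found from the slope of the horizontal EOG trace: the
smoothed derivative must exceed a threshold (default 3x the SD of the
pre-go derivative) for a minimum run.  Trials with reaction times above
750 ms, missing detections, or delay-period eye movements are excluded;
the task design retains roughly 75% of trials under these rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Recording, ms_to_samples

__all__ = [
    "SaccadeDetectParams",
    "RTStats",
    "HistoryResult",
    "detect_saccade_onset",
    "detect_trial_latencies",
    "detect_delay_artifacts",
    "apply_trial_exclusions",
    "compare_reaction_times",
    "trial_history_test",
]


@dataclass(frozen=True)
class SaccadeDetectParams:
    """Slope-detector settings (all durations in ms)."""

    smooth_ms: float = 15.0
    k_sd: float = 3.0
    min_run_ms: float = 10.0
    search_ms: float = 1500.0
    baseline_ms: float = 400.0  # pre-go span used to estimate derivative SD


def _smoothed_derivative(trace: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    # trailing (causal) moving average: a sharp onset cannot bleed backward
    # in time, so the detected latency is never earlier than the event
    width = max(int(ms_to_samples(smooth_ms, fs)), 1)
    x = np.asarray(trace, dtype=float)
    sm = np.convolve(x, np.ones(width) / width, mode="full")[: len(x)]
    return np.gradient(sm)


def detect_saccade_onset(
    trace: np.ndarray,
    sampling_rate: float,
    go_time_ms: float,
    params: SaccadeDetectParams = SaccadeDetectParams(),
) -> float | None:
    """First post-go time where the EOG slope exceeds threshold.

    Parameters
    ----------
    trace : ndarray
        EOG segment; sample 0 is time 0 ms, the go signal is at
        ``go_time_ms``.  Must cover ``[go, go + search window]``.

    Returns
    -------
    float or None
        Saccade latency in ms after go, or None if no sustained
        supra-threshold slope is found within the search window.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    fs = sampling_rate
    go = int(ms_to_samples(go_time_ms, fs))
    stop = min(go + int(ms_to_samples(params.search_ms, fs)), len(trace))
    if go < 0 or go >= len(trace):
        raise ValueError("go time outside the trace")
    deriv = _smoothed_derivative(trace, fs, params.smooth_ms)
    b0 = max(go - int(ms_to_samples(params.baseline_ms, fs)), 0)
    sd = deriv[b0:go].std() if go > b0 else 0.0
    thr = max(params.k_sd * sd, 1e-12)
    above = np.abs(deriv[go:stop]) > thr
    run = max(int(ms_to_samples(params.min_run_ms, fs)), 1)
    # first index that starts a run of >= `run` supra-threshold samples
    if above.size >= run:
        ok = np.convolve(above.astype(int), np.ones(run, dtype=int), "valid") == run
        hits = np.nonzero(ok)[0]
        if hits.size:
            return float(hits[0] * 1000.0 / fs)
    return None


def detect_trial_latencies(
    eog: Recording,
    trials: pd.DataFrame,
    channel: str = "HEOG",
    params: SaccadeDetectParams = SaccadeDetectParams(),
) -> pd.DataFrame:
    """Detect saccade latencies for every trial; fills ``saccade_latency_ms``.

    Runs the slope detector on a window around each trial's go signal.
    """
    trace = eog.channel(channel)
    fs = eog.sampling_rate
    pre = ms_to_samples(params.baseline_ms, fs)
    post = ms_to_samples(params.search_ms, fs)
    out = trials.copy()
    latencies = np.full(len(trials), np.nan)
    for i, row in enumerate(trials.itertuples()):
        i0 = max(row.cue2_onset - pre, 0)
        i1 = min(row.cue2_onset + post, eog.n_samples)
        seg = trace[i0:i1]
        lat = detect_saccade_onset(
            seg, fs, (row.cue2_onset - i0) * 1000.0 / fs, params
        )
        latencies[i] = np.nan if lat is None else lat
    out["saccade_latency_ms"] = latencies
    return out


def detect_delay_artifacts(
    eog: Recording,
    trials: pd.DataFrame,
    channel: str = "HEOG",
    params: SaccadeDetectParams = SaccadeDetectParams(),
    guard_ms: float = 300.0,
) -> np.ndarray:
    """Flag trials with eye movements during the delay period.

    The slope rule is applied between Cue 1 + ``guard_ms`` and Cue 2, with
    the derivative SD estimated before Cue 1; any sustained deflection
    marks the trial for exclusion.
    """
    trace = eog.channel(channel)
    fs = eog.sampling_rate
    deriv = _smoothed_derivative(trace, fs, params.smooth_ms)
    run = max(int(ms_to_samples(params.min_run_ms, fs)), 1)
    flags = np.zeros(len(trials), dtype=bool)
    for i, row in enumerate(trials.itertuples()):
        b0 = max(row.cue1_onset - ms_to_samples(500.0, fs), 0)
        sd = deriv[b0 : row.cue1_onset].std()
        thr = max(params.k_sd * sd, 1e-12)
        d0 = row.cue1_onset + ms_to_samples(guard_ms, fs)
        above = np.abs(deriv[d0 : row.cue2_onset]) > thr
        if above.size >= run:
            ok = np.convolve(above.astype(int), np.ones(run, dtype=int), "valid")
            flags[i] = bool(np.any(ok == run))
    return flags


def apply_trial_exclusions(
    trials: pd.DataFrame,
    rt_max_ms: float = 750.0,
    delay_artifact_flags: np.ndarray | None = None,
) -> pd.DataFrame:
    """Set ``included=False`` for bad trials; idempotent.

    A trial is excluded when its reaction time is missing or exceeds
    ``rt_max_ms`` (default 750 ms), or when a delay-period eye movement
    was flagged.  An ``exclusion_summary`` dict is attached to
    ``DataFrame.attrs``.
    """
    out = trials.copy()
    rt = out["saccade_latency_ms"].to_numpy(dtype=float)
    bad = ~np.isfinite(rt) | (rt > rt_max_ms)
    n_art = 0
    if delay_artifact_flags is not None:
        flags = np.asarray(delay_artifact_flags, dtype=bool)
        if len(flags) != len(out):
            raise ValueError("artifact flags do not match the trial count")
        n_art = int(flags.sum())
        bad |= flags
    out["included"] = ~bad
    out.attrs["exclusion_summary"] = {
        "n_trials": len(out),
        "n_retained": int((~bad).sum()),
        "n_rt_excluded": int((~np.isfinite(rt) | (rt > rt_max_ms)).sum()),
        "n_delay_artifact": n_art,
    }
    return out


# ---------------------------------------------------------------------------
# reaction-time statistics


@dataclass
class RTStats:
    """Per-condition RT summaries and bootstrap-equalized pairwise tests.

    ``pairwise[(a, b)]`` holds the aggregated two-tailed unpaired t test
    between conditions ``a`` and ``b`` on bootstrap samples equalized to
    the smallest condition count (p aggregated across bootstraps by the
    configured rule, median by default).
    """

    per_condition: pd.DataFrame
    pairwise: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition_a": a, "condition_b": b, **d}
            for (a, b), d in self.pairwise.items()
        ]
        return pd.DataFrame(rows)


def compare_reaction_times(
    trials: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    aggregate: str = "median",
) -> RTStats:
    """Within-participant RT comparison with trial-count equalization.

    For each condition pair, ``n_boot`` bootstrap iterations subsample
    (without replacement) every condition down to the smallest condition's
    trial count and apply a two-tailed unpaired Student t test; the
    reported p is the median (or mean) across bootstraps.
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    inc = trials[trials["included"] & np.isfinite(trials["saccade_latency_ms"])]
    groups = {
        c: g["saccade_latency_ms"].to_numpy(dtype=float)
        for c, g in inc.groupby("condition")
    }
    if len(groups) < 2:
        raise ValueError("need at least two conditions with included trials")
    for c, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 included trials")
    per_cond = pd.DataFrame(
        {
            "condition": list(groups),
            "mean_ms": [v.mean() for v in groups.values()],
            "sem_ms": [stats.sem(v) for v in groups.values()],
            "n": [len(v) for v in groups.values()],
        }
    )
    rng = np.random.default_rng(seed)
    agg = np.median if aggregate == "median" else np.mean
    pairwise = {}
    conds = list(groups)
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            va, vb = groups[a], groups[b]
            m = min(len(va), len(vb))
            ts = np.empty(n_boot)
            ps = np.empty(n_boot)
            for k in range(n_boot):
                sa = rng.choice(va, size=m, replace=False)
                sb = rng.choice(vb, size=m, replace=False)
                ts[k], ps[k] = stats.ttest_ind(sa, sb)
            pairwise[(a, b)] = {
                "t": float(agg(ts)),
                "p": float(agg(ps)),
                "df": float(2 * m - 2),
                "n_per_group": float(m),
            }
    return RTStats(per_condition=per_cond, pairwise=pairwise)


# ---------------------------------------------------------------------------
# trial-history (n-1) conditional probabilities


@dataclass
class HistoryResult:
    """Conditional choice probabilities with permutation bands.

    ``probs`` maps 'P(L|L)', 'P(L|R)', 'P(R|L)', 'P(R|R)' to observed
    values (NaN when the preceding state never occurs); ``lower``/
    ``upper`` are the two-sided empirical permutation quantiles at
    alpha/2 per tail; ``significant`` flags observations strictly outside
    their band.
    """

    probs: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    significant: dict[str, bool]
    n_perm: int
    alpha: float


def _conditional_probs(seq01: np.ndarray) -> np.ndarray:
    """[P(L|L), P(L|R), P(R|L), P(R|R)] for rows of 0/1 (L/R) sequences."""
    prev, nxt = seq01[..., :-1], seq01[..., 1:]
    nL = (prev == 0).sum(axis=-1).astype(float)
    nR = (prev == 1).sum(axis=-1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pLL = ((prev == 0) & (nxt == 0)).sum(axis=-1) / np.where(nL > 0, nL, np.nan)
        pRR = ((prev == 1) & (nxt == 1)).sum(axis=-1) / np.where(nR > 0, nR, np.nan)
    return np.stack([pLL, 1.0 - pRR, 1.0 - pLL, pRR], axis=-1)


_PROB_KEYS = ("P(L|L)", "P(L|R)", "P(R|L)", "P(R|R)")


def trial_history_test(
    directions: Sequence[str],
    n_perm: int = 1000,
    alpha: float = 0.001,
    seed: int = 0,
) -> HistoryResult:
    """Does the previous free choice predict the next one?

    Observed n-1 conditional probabilities are compared against a null of
    exchangeable sequences obtained by randomly permuting the L/R labels
    (``n_perm`` permutations); a probability is flagged significant when
    it falls strictly outside the two-sided empirical band at
    ``alpha / 2`` per tail.
    """
    seq = np.asarray([{"L": 0, "R": 1}[d] for d in directions], dtype=np.int8)
    if len(seq) < 3:
        raise ValueError("need at least 3 trials for a history test")
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    obs = _conditional_probs(seq)
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(seq))), axis=1)
    null = _conditional_probs(seq[order])  # (n_perm, 4)
    with np.errstate(invalid="ignore"):
        lower = np.nanquantile(null, alpha / 2.0, axis=0)
        upper = np.nanquantile(null, 1.0 - alpha / 2.0, axis=0)
    sig = np.isfinite(obs) & ((obs < lower) | (obs > upper))
    return HistoryResult(
        probs=dict(zip(_PROB_KEYS, map(float, obs))),
        lower=dict(zip(_PROB_KEYS, map(float, lower))),
        upper=dict(zip(_PROB_KEYS, map(float, upper))),
        significant=dict(zip(_PROB_KEYS, map(bool, sig))),
        n_perm=n_perm,
        alpha=alpha,
    )
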