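"""Temporal-dynamics metrics on HG envelopes and decoding curves.

Peaks of relative HG power, decoding onset (first significant window) and
duration (step times the *total* count of significant windows, contiguous
or not), per-trial HG onset detection (2 SD above baseline for at least 2
consecutive bins), group-level t statistics, and the HG-onset x
saccade-latency correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decode import DecodingResult

__all__ = [
    "SiteDynamics",
    "GroupStat",
    "peak_metrics",
    "decoding_onset_duration",
    "group_compare",
    "detect_hg_onset_trial",
    "detect_hg_onsets",
    "correlate_hg_saccade_onsets",
]


@dataclass
class SiteDynamics:
    """Per-site summary of HG and decoding dynamics (times in ms)."""

    peak_rel_amplitude: float | None = None
    peak_latency_ms: float | None = None
    decoding_onset_ms: float | None = None
    decoding_duration_ms: float = 0.0
    peak_da_latency_ms: float | None = None


@dataclass
class GroupStat:
    """Two-tailed Student t comparison between two groups."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    paired: bool


def peak_metrics(
    series: np.ndarray,
    window_centers_ms: np.ndarray,
    span_ms: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Maximum of a relative-power series and its latency within a span.

    Ties resolve to the earliest window.  Returns
    ``(peak_rel_amplitude, peak_latency_ms)``.
    """
    series = np.asarray(series, dtype=float)
    centers = np.asarray(window_centers_ms, dtype=float)
    if span_ms is not None:
        keep = (centers >= span_ms[0]) & (centers < span_ms[1])
        if not keep.any():
            raise ValueError("search span contains no windows")
        series, centers = series[keep], centers[keep]
    i = int(np.nanargmax(series))
    return float(series[i]), float(centers[i])


def decoding_onset_duration(
    result: DecodingResult,
    site: str,
    band: str,
    span_ms: tuple[float, float] | None = None,
) -> SiteDynamics:
    """Onset, total duration and peak latency of significant decoding.

    Onset is the first significant window center; duration is
    ``step * (number of significant windows)`` — non-contiguous windows
    count toward the total.  The peak-DA latency is reported whether or
    not any window is significant.
    """
    if result.sig_mask is None:
        raise ValueError("result carries no significance mask")
    si = list(result.sites).index(site)
    bi = list(result.bands).index(band)
    da = result.da[si, bi]
    mask = result.sig_mask[si, bi]
    centers = result.window_centers_ms
    if span_ms is not None:
        keep = (centers >= span_ms[0]) & (centers < span_ms[1])
        da, mask, centers = da[keep], mask[keep], centers[keep]
    peak_da_ms = float(centers[int(np.argmax(da))])
    hits = np.nonzero(mask)[0]
    if hits.size == 0:
        return SiteDynamics(
            decoding_onset_ms=None,
            decoding_duration_ms=0.0,
            peak_da_latency_ms=peak_da_ms,
        )
    return SiteDynamics(
        decoding_onset_ms=float(centers[hits[0]]),
        decoding_duration_ms=float(result.step_ms * hits.size),
        peak_da_latency_ms=peak_da_ms,
    )


def group_compare(values_a, values_b, paired: bool = False) -> GroupStat:
    """Two-tailed Student t test (paired or unpaired)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal lengths")
        res = stats.ttest_rel(a, b)
        df = len(a) - 1
    else:
        res = stats.ttest_ind(a, b)
        df = len(a) + len(b) - 2
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) and (paired and np.allclose(a, b) or not paired and
                        np.allclose(a, a[0]) and np.allclose(b, b[0])
                        and np.isclose(a[0], b[0])):
        t, p = 0.0, 1.0  # zero variance, zero difference
    return GroupStat(
        t=t,
        df=float(df),
        p=p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        paired=paired,
    )


def detect_hg_onset_trial(
    series: np.ndarray,
    window_centers_ms: np.ndarray,
    baseline_mean: float,
    baseline_sd: float,
    k_sd: float = 2.0,
    min_bins: int = 2,
    start_ms: float = 0.0,
    window_length_ms: float | None = None,
) -> float | None:
    """First window starting >= ``min_bins`` consecutive supra-threshold bins.

    The threshold is ``baseline_mean + k_sd * baseline_sd`` (default 2 SD
    above baseline).  Only windows at or after ``start_ms`` are searched.
    Returns the onset in ms: the window's *start* (center minus half the
    window length) when ``window_length_ms`` is given — the activity
    crossed threshold somewhere inside that window — or the window center
    otherwise.  None when no sufficient run exists.
    """
    if not np.isfinite(baseline_sd) or baseline_sd <= 0:
        raise ValueError("degenerate baseline SD")
    series = np.asarray(series, dtype=float)
    centers = np.asarray(window_centers_ms, dtype=float)
    keep = centers >= start_ms
    series, centers = series[keep], centers[keep]
    above = series > baseline_mean + k_sd * baseline_sd
    if above.size < min_bins:
        return None
    runs = np.convolve(above.astype(int), np.ones(min_bins, dtype=int), "valid")
    hits = np.nonzero(runs == min_bins)[0]
    if not hits.size:
        return None
    onset = centers[hits[0]]
    if window_length_ms is not None:
        onset -= window_length_ms / 2.0
    return float(onset)


def detect_hg_onsets(
    values: np.ndarray,
    window_centers_ms: np.ndarray,
    baseline_mean: np.ndarray,
    baseline_sd: np.ndarray,
    k_sd: float = 2.0,
    min_bins: int = 2,
    start_ms: float = 0.0,
    window_length_ms: float | None = None,
) -> np.ndarray:
    """Vector form of :func:`detect_hg_onset_trial` over trials.

    ``values`` is (trials, windows); baseline stats are per trial.
    Degenerate baselines yield NaN rather than raising.
    """
    out = np.full(values.shape[0], np.nan)
    for i in range(values.shape[0]):
        if not np.isfinite(baseline_sd[i]) or baseline_sd[i] <= 0:
            continue
        onset = detect_hg_onset_trial(
            values[i], window_centers_ms, baseline_mean[i], baseline_sd[i],
            k_sd, min_bins, start_ms, window_length_ms,
        )
        if onset is not None:
            out[i] = onset
    return out


def correlate_hg_saccade_onsets(
    hg_onsets_ms: np.ndarray,
    saccade_latencies_ms: np.ndarray,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between per-trial HG onsets and saccade latencies.

    Pairs with a missing value on either side are dropped; at least three
    complete pairs are required.  Two-sided p under the null of no
    correlation.  ``method`` may be 'pearson' (default, on raw values) or
    'spearman'.
    """
    x = np.asarray(hg_onsets_ms, dtype=float)
    y = np.asarray(saccade_latencies_ms, dtype=float)
    if x.shape != y.shape:
        raise ValueError("onset and latency vectors must match")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    if method == "pearson":
        r, p = stats.pearsonr(x[ok], y[ok])
    elif method == "spearman":
        r, p = stats.spearmanr(x[ok], y[ok])
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)
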