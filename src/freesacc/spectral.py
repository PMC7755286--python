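"""Bipolar re-referencing and band-envelope power features.

The feature chain mirrors standard SEEG practice: adjacent-contact bipolar
derivations, zero-phase FIR band-pass per frequency band, Hilbert analytic
envelope, mean power in sliding windows (400 ms length, 50 ms step for
classification; 60 ms / 10 ms for single-trial display grids), optional
baseline normalization ``(x - b) / b`` against the pre-stimulus rest period
[-500, -100) ms before Cue 1.  Classification consumes *non-normalized*
power; normalized power is used for visualization and dynamics metrics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len

from .core import Recording, ms_to_samples

__all__ = [
    "BandDef",
    "DEFAULT_BANDS",
    "BaselineSpec",
    "PowerTensor",
    "bipolar_rereference",
    "infer_shaft_layout",
    "fir_bandpass",
    "filter_edge_samples",
    "band_envelope",
    "windowed_power",
    "window_grid",
    "baseline_normalize",
    "epoch_features",
    "write_power_tensor",
    "read_power_tensor",
]


@dataclass(frozen=True)
class BandDef:
    """A frequency band ``[f_low, f_high]`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"invalid band limits for {self.name!r}")

    def validate(self, sampling_rate: float) -> None:
        if self.f_high >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name!r} ({self.f_high} Hz) reaches the Nyquist "
                f"frequency at {sampling_rate} Hz sampling"
            )


#: canonical band set: theta, alpha, beta, low gamma, high gamma (HG)
DEFAULT_BANDS = (
    BandDef("theta", 4, 8),
    BandDef("alpha", 8, 15),
    BandDef("beta", 16, 30),
    BandDef("low_gamma", 30, 60),
    BandDef("HG", 60, 140),
)

HG = DEFAULT_BANDS[-1]


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline interval in ms relative to Cue 1; default [-500, -100)."""

    start_ms: float = -500.0
    stop_ms: float = -100.0

    def __post_init__(self):
        if self.stop_ms <= self.start_ms:
            raise ValueError("baseline stop must exceed start")
        if self.stop_ms > 0:
            raise ValueError("baseline interval must precede Cue 1")


@dataclass
class PowerTensor:
    """Envelope power on a site x band x trial x window grid.

    ``values`` holds mean analytic-envelope amplitude (a.u.) per window, or
    unitless relative change if ``normalized``.  ``window_centers_ms`` are
    window centers in ms relative to ``alignment`` ('cue1' or 'cue2');
    windows are half-open ``[t, t + window_length_ms)`` with center
    ``t + window_length_ms / 2``.  ``trial_index`` maps the trial axis back
    to trial ids in the originating table.  ``flagged`` marks
    (site, band, trial) cells whose baseline was degenerate during
    normalization (their values are NaN).
    """

    values: np.ndarray
    sites: Sequence[str]
    bands: Sequence[str]
    trial_index: np.ndarray
    window_centers_ms: np.ndarray
    window_length_ms: float
    step_ms: float
    alignment: str = "cue1"
    normalized: bool = False
    flagged: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (site, band, trial, window)")
        self.window_centers_ms = np.asarray(self.window_centers_ms, dtype=float)
        if len(self.window_centers_ms) != self.values.shape[3]:
            raise ValueError("window grid does not match values")
        diffs = np.diff(self.window_centers_ms)
        if diffs.size and (np.any(diffs <= 0) or not np.allclose(diffs, diffs[0])):
            raise ValueError("window grid must be strictly increasing and uniform")
        if not self.normalized and np.nanmin(self.values, initial=0) < 0:
            raise ValueError("raw power values must be non-negative")
        self.trial_index = np.asarray(self.trial_index, dtype=np.int64)
        self.sites = list(self.sites)
        self.bands = list(self.bands)

    @property
    def shape(self):
        return self.values.shape

    def band_index(self, name: str) -> int:
        return self.bands.index(name)

    def site_index(self, label: str) -> int:
        return self.sites.index(label)

    def window_slice(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Indices of windows fully inside ``[start_ms, stop_ms)``."""
        half = self.window_length_ms / 2.0
        starts = self.window_centers_ms - half
        stops = self.window_centers_ms + half
        return np.nonzero((starts >= start_ms) & (stops <= stop_ms))[0]

    def centers_in(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Indices of windows whose *center* lies in ``[start_ms, stop_ms)``."""
        c = self.window_centers_ms
        return np.nonzero((c >= start_ms) & (c < stop_ms))[0]


# ---------------------------------------------------------------------------
# bipolar montage

_SHAFT_RE = re.compile(r"^([A-Za-z']+)(\d+)$")


def infer_shaft_layout(labels: Sequence[str]) -> dict[str, list[str]]:
    """Group contact labels like ``a1, a2, ... b1, ...`` into shafts.

    Contacts are ordered by their numeric index within each shaft.
    Labels that do not match ``<letters><number>`` are ignored.
    """
    shafts: dict[str, list[tuple[int, str]]] = {}
    for lab in labels:
        m = _SHAFT_RE.match(lab)
        if m:
            shafts.setdefault(m.group(1), []).append((int(m.group(2)), lab))
    return {k: [lab for _, lab in sorted(v)] for k, v in sorted(shafts.items())}


def bipolar_rereference(
    recording: Recording, shaft_layout: Mapping[str, Sequence[str]] | None = None
) -> Recording:
    """Re-reference each contact to its direct neighbor on the same shaft.

    A shaft of ``k`` contacts yields ``k - 1`` derivations labelled
    ``"b-a"`` (deeper contact minus its neighbor), which cancels signal
    components common to adjacent contacts (e.g., mains or distant sources).
    """
    if shaft_layout is None:
        shaft_layout = infer_shaft_layout(recording.channel_labels)
    rows, labels = [], []
    for shaft, contacts in shaft_layout.items():
        if len(contacts) < 2:
            raise ValueError(f"shaft {shaft!r} has fewer than 2 contacts")
        for a, b in zip(contacts[:-1], contacts[1:]):
            rows.append(recording.channel(b) - recording.channel(a))
            labels.append(f"{b}-{a}")
    return Recording(
        participant_id=recording.participant_id,
        channel_labels=labels,
        signal=np.vstack(rows) if rows else np.empty((0, recording.n_samples)),
        sampling_rate=recording.sampling_rate,
    )


# ---------------------------------------------------------------------------
# filtering and envelopes


def fir_bandpass(band: BandDef, sampling_rate: float, cycles: float = 3.0) -> np.ndarray:
    """Band-pass FIR taps spanning ``cycles`` periods of ``f_low``.

    The filter order is expressed in cycles of the band's lower edge (a
    common electrophysiology-toolbox convention), giving a transition width
    that scales with the band.  Applied forward-backward for zero phase.
    """
    band.validate(sampling_rate)
    numtaps = int(round(cycles * sampling_rate / band.f_low))
    numtaps = max(numtaps, 5)
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(
        numtaps, [band.f_low, band.f_high], pass_zero=False, fs=sampling_rate
    )


def filter_edge_samples(band: BandDef, sampling_rate: float, cycles: float = 3.0) -> int:
    """Length of the unreliable edge region (one filter length) in samples."""
    return len(fir_bandpass(band, sampling_rate, cycles))


def band_envelope(
    x: np.ndarray,
    band: BandDef,
    sampling_rate: float,
    cycles: float = 3.0,
) -> np.ndarray:
    """Analytic-signal envelope of ``x`` restricted to ``band``.

    Zero-phase FIR band-pass (forward-backward), then the magnitude of the
    Hilbert analytic signal.  Output has the same length as the input; one
    filter length at each end is edge-contaminated and should not be
    analyzed (see :func:`filter_edge_samples`).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("band_envelope expects a single channel")
    taps = fir_bandpass(band, sampling_rate, cycles)
    if len(x) <= 3 * len(taps):
        raise ValueError("signal too short for the requested band filter")
    filtered = sps.filtfilt(taps, 1.0, x)
    n = len(filtered)
    analytic = sps.hilbert(filtered, N=next_fast_len(n))[:n]
    return np.abs(analytic)


def window_grid(
    span_ms: tuple[float, float], window_length_ms: float, step_ms: float
) -> np.ndarray:
    """Window-center grid covering ``[start, stop)`` (ms).

    The number of windows is ``floor((stop - start - L) / step) + 1``.
    """
    start, stop = span_ms
    if step_ms <= 0:
        raise ValueError("step must be positive")
    if stop - start < window_length_ms:
        raise ValueError("span shorter than the window length")
    n = int(np.floor((stop - start - window_length_ms) / step_ms)) + 1
    starts = start + step_ms * np.arange(n)
    return starts + window_length_ms / 2.0


def windowed_power(
    envelope: np.ndarray,
    sampling_rate: float,
    window_length_ms: float,
    step_ms: float,
    span_ms: tuple[float, float] | None = None,
    t0_ms: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean envelope power over sliding windows.

    Parameters
    ----------
    envelope : ndarray
        Envelope samples; sample 0 corresponds to time ``t0_ms``.
    span_ms : (start, stop), optional
        Half-open span in the same time base; defaults to the full envelope.

    Returns
    -------
    centers_ms, values : ndarray
        Window centers and the mean envelope within each ``[t, t + L)``.
    """
    envelope = np.asarray(envelope, dtype=np.float64)
    if span_ms is None:
        span_ms = (t0_ms, t0_ms + len(envelope) * 1000.0 / sampling_rate)
    centers = window_grid(span_ms, window_length_ms, step_ms)
    starts = centers - window_length_ms / 2.0
    i0 = ms_to_samples(np.asarray(starts) - t0_ms, sampling_rate)
    length = int(ms_to_samples(window_length_ms, sampling_rate))
    if np.any(i0 < 0) or np.any(i0 + length > len(envelope)):
        raise ValueError("span exceeds the envelope extent")
    # cumulative sum -> O(1) window means on the uniform grid
    csum = np.concatenate([[0.0], np.cumsum(envelope)])
    values = (csum[i0 + length] - csum[i0]) / length
    return centers, values


# ---------------------------------------------------------------------------
# epoching and normalization


def epoch_features(
    recording: Recording,
    trials: pd.DataFrame,
    bands: Sequence[BandDef] = DEFAULT_BANDS,
    alignment: str = "cue1",
    span_ms: tuple[float, float] = (-500.0, 3000.0),
    window_length_ms: float = 400.0,
    step_ms: float = 50.0,
    cycles: float = 3.0,
    included_only: bool = True,
) -> PowerTensor:
    """Band-envelope power tensor for every (included) trial.

    The envelope is computed once per channel/band over the continuous
    recording, then sliced per trial relative to the alignment event
    (``cue1_onset`` or ``cue2_onset`` sample).  With ``alignment='cue2'``
    and a span such as [-2000, 0), the grid is identical across trials
    regardless of each trial's delay length.
    """
    if alignment not in ("cue1", "cue2"):
        raise ValueError("alignment must be 'cue1' or 'cue2'")
    fs = recording.sampling_rate
    tab = trials[trials["included"]] if included_only else trials
    onset_col = "cue1_onset" if alignment == "cue1" else "cue2_onset"
    onsets = tab[onset_col].to_numpy(dtype=np.int64)
    trial_ids = tab["trial"].to_numpy(dtype=np.int64)

    centers = window_grid(span_ms, window_length_ms, step_ms)
    starts_ms = centers - window_length_ms / 2.0
    length = int(ms_to_samples(window_length_ms, fs))
    rel_i0 = ms_to_samples(starts_ms, fs)

    if len(onsets):
        lo = int(onsets.min()) + int(rel_i0.min())
        hi = int(onsets.max()) + int(rel_i0.max()) + length
        if lo < 0 or hi > recording.n_samples:
            raise ValueError("an epoch exceeds the recording bounds")

    n_sites, n_bands = recording.n_channels, len(bands)
    values = np.empty((n_sites, n_bands, len(onsets), len(centers)))
    for bi, band in enumerate(bands):
        for si in range(n_sites):
            env = band_envelope(recording.signal[si], band, fs, cycles)
            csum = np.concatenate([[0.0], np.cumsum(env)])
            idx = onsets[:, None] + rel_i0[None, :]  # (trial, window)
            values[si, bi] = (csum[idx + length] - csum[idx]) / length
    return PowerTensor(
        values=values,
        sites=recording.channel_labels,
        bands=[b.name for b in bands],
        trial_index=trial_ids,
        window_centers_ms=centers,
        window_length_ms=window_length_ms,
        step_ms=step_ms,
        alignment=alignment,
    )


def baseline_normalize(
    tensor: PowerTensor, baseline: BaselineSpec = BaselineSpec()
) -> PowerTensor:
    """Relative power: ``(x - b) / b`` with ``b`` the baseline-window mean.

    Baseline windows are those fully inside the baseline interval (for the
    canonical 400 ms window and the [-500, -100) ms interval this is the
    single pre-stimulus rest window).  Trials whose baseline mean is zero or
    not finite are flagged and set to NaN rather than silently divided.
    """
    if tensor.normalized:
        raise ValueError("tensor is already normalized")
    if tensor.alignment != "cue1":
        raise ValueError("baseline normalization requires a cue1-aligned tensor")
    win = tensor.window_slice(baseline.start_ms, baseline.stop_ms)
    if win.size == 0:
        raise ValueError("no windows fall inside the baseline interval")
    b = tensor.values[:, :, :, win].mean(axis=3)  # (site, band, trial)
    bad = ~np.isfinite(b) | (b <= np.finfo(float).tiny)
    b_safe = np.where(bad, 1.0, b)
    rel = (tensor.values - b_safe[..., None]) / b_safe[..., None]
    rel[bad] = np.nan
    return replace(tensor, values=rel, normalized=True, flagged=bad)


def baseline_window_stats(
    tensor: PowerTensor, start_ms: float, stop_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per (site, band, trial) mean and SD across baseline windows."""
    win = tensor.window_slice(start_ms, stop_ms)
    if win.size < 2:
        raise ValueError("need at least 2 baseline windows for an SD")
    seg = tensor.values[:, :, :, win]
    return seg.mean(axis=3), seg.std(axis=3, ddof=1)


# ---------------------------------------------------------------------------
# persistence


def write_power_tensor(path, tensor: PowerTensor) -> None:
    """Persist a :class:`PowerTensor` to HDF5 with its grid metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values, compression="gzip")
        f.create_dataset("trial_index", data=tensor.trial_index)
        f.create_dataset("window_centers_ms", data=tensor.window_centers_ms)
        f.attrs["sites"] = [s.encode() for s in tensor.sites]
        f.attrs["bands"] = [b.encode() for b in tensor.bands]
        f.attrs["window_length_ms"] = tensor.window_length_ms
        f.attrs["step_ms"] = tensor.step_ms
        f.attrs["alignment"] = tensor.alignment
        f.attrs["normalized"] = tensor.normalized
        if tensor.flagged is not None:
            f.create_dataset("flagged", data=tensor.flagged)


def _str_list(values) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in values]


def read_power_tensor(path) -> PowerTensor:
    with h5py.File(path, "r") as f:
        return PowerTensor(
            values=f["values"][()],
            sites=_str_list(f.attrs["sites"]),
            bands=_str_list(f.attrs["bands"]),
            trial_index=f["trial_index"][()],
            window_centers_ms=f["window_centers_ms"][()],
            window_length_ms=float(f.attrs["window_length_ms"]),
            step_ms=float(f.attrs["step_ms"]),
            alignment=str(f.attrs["alignment"]),
            normalized=bool(f.attrs["normalized"]),
            flagged=f["flagged"][()] if "flagged" in f else None,
        )
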