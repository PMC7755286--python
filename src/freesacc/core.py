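"""Shared base types and unit helpers.

Conventions used throughout the package:

* time is expressed in **milliseconds** in all tables and window grids;
  raw sample indices appear only inside :class:`Recording`;
* analysis windows are half-open ``[start, stop)`` intervals in ms relative
  to an alignment event (Cue 1 = directional/choice cue, Cue 2 = go signal);
* trial tables are plain :class:`pandas.DataFrame` objects with the column
  set in :data:`TRIAL_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("Free", "Instructed", "Control")
DIRECTIONS = ("L", "R")

#: canonical trial-table columns (times in ms unless the name says otherwise;
#: ``cue1_onset``/``cue2_onset`` are sample indices into the recording)
TRIAL_COLUMNS = (
    "trial",
    "condition",
    "direction",
    "cue1_onset",
    "delay_ms",
    "cue2_onset",
    "saccade_latency_ms",
    "included",
)


def ms_to_samples(ms: float | np.ndarray, sampling_rate: float):
    """Convert milliseconds to an integer sample count at ``sampling_rate``."""
    out = np.round(np.asarray(ms) * sampling_rate / 1000.0).astype(np.int64)
    return out if out.ndim else int(out)


def samples_to_ms(samples: float | np.ndarray, sampling_rate: float):
    """Convert sample indices/counts to milliseconds."""
    return np.asarray(samples, dtype=float) * 1000.0 / sampling_rate


@dataclass
class Recording:
    """A continuous multichannel recording.

    Parameters
    ----------
    participant_id : str
        Label of the participant (or simulated participant).
    channel_labels : sequence of str
        One label per row of ``signal``.
    signal : ndarray, shape (n_channels, n_samples)
        Amplitude in arbitrary units.
    sampling_rate : float
        Sampling frequency in Hz (SEEG default: 1024 Hz).
    """

    participant_id: str
    channel_labels: Sequence[str]
    signal: np.ndarray
    sampling_rate: float = 1024.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.channel_labels = list(self.channel_labels)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the signal row for ``label``."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.signal[idx]


def empty_trial_table() -> pd.DataFrame:
    """An empty trial table with the canonical columns and dtypes."""
    df = pd.DataFrame(
        {
            "trial": pd.Series(dtype=np.int64),
            "condition": pd.Series(dtype=object),
            "direction": pd.Series(dtype=object),
            "cue1_onset": pd.Series(dtype=np.int64),
            "delay_ms": pd.Series(dtype=float),
            "cue2_onset": pd.Series(dtype=np.int64),
            "saccade_latency_ms": pd.Series(dtype=float),
            "included": pd.Series(dtype=bool),
        }
    )
    return df


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check the canonical column set and categorical values."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    bad = set(trials["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    bad = set(trials["direction"].dropna()) - set(DIRECTIONS)
    if bad:
        raise ValueError(f"unknown directions: {sorted(bad)}")
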