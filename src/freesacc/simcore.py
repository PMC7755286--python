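"""Synthetic SEEG / EOG generator for the delayed free-choice saccade task.

The generator emulates the statistical structure the downstream analysis
assumes: three interleaved trial types (Free, Instructed, Control) at equal
probability, a 250 ms central cue, a variable delay of 3,750 / 5,750 /
7,750 ms, a go signal, and condition x site-specific high-gamma (HG,
60-140 Hz) envelope responses riding on a 1/f broadband background.

Each channel is a sum of

* 1/f-shaped broadband noise (power exponent configurable),
* band-limited noise components ("oscillations"/carriers) per configured
  band, normalized to unit RMS and scaled by their amplitude,

and effects are injected **multiplicatively on the band-limited carrier**
of the effect's band: the carrier is scaled by ``1 + a * g(t)`` where
``g`` is the effect shape (transient Gaussian bump, smoothed sustained
plateau, delay-spanning persistent plateau, or go-locked execution
response) and ``a`` the relative amplitude.  At high SNR the
baseline-normalized envelope recovered downstream equals ``a`` at the
effect peak, which is what makes the generator usable as a
parameter-recovery oracle.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; the (Recording, TrialTable, GroundTruth)
triple is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    CONDITIONS,
    Recording,
    empty_trial_table,
    ms_to_samples,
    validate_trial_table,
)
from .spectral import BandDef, HG, fir_bandpass

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "GroundTruth",
    "SimulationConfig",
    "build_trial_schedule",
    "synthesize_recording",
    "synthesize_eog",
    "write_recording",
    "read_recording",
    "write_trial_table",
    "read_trial_table",
    "write_ground_truth",
]

EFFECT_SHAPES = ("transient", "sustained", "persistent", "execution")


@dataclass(frozen=True)
class EffectSpec:
    """A condition-specific band-envelope modulation on one or more sites.

    ``relative_amplitude`` is the peak multiplicative envelope change as a
    fraction of baseline (+0.39 = +39%).  ``onset_ms``/``peak_latency_ms``/
    ``duration_ms`` are relative to the alignment event (``cue1`` or
    ``cue2``).  Shapes: ``transient`` is a Gaussian bump centered at
    ``peak_latency_ms`` with sigma = duration/4; ``sustained`` is a
    raised-cosine-edged plateau from ``onset_ms`` lasting ``duration_ms``;
    ``persistent`` spans from ``onset_ms`` to the go signal regardless of
    the delay length; ``execution`` is a go-locked ramp+plateau whose
    per-trial onset follows the trial's saccade latency (plus jitter) when
    latencies are available.
    """

    conditions: tuple[str, ...]
    band: BandDef = HG
    shape: str = "transient"
    onset_ms: float = 0.0
    peak_latency_ms: float = 475.0
    duration_ms: float = 600.0
    relative_amplitude: float = 0.39
    alignment: str = "cue1"
    ramp_ms: float = 100.0

    def __post_init__(self):
        if self.shape not in EFFECT_SHAPES:
            raise ValueError(f"unknown effect shape {self.shape!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.relative_amplitude <= -1:
            raise ValueError("relative amplitude must exceed -1")
        if self.alignment not in ("cue1", "cue2"):
            raise ValueError("alignment must be 'cue1' or 'cue2'")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")


@dataclass(frozen=True)
class NoiseSpec:
    """Background model: 1/f broadband noise plus band-limited components.

    ``band_components`` are (band, RMS amplitude) pairs of filtered-noise
    "oscillations"; the component matching an effect's band doubles as the
    carrier that the effect modulates.  ``one_over_f_exponent`` is the
    power-spectral exponent beta in ``S(f) ~ 1/f**beta``.
    """

    one_over_f_exponent: float = 1.0
    broadband_scale: float = 1.0
    band_components: tuple[tuple[BandDef, float], ...] = (
        (BandDef("alpha", 8, 15), 0.5),
        (HG, 0.5),
    )

    def __post_init__(self):
        if any(a < 0 for _, a in self.band_components):
            raise ValueError("component amplitudes must be non-negative")
        if self.broadband_scale < 0:
            raise ValueError("broadband scale must be non-negative")


@dataclass
class GroundTruth:
    """Injected parameters, for parameter-recovery tests.

    ``hg_onset_ms`` holds the true per-trial onset (ms after Cue 2) of the
    go-locked execution response where one was injected, NaN otherwise.
    """

    effect_map: dict[str, list[EffectSpec]]
    hg_onset_ms: np.ndarray
    saccade_latency_ms: np.ndarray
    delay_artifact: np.ndarray


def _default_effects() -> dict[int, tuple[EffectSpec, ...]]:
    """Default effect map echoing the reported HG dynamics.

    Five of eight channels carry effects: four respond only during the
    early delay (Instructed: transient +39% peaking 475 ms after Cue 1;
    Free: sustained +24% plateau, measured peak near 812 ms) and one is
    persistent in the Free condition through the whole delay, so that the
    early/late conjunction keeps early-only sites clearly more numerous
    than early-and-late sites.  Channels 0-4 also carry a go-locked
    execution response in all conditions, tied to saccade latency.
    """
    instructed = EffectSpec(
        conditions=("Instructed",),
        shape="transient",
        peak_latency_ms=475.0,
        duration_ms=600.0,
        relative_amplitude=0.39,
    )
    free = EffectSpec(
        conditions=("Free",),
        shape="sustained",
        onset_ms=400.0,
        peak_latency_ms=812.0,
        duration_ms=1100.0,
        relative_amplitude=0.24,
    )
    free_persistent = EffectSpec(
        conditions=("Free",),
        shape="persistent",
        onset_ms=400.0,
        peak_latency_ms=812.0,
        duration_ms=3000.0,
        relative_amplitude=0.24,
    )
    execution = EffectSpec(
        conditions=CONDITIONS,
        shape="execution",
        alignment="cue2",
        onset_ms=300.0,
        peak_latency_ms=400.0,
        duration_ms=300.0,
        relative_amplitude=0.8,
        ramp_ms=20.0,
    )
    mapping: dict[int, tuple[EffectSpec, ...]] = {
        ch: (instructed, free, execution) for ch in range(4)
    }
    mapping[4] = (instructed, free_persistent, execution)
    return mapping


@dataclass
class SimulationConfig:
    """Study-condition parameters for one simulated participant.

    Defaults follow the task design: equal (1/3) condition probabilities,
    delays of 3,750/5,750/7,750 ms, a 250 ms cue, a 1,500 ms intertrial
    interval, and per-condition saccade-latency distributions of
    466 +/- 66 ms (Control), 334 +/- 36 ms (Free) and 321 +/- 33 ms
    (Instructed).  ``exclusion_fraction`` injects spontaneous delay-period
    eye movements into that fraction of trials so that behavioral
    filtering retains ~75% by default.
    """

    n_participants: int = 4
    n_channels: int = 8
    n_trials: int = 90
    condition_probs: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 / 3.0 for c in CONDITIONS}
    )
    delays_ms: tuple[float, ...] = (3750.0, 5750.0, 7750.0)
    cue_duration_ms: float = 250.0
    intertrial_ms: float = 1500.0
    fixation_ms: float = 500.0
    post_go_ms: float = 2500.0
    sampling_rate: float = 1024.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    effects: Mapping[int, Sequence[EffectSpec]] = field(default_factory=_default_effects)
    rt_ms: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Control": (466.0, 66.0),
            "Free": (334.0, 36.0),
            "Instructed": (321.0, 33.0),
        }
    )
    exclusion_fraction: float = 0.25
    hg_onset_jitter_sd_ms: float = 30.0
    eog_noise_sd: float = 0.02
    eog_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        total = float(sum(self.condition_probs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError("condition probabilities must sum to 1")
        if not self.delays_ms:
            raise ValueError("delay set must not be empty")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        for cond, (mean, _sd) in self.rt_ms.items():
            if mean < 0:
                raise ValueError(f"negative RT mean for {cond}")
        for ch in self.effects:
            if not 0 <= ch < self.n_channels:
                raise ValueError(f"effect channel {ch} out of range")

    @property
    def trial_length_ms(self) -> float:
        """Worst-case on-screen span of one trial, go signal included."""
        return (
            self.fixation_ms
            + self.cue_duration_ms
            + max(self.delays_ms)
            + self.post_go_ms
            + self.intertrial_ms
        )


# ---------------------------------------------------------------------------
# schedule


def build_trial_schedule(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Lay out a pseudorandomly interleaved trial sequence on a sample clock.

    Cue 2 onset is exactly ``cue_duration + delay`` after Cue 1 in samples.
    Free-trial directions are drawn i.i.d. fair, so the trial-history null
    holds by construction.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_trials
    if n == 0:
        return empty_trial_table()
    conds = list(config.condition_probs)
    probs = np.array([config.condition_probs[c] for c in conds], dtype=float)
    condition = rng.choice(conds, size=n, p=probs)
    direction = rng.choice(["L", "R"], size=n)
    delay = rng.choice(np.asarray(config.delays_ms, dtype=float), size=n)

    fs = config.sampling_rate
    margin = ms_to_samples(1000.0, fs)  # head room for filter edges
    cue1 = np.empty(n, dtype=np.int64)
    cue2 = np.empty(n, dtype=np.int64)
    t = margin + ms_to_samples(config.fixation_ms, fs)
    for i in range(n):
        cue1[i] = t
        cue2[i] = t + ms_to_samples(config.cue_duration_ms + delay[i], fs)
        t = cue2[i] + ms_to_samples(
            config.post_go_ms + config.intertrial_ms + config.fixation_ms, fs
        )
    df = pd.DataFrame(
        {
            "trial": np.arange(n, dtype=np.int64),
            "condition": condition,
            "direction": direction,
            "cue1_onset": cue1,
            "delay_ms": delay,
            "cue2_onset": cue2,
            "saccade_latency_ms": np.full(n, np.nan),
            "included": np.ones(n, dtype=bool),
        }
    )
    validate_trial_table(df)
    return df


def _schedule_duration_samples(schedule: pd.DataFrame, config: SimulationConfig) -> int:
    fs = config.sampling_rate
    if len(schedule) == 0:
        return ms_to_samples(2000.0, fs)
    return int(schedule["cue2_onset"].max()) + ms_to_samples(
        config.post_go_ms + config.intertrial_ms + 1000.0, fs
    )


# ---------------------------------------------------------------------------
# effect shapes


def _shape_gain(
    effect: EffectSpec,
    t_ms: np.ndarray,
    delay_ms: float,
    exec_onset_ms: float | None,
) -> np.ndarray:
    """Unit-amplitude effect time course g(t) on ``t_ms`` (ms rel. alignment)."""

    def _plateau(on, off, ramp):
        g = np.zeros_like(t_ms)
        ramp = max(ramp, 1e-9)
        up = (t_ms >= on) & (t_ms < on + ramp)
        g[up] = 0.5 * (1 - np.cos(np.pi * (t_ms[up] - on) / ramp))
        g[(t_ms >= on + ramp) & (t_ms < off - ramp)] = 1.0
        down = (t_ms >= off - ramp) & (t_ms < off)
        g[down] = 0.5 * (1 - np.cos(np.pi * (off - t_ms[down]) / ramp))
        return g

    if effect.shape == "transient":
        sigma = effect.duration_ms / 4.0
        return np.exp(-0.5 * ((t_ms - effect.peak_latency_ms) / sigma) ** 2)
    if effect.shape == "sustained":
        return _plateau(
            effect.onset_ms, effect.onset_ms + effect.duration_ms, effect.ramp_ms
        )
    if effect.shape == "persistent":
        # plateau from onset up to the go signal, whatever the delay
        off = effect.duration_ms if delay_ms is None else delay_ms + 250.0
        return _plateau(effect.onset_ms, off, effect.ramp_ms)
    # execution: go-locked, onset tied to the trial's saccade latency
    on = effect.onset_ms if exec_onset_ms is None else exec_onset_ms
    return _plateau(on, on + effect.duration_ms, effect.ramp_ms)


def _one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / max(x.std(), np.finfo(float).tiny)


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: BandDef
) -> np.ndarray:
    """Band-limited Gaussian noise, unit RMS."""
    taps = fir_bandpass(band, fs)
    x = sps.filtfilt(taps, 1.0, rng.standard_normal(n))
    return x / max(x.std(), np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# recording synthesis


def synthesize_recording(
    schedule: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    participant_id: str = "sim",
) -> tuple[Recording, GroundTruth]:
    """Generate the multichannel LFP-like recording and its ground truth.

    Background per channel = 1/f noise * ``broadband_scale`` plus the
    configured band-limited components; channels listed in
    ``config.effects`` have the matching band component multiplied by
    ``1 + sum_e a_e * g_e(t)`` within each trial of the effect's condition.

    Execution-shape effects tie their per-trial onset to the saccade
    latency already present in ``schedule`` (run :func:`synthesize_eog`
    first); when latencies are missing the fixed ``onset_ms`` is used.
    """
    if seed is None:
        seed = config.seed
    validate_trial_table(schedule)
    fs = config.sampling_rate
    n_samples = _schedule_duration_samples(schedule, config)
    if len(schedule) and int(schedule["cue1_onset"].min()) < 0:
        raise ValueError("schedule does not fit in the synthesized duration")

    ss = np.random.SeedSequence([seed, 1])
    child = ss.spawn(config.n_channels + 1)
    rng_common = np.random.default_rng(child[-1])

    n_trials = len(schedule)
    hg_onsets = np.full(n_trials, np.nan)
    latencies = schedule["saccade_latency_ms"].to_numpy(dtype=float)
    has_exec = any(
        e.shape == "execution" for specs in config.effects.values() for e in specs
    )
    if has_exec:
        jitter = rng_common.normal(0.0, config.hg_onset_jitter_sd_ms, size=n_trials)
        base = np.where(np.isfinite(latencies), latencies, np.nan)
        hg_onsets = np.where(np.isfinite(base), np.maximum(base + jitter, 0.0), np.nan)

    comp_bands = {b.name: (b, a) for b, a in config.noise.band_components}
    # every effect band needs a carrier component
    for specs in config.effects.values():
        for e in specs:
            comp_bands.setdefault(e.band.name, (e.band, 0.5))

    labels = [f"ch{c}" for c in range(config.n_channels)]
    signal = np.zeros((config.n_channels, n_samples))
    for ch in range(config.n_channels):
        rng = np.random.default_rng(child[ch])
        x = np.zeros(n_samples)
        if config.noise.broadband_scale > 0:
            x += config.noise.broadband_scale * _one_over_f_noise(
                rng, n_samples, fs, config.noise.one_over_f_exponent
            )
        effects = list(config.effects.get(ch, ()))
        for bname, (band, amp) in comp_bands.items():
            band_fx = [e for e in effects if e.band.name == bname]
            if amp == 0 and not band_fx:
                continue
            carrier = _band_noise(rng, n_samples, fs, band)
            if band_fx:
                gain = np.ones(n_samples)
                for e in band_fx:
                    _apply_effect_gain(gain, e, schedule, config, hg_onsets)
                carrier = carrier * gain
            x += amp * carrier
        signal[ch] = x

    gt = GroundTruth(
        effect_map={labels[ch]: list(specs) for ch, specs in config.effects.items()},
        hg_onset_ms=hg_onsets,
        saccade_latency_ms=latencies.copy(),
        delay_artifact=(
            schedule["true_delay_artifact"].to_numpy(dtype=bool)
            if "true_delay_artifact" in schedule
            else np.zeros(n_trials, dtype=bool)
        ),
    )
    rec = Recording(participant_id, labels, signal, fs)
    return rec, gt


def _apply_effect_gain(
    gain: np.ndarray,
    effect: EffectSpec,
    schedule: pd.DataFrame,
    config: SimulationConfig,
    hg_onsets: np.ndarray,
) -> None:
    """Add ``a * g(t)`` into the multiplicative gain around each matching trial."""
    fs = config.sampling_rate
    onset_col = "cue1_onset" if effect.alignment == "cue1" else "cue2_onset"
    if effect.shape == "transient":
        # support truncated at +/- 4 sigma = +/- duration around the peak
        lo = effect.peak_latency_ms - effect.duration_ms
        hi = effect.peak_latency_ms + effect.duration_ms
    elif effect.shape == "persistent":
        lo, hi = effect.onset_ms - 50.0, max(config.delays_ms) + 300.0
    elif effect.shape == "execution":
        lo = -50.0
        hi = effect.onset_ms + 2000.0 + effect.duration_ms
    else:
        lo = effect.onset_ms - 50.0
        hi = effect.onset_ms + effect.duration_ms + 50.0
    n_rel = ms_to_samples(hi - lo, fs)
    t_ms = lo + np.arange(n_rel) * 1000.0 / fs
    for row in schedule.itertuples():
        if row.condition not in effect.conditions:
            continue
        align = getattr(row, onset_col)
        i0 = align + ms_to_samples(lo, fs)
        exec_on = None
        if effect.shape == "execution" and np.isfinite(hg_onsets[row.Index]):
            exec_on = float(hg_onsets[row.Index])
        g = _shape_gain(effect, t_ms, float(row.delay_ms), exec_on)
        i1 = min(i0 + n_rel, gain.shape[0])
        if i0 < 0 or i1 <= i0:
            continue
        gain[i0:i1] += effect.relative_amplitude * g[: i1 - i0]


# ---------------------------------------------------------------------------
# EOG synthesis


def synthesize_eog(
    schedule: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    participant_id: str = "sim",
) -> tuple[Recording, pd.DataFrame]:
    """Two-channel EOG (horizontal, vertical) with go-locked saccades.

    Per included trial a ramp-then-plateau horizontal deflection starts at
    ``cue2 + latency``; the deflection sign encodes the direction (L
    negative, R positive).  Latencies are drawn from the condition-specific
    normal distributions, truncated at zero.  A configured fraction of
    trials additionally receives a spontaneous delay-period deflection
    (away and back), emulating fixation breaks that behavioral screening
    must exclude; these trials are marked in the returned table's
    ``true_delay_artifact`` column.

    Returns the EOG recording and a copy of ``schedule`` with
    ``saccade_latency_ms`` (and the artifact marker) filled in.
    """
    if seed is None:
        seed = config.seed
    validate_trial_table(schedule)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    fs = config.sampling_rate
    n_samples = _schedule_duration_samples(schedule, config)
    n = len(schedule)

    out = schedule.copy()
    heog = rng.normal(0.0, config.eog_noise_sd, size=n_samples)
    veog = rng.normal(0.0, config.eog_noise_sd, size=n_samples)

    latencies = np.empty(n)
    artifact = rng.random(n) < config.exclusion_fraction
    ramp = ms_to_samples(40.0, fs)
    hold = ms_to_samples(500.0, fs)
    for i, row in enumerate(schedule.itertuples()):
        mean, sd = config.rt_ms[row.condition]
        lat = rng.normal(mean, sd)
        while lat <= 0:  # truncate at zero
            lat = rng.normal(mean, sd)
        latencies[i] = lat
        sign = 1.0 if row.direction == "R" else -1.0
        start = row.cue2_onset + ms_to_samples(lat, fs)
        _deflect(heog, start, ramp, hold, sign * config.eog_amplitude)
        if artifact[i]:
            # spontaneous saccade somewhere in the middle of the delay
            frac = rng.uniform(0.25, 0.75)
            t0 = row.cue1_onset + int(
                ms_to_samples(config.cue_duration_ms + frac * row.delay_ms, fs)
            )
            s = rng.choice([-1.0, 1.0])
            _deflect(heog, t0, ramp, ms_to_samples(300.0, fs), s * config.eog_amplitude)
            _deflect(heog, t0 + ms_to_samples(400.0, fs), ramp,
                     ms_to_samples(300.0, fs), -s * config.eog_amplitude)

    out["saccade_latency_ms"] = latencies
    out["true_delay_artifact"] = artifact
    rec = Recording(
        participant_id, ["HEOG", "VEOG"], np.vstack([heog, veog]), fs
    )
    return rec, out


def _deflect(trace: np.ndarray, start: int, ramp: int, hold: int, amp: float) -> None:
    """Add a ramp-plateau-return deflection in place (clipped to bounds)."""
    n = trace.shape[0]
    shape = np.concatenate(
        [
            np.linspace(0.0, 1.0, ramp, endpoint=False),
            np.ones(hold),
            np.linspace(1.0, 0.0, ramp, endpoint=False),
        ]
    )
    i0 = max(start, 0)
    i1 = min(start + len(shape), n)
    if i1 > i0:
        trace[i0:i1] += amp * shape[i0 - start : i1 - start]


# ---------------------------------------------------------------------------
# persistence


def write_recording(path, recording: Recording) -> None:
    """Write a recording to the documented HDF5 container.

    Layout: ``/signal`` (channels x samples, float64), ``/fs`` (scalar Hz),
    ``/labels`` (UTF-8 strings), attribute ``participant_id``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=recording.signal, compression="gzip")
        f.create_dataset("fs", data=float(recording.sampling_rate))
        f.create_dataset(
            "labels", data=[s.encode() for s in recording.channel_labels]
        )
        f.attrs["participant_id"] = recording.participant_id


def read_recording(path) -> Recording:
    """Read a recording from the HDF5 container (or an EDF file via mne)."""
    p = str(path)
    if p.lower().endswith(".edf"):
        import mne  # optional dependency, only for EDF input

        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
        return Recording(
            participant_id=p,
            channel_labels=list(raw.ch_names),
            signal=raw.get_data(),
            sampling_rate=float(raw.info["sfreq"]),
        )
    with h5py.File(p, "r") as f:
        return Recording(
            participant_id=str(f.attrs.get("participant_id", "unknown")),
            channel_labels=[s.decode() for s in f["labels"][()]],
            signal=f["signal"][()],
            sampling_rate=float(f["fs"][()]),
        )


def write_trial_table(path, trials: pd.DataFrame, sampling_rate: float) -> None:
    """Write a trial table as TSV (onsets in seconds, BIDS-events-like)."""
    out = pd.DataFrame(
        {
            "trial": trials["trial"],
            "condition": trials["condition"],
            "direction": trials["direction"],
            "cue1_onset_s": trials["cue1_onset"] / sampling_rate,
            "delay_ms": trials["delay_ms"],
            "cue2_onset_s": trials["cue2_onset"] / sampling_rate,
            "saccade_latency_ms": trials["saccade_latency_ms"],
            "included": trials["included"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trial_table(path, sampling_rate: float) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    df = pd.DataFrame(
        {
            "trial": tab["trial"].astype(np.int64),
            "condition": tab["condition"],
            "direction": tab["direction"],
            "cue1_onset": np.round(tab["cue1_onset_s"] * sampling_rate).astype(np.int64),
            "delay_ms": tab["delay_ms"].astype(float),
            "cue2_onset": np.round(tab["cue2_onset_s"] * sampling_rate).astype(np.int64),
            "saccade_latency_ms": tab["saccade_latency_ms"].astype(float),
            "included": tab["included"].astype(bool),
        }
    )
    validate_trial_table(df)
    return df


def write_ground_truth(path, gt: GroundTruth) -> None:
    """Serialize ground truth to JSON (EffectSpecs as plain dicts)."""

    def _spec(e: EffectSpec):
        d = asdict(e)
        d["band"] = {"name": e.band.name, "f_low": e.band.f_low, "f_high": e.band.f_high}
        return d

    payload = {
        "effect_map": {
            ch: [_spec(e) for e in specs] for ch, specs in gt.effect_map.items()
        },
        "hg_onset_ms": [None if not np.isfinite(v) else float(v) for v in gt.hg_onset_ms],
        "saccade_latency_ms": [
            None if not np.isfinite(v) else float(v) for v in gt.saccade_latency_ms
        ],
        "delay_artifact": gt.delay_artifact.astype(bool).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
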