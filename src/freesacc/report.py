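"""Contrast direction masks, conjunction mapping, pipeline orchestration.

The conjunction logic identifies sites whose HG activity is significantly
*stronger* for one condition in two contrasts at once (e.g., Free > Control
AND Free > Instructed) within a time window, then partitions sites by
whether the conjunction holds early in the delay ([0, 2000) ms after
Cue 1), late ([-2000, 0) ms before Cue 2), or both — persistent-delay
sites land in "both".  ``run_pipeline`` chains simulate -> behavior ->
features -> decode -> dynamics -> conjunction for several simulated
participants from a TOML config, fully deterministic under its seed.
"""

from __future__ import annotations

import json
import logging
import shutil
import sys
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import behavior, decode, dynamics, simcore, spectral

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastMask",
    "ConjunctionResult",
    "contrast_masks",
    "conjunction",
    "early_late_partition",
    "run_pipeline",
    "load_config",
]


@dataclass
class ContrastMask:
    """Per-site significance and effect direction for one contrast.

    ``sign`` is the sign of mean power difference (condition A - B) over
    the window; it is meaningful only where ``significant`` is set.
    """

    contrast: tuple[str, str]
    window_ms: tuple[float, float]
    alignment: str
    sites: list[str]
    significant: np.ndarray
    sign: np.ndarray

    def significant_sites(self, required_sign: int | None = None) -> set[str]:
        keep = self.significant.copy()
        if required_sign is not None:
            keep &= self.sign == required_sign
        return {s for s, k in zip(self.sites, keep) if k}


@dataclass
class ConjunctionResult:
    """Early/late partition of conjunction sites (disjoint sets)."""

    early_only: set[str]
    late_only: set[str]
    both: set[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "early_only": sorted(self.early_only),
            "late_only": sorted(self.late_only),
            "both": sorted(self.both),
        }


def contrast_masks(
    result: decode.DecodingResult,
    tensor: spectral.PowerTensor,
    conditions: Sequence[str],
    contrast: tuple[str, str],
    window_ms: tuple[float, float],
    band: str = "HG",
) -> ContrastMask:
    """Site-level significance + direction for ``contrast`` within a window.

    A site is flagged when any of its (band, window) cells inside the
    window is significant in ``result``; its direction is the sign of the
    mean power difference (A - B) across trials and windows.
    """
    if result.sig_mask is None:
        raise ValueError("decoding result carries no significance mask")
    if list(result.sites) != list(tensor.sites):
        raise ValueError("result and tensor disagree on sites")
    conditions = np.asarray(conditions)
    if len(conditions) != tensor.values.shape[2]:
        raise ValueError("conditions do not match the tensor's trial axis")
    win = tensor.centers_in(*window_ms)
    if win.size == 0:
        raise ValueError("window contains no grid points")
    bi = tensor.band_index(band)
    a, b = contrast
    am = conditions == a
    bm = conditions == b
    vals = tensor.values[:, bi][:, :, win]  # (site, trial, win)
    mean_a = vals[:, am].mean(axis=(1, 2))
    mean_b = vals[:, bm].mean(axis=(1, 2))
    rbi = list(result.bands).index(band)
    rwin = np.nonzero(
        (result.window_centers_ms >= window_ms[0])
        & (result.window_centers_ms < window_ms[1])
    )[0]
    sig = result.sig_mask[:, rbi][:, rwin].any(axis=1)
    return ContrastMask(
        contrast=contrast,
        window_ms=window_ms,
        alignment=tensor.alignment,
        sites=list(tensor.sites),
        significant=sig,
        sign=np.sign(mean_a - mean_b).astype(np.int8),
    )


def conjunction(
    mask_a: ContrastMask,
    mask_b: ContrastMask,
    required_signs: tuple[int, int] = (1, 1),
) -> set[str]:
    """Sites significant in both masks with the required directions."""
    if mask_a.sites != mask_b.sites:
        raise ValueError("masks are defined on different site universes")
    return mask_a.significant_sites(required_signs[0]) & mask_b.significant_sites(
        required_signs[1]
    )


def early_late_partition(
    conj_early: set[str], conj_late: set[str]
) -> ConjunctionResult:
    """Partition conjunction sites into early-only / late-only / both."""
    both = conj_early & conj_late
    return ConjunctionResult(
        early_only=conj_early - both,
        late_only=conj_late - both,
        both=both,
    )


# ---------------------------------------------------------------------------
# configuration

_DEFAULT_CONFIG: dict = {
    "simulation": {
        "n_participants": 4,
        "n_trials": 90,
        "n_channels": 8,
        "sampling_rate": 1024.0,
        "broadband_scale": 1.0,
        "delays_ms": [3750.0, 5750.0, 7750.0],
        "seed": 0,
    },
    "features": {
        "bands": [b.name for b in spectral.DEFAULT_BANDS],
        "window_ms": 400.0,
        "step_ms": 50.0,
        "delay_span_ms": [-500.0, 3000.0],
        "late_span_ms": [-2000.0, 0.0],
    },
    "decoding": {"n_folds": 10, "n_perm": 100, "alpha": 0.01},
    "conjunction": {
        "early_window_ms": [0.0, 2000.0],
        "late_window_ms": [-2000.0, 0.0],
        "band": "HG",
    },
    "behavior": {"rt_max_ms": 750.0, "n_boot": 100, "history_n_perm": 1000,
                 "history_alpha": 0.001},
}

_BAND_MAP = {b.name: b for b in spectral.DEFAULT_BANDS}


def load_config(path) -> dict:
    """Load and schema-check a TOML pipeline config.

    Unknown sections or keys, and invalid band names, raise a
    ``ValueError`` naming the offending field.  Missing keys take the
    documented defaults.
    """
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    cfg = {k: dict(v) for k, v in _DEFAULT_CONFIG.items()}
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(values, dict):
            raise ValueError(f"config section [{section}] must be a table")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ValueError(f"unknown config field {section}.{key}")
            cfg[section][key] = val
    for name in cfg["features"]["bands"]:
        if name not in _BAND_MAP:
            raise ValueError(f"features.bands: unknown band {name!r}")
    if cfg["conjunction"]["band"] not in cfg["features"]["bands"]:
        raise ValueError("conjunction.band must be among features.bands")
    return cfg


# ---------------------------------------------------------------------------
# pipeline


def _simulate_participant(cfg: dict, pid: int, seed: int):
    sim = cfg["simulation"]
    config = simcore.SimulationConfig(
        n_participants=sim["n_participants"],
        n_trials=sim["n_trials"],
        n_channels=sim["n_channels"],
        sampling_rate=sim["sampling_rate"],
        delays_ms=tuple(float(d) for d in sim["delays_ms"]),
        noise=simcore.NoiseSpec(broadband_scale=sim["broadband_scale"]),
        seed=seed,
    )
    schedule = simcore.build_trial_schedule(config)
    eog, schedule = simcore.synthesize_eog(schedule, config, participant_id=f"P{pid}")
    rec, gt = simcore.synthesize_recording(
        schedule, config, participant_id=f"P{pid}"
    )
    return config, schedule, eog, rec, gt


def _decode_contrast(tensor, conditions, pair, dec_cfg, seed):
    keep = np.isin(conditions, pair)
    sub = replace(tensor, values=tensor.values[:, :, keep, :],
                  trial_index=tensor.trial_index[keep])
    return (
        decode.permutation_maxstat(
            sub,
            conditions[keep],
            n_perm=dec_cfg["n_perm"],
            alpha=dec_cfg["alpha"],
            n_folds=dec_cfg["n_folds"],
            seed=seed,
        ),
        sub,
        conditions[keep],
    )


def run_pipeline(config_path, out_dir, seed: int | None = None) -> Path:
    """Execute the full analysis chain on simulated participants.

    simulate -> EOG behavior screening -> band-envelope features ->
    per-contrast max-statistics decoding -> temporal dynamics ->
    early/late conjunction -> group statistics.  All TSV/JSON outputs and
    a run log (seeds, versions) are written under ``out_dir``; the run is
    deterministic under the config seed (or the ``seed`` override).
    Partial outputs are removed on failure.
    """
    cfg = load_config(config_path)
    if seed is not None:
        cfg["simulation"]["seed"] = int(seed)
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline(cfg, out)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _run_pipeline(cfg: dict, out: Path) -> Path:
    sim, feat = cfg["simulation"], cfg["features"]
    dec, conj_cfg, beh = cfg["decoding"], cfg["conjunction"], cfg["behavior"]
    bands = [_BAND_MAP[n] for n in feat["bands"]]
    base = np.random.SeedSequence(sim["seed"])
    part_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(sim["n_participants"])]

    group_rows = []
    per_part_metrics: dict[str, dict[str, list[float]]] = {}
    for pid in range(sim["n_participants"]):
        pdir = out / f"participant_{pid}"
        pdir.mkdir(exist_ok=True)
        pseed = part_seeds[pid]
        config, schedule, eog, rec, gt = _simulate_participant(cfg, pid, pseed)
        fs = config.sampling_rate

        # behavioral screening from the EOG traces
        trials = behavior.detect_trial_latencies(eog, schedule)
        flags = behavior.detect_delay_artifacts(eog, trials)
        trials = behavior.apply_trial_exclusions(trials, beh["rt_max_ms"], flags)
        simcore.write_trial_table(pdir / "trials.tsv", trials, fs)
        rt = behavior.compare_reaction_times(trials, n_boot=beh["n_boot"], seed=pseed)
        rt.per_condition.to_csv(pdir / "rt_stats.tsv", sep="\t", index=False,
                                float_format="%.6g")
        rt.to_frame().to_csv(pdir / "rt_pairwise.tsv", sep="\t", index=False,
                             float_format="%.6g")
        free = trials[trials["condition"] == "Free"]
        if len(free) >= 3:
            hist = behavior.trial_history_test(
                free["direction"].tolist(), n_perm=beh["history_n_perm"],
                alpha=beh["history_alpha"], seed=pseed,
            )
            with open(pdir / "history.json", "w") as fh:
                json.dump(
                    {"probs": hist.probs, "lower": hist.lower,
                     "upper": hist.upper,
                     "significant": hist.significant,
                     "n_perm": hist.n_perm, "alpha": hist.alpha},
                    fh, indent=1,
                )

        # features
        delay_tensor = spectral.epoch_features(
            rec, trials, bands, "cue1", tuple(feat["delay_span_ms"]),
            feat["window_ms"], feat["step_ms"],
        )
        late_tensor = spectral.epoch_features(
            rec, trials, bands, "cue2", tuple(feat["late_span_ms"]),
            feat["window_ms"], feat["step_ms"],
        )
        conditions = trials.loc[trials["included"], "condition"].to_numpy()

        # decoding per contrast
        results, tensors, conds = {}, {}, {}
        pairs = [("Free", "Instructed"), ("Free", "Control"), ("Instructed", "Control")]
        for k, pair in enumerate(pairs):
            res, sub, c = _decode_contrast(delay_tensor, conditions, pair, dec,
                                           pseed + 11 * k)
            results[pair] = res
            tensors[pair] = sub
            conds[pair] = c
            res.to_frame().to_csv(
                pdir / f"decoding_{pair[0].lower()}_vs_{pair[1].lower()}.tsv",
                sep="\t", index=False, float_format="%.6g",
            )
        late_results = {}
        for k, pair in enumerate([("Free", "Control"), ("Free", "Instructed")]):
            res, sub, c = _decode_contrast(late_tensor, conditions, pair, dec,
                                           pseed + 101 + 11 * k)
            late_results[pair] = (res, sub, c)

        # dynamics: peak metrics on normalized HG + onset/duration vs Control
        norm = spectral.baseline_normalize(delay_tensor)
        hg_bi = norm.band_index(conj_cfg["band"])
        fi_res = results[("Free", "Instructed")]
        sig_sites = [
            s for i, s in enumerate(norm.sites)
            if fi_res.sig_mask[i, hg_bi].any()
        ]
        dyn_rows = []
        metrics = {"peak_latency_instructed": [], "peak_latency_free": [],
                   "onset_instructed": [], "onset_free": [],
                   "duration_instructed": [], "duration_free": []}
        for site in sig_sites:
            si = norm.site_index(site)
            row = {"participant": pid, "site": site}
            for cond_name, key in (("Instructed", "instructed"), ("Free", "free")):
                cm = conditions == cond_name
                series = np.nanmean(norm.values[si, hg_bi][cm], axis=0)
                amp, lat = dynamics.peak_metrics(
                    series, norm.window_centers_ms, (0.0, feat["delay_span_ms"][1])
                )
                row[f"peak_rel_{key}"] = amp
                row[f"peak_latency_{key}_ms"] = lat
                metrics[f"peak_latency_{key}"].append(lat)
                sd = dynamics.decoding_onset_duration(
                    results[(cond_name, "Control")] if cond_name != "Free"
                    else results[("Free", "Control")],
                    site, conj_cfg["band"], (0.0, feat["delay_span_ms"][1]),
                )
                row[f"decode_onset_{key}_ms"] = sd.decoding_onset_ms
                row[f"decode_duration_{key}_ms"] = sd.decoding_duration_ms
                if sd.decoding_onset_ms is not None:
                    metrics[f"onset_{key}"].append(sd.decoding_onset_ms)
                metrics[f"duration_{key}"].append(sd.decoding_duration_ms)
            dyn_rows.append(row)
        pd.DataFrame(dyn_rows).to_csv(pdir / "dynamics.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        per_part_metrics[str(pid)] = {
            k: (float(np.mean(v)) if v else np.nan) for k, v in metrics.items()
        }

        # conjunction Free > Control AND Free > Instructed, early vs late
        early_w = tuple(conj_cfg["early_window_ms"])
        late_w = tuple(conj_cfg["late_window_ms"])
        m_fc = contrast_masks(results[("Free", "Control")], tensors[("Free", "Control")],
                              conds[("Free", "Control")], ("Free", "Control"),
                              early_w, conj_cfg["band"])
        m_fi = contrast_masks(fi_res, tensors[("Free", "Instructed")],
                              conds[("Free", "Instructed")], ("Free", "Instructed"),
                              early_w, conj_cfg["band"])
        conj_early = conjunction(m_fc, m_fi)
        res_fc_l, sub_fc_l, c_fc_l = late_results[("Free", "Control")]
        res_fi_l, sub_fi_l, c_fi_l = late_results[("Free", "Instructed")]
        lm_fc = contrast_masks(res_fc_l, sub_fc_l, c_fc_l, ("Free", "Control"),
                               late_w, conj_cfg["band"])
        lm_fi = contrast_masks(res_fi_l, sub_fi_l, c_fi_l, ("Free", "Instructed"),
                               late_w, conj_cfg["band"])
        conj_late = conjunction(lm_fc, lm_fi)
        part = early_late_partition(conj_early, conj_late)
        with open(pdir / "conjunction.json", "w") as fh:
            json.dump(part.as_dict(), fh, indent=1)
        group_rows.append({"participant": pid,
                           "n_sig_sites_free_vs_instructed": len(sig_sites),
                           "n_conj_early": len(conj_early),
                           "n_conj_late": len(conj_late)})

    # group statistics across participants (paired t on participant means)
    stats_rows = []
    if sim["n_participants"] >= 2:
        for name, (ka, kb) in {
            "peak_latency_instructed_vs_free": ("peak_latency_instructed",
                                                "peak_latency_free"),
            "onset_instructed_vs_free": ("onset_instructed", "onset_free"),
            "duration_free_vs_instructed": ("duration_free", "duration_instructed"),
        }.items():
            a = np.array([per_part_metrics[p][ka] for p in per_part_metrics])
            b = np.array([per_part_metrics[p][kb] for p in per_part_metrics])
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() >= 2:
                gs = dynamics.group_compare(a[ok], b[ok], paired=True)
                stats_rows.append({"comparison": name, "t": gs.t, "df": gs.df,
                                   "p": gs.p, "mean_a": gs.mean_a,
                                   "mean_b": gs.mean_b, "n": int(ok.sum())})
    pd.DataFrame(stats_rows).to_csv(out / "group_stats.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    pd.DataFrame(group_rows).to_csv(out / "participants.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "freesacc_version": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "base_seed": cfg["simulation"]["seed"],
                "participant_seeds": part_seeds,
                "config": cfg,
            },
            fh, indent=1,
        )
    return out
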