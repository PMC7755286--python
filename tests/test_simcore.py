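"""Trial scheduling, LFP/EOG synthesis, ground truth and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from freesacc import simcore, spectral
from freesacc.core import ms_to_samples
from freesacc.spectral import HG

FS = 512.0


def _cfg(**kw):
    kw.setdefault("sampling_rate", FS)
    kw.setdefault("delays_ms", (1750.0,))
    return simcore.SimulationConfig(**kw)


class TestSchedule:
    def test_cue2_timing_exact_in_samples(self):
        cfg = _cfg(n_trials=40, delays_ms=(3750.0, 5750.0, 7750.0))
        tab = simcore.build_trial_schedule(cfg, 3)
        for row in tab.itertuples():
            expected = ms_to_samples(250.0 + row.delay_ms, FS)
            assert row.cue2_onset - row.cue1_onset == expected

    def test_empty_schedule(self):
        tab = simcore.build_trial_schedule(_cfg(n_trials=0), 1)
        assert len(tab) == 0
        assert list(tab.columns) == list(simcore.empty_trial_table().columns)

    def test_same_seed_identical(self):
        cfg = _cfg(n_trials=30)
        a = simcore.build_trial_schedule(cfg, 7)
        b = simcore.build_trial_schedule(cfg, 7)
        pd.testing.assert_frame_equal(a, b)

    def test_condition_counts_within_binomial_band(self):
        tab = simcore.build_trial_schedule(_cfg(n_trials=90), 5)
        lo, hi = stats.binom.ppf([0.005, 0.995], 90, 1.0 / 3.0)
        for cond in ("Free", "Instructed", "Control"):
            assert lo <= (tab["condition"] == cond).sum() <= hi
        assert set(tab["delay_ms"]) <= {1750.0}

    def test_condition_delay_frequencies_chi2_calibration(self):
        # frequencies converge: chi-square GoF non-significant (alpha=0.01)
        # in at least 95% of seeded runs at n=900
        cfg = _cfg(n_trials=900, delays_ms=(3750.0, 5750.0, 7750.0))
        ok = 0
        n_runs = 40
        for seed in range(n_runs):
            tab = simcore.build_trial_schedule(cfg, 1000 + seed)
            counts = tab["condition"].value_counts().reindex(
                ["Free", "Instructed", "Control"], fill_value=0
            )
            _, p = stats.chisquare(counts)
            ok += p > 0.01
        assert ok >= int(0.95 * n_runs) - 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _cfg(condition_probs={"Free": 0.6, "Instructed": 0.6, "Control": 0.0})
        with pytest.raises(ValueError, match="delay set"):
            _cfg(delays_ms=())
        with pytest.raises(ValueError, match="out of range"):
            _cfg(n_channels=2, effects={5: ()})
        with pytest.raises(ValueError, match="negative RT"):
            _cfg(rt_ms={"Free": (-10.0, 5.0)})

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(n=st.integers(1, 60), seed=st.integers(0, 2**20))
    def test_values_drawn_from_declared_sets(self, n, seed):
        cfg = _cfg(n_trials=n, delays_ms=(3750.0, 5750.0))
        tab = simcore.build_trial_schedule(cfg, seed)
        assert set(tab["condition"]) <= {"Free", "Instructed", "Control"}
        assert set(tab["delay_ms"]) <= {3750.0, 5750.0}
        assert set(tab["direction"]) <= {"L", "R"}
        assert (np.diff(tab["cue1_onset"]) > 0).all()


class TestRecordingSynthesis:
    def test_zero_noise_no_effects_all_zero(self):
        cfg = _cfg(
            n_trials=5,
            n_channels=3,
            effects={},
            noise=simcore.NoiseSpec(broadband_scale=0.0, band_components=()),
        )
        tab = simcore.build_trial_schedule(cfg, 1)
        rec, _ = simcore.synthesize_recording(tab, cfg, 1)
        assert np.allclose(rec.signal, 0.0)

    def test_ground_truth_keys_match_effect_channels(self):
        cfg = _cfg(n_trials=5, n_channels=6)
        tab = simcore.build_trial_schedule(cfg, 1)
        _, gt = simcore.synthesize_recording(tab, cfg, 1)
        assert set(gt.effect_map) == {f"ch{c}" for c in cfg.effects}

    def test_bit_reproducible_under_seed(self):
        cfg = _cfg(n_trials=8)
        tab = simcore.build_trial_schedule(cfg, 9)
        eog_a, tab_a = simcore.synthesize_eog(tab, cfg, 9)
        eog_b, tab_b = simcore.synthesize_eog(tab, cfg, 9)
        rec_a, gt_a = simcore.synthesize_recording(tab_a, cfg, 9)
        rec_b, gt_b = simcore.synthesize_recording(tab_b, cfg, 9)
        assert np.array_equal(rec_a.signal, rec_b.signal)
        assert np.array_equal(eog_a.signal, eog_b.signal)
        pd.testing.assert_frame_equal(tab_a, tab_b)
        assert np.array_equal(
            gt_a.hg_onset_ms, gt_b.hg_onset_ms, equal_nan=True
        )

    def test_transient_amplitude_recovered_downstream(self):
        # +39% Gaussian transient peaking at 475 ms must reappear in the
        # baseline-normalized HG envelope at high SNR (spectral module as
        # the recovery oracle); 10% amplitude tolerance, one 50 ms step
        # of latency tolerance
        eff = simcore.EffectSpec(
            conditions=("Instructed",), shape="transient",
            peak_latency_ms=475.0, duration_ms=600.0, relative_amplitude=0.39,
        )
        cfg = _cfg(
            n_trials=260,
            n_channels=1,
            delays_ms=(2750.0,),
            noise=simcore.NoiseSpec(broadband_scale=0.02),
            condition_probs={"Instructed": 1.0, "Free": 0.0, "Control": 0.0},
            effects={0: (eff,)},
        )
        tab = simcore.build_trial_schedule(cfg, 21)
        rec, _ = simcore.synthesize_recording(tab, cfg, 21)
        tensor = spectral.epoch_features(
            rec, tab, [HG], "cue1", (-500.0, 2000.0), 100.0, 50.0
        )
        mean_env = tensor.values[0, 0].mean(axis=0)
        base = tensor.window_slice(-500.0, -100.0)
        rel = mean_env / mean_env[base].mean() - 1.0
        peak = rel[tensor.centers_in(375.0, 600.0)].max()
        assert abs(peak - 0.39) <= 0.039
        smooth = np.convolve(rel, np.ones(5) / 5.0, "same")
        lat = tensor.window_centers_ms[
            tensor.centers_in(0.0, 2000.0)[smooth[tensor.centers_in(0.0, 2000.0)].argmax()]
        ]
        assert abs(lat - 475.0) <= 50.0


class TestEOG:
    def test_direction_sign_convention(self, clean_eog_corpus):
        cfg, eog, tab = clean_eog_corpus
        h = eog.channel("HEOG")
        for row in tab.head(40).itertuples():
            start = row.cue2_onset + ms_to_samples(row.saccade_latency_ms + 100, FS)
            level = h[start : start + ms_to_samples(200.0, FS)].mean()
            assert (level > 0.5) == (row.direction == "R")

    def test_no_deflection_during_delay_on_clean_trials(self, clean_eog_corpus):
        cfg, eog, tab = clean_eog_corpus
        h = eog.channel("HEOG")
        for row in tab.head(40).itertuples():
            seg = h[row.cue1_onset : row.cue2_onset]
            assert np.abs(seg).max() < 0.5

    def test_free_latency_distribution(self):
        cfg = _cfg(n_trials=900, exclusion_fraction=0.0)
        tab = simcore.build_trial_schedule(cfg, 17)
        _, tab = simcore.synthesize_eog(tab, cfg, 17)
        free = tab[tab["condition"] == "Free"]["saccade_latency_ms"]
        assert abs(free.mean() - 334.0) < 3 * 36.0 / np.sqrt(len(free)) + 2.0


class TestPersistence:
    def test_recording_roundtrip(self, tmp_path):
        cfg = _cfg(n_trials=3, n_channels=2, effects={})
        tab = simcore.build_trial_schedule(cfg, 2)
        rec, gt = simcore.synthesize_recording(tab, cfg, 2)
        simcore.write_recording(tmp_path / "r.h5", rec)
        back = simcore.read_recording(tmp_path / "r.h5")
        assert np.array_equal(back.signal, rec.signal)
        assert back.channel_labels == rec.channel_labels
        assert back.sampling_rate == rec.sampling_rate

    def test_trial_table_roundtrip(self, tmp_path):
        cfg = _cfg(n_trials=12)
        tab = simcore.build_trial_schedule(cfg, 2)
        _, tab = simcore.synthesize_eog(tab, cfg, 2)
        simcore.write_trial_table(tmp_path / "t.tsv", tab, FS)
        back = simcore.read_trial_table(tmp_path / "t.tsv", FS)
        assert np.array_equal(back["cue1_onset"], tab["cue1_onset"])
        assert np.array_equal(back["cue2_onset"], tab["cue2_onset"])
        assert np.allclose(back["saccade_latency_ms"], tab["saccade_latency_ms"])

    def test_ground_truth_json(self, tmp_path):
        cfg = _cfg(n_trials=4)
        tab = simcore.build_trial_schedule(cfg, 2)
        _, tab = simcore.synthesize_eog(tab, cfg, 2)
        _, gt = simcore.synthesize_recording(tab, cfg, 2)
        simcore.write_ground_truth(tmp_path / "gt.json", gt)
        import json

        payload = json.loads((tmp_path / "gt.json").read_text())
        assert set(payload["effect_map"]) == set(gt.effect_map)
        assert len(payload["hg_onset_ms"]) == len(tab)
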