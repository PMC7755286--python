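"""Bipolar montage, band envelopes, windowed power, baseline normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from freesacc import simcore, spectral
from freesacc.core import Recording
from freesacc.spectral import (
    HG,
    BandDef,
    BaselineSpec,
    PowerTensor,
    band_envelope,
    baseline_normalize,
    bipolar_rereference,
    epoch_features,
    filter_edge_samples,
    infer_shaft_layout,
    window_grid,
    windowed_power,
)

FS = 1024.0
THETA = BandDef("theta", 4, 8)


def _sine(freq, amp, seconds=10.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBipolar:
    def _rec(self, n=4):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(n, 2000))
        return Recording("p", [f"a{i+1}" for i in range(n)], sig, FS)

    def test_adjacent_differences_and_labels(self):
        rec = self._rec(4)
        out = bipolar_rereference(rec, {"a": ["a1", "a2", "a3", "a4"]})
        assert out.channel_labels == ["a2-a1", "a3-a2", "a4-a3"]
        assert np.allclose(out.signal[0], rec.signal[1] - rec.signal[0])

    def test_k_contacts_give_k_minus_1_derivations(self):
        for k in (2, 5, 9):
            out = bipolar_rereference(self._rec(k))
            assert out.n_channels == k - 1

    def test_common_mode_rejection(self):
        rec = self._rec(3)
        common = np.sin(np.arange(2000) / 7.0)
        contaminated = Recording(
            "p", rec.channel_labels, rec.signal + common, FS
        )
        a = bipolar_rereference(rec)
        b = bipolar_rereference(contaminated)
        assert np.allclose(a.signal, b.signal)

    def test_missing_contact_raises(self):
        with pytest.raises(KeyError):
            bipolar_rereference(self._rec(3), {"a": ["a1", "zz"]})
        with pytest.raises(ValueError, match="fewer than 2"):
            bipolar_rereference(self._rec(3), {"a": ["a1"]})

    def test_infer_shaft_layout(self):
        labels = ["b2", "a1", "a10", "b1", "a2", "EKG+"]
        layout = infer_shaft_layout(labels)
        assert layout == {"a": ["a1", "a2", "a10"], "b": ["b1", "b2"]}


class TestEnvelope:
    def test_in_band_amplitude_recovered(self):
        env = band_envelope(_sine(100.0, 2.0), HG, FS)
        edge = 4 * filter_edge_samples(HG, FS)
        assert np.abs(env[edge:-edge] / 2.0 - 1.0).max() < 0.05

    def test_stop_band_leakage(self):
        env = band_envelope(_sine(5.0, 1.0), HG, FS)
        edge = 4 * filter_edge_samples(HG, FS)
        assert env[edge:-edge].max() < 0.02

    def test_superposition_separates_bands(self):
        x = _sine(6.0, 1.0) + _sine(100.0, 3.0)
        edge = 4 * filter_edge_samples(THETA, FS)
        theta_env = band_envelope(x, THETA, FS)[edge:-edge]
        hg_env = band_envelope(x, HG, FS)[edge:-edge]
        assert np.abs(theta_env.mean() - 1.0) < 0.05
        assert np.abs(hg_env.mean() - 3.0) < 0.15

    def test_envelope_homogeneity(self, rng):
        x = rng.normal(size=8192)
        assert np.allclose(
            band_envelope(3.5 * x, HG, FS), 3.5 * band_envelope(x, HG, FS)
        )

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_envelope(np.zeros(4096), HG, 256.0)
        with pytest.raises(ValueError, match="invalid band"):
            BandDef("bad", 30, 20)


class TestWindowedPower:
    def test_constant_envelope(self):
        env = np.full(int(4 * FS), 2.0)
        centers, vals = windowed_power(env, FS, 400.0, 50.0, (0.0, 3000.0))
        assert np.allclose(vals, 2.0)
        assert np.allclose(centers[0], 200.0)

    def test_window_count_formula(self):
        env = np.zeros(int(4 * FS))
        centers, _ = windowed_power(env, FS, 400.0, 50.0, (0.0, 3000.0))
        assert len(centers) == 53  # floor((3000 - 400) / 50) + 1

    def test_disjoint_blocks_when_step_equals_length(self):
        env = np.concatenate([np.full(512, 1.0), np.full(512, 3.0)])
        centers, vals = windowed_power(env, FS, 500.0, 500.0, (0.0, 1000.0))
        assert np.allclose(vals, [1.0, 3.0])

    def test_step_must_be_positive(self):
        with pytest.raises(ValueError, match="step"):
            window_grid((0.0, 1000.0), 400.0, 0.0)
        with pytest.raises(ValueError, match="span"):
            window_grid((0.0, 300.0), 400.0, 50.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0))
    def test_commutes_with_scaling(self, scale):
        rng = np.random.default_rng(5)
        env = rng.random(int(2 * FS))
        _, a = windowed_power(env * scale, FS, 200.0, 100.0, (0.0, 1500.0))
        _, b = windowed_power(env, FS, 200.0, 100.0, (0.0, 1500.0))
        assert np.allclose(a, scale * b)


def _tensor(values, centers, length=400.0, step=50.0, **kw):
    values = np.asarray(values, dtype=float)
    return PowerTensor(
        values=values,
        sites=[f"s{i}" for i in range(values.shape[0])],
        bands=[f"b{i}" for i in range(values.shape[1])],
        trial_index=np.arange(values.shape[2]),
        window_centers_ms=centers,
        window_length_ms=length,
        step_ms=step,
        **kw,
    )


class TestBaselineNormalize:
    def test_relative_change(self):
        centers = np.array([-300.0, 200.0])
        vals = np.zeros((1, 1, 1, 2))
        vals[0, 0, 0] = [10.0, 15.0]
        out = baseline_normalize(_tensor(vals, centers))
        assert out.values[0, 0, 0, 1] == pytest.approx(0.5)
        assert out.values[0, 0, 0, 0] == pytest.approx(0.0)
        assert out.normalized

    def test_zero_baseline_flagged_not_divided(self):
        centers = np.array([-300.0, 200.0])
        vals = np.zeros((1, 1, 2, 2))
        vals[0, 0, 0] = [0.0, 5.0]   # degenerate baseline
        vals[0, 0, 1] = [2.0, 3.0]
        out = baseline_normalize(_tensor(vals, centers))
        assert out.flagged[0, 0, 0] and not out.flagged[0, 0, 1]
        assert np.isnan(out.values[0, 0, 0]).all()
        assert out.values[0, 0, 1, 1] == pytest.approx(0.5)

    def test_double_normalization_rejected(self):
        centers = np.array([-300.0, 200.0])
        vals = np.ones((1, 1, 1, 2))
        out = baseline_normalize(_tensor(vals, centers))
        with pytest.raises(ValueError, match="already normalized"):
            baseline_normalize(out)

    def test_invalid_baseline_interval(self):
        with pytest.raises(ValueError):
            BaselineSpec(-100.0, -500.0)
        with pytest.raises(ValueError, match="precede"):
            BaselineSpec(-100.0, 200.0)


@pytest.fixture(scope="module")
def corpus():
    cfg = simcore.SimulationConfig(
        n_trials=12, sampling_rate=512.0, delays_ms=(2750.0, 4750.0), seed=3
    )
    tab = simcore.build_trial_schedule(cfg, 3)
    rec, _ = simcore.synthesize_recording(tab, cfg, 3)
    return rec, tab


class TestEpochFeatures:

    def test_output_shape(self, corpus):
        rec, tab = corpus
        t = epoch_features(rec, tab, [THETA, HG], "cue1", (-500.0, 1500.0),
                           400.0, 50.0)
        n_inc = int(tab["included"].sum())
        assert t.shape == (rec.n_channels, 2, n_inc, 33)

    def test_cue2_alignment_uniform_grid_across_delays(self, corpus):
        rec, tab = corpus
        t = epoch_features(rec, tab, [HG], "cue2", (-2000.0, 0.0), 400.0, 50.0)
        assert t.alignment == "cue2"
        assert t.window_centers_ms[0] == pytest.approx(-1800.0)
        assert t.window_centers_ms[-1] == pytest.approx(-200.0)
        assert len(t.window_centers_ms) == 33

    def test_display_grid_supported(self, corpus):
        rec, tab = corpus
        t = epoch_features(rec, tab, [HG], "cue1", (-200.0, 500.0), 60.0, 10.0)
        assert len(t.window_centers_ms) == 65  # floor((700 - 60) / 10) + 1

    def test_epoch_outside_recording_raises(self, corpus):
        rec, tab = corpus
        with pytest.raises(ValueError, match="bounds"):
            epoch_features(rec, tab, [HG], "cue1", (-500.0, 500000.0), 400.0, 50.0)

    def test_roundtrip_hdf5(self, corpus, tmp_path):
        rec, tab = corpus
        t = epoch_features(rec, tab, [HG], "cue1", (-500.0, 1000.0), 400.0, 50.0)
        spectral.write_power_tensor(tmp_path / "t.h5", t)
        back = spectral.read_power_tensor(tmp_path / "t.h5")
        assert np.array_equal(back.values, t.values)
        assert back.bands == t.bands and back.sites == t.sites
        assert back.step_ms == t.step_ms


class TestPowerTensorInvariants:
    def test_negative_raw_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _tensor(-np.ones((1, 1, 1, 2)), np.array([0.0, 50.0]))

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            _tensor(np.ones((1, 1, 1, 3)), np.array([0.0, 50.0, 175.0]))
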