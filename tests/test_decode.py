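"""LDA decoding, max-statistics inference, generalization, band selection."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from freesacc import decode
from freesacc.decode import (
    binomial_da_threshold,
    cross_validated_da,
    exhaustive_band_selection,
    multisite_decoding,
    permutation_maxstat,
    stratified_folds,
    temporal_generalization,
    time_resolved_decoding,
)
from freesacc.spectral import PowerTensor


def _tensor(values, step=50.0, bands=None):
    values = np.asarray(values, dtype=float)
    s, b, n, w = values.shape
    centers = 200.0 + step * np.arange(w)
    return PowerTensor(
        values=values,
        sites=[f"s{i}" for i in range(s)],
        bands=bands or [f"b{i}" for i in range(b)],
        trial_index=np.arange(n),
        window_centers_ms=centers,
        window_length_ms=400.0,
        step_ms=step,
    )


def _labels(n):
    return np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))


class TestCrossValidatedDA:
    def test_fast_path_matches_sklearn_exactly(self, rng):
        # the closed-form univariate LDA and sklearn's shrinkage LDA are the
        # same estimator for d = 1; predictions must agree exactly
        for trial in range(10):
            x = rng.normal(size=80) + np.repeat([0.0, 0.7], 40)
            x -= x.min() - 1.0
            y = np.repeat([0, 1], 40)
            order = rng.permutation(80)
            x, y = x[order], y[order]
            folds = stratified_folds(y, 10, seed=trial)
            mine = decode._da_cells_1d(x[None, :], y, folds)[0]
            correct = 0
            for tr, te in folds:
                clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                clf.fit(x[tr][:, None], y[tr])
                correct += int((clf.predict(x[te][:, None]) == y[te]).sum())
            assert mine == pytest.approx(correct / 80)

    def test_perfectly_separable(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(5, 6, 30)])
        assert cross_validated_da(x, _labels(60), seed=0) == 1.0

    def test_chance_level_many_null_cells(self, rng):
        # 200 independent label-free cells of 200 observations: mean DA 0.5
        X = rng.uniform(0.5, 1.5, size=(200, 1, 200, 1))
        res = time_resolved_decoding(_tensor(X), _labels(200), seed=4)
        assert res.da.mean() == pytest.approx(0.5, abs=0.01)

    def test_stratified_folds_balanced(self):
        y = np.repeat([0, 1], 20)
        folds = stratified_folds(y, 10, seed=0)
        assert len(folds) == 10
        for _, te in folds:
            assert (y[te] == 0).sum() == 2 and (y[te] == 1).sum() == 2

    def test_label_swap_leaves_da_unchanged(self, rng):
        x = rng.normal(size=60) + np.repeat([0.0, 0.5], 30)
        x -= x.min() - 1
        y = _labels(60)
        swapped = np.where(y == "A", "B", "A")
        assert cross_validated_da(x, y, seed=3) == cross_validated_da(
            x, swapped, seed=3
        )

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            cross_validated_da(rng.normal(size=10), ["A"] * 10)

    def test_missing_values_rejected(self):
        x = np.ones(20)
        x[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cross_validated_da(x, _labels(20))


class TestTimeResolved:
    def test_output_shape_and_determinism(self, rng):
        X = rng.uniform(0.5, 1.5, size=(3, 2, 40, 5))
        y = _labels(40)
        a = time_resolved_decoding(_tensor(X), y, seed=9)
        b = time_resolved_decoding(_tensor(X), y, seed=9)
        assert a.da.shape == (3, 2, 5)
        assert np.array_equal(a.da, b.da)

    def test_effect_confined_to_informative_windows(self, rng):
        # strong separation only at windows 4-8: supra-threshold cells must
        # stay within one window of that span
        n, w = 80, 12
        X = rng.uniform(0.9, 1.1, size=(1, 1, n, w))
        y = _labels(n)
        X[0, 0, y == "B", 4:9] += 1.0
        res = permutation_maxstat(_tensor(X), y, n_perm=100, alpha=0.01, seed=2)
        sig_windows = np.nonzero(res.sig_mask[0, 0])[0]
        assert len(sig_windows) > 0
        assert sig_windows.min() >= 3 and sig_windows.max() <= 9


class TestPermutationMaxstat:
    def test_threshold_is_extreme_order_statistic(self, rng):
        X = rng.uniform(0.5, 1.5, size=(2, 1, 40, 3))
        res = permutation_maxstat(_tensor(X), _labels(40), n_perm=100,
                                  alpha=0.01, seed=0)
        assert res.threshold == res.null_maxima.max()
        assert np.array_equal(res.sig_mask, res.da > res.threshold)

    def test_maxstat_dominates_pointwise_threshold(self, rng):
        # the global-maximum null stochastically dominates any single cell's
        # null, so its quantile can never be smaller
        X = rng.uniform(0.5, 1.5, size=(4, 1, 40, 4))
        y = _labels(40)
        res = permutation_maxstat(_tensor(X), y, n_perm=60, alpha=0.05, seed=1)
        single = _tensor(X[:1, :, :, :1])
        res1 = permutation_maxstat(single, y, n_perm=60, alpha=0.05, seed=1)
        assert res.threshold >= res1.threshold - 1e-12

    def test_invalid_parameters(self, rng):
        X = rng.uniform(0.5, 1.5, size=(1, 1, 20, 1))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_maxstat(_tensor(X), _labels(20), n_perm=0)
        with pytest.raises(ValueError, match="alpha"):
            permutation_maxstat(_tensor(X), _labels(20), alpha=1.5)

    def test_small_n_perm_warns(self, rng):
        X = rng.uniform(0.5, 1.5, size=(1, 1, 20, 1))
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_maxstat(_tensor(X), _labels(20), n_perm=10, alpha=0.01,
                                seed=0)


class TestMultisite:
    def test_single_site_reduces_to_time_resolved(self, rng):
        X = rng.uniform(0.5, 1.5, size=(1, 1, 40, 4))
        y = _labels(40)
        ms = multisite_decoding(_tensor(X), y, seed=5)
        tr = time_resolved_decoding(_tensor(X), y, seed=5)
        assert np.array_equal(ms.da[0], tr.da[0])

    def test_redundant_sites_do_not_hurt(self, rng):
        # several weakly informative sites: multisite DA at least matches the
        # best single site (median over repeated draws)
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.uniform(0.8, 1.2, size=(4, 1, 60, 1))
            y = _labels(60)
            X[:, 0, y == "B", :] += 0.25
            t = _tensor(X)
            best_single = time_resolved_decoding(t, y, seed=seed).da.max()
            ms = multisite_decoding(t, y, seed=seed).da[0, 0, 0]
            diffs.append(ms - best_single)
        assert np.median(diffs) >= 0.0

    def test_uninformative_sites_stay_at_chance(self, rng):
        das = []
        for seed in range(15):
            r = np.random.default_rng(100 + seed)
            X = r.uniform(0.5, 1.5, size=(5, 1, 60, 1))
            das.append(multisite_decoding(_tensor(X), _labels(60),
                                          seed=seed).da[0, 0, 0])
        assert abs(np.mean(das) - 0.5) < 0.06


class TestBinomialThreshold:
    def test_exact_example(self):
        # P(X >= 9 | n=10, p=.5) = 11/1024 < .05 but P(X >= 8) = 56/1024
        assert binomial_da_threshold(10, 2, 0.05) == pytest.approx(0.9)

    def test_limit_alpha_near_one(self):
        assert binomial_da_threshold(100, 2, 0.999) <= 0.52

    def test_non_increasing_in_n(self):
        ts = [binomial_da_threshold(n, 2, 0.01) for n in (10, 20, 50, 100, 400)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    def test_invalid(self):
        with pytest.raises(ValueError):
            binomial_da_threshold(0, 2, 0.05)
        with pytest.raises(ValueError):
            binomial_da_threshold(10, 2, 1.0)


class TestTemporalGeneralization:
    def test_diagonal_equals_multisite_decoding(self, rng):
        X = rng.uniform(0.8, 1.2, size=(3, 1, 40, 6))
        y = _labels(40)
        X[:, 0, y == "B", 2:5] += 0.5
        t = _tensor(X, bands=["HG"])
        gm = temporal_generalization(t, y, band="HG", seed=11)
        ms = multisite_decoding(t, y, seed=11)
        assert np.allclose(gm.diagonal, ms.da[0, 0])

    def test_sustained_pattern_generalizes_as_block(self, rng):
        n, w = 80, 8
        X = rng.uniform(0.9, 1.1, size=(2, 1, n, w))
        y = _labels(n)
        X[:, 0, y == "B", 2:7] += 0.8  # constant pattern over windows 2..6
        gm = temporal_generalization(_tensor(X, bands=["HG"]), y, band="HG",
                                     seed=0)
        block = gm.sig_mask[2:7, 2:7]
        assert block.mean() > 0.9

    def test_orthogonal_transients_do_not_cross_generalize(self, rng):
        n, w = 80, 8
        X = rng.uniform(0.9, 1.1, size=(2, 1, n, w))
        y = _labels(n)
        X[0, 0, y == "B", 1] += 1.0   # site 0 codes at window 1
        X[1, 0, y == "B", 6] += 1.0   # site 1 codes at window 6
        gm = temporal_generalization(_tensor(X, bands=["HG"]), y, band="HG",
                                     seed=0)
        assert gm.sig_mask[1, 1] and gm.sig_mask[6, 6]
        assert not gm.sig_mask[1, 6] and not gm.sig_mask[6, 1]

    def test_empty_site_set_rejected(self, rng):
        X = rng.uniform(0.5, 1.5, size=(2, 1, 20, 3))
        with pytest.raises(ValueError, match="site_set"):
            temporal_generalization(_tensor(X, bands=["HG"]), _labels(20),
                                    site_set=[], band="HG")


class TestBandSelection:
    def test_informative_band_wins_every_split(self, rng):
        n = 90
        bands = ["theta", "alpha", "beta", "low_gamma", "HG"]
        X = rng.uniform(0.8, 1.2, size=(2, 5, n, 4))
        y = _labels(n)
        X[:, 4, y == "B", :] += 1.0  # only HG carries signal
        res = exhaustive_band_selection(_tensor(X, bands=bands), y, seed=0)
        for site, tally in res.counts.items():
            assert sum(tally.values()) == 3
            assert tally.get(("HG",), 0) == 3

    def test_subset_count(self):
        from itertools import combinations

        subs = [c for r in range(1, 6) for c in combinations(range(5), r)]
        assert len(subs) == 31

    def test_tie_breaks_prefer_smaller_earlier_subset(self, rng):
        # two identical informative bands: subsets {b0}, {b1}, {b0,b1} tie on
        # score; the declared contract picks the smallest, earliest subset
        n = 60
        sig = rng.uniform(0.8, 1.2, size=(1, 1, n, 2))
        y = _labels(n)
        sig[0, 0, y == "B", :] += 2.0
        X = np.concatenate([sig, sig], axis=1)
        res = exhaustive_band_selection(_tensor(X, bands=["b0", "b1"]), y, seed=0)
        assert res.counts["s0"] == {("b0",): 3}

    def test_too_few_observations_rejected(self, rng):
        X = rng.uniform(0.5, 1.5, size=(1, 2, 4, 2))
        with pytest.raises(ValueError, match="thirds"):
            exhaustive_band_selection(_tensor(X, bands=["a", "b"]), _labels(4))
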