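"""LDA decoding: time-resolved, multisite, cross-temporal, with inference.

Decoding accuracy (DA) is the fraction of held-out trials correctly
classified under stratified 10-fold cross-validation.  Family-wise
inference over (site, band, window) cells uses maximum statistics: the
null distribution of the *global maximum* DA over all cells is built from
label permutations (labels are shuffled once per permutation and reused
across every cell, which is what makes the maximum distribution valid),
and a cell is significant when its observed DA exceeds the permutation
quantile of that maximum.  Cross-temporal generalization matrices are
thresholded with the binomial cumulative distribution instead.

The two-class classifier is Fisher's linear discriminant with a
shrinkage-regularized covariance.  Multivariate cells go through
scikit-learn (``lsqr`` solver, Ledoit-Wolf shrinkage); univariate cells
(one site x band x window feature), which dominate permutation runs by
orders of magnitude, use a closed-form implementation vectorized across
all cells at once.  For d = 1 the shrinkage target coincides with the
variance itself, so the two paths are the same estimator (a test asserts
exact prediction agreement with scikit-learn).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .spectral import PowerTensor

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingResult",
    "GeneralizationMatrix",
    "BandSelectionResult",
    "cross_validated_da",
    "time_resolved_decoding",
    "permutation_maxstat",
    "multisite_decoding",
    "temporal_generalization",
    "binomial_da_threshold",
    "exhaustive_band_selection",
    "stratified_folds",
]


# ---------------------------------------------------------------------------
# fold construction


def stratified_folds(
    labels: np.ndarray, n_folds: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified folds; reduced (with a log note) if a class is small."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes")
    k = min(n_folds, counts.min())
    if k < 2:
        raise ValueError("each class needs at least 2 observations")
    if k < n_folds:
        logger.info("reducing folds from %d to %d (smallest class)", n_folds, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {len(classes)}")
    return (labels == classes[1]).astype(np.int8)


# ---------------------------------------------------------------------------
# LDA engines


def _da_cells_1d(
    X: np.ndarray, y: np.ndarray, folds: Sequence[tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Cross-validated DA for many univariate cells at once.

    ``X`` is (cells, observations); the closed-form linear discriminant
    uses class means, the prior-weighted pooled ML variance and empirical
    log priors, matching scikit-learn's ``lsqr`` solution for d = 1.
    """
    X = np.asarray(X, dtype=np.float64)
    n_cells, n = X.shape
    correct = np.zeros(n_cells)
    tiny = np.finfo(float).tiny
    for tr, te in folds:
        ytr = y[tr]
        n1 = int(ytr.sum())
        n0 = len(tr) - n1
        X0 = X[:, tr[ytr == 0]]
        X1 = X[:, tr[ytr == 1]]
        m0 = X0.mean(axis=1)
        m1 = X1.mean(axis=1)
        ss = ((X0 - m0[:, None]) ** 2).sum(axis=1) + (
            (X1 - m1[:, None]) ** 2
        ).sum(axis=1)
        v = np.maximum(ss / len(tr), tiny)
        log_prior = np.log(n1 / len(tr)) - np.log(n0 / len(tr))
        # decision: score1 - score0 > 0  -> predict class 1
        w = (m1 - m0) / v
        b = -(m1**2 - m0**2) / (2.0 * v) + log_prior
        scores = w[:, None] * X[:, te] + b[:, None]
        pred = (scores > 0).astype(np.int8)
        correct += (pred == y[te][None, :]).sum(axis=1)
    return correct / n


def _sk_lda() -> LinearDiscriminantAnalysis:
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def _da_cell_nd(
    X: np.ndarray, y: np.ndarray, folds: Sequence[tuple[np.ndarray, np.ndarray]]
) -> float:
    """Cross-validated DA for a single d-dimensional cell (shrinkage LDA)."""
    correct = 0
    for tr, te in folds:
        clf = _sk_lda().fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def cross_validated_da(
    features: np.ndarray, labels, n_folds: int = 10, seed: int = 0
) -> float:
    """DA of shrinkage LDA under stratified ``n_folds``-fold CV.

    Every observation is tested exactly once; DA is the overall fraction
    of correct held-out predictions.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing values")
    y = _encode_labels(labels)
    if X.shape[0] != len(y):
        raise ValueError("features and labels disagree on observations")
    folds = stratified_folds(y, n_folds, seed)
    if X.shape[1] == 1:
        return float(_da_cells_1d(X.T, y, folds)[0])
    return float(_da_cell_nd(X, y, folds))


# ---------------------------------------------------------------------------
# results containers


@dataclass
class DecodingResult:
    """Time-resolved DA with (optionally) its max-statistics inference.

    ``da`` has shape (sites, bands, windows).  ``null_maxima`` is the
    permutation distribution of the global maximum DA across all cells;
    ``threshold`` its ``ceil((1 - alpha) (n_perm + 1))``-th order
    statistic; ``sig_mask`` flags cells with ``da > threshold``.
    """

    da: np.ndarray
    sites: Sequence[str]
    bands: Sequence[str]
    window_centers_ms: np.ndarray
    step_ms: float
    n_folds: int
    alignment: str = "cue1"
    null_maxima: np.ndarray | None = None
    threshold: float | None = None
    sig_mask: np.ndarray | None = None
    alpha: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format summary (site, band, window_center_ms, DA, significant)."""
        s, b, w = self.da.shape
        si, bi, wi = np.meshgrid(range(s), range(b), range(w), indexing="ij")
        out = pd.DataFrame(
            {
                "site": np.asarray(self.sites)[si.ravel()],
                "band": np.asarray(self.bands)[bi.ravel()],
                "window_center_ms": self.window_centers_ms[wi.ravel()],
                "DA": self.da.ravel(),
            }
        )
        if self.sig_mask is not None:
            out["significant"] = self.sig_mask.ravel().astype(int)
        return out


@dataclass
class GeneralizationMatrix:
    """Train-time x test-time DA with a binomial significance threshold."""

    da: np.ndarray  # (train windows, test windows)
    window_centers_ms: np.ndarray
    band: str
    sites: Sequence[str]
    n_test: int
    threshold: float
    alpha: float
    n_folds: int

    def __post_init__(self):
        if self.da.shape[0] != self.da.shape[1]:
            raise ValueError("generalization matrix must be square")

    @property
    def sig_mask(self) -> np.ndarray:
        return self.da > self.threshold

    @property
    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.da).copy()


# ---------------------------------------------------------------------------
# time-resolved decoding over (site, band, window) cells


def _tensor_cells(tensor: PowerTensor) -> np.ndarray:
    """Reshape tensor values to (cells, observations) for univariate LDA."""
    s, b, n, w = tensor.values.shape
    return tensor.values.transpose(0, 1, 3, 2).reshape(s * b * w, n)


def _all_cells_da(
    tensor: PowerTensor,
    y: np.ndarray,
    folds,
    multisite: bool,
) -> np.ndarray:
    """DA for all cells; (sites, bands, windows) or (1, bands, windows)."""
    s, b, n, w = tensor.values.shape
    if not multisite:
        da = _da_cells_1d(_tensor_cells(tensor), y, folds)
        return da.reshape(s, b, w)
    da = np.empty((1, b, w))
    for bi in range(b):
        for wi in range(w):
            X = tensor.values[:, bi, :, wi].T  # (n, sites)
            da[0, bi, wi] = _da_cell_nd(X, y, folds)
    return da


def time_resolved_decoding(
    tensor: PowerTensor,
    labels,
    n_folds: int = 10,
    seed: int = 0,
) -> DecodingResult:
    """One DA per (site, band, window), sharing a single fold assignment.

    The same (seed-fixed) folds are used for every cell, so comparisons
    across windows/sites are paired.
    """
    y = _encode_labels(labels)
    if len(y) != tensor.values.shape[2]:
        raise ValueError("labels do not match the tensor's trial axis")
    folds = stratified_folds(y, n_folds, seed)
    da = _all_cells_da(tensor, y, folds, multisite=False)
    return DecodingResult(
        da=da,
        sites=tensor.sites,
        bands=tensor.bands,
        window_centers_ms=tensor.window_centers_ms,
        step_ms=tensor.step_ms,
        n_folds=len(folds),
        alignment=tensor.alignment,
    )


def permutation_maxstat(
    tensor: PowerTensor,
    labels,
    n_perm: int = 100,
    alpha: float = 0.01,
    n_folds: int = 10,
    seed: int = 0,
    multisite: bool = False,
) -> DecodingResult:
    """Max-statistics inference over all (site, band, window) cells.

    Per permutation the labels are shuffled once and the complete DA array
    recomputed; ``null_maxima`` collects the global maximum of each
    permutation, correcting the threshold across sites, bands and time.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 1.0 / alpha - 1:
        warnings.warn(
            f"n_perm={n_perm} is small for alpha={alpha}; the threshold "
            "is the extreme order statistic",
            stacklevel=2,
        )
    y = _encode_labels(labels)
    if len(y) != tensor.values.shape[2]:
        raise ValueError("labels do not match the tensor's trial axis")
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    folds = stratified_folds(y, n_folds, fold_seed)
    da = _all_cells_da(tensor, y, folds, multisite)

    null_max = np.empty(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(y)
        perm_folds = stratified_folds(yp, n_folds, int(rng.integers(2**31)))
        null_max[p] = _all_cells_da(tensor, yp, perm_folds, multisite).max()

    k = min(int(np.ceil((1.0 - alpha) * (n_perm + 1))), n_perm)
    threshold = float(np.sort(null_max)[k - 1])
    sites = tensor.sites if not multisite else ["multisite"]
    return DecodingResult(
        da=da,
        sites=sites,
        bands=tensor.bands,
        window_centers_ms=tensor.window_centers_ms,
        step_ms=tensor.step_ms,
        n_folds=len(folds),
        alignment=tensor.alignment,
        null_maxima=null_max,
        threshold=threshold,
        sig_mask=da > threshold,
        alpha=alpha,
    )


def multisite_decoding(
    tensor: PowerTensor,
    labels,
    n_folds: int = 10,
    seed: int = 0,
) -> DecodingResult:
    """Decode with all sites in the feature space simultaneously.

    At each (band, window) the feature vector concatenates every site; the
    result's ``da`` has shape (1, bands, windows).  With a single site
    this reduces exactly to :func:`time_resolved_decoding`.
    """
    y = _encode_labels(labels)
    if len(y) != tensor.values.shape[2]:
        raise ValueError("labels do not match the tensor's trial axis")
    folds = stratified_folds(y, n_folds, seed)
    if tensor.values.shape[0] == 1:
        da = _all_cells_da(tensor, y, folds, multisite=False)
    else:
        da = _all_cells_da(tensor, y, folds, multisite=True)
    return DecodingResult(
        da=da,
        sites=["multisite"],
        bands=tensor.bands,
        window_centers_ms=tensor.window_centers_ms,
        step_ms=tensor.step_ms,
        n_folds=len(folds),
        alignment=tensor.alignment,
    )


# ---------------------------------------------------------------------------
# cross-temporal generalization


def binomial_da_threshold(n_test: int, n_classes: int = 2, alpha: float = 0.01) -> float:
    """Smallest ``k / n_test`` with ``P(X >= k) < alpha``, X ~ Bin(n, 1/c).

    Returns ``inf`` when even ``k = n_test`` does not reach ``alpha``.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = np.arange(n_test + 1)
    tail = stats.binom.sf(k - 1, n_test, 1.0 / n_classes)  # P(X >= k)
    hits = np.nonzero(tail < alpha)[0]
    if hits.size == 0:
        return float("inf")
    return float(k[hits[0]]) / n_test


def temporal_generalization(
    tensor: PowerTensor,
    labels,
    site_set: Sequence[str] | None = None,
    band: str = "HG",
    n_folds: int = 10,
    alpha: float = 0.01,
    seed: int = 0,
) -> GeneralizationMatrix:
    """Train at each window, test at every other window.

    Classifiers are fitted per fold on the training trials at window ``t``
    and applied to that fold's *held-out* trials at every window ``t'``
    (no train/test leakage off the diagonal).  Each cell therefore
    aggregates one prediction per trial; significance uses the binomial
    threshold at the total held-out count.  The diagonal equals
    :func:`multisite_decoding` restricted to the same sites/band under the
    same seed.
    """
    if site_set is None:
        site_set = list(tensor.sites)
    if len(site_set) == 0:
        raise ValueError("site_set must not be empty")
    y = _encode_labels(labels)
    if len(y) != tensor.values.shape[2]:
        raise ValueError("labels do not match the tensor's trial axis")
    si = [tensor.site_index(s) for s in site_set]
    bi = tensor.band_index(band)
    F = tensor.values[si, bi].transpose(1, 0, 2)  # (trials, sites, windows)
    n, d, W = F.shape
    folds = stratified_folds(y, n_folds, seed)
    correct = np.zeros((W, W))
    for tr, te in folds:
        yte = y[te]
        for t in range(W):
            clf = _sk_lda().fit(F[tr, :, t], y[tr])
            test_block = F[te, :, :].transpose(2, 0, 1).reshape(W * len(te), d)
            pred = clf.predict(test_block).reshape(W, len(te))
            correct[t] += (pred == yte[None, :]).sum(axis=1)
    da = correct / n
    return GeneralizationMatrix(
        da=da,
        window_centers_ms=tensor.window_centers_ms,
        band=band,
        sites=list(site_set),
        n_test=n,
        threshold=binomial_da_threshold(n, 2, alpha),
        alpha=alpha,
        n_folds=len(folds),
    )


# ---------------------------------------------------------------------------
# exhaustive frequency-band selection


@dataclass
class BandSelectionResult:
    """Winning band-subset counts per site over the validation splits."""

    counts: dict[str, dict[tuple[str, ...], int]]
    n_splits: int

    def winners(self) -> dict[str, tuple[str, ...]]:
        """Most frequently winning subset per site (ties: first in order)."""
        return {
            site: max(subs.items(), key=lambda kv: kv[1])[0]
            for site, subs in self.counts.items()
        }


def exhaustive_band_selection(
    tensor: PowerTensor,
    labels,
    seed: int = 0,
    span_ms: tuple[float, float] | None = None,
) -> BandSelectionResult:
    """Which frequency-band subset best decodes the two conditions?

    Per site, every nonempty subset of the bands (2^B - 1; 31 for the five
    canonical bands) is fitted on two thirds of the trials and scored on
    the stratified held-out third; this is repeated over the three
    disjoint validation thirds and the winning subset counted per
    repetition.  One feature per band: its mean non-normalized power over
    ``span_ms`` (full grid by default).  Score ties prefer the smaller
    subset, residual ties the earlier band order.
    """
    if len(tensor.bands) < 2:
        raise ValueError("need at least 2 bands")
    y = _encode_labels(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("need at least 3 observations per class to form thirds")
    win = (
        np.arange(len(tensor.window_centers_ms))
        if span_ms is None
        else tensor.centers_in(*span_ms)
    )
    feats = tensor.values[:, :, :, win].mean(axis=3)  # (site, band, trial)
    subsets = [
        tuple(c)
        for r in range(1, len(tensor.bands) + 1)
        for c in combinations(range(len(tensor.bands)), r)
    ]
    subsets.sort(key=lambda s: (len(s), s))
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=int(seed) % (2**32))
    splits = list(skf.split(np.zeros(len(y)), y))
    counts_out: dict[str, dict[tuple[str, ...], int]] = {}
    for si, site in enumerate(tensor.sites):
        tally: dict[tuple[str, ...], int] = {}
        for train, val in splits:
            best, best_score = None, -np.inf
            for sub in subsets:
                X = feats[si, list(sub), :].T  # (trial, bands-in-subset)
                clf = _sk_lda().fit(X[train], y[train])
                score = float((clf.predict(X[val]) == y[val]).mean())
                if score > best_score:  # strict: earlier (smaller) subset wins ties
                    best, best_score = sub, score
            key = tuple(tensor.bands[i] for i in best)
            tally[key] = tally.get(key, 0) + 1
        counts_out[site] = tally
    return BandSelectionResult(counts=counts_out, n_splits=len(splits))


# ---------------------------------------------------------------------------
# persistence


def write_decoding_result(h5_path, result: DecodingResult, tsv_path=None) -> None:
    """HDF5 dump of a DecodingResult, plus an optional TSV summary."""
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("da", data=result.da)
        f.create_dataset("window_centers_ms", data=result.window_centers_ms)
        f.attrs["sites"] = [s.encode() for s in result.sites]
        f.attrs["bands"] = [b.encode() for b in result.bands]
        f.attrs["step_ms"] = result.step_ms
        f.attrs["n_folds"] = result.n_folds
        f.attrs["alignment"] = result.alignment
        if result.null_maxima is not None:
            f.create_dataset("null_maxima", data=result.null_maxima)
            f.create_dataset("sig_mask", data=result.sig_mask)
            f.attrs["threshold"] = result.threshold
            f.attrs["alpha"] = result.alpha
    if tsv_path is not None:
        result.to_frame().to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")


def read_decoding_result(h5_path) -> DecodingResult:
    with h5py.File(h5_path, "r") as f:
        has_null = "null_maxima" in f
        from .spectral import _str_list

        return DecodingResult(
            da=f["da"][()],
            sites=_str_list(f.attrs["sites"]),
            bands=_str_list(f.attrs["bands"]),
            window_centers_ms=f["window_centers_ms"][()],
            step_ms=float(f.attrs["step_ms"]),
            n_folds=int(f.attrs["n_folds"]),
            alignment=str(f.attrs["alignment"]),
            null_maxima=f["null_maxima"][()] if has_null else None,
            sig_mask=f["sig_mask"][()].astype(bool) if has_null else None,
            threshold=float(f.attrs["threshold"]) if has_null else None,
            alpha=float(f.attrs["alpha"]) if has_null else None,
        )


def write_generalization_matrix(h5_path, gm: GeneralizationMatrix, tsv_path=None) -> None:
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("da", data=gm.da)
        f.create_dataset("window_centers_ms", data=gm.window_centers_ms)
        f.attrs["band"] = gm.band
        f.attrs["sites"] = [s.encode() for s in gm.sites]
        f.attrs["n_test"] = gm.n_test
        f.attrs["threshold"] = gm.threshold
        f.attrs["alpha"] = gm.alpha
        f.attrs["n_folds"] = gm.n_folds
    if tsv_path is not None:
        W = len(gm.window_centers_ms)
        ti, wi = np.meshgrid(range(W), range(W), indexing="ij")
        pd.DataFrame(
            {
                "train_ms": gm.window_centers_ms[ti.ravel()],
                "test_ms": gm.window_centers_ms[wi.ravel()],
                "DA": gm.da.ravel(),
                "significant": gm.sig_mask.ravel().astype(int),
            }
        ).to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
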