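import hashlib

import numpy as np
import pandas as pd
import pytest

from afstress.battery import HISTORY_COLUMNS, IMAGING_COLUMNS
from afstress.classify import (
    CLASSIFIERS,
    FEATURE_SETS,
    compare_and_select,
    fit_evaluate,
    resolve_feature_set,
    roc_curve,
)


def auc_pair_counting(scores, labels):
    """Oracle: P(score_pos > score_neg) with ties counted half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def synthetic_table(n, seed, signal_in="none", noise=1.0):
    """Signature-shaped table with optional planted signal in one block."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    cols = {}
    for c in ["s1_post_df_hz", "s1_post_sustained", "s1_pre_ps_count"]:
        x = rng.normal(size=n) * noise
        if signal_in == "sim":
            x = x + 3.0 * y
        cols[c] = x
    for c in IMAGING_COLUMNS:
        x = rng.normal(size=n) * noise
        if signal_in == "imaging":
            x = x + 3.0 * y
        cols[c] = x
    for c in HISTORY_COLUMNS:
        cols[c] = rng.normal(size=n) * noise
    return pd.DataFrame(cols), y


class TestRocCurve:
    def test_perfect_scores(self):
        assert roc_curve([0, 0, 1, 1], [0, 0, 1, 1])["auc"] == 1.0

    def test_worked_example(self):
        # pair counting: 4 pairs ordered correctly out of... -> 0.75
        out = roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert out["auc"] == pytest.approx(0.75)
        assert out["auc"] == pytest.approx(
            auc_pair_counting([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        s = rng.normal(size=10_000)
        assert abs(roc_curve(s, y)["auc"] - 0.5) < 0.02

    @pytest.mark.parametrize("seed", range(10))
    def test_pair_counting_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        y = np.zeros(n, int)
        y[: n // 2] = 1
        rng.shuffle(y)
        s = np.round(rng.normal(size=n), 1)  # coarse scores force ties
        assert roc_curve(s, y)["auc"] == pytest.approx(auc_pair_counting(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_auc_equals_oracle_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=60, deadline=None)
        @given(st.lists(st.tuples(st.integers(0, 1),
                                  st.integers(-5, 5)),
                        min_size=4, max_size=40))
        def check(pairs):
            y = np.array([p[0] for p in pairs])
            s = np.array([p[1] for p in pairs], dtype=float) / 2.0
            if len(np.unique(y)) < 2:
                return
            assert roc_curve(s, y)["auc"] == pytest.approx(
                auc_pair_counting(s, y))

        check()


class TestFeatureSets:
    def test_nesting(self):
        table, _ = synthetic_table(10, 0)
        h = set(resolve_feature_set(table.columns, "history"))
        ih = set(resolve_feature_set(table.columns, "imaging_history"))
        sih = set(resolve_feature_set(table.columns, "sim_imaging_history"))
        assert h < ih < sih

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            resolve_feature_set(["age"], "genomics")


class TestFitEvaluate:
    def test_null_auc_near_half(self):
        table, y = synthetic_table(500, 1)
        res = fit_evaluate(table, y, "sim_imaging_history", "logreg",
                           use_pca=False, folds=10, seed=0)
        assert 0.4 <= np.nanmean(res["roc_auc"]) <= 0.6

    @pytest.mark.parametrize("clf", CLASSIFIERS)
    def test_separable_signal_high_auc(self, clf):
        table, y = synthetic_table(300, 2, signal_in="sim", noise=0.3)
        res = fit_evaluate(table, y, "sim_imaging_history", clf,
                           use_pca=False, folds=10, seed=0)
        assert np.nanmean(res["roc_auc"]) >= 0.95

    def test_pca_component_count_exact(self):
        """3 equal-variance informative directions -> exactly 3 kept."""
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(0)
        latent = rng.normal(size=(400, 3))
        mix = rng.normal(size=(3, 8))
        X = latent @ mix  # rank 3, arbitrary 8-d embedding
        Xs = StandardScaler().fit_transform(X)
        pca = PCA(n_components=0.95, svd_solver="full").fit(Xs)
        assert pca.n_components_ == 3

    def test_insufficient_balance_rejected(self):
        table, y = synthetic_table(30, 3)
        y[:] = 0
        y[:4] = 1
        with pytest.raises(ValueError, match="class"):
            fit_evaluate(table, y, "history", "knn", False, folds=10, seed=0)

    def test_missing_cells_rejected(self):
        table, y = synthetic_table(40, 4)
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_evaluate(table, y, "sim_imaging_history", "knn", False,
                         folds=5, seed=0)

    def test_leak_freedom_transform_checksums(self):
        """Shuffling test-fold labels never changes training-fold
        transforms (standardizer + PCA fit on train only)."""
        from sklearn.decomposition import PCA
        from sklearn.model_selection import StratifiedKFold
        from sklearn.preprocessing import StandardScaler

        table, y = synthetic_table(100, 5)
        X = table[resolve_feature_set(table.columns, "sim_imaging_history")].to_numpy()

        def transform_checksums(labels):
            sums = []
            skf = StratifiedKFold(5, shuffle=True, random_state=0)
            for tr, te in skf.split(X, labels):
                scaler = StandardScaler().fit(X[tr])
                pca = PCA(n_components=0.95, svd_solver="full").fit(
                    scaler.transform(X[tr]))
                blob = scaler.mean_.tobytes() + pca.components_.tobytes()
                sums.append(hashlib.sha256(blob).hexdigest())
            return sums

        y2 = y.copy()
        # shuffle labels within one held-out fold only
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        _, te = next(iter(skf.split(X, y)))
        rng = np.random.default_rng(0)
        y2[te] = rng.permutation(y2[te])
        if np.array_equal(
                [tuple(x) for x in skf.split(X, y)][0][0],
                [tuple(x) for x in list(skf.split(X, y2))][0][0]):
            assert transform_checksums(y)[0] == transform_checksums(y2)[0]


class TestCompareAndSelect:
    def test_deterministic(self):
        table, y = synthetic_table(80, 6, signal_in="sim")
        r1 = compare_and_select(table, y, "sim_imaging_history", folds=5, seed=3)
        r2 = compare_and_select(table, y, "sim_imaging_history", folds=5, seed=3)
        assert r1.grid.equals(r2.grid)
        assert (r1.selected_classifier, r1.selected_pca) == \
            (r2.selected_classifier, r2.selected_pca)

    def test_grid_shape(self):
        table, y = synthetic_table(60, 7)
        rep = compare_and_select(table, y, "history", folds=5, seed=0)
        assert len(rep.grid) == 8  # 4 classifiers x {pca, no pca}
        assert set(rep.grid["classifier"]) == set(CLASSIFIERS)

    def test_metrics_in_unit_interval(self):
        table, y = synthetic_table(60, 8)
        rep = compare_and_select(table, y, "imaging_history", folds=5, seed=0)
        for m in ("roc_auc", "accuracy", "recall", "precision"):
            assert (rep.grid[f"{m}_mean"].between(0, 1)).all()
            assert (rep.grid[f"{m}_sd"] >= 0).all()

    def test_nested_information_ordering(self):
        """Signal planted only in simulation columns: the sim feature set
        beats history by a wide margin."""
        table, y = synthetic_table(500, 9, signal_in="sim")
        sim = compare_and_select(table, y, "sim_imaging_history", folds=10, seed=0)
        hist = compare_and_select(table, y, "history", folds=10, seed=0)
        assert sim.selected_auc > hist.selected_auc + 0.15

    @pytest.mark.filterwarnings("ignore::RuntimeWarning",
                                "ignore::UserWarning")
    def test_degenerate_constant_features_tiebreak(self):
        rng = np.random.default_rng(1)
        table, y = synthetic_table(60, 10)
        for c in table.columns:
            table[c] = 1.0  # constant features, AUC ~ 0.5 everywhere
        rep = compare_and_select(table, y, "history", folds=5, seed=0)
        assert rep.selected_classifier in CLASSIFIERS
        assert 0.3 <= rep.selected_auc <= 0.7
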