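import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vfprog.diagnostics import (
    combine_with_gi,
    compare_auc,
    fit_logistic,
    lr_test,
    metric_correlations,
    pauc,
    roc,
    select_threshold,
)


def newton_logistic_oracle(Z, y, iters=200):
    """Independent from-scratch Newton-Raphson for logistic MLE."""
    beta = np.zeros(Z.shape[1])
    for _ in range(iters):
        eta = Z @ beta
        p = 1 / (1 + np.exp(-eta))
        g = Z.T @ (y - p)
        W = p * (1 - p)
        H = Z.T @ (Z * W[:, None])
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(g).max() < 1e-10:
            break
    return beta


def random_design(rng, n=150, k=3, beta=None):
    X = rng.normal(size=(n, k))
    if beta is None:
        beta = rng.normal(0, 1, k + 1)
    eta = beta[0] + X @ beta[1:]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(k)]), y


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.concatenate([np.ones(50), np.zeros(141)])
        X = pd.DataFrame(index=range(191))
        m = fit_logistic(X, y)
        assert m.params[0] == pytest.approx(math.log(50 / 141), abs=1e-8)
        assert np.allclose(m.fitted_probs, 50 / 191, atol=1e-8)
        assert m.aic == pytest.approx(2 * 1 - 2 * m.llf)

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            X, y = random_design(rng)
            m = fit_logistic(X, y)
            Z = np.column_stack([np.ones(len(X)), X.to_numpy()])
            np.testing.assert_allclose(m.params, newton_logistic_oracle(Z, y), atol=1e-6)

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(1)
        X, y = random_design(rng, n=60)
        X.iloc[0, 0] = np.nan
        m = fit_logistic(X, y)
        assert m.n_used == 59 and m.n_dropped == 1

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        X, _ = random_design(rng, n=30)
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(X, np.ones(30))

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(3)
        X, y = random_design(rng, n=80, k=2)
        X["dup"] = X["x0"] * 2.0
        with pytest.raises(ValueError, match="dup|x0"):
            fit_logistic(X, y)

    def test_quasi_separation_warns_but_fits(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.warns(UserWarning, match="separation"):
            m = fit_logistic(X, y)
        assert np.isfinite(m.aic)


class TestNesting:
    def test_nested_loglik_monotone(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X, y = random_design(rng, n=100, k=3)
            full = fit_logistic(X, y)
            reduced = fit_logistic(X[["x0"]], y)
            assert full.llf >= reduced.llf - 1e-9

    def test_combine_with_gi(self):
        rng = np.random.default_rng(5)
        X, y = random_design(rng, n=200, k=2)
        gi = X[["x0"]]
        other = X[["x1"]]
        combined, p = combine_with_gi(gi, other, y)
        assert 0 <= p <= 1
        gi_only = fit_logistic(gi, y)
        assert combined.llf >= gi_only.llf

    def test_combine_duplicate_columns_rejected(self):
        rng = np.random.default_rng(6)
        X, y = random_design(rng, n=50, k=1)
        with pytest.raises(ValueError, match="duplicated"):
            combine_with_gi(X, X, y)

    def test_added_true_predictor_improves_loglik(self):
        rng = np.random.default_rng(7)
        X, y = random_design(rng, n=300, k=2, beta=np.array([0.0, 0.2, 2.5]))
        combined, p = combine_with_gi(X[["x0"]], X[["x1"]], y)
        gi_only = fit_logistic(X[["x0"]], y)
        assert combined.llf > gi_only.llf
        assert p < 0.01

    def test_lr_test_requires_nesting(self):
        rng = np.random.default_rng(8)
        X, y = random_design(rng, n=60, k=2)
        m = fit_logistic(X, y)
        with pytest.raises(ValueError):
            lr_test(m, m)


class TestROC:
    def test_perfect_classifier(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        p = np.r_[np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)]
        s = roc(p, y)
        assert s.auc == 1.0
        assert pauc(p, y) == 1.0

    def test_constant_probs_chance(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        p = np.full(20, 0.3)
        s = roc(p, y)
        assert s.auc == pytest.approx(0.5)
        assert pauc(p, y) == pytest.approx(0.15**2 / 2 / 0.15)  # = 0.075

    def test_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(9)
        y = (rng.uniform(size=50) < 0.4).astype(float)
        y[:2] = [0, 1]
        p = np.round(rng.uniform(size=50), 2)  # force ties
        wins = 0.0
        pos = p[y == 1]
        neg = p[y == 0]
        for a in pos:
            for b in neg:
                wins += 1.0 if a > b else 0.5 if a == b else 0.0
        assert roc(p, y).auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_pauc_matches_segment_oracle(self):
        rng = np.random.default_rng(10)
        y = (rng.uniform(size=80) < 0.3).astype(float)
        y[:2] = [0, 1]
        p = rng.uniform(size=80)
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
        # oracle: walk segments, clip at fpr = 0.15, accumulate trapezoids
        area = 0.0
        for (x0, y0), (x1, y1) in zip(zip(fpr, tpr), zip(fpr[1:], tpr[1:])):
            if x0 >= 0.15:
                break
            if x1 > 0.15:
                y1 = y0 + (y1 - y0) * (0.15 - x0) / (x1 - x0)
                x1 = 0.15
            area += 0.5 * (y0 + y1) * (x1 - x0)
        assert pauc(p, y) == pytest.approx(area / 0.15, abs=1e-9)

    def test_auc_complement_symmetry(self):
        rng = np.random.default_rng(11)
        y = np.r_[np.zeros(30), np.ones(20)]
        p = rng.permutation(np.linspace(0.01, 0.99, 50))  # tie-free
        assert roc(p, y).auc + roc(-p, y).auc == pytest.approx(1.0, abs=1e-12)

    def test_pauc_bounds(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            y = (rng.uniform(size=40) < 0.4).astype(float)
            y[:2] = [0, 1]
            p = rng.uniform(size=40)
            v = pauc(p, y)
            assert 0.0 <= v <= 1.0
            assert v <= roc(p, y).auc / 0.15 + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc(np.array([0.1, 0.2]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="spec_lo"):
            pauc(np.array([0.1, 0.2]), np.array([1.0, 0.0]), spec_lo=1.5)


class TestCompareAUC:
    def test_identical_probs_p_one(self):
        rng = np.random.default_rng(13)
        y = np.r_[np.zeros(30), np.ones(30)]
        p = rng.uniform(size=60)
        assert compare_auc(p, p, y, kind="auc") == 1.0
        assert compare_auc(p, p, y, kind="pauc", n_boot=200, seed=0) == 1.0

    def test_strong_vs_noise_detected(self):
        rng = np.random.default_rng(14)
        n = 200
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        strong = y + rng.normal(0, 0.3, n)
        noise = rng.uniform(size=n)
        assert compare_auc(strong, noise, y, kind="auc") < 0.01
        assert compare_auc(strong, noise, y, kind="pauc", n_boot=500, seed=1) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            compare_auc(np.ones(3), np.ones(4), np.array([0, 1, 0]))


class TestCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(size=20)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.uniform(size=20)})
        r, p = metric_correlations(df)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] < 1e-12

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        r, p = metric_correlations(df)
        rr = float(np.corrcoef(df["a"], df["b"])[0, 1])
        n = 10
        tstat = rr * math.sqrt((n - 2) / (1 - rr**2))
        pp = 2 * stats.t.sf(abs(tstat), n - 2)
        assert r.loc["a", "b"] == pytest.approx(rr, abs=1e-12)
        assert p.loc["a", "b"] == pytest.approx(pp, abs=1e-12)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.1, 0.5, 0.9]})
        with pytest.raises(ValueError, match="a"):
            metric_correlations(df)


class TestSelectThreshold:
    def test_perfect_separation(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        p = np.r_[np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)]
        thr, sens, spec = select_threshold(p, y)
        assert sens == 1.0 and spec == 1.0
        assert 0.4 < thr < 0.6

    def test_false_positive_budget(self):
        rng = np.random.default_rng(17)
        y = np.r_[np.zeros(141), np.ones(50)]
        p = rng.uniform(size=191)
        thr, sens, spec = select_threshold(p, y, min_spec=0.85)
        fp = int(((p >= thr) & (y == 0)).sum())
        assert spec >= 0.85
        assert fp <= 21  # spec >= 0.85 over 141 stable eyes

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            y = (rng.uniform(size=n) < 0.4).astype(float)
            y[:2] = [0, 1]
            p = np.round(rng.uniform(size=n), 2)
            thr, sens, spec = select_threshold(p, y, min_spec=0.85)
            # oracle: scan every candidate, track the best (sens, spec)
            uniq = np.unique(p)
            cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
            best = (-1.0, -1.0)
            for c in cands:
                pred = p >= c
                s = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
                sp = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
                if sp >= 0.85 and (s, sp) > best:
                    best = (float(s), float(sp))
            assert (sens, spec) == best


class TestCalibration:
    def test_lr_p_uniform_under_null_added_noise(self):
        """Adding a pure-noise column to GI yields ~Uniform(0,1) LR p-values."""
        rng = np.random.default_rng(19)
        ps = []
        for _ in range(300):
            X, y = random_design(rng, n=150, k=1, beta=np.array([-0.5, 1.0]))
            X["noise"] = rng.normal(size=150)
            _, p = combine_with_gi(X[["x0"]], X[["noise"]], y)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_delong_size_under_null(self):
        """Two independent noise classifiers: ~5% rejections at alpha = 0.05."""
        rng = np.random.default_rng(20)
        n = 100
        rejections = 0
        reps = 500
        for _ in range(reps):
            y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            pa = rng.uniform(size=n)
            pb = rng.uniform(size=n)
            rejections += compare_auc(pa, pb, y, kind="auc") < 0.05
        assert 0.03 <= rejections / reps <= 0.07
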