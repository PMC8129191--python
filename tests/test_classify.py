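"""Leave-one-out decoding, permutation significance, three-class metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import seegdecode as sd
from seegdecode.classify import accuracy_significance, compare_bands

from conftest import make_feature_set


def _labels(n_per_class, classes=("own", "other")):
    out = []
    for c in classes:
        out.extend([c] * n_per_class)
    return np.array(out, dtype=object)


def separable_set(rng, n_per_class=20, n_features=30, margin=10.0, noise=0.01):
    labels = _labels(n_per_class)
    X = noise * rng.standard_normal((2 * n_per_class, n_features))
    X[labels == "own"] += margin
    X[labels == "other"] -= margin
    return make_feature_set(X, labels)


class TestLooDecode:
    @pytest.mark.parametrize("classifier", ["lda", "random_forest"])
    def test_separable_toy_perfect(self, classifier):
        fset = separable_set(np.random.default_rng(0))
        res = sd.loo_decode(fset, classifier=classifier, k=10,
                            selection_mode="none", seed=1)
        assert res.accuracy == 100.0
        assert res.permutation_p <= 1 / 1000

    def test_minimal_mechanics(self):
        fset = make_feature_set(
            np.array([[0.0], [0.1], [5.0], [5.1]]), _labels(2)
        )
        res = sd.loo_decode(fset, classifier="lda", k=1, selection_mode="none",
                            seed=0)
        assert res.n_trials == 4
        assert len(res.y_pred) == 4

    def test_pca_components_recorded(self):
        rng = np.random.default_rng(2)
        fset = separable_set(rng, n_features=20, noise=1.0, margin=2.0)
        res = sd.loo_decode(fset, classifier="lda", k=20, selection_mode="none",
                            seed=3)
        assert res.n_components_used is not None
        assert all(1 <= n <= 20 for n in res.n_components_used)

    def test_rf_seed_reproducible_and_stable(self):
        fset = separable_set(np.random.default_rng(4), margin=1.0, noise=1.0)
        a = sd.loo_decode(fset, classifier="random_forest", k=10,
                          selection_mode="none", seed=7)
        b = sd.loo_decode(fset, classifier="random_forest", k=10,
                          selection_mode="none", seed=7)
        assert a.accuracy == b.accuracy
        accs = [
            sd.loo_decode(fset, classifier="random_forest", k=10,
                          selection_mode="none", seed=s).accuracy
            for s in range(3)
        ]
        assert max(accs) - min(accs) < 3.0

    def test_predictions_invariant_to_trial_order(self):
        rng = np.random.default_rng(5)
        fset = separable_set(rng, margin=3.0, noise=1.0)
        res = sd.loo_decode(fset, classifier="lda", k=10, seed=11)
        perm = rng.permutation(fset.n_trials)
        fset_p = make_feature_set(fset.matrix[perm], fset.labels[perm])
        res_p = sd.loo_decode(fset_p, classifier="lda", k=10, seed=11)
        np.testing.assert_array_equal(res.y_pred[perm], res_p.y_pred)

    def test_too_few_trials_per_class_rejected(self):
        fset = make_feature_set(np.zeros((3, 4)), np.array(
            ["own", "own", "other"], dtype=object))
        with pytest.raises(ValueError, match="2 trials"):
            sd.loo_decode(fset, selection_mode="none")


class TestAccuracySignificance:
    def test_perfect_predictions_minimal_p(self):
        y = _labels(60)
        thr, p = accuracy_significance(y, y, n_perm=1000, seed=0)
        assert p <= 1 / 1000

    def test_threshold_matches_hypergeometric_oracle(self):
        """Balanced n=120: agreements under label shuffles are 2X with
        X ~ Hypergeometric(120, 60, 60).

        The hypergeometric CDF hits 0.95 exactly at X=34, so a single
        empirical 95th percentile flips between the adjacent lattice
        values (56.67 and 58.33); the across-stream mean is compared
        against the half-step oracle 2*34.5/120 = 57.5.
        """
        assert stats.hypergeom.cdf(34, 120, 60, 60) == pytest.approx(0.95, abs=1e-3)
        y_true = _labels(60)
        rng = np.random.default_rng(1)
        y_pred = y_true[rng.permutation(120)]
        thrs = [
            accuracy_significance(y_pred, y_true, n_perm=2000, seed=s)[0]
            for s in range(10)
        ]
        oracle = 100.0 * 2 * 34.5 / 120
        assert abs(np.mean(thrs) - oracle) <= 1.0

    def test_independent_predictions_p_half(self):
        rng = np.random.default_rng(3)
        ps = []
        for s in range(20):
            y_true = _labels(30)
            y_pred = y_true[rng.permutation(60)]
            _, p = accuracy_significance(y_pred, y_true, n_perm=500, seed=s)
            ps.append(p)
        assert abs(np.mean(ps) - 0.5) < 0.12

    def test_threshold_shrinks_with_trial_count(self):
        thrs = []
        for n in (40, 80, 120, 240):
            y = _labels(n // 2)
            thr, _ = accuracy_significance(y, y, n_perm=2000, seed=n)
            thrs.append(thr)
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))
        assert thrs[-1] < 58.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            accuracy_significance(_labels(5), _labels(6))


class TestThreeClassEvaluation:
    def _result(self, y_true, y_pred, scores=None):
        classes = sorted(set(y_true))
        if scores is None:
            scores = np.array(
                [[1.0 if c == p else 0.0 for c in classes] for p in y_pred]
            )
        return sd.DecodingResult(
            y_true=np.asarray(y_true, dtype=object),
            y_pred=np.asarray(y_pred, dtype=object),
            classes=classes,
            scores=scores,
            accuracy=100.0 * float(np.mean(np.asarray(y_true) == np.asarray(y_pred))),
            classifier="lda",
        )

    def test_sensitivity_precision_hand_built(self):
        # class 'a': TP=8, FN=2 -> sensitivity 80; TP=8, FP=2 -> precision 80
        y_true = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        y_pred = (
            ["a"] * 8 + ["b"] * 2  # 2 a-trials missed
            + ["b"] * 9 + ["a"]    # 1 b-trial predicted a
            + ["c"] * 9 + ["a"]    # 1 c-trial predicted a
        )
        rep = sd.evaluate_threeclass(self._result(y_true, y_pred))
        assert rep.sensitivity["a"] == pytest.approx(80.0)
        assert rep.precision["a"] == pytest.approx(80.0)
        # per-class accuracy equals the sensitivity (diagonal over row sum)
        cm = rep.confusion_matrix
        for i, cls in enumerate(rep.classes):
            assert rep.sensitivity[cls] == pytest.approx(
                100.0 * cm[i, i] / cm[i].sum()
            )
        assert cm.sum(axis=1).tolist() == [10, 10, 10]

    def test_perfect_predictions(self):
        y = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        rep = sd.evaluate_threeclass(self._result(y, list(y)))
        assert np.all(np.diag(rep.confusion_matrix) == 5)
        for cls in rep.classes:
            assert rep.sensitivity[cls] == 100.0
            assert rep.precision[cls] == 100.0
            assert rep.roc[cls]["auc"] == 1.0

    def test_missing_scores_rejected(self):
        res = self._result(["a", "b", "c"], ["a", "b", "c"])
        res.scores = None
        with pytest.raises(ValueError, match="scores"):
            sd.evaluate_threeclass(res)


class TestCompareBands:
    def _table(self, accs):
        rows = []
        for (band, clf), values in accs.items():
            for v in values:
                rows.append({"band": band, "classifier": clf, "accuracy": v})
        return pd.DataFrame(rows)

    def test_identical_accuracies_f_zero(self):
        table = self._table({
            (b, c): [70.0] * 3
            for b in ("high_gamma", "beta") for c in ("lda", "rf")
        })
        out = compare_bands(table)
        assert (out["F"] == 0.0).all()
        assert (out["p"] == 1.0).all()

    def test_zero_residual_variance_guarded(self):
        table = self._table({
            ("high_gamma", "lda"): [90.0] * 3,
            ("beta", "lda"): [70.0] * 3,
            ("high_gamma", "rf"): [90.0] * 3,
            ("beta", "rf"): [70.0] * 3,
        })
        with pytest.raises(ValueError, match="residual"):
            compare_bands(table)

    def test_matches_closed_form_balanced_anova(self):
        rng = np.random.default_rng(0)
        bands = ["high_gamma", "beta", "alpha"]
        clfs = ["lda", "rf"]
        rows = []
        for bi, b in enumerate(bands):
            for c in clfs:
                for _ in range(9):
                    rows.append({
                        "band": b, "classifier": c,
                        "accuracy": 70 + 5 * bi + rng.standard_normal(),
                    })
        table = pd.DataFrame(rows)
        out = compare_bands(table).set_index("factor")

        # independent closed-form balanced two-way ANOVA (no interaction)
        y = table["accuracy"].to_numpy()
        grand = y.mean()
        n = len(y)
        ss_band = sum(
            len(g) * (g["accuracy"].mean() - grand) ** 2
            for _, g in table.groupby("band")
        )
        ss_clf = sum(
            len(g) * (g["accuracy"].mean() - grand) ** 2
            for _, g in table.groupby("classifier")
        )
        ss_tot = ((y - grand) ** 2).sum()
        df_band, df_clf = len(bands) - 1, len(clfs) - 1
        df_res = n - 1 - df_band - df_clf
        ss_res = ss_tot - ss_band - ss_clf
        f_band = (ss_band / df_band) / (ss_res / df_res)
        f_clf = (ss_clf / df_clf) / (ss_res / df_res)
        assert out.loc["band", "F"] == pytest.approx(f_band, abs=1e-6)
        assert out.loc["classifier", "F"] == pytest.approx(f_clf, abs=1e-6)

    def test_unbalanced_design_rejected(self):
        table = self._table({
            ("high_gamma", "lda"): [70.0, 71.0],
            ("beta", "lda"): [70.0],
        })
        with pytest.raises(ValueError, match="unbalanced"):
            compare_bands(table)
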