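import itertools
import json

import numpy as np
import pandas as pd
import pytest

from tapkin import severity_models as sm
from tapkin.errors import (
    CannotSynthesizeError,
    SchemaError,
    TierDegeneracyError,
    UndefinedMetricError,
    UsageError,
)
from tapkin.features import CSV_HEADER, FEATURE_NAMES
from tapkin.severity_models import (
    CANDIDATE_FEATURES,
    SeverityModelBundle,
    SplitProtocol,
    balance_classes,
    binary_prf,
    confusion_counts,
    count_nonmonotone_votes,
    evaluate,
    fit_scheme,
    predict,
    predict_multiclass,
    predict_ordinal,
    predict_tiered,
    rfe_select,
    route_ordinal,
    route_tiered,
)


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

class TestBalanceClasses:
    def _toy(self, counts, n_features=2, seed=0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for cls, n in counts.items():
            X.append(rng.random((n, n_features)) + 5 * ord(cls))
            y += [cls] * n
        return np.vstack(X), np.array(y)

    def test_median_target(self):
        X, y = self._toy({"A": 10, "B": 30, "C": 20})
        Xb, yb = balance_classes(X, y, seed=0)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [20, 20, 20]

    def test_already_balanced_is_identity(self):
        X, y = self._toy({"A": 15, "B": 15})
        Xb, yb = balance_classes(X, y, seed=0)
        assert Xb.shape == X.shape
        np.testing.assert_array_equal(np.sort(Xb, axis=0), np.sort(X, axis=0))

    def test_synthetic_points_on_segments(self):
        # geometric oracle: every new point must be a convex combination of
        # two original same-class points
        X, y = self._toy({"A": 6, "B": 20}, n_features=2, seed=1)
        Xb, yb = balance_classes(X, y, seed=2)
        originals = {tuple(row) for row in X[y == "A"]}
        added = [row for row in Xb[yb == "A"] if tuple(row) not in originals]
        assert added  # A grew from 6 to 13
        pool = X[y == "A"]
        for p in added:
            on_segment = False
            for a, b in itertools.combinations(pool, 2):
                d = b - a
                denom = float(d @ d)
                lam = float((p - a) @ d) / denom
                if -1e-9 <= lam <= 1 + 1e-9 and np.linalg.norm(a + lam * d - p) < 1e-9:
                    on_segment = True
                    break
            assert on_segment, p

    def test_singleton_class_rejected(self):
        X, y = self._toy({"A": 1, "B": 10})
        with pytest.raises(CannotSynthesizeError):
            balance_classes(X, y)

    def test_single_class_rejected(self):
        X, y = self._toy({"A": 10})
        with pytest.raises(UsageError):
            balance_classes(X, y)

    def test_deterministic(self):
        X, y = self._toy({"A": 5, "B": 25, "C": 12}, seed=3)
        a = balance_classes(X, y, seed=7)
        b = balance_classes(X, y, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# RFE
# ---------------------------------------------------------------------------

def separable_data(n=100, n_noise=5, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    informative = y[:, None] * 3.0 + 0.3 * rng.standard_normal((n, 3))
    noise = rng.standard_normal((n, n_noise))
    X = np.hstack([informative, noise])
    X = (X - X.mean(0)) / X.std(0)
    names = [f"info{i}" for i in range(3)] + [f"noise{i}" for i in range(n_noise)]
    return X, y, names


class TestRfeSelect:
    def test_noise_features_eliminated(self):
        hits = 0
        for seed in range(20):
            X, y, names = separable_data(seed=seed)
            selected = rfe_select(X, y, names, seed=seed)
            if all(not f.startswith("noise") for f in selected) and any(
                f.startswith("info") for f in selected
            ):
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_infinite_epsilon_leaves_one_feature(self):
        X, y, names = separable_data(seed=1)
        selected = rfe_select(X, y, names, epsilon=np.inf, seed=1)
        assert len(selected) == 1

    def test_identical_copies_tie_broken_by_order(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 80)
        col = y * 2.0 + 0.2 * rng.standard_normal(80)
        col = (col - col.mean()) / col.std()
        X = np.column_stack([col, col, col])
        selected = rfe_select(X, y, ["copy_a", "copy_b", "copy_c"], seed=2)
        assert selected == ["copy_a"]

    def test_requires_three_candidates(self):
        X, y, names = separable_data(seed=0)
        with pytest.raises(UsageError):
            rfe_select(X[:, :2], y, names[:2])


# ---------------------------------------------------------------------------
# routing oracles
# ---------------------------------------------------------------------------

def brute_force_tiered(p1, p2, p3):
    if p1 <= 0.5:
        return 0
    if p2 <= 0.5:
        return 1
    return 2 if p3 <= 0.5 else 3


class TestRouting:
    grid = np.round(np.linspace(0.0, 1.0, 11), 2)

    def test_tiered_matches_enumeration(self):
        for p1, p2, p3 in itertools.product(self.grid, repeat=3):
            expected = brute_force_tiered(p1, p2, p3)
            assert route_tiered(np.array([[p1, p2, p3]]))[0] == expected, (p1, p2, p3)

    def test_ordinal_sum_rule_matches_enumeration(self):
        for p1, p2, p3 in itertools.product(self.grid, repeat=3):
            votes = [int(p > 0.5) for p in (p1, p2, p3)]
            assert route_ordinal(np.array([[p1, p2, p3]]))[0] == sum(votes)

    def test_tiered_early_exit(self):
        assert route_tiered(np.array([[0.2, 0.9, 0.9]]))[0] == 0
        assert route_tiered(np.array([[0.9, 0.9, 0.2]]))[0] == 2

    def test_ordinal_vote_patterns(self):
        assert route_ordinal(np.array([[0.9, 0.9, 0.1]]))[0] == 2
        assert route_ordinal(np.array([[0.1, 0.1, 0.1]]))[0] == 0
        assert route_ordinal(np.array([[0.9, 0.1, 0.9]]))[0] == 2  # non-monotone

    def test_nonmonotone_counting(self):
        votes = np.array([[1, 0, 1], [1, 1, 0], [0, 0, 0], [0, 1, 0]])
        assert count_nonmonotone_votes(votes) == 2


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------

def oracle_prf(y_true, y_pred):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


class TestMetrics:
    def test_f1_formula(self):
        # precision 1.0, recall 0.5 -> f1 = 2/3
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 0, 0, 0])
        prec, rec, f1 = binary_prf(y_true, y_pred)
        assert (prec, rec) == (1.0, 0.5)
        assert f1 == pytest.approx(2 / 3)

    def test_prf_matches_counting_oracle_50_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 20))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            assert binary_prf(y_true, y_pred) == oracle_prf(y_true, y_pred)

    def test_confusion_matches_counting_oracle_50_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            labels = [0, 1, 2, 3]
            y_true = rng.integers(0, 4, n)
            y_pred = rng.integers(0, 4, n)
            cm = confusion_counts(y_true, y_pred, labels)
            for i, j in itertools.product(range(4), repeat=2):
                expected = sum(
                    1 for t, p in zip(y_true, y_pred) if t == i and p == j
                )
                assert cm[i, j] == expected
            assert cm.sum() == n
            # rows sum to class counts
            for i in range(4):
                assert cm[i].sum() == int((y_true == i).sum())


# ---------------------------------------------------------------------------
# fitting end to end
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiered_bundle(small_cohort):
    return fit_scheme(small_cohort, "tiered", SplitProtocol(seed=11))


class TestFitScheme:
    def test_tiered_macro_accuracy(self, tiered_bundle):
        assert tiered_bundle.metrics.macro_accuracy >= 0.8

    def test_selected_features_are_candidates(self, tiered_bundle):
        for m in tiered_bundle.models:
            assert set(m["features"]) <= set(CANDIDATE_FEATURES)

    def test_multiclass_separable_pr_auc_1(self):
        rng = np.random.default_rng(3)
        n = 60
        rows = {f: rng.random(n) for f in CANDIDATE_FEATURES}
        table = pd.DataFrame(rows)
        table["score"] = (np.arange(n) < n // 2).astype(int) * 2  # scores 0 and 2
        table.loc[table["score"] == 0, "mean_amplitude"] += 50.0  # perfectly separated
        table["is_control"] = table["score"] == 0
        bundle = fit_scheme(table, "multiclass", SplitProtocol(seed=4))
        assert bundle.metrics.per_model["multiclass"]["pr_auc"] == pytest.approx(1.0)

    def test_ordinal_fit_and_report(self, small_cohort):
        bundle = fit_scheme(small_cohort, "ordinal", SplitProtocol(seed=11))
        assert len(bundle.models) == 3
        assert bundle.metrics.n_nonmonotone_votes is not None

    def test_unknown_scheme_rejected(self, small_cohort):
        with pytest.raises(UsageError):
            fit_scheme(small_cohort, "deep", SplitProtocol())

    def test_tier_degeneracy(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({f: rng.random(40) for f in CANDIDATE_FEATURES})
        table["score"] = [0] * 20 + [1] * 20  # no rows ever reach tier 3
        table["is_control"] = table["score"] == 0
        with pytest.raises(TierDegeneracyError):
            fit_scheme(table, "tiered", SplitProtocol(seed=0))

    def test_missing_columns_rejected(self):
        with pytest.raises(SchemaError):
            fit_scheme(pd.DataFrame({"mean_amplitude": [1, 2]}), "multiclass")

    def test_reproducibility(self, small_cohort):
        a = fit_scheme(small_cohort, "tiered", SplitProtocol(seed=21))
        b = fit_scheme(small_cohort, "tiered", SplitProtocol(seed=21))
        assert a.to_json() == b.to_json()


class TestSerialization:
    def test_roundtrip_identical_predictions(self, tiered_bundle, small_cohort, tmp_path):
        path = tmp_path / "bundle.json"
        tiered_bundle.to_json(path)
        restored = SeverityModelBundle.from_json(path)
        original, _ = predict_tiered(tiered_bundle, small_cohort)
        roundtrip, _ = predict_tiered(restored, small_cohort)
        np.testing.assert_array_equal(original, roundtrip)

    def test_bundle_is_plain_json(self, tiered_bundle):
        payload = json.loads(tiered_bundle.to_json())
        assert payload["scheme"] == "tiered"
        assert len(payload["models"]) == 3

    def test_missing_feature_column_rejected(self, tiered_bundle, small_cohort):
        broken = small_cohort.drop(columns=["rate"])
        with pytest.raises(SchemaError, match="rate"):
            predict_tiered(tiered_bundle, broken)


class TestEvaluate:
    def test_perfect_classifier_metrics(self):
        # craft a bundle-free check through the public metric helpers
        y = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        cm = confusion_counts(y, y, [0, 1, 2, 3])
        assert np.trace(cm) == len(y)

    def test_test_train_overlap_rejected(self, tiered_bundle, small_cohort):
        train_rows = small_cohort.loc[list(tiered_bundle.train_ids)[:5]]
        with pytest.raises(UsageError, match="overlap"):
            evaluate(tiered_bundle, train_rows)

    def test_single_class_test_rejected(self, tiered_bundle, small_cohort):
        test_ids = [i for i in small_cohort.index if i not in set(tiered_bundle.train_ids)]
        test = small_cohort.loc[test_ids]
        only0 = test[test["score"] == 0]
        with pytest.raises(UndefinedMetricError):
            evaluate(tiered_bundle, only0)

    def test_random_predictions_pr_auc_near_prevalence(self):
        # permutation baseline: with random scores PR-AUC concentrates at the
        # positive prevalence
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(8)
        n = 400
        y = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
        aucs = [
            average_precision_score(y, rng.random(n)) for _ in range(200)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


class TestNoLeakage:
    def test_perturbing_test_rows_does_not_change_fit(self, small_cohort):
        protocol = SplitProtocol(seed=31)
        base = fit_scheme(small_cohort, "tiered", protocol)
        perturbed = small_cohort.copy()
        test_ids = [i for i in perturbed.index if i not in set(base.train_ids)]
        perturbed.loc[test_ids, FEATURE_NAMES] *= 3.7
        perturbed.loc[test_ids, FEATURE_NAMES] += 11.0
        refit = fit_scheme(perturbed, "tiered", protocol)
        assert refit.scaler_mean == base.scaler_mean
        assert refit.scaler_sd == base.scaler_sd
        for ma, mb in zip(base.models, refit.models):
            assert ma["features"] == mb["features"]
            np.testing.assert_array_equal(ma["coef"], mb["coef"])
            np.testing.assert_array_equal(ma["intercept"], mb["intercept"])


class TestPredictDispatch:
    def test_predict_routes_by_scheme(self, tiered_bundle, small_cohort):
        scores = predict(tiered_bundle, small_cohort)
        assert set(np.unique(scores)) <= {0, 1, 2, 3}

    def test_scheme_mismatch_rejected(self, tiered_bundle, small_cohort):
        with pytest.raises(UsageError):
            predict_ordinal(tiered_bundle, small_cohort)
        with pytest.raises(UsageError):
            predict_multiclass(tiered_bundle, small_cohort)
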