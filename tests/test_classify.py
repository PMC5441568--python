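import numpy as np
import pytest

from icnpipe import classify
from icnpipe.classify import (
    FeatureSet,
    SVMParams,
    _platt_prob,
    classification_score,
    default_grid,
    evaluate,
    forward_select,
    loo_ensemble,
    score_followup,
)
from icnpipe.errors import InvalidInputError, UndefinedMetricError


def planted_features(seed, n=20, k=8, v=100, shift=1.5, comps=(3, 7)):
    """Half patients, half controls; the two planted components carry
    complementary signal (a shared latent cancels only when both are used)."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n, k, v))
    labels = np.array([1] * (n // 2) + [0] * (n - n // 2))
    d_a = rng.normal(size=v)
    d_a /= np.linalg.norm(d_a)
    d_b = rng.normal(size=v)
    d_b /= np.linalg.norm(d_b)
    z = rng.normal(size=n)
    amp = 4.0
    data[:, comps[0]] += amp * (shift * labels + z)[:, None] * d_a[None, :]
    data[:, comps[1]] += amp * (shift * labels - z)[:, None] * d_b[None, :]
    sids = [f"S{i:02d}" for i in range(n)]
    fs = FeatureSet(data, [f"IC{c}" for c in range(k)], sids, ["baseline"] * n)
    return fs, labels


class TestForwardSelect:
    def test_planted_pair_recovered(self, small_grid):
        hits = {3: 0, 7: 0}
        null_selected = []
        for seed in range(10):
            fs, y = planted_features(seed)
            clf = forward_select(fs, y, anchors=(0, 1), grid=small_grid)
            assert set(clf.selected_components) >= {0, 1}
            for c in (3, 7):
                hits[c] += c in clf.selected_components
            null_selected.extend(
                c for c in clf.selected_components if c not in (0, 1, 3, 7)
            )
        assert hits[3] >= 9 and hits[7] >= 9
        # each null component appears in at most 1 of 10 seeds
        for c in (2, 4, 5, 6):
            assert null_selected.count(c) <= 1

    def test_perfect_anchors_terminate_immediately(self, small_grid):
        fs, y = planted_features(0, comps=(0, 1), shift=6.0)
        clf = forward_select(fs, y, anchors=(0, 1), grid=small_grid)
        assert clf.selected_components == [0, 1]
        assert clf.inner_accuracy == 1.0

    def test_all_noise_rarely_grows_beyond_anchors(self, small_grid):
        extra = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            fs = FeatureSet(
                rng.normal(size=(20, 6, 60)), [f"IC{c}" for c in range(6)],
                [f"S{i}" for i in range(20)], ["baseline"] * 20,
            )
            y = np.array([1] * 10 + [0] * 10)
            clf = forward_select(fs, y, anchors=(0, 1), grid=small_grid)
            assert set(clf.selected_components) >= {0, 1}
            extra += len(clf.selected_components) - 2
        assert extra / 5 <= 2.0

    def test_deterministic(self, small_grid):
        fs, y = planted_features(4)
        a = forward_select(fs, y, anchors=(0, 1), grid=small_grid)
        b = forward_select(fs, y, anchors=(0, 1), grid=small_grid)
        assert a.selected_components == b.selected_components
        assert a.svm_params == b.svm_params

    def test_single_class_rejected(self, small_grid):
        fs, _ = planted_features(0)
        with pytest.raises(InvalidInputError):
            forward_select(fs, np.ones(fs.n_subjects, dtype=int), grid=small_grid)

    def test_too_few_subjects_rejected(self, small_grid):
        fs, y = planted_features(0, n=3)
        with pytest.raises(InvalidInputError):
            forward_select(fs, y[:3], grid=small_grid)

    def test_default_grid_contents(self):
        grid = default_grid()
        assert len(grid) == 15
        assert {p.C for p in grid} == {0.01, 0.1, 1.0, 10.0, 100.0}
        assert {p.kernel for p in grid} == {"linear", "rbf"}


class TestClassificationScore:
    def test_probability_to_score_mapping(self):
        # s = 2p - 1: certainty patient -> +1, certainty control -> -1,
        # p = 0.5 -> 0 (decision boundary)
        assert 2 * _platt_prob(np.array([1e3]), (10.0, 0.0))[0] - 1 == pytest.approx(1)
        assert 2 * _platt_prob(np.array([-1e3]), (10.0, 0.0))[0] - 1 == pytest.approx(-1)
        assert 2 * _platt_prob(np.array([0.0]), (10.0, 0.0))[0] - 1 == pytest.approx(0)

    def test_score_range_and_sign(self, small_grid):
        fs, y = planted_features(1, shift=3.0)
        clf = forward_select(fs, y, anchors=(0, 1), grid=small_grid)
        scores = classification_score(clf, fs.data)
        assert np.all(scores >= -1) and np.all(scores <= 1)
        # strongly separated training data: scores track the labels
        assert np.mean((scores > 0) == (y == 1)) >= 0.9

    def test_single_map_returns_float(self, small_grid):
        fs, y = planted_features(2)
        clf = forward_select(fs, y, anchors=(0, 1), grid=small_grid)
        s = classification_score(clf, fs.data[0])
        assert isinstance(s, float)

    def test_dimension_mismatch_rejected(self, small_grid):
        fs, y = planted_features(3)
        clf = forward_select(fs, y, anchors=(0, 1), grid=small_grid)
        with pytest.raises(InvalidInputError):
            classification_score(clf, np.zeros((4, 50)))


class TestEvaluate:
    def test_headline_metrics_exact(self):
        labels = [1] * 34 + [0] * 34
        preds = [1] * 26 + [0] * 8 + [0] * 31 + [1] * 3
        m = evaluate(preds, labels)
        assert round(100 * m.accuracy, 2) == 83.82
        assert round(100 * m.sensitivity, 2) == 76.47
        assert round(100 * m.specificity, 2) == 91.18

    def test_independent_testset_metrics_exact(self):
        labels = [1] * 33 + [0] * 20
        preds = [1] * 26 + [0] * 7 + [0] * 14 + [1] * 6
        m = evaluate(preds, labels)
        assert round(100 * m.accuracy, 1) == 75.5
        assert round(100 * m.specificity, 2) == 70.00
        assert round(100 * m.sensitivity, 2) == 78.79

    def test_auc_perfect_separation(self):
        labels = [0, 0, 0, 1, 1, 1]
        scores = [-0.9, -0.5, -0.1, 0.2, 0.6, 0.9]
        m = evaluate([int(s > 0) for s in scores], labels, scores)
        assert m.auc == 1.0

    def test_balanced_class_identity(self, rng):
        labels = np.array([1] * 15 + [0] * 15)
        preds = rng.integers(0, 2, size=30)
        m = evaluate(preds, labels)
        assert m.accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            evaluate([1, 1, 0], [1, 1, 1])


@pytest.fixture(scope="module")
def ensemble(small_grid):
    fs, y = planted_features(5, n=12, shift=2.0)
    result, metrics = loo_ensemble(fs, y, anchors=(0, 1), grid=small_grid)
    return fs, y, result, metrics


class TestLooEnsemble:
    def test_base_score_count_is_n_minus_one(self, ensemble):
        fs, y, result, _ = ensemble
        assert result.base_scores.shape == (12, 11)
        assert not np.isnan(result.base_scores).any()

    def test_median_aggregation_bounds(self, ensemble):
        _, _, result, _ = ensemble
        for i in range(12):
            row = result.base_scores[i]
            assert row.min() <= result.aggregated_scores[i] <= row.max()
            # odd base count: the median is an actual base score
            assert result.aggregated_scores[i] in row

    def test_predicted_label_is_score_sign(self, ensemble):
        _, _, result, _ = ensemble
        assert np.array_equal(result.predicted, (result.aggregated_scores > 0))

    def test_anchors_always_selected(self, ensemble):
        _, _, result, _ = ensemble
        for fold in result.folds:
            assert set(fold.selected_components) >= {0, 1}
        assert result.selection_frequency[0] == 1.0
        assert result.selection_frequency[1] == 1.0

    def test_no_leakage_into_fold_selection(self, small_grid):
        fs, y = planted_features(6, n=12, shift=2.0)
        result, _ = loo_ensemble(fs, y, anchors=(0, 1), grid=small_grid)
        noisy = FeatureSet(
            fs.data.copy(), fs.component_labels, fs.subject_ids, fs.sessions
        )
        noisy.data[4] = np.random.default_rng(99).normal(size=fs.data[4].shape)
        result2, _ = loo_ensemble(noisy, y, anchors=(0, 1), grid=small_grid)
        # fold 4 trained without subject 4: its selection cannot change
        assert result.folds[4].selected_components == result2.folds[4].selected_components
        assert result.folds[4].svm_params == result2.folds[4].svm_params
        assert result.aggregated_scores[4] != result2.aggregated_scores[4]

    def test_label_permutation_near_chance(self, small_grid):
        fs, y = planted_features(7, n=16, shift=2.0)
        y_perm = np.random.default_rng(3).permutation(y)
        _, m = loo_ensemble(fs, y_perm, anchors=(0, 1), grid=small_grid)
        # 95% binomial interval around 0.5 for n=16
        assert 0.5 - 1.96 * 0.125 <= m.accuracy <= 0.5 + 1.96 * 0.125

    def test_too_few_subjects(self, small_grid):
        fs, y = planted_features(0, n=4)
        with pytest.raises(InvalidInputError):
            loo_ensemble(fs, y, grid=small_grid)


class TestScoreFollowup:
    def test_identical_followup_scores_exactly_equal(self, small_grid):
        fs, y = planted_features(8, n=12, shift=2.0)
        result, _ = loo_ensemble(fs, y, anchors=(0, 1), grid=small_grid)
        fu = FeatureSet(
            fs.data[:4].copy(), fs.component_labels, fs.subject_ids[:4],
            ["followup"] * 4,
        )
        pairs = score_followup(result, fu)
        for sid, (baseline, followup) in pairs.items():
            assert followup == baseline

    def test_normalized_followup_scores_lower(self, small_grid):
        fs, y = planted_features(9, n=12, shift=2.5)
        result, _ = loo_ensemble(fs, y, anchors=(0, 1), grid=small_grid)
        rng = np.random.default_rng(9)
        # full responders: patient rows replaced by control-like feature maps
        fu_data = rng.normal(size=(4, fs.k, fs.data.shape[2]))
        fu = FeatureSet(
            fu_data, fs.component_labels, fs.subject_ids[:4], ["followup"] * 4
        )
        pairs = score_followup(result, fu)
        lower = sum(f < b for b, f in pairs.values())
        assert lower >= 3

    def test_unknown_subject_rejected(self, small_grid):
        fs, y = planted_features(0, n=12)
        result, _ = loo_ensemble(fs, y, anchors=(0, 1), grid=small_grid)
        fu = FeatureSet(
            fs.data[:1], fs.component_labels, ["GHOST"], ["followup"]
        )
        with pytest.raises(InvalidInputError):
            score_followup(result, fu)
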