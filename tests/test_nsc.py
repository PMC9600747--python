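"""Nearest shrunken centroids: closed forms, oracle equivalence, CV rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ercdc import nsc
from ercdc.nsc import CVResult, NearestShrunkenCentroids

from conftest import make_expr


def brute_force_predict(model, X, delta):
    """Independent discriminant evaluation with explicit loops."""
    n_classes = len(model.classes_)
    s = model.pooled_sd_ + model.s0_
    labels = []
    for row in np.asarray(X, dtype=float):
        best, best_score = None, np.inf
        for k in range(n_classes):
            score = 0.0
            for i in range(model.n_features_in_):
                d = model.d_[k, i]
                d_shrunk = np.sign(d) * max(abs(d) - delta, 0.0)
                centroid = model.overall_centroid_[i] + \
                    model.mk_[k] * s[i] * d_shrunk
                score += (row[i] - centroid) ** 2 / s[i] ** 2
            score -= 2.0 * np.log(model.priors_[k])
            if score < best_score:  # strict: ties keep the earlier class
                best, best_score = k, score
        labels.append(model.classes_[best])
    return np.array(labels)


def two_class_toy():
    """Balanced two-class data with unit pooled SD on the single gene."""
    c = np.sqrt(0.6)  # within-class SS = 2 * 5c^2 -> pooled sd over n-K=6 is 1
    spread = np.array([-1.5, -0.5, 0.5, 1.5]) * c
    x = np.concatenate([spread, spread + 2.0])[:, None]
    y = np.array(["a"] * 4 + ["b"] * 4)
    return x, y


class TestTrainCentroids:
    def test_closed_form_standardized_difference(self):
        x, y = two_class_toy()
        model = NearestShrunkenCentroids(s0=0.0).fit(x, y)
        assert np.allclose(model.pooled_sd_, [1.0])
        m_k = np.sqrt(1 / 4 - 1 / 8)
        assert np.allclose(model.d_[:, 0], [-1 / m_k, 1 / m_k])

    def test_equal_class_means_give_zero_difference(self, rng):
        x = np.vstack([rng.normal(0, 1, (4, 3)), rng.normal(0, 1, (4, 3))])
        x[:, 0] = np.tile([1.0, 2.0, 3.0, 4.0], 2)  # identical per class
        model = NearestShrunkenCentroids().fit(x, ["a"] * 4 + ["b"] * 4)
        assert np.allclose(model.d_[:, 0], 0.0)

    def test_default_priors_are_class_proportions(self, rng):
        x = rng.normal(0, 1, (8, 2))
        model = NearestShrunkenCentroids().fit(x, ["a"] * 6 + ["b"] * 2)
        assert np.allclose(model.priors_, [0.75, 0.25])

    def test_small_class_is_an_error(self, rng):
        with pytest.raises(ValueError, match=">= 2 samples"):
            NearestShrunkenCentroids().fit(rng.normal(0, 1, (3, 2)),
                                           ["a", "a", "b"])


class TestShrink:
    def test_zero_threshold_returns_unshrunken_centroids(self, rng):
        x = rng.normal(0, 1, (12, 5))
        y = ["a"] * 6 + ["b"] * 6
        model = NearestShrunkenCentroids().fit(x, y)
        _, shrunken = model.shrink(0.0)
        assert np.allclose(shrunken, model.centroids_)

    def test_threshold_beyond_max_collapses_to_overall(self, rng):
        x = rng.normal(0, 1, (12, 5))
        model = NearestShrunkenCentroids().fit(x, ["a"] * 6 + ["b"] * 6)
        d_shrunk, shrunken = model.shrink(np.abs(model.d_).max() + 0.1)
        assert np.all(d_shrunk == 0)
        assert np.allclose(shrunken, model.overall_centroid_[None, :])

    def test_soft_threshold_arithmetic(self):
        assert np.isclose(np.sign(2.5) * max(abs(2.5) - 1.88, 0), 0.62)
        x, y = two_class_toy()
        model = NearestShrunkenCentroids(s0=0.0).fit(x, y)
        d = model.d_[1, 0]
        d_shrunk, _ = model.shrink(d - 0.62)
        assert np.isclose(d_shrunk[1, 0], 0.62)

    def test_negative_threshold_rejected(self, rng):
        model = NearestShrunkenCentroids().fit(rng.normal(0, 1, (8, 3)),
                                               ["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match=">= 0"):
            model.shrink(-0.5)

    def test_active_gene_count_monotone_in_threshold(self, rng):
        x = rng.normal(0, 1, (20, 30))
        x[:10, :5] += 2.0
        model = NearestShrunkenCentroids().fit(x, ["a"] * 10 + ["b"] * 10)
        grid = nsc.default_threshold_grid(model)
        counts = [int((np.abs(model.shrink(t)[0]) > 0).any(axis=0).sum())
                  for t in grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestClassify:
    def test_sample_at_centroid_with_equal_priors(self, rng):
        x = np.vstack([rng.normal(0, 1, (5, 4)), rng.normal(3, 1, (5, 4))])
        y = ["a"] * 5 + ["b"] * 5
        model = NearestShrunkenCentroids(priors=[0.5, 0.5]).fit(x, y)
        pred = model.predict(model.centroids_, threshold=0.0)
        assert list(pred) == ["a", "b"]

    def test_prior_only_limit_assigns_everything_to_big_prior(self, rng):
        x = np.vstack([rng.normal(0, 1, (5, 4)), rng.normal(3, 1, (5, 4))])
        model = NearestShrunkenCentroids(priors=[0.1, 0.9]).fit(
            x, ["a"] * 5 + ["b"] * 5)
        pred = model.predict(x, threshold=np.abs(model.d_).max() + 1)
        assert set(pred) == {"b"}

    def test_zero_training_error_on_separated_classes(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (6, 8)), rng.normal(3, 0.3, (6, 8)),
                       rng.normal(-3, 0.3, (6, 8))])
        y = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        model = NearestShrunkenCentroids().fit(x, y)
        assert list(model.predict(x, threshold=0.0)) == y

    @pytest.mark.parametrize("delta", [0.0, 0.7, 2.0])
    def test_matches_bruteforce_discriminant(self, delta, rng):
        x = rng.normal(0, 1, (20, 25))
        x[:7, :4] += 1.5
        x[7:13, 4:8] -= 1.5
        y = ["a"] * 7 + ["b"] * 6 + ["c"] * 7
        model = NearestShrunkenCentroids().fit(x, y)
        newdata = rng.normal(0, 1.5, (20, 25))
        assert np.array_equal(model.predict(newdata, delta),
                              brute_force_predict(model, newdata, delta))

    def test_missing_genes_listed(self, rng):
        m = make_expr(rng.normal(0, 1, (6, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=m.columns)
        model = nsc.train_centroids(m, labels)
        with pytest.raises(ValueError, match="g5"):
            nsc.classify(model, 0.0, m.drop(index="g5"))


class TestCrossValidate:
    @staticmethod
    def _separated(rng, n_per=10):
        x = np.vstack([rng.normal(0, 0.3, (n_per, 12)),
                       rng.normal(3, 0.3, (n_per, 12))])
        m = make_expr(x.T)
        labels = pd.Series(["a"] * n_per + ["b"] * n_per, index=m.columns)
        return m, labels

    def test_deterministic_under_fixed_seed(self, rng):
        m, labels = self._separated(rng)
        a = nsc.cross_validate(m, labels, seed=3)
        b = nsc.cross_validate(m, labels, seed=3)
        assert np.array_equal(a.confusion, b.confusion)
        assert a.fpr.equals(b.fpr)

    def test_separated_classes_have_zero_fpr_at_small_threshold(self, rng):
        m, labels = self._separated(rng)
        cv = nsc.cross_validate(m, labels, np.array([0.0, 0.5]), seed=0)
        assert cv.fpr.iloc[0].max() == 0.0

    def test_single_threshold_grid(self, rng):
        m, labels = self._separated(rng)
        cv = nsc.cross_validate(m, labels, np.array([1.0]), seed=0)
        assert cv.confusion.shape[0] == 1 and len(cv.thresholds) == 1

    def test_confusion_rows_sum_to_class_sizes(self, rng):
        m, labels = self._separated(rng)
        cv = nsc.cross_validate(m, labels, np.array([0.0, 2.0]), seed=0)
        assert np.array_equal(cv.confusion.sum(axis=2),
                              np.tile([10, 10], (2, 1)))

    def test_permuted_labels_fpr_near_prior(self, rng):
        x = rng.normal(0, 1, (40, 30))
        m = make_expr(x.T)
        labels = pd.Series(rng.permutation(["a"] * 20 + ["b"] * 20),
                           index=m.columns)
        cv = nsc.cross_validate(m, labels, np.array([0.0]), k_folds=5, seed=1)
        # balanced null: non-"a" samples land in "a" near its 0.5 prior
        assert abs(cv.fpr["a"].iloc[0] - 0.5) < 0.25

    def test_too_few_samples_for_two_folds(self, rng):
        m = make_expr(rng.normal(0, 1, (5, 4)))
        labels = pd.Series(["a", "a", "b", "b"], index=m.columns)
        with pytest.raises(ValueError, match="folds"):
            nsc.cross_validate(m, labels, np.array([0.0]), k_folds=1, seed=0)


class TestSelectThreshold:
    @staticmethod
    def _cv(fprs, counts, thresholds=None):
        fprs = np.asarray(fprs, dtype=float)
        thresholds = np.asarray(thresholds if thresholds is not None
                                else np.arange(len(fprs), dtype=float))
        return CVResult(
            thresholds=thresholds, classes=np.array(["t", "o"]),
            confusion=np.zeros((len(fprs), 2, 2), dtype=int),
            fpr=pd.DataFrame({"t": fprs, "o": fprs}, index=thresholds),
            error_rate=fprs.copy(), n_active=np.asarray(counts),
        )

    def test_tied_minimal_counts_take_largest_threshold(self):
        cv = self._cv([0.5, 0.15, 0.10], [300, 80, 80])
        assert nsc.select_threshold(cv, "t") == 2.0

    def test_all_feasible_distinct_counts_take_minimum(self):
        cv = self._cv([0.0, 0.0, 0.0], [30, 12, 5])
        assert nsc.select_threshold(cv, "t") == 2.0

    def test_stable_count_preferred_over_one_off_minimum(self):
        cv = self._cv([0.0] * 5, [300, 120, 120, 40, 3])
        assert nsc.select_threshold(cv, "t") == 2.0  # plateau at 120

    def test_infeasible_grid_advises_extension(self):
        cv = self._cv([0.5, 0.4], [10, 5])
        with pytest.raises(ValueError, match="grid"):
            nsc.select_threshold(cv, "t")

    def test_overall_error_mode(self):
        cv = self._cv([0.5, 0.1, 0.1], [300, 90, 90])
        assert nsc.select_threshold(cv, "t", mode="overall") == 2.0


class TestExtractMarkers:
    def test_zero_threshold_keeps_all_nonzero_differences(self, discovery):
        model = discovery["model"]
        markers = nsc.extract_markers(model, 0.0, "ercDC")
        d = nsc.shrink(model, 0.0).d_shrunk["ercDC"]
        assert set(markers.index) == set(d.index[d != 0])

    def test_up_down_partition_and_sorted_magnitudes(self, discovery):
        markers = discovery["markers"]
        n_up = (markers["direction"] == "up").sum()
        n_down = (markers["direction"] == "down").sum()
        assert n_up + n_down == len(markers)
        mags = markers["magnitude"].to_numpy()
        assert np.all(mags[:-1] >= mags[1:]) and (mags > 0).all()

    def test_planted_directions_recovered(self, discovery):
        truth = discovery["truth"]
        markers = discovery["markers"]
        planted = {g for g, ct in truth.signature_gene_assignment.items()
                   if ct == "ercDC"}
        for g in planted & set(markers.index):
            expected = "up" if truth.signature_direction[g] > 0 else "down"
            assert markers.loc[g, "direction"] == expected

    def test_empty_marker_set_warns(self, rng):
        x = rng.normal(0, 1, (8, 5))
        model = NearestShrunkenCentroids().fit(x, ["a"] * 4 + ["b"] * 4)
        model.gene_ids_ = np.array([f"g{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="no marker genes"):
            out = nsc.extract_markers(model, np.abs(model.d_).max() + 1, "a")
        assert out.empty


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.floats(min_value=0, max_value=5), st.floats(min_value=0, max_value=5))
def test_shrinkage_nesting_property(d1, d2):
    """Larger thresholds keep a subset of the active genes."""
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, (16, 20))
    x[:8, :6] += 1.0
    model = NearestShrunkenCentroids().fit(x, ["a"] * 8 + ["b"] * 8)
    lo, hi = sorted([d1, d2])
    active_lo = np.abs(model.shrink(lo)[0]) > 0
    active_hi = np.abs(model.shrink(hi)[0]) > 0
    assert np.all(active_hi <= active_lo)
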