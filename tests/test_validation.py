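"""Cross-validation, permutation null, refit metrics, transfer."""

import numpy as np
import pandas as pd
import pytest

from sparsecoh.svm import SparseHingeSVM
from sparsecoh.validation import (
    CVConfig,
    ValidationError,
    contrast_arrays,
    default_c_grid,
    leave_two_out_cv,
    permutation_test,
    refit_and_metrics,
    run_contrasts,
    transfer_apply,
)


def separable_data(rng, n_pos=10, n_neg=8, p=6, gap=4.0):
    X = rng.standard_normal((n_pos + n_neg, p))
    y = np.array([1.0] * n_pos + [-1.0] * n_neg)
    X[:n_pos, 0] += gap
    return X, y


class TestConfig:
    def test_default_grid_is_30_log_bins_from_01_to_100(self):
        g = default_c_grid()
        assert len(g) == 30
        assert g[0] == pytest.approx(0.1)
        assert g[-1] == pytest.approx(100.0)
        assert np.allclose(np.diff(np.log10(g)), np.diff(np.log10(g))[0])

    def test_full_protocol_defaults(self):
        cfg = CVConfig()
        assert cfg.n_iterations == 500
        assert cfg.n_permutations == 1000

    def test_reduced_preset(self):
        cfg = CVConfig.reduced(seed=3)
        assert cfg.n_iterations == 100
        assert cfg.n_permutations == 200
        assert cfg.perm_n_iterations == 50

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValidationError):
            CVConfig(c_grid=np.array([1.0, 1.0, 2.0]))


class TestLeaveTwoOut:
    def test_single_iteration_records_two_predictions(self):
        rng = np.random.default_rng(0)
        X, y = separable_data(rng)
        cfg = CVConfig(n_iterations=1, seed=5)
        res = leave_two_out_cv(X, y, cfg)
        assert res.predictions.shape == (1, 2, 30)
        res2 = leave_two_out_cv(X, y, CVConfig(n_iterations=1, seed=5))
        np.testing.assert_array_equal(res.predictions, res2.predictions)
        np.testing.assert_array_equal(res.test_pairs, res2.test_pairs)

    def test_left_out_pair_is_one_per_class(self):
        rng = np.random.default_rng(1)
        X, y = separable_data(rng)
        res = leave_two_out_cv(X, y, CVConfig(n_iterations=20, seed=2))
        assert np.all(y[res.test_pairs[:, 0]] == 1.0)
        assert np.all(y[res.test_pairs[:, 1]] == -1.0)

    def test_separable_clusters_reach_perfect_accuracy(self):
        rng = np.random.default_rng(2)
        X, y = separable_data(rng, gap=8.0)
        res = leave_two_out_cv(X, y, CVConfig(n_iterations=50, seed=1))
        assert res.best_accuracy == 1.0
        # ties break toward the smallest C
        perfect = res.c_grid[res.accuracies == res.best_accuracy]
        assert res.best_C == perfect[0]

    def test_null_features_stay_well_below_perfect(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 8))
        y = np.array([1.0] * 10 + [-1.0] * 10)
        res = leave_two_out_cv(X, y, CVConfig(n_iterations=60, seed=4))
        # selection-maximum bias keeps the best above 0.5, but labels
        # independent of features can never approach 1 systematically
        assert 0.35 < res.best_accuracy < 0.9

    def test_single_member_class_rejected(self):
        X = np.zeros((4, 2))
        y = np.array([1.0, -1.0, -1.0, -1.0])
        with pytest.raises(ValidationError):
            leave_two_out_cv(X, y, CVConfig(n_iterations=1))

    def test_participant_aware_variant(self):
        # paired design: each participant contributes one pre (-1) and
        # one post (+1) recording
        rng = np.random.default_rng(20)
        n_part = 8
        X = rng.standard_normal((2 * n_part, 5))
        X[:n_part, 0] += 3.0
        y = np.array([1.0] * n_part + [-1.0] * n_part)
        participants = np.array([f"p{i}" for i in range(n_part)] * 2)
        cfg = CVConfig(n_iterations=10, seed=3)
        res = leave_two_out_cv(X, y, cfg, participants=participants,
                               participant_aware=True)
        assert res.predictions.shape == (10, 2, 30)
        assert 0.0 <= res.best_accuracy <= 1.0
        res2 = leave_two_out_cv(X, y, CVConfig(n_iterations=10, seed=3),
                                participants=participants,
                                participant_aware=True)
        np.testing.assert_array_equal(res.predictions, res2.predictions)

    def test_participant_aware_needs_labels(self):
        X = np.zeros((6, 2))
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        with pytest.raises(ValidationError, match="participants"):
            leave_two_out_cv(X, y, CVConfig(n_iterations=1),
                             participant_aware=True)


class TestPermutation:
    def test_p_value_never_zero_and_bounded(self):
        rng = np.random.default_rng(5)
        X, y = separable_data(rng, gap=8.0)
        cfg = CVConfig(n_iterations=10, seed=6)
        res = permutation_test(X, y, cfg, n_permutations=19)
        assert 0.0 < res.p_value <= 1.0
        assert res.p_value >= 1.0 / 20.0

    def test_all_nulls_at_or_above_observed_gives_p_one(self):
        # constant features: every CV (observed and null) performs the
        # same, so all null accuracies >= observed and p = 1
        X = np.zeros((8, 3))
        y = np.array([1.0] * 4 + [-1.0] * 4)
        cfg = CVConfig(n_iterations=5, seed=0)
        res = permutation_test(X, y, cfg, n_permutations=9)
        assert res.p_value == 1.0

    def test_planted_effect_reaches_small_p(self):
        rng = np.random.default_rng(7)
        X, y = separable_data(rng, n_pos=9, n_neg=9, gap=6.0)
        cfg = CVConfig(n_iterations=20, perm_n_iterations=10, seed=8)
        res = permutation_test(X, y, cfg, n_permutations=99)
        assert res.observed_accuracy == 1.0
        assert res.p_value <= 0.05


class TestRefitMetrics:
    def test_separated_scores_give_perfect_metrics(self):
        rng = np.random.default_rng(9)
        X, y = separable_data(rng, gap=8.0)
        m = refit_and_metrics(X, y, best_C=10.0, n_bootstrap=200)
        assert m.auc == 1.0
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0
        assert m.auc_ci == (1.0, 1.0)

    def test_zero_model_flags_degenerate_auc_half(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((12, 4))
        y = np.array([1.0] * 6 + [-1.0] * 6)
        with pytest.warns(RuntimeWarning, match="identical"):
            m = refit_and_metrics(X, y, best_C=1e-6, n_bootstrap=50)
        assert m.degenerate
        assert m.auc == 0.5
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_auc_ci_contains_point_estimate(self):
        rng = np.random.default_rng(11)
        X, y = separable_data(rng, gap=1.0)
        m = refit_and_metrics(X, y, best_C=1.0, n_bootstrap=500)
        assert m.auc_ci[0] <= m.auc <= m.auc_ci[1] or m.degenerate


class TestTransfer:
    def _fitted(self, rng, gap=6.0):
        X, y = separable_data(rng, gap=gap)
        return SparseHingeSVM(C=10.0).fit(X, y), X, y

    def test_zero_model_assigns_all_negative(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((10, 4))
        y = np.array([1.0] * 5 + [-1.0] * 5)
        m = SparseHingeSVM(C=1e-8, fit_intercept=False).fit(X, y)
        res = transfer_apply(m, rng.standard_normal((7, 4)))
        assert res.n_negative == 7
        assert res.fraction_negative == 1.0

    def test_feature_mismatch_raises(self):
        rng = np.random.default_rng(13)
        m, X, y = self._fitted(rng)
        with pytest.raises(ValueError, match="features"):
            transfer_apply(m, rng.standard_normal((5, X.shape[1] - 1)))

    def test_frozen_standardization_is_used(self):
        rng = np.random.default_rng(14)
        m, X, y = self._fitted(rng)
        # applying to the training data reproduces decision_function
        res = transfer_apply(m, X)
        np.testing.assert_allclose(res.scores, m.decision_function(X))


class TestRunContrasts:
    def make_features(self, rng, n_per_cell=4):
        rows = []
        cols = [f"p{i}" for i in range(6)]
        for arm in ("active", "sham"):
            for tp in ("pre", "post"):
                for k in range(n_per_cell):
                    for band in ("delta", "theta"):
                        row = {
                            "participant": f"{arm[0]}{k}",
                            "arm": arm, "timepoint": tp, "band": band,
                        }
                        vals = rng.normal(0.2, 0.05, 6)
                        if arm == "active" and tp == "post" and band == "delta":
                            vals[0] += 0.5
                        row.update(dict(zip(cols, vals)))
                        rows.append(row)
        return pd.DataFrame(rows), cols

    def test_contrast_arrays_labels(self):
        rng = np.random.default_rng(15)
        df, cols = self.make_features(rng)
        X, y, _ = contrast_arrays(df[df.band == "delta"],
                                  "active-vs-sham-post", cols)
        assert len(y) == 8
        assert np.sum(y == 1.0) == 4  # active coded positive

    def test_unknown_contrast_rejected(self):
        rng = np.random.default_rng(16)
        df, cols = self.make_features(rng)
        with pytest.raises(ValidationError, match="unknown contrast"):
            contrast_arrays(df, "foo-vs-bar", cols)

    def test_missing_cell_named_in_error(self):
        rng = np.random.default_rng(17)
        df, cols = self.make_features(rng)
        df = df[~((df.arm == "sham") & (df.timepoint == "pre"))]
        with pytest.raises(ValidationError, match="sham-pre"):
            run_contrasts(df, CVConfig(n_iterations=1), cols,
                          bands=("delta",))

    def test_all_cells_executed_and_seeded(self):
        rng = np.random.default_rng(18)
        df, cols = self.make_features(rng)
        cfg = CVConfig(n_iterations=3, seed=9)
        res = run_contrasts(df, cfg, cols, bands=("delta", "theta"))
        assert len(res) == 8  # 4 contrasts x 2 bands
        res2 = run_contrasts(df, cfg, cols, bands=("delta", "theta"))
        for key in res:
            np.testing.assert_array_equal(
                res[key]["cv"].accuracies, res2[key]["cv"].accuracies
            )
        # the planted delta effect separates best in its own cell
        planted = res[("active-vs-sham-post", "delta")]["cv"].best_accuracy
        control = res[("active-vs-sham-pre", "delta")]["cv"].best_accuracy
        assert planted >= control
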