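"""One-class model oracles: MAD filter, z-score, Mahalanobis, autoencoder."""

import numpy as np
import pandas as pd
import pytest

from oarqa.models import (AeModel, FeatureStats, ae_metric, ae_reconstruct,
                          fit_autoencoder, fit_feature_stats, fit_md,
                          mad_filter, md_metric, zscore_metric,
                          zscore_transform)


def stats_from(mean, std):
    mean = np.asarray(mean, float)
    std = np.asarray(std, float)
    return FeatureStats(names=[f"f{i}" for i in range(mean.size)],
                        mean=mean, std=std, median=mean,
                        mad=np.maximum(std, 0))


class TestMadFilter:
    def test_clean_gaussian_removes_almost_nothing(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 8)),
                          columns=[f"f{i}" for i in range(8)])
        kept, removed = mad_filter(df, list(df.columns), k=12)
        # 12 unscaled MAD is roughly 8 sigma for normal data
        assert len(removed) <= 0.02 * len(df)

    def test_displaced_row_is_removed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 4)),
                          columns=list("abcd"))
        med, mad = df["b"].median(), (df["b"] - df["b"].median()).abs().median()
        df.loc[17, "b"] = med + 20 * mad
        kept, removed = mad_filter(df, list("abcd"), k=12)
        assert list(removed) == [17]

    def test_constant_column_is_skipped(self):
        df = pd.DataFrame({"a": np.r_[np.zeros(30), 5.0],
                           "b": np.arange(31.0)})
        kept, removed = mad_filter(df, ["a", "b"], k=12)
        # column a has MAD 0: even the 5.0 row survives on that feature
        assert len(removed) == 0

    def test_all_removed_is_fatal(self):
        df = pd.DataFrame({"a": [0.0, 100.0], "b": [100.0, 0.0]})
        with pytest.raises(ValueError):
            mad_filter(df, ["a", "b"], k=0.1)


class TestZscore:
    def test_at_mean_is_zero(self):
        s = stats_from([10, 20], [2, 3])
        assert zscore_metric(np.array([10.0, 20.0]), s) == 0.0

    def test_single_feature_deviation(self):
        s = stats_from([10, 0, 0], [2, 1, 1])
        assert zscore_metric(np.array([16.0, 0, 0]), s) == pytest.approx(3.0)

    def test_max_of_absolute_zscores(self):
        s = stats_from([0, 0, 0], [1, 1, 1])
        assert zscore_metric(np.array([1.0, -2.0, 0.5]), s) == pytest.approx(2.0)

    def test_zero_sigma_feature_flags_any_deviation(self):
        s = stats_from([5.0], [0.0])
        assert zscore_metric(np.array([5.0]), s) == 0.0
        assert zscore_metric(np.array([5.1]), s) == np.inf

    def test_nan_features_are_neutral(self):
        s = stats_from([10, 20], [2, 3])
        assert zscore_metric(np.array([np.nan, 20.0]), s) == 0.0


class TestMahalanobis:
    def test_identity_covariance_recovery(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        model = fit_md(df, ["a", "b"])
        np.testing.assert_allclose(model.cov, np.eye(2), atol=0.05)

    def test_rank_deficient_is_invertible(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 4.0]})
        model = fit_md(df, ["a", "b"])  # n = d = 2
        assert np.all(np.isfinite(model.cov_inv))

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        m1 = fit_md(df, list("abc"))
        m2 = fit_md(df.iloc[::-1], list("abc"))
        np.testing.assert_allclose(m1.cov_inv, m2.cov_inv, rtol=1e-10)

    @pytest.mark.parametrize("cov,delta,expected", [
        (np.eye(2), [3.0, 4.0], 25.0),
        (np.diag([4.0, 1.0]), [2.0, 3.0], 10.0),
    ])
    def test_quadratic_form_hand_values(self, cov, delta, expected):
        from oarqa.models import MdModel
        model = MdModel(mean=np.zeros(2), cov=cov, cov_inv=np.linalg.inv(cov))
        assert md_metric(np.asarray(delta), model) == pytest.approx(expected)

    def test_at_mean_is_zero(self):
        from oarqa.models import MdModel
        model = MdModel(mean=np.array([1.0, 2.0]), cov=np.eye(2),
                        cov_inv=np.eye(2))
        assert md_metric(np.array([1.0, 2.0]), model) == 0.0

    def test_feature_reordering_invariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        x = rng.normal(size=4)
        m = fit_md(df, list("abcd"))
        perm = [2, 0, 3, 1]
        mp = fit_md(df, [list("abcd")[i] for i in perm])
        assert md_metric(x, m) == pytest.approx(md_metric(x[perm], mp),
                                                rel=1e-9)
        s = fit_feature_stats(df, list("abcd"))
        sp = fit_feature_stats(df, [list("abcd")[i] for i in perm])
        assert zscore_metric(x, s) == pytest.approx(zscore_metric(x[perm], sp))


class TestAutoencoder:
    def test_rank_one_data_is_reconstructed(self):
        # capacity check: 18 hidden units >> 1 intrinsic dimension, so the
        # unregularised network reconstructs almost perfectly
        rng = np.random.default_rng(6)
        t = rng.normal(size=(200, 1))
        v = rng.normal(size=(1, 20))
        z = t @ v
        model = fit_autoencoder(z, l2=0.0, seed=0)
        msre = float(((ae_reconstruct(z, model) - z) ** 2).mean())
        assert msre < 0.01

    def test_weight_penalty_floors_reconstruction_error(self):
        # with the default L2 penalty the optimum trades a little
        # reconstruction error for smaller weights; the error stays well
        # below the input variance but does not vanish
        rng = np.random.default_rng(6)
        z = rng.normal(size=(200, 1)) @ rng.normal(size=(1, 20))
        model = fit_autoencoder(z, seed=0)
        msre = float(((ae_reconstruct(z, model) - z) ** 2).mean())
        assert 0.0 < msre < 0.2 * z.var()

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(50, 20))
        m1 = fit_autoencoder(z, seed=3, max_epochs=300)
        m2 = fit_autoencoder(z, seed=3, max_epochs=300)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)

    def test_loss_is_non_increasing(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(60, 20))
        model = fit_autoencoder(z, seed=1, max_epochs=500)
        hist = np.asarray(model.loss_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_trivial_model_reconstructs_mean_exactly(self):
        model = AeModel(w1=np.zeros((3, 2)), b1=np.zeros(2),
                        w2=np.zeros((2, 3)), b2=np.zeros(3))
        s = stats_from([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert ae_metric(np.array([1.0, 2.0, 3.0]), model, s) == 0.0

    def test_outlier_ranks_above_training_distribution(self):
        rng = np.random.default_rng(9)
        t = rng.normal(size=(200, 1))
        v = rng.normal(size=(1, 20))
        z = t @ v
        model = fit_autoencoder(z, seed=0)
        s = stats_from(np.zeros(20), np.ones(20))
        train_scores = [ae_metric(row, model, s) for row in z]
        off_manifold = rng.normal(size=20) * 3.0
        assert ae_metric(off_manifold, model, s) > np.percentile(train_scores, 95)

    def test_median_point_scores_below_far_outlier(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(80, 20))
        model = fit_autoencoder(z, seed=0, max_epochs=800)
        s = stats_from(np.zeros(20), np.ones(20))
        assert (ae_metric(np.median(z, axis=0), model, s)
                <= ae_metric(np.full(20, 10.0), model, s))


def test_zscore_transform_handles_zero_sigma():
    s = stats_from([1.0, 2.0], [0.0, 2.0])
    np.testing.assert_allclose(zscore_transform(np.array([9.0, 4.0]), s),
                               [0.0, 1.0])
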