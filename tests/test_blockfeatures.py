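import numpy as np
import pytest

from cocoonsex.blockfeatures import (
    BlockLDAModel,
    WeightStats,
    class_scatter,
    fit_block_lda,
    fuse_weight,
    transform_block_lda,
)
from cocoonsex.fasthog import HOGParams


def _fisher_ratio(w, X, y):
    """Between-over-within variance of the 1-D projection Xw."""
    z = X @ w
    z0, z1 = z[y == 0], z[y == 1]
    between = (z1.mean() - z0.mean()) ** 2
    within = ((z0 - z0.mean()) ** 2).sum() + ((z1 - z1.mean()) ** 2).sum()
    return between / within


class TestClassScatter:
    def test_hand_computed_1d_case(self):
        # classes {0,0} and {2,2}: zero within-class spread, means 0 and 2
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        means, S_W, S_B = class_scatter(X, y)
        assert means[0] == 0.0 and means[1] == 2.0
        assert np.allclose(S_W, 0.0)
        assert np.allclose(S_B, 4.0)  # 2*(0-1)^2 + 2*(2-1)^2

    def test_identical_means_zero_between_scatter(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        y = np.array([0, 0, 1, 1])
        _, _, S_B = class_scatter(X, y)
        assert np.allclose(S_B, 0.0)

    def test_total_scatter_decomposition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 5))
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]  # both classes guaranteed
        mu = X.mean(axis=0)
        total = (X - mu).T @ (X - mu)
        _, S_W, S_B = class_scatter(X, y)
        assert np.allclose(S_W + S_B, total)
        assert np.allclose(S_W, S_W.T)
        assert np.all(np.linalg.eigvalsh(S_W) >= -1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            class_scatter(np.zeros((10, 2)), np.zeros(10, dtype=int))


class TestFitBlockLDA:
    def test_model_has_105_unit_projections(self):
        rng = np.random.default_rng(1)
        params = HOGParams()
        D = rng.uniform(size=(40, params.descriptor_length))
        y = np.repeat([0, 1], 20)
        model = fit_block_lda(D, y, params=params)
        assert model.n_blocks == 105
        assert np.allclose(np.linalg.norm(model.projections, axis=1), 1.0,
                           atol=1e-9)

    def test_recovers_fisher_direction_on_gaussian_blocks(self):
        # N(0, I) vs N(3 e1, I): the Fisher direction is e1
        rng = np.random.default_rng(2)
        n = 500
        X0 = rng.normal(size=(n, 36))
        X1 = rng.normal(size=(n, 36))
        X1[:, 0] += 3.0
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], n)
        model = fit_block_lda(X, y, block_width=36)
        cos = abs(model.projections[0, 0])
        assert cos >= 0.9

    def test_sample_duplication_leaves_projection_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 36))
        y = np.repeat([0, 1], 50)
        X[y == 1, 3] += 1.5
        w1 = fit_block_lda(X, y, block_width=36).projections
        w2 = fit_block_lda(np.vstack([X, X]), np.concatenate([y, y]),
                           block_width=36).projections
        assert np.allclose(w1, w2, atol=1e-6)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 72))
        y = np.repeat([0, 1], 30)
        m1 = fit_block_lda(X, y, block_width=36)
        m2 = fit_block_lda(X, y, block_width=36)
        assert np.array_equal(m1.projections, m2.projections)

    def test_degenerate_all_zero_block_falls_back_with_warning(self):
        X = np.zeros((40, 36))
        y = np.repeat([0, 1], 20)
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_block_lda(X, y, block_width=36)
        assert np.array_equal(model.projections[0], np.eye(36)[0])

    def test_male_mean_projects_at_or_above_female(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 36))
        y = np.repeat([0, 1], 100)
        X[y == 0, 7] += 2.0  # signal favours the female class pre-sign-fix
        model = fit_block_lda(X, y, block_width=36)
        z = transform_block_lda(model, X)
        assert z[y == 1].mean() >= z[y == 0].mean()

    def test_fisher_ratio_beats_random_directions(self):
        # brute-force optimality oracle on small 4-D blocks
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 4)) @ rng.normal(size=(4, 4))
        y = np.repeat([0, 1], 100)
        X[y == 1] += rng.normal(size=4) * 0.8
        model = fit_block_lda(X, y, block_width=4)
        w = model.projections[0]
        best_random = 0.0
        dirs = rng.normal(size=(10_000, 4))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for d in dirs:
            best_random = max(best_random, _fisher_ratio(d, X, y))
        assert _fisher_ratio(w, X, y) >= best_random


class TestTransform:
    def test_output_length_105(self):
        rng = np.random.default_rng(7)
        params = HOGParams()
        D = rng.uniform(size=(30, params.descriptor_length))
        y = np.repeat([0, 1], 15)
        model = fit_block_lda(D, y, params=params)
        out = transform_block_lda(model, D[0])
        assert out.shape == (105,)
        assert transform_block_lda(model, D).shape == (30, 105)

    def test_descriptor_at_offsets_maps_to_zero(self):
        rng = np.random.default_rng(8)
        D = rng.uniform(size=(20, 72))
        y = np.repeat([0, 1], 10)
        model = fit_block_lda(D, y, block_width=36)
        assert np.allclose(transform_block_lda(model, model.offsets.ravel()), 0.0)

    def test_transform_is_affine_in_the_descriptor(self):
        rng = np.random.default_rng(9)
        D = rng.uniform(size=(20, 72))
        y = np.repeat([0, 1], 10)
        model = fit_block_lda(D, y, block_width=36)
        x1, x2, a = D[0], D[1], 0.3
        lhs = transform_block_lda(model, a * x1 + (1 - a) * x2)
        rhs = a * transform_block_lda(model, x1) + (1 - a) * transform_block_lda(
            model, x2
        )
        assert np.allclose(lhs, rhs)

    def test_length_mismatch_names_expected_and_actual(self):
        rng = np.random.default_rng(10)
        D = rng.uniform(size=(20, 72))
        y = np.repeat([0, 1], 10)
        model = fit_block_lda(D, y, block_width=36)
        with pytest.raises(ValueError, match="72.*100"):
            transform_block_lda(model, np.zeros(100))

    def test_json_round_trip(self):
        rng = np.random.default_rng(11)
        D = rng.uniform(size=(20, 72))
        y = np.repeat([0, 1], 10)
        model = fit_block_lda(D, y, block_width=36)
        back = BlockLDAModel.from_json(model.to_json())
        assert np.allclose(back.projections, model.projections)
        assert np.allclose(
            transform_block_lda(back, D), transform_block_lda(model, D)
        )


class TestFuseWeight:
    def test_fused_vector_has_106_entries(self):
        stats = WeightStats(mean=1.1, sd=0.2)
        fused = fuse_weight(np.zeros(105), 1.3, stats)
        assert fused.shape == (106,)

    def test_training_mean_weight_standardizes_to_zero(self):
        stats = WeightStats.fit(np.array([1.0, 1.2, 1.4]))
        fused = fuse_weight(np.zeros(3), 1.2, stats)
        assert fused[-1] == pytest.approx(0.0)

    def test_hand_zscore(self):
        # weights {1, 2, 3}: mean 2, sample sd 1; w=3 -> z = 1
        stats = WeightStats.fit(np.array([1.0, 2.0, 3.0]))
        fused = fuse_weight(np.zeros(2), 3.0, stats)
        assert fused[-1] == pytest.approx(1.0)

    def test_degenerate_training_weights_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            WeightStats.fit(np.full(5, 1.0))

    def test_matrix_fusion_matches_rowwise(self):
        stats = WeightStats(mean=1.0, sd=0.5)
        F = np.arange(10.0).reshape(2, 5)
        w = np.array([1.5, 2.0])
        fused = fuse_weight(F, w, stats)
        assert fused.shape == (2, 6)
        assert np.allclose(fused[0], fuse_weight(F[0], w[0], stats))
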