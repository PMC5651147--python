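"""Slope network: PCA layer, forward pass, pretraining, fine-tuning."""

import numpy as np
import pytest

import cobbnet as cn
from cobbnet.dnn import PCA_COMPONENTS, fit_pca_layer, forward


def _toy_params(h2=2, h3=2, W2=None, W3=None, W4=None, b4=0.0):
    """Shape-consistent parameters with an identity-block PCA layer."""
    W1 = np.zeros((PCA_COMPONENTS, 2500))
    W1[np.arange(PCA_COMPONENTS), np.arange(PCA_COMPONENTS)] = 1.0
    z = np.zeros
    return cn.DNNParameters(
        W1=W1, b1=z(2500),
        W2=W2 if W2 is not None else z((h2, PCA_COMPONENTS)),
        b2=z(h2),
        W3=W3 if W3 is not None else z((h3, h2)), b3=z(h3),
        W4=W4 if W4 is not None else z((1, h3)), b4=b4,
        h2_size=h2, h3_size=h3,
    )


class TestPCALayer:
    def test_orthonormal_rows(self, random_patch_vectors):
        W1, b1, _ = fit_pca_layer(random_patch_vectors)
        assert np.allclose(W1 @ W1.T, np.eye(PCA_COMPONENTS), atol=1e-6)

    def test_mean_patch_projects_to_zero(self, random_patch_vectors):
        W1, b1, _ = fit_pca_layer(random_patch_vectors)
        assert np.allclose(W1 @ (b1 - b1), 0.0)
        assert np.allclose(b1, random_patch_vectors.mean(axis=0))

    def test_too_few_patches_rejected(self):
        with pytest.raises(cn.ValidationError):
            fit_pca_layer(np.zeros((100, 2500)))

    def test_matches_svd_oracle_subspace(self, random_patch_vectors):
        # independent oracle: sklearn's SVD-based PCA on the same data
        from sklearn.decomposition import PCA

        W1, b1, eigvals = fit_pca_layer(random_patch_vectors)
        oracle = PCA(n_components=PCA_COMPONENTS, svd_solver="full")
        oracle.fit(random_patch_vectors)
        # principal angles between the two 100-dim subspaces
        s = np.linalg.svd(W1 @ oracle.components_.T, compute_uv=False)
        angles = np.arccos(np.clip(s, -1, 1))
        assert np.max(angles) < 1e-4
        assert np.allclose(
            eigvals, oracle.explained_variance_, rtol=1e-8
        )
        assert np.all(np.diff(eigvals) <= 1e-12)  # nonincreasing variance


class TestForward:
    def test_constant_network(self):
        params = _toy_params(b4=7.0)
        rng = np.random.default_rng(0)
        for _ in range(3):
            assert forward(params, rng.uniform(size=2500)) == 7.0

    def test_output_bounded_by_w4_mass(self):
        rng = np.random.default_rng(1)
        W4 = rng.normal(size=(1, 2))
        params = _toy_params(
            W2=rng.normal(size=(2, PCA_COMPONENTS)),
            W3=rng.normal(size=(2, 2)), W4=W4, b4=3.0,
        )
        for _ in range(20):
            out = forward(params, rng.uniform(size=2500))
            assert abs(out - 3.0) <= np.sum(np.abs(W4)) + 1e-12

    def test_toy_network_matches_hand_evaluation(self):
        # h2 = h3 = 2, integer weights, patch touching the first two PCA
        # coordinates only
        W2 = np.zeros((2, PCA_COMPONENTS))
        W2[0, 0], W2[0, 1], W2[1, 0] = 1, -2, 3
        W3 = np.array([[2.0, -1.0], [0.0, 1.0]])
        W4 = np.array([[1.0, -3.0]])
        params = _toy_params(W2=W2, W3=W3, W4=W4, b4=0.5)
        patch = np.zeros(2500)
        patch[0], patch[1] = 0.2, -0.1
        z1, z2 = 0.2, -0.1  # identity-block PCA
        h2 = np.tanh([z1 - 2 * z2, 3 * z1])
        h3 = np.tanh([2 * h2[0] - h2[1], h2[1]])
        expected = 0.5 + h3[0] - 3 * h3[1]
        assert forward(params, patch) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        params = _toy_params()
        with pytest.raises(cn.ValidationError):
            forward(params, np.zeros(1000))

    def test_batch_equals_loop(self, small_trained, tiny_patchset):
        X = tiny_patchset.vectors[:7]
        batch = forward(small_trained.params, X)
        loop = [forward(small_trained.params, x) for x in X]
        assert np.allclose(batch, loop, atol=1e-12)


@pytest.fixture(scope="module")
def synthetic_patchset():
    rng = np.random.default_rng(11)
    n = 1000
    X = rng.uniform(0, 1, size=(n, 2500)).astype(np.float32)
    return cn.PatchSet(
        vectors=X,
        labels=rng.uniform(-30, 30, size=n),
        source_ids=np.array(["synthetic"] * n),
        vertebra_indices=np.zeros(n, dtype=np.int64),
        offsets=np.zeros((n, 2)),
    )


class TestPretrain:
    def test_autoencoder_losses_decrease(self, synthetic_patchset):
        cfg = cn.TrainingConfig(
            h2_size=40, h3_size=10, pretrain_epochs=10, seed=0
        )
        params = cn.pretrain(synthetic_patchset, cfg)
        hist = params.metadata["pretrain"]
        assert hist["ae1_loss"][-1] <= hist["ae1_loss"][0]
        assert hist["ae2_loss"][-1] <= hist["ae2_loss"][0]

    def test_seeded_determinism(self, synthetic_patchset):
        cfg = cn.TrainingConfig(h2_size=20, h3_size=5, pretrain_epochs=2)
        a = cn.pretrain(synthetic_patchset, cfg)
        b = cn.pretrain(synthetic_patchset, cfg)
        for name in ("W1", "b1", "W2", "b2", "W3", "b3", "W4"):
            assert np.array_equal(getattr(a, name), getattr(b, name))
        assert a.b4 == b.b4

    def test_default_pretrain_rate_is_0_1(self):
        assert cn.TrainingConfig().pretrain_learning_rate == 0.1


class TestFinetune:
    def test_overfits_twenty_patches(self):
        # over-parameterized network memorizes a tiny labeled set; the
        # PCA layer and pretraining use a larger unlabeled pool (the PCA
        # basis needs > 100 patches to be well defined)
        rng = np.random.default_rng(3)
        pool = cn.PatchSet(
            vectors=rng.uniform(0, 1, size=(200, 2500)).astype(np.float32),
            labels=np.full(200, np.nan),
            source_ids=np.array(["pool"] * 200),
            vertebra_indices=np.zeros(200, dtype=np.int64),
            offsets=np.zeros((200, 2)),
        )
        n = 20
        ps = cn.PatchSet(
            vectors=pool.vectors[:n],
            labels=rng.uniform(-20, 20, size=n),
            source_ids=np.array(["s"] * n),
            vertebra_indices=np.zeros(n, dtype=np.int64),
            offsets=np.zeros((n, 2)),
        )
        cfg = cn.TrainingConfig(
            pretrain_epochs=5, finetune_epochs=2000, seed=0
        )
        params = cn.finetune(cn.pretrain(pool, cfg), ps, cfg)
        mse = params.metadata["finetune"]["mse"][-1]
        assert mse < 0.1

    def test_loss_curve_nonincreasing_after_smoothing(self, small_trained):
        mse = np.asarray(small_trained.training_history["finetune"]["mse"])
        smooth = np.convolve(mse, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-3 * smooth[:-1] + 1e-9)

    def test_unlabeled_patch_rejected(self, tiny_patchset):
        ps = cn.PatchSet(
            vectors=tiny_patchset.vectors[:200].copy(),
            labels=tiny_patchset.labels[:200].copy(),
            source_ids=tiny_patchset.source_ids[:200],
            vertebra_indices=tiny_patchset.vertebra_indices[:200],
            offsets=tiny_patchset.offsets[:200],
        )
        ps.labels[13] = np.nan
        cfg = cn.TrainingConfig(pretrain_epochs=1, finetune_epochs=1)
        with pytest.raises(cn.ValidationError, match="index 13"):
            cn.finetune(cn.pretrain(ps, cfg), ps, cfg)

    def test_recovers_function_of_first_pca_coordinate(self):
        # labels linear in the top PCA coordinate are inside the model
        # class, so training should drive held-out MAE below 0.5 degrees
        rng = np.random.default_rng(8)
        n = 1200
        basis = rng.normal(size=(4, 2500))
        basis[0] *= 3.0  # dominant direction
        coords = rng.normal(size=(n, 4))
        X = np.clip(0.5 + 0.004 * (coords @ basis), 0, 1).astype(np.float32)
        W1, b1, _ = fit_pca_layer(X)
        z1 = (X - b1) @ W1[0]
        y = 15.0 * z1 / z1.std() + 2.0
        ps = cn.PatchSet(
            vectors=X, labels=y, source_ids=np.array(["s"] * n),
            vertebra_indices=np.zeros(n, dtype=np.int64),
            offsets=np.zeros((n, 2)),
        )
        cfg = cn.TrainingConfig(
            h2_size=100, h3_size=10, pretrain_epochs=10,
            finetune_epochs=600, finetune_learning_rate=0.02, seed=1,
        )
        res = cn.SlopeRegression(ps, cfg).fit()
        pred = res.predict(X[1000:])
        assert np.mean(np.abs(pred - y[1000:])) < 0.5


@pytest.mark.parametrize("h2,h3", [(500, 50), (800, 100), (500, 250)])
def test_architecture_grid_runs(h2, h3, tiny_patchset):
    """All three studied (h2, h3) configurations train and evaluate."""
    sub = cn.PatchSet(
        vectors=tiny_patchset.vectors[:300],
        labels=tiny_patchset.labels[:300],
        source_ids=tiny_patchset.source_ids[:300],
        vertebra_indices=tiny_patchset.vertebra_indices[:300],
        offsets=tiny_patchset.offsets[:300],
    )
    cfg = cn.TrainingConfig(
        h2_size=h2, h3_size=h3, pretrain_epochs=1, finetune_epochs=2
    )
    res = cn.SlopeRegression(sub, cfg).fit()
    assert res.params.W2.shape == (h2, PCA_COMPONENTS)
    assert res.params.W3.shape == (h3, h2)
    assert np.isfinite(res.evaluate(sub)["mae"])


class TestPredictAndPersistence:
    def test_predict_slope_is_definitional_composition(
        self, small_trained, noise_free_phantom
    ):
        rad = noise_free_phantom
        click = rad.truth.vertebrae[8].center
        direct = cn.predict_slope(small_trained.params, rad.image, click)
        composed = forward(
            small_trained.params, cn.patch_vector(rad.image, click)
        )
        assert direct == composed

    def test_prediction_locally_stable_around_click(
        self, small_trained, noise_free_phantom
    ):
        rad = noise_free_phantom
        cx, cy = rad.truth.vertebrae[8].center
        a = cn.predict_slope(small_trained.params, rad.image, (cx, cy))
        b = cn.predict_slope(small_trained.params, rad.image, (cx + 1, cy))
        assert abs(a - b) < 1.0

    def test_container_round_trip_bit_identical(
        self, tmp_path, small_trained, tiny_patchset
    ):
        path = tmp_path / "model.npz"
        small_trained.save(path)
        loaded = cn.SlopeRegressionResults.load(path)
        x = tiny_patchset.vectors[5]
        assert forward(loaded.params, x) == forward(small_trained.params, x)
        assert loaded.params.h2_size == small_trained.params.h2_size

    def test_truncated_container_rejected(self, tmp_path, small_trained):
        path = tmp_path / "model.npz"
        small_trained.save(path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(cn.DataIntegrityError):
            cn.load_model(path)

    def test_cross_architecture_metadata(self, tmp_path, tiny_patchset):
        sub = cn.PatchSet(
            vectors=tiny_patchset.vectors[:150],
            labels=tiny_patchset.labels[:150],
            source_ids=tiny_patchset.source_ids[:150],
            vertebra_indices=tiny_patchset.vertebra_indices[:150],
            offsets=tiny_patchset.offsets[:150],
        )
        cfg = cn.TrainingConfig(
            h2_size=80, h3_size=10, pretrain_epochs=1, finetune_epochs=1
        )
        res = cn.SlopeRegression(sub, cfg).fit()
        path = tmp_path / "m.npz"
        res.save(path)
        loaded = cn.load_model(path)
        assert (loaded.h2_size, loaded.h3_size) == (80, 10)

    def test_summary_mentions_architecture(self, small_trained):
        s = small_trained.summary()
        assert "500" in s and "50" in s and "MSE" in s
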