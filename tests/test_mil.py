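"""Bag model, block network, attention pooling and serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dreamers import (
    AttentionParams,
    Bag,
    HyperCube,
    InvalidArgumentError,
    ModelConfig,
    attention_pool,
    bag_from_cube,
    build_model,
    generate_axis,
    layer_widths,
)


class TestLayerWidths:
    @pytest.mark.parametrize(
        "n_blocks,first_hidden,expansion,expected",
        [
            (2, 64, "half", [64, 32]),
            (2, 64, "double", [64, 128]),
            (1, 256, "half", [256]),
            (1, 256, "double", [256]),
            (3, 128, "half", [128, 64, 32]),
        ],
    )
    def test_expansion_rules(self, n_blocks, first_hidden, expansion, expected):
        cfg = ModelConfig(n_blocks=n_blocks, first_hidden=first_hidden, expansion=expansion)
        assert layer_widths(cfg) == expected

    def test_width_underflow_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ModelConfig(n_blocks=3, first_hidden=2, expansion="half")

    @pytest.mark.parametrize("kw", [{"n_blocks": 4}, {"expansion": "triple"}, {"first_hidden": 0}])
    def test_invalid_config(self, kw):
        with pytest.raises(InvalidArgumentError):
            ModelConfig(**kw)


class TestBuildModel:
    def test_final_architecture_shapes(self):
        cfg = ModelConfig(input_dim=213, n_blocks=2, first_hidden=64, expansion="half")
        model = build_model(cfg, seed=0)
        assert model.params["input.W"].shape == (64, 213)
        assert model.params["block0.W"].shape == (64, 64)
        assert model.params["block1.W"].shape == (32, 64)
        assert model.params["attn.V"].shape == (128, 32)
        assert cfg.embedding_dim == 32

    def test_same_seed_identical_parameters(self):
        cfg = ModelConfig(input_dim=20, first_hidden=8, attention_dim=4)
        a, b = build_model(cfg, seed=5), build_model(cfg, seed=5)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])
        c = build_model(cfg, seed=6)
        assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)

    def test_parameter_count_closed_form(self):
        cfg = ModelConfig(input_dim=213, n_blocks=2, first_hidden=64, expansion="half")
        model = build_model(cfg, seed=0)
        expected = (
            64 * 213 + 64            # input layer
            + 64 * 64 + 64 + 2 * 64  # block 0 linear + batch-norm affine
            + 32 * 64 + 32 + 2 * 32  # block 1
            + 128 * 32 + 128         # attention V, w
            + 2 * 32 + 2             # classifier
        )
        assert model.n_parameters == expected

    def test_residual_projection_only_on_width_change(self):
        same = build_model(ModelConfig(input_dim=8, n_blocks=1, first_hidden=8, residual=True))
        assert "block0.skip.W" not in same.params
        chg = build_model(
            ModelConfig(input_dim=8, n_blocks=2, first_hidden=8, expansion="double", residual=True)
        )
        assert "block1.skip.W" in chg.params and "block0.skip.W" not in chg.params


class TestAttentionPool:
    def test_singleton_bag(self):
        params = AttentionParams(np.eye(3), np.ones(3))
        h = np.array([[1.0, -2.0, 0.5]])
        z, a = attention_pool(h, params)
        np.testing.assert_array_equal(a, [1.0])
        np.testing.assert_array_equal(z, h[0])

    def test_identical_instances_uniform_weights(self):
        params = AttentionParams(np.ones((2, 4)), np.array([0.3, -0.7]))
        h = np.tile(np.array([0.1, 0.2, 0.3, 0.4]), (6, 1))
        z, a = attention_pool(h, params)
        np.testing.assert_allclose(a, 1 / 6)
        np.testing.assert_allclose(z, h[0])

    def test_matches_brute_force_formula(self):
        # direct evaluation of the softmax/weighted-average formulas
        V = np.array([[0.2, -0.1], [0.05, 0.3], [-0.4, 0.1]])
        w = np.array([1.0, -0.5, 0.25])
        H = np.array([[0.5, -1.0], [2.0, 0.3], [-0.7, 0.9]])
        exps = [np.exp(w @ np.tanh(V @ h)) for h in H]
        a_expected = np.array(exps) / sum(exps)
        z_expected = sum(ak * h for ak, h in zip(a_expected, H))
        z, a = attention_pool(H, AttentionParams(V, w))
        np.testing.assert_allclose(a, a_expected, atol=1e-12)
        np.testing.assert_allclose(z, z_expected, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 40), m=st.integers(1, 6))
    def test_simplex_and_permutation_invariance(self, seed, k, m):
        r = np.random.default_rng(seed)
        H = r.normal(size=(k, m)) * 3
        params = AttentionParams(r.normal(size=(4, m)), r.normal(size=4))
        z, a = attention_pool(H, params)
        assert np.all(a >= 0) and a.sum() == pytest.approx(1.0, abs=1e-9)
        # z is a convex combination: inside the per-coordinate envelope
        assert np.all(z <= H.max(axis=0) + 1e-12) and np.all(z >= H.min(axis=0) - 1e-12)
        perm = r.permutation(k)
        z2, a2 = attention_pool(H[perm], params)
        np.testing.assert_allclose(z2, z, atol=1e-12)
        np.testing.assert_allclose(a2, a[perm], atol=1e-12)

    def test_nonfinite_rejected(self):
        params = AttentionParams(np.eye(2), np.ones(2))
        from dreamers import NumericError

        with pytest.raises(NumericError):
            attention_pool(np.array([[np.nan, 1.0]]), params)


class TestForward:
    @pytest.fixture()
    def small_model(self):
        cfg = ModelConfig(input_dim=10, n_blocks=2, first_hidden=8, attention_dim=4)
        return build_model(cfg, seed=3)

    def _bag(self, X, label=0):
        idx = np.stack([np.arange(len(X)), np.zeros(len(X), int)], axis=1)
        return Bag(instances=X, label=label, index_map=idx)

    def test_identical_instances_match_singleton(self, small_model, rng):
        x = rng.normal(size=10)
        lone, _ = small_model.forward(self._bag(x[None, :]))
        many, a = small_model.forward(self._bag(np.tile(x, (7, 1))))
        np.testing.assert_allclose(many, lone, atol=1e-10)
        np.testing.assert_allclose(a, 1 / 7)

    def test_permutation_invariance(self, small_model, rng):
        X = rng.normal(size=(20, 10))
        logits, a = small_model.forward(self._bag(X))
        perm = rng.permutation(20)
        logits2, a2 = small_model.forward(self._bag(X[perm]))
        np.testing.assert_allclose(logits2, logits, atol=1e-10)
        np.testing.assert_allclose(a2, a[perm], atol=1e-10)

    def test_width_mismatch_rejected(self, small_model):
        with pytest.raises(InvalidArgumentError):
            small_model.forward(self._bag(np.zeros((3, 11))))

    def test_identity_activation_matches_manual_affine(self):
        """With the linear test hook the whole instance map is affine."""
        cfg = ModelConfig(
            input_dim=6, n_blocks=1, first_hidden=4, attention_dim=3, activation="identity"
        )
        model = build_model(cfg, seed=1)
        p = model.params
        r = np.random.default_rng(0)
        X = r.normal(size=(5, 6))
        h0 = X @ p["input.W"].T + p["input.b"]
        u = h0 @ p["block0.W"].T + p["block0.b"]
        inv = 1 / np.sqrt(p["block0.bn.running_var"] + 1e-5)
        h = p["block0.bn.gamma"] * (u - p["block0.bn.running_mean"]) * inv + p["block0.bn.beta"]
        z, a = attention_pool(h, model.attention)
        expected = p["clf.W"] @ z + p["clf.b"]
        logits, _ = model.forward(self._bag(X))
        np.testing.assert_allclose(logits, expected, atol=1e-12)

    @pytest.mark.parametrize("bn_mode", ["running", "batch"])
    def test_gradients_match_finite_differences(self, bn_mode):
        """Backprop of the full bag loss vs central differences."""
        cfg = ModelConfig(
            input_dim=5, n_blocks=2, first_hidden=4, expansion="double",
            residual=True, attention_dim=3, bn_train_mode=bn_mode,
        )
        model = build_model(cfg, seed=2)
        r = np.random.default_rng(4)
        X = r.normal(size=(6, 5))
        base_params = model.copy_params()

        def loss_at(params):
            m = type(model)(cfg, {k: v.copy() for k, v in params.items()})
            return m.loss_and_grads(X, 1)[0]

        _, grads = type(model)(cfg, {k: v.copy() for k, v in base_params.items()}).loss_and_grads(X, 1)
        eps = 1e-6
        rchk = np.random.default_rng(9)
        for key, g in grads.items():
            flat = base_params[key].ravel()
            for idx in rchk.choice(flat.size, size=min(4, flat.size), replace=False):
                pp = {k: v.copy() for k, v in base_params.items()}
                pp[key].ravel()[idx] += eps
                up = loss_at(pp)
                pp[key].ravel()[idx] -= 2 * eps
                down = loss_at(pp)
                fd = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(fd, abs=1e-5, rel=1e-4), key

    def test_serialisation_round_trip_bitwise(self, small_model, rng, tmp_path):
        X = rng.normal(size=(12, 10))
        bag = self._bag(X)
        logits, a = small_model.forward(bag)
        path = tmp_path / "ckpt.npz"
        small_model.save(path)
        loaded = type(small_model).load(path)
        logits2, a2 = loaded.forward(bag)
        assert np.array_equal(logits, logits2)
        assert np.array_equal(a, a2)
        assert loaded.config == small_model.config


class TestBagFromCube:
    def test_flattening_counts(self, rng):
        ax = generate_axis(952, 1800, 5)
        for h, w, k in [(8, 8, 64), (1, 1, 1), (64, 64, 4096)]:
            cube = HyperCube(rng.random((h, w, 5)), ax)
            bag = bag_from_cube(cube, label=0)
            assert bag.n_instances == k
            assert bag.instances.shape == (k, 5)

    def test_row_major_index_map(self, rng):
        ax = generate_axis(952, 1800, 3)
        arr = rng.random((2, 3, 3))
        bag = bag_from_cube(HyperCube(arr, ax), label=1)
        np.testing.assert_array_equal(bag.index_map[:3, 0], 0)
        np.testing.assert_array_equal(bag.index_map[:3, 1], [0, 1, 2])
        for k, (r, c) in enumerate(bag.index_map):
            np.testing.assert_array_equal(bag.instances[k], arr[r, c])

    def test_duplicate_index_map_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Bag(
                instances=np.zeros((2, 3)),
                label=0,
                index_map=np.array([[0, 0], [0, 0]]),
            )
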