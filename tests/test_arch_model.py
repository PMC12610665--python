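import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pcgnet as pn
from pcgnet import nn
from pcgnet.arch import LayerSpec


class TestForwardShapes:
    def test_default_architecture_shape_chain(self):
        arch = pn.default_architecture()
        shapes = pn.forward_shapes(arch)
        convs = [s for s, l in zip(shapes, arch.layers) if l.kind == "conv"]
        assert convs == [(16, 12, 32), (15, 11, 64), (7, 5, 64)]
        flat = [s for s, l in zip(shapes, arch.layers) if l.kind == "flatten"][0]
        assert flat == 2240

    def test_13x9_input_chain(self):
        arch = pn.default_architecture(dims=13, frames=9)
        shapes = pn.forward_shapes(arch)
        convs = [s for s, l in zip(shapes, arch.layers) if l.kind == "conv"]
        assert convs[-1] == (5, 3, 64)
        assert [s for s, l in zip(shapes, arch.layers) if l.kind == "flatten"][0] == 960

    def test_exact_fit_single_conv(self):
        arch = pn.ArchitectureSpec(
            input_shape=(2, 2, 1),
            layers=[LayerSpec("conv", out_channels=1, kernel=(2, 2), stride=1)],
        )
        assert pn.forward_shapes(arch) == [(1, 1, 1)]

    def test_underflow_raises(self):
        arch = pn.ArchitectureSpec(
            input_shape=(1, 1, 1),
            layers=[LayerSpec("conv", out_channels=1, kernel=(2, 2), stride=1)],
        )
        with pytest.raises(ValueError):
            pn.forward_shapes(arch)


class TestCounts:
    def test_default_per_layer_parameters(self):
        arch = pn.default_architecture()
        per = [c for c in pn.count_parameters(arch, per_layer=True) if c]
        assert per == [160, 8256, 16448, 286848, 645]
        assert pn.count_parameters(arch) == 312_357

    @pytest.mark.parametrize(
        "dims,frames,total",
        [(13, 13, 230_437), (39, 13, 762_917), (13, 9, 148_517), (17, 13, 312_357)],
    )
    def test_parameter_table_entries(self, dims, frames, total):
        assert pn.count_parameters(pn.default_architecture(dims=dims, frames=frames)) == total

    def test_default_flops(self):
        assert pn.count_flops(pn.default_architecture()) == 4_474_112

    def test_single_dense_and_tiny_conv(self):
        dense = pn.ArchitectureSpec(
            input_shape=(1, 1, 1),
            layers=[LayerSpec("flatten"), LayerSpec("dense", out_units=1)],
            n_classes=1,
        )
        assert pn.count_parameters(dense) == 2
        assert pn.count_flops(dense) == 2
        conv = pn.ArchitectureSpec(
            input_shape=(1, 1, 1),
            layers=[LayerSpec("conv", out_channels=1, kernel=(1, 1), stride=1)],
        )
        assert pn.count_flops(conv) == 2

    def test_dense_hidden_flops(self):
        arch = pn.default_architecture()
        flops_no_dense2 = 2 * 2240 * 128
        assert flops_no_dense2 == 573_440
        assert pn.count_flops(arch) > flops_no_dense2

    @settings(max_examples=30, deadline=None)
    @given(d=st.integers(13, 39).filter(lambda v: v % 2 == 0), frames=st.integers(9, 16))
    def test_even_odd_dimension_parity(self, d, frames):
        """An even input height and the next odd one give identical parameter
        counts: the stride-2 conv floors away the extra row (the published
        parameter table pairs 14/15, 16/17, 18/19)."""
        a = pn.count_parameters(pn.default_architecture(dims=d, frames=frames))
        b = pn.count_parameters(pn.default_architecture(dims=d + 1, frames=frames))
        assert a == b

    def test_kwc_removal_leaves_count_unchanged(self):
        with_kwc = pn.default_architecture(use_kwc=True)
        without = pn.default_architecture(use_kwc=False)
        assert pn.count_parameters(with_kwc) == pn.count_parameters(without)


class TestKwcLayer:
    def test_single_channel_example(self):
        out = pn.kwc_forward(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
        np.testing.assert_allclose(out, [[[2.5, 5.0], [7.5, 10.0]]])

    def test_zero_tensor_maps_to_zero(self):
        np.testing.assert_array_equal(pn.kwc_forward(np.zeros((3, 2, 2))), 0.0)

    def test_high_mean_amplified_low_mean_attenuated(self):
        F = np.stack([np.full((2, 2), 2.0), np.full((2, 2), 0.5)])
        out = pn.kwc_forward(F)
        np.testing.assert_allclose(out[0], 4.0)
        np.testing.assert_allclose(out[1], 0.25)

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    def test_positive_homogeneity_degree_two(self, a, seed):
        F = np.random.default_rng(seed).normal(size=(4, 3, 5))
        np.testing.assert_allclose(
            pn.kwc_forward(a * F), a * a * pn.kwc_forward(F), rtol=1e-9
        )

    def test_gradient_flows_through_both_factors(self, rng):
        """Backward must apply the product rule, not treat the weight as a
        constant."""
        layer = nn.KWC()
        x = rng.normal(size=(1, 2, 2, 2))
        cot = rng.normal(size=(1, 2, 2, 2))
        layer.forward(x, training=True)
        dx = layer.backward(cot)
        eps = 1e-6
        num = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            up = float((layer.forward(x) * cot).sum())
            x[i] -= 2 * eps
            dn = float((layer.forward(x) * cot).sum())
            x[i] += eps
            num[i] = (up - dn) / (2 * eps)
        layer.forward(x, training=True)
        np.testing.assert_allclose(dx, num, atol=1e-6)


class TestBuildModel:
    def test_framework_count_matches_analytic(self):
        arch = pn.default_architecture()
        net = pn.build_model(arch, seed=0)
        assert net.n_parameters() == pn.count_parameters(arch) == 312_357

    @settings(max_examples=10, deadline=None)
    @given(
        f1=st.integers(2, 8),
        f2=st.integers(2, 8),
        dense=st.integers(4, 32),
        dims=st.integers(6, 20),
    )
    def test_framework_count_matches_analytic_fuzz(self, f1, f2, dense, dims):
        arch = pn.ArchitectureSpec(
            input_shape=(dims, 9, 1),
            layers=[
                LayerSpec("conv", out_channels=f1, kernel=(2, 2), stride=1, batch_norm=True),
                LayerSpec("conv", out_channels=f2, kernel=(2, 2), stride=2),
                LayerSpec("kwc"),
                LayerSpec("flatten"),
                LayerSpec("dense", out_units=dense),
                LayerSpec("dense", out_units=3),
            ],
            n_classes=3,
        )
        net = pn.build_model(arch, seed=1)
        assert net.n_parameters() == pn.count_parameters(arch)

    def test_forward_softmax_rows_sum_to_one(self, rng):
        net = pn.build_model(pn.default_architecture(), seed=2)
        logits = net.forward(rng.normal(size=(6, 1, 17, 13)))
        proba = nn.softmax(logits)
        assert proba.shape == (6, 5)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_seeded_initialization_deterministic(self):
        a = pn.build_model(pn.default_architecture(), seed=5)
        b = pn.build_model(pn.default_architecture(), seed=5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)


class TestTrainingMechanics:
    def test_learning_rate_staircase_decay(self):
        opt = nn.Adam([np.zeros(1)], lr=1e-3, decay_rate=0.95, decay_steps=10_000)
        assert opt.current_lr() == 1e-3
        opt.t = 9_999
        assert opt.current_lr() == 1e-3
        opt.t = 10_000
        assert np.isclose(opt.current_lr(), 1e-3 * 0.95)
        opt.t = 25_000
        assert np.isclose(opt.current_lr(), 1e-3 * 0.95**2)

    def test_classifier_records_decayed_lr(self, rng):
        X = rng.normal(size=(20, 6, 6))
        y = np.array(["a", "b"] * 10)
        clf = pn.WCNNClassifier(
            epochs=2, batch_size=5, decay_steps=3, n_filters=(2, 2, 2),
            dense_units=4, random_state=0,
        )
        clf.fit(X, y)
        # 4 iterations/epoch: epoch 1 ends at t=4 -> one decay step applied
        assert np.isclose(clf.history_["lr"][0], 1e-3 * 0.95)
        assert clf.history_["lr"][1] < clf.history_["lr"][0]

    def test_same_seed_identical_history(self, rng):
        X = rng.normal(size=(30, 8, 8))
        y = np.array(["a", "b", "c"] * 10)
        kw = dict(epochs=3, n_filters=(2, 3, 3), dense_units=8, random_state=11)
        h1 = pn.WCNNClassifier(**kw).fit(X, y).history_
        h2 = pn.WCNNClassifier(**kw).fit(X, y).history_
        assert h1 == h2

    def test_non_finite_loss_raises_training_error(self, rng):
        X = rng.normal(size=(16, 6, 6))
        X[0, 0, 0] = np.nan  # corrupt input drives the loss non-finite
        y = np.array(["a", "b"] * 8)
        clf = pn.WCNNClassifier(epochs=2, n_filters=(2, 2, 2), dense_units=4,
                                random_state=0)
        with pytest.raises(pn.TrainingDivergedError, match="non-finite"):
            clf.fit(X, y)

    def test_binary_cross_entropy_single_logit(self, rng):
        X = rng.normal(size=(24, 8, 8))
        X[:12] += 2.0
        y = np.array(["abn"] * 12 + ["nor"] * 12)
        clf = pn.WCNNClassifier(
            epochs=12, loss="binary_cross_entropy", n_filters=(2, 3, 3),
            dense_units=8, random_state=0,
        )
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (24, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert clf.decision_function(X).shape[1] == 1

    def test_fitted_classifier_parameter_count(self, small_clean_dataset):
        _, X, y = small_clean_dataset
        clf = pn.WCNNClassifier(epochs=1, random_state=0)
        clf.fit(X, y)
        assert clf.n_parameters() == 312_357

    def test_save_load_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(20, 8, 8))
        y = np.array(["a", "b"] * 10)
        clf = pn.WCNNClassifier(epochs=2, n_filters=(2, 3, 3), dense_units=8,
                                random_state=3)
        clf.fit(X, y)
        path = tmp_path / "model.npz"
        clf.save(str(path))
        back = pn.WCNNClassifier.load(str(path))
        np.testing.assert_allclose(back.predict_proba(X), clf.predict_proba(X))

    def test_sklearn_get_set_params(self):
        clf = pn.WCNNClassifier(epochs=7)
        assert clf.get_params()["epochs"] == 7
        clf.set_params(use_kwc=False)
        assert not clf.use_kwc
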