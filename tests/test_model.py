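import numpy as np
import pytest

from dicarn.autograd import Adam, Parameter, Tensor, concat, conv2d
from dicarn.errors import DataError, ShapeError, ValidationError
from dicarn.metrics import ssim
from dicarn.model import (
    DiCARN,
    ModelConfig,
    NetworkState,
    TrainConfig,
    count_parameters,
    dilated_conv_reference,
    load_checkpoint,
    model_forward,
    receptive_field_radius,
    residual_block_forward,
    save_checkpoint,
    spatial_self_attention,
    train_model,
)
from dicarn.hic_io import Tile, TileSet


# ---------------------------------------------------------------------------
# Autograd: finite-difference verification
# ---------------------------------------------------------------------------

def _numgrad(f, x, i, eps=1e-6):
    xp, xm = x.copy(), x.copy()
    xp[i] += eps
    xm[i] -= eps
    return (f(xp) - f(xm)) / (2 * eps)


class TestAutogradGradients:
    @pytest.mark.parametrize("dilation,padding", [(1, 1), (2, 2), (3, 0)])
    def test_conv2d_gradients(self, dilation, padding):
        rng = np.random.default_rng(dilation)
        x = Tensor(rng.normal(size=(2, 3, 9, 9)), requires_grad=True)
        w = Parameter(rng.normal(size=(4, 3, 3, 3)) * 0.2)
        b = Parameter(rng.normal(size=4) * 0.1)
        loss = conv2d(x, w, b, dilation=dilation, padding=padding).relu().square().mean()
        loss.backward()

        def f_x(xd):
            return float(
                conv2d(Tensor(xd), w, b, dilation=dilation, padding=padding)
                .relu().square().mean().data
            )

        def f_w(wd):
            return float(
                conv2d(x, Tensor(wd), b, dilation=dilation, padding=padding)
                .relu().square().mean().data
            )

        for idx in [(0, 0, 0, 0), (1, 2, 4, 7), (0, 1, 8, 3)]:
            assert x.grad[idx] == pytest.approx(_numgrad(f_x, x.data, idx), abs=1e-7)
        for idx in [(0, 0, 0, 0), (3, 2, 1, 2)]:
            assert w.grad[idx] == pytest.approx(_numgrad(f_w, w.data, idx), abs=1e-7)

    def test_softmax_matmul_concat_gradients(self):
        rng = np.random.default_rng(0)
        a = Tensor(rng.normal(size=(2, 4, 5)), requires_grad=True)
        b = Tensor(rng.normal(size=(2, 5, 3)), requires_grad=True)

        def compose(ad, bd):
            t = Tensor(ad).matmul(Tensor(bd)).softmax(axis=-1)
            return concat([t, t * 2.0], axis=1).square().mean()

        loss = concat(
            [a.matmul(b).softmax(axis=-1), a.matmul(b).softmax(axis=-1) * 2.0], axis=1
        ).square().mean()
        loss.backward()
        for idx in [(0, 0, 0), (1, 3, 4)]:
            num = _numgrad(lambda d: float(compose(d, b.data).data), a.data, idx)
            assert a.grad[idx] == pytest.approx(num, abs=1e-7)
        for idx in [(0, 0, 0), (1, 4, 2)]:
            num = _numgrad(lambda d: float(compose(a.data, d).data), b.data, idx)
            assert b.grad[idx] == pytest.approx(num, abs=1e-7)

    def test_full_network_gradient(self):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=(1,), tail_dilated_stack=1)
        net = DiCARN(cfg, seed=0)
        rng = np.random.default_rng(1)
        xd = rng.random((1, 1, 8, 8))
        params = net.named_parameters()
        name, p = "cascade1.res.conv1.w", params["cascade1.res.conv1.w"]

        def f(pd):
            p.data = pd
            return float(net.forward(Tensor(xd)).square().mean().data)

        x = Tensor(xd)
        loss = net.forward(x).square().mean()
        for q in params.values():
            q.grad = None
        loss.backward()
        g = p.grad.copy()
        for idx in [(0, 0, 0, 0), (3, 2, 2, 1)]:
            assert g[idx] == pytest.approx(_numgrad(f, p.data.copy(), idx), abs=1e-6)

    def test_adam_reduces_quadratic(self):
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            loss = p.square().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.all(np.abs(p.data) < 0.05)


# ---------------------------------------------------------------------------
# Dilated convolution semantics
# ---------------------------------------------------------------------------

def conv1d_oracle(x, w, d):
    """Naive sliding-window evaluation with taps spaced d apart."""
    out = []
    i = 0
    while i + d * (len(w) - 1) < len(x):
        out.append(sum(x[i + d * k] * w[k] for k in range(len(w))))
        i += 1
    return np.array(out)


class TestDilatedReference:
    def test_hand_summation(self):
        np.testing.assert_allclose(dilated_conv_reference([1, 0, 2, 0, 3], [1, 1, 1], 2), [6.0])

    def test_identity_kernel(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0]
        for d in (1, 2, 3):
            np.testing.assert_allclose(dilated_conv_reference(x, [1.0], d), x)

    def test_d1_is_ordinary_convolution(self):
        np.testing.assert_allclose(dilated_conv_reference([1, 2, 3], [1, 1], 1), [3.0, 5.0])

    def test_matches_brute_force_on_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(1, 5))
            d = int(rng.integers(1, 4))
            n = int(rng.integers(1 + d * (k - 1), 20 + d * k))
            x = rng.normal(size=n)
            w = rng.normal(size=k)
            np.testing.assert_array_equal(
                dilated_conv_reference(x, w, d), conv1d_oracle(x, w, d)
            )

    def test_too_short_sequence(self):
        with pytest.raises(ShapeError):
            dilated_conv_reference([1.0, 2.0], [1.0, 1.0, 1.0], 2)


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

class TestAttention:
    def test_gamma_zero_is_bit_exact_identity(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(6, 7, 5))
        out = spatial_self_attention(feats, gamma=0.0, seed=3)
        assert np.array_equal(out, feats)

    def test_single_position_softmax(self):
        feats = np.array([[[2.0]], [[3.0]]])  # C=2, H=W=1
        out, attn = spatial_self_attention(feats, gamma=0.5, seed=1, return_attention=True)
        assert attn.shape == (1, 1) and attn[0, 0] == 1.0
        # output = gamma * value + input where value is the 1x1 conv of feats
        assert out.shape == feats.shape

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(4, 3, 3))
        _, attn = spatial_self_attention(feats, gamma=0.7, seed=2, return_attention=True)
        assert attn.shape == (9, 9)
        assert np.all(attn >= 0)
        np.testing.assert_allclose(attn.sum(axis=-1), np.ones(9), atol=1e-6)

    def test_non_finite_features_rejected(self):
        feats = np.full((2, 3, 3), np.nan)
        with pytest.raises(ValidationError):
            spatial_self_attention(feats, gamma=0.0)


# ---------------------------------------------------------------------------
# Residual block and network forward
# ---------------------------------------------------------------------------

def _zero_state(cfg: ModelConfig) -> NetworkState:
    net = DiCARN(cfg, seed=0)
    weights = {k: np.zeros_like(v) for k, v in net.state_weights().items()}
    return NetworkState(weights=weights, config=cfg)


class TestResidualBlock:
    CFG = ModelConfig(n_cascades=2, channels=4, attention_blocks=())

    def test_zero_weights_zero_input_gives_zero(self):
        state = _zero_state(self.CFG)
        x = np.zeros((1, 4, 10, 10))
        np.testing.assert_array_equal(residual_block_forward(x, state, 1), x)

    def test_spatial_shape_preserved(self):
        net = DiCARN(self.CFG, seed=1)
        x = Tensor(np.random.default_rng(0).random((2, 4, 40, 40)))
        assert net.blocks[0](x).data.shape == (2, 4, 40, 40)

    def test_zero_conv_weights_identity_skip(self):
        state = _zero_state(self.CFG)
        x = np.random.default_rng(1).normal(size=(1, 4, 8, 8))
        np.testing.assert_array_equal(residual_block_forward(x, state, 2), x)

    def test_channel_mismatch(self):
        state = _zero_state(self.CFG)
        with pytest.raises(ShapeError):
            residual_block_forward(np.zeros((1, 3, 8, 8)), state, 1)

    def test_gradient_flows_through_skip_with_zero_convs(self):
        # vanishing-gradient mitigation: the skip path carries gradient even
        # when every convolution is frozen at zero
        net = DiCARN(self.CFG, seed=0)
        for k, p in net.named_parameters().items():
            p.data = np.zeros_like(p.data)
            p.requires_grad = False
        x = Tensor(np.random.default_rng(2).normal(size=(1, 4, 8, 8)), requires_grad=True)
        loss = net.blocks[0](x).square().mean()
        loss.backward()
        assert np.abs(x.grad).max() > 0


class TestModelForward:
    def _tiles(self, values_list):
        tiles = [Tile(i * 40, i * 40, v, "chrT") for i, v in enumerate(values_list)]
        n = 40 * (len(values_list) + 1)
        return TileSet(tiles, (n, n), stride=40, chrom="chrT", resolution=10_000)

    def test_identical_tiles_identical_outputs(self):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=())
        state = NetworkState(weights=DiCARN(cfg, seed=5).state_weights(), config=cfg)
        v = np.random.default_rng(0).random((40, 40))
        out = model_forward(self._tiles([v, v.copy()]), state)
        np.testing.assert_array_equal(out.tiles[0].values, out.tiles[1].values)

    def test_permutation_equivariance(self):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=())
        state = NetworkState(weights=DiCARN(cfg, seed=5).state_weights(), config=cfg)
        rng = np.random.default_rng(1)
        vals = [rng.random((40, 40)) for _ in range(3)]
        fwd = model_forward(self._tiles(vals), state)
        rev = model_forward(self._tiles(vals[::-1]), state)
        for a, b in zip(fwd.tiles, rev.tiles[::-1]):
            np.testing.assert_array_equal(a.values, b.values)

    def test_wrong_tile_size_rejected(self):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=())
        state = NetworkState(weights=DiCARN(cfg, seed=5).state_weights(), config=cfg)
        ts = TileSet([Tile(0, 0, np.zeros((20, 20)))], (40, 40), stride=20)
        with pytest.raises(ShapeError):
            model_forward(ts, state)


class TestParameterCounting:
    @pytest.mark.parametrize(
        "cfg",
        [
            ModelConfig(),
            ModelConfig(n_cascades=1, channels=8, attention_blocks=()),
            ModelConfig(n_cascades=3, channels=16, attention_blocks=(1, 3), tail_dilated_stack=1),
        ],
        ids=["default", "tiny", "mixed"],
    )
    def test_analytic_count_matches_instantiation(self, cfg):
        assert DiCARN(cfg, seed=0).n_parameters() == count_parameters(cfg)

    def test_count_invariant_in_dilation_rate(self):
        for d1, d2 in [(1, 2), (2, 5)]:
            c1 = ModelConfig(dilation_rate=d1)
            c2 = ModelConfig(dilation_rate=d2)
            assert count_parameters(c1) == count_parameters(c2)
            assert DiCARN(c1, seed=0).n_parameters() == DiCARN(c2, seed=0).n_parameters()


class TestReceptiveField:
    @staticmethod
    def _observed_radius(cfg: ModelConfig, size: int = 39) -> int:
        """Chebyshev radius of outputs changed by a center-pixel perturbation.

        Conv weights are made strictly positive and biases slightly positive so
        every path propagates through the ReLUs.
        """
        net = DiCARN(cfg, seed=0)
        for name, p in net.named_parameters().items():
            if name.endswith(".w"):
                p.data = np.abs(p.data) + 0.01
            elif name.endswith(".b"):
                p.data = np.full_like(p.data, 0.05)
        x = np.random.default_rng(0).random((1, 1, size, size)) * 0.1
        base = net.predict(x[0])
        xp = x.copy()
        c = size // 2
        xp[0, 0, c, c] += 1.0
        pert = net.predict(xp[0])
        changed = np.argwhere(np.abs(pert - base)[0] > 1e-12)
        return int(np.max(np.maximum(np.abs(changed[:, 0] - c), np.abs(changed[:, 1] - c))))

    def test_perturbation_outside_radius_has_no_effect(self):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=(), tail_dilated_stack=1)
        r = receptive_field_radius(cfg)
        obs = self._observed_radius(cfg)
        assert obs == r  # locality is exactly the analytic radius

    def test_dilation_strictly_enlarges_radius_at_equal_params(self):
        c1 = ModelConfig(n_cascades=1, channels=4, attention_blocks=(),
                         tail_dilated_stack=1, dilation_rate=1)
        c2 = ModelConfig(n_cascades=1, channels=4, attention_blocks=(),
                         tail_dilated_stack=1, dilation_rate=2)
        assert count_parameters(c1) == count_parameters(c2)
        assert receptive_field_radius(c2) > receptive_field_radius(c1)
        assert self._observed_radius(c2) > self._observed_radius(c1)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class TestTraining:
    def _identity_pairs(self, n=6, size=16, seed=0):
        rng = np.random.default_rng(seed)
        tiles = [rng.random((size, size)) for _ in range(n)]
        return [(t, t) for t in tiles]

    def test_empty_training_set_rejected(self):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=())
        with pytest.raises(DataError):
            train_model([], [], cfg, TrainConfig(epochs=1))

    def test_identity_task_beats_untrained_baseline(self):
        cfg = ModelConfig(n_cascades=1, channels=8, attention_blocks=())
        pairs = self._identity_pairs()
        tc = TrainConfig(learning_rate=3e-3, batch_size=2, epochs=10, seed=0)
        state = train_model(pairs, pairs, cfg, tc)
        untrained = DiCARN(cfg, seed=tc.seed)
        x = np.stack([a for a, _ in pairs])
        base = np.mean([ssim(p, t) for p, (_, t) in zip(untrained.predict(x), pairs)])
        assert state.best_validation_score > base

    def test_same_seed_bit_identical(self):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=())
        pairs = self._identity_pairs(n=4)
        tc = TrainConfig(learning_rate=1e-3, batch_size=2, epochs=3, seed=9)
        s1 = train_model(pairs, pairs, cfg, tc)
        s2 = train_model(pairs, pairs, cfg, tc)
        assert s1.best_validation_score == s2.best_validation_score
        for k in s1.weights:
            np.testing.assert_array_equal(s1.weights[k], s2.weights[k])

    def test_best_epoch_matches_logged_curve(self):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=())
        pairs = self._identity_pairs(n=4)
        tc = TrainConfig(learning_rate=3e-3, batch_size=2, epochs=8, seed=1)
        state = train_model(pairs, pairs, cfg, tc)
        curve = [v for _, _, v in state.log]
        assert state.epoch == int(np.argmax(curve)) + 1
        assert state.best_validation_score == max(curve)


class TestCheckpoint:
    def test_roundtrip_bit_identical_predictions(self, tmp_path):
        cfg = ModelConfig(n_cascades=1, channels=4, attention_blocks=(1,))
        net = DiCARN(cfg, seed=3)
        state = NetworkState(weights=net.state_weights(), config=cfg, epoch=7,
                             best_validation_score=0.5,
                             train_config=TrainConfig(epochs=7, seed=3),
                             log=[(1, 0.1, 0.4), (7, 0.05, 0.5)])
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, path)
        back = load_checkpoint(path)
        assert back.epoch == 7 and back.config == cfg
        assert back.log == state.log
        x = np.random.default_rng(0).random((3, 40, 40))
        np.testing.assert_array_equal(
            DiCARN.from_state(state).predict(x), DiCARN.from_state(back).predict(x)
        )
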