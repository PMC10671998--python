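import numpy as np
import pytest

from octdet.augmentation import extract_patches
from octdet.data_io import ScanImage
from octdet.detector import (ModelConfig, embed_with_positions, forward,
                             forward_tensor, init_model_state,
                             load_checkpoint, n_patches, save_checkpoint,
                             transformer_block)
from octdet.losses import lloss_tensor
from octdet.nn import Tensor
from octdet.patch_encoder import sliding_box_queries

CFG = ModelConfig(n_blocks=2, image_height=128, image_width=128)


def small_state(seed=0):
    return init_model_state(CFG, np.random.default_rng(seed))


class TestConfig:
    def test_latent_dim_head_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(latent_dim=66, n_heads=4, mlp_units=(128, 66))

    def test_mlp_must_close_residual(self):
        with pytest.raises(ValueError):
            ModelConfig(mlp_units=(128, 32))

    def test_patch_grid_size(self):
        assert n_patches(CFG) == 16
        assert n_patches(ModelConfig()) == 64  # 250/32 -> 8x8 padded


class TestEmbedWithPositions:
    def test_prepends_summary_token(self):
        state = small_state()
        tokens = Tensor(np.zeros((16, 64)))
        z0 = embed_with_positions(tokens, state)
        assert z0.shape == (17, 64)

    def test_zero_positional_table_passes_tokens_through(self, rng):
        state = small_state()
        state["pos_table"].data[:] = 0.0
        tokens = Tensor(rng.normal(size=(16, 64)))
        z0 = embed_with_positions(tokens, state)
        np.testing.assert_allclose(z0.data[1:], tokens.data, atol=1e-12)
        np.testing.assert_allclose(z0.data[0], state["cls_token"].data[0],
                                   atol=1e-12)

    def test_token_count_mismatch_rejected(self):
        state = small_state()
        with pytest.raises(ValueError):
            embed_with_positions(Tensor(np.zeros((9, 64))), state)


class TestTransformerBlock:
    def test_zero_weights_make_identity(self, rng):
        state = small_state()
        for name in list(state):
            if name.startswith("block0_") and "ln" not in name:
                state[name].data[:] = 0.0
        z = Tensor(rng.normal(size=(17, 64)))
        out = transformer_block(z, state, CFG, 0)
        np.testing.assert_allclose(out.data, z.data, atol=1e-12)

    def test_shape_preserved(self, rng):
        state = small_state()
        z = Tensor(rng.normal(size=(17, 64)))
        assert transformer_block(z, state, CFG, 1).shape == (17, 64)

    def test_single_token_hand_oracle(self):
        # one token, one head, 2-dim latent: evaluate the pre-norm block by
        # straight-line arithmetic (softmax over one key is exactly 1)
        cfg = ModelConfig(n_blocks=1, n_heads=1, latent_dim=2,
                          mlp_units=(3, 2), dropout=0.0, image_height=64,
                          image_width=64,
                          encoder=__import__("octdet").EncoderConfig(
                              embed_dim=2, conv_filters=(2, 2)))
        state = init_model_state(cfg, np.random.default_rng(5))
        z = Tensor(np.array([[1.5, -0.5]]))

        def ln(x, g, b, eps=1e-6):
            mu, var = x.mean(), x.var()
            return (x - mu) / np.sqrt(var + eps) * g + b

        h = ln(z.data[0], state["block0_ln1_g"].data, state["block0_ln1_b"].data)
        attn = (h @ state["block0_wv"].data) @ state["block0_wo"].data
        z1 = z.data[0] + attn
        m = ln(z1, state["block0_ln2_g"].data, state["block0_ln2_b"].data)
        m = m @ state["block0_mlp0_w"].data + state["block0_mlp0_b"].data
        m = m * 0.5 * (1 + __import__("scipy.special", fromlist=["erf"]).erf(
            m / np.sqrt(2)))
        m = m @ state["block0_mlp1_w"].data + state["block0_mlp1_b"].data
        expected = z1 + m
        out = transformer_block(z, state, cfg, 0)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-10)


def numpy_forward_oracle(pixels: np.ndarray, state, cfg: ModelConfig) -> np.ndarray:
    """Independent plain-numpy re-implementation of the full forward pass."""
    from scipy.special import erf

    def gelu(x):
        return x * 0.5 * (1 + erf(x / np.sqrt(2)))

    def softmax(x):
        e = np.exp(x - x.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    def ln(x, g, b, eps=1e-6):
        mu = x.mean(-1, keepdims=True)
        var = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * g + b

    grid = extract_patches(ScanImage(id="o", pixels=pixels), cfg.patch_size)
    queries = sliding_box_queries(grid)
    n = len(grid)
    x = grid.patches.reshape(n, -1)
    q = queries.reshape(n, -1)
    emb_in = x @ state["embed_in_w"].data + state["embed_in_b"].data
    emb_q = q @ state["embed_q_w"].data + state["embed_q_b"].data
    att = softmax(emb_q @ emb_in.T / np.sqrt(cfg.encoder.embed_dim)) @ emb_in
    gated = emb_in + att

    # conv stage with zero 'same' padding and stride
    def conv(x2d, w, b, stride):
        H, W, cin = x2d.shape
        kh, kw, _, cout = w.shape
        oh, ow = -(-H // stride), -(-W // stride)
        ph = max((oh - 1) * stride + kh - H, 0)
        pw = max((ow - 1) * stride + kw - W, 0)
        xp = np.pad(x2d, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2),
                          (0, 0)))
        out = np.zeros((oh, ow, cout))
        for i in range(oh):
            for j in range(ow):
                block = xp[i * stride:i * stride + kh, j * stride:j * stride + kw]
                out[i, j] = np.einsum("abc,abco->o", block, w) + b
        return out

    g2 = gated.reshape(grid.grid_rows, grid.grid_cols, -1)
    c1 = gelu(conv(g2, state["conv1_w"].data, state["conv1_b"].data,
                   cfg.encoder.conv_stride))
    c2 = gelu(conv(c1, state["conv2_w"].data, state["conv2_b"].data,
                   cfg.encoder.conv_stride))
    ri = (np.arange(grid.grid_rows) * c2.shape[0]) // grid.grid_rows
    ci = (np.arange(grid.grid_cols) * c2.shape[1]) // grid.grid_cols
    up = c2[np.ix_(ri, ci)].reshape(n, -1)
    tokens = gated + up
    sq = tokens @ state["attn_q"].data
    sk = tokens @ state["attn_k"].data
    sv = tokens @ state["attn_v"].data
    out = softmax(sq @ sk.T / np.sqrt(cfg.encoder.embed_dim)) @ sv
    tokens = ln(out @ state["attn_o"].data, state["enc_ln_g"].data,
                state["enc_ln_b"].data)

    z = np.vstack([state["cls_token"].data, tokens]) + state["pos_table"].data
    dh = cfg.latent_dim // cfg.n_heads
    for l in range(cfg.n_blocks):
        pre = f"block{l}_"
        h = ln(z, state[pre + "ln1_g"].data, state[pre + "ln1_b"].data)
        qh = (h @ state[pre + "wq"].data).reshape(-1, cfg.n_heads, dh)
        kh_ = (h @ state[pre + "wk"].data).reshape(-1, cfg.n_heads, dh)
        vh = (h @ state[pre + "wv"].data).reshape(-1, cfg.n_heads, dh)
        heads = []
        for a in range(cfg.n_heads):
            w = softmax(qh[:, a] @ kh_[:, a].T / np.sqrt(dh))
            heads.append(w @ vh[:, a])
        z = z + np.concatenate(heads, axis=1) @ state[pre + "wo"].data
        m = ln(z, state[pre + "ln2_g"].data, state[pre + "ln2_b"].data)
        for i in range(len(cfg.mlp_units)):
            m = m @ state[pre + f"mlp{i}_w"].data + state[pre + f"mlp{i}_b"].data
            if i < len(cfg.mlp_units) - 1:
                m = gelu(m)
        z = z + m
    z = ln(z, state["final_ln_g"].data, state["final_ln_b"].data)
    h = gelu(z[0] @ state["head0_w"].data + state["head0_b"].data)
    raw = 1 / (1 + np.exp(-(h @ state["head1_w"].data + state["head1_b"].data)))
    raw = raw.reshape(cfg.max_boxes, 4)
    out = np.empty_like(raw)
    out[:, 0] = np.minimum(raw[:, 0], raw[:, 2])
    out[:, 2] = np.maximum(raw[:, 0], raw[:, 2])
    out[:, 1] = np.minimum(raw[:, 1], raw[:, 3])
    out[:, 3] = np.maximum(raw[:, 1], raw[:, 3])
    return out


class TestForward:
    def test_output_is_k_valid_boxes(self, rng):
        state = small_state()
        img = ScanImage(id="a", pixels=rng.random((128, 128)))
        arr = forward(img, state, CFG)
        assert arr.boxes.shape == (3, 4)
        assert np.all(arr.boxes >= 0) and np.all(arr.boxes <= 1)
        assert np.all(arr.boxes[:, 2] >= arr.boxes[:, 0])
        assert np.all(arr.boxes[:, 3] >= arr.boxes[:, 1])

    def test_deterministic_in_inference_mode(self, rng):
        state = small_state()
        img = ScanImage(id="a", pixels=rng.random((128, 128)))
        a = forward(img, state, CFG).boxes
        b = forward(img, state, CFG).boxes
        np.testing.assert_array_equal(a, b)

    def test_resizes_arbitrary_input(self, rng):
        state = small_state()
        img = ScanImage(id="a", pixels=rng.random((200, 160)))
        assert forward(img, state, CFG).boxes.shape == (3, 4)

    def test_outputs_vary_with_input(self, rng):
        state = small_state()
        outs = [forward(ScanImage(id=f"{i}", pixels=rng.random((128, 128))),
                        state, CFG).boxes for i in range(10)]
        assert np.std([o[0] for o in outs], axis=0).max() > 1e-6

    def test_matches_independent_numpy_oracle(self, rng):
        state = small_state(seed=11)
        pixels = rng.random((128, 128))
        mine = forward(ScanImage(id="a", pixels=pixels), state, CFG).boxes
        ref = numpy_forward_oracle(pixels, state, CFG)
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_tear_hook_is_applied(self, rng):
        state = small_state()
        pixels = rng.random((128, 128))
        base = forward(ScanImage(id="a", pixels=pixels), state, CFG).boxes

        def denoise(img):
            return ScanImage(id=img.id, pixels=np.clip(img.pixels * 0.5, 0, 1))

        hooked = forward(ScanImage(id="a", pixels=pixels), state, CFG,
                         tear=denoise).boxes
        assert not np.array_equal(base, hooked)

    def test_gradients_finite_at_initialization(self, rng):
        state = small_state(seed=3)
        img = ScanImage(id="a", pixels=rng.random((128, 128)))
        actual = np.array([[0.2, 0.2, 0.5, 0.5], [0, 0, 0, 0], [0, 0, 0, 0]])
        pred = forward_tensor(img, state, CFG)
        total, _ = lloss_tensor(pred, actual, (128, 128))
        total.backward()
        for name, p in state.items():
            if p.grad is not None:
                assert np.isfinite(p.grad).all(), name


class TestCheckpoint:
    def test_round_trip_restores_bit_identical_inference(self, rng, tmp_path):
        state = small_state(seed=7)
        img = ScanImage(id="a", pixels=rng.random((128, 128)))
        before = forward(img, state, CFG).boxes
        path = tmp_path / "model.npz"
        save_checkpoint(state, CFG, path)
        state2, cfg2 = load_checkpoint(path)
        assert cfg2 == CFG
        after = forward(img, state2, cfg2).boxes
        np.testing.assert_array_equal(before, after)
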