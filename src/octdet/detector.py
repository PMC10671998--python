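"""Transformer detector trunk: positional embedding, pre-norm transformer
blocks, and a box-regression head.

The encoded patch tokens are prepended with a learnable summary token and
offset by a learned positional table; the sequence then passes through
``n_blocks`` pre-norm transformer blocks (LayerNorm -> multi-head
self-attention -> residual; LayerNorm -> GELU MLP -> residual) and a final
LayerNorm.  The box head reads the summary token and regresses 4*K numbers
through a sigmoid, reshaped into K corner-format boxes; per-box coordinate
sorting (min/max over each axis pair) guarantees x_min <= x_max and
y_min <= y_max for any head output.

There is no objectness score: the model is single-class and always emits K
box slots, with near-zero-area slots interpreted as sentinels downstream.

An optional ``tear`` hook (an image -> image callable) can denoise scans
before patching; the default is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .augmentation import extract_patches
from .data_io import BoxArray, ScanImage, resize_image
from .nn import Tensor, concat, gelu, layer_norm, sigmoid, softmax
from .patch_encoder import (EncoderConfig, gated_attention, init_encoder_state,
                            sliding_box_queries)

__all__ = ["ModelConfig", "init_model_state", "embed_with_positions",
           "transformer_block", "forward", "forward_tensor",
           "save_checkpoint", "load_checkpoint", "n_patches"]


@dataclass(frozen=True)
class ModelConfig:
    n_blocks: int = 8
    n_heads: int = 4
    latent_dim: int = 64
    mlp_units: tuple[int, ...] = (128, 64)
    dropout: float = 0.1
    max_boxes: int = 3
    patch_size: int = 32
    image_height: int = 250
    image_width: int = 250
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self):
        if self.latent_dim % self.n_heads != 0:
            raise ValueError("latent_dim must be divisible by n_heads")
        if self.max_boxes < 1:
            raise ValueError("max_boxes must be at least 1")
        if self.mlp_units[-1] != self.latent_dim:
            raise ValueError("last MLP width must equal latent_dim "
                             "(residual connection)")
        if self.encoder.embed_dim != self.latent_dim:
            raise ValueError("encoder embed_dim must equal latent_dim")


def n_patches(cfg: ModelConfig) -> int:
    rows = -(-cfg.image_height // cfg.patch_size)
    cols = -(-cfg.image_width // cfg.patch_size)
    return rows * cols


def init_model_state(cfg: ModelConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """All learnable parameters; shapes are a pure function of the config."""
    d = cfg.latent_dim
    n = n_patches(cfg)

    def glorot(*shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

    state = init_encoder_state(cfg.encoder, cfg.patch_size, rng)
    state["cls_token"] = Tensor(rng.normal(0.0, 0.02, size=(1, d)),
                                requires_grad=True)
    state["pos_table"] = Tensor(rng.normal(0.0, 0.02, size=(n + 1, d)),
                                requires_grad=True)
    for l in range(cfg.n_blocks):
        pre = f"block{l}_"
        for name in ("wq", "wk", "wv", "wo"):
            state[pre + name] = glorot(d, d, fan_in=d, fan_out=d)
        state[pre + "ln1_g"] = Tensor(np.ones(d), requires_grad=True)
        state[pre + "ln1_b"] = Tensor(np.zeros(d), requires_grad=True)
        state[pre + "ln2_g"] = Tensor(np.ones(d), requires_grad=True)
        state[pre + "ln2_b"] = Tensor(np.zeros(d), requires_grad=True)
        widths = [d, *cfg.mlp_units]
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            state[pre + f"mlp{i}_w"] = glorot(a, b, fan_in=a, fan_out=b)
            state[pre + f"mlp{i}_b"] = Tensor(np.zeros(b), requires_grad=True)
    state["final_ln_g"] = Tensor(np.ones(d), requires_grad=True)
    state["final_ln_b"] = Tensor(np.zeros(d), requires_grad=True)
    h = cfg.mlp_units[0]
    state["head0_w"] = glorot(d, h, fan_in=d, fan_out=h)
    state["head0_b"] = Tensor(np.zeros(h), requires_grad=True)
    state["head1_w"] = glorot(h, 4 * cfg.max_boxes, fan_in=h,
                              fan_out=4 * cfg.max_boxes)
    state["head1_b"] = Tensor(np.zeros(4 * cfg.max_boxes), requires_grad=True)
    return state


def embed_with_positions(tokens: Tensor, state: dict[str, Tensor]) -> Tensor:
    """Prepend the summary token and add the positional table: (N+1, D)."""
    n_plus_1 = state["pos_table"].shape[0]
    if tokens.shape[0] + 1 != n_plus_1:
        raise ValueError(f"{tokens.shape[0]} tokens do not match positional "
                         f"table of length {n_plus_1}")
    z = concat([state["cls_token"], tokens], axis=0)
    return z + state["pos_table"]


def _dropout(x: Tensor, rate: float, train: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not train or rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def _msa(z: Tensor, state: dict[str, Tensor], prefix: str, n_heads: int) -> Tensor:
    t, d = z.shape
    dh = d // n_heads
    q = (z @ state[prefix + "wq"]).reshape(t, n_heads, dh).transpose(1, 0, 2)
    k = (z @ state[prefix + "wk"]).reshape(t, n_heads, dh).transpose(1, 0, 2)
    v = (z @ state[prefix + "wv"]).reshape(t, n_heads, dh).transpose(1, 0, 2)
    attn = softmax((q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh)), axis=-1)
    out = (attn @ v).transpose(1, 0, 2).reshape(t, d)
    return out @ state[prefix + "wo"]


def transformer_block(z_prev: Tensor, state: dict[str, Tensor], cfg: ModelConfig,
                      block_index: int, train: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
    """One pre-norm block: MSA and GELU-MLP sublayers, each residual."""
    pre = f"block{block_index}_"
    attn_in = layer_norm(z_prev, state[pre + "ln1_g"], state[pre + "ln1_b"])
    z = z_prev + _dropout(_msa(attn_in, state, pre, cfg.n_heads),
                          cfg.dropout, train, rng)
    h = layer_norm(z, state[pre + "ln2_g"], state[pre + "ln2_b"])
    for i in range(len(cfg.mlp_units)):
        h = h @ state[pre + f"mlp{i}_w"] + state[pre + f"mlp{i}_b"]
        if i < len(cfg.mlp_units) - 1:
            h = _dropout(gelu(h), cfg.dropout, train, rng)
    return z + _dropout(h, cfg.dropout, train, rng)


def forward_tensor(img: ScanImage, state: dict[str, Tensor], cfg: ModelConfig,
                   train: bool = False, rng: np.random.Generator | None = None,
                   tear: Callable[[ScanImage], ScanImage] | None = None) -> Tensor:
    """Full forward pass to a differentiable (K, 4) corner-format box tensor."""
    if tear is not None:
        img = tear(img)
    if (img.height, img.width) != (cfg.image_height, cfg.image_width):
        img = resize_image(img, cfg.image_height, cfg.image_width)
    grid = extract_patches(img, cfg.patch_size)
    queries = sliding_box_queries(grid)
    encoded = gated_attention(grid.patches, queries, cfg.encoder, state,
                              grid_shape=(grid.grid_rows, grid.grid_cols))
    z = embed_with_positions(encoded.tokens, state)
    for l in range(cfg.n_blocks):
        z = transformer_block(z, state, cfg, l, train=train, rng=rng)
    z = layer_norm(z, state["final_ln_g"], state["final_ln_b"])
    summary = z[0:1]  # keep 2-D: (1, D)
    h = gelu(summary @ state["head0_w"] + state["head0_b"])
    raw = sigmoid(h @ state["head1_w"] + state["head1_b"]).reshape(cfg.max_boxes, 4)
    # enforce validity: sort each coordinate pair
    x_min = raw[:, 0].minimum(raw[:, 2]).reshape(-1, 1)
    x_max = raw[:, 0].maximum(raw[:, 2]).reshape(-1, 1)
    y_min = raw[:, 1].minimum(raw[:, 3]).reshape(-1, 1)
    y_max = raw[:, 1].maximum(raw[:, 3]).reshape(-1, 1)
    return concat([x_min, y_min, x_max, y_max], axis=1)


def forward(img: ScanImage, state: dict[str, Tensor], cfg: ModelConfig,
            tear: Callable[[ScanImage], ScanImage] | None = None) -> BoxArray:
    """Inference-mode forward pass (dropout off, deterministic)."""
    boxes = forward_tensor(img, state, cfg, train=False, tear=tear)
    return BoxArray(boxes.data.copy())


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(state: dict[str, Tensor], cfg: ModelConfig,
                    path: str | Path) -> None:
    """One archive holding the JSON-encoded config and all parameter arrays;
    loading restores bit-identical inference."""
    cfg_dict = asdict(cfg)
    arrays = {name: t.data for name, t in state.items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg_dict).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, Tensor], ModelConfig]:
    with np.load(path) as archive:
        cfg_dict = json.loads(bytes(archive["__config__"]).decode())
        enc_dict = {k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in cfg_dict.pop("encoder").items()}
        cfg_dict["mlp_units"] = tuple(cfg_dict["mlp_units"])
        cfg = ModelConfig(encoder=EncoderConfig(**enc_dict), **cfg_dict)
        state = {name: Tensor(archive[name], requires_grad=True)
                 for name in archive.files if name != "__config__"}
    return state, cfg
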