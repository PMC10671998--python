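"""Attention-gated patch encoder.

The encoder scores the patch stream of an image against a second stream of
sliding-box query windows, so that attention acts as a gate: regions whose
query windows resemble lesion content up-weight the corresponding patch
embeddings, while background is suppressed.

Stages, in order:

1. both streams are flattened and linearly embedded to ``embed_dim``;
2. gating attention: logits are the scaled dot products of embedded queries
   against embedded inputs, row-softmaxed; the score-weighted values are
   added to the patch embeddings (gating emphasizes foreground content on
   top of each patch's own features rather than replacing them, which would
   average away per-patch spatial identity before any positional encoding
   exists);
3. the gated tokens, arranged back on the patch grid, pass through two
   strided 3x3 convolutions (GELU between); the strided output is resampled
   back to the grid resolution and added to the gated tokens as a residual,
   so the token count is preserved and per-token spatial identity survives
   the stride (two stride-3 convolutions alone would collapse any practical
   grid to a single cell and erase location information);
4. a final single-head self-attention layer with learned projections,
   followed by a LayerNorm so the token scale handed to the transformer
   trunk stays bounded during training.

Token count and dimension are therefore invariant: N patches in, N tokens of
``embed_dim`` out, whatever the image size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augmentation import PatchGrid, assemble_patches
from .nn import Tensor, conv2d_same, gelu, layer_norm, softmax, take

__all__ = ["EncoderConfig", "EncodedPatches", "half_stride_windows",
           "sliding_box_queries", "gated_attention", "init_encoder_state"]


@dataclass(frozen=True)
class EncoderConfig:
    embed_dim: int = 64
    conv_filters: tuple[int, int] = (32, 64)
    conv_kernel: int = 3
    conv_stride: int = 3
    attention_heads: int = 1  # the gate is single-head by design

    def __post_init__(self):
        if self.embed_dim <= 0 or min(self.conv_filters) <= 0:
            raise ValueError("embed_dim and conv filter counts must be positive")
        if self.conv_filters[1] != self.embed_dim:
            raise ValueError("second conv filter count must equal embed_dim "
                             "so the final attention operates on full tokens")


@dataclass
class EncodedPatches:
    tokens: Tensor            # (N, embed_dim)
    attention_weights: np.ndarray  # (N, N), rows sum to 1


def half_stride_windows(grid: PatchGrid) -> np.ndarray:
    """All sliding-box windows over the padded image at 50% overlap:
    an (2r-1, 2c-1, P, P) stack for an r x c patch grid."""
    if len(grid) == 0:
        raise ValueError("empty patch grid")
    p = grid.patch_size
    half = max(p // 2, 1)
    image = assemble_patches(grid)
    nr, nc = 2 * grid.grid_rows - 1, 2 * grid.grid_cols - 1
    windows = np.empty((nr, nc, p, p))
    for i in range(nr):
        for j in range(nc):
            windows[i, j] = image[i * half:i * half + p, j * half:j * half + p]
    return windows


def sliding_box_queries(grid: PatchGrid) -> np.ndarray:
    """The query stream: half-stride sliding-box windows resampled by nearest
    index back to N = r*c windows, index-aligned with the input stream."""
    windows = half_stride_windows(grid)
    nr, nc = windows.shape[:2]
    ri = np.round(np.linspace(0, nr - 1, grid.grid_rows)).astype(int)
    ci = np.round(np.linspace(0, nc - 1, grid.grid_cols)).astype(int)
    return windows[np.ix_(ri, ci)].reshape(len(grid), grid.patch_size,
                                           grid.patch_size)


def init_encoder_state(cfg: EncoderConfig, patch_size: int,
                       rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-scaled random initialization of all encoder parameters."""
    d = cfg.embed_dim
    p2 = patch_size * patch_size
    f1, f2 = cfg.conv_filters
    k = cfg.conv_kernel

    def glorot(*shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

    state = {
        "embed_in_w": glorot(p2, d, fan_in=p2, fan_out=d),
        "embed_in_b": Tensor(np.zeros(d), requires_grad=True),
        "embed_q_w": glorot(p2, d, fan_in=p2, fan_out=d),
        "embed_q_b": Tensor(np.zeros(d), requires_grad=True),
        "conv1_w": glorot(k, k, d, f1, fan_in=k * k * d, fan_out=k * k * f1),
        "conv1_b": Tensor(np.zeros(f1), requires_grad=True),
        "conv2_w": glorot(k, k, f1, f2, fan_in=k * k * f1, fan_out=k * k * f2),
        "conv2_b": Tensor(np.zeros(f2), requires_grad=True),
    }
    for name in ("attn_q", "attn_k", "attn_v", "attn_o"):
        state[name] = glorot(d, d, fan_in=d, fan_out=d)
    state["enc_ln_g"] = Tensor(np.ones(d), requires_grad=True)
    state["enc_ln_b"] = Tensor(np.zeros(d), requires_grad=True)
    return state


def _single_head_attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    d = q.shape[-1]
    weights = softmax((q @ k.T) * (1.0 / np.sqrt(d)), axis=-1)
    return weights @ v, weights


def gated_attention(inputs: np.ndarray, queries: np.ndarray,
                    cfg: EncoderConfig, state: dict[str, Tensor],
                    grid_shape: tuple[int, int] | None = None) -> EncodedPatches:
    """Run the encoder on index-aligned input and query patch streams.

    `inputs` and `queries` are (N, P, P) stacks; `grid_shape` gives the
    (rows, cols) layout for the convolution stage (a flat 1 x N strip when
    omitted).
    """
    if inputs.shape != queries.shape:
        raise ValueError(f"input stream {inputs.shape} and query stream "
                         f"{queries.shape} must have identical shapes")
    n = inputs.shape[0]
    rows, cols = grid_shape if grid_shape is not None else (1, n)
    if rows * cols != n:
        raise ValueError("grid_shape inconsistent with patch count")

    x = Tensor(inputs.reshape(n, -1))
    q = Tensor(queries.reshape(n, -1))
    emb_in = x @ state["embed_in_w"] + state["embed_in_b"]
    emb_q = q @ state["embed_q_w"] + state["embed_q_b"]

    # gate: queries attend over inputs; the score-weighted values emphasize
    # attended content on top of each patch's own embedding
    attended, _ = _single_head_attention(emb_q, emb_in, emb_in)
    gated = emb_in + attended

    # convolution stage on the token grid; strided output is resampled back
    grid_tokens = gated.reshape(rows, cols, cfg.embed_dim)
    c1 = gelu(conv2d_same(grid_tokens, state["conv1_w"], state["conv1_b"],
                          stride=cfg.conv_stride))
    c2 = gelu(conv2d_same(c1, state["conv2_w"], state["conv2_b"],
                          stride=cfg.conv_stride))
    gh, gw = c2.shape[0], c2.shape[1]
    up = take(c2, (np.arange(rows) * gh) // rows, axis=0)
    up = take(up, (np.arange(cols) * gw) // cols, axis=1)
    # residual around the conv stage keeps per-token spatial identity
    conv_tokens = gated + up.reshape(n, cfg.embed_dim)

    out, weights = _single_head_attention(conv_tokens @ state["attn_q"],
                                          conv_tokens @ state["attn_k"],
                                          conv_tokens @ state["attn_v"])
    out = layer_norm(out @ state["attn_o"], state["enc_ln_g"], state["enc_ln_b"])
    return EncodedPatches(tokens=out, attention_weights=weights.data.copy())
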