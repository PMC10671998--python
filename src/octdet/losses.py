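"""Composite detection loss: MSE + structural-similarity difference + IOU.

The training objective compares a predicted fixed-length box array against the
ground-truth array slot by slot (ground truth is canonically sorted at load
time, so slot order is deterministic):

* ``loss_mse`` — mean squared error over all 4K normalized coordinates;
* ``loss_difference`` — one minus the structural similarity (SSIM) between
  soft rasterized union-of-boxes masks of the two arrays, so box layout is
  compared as an image;
* ``loss_iou`` — one minus the mean intersection-over-union of index-aligned
  pairs.

The total is the mean of the three components, each bounded in [0, 1], so the
combined loss is itself normalized to [0, 1].

Everything is built on the autodiff graph in :mod:`octdet.nn`; the public
functions taking :class:`BoxArray` values are thin numeric wrappers, and the
``*_tensor`` forms are what the training loop differentiates.  The SSIM here
is a uniform 7x7-window implementation with the standard constants
K1 = 0.01, K2 = 0.03 and sample-covariance normalization, evaluated on fully
covered windows only; masks are rasterized with anti-aliased (pixel-coverage)
edges and smoothed by a sigma = 2 px Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import BoundingBox, BoxArray
from .nn import Tensor, gaussian_blur, uniform_filter_valid

__all__ = ["LossBreakdown", "iou", "loss_iou", "loss_mse", "loss_difference",
           "lloss", "lloss_tensor", "render_box_mask"]

_EPS = 1e-12
_SSIM_WIN = 7
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03
_MASK_SIGMA = 2.0


@dataclass(frozen=True)
class LossBreakdown:
    l_mse: float
    l_difference: float
    l_iou: float

    @property
    def l_total(self) -> float:
        return (self.l_mse + self.l_difference + self.l_iou) / 3.0


# ---------------------------------------------------------------------------
# geometric IOU


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Continuous-geometry intersection over union; two empty boxes give 0."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0.0 else 0.0


def _pair_iou_tensor(pred: Tensor, actual: Tensor) -> Tensor:
    """Vector of per-slot IOUs for (K, 4) corner arrays, differentiable."""
    ix0 = pred[:, 0].maximum(actual[:, 0])
    iy0 = pred[:, 1].maximum(actual[:, 1])
    ix1 = pred[:, 2].minimum(actual[:, 2])
    iy1 = pred[:, 3].minimum(actual[:, 3])
    zeros = Tensor(np.zeros(pred.shape[0]))
    inter = (ix1 - ix0).maximum(zeros) * (iy1 - iy0).maximum(zeros)
    area_p = (pred[:, 2] - pred[:, 0]) * (pred[:, 3] - pred[:, 1])
    area_a = (actual[:, 2] - actual[:, 0]) * (actual[:, 3] - actual[:, 1])
    union = area_p + area_a - inter
    return inter / (union + _EPS)


# ---------------------------------------------------------------------------
# soft mask rendering and SSIM


def _coverage(lo: Tensor, hi: Tensor, n: int) -> Tensor:
    """Per-pixel overlap of the interval [lo, hi] (in pixel units) with each
    unit pixel cell; anti-aliased box edge profile."""
    cells = np.arange(n, dtype=np.float64)
    left = lo.reshape(-1, 1).maximum(Tensor(cells[None, :]))
    right = hi.reshape(-1, 1).minimum(Tensor(cells[None, :] + 1.0))
    return (right - left).clip(0.0, 1.0)


def render_box_mask(boxes: Tensor | np.ndarray, shape: tuple[int, int]) -> Tensor:
    """Rasterize the union of K boxes as a soft mask on an (H, W) grid:
    pixel-coverage edges, union by complement product, Gaussian smoothing."""
    if not isinstance(boxes, Tensor):
        boxes = Tensor(boxes)
    h, w = shape
    covx = _coverage(boxes[:, 0] * float(w), boxes[:, 2] * float(w), w)  # (K, W)
    covy = _coverage(boxes[:, 1] * float(h), boxes[:, 3] * float(h), h)  # (K, H)
    k = boxes.shape[0]
    complement = Tensor(np.ones((h, w)))
    for i in range(k):
        mask_i = covy[i].reshape(h, 1) @ covx[i].reshape(1, w)
        complement = complement * (1.0 - mask_i)
    return gaussian_blur(1.0 - complement, sigma=_MASK_SIGMA)


def ssim(x: Tensor | np.ndarray, y: Tensor | np.ndarray,
         data_range: float = 1.0) -> Tensor:
    """Mean SSIM with a uniform 7x7 window over fully covered windows."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if not isinstance(y, Tensor):
        y = Tensor(y)
    npix = _SSIM_WIN * _SSIM_WIN
    cov_norm = npix / (npix - 1.0)  # sample covariance
    ux = uniform_filter_valid(x, _SSIM_WIN)
    uy = uniform_filter_valid(y, _SSIM_WIN)
    uxx = uniform_filter_valid(x * x, _SSIM_WIN)
    uyy = uniform_filter_valid(y * y, _SSIM_WIN)
    uxy = uniform_filter_valid(x * y, _SSIM_WIN)
    vx = (uxx - ux * ux) * cov_norm
    vy = (uyy - uy * uy) * cov_norm
    vxy = (uxy - ux * uy) * cov_norm
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    s = ((ux * uy * 2.0 + c1) * (vxy * 2.0 + c2)) / \
        ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    return s.mean()


# ---------------------------------------------------------------------------
# loss components (graph forms)


def _active_mask(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Slots where at least one side is a real (non-sentinel) box; sentinel
    pairs are excluded by the package-wide zero-area test."""
    pred_sent = BoxArray(pred).sentinel_mask
    act_sent = BoxArray(actual).sentinel_mask
    return ~(pred_sent & act_sent)


def loss_iou_tensor(pred: Tensor, actual: Tensor) -> Tensor:
    active = _active_mask(pred.data, actual.data)
    if not active.any():
        return Tensor(0.0)
    ious = _pair_iou_tensor(pred, actual)
    sel = ious[np.nonzero(active)[0]]
    return 1.0 - sel.mean()


def loss_mse_tensor(pred: Tensor, actual: Tensor) -> Tensor:
    return ((pred - actual) ** 2).mean(axis=None)


def loss_difference_tensor(pred: Tensor, actual: Tensor,
                           image_shape: tuple[int, int]) -> Tensor:
    mask_p = render_box_mask(pred, image_shape)
    mask_a = render_box_mask(actual, image_shape)
    return 1.0 - ssim(mask_p, mask_a).clip(0.0, 1.0)


def lloss_tensor(pred: Tensor, actual: Tensor | np.ndarray,
                 image_shape: tuple[int, int]) -> tuple[Tensor, LossBreakdown]:
    """Differentiable combined loss; returns the graph node and a numeric
    per-component breakdown."""
    if not isinstance(actual, Tensor):
        actual = Tensor(np.asarray(actual, dtype=np.float64))
    l_mse = loss_mse_tensor(pred, actual)
    l_diff = loss_difference_tensor(pred, actual, image_shape)
    l_iou = loss_iou_tensor(pred, actual)
    total = (l_mse + l_diff + l_iou) * (1.0 / 3.0)
    return total, LossBreakdown(l_mse=l_mse.item(), l_difference=l_diff.item(),
                                l_iou=l_iou.item())


# ---------------------------------------------------------------------------
# numeric wrappers on BoxArray


def _pair(pred: BoxArray, actual: BoxArray) -> tuple[np.ndarray, np.ndarray]:
    if len(pred) != len(actual):
        raise ValueError("box arrays must have equal length")
    return pred.boxes, actual.boxes


def loss_iou(pred: BoxArray, actual: BoxArray) -> float:
    p, a = _pair(pred, actual)
    return float(loss_iou_tensor(Tensor(p), Tensor(a)).item())


def loss_mse(pred: BoxArray, actual: BoxArray) -> float:
    p, a = _pair(pred, actual)
    return float(np.mean((p - a) ** 2))


def loss_difference(pred: BoxArray, actual: BoxArray,
                    image_shape: tuple[int, int]) -> float:
    p, a = _pair(pred, actual)
    return float(loss_difference_tensor(Tensor(p), Tensor(a), image_shape).item())


def lloss(pred: BoxArray, actual: BoxArray,
          image_shape: tuple[int, int]) -> LossBreakdown:
    p, a = _pair(pred, actual)
    _, breakdown = lloss_tensor(Tensor(p), a, image_shape)
    return breakdown
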