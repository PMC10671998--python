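"""Geometric training-set augmentation and patch extraction.

Augmentation applies, in order: an optional left-right flip, a small random
rotation (angle uniform in +/- rotation_factor of a full turn), and a random
isotropic zoom (scale uniform in 1 +/- zoom_factor), all about the image
centre.  Boxes are carried through the same transform as the axis-aligned
hull of their transformed corners, clipped to the frame; a box that loses
more than 90% of its area to clipping is dropped (replaced by the sentinel).

Patch extraction pads the image by edge replication up to the next multiple
of the patch size and tiles it without overlap, row-major — the token stream
the patch encoder consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .data_io import AnnotatedRecord, BoundingBox, BoxArray, ScanImage

__all__ = ["AugmentParams", "PatchGrid", "augment", "flip_box",
           "extract_patches", "assemble_patches"]


@dataclass(frozen=True)
class AugmentParams:
    """Augmentation strengths.

    rotation_factor is a fraction of a full turn (0.02 -> +/- 7.2 degrees);
    zoom_factor a fractional scale range (0.2 -> scale in [0.8, 1.2]).
    """

    flip_horizontal: bool = True
    rotation_factor: float = 0.02
    zoom_factor: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rotation_factor <= 0.5:
            raise ValueError("rotation_factor must lie in [0, 0.5]")
        if not 0.0 <= self.zoom_factor <= 0.9:
            raise ValueError("zoom_factor must lie in [0, 0.9]")


@dataclass
class PatchGrid:
    patches: np.ndarray  # (N, P, P), row-major over the padded image
    grid_rows: int
    grid_cols: int
    patch_size: int
    padded_shape: tuple[int, int]

    def __len__(self) -> int:
        return self.patches.shape[0]


def flip_box(box: BoundingBox) -> BoundingBox:
    """Left-right mirror in normalized coordinates: x -> 1 - x."""
    if box.is_sentinel:
        return box
    return BoundingBox(1.0 - box.x_max, box.y_min, 1.0 - box.x_min, box.y_max)


def _transform_boxes(arr: BoxArray, matrix: np.ndarray, h: int, w: int) -> BoxArray:
    out = np.zeros_like(arr.boxes)
    for i, (row, pad) in enumerate(zip(arr.boxes, arr.sentinel_mask)):
        if pad:
            continue
        x0, y0, x1, y1 = row
        corners = np.array([[x0 * w, y0 * h, 1.0], [x1 * w, y0 * h, 1.0],
                            [x0 * w, y1 * h, 1.0], [x1 * w, y1 * h, 1.0]])
        moved = corners @ matrix.T
        xs, ys = moved[:, 0] / w, moved[:, 1] / h
        nx0, nx1 = np.clip([xs.min(), xs.max()], 0.0, 1.0)
        ny0, ny1 = np.clip([ys.min(), ys.max()], 0.0, 1.0)
        orig_area = (x1 - x0) * (y1 - y0)
        new_area = (nx1 - nx0) * (ny1 - ny0)
        if orig_area > 0 and new_area >= 0.1 * orig_area:
            out[i] = (nx0, ny0, nx1, ny1)
    return BoxArray(out)


def augment(record: AnnotatedRecord, params: AugmentParams,
            draw: np.random.Generator) -> AnnotatedRecord:
    """One random augmentation draw applied consistently to image and boxes.

    The random state is an explicit argument so an epoch of augmentation is
    reproducible under a fixed seed.
    """
    img = record.image.pixels
    h, w = img.shape
    do_flip = bool(params.flip_horizontal and draw.random() < 0.5)
    angle = draw.uniform(-1.0, 1.0) * params.rotation_factor * 2.0 * np.pi
    scale = 1.0 + draw.uniform(-1.0, 1.0) * params.zoom_factor

    boxes = record.boxes
    if do_flip:
        img = img[:, ::-1]
        boxes = BoxArray(np.array([flip_box(BoundingBox(*b)).as_tuple()
                                   if not s else (0.0,) * 4
                                   for b, s in zip(boxes.boxes, boxes.sentinel_mask)]))

    if angle != 0.0 or scale != 1.0:
        # rotation+zoom about the image centre, in (x, y) pixel coordinates
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        t_in = AffineTransform(translation=(-cx, -cy))
        rotzoom = AffineTransform(rotation=angle, scale=(scale, scale))
        t_out = AffineTransform(translation=(cx, cy))
        forward = t_in + rotzoom + t_out  # composition applies left-to-right
        img = warp(img, np.linalg.inv(forward.params), order=1, mode="edge",
                   preserve_range=True)
        boxes = _transform_boxes(boxes, forward.params, h, w)

    out_img = ScanImage(id=record.image.id, pixels=np.ascontiguousarray(img))
    return AnnotatedRecord(image=out_img, boxes=boxes.sorted_canonical())


def extract_patches(img: ScanImage, patch_size: int = 32) -> PatchGrid:
    """Cut into non-overlapping patch_size x patch_size tiles, padding the
    bottom/right edges by replication to reach an exact multiple."""
    pixels = img.pixels
    h, w = pixels.shape
    rows = -(-h // patch_size)
    cols = -(-w // patch_size)
    pad_h, pad_w = rows * patch_size - h, cols * patch_size - w
    padded = np.pad(pixels, ((0, pad_h), (0, pad_w)), mode="edge")
    tiles = (padded.reshape(rows, patch_size, cols, patch_size)
             .transpose(0, 2, 1, 3)
             .reshape(rows * cols, patch_size, patch_size))
    return PatchGrid(patches=tiles, grid_rows=rows, grid_cols=cols,
                     patch_size=patch_size, padded_shape=padded.shape)


def assemble_patches(grid: PatchGrid) -> np.ndarray:
    """Inverse of the tiling (returns the padded image)."""
    p = grid.patch_size
    return (grid.patches.reshape(grid.grid_rows, grid.grid_cols, p, p)
            .transpose(0, 2, 1, 3)
            .reshape(grid.grid_rows * p, grid.grid_cols * p))
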