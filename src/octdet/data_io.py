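"""Core data types and dataset I/O.

Boxes live in normalized continuous coordinates: the image is the unit square,
origin at the top-left corner, x increasing rightward and y downward.  A box
is the corner quadruple ``(x_min, y_min, x_max, y_max)``.  Annotation files on
disk store pixel corners together with the image dimensions used to normalize
them; both a flat CSV table and COCO-style JSON are supported.

The all-zero box is the *sentinel* used to pad fixed-length box arrays where
an image has fewer lesions than slots.  Sentinel-ness is decided everywhere
by one zero-area test: a box whose area falls below ``MIN_BOX_AREA`` (1e-4 of
the unit square) counts as empty.  The exact all-zero box is the canonical
sentinel written by the generator and annotation readers; the area test also
absorbs regressed boxes that have collapsed to (numerically) nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "MIN_BOX_AREA",
    "BoundingBox",
    "BoxArray",
    "ScanImage",
    "AnnotatedRecord",
    "load_image",
    "save_image",
    "resize_image",
    "read_box_table",
    "write_box_table",
    "read_coco",
    "write_coco",
    "split_dataset",
]


MIN_BOX_AREA = 1e-4  # area below this (unit square) is an empty box


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in normalized [0, 1] corner coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (0.0 <= self.x_min <= self.x_max <= 1.0
                and 0.0 <= self.y_min <= self.y_max <= 1.0):
            raise ValueError(f"invalid box {self.as_tuple()}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def is_sentinel(self) -> bool:
        return self.area < MIN_BOX_AREA

    @staticmethod
    def sentinel() -> "BoundingBox":
        return BoundingBox(0.0, 0.0, 0.0, 0.0)


class BoxArray:
    """Fixed-length ordered array of K boxes, padded with sentinels.

    This is the tensor the detector regresses: shape (K, 4) in normalized
    corner format.  Ground-truth arrays are canonically sorted so slot order
    is a deterministic function of geometry, with real boxes first.
    """

    def __init__(self, boxes: np.ndarray):
        boxes = np.asarray(boxes, dtype=np.float64)
        if boxes.ndim != 2 or boxes.shape[1] != 4:
            raise ValueError(f"expected (K, 4) array, got {boxes.shape}")
        self.boxes = boxes

    @classmethod
    def from_boxes(cls, boxes: Sequence[BoundingBox], k: int) -> "BoxArray":
        if len(boxes) > k:
            raise ValueError(f"{len(boxes)} boxes exceed capacity K={k}")
        arr = np.zeros((k, 4))
        for i, b in enumerate(boxes):
            arr[i] = b.as_tuple()
        return cls(arr)

    def __len__(self) -> int:
        return self.boxes.shape[0]

    def __eq__(self, other) -> bool:
        return isinstance(other, BoxArray) and np.array_equal(self.boxes, other.boxes)

    @property
    def sentinel_mask(self) -> np.ndarray:
        """True for empty slots, by the package-wide zero-area test."""
        areas = ((self.boxes[:, 2] - self.boxes[:, 0])
                 * (self.boxes[:, 3] - self.boxes[:, 1]))
        return areas < MIN_BOX_AREA

    @property
    def n_real(self) -> int:
        return int((~self.sentinel_mask).sum())

    def real_boxes(self) -> list[BoundingBox]:
        return [BoundingBox(*row) for row in self.boxes[~self.sentinel_mask]]

    def sorted_canonical(self) -> "BoxArray":
        """Real boxes ordered by (y_min, x_min), sentinels last."""
        real = self.boxes[~self.sentinel_mask]
        order = np.lexsort((real[:, 0], real[:, 1]))
        out = np.zeros_like(self.boxes)
        out[: len(real)] = real[order]
        return BoxArray(out)

    def validate(self) -> None:
        for row, pad in zip(self.boxes, self.sentinel_mask):
            if not pad:
                BoundingBox(*row)


@dataclass
class ScanImage:
    """Single-channel 2-D scan with intensities in [0, 1]."""

    id: str
    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class AnnotatedRecord:
    image: ScanImage
    boxes: BoxArray

    def __post_init__(self):
        self.boxes.validate()


# ---------------------------------------------------------------------------
# images


def load_image(path: str | Path) -> ScanImage:
    """Load a PNG or TIFF as a grayscale [0, 1] scan.

    Multi-channel images are collapsed by the unweighted channel mean; integer
    images are rescaled by their dtype range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {arr.shape}: {path}")
    return ScanImage(id=path.stem, pixels=arr)


def save_image(img: ScanImage, path: str | Path) -> None:
    """Write as 8-bit grayscale PNG or float TIFF depending on suffix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img.pixels.astype(np.float32))
    else:
        data = np.round(np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(data, mode="L").save(path)


def resize_image(img: ScanImage, height: int, width: int) -> ScanImage:
    """Bilinear resize.  Normalized boxes are resolution-free and unchanged."""
    if height < 8 or width < 8:
        raise ValueError("target dimensions must be at least 8 pixels")
    if (height, width) == (img.height, img.width):
        return ScanImage(id=img.id, pixels=img.pixels.copy())
    out = _sk_resize(img.pixels, (height, width), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return ScanImage(id=img.id, pixels=out)


# ---------------------------------------------------------------------------
# annotation tables

_CSV_COLUMNS = ["image_id", "x_min", "y_min", "x_max", "y_max", "width", "height"]


def write_box_table(records: dict[str, tuple[BoxArray, tuple[int, int]]],
                    path: str | Path) -> None:
    """Write a CSV of pixel-corner boxes.

    `records` maps image_id -> (BoxArray in normalized coords, (height, width));
    sentinel slots are not written.
    """
    rows = []
    for image_id, (arr, (h, w)) in records.items():
        for box in arr.real_boxes():
            rows.append({
                "image_id": image_id,
                "x_min": box.x_min * w, "y_min": box.y_min * h,
                "x_max": box.x_max * w, "y_max": box.y_max * h,
                "width": w, "height": h,
            })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_box_table(path: str | Path, k: int = 3) -> dict[str, BoxArray]:
    """Read the CSV schema image_id,x_min,y_min,x_max,y_max,width,height and
    normalize pixel corners by the per-row image dimensions."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"box table missing columns: {sorted(missing)}")
    out: dict[str, BoxArray] = {}
    grouped: dict[str, list[BoundingBox]] = {}
    for row in df.itertuples(index=False):
        w, h = float(row.width), float(row.height)
        if row.x_max < row.x_min or row.y_max < row.y_min:
            raise ValueError(f"malformed box for {row.image_id}: max < min")
        if row.x_min < 0 or row.y_min < 0 or row.x_max > w or row.y_max > h:
            raise ValueError(f"box outside image bounds for {row.image_id}")
        grouped.setdefault(str(row.image_id), []).append(
            BoundingBox(row.x_min / w, row.y_min / h, row.x_max / w, row.y_max / h))
    for image_id, boxes in grouped.items():
        out[image_id] = BoxArray.from_boxes(boxes, max(k, len(boxes)))
    return out


def write_coco(records: dict[str, tuple[BoxArray, tuple[int, int]]],
               path: str | Path) -> None:
    """Export a COCO-style annotation file; one category, id 1 = "lesion";
    boxes as [x, y, w, h] in pixels."""
    images, annotations = [], []
    ann_id = 1
    for img_id_num, (image_id, (arr, (h, w))) in enumerate(records.items(), 1):
        images.append({"id": img_id_num, "file_name": f"{image_id}.png",
                       "height": h, "width": w})
        for box in arr.real_boxes():
            x, y = box.x_min * w, box.y_min * h
            bw, bh = (box.x_max - box.x_min) * w, (box.y_max - box.y_min) * h
            annotations.append({
                "id": ann_id, "image_id": img_id_num, "category_id": 1,
                "bbox": [x, y, bw, bh], "area": bw * bh, "iscrowd": 0,
            })
            ann_id += 1
    doc = {"images": images, "annotations": annotations,
           "categories": [{"id": 1, "name": "lesion"}]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: str | Path, k: int = 3) -> dict[str, BoxArray]:
    doc = json.loads(Path(path).read_text())
    dims = {im["id"]: (im["height"], im["width"], Path(im["file_name"]).stem)
            for im in doc["images"]}
    grouped: dict[str, list[BoundingBox]] = {stem: [] for _, _, stem in dims.values()}
    for ann in doc["annotations"]:
        h, w, stem = dims[ann["image_id"]]
        x, y, bw, bh = ann["bbox"]
        grouped[stem].append(
            BoundingBox(x / w, y / h, (x + bw) / w, (y + bh) / h))
    return {stem: BoxArray.from_boxes(boxes, max(k, len(boxes)))
            for stem, boxes in grouped.items()}


# ---------------------------------------------------------------------------
# dataset split


def split_dataset(records: Sequence, fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
                  seed: int = 0):
    """Shuffle and partition into (train, val, test).

    Counts are floor allocations of the fractions; remainder records go to the
    training split, which is the largest and absorbs rounding.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    records = list(records)
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_val - n_test
    idx = [order[:n_train], order[n_train:n_train + n_val], order[n_train + n_val:]]
    return tuple([records[i] for i in part] for part in idx)
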