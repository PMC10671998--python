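"""Synthetic speckled B-scan generator with exact ground-truth boxes.

Emulates the structure of spectral-domain OCT B-scans of layered tissue:
a stack of horizontal intensity bands with smoothly undulating boundaries
(tissue layers), multiplied by gamma-distributed speckle (the fully-developed
speckle approximation: shape k, unit mean, contrast 1/sqrt(k)), with zero to a
few elliptical lesions inserted as soft-edged intensity perturbations.  Each
lesion's tight axis-aligned bounding box is returned alongside the image, so
detector training and evaluation run end-to-end without external data.

Defaults model the acquisition regime the detector targets: scans with
pronounced speckle, a handful of tissue layers, and one to three lesions per
image.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import (AnnotatedRecord, BoundingBox, BoxArray, ScanImage,
                      save_image, write_box_table)

__all__ = ["SyntheticParams", "generate_scan", "generate_dataset",
           "write_dataset"]

K_MAX = 3  # box-array capacity; mirrors the detector's default slot count


@dataclass(frozen=True)
class SyntheticParams:
    """Conditions of the simulated acquisition.

    image_height / image_width : scan size in pixels (>= 64).  128x128 is the
        desk-scale default; the nominal full scan is 500x412.
    n_layers : number of horizontal tissue bands.
    layer_intensity_range : [0, 1] pair the band reflectivities are drawn from.
    speckle_shape : gamma shape k of the multiplicative speckle (unit mean);
        smaller k means harsher speckle (contrast 1/sqrt(k)).
    lesion_count_range : inclusive integer pair; count drawn uniformly.
    lesion_size_range : lesion diameter as a fraction of the shorter image
        side, pair within (0, 0.5].
    lesion_contrast : signed intensity offset of the lesion relative to the
        underlying tissue (positive = hyper-reflective).
    seed : base seed; (seed, index) fully determines a scan.
    """

    image_height: int = 128
    image_width: int = 128
    n_layers: int = 4
    layer_intensity_range: tuple[float, float] = (0.25, 0.75)
    speckle_shape: float = 3.0
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_size_range: tuple[float, float] = (0.12, 0.30)
    lesion_contrast: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be at least 64 pixels")
        lo, hi = self.lesion_count_range
        if not (0 <= lo <= hi <= K_MAX):
            raise ValueError(f"lesion_count_range must lie within [0, {K_MAX}]")
        slo, shi = self.lesion_size_range
        if not (0.0 < slo <= shi <= 0.5):
            raise ValueError("lesion_size_range must lie within (0, 0.5]")
        if shi * min(self.image_height, self.image_width) < 2:
            raise ValueError("lesions cannot fit: size below 2 pixels")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.n_layers < 1:
            raise ValueError("need at least one tissue layer")


def _layered_background(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Horizontal bands with smooth sinusoidal boundary undulation."""
    h, w = params.image_height, params.image_width
    lo, hi = params.layer_intensity_range
    intensities = rng.uniform(lo, hi, size=params.n_layers)
    # boundary depth per column for each internal interface
    x = np.linspace(0, 2 * np.pi, w)
    bounds = []
    for i in range(1, params.n_layers):
        base = h * i / params.n_layers
        amp = rng.uniform(0.01, 0.05) * h
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.5, 2.0)
        bounds.append(base + amp * np.sin(freq * x + phase))
    rows = np.arange(h)[:, None]
    img = np.full((h, w), intensities[0])
    for i, b in enumerate(bounds):
        img = np.where(rows >= b[None, :], intensities[i + 1], img)
    # soften interfaces so layer edges are not single-pixel steps
    return ndimage.gaussian_filter(img, sigma=1.5, mode="nearest")


def _place_lesions(params: SyntheticParams, rng: np.random.Generator,
                   background: np.ndarray) -> tuple[np.ndarray, list[BoundingBox]]:
    h, w = background.shape
    n = int(rng.integers(params.lesion_count_range[0],
                         params.lesion_count_range[1] + 1))
    img = background.copy()
    boxes: list[BoundingBox] = []
    short = min(h, w)
    for _ in range(n):
        d = rng.uniform(*params.lesion_size_range) * short
        ax = max(d / 2 * rng.uniform(0.7, 1.3), 1.5)
        ay = max(d / 2 * rng.uniform(0.7, 1.3), 1.5)
        margin = 3.0  # keep the soft edge inside the frame
        cx = rng.uniform(ax + margin, w - ax - margin)
        cy = rng.uniform(ay + margin, h - ay - margin)
        yy, xx = np.mgrid[0:h, 0:w]
        ellipse = (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2) <= 1.0
        soft = ndimage.gaussian_filter(ellipse.astype(float), sigma=1.5,
                                       mode="constant")
        img = img + params.lesion_contrast * soft
        # tight box of the solid part of the perturbation
        core = soft >= 0.5
        ys, xs = np.nonzero(core if core.any() else ellipse)
        boxes.append(BoundingBox(xs.min() / w, ys.min() / h,
                                 (xs.max() + 1) / w, (ys.max() + 1) / h))
    return img, boxes


def generate_scan(params: SyntheticParams, index: int) -> tuple[ScanImage, BoxArray]:
    """Generate one speckled scan and its ground-truth box array.

    Bit-identical output for identical (params, index): the random stream is
    seeded by the pair (params.seed, index).
    """
    params.validate()
    rng = np.random.default_rng([params.seed & 0x7FFFFFFF, index])
    clean = _layered_background(params, rng)
    clean, boxes = _place_lesions(params, rng, clean)
    speckle = rng.gamma(shape=params.speckle_shape,
                        scale=1.0 / params.speckle_shape, size=clean.shape)
    img = np.clip(clean * speckle, 0.0, 1.0)
    scan = ScanImage(id=f"synthetic_{params.seed}_{index:05d}", pixels=img)
    return scan, BoxArray.from_boxes(boxes, K_MAX).sorted_canonical()


def generate_dataset(params: SyntheticParams, n_images: int) -> list[AnnotatedRecord]:
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    out = []
    for i in range(n_images):
        img, boxes = generate_scan(params, i)
        out.append(AnnotatedRecord(image=img, boxes=boxes))
    return out


def write_dataset(records: list[AnnotatedRecord], out_dir: str | Path,
                  params: SyntheticParams | None = None) -> None:
    """Write images/ as PNGs, annotations.csv, and a manifest of parameters."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    table = {}
    for rec in records:
        save_image(rec.image, out_dir / "images" / f"{rec.image.id}.png")
        table[rec.image.id] = (rec.boxes, (rec.image.height, rec.image.width))
    write_box_table(table, out_dir / "annotations.csv")
    if params is not None:
        lines = [f"{k} = {v}" for k, v in asdict(params).items()]
        lines.append(f"n_images = {len(records)}")
        (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
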