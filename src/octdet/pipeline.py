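"""Training, prediction and evaluation orchestration.

Defaults follow the detector's intended operating point: batch size 4,
learning rate 5e-4, Adam, 200 epochs, with every source of randomness
(parameter init, shuffling, augmentation draws, dropout) funnelled through
one seeded generator so a run is exactly reproducible from its config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augmentation import AugmentParams, augment
from .data_io import (MIN_BOX_AREA, AnnotatedRecord, BoxArray, ScanImage,
                      load_image, read_box_table, resize_image, split_dataset)
from .detector import (ModelConfig, forward, forward_tensor, init_model_state,
                       save_checkpoint)
from .losses import lloss_tensor
from .metrics import DetectionReport, confusion_counts, match_boxes
from .nn import Adam, AdamW

__all__ = ["TrainConfig", "TrainHistory", "train", "predict", "evaluate",
           "load_dataset"]

logger = logging.getLogger("octdet")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    epochs: int = 200
    batch_size: int = 4
    optimizer: str = "adam"  # or "adamw"
    seed: int = 0
    augmentations_per_image: int = 2
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.optimizer not in {"adam", "adamw"}:
            raise ValueError("optimizer must be 'adam' or 'adamw'")


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_dataset(dataset_dir: str | Path, k: int = 3) -> list[AnnotatedRecord]:
    """Read an images/ directory plus annotations.csv into records."""
    dataset_dir = Path(dataset_dir)
    tables = read_box_table(dataset_dir / "annotations.csv", k=k)
    records = []
    for img_path in sorted((dataset_dir / "images").iterdir()):
        if img_path.suffix.lower() not in {".png", ".tif", ".tiff"}:
            continue
        img = load_image(img_path)
        boxes = tables.get(img.id, BoxArray(np.zeros((k, 4))))
        records.append(AnnotatedRecord(image=img,
                                       boxes=boxes.sorted_canonical()))
    return records


def _prepare(record: AnnotatedRecord, cfg: ModelConfig) -> AnnotatedRecord:
    img = resize_image(record.image, cfg.image_height, cfg.image_width)
    boxes = record.boxes
    if len(boxes) != cfg.max_boxes:
        if boxes.n_real > cfg.max_boxes:
            raise ValueError("record has more lesions than box slots")
        boxes = BoxArray.from_boxes(boxes.real_boxes(), cfg.max_boxes)
    return AnnotatedRecord(image=img, boxes=boxes.sorted_canonical())


def _epoch_loss(records, state, cfg: ModelConfig, train: bool,
                rng: np.random.Generator | None = None):
    """Mean loss (graph for train, numeric components always)."""
    shape = (cfg.image_height, cfg.image_width)
    totals = np.zeros(3)
    graph_terms = []
    for rec in records:
        pred = forward_tensor(rec.image, state, cfg, train=train, rng=rng)
        total, parts = lloss_tensor(pred, rec.boxes.boxes, shape)
        graph_terms.append(total)
        totals += (parts.l_mse, parts.l_difference, parts.l_iou)
    mean_graph = sum(graph_terms[1:], graph_terms[0]) * (1.0 / len(graph_terms))
    return mean_graph, totals / len(records)


def train(data, model_cfg: ModelConfig, train_cfg: TrainConfig,
          augment_params: AugmentParams | None = None):
    """Minimize the combined loss over the training split.

    `data` is either a dataset directory (images/ + annotations.csv) or a
    list of :class:`AnnotatedRecord`; it is shuffled and split 60/10/30 into
    train/validation/test with the configured seed.  Returns the final model
    state and the per-epoch loss history; the best-validation checkpoint is
    written to ``checkpoint_dir`` when one is set.
    """
    if isinstance(data, (str, Path)):
        records = load_dataset(data, k=model_cfg.max_boxes)
    else:
        records = list(data)
    train_recs, val_recs, _ = split_dataset(records, seed=train_cfg.seed)
    if not train_recs:
        raise ValueError("empty training split")
    train_recs = [_prepare(r, model_cfg) for r in train_recs]
    val_recs = [_prepare(r, model_cfg) for r in val_recs]

    rng = np.random.default_rng(train_cfg.seed)
    state = init_model_state(model_cfg, rng)
    params = list(state.values())
    opt_cls = Adam if train_cfg.optimizer == "adam" else AdamW
    opt = opt_cls(params, lr=train_cfg.learning_rate)
    if augment_params is None:
        augment_params = AugmentParams(seed=train_cfg.seed)
    shape = (model_cfg.image_height, model_cfg.image_width)

    history = TrainHistory()
    best_val = np.inf
    ckpt_dir = Path(train_cfg.checkpoint_dir) if train_cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(train_cfg.epochs):
        epoch_set = list(train_recs)
        for rec in train_recs:
            for _ in range(train_cfg.augmentations_per_image):
                epoch_set.append(augment(rec, augment_params, rng))
        order = rng.permutation(len(epoch_set))
        comp_sum = np.zeros(3)
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [epoch_set[i] for i in order[start:start + train_cfg.batch_size]]
            terms = []
            for rec in batch:
                pred = forward_tensor(rec.image, state, model_cfg,
                                      train=True, rng=rng)
                total, parts = lloss_tensor(pred, rec.boxes.boxes, shape)
                terms.append(total)
                comp_sum += (parts.l_mse, parts.l_difference, parts.l_iou)
            batch_loss = sum(terms[1:], terms[0]) * (1.0 / len(terms))
            if not np.isfinite(batch_loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"{batch_loss.item()}")
            opt.zero_grad()
            batch_loss.backward()
            opt.step()
            n_batches += 1
        train_comps = comp_sum / len(epoch_set)
        row = {"epoch": epoch,
               "train_mse": train_comps[0], "train_difference": train_comps[1],
               "train_iou": train_comps[2], "train_total": train_comps.mean()}
        if val_recs:
            _, val_comps = _epoch_loss(val_recs, state, model_cfg, train=False)
            row.update(val_mse=val_comps[0], val_difference=val_comps[1],
                       val_iou=val_comps[2], val_total=val_comps.mean())
            if ckpt_dir and row["val_total"] < best_val:
                best_val = row["val_total"]
                save_checkpoint(state, model_cfg, ckpt_dir / "best.npz")
        history.append(**row)
        logger.info("epoch %d: train %.4f%s", epoch, row["train_total"],
                    f" val {row['val_total']:.4f}" if val_recs else "")
    if ckpt_dir:
        save_checkpoint(state, model_cfg, ckpt_dir / "final.npz")
        history.write(ckpt_dir / "history.csv")
    return state, history


def overfit_batch(records: list[AnnotatedRecord], model_cfg: ModelConfig,
                  train_cfg: TrainConfig, n_steps: int) -> list[float]:
    """Repeatedly fit one fixed batch; returns the per-step loss trace.

    A fast optimization sanity check: on a handful of images the combined
    loss should collapse well below its initial value.
    """
    recs = [_prepare(r, model_cfg) for r in records]
    rng = np.random.default_rng(train_cfg.seed)
    state = init_model_state(model_cfg, rng)
    opt_cls = Adam if train_cfg.optimizer == "adam" else AdamW
    opt = opt_cls(list(state.values()), lr=train_cfg.learning_rate)
    shape = (model_cfg.image_height, model_cfg.image_width)
    trace = []
    for _ in range(n_steps):
        terms = []
        for rec in recs:
            pred = forward_tensor(rec.image, state, model_cfg, train=False)
            total, _ = lloss_tensor(pred, rec.boxes.boxes, shape)
            terms.append(total)
        loss = sum(terms[1:], terms[0]) * (1.0 / len(terms))
        trace.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
    return trace


def predict(state, model_cfg: ModelConfig,
            images: list[ScanImage]) -> list[BoxArray]:
    """Deterministic inference; near-zero-area boxes become sentinels."""
    out = []
    for img in images:
        arr = forward(img, state, model_cfg).boxes
        areas = (arr[:, 2] - arr[:, 0]) * (arr[:, 3] - arr[:, 1])
        arr[areas < MIN_BOX_AREA] = 0.0
        out.append(BoxArray(arr))
    return out


def evaluate(state, model_cfg: ModelConfig,
             records: list[AnnotatedRecord]) -> DetectionReport:
    """Run the single-class evaluation protocol over an annotated split.

    Scalar metrics are averaged over images; tp/fp are summed counts.  The
    per_image field holds each image's mean matched IOU.
    """
    if not records:
        raise ValueError("empty evaluation split")
    preds = predict(state, model_cfg, [r.image for r in records])
    tp_total = fp_total = 0
    per_image_prec, per_image_iou = [], []
    for rec, pred in zip(records, preds):
        gt = _prepare(rec, model_cfg).boxes
        matches = match_boxes(pred, gt)
        ious = [m[2] for m in matches]
        if not ious:
            continue
        tp, fp, _, _ = confusion_counts(ious)
        tp_total += tp
        fp_total += fp
        per_image_prec.append(tp / (tp + fp))
        per_image_iou.append(float(np.mean(ious)))
    if tp_total + fp_total == 0:
        return DetectionReport(tp=0, fp=0, accuracy=0.0, precision=0.0,
                               sensitivity=0.0, f1=0.0, mean_iou=0.0,
                               per_image=[], no_detections=True)
    p = float(np.mean(per_image_prec))
    return DetectionReport(
        tp=tp_total, fp=fp_total, accuracy=p, precision=p, sensitivity=1.0,
        f1=2 * p / (p + 1) if p > 0 else 0.0,
        mean_iou=float(np.mean(per_image_iou)), per_image=per_image_iou)
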