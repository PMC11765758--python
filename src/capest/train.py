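"""Training loop, configuration, logging and checkpoints.

The full-scale optimization schedule follows the study conditions for
this detector family: SGD with momentum 0.9, base learning rate 0.0025,
mini-batch 2, 24 epochs with x10 learning-rate drops at epochs 16 and 19,
images resized to 800x600, horizontal-flip augmentation.  The desk-scale
profile trains the tiny detector on 128x128 synthetic scenes with the
same schedule shape compressed to 12 epochs (drops at 8 and 11) and a
larger batch, which a single CPU handles in about a minute.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Tensor
from .detection_head import GTObject
from .detector import (PestDetector, default_profile, desk_profile,
                       prepare_image)
from .losses import detection_loss
from .nn import SGD
from .synthetic_scenes import SceneSample, load_coco_dataset

__all__ = ["TrainConfig", "train", "lr_at_epoch", "evaluate_model",
           "desk_train_config"]


@dataclass
class TrainConfig:
    optimizer: str = "sgd"
    momentum: float = 0.9
    base_lr: float = 0.0025
    weight_decay: float = 1e-4
    batch_size: int = 2
    epochs: int = 24
    lr_drop_epochs: tuple = (16, 19)
    lr_drop_factor: float = 10.0
    image_size: tuple = (800, 600)          # (width, height)
    seed: int = 0
    backbone: str = "resnet50"
    num_classes: int = 21
    use_ca: bool = True
    dynamic_weighting: bool = True
    flip_augmentation: bool = True
    warmup_iters: int = 0                   # linear lr ramp from lr/10
    prior_warmup_epochs: int = 0            # epochs with the prior detached
    score_thresh: float = 0.05
    nms_iou: float = 0.6
    out_dir: str = "runs/default"
    data_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.base_lr <= 0:
            raise ValueError("epochs must be >= 1 and base_lr > 0")
        if any(e >= self.epochs for e in self.lr_drop_epochs):
            raise ValueError("lr drop epochs must precede the final epoch")

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d["lr_drop_epochs"] = list(self.lr_drop_epochs)
        d["image_size"] = list(self.image_size)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["lr_drop_epochs"] = tuple(d.get("lr_drop_epochs", (16, 19)))
        d["image_size"] = tuple(d.get("image_size", (800, 600)))
        return cls(**d)


def desk_train_config(seed: int = 0, use_ca: bool = True,
                      dynamic: bool = True, out_dir: str = "runs/desk",
                      epochs: int = 12) -> TrainConfig:
    """The CPU-scale schedule (12-epoch analog of the full 24-epoch one,
    drops at the same 2/3 and 11/12 fractions of the run)."""
    drops = tuple(sorted({max(1, round(epochs * 2 / 3)),
                          max(1, epochs - 1)})) if epochs > 1 else ()
    return TrainConfig(base_lr=0.005, batch_size=4, epochs=epochs,
                       lr_drop_epochs=drops, image_size=(128, 128),
                       backbone="tiny", num_classes=4, use_ca=use_ca,
                       dynamic_weighting=dynamic, warmup_iters=100,
                       seed=seed, out_dir=out_dir)


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Learning rate in force during a given epoch (1-indexed)."""
    lr = config.base_lr
    for drop in config.lr_drop_epochs:
        if epoch >= drop:
            lr /= config.lr_drop_factor
    return lr


def build_model(config: TrainConfig) -> PestDetector:
    if config.backbone == "tiny":
        return desk_profile(num_classes=config.num_classes,
                            use_ca=config.use_ca, seed=config.seed)
    return default_profile(num_classes=config.num_classes,
                           use_ca=config.use_ca, seed=config.seed)


def _resize_sample(sample: SceneSample, size) -> SceneSample:
    from PIL import Image as PILImage
    w, h = size
    ih, iw = sample.image.shape[:2]
    if (iw, ih) == (w, h):
        return sample
    img = np.asarray(PILImage.fromarray(sample.image).resize((w, h),
                                                             PILImage.BILINEAR))
    sx, sy = w / iw, h / ih
    objs = [GTObject(box=(g.box[0] * sx, g.box[1] * sy,
                          g.box[2] * sx, g.box[3] * sy), label=g.label)
            for g in sample.objects]
    return SceneSample(image=img, objects=objs)


def _flip_sample(sample: SceneSample) -> SceneSample:
    w = sample.image.shape[1]
    img = sample.image[:, ::-1].copy()
    objs = [GTObject(box=(w - g.box[2], g.box[1], w - g.box[0], g.box[3]),
                     label=g.label) for g in sample.objects]
    return SceneSample(image=img, objects=objs)


def train(config: TrainConfig, dataset: list | None = None,
          model: PestDetector | None = None) -> tuple:
    """Train a detector; returns (model, list of per-iteration log records).

    ``dataset`` is a list of :class:`SceneSample`; when omitted it is read
    from ``config.data_dir`` (COCO-format annotations).  Checkpoints and a
    JSONL loss log are written under ``config.out_dir``.
    """
    if dataset is None:
        if config.data_dir is None:
            raise ValueError("either a dataset or config.data_dir is required")
        ann = Path(config.data_dir) / "annotations.json"
        if not ann.exists():
            raise FileNotFoundError(f"annotations not found: {ann}")
        dataset = load_coco_dataset(ann)
        bad = [i for i, s in enumerate(dataset) if s.image is None]
        if bad:
            raise FileNotFoundError(f"missing image files for records {bad[:5]}")
    dataset = [_resize_sample(s, config.image_size) for s in dataset]

    rng = np.random.default_rng(config.seed)
    if model is None:
        model = build_model(config)
    opt = SGD(model.parameters(), lr=config.base_lr, momentum=config.momentum,
              weight_decay=config.weight_decay)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    log_records = []
    log_fh = open(out_dir / "train_log.jsonl", "w")

    strategy = "dynamic" if config.dynamic_weighting else "center"
    iteration = 0
    t0 = time.perf_counter()
    for epoch in range(1, config.epochs + 1):
        epoch_lr = lr_at_epoch(config, epoch)
        order = rng.permutation(len(dataset))
        for start in range(0, len(order), config.batch_size):
            if iteration < config.warmup_iters:
                frac = (iteration + 1) / config.warmup_iters
                opt.lr = epoch_lr * (0.1 + 0.9 * frac)
            else:
                opt.lr = epoch_lr
            idx = order[start:start + config.batch_size]
            batch = [dataset[i] for i in idx]
            if config.flip_augmentation:
                flips = rng.random(len(batch)) < 0.5
                batch = [_flip_sample(s) if f else s
                         for s, f in zip(batch, flips)]
            images = np.stack([prepare_image(s.image) for s in batch])
            gts = [s.objects for s in batch]

            outputs = model(Tensor(images))
            breakdown = detection_loss(
                outputs, gts, model.prior, model.level_ranges,
                strategy=strategy,
                learn_prior=epoch > config.prior_warmup_epochs)
            model.zero_grad()
            breakdown.total_tensor.backward()
            opt.step()

            iteration += 1
            rec = {"iteration": iteration, "epoch": epoch, "lr": opt.lr,
                   "cls_loss": breakdown.cls_loss,
                   "reg_loss": breakdown.reg_loss,
                   "ctr_loss": breakdown.ctr_loss,
                   "total": breakdown.total,
                   "elapsed_s": round(time.perf_counter() - t0, 3)}
            log_records.append(rec)
            log_fh.write(json.dumps(rec) + "\n")
        np.savez(out_dir / f"epoch_{epoch:03d}.npz", **model.state_dict())
        np.savez(out_dir / "last.npz", **model.state_dict())
    log_fh.close()
    return model, log_records


def evaluate_model(model: PestDetector, dataset: list,
                   score_thresh: float = 0.05, nms_iou: float = 0.6,
                   max_dets: int = 100, batch_size: int = 8):
    """Decode detections for every sample; returns (detections, ground_truth)
    dicts keyed by image index, ready for :func:`capest.evaluation.evaluate`."""
    from .detection_head import decode

    detections, ground_truth = {}, {}
    for start in range(0, len(dataset), batch_size):
        batch = dataset[start:start + batch_size]
        images = np.stack([prepare_image(s.image) for s in batch])
        outputs = model(Tensor(images))
        for bi, sample in enumerate(batch):
            img_id = start + bi
            h, w = sample.image.shape[:2]
            detections[img_id] = decode(outputs, score_thresh=score_thresh,
                                        nms_iou=nms_iou, max_dets=max_dets,
                                        image_size=(w, h), batch_index=bi)
            ground_truth[img_id] = sample.objects
    return detections, ground_truth
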