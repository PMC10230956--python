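"""Config-driven training and evaluation orchestration.

Training uses plain SGD with momentum 0.9 and weight decay 1e-4 at an
initial learning rate of 0.0025 over 24 epochs (full-scale defaults), with
a step decay of x0.1 at epochs 16 and 22.  ``tiny_mode`` overrides these
to a CPU-minutes budget: higher learning rate, few epochs, small batches.
Everything is seeded — parameter init, data order, augmentation — so two
runs with the same config produce identical loss traces and reports.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import SGD
from .coco_io import CocoDataset, InstanceAnnotation
from .model import SECOTR, ModelConfig, tiny_model_config, save_checkpoint, load_checkpoint
from .metrics import EvalReport, evaluate
from .synthetic import AugmentConfig, augment

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 0.0025
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 24
    batch_size: int = 8
    seed: int = 0
    lr_decay_epochs: tuple[int, ...] = (16, 22)
    lr_decay_factor: float = 0.1
    device: str = "cpu"
    tiny_mode: bool = False
    max_iterations: int | None = None   # hard cap across epochs (tiny runs)
    augment: bool = True
    clip_grad_norm: float = 10.0        # global-norm gradient clipping
    warmup_iters: int = 100             # linear LR warmup from 10% of lr

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def tiny(cls, seed: int = 0, iterations: int = 300) -> "TrainConfig":
        return cls(lr=0.01, epochs=max(1, -(-iterations // 16)), batch_size=4,
                   seed=seed, lr_decay_epochs=(), tiny_mode=True,
                   max_iterations=iterations, augment=False,
                   warmup_iters=50)


@dataclass
class RunArtifacts:
    checkpoint: Path
    loss_csv: Path
    config_json: Path
    log_file: Path
    losses: list[float]
    report: EvalReport | None = None


def _dataset_pairs(dataset: CocoDataset) -> list[tuple[np.ndarray, list[InstanceAnnotation]]]:
    pairs = []
    for im in dataset.images:
        if im.pixels is None:
            raise ValueError(f"image {im.id} has no pixel data loaded")
        pairs.append((im.pixels, dataset.annotations_for(im.id)))
    return pairs


def train(model: SECOTR, dataset: CocoDataset, config: TrainConfig,
          out_dir: str | Path) -> RunArtifacts:
    """Run the SGD loop, logging per-iteration losses and checkpointing.

    Raises :class:`FloatingPointError` naming the first non-finite loss
    term if training diverges.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = out / "train.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    logger.setLevel(min(logger.level or logging.INFO, logging.INFO))
    pairs = _dataset_pairs(dataset)
    if not pairs:
        raise ValueError("empty training dataset")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
              weight_decay=config.weight_decay)
    aug_cfg = AugmentConfig()

    losses: list[float] = []
    rows = []
    it = 0
    t0 = time.time()
    stop = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            images, anns = [], []
            for i in sel:
                img, ann = pairs[i]
                if config.augment:
                    img, ann = augment(img, ann, rng, aug_cfg)
                images.append(img)
                anns.append(ann)
            batch = np.stack(images)
            opt.zero_grad()
            outputs = model(batch)
            loss, report = model.compute_loss(outputs, anns)
            loss.backward()
            if config.clip_grad_norm:
                total_sq = sum(float((p.grad ** 2).sum())
                               for p in opt.params if p.grad is not None)
                norm = np.sqrt(total_sq)
                if norm > config.clip_grad_norm:
                    scale = config.clip_grad_norm / norm
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad *= scale
            base_lr = config.lr
            if config.lr_decay_epochs:
                base_lr *= config.lr_decay_factor ** sum(epoch >= e for e in config.lr_decay_epochs)
            if it < config.warmup_iters:
                base_lr *= 0.1 + 0.9 * it / config.warmup_iters
            opt.lr = base_lr
            opt.step()
            losses.append(report.total)
            rows.append((it, epoch, report.cls_loss, report.box_loss,
                         report.mask_loss, report.total))
            it += 1
            if config.max_iterations is not None and it >= config.max_iterations:
                stop = True
                break
        epoch_rows = [r for r in rows if r[1] == epoch]
        logger.info("epoch %d: %d iters, mean loss %.4f", epoch,
                    len(epoch_rows), float(np.mean([r[5] for r in epoch_rows])))
        ckpt = out / "checkpoint.npz"
        save_checkpoint(model, ckpt, epoch=epoch, iteration=it,
                        train_seed=config.seed)
        if stop:
            break
    logger.info("training finished: %d iterations in %.1fs", it, time.time() - t0)
    logger.removeHandler(handler)
    handler.close()

    loss_csv = out / "loss.csv"
    with loss_csv.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "epoch", "cls", "box", "mask", "total"])
        w.writerows(rows)
    config_json = out / "config.json"
    config_json.write_text(json.dumps(
        {"train": dataclasses.asdict(config), "model": model.config.to_dict()},
        indent=2, default=list))
    return RunArtifacts(checkpoint=out / "checkpoint.npz", loss_csv=loss_csv,
                        config_json=config_json, log_file=log_file,
                        losses=losses)


def evaluate_run(checkpoint: str | Path | SECOTR, dataset: CocoDataset) -> EvalReport:
    """Full forward + postprocess + metric evaluation over a dataset."""
    if isinstance(checkpoint, SECOTR):
        model = checkpoint
    else:
        model, _ = load_checkpoint(checkpoint)
    pairs = _dataset_pairs(dataset)
    if not pairs:
        raise ValueError("empty evaluation dataset")
    detections, gts = [], []
    for img, ann in pairs:
        detections.append(model.predict(img[None])[0])
        gts.append(ann)
    h, w = pairs[0][0].shape[:2]
    return evaluate(detections, gts, (h, w))


def smoothed(values: list[float], window: int = 20) -> np.ndarray:
    """Moving average used for the training-curve health check."""
    v = np.asarray(values, dtype=float)
    if len(v) < window:
        return v
    kernel = np.ones(window) / window
    return np.convolve(v, kernel, mode="valid")
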