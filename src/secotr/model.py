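"""End-to-end network: backbone+FPN -> COTR -> JPU -> heads -> dynamic conv.

`SECOTR.forward` maps an image batch to per-level head outputs plus the
unified mask feature; `compute_loss` builds the focal/smooth-L1/dice
training objective from ground-truth annotations; `predict` decodes final
detections.  A reduced `tiny_model_config` keeps the same wiring at a size
that trains in minutes on one CPU core (128 px images, two head levels,
~0.3 M parameters).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .backbone import BackboneConfig, BackboneFPN
from .cotr import Cotr, CotrConfig
from .jpu import Jpu, JpuConfig
from .heads import (HeadsConfig, FunctionHeads, assign_targets, kernel_dim)
from .mask_decode import PostprocessConfig, dynamic_conv, postprocess, Detection
from .losses import focal_loss, smooth_l1, dice_loss, LossReport
from .coco_io import InstanceAnnotation

# input standardisation constants (natural-image scale)
_MEAN, _STD = 0.45, 0.225


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    cotr: CotrConfig = field(default_factory=CotrConfig)
    jpu: JpuConfig = field(default_factory=JpuConfig)
    heads: HeadsConfig = field(default_factory=HeadsConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 3.0)  # cls, box, mask

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        def fix(dc_cls, d):
            kwargs = {}
            for f in dataclasses.fields(dc_cls):
                if f.name not in d:
                    continue
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kwargs[f.name] = v
            return dc_cls(**kwargs)

        return cls(backbone=fix(BackboneConfig, doc["backbone"]),
                   cotr=fix(CotrConfig, doc["cotr"]),
                   jpu=fix(JpuConfig, doc["jpu"]),
                   heads=fix(HeadsConfig, doc["heads"]),
                   postprocess=fix(PostprocessConfig, doc["postprocess"]),
                   loss_weights=tuple(doc.get("loss_weights", (1.0, 1.0, 3.0))))


def tiny_model_config() -> ModelConfig:
    """Desk-scale configuration: two head levels, 32-channel pyramid."""
    return ModelConfig(
        backbone=BackboneConfig(fpn_channels=32, tiny_mode=True),
        cotr=CotrConfig(k=1, n_patch=4, mlp_ratio=2.0, reduction=4,
                        grid_sizes=(12, 8)),
        jpu=JpuConfig(c_mask=32),
        heads=HeadsConfig(levels=("P3", "P4"), grid_sizes=(12, 8),
                          scale_ranges=((0.0, 28.0), (20.0, 2048.0)),
                          gamma=1, eps_center=0.2),
    )


class SECOTR(nn.Module):
    def __init__(self, config: ModelConfig, *, seed: int = 0):
        nn.manual_seed(seed)
        self.config = config
        c = config.backbone.fpn_channels
        norm = config.backbone.norm_kind
        self.backbone = BackboneFPN(config.backbone)
        self.cotr = Cotr(c, config.cotr, norm_kind=norm)
        self.jpu = Jpu(c, config.jpu, norm_kind=norm)
        self.heads = FunctionHeads(c, config.jpu.c_mask, config.heads)

    # -- forward ------------------------------------------------------------

    @staticmethod
    def _to_input(images: np.ndarray) -> Tensor:
        """(B, H, W, 3) uint8 -> standardized (B, 3, H, W) tensor."""
        x = images.astype(np.float32) / 255.0
        x = (x - _MEAN) / _STD
        return Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))

    def forward(self, images: np.ndarray) -> dict:
        x = self._to_input(images)
        pyramid = self.backbone.extract_features(x)
        seq, refined_p5 = self.cotr(pyramid["P5"])
        pyramid = dict(pyramid, P5=refined_p5)
        feature = self.jpu([pyramid[k] for k in ("P2", "P3", "P4", "P5")])
        head_out = self.heads.run_heads(pyramid)
        return {"feature": feature, "heads": head_out, "sequence": seq,
                "image_size": images.shape[1:3]}

    # -- training objective --------------------------------------------------

    def compute_loss(self, outputs: dict,
                     annotations: list[list[InstanceAnnotation]]
                     ) -> tuple[Tensor, LossReport]:
        cfg = self.config.heads
        feature = outputs["feature"]
        B, C, Hf, Wf = feature.shape
        image_size = outputs["image_size"]
        gamma = cfg.gamma

        assigns = [assign_targets(anns, image_size, cfg, (Hf, Wf))
                   for anns in annotations]
        n_pos = sum(len(a.positive_cells) for a in assigns)

        cls_terms, box_preds, box_tgts = [], [], []
        mask_pred_list, mask_tgt_list = [], []
        for li, lvl in enumerate(cfg.levels):
            kernels, scores, boxes = outputs["heads"][lvl]
            n = cfg.grid_sizes[li]
            q = n * n
            # classification: one-hot targets over the whole grid
            tgt = np.zeros((B, q, cfg.num_classes), dtype=np.float32)
            for b, a in enumerate(assigns):
                grid = a.class_targets[lvl].reshape(-1)
                pos = grid > 0
                tgt[b, pos, grid[pos] - 1] = 1.0
            cls_terms.append((scores, tgt))
            # box + mask terms on positive cells
            for b, a in enumerate(assigns):
                idx = [i * n + j for (l, i, j, _) in a.positive_cells if l == lvl]
                if not idx:
                    continue
                sel = np.asarray(idx, dtype=np.int64)
                rows = [k for k, (l, _, _, _) in enumerate(a.positive_cells) if l == lvl]
                box_preds.append(nn.take_rows(boxes[b], sel))
                box_tgts.append(np.stack([a.box_targets[k] for k in rows]))
                pos_kernels = nn.take_rows(kernels[b], sel)  # (n_b, D)
                logits = dynamic_conv(feature[b:b + 1],
                                      pos_kernels.reshape(1, len(sel), -1),
                                      gamma)[0]
                mask_pred_list.append(logits.sigmoid())
                mask_tgt_list.append(np.stack([a.mask_targets[k] for k in rows]))

        all_scores = nn.concat([s.reshape(-1) for s, _ in cls_terms], axis=0)
        all_tgt = np.concatenate([t.reshape(-1) for _, t in cls_terms])
        cls = focal_loss(all_scores, all_tgt, normalizer=float(max(n_pos, 1)))
        if box_preds:
            box = smooth_l1(nn.concat(box_preds, axis=0), np.concatenate(box_tgts))
            mask = sum((dice_loss(p, t) * p.shape[0] for p, t
                        in zip(mask_pred_list, mask_tgt_list)),
                       start=Tensor(0.0)) * (1.0 / n_pos)
        else:
            box = Tensor(0.0)
            mask = Tensor(0.0)

        w_cls, w_box, w_mask = self.config.loss_weights
        total = cls * w_cls + box * w_box + mask * w_mask
        for name, term in (("cls_loss", cls), ("box_loss", box),
                           ("mask_loss", mask)):
            if not np.isfinite(term.data).all():
                raise FloatingPointError(f"non-finite loss term: {name}")
        report = LossReport(cls_loss=float(cls.data), box_loss=float(box.data),
                            mask_loss=float(mask.data), total=float(total.data))
        return total, report

    # -- inference ------------------------------------------------------------

    def predict(self, images: np.ndarray) -> list[list[Detection]]:
        """Decode detections for a (B, H, W, 3) uint8 batch."""
        cfg = self.config
        with nn.no_grad():
            outputs = self.forward(images)
            feature = outputs["feature"]
            B = feature.shape[0]
            results = []
            for b in range(B):
                mask_logits, class_logits = {}, {}
                for lvl in cfg.heads.levels:
                    kernels, scores, _ = outputs["heads"][lvl]
                    z = dynamic_conv(feature[b:b + 1], kernels[b:b + 1],
                                     cfg.heads.gamma)
                    mask_logits[lvl] = z.data[0]
                    class_logits[lvl] = scores.data[b]
                results.append(postprocess(mask_logits, class_logits,
                                           tuple(outputs["image_size"]),
                                           cfg.postprocess))
        return results


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SECOTR, path: str | Path, **meta) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps({"model": model.config.to_dict(), "meta": meta}).encode(),
        dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> tuple[SECOTR, dict]:
    with np.load(path) as npz:
        doc = json.loads(bytes(npz["__config__"].tobytes()).decode())
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    model = SECOTR(ModelConfig.from_dict(doc["model"]))
    model.load_state_dict(state)
    return model, doc.get("meta", {})
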