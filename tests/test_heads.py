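"""Function-head shapes and the grid assignment rule against a brute-force
predicate oracle."""

import numpy as np
import pytest

from secotr import nn
from secotr.nn import Tensor
from secotr.coco_io import InstanceAnnotation
from secotr.heads import (AssignmentResult, FunctionHeads, HeadsConfig,
                          assign_targets, decode_box, kernel_dim)
from secotr.backbone import LEVEL_STRIDES
from secotr.synthetic import tiny_scene_config, generate_scene

TINY_HEADS = HeadsConfig(levels=("P3", "P4"), grid_sizes=(12, 8),
                         scale_ranges=((0.0, 28.0), (20.0, 2048.0)))


def _rect_ann(y0, y1, x0, x1, h=64, w=64, ann_id=1):
    m = np.zeros((h, w), dtype=bool)
    m[y0:y1, x0:x1] = True
    return InstanceAnnotation(m, id=ann_id)


# -- head shapes -------------------------------------------------------------

@pytest.mark.parametrize("gamma,c_mask,expect", [(1, 256, 256), (3, 8, 72)])
def test_kernel_dim_formula(gamma, c_mask, expect):
    assert kernel_dim(gamma, c_mask) == expect


def test_run_heads_shapes(rng):
    nn.manual_seed(20)
    heads = FunctionHeads(8, c_mask=16, config=TINY_HEADS)
    pyramid = {"P3": Tensor(rng.normal(size=(2, 8, 16, 16))),
               "P4": Tensor(rng.normal(size=(2, 8, 8, 8)))}
    out = heads.run_heads(pyramid)
    assert out["P3"][0].shape == (2, 144, 16)   # kernels, D = 1*16
    assert out["P3"][1].shape == (2, 144, 1)    # class logits
    assert out["P3"][2].shape == (2, 144, 4)    # box offsets
    assert out["P4"][0].shape == (2, 64, 16)


def test_zero_weight_heads_constant_scores(rng):
    nn.manual_seed(21)
    heads = FunctionHeads(8, c_mask=4, config=TINY_HEADS)
    heads.class_head.weight.data[...] = 0.0
    pyramid = {"P3": Tensor(rng.normal(size=(1, 8, 16, 16))),
               "P4": Tensor(rng.normal(size=(1, 8, 8, 8)))}
    out = heads.run_heads(pyramid)
    scores = out["P3"][1].data
    assert np.allclose(scores, scores[0, 0, 0])
    assert np.allclose(scores[0, 0, 0], heads.class_head.bias.data[0])


def test_shared_weights_across_levels(rng):
    """The same linear map serves every level: feeding P4's pooled grid
    through P3's path gives identical head outputs."""
    nn.manual_seed(22)
    heads = FunctionHeads(8, c_mask=4, config=TINY_HEADS)
    x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
    # same pooled content at both levels (grid 8 on an 8x8 map is identity)
    cfg_same = HeadsConfig(levels=("P3", "P4"), grid_sizes=(8, 8),
                           scale_ranges=((0.0, 28.0), (20.0, 2048.0)))
    nn.manual_seed(22)
    heads_same = FunctionHeads(8, c_mask=4, config=cfg_same)
    for p in heads_same.pos:
        p.data[...] = 0.0
    out = heads_same.run_heads({"P3": Tensor(x), "P4": Tensor(x)})
    for a, b in zip(out["P3"], out["P4"]):
        assert np.array_equal(a.data, b.data)


# -- assignment ---------------------------------------------------------------

def brute_force_cells(box, n, image_size, eps):
    """Exhaustive per-cell evaluation of the center-region predicate."""
    h, w = image_size
    x0, y0, x1, y1 = box
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    rx0, rx1 = cx - eps * (x1 - x0) / 2, cx + eps * (x1 - x0) / 2
    ry0, ry1 = cy - eps * (y1 - y0) / 2, cy + eps * (y1 - y0) / 2
    cells = []
    for i in range(n):
        for j in range(n):
            cy0, cy1 = i * h / n, (i + 1) * h / n
            cx0, cx1 = j * w / n, (j + 1) * w / n
            overlaps = not (cx1 <= rx0 or cx0 > rx1 or cy1 <= ry0 or cy0 > ry1)
            yc, xc = (i + 0.5) * h / n, (j + 0.5) * w / n
            center_in_box = x0 <= xc <= x1 and y0 <= yc <= y1
            if overlaps and center_in_box:
                cells.append((i, j))
    if not cells:
        cells = [(int(np.floor(cy * n / h)), int(np.floor(cx * n / w)))]
    return set(cells)


def test_centered_instance_epsilon_zero_single_cell():
    cfg = HeadsConfig(levels=("P4",), grid_sizes=(8,),
                      scale_ranges=((0.0, 2048.0),), eps_center=0.0)
    # cell (3, 3) of an 8-grid on 64 px spans [24, 32); center it exactly
    ann = _rect_ann(22, 34, 22, 34)
    res = assign_targets([ann], (64, 64), cfg, (16, 16))
    assert [(l, i, j) for l, i, j, _ in res.positive_cells] == [("P4", 3, 3)]


def test_empty_annotations_give_all_background():
    res = assign_targets([], (64, 64), TINY_HEADS, (16, 16))
    assert res.positive_cells == []
    assert all((g == 0).all() for g in res.class_targets.values())


def test_assignment_matches_brute_force_on_random_scenes():
    """Positive-cell sets equal exhaustive predicate evaluation, 50 scenes."""
    scene_cfg = tiny_scene_config(seed=31)
    cfg = TINY_HEADS
    checked = 0
    for i in range(50):
        _, anns = generate_scene(scene_cfg, i)
        res = assign_targets(anns, scene_cfg.image_size, cfg, (32, 32))
        got = {}
        for lvl, ii, jj, idx in res.positive_cells:
            got.setdefault((lvl, ii, jj), idx)
        # rebuild expectation: larger instances first, smaller overwrite
        expect = {}
        order = sorted(range(len(anns)), key=lambda k: -anns[k].area)
        for idx in order:
            ann = anns[idx]
            sq = np.sqrt(ann.area)
            for lvl, n, (lo, hi) in zip(cfg.levels, cfg.grid_sizes,
                                        cfg.scale_ranges):
                if not (lo <= sq <= hi):
                    continue
                for (ii, jj) in brute_force_cells(ann.box, n,
                                                  scene_cfg.image_size,
                                                  cfg.eps_center):
                    expect[(lvl, ii, jj)] = idx
        assert got == expect
        checked += len(expect)
    assert checked > 50


def test_every_positive_cell_has_nonempty_mask_target():
    scene_cfg = tiny_scene_config(seed=32)
    for i in range(10):
        _, anns = generate_scene(scene_cfg, i)
        res = assign_targets(anns, scene_cfg.image_size, TINY_HEADS, (32, 32))
        for m in res.mask_targets:
            assert m.any()


def test_translation_by_one_cell_pitch_shifts_assignment():
    cfg = HeadsConfig(levels=("P4",), grid_sizes=(8,),
                      scale_ranges=((0.0, 2048.0),), eps_center=0.2)
    pitch = 64 // 8
    a = _rect_ann(18, 30, 18, 30)
    b = _rect_ann(18 + pitch, 30 + pitch, 18 + pitch, 30 + pitch)
    ra = assign_targets([a], (64, 64), cfg, (16, 16))
    rb = assign_targets([b], (64, 64), cfg, (16, 16))
    cells_a = sorted((i, j) for _, i, j, _ in ra.positive_cells)
    cells_b = sorted((i, j) for _, i, j, _ in rb.positive_cells)
    assert cells_b == [(i + 1, j + 1) for i, j in cells_a]


def test_box_targets_nonnegative_and_decode_within_one_pixel():
    scene_cfg = tiny_scene_config(seed=33)
    for i in range(20):
        _, anns = generate_scene(scene_cfg, i)
        res = assign_targets(anns, scene_cfg.image_size, TINY_HEADS, (32, 32))
        for cell, tgt in zip(res.positive_cells, res.box_targets):
            assert (tgt >= 0).all()
            ann = anns[cell[3]]
            if min(ann.box[2] - ann.box[0], ann.box[3] - ann.box[1]) < 12:
                continue  # sub-cell instances use the clamped fallback
            decoded = decode_box(cell[:3], tgt, scene_cfg.image_size, TINY_HEADS)
            assert max(abs(d - g) for d, g in zip(decoded, ann.box)) <= 1.0


def test_instance_may_own_multiple_cells_each_cell_single_owner():
    cfg = HeadsConfig(levels=("P4",), grid_sizes=(8,),
                      scale_ranges=((0.0, 2048.0),), eps_center=1.0)
    ann = _rect_ann(8, 56, 8, 56)
    res = assign_targets([ann], (64, 64), cfg, (16, 16))
    cells = [(i, j) for _, i, j, _ in res.positive_cells]
    assert len(cells) > 1
    assert len(set(cells)) == len(cells)
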