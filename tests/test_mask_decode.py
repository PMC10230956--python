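"""Dynamic convolution, Matrix NMS and postprocess decoding."""

import numpy as np
import pytest

from secotr.nn import Tensor
from secotr.mask_decode import (Detection, PostprocessConfig, dynamic_conv,
                                mask_iou_matrix, matrix_nms, postprocess)

from conftest import random_blob_mask


# -- dynamic convolution -------------------------------------------------------

def naive_dynamic_conv(F, K, gamma):
    """Quadruple-loop reference: per cell, per pixel, per channel, per tap."""
    C, H, W = F.shape
    Q = K.shape[0]
    Z = np.zeros((Q, H, W))
    pad = gamma // 2
    for q in range(Q):
        kern = K[q].reshape(C, gamma, gamma)
        for y in range(H):
            for x in range(W):
                acc = 0.0
                for c in range(C):
                    for u in range(gamma):
                        for v in range(gamma):
                            yy, xx = y + u - pad, x + v - pad
                            if 0 <= yy < H and 0 <= xx < W:
                                acc += F[c, yy, xx] * kern[c, u, v]
                Z[q, y, x] = acc
    return Z


def test_gamma1_one_hot_kernel_selects_channel(rng):
    F = rng.normal(size=(1, 5, 6, 7)).astype(np.float32)
    K = np.zeros((1, 3, 5), dtype=np.float32)
    K[0, 0, 2] = 1.0
    K[0, 1, 4] = 1.0
    K[0, 2, 0] = 1.0
    Z = dynamic_conv(Tensor(F), Tensor(K), gamma=1)
    assert np.array_equal(Z.data[0, 0], F[0, 2])
    assert np.array_equal(Z.data[0, 1], F[0, 4])
    assert np.array_equal(Z.data[0, 2], F[0, 0])


def test_gamma1_single_pixel_dot_product():
    F = np.array([1.0, 2.0]).reshape(1, 2, 1, 1)
    K = np.array([0.5, 0.5]).reshape(1, 1, 2)
    Z = dynamic_conv(Tensor(F), Tensor(K), gamma=1)
    assert np.allclose(Z.data, 1.5)


@pytest.mark.parametrize("gamma", [1, 3])
def test_dynamic_conv_matches_quadruple_loop(rng, gamma):
    C, H, W, Q = 4, 6, 5, 3
    F = rng.normal(scale=0.3, size=(C, H, W)).astype(np.float32)
    K = rng.normal(scale=0.3, size=(Q, gamma * gamma * C)).astype(np.float32)
    Z = dynamic_conv(Tensor(F[None]), Tensor(K[None]), gamma=gamma)
    ref = naive_dynamic_conv(F, K, gamma)
    assert np.abs(Z.data[0] - ref).max() < 1e-6


@pytest.mark.parametrize("gamma", [1, 3])
def test_dynamic_conv_linear_in_kernels(rng, gamma):
    C, Q = 3, 4
    F = Tensor(rng.normal(size=(1, C, 5, 5)))
    K1 = rng.normal(scale=0.3, size=(1, Q, gamma * gamma * C)).astype(np.float32)
    K2 = rng.normal(scale=0.3, size=(1, Q, gamma * gamma * C)).astype(np.float32)
    a, b = 0.7, -1.3
    Zc = dynamic_conv(F, Tensor(a * K1 + b * K2), gamma=gamma).data
    Z1 = dynamic_conv(F, Tensor(K1), gamma=gamma).data
    Z2 = dynamic_conv(F, Tensor(K2), gamma=gamma).data
    assert np.abs(Zc - (a * Z1 + b * Z2)).max() < 1e-6


def test_dynamic_conv_dimension_mismatch(rng):
    F = Tensor(rng.normal(size=(1, 4, 5, 5)))
    K = Tensor(rng.normal(size=(1, 2, 9)))
    with pytest.raises(ValueError):
        dynamic_conv(F, K, gamma=1)


# -- Matrix NMS ----------------------------------------------------------------

def naive_matrix_nms(masks, scores, categories, mode, sigma):
    """O(n^2) straight-line evaluation of the decay definition."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    n = len(masks)
    decayed = np.array(scores, dtype=np.float64)
    ious = mask_iou_matrix(np.asarray(masks)[order])
    for jj in range(n):
        factors = []
        for ii in range(jj):
            if categories[order[ii]] != categories[order[jj]]:
                continue
            iou_ij = ious[ii, jj]
            iou_max = 0.0
            for kk in range(ii):
                if categories[order[kk]] == categories[order[ii]]:
                    iou_max = max(iou_max, ious[kk, ii])
            if mode == "gaussian":
                f = np.exp(-(iou_ij ** 2) / sigma) / np.exp(-(iou_max ** 2) / sigma)
            else:
                denom = 1.0 - iou_max
                f = (1.0 - iou_ij) / denom if denom > 0 else \
                    (1.0 if iou_ij == 1.0 else np.inf)
            factors.append(f)
        if factors:
            decayed[order[jj]] *= min(1.0, min(factors))
    return decayed


def test_single_mask_score_unchanged(rng):
    m = random_blob_mask(rng, 32, 32)[None]
    out = matrix_nms(m, np.array([0.7]), np.array([1]))
    assert np.allclose(out, [0.7])


def test_identical_duplicates_fully_suppressed_linear(rng):
    m = random_blob_mask(rng, 32, 32)
    masks = np.stack([m, m])
    out = matrix_nms(masks, np.array([0.9, 0.8]), np.array([1, 1]),
                     mode="linear")
    assert out[0] == pytest.approx(0.9)
    assert out[1] == pytest.approx(0.0)


def test_different_categories_do_not_suppress(rng):
    m = random_blob_mask(rng, 32, 32)
    out = matrix_nms(np.stack([m, m]), np.array([0.9, 0.8]),
                     np.array([1, 2]), mode="linear")
    assert np.allclose(out, [0.9, 0.8])


@pytest.mark.parametrize("mode", ["gaussian", "linear"])
def test_matrix_nms_equals_quadratic_reference(rng, mode):
    for trial in range(8):
        n = int(rng.integers(2, 21))
        masks = np.stack([random_blob_mask(rng, 24, 24) for _ in range(n)])
        scores = rng.uniform(0.1, 1.0, size=n)
        cats = rng.integers(1, 3, size=n)
        got = matrix_nms(masks, scores, cats, mode=mode, sigma=2.0)
        ref = naive_matrix_nms(masks, scores, cats, mode, 2.0)
        assert np.allclose(got, ref, rtol=0, atol=1e-12)


def test_matrix_nms_is_score_monotone(rng):
    n = 15
    masks = np.stack([random_blob_mask(rng, 24, 24) for _ in range(n)])
    scores = rng.uniform(0.1, 1.0, size=n)
    out = matrix_nms(masks, scores, np.ones(n, dtype=int))
    assert np.all(out <= scores + 1e-12)


def test_matrix_nms_length_mismatch(rng):
    with pytest.raises(ValueError):
        matrix_nms(np.zeros((2, 4, 4), dtype=bool), np.array([0.5]),
                   np.array([1, 1]))


# -- postprocess ---------------------------------------------------------------

def _grids(n_cells, hf=16, wf=16, active=(), logit=8.0):
    """Fabricated per-level outputs with chosen active cells."""
    mask_logits = np.full((n_cells, hf, wf), -12.0, dtype=np.float32)
    class_logits = np.full((n_cells, 1), -12.0, dtype=np.float32)
    for k, cell in enumerate(active):
        y = (k * 3) % (hf - 4)
        x = (k * 5) % (wf - 4)
        mask_logits[cell, y:y + 3, x:x + 3] = logit
        class_logits[cell, 0] = logit
    return {"P4": mask_logits}, {"P4": class_logits}


def test_all_negative_logits_give_no_detections():
    ml, cl = _grids(20)
    assert postprocess(ml, cl, (64, 64), PostprocessConfig()) == []


def test_single_activated_cell_single_detection():
    ml, cl = _grids(20, active=(7,))
    dets = postprocess(ml, cl, (64, 64), PostprocessConfig())
    assert len(dets) == 1
    det = dets[0]
    # mask equals the thresholded upsampled channel
    from secotr.nn.functional import bilinear_resize_array
    soft = 1.0 / (1.0 + np.exp(-ml["P4"][7]))
    expect = bilinear_resize_array(soft, (64, 64)) > 0.5
    assert np.array_equal(det.mask, expect)
    assert det.score > 0.5


def test_truncation_to_top_100():
    """150 strong disjoint candidates -> exactly 100 survivors."""
    hf = wf = 40
    n = 150
    mask_logits = np.full((n, hf, wf), -12.0, dtype=np.float32)
    class_logits = np.full((n, 1), -12.0, dtype=np.float32)
    for k in range(n):
        y, x = divmod(k, 13)
        mask_logits[k, 3 * y:3 * y + 2, 3 * x:3 * x + 2] = 9.0
        class_logits[k, 0] = 9.0
    dets = postprocess({"P4": mask_logits}, {"P4": class_logits}, (80, 80),
                       PostprocessConfig(pre_nms=500))
    assert len(dets) == 100


def test_postprocess_count_never_exceeds_100(rng):
    for trial in range(3):
        n = int(rng.integers(1, 30))
        active = tuple(rng.choice(n, size=min(n, 10), replace=False))
        ml, cl = _grids(n, active=active)
        dets = postprocess(ml, cl, (64, 64), PostprocessConfig())
        assert len(dets) <= 100
        for det in dets:
            assert 0.0 <= det.score <= 1.0


def test_detection_invariants():
    with pytest.raises(ValueError):
        Detection(mask=np.zeros((4, 4), dtype=bool), score=0.5, category=1,
                  box=(0, 0, 1, 1))
    with pytest.raises(ValueError):
        Detection(mask=np.ones((4, 4), dtype=bool), score=1.5, category=1,
                  box=(0, 0, 4, 4))
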