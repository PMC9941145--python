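"""Box arithmetic, CAM box extraction, anchor clustering/matching,
detector contracts and localization metrics."""

import warnings

import numpy as np
import pytest

from angioscreen import localize as L
from angioscreen import profiles as P
from angioscreen.boxes import box_area, clip_box, iou, nms
from angioscreen.synth import Lesion


def _det(box, score=0.9):
    return L.Detection(box=box, score=score)


def _lesion(box, severity=70.0):
    return Lesion(severity=severity, category="25-99%", box=box,
                  branch_index=0, position=0.5)


# ---------------------------------------------------------------------- IoU
def test_iou_worked_examples():
    assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == pytest.approx(1.0)
    assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == pytest.approx(0.0)
    # overlap 50, union 150
    assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        iou((0, 0, 0, 10), (0, 0, 10, 10))


def test_iou_matches_pixel_set_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        a = _rand_box(rng)
        b = _rand_box(rng)
        grid_a = _pixels(a)
        grid_b = _pixels(b)
        expected = len(grid_a & grid_b) / len(grid_a | grid_b)
        assert iou(a, b) == pytest.approx(expected)


def _rand_box(rng, lim=30):
    x0, y0 = rng.integers(0, lim - 2, 2)
    return (int(x0), int(y0), int(x0 + rng.integers(1, lim - x0)),
            int(y0 + rng.integers(1, lim - y0)))


def _pixels(box):
    x0, y0, x1, y1 = box
    return {(x, y) for x in range(x0, x1) for y in range(y0, y1)}


def test_box_helpers():
    assert box_area((0, 0, 4, 5)) == 20
    assert clip_box((-3, -2, 70, 70), 64, 64) == (0, 0, 64, 64)


def test_nms_suppresses_duplicates():
    boxes = [(0, 0, 10, 10), (1, 0, 11, 10), (30, 30, 40, 40)]
    keep = nms(boxes, np.array([0.9, 0.8, 0.7]), iou_threshold=0.5)
    assert keep == [0, 2]


# ---------------------------------------------------------------------- CAM
def test_cam_to_boxes_single_hot_region():
    m = np.zeros((32, 32))
    m[10:18, 5:12] = 1.0
    hm = L.CamHeatmap(grid=m, upsampled=m, source_class=1)
    dets = L.cam_to_boxes(hm, rel_threshold=0.5)
    assert len(dets) == 1
    assert dets[0].box == (5, 10, 12, 18)
    assert dets[0].score == pytest.approx(1.0)


def test_cam_to_boxes_zero_map_and_peak_ordering():
    zero = L.CamHeatmap(grid=np.zeros((8, 8)), upsampled=np.zeros((32, 32)),
                        source_class=1)
    assert L.cam_to_boxes(zero) == []
    m = np.zeros((32, 32))
    m[2:8, 2:8] = 0.6       # lower peak
    m[20:26, 20:26] = 1.0   # higher peak
    hm = L.CamHeatmap(grid=m, upsampled=m, source_class=1)
    dets = L.cam_to_boxes(hm, rel_threshold=0.5, max_boxes=1)
    assert len(dets) == 1 and dets[0].box == (20, 20, 26, 26)


def test_cam_min_area_filter():
    m = np.zeros((32, 32))
    m[0, 0] = 1.0           # single hot pixel, below min_area
    m[10:16, 10:16] = 0.9
    hm = L.CamHeatmap(grid=m, upsampled=m, source_class=1)
    dets = L.cam_to_boxes(hm, rel_threshold=0.5, min_area=4)
    assert len(dets) == 1 and dets[0].box == (10, 10, 16, 16)


# -------------------------------------------------------------- anchor kmeans
def test_anchor_clustering_two_tight_clusters():
    rng = np.random.default_rng(1)
    boxes = [(0, 0, 40 + rng.integers(-1, 2), 40 + rng.integers(-1, 2))
             for _ in range(25)]
    boxes += [(0, 0, 120 + rng.integers(-1, 2), 80 + rng.integers(-1, 2))
              for _ in range(25)]
    anch = L.cluster_anchor_shapes(boxes, k=2, seed=0)
    small, large = anch.shapes
    assert small == pytest.approx((40, 40), abs=1.5)
    assert large == pytest.approx((80, 120), abs=1.5)


def test_anchor_clustering_wcss_monotone_and_deterministic():
    rng = np.random.default_rng(2)
    boxes = [(0, 0, int(w), int(h))
             for h, w in rng.integers(20, 100, size=(60, 2))]
    a1 = L.cluster_anchor_shapes(boxes, k=7, seed=3)
    a2 = L.cluster_anchor_shapes(boxes, k=7, seed=3)
    assert np.array_equal(a1.shapes, a2.shapes)
    assert all(b <= a + 1e-9 for a, b in zip(a1.wcss_history, a1.wcss_history[1:]))
    areas = a1.shapes.prod(axis=1)
    assert all(areas[i] <= areas[i + 1] for i in range(len(areas) - 1))


def test_anchor_clustering_degenerate_shapes_reduce_k():
    boxes = [(0, 0, 40, 40)] * 50
    with pytest.warns(UserWarning, match="reducing k"):
        anch = L.cluster_anchor_shapes(boxes, k=7, seed=0)
    assert anch.shapes.shape == (1, 2)
    assert tuple(anch.shapes[0]) == (40.0, 40.0)


def test_anchor_set_validation():
    with pytest.raises(ValueError):
        L.AnchorSet(shapes=[(10, 10), (0, 5)])
    with pytest.raises(ValueError):
        L.cluster_anchor_shapes([(0, 0, 10, 10)] * 3, k=7)


# ----------------------------------------------------------------- detector
@pytest.fixture(scope="module")
def tiny_detector_setup():
    images, lesions = P.easy_detection_dataset(12, seed=3)
    boxes = [[l.box for l in ls] for ls in lesions]
    anch = L.cluster_anchor_shapes([b for bs in boxes for b in bs],
                                   k=5, seed=0)
    return images, boxes, lesions, anch


def test_pyramid_has_five_decreasing_levels(tiny_detector_setup):
    from angioscreen import nn

    _, _, _, anch = tiny_detector_setup
    det = L.FPNDetector(anch, L.DetectorConfig(image_size=128, width=3,
                                               head_channels=6, seed=0))
    pyr = det.pyramid(nn.Tensor(np.zeros((1, 1, 128, 128))))
    sizes = [f.shape[2] for f in pyr]
    assert len(sizes) == 5
    assert all(b < a for a, b in zip(sizes, sizes[1:]))


def test_every_truth_box_has_a_matching_anchor(tiny_detector_setup):
    images, boxes, _, anch = tiny_detector_setup
    det = L.FPNDetector(anch, L.DetectorConfig(image_size=64, width=3,
                                               head_channels=6, seed=0))
    ab = det.anchor_boxes(64)
    for per_image in boxes:
        for tb in per_image:
            best = max(iou(tuple(a), tb) for a in ab)
            assert best >= 0.4


def test_fpn_training_reduces_loss(tiny_detector_setup):
    images, boxes, _, anch = tiny_detector_setup
    cfg = L.DetectorConfig(image_size=64, width=3, head_channels=8,
                           lr=1e-3, epochs=5, batch_size=6, seed=0)
    det = L.build_and_train_fpn(images, boxes, anch, cfg)
    assert det.epoch_losses[-1] < det.epoch_losses[0]


def test_detect_contracts(tiny_detector_setup):
    images, boxes, _, anch = tiny_detector_setup
    cfg = L.DetectorConfig(image_size=64, width=3, head_channels=8,
                           lr=1e-3, epochs=2, batch_size=6, seed=0)
    det = L.build_and_train_fpn(images, boxes, anch, cfg)
    out = L.detect_stenoses(det, images[0], score_threshold=1.0)
    assert out == []                               # nothing clears threshold 1
    out = L.detect_stenoses(det, images[0], score_threshold=0.0)
    for d in out:
        x0, y0, x1, y1 = d.box
        assert 0 <= x0 < x1 <= 64 and 0 <= y0 < y1 <= 64
        assert 0.0 <= d.score <= 1.0


def test_no_positive_match_warns():
    rng = np.random.default_rng(0)
    images = rng.random((4, 64, 64))
    anch = L.AnchorSet(shapes=[(4.0, 4.0)])
    # truth boxes far larger than any anchor: no IoU >= 0.5 matches, but the
    # forced best-anchor rule still creates positives, so craft empty truths
    cfg = L.DetectorConfig(image_size=64, width=2, head_channels=4,
                           epochs=1, seed=0)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        L.build_and_train_fpn(images, [[], [], [], []], anch, cfg)
    assert any("no positive anchor" in str(w.message) for w in rec)


# ------------------------------------------------------------------- report
def test_report_thresholds_by_mode():
    truth = [_lesion((10, 10, 30, 30))]
    det_iou06 = [_det((12, 12, 30, 30))]          # IoU ~ 0.81
    det_iou03 = [_det((20, 10, 40, 30))]          # IoU = 1/3
    rep = L.localization_report([det_iou06], [truth], "anchor")
    assert rep["global_sensitivity"] == 1.0
    rep = L.localization_report([det_iou03], [truth], "anchor")
    assert rep["global_sensitivity"] == 0.0       # 1/3 < 0.5
    rep = L.localization_report([det_iou03], [truth], "cam")
    assert rep["global_sensitivity"] == 1.0       # 1/3 > 0.2


def test_report_most_severe_and_matching():
    truths = [_lesion((10, 10, 30, 30), severity=90.0),
              _lesion((40, 40, 60, 60), severity=40.0)]
    dets = [_det((40, 40, 60, 60))]               # hits the less severe lesion
    rep = L.localization_report([dets], [truths], "anchor")
    assert rep["global_sensitivity"] == 0.0
    assert rep["sens_s"] == pytest.approx(0.5)
    assert rep["spec_s"] == pytest.approx(1.0)


def test_report_perfect_detections():
    truths = [[_lesion((10, 10, 30, 30))], [_lesion((5, 5, 25, 25))]]
    dets = [[_det(t[0].box)] for t in truths]
    rep = L.localization_report(dets, truths, "anchor")
    assert rep["global_sensitivity"] == 1.0
    assert rep["sens_s"] == 1.0 and rep["spec_s"] == 1.0
    assert rep["mse"] == 0.0


def test_report_order_invariance_and_empty_truth():
    truths = [_lesion((10, 10, 30, 30), 90.0), _lesion((40, 40, 60, 60), 50.0)]
    dets = [_det((11, 11, 30, 30), 0.8), _det((41, 40, 60, 60), 0.7)]
    r1 = L.localization_report([dets], [truths], "anchor")
    r2 = L.localization_report([dets[::-1]], [truths], "anchor")
    for key in ("global_sensitivity", "sens_s", "spec_s", "mse"):
        assert r1[key] == pytest.approx(r2[key])
    r3 = L.localization_report([dets, []], [truths, []], "anchor")
    assert r3["n_images_excluded"] == 1


def test_report_mse_scaled_to_nominal_frame():
    truth = [_lesion((10, 10, 20, 20))]
    det = [_det((12, 10, 22, 20))]                # center offset 2 px at 64
    rep = L.localization_report([det], [truth], "cam", image_size=64)
    assert rep["mse"] == pytest.approx((2 * 512 / 64) ** 2)


# ------------------------------------------------------------- Grad-CAM maps
def test_cam_contracts_and_highlights_lesion(easy_trained_classifier,
                                             easy_detection_testset):
    """Maps are non-negative, upsampled to image size, and the activation
    peak falls inside the (dilated) lesion box in a majority of easy cases."""
    images, lesions = easy_detection_testset
    hits = 0
    for img, les in zip(images, lesions):
        cam = L.compute_cam(easy_trained_classifier, img, target_class=1)
        assert cam.grid.min() >= 0.0
        assert cam.upsampled.shape == img.shape
        r, c = np.unravel_index(np.argmax(cam.upsampled), cam.upsampled.shape)
        x0, y0, x1, y1 = les[0].box
        w, h = x1 - x0, y1 - y0
        if (x0 - 0.25 * w <= c <= x1 + 0.25 * w
                and y0 - 0.25 * h <= r <= y1 + 0.25 * h):
            hits += 1
    assert hits / len(images) >= 0.5
    with pytest.raises(ValueError):
        L.compute_cam(easy_trained_classifier, images[0], target_class=9)
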