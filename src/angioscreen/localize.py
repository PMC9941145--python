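"""Stenosis localization: class-activation maps and an anchor-based detector.

Two routes, mirroring the weakly- and fully-supervised options:

* **CAM-based** — a gradient-weighted class activation map (Grad-CAM) is
  derived from a trained severity classifier: channel weights are the
  spatially averaged gradients of the class score with respect to the last
  pre-pool feature map, the map is the rectified weighted channel sum,
  upsampled bilinearly to image resolution. Connected components of the
  thresholded map become scored boxes.

* **Anchor-based** — a single-stage detector over a 5-level feature pyramid
  on the inception-style backbone: the first three levels are the
  concatenated features before each pooling stage, the 4th and 5th are
  downsampled from them. Anchor shapes are preset by K-means clustering of
  annotated box heights/widths into seven groups; shared convolutional heads
  predict a per-anchor stenosis score (focal loss) and center/size offsets
  (smooth-L1). Anchors match a truth box at IoU >= 0.5, count as background
  below 0.4, and are ignored in between; the best anchor per truth is always
  positive.

Because CAM maps live at coarse feature resolution, CAM boxes are scored at
IoU > 0.2 while anchor boxes are held to IoU > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .boxes import box_area, box_center, clip_box, iou, nms
from .classify import ViewClassifier
from .synth import generate_labeled_frame

__all__ = ["CamHeatmap", "AnchorSet", "Detection", "DetectorConfig",
           "compute_cam", "cam_to_boxes", "cluster_anchor_shapes",
           "FPNDetector", "build_and_train_fpn", "detect_stenoses", "iou",
           "localization_report", "build_detection_dataset"]

IOU_THRESHOLD = {"cam": 0.2, "anchor": 0.5}


@dataclass
class CamHeatmap:
    grid: np.ndarray               # feature-resolution activation, >= 0
    upsampled: np.ndarray          # image-resolution activation, >= 0
    source_class: int
    flagged: bool = False          # True when the gradient was zero everywhere


@dataclass
class Detection:
    box: tuple                     # (x_min, y_min, x_max, y_max), half-open
    score: float
    cls: str = "stenosis"

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass
class AnchorSet:
    shapes: np.ndarray             # (k, 2) positive (height, width) pairs
    level_scales: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    wcss_history: list = field(default_factory=list)

    def __post_init__(self):
        self.shapes = np.asarray(self.shapes, dtype=float)
        if (self.shapes <= 0).any():
            raise ValueError("anchor shapes must be positive")


# ----------------------------------------------------------------- Grad-CAM
def compute_cam(model: ViewClassifier, image: np.ndarray,
                target_class: int) -> CamHeatmap:
    """Gradient-weighted class activation map for one image."""
    if not 0 <= target_class < model.backbone.head.w.shape[1]:
        raise ValueError(f"invalid target class {target_class}")
    x = model._prep(image[None])
    taps, emb = model.backbone.forward_features(nn.Tensor(x))
    logits = model.backbone.head(emb)
    score = logits[0, target_class]
    score.backward()
    feat = taps[-1]
    grad = feat.grad[0]                          # (C, h, w)
    act = feat.data[0]
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    flagged = not np.any(grad)
    up = resize(cam, image.shape, order=1, anti_aliasing=False)
    return CamHeatmap(grid=cam, upsampled=np.maximum(up, 0.0),
                      source_class=target_class, flagged=flagged)


def cam_to_boxes(heatmap: CamHeatmap, rel_threshold: float = 0.5,
                 max_boxes: int = 5, min_area: int = 4) -> list:
    """Boxes from connected components of the thresholded activation map.

    Confidence is the component peak normalised by the global maximum;
    components below `min_area` pixels are dropped.
    """
    m = heatmap.upsampled
    peak = m.max()
    if peak <= 0:
        return []
    labeled, n = ndimage.label(m >= rel_threshold * peak)
    dets = []
    for obj_slice, idx in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        region = labeled[obj_slice] == idx
        if region.sum() < min_area:
            continue
        ys, xs = obj_slice
        conf = float(m[obj_slice][region].max() / peak)
        dets.append(Detection(box=(xs.start, ys.start, xs.stop, ys.stop),
                              score=conf))
    dets.sort(key=lambda d: -d.score)
    return dets[:max_boxes]


# ------------------------------------------------------------------ anchors
def cluster_anchor_shapes(boxes, k: int = 7, seed: int = 0,
                          max_iter: int = 100) -> AnchorSet:
    """Lloyd's algorithm on (height, width) pairs, seeded.

    Accepts BoxAnnotation-like objects (with ``.box``) or raw box tuples.
    With fewer than k distinct shapes, k is reduced with a warning. Centroids
    are returned sorted by area; the within-cluster sum of squares recorded
    per iteration is non-increasing.
    """
    hw = []
    for b in boxes:
        x0, y0, x1, y1 = getattr(b, "box", b)
        hw.append((y1 - y0, x1 - x0))
    hw = np.asarray(hw, dtype=float)
    if len(hw) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(hw)}")
    distinct = np.unique(hw, axis=0)
    if len(distinct) < k:
        warnings.warn(f"only {len(distinct)} distinct shapes; reducing k from "
                      f"{k}")
        k = len(distinct)
    rng = np.random.default_rng(seed)
    centroids = distinct[rng.choice(len(distinct), size=k, replace=False)].copy()
    history = []
    assign = None
    for _ in range(max_iter):
        d2 = ((hw[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        history.append(float(d2[np.arange(len(hw)), new_assign].sum()))
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            members = hw[assign == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
    order = np.argsort(centroids.prod(axis=1))
    return AnchorSet(shapes=centroids[order], wcss_history=history)


# ----------------------------------------------------------- fused FPN loss
def _focal_loss_with_logits(logits: nn.Tensor, targets: np.ndarray,
                            weights: np.ndarray, normalizer: float,
                            gamma: float = 2.0, alpha: float = 0.25) -> nn.Tensor:
    """Focal binary loss on raw logits; `weights` zeroes ignored anchors."""
    z = logits.data
    t = np.asarray(targets, dtype=float)
    w = np.asarray(weights, dtype=float)
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    pc = np.clip(p, 1e-9, 1 - 1e-9)
    loss_pos = -alpha * (1 - pc) ** gamma * np.log(pc)
    loss_neg = -(1 - alpha) * pc ** gamma * np.log(1 - pc)
    loss = float((w * (t * loss_pos + (1 - t) * loss_neg)).sum() / normalizer)
    out = nn.Tensor(loss, parents=(logits,))
    dz_pos = alpha * (gamma * pc * (1 - pc) ** gamma * np.log(pc)
                      - (1 - pc) ** (gamma + 1))
    dz_neg = (1 - alpha) * (pc ** (gamma + 1)
                            - gamma * (1 - pc) * pc ** gamma * np.log(1 - pc))
    dz = w * (t * dz_pos + (1 - t) * dz_neg) / normalizer
    out._backward = lambda g: (g * dz,)
    return out


def _smooth_l1(pred: nn.Tensor, target: np.ndarray, weights: np.ndarray,
               normalizer: float, beta: float = 1.0) -> nn.Tensor:
    x = pred.data - np.asarray(target, dtype=float)
    w = np.asarray(weights, dtype=float)
    quad = np.abs(x) < beta
    loss = float((w * np.where(quad, 0.5 * x ** 2 / beta,
                               np.abs(x) - 0.5 * beta)).sum() / normalizer)
    out = nn.Tensor(loss, parents=(pred,))
    dz = w * np.where(quad, x / beta, np.sign(x)) / normalizer
    out._backward = lambda g: (g * dz,)
    return out


# ----------------------------------------------------------------- detector
@dataclass
class DetectorConfig:
    image_size: int = 64
    width: int = 6
    depth: int = 3
    head_channels: int = 18
    lr: float = 1e-4
    epochs: int = 500
    batch_size: int = 8
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    reg_loss_weight: float = 1.0   # box-regression loss multiplier
    augment: bool = True           # random horizontal/vertical flips
    seed: int = 0


class FPNDetector(nn.Module):
    """RetinaNet-style single-class detector on a 5-level pyramid."""

    def __init__(self, anchors: AnchorSet, config: DetectorConfig,
                 backbone: nn.InceptionBackbone | None = None):
        self.config = config
        self.anchors = anchors
        rng = np.random.default_rng(config.seed)
        # stride-2 stem: pyramid strides 2, 4, 8, 16, 32
        self.backbone = backbone or nn.InceptionBackbone(
            n_out=1, rng=rng, width=config.width, depth=config.depth,
            stem_stride=2)
        hc = config.head_channels
        self.laterals = [nn.Conv2d(blk.c_out, hc, 1, rng)
                         for blk in self.backbone.blocks]
        self.down4 = nn.Conv2d(hc, hc, 3, rng, stride=2)
        self.down5 = nn.Conv2d(hc, hc, 3, rng, stride=2)
        a = len(anchors.shapes)
        self.cls_head = [nn.Conv2d(hc, hc, 3, rng), nn.Conv2d(hc, a, 3, rng)]
        self.reg_head = [nn.Conv2d(hc, hc, 3, rng), nn.Conv2d(hc, 4 * a, 3, rng)]
        # bias so initial stenosis probability is low (focal-loss convention)
        self.cls_head[-1].b.data[:] = -2.0
        self.strides = [2 ** (i + 1) for i in range(config.depth + 2)]
        self._anchor_cache: dict = {}
        self.epoch_losses: list = []

    # ------------------------------------------------------------- pyramid
    def pyramid(self, x: nn.Tensor) -> list:
        taps, _ = self.backbone.forward_features(x)
        feats = [lat(t).relu() for lat, t in zip(self.laterals, taps)]
        p4 = self.down4(feats[-1]).relu()
        p5 = self.down5(p4).relu()
        return feats + [p4, p5]

    def heads(self, pyramid: list):
        """Per-level (cls_logits, reg) with anchors flattened per cell."""
        cls_out, reg_out = [], []
        for f in pyramid:
            c = self.cls_head[1](self.cls_head[0](f).relu())
            r = self.reg_head[1](self.reg_head[0](f).relu())
            n, a, h, w = c.shape
            cls_out.append(c.transpose(0, 2, 3, 1).reshape(n, h * w * a))
            reg_out.append(r.transpose(0, 2, 3, 1).reshape(n, h * w * a, 4))
        return nn.concatenate(cls_out, axis=1), nn.concatenate(reg_out, axis=1)

    # ------------------------------------------------------------- anchors
    def anchor_boxes(self, image_size: int) -> np.ndarray:
        """All anchor boxes (x0, y0, x1, y1) for a square input, fixed order
        matching the flattened head outputs."""
        if image_size in self._anchor_cache:
            return self._anchor_cache[image_size]
        all_boxes = []
        for stride, scale in zip(self.strides, self.anchors.level_scales):
            n_cells = image_size // stride
            cs = (np.arange(n_cells) + 0.5) * stride
            cx, cy = np.meshgrid(cs, cs)                  # row-major over (y, x)
            for yi in range(n_cells):
                for xi in range(n_cells):
                    for h, w in self.anchors.shapes * scale:
                        x, y = cx[yi, xi], cy[yi, xi]
                        all_boxes.append((x - w / 2, y - h / 2,
                                          x + w / 2, y + h / 2))
        boxes = np.asarray(all_boxes)
        self._anchor_cache[image_size] = boxes
        return boxes


def _iou_matrix(anchors: np.ndarray, truths: np.ndarray) -> np.ndarray:
    ax0, ay0, ax1, ay1 = anchors.T
    area_a = (ax1 - ax0) * (ay1 - ay0)
    out = np.zeros((len(anchors), len(truths)))
    for j, (tx0, ty0, tx1, ty1) in enumerate(truths):
        iw = np.clip(np.minimum(ax1, tx1) - np.maximum(ax0, tx0), 0, None)
        ih = np.clip(np.minimum(ay1, ty1) - np.maximum(ay0, ty0), 0, None)
        inter = iw * ih
        out[:, j] = inter / (area_a + (tx1 - tx0) * (ty1 - ty0) - inter)
    return out


def _encode(anchors: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """(dx, dy, dw, dh) offsets of truth boxes relative to anchors."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = (anchors[:, 0] + anchors[:, 2]) / 2
    acy = (anchors[:, 1] + anchors[:, 3]) / 2
    tw = truths[:, 2] - truths[:, 0]
    th = truths[:, 3] - truths[:, 1]
    tcx = (truths[:, 0] + truths[:, 2]) / 2
    tcy = (truths[:, 1] + truths[:, 3]) / 2
    return np.stack([(tcx - acx) / aw, (tcy - acy) / ah,
                     np.log(tw / aw), np.log(th / ah)], axis=1)


def _decode(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = (anchors[:, 0] + anchors[:, 2]) / 2
    acy = (anchors[:, 1] + anchors[:, 3]) / 2
    cx = acx + deltas[:, 0] * aw
    cy = acy + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -4, 4))
    h = ah * np.exp(np.clip(deltas[:, 3], -4, 4))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def match_anchors(anchor_boxes: np.ndarray, truth_boxes: np.ndarray,
                  pos_iou: float = 0.5, neg_iou: float = 0.4):
    """Per-anchor class target (1/0), sample weight (0 for ignored anchors),
    matched-truth index and regression targets."""
    n = len(anchor_boxes)
    cls_t = np.zeros(n)
    w = np.ones(n)
    match = np.full(n, -1, dtype=int)
    reg_t = np.zeros((n, 4))
    if len(truth_boxes):
        m = _iou_matrix(anchor_boxes, truth_boxes)
        best = m.argmax(axis=1)
        best_iou = m[np.arange(n), best]
        cls_t[best_iou >= pos_iou] = 1.0
        w[(best_iou >= neg_iou) & (best_iou < pos_iou)] = 0.0
        # the best anchor for each truth is always positive
        forced = m.argmax(axis=0)
        cls_t[forced] = 1.0
        w[forced] = 1.0
        best[forced] = np.arange(len(truth_boxes))
        pos = cls_t == 1.0
        match[pos] = best[pos]
        reg_t[pos] = _encode(anchor_boxes[pos], truth_boxes[best[pos]])
    return cls_t, w, match, reg_t


def build_and_train_fpn(images, truth_boxes, anchors: AnchorSet,
                        config: DetectorConfig | None = None,
                        backbone: nn.InceptionBackbone | None = None) -> FPNDetector:
    """Train the anchor-based detector on images with their truth boxes.

    `truth_boxes` is a list (per image) of (x0, y0, x1, y1) tuples. An
    optional pre-trained classification backbone can be supplied; otherwise
    the pyramid backbone trains from scratch with the heads.
    """
    config = config or DetectorConfig()
    det = FPNDetector(anchors, config, backbone)
    images = np.asarray(images, dtype=float)
    n = len(images)
    size = config.image_size
    if images.shape[1] != size:
        images = resize(images, (n, size, size), order=1, anti_aliasing=True)
    x = (images - 0.5)[:, None]
    ab = det.anchor_boxes(size)

    def _flip_boxes(tb, flip):
        out = []
        for (x0, y0, x1, y1) in tb:
            if flip & 1:
                x0, x1 = size - x1, size - x0
            if flip & 2:
                y0, y1 = size - y1, size - y0
            out.append((x0, y0, x1, y1))
        return out

    # anchor/truth matchings for the identity and the three flip variants
    n_var = 4 if config.augment else 1
    targets = [[match_anchors(ab, np.asarray(_flip_boxes(tb, v),
                                             dtype=float).reshape(-1, 4),
                              config.pos_iou, config.neg_iou)
                for v in range(n_var)]
               for tb in truth_boxes]
    if not any((t[0][0] == 1).any() for t in targets):
        warnings.warn("no positive anchor matches in the training set; "
                      f"anchors={len(ab)}, shapes={det.anchors.shapes.tolist()}")
    opt = nn.Adam(det.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            flips = (rng.integers(0, 4, size=len(idx)) if config.augment
                     else np.zeros(len(idx), dtype=int))
            xb = np.stack([
                x[j, :, ::-1 if f & 2 else 1, ::-1 if f & 1 else 1]
                for j, f in zip(idx, flips)])
            cls_t = np.stack([targets[j][f][0] for j, f in zip(idx, flips)])
            wgt = np.stack([targets[j][f][1] for j, f in zip(idx, flips)])
            reg_t = np.stack([targets[j][f][3] for j, f in zip(idx, flips)])
            pos = cls_t == 1.0
            n_pos = max(pos.sum(), 1.0)
            cls_logits, reg = det.heads(det.pyramid(nn.Tensor(xb)))
            loss = _focal_loss_with_logits(cls_logits, cls_t, wgt, n_pos,
                                           config.focal_gamma, config.focal_alpha)
            loss = loss + config.reg_loss_weight * _smooth_l1(
                reg, reg_t, pos[:, :, None], n_pos)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        det.epoch_losses.append(float(np.mean(losses)))
    return det


def detect_stenoses(detector: FPNDetector, image: np.ndarray,
                    score_threshold: float = 0.3, nms_iou: float = 0.5,
                    max_detections: int = 10) -> list:
    """Decode, threshold, greedily suppress and clip detector output."""
    size = detector.config.image_size
    orig = image.shape[0]
    img = image
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, anti_aliasing=True)
    x = (img - 0.5)[None, None]
    cls_logits, reg = detector.heads(detector.pyramid(nn.Tensor(x)))
    scores = 1.0 / (1.0 + np.exp(-cls_logits.data[0]))
    keep = np.where(scores >= score_threshold)[0]
    if len(keep) == 0:
        return []
    keep = keep[np.argsort(scores[keep])[::-1][:200]]
    boxes = _decode(detector.anchor_boxes(size)[keep], reg.data[0][keep])
    if orig != size:
        boxes = boxes * (orig / size)
    boxes = [clip_box(tuple(b), orig, orig) for b in boxes]
    valid = [i for i, b in enumerate(boxes) if b[2] > b[0] and b[3] > b[1]]
    boxes = [boxes[i] for i in valid]
    sc = scores[keep][valid]
    kept = nms(boxes, sc, nms_iou)[:max_detections]
    return [Detection(box=tuple(float(v) for v in boxes[i]), score=float(sc[i]))
            for i in kept]


# ------------------------------------------------------------------ scoring
def localization_report(detections_per_image, truths_per_image, mode: str,
                        nominal_size: int = 512, image_size: int | None = None) -> dict:
    """Global-sensitivity, per-stenosis sensitivity/specificity and MSE.

    A detection hits a truth when IoU exceeds the mode threshold (0.2 for cam,
    0.5 for anchor). Global-sensitivity is the fraction of images whose single
    most severe truth lesion is hit by at least one detection. Sens_s / Spec_s
    use one-to-one greedy matching by descending IoU. MSE is the mean squared
    center-to-center distance over matched pairs, scaled to the nominal
    512x512 frame (pass `image_size` when images are smaller).
    """
    thr = IOU_THRESHOLD[mode]
    n_hit_global = n_images = n_excluded = 0
    n_truth = n_det = n_matched = 0
    sq_dists = []
    scale = 1.0 if image_size is None else nominal_size / image_size
    for dets, truths in zip(detections_per_image, truths_per_image):
        truths = list(truths)
        n_det += len(dets)
        if not truths:
            n_excluded += 1
            continue
        n_images += 1
        n_truth += len(truths)
        most_severe = max(range(len(truths)),
                          key=lambda i: getattr(truths[i], "severity", 0.0))
        pairs = [(iou(d.box, t.box), i, j)
                 for i, d in enumerate(dets) for j, t in enumerate(truths)]
        if any(v > thr and j == most_severe for v, _, j in pairs):
            n_hit_global += 1
        used_d, used_t = set(), set()
        for v, i, j in sorted(pairs, key=lambda p: -p[0]):
            if v <= thr or i in used_d or j in used_t:
                continue
            used_d.add(i)
            used_t.add(j)
            n_matched += 1
            (dx, dy), (tx, ty) = box_center(dets[i].box), box_center(truths[j].box)
            sq_dists.append(((dx - tx) * scale) ** 2 + ((dy - ty) * scale) ** 2)
    return {
        "mode": mode,
        "iou_threshold": thr,
        "n_images": n_images,
        "n_images_excluded": n_excluded,
        "global_sensitivity": (n_hit_global / n_images) if n_images else float("nan"),
        "sens_s": (n_matched / n_truth) if n_truth else float("nan"),
        "spec_s": (n_matched / n_det) if n_det else float("nan"),
        "mse": float(np.mean(sq_dists)) if sq_dists else float("nan"),
    }


# ------------------------------------------------------------- dataset build
def build_detection_dataset(n_images: int, seed: int = 0, size: int = 64,
                            severity_range: tuple = (60.0, 100.0),
                            coronary: str = "RCA", clutter_lines: int = 3,
                            geometry=None, extent_range: tuple = (0.10, 0.18),
                            position_range: tuple = (0.25, 0.75)):
    """Single-lesion frames with truth boxes for detector experiments."""
    rng = np.random.default_rng(seed)
    images, lesions = [], []
    for _ in range(n_images):
        sev = float(rng.uniform(*severity_range))
        img, les, _ = generate_labeled_frame(
            coronary, [sev], seed=int(rng.integers(2 ** 31)), size=size,
            clutter_lines=clutter_lines, geometry=geometry,
            extent_range=extent_range, position_range=position_range)
        images.append(img)
        lesions.append(les)
    return np.stack(images), lesions
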