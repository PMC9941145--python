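"""Stenosis severity classification and multi-view fusion.

Per-view inception-style classifiers score candidate frames into the
screening categories — {<25%, >=25%} (2-CAT) or {<25%, 25-99%, 100%} (3-CAT).
With *redundancy training* enabled, label-free background frames (no contrast
agent) are added to the training set as one extra category, with roughly the
same number of samples as the target categories; validation sets never
contain redundancy frames, and at inference the redundancy score is dropped
and the remaining scores renormalised. Redundancy training teaches the
network that background clutter is its own class, suppressing spurious
attention on catheters, ribs and other confounders.

View-level scores are fused to the artery level, and artery scores to the
patient level, by element-wise max pooling over the per-category scores
(renormalised to sum to one): a severe finding in any single view is never
diluted by the other views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .synth import CATEGORIES, LCA, RCA, category_index, generate_labeled_frame

__all__ = ["TWO_CAT", "THREE_CAT", "ClassifierConfig", "ScoreVector",
           "ViewClassifier", "CoronaryTypeClassifier", "train_view_classifier",
           "train_coronary_classifier", "classify_coronary_type",
           "predict_image_scores", "predict_scores", "max_fuse",
           "classification_report", "to_two_cat", "build_image_dataset"]

TWO_CAT = ("<25%", ">=25%")
THREE_CAT = CATEGORIES
LEVELS = ("image", "view", "artery", "patient")


def to_two_cat(cat3_index: int) -> int:
    """Collapse a 3-CAT index to 2-CAT (<25% vs >=25%)."""
    return 0 if cat3_index == 0 else 1


@dataclass
class ClassifierConfig:
    categories: int = 2            # 2 -> 2-CAT, 3 -> 3-CAT
    redundancy: bool = False
    image_size: int = 64
    width: int = 5
    depth: int = 3
    lr: float = 1e-4
    epochs: int = 40
    batch_size: int = 64
    seed: int = 0
    pool: str = "max"              # global pooling of the class head; "max"
                                   # suits detecting a focal narrowing anywhere
    augment: bool = True           # random horizontal/vertical flips
    imagenet_init: bool = False    # no pretrained weights ship with the package

    def __post_init__(self):
        if self.categories not in (2, 3):
            raise ValueError("categories must be 2 or 3")
        if self.imagenet_init:
            warnings.warn("imagenet_init requested but no pretrained weights "
                          "are bundled; training from random init")

    @property
    def category_names(self):
        return TWO_CAT if self.categories == 2 else THREE_CAT


@dataclass
class ScoreVector:
    """Per-category scores at one prediction level; scores sum to 1."""

    scores: np.ndarray
    level: str
    categories: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("scores must be non-negative")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def label_index(self) -> int:
        # argmax with the documented tie-break: the lower-severity category
        # wins ties (categories are ordered by ascending severity)
        return int(np.argmax(self.scores))

    @property
    def label(self) -> str:
        return self.categories[self.label_index]


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class ViewClassifier:
    """Severity classifier for one view group (e.g. 'LCA LAO Cranial')."""

    def __init__(self, config: ClassifierConfig, view_group: str = ""):
        self.config = config
        self.view_group = view_group
        n_out = config.categories + (1 if config.redundancy else 0)
        self.n_target = config.categories
        rng = np.random.default_rng(config.seed)
        self.backbone = nn.InceptionBackbone(n_out=n_out, rng=rng,
                                             width=config.width,
                                             depth=config.depth,
                                             pool=config.pool)
        self.epoch_losses: list = []

    def _prep(self, images: np.ndarray) -> np.ndarray:
        from skimage.transform import resize
        s = self.config.image_size
        if images.ndim == 2:
            images = images[None]
        if images.shape[1:] != (s, s):
            images = resize(images, (images.shape[0], s, s), order=1,
                            anti_aliasing=True)
        return (images - 0.5)[:, None, :, :]

    def raw_scores(self, images: np.ndarray) -> np.ndarray:
        """Softmax over all output categories (incl. redundancy if present)."""
        x = self._prep(images)
        out = []
        for i in range(0, len(x), self.config.batch_size):
            out.append(self.backbone(nn.Tensor(x[i:i + self.config.batch_size])).data)
        return _softmax(np.concatenate(out, axis=0))


class CoronaryTypeClassifier(ViewClassifier):
    """LCA-vs-RCA image classifier (same backbone, binary output)."""

    def __init__(self, config: ClassifierConfig | None = None):
        config = config or ClassifierConfig(categories=2)
        super().__init__(config, view_group="coronary-type")
        self.trained = False


def _train_softmax(model: ViewClassifier, images: np.ndarray,
                   labels: np.ndarray, epochs: int, lr: float, seed: int):
    x = model._prep(images)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.backbone.parameters(), lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), model.config.batch_size):
            idx = order[i:i + model.config.batch_size]
            xb = x[idx]
            if model.config.augment:       # orientation-free cue: flips are free
                if rng.random() < 0.5:
                    xb = xb[:, :, ::-1, :]
                if rng.random() < 0.5:
                    xb = xb[:, :, :, ::-1]
                xb = np.ascontiguousarray(xb)
            logits = model.backbone(nn.Tensor(xb))
            loss = nn.softmax_cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.epoch_losses.append(float(np.mean(losses)))
    return model


def train_view_classifier(images, labels, config: ClassifierConfig | None = None,
                          redundancy_frames=None, view_group: str = "") -> ViewClassifier:
    """Train one per-view severity classifier.

    With ``config.redundancy`` on, `redundancy_frames` (label-free background
    frames) are added as one extra training category, sampled to roughly the
    mean target-category size. They must never appear in validation data —
    that is the caller's contract, enforced by the pipeline.
    """
    config = config or ClassifierConfig()
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=config.categories)
    for c, cnt in enumerate(counts):
        if cnt == 0:
            raise ValueError(f"empty training category {config.category_names[c]!r}")
    if config.redundancy:
        if redundancy_frames is None or len(redundancy_frames) == 0:
            raise ValueError("redundancy=True requires redundancy_frames")
        red = np.asarray(redundancy_frames, dtype=float)
        n_red = int(round(counts.mean()))
        rng = np.random.default_rng(config.seed + 7)
        idx = rng.choice(len(red), size=n_red, replace=len(red) < n_red)
        images = np.concatenate([images, red[idx]], axis=0)
        labels = np.concatenate([labels,
                                 np.full(n_red, config.categories, dtype=int)])
    model = ViewClassifier(config, view_group)
    return _train_softmax(model, images, labels, config.epochs, config.lr,
                          config.seed + 1)


def train_coronary_classifier(images, coronaries,
                              config: ClassifierConfig | None = None) -> CoronaryTypeClassifier:
    """Train the LCA/RCA coronary-type classifier (labels 0=LCA, 1=RCA)."""
    model = CoronaryTypeClassifier(config)
    labels = np.array([0 if c == LCA else 1 for c in coronaries])
    _train_softmax(model, np.asarray(images, dtype=float), labels,
                   model.config.epochs, model.config.lr, model.config.seed + 1)
    model.trained = True
    return model


def classify_coronary_type(model: CoronaryTypeClassifier, image: np.ndarray):
    """Hard LCA/RCA label with its probability."""
    if not getattr(model, "trained", False):
        raise RuntimeError("coronary-type classifier has not been trained")
    scores = model.raw_scores(image[None])[0]
    label = LCA if scores[0] >= scores[1] else RCA
    return label, float(scores.max())


def predict_scores(model: ViewClassifier, images) -> list:
    """Image-level ScoreVectors for a batch; the redundancy-class score, if
    present, is dropped and the target scores renormalised to sum to 1."""
    raw = model.raw_scores(np.asarray(images, dtype=float))
    target = raw[:, :model.n_target]
    target = target / target.sum(axis=1, keepdims=True)
    return [ScoreVector(scores=row, level="image",
                        categories=model.config.category_names,
                        provenance={"view_group": model.view_group})
            for row in target]


def predict_image_scores(model: ViewClassifier, image: np.ndarray) -> ScoreVector:
    return predict_scores(model, image[None])[0]


def max_fuse(scores, out_level: str) -> ScoreVector:
    """Element-wise max over per-category scores, renormalised to sum to 1.

    All inputs must sit one level below `out_level` and share a category
    scheme. Adding a view can only raise the raw fused score of a category —
    a severe finding anywhere is never averaged away.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("max_fuse requires at least one input score")
    if out_level not in LEVELS[1:]:
        raise ValueError(f"invalid fusion output level {out_level!r}")
    below = LEVELS[LEVELS.index(out_level) - 1]
    cats = scores[0].categories
    for s in scores:
        if s.categories != cats:
            raise ValueError("mixed category schemes in fusion input")
        if s.level != below:
            raise ValueError(f"fusion to {out_level!r} expects {below!r}-level "
                             f"inputs, got {s.level!r}")
    raw = np.max(np.stack([s.scores for s in scores]), axis=0)
    return ScoreVector(scores=raw / raw.sum(), level=out_level, categories=cats,
                       provenance={"fused_from": len(scores)})


def classification_report(truths, predictions, score_matrix=None,
                          categories: int = 2) -> dict:
    """Accuracy, sensitivity, weighted F1, Cohen's kappa and AUC.

    Sensitivity is the recall of the >=25% class in 2-CAT and the macro
    recall in 3-CAT. AUC is the >=25%-vs-<25% contrast in 2-CAT and the
    one-vs-rest macro average in 3-CAT; a single-class truth set reports AUC
    as None (undefined), never as a number.
    """
    from . import metrics as M

    truths = np.asarray(truths, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    cm = M.confusion_matrix(truths, predictions, categories)
    auc = None
    if score_matrix is not None:
        score_matrix = np.asarray(score_matrix, dtype=float)
        if categories == 2:
            auc = M.roc_auc(score_matrix[:, 1], truths)
        else:
            auc = M.macro_ovr_auc(score_matrix, truths)
    return {
        "n": int(cm.sum()),
        "confusion_matrix": cm,
        "accuracy": M.accuracy(cm),
        "sensitivity": (M.sensitivity(cm, positive=1) if categories == 2
                        else M.sensitivity(cm)),
        "weighted_f1": M.weighted_f1(cm),
        "kappa": M.cohen_kappa(cm),
        "auc": auc,
    }


# ------------------------------------------------------------- dataset build
_DEFAULT_SEVERITIES = {
    2: ([], [70.0]),                       # no lesion vs 70% narrowing
    3: ([10.0], [70.0], [100.0]),
}


def build_image_dataset(n_per_class: int, categories: int = 2, seed: int = 0,
                        size: int = 128, coronary: str = RCA,
                        severities=None, clutter_corr: float | None = None,
                        n_redundancy: int = 0, clutter_lines: int = 3,
                        geometry=None, extent_range: tuple = (0.10, 0.18),
                        position_range: tuple = (0.25, 0.75),
                        matched_redundancy: bool = False):
    """Generate a labelled single-frame dataset for classifier experiments.

    `clutter_corr` injects a bright marker blob whose presence correlates
    with the diseased classes (probability ``clutter_corr`` for class > 0,
    ``1 - clutter_corr`` for class 0); at 0.5 it is uninformative.

    Redundancy frames carry no label and are returned separately. With
    ``matched_redundancy=True`` they are the *backgrounds of the generated
    images themselves* (same seed, no contrast) — the synthetic equivalent of
    harvesting pre-contrast frames from the same videos, which is what makes
    background memorisation costly for a redundancy-trained model. Otherwise
    ``n_redundancy`` independent background frames are drawn.
    """
    from .synth import render_background

    severities = severities or _DEFAULT_SEVERITIES[categories]
    if len(severities) != categories:
        raise ValueError("need one severity list per category")
    rng = np.random.default_rng(seed)
    images, labels, redundancy = [], [], []
    for cls, sev in enumerate(severities):
        for _ in range(n_per_class):
            if clutter_corr is None:
                extra = False
            else:
                p = clutter_corr if cls > 0 else 1.0 - clutter_corr
                extra = bool(rng.random() < p)
            out = generate_labeled_frame(
                coronary, sev, seed=int(rng.integers(2 ** 31)), size=size,
                extra_clutter=extra, clutter_lines=clutter_lines,
                geometry=geometry, extent_range=extent_range,
                position_range=position_range,
                return_background=matched_redundancy)
            images.append(out[0])
            labels.append(cls)
            if matched_redundancy:
                redundancy.append(out[3])
    if not matched_redundancy:
        redundancy = [render_background(int(rng.integers(2 ** 31)), size,
                                        clutter_lines=clutter_lines,
                                        extra_clutter=bool(rng.random() < 0.5))
                      for _ in range(n_redundancy)]
    return (np.stack(images), np.asarray(labels, dtype=int),
            np.stack(redundancy) if redundancy else None)
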