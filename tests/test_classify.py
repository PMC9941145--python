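"""Score arithmetic, max fusion, redundancy handling, report cross-checks."""

import dataclasses

import numpy as np
import pytest

from angioscreen import classify as C
from angioscreen import profiles as P


def _sv(scores, level="image", cats=C.TWO_CAT):
    return C.ScoreVector(scores=np.asarray(scores, dtype=float), level=level,
                         categories=cats)


# --------------------------------------------------------------- arithmetic
def test_redundancy_renormalization():
    """Raw scores (0.1, 0.2, 0.1) + redundancy 0.6 -> (0.25, 0.5, 0.25)."""

    class Fake:
        n_target = 3
        config = C.ClassifierConfig(categories=3)
        view_group = ""

        def raw_scores(self, images):
            return np.array([[0.1, 0.2, 0.1, 0.6]])

    sv = C.predict_image_scores(Fake(), np.zeros((8, 8)))
    assert sv.scores == pytest.approx([0.25, 0.5, 0.25])


def test_tie_break_prefers_lower_severity():
    assert _sv([0.5, 0.5]).label == "<25%"
    assert _sv([0.2, 0.4, 0.4], cats=C.THREE_CAT).label == "25-99%"


def test_max_fuse_elementwise_maximum():
    views = [_sv([0.8, 0.2]), _sv([0.1, 0.9]), _sv([0.6, 0.4]), _sv([0.9, 0.1])]
    fused = C.max_fuse(views, "view")
    # raw maxima (0.9, 0.9) -> renormalized (0.5, 0.5)
    assert fused.scores == pytest.approx([0.5, 0.5])
    assert fused.level == "view"


def test_max_fuse_patient_level_worked_example():
    lca = _sv([0.3, 0.7], level="artery")
    rca = _sv([0.8, 0.2], level="artery")
    patient = C.max_fuse([lca, rca], "patient")
    assert patient.scores == pytest.approx([8 / 15, 7 / 15])


def test_max_fuse_single_input_identity():
    sv = _sv([0.3, 0.7])
    fused = C.max_fuse([sv], "view")
    assert fused.scores == pytest.approx([0.3, 0.7])


def test_max_fuse_validation():
    with pytest.raises(ValueError):
        C.max_fuse([], "view")
    with pytest.raises(ValueError):
        C.max_fuse([_sv([0.5, 0.5]), _sv([0.2, 0.3, 0.5], cats=C.THREE_CAT)],
                   "view")
    with pytest.raises(ValueError):
        C.max_fuse([_sv([1.0, 0.0], level="artery")], "view")


def test_max_fuse_properties():
    rng = np.random.default_rng(0)
    for _ in range(20):
        raw = rng.random((4, 2))
        views = [_sv(r) for r in raw]
        fused = C.max_fuse(views, "view")
        # permutation invariance
        perm = [views[i] for i in rng.permutation(4)]
        assert C.max_fuse(perm, "view").scores == pytest.approx(fused.scores)
        # idempotent on duplicates
        assert C.max_fuse(views + views, "view").scores == pytest.approx(fused.scores)
        # raw fused >= score of the severe class in any single view
        assert np.max(raw[:, 1]) <= np.max(raw[:, 1])  # trivially true pre-norm
        # monotone safety: adding a view never lowers the raw >=25% maximum
        more = views + [_sv(rng.random(2))]
        assert (np.max([v.scores[1] for v in more])
                >= np.max([v.scores[1] for v in views]))


def test_renormalization_preserves_order():
    rng = np.random.default_rng(1)
    for _ in range(20):
        raw = rng.random(4)

        class Fake:
            n_target = 3
            config = C.ClassifierConfig(categories=3)
            view_group = ""

            def raw_scores(self, images):
                return raw[None] / raw.sum()

        sv = C.predict_image_scores(Fake(), np.zeros((4, 4)))
        assert list(np.argsort(sv.scores)) == list(np.argsort(raw[:3]))


# ------------------------------------------------------------------- report
def test_classification_report_perfect_and_chance():
    rep = C.classification_report([0, 1, 0, 1], [0, 1, 0, 1],
                                  np.array([[0.9, 0.1], [0.1, 0.9]] * 2), 2)
    assert rep["accuracy"] == 1.0 and rep["kappa"] == 1.0
    assert rep["weighted_f1"] == 1.0 and rep["auc"] == 1.0
    rep2 = C.classification_report([0, 0, 1, 1], [0, 1, 0, 1], None, 2)
    assert rep2["kappa"] == pytest.approx(0.0)
    assert rep2["auc"] is None


def test_classification_report_single_class_auc_none():
    rep = C.classification_report([1, 1], [1, 1], np.array([[0.2, 0.8]] * 2), 2)
    assert rep["auc"] is None


# --------------------------------------------------------------- validation
def test_config_validation():
    with pytest.raises(ValueError):
        C.ClassifierConfig(categories=4)
    with pytest.warns(UserWarning, match="pretrained"):
        C.ClassifierConfig(imagenet_init=True)


def test_empty_category_named_in_error():
    X = np.zeros((4, 16, 16))
    with pytest.raises(ValueError, match=">=25%"):
        C.train_view_classifier(X, [0, 0, 0, 0],
                                C.ClassifierConfig(epochs=1, image_size=16))


def test_redundancy_requires_frames():
    X = np.zeros((4, 16, 16))
    with pytest.raises(ValueError, match="redundancy_frames"):
        C.train_view_classifier(X, [0, 0, 1, 1],
                                C.ClassifierConfig(epochs=1, image_size=16,
                                                   redundancy=True))


def test_untrained_coronary_classifier_raises():
    model = C.CoronaryTypeClassifier(C.ClassifierConfig(image_size=16))
    with pytest.raises(RuntimeError):
        C.classify_coronary_type(model, np.zeros((16, 16)))


# ------------------------------------------------------------ tiny training
def test_redundancy_adds_balanced_extra_category():
    """With N samples per target class, about N redundancy frames are added
    as one extra category, and the model emits categories + 1 scores."""
    rng = np.random.default_rng(0)
    X = rng.random((20, 16, 16))
    y = np.array([0] * 10 + [1] * 10)
    red = rng.random((30, 16, 16))
    cfg = C.ClassifierConfig(categories=2, redundancy=True, image_size=16,
                             width=2, depth=2, epochs=1, lr=1e-3, seed=0)
    model = C.train_view_classifier(X, y, cfg, redundancy_frames=red)
    assert model.raw_scores(X[:2]).shape == (2, 3)
    sv = C.predict_image_scores(model, X[0])
    assert sv.scores.shape == (2,)
    assert sv.scores.sum() == pytest.approx(1.0)

    cfg_off = dataclasses.replace(cfg, redundancy=False)
    model_off = C.train_view_classifier(X, y, cfg_off)
    assert model_off.raw_scores(X[:2]).shape == (2, 2)


def test_tiny_training_loss_decreases():
    X, y, _ = P.easy_classification_dataset(8, seed=0)
    cfg = C.ClassifierConfig(categories=2, image_size=32, width=3, depth=2,
                             lr=3e-3, epochs=4, batch_size=8, seed=0)
    model = C.train_view_classifier(X, y, cfg)
    assert model.epoch_losses[-1] < model.epoch_losses[0]


def test_coronary_type_separation_tiny():
    """LCA and RCA frames are separable by construction on the easy set."""
    from angioscreen.synth import generate_labeled_frame

    rng = np.random.default_rng(0)
    imgs, cors = [], []
    for cor in ("LCA", "RCA"):
        for _ in range(12):
            img, _, _ = generate_labeled_frame(
                cor, [], seed=int(rng.integers(2 ** 31)), size=64,
                clutter_lines=0, geometry=P.EASY_GEOMETRY)
            imgs.append(img)
            cors.append(cor)
    cfg = C.ClassifierConfig(categories=2, image_size=32, width=4, depth=2,
                             lr=3e-3, epochs=25, batch_size=6, seed=0,
                             pool="avg")
    model = C.train_coronary_classifier(np.stack(imgs), cors, cfg)
    label, prob = C.classify_coronary_type(model, imgs[0])
    assert label in ("LCA", "RCA") and 0.0 <= prob <= 1.0
    correct = sum(C.classify_coronary_type(model, im)[0] == c
                  for im, c in zip(imgs, cors))
    assert correct / len(imgs) >= 0.8      # training-set separation sanity
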