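"""Soft-F1 loss, BCF/ECF decoding, selection report, tiny training sanity."""

import numpy as np
import pytest

from angioscreen import frame_select as FS
from angioscreen import synth as S
from angioscreen.synth import ContrastTruth


# ------------------------------------------------------------------ soft F1
def test_soft_f1_worked_examples():
    assert FS.soft_f1_loss([0, 1, 1, 0], [0, 1, 1, 0]) == pytest.approx(0.0, abs=1e-6)
    assert FS.soft_f1_loss([0, 0, 0], [1, 1, 1]) == pytest.approx(1.0)
    # soft-F1 = 2*0.5 / (1.0 + 1.0) = 0.5 -> loss 0.5
    assert FS.soft_f1_loss([0.5, 0.5], [1, 0]) == pytest.approx(0.5, abs=1e-6)


def test_soft_f1_bounds_and_validation():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(2, 30)
        p = rng.random(n)
        t = rng.integers(0, 2, n)
        assert 0.0 <= FS.soft_f1_loss(p, t) <= 1.0
    with pytest.raises(ValueError):
        FS.soft_f1_loss([0.5, 0.5], [1, 0, 1])
    with pytest.raises(ValueError):
        FS.soft_f1_loss([1.5, 0.5], [1, 0])


def test_soft_f1_decreases_toward_truth():
    t = np.array([0, 1, 1, 0, 1])
    p = np.full(5, 0.5)
    base = FS.soft_f1_loss(p, t)
    better = np.where(t == 1, 0.8, 0.2)
    assert FS.soft_f1_loss(better, t) < base


# ------------------------------------------------------------------ decoding
def test_decode_single_run():
    pred = FS.decode_contrast([0, 0, .9, .9, .9, 0], threshold=0.5)
    assert (pred.bcf, pred.ecf) == (2, 4)
    assert not pred.flagged


def test_decode_all_below_threshold_flagged():
    pred = FS.decode_contrast(np.zeros(10))
    assert pred.flagged and pred.candidates == [] and pred.bcf is None


def test_decode_longest_run_wins():
    p = np.zeros(40)
    p[2:5] = 0.9          # run of 3
    p[10:31] = 0.9        # run of 21
    pred = FS.decode_contrast(p)
    assert (pred.bcf, pred.ecf) == (10, 30)


def test_candidates_capped_and_within_run():
    p = np.zeros(100)
    p[20:81] = 0.9
    pred = FS.decode_contrast(p, max_candidates=10)
    assert 5 <= len(pred.candidates) <= 10
    assert all(20 <= c <= 80 for c in pred.candidates)
    assert pred.candidates == sorted(pred.candidates)


def test_threshold_monotone_interval():
    """Raising the threshold never widens [bcf, ecf]."""
    rng = np.random.default_rng(1)
    for _ in range(30):
        p = rng.random(60)
        lo = FS.decode_contrast(p, threshold=0.3)
        hi = FS.decode_contrast(p, threshold=0.7)
        if hi.flagged or lo.flagged:
            continue
        assert (hi.ecf - hi.bcf) <= (lo.ecf - lo.bcf)


# -------------------------------------------------------------------- report
def _truth(bcf, ecf, t=100):
    labels = np.zeros(t, dtype=int)
    labels[bcf:ecf + 1] = 1
    return ContrastTruth(bcf=bcf, ecf=ecf, frame_labels=labels)


def _pred(bcf, ecf):
    return FS.ContrastPrediction(probabilities=np.zeros(1), bcf=bcf, ecf=ecf,
                                 candidates=[bcf])


def test_report_worked_examples():
    rep = FS.frame_selection_report([_pred(12, 60)], [_truth(10, 60)])
    assert rep["bcf_mean_error"] == 2 and rep["ecf_mean_error"] == 0
    assert rep["accept_rate"] == 1.0 and rep["error_rate"] == 0.0

    rep = FS.frame_selection_report([_pred(30, 90)], [_truth(10, 60, t=120)])
    assert rep["accept_rate"] == 0.0 and rep["error_rate"] == 1.0


def test_report_rates_against_thresholds():
    preds = [_pred(10, 60), _pred(12, 60), _pred(15, 60), _pred(22, 60)]
    truths = [_truth(9, 61), _truth(10, 60), _truth(10, 60), _truth(10, 60)]
    # per-video errors: 1, 1, 2.5, 6 -> wait: |15-10|=5,|60-60|=0 -> 2.5; |22-10|=12 -> 6
    rep = FS.frame_selection_report(preds, truths)
    assert rep["accept_rate"] == pytest.approx(3 / 4)
    assert rep["error_rate"] == pytest.approx(0.0)
    rep_max = FS.frame_selection_report(preds, truths, per_video="max")
    assert rep_max["accept_rate"] == pytest.approx(2 / 4)
    assert rep_max["error_rate"] == pytest.approx(1 / 4)


def test_report_validation_and_missing():
    with pytest.raises(ValueError):
        FS.frame_selection_report([], [])
    flagged = FS.ContrastPrediction(np.zeros(1), None, None, [], flagged=True)
    rep = FS.frame_selection_report([flagged, _pred(10, 60)],
                                    [_truth(10, 60), _truth(10, 60)])
    assert rep["n_missing"] == 1
    assert rep["error_rate"] == 0.5


def test_oracle_selector_gives_zero_error():
    """Plumbing check: decoding ground-truth labels recovers BCF/ECF exactly."""
    cfg = S.StudyConfig(size=64, frame_count_range=(36, 44))
    preds, truths = [], []
    for seed in range(4):
        st = S.generate_study(seed, cfg)
        for ct in st.contrast_truth[:2]:
            preds.append(FS.decode_contrast(ct.frame_labels.astype(float)))
            truths.append(ct)
    rep = FS.frame_selection_report(preds, truths)
    assert rep["bcf_mean_error"] == 0.0 and rep["ecf_mean_error"] == 0.0
    assert rep["accept_rate"] == 1.0


# ------------------------------------------------------------------ training
def test_config_validation():
    with pytest.raises(ValueError):
        FS.FrameSelectorConfig(time_steps=1)
    with pytest.raises(ValueError):
        FS.FrameSelectorConfig(backbone_lr=0.0)


@pytest.fixture(scope="module")
def tiny_videos():
    cfg = S.StudyConfig(size=64, frame_count_range=(36, 44))
    videos, truths = [], []
    for seed in range(6):
        st = S.generate_study(seed, cfg)
        videos.append(st.videos[4])
        truths.append(st.contrast_truth[4])
    return videos, truths


def test_training_reduces_loss_and_is_deterministic(tiny_videos):
    videos, truths = tiny_videos
    cfg = FS.FrameSelectorConfig(frame_size=32, backbone_width=3,
                                 backbone_depth=2, backbone_epochs=3,
                                 sequence_epochs=3, backbone_lr=3e-3,
                                 sequence_lr=3e-3, batch_size=32, seed=1)
    sel1 = FS.build_and_train_selector(videos, truths, cfg)
    assert sel1.backbone_losses[-1] < sel1.backbone_losses[0]
    assert sel1.sequence_losses[-1] < sel1.sequence_losses[0]
    sel2 = FS.build_and_train_selector(videos, truths, cfg)
    assert sel1.backbone_losses == sel2.backbone_losses
    assert sel1.sequence_losses == sel2.sequence_losses
    p1 = sel1.predict_proba(videos[0])
    p2 = sel2.predict_proba(videos[0])
    assert np.array_equal(p1, p2)


def test_training_validates_inputs(tiny_videos):
    videos, truths = tiny_videos
    bad = ContrastTruth(bcf=1, ecf=2, frame_labels=np.array([0, 1, 1]))
    with pytest.raises(ValueError):
        FS.build_and_train_selector([videos[0]], [bad])
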