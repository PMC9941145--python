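"""Candidate-frame selection from angiography videos.

A per-frame inception-style backbone is first pre-trained with binary
cross-entropy to tell contrast-filled from background frames; its pooled
embedding then feeds a bi-directional LSTM over fixed-length time windows,
whose per-step forward/backward states are concatenated into a one-hidden-
layer perceptron with a sigmoid output. The sequence stage is trained with a
differentiable (soft) F1 loss computed per window.

From the per-frame probabilities, the beginning and ending contrasting frames
(BCF/ECF) are decoded as the endpoints of the longest above-threshold run —
robust to isolated false positives — and 5-10 candidate frames are sampled
evenly from that interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .synth import AngioVideo, ContrastTruth

__all__ = ["FrameSelectorConfig", "ContrastPrediction", "soft_f1_loss",
           "build_and_train_selector", "predict_contrast",
           "frame_selection_report", "decode_contrast", "FrameSelector"]


@dataclass
class FrameSelectorConfig:
    frame_size: int = 32           # frames are downscaled to this before the CNN
    backbone_width: int = 4
    backbone_depth: int = 2
    time_steps: int = 32
    lstm_hidden: int = 16
    mlp_hidden: int = 16
    backbone_lr: float = 1e-4
    sequence_lr: float = 4e-5
    backbone_epochs: int = 200
    sequence_epochs: int = 100
    window_stride: int = 16
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.time_steps < 2:
            raise ValueError("time_steps must be >= 2")
        if self.backbone_lr <= 0 or self.sequence_lr <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class ContrastPrediction:
    probabilities: np.ndarray
    bcf: int | None
    ecf: int | None
    candidates: list
    flagged: bool = False          # True when no frame exceeded the threshold


def soft_f1_loss(predicted, truth, eps: float = 1e-7) -> float:
    """1 - soft-F1 where soft-F1 = 2 * sum(p*t) / (sum(p) + sum(t) + eps).

    Differentiable in the predictions; 0 for a perfect binary prediction (up
    to the stabiliser), 1 for a total miss.
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError("predicted and truth must have equal length")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("predicted values must lie in [0, 1]")
    return float(1.0 - 2.0 * (p * t).sum() / (p.sum() + t.sum() + eps))


def _soft_f1_loss_t(p: nn.Tensor, truth: np.ndarray, eps: float = 1e-7) -> nn.Tensor:
    """Batched tensor version: mean over rows of (B, T) windows."""
    t = np.asarray(truth, dtype=float)
    num = (p * t).sum(axis=1) * 2.0
    den = p.sum(axis=1) + t.sum(axis=1) + eps
    return (1.0 - num / den).mean()


class FrameSelector:
    """Trained per-frame CNN + bi-LSTM contrast-frame selector."""

    def __init__(self, config: FrameSelectorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = nn.InceptionBackbone(
            n_out=1, rng=rng, width=config.backbone_width,
            depth=config.backbone_depth)
        self.bilstm = nn.BiLSTM(self.backbone.feat_dim, config.lstm_hidden, rng)
        self.mlp = nn.MLP(2 * config.lstm_hidden, config.mlp_hidden, 1, rng)
        self.backbone_losses: list = []
        self.sequence_losses: list = []

    # ------------------------------------------------------------- features
    def _prep_frames(self, frames: np.ndarray) -> np.ndarray:
        fs = self.config.frame_size
        if frames.shape[1:] != (fs, fs):
            frames = resize(frames, (frames.shape[0], fs, fs), order=1,
                            anti_aliasing=True)
        return (frames - frames.mean()) [:, None, :, :]

    def frame_features(self, frames: np.ndarray) -> np.ndarray:
        x = self._prep_frames(frames)
        feats = []
        for i in range(0, len(x), self.config.batch_size):
            _, emb = self.backbone.forward_features(nn.Tensor(x[i:i + self.config.batch_size]))
            feats.append(emb.data)
        return np.concatenate(feats, axis=0)

    # --------------------------------------------------------------- windows
    def _windows(self, n_frames: int):
        """Start indices of time-step windows covering [0, n_frames)."""
        ts, stride = self.config.time_steps, self.config.window_stride
        if n_frames <= ts:
            return [0]
        starts = list(range(0, n_frames - ts + 1, stride))
        if starts[-1] != n_frames - ts:
            starts.append(n_frames - ts)
        return starts

    def _pad(self, arr: np.ndarray) -> np.ndarray:
        """Edge-repetition padding of short sequences up to time_steps."""
        ts = self.config.time_steps
        if len(arr) >= ts:
            return arr
        reps = [(0, ts - len(arr))] + [(0, 0)] * (arr.ndim - 1)
        return np.pad(arr, reps, mode="edge")

    # -------------------------------------------------------------- predict
    def predict_proba(self, video: AngioVideo) -> np.ndarray:
        feats = self.frame_features(video.frames)
        t = len(feats)
        ts = self.config.time_steps
        acc = np.zeros(t)
        cnt = np.zeros(t)
        padded = self._pad(feats)
        for s in self._windows(t):
            win = padded[s:s + ts][None]                    # (1, T, D)
            h = self.bilstm(nn.Tensor(win))
            p = self.mlp(h.reshape(ts, -1)).sigmoid().data[:, 0]
            end = min(s + ts, t)
            acc[s:end] += p[:end - s]
            cnt[s:end] += 1
        return acc / np.maximum(cnt, 1)


def build_and_train_selector(videos, truths, config: FrameSelectorConfig | None = None,
                             ) -> FrameSelector:
    """Two-stage training: per-frame backbone (binary cross-entropy), then the
    sequence model (soft-F1 over windows) on cached backbone embeddings."""
    config = config or FrameSelectorConfig()
    for v, ct in zip(videos, truths):
        if v.n_frames < 1:
            raise ValueError("empty video")
        if len(ct.frame_labels) != v.n_frames:
            raise ValueError("truth labels do not match video length")
    sel = FrameSelector(config)
    rng = np.random.default_rng(config.seed + 1)

    # ---- stage 1: backbone on individual frames
    x = np.concatenate([sel._prep_frames(v.frames) for v in videos], axis=0)
    y = np.concatenate([np.asarray(ct.frame_labels, dtype=float) for ct in truths])
    params = sel.backbone.parameters()
    opt = nn.Adam(params, lr=config.backbone_lr)
    n = len(x)
    for _ in range(config.backbone_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = sel.backbone(nn.Tensor(x[idx]))
            loss = nn.bce_with_logits(logits, y[idx][:, None])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        sel.backbone_losses.append(float(np.mean(losses)))

    # ---- stage 2: sequence model on cached embeddings
    seq_x, seq_y = [], []
    for v, ct in zip(videos, truths):
        feats = sel._pad(sel.frame_features(v.frames))
        labels = sel._pad(np.asarray(ct.frame_labels, dtype=float))
        for s in sel._windows(len(feats)):
            seq_x.append(feats[s:s + config.time_steps])
            seq_y.append(labels[s:s + config.time_steps])
    seq_x = np.stack(seq_x)
    seq_y = np.stack(seq_y)
    params = sel.bilstm.parameters() + sel.mlp.parameters()
    opt = nn.Adam(params, lr=config.sequence_lr)
    m, ts = seq_x.shape[0], config.time_steps
    bs = max(1, config.batch_size // 4)
    for _ in range(config.sequence_epochs):
        order = rng.permutation(m)
        losses = []
        for i in range(0, m, bs):
            idx = order[i:i + bs]
            h = sel.bilstm(nn.Tensor(seq_x[idx]))
            p = sel.mlp(h.reshape(len(idx) * ts, -1)).sigmoid().reshape(len(idx), ts)
            loss = _soft_f1_loss_t(p, seq_y[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        sel.sequence_losses.append(float(np.mean(losses)))
    return sel


# ------------------------------------------------------------------ decoding
def decode_contrast(probabilities: np.ndarray, threshold: float = 0.5,
                    max_candidates: int = 10) -> ContrastPrediction:
    """BCF/ECF = endpoints of the longest above-threshold run (earliest run on
    ties); candidates sampled evenly from [BCF, ECF], capped at
    `max_candidates`."""
    p = np.asarray(probabilities, dtype=float)
    above = p > threshold
    best_start, best_len = None, 0
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    if best_start is None:
        return ContrastPrediction(probabilities=p, bcf=None, ecf=None,
                                  candidates=[], flagged=True)
    bcf, ecf = best_start, best_start + best_len - 1
    k = min(max_candidates, best_len)
    cand = sorted(set(int(round(v)) for v in np.linspace(bcf, ecf, k)))
    return ContrastPrediction(probabilities=p, bcf=bcf, ecf=ecf,
                              candidates=cand, flagged=False)


def predict_contrast(selector: FrameSelector, video: AngioVideo,
                     threshold: float = 0.5,
                     max_candidates: int = 10) -> ContrastPrediction:
    return decode_contrast(selector.predict_proba(video), threshold,
                           max_candidates)


def frame_selection_report(predictions, truths, per_video: str = "mean") -> dict:
    """BCF/ECF errors and accept/error rates.

    Per-video error is the mean (or, with ``per_video='max'``, the max) of the
    absolute BCF and ECF differences; a video is accepted when that error is
    <= 3 frames and counted as an error case when >= 10 frames. Predictions
    with no detected run count as error cases and are excluded from the mean
    error statistics (their count is reported).
    """
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("need equal, non-empty prediction/truth lists")
    reducer = {"mean": np.mean, "max": np.max}[per_video]
    bcf_err, ecf_err, per_errs, n_missing = [], [], [], 0
    for pred, truth in zip(predictions, truths):
        if pred.bcf is None:
            n_missing += 1
            per_errs.append(np.inf)
            continue
        eb = abs(pred.bcf - truth.bcf)
        ee = abs(pred.ecf - truth.ecf)
        bcf_err.append(eb)
        ecf_err.append(ee)
        per_errs.append(float(reducer([eb, ee])))
    per_errs = np.asarray(per_errs)
    return {
        "n_videos": len(predictions),
        "n_missing": n_missing,
        "bcf_mean_error": float(np.mean(bcf_err)) if bcf_err else float("nan"),
        "bcf_sd_error": float(np.std(bcf_err)) if bcf_err else float("nan"),
        "ecf_mean_error": float(np.mean(ecf_err)) if ecf_err else float("nan"),
        "ecf_sd_error": float(np.std(ecf_err)) if ecf_err else float("nan"),
        "accept_rate": float(np.mean(per_errs <= 3)),
        "error_rate": float(np.mean(per_errs >= 10)),
    }
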