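"""End-to-end orchestration: data preparation -> candidate-frame selection ->
multi-view severity classification (with optional redundancy training) ->
stenosis localization, under patient-level stratified k-fold cross-validation.

Patients are the unit of the folds: all frames of a patient live in exactly
one validation fold, so no pixel from a validation patient is ever seen in
training. Redundancy frames are harvested from the *pre-contrast* frames of
training-fold videos only; validation sets never contain them. Studies can be
flagged ``train_excluded`` to be kept out of every training fold while still
being evaluated.

Everything is seeded; with ``deterministic=True`` (default) a config re-run
reproduces the report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify as CL
from . import frame_select as FS
from . import localize as LO
from .synth import (LCA, RCA, StudyConfig, category_index, generate_study,
                    worst_category)

__all__ = ["RunConfig", "make_folds", "run_end_to_end", "demo_config"]


@dataclass
class RunConfig:
    n_patients: int = 12
    folds: int = 4
    seed: int = 0
    study_config: StudyConfig = field(default_factory=StudyConfig)
    # stage toggles
    run_frame_selection: bool = True
    run_classification: bool = True
    run_localization: bool = True
    redundancy: bool = False
    # desk-scale knobs
    videos_per_patient_fs: int = 1     # videos per patient for selector training
    frames_per_video: int = 2          # candidate frames used per video
    selector_config: FS.FrameSelectorConfig | None = None
    classifier_config: CL.ClassifierConfig | None = None
    detector_config: LO.DetectorConfig | None = None
    deterministic: bool = True
    train_excluded: tuple = ()         # patient ids kept out of training folds
    out_dir: str | None = None

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("fold count must be >= 2")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def make_folds(patient_labels: dict, k: int, seed: int) -> list:
    """Stratified patient-level partition into k folds.

    `patient_labels` maps patient id -> label. Within each label group,
    patients are shuffled (seeded) and dealt round-robin, so per-fold class
    proportions match the global ones to within one patient.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(patient_labels) < k:
        raise ValueError(f"fewer patients ({len(patient_labels)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    groups: dict = {}
    for pid, lab in patient_labels.items():
        groups.setdefault(lab, []).append(pid)
    offset = 0
    for lab in sorted(groups):
        members = sorted(groups[lab])
        rng.shuffle(members)
        for i, pid in enumerate(members):
            folds[(offset + i) % k].append(pid)
        offset += len(members)
    return folds


def demo_config(seed: int = 0) -> RunConfig:
    """Micro-scale end-to-end demo: 8 patients, 2 folds, 64x64 frames."""
    from .profiles import EASY_GEOMETRY

    study = StudyConfig(size=64, frame_count_range=(36, 48),
                        geometry=EASY_GEOMETRY)
    return RunConfig(
        n_patients=8, folds=2, seed=seed, study_config=study,
        selector_config=FS.FrameSelectorConfig(
            frame_size=32, backbone_width=4, backbone_depth=2,
            backbone_epochs=6, sequence_epochs=16, backbone_lr=3e-3,
            sequence_lr=3e-3, batch_size=32, seed=seed),
        classifier_config=CL.ClassifierConfig(
            categories=2, image_size=64, width=5, depth=3, lr=1e-3,
            epochs=14, batch_size=16, seed=seed),
        detector_config=LO.DetectorConfig(
            image_size=64, width=4, depth=3, head_channels=12, lr=1e-3,
            epochs=8, batch_size=8, seed=seed))


# ----------------------------------------------------------------- pipeline
def _study_label2(study) -> int:
    return 0 if category_index(study.patient_label) == 0 else 1


def _artery_label2(study, coronary) -> int:
    return 0 if category_index(study.artery_labels[coronary]) == 0 else 1


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full workflow under k-fold cross-validation; returns the report.

    The report carries per-fold and mean +/- SD metrics for every enabled
    stage, integrity checks (patient leakage, redundancy containment) and
    provenance (config hash, seed).
    """
    seed = config.seed if config.deterministic else np.random.SeedSequence().entropy % (2 ** 31)
    rng = np.random.default_rng(seed)

    studies = {f"synt{config.seed * 1000 + i:05d}": None for i in range(config.n_patients)}
    studies = {}
    for i in range(config.n_patients):
        st = generate_study(seed * 1000 + i, config.study_config)
        studies[st.patient_id] = st

    labels = {pid: st.patient_label for pid, st in studies.items()}
    folds = make_folds(labels, config.folds, seed)
    report = {"provenance": {"config_hash": config.config_hash(), "seed": seed,
                             "n_patients": config.n_patients,
                             "folds": config.folds},
              "folds": [], "integrity": {}}
    leakage = False
    redundancy_in_validation = False

    for fi, val_ids in enumerate(folds):
        val_ids = set(val_ids)
        train_ids = {pid for pid in studies
                     if pid not in val_ids and pid not in set(config.train_excluded)}
        leakage |= bool(train_ids & val_ids)
        fold_rep = {"fold": fi,
                    "n_train_patients": len(train_ids),
                    "n_val_patients": len(val_ids)}
        fold_seed = seed + 101 * (fi + 1)

        # ---- stage 1: candidate frame selection
        candidates: dict = {}
        if config.run_frame_selection:
            sel_cfg = config.selector_config or FS.FrameSelectorConfig(seed=fold_seed)
            sel_cfg = dataclasses.replace(sel_cfg, seed=fold_seed)
            tr_videos, tr_truths = [], []
            for pid in sorted(train_ids):
                st = studies[pid]
                take = min(config.videos_per_patient_fs, len(st.videos))
                for vi in range(take):
                    tr_videos.append(st.videos[vi])
                    tr_truths.append(st.contrast_truth[vi])
            selector = FS.build_and_train_selector(tr_videos, tr_truths, sel_cfg)
            preds, truths = [], []
            for pid in sorted(val_ids):
                st = studies[pid]
                for vi, video in enumerate(st.videos):
                    pred = FS.predict_contrast(selector, video)
                    preds.append(pred)
                    truths.append(st.contrast_truth[vi])
                    candidates[(pid, vi)] = (pred.candidates
                                             if not pred.flagged else [])
            fold_rep["frame_selection"] = FS.frame_selection_report(preds, truths)

        def _candidate_frames(pid, vi, st):
            """Candidate frame indices: predicted when available, else truth."""
            if (pid, vi) in candidates and candidates[(pid, vi)]:
                idxs = candidates[(pid, vi)]
            else:
                ct = st.contrast_truth[vi]
                idxs = list(range(ct.bcf, ct.ecf + 1))
            step = max(1, len(idxs) // config.frames_per_video)
            return idxs[::step][:config.frames_per_video]

        # ---- stage 2: classification + fusion
        if config.run_classification:
            cls_cfg = config.classifier_config or CL.ClassifierConfig(seed=fold_seed)
            cls_cfg = dataclasses.replace(cls_cfg, seed=fold_seed,
                                          redundancy=config.redundancy)
            models = {}
            for coronary in (LCA, RCA):
                imgs, labs, red = [], [], []
                for pid in sorted(train_ids):
                    st = studies[pid]
                    lab = _artery_label2(st, coronary)
                    for vi, video in enumerate(st.videos):
                        if video.coronary != coronary:
                            continue
                        for f in _candidate_frames(pid, vi, st):
                            imgs.append(video.frames[f])
                            labs.append(lab)
                        ct = st.contrast_truth[vi]
                        pre = ct.bcf - config.study_config.ramp
                        if pre > 0:
                            red.append(video.frames[0])
                if len(set(labs)) < 2:    # degenerate draw: skip this coronary
                    models[coronary] = None
                    continue
                models[coronary] = CL.train_view_classifier(
                    np.stack(imgs), np.asarray(labs), cls_cfg,
                    redundancy_frames=np.stack(red) if red else None,
                    view_group=coronary)

            img_t, img_p, img_s = [], [], []
            lvl = {"artery": ([], [], []), "patient": ([], [], [])}
            for pid in sorted(val_ids):
                st = studies[pid]
                artery_scores = []
                for coronary in (LCA, RCA):
                    model = models[coronary]
                    if model is None:
                        continue
                    view_scores = []
                    for vi, video in enumerate(st.videos):
                        if video.coronary != coronary:
                            continue
                        fidx = _candidate_frames(pid, vi, st)
                        # validation candidates come from the contrast
                        # interval only — never redundancy frames
                        redundancy_in_validation |= any(
                            st.contrast_truth[vi].frame_labels[f] == 0
                            and not candidates.get((pid, vi))
                            for f in fidx)
                        svs = CL.predict_scores(model,
                                                video.frames[np.asarray(fidx)])
                        lab = _artery_label2(st, coronary)
                        for sv in svs:
                            img_t.append(lab)
                            img_p.append(sv.label_index)
                            img_s.append(sv.scores)
                        view_scores.append(CL.max_fuse(svs, "view"))
                    if view_scores:
                        art = CL.max_fuse(view_scores, "artery")
                        artery_scores.append(art)
                        lvl["artery"][0].append(_artery_label2(st, coronary))
                        lvl["artery"][1].append(art.label_index)
                        lvl["artery"][2].append(art.scores)
                if artery_scores:
                    pat = CL.max_fuse(artery_scores, "patient")
                    lvl["patient"][0].append(_study_label2(st))
                    lvl["patient"][1].append(pat.label_index)
                    lvl["patient"][2].append(pat.scores)
            cls_rep = {}
            if img_t:
                cls_rep["image"] = CL.classification_report(
                    img_t, img_p, np.stack(img_s), cls_cfg.categories)
            for level, (t, p, s) in lvl.items():
                if t:
                    cls_rep[level] = CL.classification_report(
                        t, p, np.stack(s), cls_cfg.categories)
            for rep in cls_rep.values():
                rep.pop("confusion_matrix", None)
            if cls_rep:
                fold_rep["classification"] = cls_rep

        # ---- stage 3: localization (anchor-based on candidate frames)
        if config.run_localization:
            det_cfg = config.detector_config or LO.DetectorConfig(seed=fold_seed)
            det_cfg = dataclasses.replace(det_cfg, seed=fold_seed)
            tr_imgs, tr_boxes = [], []
            for pid in sorted(train_ids):
                st = studies[pid]
                for vi, video in enumerate(st.videos):
                    boxes = [l.box for l in st.stenosis_truth[vi]
                             if l.severity >= 25.0]
                    if not boxes:
                        continue
                    f = _candidate_frames(pid, vi, st)[0]
                    tr_imgs.append(video.frames[f])
                    tr_boxes.append(boxes)
            flat = [b for bs in tr_boxes for b in bs]
            if len(flat) >= 2:
                k = min(7, len(flat))
                anchors = LO.cluster_anchor_shapes(flat, k=k, seed=fold_seed)
                det = LO.build_and_train_fpn(np.stack(tr_imgs), tr_boxes,
                                             anchors, det_cfg)
                dets_all, truth_all = [], []
                for pid in sorted(val_ids):
                    st = studies[pid]
                    for vi, video in enumerate(st.videos):
                        lesions = [l for l in st.stenosis_truth[vi]
                                   if l.severity >= 25.0]
                        if not lesions:
                            continue
                        f = _candidate_frames(pid, vi, st)[0]
                        dets_all.append(LO.detect_stenoses(det, video.frames[f]))
                        truth_all.append(lesions)
                fold_rep["localization"] = {"anchor": LO.localization_report(
                    dets_all, truth_all, "anchor",
                    image_size=config.study_config.size)}
        report["folds"].append(fold_rep)

    report["integrity"] = {
        "patient_leakage": leakage,
        "redundancy_frames_in_validation": redundancy_in_validation,
    }
    report["summary"] = _summarize(report["folds"])
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_report.json").write_text(
            json.dumps(_jsonable(report), indent=1))
    return report


def _summarize(fold_reps: list) -> dict:
    """Mean +/- SD across folds for every numeric leaf metric."""
    flat: dict = {}

    def walk(prefix, node):
        if isinstance(node, dict):
            for k, v in node.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(node, (int, float)) and not isinstance(node, bool):
            flat.setdefault(prefix, []).append(float(node))

    for fr in fold_reps:
        walk("", {k: v for k, v in fr.items() if k != "fold"})
    return {k: {"mean": float(np.mean(v)), "sd": float(np.std(v)),
                "n_folds": len(v)}
            for k, v in flat.items()
            if not np.any(np.isnan(v)) and not np.any(np.isinf(v))}
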