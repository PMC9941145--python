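"""Reading and writing study data, metadata, and annotations.

Studies live in a directory with a ``manifest.json`` describing each
single-view video (path, coronary, view label, frame count, fps) plus the
artery-level labels; per-video ground truth (contrast frame labels, lesion
boxes) sits in sidecar ``*.truth.json`` files. Videos are stored as 8-bit
multi-page TIFF stacks (or per-frame PNG directories) and, optionally, as
minimal multi-frame DICOM files carrying the C-arm positioner angles from
which the view label can be recovered through a documented angle-bin table.

Readers validate rather than coerce: an invalid coronary/view combination or
an unresolvable view is an explicit error naming the offending video.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .boxes import box_area, iou
from .synth import (AngioVideo, ContrastTruth, Lesion, SyntheticStudy,
                    VALID_VIEWS, VIEW_ANGLES, worst_category)

__all__ = ["MetadataError", "AnnotationError", "VideoEntry", "StudyManifest",
           "BoxAnnotation", "write_study", "read_study", "read_truth",
           "read_annotations", "write_annotations", "merge_annotations",
           "map_angles_to_view", "write_video_dicom", "read_video_dicom"]


class MetadataError(ValueError):
    """Missing or contradictory study metadata."""


class AnnotationError(ValueError):
    """Malformed annotation record."""


@dataclass
class VideoEntry:
    path: str
    coronary: str
    view: str
    frame_count: int
    fps: float
    truth: str | None = None


@dataclass
class StudyManifest:
    patient_id: str
    videos: list
    artery_labels: dict = field(default_factory=dict)
    patient_label: str | None = None
    train_excluded: bool = False

    def validate(self):
        for v in self.videos:
            if v.coronary not in VALID_VIEWS:
                raise MetadataError(f"video {v.path}: unknown coronary {v.coronary!r}")
            if v.view not in VALID_VIEWS[v.coronary]:
                raise MetadataError(
                    f"video {v.path}: view {v.view!r} is not valid for {v.coronary}")
            if v.frame_count < 1:
                raise MetadataError(f"video {v.path}: frame_count must be >= 1")


@dataclass
class BoxAnnotation:
    video: str
    frame: int
    box: tuple                 # (x_min, y_min, x_max, y_max), half-open
    category: str
    annotator: str = "reader1"


# ------------------------------------------------------------------- studies
def _to_uint8(frames: np.ndarray) -> np.ndarray:
    return np.round(np.clip(frames, 0.0, 1.0) * 255.0).astype(np.uint8)


def write_study(study: SyntheticStudy, out_dir, fmt: str = "tiff",
                dicom: bool = False) -> Path:
    """Persist a study; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for video, ct, lesions in zip(study.videos, study.contrast_truth,
                                  study.stenosis_truth):
        stem = f"{video.coronary}_{video.view.replace(' ', '_').replace('/', '-')}"
        if fmt == "tiff":
            vpath = out / f"{stem}.tif"
            tifffile.imwrite(vpath, _to_uint8(video.frames))
        elif fmt == "png":
            vdir = out / stem
            vdir.mkdir(exist_ok=True)
            for i, frame in enumerate(_to_uint8(video.frames)):
                iio.imwrite(vdir / f"frame{i:04d}.png", frame)
            vpath = vdir
        else:
            raise ValueError(f"unknown format {fmt!r}")
        tpath = out / f"{stem}.truth.json"
        tpath.write_text(json.dumps({
            "bcf": int(ct.bcf), "ecf": int(ct.ecf),
            "frame_labels": [int(x) for x in ct.frame_labels],
            "lesions": [asdict(le) for le in lesions],
        }, indent=1))
        if dicom:
            write_video_dicom(video, out / f"{stem}.dcm")
        entries.append(VideoEntry(path=vpath.name, coronary=video.coronary,
                                  view=video.view, frame_count=video.n_frames,
                                  fps=video.fps, truth=tpath.name))
    manifest = StudyManifest(patient_id=study.patient_id, videos=entries,
                             artery_labels=dict(study.artery_labels),
                             patient_label=study.patient_label)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(asdict(manifest), indent=1))
    return mpath


def _load_frames(path: Path) -> np.ndarray:
    if path.is_dir():
        files = sorted(path.glob("frame*.png"))
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.dtype == np.uint8:
        frames = frames.astype(np.float64) / 255.0
    return frames


def read_study(path) -> tuple[list, StudyManifest]:
    """Load all videos of a study; pixel values returned as floats in [0, 1]."""
    path = Path(path)
    mpath = path / "manifest.json" if path.is_dir() else path
    if not mpath.exists():
        raise FileNotFoundError(mpath)
    raw = json.loads(mpath.read_text())
    manifest = StudyManifest(
        patient_id=raw["patient_id"],
        videos=[VideoEntry(**v) for v in raw["videos"]],
        artery_labels=raw.get("artery_labels", {}),
        patient_label=raw.get("patient_label"),
        train_excluded=raw.get("train_excluded", False))
    manifest.validate()
    videos = []
    for entry in manifest.videos:
        frames = _load_frames(mpath.parent / entry.path)
        if frames.shape[0] != entry.frame_count:
            raise MetadataError(
                f"video {entry.path}: manifest says {entry.frame_count} frames, "
                f"file has {frames.shape[0]}")
        videos.append(AngioVideo(frames=frames, coronary=entry.coronary,
                                 view=entry.view,
                                 patient_id=manifest.patient_id, fps=entry.fps))
    return videos, manifest


def read_truth(study_dir, entry: VideoEntry):
    """Sidecar ground truth for one video: (ContrastTruth, [Lesion, ...])."""
    raw = json.loads((Path(study_dir) / entry.truth).read_text())
    ct = ContrastTruth(bcf=raw["bcf"], ecf=raw["ecf"],
                       frame_labels=np.asarray(raw["frame_labels"], dtype=int))
    lesions = [Lesion(severity=r["severity"], category=r["category"],
                      box=tuple(r["box"]), branch_index=r["branch_index"],
                      position=r["position"]) for r in raw["lesions"]]
    return ct, lesions


# --------------------------------------------------------------- annotations
def write_annotations(annotations, path):
    recs = [asdict(a) for a in annotations]
    Path(path).write_text(json.dumps(recs, indent=1))


def read_annotations(path, min_size: int = 35, frame_shape=None):
    """Read box annotations; returns (accepted, rejected).

    Boxes smaller than ``min_size`` on either side (default 35 px, the
    minimum annotated lesion size) or outside the frame bounds are rejected;
    the second list reports the offenders with reasons.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise AnnotationError(f"malformed annotation file {path}: {e}") from e
    accepted, rejected = [], []
    for i, rec in enumerate(raw):
        try:
            ann = BoxAnnotation(video=rec["video"], frame=int(rec["frame"]),
                                box=tuple(rec["box"]), category=rec["category"],
                                annotator=rec.get("annotator", "reader1"))
            box_area(ann.box)
        except (KeyError, TypeError, ValueError) as e:
            raise AnnotationError(f"malformed annotation record {i}: {e}") from e
        x0, y0, x1, y1 = ann.box
        if (x1 - x0) < min_size or (y1 - y0) < min_size:
            rejected.append((ann, f"box {x1-x0}x{y1-y0} below minimum "
                                  f"{min_size}x{min_size}"))
            continue
        if frame_shape is not None:
            h, w = frame_shape
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                rejected.append((ann, "box outside frame bounds"))
                continue
        accepted.append(ann)
    return accepted, rejected


def merge_annotations(annotations, iou_threshold: float = 0.5):
    """Merge multi-reader boxes on the same lesion by coordinate averaging.

    Two annotations of the same video/frame from different annotators whose
    boxes overlap with IoU > `iou_threshold` are treated as one lesion.
    """
    merged, used = [], [False] * len(annotations)
    for i, a in enumerate(annotations):
        if used[i]:
            continue
        group = [a]
        used[i] = True
        for j in range(i + 1, len(annotations)):
            b = annotations[j]
            if (not used[j] and a.video == b.video and a.frame == b.frame
                    and a.annotator != b.annotator
                    and iou(a.box, b.box) > iou_threshold):
                group.append(b)
                used[j] = True
        box = tuple(float(np.mean([g.box[k] for g in group])) for k in range(4))
        merged.append(BoxAnnotation(video=a.video, frame=a.frame, box=box,
                                    category=a.category,
                                    annotator="+".join(g.annotator for g in group)))
    return merged


# -------------------------------------------------------------------- DICOM
# Documented positioner-angle binning (degrees; primary: LAO > 0 > RAO,
# secondary: cranial > 0 > caudal):
#   LCA: |primary| >= 10 picks the LAO/RAO side, |secondary| >= 10 picks
#        cranial/caudal; anything shallower is unresolved.
#   RCA: secondary >= 10 -> "shallow LAO/RAO Cranial"; otherwise
#        primary >= 10 -> "LAO", primary <= -10 -> "straight RAO";
#        anything else is unresolved.
def map_angles_to_view(coronary: str, primary: float, secondary: float) -> str | None:
    """Map C-arm positioner angles to a view label; None when unresolved."""
    if coronary == "LCA":
        if abs(primary) < 10 or abs(secondary) < 10:
            return None
        side = "LAO" if primary > 0 else "RAO"
        tilt = "Cranial" if secondary > 0 else "Caudal"
        return f"{side} {tilt}"
    if coronary == "RCA":
        if secondary >= 10:
            return "shallow LAO/RAO Cranial"
        if primary >= 10:
            return "LAO"
        if primary <= -10:
            return "straight RAO"
        return None
    raise MetadataError(f"unknown coronary {coronary!r}")


def write_video_dicom(video: AngioVideo, path):
    """Write a minimal multi-frame secondary-capture DICOM file."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = video.patient_id
    ds.Modality = "XA"
    ds.SeriesDescription = video.coronary
    primary, secondary = VIEW_ANGLES[(video.coronary, video.view)]
    ds.PositionerPrimaryAngle = str(primary)
    ds.PositionerSecondaryAngle = str(secondary)
    ds.CineRate = int(round(video.fps))
    frames = _to_uint8(video.frames)
    ds.NumberOfFrames = frames.shape[0]
    ds.Rows, ds.Columns = frames.shape[1:]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = frames.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_video_dicom(path) -> AngioVideo:
    """Read a multi-frame DICOM video; view resolved from positioner angles.

    An unresolvable angle combination raises MetadataError (views are never
    guessed).
    """
    import pydicom

    ds = pydicom.dcmread(path)
    coronary = str(getattr(ds, "SeriesDescription", "")).strip()
    if coronary not in VALID_VIEWS:
        raise MetadataError(f"{path}: SeriesDescription does not name a coronary")
    primary = float(getattr(ds, "PositionerPrimaryAngle", 0.0))
    secondary = float(getattr(ds, "PositionerSecondaryAngle", 0.0))
    view = map_angles_to_view(coronary, primary, secondary)
    if view is None:
        raise MetadataError(
            f"{path}: positioner angles ({primary}, {secondary}) do not "
            f"resolve to a known {coronary} view")
    frames = ds.pixel_array
    if frames.ndim == 2:
        frames = frames[None]
    return AngioVideo(frames=frames.astype(np.float64) / 255.0,
                      coronary=coronary, view=view,
                      patient_id=str(getattr(ds, "PatientID", "")),
                      fps=float(getattr(ds, "CineRate", 15)))
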