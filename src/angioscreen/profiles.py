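"""Desk-scale experiment profiles shared by tests, examples and the
reproduction script.

The full-scale workflow targets 512x512 cine videos and hundreds of patients;
the profiles here define the scaled-down study conditions this package's
experiments run at on one CPU: 48-64 px frames, vessels of near-constant
caliber, long lesions, and little background clutter — the "easy" regime in
which every learned stage is expected to recover its ground truth — plus a
branching-geometry benchmark for localization. Keeping the profiles in one
place guarantees that the test suite, the examples and the reproduction
script all describe the same experiments.
"""

from __future__ import annotations

from .classify import ClassifierConfig, build_image_dataset
from .frame_select import FrameSelectorConfig
from .localize import DetectorConfig, build_detection_dataset
from .synth import GeometryParams, StudyConfig

__all__ = ["EASY_GEOMETRY", "easy_study_config", "easy_selector_config",
           "easy_classifier_config", "easy_detector_config",
           "easy_classification_dataset", "easy_redundancy_dataset",
           "easy_detection_dataset", "detection_benchmark_dataset",
           "EASY_EXTENT_RANGE", "EASY_POSITION_RANGE"]

# Single gently-curved vessel per frame: a severity-70 narrowing is then an
# unambiguous thin-segment cue — no thin side branches to mimic it, and no
# branch overlaps to hide it. 48x48 native rendering keeps training steps
# cheap while the narrowed lumen stays above one pixel.
EASY_SIZE = 48
EASY_GEOMETRY = GeometryParams(size=EASY_SIZE, radius_range=(3.0, 4.0),
                               n_side_range=(0, 0), wiggle=0.08, margin=6)
# Long mid-vessel lesions: about a third of the branch shows the narrowing.
EASY_EXTENT_RANGE = (0.30, 0.42)
EASY_POSITION_RANGE = (0.30, 0.70)


def easy_study_config(size: int = 64) -> StudyConfig:
    """Frame-selection study profile: long full-contrast plateaus."""
    return StudyConfig(size=size, frame_count_range=(40, 60), ramp=4,
                       geometry=GeometryParams(size=size))


def easy_video_set(n_videos: int, seed: int, size: int = 64):
    """Single-view contrast videos for frame-selection experiments."""
    from .synth import generate_contrast_video

    cfg = easy_study_config(size)
    pairs = [generate_contrast_video(seed * 100000 + i, cfg)
             for i in range(n_videos)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def easy_selector_config(seed: int = 0) -> FrameSelectorConfig:
    """Tiny selector sized for tens of videos on one CPU."""
    return FrameSelectorConfig(frame_size=32, backbone_width=4,
                               backbone_depth=2, lstm_hidden=16,
                               backbone_epochs=8, sequence_epochs=30,
                               backbone_lr=3e-3, sequence_lr=3e-3,
                               batch_size=32, seed=seed)


def easy_classifier_config(seed: int = 0, categories: int = 2,
                           image_size: int = EASY_SIZE, epochs: int = 40,
                           redundancy: bool = False) -> ClassifierConfig:
    return ClassifierConfig(categories=categories, redundancy=redundancy,
                            image_size=image_size, width=6, depth=3,
                            lr=1e-3, epochs=epochs, batch_size=16, seed=seed)


def easy_detector_config(seed: int = 0, epochs: int = 60) -> DetectorConfig:
    return DetectorConfig(image_size=64, width=6, depth=3, head_channels=18,
                          lr=1e-3, epochs=epochs, batch_size=8, seed=seed)


def easy_classification_dataset(n_per_class: int, seed: int,
                                clutter_corr: float | None = None,
                                n_redundancy: int = 0, clutter_lines: int = 0):
    """2-CAT dataset: no lesion vs a 70% focal narrowing."""
    return build_image_dataset(
        n_per_class, categories=2, seed=seed, size=EASY_SIZE,
        severities=([], [70.0]), clutter_corr=clutter_corr,
        n_redundancy=n_redundancy, clutter_lines=clutter_lines,
        geometry=EASY_GEOMETRY, extent_range=EASY_EXTENT_RANGE,
        position_range=EASY_POSITION_RANGE)


def easy_redundancy_dataset(n_per_class: int, seed: int, train: bool,
                            n_redundancy: int = 0):
    """Redundancy-effect dataset with a planted background shortcut.

    A bright marker blob accompanies every diseased training image and no
    healthy one (perfect label correlation), so a plainly trained classifier
    locks onto the marker instead of the vessel; held-out images invert the
    correlation, exposing that reliance. Redundancy frames carry the marker
    half the time, which makes it useless as a disease feature for a
    redundancy-trained model — the suppression mechanism under test."""
    return easy_classification_dataset(
        n_per_class, seed, clutter_corr=1.0 if train else 0.0,
        n_redundancy=n_redundancy)


def easy_detection_dataset(n_images: int, seed: int):
    """Single severe lesion on a single clean vessel (severity 60-100);
    matches the classification profile, used for the CAM map checks."""
    return build_detection_dataset(
        n_images, seed=seed, size=64, severity_range=(60.0, 100.0),
        clutter_lines=0, geometry=EASY_GEOMETRY,
        extent_range=EASY_EXTENT_RANGE, position_range=EASY_POSITION_RANGE)


def detection_benchmark_dataset(n_images: int, seed: int):
    """Localization benchmark: a severe lesion on the default branching
    geometry with catheter/rib clutter — enough scene complexity that box
    quality separates the supervised detector from the CAM route."""
    return build_detection_dataset(
        n_images, seed=seed, size=64, severity_range=(60.0, 100.0))
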