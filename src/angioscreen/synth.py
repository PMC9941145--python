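"""Seeded synthetic coronary angiography studies with full ground truth.

The generator emulates the features of cine X-ray angiograms that the
downstream stages must learn from: a branching vessel tree rendered dark on a
structured background (catheter- and rib-like clutter), contrast agent that
washes in and out over the video (so early/late frames show background only),
focal lumen narrowings whose percent-diameter reduction maps onto the
screening taxonomy (<25%, 25-99%, total occlusion), and multi-view studies —
four projection views of the left coronary artery (LCA) and three of the
right (RCA) — that share per-artery lesion severities while each view has its
own projected geometry.

Severity is encoded geometrically: the local vessel diameter at a lesion is
``base diameter x (1 - severity/100)``, matching the diameter-based grading of
quantitative coronary angiography. A total occlusion renders a visible gap
with attenuated contrast distal to it.

Everything is deterministic in the seeds; identical seeds give bit-identical
studies.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

__all__ = [
    "LCA", "RCA", "LCA_VIEWS", "RCA_VIEWS", "CATEGORIES", "VIEW_ANGLES",
    "GeometryParams", "StudyConfig", "VesselTree", "StenosisSpec", "Lesion",
    "ContrastTruth", "AngioVideo", "SyntheticStudy",
    "severity_to_category", "category_index", "worst_category",
    "generate_vessel_tree", "contrast_profile", "render_frame",
    "render_vessel_layer", "render_background", "generate_study",
    "generate_labeled_frame", "measure_lumen_width",
]

LCA = "LCA"
RCA = "RCA"
LCA_VIEWS = ("LAO Cranial", "LAO Caudal", "RAO Cranial", "RAO Caudal")
RCA_VIEWS = ("LAO", "straight RAO", "shallow LAO/RAO Cranial")
CATEGORIES = ("<25%", "25-99%", "100%")

# Representative C-arm positioner angles (primary LAO+/RAO-, secondary
# cranial+/caudal-) used when studies are exported as DICOM.
VIEW_ANGLES = {
    (LCA, "LAO Cranial"): (30.0, 25.0),
    (LCA, "LAO Caudal"): (30.0, -25.0),
    (LCA, "RAO Cranial"): (-30.0, 25.0),
    (LCA, "RAO Caudal"): (-30.0, -25.0),
    (RCA, "LAO"): (30.0, 0.0),
    (RCA, "straight RAO"): (-30.0, 0.0),
    (RCA, "shallow LAO/RAO Cranial"): (5.0, 25.0),
}

VALID_VIEWS = {LCA: LCA_VIEWS, RCA: RCA_VIEWS}


def severity_to_category(severity: float) -> str:
    """Map percent diameter reduction to the screening category."""
    if not 0.0 <= severity <= 100.0:
        raise ValueError(f"severity {severity} outside [0, 100]")
    if severity < 25.0:
        return CATEGORIES[0]
    if severity < 100.0:
        return CATEGORIES[1]
    return CATEGORIES[2]


def category_index(category: str) -> int:
    return CATEGORIES.index(category)


def worst_category(categories) -> str:
    """Highest-severity category in a collection (default: no disease)."""
    cats = list(categories)
    if not cats:
        return CATEGORIES[0]
    return CATEGORIES[max(category_index(c) for c in cats)]


# --------------------------------------------------------------------- types
@dataclass
class VesselTree:
    """Projected coronary tree: per-branch centerline polylines in pixels."""

    centerlines: list          # list of (N, 2) float arrays, (row, col)
    base_radius: list          # per-branch radius in pixels
    branch_parents: list       # parent topology index, -1 for a primary branch
    coronary: str

    def __post_init__(self):
        if any(r <= 0 for r in self.base_radius):
            raise ValueError("vessel radii must be strictly positive")

    @property
    def n_primary(self) -> int:
        return sum(1 for p in self.branch_parents if p == -1)


@dataclass
class StenosisSpec:
    """A focal narrowing on one branch."""

    branch_index: int
    position: float            # arc-length fraction in [0, 1]
    severity: float            # percent diameter reduction
    extent: float = 0.15       # arc-length fraction of the affected segment

    def __post_init__(self):
        if not 0.0 <= self.severity <= 100.0:
            raise ValueError("severity must be in [0, 100]")
        if not 0.0 <= self.position <= 1.0:
            raise ValueError("position must be in [0, 1]")

    @property
    def category(self) -> str:
        return severity_to_category(self.severity)


@dataclass
class Lesion:
    """Ground-truth record of a rendered stenosis in one video."""

    severity: float
    category: str
    box: tuple                 # (x_min, y_min, x_max, y_max), 0-based half-open
    branch_index: int
    position: float


@dataclass
class ContrastTruth:
    bcf: int
    ecf: int
    frame_labels: np.ndarray

    def __post_init__(self):
        t = len(self.frame_labels)
        if not 0 <= self.bcf <= self.ecf < t:
            raise ValueError("require 0 <= bcf <= ecf < n_frames")
        expected = np.zeros(t, dtype=int)
        expected[self.bcf:self.ecf + 1] = 1
        if not np.array_equal(np.asarray(self.frame_labels), expected):
            raise ValueError("frame_labels inconsistent with bcf/ecf")


@dataclass
class AngioVideo:
    frames: np.ndarray         # (T, H, W) float in [0, 1]
    coronary: str
    view: str
    patient_id: str
    fps: float = 15.0

    def __post_init__(self):
        if self.view not in VALID_VIEWS[self.coronary]:
            raise ValueError(f"view {self.view!r} invalid for {self.coronary}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SyntheticStudy:
    patient_id: str
    videos: list               # 7 AngioVideo (4 LCA + 3 RCA)
    contrast_truth: list       # ContrastTruth per video
    stenosis_truth: list       # list[Lesion] per video
    artery_labels: dict        # coronary -> category
    patient_label: str


# -------------------------------------------------------------------- config
@dataclass
class GeometryParams:
    size: int = 128
    margin: int = 8
    radius_range: tuple = (3.2, 4.6)       # primary-branch radius, pixels
    side_radius_factor: tuple = (0.55, 0.75)
    n_side_range: tuple = (1, 2)           # side branches per primary branch
    side_start_range: tuple = (0.25, 0.75) # arc fraction where sides originate
    lca_primary_range: tuple = (2, 3)
    wiggle: float = 0.12                   # control-point jitter, frame fraction

    def validate(self):
        if self.radius_range[0] <= 0:
            raise ValueError("geometry params would produce zero-radius vessels")
        if self.size < 32:
            raise ValueError("frame size below minimum of 32 pixels")


@dataclass
class StudyConfig:
    """Study-level generation profile.

    Defaults are the desk-scale profile: 128x128 frames, 40-80 frames per
    video at 15 fps (overridable up to the 512x512 / 60-200 nominal), with
    per-artery severity-category priors matching the artery-level class mix
    of the cohort the workflow targets.
    """

    size: int = 128
    frame_count_range: tuple = (40, 80)
    fps: float = 15.0
    ramp: int = 4                          # contrast wash-in/out, frames
    vessel_depth: float = 0.45             # peak intensity drop under contrast
    clutter_lines: int = 3                 # catheter/rib-like structures
    lca_category_probs: tuple = (0.25, 0.57, 0.18)
    rca_category_probs: tuple = (0.37, 0.51, 0.12)
    artery_severities: dict | None = None  # override: coronary -> [severity,...]
    geometry: GeometryParams = field(default_factory=GeometryParams)
    # Extra clutter blob whose presence can be tied to the label by dataset
    # builders (see classify): None here = plain background.
    extra_clutter: bool = False

    def __post_init__(self):
        self.geometry = dataclasses.replace(self.geometry, size=self.size)


# ------------------------------------------------------------------ geometry
def _smooth_polyline(control: np.ndarray, spacing: float = 0.75) -> np.ndarray:
    """Cubic-spline interpolation through control points, ~`spacing` px apart."""
    d = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(control, axis=0), axis=1))]
    d += np.arange(len(d)) * 1e-6          # strictly increasing parameter
    cs = CubicSpline(d, control, axis=0)
    n = max(int(d[-1] / spacing), 8)
    return cs(np.linspace(0.0, d[-1], n))


def _primary_branch(rng, params: GeometryParams, start, end, via=None):
    lo, hi = params.margin, params.size - params.margin
    n_ctrl = 4
    pts = np.linspace(start, end, n_ctrl)
    jitter = rng.normal(0.0, params.wiggle * params.size, size=(n_ctrl, 2))
    jitter[0] = 0
    pts = pts + jitter
    if via is not None:
        pts = np.insert(pts, n_ctrl // 2, via, axis=0)
    pts = np.clip(pts, lo, hi)
    return np.clip(_smooth_polyline(pts), lo, hi)


def _side_branch(rng, params: GeometryParams, parent_line: np.ndarray):
    lo, hi = params.margin, params.size - params.margin
    s0, s1 = params.side_start_range
    idx = rng.integers(int(s0 * len(parent_line)),
                       max(int(s1 * len(parent_line)), int(s0 * len(parent_line)) + 1))
    start = parent_line[idx]
    tangent = parent_line[min(idx + 3, len(parent_line) - 1)] - parent_line[max(idx - 3, 0)]
    norm = np.linalg.norm(tangent)
    if norm < 1e-6:                       # degenerate (clipped) parent segment
        theta = rng.uniform(0, 2 * np.pi)
        tangent = np.array([np.sin(theta), np.cos(theta)])
    else:
        tangent = tangent / norm
    normal = np.array([-tangent[1], tangent[0]]) * rng.choice([-1.0, 1.0])
    length = rng.uniform(0.2, 0.4) * params.size
    direction = 0.55 * tangent + 0.85 * normal
    direction /= np.linalg.norm(direction)
    end = np.clip(start + direction * length, lo, hi)
    mid = np.clip(start + direction * length * 0.5
                  + rng.normal(0, 0.03 * params.size, 2), lo, hi)
    return np.clip(_smooth_polyline(np.array([start, mid, end])), lo, hi)


def generate_vessel_tree(coronary: str, rng_seed: int,
                         geometry_params: GeometryParams | None = None) -> VesselTree:
    """Generate one projected coronary tree.

    RCA trees have exactly one primary branch (plus side branches); LCA trees
    have at least two, and the second primary is routed through a point on the
    first so that the projection always contains a branch overlap — mirroring
    the greater morphological complexity of the left coronary tree.
    """
    if coronary not in (LCA, RCA):
        raise ValueError(f"invalid coronary {coronary!r}")
    params = geometry_params or GeometryParams()
    params.validate()
    rng = np.random.default_rng(rng_seed)
    size, m = params.size, params.margin

    centerlines, radii, parents = [], [], []
    origin = np.array([rng.uniform(m, 0.25 * size), rng.uniform(0.35, 0.65) * size])

    if coronary == RCA:
        end = np.array([rng.uniform(0.75, 1.0) * size - m,
                        rng.uniform(0.2, 0.8) * size])
        line = _primary_branch(rng, params, origin, end)
        centerlines.append(line)
        radii.append(rng.uniform(*params.radius_range))
        parents.append(-1)
    else:
        n_primary = int(rng.integers(params.lca_primary_range[0],
                                     params.lca_primary_range[1] + 1))
        first_end = np.array([rng.uniform(0.7, 0.95) * size,
                              rng.uniform(0.55, 0.9) * size])
        first = _primary_branch(rng, params, origin, first_end)
        centerlines.append(first)
        radii.append(rng.uniform(*params.radius_range))
        parents.append(-1)
        # route the second primary through the first's middle third: the two
        # main branches interlap in projection, as LAD/LCX do
        via = first[rng.integers(len(first) // 3, 2 * len(first) // 3)]
        second_end = np.array([rng.uniform(0.55, 0.9) * size,
                               rng.uniform(0.1, 0.4) * size])
        second = _primary_branch(rng, params, origin, second_end, via=via)
        centerlines.append(second)
        radii.append(rng.uniform(*params.radius_range))
        parents.append(-1)
        for _ in range(n_primary - 2):
            extra_end = np.array([rng.uniform(0.5, 0.95) * size,
                                  rng.uniform(m, size - m)])
            centerlines.append(_primary_branch(rng, params, origin, extra_end))
            radii.append(rng.uniform(*params.radius_range) * 0.85)
            parents.append(-1)

    n_primary = len(centerlines)
    for p in range(n_primary):
        for _ in range(int(rng.integers(params.n_side_range[0],
                                        params.n_side_range[1] + 1))):
            centerlines.append(_side_branch(rng, params, centerlines[p]))
            radii.append(radii[p] * rng.uniform(*params.side_radius_factor))
            parents.append(p)

    return VesselTree(centerlines=centerlines, base_radius=radii,
                      branch_parents=parents, coronary=coronary)


# ------------------------------------------------------------------ contrast
def contrast_profile(frame_index: int, bcf: int, ecf: int, ramp: int) -> float:
    """Contrast opacity of a frame: linear wash-in over `ramp` frames before
    the beginning contrasting frame (BCF), full opacity on [BCF, ECF], linear
    wash-out after the ending contrasting frame (ECF)."""
    if bcf > ecf:
        raise ValueError("bcf must not exceed ecf")
    if ramp < 0:
        raise ValueError("ramp must be >= 0")
    f = frame_index
    if bcf <= f <= ecf:
        return 1.0
    if f < bcf:
        if ramp == 0 or f <= bcf - ramp:
            return 0.0
        return (f - (bcf - ramp)) / ramp
    if ramp == 0 or f >= ecf + ramp:
        return 0.0
    return ((ecf + ramp) - f) / ramp


# ----------------------------------------------------------------- rendering
def _arc_lengths(line: np.ndarray) -> np.ndarray:
    d = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(line, axis=0), axis=1))]
    return d / max(d[-1], 1e-9)


def _width_factor(s: np.ndarray, stenoses_on_branch) -> np.ndarray:
    """Multiplicative diameter factor along arc length for a branch."""
    factor = np.ones_like(s)
    for st in stenoses_on_branch:
        half = st.extent / 2.0
        in_seg = np.abs(s - st.position) <= half
        # cosine profile: full reduction at the lesion center, none at edges
        depth = st.severity / 100.0
        local = 1.0 - depth * 0.5 * (1.0 + np.cos(np.pi * (s - st.position) / half))
        factor = np.where(in_seg, np.minimum(factor, local), factor)
    return factor


def _stamp(mask: np.ndarray, points: np.ndarray, radii: np.ndarray,
           weights: np.ndarray):
    """Stamp soft disks of per-point radius/weight into `mask` (max-combine)."""
    size = mask.shape[0]
    rmax = int(np.ceil(radii.max())) + 1 if len(radii) else 0
    for (r, c), rad, wgt in zip(points, radii, weights):
        if rad <= 0 or wgt <= 0:
            continue
        r0, r1 = max(int(r - rad - 1), 0), min(int(r + rad + 2), size)
        c0, c1 = max(int(c - rad - 1), 0), min(int(c + rad + 2), size)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d = np.sqrt((yy - r) ** 2 + (xx - c) ** 2)
        disk = np.clip(rad - d + 0.5, 0.0, 1.0) * wgt
        np.maximum(mask[r0:r1, c0:c1], disk, out=mask[r0:r1, c0:c1])
    del rmax


def render_vessel_layer(tree: VesselTree, stenoses=(), size: int = 128,
                        attenuate: bool = False) -> np.ndarray:
    """Render the contrast-filled tree as an intensity-drop layer in [0, 1].

    The local vessel width at a stenosis is ``base width x (1 - severity/100)``;
    a 100% lesion leaves a gap and attenuates the contrast distal to it.

    With ``attenuate=True`` the layer intensity additionally scales with the
    local lumen diameter (Beer-Lambert: absorption follows the contrast-agent
    path length through the lumen), so narrowed segments render fainter as
    well as thinner. Frames are composed from the attenuated layer; the plain
    layer is the geometric mask used for width measurements.
    """
    mask = np.zeros((size, size))
    for b, line in enumerate(tree.centerlines):
        s = _arc_lengths(line)
        on_branch = [st for st in stenoses if st.branch_index == b]
        factor = _width_factor(s, on_branch)
        radii = tree.base_radius[b] * factor
        weights = np.ones_like(s)
        if attenuate:
            weights = np.clip(factor, 0.0, 1.0)
        for st in on_branch:
            if st.severity >= 100.0:
                # distal run-off: contrast barely fills beyond an occlusion
                weights = np.where(s > st.position, weights * 0.25, weights)
        _stamp(mask, line, radii, weights)
    return mask


def render_background(background_seed: int, size: int = 128,
                      clutter_lines: int = 3, extra_clutter: bool = False) -> np.ndarray:
    """Structured background: low-frequency field plus catheter/rib-like
    linear structures. Deterministic in the seed."""
    rng = np.random.default_rng(background_seed)
    base = 0.55 + 0.10 * _normalized_field(rng, size)
    img = base
    for _ in range(clutter_lines):
        img = img - _clutter_line(rng, size)
    if extra_clutter:
        img = img - _clutter_blob(rng, size)
    return _quantize(np.clip(img, 0.0, 1.0))


def _normalized_field(rng, size):
    f = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 10.0)
    return (f - f.mean()) / (f.std() + 1e-9)


def _clutter_line(rng, size):
    """A dark elongated structure (catheter or rib edge surrogate)."""
    layer = np.zeros((size, size))
    start = rng.uniform(0, size, 2)
    angle = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.5, 1.2) * size
    direction = np.array([np.sin(angle), np.cos(angle)])
    mid = start + direction * length * 0.5 + rng.normal(0, 0.05 * size, 2)
    end = start + direction * length
    line = _smooth_polyline(np.clip(np.array([start, mid, end]), 0, size - 1))
    rad = rng.uniform(1.0, 2.2)
    depth = rng.uniform(0.08, 0.16)
    _stamp(layer, line, np.full(len(line), rad), np.full(len(line), depth))
    return layer


def _clutter_blob(rng, size):
    """A small bright marker spot (confounder for redundancy experiments).

    Salient by design: nothing else in a frame is brighter than the
    background, so the marker is a trivially learnable shortcut feature when
    its presence correlates with the class labels. (Returned negated: the
    background subtracts clutter layers, so negative values brighten.)
    """
    center = rng.uniform(0.15 * size, 0.85 * size, 2)
    rad = rng.uniform(0.06, 0.09) * size
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.sqrt((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
    return -0.40 * np.clip(1.0 - d / rad, 0.0, 1.0)


def render_frame(tree: VesselTree, stenoses, opacity: float, background_seed: int,
                 size: int = 128, vessel_depth: float = 0.45,
                 clutter_lines: int = 3, extra_clutter: bool = False) -> np.ndarray:
    """Compose one grayscale frame: background minus contrast-weighted vessels.

    At ``opacity == 0`` the result is pixel-identical to the pure background
    render for the same seed (a redundancy frame in the screening sense).
    """
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must be in [0, 1]")
    if size < 32:
        raise ValueError("frame size below minimum of 32 pixels")
    bg = render_background(background_seed, size, clutter_lines, extra_clutter)
    if opacity == 0.0:
        return bg
    layer = render_vessel_layer(tree, stenoses, size)
    return _quantize(np.clip(bg - vessel_depth * opacity * layer, 0.0, 1.0))


def _quantize(img: np.ndarray) -> np.ndarray:
    """Quantize to 8-bit levels so written stacks round-trip bit-exactly."""
    return np.round(img * 255.0) / 255.0


# -------------------------------------------------------------- ground truth
def lesion_box(tree: VesselTree, st: StenosisSpec, size: int,
               pad: float = 2.0) -> tuple:
    """Tight half-open pixel box around the rendered extent of a stenosis."""
    line = tree.centerlines[st.branch_index]
    s = _arc_lengths(line)
    half = st.extent / 2.0
    seg = line[np.abs(s - st.position) <= half]
    if len(seg) == 0:
        seg = line[[np.argmin(np.abs(s - st.position))]]
    r = tree.base_radius[st.branch_index] + pad
    y0, x0 = np.floor(seg.min(axis=0) - r)
    y1, x1 = np.ceil(seg.max(axis=0) + r) + 1
    return (int(max(x0, 0)), int(max(y0, 0)),
            int(min(x1, size)), int(min(y1, size)))


def measure_lumen_width(mask: np.ndarray, point, tangent,
                        threshold: float = 0.5, max_steps: int = 40) -> float:
    """Vessel width at `point`, measured perpendicular to `tangent` on a
    rendered layer: steps along the normal until the layer falls below
    `threshold` on both sides."""
    normal = np.array([-tangent[1], tangent[0]], dtype=float)
    normal /= np.linalg.norm(normal) + 1e-9
    width = 0.0
    for sign in (1.0, -1.0):
        for k in np.arange(0.0, max_steps, 0.25):
            p = np.asarray(point) + sign * k * normal
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
                break
            if mask[r, c] < threshold:
                break
        width += k
    return width


# --------------------------------------------------------------------- study
def _severities_for_category(rng, cat_idx: int):
    if cat_idx == 0:
        return [] if rng.random() < 0.5 else [float(rng.uniform(5, 20))]
    if cat_idx == 1:
        sev = [float(rng.uniform(40, 90))]
        if rng.random() < 0.4:
            sev.append(float(rng.uniform(30, sev[0])))
        return sev
    sev = [100.0]
    if rng.random() < 0.3:
        sev.append(float(rng.uniform(30, 80)))
    return sev


def generate_contrast_video(seed: int, difficulty: StudyConfig | None = None,
                            coronary: str = RCA, view: str | None = None,
                            patient_id: str | None = None):
    """One single-view video with its contrast truth (no full study).

    The cheap unit for frame-selection experiments; uses the same contrast
    kinetics and rendering as ``generate_study``.
    """
    cfg = difficulty or StudyConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    view = view or VALID_VIEWS[coronary][0]
    tree = generate_vessel_tree(coronary, int(rng.integers(2 ** 31)), cfg.geometry)
    severities = cfg.artery_severities.get(coronary, []) if cfg.artery_severities else []
    stenoses = [StenosisSpec(0, float(rng.uniform(0.25, 0.75)), float(s))
                for s in severities]
    bg_seed = int(rng.integers(2 ** 31))
    t = int(rng.integers(cfg.frame_count_range[0], cfg.frame_count_range[1] + 1))
    bcf = int(rng.integers(max(cfg.ramp, 4), max(t // 3, cfg.ramp + 5)))
    ecf = int(rng.integers(int(2 * t / 3), t - 2))
    labels = np.zeros(t, dtype=int)
    labels[bcf:ecf + 1] = 1
    bg = render_background(bg_seed, cfg.size, cfg.clutter_lines, cfg.extra_clutter)
    layer = render_vessel_layer(tree, stenoses, cfg.size)
    frames = np.empty((t, cfg.size, cfg.size))
    for f in range(t):
        op = contrast_profile(f, bcf, ecf, cfg.ramp)
        frames[f] = bg if op == 0.0 else _quantize(
            np.clip(bg - cfg.vessel_depth * op * layer, 0.0, 1.0))
    video = AngioVideo(frames=frames, coronary=coronary, view=view,
                       patient_id=patient_id or f"synt{seed:05d}", fps=cfg.fps)
    return video, ContrastTruth(bcf=bcf, ecf=ecf, frame_labels=labels)


def generate_study(patient_seed: int, difficulty: StudyConfig | None = None) -> SyntheticStudy:
    """Generate one multi-view synthetic patient study.

    Seven videos (4 LCA views, 3 RCA views); lesion severities are drawn once
    per artery and rendered consistently in every view of that artery, each
    view with its own projected geometry. The artery label is the worst lesion
    category on that artery; the patient label is the worst artery label.
    """
    cfg = difficulty or StudyConfig()
    ss = np.random.SeedSequence(patient_seed)
    rng = np.random.default_rng(ss)
    patient_id = f"synt{patient_seed:05d}"

    artery_severities, artery_labels = {}, {}
    for coronary, probs in ((LCA, cfg.lca_category_probs), (RCA, cfg.rca_category_probs)):
        if cfg.artery_severities is not None:
            sev = [float(s) for s in cfg.artery_severities.get(coronary, [])]
        else:
            cat = int(rng.choice(3, p=np.asarray(probs) / np.sum(probs)))
            sev = _severities_for_category(rng, cat)
        artery_severities[coronary] = sev
        artery_labels[coronary] = worst_category(severity_to_category(s) for s in sev)
    patient_label = worst_category(artery_labels.values())

    videos, contrast_truths, stenosis_truths = [], [], []
    for coronary in (LCA, RCA):
        # lesion placement (branch/arc position) is shared across the artery's
        # views; 0 is always a primary-branch index in every view's tree
        placements = [
            StenosisSpec(branch_index=0,
                         position=float(rng.uniform(0.25, 0.75)),
                         severity=s,
                         extent=float(rng.uniform(0.10, 0.18)))
            for s in artery_severities[coronary]
        ]
        for view in VALID_VIEWS[coronary]:
            tree_seed = int(rng.integers(2 ** 31))
            bg_seed = int(rng.integers(2 ** 31))
            tree = generate_vessel_tree(coronary, tree_seed, cfg.geometry)
            t = int(rng.integers(cfg.frame_count_range[0],
                                 cfg.frame_count_range[1] + 1))
            bcf = int(rng.integers(max(cfg.ramp, 4), max(t // 3, cfg.ramp + 5)))
            ecf = int(rng.integers(int(2 * t / 3), t - 2))
            labels = np.zeros(t, dtype=int)
            labels[bcf:ecf + 1] = 1

            bg = render_background(bg_seed, cfg.size, cfg.clutter_lines,
                                   cfg.extra_clutter)
            layer = render_vessel_layer(tree, placements, cfg.size)
            frames = np.empty((t, cfg.size, cfg.size))
            for f in range(t):
                op = contrast_profile(f, bcf, ecf, cfg.ramp)
                frames[f] = bg if op == 0.0 else _quantize(
                    np.clip(bg - cfg.vessel_depth * op * layer, 0.0, 1.0))

            videos.append(AngioVideo(frames=frames, coronary=coronary,
                                     view=view, patient_id=patient_id,
                                     fps=cfg.fps))
            contrast_truths.append(ContrastTruth(bcf=bcf, ecf=ecf,
                                                 frame_labels=labels))
            stenosis_truths.append([
                Lesion(severity=st.severity, category=st.category,
                       box=lesion_box(tree, st, cfg.size),
                       branch_index=st.branch_index, position=st.position)
                for st in placements
            ])

    return SyntheticStudy(patient_id=patient_id, videos=videos,
                          contrast_truth=contrast_truths,
                          stenosis_truth=stenosis_truths,
                          artery_labels=artery_labels,
                          patient_label=patient_label)


def generate_labeled_frame(coronary: str, severities, seed: int, size: int = 128,
                           clutter_lines: int = 3, extra_clutter: bool = False,
                           geometry: GeometryParams | None = None,
                           extent_range: tuple = (0.10, 0.18),
                           position_range: tuple = (0.25, 0.75),
                           return_background: bool = False):
    """One full-contrast frame with its lesions — the unit the classifiers and
    detectors train on. Returns (image, lesions, category).

    With ``return_background=True`` the frame's own background-only render
    (its redundancy frame: same seed, no contrast agent) is appended to the
    returned tuple.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    geo = dataclasses.replace(geometry or GeometryParams(), size=size)
    tree = generate_vessel_tree(coronary, int(rng.integers(2 ** 31)), geo)
    stenoses = [
        StenosisSpec(branch_index=0,
                     position=float(rng.uniform(*position_range)),
                     severity=float(s), extent=float(rng.uniform(*extent_range)))
        for s in severities
    ]
    bg_seed = int(rng.integers(2 ** 31))
    img = render_frame(tree, stenoses, 1.0, bg_seed, size,
                       clutter_lines=clutter_lines, extra_clutter=extra_clutter,
                       vessel_depth=0.45)
    lesions = [Lesion(severity=st.severity, category=st.category,
                      box=lesion_box(tree, st, size),
                      branch_index=st.branch_index, position=st.position)
               for st in stenoses]
    label = worst_category(le.category for le in lesions)
    if return_background:
        bg = render_background(bg_seed, size, clutter_lines, extra_clutter)
        return img, lesions, label, bg
    return img, lesions, label
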