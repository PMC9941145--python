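"""Synthetic angiogram generator: topology, contrast kinetics, severity
encoding and determinism."""

import numpy as np
import pytest

from angioscreen import synth as S


@pytest.fixture(scope="module")
def clean_geometry():
    """Single-branch-friendly geometry for width measurements."""
    return S.GeometryParams(size=128, radius_range=(5.0, 5.0),
                            n_side_range=(0, 0))


# ------------------------------------------------------------------ topology
def test_rca_has_exactly_one_primary_branch():
    tree = S.generate_vessel_tree("RCA", 1)
    assert tree.n_primary == 1
    assert len(tree.centerlines) > 1          # side branches exist


def test_lca_has_at_least_two_primary_branches():
    tree = S.generate_vessel_tree("LCA", 1)
    assert tree.n_primary >= 2


def test_lca_primaries_overlap_in_projection():
    """The two main LCA branches interlap in the projected view."""
    for seed in range(5):
        tree = S.generate_vessel_tree("LCA", seed)
        a, b = tree.centerlines[0], tree.centerlines[1]
        # skip b's first third: both primaries trivially share the ostium
        tail = b[len(b) // 3:]
        d = np.min(np.linalg.norm(a[:, None, :] - tail[None], axis=2))
        assert d < 2.0


def test_children_start_on_parent_centerline():
    tree = S.generate_vessel_tree("LCA", 3)
    for child, parent in enumerate(tree.branch_parents):
        if parent == -1:
            continue
        start = tree.centerlines[child][0]
        dist = np.min(np.linalg.norm(tree.centerlines[parent] - start, axis=1))
        assert dist < 1.5


def test_seeded_tree_determinism():
    a = S.generate_vessel_tree("RCA", 7)
    b = S.generate_vessel_tree("RCA", 7)
    for la, lb in zip(a.centerlines, b.centerlines):
        assert np.array_equal(la, lb)


def test_tree_fits_inside_margin():
    params = S.GeometryParams(size=96, margin=6)
    tree = S.generate_vessel_tree("LCA", 11, params)
    for line in tree.centerlines:
        assert line.min() >= 6 - 1e-9 and line.max() <= 90 + 1e-9


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        S.generate_vessel_tree("LAD", 0)
    with pytest.raises(ValueError):
        S.generate_vessel_tree("RCA", 0, S.GeometryParams(radius_range=(0.0, 2.0)))
    with pytest.raises(ValueError):
        S.VesselTree([np.zeros((4, 2))], [0.0], [-1], "RCA")


# ------------------------------------------------------------------ contrast
def test_contrast_profile_shape():
    assert S.contrast_profile(0, 20, 60, 3) == 0.0
    assert S.contrast_profile(40, 20, 60, 3) == 1.0
    assert S.contrast_profile(19, 20, 60, 3) == pytest.approx(2.0 / 3.0)
    assert S.contrast_profile(62, 20, 60, 3) == pytest.approx(1.0 / 3.0)
    with pytest.raises(ValueError):
        S.contrast_profile(0, 10, 5, 3)


def test_contrast_profile_monotone_on_ramps():
    vals_in = [S.contrast_profile(f, 20, 60, 5) for f in range(14, 21)]
    assert all(b >= a for a, b in zip(vals_in, vals_in[1:]))
    vals_out = [S.contrast_profile(f, 20, 60, 5) for f in range(60, 67)]
    assert all(b <= a for a, b in zip(vals_out, vals_out[1:]))


# ----------------------------------------------------------------- rendering
def test_zero_opacity_frame_is_pure_background():
    tree = S.generate_vessel_tree("RCA", 2)
    frame = S.render_frame(tree, [], 0.0, background_seed=5, size=128)
    bg = S.render_background(5, 128)
    assert np.array_equal(frame, bg)


def _center_width(tree, stenoses, severity_probe=0.5, size=128):
    mask = S.render_vessel_layer(tree, stenoses, size)
    line = tree.centerlines[0]
    s = S._arc_lengths(line)
    i = int(np.argmin(np.abs(s - severity_probe)))
    tang = line[min(i + 3, len(line) - 1)] - line[max(i - 3, 0)]
    return S.measure_lumen_width(mask, line[i], tang)


def test_severity_encoded_as_diameter_reduction(clean_geometry):
    tree = S.generate_vessel_tree("RCA", 3, clean_geometry)
    healthy = _center_width(tree, [])
    assert healthy == pytest.approx(10.0, abs=1.0)
    st50 = S.StenosisSpec(0, 0.5, 50.0, extent=0.2)
    assert _center_width(tree, [st50]) == pytest.approx(5.0, abs=1.0)


def test_total_occlusion_renders_a_gap(clean_geometry):
    tree = S.generate_vessel_tree("RCA", 3, clean_geometry)
    st = S.StenosisSpec(0, 0.5, 100.0, extent=0.2)
    assert _center_width(tree, [st]) == 0.0


def test_lumen_width_monotone_in_severity(clean_geometry):
    tree = S.generate_vessel_tree("RCA", 4, clean_geometry)
    widths = [_center_width(tree, [S.StenosisSpec(0, 0.5, sev, extent=0.2)])
              for sev in (0.0, 25.0, 50.0, 75.0, 100.0)]
    assert all(b <= a for a, b in zip(widths, widths[1:]))


def test_render_frame_validation():
    tree = S.generate_vessel_tree("RCA", 1)
    with pytest.raises(ValueError):
        S.render_frame(tree, [], 1.5, 0)
    with pytest.raises(ValueError):
        S.render_frame(tree, [], 1.0, 0, size=16)


# -------------------------------------------------------------------- study
@pytest.fixture(scope="module")
def small_study():
    return S.generate_study(3, S.StudyConfig(size=64, frame_count_range=(36, 44)))


def test_study_has_seven_views(small_study):
    views = [(v.coronary, v.view) for v in small_study.videos]
    assert len(views) == 7 and len(set(views)) == 7
    assert sum(1 for c, _ in views if c == "LCA") == 4


def test_study_determinism():
    cfg = S.StudyConfig(size=64, frame_count_range=(36, 40))
    a, b = S.generate_study(5, cfg), S.generate_study(5, cfg)
    for va, vb in zip(a.videos, b.videos):
        assert np.array_equal(va.frames, vb.frames)
    assert a.artery_labels == b.artery_labels


def test_label_consistency_over_random_seeds():
    """Artery label = worst lesion; patient label = worst artery."""
    cfg = S.StudyConfig(size=64, frame_count_range=(36, 40))
    for seed in range(0, 100, 10):   # 10 studies stand in for the full sweep
        st = S.generate_study(seed, cfg)
        per_artery = {"LCA": [], "RCA": []}
        for video, lesions in zip(st.videos, st.stenosis_truth):
            per_artery[video.coronary].extend(l.category for l in lesions)
        for coronary, cats in per_artery.items():
            # each view repeats the artery's lesions; the worst matches
            assert S.worst_category(cats) == st.artery_labels[coronary]
        assert st.patient_label == S.worst_category(st.artery_labels.values())


def test_category_boundaries():
    assert S.severity_to_category(0.0) == "<25%"
    assert S.severity_to_category(24.9) == "<25%"
    assert S.severity_to_category(25.0) == "25-99%"
    assert S.severity_to_category(80.0) == "25-99%"
    assert S.severity_to_category(100.0) == "100%"
    with pytest.raises(ValueError):
        S.severity_to_category(101.0)


def test_forced_severity_labels():
    cfg = S.StudyConfig(size=64, frame_count_range=(36, 40),
                        artery_severities={"LCA": [], "RCA": []})
    st = S.generate_study(3, cfg)
    assert st.artery_labels == {"LCA": "<25%", "RCA": "<25%"}
    assert st.patient_label == "<25%"
    cfg2 = S.StudyConfig(size=64, frame_count_range=(36, 40),
                         artery_severities={"LCA": [], "RCA": [80.0]})
    st2 = S.generate_study(3, cfg2)
    assert st2.artery_labels["RCA"] == "25-99%"
    assert st2.patient_label == "25-99%"


def test_contrast_conservation(small_study):
    """Frames outside the wash-in/out window equal the background render."""
    for video, ct in zip(small_study.videos, small_study.contrast_truth):
        ramp = 4
        lo, hi = ct.bcf - ramp, ct.ecf + ramp
        outside = [f for f in range(video.n_frames) if f <= lo or f >= hi]
        if len(outside) < 2:
            continue
        ref = video.frames[outside[0]]
        for f in outside[1:]:
            assert np.array_equal(video.frames[f], ref)


def test_contrast_truth_invariants(small_study):
    for ct in small_study.contrast_truth:
        t = len(ct.frame_labels)
        assert 0 <= ct.bcf <= ct.ecf < t
        expected = np.zeros(t, dtype=int)
        expected[ct.bcf:ct.ecf + 1] = 1
        assert np.array_equal(ct.frame_labels, expected)


def test_lesion_boxes_inside_frame(small_study):
    size = 64
    for lesions in small_study.stenosis_truth:
        for l in lesions:
            x0, y0, x1, y1 = l.box
            assert 0 <= x0 < x1 <= size and 0 <= y0 < y1 <= size
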