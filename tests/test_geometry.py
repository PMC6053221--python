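"""Geometry: resampling, exact distances, classification, coverage, gaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

import synmorph as sm
from synmorph.geometry import GLIAL_FACING, _closed_resample


def _polyline_strategy():
    # coordinates on a 0.001 nm grid, as a pixel-based tracing export would
    # produce; avoids degenerate sub-resolution segments
    coord = st.floats(-200, 200, allow_nan=False, allow_infinity=False).map(
        lambda v: round(v, 3)
    )
    point = st.tuples(coord, coord)
    return st.lists(point, min_size=2, max_size=8).filter(
        lambda pts: len({p for p in pts}) >= 2
    )


# ---------------------------------------------------------------- resampling


def test_straight_segment_resample_count():
    t = sm.Trace(np.array([[0.0, 0.0], [10.0, 0.0]]))
    pts = sm.resample_trace(t, 1.0)
    assert len(pts) == 11
    np.testing.assert_allclose(pts[:, 0], np.arange(11.0))


def test_closed_square_resample_conserves_perimeter():
    sq = sm.Trace(
        np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]]), closed=True
    )
    pts = sm.resample_trace(sq, 1.0)
    gaps = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    assert abs(gaps.sum() - 400.0) <= 1.0
    assert gaps.max() <= 1.0 + 1e-9


@settings(max_examples=50, derandomize=True, deadline=None)
@given(_polyline_strategy(), st.floats(0.5, 5.0))
def test_resample_arc_length_matches_exact(points, step):
    t = sm.Trace(np.array(points, dtype=float))
    pts = sm.resample_trace(t, step)
    gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    assert abs(gaps.sum() - t.length) <= step
    assert gaps.max() <= step + 1e-9


def test_degenerate_trace_raises():
    with pytest.raises(ValueError):
        sm.Trace(np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]]))


# ------------------------------------------------------------ point-to-trace


def test_distance_zero_at_vertex_and_perpendicular_offset():
    t = sm.Trace(np.array([[0.0, 0.0], [100.0, 0.0]]))
    assert sm.point_to_trace_distance([0.0, 0.0], t) == 0.0
    assert sm.point_to_trace_distance([50.0, 25.0], t) == pytest.approx(25.0)
    # nearest point on the segment interior, not a vertex
    assert sm.point_to_trace_distance([50.0, -7.0], t) == pytest.approx(7.0)


def test_v_shape_concave_vertex_matches_dense_resampling():
    v = sm.Trace(np.array([[-50.0, 50.0], [0.0, 0.0], [50.0, 50.0]]))
    p = np.array([0.0, 30.0])
    dense = sm.resample_trace(v, 0.01)
    oracle = np.min(np.linalg.norm(dense - p, axis=1))
    assert sm.point_to_trace_distance(p, v) == pytest.approx(oracle, abs=0.01)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(_polyline_strategy(), st.tuples(st.floats(-250, 250), st.floats(-250, 250)))
def test_random_polyline_distance_matches_dense_resampling(points, p):
    t = sm.Trace(np.array(points, dtype=float))
    dense = sm.resample_trace(t, 0.01)
    oracle = cKDTree(dense).query(np.asarray(p))[0]
    assert sm.point_to_trace_distance(p, t) == pytest.approx(oracle, abs=0.01)


# ------------------------------------------------------------ classification


def test_no_traces_gives_all_other(square_terminal, params):
    bare = sm.TerminalAnnotation(
        terminal_id="bare",
        condition="unstimulated",
        perimeter=square_terminal.perimeter,
        vesicles=square_terminal.vesicles,
    )
    seg = sm.classify_membrane(bare, params)
    assert seg.active_zone_length == 0.0
    assert seg.glial_facing_length == 0.0
    assert sm.glial_coverage_fraction(seg) == 0.0


def test_square_terminal_compartments(square_terminal, params):
    seg = sm.classify_membrane(square_terminal, params)
    # PSD spans x in [150, 250] at 20 nm offset; tau 30 extends each end by
    # sqrt(30^2 - 20^2) ~ 22.4 nm
    expected_az = 100 + 2 * np.sqrt(30**2 - 20**2)
    assert seg.active_zone_length == pytest.approx(expected_az, abs=3.0)
    expected_gl = 200 + 2 * np.sqrt(30**2 - 6**2)
    assert seg.glial_facing_length == pytest.approx(expected_gl, abs=3.0)
    assert len(seg.compartment_regions(sm.ACTIVE_ZONE)) == 1
    assert len(seg.compartment_regions(sm.GLIAL_FACING)) == 1


def test_fully_apposed_perimeter_has_coverage_one(params):
    sq = sm.Trace(
        np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]]), closed=True
    )
    ring = sm.Trace(
        np.array([[-6.0, -6.0], [106.0, -6.0], [106.0, 106.0], [-6.0, 106.0]]),
        closed=True,
    )
    ann = sm.TerminalAnnotation(
        terminal_id="wrapped", condition="US", perimeter=sq, glial=[ring]
    )
    seg = sm.classify_membrane(ann, params)
    assert sm.glial_coverage_fraction(seg) == 1.0


def test_generator_truth_az_extent_recovered(params):
    cfg = sm.SyntheticConfig(n_terminals=3, seed=21, vesicle_count_mean=10)
    anns, truths = sm.generate_condition(cfg)
    slack = 2 * params.resample_step_nm + 2 * params.tau_az_nm
    for ann, truth in zip(anns, truths):
        seg = sm.classify_membrane(ann, params)
        assert seg.active_zone_length == pytest.approx(truth.az_length_nm, abs=slack)


def test_generator_glial_region_count_recovered(params):
    cfg = sm.SyntheticConfig(
        n_terminals=6, seed=9, vesicle_count_mean=10,
        glial_region_counts=(3,), glial_region_probs=(1.0,),
    )
    anns, truths = sm.generate_condition(cfg)
    for ann, truth in zip(anns, truths):
        seg = sm.classify_membrane(ann, params)
        assert len(seg.compartment_regions(GLIAL_FACING)) == 3


def test_explicit_compartments_bypass_classifier(square_terminal, params):
    square_terminal.compartments = {
        "active_zone": [[200.0, 320.0]],
        "glial_facing": [[1500.0, 1700.0]],  # wraps past L = 1600
    }
    seg = sm.classify_membrane(square_terminal, params)
    assert seg.active_zone_length == pytest.approx(120.0, abs=2.0)
    assert seg.glial_facing_length == pytest.approx(200.0, abs=2.0)


# ------------------------------------------------------- vesicle distances


def test_vesicle_distance_contracts(square_terminal, params):
    seg = sm.classify_membrane(square_terminal, params)
    table = sm.vesicle_distances(square_terminal, seg)
    # vesicle (200, 40): 40 nm above the bottom (active-zone) edge
    assert table.d_active_zone[0] == pytest.approx(40.0, abs=0.1)
    assert table.d_membrane[0] == pytest.approx(40.0, abs=1e-9)
    # d to compartments always >= d to whole membrane
    assert (table.d_active_zone >= table.d_membrane - 1e-9).all()
    assert (table.d_glial >= table.d_membrane - 1e-9).all()


def test_vesicle_on_active_zone_sample_has_zero_distance(square_terminal, params):
    seg = sm.classify_membrane(square_terminal, params)
    az = seg.compartment_samples(sm.ACTIVE_ZONE)
    square_terminal.vesicles = az[:1].copy()
    table = sm.vesicle_distances(square_terminal, seg)
    assert table.d_active_zone[0] == 0.0


def test_empty_compartment_distance_is_undefined(params):
    sq = sm.Trace(
        np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]]), closed=True
    )
    ann = sm.TerminalAnnotation(
        terminal_id="noaz", condition="US", perimeter=sq,
        vesicles=np.array([[50.0, 50.0]]),
    )
    seg = sm.classify_membrane(ann, params)
    table = sm.vesicle_distances(ann, seg)
    assert np.isnan(table.d_active_zone[0]) and np.isnan(table.d_glial[0])


def test_compartment_distance_matches_brute_force(rng, params):
    cfg = sm.SyntheticConfig(n_terminals=1, seed=33, vesicle_count_mean=50)
    anns, _ = sm.generate_condition(cfg)
    ann = anns[0]
    seg = sm.classify_membrane(ann, params)
    table = sm.vesicle_distances(ann, seg)
    az = seg.compartment_samples(sm.ACTIVE_ZONE)
    for i in range(len(ann.vesicles)):
        brute = np.min(np.linalg.norm(az - ann.vesicles[i], axis=1))
        assert table.d_active_zone[i] == pytest.approx(brute, abs=1e-9)


# --------------------------------------------------------------- invariants


def test_compartment_lengths_partition_perimeter(params):
    cfg = sm.SyntheticConfig(n_terminals=4, seed=2, vesicle_count_mean=10)
    anns, _ = sm.generate_condition(cfg)
    for ann in anns:
        seg = sm.classify_membrane(ann, params)
        total = seg.active_zone_length + seg.glial_facing_length + seg.other_length
        assert total == pytest.approx(seg.perimeter_length_nm, abs=1e-6)


def test_rigid_motion_leaves_metrics_unchanged(params):
    cfg = sm.SyntheticConfig(n_terminals=1, seed=17, vesicle_count_mean=60)
    anns, _ = sm.generate_condition(cfg)
    ann = anns[0]
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = ann.transformed(rot, [123.4, -56.7])

    seg0 = sm.classify_membrane(ann, params)
    seg1 = sm.classify_membrane(moved, params)
    assert seg1.perimeter_length_nm == pytest.approx(seg0.perimeter_length_nm, rel=1e-6)
    assert seg1.active_zone_length == pytest.approx(seg0.active_zone_length, rel=1e-6)
    assert sm.glial_coverage_fraction(seg1) == pytest.approx(
        sm.glial_coverage_fraction(seg0), rel=1e-6
    )
    d0 = sm.vesicle_distances(ann, seg0)
    d1 = sm.vesicle_distances(moved, seg1)
    np.testing.assert_allclose(d1.d_membrane, d0.d_membrane, rtol=1e-6, atol=1e-6)
    np.testing.assert_allclose(d1.d_active_zone, d0.d_active_zone, rtol=1e-6, atol=1e-4)
    g0 = [g.midpoint_gap_nm for g in sm.midpoint_gap_distances(ann, seg0)]
    g1 = [g.midpoint_gap_nm for g in sm.midpoint_gap_distances(moved, seg1)]
    np.testing.assert_allclose(g1, g0, rtol=1e-6, atol=1e-6)


def test_step_refinement_converges(params):
    cfg = sm.SyntheticConfig(n_terminals=2, seed=4, vesicle_count_mean=80)
    anns, _ = sm.generate_condition(cfg)
    for ann in anns:
        coarse = sm.classify_membrane(
            ann, sm.ClassificationParams(resample_step_nm=2.0)
        )
        fine = sm.classify_membrane(
            ann, sm.ClassificationParams(resample_step_nm=0.5)
        )
        dc = sm.vesicle_distances(ann, coarse).d_active_zone
        df = sm.vesicle_distances(ann, fine).d_active_zone
        assert np.nanmax(np.abs(dc - df)) < 1.0


# ------------------------------------------------------------- midpoint gap


def test_parallel_apposition_gap_is_offset(square_terminal, params):
    seg = sm.classify_membrane(square_terminal, params)
    gaps = sm.midpoint_gap_distances(square_terminal, seg)
    assert len(gaps) == 1
    assert gaps[0].midpoint_gap_nm == pytest.approx(6.0, abs=1e-6)


def test_touching_glial_trace_gives_zero_gap(params):
    sq = sm.Trace(
        np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]]), closed=True
    )
    touching = sm.Trace(np.array([[20.0, 100.0], [80.0, 100.0]]))
    ann = sm.TerminalAnnotation(
        terminal_id="touch", condition="US", perimeter=sq, glial=[touching]
    )
    seg = sm.classify_membrane(ann, params)
    gaps = sm.midpoint_gap_distances(ann, seg)
    assert len(gaps) == 1
    assert gaps[0].midpoint_gap_nm == pytest.approx(0.0, abs=1e-9)


def test_no_glial_regions_gives_empty_sequence(params):
    sq = sm.Trace(
        np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]]), closed=True
    )
    ann = sm.TerminalAnnotation(terminal_id="none", condition="US", perimeter=sq)
    seg = sm.classify_membrane(ann, params)
    assert sm.midpoint_gap_distances(ann, seg) == []


def test_curved_apposition_matches_dense_oracle(params):
    cfg = sm.SyntheticConfig(n_terminals=1, seed=12, vesicle_count_mean=5)
    anns, _ = sm.generate_condition(cfg)
    ann = anns[0]
    seg = sm.classify_membrane(ann, params)
    for rec in sm.midpoint_gap_distances(ann, seg):
        region = seg.compartment_regions(GLIAL_FACING)[rec.region_index]
        mid = seg.samples[region.sample_indices[len(region.sample_indices) // 2]]
        oracle = min(
            cKDTree(sm.resample_trace(t, 0.01)).query(mid)[0] for t in ann.glial
        )
        assert rec.midpoint_gap_nm == pytest.approx(oracle, abs=0.1)
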