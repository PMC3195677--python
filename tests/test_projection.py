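"""Planar areas, the bone-loss ratio, and their discretization properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trabl
from trabl.errors import UndefinedRatioError
from trabl.grid import build_grid
from trabl.projection import (cell_areas, evaluate, masked_area,
                              project_to_plane, trabl_ratio)
from trabl.raycast import DeviationMap
from trabl.regions import assign_regions


@pytest.fixture(scope="module")
def dense(request):
    get = request.getfixturevalue("preset_cache")
    _, _, config, _ = get("identity")
    frame = trabl.frame_from_case(None, config)[0]
    grid = build_grid(frame, 400, 400)
    return grid, project_to_plane(grid)


def test_total_area_converges_to_disk(dense):
    grid, planar = dense
    full = np.ones(grid.shape, dtype=bool)
    area = masked_area(planar, full)
    assert area == pytest.approx(np.pi * np.pi**2, rel=0.01)  # disk radius pi


def test_masked_area_empty_and_half_disk(dense):
    grid, planar = dense
    assert masked_area(planar, np.zeros(grid.shape, dtype=bool)) == 0.0
    half = np.broadcast_to(grid.phi[:, None] <= np.pi / 2, grid.shape)
    area = masked_area(planar, half)
    assert area == pytest.approx(np.pi * (np.pi / 2) ** 2, rel=0.01)


def test_all_corner_membership_is_conservative(dense):
    grid, planar = dense
    half = np.broadcast_to(grid.phi[:, None] <= np.pi / 2, grid.shape)
    frac = masked_area(planar, half, membership="fractional")
    strict = masked_area(planar, half, membership="all_corners")
    assert strict <= frac
    assert strict == pytest.approx(np.pi * (np.pi / 2) ** 2, rel=0.02)


@given(a_def=st.floats(0, 1e4), a_rec=st.floats(1e-6, 1e4))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_ratio_bounds(a_def, a_rec):
    r = trabl_ratio(a_def, a_rec)
    assert r <= 100.0
    if a_def <= a_rec:
        assert 0.0 <= r <= 100.0


def test_ratio_worked_values():
    assert trabl_ratio(100.0, 100.0) == 0.0
    assert trabl_ratio(0.0, 100.0) == 100.0
    assert trabl_ratio(75.0, 100.0) == 25.0
    with pytest.raises(UndefinedRatioError):
        trabl_ratio(1.0, 0.0)


def test_mask_monotonicity(dense):
    grid, planar = dense
    rng = np.random.default_rng(1)
    mask = rng.random(grid.shape) < 0.4
    bigger = mask | (rng.random(grid.shape) < 0.2)
    assert masked_area(planar, bigger) >= masked_area(planar, mask)


def test_region_areas_partition_global(pipeline_cache):
    result, _, _ = pipeline_cache("wedge25")
    assert sum(r.A_rec for r in result.per_region.values()) == pytest.approx(
        result.A_rec, abs=1e-6)
    assert sum(r.A_def for r in result.per_region.values()) == pytest.approx(
        result.A_def, abs=1e-6)


def test_wedge_family_monotone(preset_cache):
    """Widening the uncontained wedge never decreases the global ratio."""
    from trabl.phantom import DefectOp, PhantomSpec, make_phantom

    ratios = []
    for width_deg in (45, 90, 135, 180):
        lo = np.pi / 4
        spec = PhantomSpec(defects=(DefectOp("theta_wedge", {
            "theta_min": lo, "theta_max": lo + np.deg2rad(width_deg)}),))
        d, r, config, _ = make_phantom(spec)
        res, _ = trabl.run_case_objects(d, r, config)
        ratios.append(res.ratio)
    assert all(b >= a - 1e-9 for a, b in zip(ratios, ratios[1:]))
    # and roughly proportional to the angular fraction removed
    assert ratios[1] == pytest.approx(25.0, abs=2.0)
    assert ratios[3] == pytest.approx(50.0, abs=2.0)


def test_grid_refinement_is_cauchy(preset_cache):
    d, r, config, _ = preset_cache("wedge25")
    vals = []
    for n in (100, 200, 400):
        res, _ = trabl.run_case_objects(d, r, config, n_phi=n, n_theta=n)
        vals.append(res.ratio)
    assert abs(vals[1] - vals[0]) < 1.0
    assert abs(vals[2] - vals[1]) < 1.0


def test_overgrowth_yields_negative_ratio_with_warning(pipeline_cache):
    _, state, _ = pipeline_cache("identity")
    dev = state["deviation"]
    # synthetic: deficient bone seen on more rays than the reconstruction
    hit_def = dev.hit_rec.copy()
    extra = ~dev.hit_rec
    hit_def |= extra
    distance = np.where(hit_def & dev.hit_rec, 0.0, np.inf)
    fake = DeviationMap(t_rec=dev.t_rec, t_def=dev.t_def, hit_rec=dev.hit_rec,
                        hit_def=hit_def, distance=distance)
    labels = assign_regions(state["grid"])
    res = evaluate(fake, state["planar"], labels)
    assert res.ratio < 0.0
    assert any("exceeds reconstructed" in w for w in res.metadata["warnings"])


def test_region_without_reconstructed_hits_not_assessable(pipeline_cache):
    _, state, _ = pipeline_cache("identity")
    dev = state["deviation"]
    labels = assign_regions(state["grid"])
    # blank out the medial cap of the reconstructed hits, including the
    # corner ring of the outermost medial cells
    grid = state["grid"]
    dphi = grid.phi[1] - grid.phi[0]
    med = np.broadcast_to((grid.phi <= np.pi / 6 + 2 * dphi)[:, None], grid.shape)
    fake = DeviationMap(t_rec=dev.t_rec, t_def=dev.t_def,
                        hit_rec=dev.hit_rec & ~med, hit_def=dev.hit_def & ~med,
                        distance=np.where(med, np.inf, dev.distance))
    res = evaluate(fake, state["planar"], labels)
    assert res.per_region["Med"].ratio is None
    assert res.per_region["Inf"].ratio == 0.0


def test_spherical_metric_option(pipeline_cache):
    result, state, _ = pipeline_cache("identity")
    labels = assign_regions(state["grid"])
    res = evaluate(state["deviation"], state["planar"], labels,
                   metric="spherical", phi=state["grid"].phi)
    # hemispherical cavity: spherical hit area approaches 2*pi*r_u^2
    assert res.A_rec == pytest.approx(2 * np.pi, rel=0.02)
    assert res.ratio == 0.0


def test_cell_areas_shapes(dense):
    grid, planar = dense
    areas = cell_areas(planar)
    assert areas.shape == (399, 400)
    assert np.all(areas >= 0)
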