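"""Phantom assembly, point location, ray tracing and region masses."""

import math

import numpy as np
import pytest

import mammomc as mm
from mammomc.geometry import (
    Box, DPrism, GeometryConfig, Region, build_assembly, locate, trace,
    region_mass, WORLD_ID,
)


def test_default_layers_are_ordered_by_density(default_assembly):
    rho = [default_assembly.region(i).material.density for i in (3, 4, 5)]
    assert rho == [0.955, 0.982, 1.010]
    assert rho == sorted(rho)  # least dense layer on top


def test_default_build_has_seven_regions(default_assembly):
    assert len(default_assembly.regions) == 7
    roles = {r.role for r in default_assembly.regions}
    assert roles == {"layer1", "layer2", "layer3", "skin",
                     "plate_top", "plate_bottom", "body"}


def test_zero_skin_thickness_requires_explicit_flag():
    with pytest.raises(ValueError, match="skin"):
        build_assembly(GeometryConfig(skin_thickness=0.0))
    asm = build_assembly(GeometryConfig(include_skin=False))
    assert all(r.role != "skin" for r in asm.regions)


def test_nonpositive_layer_thickness_is_rejected():
    with pytest.raises(ValueError, match="thickness"):
        build_assembly(GeometryConfig(layer_thicknesses=(1.0, -0.5, 1.0)))


def test_unknown_material_is_rejected():
    with pytest.raises(ValueError, match="nosuch"):
        build_assembly(GeometryConfig(layer_materials=("GF25", "nosuch", "GF75")))


# -- locate ----------------------------------------------------------------

def test_locate_interior_points(default_assembly):
    # centroid-ish interior point of layer2 (z in [-1.65-1.5, -1.65])
    assert locate(default_assembly, (0.0, 4.0, -2.4)) == 4
    assert locate(default_assembly, (0.0, 4.0, 100.0)) == WORLD_ID


def test_locate_rejects_non_finite_points(default_assembly):
    with pytest.raises(ValueError):
        locate(default_assembly, (np.nan, 0.0, 0.0))


def test_locate_agrees_with_brute_force_containment(default_assembly, rng):
    pts = np.column_stack([
        rng.uniform(-16, 16, 10_000),
        rng.uniform(-16, 9, 10_000),
        rng.uniform(-21, 2, 10_000),
    ])
    ids = default_assembly.locate_many(pts)
    contains = np.stack([r.contains(pts) for r in default_assembly.regions])
    # regions are pairwise disjoint: at most one contains each point
    assert contains.sum(axis=0).max() <= 1
    expected = np.full(pts.shape[0], WORLD_ID, dtype=int)
    for row, r in enumerate(default_assembly.regions):
        expected[contains[row]] = r.id
    assert np.array_equal(ids, expected)


def test_no_overlap_for_many_random_points(default_assembly, rng):
    pts = np.column_stack([
        rng.uniform(-20, 20, 100_000),
        rng.uniform(-20, 12, 100_000),
        rng.uniform(-25, 5, 100_000),
    ])
    counts = sum(r.contains(pts).astype(int) for r in default_assembly.regions)
    assert counts.max() <= 1


# -- trace -----------------------------------------------------------------

def test_trace_through_slab_thickness(default_assembly):
    # from inside layer1 straight down: boundary to layer2 at known distance
    start = np.array([0.0, 4.0, -0.5])
    d, nxt = trace(default_assembly, start, (0.0, 0.0, -1.0))
    assert nxt == 4
    assert d == pytest.approx(1.65 - 0.5, abs=1e-9)


def test_trace_parallel_ray_is_bounded(default_assembly):
    # horizontal ray inside layer2 must exit via lateral faces, not run forever
    d, nxt = trace(default_assembly, (0.0, 4.0, -2.4), (1.0, 0.0, 0.0))
    assert np.isfinite(d)
    assert nxt in (7, WORLD_ID)


def test_central_ray_traverses_expected_region_sequence(default_assembly):
    pos = np.array(default_assembly.source_position, dtype=float)
    direction = np.array([0.0, 0.0, -1.0])
    seq = []
    current = locate(default_assembly, pos)
    for _ in range(20):
        d, nxt = trace(default_assembly, pos, direction)
        if not np.isfinite(d):
            break
        pos = pos + (d + 1e-9) * direction
        seq.append(nxt)
        current = nxt
    roles = [default_assembly.region(i).role for i in seq if i != WORLD_ID]
    assert roles == ["plate_top", "skin", "layer1", "layer2", "layer3",
                     "skin", "plate_bottom"]


def _march_boundary(assembly, p, d, coarse=0.05, tol=1e-10, tmax=40.0):
    """Independent boundary finder: marching (finer than the thinnest
    region) plus bisection refinement."""
    r0 = assembly.locate_many(p[None, :])[0]
    t = 0.0
    while t < tmax:
        t_next = t + coarse
        r = assembly.locate_many((p + t_next * d)[None, :])[0]
        if r != r0:
            lo, hi = t, t_next
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if assembly.locate_many((p + mid * d)[None, :])[0] != r0:
                    hi = mid
                else:
                    lo = mid
            return hi
        t = t_next
    return math.inf


def test_trace_matches_marching_oracle_on_random_rays(default_assembly, rng):
    n = 300  # rays; marching is slow, tracing is exact
    starts = np.column_stack([
        rng.uniform(-9, 9, n), rng.uniform(-2, 9, n), rng.uniform(-6, 1, n)])
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    checked = 0
    for p, d in zip(starts, dirs):
        expected = _march_boundary(default_assembly, p, d)
        got, _ = trace(default_assembly, p, d)
        if math.isinf(expected) or math.isinf(got):
            continue  # escaping rays: no boundary to compare
        assert got == pytest.approx(expected, abs=1e-6)
        checked += 1
    assert checked > n // 2


def test_chord_segments_sum_to_total_chord_length(default_assembly):
    # walk a vertical chord through the assembly; segments must add up
    z_top, z_bot = 5.0, -8.0
    pos = np.array([1.0, 3.0, z_top])
    direction = np.array([0.0, 0.0, -1.0])
    total = 0.0
    while pos[2] > z_bot:
        d, _ = trace(default_assembly, pos, direction)
        if not np.isfinite(d):
            total += pos[2] - z_bot  # unbounded world tail of the chord
            break
        step = min(d + 1e-9, pos[2] - z_bot)
        total += step
        pos = pos + step * direction
    assert total == pytest.approx(z_top - z_bot, abs=1e-6)


# -- masses ----------------------------------------------------------------

def test_region_mass_is_density_times_volume(materials):
    r = Region(1, "cube", "layer1", materials["GF25"],
               Box((0, 0, 0), (1, 1, 1)))
    asm = mm.PhantomAssembly([r], (0, 0, 10), (-1, 1, 0, 1), 1.0)
    assert region_mass(asm, 1) == pytest.approx(0.955)
    with pytest.raises(ValueError, match="world"):
        region_mass(asm, WORLD_ID)


def test_doubling_layer_thickness_doubles_its_mass():
    a1 = build_assembly(GeometryConfig(layer_thicknesses=(1.5, 1.5, 1.5)))
    a2 = build_assembly(GeometryConfig(layer_thicknesses=(3.0, 1.5, 1.5)))
    assert region_mass(a2, 3) == pytest.approx(2 * region_mass(a1, 3))


def test_breast_volumes_match_voxel_integration_oracle(default_assembly, rng):
    # Monte Carlo volume of each breast region vs the analytic volume
    n = 400_000
    lo = np.array([-8.2, -0.1, -5.2])
    hi = np.array([8.2, 8.2, 0.1])
    pts = lo + rng.random((n, 3)) * (hi - lo)
    box_vol = np.prod(hi - lo)
    for rid in (3, 4, 5, 7):
        r = default_assembly.region(rid)
        frac = r.contains(pts).mean()
        sigma = box_vol * math.sqrt(frac * (1 - frac) / n)
        assert frac * box_vol == pytest.approx(r.volume, abs=3.5 * sigma)


def test_dprism_volume_formula():
    p = DPrism(2.0, -1.0, 0.0)
    assert p.volume == pytest.approx(0.5 * math.pi * 4.0)
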