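"""Radial plane resampling: geometry, interpolation, context planes."""

import numpy as np
import pytest

from trusseg.radial_geometry import (
    RadialGeometry,
    extract_context,
    extract_plane,
    extract_stack,
    plane_count,
    plane_point_to_world,
)
from trusseg.volume_io import Volume3D


def radial_volume(fn, shape=(48, 48, 24), spacing=1.0):
    """Volume whose intensity depends only on (radius from the z axis
    through the centre, z)."""
    ax = [np.arange(n) * spacing for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    cx, cy = (shape[0] - 1) / 2 * spacing, (shape[1] - 1) / 2 * spacing
    r = np.hypot(X - cx, Y - cy)
    return Volume3D(fn(r, Z), spacing=(spacing,) * 3)


@pytest.mark.parametrize("interval,expected", [(10.0, 18), (90.0, 2),
                                               (180.0, 1), (5.0, 36)])
def test_plane_count(interval, expected):
    assert plane_count(interval) == expected


@pytest.mark.parametrize("interval", [7.0, 0.0, 200.0, 11.0])
def test_plane_count_rejects_non_divisors(interval):
    with pytest.raises(ValueError):
        plane_count(interval)


def test_axis_symmetric_volume_gives_identical_planes():
    vol = radial_volume(lambda r, z: np.cos(r / 4.0) + 0.05 * z)
    geom = RadialGeometry.from_volume(vol, angular_interval=10.0,
                                      in_plane_spacing=1.0)
    planes = [extract_plane(vol, geom, k).pixels for k in range(geom.n_planes)]
    assert len(planes) == 18
    # planes agree up to trilinear interpolation error, O(h^2) for this
    # curvature at 1 mm sampling
    for p in planes[1:]:
        np.testing.assert_allclose(p, planes[0], atol=0.02)


def test_axis_symmetric_planes_match_analytic_radial_function():
    fn = lambda r, z: np.cos(r / 4.0) + 0.05 * z
    vol = radial_volume(fn)
    geom = RadialGeometry.from_volume(vol, angular_interval=10.0,
                                      in_plane_spacing=1.0)
    plane = extract_plane(vol, geom, 3)
    S, Z = np.meshgrid(np.abs(geom.s_coords), geom.z_coords, indexing="ij")
    expected = fn(S, Z)
    # interior only: trilinear sampling of a smooth function, small tolerance
    np.testing.assert_allclose(plane.pixels, expected, atol=0.02)


def test_axis_column_constant_for_every_plane(rng):
    vol = Volume3D(rng.random((16, 16, 8)))
    # make the axis column constant
    c = 7.5  # centre index for 16 nodes
    geom = RadialGeometry.from_volume(vol, angular_interval=30.0,
                                      in_plane_spacing=1.0)
    vol.voxels[7:9, 7:9, :] = 0.42
    for k in range(geom.n_planes):
        plane = extract_plane(vol, geom, k)
        axis_col = plane.pixels[np.argmin(np.abs(plane.s))]
        np.testing.assert_allclose(axis_col, 0.42, atol=1e-9)


def test_plane_point_to_world_rotation_oracle():
    geom = RadialGeometry(axis_point=(10.0, -5.0), angular_interval=10.0,
                          plane_half_width=20, z_min=0, z_max=10)
    delta = np.deg2rad(10.0)
    rot = np.array([[np.cos(delta), -np.sin(delta)],
                    [np.sin(delta), np.cos(delta)]])
    for k in range(geom.n_planes - 1):
        for s, z in [(5.0, 2.0), (-7.5, 9.0), (0.0, 4.0)]:
            p0 = plane_point_to_world(geom, k, s, z)
            p1 = plane_point_to_world(geom, k + 1, s, z)
            xy = rot @ (p0[:2] - np.array(geom.axis_point)) + geom.axis_point
            np.testing.assert_allclose(p1[:2], xy, atol=1e-9)
            assert p1[2] == pytest.approx(z)


def test_axis_point_and_sign_symmetry():
    geom = RadialGeometry(axis_point=(3.0, 4.0), angular_interval=20.0,
                          plane_half_width=15, z_min=0, z_max=10)
    for k in range(geom.n_planes):
        p = plane_point_to_world(geom, k, 0.0, 7.0)
        np.testing.assert_allclose(p, [3.0, 4.0, 7.0], atol=1e-12)
    # (k, -s) is the point at angle theta_k + 180 deg with +s
    p_neg = plane_point_to_world(geom, 2, -6.0, 1.0)
    theta = np.deg2rad(2 * 20.0 + 180.0)
    expected = [3.0 + 6.0 * np.cos(theta), 4.0 + 6.0 * np.sin(theta), 1.0]
    np.testing.assert_allclose(p_neg, expected, atol=1e-9)


def test_plane_index_out_of_range_raises(small_volume):
    geom = RadialGeometry.from_volume(small_volume)
    with pytest.raises(ValueError):
        extract_plane(small_volume, geom, geom.n_planes)
    with pytest.raises(ValueError):
        extract_plane(small_volume, geom, -1)


def test_zero_context_offset_reproduces_central_plane(rng):
    vol = Volume3D(rng.random((16, 16, 8)))
    geom = RadialGeometry.from_volume(vol, angular_interval=45.0,
                                      in_plane_spacing=1.0, context_offset=0.0)
    for k in range(geom.n_planes):
        centre = extract_plane(vol, geom, k)
        ctx_m, ctx_p = extract_context(vol, geom, k)
        np.testing.assert_array_equal(ctx_m.pixels, centre.pixels)
        np.testing.assert_array_equal(ctx_p.pixels, centre.pixels)


def test_context_planes_on_linear_ramp_differ_by_offset():
    # intensity = y coordinate; plane k=0 has normal +y, so the context
    # planes at -/+ offset differ from the centre by -/+ offset everywhere
    shape = (32, 32, 8)
    ax = [np.arange(n) * 1.0 for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    vol = Volume3D(Y, spacing=(1, 1, 1))
    geom = RadialGeometry.from_volume(vol, angular_interval=10.0,
                                      in_plane_spacing=1.0, context_offset=4.0)
    centre = extract_plane(vol, geom, 0)
    ctx_m, ctx_p = extract_context(vol, geom, 0)
    interior = slice(4, -4)  # stay away from edge-replicated borders
    np.testing.assert_allclose(
        ctx_m.pixels[interior] - centre.pixels[interior], -4.0, atol=1e-9)
    np.testing.assert_allclose(
        ctx_p.pixels[interior] - centre.pixels[interior], +4.0, atol=1e-9)


def test_out_of_volume_context_uses_edge_replication():
    shape = (12, 12, 6)
    ax = [np.arange(n) * 1.0 for n in shape]
    _, Y, _ = np.meshgrid(*ax, indexing="ij")
    vol = Volume3D(Y)
    geom = RadialGeometry(axis_point=(5.5, 5.5), angular_interval=90.0,
                          plane_half_width=5.5, z_min=0, z_max=5,
                          in_plane_spacing=1.0, context_offset=100.0)
    ctx_m, ctx_p = extract_context(vol, geom, 0)
    # offsets far beyond the volume clamp to the boundary values (y = 0 / 11)
    np.testing.assert_allclose(ctx_m.pixels, 0.0, atol=1e-9)
    np.testing.assert_allclose(ctx_p.pixels, 11.0, atol=1e-9)


def test_sampling_grid_inverse_map_is_exact():
    geom = RadialGeometry(axis_point=(1.0, 2.0), angular_interval=10.0,
                          plane_half_width=10, z_min=-5, z_max=5,
                          in_plane_spacing=0.5)
    k = 4
    theta = geom.angle_rad(k)
    for s in geom.s_coords[::7]:
        for z in geom.z_coords[::5]:
            w = plane_point_to_world(geom, k, s, z)
            # project back: signed radius along the plane direction
            d = w[:2] - np.array(geom.axis_point)
            s_back = d @ np.array([np.cos(theta), np.sin(theta)])
            np.testing.assert_allclose([s_back, w[2]], [s, z], atol=1e-9)


def test_stack_has_ordered_angles(small_volume):
    geom = RadialGeometry.from_volume(small_volume, angular_interval=30.0,
                                      in_plane_spacing=1.0)
    stack = extract_stack(small_volume, geom)
    assert len(stack) == 6
    angles = [triple[0].angle_deg for triple in stack.planes]
    assert angles == [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]
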