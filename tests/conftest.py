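"""Shared fixtures: small geometries, operators, phantoms, and the
brute-force dense system-matrix oracle used to validate the projectors."""

from __future__ import annotations

import numpy as np
import pytest

import dbtsim as d


def dense_system_matrix(op: "d.SystemOperator") -> np.ndarray:
    """Brute-force dense system matrix by per-ray voxel-intersection
    enumeration.

    For every (view, detector pixel) ray and every voxel, the entry is the
    exact chord length of the ray through that voxel's axis-aligned box,
    found by the slab method.  O(rays × voxels) and deliberately naive —
    independent of the package's own ray tracing.
    """
    g = op.geometry
    nz, ny, nx = op.volume_shape
    dz, dy, dx = op.voxel_size
    (xlo, _), (ylo, _), (zlo, _) = op._volume_bounds()
    det_x = g.detector_x()
    det_y = g.detector_y()
    n_rays = g.n_views * g.detector_rows * g.detector_cols
    mat = np.zeros((n_rays, nz * ny * nx))
    ray = 0
    for view in range(g.n_views):
        src = g.source_position(g.view_angles[view])
        for yy in det_y:
            for xx in det_x:
                dvec = np.array([xx, yy, 0.0]) - src
                length = np.linalg.norm(dvec)
                col = 0
                for kz in range(nz):
                    z0v, z1v = zlo + kz * dz, zlo + (kz + 1) * dz
                    for ky in range(ny):
                        y0v, y1v = ylo + ky * dy, ylo + (ky + 1) * dy
                        for kx in range(nx):
                            x0v, x1v = xlo + kx * dx, xlo + (kx + 1) * dx
                            tmin, tmax = 0.0, 1.0
                            ok = True
                            for c, lo, hi in (
                                (0, x0v, x1v),
                                (1, y0v, y1v),
                                (2, z0v, z1v),
                            ):
                                if dvec[c] == 0.0:
                                    if not (lo <= src[c] <= hi):
                                        ok = False
                                        break
                                else:
                                    t1 = (lo - src[c]) / dvec[c]
                                    t2 = (hi - src[c]) / dvec[c]
                                    tmin = max(tmin, min(t1, t2))
                                    tmax = min(tmax, max(t1, t2))
                            if ok and tmax > tmin:
                                mat[ray, col] = (tmax - tmin) * length
                            col += 1
                ray += 1
    return mat


def small_geometry(n_views=3, arc=10.0, det=12, pitch=1.2):
    return d.make_geometry(
        n_views,
        arc,
        dict(
            detector_rows=det,
            detector_cols=det,
            pixel_pitch=pitch,
            source_to_detector=200.0,
            source_to_support=160.0,
        ),
    )


@pytest.fixture(scope="session")
def tiny_op():
    """8³ Joseph operator over a 3-view, 10° geometry."""
    return d.SystemOperator(small_geometry(), (8, 8, 8), 1.0)


@pytest.fixture(scope="session")
def tiny_op_siddon():
    return d.SystemOperator(
        small_geometry(), (8, 8, 8), 1.0, interpolation="siddon"
    )


@pytest.fixture(scope="session")
def tiny_dense_matrix(tiny_op_siddon):
    return dense_system_matrix(tiny_op_siddon)


def small_phantom_spec(seed=0, nz=16, n_inplane=64):
    """Reduced phantom for stochastic property tests: same composition and
    insert sizes, quarter-scale grid."""
    vz, vy, vx = 1.0, 0.14, 0.14
    return d.PhantomSpec(
        shape=(nz, n_inplane, n_inplane),
        voxel_size=(vz, vy, vx),
        mc_inserts=[
            d.Insert("microcalcification", 0.29, (nz / 2 - 0.5, 2.2, -2.2), 0.50),
            d.Insert("microcalcification", 0.40, (nz / 2 - 0.5, 2.2, 2.2), 0.50),
        ],
        mass_inserts=[
            d.Insert("mass", 3.9, (nz / 2 - 0.5, -2.2, 0.0), 0.015),
        ],
        background_center=(1.3, 0.0),
        seed=seed,
    )


def small_config(seeds=(0,), n_views=15):
    """Experiment config over the reduced phantom and a matching detector."""
    spec = small_phantom_spec(seed=seeds[0])
    return d.ExperimentConfig(
        phantom=spec,
        n_views=n_views,
        arc_span=15.0,
        geometry_config=dict(detector_rows=80, detector_cols=160, pixel_pitch=0.14),
        seeds=tuple(seeds),
        profile_half_length=1.2,
        cnr_background_offset_mm=3.5,
    )


@pytest.fixture(scope="session")
def default_config_one_seed():
    return d.ExperimentConfig(seeds=(0,))
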