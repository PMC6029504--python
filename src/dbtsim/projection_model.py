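"""Acquisition geometry and linear projection operators for digital breast
tomosynthesis (DBT).

The model is a partial-isocentric narrow-arc scanner: a stationary flat-panel
detector lies in the ``z = 0`` plane, the breast support plane sits at
``z = source_to_detector - source_to_support``, and the x-ray source swings on
an arc of radius ``source_to_support`` about a pivot on the support plane.
Tube motion is along the detector column axis (``x``); detector rows run along
``y``; the reconstruction slice axis is ``z``, perpendicular to the detector.

Coordinates are right-handed with the origin at the detector centre: a pixel
or voxel with 0-based index ``i`` along an axis of ``n`` elements has its
centre at ``(i - (n - 1)/2) * pitch`` mm, so centres sit at half-integer
multiples of the pitch whenever ``n`` is even.

Two ray models are provided through :class:`SystemOperator`:

``joseph``
    Voxel-driven interpolating ray tracing: each ray is sampled once per
    slice, the slice is bilinearly interpolated at the intersection point and
    weighted by the slant path length through the slice.  Fast, smooth, and
    vectorised — the default for reconstruction.

``siddon``
    Exact ray/voxel intersection lengths, assembled into a cached sparse
    system matrix per view.  Exact but built with a per-ray Python loop, so
    intended for small volumes and as an independently checkable reference.

Forward and backward application of either operator form an exact adjoint
pair (the backprojector scatters with the same weights the projector
gathers), rays that miss the volume contribute exactly zero, and the mapping
is linear in the volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "ContractError",
    "AcquisitionGeometry",
    "ProjectionSet",
    "SystemOperator",
    "make_geometry",
    "forward_project",
    "back_project",
    "save_projections_tiff",
    "load_projections_tiff",
    "save_projections_hdf5",
    "load_projections_hdf5",
]


class ConfigurationError(ValueError):
    """Invalid scanner/phantom/algorithm configuration."""


class ContractError(ValueError):
    """A caller violated an operation's precondition (e.g. shape mismatch)."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

_GEOMETRY_FIELDS = (
    "n_views",
    "arc_span",
    "view_angles",
    "source_to_detector",
    "source_to_support",
    "detector_rows",
    "detector_cols",
    "pixel_pitch",
    "detector_motion",
)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Source arc, detector layout and view angles of one DBT acquisition.

    Parameters
    ----------
    n_views : int
        Number of projection views.
    arc_span : float
        Total angular range of the source arc, degrees.
    view_angles : tuple of float
        One angle per view, degrees, strictly increasing and symmetric
        about 0°.
    source_to_detector, source_to_support : float
        Distances in mm from the source (at the central view) to the detector
        plane and to the breast-support plane (the arc pivot).
    detector_rows, detector_cols : int
        Detector size in pixels; columns run along the tube-motion axis.
    pixel_pitch : float
        Detector pixel pitch, mm.
    detector_motion : str
        Only ``"stationary"`` is supported.
    """

    n_views: int
    arc_span: float
    view_angles: tuple = ()
    source_to_detector: float = 700.0
    source_to_support: float = 660.0
    detector_rows: int = 144
    detector_cols: int = 288
    pixel_pitch: float = 0.14
    detector_motion: str = "stationary"

    def __post_init__(self):
        if self.detector_motion != "stationary":
            raise ConfigurationError(
                f"unsupported detector_motion {self.detector_motion!r}"
            )
        for name in ("source_to_detector", "source_to_support", "pixel_pitch"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.source_to_support > self.source_to_detector:
            raise ConfigurationError(
                "source_to_support cannot exceed source_to_detector"
            )
        if self.detector_rows <= 0 or self.detector_cols <= 0:
            raise ConfigurationError("detector size must be positive")
        angles = np.asarray(self.view_angles, dtype=float)
        if angles.size != self.n_views:
            raise ConfigurationError(
                f"view_angles has {angles.size} entries, expected {self.n_views}"
            )
        if self.n_views >= 2:
            if not np.all(np.diff(angles) > 0):
                raise ConfigurationError("view_angles must be strictly increasing")
            if not math.isclose(
                angles.max() - angles.min(), self.arc_span, rel_tol=1e-9, abs_tol=1e-9
            ):
                raise ConfigurationError("view angle range must equal arc_span")
        if not np.allclose(angles + angles[::-1], 0.0, atol=1e-9):
            raise ConfigurationError("view_angles must be symmetric about 0°")
        object.__setattr__(self, "view_angles", tuple(float(a) for a in angles))

    # -- derived quantities -------------------------------------------------

    @property
    def support_height(self) -> float:
        """Height of the breast-support plane above the detector, mm."""
        return self.source_to_detector - self.source_to_support

    def source_position(self, angle_deg: float) -> np.ndarray:
        """Source position ``(x, y, z)`` in mm for one view angle."""
        th = math.radians(angle_deg)
        r = self.source_to_support
        return np.array(
            [r * math.sin(th), 0.0, self.support_height + r * math.cos(th)]
        )

    def detector_x(self) -> np.ndarray:
        """Pixel-centre x coordinates (mm) of the detector columns."""
        n = self.detector_cols
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    def detector_y(self) -> np.ndarray:
        """Pixel-centre y coordinates (mm) of the detector rows."""
        n = self.detector_rows
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch

    def with_views(self, view_angles: Sequence[float]) -> "AcquisitionGeometry":
        """Copy of this geometry with a different (symmetric) view set."""
        angles = tuple(float(a) for a in view_angles)
        span = (max(angles) - min(angles)) if len(angles) > 1 else 0.0
        return replace(self, n_views=len(angles), arc_span=span, view_angles=angles)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_views": self.n_views,
            "arc_span": self.arc_span,
            "view_angles": list(self.view_angles),
            "source_to_detector": self.source_to_detector,
            "source_to_support": self.source_to_support,
            "detector_rows": self.detector_rows,
            "detector_cols": self.detector_cols,
            "pixel_pitch": self.pixel_pitch,
            "detector_motion": self.detector_motion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        unknown = set(d) - set(_GEOMETRY_FIELDS)
        if unknown:
            raise ConfigurationError(f"unknown geometry keys: {sorted(unknown)}")
        kwargs = dict(d)
        kwargs["view_angles"] = tuple(kwargs.get("view_angles", ()))
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_geometry(
    n_views: int,
    arc_span: float,
    config: Optional[dict] = None,
) -> AcquisitionGeometry:
    """Build a geometry with ``n_views`` evenly spaced over ``arc_span``.

    Angles span ``[-arc_span/2, +arc_span/2]`` inclusive of both endpoints and
    are exactly symmetric about 0°.  ``config`` supplies any other
    :class:`AcquisitionGeometry` field (distances, detector layout) verbatim.
    """
    if n_views < 1:
        raise ConfigurationError("n_views must be >= 1")
    if arc_span < 0:
        raise ConfigurationError("arc_span must be >= 0")
    if arc_span == 0 and n_views != 1:
        raise ConfigurationError("arc_span = 0 requires n_views = 1")
    if n_views == 1:
        if arc_span != 0:
            raise ConfigurationError("a single view requires arc_span = 0")
        angles = (0.0,)
    else:
        step = arc_span / (n_views - 1)
        # (k - (n-1)/2) * step is exactly antisymmetric in floating point
        angles = tuple((k - (n_views - 1) / 2.0) * step for k in range(n_views))
    extra = dict(config or {})
    extra.pop("n_views", None)
    extra.pop("arc_span", None)
    extra.pop("view_angles", None)
    return AcquisitionGeometry(
        n_views=n_views, arc_span=float(arc_span), view_angles=angles, **extra
    )


# ---------------------------------------------------------------------------
# projection data
# ---------------------------------------------------------------------------


@dataclass
class ProjectionSet:
    """Stack of log-converted line-integral detector images, one per view.

    ``data`` has shape ``(n_views, detector_rows, detector_cols)`` and holds
    dimensionless line integrals (−ln transmission).  Noiseless data are
    nonnegative.  Noisy data may contain small negatives (upward count
    fluctuations are not clipped); the one-photon count floor only bounds
    the values from above by ``ln(fluence)``.
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    per_view_fluence: Optional[float] = None
    noise_seed: Optional[int] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        expected = (
            self.geometry.n_views,
            self.geometry.detector_rows,
            self.geometry.detector_cols,
        )
        if self.data.shape != expected:
            raise ContractError(
                f"projection data shape {self.data.shape} does not match "
                f"geometry {expected}"
            )

    @property
    def n_views(self) -> int:
        return self.geometry.n_views


# ---------------------------------------------------------------------------
# system operator
# ---------------------------------------------------------------------------


class SystemOperator:
    """Linear forward/back projection operator for one geometry and grid.

    Parameters
    ----------
    geometry : AcquisitionGeometry
    volume_shape : (nz, ny, nx)
        Voxel counts; ``z`` is the slice axis (perpendicular to the
        detector), ``y`` the detector-row axis, ``x`` the tube-motion axis.
    voxel_size : float or (dz, dy, dx)
        Voxel edge lengths in mm.  A scalar means an isotropic grid.
    interpolation : {"joseph", "siddon"}
        Ray model (see module docstring).

    The volume's lower face rests on the breast-support plane and the grid is
    centred on the detector axis in ``x`` and ``y``.
    """

    def __init__(
        self,
        geometry: AcquisitionGeometry,
        volume_shape,
        voxel_size,
        interpolation: str = "joseph",
    ):
        if interpolation not in ("joseph", "siddon"):
            raise ConfigurationError(f"unknown interpolation {interpolation!r}")
        self.geometry = geometry
        self.volume_shape = tuple(int(n) for n in volume_shape)
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 1:
            raise ConfigurationError("volume_shape must be three positive counts")
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        if np.any(vs <= 0):
            raise ConfigurationError("voxel sizes must be strictly positive")
        self.voxel_size = tuple(float(v) for v in vs)  # (dz, dy, dx)
        self.interpolation = interpolation
        self._siddon_cache: dict = {}

    # -- grid helpers -------------------------------------------------------

    @property
    def projection_shape(self):
        g = self.geometry
        return (g.n_views, g.detector_rows, g.detector_cols)

    def slice_heights(self) -> np.ndarray:
        """z coordinate (mm) of each slice's voxel centres."""
        nz = self.volume_shape[0]
        dz = self.voxel_size[0]
        return self.geometry.support_height + (np.arange(nz) + 0.5) * dz

    def _volume_bounds(self):
        nz, ny, nx = self.volume_shape
        dz, dy, dx = self.voxel_size
        z0 = self.geometry.support_height
        return (
            (-nx * dx / 2.0, nx * dx / 2.0),
            (-ny * dy / 2.0, ny * dy / 2.0),
            (z0, z0 + nz * dz),
        )

    # -- public API ---------------------------------------------------------

    def forward(self, volume: np.ndarray) -> np.ndarray:
        """Apply the system matrix: volume (mm⁻¹) → line integrals."""
        vol = self._check_volume(volume)
        out = np.empty(self.projection_shape)
        for v in range(self.geometry.n_views):
            out[v] = self.forward_view(vol, v)
        return out

    def back(self, projections: np.ndarray) -> np.ndarray:
        """Apply the exact adjoint: line integrals → volume-shaped array."""
        proj = self._check_projections(projections)
        out = np.zeros(self.volume_shape)
        for v in range(self.geometry.n_views):
            out += self.back_view(proj[v], v)
        return out

    def forward_view(self, volume: np.ndarray, view: int) -> np.ndarray:
        vol = self._check_volume(volume)
        if self.interpolation == "joseph":
            return self._joseph_forward_view(vol, view)
        m = self._siddon_matrix(view)
        g = self.geometry
        return (m @ vol.ravel()).reshape(g.detector_rows, g.detector_cols)

    def back_view(self, view_data: np.ndarray, view: int) -> np.ndarray:
        arr = np.asarray(view_data, dtype=float)
        g = self.geometry
        if arr.shape != (g.detector_rows, g.detector_cols):
            raise ContractError(
                f"view data shape {arr.shape} does not match detector "
                f"({g.detector_rows}, {g.detector_cols})"
            )
        if self.interpolation == "joseph":
            return self._joseph_back_view(arr, view)
        m = self._siddon_matrix(view)
        return (m.T @ arr.ravel()).reshape(self.volume_shape)

    # -- validation ---------------------------------------------------------

    def _check_volume(self, volume) -> np.ndarray:
        vol = np.asarray(getattr(volume, "data", volume), dtype=float)
        if vol.shape != self.volume_shape:
            raise ContractError(
                f"volume shape {vol.shape} does not match operator "
                f"{self.volume_shape}"
            )
        return vol

    def _check_projections(self, projections) -> np.ndarray:
        proj = np.asarray(getattr(projections, "data", projections), dtype=float)
        if proj.shape != self.projection_shape:
            raise ContractError(
                f"projection shape {proj.shape} does not match operator "
                f"{self.projection_shape}"
            )
        return proj

    # -- Joseph kernel ------------------------------------------------------

    def _joseph_forward_view(self, vol, view):
        from ._kernels import joseph_forward

        g = self.geometry
        src = g.source_position(g.view_angles[view])
        dz, dy, dx = self.voxel_size
        return joseph_forward(
            np.ascontiguousarray(vol),
            g.detector_x(),
            g.detector_y(),
            src,
            g.support_height,
            dz,
            dy,
            dx,
        )

    def _joseph_back_view(self, arr, view):
        from ._kernels import joseph_back

        g = self.geometry
        src = g.source_position(g.view_angles[view])
        dz, dy, dx = self.voxel_size
        return joseph_back(
            np.ascontiguousarray(arr),
            self.volume_shape,
            g.detector_x(),
            g.detector_y(),
            src,
            g.support_height,
            dz,
            dy,
            dx,
        )

    # -- Siddon kernel ------------------------------------------------------

    def _siddon_matrix(self, view: int):
        """Sparse exact-intersection system matrix for one view (cached)."""
        if view in self._siddon_cache:
            return self._siddon_cache[view]
        from scipy import sparse

        g = self.geometry
        nz, ny, nx = self.volume_shape
        dz, dy, dx = self.voxel_size
        (xlo, xhi), (ylo, yhi), (zlo, zhi) = self._volume_bounds()
        src = g.source_position(g.view_angles[view])
        det_x = g.detector_x()
        det_y = g.detector_y()

        rows, cols, vals = [], [], []
        ray = 0
        for yy in det_y:
            for xx in det_x:
                dst = np.array([xx, yy, 0.0])
                d = dst - src
                length = float(np.linalg.norm(d))
                # entry/exit parameters of the volume box along the ray
                tmin, tmax = 0.0, 1.0
                for comp, lo, hi in ((0, xlo, xhi), (1, ylo, yhi), (2, zlo, zhi)):
                    if d[comp] == 0.0:
                        if not (lo <= src[comp] <= hi):
                            tmin, tmax = 1.0, 0.0
                            break
                    else:
                        t1 = (lo - src[comp]) / d[comp]
                        t2 = (hi - src[comp]) / d[comp]
                        tmin = max(tmin, min(t1, t2))
                        tmax = min(tmax, max(t1, t2))
                if tmax > tmin:
                    ts = [np.array([tmin, tmax])]
                    for comp, lo, step, n in (
                        (0, xlo, dx, nx),
                        (1, ylo, dy, ny),
                        (2, zlo, dz, nz),
                    ):
                        if d[comp] != 0.0:
                            planes = lo + step * np.arange(n + 1)
                            t = (planes - src[comp]) / d[comp]
                            ts.append(t[(t > tmin) & (t < tmax)])
                    t_all = np.unique(np.concatenate(ts))
                    mids = 0.5 * (t_all[:-1] + t_all[1:])
                    seg = np.diff(t_all) * length
                    px = src[0] + mids * d[0]
                    py = src[1] + mids * d[1]
                    pz = src[2] + mids * d[2]
                    ix = np.floor((px - xlo) / dx).astype(int)
                    iy = np.floor((py - ylo) / dy).astype(int)
                    iz = np.floor((pz - zlo) / dz).astype(int)
                    ok = (
                        (ix >= 0) & (ix < nx)
                        & (iy >= 0) & (iy < ny)
                        & (iz >= 0) & (iz < nz)
                        & (seg > 0)
                    )
                    flat = (iz[ok] * ny + iy[ok]) * nx + ix[ok]
                    rows.extend([ray] * flat.size)
                    cols.extend(flat.tolist())
                    vals.extend(seg[ok].tolist())
                ray += 1
        m = sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(g.detector_rows * g.detector_cols, nz * ny * nx),
        )
        self._siddon_cache[view] = m
        return m


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def forward_project(volume, op: SystemOperator) -> ProjectionSet:
    """Project a volume through the system operator.

    Each detector pixel receives the line integral of attenuation (mm⁻¹ ×
    mm path) along the ray from the view's source position through the pixel
    centre.  The map is linear in the volume and rays missing the volume
    contribute exactly zero.
    """
    return ProjectionSet(data=op.forward(op._check_volume(volume)), geometry=op.geometry)


def back_project(projections, op: SystemOperator) -> np.ndarray:
    """Apply the exact adjoint of :func:`forward_project`."""
    return op.back(op._check_projections(projections))


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def save_projections_tiff(path, projections: ProjectionSet) -> None:
    """Write one 32-bit float TIFF page per view."""
    import tifffile

    tifffile.imwrite(
        path, projections.data.astype(np.float32), photometric="minisblack"
    )


def load_projections_tiff(path, geometry: AcquisitionGeometry) -> ProjectionSet:
    import tifffile

    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return ProjectionSet(data=data, geometry=geometry)


def save_projections_hdf5(path, projections: ProjectionSet) -> None:
    """Single ``[view, row, col]`` dataset with the geometry as attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("projections", data=projections.data)
        for key, val in projections.geometry.to_dict().items():
            ds.attrs[key] = val
        if projections.per_view_fluence is not None:
            ds.attrs["per_view_fluence"] = projections.per_view_fluence
        if projections.noise_seed is not None:
            ds.attrs["noise_seed"] = projections.noise_seed


def load_projections_hdf5(path) -> ProjectionSet:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["projections"]
        data = ds[()]
        attrs = dict(ds.attrs)
    fluence = attrs.pop("per_view_fluence", None)
    seed = attrs.pop("noise_seed", None)
    attrs["view_angles"] = [float(a) for a in attrs["view_angles"]]
    for key in ("n_views", "detector_rows", "detector_cols"):
        attrs[key] = int(attrs[key])
    geom = AcquisitionGeometry.from_dict(
        {k: attrs[k] for k in _GEOMETRY_FIELDS if k in attrs}
    )
    return ProjectionSet(
        data=data,
        geometry=geom,
        per_view_fluence=None if fluence is None else float(fluence),
        noise_seed=None if seed is None else int(seed),
    )
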