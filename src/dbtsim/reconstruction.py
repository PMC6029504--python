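"""Limited-angle DBT reconstruction: FBP, SART, MLEM and ASD-POCS.

All four algorithms are deterministic mappings of (projections, geometry,
parameters).  Iterative defaults follow the study convention: 5 iterations
for SART and ASD-POCS, 2 for MLEM, and the ASD-POCS total-variation
hyperparameters α = 0.002 with ng = 25 steepest-descent substeps.

FBP filters each projection row-wise along the tube-motion axis with a
frequency-domain ramp (optionally apodized by the Shepp–Logan sinc roll-off),
backprojects, and normalises by the view count.  SART sweeps the views in
ascending angle order, updating every voxel from all rays of one view with
the standard ray-sum / voxel-sensitivity normalisations.  MLEM applies the
multiplicative expectation-maximisation update to the line-integral data
treated as a nonnegative sinogram, starting from a uniform strictly positive
volume.  ASD-POCS alternates one SART sweep (the POCS data-consistency step,
with positivity) against ``ng`` steepest-descent substeps along the
normalised total-variation gradient, adaptively shrinking the ART relaxation
β and the TV step scale α.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .projection_model import (
    ConfigurationError,
    ProjectionSet,
    SystemOperator,
)

__all__ = [
    "FBPParams",
    "SARTParams",
    "MLEMParams",
    "ASDPOCSParams",
    "ReconVolume",
    "fbp",
    "sart",
    "mlem",
    "asd_pocs",
    "total_variation",
    "tv_gradient",
    "reconstruct",
    "save_recon_hdf5",
    "load_recon_hdf5",
]

_WEIGHT_FLOOR = 1e-12  # treat smaller ray/voxel normalisation weights as zero


@dataclass(frozen=True)
class FBPParams:
    """kernel: ``"ramp"`` or ``"shepp_logan"``.

    ``filter_mode="2d"`` (default) multiplies the 2D Fourier transform of
    each projection by the radially symmetric kernel — the image-domain
    filtering used for tomosynthesis FBP here, which restores the impulse
    shape in both detector directions.  ``filter_mode="1d"`` applies the
    kernel along ``filter_axis`` only (the detector axis parallel to tube
    motion, columns by default), the classical CT row-filter convention.
    """

    kernel: str = "ramp"
    filter_mode: str = "2d"
    filter_axis: int = -1

    def __post_init__(self):
        if self.kernel not in ("ramp", "shepp_logan"):
            raise ConfigurationError(f"unknown FBP kernel {self.kernel!r}")
        if self.filter_mode not in ("1d", "2d"):
            raise ConfigurationError(f"unknown filter_mode {self.filter_mode!r}")


@dataclass(frozen=True)
class SARTParams:
    n_iterations: int = 5
    relaxation: float = 1.0
    nonnegativity: bool = True

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not 0.0 < self.relaxation < 2.0:
            raise ConfigurationError("relaxation must lie in (0, 2)")


@dataclass(frozen=True)
class MLEMParams:
    n_iterations: int = 2
    epsilon_guard: float = 1e-10

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.epsilon_guard <= 0:
            raise ConfigurationError("epsilon_guard must be positive")


@dataclass(frozen=True)
class ASDPOCSParams:
    """ASD-POCS control parameters.

    ``beta`` is the ART/SART relaxation, reduced by ``beta_red`` each outer
    iteration; ``alpha`` scales the TV step relative to the POCS image change
    and shrinks by ``alpha_red`` whenever the TV excursion exceeds
    ``gamma_max`` times the POCS excursion while the data residual is still
    above the inconsistency tolerance ``epsilon`` (0 disables the residual
    gate, so α stays eligible to shrink).
    """

    n_iterations: int = 5
    beta: float = 1.0
    beta_red: float = 0.995
    alpha: float = 0.002
    alpha_red: float = 0.95
    gamma_max: float = 0.95
    ng: int = 25
    epsilon: float = 0.0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not 0.0 < self.beta_red <= 1.0:
            raise ConfigurationError("beta_red must lie in (0, 1]")
        if not 0.0 < self.alpha_red <= 1.0:
            raise ConfigurationError("alpha_red must lie in (0, 1]")
        if self.ng < 0:
            raise ConfigurationError("ng must be >= 0")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be >= 0")


@dataclass
class ReconVolume:
    """Reconstructed attenuation estimate plus provenance."""

    data: np.ndarray
    algorithm: str
    params_used: dict
    residual_history: List[float] = field(default_factory=list)
    tv_history: Optional[List[float]] = None


# ---------------------------------------------------------------------------
# total variation
# ---------------------------------------------------------------------------


def _forward_diffs(volume: np.ndarray):
    """Forward differences along each axis, zero at the far boundary."""
    g = []
    for ax in range(volume.ndim):
        d = np.zeros_like(volume)
        sl = [slice(None)] * volume.ndim
        sl[ax] = slice(0, volume.shape[ax] - 1)
        d[tuple(sl)] = np.diff(volume, axis=ax)
        g.append(d)
    return g


def total_variation(volume: np.ndarray) -> float:
    """Isotropic total variation: Σ_voxels ‖forward-difference gradient‖₂."""
    vol = np.asarray(volume, dtype=float)
    if vol.size == 0:
        raise ConfigurationError("volume must be nonempty")
    sq = sum(d * d for d in _forward_diffs(vol))
    return float(np.sum(np.sqrt(sq)))


def tv_gradient(volume: np.ndarray, smoothing_delta: float = 1e-8) -> np.ndarray:
    """Gradient of the smoothed TV functional Σ √(‖∇x‖² + δ²).

    ``smoothing_delta`` regularises the gradient norm at exactly flat
    regions; it enters only the denominators.  The result is *not*
    normalised here — ASD-POCS divides by the gradient's own Euclidean norm
    before stepping.
    """
    if smoothing_delta <= 0:
        raise ConfigurationError("smoothing_delta must be positive")
    vol = np.asarray(volume, dtype=float)
    diffs = _forward_diffs(vol)
    r = np.sqrt(sum(d * d for d in diffs) + smoothing_delta**2)
    grad = np.zeros_like(vol)
    for ax, d in enumerate(diffs):
        grad -= d / r
        # contribution of the neighbour behind along this axis
        sl_to = [slice(None)] * vol.ndim
        sl_from = [slice(None)] * vol.ndim
        sl_to[ax] = slice(1, None)
        sl_from[ax] = slice(0, vol.shape[ax] - 1)
        grad[tuple(sl_to)] += (d / r)[tuple(sl_from)]
    return grad


# ---------------------------------------------------------------------------
# FBP
# ---------------------------------------------------------------------------


def _kernel_response(freq_mag: np.ndarray, pitch: float, kernel: str) -> np.ndarray:
    h = np.abs(freq_mag)
    if kernel == "shepp_logan":
        nyquist = 0.5 / pitch
        h = h * np.sinc(freq_mag / (2.0 * nyquist))
    return h


def _filter_projections_1d(data, pitch, kernel, axis):
    axis = axis % data.ndim
    if axis != data.ndim - 1:
        data = np.moveaxis(data, axis, -1)
    n = data.shape[-1]
    npad = 1 << max(1, int(np.ceil(np.log2(2 * n))))
    h = _kernel_response(np.fft.rfftfreq(npad, d=pitch), pitch, kernel)
    spec = np.fft.rfft(data, n=npad, axis=-1)
    out = np.fft.irfft(spec * h, n=npad, axis=-1)[..., :n] * pitch
    if axis != data.ndim - 1:
        out = np.moveaxis(out, -1, axis)
    return out


def _filter_projections_2d(data, pitch, kernel):
    nr, nc = data.shape[-2:]
    pr = 1 << max(1, int(np.ceil(np.log2(2 * nr))))
    pc = 1 << max(1, int(np.ceil(np.log2(2 * nc))))
    fr = np.fft.fftfreq(pr, d=pitch)[:, None]
    fc = np.fft.rfftfreq(pc, d=pitch)[None, :]
    h = _kernel_response(np.sqrt(fr**2 + fc**2), pitch, kernel)
    spec = np.fft.rfft2(data, s=(pr, pc))
    return np.fft.irfft2(spec * h, s=(pr, pc))[..., :nr, :nc] * pitch

def fbp(
    projections: ProjectionSet,
    op: SystemOperator,
    params: FBPParams = FBPParams(),
) -> ReconVolume:
    """Filtered backprojection with a Ramp or Shepp–Logan kernel.

    Projections are zero-padded to the next power of two, filtered in the
    frequency domain (2D radial kernel by default, or 1D along the
    tube-motion axis), scaled by the detector sampling pitch, backprojected,
    and normalised by the view count.
    """
    data = op._check_projections(projections)
    if data.shape[0] == 0:
        raise ConfigurationError("projections must be nonempty")
    pitch = op.geometry.pixel_pitch
    if params.filter_mode == "2d":
        filtered = _filter_projections_2d(data, pitch, params.kernel)
    else:
        filtered = _filter_projections_1d(data, pitch, params.kernel, params.filter_axis)
    vol = op.back(filtered) / op.geometry.n_views
    return ReconVolume(
        data=vol, algorithm="fbp", params_used=asdict(params), residual_history=[]
    )


# ---------------------------------------------------------------------------
# algebraic solvers
# ---------------------------------------------------------------------------


def _view_normalisations(op: SystemOperator):
    """Per-view SART weights: ray sums A_v·1 and voxel sensitivities A_vᵀ·1."""
    ones_vol = np.ones(op.volume_shape)
    g = op.geometry
    ones_view = np.ones((g.detector_rows, g.detector_cols))
    ray_sums, col_sums = [], []
    for v in range(g.n_views):
        ray_sums.append(op.forward_view(ones_vol, v))
        col_sums.append(op.back_view(ones_view, v))
    return ray_sums, col_sums


def _sart_sweep(x, data, op, relaxation, nonnegativity, ray_sums, col_sums):
    """One SART pass over all views in ascending angle order (in place)."""
    for v in range(op.geometry.n_views):
        r = ray_sums[v]
        c = col_sums[v]
        resid = data[v] - op.forward_view(x, v)
        resid = np.where(r > _WEIGHT_FLOOR, resid / np.maximum(r, _WEIGHT_FLOOR), 0.0)
        upd = op.back_view(resid, v)
        upd = np.where(c > _WEIGHT_FLOOR, upd / np.maximum(c, _WEIGHT_FLOOR), 0.0)
        x += relaxation * upd
        if nonnegativity:
            np.maximum(x, 0.0, out=x)
    return x


def _data_residual(x, data, op) -> float:
    return float(np.linalg.norm(op.forward(x) - data))


def sart(
    projections: ProjectionSet,
    op: SystemOperator,
    params: SARTParams = SARTParams(),
    x0: Optional[np.ndarray] = None,
    callback: Optional[Callable[[int, np.ndarray], None]] = None,
) -> ReconVolume:
    """Simultaneous algebraic reconstruction technique.

    Per view ``v``: ``x ← x + λ · A_vᵀ[(b_v − A_v x) / ray-sums] /
    voxel-sensitivities`` with an optional positivity projection after each
    view.  One iteration is one sweep over all views; the ℓ₂ data residual
    is recorded per iteration.
    """
    data = op._check_projections(projections)
    x = np.zeros(op.volume_shape) if x0 is None else np.array(x0, dtype=float)
    ray_sums, col_sums = _view_normalisations(op)
    residuals = []
    for it in range(params.n_iterations):
        _sart_sweep(
            x, data, op, params.relaxation, params.nonnegativity, ray_sums, col_sums
        )
        residuals.append(_data_residual(x, data, op))
        if callback is not None:
            callback(it, x.copy())
    return ReconVolume(
        data=x,
        algorithm="sart",
        params_used=asdict(params),
        residual_history=residuals,
    )


def mlem(
    projections: ProjectionSet,
    op: SystemOperator,
    params: MLEMParams = MLEMParams(),
    x0: Optional[np.ndarray] = None,
    callback: Optional[Callable[[int, np.ndarray], None]] = None,
) -> ReconVolume:
    """Maximum-likelihood expectation maximisation on line-integral data.

    Multiplicative update ``x ← x · Aᵀ(b / (A x + ε)) / Aᵀ1``; positivity is
    preserved by construction.  The line integrals are clamped to be
    nonnegative and treated as a Poisson-model sinogram.  Initialisation is
    the uniform strictly positive volume ``mean(b) / mean(Aᵀ1)``.
    """
    data = np.maximum(op._check_projections(projections), 0.0)
    eps = params.epsilon_guard
    sens = op.back(np.ones(op.projection_shape))
    support = sens > _WEIGHT_FLOOR
    if x0 is None:
        mean_sens = float(np.mean(sens))
        init = float(np.mean(data)) / mean_sens if mean_sens > 0 else 1.0
        x = np.full(op.volume_shape, max(init, eps))
    else:
        x = np.array(x0, dtype=float)
    residuals = []
    for it in range(params.n_iterations):
        ratio = data / (op.forward(x) + eps)
        mult = op.back(ratio)
        x = np.where(support, x * mult / np.maximum(sens, _WEIGHT_FLOOR), 0.0)
        residuals.append(_data_residual(x, data, op))
        if callback is not None:
            callback(it, x.copy())
    return ReconVolume(
        data=x,
        algorithm="mlem",
        params_used=asdict(params),
        residual_history=residuals,
    )


def asd_pocs(
    projections: ProjectionSet,
    op: SystemOperator,
    params: ASDPOCSParams = ASDPOCSParams(),
    callback: Optional[Callable[[int, np.ndarray], None]] = None,
) -> ReconVolume:
    """Adaptive steepest descent — projection onto convex sets.

    Each outer iteration performs (1) one SART sweep with relaxation β and
    positivity (the POCS step), measuring the image change ``dp``; (2) ``ng``
    TV-steepest-descent substeps of size ``dtvg = α·dp`` along the
    unit-normalised TV gradient, measuring the total TV excursion ``dg``;
    (3) adaptation: ``β ← β·β_red`` and, if ``dg > γ_max·dp`` while the data
    residual exceeds ε, ``α ← α·α_red``.  With ``ng = 0`` the method
    degenerates to the POCS-only (SART + positivity) trajectory.
    """
    data = op._check_projections(projections)
    x = np.zeros(op.volume_shape)
    ray_sums, col_sums = _view_normalisations(op)
    beta = params.beta
    alpha = params.alpha
    residuals, tvs = [], []
    for it in range(params.n_iterations):
        x_prev = x.copy()
        _sart_sweep(x, data, op, beta, True, ray_sums, col_sums)
        dp = float(np.linalg.norm(x - x_prev))
        residual = _data_residual(x, data, op)
        x_pocs = x.copy()
        dtvg = alpha * dp
        for _ in range(params.ng):
            g = tv_gradient(x)
            norm = float(np.linalg.norm(g))
            if norm > 0:
                x = x - dtvg * (g / norm)
        dg = float(np.linalg.norm(x - x_pocs))
        beta *= params.beta_red
        if dg > params.gamma_max * dp and residual > params.epsilon:
            alpha *= params.alpha_red
        residuals.append(residual)
        tvs.append(total_variation(x))
        if callback is not None:
            callback(it, x.copy())
    return ReconVolume(
        data=x,
        algorithm="asd_pocs",
        params_used=asdict(params),
        residual_history=residuals,
        tv_history=tvs,
    )


_ALGORITHMS = {
    "fbp": (fbp, FBPParams),
    "sart": (sart, SARTParams),
    "mlem": (mlem, MLEMParams),
    "asd_pocs": (asd_pocs, ASDPOCSParams),
}


def reconstruct(algorithm: str, projections, op, params=None, **kwargs) -> ReconVolume:
    """Dispatch by algorithm name (``fbp``, ``sart``, ``mlem``, ``asd_pocs``)."""
    try:
        fn, cls = _ALGORITHMS[algorithm]
    except KeyError:
        raise ConfigurationError(f"unknown algorithm {algorithm!r}") from None
    if params is None:
        params = cls()
    elif isinstance(params, dict):
        params = cls(**params)
    return fn(projections, op, params, **kwargs)


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------


def save_recon_hdf5(path, recon: ReconVolume) -> None:
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("volume", data=recon.data)
        ds.attrs["algorithm"] = recon.algorithm
        ds.attrs["params_used"] = json.dumps(recon.params_used)
        ds.attrs["residual_history"] = recon.residual_history
        if recon.tv_history is not None:
            ds.attrs["tv_history"] = recon.tv_history


def load_recon_hdf5(path) -> ReconVolume:
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["volume"]
        data = ds[()]
        algorithm = str(ds.attrs["algorithm"])
        params = json.loads(ds.attrs["params_used"])
        residuals = [float(r) for r in ds.attrs.get("residual_history", [])]
        tvs = ds.attrs.get("tv_history")
    return ReconVolume(
        data=data,
        algorithm=algorithm,
        params_used=params,
        residual_history=residuals,
        tv_history=None if tvs is None else [float(t) for t in tvs],
    )
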