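"""Image-quality measures for reconstructed DBT volumes.

Covers every measure used in the projection-reduction comparison:

* **FWHM** of intensity profiles through a microcalcification — a spatial
  resolution proxy.  Profiles run perpendicular to the x-ray sweep
  direction; three neighbouring single-pixel lines are averaged.
* **CNR** ``(μ_Feature − μ_BG) / σ_BG`` for low-contrast masses, with the
  study's feature ROI shapes (21×21 px for the 3.9-mm mass, 33×25 px for
  the 4.7-mm mass).
* **SSIM / MSSIM** with configurable exponents (all 1 by default) and the
  canonical 11×11, σ = 1.5 Gaussian window; the mean over all fully interior
  windows gives the MSSIM.
* **RMSE** and the **universal quality index QI** — the zero-stabiliser
  specialisation of SSIM over an 8×8 uniform sliding window — used to judge
  iteration-to-iteration convergence.
* **Rate of change** between the normal (15-view) and half (7-view) arms,
  ``100 · (value_7 − value_15) / value_15``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .projection_model import ConfigurationError, ContractError

__all__ = [
    "MeasurementFailure",
    "ProfileMeasurement",
    "ROIStats",
    "SSIMParams",
    "SSIMResult",
    "ConvergenceRecord",
    "MetricRecord",
    "extract_profiles",
    "fwhm",
    "cnr",
    "ssim",
    "mssim",
    "rmse",
    "qi",
    "rate_of_change",
    "FEATURE_ROI_SHAPES",
]

#: study feature-ROI pixel extents (rows, cols) keyed by mass diameter (mm)
FEATURE_ROI_SHAPES = {3.9: (21, 21), 4.7: (33, 25)}


class MeasurementFailure(RuntimeError):
    """A metric could not be measured (no peak, unbracketed half-maximum,
    zero background variance, zero reference).  Raised — never silently
    reported as zero — so that pipeline code can flag the cell."""


@dataclass
class ProfileMeasurement:
    positions: np.ndarray  # mm
    values: np.ndarray
    fwhm: Optional[float] = None  # mm
    lines_used: int = 3


@dataclass
class ROIStats:
    mu_feature: float
    mu_bg: float
    sigma_bg: float
    roi_shape_feature: Tuple[int, int]
    roi_shape_bg: Tuple[int, int]


@dataclass
class SSIMParams:
    """Structural-similarity configuration.

    ``C1 = (K1·L)²`` and ``C2 = (K2·L)²`` with ``L`` the dynamic range
    (max − min of the reference unless given); ``C3 = C2/2``.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    window_size: int = 11
    taper: str = "gaussian"  # or "uniform"
    gaussian_sigma: float = 1.5
    K1: float = 0.01
    K2: float = 0.03
    dynamic_range: Optional[float] = None

    def __post_init__(self):
        if self.taper not in ("gaussian", "uniform"):
            raise ConfigurationError(f"unknown window taper {self.taper!r}")
        if self.window_size < 2:
            raise ConfigurationError("window_size must be >= 2")


@dataclass
class SSIMResult:
    map: np.ndarray  # per-window SSIM values, valid-window grid
    mssim: float
    reference_id: Optional[str] = None
    objective_id: Optional[str] = None


@dataclass
class ConvergenceRecord:
    iteration: int
    rmse_prev_curr: float
    qi_prev_curr: float


@dataclass
class MetricRecord:
    """One tidy measured quantity, exportable as a CSV row."""

    phantom_seed: int
    algorithm: str
    kernel: Optional[str]
    n_views: int
    metric: str
    target_insert: Optional[str]
    value: float
    flags: str = ""


# ---------------------------------------------------------------------------
# profiles and FWHM
# ---------------------------------------------------------------------------


def extract_profiles(
    volume,
    center,
    half_length: float,
    voxel_size=None,
    lines: int = 3,
) -> List[ProfileMeasurement]:
    """Three parallel single-pixel profiles through an insert centre.

    ``center`` is a (z, y, x) voxel coordinate (continuous values are rounded
    to the nearest voxel).  Lines run along the row axis ``y`` —
    perpendicular to the tube sweep — through the centre column and its two
    neighbours offset ±1 pixel along the tube-motion axis ``x``.
    ``half_length`` is in mm and must span the insert plus a background
    margin; profiles that would leave the volume raise :class:`ContractError`.
    """
    data = np.asarray(getattr(volume, "data", volume), dtype=float)
    if voxel_size is None:
        voxel_size = getattr(volume, "voxel_size", None)
    if voxel_size is None:
        raise ConfigurationError("voxel_size required when volume is a bare array")
    dz, dy, dx = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    kz, ky, kx = (int(round(c)) for c in center)
    nz, ny, nx = data.shape
    half = int(round(half_length / dy))
    if half < 1:
        raise ConfigurationError("half_length shorter than one pixel")
    offsets = range(-(lines // 2), lines // 2 + 1)
    y0, y1 = ky - half, ky + half
    if not (0 <= kz < nz and 0 <= y0 and y1 < ny):
        raise ContractError("profile exits the volume")
    out = []
    for off in offsets:
        x = kx + off
        if not 0 <= x < nx:
            raise ContractError("profile exits the volume")
        values = data[kz, y0 : y1 + 1, x].copy()
        positions = (np.arange(y0, y1 + 1) - ky) * dy
        out.append(ProfileMeasurement(positions=positions, values=values, lines_used=lines))
    return out


def fwhm(positions, values) -> float:
    """Full width at half maximum of a single peaked profile, in the units of
    ``positions``.

    The background is the mean of the outer 20% of samples at each end; the
    half-maximum level is background + (peak − background)/2; the two
    crossings are located by linear interpolation between bracketing samples.
    Raises :class:`MeasurementFailure` when no interior peak rises above
    background or the half-maximum is not bracketed on both sides.
    """
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.shape != val.shape or pos.size < 5:
        raise ContractError("profile needs matching positions/values, >= 5 samples")
    n_edge = max(1, int(round(0.2 * val.size)))
    background = 0.5 * (np.mean(val[:n_edge]) + np.mean(val[-n_edge:]))
    ipk = int(np.argmax(val))
    peak = val[ipk]
    if ipk == 0 or ipk == val.size - 1 or peak <= background:
        raise MeasurementFailure("no interior peak above background")
    level = background + (peak - background) / 2.0

    def _cross(idx_range):
        prev = None
        for i in idx_range:
            if prev is not None and (val[prev] - level) * (val[i] - level) <= 0:
                lo, hi = (prev, i) if val[prev] <= val[i] else (i, prev)
                if val[hi] == val[lo]:
                    return 0.5 * (pos[prev] + pos[i])
                t = (level - val[prev]) / (val[i] - val[prev])
                return pos[prev] + t * (pos[i] - pos[prev])
            prev = i
        return None

    left = _cross(range(ipk, -1, -1))
    right = _cross(range(ipk, val.size))
    if left is None or right is None:
        raise MeasurementFailure("half-maximum not bracketed on both sides")
    return float(abs(right - left))


def fwhm_of_insert(volume, center, half_length, voxel_size=None) -> float:
    """Mean FWHM (mm) over the three standard profiles through an insert.

    The two ±1-pixel side lines graze the smallest (sub-voxel)
    microcalcifications and may show no peak; lines without a measurable
    peak are dropped from the mean.  Only when *no* line yields a width is
    :class:`MeasurementFailure` raised.
    """
    profiles = extract_profiles(volume, center, half_length, voxel_size)
    widths = []
    for p in profiles:
        try:
            p.fwhm = fwhm(p.positions, p.values)
            widths.append(p.fwhm)
        except MeasurementFailure:
            p.fwhm = None
    if not widths:
        raise MeasurementFailure("no profile line yielded a peak width")
    return float(np.mean(widths))


# ---------------------------------------------------------------------------
# CNR
# ---------------------------------------------------------------------------


def _roi_box(image, center, shape):
    rows, cols = shape
    cy, cx = (int(round(c)) for c in center)
    r0, c0 = cy - rows // 2, cx - cols // 2
    if r0 < 0 or c0 < 0 or r0 + rows > image.shape[0] or c0 + cols > image.shape[1]:
        raise ContractError("ROI out of image bounds")
    return image[r0 : r0 + rows, c0 : c0 + cols]


def cnr(image, feature_center, bg_center, feature_shape, bg_shape=None):
    """Contrast-to-noise ratio ``(μ_Feature − μ_BG) / σ_BG`` on one slice.

    ``feature_shape`` is the (rows, cols) pixel extent of the feature ROI;
    the background ROI defaults to the same shape at a lesion-free location.
    σ_BG is the sample standard deviation (ddof = 1) of the background ROI.
    Raises :class:`MeasurementFailure` when σ_BG = 0.
    """
    img = np.asarray(getattr(image, "data", image), dtype=float)
    if img.ndim != 2:
        raise ContractError("cnr expects a 2D slice")
    if bg_shape is None:
        bg_shape = feature_shape
    feat = _roi_box(img, feature_center, feature_shape)
    bg = _roi_box(img, bg_center, bg_shape)
    if bg.size < 2:
        raise ContractError("background ROI needs >= 2 pixels")
    sigma_bg = float(np.std(bg, ddof=1))
    if sigma_bg == 0.0:
        raise MeasurementFailure("zero background standard deviation")
    stats = ROIStats(
        mu_feature=float(np.mean(feat)),
        mu_bg=float(np.mean(bg)),
        sigma_bg=sigma_bg,
        roi_shape_feature=tuple(feature_shape),
        roi_shape_bg=tuple(bg_shape),
    )
    return (stats.mu_feature - stats.mu_bg) / stats.sigma_bg, stats


# ---------------------------------------------------------------------------
# SSIM / MSSIM / QI
# ---------------------------------------------------------------------------


def _window_weights(params: SSIMParams) -> np.ndarray:
    n = params.window_size
    if params.taper == "uniform":
        w = np.ones((n, n))
    else:
        ax = np.arange(n) - (n - 1) / 2.0
        g = np.exp(-(ax**2) / (2.0 * params.gaussian_sigma**2))
        w = np.outer(g, g)
    return w / w.sum()


def _window_moments(img: np.ndarray, w: np.ndarray):
    """Weighted mean and raw second moment over all fully interior windows."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(img, w.shape)
    mu = np.einsum("ijkl,kl->ij", win, w)
    m2 = np.einsum("ijkl,kl->ij", win * win, w)
    return win, mu, m2


def ssim(reference, objective, params: SSIMParams = SSIMParams()) -> SSIMResult:
    """Structural similarity between two equally shaped 2D images.

    Per window the luminance ``l``, contrast ``c`` and structure ``s`` terms
    are combined as ``l^α · c^β · s^γ`` (all exponents 1 by default, in which
    case the familiar single-fraction form is used).  The map covers every
    window fully inside the images; its arithmetic mean is the MSSIM.
    """
    x = np.asarray(getattr(reference, "data", reference), dtype=float)
    y = np.asarray(getattr(objective, "data", objective), dtype=float)
    if x.shape != y.shape:
        raise ContractError("reference/objective shapes differ")
    if x.ndim != 2 or min(x.shape) < params.window_size:
        raise ContractError("images must be 2D and at least one window wide")
    L = params.dynamic_range
    if L is None:
        L = float(x.max() - x.min())
        if L == 0.0:
            L = 1.0
    c1 = (params.K1 * L) ** 2
    c2 = (params.K2 * L) ** 2
    c3 = c2 / 2.0
    w = _window_weights(params)
    winx, mux, m2x = _window_moments(x, w)
    winy, muy, m2y = _window_moments(y, w)
    varx = np.maximum(m2x - mux**2, 0.0)
    vary = np.maximum(m2y - muy**2, 0.0)
    cov = np.einsum("ijkl,kl->ij", winx * winy, w) - mux * muy
    sx = np.sqrt(varx)
    sy = np.sqrt(vary)
    exps = (params.alpha, params.beta, params.gamma)
    if exps == (1.0, 1.0, 1.0):
        smap = ((2 * mux * muy + c1) * (2 * cov + c2)) / (
            (mux**2 + muy**2 + c1) * (varx + vary + c2)
        )
    else:
        lum = (2 * mux * muy + c1) / (mux**2 + muy**2 + c1)
        con = (2 * sx * sy + c2) / (varx + vary + c2)
        stru = (cov + c3) / (sx * sy + c3)
        smap = (
            np.power(lum, params.alpha)
            * np.power(con, params.beta)
            * np.power(np.abs(stru), params.gamma) * np.sign(stru)
        )
    return SSIMResult(map=smap, mssim=float(np.mean(smap)))


def mssim(reference, objective, params: SSIMParams = SSIMParams()) -> float:
    """Mean SSIM; reference is the 15-view arm by convention."""
    return ssim(reference, objective, params).mssim


def rmse(a, b) -> float:
    """Root-mean-square difference between two equally shaped arrays."""
    x = np.asarray(getattr(a, "data", a), dtype=float)
    y = np.asarray(getattr(b, "data", b), dtype=float)
    if x.shape != y.shape:
        raise ContractError("rmse operands must share a shape")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def qi(a, b, window: int = 8, return_details: bool = False):
    """Universal image quality index over an 8×8 uniform sliding window.

    The zero-stabiliser specialisation of SSIM: per window the product of
    correlation loss, luminance distortion and contrast distortion,
    ``4·σ_xy·μ_x·μ_y / ((σ_x² + σ_y²)(μ_x² + μ_y²))``, averaged over all
    windows where the denominator is nonzero.  Windows with zero variance
    and zero mean energy are skipped; their count is available via
    ``return_details``.  3D inputs are processed slice by slice along the
    first axis.
    """
    x = np.asarray(getattr(a, "data", a), dtype=float)
    y = np.asarray(getattr(b, "data", b), dtype=float)
    if x.shape != y.shape:
        raise ContractError("qi operands must share a shape")
    if x.ndim == 2:
        x = x[None]
        y = y[None]
    elif x.ndim != 3:
        raise ContractError("qi expects 2D or 3D input")
    w = np.full((window, window), 1.0 / window**2)
    vals = []
    skipped = 0
    for xs, ys in zip(x, y):
        if min(xs.shape) < window:
            raise ContractError("slice smaller than the QI window")
        winx, mux, m2x = _window_moments(xs, w)
        winy, muy, m2y = _window_moments(ys, w)
        varx = m2x - mux**2
        vary = m2y - muy**2
        cov = np.einsum("ijkl,kl->ij", winx * winy, w) - mux * muy
        denom = (varx + vary) * (mux**2 + muy**2)
        ok = denom > 0
        skipped += int(np.sum(~ok))
        vals.append((4.0 * cov[ok] * mux[ok] * muy[ok]) / denom[ok])
    allv = np.concatenate(vals) if vals else np.array([])
    if allv.size == 0:
        raise MeasurementFailure("all QI windows degenerate")
    value = float(np.mean(allv))
    if return_details:
        return value, skipped
    return value


def rate_of_change(value_15: float, value_7: float) -> float:
    """Percent change of the half-projection arm relative to the normal arm:
    ``100 · (value_7 − value_15) / value_15``."""
    if value_15 == 0:
        raise MeasurementFailure("zero reference value in rate_of_change")
    return 100.0 * (value_7 - value_15) / value_15
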