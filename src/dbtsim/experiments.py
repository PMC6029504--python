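"""Experiment designs for the projection-reduction study.

Three orchestrated designs, each driven by one :class:`ExperimentConfig`:

* **Parameter sweep** — ASD-POCS over a grid of the TV hyperparameter α and
  TV-descent substep count ng, recording FWHM, CNR and background standard
  deviation per cell (the optimisation that motivates α = 0.002, ng = 25).
* **Convergence study** — SART, MLEM and ASD-POCS on the 15-view
  acquisition, with the RMSE and universal quality index between consecutive
  iterates recorded at every iteration (the iteration-count selection
  procedure: 5 iterations for SART/ASD-POCS, 2 for MLEM).
* **Projection comparison** — the headline normal-vs-half design: one
  15-view acquisition per seed, a 7-view arm obtained purely by thinning,
  all five algorithm variants (FBP with ramp and Shepp–Logan kernels, SART,
  MLEM, ASD-POCS) reconstructed at both view counts, and FWHM, CNR, MSSIM
  and rate-of-change tabulated with across-seed means and standard errors.

One physical phantom underlies the original measurements; this pipeline
replicates the design over a list of phantom seeds and reports mean ±
standard error across seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import metrics as mx
from . import reconstruction as rc
from .projection_model import (
    AcquisitionGeometry,
    ConfigurationError,
    ContractError,
    SystemOperator,
    make_geometry,
)
from .synthetic_data import (
    PhantomSpec,
    PhantomVolume,
    build_phantom,
    simulate_acquisition,
    thin_projections,
)

__all__ = [
    "ExperimentConfig",
    "ComparisonReport",
    "run_parameter_sweep",
    "run_convergence_study",
    "run_projection_comparison",
]

#: offset separating the photon-noise RNG stream from the texture RNG
_NOISE_SEED_OFFSET = 100003

#: the five reconstruction variants of the comparison design
VARIANTS: Tuple[Tuple[str, Optional[str]], ...] = (
    ("fbp", "ramp"),
    ("fbp", "shepp_logan"),
    ("sart", None),
    ("mlem", None),
    ("asd_pocs", None),
)


@dataclass
class ExperimentConfig:
    """Everything one experiment needs: phantom, scanner, dose, algorithms.

    ``profile_half_length`` (mm) sets the FWHM profile span around each
    microcalcification; CNR feature ROIs take the study shapes from
    :data:`dbtsim.metrics.FEATURE_ROI_SHAPES` and the background ROI sits at
    the phantom's registered lesion-free location.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec.default)
    n_views: int = 15
    arc_span: float = 15.0
    geometry_config: Dict = field(default_factory=dict)
    fluence_per_view: float = 5.0e4
    fbp_params: rc.FBPParams = field(default_factory=rc.FBPParams)
    sart_params: rc.SARTParams = field(default_factory=rc.SARTParams)
    mlem_params: rc.MLEMParams = field(default_factory=rc.MLEMParams)
    asd_pocs_params: rc.ASDPOCSParams = field(default_factory=rc.ASDPOCSParams)
    seeds: Sequence[int] = (0,)
    profile_half_length: float = 1.5
    #: y-offset (mm) from a mass centre to its lesion-free background ROI
    cnr_background_offset_mm: float = 4.5
    output_dir: Optional[str] = None

    def __post_init__(self):
        if len(self.seeds) == 0:
            raise ConfigurationError("seeds must be nonempty")
        if self.fluence_per_view is not None and self.fluence_per_view <= 0:
            raise ConfigurationError("fluence_per_view must be positive")

    # -- construction helpers ----------------------------------------------

    def geometry(self, n_views: Optional[int] = None) -> AcquisitionGeometry:
        return make_geometry(
            n_views or self.n_views, self.arc_span, self.geometry_config
        )

    def operator(self, geometry: Optional[AcquisitionGeometry] = None) -> SystemOperator:
        return SystemOperator(
            geometry or self.geometry(),
            volume_shape=self.phantom.shape,
            voxel_size=self.phantom.voxel_size,
        )

    def params_for(self, algorithm: str):
        return {
            "fbp": self.fbp_params,
            "sart": self.sart_params,
            "mlem": self.mlem_params,
            "asd_pocs": self.asd_pocs_params,
        }[algorithm]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            ph = dict(kwargs["phantom"])
            for key in ("shape", "voxel_size", "background_center"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            for key in ("mc_inserts", "mass_inserts"):
                if key in ph:
                    from .synthetic_data import Insert

                    ph[key] = [
                        Insert(
                            kind=i["kind"],
                            diameter=i["diameter"],
                            center=tuple(i["center"]),
                            attenuation=i["attenuation"],
                        )
                        for i in ph[key]
                    ]
            kwargs["phantom"] = PhantomSpec(**ph)
        for name, pcls in (
            ("fbp_params", rc.FBPParams),
            ("sart_params", rc.SARTParams),
            ("mlem_params", rc.MLEMParams),
            ("asd_pocs_params", rc.ASDPOCSParams),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = pcls(**kwargs[name])
        if "seeds" in kwargs:
            kwargs["seeds"] = tuple(int(s) for s in kwargs["seeds"])
        return cls(**kwargs)


@dataclass
class ComparisonReport:
    """Normal-vs-half comparison output.

    ``records`` is the tidy per-measurement table (one MetricRecord per row);
    ``table`` is the wide per-(seed, algorithm, kernel, n_views) layout with
    rate-of-change columns on the 7-view rows; ``summary`` aggregates the
    wide table across seeds (mean and standard error).
    """

    records: pd.DataFrame
    table: pd.DataFrame
    summary: pd.DataFrame
    view_hashes: Dict[int, Dict[int, str]] = field(default_factory=dict)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "metric_records.csv", index=False)
        self.table.to_csv(out / "comparison_table.csv", index=False)
        self.summary.to_csv(out / "comparison_summary.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                self.summary.to_dict(orient="records"), fh, indent=2, default=float
            )


# ---------------------------------------------------------------------------
# shared per-seed machinery
# ---------------------------------------------------------------------------


def _acquire(config: ExperimentConfig, seed: int, op: SystemOperator):
    """Phantom + noisy 15-view acquisition + thinned 7-view arm for one seed."""
    spec = PhantomSpec(**{**config.phantom.__dict__, "seed": seed})
    phantom = build_phantom(spec)
    full = simulate_acquisition(
        phantom, op, config.fluence_per_view, seed=seed + _NOISE_SEED_OFFSET
    )
    half = thin_projections(full)
    return phantom, full, half


def _measure_variant(
    config: ExperimentConfig,
    phantom: PhantomVolume,
    recon: rc.ReconVolume,
    seed: int,
    algorithm: str,
    kernel: Optional[str],
    n_views: int,
) -> List[mx.MetricRecord]:
    """FWHM per MC and CNR per mass on one reconstruction's in-focus plane."""
    records = []
    spec = phantom.spec
    vz, vy, vx = spec.voxel_size

    for reg in phantom.insert_registry:
        if reg.kind != "microcalcification":
            continue
        flags, value = "", np.nan
        try:
            value = mx.fwhm_of_insert(
                recon.data,
                reg.center_voxel,
                config.profile_half_length,
                voxel_size=spec.voxel_size,
            )
        except (mx.MeasurementFailure, ContractError) as exc:
            flags = f"fwhm_failed:{exc}"
        records.append(
            mx.MetricRecord(
                seed, algorithm, kernel, n_views, "fwhm_mm",
                f"mc_{reg.diameter_mm:g}mm", value, flags,
            )
        )

    for reg in phantom.insert_registry:
        if reg.kind != "mass":
            continue
        shape = mx.FEATURE_ROI_SHAPES.get(reg.diameter_mm)
        if shape is None:
            # fall back to the insert's pixel footprint
            n = int(round(reg.diameter_mm / vy))
            shape = (n, n)
        kz = int(round(reg.center_voxel[0]))
        # background ROI adjacent to the mass: same structural neighbourhood
        bg_center = (
            reg.center_voxel[1] + config.cnr_background_offset_mm / vy,
            reg.center_voxel[2],
        )
        flags, value = "", np.nan
        try:
            value, _ = mx.cnr(
                recon.data[kz],
                (reg.center_voxel[1], reg.center_voxel[2]),
                bg_center,
                shape,
            )
        except (mx.MeasurementFailure, ContractError) as exc:
            flags = f"cnr_failed:{exc}"
        records.append(
            mx.MetricRecord(
                seed, algorithm, kernel, n_views, "cnr",
                f"mass_{reg.diameter_mm:g}mm", value, flags,
            )
        )
    return records


def _in_focus_slice(phantom: PhantomVolume) -> int:
    regs = phantom.insert_registry
    if regs:
        return int(round(regs[0].center_voxel[0]))
    return phantom.data.shape[0] // 2


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


def run_parameter_sweep(
    config: ExperimentConfig,
    alpha_grid: Sequence[float],
    ng_grid: Sequence[int],
) -> pd.DataFrame:
    """ASD-POCS metric surface over an (α, ng) grid.

    For every grid cell and every configured seed the 15-view acquisition is
    reconstructed with ASD-POCS and FWHM (per MC), CNR (per mass) and the
    background ROI standard deviation are recorded.  Failures are recorded
    per cell and the sweep continues.
    """
    if len(alpha_grid) == 0 or len(ng_grid) == 0:
        raise ConfigurationError("parameter grids must be nonempty")
    op = config.operator()
    rows = []
    for seed in config.seeds:
        phantom, full, _ = _acquire(config, seed, op)
        spec = phantom.spec
        bg_y, bg_x = spec.background_center
        vy = spec.voxel_size[1]
        bg_center = (bg_y / vy + (spec.shape[1] - 1) / 2.0,
                     bg_x / spec.voxel_size[2] + (spec.shape[2] - 1) / 2.0)
        kz = _in_focus_slice(phantom)
        for alpha in alpha_grid:
            for ng in ng_grid:
                params = rc.ASDPOCSParams(
                    **{**config.asd_pocs_params.__dict__, "alpha": alpha, "ng": ng}
                )
                row = {"seed": seed, "alpha": alpha, "ng": ng, "flags": ""}
                try:
                    recon = rc.asd_pocs(full, op, params)
                    for reg in phantom.insert_registry:
                        try:
                            if reg.kind == "microcalcification":
                                row[f"fwhm_mc_{reg.diameter_mm:g}mm"] = (
                                    mx.fwhm_of_insert(
                                        recon.data,
                                        reg.center_voxel,
                                        config.profile_half_length,
                                        voxel_size=spec.voxel_size,
                                    )
                                )
                            else:
                                shape = mx.FEATURE_ROI_SHAPES.get(
                                    reg.diameter_mm, (21, 21)
                                )
                                val, _ = mx.cnr(
                                    recon.data[int(round(reg.center_voxel[0]))],
                                    (reg.center_voxel[1], reg.center_voxel[2]),
                                    (
                                        reg.center_voxel[1]
                                        + config.cnr_background_offset_mm / vy,
                                        reg.center_voxel[2],
                                    ),
                                    shape,
                                )
                                row[f"cnr_mass_{reg.diameter_mm:g}mm"] = val
                        except (mx.MeasurementFailure, ContractError) as exc:
                            row["flags"] += f"{reg.kind}:{exc};"
                    bg = mx._roi_box(recon.data[kz], bg_center, (21, 21))
                    row["bg_sd"] = float(np.std(bg, ddof=1))
                except Exception as exc:  # reconstruction failure: flag, continue
                    row["flags"] += f"recon_failed:{exc}"
                rows.append(row)
    return pd.DataFrame(rows)


def run_convergence_study(
    config: ExperimentConfig, max_iterations: int
) -> Dict[str, List[mx.ConvergenceRecord]]:
    """RMSE/QI between consecutive iterates for SART, MLEM and ASD-POCS.

    Runs each algorithm for ``max_iterations`` outer iterations on the
    15-view acquisition of the first configured seed and records, at every
    iteration ≥ 1, the root-mean-square difference and universal quality
    index between the current and previous volume iterate.
    """
    if max_iterations < 2:
        raise ConfigurationError("max_iterations must be >= 2")
    op = config.operator()
    seed = config.seeds[0]
    _, full, _ = _acquire(config, seed, op)
    out: Dict[str, List[mx.ConvergenceRecord]] = {}
    for algorithm in ("sart", "mlem", "asd_pocs"):
        iterates: List[np.ndarray] = []

        def grab(it, x, _store=iterates):
            _store.append(x)

        base = config.params_for(algorithm)
        params = type(base)(**{**base.__dict__, "n_iterations": max_iterations})
        rc.reconstruct(algorithm, full, op, params, callback=grab)
        recs = []
        for it in range(1, len(iterates)):
            prev, curr = iterates[it - 1], iterates[it]
            recs.append(
                mx.ConvergenceRecord(
                    iteration=it,
                    rmse_prev_curr=mx.rmse(prev, curr),
                    qi_prev_curr=mx.qi(prev, curr),
                )
            )
        out[algorithm] = recs
    return out


def run_projection_comparison(config: ExperimentConfig) -> ComparisonReport:
    """The normal-vs-half design over all configured seeds.

    Per seed: one noisy 15-view acquisition; the 7-view arm is produced by
    thinning (never re-simulated; per-view SHA-256 hashes are kept so subset
    purity is checkable); the five algorithm variants are reconstructed at
    both view counts with the study iteration defaults; FWHM, CNR, MSSIM
    (7-view objective against the 15-view reference, in-focus plane) and
    rate-of-change are tabulated.
    """
    op_full = config.operator()
    records: List[mx.MetricRecord] = []
    view_hashes: Dict[int, Dict[int, str]] = {}
    for seed in config.seeds:
        phantom, full, half = _acquire(config, seed, op_full)
        op_half = SystemOperator(
            half.geometry, op_full.volume_shape, op_full.voxel_size
        )
        view_hashes[seed] = {
            v: hashlib.sha256(np.ascontiguousarray(full.data[v]).tobytes()).hexdigest()
            for v in range(full.geometry.n_views)
        }
        kz = _in_focus_slice(phantom)
        recons: Dict[Tuple[str, Optional[str], int], rc.ReconVolume] = {}
        for algorithm, kernel in VARIANTS:
            for proj, op, n_views in ((full, op_full, full.geometry.n_views),
                                      (half, op_half, half.geometry.n_views)):
                params = config.params_for(algorithm)
                if algorithm == "fbp":
                    params = rc.FBPParams(kernel=kernel, filter_axis=params.filter_axis)
                try:
                    recon = rc.reconstruct(algorithm, proj, op, params)
                except Exception as exc:
                    records.append(
                        mx.MetricRecord(
                            seed, algorithm, kernel, n_views, "recon", None,
                            np.nan, f"recon_failed:{exc}",
                        )
                    )
                    continue
                recons[(algorithm, kernel, n_views)] = recon
                records.extend(
                    _measure_variant(
                        config, phantom, recon, seed, algorithm, kernel, n_views
                    )
                )
        # MSSIM: 15-view reconstruction is the reference, 7-view the objective
        n15, n7 = full.geometry.n_views, half.geometry.n_views
        for algorithm, kernel in VARIANTS:
            ref = recons.get((algorithm, kernel, n15))
            obj = recons.get((algorithm, kernel, n7))
            if ref is None or obj is None:
                continue
            value = mx.mssim(ref.data[kz], obj.data[kz])
            records.append(
                mx.MetricRecord(
                    seed, algorithm, kernel, n7, "mssim", "in_focus_plane", value
                )
            )
    rec_df = pd.DataFrame([r.__dict__ for r in records])
    table = _widen(rec_df)
    summary = _summarise(table)
    return ComparisonReport(
        records=rec_df, table=table, summary=summary, view_hashes=view_hashes
    )


def _widen(rec_df: pd.DataFrame) -> pd.DataFrame:
    df = rec_df[rec_df.metric != "recon"].copy()
    df["kernel"] = df["kernel"].fillna("")
    df["column"] = np.where(
        df.target_insert.isna() | (df.metric == "mssim"),
        df.metric,
        df.metric.str.cat(df.target_insert, sep="_"),
    )
    wide = df.pivot_table(
        index=["phantom_seed", "algorithm", "kernel", "n_views"],
        columns="column",
        values="value",
        dropna=False,
        observed=True,
    ).reset_index()
    wide.columns.name = None
    # keep only combinations that were actually measured (pivot_table
    # expands the index to the full cartesian product of its levels)
    observed = df[
        ["phantom_seed", "algorithm", "kernel", "n_views"]
    ].drop_duplicates()
    wide = wide.merge(observed, how="inner")
    # rate-of-change columns live on the half-projection rows
    n_views_sorted = sorted(wide.n_views.unique(), reverse=True)
    if len(n_views_sorted) == 2:
        n15, n7 = n_views_sorted
        keys = ["phantom_seed", "algorithm", "kernel"]
        metric_cols = [c for c in wide.columns if c.startswith(("fwhm", "cnr"))]
        ref = wide[wide.n_views == n15][keys + metric_cols]
        merged = wide[keys].merge(ref, on=keys, how="left")
        for col in metric_cols:
            with np.errstate(divide="ignore", invalid="ignore"):
                roc = (
                    100.0
                    * (wide[col].to_numpy() - merged[col].to_numpy())
                    / merged[col].to_numpy()
                )
            wide[f"{col}_rate_of_change_pct"] = np.where(
                wide.n_views.to_numpy() == n7, roc, np.nan
            )
    return wide


def _summarise(table: pd.DataFrame) -> pd.DataFrame:
    value_cols = [
        c for c in table.columns
        if c not in ("phantom_seed", "algorithm", "kernel", "n_views")
    ]
    grouped = table.groupby(["algorithm", "kernel", "n_views"], dropna=False)
    mean = grouped[value_cols].mean()
    sem = grouped[value_cols].sem()
    out = mean.join(sem, lsuffix="_mean", rsuffix="_sem").reset_index()
    return out
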