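"""Pipeline orchestration: geometry -> strain -> CV_T -> monodomain ->
protocol -> metrics, with all intermediate artifacts written to disk."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, analysis, ionic, monodomain as md, protocols as pr
from .config import RunConfig, config_hash, save_config
from .errors import ValidationError
from .geometry import (LAYER_CODES, REGION_CODES, InfarctDensityField,
                       InfarctSpec, Mesh, assign_infarct,
                       assign_infarct_radial, assign_layers, build_fixture,
                       build_lv_mesh)
from .strain_cv import CVField, StrainCVParams, cvt_field, discretize_cvt
from .synthetic_strain import generate_strain_field
from .vtkio import write_vtu

__all__ = ["PipelineResult", "build_geometry", "build_cvt",
           "run_pipeline", "sweep_sensitivity"]


@dataclass
class PipelineResult:
    mesh: Mesh
    density: InfarctDensityField
    strain: object
    cvt: CVField
    metrics: dict
    window: pr.VulnerableWindow | None
    outdir: Path | None


def build_geometry(cfg: RunConfig) -> tuple[Mesh, InfarctDensityField]:
    g = cfg.geometry
    if g.kind == "lv":
        mesh = build_lv_mesh(g.wall_volume, g.cavity_volume,
                             g.truncation_fraction, g.resolution)
        from .geometry import assign_fibers
        assign_fibers(mesh, g.helix_endo, g.helix_epi)
        assign_layers(mesh, g.layer_fractions)
        if g.infarct:
            mesh, dens = assign_infarct(mesh, InfarctSpec(
                height_extent=tuple(g.height_extent),
                transmurality=g.transmurality,
                bz_thickness=g.bz_thickness,
                angular_extent=g.angular_extent))
        else:
            dens = InfarctDensityField.healthy(mesh.n_nodes)
        return mesh, dens

    lengths = g.lengths if len(np.atleast_1d(g.lengths)) > 1 else g.lengths[0]
    mesh = build_fixture(g.kind, lengths, g.resolution)
    if g.fibers_transverse:
        # propagation along the first axis / loop exercises CV_T
        mesh.fiber_vectors = mesh.frame_l.copy()
    if g.uniform_layer is not None:
        mesh.layer_label[:] = LAYER_CODES[g.uniform_layer]
    else:
        assign_layers(mesh, g.layer_fractions)
    if g.infarct:
        center = (np.asarray(g.core_center, float) if g.core_center is not None
                  else mesh.nodes.mean(axis=0))
        mesh, dens = assign_infarct_radial(mesh, center, g.core_radius,
                                           g.bz_thickness)
    else:
        dens = InfarctDensityField.healthy(mesh.n_nodes)
    return mesh, dens


def build_cvt(cfg: RunConfig, mesh: Mesh, dens: InfarctDensityField,
              strain, discretized: bool = True) -> CVField:
    """CV_T field for the configured model variant.

    The extended variant is discretized into the configured number of
    levels for imposing conductivities; pass ``discretized=False`` for the
    raw law output, which the distribution metrics (histogram, slow-CV
    volume) are computed on.
    """
    if cfg.model_variant == "reference":
        cvt = np.full(mesh.n_nodes, cfg.ref_cvt_remote)
        cvt[mesh.region_label == REGION_CODES["structural_bz"]] = cfg.ref_cvt_bz
        cvt[mesh.region_label == REGION_CODES["core"]] = 0.0
        return CVField(cvt, cv_long=cfg.cv_long)
    field = cvt_field(strain, dens, cfg.strain_cv, cv_long=cfg.cv_long)
    return discretize_cvt(field, cfg.n_levels) if discretized else field


def _pacing_site(cfg: RunConfig, mesh: Mesh) -> np.ndarray:
    if cfg.pacing_site is not None:
        return np.asarray(cfg.pacing_site, float)
    if cfg.geometry.kind in ("sheet", "slab", "cable"):
        # first-axis start, mid transverse: planar-ish entry wave
        c = mesh.nodes.mean(axis=0)
        return np.array([mesh.nodes[:, 0].min(), c[1], c[2]])
    return pr.place_pacing_sites(mesh, 1)[0]


def run_pipeline(cfg: RunConfig, write: bool = True) -> PipelineResult:
    """Execute all stages; idempotent for identical config + seed."""
    t_start = time.time()
    timings = {}

    t0 = time.time()
    mesh, dens = build_geometry(cfg)
    timings["geometry"] = time.time() - t0

    t0 = time.time()
    strain = generate_strain_field(mesh, cfg.strain)
    timings["strain"] = time.time() - t0

    t0 = time.time()
    cvt = build_cvt(cfg, mesh, dens, strain)
    cvt_raw = build_cvt(cfg, mesh, dens, strain, discretized=False)
    timings["cvt"] = time.time() - t0

    t0 = time.time()
    levels = sorted(set(np.unique(cvt.cvt)) - {0.0}) + [cfg.cv_long]
    cal = md.build_calibration(levels, resolution=cfg.geometry.resolution,
                               dt=cfg.dt)
    params = md.assemble_conductivity(mesh, cfg.cv_long, cvt, cal)
    params.dt = cfg.dt
    timings["calibration"] = time.time() - t0

    t0 = time.time()
    cells = md.tissue_cells(mesh, bcl=cfg.stress.s1_bcl,
                            n_beats=cfg.cell_warm_beats)
    model = pr.TissueModel(mesh, params, cells)
    timings["cells"] = time.time() - t0

    # S1-only run for the substrate metrics
    t0 = time.time()
    site = _pacing_site(cfg, mesh)
    s = cfg.stress
    stims = [md.StimulusSpec(center=site, onset=1.0 + k * s.s1_bcl,
                             diameter=s.stim_diameter,
                             amplitude=s.stim_amplitude,
                             duration=s.stim_duration)
             for k in range(s.n_s1)]
    rec = md.solve_monodomain(mesh, params, cells, stims,
                              s.n_s1 * s.s1_bcl + 300.0)
    rt = analysis.repolarization_map(rec)
    rtg = analysis.rtg_metrics(analysis.rtg_map(rt, mesh))
    timings["simulate"] = time.time() - t0

    metrics = {
        "model_variant": cfg.model_variant,
        "rtg_vol_ml": rtg.rtg_vol,
        "rtg_mean_ms_per_mm": rtg.rtg_mean,
        "slow_cv_volume_ml": analysis.slow_cv_volume(cvt_raw, mesh),
        "wall_volume_ml": mesh.wall_volume_ml(),
        "config_hash": config_hash(cfg),
    }

    window = None
    if cfg.run_stress_test:
        t0 = time.time()
        window = pr.StressTest(model, s).scan()
        metrics["vulnerable_window_total_ms"] = window.total_width()
        timings["stress_test"] = time.time() - t0

    outdir = None
    if write:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_config(cfg, outdir / "config.yaml")
        write_vtu(mesh, outdir / "fields.vtu",
                  point_data={
                      "fact": dens.fact, "fpas": dens.fpas,
                      "region_label": mesh.region_label.astype(np.int64),
                      "layer_label": mesh.layer_label.astype(np.int64),
                      "strain_amplitude": strain.eps, "cvt": cvt.cvt,
                      "repolarization_time": np.nan_to_num(rt, nan=-1.0),
                  },
                  cell_data={"fiber": mesh.fiber_vectors})
        pd.DataFrame([metrics]).to_csv(outdir / "metrics.csv", index=False)
        with open(outdir / "metrics.json", "w") as f:
            json.dump(metrics, f, indent=2)
        if window is not None:
            window.to_frame().to_csv(outdir / "vulnerable_window.csv")
        with open(outdir / "log.json", "w") as f:
            json.dump({"version": __version__, "seed": cfg.seed,
                       "config_hash": metrics["config_hash"],
                       "timings_s": timings,
                       "total_s": time.time() - t_start}, f, indent=2)
    return PipelineResult(mesh, dens, strain, cvt, metrics, window, outdir)


def sweep_sensitivity(cfg: RunConfig, alpha_factors=(0.5, 0.7, 1.0, 1.5, 2.5),
                      eps_ref_factors=(1.22, 1.11, 1.0, 0.89, 0.78),
                      pairs=None) -> pd.DataFrame:
    """Sensitivity of the RTG metrics to the strain-CV law parameters.

    Varies alpha and eps_ref one axis at a time relative to the config's
    baseline (the shared 100%/100% setting is run once), plus optional
    explicit (alpha_factor, eps_factor) pairs -- conventionally larger alpha
    with smaller eps_ref, where the curves overlap in the low-CV_T range.
    Metrics use a single pacing site.
    """
    settings = []
    for fa in alpha_factors:
        settings.append((float(fa), 1.0))
    for fe in eps_ref_factors:
        if (1.0, float(fe)) not in settings:
            settings.append((1.0, float(fe)))
    for p in pairs or []:
        p = (float(p[0]), float(p[1]))
        if p not in settings:
            settings.append(p)

    base = cfg.strain_cv
    rows = []
    for fa, fe in settings:
        p = StrainCVParams(cvt_ref=base.cvt_ref, cvt_var=base.cvt_var,
                           alpha=base.alpha * fa, eps_ref=base.eps_ref * fe)
        sub = RunConfig(**{**cfg.__dict__, "strain_cv": p,
                           "run_stress_test": False})
        res = run_pipeline(sub, write=False)
        rows.append({"alpha_factor": fa, "eps_ref_factor": fe,
                     "alpha": p.alpha, "eps_ref": p.eps_ref,
                     "rtg_vol_ml": res.metrics["rtg_vol_ml"],
                     "rtg_mean_ms_per_mm": res.metrics["rtg_mean_ms_per_mm"],
                     "slow_cv_volume_ml": res.metrics["slow_cv_volume_ml"]})
    return pd.DataFrame(rows)
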