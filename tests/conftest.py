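"""Shared fixtures.

The expensive simulation experiments (single-cell pacing trains, CV
calibration, the transmural cable, the paired reference-vs-extended sheet,
the ring reentry scans) are session-scoped so every test file shares one
computation.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from straincv import analysis, ionic
from straincv import monodomain as md
from straincv import protocols as pr
from straincv.geometry import (LAYER_CODES, REGION_CODES, assign_infarct_radial,
                               assign_layers, build_fixture)
from straincv.strain_cv import CVField, StrainCVParams, cvt_field, discretize_cvt
from straincv.synthetic_strain import StrainProfileSpec, generate_strain_field

try:  # derandomize hypothesis where available
    from hypothesis import settings as _hs

    _hs.register_profile("ci", derandomize=True, max_examples=50)
    _hs.load_profile("ci")
except ImportError:
    pass


# ---------------------------------------------------------------------------
# single-cell steady states


@pytest.fixture(scope="session")
def steady_apds():
    """Intrinsic APD per layer after the 500-beat train at BCL 600 ms."""
    out = {}
    for layer in ionic.LAYER_NAMES:
        params = ionic.make_cell_params(layer, "remote")
        trace, _ = ionic.pace_cell(params, ionic.PacingSpec())
        out[layer] = ionic.measure_apd(trace)
    return out


# ---------------------------------------------------------------------------
# conductivity calibration at the working resolution (0.5 mm)


@pytest.fixture(scope="session")
def cal05():
    """{CV target [m/s] -> diffusivity [mm^2/ms]} at 0.5 mm resolution."""
    return md.build_calibration([0.6, 0.3, 0.08], resolution=0.5)


# ---------------------------------------------------------------------------
# transmural cable (manifested APDs)


@dataclass
class CableResult:
    mesh: object
    apd: np.ndarray
    intrinsic_range: float


@pytest.fixture(scope="session")
def transmural_cable(cal05, steady_apds):
    """Four-layer transmural cable paced with 6 S1 beats at 600 ms through
    transverse (0.3 m/s) coupling; per-node manifested APD of the last beat."""
    mesh = build_fixture("cable", 14.0, 0.5)
    assign_layers(mesh)
    cells = md.tissue_cells(mesh)
    params = md.TissueParams(tensors=md.isotropic_tensors(mesh, cal05[0.3]))
    stims = [md.StimulusSpec(center=(0.0, 0.0, 0.0), onset=1.0 + k * 600.0,
                             diameter=3.0) for k in range(6)]
    rec = md.solve_monodomain(mesh, params, cells, stims, 6 * 600.0)
    act = rec.first_activation(rec.stim_onsets[-1], rec.t_end)
    rt = analysis.repolarization_map(rec)
    apd = rt - act
    rng = max(steady_apds.values()) - min(steady_apds.values())
    return CableResult(mesh, apd, rng)


# ---------------------------------------------------------------------------
# paired sheet experiment: reference vs extended CV_T


@dataclass
class PairedSheet:
    mesh: object
    metrics_ref: analysis.RTGMetrics
    metrics_ext: analysis.RTGMetrics
    slow_vol_ref: float
    slow_vol_ext: float
    apd_remote: float
    apd_bz: float
    rt_ref: np.ndarray


def _sheet_infarct_model():
    mesh = build_fixture("sheet", (25.0, 25.0), 0.5)
    # fibers along y: propagation along x exercises the transverse CV
    mesh.fiber_vectors = np.tile([0.0, 1.0, 0.0], (mesh.n_elements, 1))
    mesh, dens = assign_infarct_radial(mesh, (12.5, 12.5, 0.0), 3.0, 6.0)
    mesh.layer_label[:] = LAYER_CODES["mid"]
    return mesh, dens


@pytest.fixture(scope="session")
def paired_sheet(cal05):
    """S1 runs of the reference and strain-extended conduction models on one
    synthetic infarct sheet."""
    mesh, dens = _sheet_infarct_model()
    n = mesh.n_nodes
    pcv = StrainCVParams()
    strain = generate_strain_field(mesh, StrainProfileSpec())
    cv_ext_cont = cvt_field(strain, dens, pcv)  # metrics use the raw law
    cv_ext = discretize_cvt(cv_ext_cont, 9)     # conduction uses levels
    cvt_ref = np.full(n, 0.3)
    cvt_ref[mesh.region_label == REGION_CODES["structural_bz"]] = 0.08
    cvt_ref[mesh.region_label == REGION_CODES["core"]] = 0.0
    cv_ref = CVField(cvt_ref)
    cells = md.tissue_cells(mesh)

    def run(cv):
        levels = sorted(set(np.unique(cv.cvt)) - {0.0})
        cal = md.build_calibration(levels + [0.6], resolution=0.5)
        tp = md.assemble_conductivity(mesh, 0.6, cv, cal)
        stims = [md.StimulusSpec(center=(0.0, 12.5, 0.0), onset=1.0 + k * 600.0)
                 for k in range(2)]
        rec = md.solve_monodomain(mesh, tp, cells, stims, 2 * 600.0 + 300.0)
        rt = analysis.repolarization_map(rec)
        act = rec.first_activation(rec.stim_onsets[-1], rec.t_end)
        met = analysis.rtg_metrics(analysis.rtg_map(rt, mesh))
        return rt, act, met

    rt_ref, act_ref, met_ref = run(cv_ref)
    rt_ext, act_ext, met_ext = run(cv_ext)
    apd = rt_ref - act_ref
    return PairedSheet(
        mesh, met_ref, met_ext,
        analysis.slow_cv_volume(cv_ref, mesh),
        analysis.slow_cv_volume(cv_ext_cont, mesh),
        float(np.nanmean(apd[mesh.region_label == REGION_CODES["remote"]])),
        float(np.nanmean(apd[mesh.region_label == REGION_CODES["structural_bz"]])),
        rt_ref)


# ---------------------------------------------------------------------------
# ring reentry: vulnerable windows with and without a slow-CV_T halo


def _ring_model(halo: bool):
    L = 80.0
    mesh = build_fixture("ring", L, 0.5)
    n = mesh.n_nodes
    mesh.fiber_vectors = np.tile([0.0, 0.0, 1.0], (mesh.n_elements, 1))
    s = L * np.arange(n) / n
    bz = (s >= 30) & (s < 50)
    mesh.region_label[:] = 0
    mesh.region_label[bz] = REGION_CODES["structural_bz"]
    mesh.layer_label[:] = LAYER_CODES["mid"]
    cvt = np.full(n, 0.3)
    cvt[bz] = 0.08
    if halo:
        cvt[((s >= 24) & (s < 30)) | ((s >= 50) & (s < 56))] = 0.12
    cal = md.build_calibration([0.08, 0.12, 0.3], resolution=0.5)
    tp = md.assemble_conductivity(mesh, 0.3, CVField(cvt), cal)
    cells = md.tissue_cells(mesh)
    model = pr.TissueModel(mesh, tp, cells)
    site = mesh.nodes[int(26 / 0.5)]
    return model, site


@dataclass
class RingWindows:
    width_control: float
    width_halo: float
    window_halo: pr.VulnerableWindow
    test_halo: pr.StressTest


@pytest.fixture(scope="session")
def ring_windows():
    results = {}
    for halo in (False, True):
        model, site = _ring_model(halo)
        spec = pr.StressTestSpec(pacing_sites=[site], n_s1=2,
                                 s2_min=240.0, s2_max=420.0)
        st = pr.StressTest(model, spec)
        with np.errstate(all="ignore"):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                vw = st.scan()
        results[halo] = (vw, st)
    return RingWindows(results[False][0].width(0), results[True][0].width(0),
                       results[True][0], results[True][1])


# ---------------------------------------------------------------------------
# healthy negative control


@pytest.fixture(scope="session")
def healthy_scan():
    """Homogeneous healthy sheet: S2 bounds exist but no interval induces VT."""
    mesh = build_fixture("sheet", (12.0, 12.0), 0.5)
    mesh.layer_label[:] = LAYER_CODES["mid"]
    cells = md.tissue_cells(mesh)
    cal = md.build_calibration([0.3], resolution=0.5)
    tp = md.assemble_conductivity(mesh, 0.3,
                                  CVField(np.full(mesh.n_nodes, 0.3)), cal)
    model = pr.TissueModel(mesh, tp, cells)
    spec = pr.StressTestSpec(pacing_sites=[np.array([0.0, 6.0, 0.0])], n_s1=2,
                             s2_min=220.0, s2_max=320.0)
    st = pr.StressTest(model, spec)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        vw = st.scan()
    return vw
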