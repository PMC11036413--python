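"""Monodomain solver: propagation, CV measurement, conductivity
calibration and tensor assembly."""

import numpy as np
import pytest

from straincv import ionic
from straincv import monodomain as md
from straincv.errors import CalibrationError, MeasurementError
from straincv.geometry import build_fixture
from straincv.strain_cv import CVField


@pytest.fixture(scope="module")
def base_cell_state():
    return md._warm_cell_state(ionic.CellParams())


def _cable_run(d, length=20.0, res=0.5, duration=80.0, state=None,
               stim_center=(0.0, 0.0, 0.0)):
    mesh = build_fixture("cable", length, res)
    cells = md.uniform_cells(mesh, ionic.CellParams(), state)
    params = md.TissueParams(tensors=md.isotropic_tensors(mesh, d))
    stim = md.StimulusSpec(center=stim_center, onset=1.0, diameter=2.0)
    rec = md.solve_monodomain(mesh, params, cells, [stim], duration)
    return mesh, rec


class TestSolver:
    def test_quiescence_without_stimulus(self, base_cell_state):
        mesh = build_fixture("cable", 10.0, 0.5)
        cells = md.uniform_cells(mesh, ionic.CellParams(), base_cell_state)
        params = md.TissueParams(tensors=md.isotropic_tensors(mesh, 0.1))
        rec = md.solve_monodomain(mesh, params, cells, [], 100.0,
                                  keep_final_states=True)
        assert rec.act_times.size == 0
        assert np.all(np.abs(rec.final_states[:, 0]
                             - cells.states[:, 0]) < 1.0)

    def test_mid_cable_symmetry(self, base_cell_state):
        mesh, rec = _cable_run(0.1, state=base_cell_state,
                               stim_center=(10.0, 0.0, 0.0))
        fa = rec.first_activation()
        x = mesh.nodes[:, 0]
        left = fa[np.argsort(x)][:20]
        right = fa[np.argsort(-x)][:20]
        np.testing.assert_allclose(left, right, atol=0.15)

    def test_dt_refinement_changes_cv_little(self, base_cell_state, cal05):
        cvs = {}
        for dt in (0.02, 0.01):
            mesh = build_fixture("slab", (20.0, 2.0, 1.0), 0.5)
            cells = md.uniform_cells(mesh, ionic.CellParams(), base_cell_state)
            params = md.TissueParams(
                dt=dt, tensors=md.isotropic_tensors(mesh, cal05[0.6]))
            stim_nodes = np.nonzero(mesh.nodes[:, 0] <= 1.0 + 1e-9)[0]
            rec = md._planar_wave(mesh, params, cells, stim_nodes, 60.0)
            cvs[dt] = md.measure_cv(rec, (6, 1, 0.5), (14, 1, 0.5), mesh)
        assert abs(cvs[0.01] - cvs[0.02]) / cvs[0.02] < 0.02


class TestMeasureCV:
    def _analytic_record(self, mesh):
        x = mesh.nodes[:, 0]
        return md.SolutionRecord(mesh.n_nodes, 100.0,
                                 act_nodes=np.arange(mesh.n_nodes),
                                 act_times=x / 0.6)

    def test_analytic_record(self):
        mesh = build_fixture("cable", 20.0, 0.5)
        rec = self._analytic_record(mesh)
        cv = md.measure_cv(rec, (5, 0, 0), (15, 0, 0), mesh)
        assert cv == pytest.approx(0.6, rel=1e-6)

    def test_probe_symmetry(self):
        mesh = build_fixture("cable", 20.0, 0.5)
        rec = self._analytic_record(mesh)
        a = md.measure_cv(rec, (5, 0, 0), (15, 0, 0), mesh)
        b = md.measure_cv(rec, (15, 0, 0), (5, 0, 0), mesh)
        assert a == pytest.approx(b)

    def test_unactivated_probe(self):
        mesh = build_fixture("cable", 20.0, 0.5)
        rec = md.SolutionRecord(mesh.n_nodes, 100.0,
                                act_nodes=np.array([0]),
                                act_times=np.array([1.0]))
        with pytest.raises(MeasurementError):
            md.measure_cv(rec, (5, 0, 0), (15, 0, 0), mesh)


class TestCalibration:
    def test_sqrt_sigma_scaling(self, base_cell_state):
        """Continuum oracle: quadrupling the conductivity doubles CV.

        Checked in the well-resolved regime (0.25 mm elements, moderate
        velocities); fast waves on coarse grids inflate numerical CV,
        which is exactly why the calibration is resolution-keyed.
        """
        mesh, rec1 = _cable_run(0.05, res=0.125, state=base_cell_state,
                                duration=140.0)
        cv1 = md.measure_cv(rec1, (6, 0, 0), (14, 0, 0), mesh)
        _, rec4 = _cable_run(0.20, res=0.125, state=base_cell_state,
                             duration=140.0)
        cv4 = md.measure_cv(rec4, (6, 0, 0), (14, 0, 0), mesh)
        assert cv4 / cv1 == pytest.approx(2.0, rel=0.10)

    def test_zero_target_fails(self):
        with pytest.raises(CalibrationError):
            md.calibrate_conductivity(0.0)

    def test_calibration_is_resolution_specific(self, cal05):
        assert set(cal05) == {0.6, 0.3, 0.08}
        assert cal05[0.6] > cal05[0.3] > cal05[0.08] > 0


class TestAssembly:
    def test_anisotropy_ratio_and_core_zero(self, cal05):
        mesh = build_fixture("cable", 5.0, 1.0)
        cvt = np.full(mesh.n_nodes, 0.3)
        cvt[:2] = 0.0  # first element all-core
        tp = md.assemble_conductivity(mesh, 0.6, CVField(cvt), cal05)
        np.testing.assert_array_equal(tp.tensors[0], np.zeros((3, 3)))
        w = np.linalg.eigvalsh(tp.tensors[-1])
        assert w.max() == pytest.approx(cal05[0.6])
        assert w.min() == pytest.approx(cal05[0.3])
        assert w.max() / w.min() == pytest.approx(cal05[0.6] / cal05[0.3])

    def test_isotropic_when_cvt_equals_cvl(self, cal05):
        mesh = build_fixture("cable", 5.0, 1.0)
        tp = md.assemble_conductivity(
            mesh, 0.3, CVField(np.full(mesh.n_nodes, 0.3)), cal05)
        np.testing.assert_allclose(tp.tensors[0],
                                   cal05[0.3] * np.eye(3), atol=1e-15)

    def test_missing_level_listed(self, cal05):
        mesh = build_fixture("cable", 5.0, 1.0)
        with pytest.raises(CalibrationError, match="0.2"):
            md.assemble_conductivity(
                mesh, 0.6, CVField(np.full(mesh.n_nodes, 0.2)), cal05)


class TestElectrotonic:
    def test_tissue_apd_range_smaller_than_intrinsic(self, transmural_cable):
        """Electrotonic coupling compresses the transmural APD range
        relative to the isolated-cell (intrinsic) range."""
        apd = transmural_cable.apd
        rng = np.nanmax(apd) - np.nanmin(apd)
        assert 0.0 < rng < transmural_cable.intrinsic_range
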