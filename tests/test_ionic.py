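"""Single-cell membrane model, remodeling scalings, APD measurement."""

import numpy as np
import pytest

from straincv import _tt06, ionic
from straincv.errors import MeasurementError, ValidationError


class TestCellParams:
    @pytest.mark.parametrize("layer,region,expect", [
        ("endo", "remote", {"gks_scale": 2.10, "gna_scale": 1.0}),
        ("mid", "remote", {"gks_scale": 1.30}),
        ("sub_endo", "remote", {"gks_scale": 0.95}),
        ("epi", "structural_bz",
         {"gna_scale": 0.38, "gcal_scale": 0.31, "gkr_scale": 0.30,
          "gks_scale": 2.45 * 0.20}),
    ])
    def test_layer_region_scalings(self, layer, region, expect):
        p = ionic.make_cell_params(layer, region)
        for k, v in expect.items():
            assert getattr(p, k) == pytest.approx(v)

    def test_layer_independent_bz(self):
        p = ionic.make_cell_params("epi", "structural_bz",
                                   bz_layer_gradient=False)
        assert p.gks_scale == pytest.approx(0.20)

    def test_unknown_labels(self):
        with pytest.raises(ValidationError):
            ionic.make_cell_params("papillary")
        with pytest.raises(ValidationError):
            ionic.make_cell_params("endo", "lava")

    def test_negative_scale_rejected(self):
        with pytest.raises(ValidationError):
            ionic.CellParams(gks_scale=-0.1)

    def test_pacing_validation(self):
        with pytest.raises(ValidationError):
            ionic.PacingSpec(n_beats=0)
        with pytest.raises(ValidationError):
            ionic.PacingSpec(bcl=1.0, duration=2.0)


class TestDynamics:
    def test_rest_is_stationary(self):
        trace, state = ionic.free_run(ionic.CellParams(), 1000.0)
        assert np.max(np.abs(trace.vm - trace.vm[0])) < 1.0

    def test_steady_state_reached(self):
        params = ionic.make_cell_params("mid")
        _, s100 = ionic.pace_cell(params, ionic.PacingSpec(n_beats=100))
        t1, s101 = ionic.pace_cell(params, ionic.PacingSpec(n_beats=1),
                                   initial=s100)
        t2, _ = ionic.pace_cell(params, ionic.PacingSpec(n_beats=1),
                                initial=s101)
        a1, a2 = ionic.measure_apd(t1), ionic.measure_apd(t2)
        assert abs(a1 - a2) < 1.0

    def test_bz_depresses_upstroke_and_peak(self):
        pace = ionic.PacingSpec(n_beats=30)
        tr_rem, _ = ionic.pace_cell(ionic.make_cell_params("mid", "remote"), pace)
        tr_bz, _ = ionic.pace_cell(
            ionic.make_cell_params("mid", "structural_bz"), pace)

        def dvdt_max(tr):
            return np.max(np.diff(tr.vm) / np.diff(tr.t))

        assert dvdt_max(tr_bz) < dvdt_max(tr_rem)
        assert tr_bz.vm.max() < tr_rem.vm.max()

    def test_gks_monotonically_shortens_apd(self, steady_apds):
        by_scale = sorted(ionic.LAYER_GKS_SCALE.items(), key=lambda kv: kv[1])
        apds = [steady_apds[layer] for layer, _ in by_scale]
        assert all(a > b for a, b in zip(apds, apds[1:]))

    def test_tabulated_kernel_matches_exact(self):
        """The table-interpolated tissue kernel reproduces the reference
        kernel's action potential to sub-millisecond APD accuracy."""
        dt = 0.02
        tab, k1tab = _tt06.build_tables(dt)
        base = ionic.CellParams().base_vector()
        scales = np.ones((1, 4))
        y_ex = _tt06.initial_state().reshape(1, -1).copy()
        y_tab = y_ex.copy()
        istim = np.zeros(1)
        traces = {"exact": [], "tab": []}
        n = int(500.0 / dt)
        for k in range(n):
            istim[0] = 40.0 if k * dt < 2.0 else 0.0
            _tt06.step_nodes(y_ex, scales, base, istim, dt)
            _tt06.step_nodes_tab(y_tab, scales, base, istim, dt, tab, k1tab)
            if k % 5 == 0:
                traces["exact"].append(y_ex[0, 0])
                traces["tab"].append(y_tab[0, 0])
        t = np.arange(len(traces["exact"])) * 5 * dt
        a_ex = ionic.measure_apd(ionic.Trace(t, np.array(traces["exact"])))
        a_tab = ionic.measure_apd(ionic.Trace(t, np.array(traces["tab"])))
        assert abs(a_ex - a_tab) < 1.0


class TestMeasureAPD:
    def _trace(self):
        t = np.arange(0.0, 400.0, 0.5)
        vm = np.full(t.size, -85.0)
        vm[(t >= 10.0) & (t < 210.0)] = 0.0  # upstroke at 10, drop at 210
        return ionic.Trace(t, vm)

    def test_square_pulse(self):
        assert ionic.measure_apd(self._trace()) == pytest.approx(200.0, abs=1.0)

    def test_no_repolarization(self):
        t = np.arange(0.0, 100.0, 0.5)
        vm = np.where(t > 10, 0.0, -85.0)
        with pytest.raises(MeasurementError):
            ionic.measure_apd(ionic.Trace(t, vm))

    def test_no_upstroke(self):
        t = np.arange(0.0, 100.0, 0.5)
        with pytest.raises(MeasurementError):
            ionic.measure_apd(ionic.Trace(t, np.full(t.size, -85.0)))


class TestStateCheckpoint:
    def test_hdf5_roundtrip(self, tmp_path):
        st = ionic.steady_state("epi", bcl=600.0, n_beats=2)
        path = tmp_path / "states.h5"
        ionic.save_states(path)
        backup = dict(ionic._STEADY_CACHE)
        try:
            ionic._STEADY_CACHE.clear()
            n = ionic.load_states(path)
            assert n >= 1
            st2 = ionic.steady_state("epi", bcl=600.0, n_beats=2)
            np.testing.assert_array_equal(st.y, st2.y)
        finally:
            ionic._STEADY_CACHE.update(backup)
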