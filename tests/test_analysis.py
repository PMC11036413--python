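"""Repolarization maps, RTG metrics, slow-CV volume, CV_T histograms."""

import numpy as np
import pytest

from straincv import analysis, monodomain as md
from straincv.errors import ValidationError
from straincv.geometry import REGION_CODES, build_fixture
from straincv.strain_cv import CVField


class TestRepolarizationMap:
    def test_requires_stimuli(self):
        rec = md.SolutionRecord(5, 100.0)
        with pytest.raises(ValidationError):
            analysis.repolarization_map(rec)

    def test_wave_ordering_and_missing(self):
        """Planar wave: repolarization times increase along the cable;
        never-activated nodes are missing."""
        n = 10
        act = np.arange(n) * 2.0 + 5.0
        rep = act + 200.0
        rec = md.SolutionRecord(
            n, 400.0,
            act_nodes=np.arange(n - 2), act_times=act[:-2],
            rep_nodes=np.arange(n - 2), rep_times=rep[:-2],
            stim_onsets=[0.0])
        rt = analysis.repolarization_map(rec)
        assert np.all(np.diff(rt[:-2]) > 0)
        assert np.all(np.isnan(rt[-2:]))


class TestRTG:
    def test_uniform_rt_zero_gradient(self):
        mesh = build_fixture("sheet", (10.0, 10.0), 1.0)
        m = analysis.rtg_map(np.full(mesh.n_nodes, 50.0), mesh)
        np.testing.assert_allclose(m.magnitudes, 0.0, atol=1e-12)

    @pytest.mark.parametrize("kind,lengths", [
        ("cable", 10.0), ("sheet", (10.0, 6.0)), ("slab", (8.0, 4.0, 3.0))])
    def test_linear_field_exact(self, kind, lengths):
        mesh = build_fixture(kind, lengths, 1.0)
        rt = 12.0 * mesh.nodes[:, 0]
        m = analysis.rtg_map(rt, mesh)
        np.testing.assert_allclose(m.magnitudes, 12.0, rtol=1e-9)

    def test_smooth_field_matches_finite_differences(self):
        """Interior nodes (where a central stencil exists) agree with the
        analytic gradient to well under 1%."""
        mesh = build_fixture("slab", (20.0, 4.0, 3.0), 0.5)
        x, y, z = mesh.nodes.T
        rt = 30.0 * np.sin(2 * np.pi * x / 40.0)
        m = analysis.rtg_map(rt, mesh)
        exact = np.abs(30.0 * 2 * np.pi / 40.0 * np.cos(2 * np.pi * x / 40.0))
        interior = ((x > 1.0) & (x < 19.0) & (exact > 1.0)
                    & (y > 0.4) & (y < 3.6) & (z > 0.4) & (z < 2.6))
        err = np.abs(m.magnitudes[interior] - exact[interior]) / exact[interior]
        assert err.max() < 0.01

    def test_step_concentrates_gradient(self):
        mesh = build_fixture("cable", 10.0, 0.5)
        rt = np.where(mesh.nodes[:, 0] < 5.0, 100.0, 160.0)
        m = analysis.rtg_map(rt, mesh)
        # the two nodes flanking the step tie for the maximum magnitude
        assert abs(mesh.nodes[np.argmax(m.magnitudes), 0] - 5.0) <= 0.5
        assert m.magnitudes.max() > 10 * np.median(m.magnitudes)


class TestRTGMetrics:
    def _uniform_map(self, mag, vol_ml=2.0, n=100):
        return analysis.RTGMap(np.full(n, float(mag)),
                               np.full(n, vol_ml * 1000.0 / n))

    def test_uniform_above_threshold(self):
        met = analysis.rtg_metrics(self._uniform_map(12.0))
        assert met.rtg_vol == pytest.approx(2.0)
        assert met.rtg_mean == pytest.approx(12.0)
        assert not met.empty

    def test_uniform_below_threshold(self):
        met = analysis.rtg_metrics(self._uniform_map(5.0))
        assert met.rtg_vol == 0.0 and met.empty

    def test_half_domain(self):
        mags = np.concatenate([np.full(50, 15.0), np.full(50, 5.0)])
        m = analysis.RTGMap(mags, np.full(100, 20.0))
        met = analysis.rtg_metrics(m)
        assert met.rtg_vol == pytest.approx(1.0)
        assert met.rtg_mean == pytest.approx(15.0)

    def test_mean_at_least_threshold_when_nonempty(self):
        rng = np.random.default_rng(0)
        m = analysis.RTGMap(rng.uniform(0, 30, 200), np.full(200, 10.0))
        met = analysis.rtg_metrics(m)
        assert met.rtg_mean >= 10.0
        assert met.rtg_vol <= 2.0  # never exceeds total volume

    def test_negative_threshold(self):
        with pytest.raises(ValidationError):
            analysis.rtg_metrics(self._uniform_map(5.0), threshold=-1.0)


class TestSlowVolumeAndHistogram:
    def test_no_slow_tissue(self):
        mesh = build_fixture("cable", 10.0, 1.0)
        assert analysis.slow_cv_volume(
            CVField(np.full(mesh.n_nodes, 0.3)), mesh) == 0.0

    def test_known_slow_volume(self):
        mesh = build_fixture("slab", (10.0, 10.0, 10.0), 1.0)
        cvt = np.where(mesh.nodes[:, 0] <= 5.0, 0.08, 0.3)
        vol = analysis.slow_cv_volume(CVField(cvt), mesh)
        nv = mesh.node_volumes()
        assert vol == pytest.approx(nv[mesh.nodes[:, 0] <= 5.0].sum() / 1000.0)

    def test_extended_slowing_exceeds_reference(self, paired_sheet):
        """Strain-extension enlarges the severely slowed volume (and the
        RTG volume) relative to the image-based reference model."""
        assert paired_sheet.slow_vol_ext >= paired_sheet.slow_vol_ref

    def test_histogram_conservation(self):
        mesh = build_fixture("sheet", (10.0, 10.0), 1.0)
        rng = np.random.default_rng(1)
        cvt = rng.choice([0.1, 0.2, 0.3], mesh.n_nodes)
        edges, vols = analysis.cvt_histogram(CVField(cvt), mesh)
        assert vols.sum() == pytest.approx(mesh.wall_volume_ml())
        assert len(vols) == 3  # one bin per discrete level

    def test_uniform_single_bin(self):
        mesh = build_fixture("cable", 10.0, 1.0)
        edges, vols = analysis.cvt_histogram(
            CVField(np.full(mesh.n_nodes, 0.3)), mesh)
        assert vols.sum() == pytest.approx(mesh.wall_volume_ml())
        assert (vols > 0).sum() == 1


class TestPairedSheetExperiment:
    def test_bz_repolarizes_later_via_longer_apd(self, paired_sheet):
        assert paired_sheet.apd_bz > paired_sheet.apd_remote + 10.0

    def test_core_is_missing_in_rt_map(self, paired_sheet):
        core = paired_sheet.mesh.region_label == REGION_CODES["core"]
        assert np.all(np.isnan(paired_sheet.rt_ref[core]))
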