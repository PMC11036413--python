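"""Geometry: LV shell, fibers, layers, infarct labeling, fixtures."""

import numpy as np
import pytest

from straincv.errors import GeometryError, ValidationError
from straincv.geometry import (InfarctSpec, LAYER_CODES, REGION_CODES,
                               assign_fibers, assign_infarct,
                               assign_infarct_radial, assign_layers,
                               build_fixture, build_lv_mesh)


@pytest.fixture(scope="module")
def lv_coarse():
    return build_lv_mesh(136.0, 44.0, resolution=2.5)


class TestFixtures:
    def test_cable_node_count(self):
        mesh = build_fixture("cable", 20.0, 0.25)
        assert mesh.n_nodes == 81

    def test_slab_volume(self):
        mesh = build_fixture("slab", (20.0, 5.0, 5.0), 1.0)
        assert mesh.wall_volume_ml() == pytest.approx(0.5, rel=1e-9)

    @pytest.mark.parametrize("kind,lengths", [
        ("cable", 10.0), ("ring", 30.0), ("sheet", (10.0, 8.0)),
        ("slab", (8.0, 4.0, 2.0))])
    def test_fixture_invariants(self, kind, lengths):
        mesh = build_fixture(kind, lengths, 0.5)
        mesh.validate()  # unit fibers, positive volumes, label codes
        assert np.all(mesh.region_label == REGION_CODES["remote"])

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            build_fixture("cable", -1.0, 0.5)
        with pytest.raises(ValidationError):
            build_fixture("pyramid", 1.0, 0.5)


class TestLVMesh:
    def test_wall_volume_converges(self):
        errs = []
        for res in (4.0, 2.0):
            mesh = build_lv_mesh(136.0, 44.0, resolution=res)
            errs.append(abs(mesh.wall_volume_ml() - 136.0) / 136.0)
        assert errs[1] < errs[0]
        assert errs[1] < 0.01

    def test_infeasible_volumes(self):
        with pytest.raises(GeometryError):
            build_lv_mesh(136.0, 0.0)
        with pytest.raises(GeometryError):
            build_lv_mesh(-5.0, 44.0)

    def test_coordinates_and_fibers(self, lv_coarse):
        mesh = lv_coarse
        assert mesh.transmural.min() == 0.0 and mesh.transmural.max() == 1.0
        assert np.all((mesh.height >= 0) & (mesh.height <= 1))
        norms = np.linalg.norm(mesh.fiber_vectors, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_helix_midpoint(self, lv_coarse):
        mesh = assign_fibers(lv_coarse, 60.0, -60.0)
        u = mesh.element_mean(mesh.transmural)
        mid = np.abs(u - 0.5) < 0.02
        # at mid-wall the helix angle vanishes: fibers lie along e_c
        cosang = np.abs(np.einsum("ij,ij->i", mesh.fiber_vectors[mid],
                                  mesh.frame_c[mid]))
        assert np.all(cosang > np.cos(np.deg2rad(8.0)))

    def test_flat_slab_zero_helix(self):
        mesh = build_fixture("slab", (10.0, 4.0, 2.0), 1.0)
        assign_fibers(mesh, 0.0, 0.0)
        np.testing.assert_allclose(mesh.fiber_vectors,
                                   np.tile([1.0, 0, 0], (mesh.n_elements, 1)),
                                   atol=1e-12)


class TestLayers:
    def test_bin_membership(self):
        mesh = build_fixture("cable", 10.0, 1.0)  # transmural = x/L
        assign_layers(mesh, (0.25, 0.25, 0.25, 0.25))
        node = np.argmin(np.abs(mesh.transmural - 0.1))
        assert mesh.layer_label[node] == LAYER_CODES["endo"]

    def test_degenerate_all_endo(self):
        mesh = build_fixture("cable", 10.0, 1.0)
        assign_layers(mesh, (1.0, 0.0, 0.0, 0.0))
        assert np.all(mesh.layer_label == LAYER_CODES["endo"])

    def test_partition_of_volume(self, lv_coarse):
        mesh = assign_layers(lv_coarse)
        nv = mesh.node_volumes()
        per_layer = [nv[mesh.layer_label == c].sum() for c in range(4)]
        assert sum(per_layer) == pytest.approx(nv.sum())
        assert all(v > 0 for v in per_layer)

    def test_bad_fractions(self):
        mesh = build_fixture("cable", 10.0, 1.0)
        with pytest.raises(ValidationError):
            assign_layers(mesh, (0.3, 0.3, 0.3, 0.3))


class TestInfarct:
    def test_radial_fact_ramp(self):
        # structured sheet: nearest-core-node distance is exact along x
        mesh = build_fixture("sheet", (20.0, 4.0), 0.5)
        mesh, dens = assign_infarct_radial(mesh, (0.0, 2.0, 0.0), 4.0, 8.0)
        x = mesh.nodes[:, 0]
        mid_row = mesh.nodes[:, 1] == 2.0
        core = mid_row & (x <= 4.0)
        assert np.all(dens.fact[core] == 0.0)
        assert np.all(dens.fpas[core] == 10.0)
        at_mid = mid_row & np.isclose(x, 8.0)   # halfway across the BZ
        assert dens.fact[at_mid] == pytest.approx(0.5)
        at_outer = mid_row & np.isclose(x, 12.0)  # BZ outer boundary
        assert dens.fact[at_outer] == pytest.approx(1.0)
        assert np.all(mesh.region_label[at_outer] == REGION_CODES["structural_bz"])

    def test_partition_disjoint_exhaustive(self, lv_coarse):
        mesh, dens = assign_infarct(lv_coarse, InfarctSpec())
        counts = np.bincount(mesh.region_label, minlength=3)
        assert counts.sum() == mesh.n_nodes
        assert np.all(counts > 0)

    def test_transmural_core_fact_zero(self, lv_coarse):
        mesh, dens = assign_infarct(lv_coarse, InfarctSpec(transmurality=1.0))
        core = mesh.region_label == REGION_CODES["core"]
        assert np.all(dens.fact[core] == 0.0)

    def test_total_infarct_volume_default(self, lv_coarse):
        # default angular extent is calibrated to ~15 mL core+BZ
        mesh, dens = assign_infarct(lv_coarse, InfarctSpec())
        nv = mesh.node_volumes()
        vol = nv[mesh.region_label > 0].sum() / 1000.0
        assert vol == pytest.approx(15.0, rel=0.15)

    def test_fact_lipschitz_along_distance(self, lv_coarse):
        mesh, dens = assign_infarct(lv_coarse, InfarctSpec())
        bz = mesh.region_label == REGION_CODES["structural_bz"]
        from scipy.spatial import cKDTree

        core = mesh.region_label == REGION_CODES["core"]
        d, _ = cKDTree(mesh.nodes[core]).query(mesh.nodes[bz], k=1)
        np.testing.assert_allclose(dens.fact[bz], d / 9.0, atol=1e-9)

    def test_empty_core_warns(self):
        mesh = build_fixture("cable", 10.0, 1.0)  # height = 0.5 everywhere
        with pytest.warns(UserWarning):
            mesh, dens = assign_infarct(
                mesh, InfarctSpec(height_extent=(0.8, 0.9)))
        assert np.all(dens.fact == 1.0)
        assert np.all(mesh.region_label == REGION_CODES["remote"])
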