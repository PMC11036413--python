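"""Idealized left-ventricular geometry, fibers, layers and infarct labeling.

The LV is a truncated prolate-ellipsoid shell meshed by a structured
(transmural x meridional x circumferential) grid split into tetrahedra.
Myofibers follow a rule-based helix-angle field varying linearly across the
wall; transmural layers and the infarct core / structural border zone (BZ)
are assigned from the normalized transmural and height coordinates.  Small
1D/2D/3D fixtures (cable, ring, sheet, slab) share the same Mesh container
so the electrophysiology stack can be exercised at desk scale.

Units: lengths mm, volumes reported in mL (1 mL = 1000 mm^3). Node indices
are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve
from scipy.spatial import cKDTree

from .errors import GeometryError, ValidationError

__all__ = [
    "Mesh", "InfarctSpec", "InfarctDensityField",
    "build_lv_mesh", "assign_fibers", "assign_layers", "assign_infarct",
    "build_fixture",
    "REGION_CODES", "LAYER_CODES",
]

REGION_CODES = {"remote": 0, "structural_bz": 1, "core": 2}
LAYER_CODES = {"endo": 0, "sub_endo": 1, "mid": 2, "epi": 3}

_NODES_PER_ELEM = {"line": 2, "triangle": 3, "tetra": 4}


@dataclass
class Mesh:
    """Unstructured mesh with per-node labels and per-element fibers.

    nodes          (N, 3) coordinates [mm]
    elements       (M, k) connectivity, k = 2 (line), 3 (triangle), 4 (tetra)
    element_type   "line" | "triangle" | "tetra"
    fiber_vectors  (M, 3) unit fiber direction per element
    transmural     (N,) normalized wall-depth coordinate, 0 = endo, 1 = epi
    height         (N,) normalized long-axis coordinate, 0 = apex, 1 = base
    region_label   (N,) codes from REGION_CODES
    layer_label    (N,) codes from LAYER_CODES (-1 = unassigned)
    cross_section  [mm^2] converts line-element length to volume
    thickness      [mm] converts triangle area to volume
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_type: str
    fiber_vectors: np.ndarray | None = None
    transmural: np.ndarray | None = None
    height: np.ndarray | None = None
    region_label: np.ndarray | None = None
    layer_label: np.ndarray | None = None
    cross_section: float = 1.0
    thickness: float = 1.0
    # local orthonormal frame per element (circumferential, longitudinal)
    # used by the helix-angle fiber rule
    frame_c: np.ndarray | None = None
    frame_l: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float)
        self.elements = np.asarray(self.elements, np.int64)
        if self.element_type not in _NODES_PER_ELEM:
            raise ValidationError(f"unknown element type {self.element_type!r}")
        if self.elements.shape[1] != _NODES_PER_ELEM[self.element_type]:
            raise ValidationError("connectivity width does not match element type")
        if self.region_label is None:
            self.region_label = np.zeros(self.n_nodes, np.int8)
        if self.layer_label is None:
            self.layer_label = np.full(self.n_nodes, -1, np.int8)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_volumes(self) -> np.ndarray:
        """Per-element volume [mm^3]."""
        x = self.nodes[self.elements]
        if self.element_type == "line":
            return np.linalg.norm(x[:, 1] - x[:, 0], axis=1) * self.cross_section
        if self.element_type == "triangle":
            a, b = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]
            return 0.5 * np.linalg.norm(np.cross(a, b), axis=1) * self.thickness
        a, b, c = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
        return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0

    def node_volumes(self) -> np.ndarray:
        """Lumped nodal volumes [mm^3]: each element's volume split equally
        over its vertices."""
        vol = np.zeros(self.n_nodes)
        ev = self.element_volumes() / self.elements.shape[1]
        np.add.at(vol, self.elements.ravel(), np.repeat(ev, self.elements.shape[1]))
        return vol

    def wall_volume_ml(self) -> float:
        return float(self.element_volumes().sum()) / 1000.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_mean(self, node_values: np.ndarray) -> np.ndarray:
        """Average a per-node field onto elements."""
        return np.asarray(node_values, float)[self.elements].mean(axis=1)

    def edge_length(self) -> float:
        """Mean first-edge length, used as the mesh resolution estimate."""
        x = self.nodes[self.elements]
        return float(np.linalg.norm(x[:, 1] - x[:, 0], axis=1).mean())

    def validate(self) -> None:
        """Check the container invariants; raises ValidationError."""
        if self.fiber_vectors is not None:
            norms = np.linalg.norm(self.fiber_vectors, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValidationError("fiber vectors are not unit length")
        if np.any(self.element_volumes() <= 0):
            raise ValidationError("degenerate (non-positive volume) elements")
        if not np.all(np.isin(self.region_label, list(REGION_CODES.values()))):
            raise ValidationError("invalid region labels")


@dataclass
class InfarctSpec:
    """Geometric extent of the infarct core and its border zone."""

    height_extent: tuple[float, float] = (0.14, 0.51)
    transmurality: float = 1.0       # wall-depth fraction from the endocardium
    bz_thickness: float = 9.0        # [mm]
    angular_extent: float = 0.20     # [rad]; default calibrated so the
    #                                  transmural case's core+BZ volume ~ 15 mL
    angular_center: float = 0.0      # [rad]

    def __post_init__(self) -> None:
        h0, h1 = self.height_extent
        if not (0.0 <= h0 <= h1 <= 1.0):
            raise ValidationError("height_extent must satisfy 0 <= h0 <= h1 <= 1")
        if not 0.0 <= self.transmurality <= 1.0:
            raise ValidationError("transmurality must be in [0, 1]")
        if self.bz_thickness < 0:
            raise ValidationError("bz_thickness must be >= 0")
        if self.angular_extent < 0:
            raise ValidationError("angular_extent must be >= 0")


@dataclass
class InfarctDensityField:
    """Infarct-density factor fact (1 healthy -> 0 core, linear across the
    BZ) and the passive-stiffness factor fpas (1 -> 10), carried for
    completeness."""

    fact: np.ndarray
    fpas: np.ndarray

    def __post_init__(self) -> None:
        self.fact = np.asarray(self.fact, float)
        self.fpas = np.asarray(self.fpas, float)
        if np.any((self.fact < 0) | (self.fact > 1)):
            raise ValidationError("fact must lie in [0, 1]")
        if np.any(self.fpas < 1):
            raise ValidationError("fpas must be >= 1")

    @classmethod
    def healthy(cls, n_nodes: int) -> "InfarctDensityField":
        return cls(np.ones(n_nodes), np.ones(n_nodes))


# ---------------------------------------------------------------------------
# truncated-ellipsoid LV


def _ellipsoid_cap_volume(a: float, c: float, h: float) -> float:
    """Volume of x^2/a^2 + y^2/a^2 + z^2/c^2 <= 1 below the plane z = h."""
    h = min(h, c)
    return np.pi * a * a * ((h + c) - (h ** 3 + c ** 3) / (3.0 * c * c))


def _solve_lv_dimensions(wall_volume: float, cavity_volume: float,
                         truncation_fraction: float,
                         long_axis_ratio: float) -> tuple[float, float, float]:
    """Inner short semi-axis a_i, wall thickness t, basal plane height z_b."""

    def residual(x):
        a_i, t = x
        if a_i <= 0 or t <= 0:
            return [1e9, 1e9]
        c_i = long_axis_ratio * a_i
        a_o, c_o = a_i + t, c_i + t
        z_b = truncation_fraction * c_o
        cav = _ellipsoid_cap_volume(a_i, c_i, min(z_b, c_i)) / 1000.0
        outer = _ellipsoid_cap_volume(a_o, c_o, z_b) / 1000.0
        return [cav - cavity_volume, outer - cav - wall_volume]

    a0 = (cavity_volume * 1000.0 / (2.25 * np.pi)) ** (1.0 / 3.0)
    sol, info, ier, _ = fsolve(residual, [a0, 10.0], full_output=True)
    a_i, t = sol
    if ier != 1 or a_i <= 0 or t <= 0:
        raise GeometryError(
            f"no truncated ellipsoid realizes wall={wall_volume} mL, "
            f"cavity={cavity_volume} mL")
    c_o = long_axis_ratio * a_i + t
    z_b = truncation_fraction * c_o
    if z_b >= long_axis_ratio * a_i:
        raise GeometryError("basal plane lies above the endocardial apex-to-"
                            "base range; lower truncation_fraction")
    return float(a_i), float(t), float(z_b)


def build_lv_mesh(wall_volume: float = 136.0, cavity_volume: float = 44.0,
                  truncation_fraction: float = 0.5,
                  resolution: float = 1.0, *,
                  long_axis_ratio: float = 2.0) -> Mesh:
    """Truncated prolate-ellipsoid LV shell.

    The inner and outer surfaces are confocal-free ellipsoids of uniform
    wall thickness, solved so the integrated cavity and wall volumes match
    the requested values (the defaults are the 136/44 mL idealized LV); the
    basal truncation plane sits at ``truncation_fraction`` of the outer long
    semi-axis above the equator.  A sub-resolution apical puncture avoids
    the degenerate pole of the structured grid; its volume is O(resolution^4)
    and vanishes under refinement.
    """
    if wall_volume <= 0 or cavity_volume <= 0:
        raise GeometryError("wall and cavity volumes must be positive")
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    a_i, t, z_b = _solve_lv_dimensions(wall_volume, cavity_volume,
                                       truncation_fraction, long_axis_ratio)
    c_i = long_axis_ratio * a_i
    a_o, c_o = a_i + t, c_i + t

    def surf(v, a, c):
        """Point on the surface at meridional parameter v in [0, 1]."""
        z = -c + v * (z_b + c)
        r = a * np.sqrt(np.maximum(1.0 - (z / c) ** 2, 0.0))
        return r, z

    # apical puncture: first meridional station where the outer radius
    # reaches half the target resolution
    v0 = brentq(lambda v: surf(v, a_o, c_o)[0] - 0.5 * resolution, 1e-9, 0.5)

    meridian = c_o * 1.3  # generous meridional arc-length estimate
    n_u = max(2, int(round(t / resolution)))
    n_v = max(8, int(round(meridian / resolution)))
    n_phi = max(8, int(round(2.0 * np.pi * a_o / resolution)))

    u = np.linspace(0.0, 1.0, n_u + 1)
    v = np.linspace(v0, 1.0, n_v + 1)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi

    uu, vv, pp = np.meshgrid(u, v, phi, indexing="ij")
    r_in, z_in = surf(vv, a_i, c_i)
    r_out, z_out = surf(vv, a_o, c_o)
    r = (1.0 - uu) * r_in + uu * r_out
    z = (1.0 - uu) * z_in + uu * z_out
    nodes = np.stack([r * np.cos(pp), r * np.sin(pp), z], axis=-1)
    nodes = nodes.reshape(-1, 3)

    def nid(iu, iv, ip):
        return (iu * (n_v + 1) + iv) * n_phi + (ip % n_phi)

    iu, iv, ip = np.meshgrid(np.arange(n_u), np.arange(n_v), np.arange(n_phi),
                             indexing="ij")
    iu, iv, ip = iu.ravel(), iv.ravel(), ip.ravel()
    hexes = np.stack([
        nid(iu, iv, ip), nid(iu + 1, iv, ip),
        nid(iu + 1, iv + 1, ip), nid(iu, iv + 1, ip),
        nid(iu, iv, ip + 1), nid(iu + 1, iv, ip + 1),
        nid(iu + 1, iv + 1, ip + 1), nid(iu, iv + 1, ip + 1),
    ], axis=1)
    # six tetrahedra per hexahedron sharing the 0-6 diagonal
    tet_local = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
                 (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]
    elements = np.concatenate([hexes[:, list(tl)] for tl in tet_local], axis=0)

    transmural = np.repeat(u, (n_v + 1) * n_phi)
    z_all = nodes[:, 2]
    height = (z_all + c_o) / (z_b + c_o)

    mesh = Mesh(nodes, elements, "tetra", transmural=transmural,
                height=np.clip(height, 0.0, 1.0))

    # local frame per hexahedron, repeated over its six tetrahedra
    cen = nodes[hexes].mean(axis=1)
    phi_c = np.arctan2(cen[:, 1], cen[:, 0])
    e_c = np.stack([-np.sin(phi_c), np.cos(phi_c), np.zeros_like(phi_c)], axis=1)
    ev = (nodes[hexes[:, 3]] + nodes[hexes[:, 7]]
          - nodes[hexes[:, 0]] - nodes[hexes[:, 4]])  # meridional edge average
    ev -= (ev * e_c).sum(axis=1, keepdims=True) * e_c
    e_l = ev / np.linalg.norm(ev, axis=1, keepdims=True)
    mesh.frame_c = np.concatenate([e_c] * 6, axis=0)
    mesh.frame_l = np.concatenate([e_l] * 6, axis=0)

    assign_fibers(mesh)
    return mesh


def assign_fibers(mesh: Mesh, helix_endo: float = 60.0,
                  helix_epi: float = -60.0) -> Mesh:
    """Rule-based myofiber field: the helix angle varies linearly in the
    transmural coordinate from ``helix_endo`` (endo) to ``helix_epi`` (epi),
    within each element's local circumferential-longitudinal plane."""
    if mesh.transmural is None:
        raise ValidationError("mesh lacks a transmural coordinate")
    if mesh.frame_c is None or mesh.frame_l is None:
        raise ValidationError("mesh lacks a local element frame")
    u = mesh.element_mean(mesh.transmural)
    alpha = np.deg2rad(helix_endo + u * (helix_epi - helix_endo))
    f = (np.cos(alpha)[:, None] * mesh.frame_c
         + np.sin(alpha)[:, None] * mesh.frame_l)
    mesh.fiber_vectors = f / np.linalg.norm(f, axis=1, keepdims=True)
    return mesh


def assign_layers(mesh: Mesh,
                  thickness_fractions=(0.25, 0.25, 0.25, 0.25)) -> Mesh:
    """Label nodes endo/sub_endo/mid/epi by transmural coordinate bins of
    the given wall-depth fractions (endo adjacent to the cavity)."""
    frac = np.asarray(thickness_fractions, float)
    if frac.size != 4 or np.any(frac < 0):
        raise ValidationError("need 4 non-negative thickness fractions")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ValidationError("thickness fractions must sum to 1")
    if mesh.transmural is None:
        raise ValidationError("mesh lacks a transmural coordinate")
    # right-continuous bins [c_{i-1}, c_i); indices falling into zero-width
    # trailing bins (degenerate fractions) are mapped down to the nearest
    # layer with positive thickness
    edges = np.cumsum(frac)[:-1]
    idx = np.searchsorted(edges, mesh.transmural, side="right")
    pos = np.nonzero(frac > 0)[0]
    idx = pos[np.clip(np.searchsorted(pos, idx, side="right") - 1, 0, None)]
    mesh.layer_label = idx.astype(np.int8)
    return mesh


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def assign_infarct(mesh: Mesh, spec: InfarctSpec
                   ) -> tuple[Mesh, InfarctDensityField]:
    """Label the infarct core and structural BZ and build the density field.

    Core: nodes inside the height/angular extent and within the requested
    transmural depth from the endocardium.  Structural BZ: nodes within
    ``bz_thickness`` (Euclidean distance to the core node set) of the core.
    fact ramps linearly 0 (core) -> 1 (BZ outer boundary); fpas 10 -> 1.
    """
    if mesh.transmural is None or mesh.height is None:
        raise ValidationError("mesh lacks transmural/height coordinates")
    h0, h1 = spec.height_extent
    phi = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    in_angle = np.abs(_wrap_angle(phi - spec.angular_center)) <= spec.angular_extent / 2.0
    core = ((mesh.height >= h0) & (mesh.height <= h1) & in_angle
            & (mesh.transmural <= spec.transmurality + 1e-12))

    fact = np.ones(mesh.n_nodes)
    region = np.zeros(mesh.n_nodes, np.int8)
    if not np.any(core):
        warnings.warn("infarct spec lies outside the mesh: empty core",
                      stacklevel=2)
        mesh.region_label = region
        return mesh, InfarctDensityField(fact, np.ones(mesh.n_nodes))

    region[core] = REGION_CODES["core"]
    fact[core] = 0.0
    rest = ~core
    if spec.bz_thickness > 0 and np.any(rest):
        tree = cKDTree(mesh.nodes[core])
        d, _ = tree.query(mesh.nodes[rest], k=1)
        bz = d <= spec.bz_thickness
        idx = np.nonzero(rest)[0]
        region[idx[bz]] = REGION_CODES["structural_bz"]
        fact[idx] = np.minimum(d / spec.bz_thickness, 1.0)
    fpas = 10.0 - 9.0 * fact
    mesh.region_label = region
    return mesh, InfarctDensityField(fact, fpas)


def assign_infarct_radial(mesh: Mesh, center, core_radius: float,
                          bz_thickness: float = 9.0
                          ) -> tuple[Mesh, InfarctDensityField]:
    """Distance-based infarct labeling for fixture meshes: core within
    ``core_radius`` of ``center``, structural BZ within ``bz_thickness``
    beyond it, fact/fpas ramping linearly across the BZ."""
    if core_radius < 0 or bz_thickness < 0:
        raise ValidationError("radii must be >= 0")
    d = np.linalg.norm(mesh.nodes - np.asarray(center, float)[None, :], axis=1)
    region = np.zeros(mesh.n_nodes, np.int8)
    core = d <= core_radius
    bz = (~core) & (d <= core_radius + bz_thickness)
    region[core] = REGION_CODES["core"]
    region[bz] = REGION_CODES["structural_bz"]
    fact = np.clip((d - core_radius) / max(bz_thickness, 1e-12), 0.0, 1.0)
    fact[core] = 0.0
    mesh.region_label = region
    return mesh, InfarctDensityField(fact, 10.0 - 9.0 * fact)


# ---------------------------------------------------------------------------
# desk-scale fixtures


def build_fixture(kind: str, lengths, resolution: float, *,
                  cross_section: float = 1.0, thickness: float = 1.0) -> Mesh:
    """Regular cable / ring / sheet / slab fixture.

    ``lengths`` is a scalar (cable: length; ring: circumference) or a tuple
    (sheet: Lx, Ly; slab: Lx, Ly, Lz) in mm.  Fibers run along the first
    axis (the local tangent on rings), all nodes are remote, and the
    transmural coordinate runs along x so layered cables come for free.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    dims = np.atleast_1d(np.asarray(lengths, float))
    if np.any(dims <= 0):
        raise ValidationError("fixture dimensions must be positive")

    if kind == "cable":
        (L,) = dims
        n = int(round(L / resolution)) + 1
        x = np.linspace(0.0, L, n)
        nodes = np.column_stack([x, np.zeros(n), np.zeros(n)])
        elements = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        mesh = Mesh(nodes, elements, "line", cross_section=cross_section,
                    transmural=x / L, height=np.full(n, 0.5))
        mesh.frame_c = np.tile([1.0, 0.0, 0.0], (n - 1, 1))
        mesh.frame_l = np.tile([0.0, 1.0, 0.0], (n - 1, 1))
        mesh.fiber_vectors = mesh.frame_c.copy()
        return mesh

    if kind == "ring":
        (L,) = dims
        n = int(round(L / resolution))
        theta = 2.0 * np.pi * np.arange(n) / n
        radius = L / (2.0 * np.pi)
        nodes = np.column_stack([radius * np.cos(theta),
                                 radius * np.sin(theta), np.zeros(n)])
        elements = np.column_stack([np.arange(n), (np.arange(n) + 1) % n])
        mesh = Mesh(nodes, elements, "line", cross_section=cross_section,
                    transmural=np.full(n, 0.5), height=theta / (2.0 * np.pi))
        tang = nodes[elements[:, 1]] - nodes[elements[:, 0]]
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        mesh.frame_c = tang
        mesh.frame_l = np.tile([0.0, 0.0, 1.0], (n, 1))
        mesh.fiber_vectors = tang.copy()
        return mesh

    if kind == "sheet":
        Lx, Ly = dims
        nx = int(round(Lx / resolution)) + 1
        ny = int(round(Ly / resolution)) + 1
        X, Y = np.meshgrid(np.linspace(0, Lx, nx), np.linspace(0, Ly, ny),
                           indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])

        def nid(i, j):
            return i * ny + j

        i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
        i, j = i.ravel(), j.ravel()
        quad = np.stack([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1),
                         nid(i, j + 1)], axis=1)
        # checkerboard the split diagonal to avoid directional grid bias
        even = (i + j) % 2 == 0
        tri_a = np.where(even[:, None], quad[:, [0, 1, 2]], quad[:, [0, 1, 3]])
        tri_b = np.where(even[:, None], quad[:, [0, 2, 3]], quad[:, [1, 2, 3]])
        elements = np.concatenate([tri_a, tri_b], axis=0)
        mesh = Mesh(nodes, elements, "triangle", thickness=thickness,
                    transmural=np.full(nx * ny, 0.5),
                    height=nodes[:, 1] / Ly)
        m = elements.shape[0]
        mesh.frame_c = np.tile([1.0, 0.0, 0.0], (m, 1))
        mesh.frame_l = np.tile([0.0, 1.0, 0.0], (m, 1))
        mesh.fiber_vectors = mesh.frame_c.copy()
        return mesh

    if kind == "slab":
        Lx, Ly, Lz = dims
        nx = int(round(Lx / resolution)) + 1
        ny = int(round(Ly / resolution)) + 1
        nz = int(round(Lz / resolution)) + 1
        X, Y, Z = np.meshgrid(np.linspace(0, Lx, nx), np.linspace(0, Ly, ny),
                              np.linspace(0, Lz, nz), indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

        def nid3(i, j, k):
            return (i * ny + j) * nz + k

        i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                              np.arange(nz - 1), indexing="ij")
        i, j, k = i.ravel(), j.ravel(), k.ravel()
        hexes = np.stack([
            nid3(i, j, k), nid3(i + 1, j, k), nid3(i + 1, j + 1, k),
            nid3(i, j + 1, k), nid3(i, j, k + 1), nid3(i + 1, j, k + 1),
            nid3(i + 1, j + 1, k + 1), nid3(i, j + 1, k + 1)], axis=1)
        tet_local = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
                     (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]
        elements = np.concatenate([hexes[:, list(tl)] for tl in tet_local],
                                  axis=0)
        mesh = Mesh(nodes, elements, "tetra",
                    transmural=np.full(nodes.shape[0], 0.5),
                    height=nodes[:, 1] / Ly)
        m = elements.shape[0]
        mesh.frame_c = np.tile([1.0, 0.0, 0.0], (m, 1))
        mesh.frame_l = np.tile([0.0, 1.0, 0.0], (m, 1))
        mesh.fiber_vectors = mesh.frame_c.copy()
        return mesh

    raise ValidationError(f"unknown fixture kind {kind!r}")
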