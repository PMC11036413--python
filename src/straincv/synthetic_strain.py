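"""Synthetic fiber-strain-amplitude fields.

Stand-in for a finite-element mechanics simulation: it reproduces the
spatial structure that weak electromechanical coupling transmits to the
electrophysiology model -- a transmural epi -> endo increase of strain
amplitude in remote tissue, depressed amplitudes (~0.15) in the structural
border zone whose contractile function is impaired, and elevated amplitudes
in the bulging (passively stretched) infarct core -- without computing any
stresses.  PV-loops, stroke volumes and ejection fractions are outside its
scope.

The remote transmural endpoints default to eps_endo = 0.230 and
eps_epi = 0.143; through the default strain-CV law these map to transverse
velocities of 0.49 and 0.20 m/s, the bounds of the healthy CV_T
distribution, anchoring the profile without inventing figure-derived
constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .geometry import Mesh, REGION_CODES
from .strain_cv import StrainField

__all__ = ["StrainProfileSpec", "generate_strain_field"]


@dataclass
class StrainProfileSpec:
    """Shape of the synthetic strain-amplitude field."""

    eps_endo: float = 0.230       # remote amplitude at the endocardium
    eps_epi: float = 0.143        # remote amplitude at the epicardium
    bz_amplitude: float = 0.15    # depressed amplitude mid structural BZ
    core_amplitude: float = 0.25  # elevated amplitude in the bulging core
    halo_amplitude: float = 0.08  # minimum at the BZ outer boundary, where
    #                               tethering to the stiff scar depresses
    #                               strain below the BZ-interior plateau;
    #                               low enough that severe conduction slowing
    #                               (CV_T <= 0.1 m/s) extends into remote
    #                               tissue, as observed for infarcted LVs
    halo_width: float = 3.0       # [mm] depressed shelf in remote tissue
    #                               beyond the structural BZ (the functional
    #                               border zone) before recovery begins
    transition_width: float = 5.0  # [mm] blending length into remote tissue
    noise_sd: float = 0.0         # spatial Gaussian noise (dimensionless)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eps_endo", "eps_epi", "bz_amplitude", "core_amplitude",
                     "halo_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.eps_endo < self.eps_epi:
            raise ValidationError("eps_endo must be >= eps_epi")
        if self.core_amplitude <= self.bz_amplitude:
            raise ValidationError("core_amplitude must exceed bz_amplitude "
                                  "(core bulging)")
        if self.transition_width <= 0:
            raise ValidationError("transition_width must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _blend_weight(dist: np.ndarray, width: float) -> np.ndarray:
    """Linear taper: 1 at distance 0, 0 beyond ``width``."""
    return np.clip(1.0 - dist / width, 0.0, 1.0)


def generate_strain_field(mesh: Mesh, spec: StrainProfileSpec = StrainProfileSpec()
                          ) -> StrainField:
    """Per-node strain amplitudes with the infarct's spatial signature.

    Remote tissue follows the transmural profile
    eps(u) = eps_endo + u (eps_epi - eps_endo).  Core nodes take
    core_amplitude (passive bulging), BZ nodes sit on the bz_amplitude
    plateau blended toward the core value at the inner edge and toward
    halo_amplitude -- the field minimum -- at the outer edge, and remote
    nodes within ``transition_width`` of the structural region are pulled
    toward halo_amplitude too (the functional border zone, where tethering
    to the stiff scar depresses strain below the remote profile).  Optional
    per-node Gaussian noise is smoothed by one neighbor-averaging pass and
    is reproducible from ``seed``.
    """
    if mesh.transmural is None:
        raise ValidationError("mesh lacks a transmural coordinate")
    u = mesh.transmural
    eps = spec.eps_endo + u * (spec.eps_epi - spec.eps_endo)

    region = mesh.region_label
    bz = region == REGION_CODES["structural_bz"]
    core = region == REGION_CODES["core"]
    struct = bz | core
    if np.any(struct):
        target = np.where(core, spec.core_amplitude, spec.bz_amplitude)
        if np.any(bz):
            ibz = np.nonzero(bz)[0]
            val = np.full(ibz.size, spec.bz_amplitude)
            if np.any(core):
                d_core = cKDTree(mesh.nodes[core]).query(mesh.nodes[bz], k=1)[0]
                w = _blend_weight(d_core, spec.transition_width)
                val += w * (spec.core_amplitude - spec.bz_amplitude)
            if np.any(~struct):
                d_out = cKDTree(mesh.nodes[~struct]).query(mesh.nodes[bz], k=1)[0]
                w = _blend_weight(d_out, spec.transition_width)
                val += w * (spec.halo_amplitude - spec.bz_amplitude)
            target[ibz] = val
        eps[struct] = target[struct]
        # functional border zone: a depressed shelf of halo_width beyond the
        # structural boundary, then linear recovery over transition_width
        remote_idx = np.nonzero(~struct)[0]
        if remote_idx.size:
            d = cKDTree(mesh.nodes[struct]).query(mesh.nodes[remote_idx], k=1)[0]
            w = _blend_weight(np.maximum(d - spec.halo_width, 0.0),
                              spec.transition_width)
            eps[remote_idx] = (w * spec.halo_amplitude
                               + (1.0 - w) * eps[remote_idx])

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, mesh.n_nodes)
        # one neighbor-averaging (Laplacian) pass for spatial smoothness
        acc = noise.copy()
        cnt = np.ones(mesh.n_nodes)
        elems = mesh.elements
        for a in range(elems.shape[1]):
            for b in range(elems.shape[1]):
                if a == b:
                    continue
                np.add.at(acc, elems[:, a], noise[elems[:, b]])
                np.add.at(cnt, elems[:, a], 1.0)
        eps = eps + acc / cnt

    return StrainField(np.maximum(eps, 0.0))
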