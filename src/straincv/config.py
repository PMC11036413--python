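"""YAML run configuration.

One config describes the whole pipeline: geometry, synthetic strain, the
strain-CV law, tissue/solver parameters and the stress-test protocol.  The
``model_variant`` selects between the *reference* conduction model
(constant CV_T: 0.3 m/s remote, 0.08 m/s structural BZ, 0 core) and the
*extended* model (CV_T from the strain/density law, discretized in
``n_levels`` nonzero levels).  Serialization is canonical (sorted keys), so
serialize -> parse -> serialize round-trips byte-identically and the config
hash is stable.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ValidationError
from .protocols import StressTestSpec
from .strain_cv import StrainCVParams
from .synthetic_strain import StrainProfileSpec

__all__ = ["GeometryConfig", "RunConfig", "load_config", "save_config",
           "config_hash"]


@dataclass
class GeometryConfig:
    """Domain to simulate on: the idealized LV or a desk-scale fixture."""

    kind: str = "sheet"               # lv | sheet | slab | cable | ring
    lengths: list = field(default_factory=lambda: [25.0, 25.0])
    resolution: float = 0.5           # [mm]
    # lv parameters
    wall_volume: float = 136.0        # [mL]
    cavity_volume: float = 44.0       # [mL]
    truncation_fraction: float = 0.5
    helix_endo: float = 60.0          # [deg]
    helix_epi: float = -60.0
    # layers & infarct
    layer_fractions: list = field(default_factory=lambda: [0.25, 0.25, 0.25, 0.25])
    uniform_layer: str | None = "mid"  # fixtures: single layer label; None = by coordinate
    infarct: bool = True
    height_extent: list = field(default_factory=lambda: [0.14, 0.51])
    transmurality: float = 1.0
    bz_thickness: float = 9.0         # [mm]
    angular_extent: float = 0.20      # [rad] (lv)
    core_radius: float = 3.0          # [mm] (fixtures, radial infarct)
    core_center: list | None = None   # fixtures; None = domain center
    fibers_transverse: bool = True    # fixtures: fibers normal to the first
    #                                   axis, so x-propagation is transverse

    def __post_init__(self) -> None:
        if self.kind not in ("lv", "sheet", "slab", "cable", "ring"):
            raise ValidationError(f"unknown geometry kind {self.kind!r}")


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    strain: StrainProfileSpec = field(default_factory=StrainProfileSpec)
    strain_cv: StrainCVParams = field(default_factory=StrainCVParams)
    stress: StressTestSpec = field(default_factory=StressTestSpec)
    model_variant: str = "extended"   # extended | reference
    n_levels: int = 9
    cv_long: float = 0.6              # [m/s]
    ref_cvt_remote: float = 0.3       # [m/s] reference-model values
    ref_cvt_bz: float = 0.08
    dt: float = 0.02                  # [ms]
    cell_warm_beats: int = 500
    run_stress_test: bool = False
    pacing_site: list | None = None   # S1-only metrics site; None = auto
    outdir: str = "straincv_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_variant not in ("extended", "reference"):
            raise ValidationError("model_variant must be extended or reference")
        if self.n_levels < 1:
            raise ValidationError("n_levels must be >= 1")


_SECTIONS = {"geometry": GeometryConfig, "strain": StrainProfileSpec,
             "strain_cv": StrainCVParams, "stress": StressTestSpec}


def _to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)


def _from_dict(d: dict) -> RunConfig:
    kw = dict(d)
    for name, cls in _SECTIONS.items():
        if name in kw and isinstance(kw[name], dict):
            known = {f.name for f in fields(cls)}
            bad = set(kw[name]) - known
            if bad:
                raise ValidationError(f"unknown keys in {name}: {sorted(bad)}")
            kw[name] = cls(**kw[name])
    known = {f.name for f in fields(RunConfig)}
    bad = set(kw) - known
    if bad:
        raise ValidationError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(**kw)


def dumps_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(_to_dict(cfg), sort_keys=True,
                          default_flow_style=False)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as f:
        f.write(dumps_config(cfg))


def load_config(path) -> RunConfig:
    with open(path) as f:
        return _from_dict(yaml.safe_load(f))


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the canonical YAML serialization (first 12 hex)."""
    return hashlib.sha256(dumps_config(cfg).encode()).hexdigest()[:12]
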