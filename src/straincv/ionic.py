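"""Single ventricular myocyte: ten Tusscher-Panfilov (2006) dynamics with
transmural-layer and border-zone conductance remodeling.

The four transmural layers (endo, sub_endo, mid, epi) differ only in their
slow delayed-rectifier conductance G_Ks, scaled by 2.10 / 0.95 / 1.30 / 2.45
relative to the base cell.  Structural border-zone (BZ) tissue additionally
carries post-infarct remodeling of peak conductances: G_Na x0.38,
G_CaL x0.31, G_Kr x0.30, G_Ks x0.20.  The base cell is the 2006 epicardial
variant with base G_Kr calibrated to 0.13005 nS/pF so that the four layers
paced to steady state at BCL 600 ms reproduce intrinsic APDs of
~242/294/274/232 ms (repolarization measured at the -70 mV crossing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _tt06
from .errors import IntegrationError, MeasurementError, ValidationError

__all__ = [
    "CellParams", "CellState", "PacingSpec", "Trace",
    "make_cell_params", "pace_cell", "free_run", "measure_apd",
    "steady_state", "save_states", "load_states",
    "LAYER_GKS_SCALE", "BZ_SCALES", "LAYER_NAMES", "REGION_NAMES",
]

LAYER_NAMES = ("endo", "sub_endo", "mid", "epi")
REGION_NAMES = ("remote", "structural_bz", "core")

#: G_Ks multipliers per transmural layer (endo +110%, sub-endo -5%,
#: mid +30%, epi +145%).
LAYER_GKS_SCALE = {"endo": 2.10, "sub_endo": 0.95, "mid": 1.30, "epi": 2.45}

#: structural border-zone remodeling multipliers (I_Na -62%, I_CaL -69%,
#: G_Kr -70%, G_Ks -80%).
BZ_SCALES = {"gna_scale": 0.38, "gcal_scale": 0.31, "gkr_scale": 0.30,
             "gks_scale": 0.20}

# base-cell conductances: published 2006 epicardial values, except gkr which
# is calibrated so the printed intrinsic APD set is met (see docs/methods.md).
_BASE_GNA = 14.838
_BASE_GCAL = 3.98e-5
_BASE_GKR = 0.13005
_BASE_GKS = 0.392
_BASE_GTO = 0.294


@dataclass
class CellParams:
    """Base conductances plus dimensionless remodeling multipliers."""

    gna: float = _BASE_GNA
    gcal: float = _BASE_GCAL
    gkr: float = _BASE_GKR
    gks: float = _BASE_GKS
    gto: float = _BASE_GTO
    endo_s_gate: bool = False
    gna_scale: float = 1.0
    gcal_scale: float = 1.0
    gkr_scale: float = 1.0
    gks_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gna_scale", "gcal_scale", "gkr_scale", "gks_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def base_vector(self) -> np.ndarray:
        return np.array([self.gna, self.gcal, self.gkr, self.gks, self.gto,
                         1.0 if self.endo_s_gate else 0.0])

    def scale_vector(self) -> np.ndarray:
        return np.array([self.gna_scale, self.gcal_scale, self.gkr_scale,
                         self.gks_scale])


@dataclass
class CellState:
    """Membrane voltage plus gating/ionic variables at a time point."""

    y: np.ndarray  # (_tt06.NVAR,) state vector, y[0] = Vm [mV]
    t: float = 0.0  # [ms]

    @property
    def vm(self) -> float:
        return float(self.y[_tt06.I_V])

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), self.t)


@dataclass
class PacingSpec:
    """Stimulation train: n_beats stimuli at a fixed basic cycle length."""

    n_beats: int = 500
    bcl: float = 600.0        # [ms]
    amplitude: float = 40.0   # [uA/cm^2], depolarizing
    duration: float = 2.0     # [ms]

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValidationError("n_beats must be >= 1")
        if self.bcl <= self.duration:
            raise ValidationError("bcl must exceed stimulus duration")


@dataclass
class Trace:
    """Sampled membrane-voltage trace; time restarts at the last stimulus."""

    t: np.ndarray   # [ms]
    vm: np.ndarray  # [mV]


def make_cell_params(layer: str, region: str = "remote", *,
                     bz_layer_gradient: bool = True) -> CellParams:
    """Cell parameters for a (transmural layer, tissue region) pair.

    The layer sets the G_Ks multiplier; a structural-BZ region composes its
    remodeling multiplicatively on top.  With ``bz_layer_gradient=False`` BZ
    cells drop the layer gradient and use the plain BZ G_Ks factor, modeling
    a single layer-independent BZ phenotype.
    """
    if layer not in LAYER_GKS_SCALE:
        raise ValidationError(f"unknown layer {layer!r}; expected one of {LAYER_NAMES}")
    if region not in ("remote", "structural_bz"):
        raise ValidationError(
            f"unknown region {region!r}; expected 'remote' or 'structural_bz'")
    p = CellParams(gks_scale=LAYER_GKS_SCALE[layer])
    if region == "structural_bz":
        gks = (p.gks_scale * BZ_SCALES["gks_scale"] if bz_layer_gradient
               else BZ_SCALES["gks_scale"])
        p = replace(p, gna_scale=BZ_SCALES["gna_scale"],
                    gcal_scale=BZ_SCALES["gcal_scale"],
                    gkr_scale=BZ_SCALES["gkr_scale"], gks_scale=gks)
    return p


def pace_cell(params: CellParams, pacing: PacingSpec, *, dt: float = 0.02,
              record_dt: float = 0.1,
              initial: CellState | None = None) -> tuple[Trace, CellState]:
    """Pace a single cell and return the final-beat trace and end state.

    Integration is fixed-step Rush-Larsen at ``dt`` ms, identical to the
    scheme used in tissue so intrinsic and manifested APDs share one
    numerical footing.
    """
    y0 = initial.y.copy() if initial is not None else _tt06.initial_state()
    stride = max(1, int(round(record_dt / dt)))
    t, vm, y_end = _tt06.run_paced(
        y0, params.scale_vector().reshape(1, -1), params.base_vector(),
        dt, pacing.bcl, pacing.n_beats, pacing.amplitude, pacing.duration,
        stride)
    if not np.all(np.isfinite(y_end)):
        raise IntegrationError("cell integration diverged (non-finite state)")
    return Trace(t, vm), CellState(y_end, pacing.n_beats * pacing.bcl)


def free_run(params: CellParams, duration: float, *, dt: float = 0.02,
             record_dt: float = 0.1,
             initial: CellState | None = None) -> tuple[Trace, CellState]:
    """Integrate an unstimulated cell (rest-stationarity checks)."""
    y0 = initial.y.copy() if initial is not None else _tt06.initial_state()
    stride = max(1, int(round(record_dt / dt)))
    t, vm, y_end = _tt06.run_free(
        y0, params.scale_vector().reshape(1, -1), params.base_vector(),
        dt, duration, stride)
    if not np.all(np.isfinite(y_end)):
        raise IntegrationError("cell integration diverged (non-finite state)")
    return Trace(t, vm), CellState(y_end, duration)


def measure_apd(trace: Trace, repol_threshold: float = -70.0,
                min_upstroke: float = 2.0) -> float:
    """APD [ms]: time from maximum dVm/dt to the next downward crossing of
    ``repol_threshold``, linearly interpolated between samples."""
    t, vm = np.asarray(trace.t, float), np.asarray(trace.vm, float)
    if t.size < 3:
        raise MeasurementError("trace too short")
    dv = np.diff(vm) / np.diff(t)
    iup = int(np.argmax(dv))
    if dv[iup] < min_upstroke:
        raise MeasurementError("no upstroke found in trace")
    t_up = t[iup]
    down = np.nonzero((vm[:-1] >= repol_threshold) & (vm[1:] < repol_threshold))[0]
    down = down[down >= iup]
    if down.size == 0:
        raise MeasurementError("no repolarization crossing in trace")
    i = down[0]
    frac = (repol_threshold - vm[i]) / (vm[i + 1] - vm[i])
    return float(t[i] + frac * (t[i + 1] - t[i]) - t_up)


# ---------------------------------------------------------------------------
# steady-state warm starts

_STEADY_CACHE: dict[tuple, CellState] = {}


def _cache_key(layer: str, region: str, bcl: float, n_beats: int,
               bz_layer_gradient: bool) -> tuple:
    return (layer, region, float(bcl), int(n_beats), bool(bz_layer_gradient))


def steady_state(layer: str, region: str = "remote", *, bcl: float = 600.0,
                 n_beats: int = 500, bz_layer_gradient: bool = True,
                 dt: float = 0.02) -> CellState:
    """Post-train cell state for warm-starting tissue simulations.

    Results are memoized per (layer, region, bcl, n_beats) within the
    process; use :func:`save_states` / :func:`load_states` to persist them.
    """
    key = _cache_key(layer, region, bcl, n_beats, bz_layer_gradient)
    if key not in _STEADY_CACHE:
        params = make_cell_params(layer, region,
                                  bz_layer_gradient=bz_layer_gradient)
        _, state = pace_cell(params, PacingSpec(n_beats=n_beats, bcl=bcl),
                             dt=dt)
        _STEADY_CACHE[key] = state
    return _STEADY_CACHE[key].copy()


def save_states(path) -> None:
    """Serialize every cached steady state to an HDF5 checkpoint."""
    import h5py

    with h5py.File(path, "w") as f:
        for key, state in _STEADY_CACHE.items():
            layer, region, bcl, n_beats, grad = key
            name = f"{layer}|{region}|{bcl}|{n_beats}|{int(grad)}"
            ds = f.create_dataset(name, data=state.y)
            ds.attrs["t"] = state.t


def load_states(path) -> int:
    """Load an HDF5 checkpoint into the in-process cache; returns count."""
    import h5py

    n = 0
    with h5py.File(path, "r") as f:
        for name, ds in f.items():
            layer, region, bcl, n_beats, grad = name.split("|")
            key = _cache_key(layer, region, float(bcl), int(n_beats),
                             bool(int(grad)))
            _STEADY_CACHE[key] = CellState(ds[()], float(ds.attrs["t"]))
            n += 1
    return n
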