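"""Phenomenological fiber-strain-amplitude -> transverse conduction velocity
law, its parameter fit, and field plumbing (discretization, interpolation).

The law is

    CV_T(x) = CV_T,ref * fact(x) * g(eps_a(x)),
    g(eps)  = 1 + (CV_T,var / (2 CV_T,ref)) * tanh(alpha * (eps - eps_ref)),

a sigmoid in the recurring fiber-strain amplitude eps_a, scaled by the
infarct-density factor fact (1 healthy, 0 in the scar core).  With the
default parameters the transverse velocity spans [0.08, 0.52] m/s in viable
tissue and equals 0.30 m/s at the reference strain amplitude 0.1665.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.interpolate import LinearNDInterpolator

from .errors import FitError, ProjectionError, ValidationError
from .geometry import Mesh

__all__ = [
    "StrainCVParams", "StrainField", "CVField", "FitDiagnostics",
    "g_strain", "cvt_field", "fit_strain_cv", "discretize_cvt",
    "interpolate_field",
]


@dataclass
class StrainCVParams:
    """Parameters of the strain-CV relation (defaults: fitted values)."""

    cvt_ref: float = 0.30    # [m/s] basic transverse velocity
    cvt_var: float = 0.44    # [m/s] allowed variability around cvt_ref
    alpha: float = 20.6      # [-]   sensitivity (sigmoid steepness)
    eps_ref: float = 0.1665  # [-]   strain amplitude giving CV_T = cvt_ref

    def __post_init__(self) -> None:
        if self.cvt_ref <= 0:
            raise ValidationError("cvt_ref must be > 0")
        if self.cvt_var < 0:
            raise ValidationError("cvt_var must be >= 0")
        if self.cvt_ref - self.cvt_var / 2.0 < -1e-12:
            raise ValidationError("cvt_ref - cvt_var/2 must be >= 0 "
                                  "(no negative velocities)")
        if self.alpha <= 0:
            raise ValidationError("alpha must be > 0")

    def cv_bounds(self) -> tuple[float, float]:
        """Asymptotic (min, max) CV_T at fact = 1 [m/s]."""
        return (self.cvt_ref - self.cvt_var / 2.0,
                self.cvt_ref + self.cvt_var / 2.0)


@dataclass
class StrainField:
    """Per-node fiber-strain amplitude (dimensionless, >= 0)."""

    eps: np.ndarray

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, float)
        if not np.all(np.isfinite(self.eps)):
            raise ValidationError("strain amplitudes must be finite")
        if np.any(self.eps < 0):
            raise ValidationError("strain amplitudes must be non-negative")


@dataclass
class CVField:
    """Per-node transverse CV [m/s] plus the (region-uniform by default)
    longitudinal CV."""

    cvt: np.ndarray
    cv_long: float = 0.6  # [m/s]

    def __post_init__(self) -> None:
        self.cvt = np.asarray(self.cvt, float)


def g_strain(eps, params: StrainCVParams = StrainCVParams()):
    """Sigmoid strain factor g(eps); strictly increasing, bounded in
    (1 - cvt_var/(2 cvt_ref), 1 + cvt_var/(2 cvt_ref))."""
    eps = np.asarray(eps, float)
    out = 1.0 + params.cvt_var / (2.0 * params.cvt_ref) * np.tanh(
        params.alpha * (eps - params.eps_ref))
    return out if out.ndim else float(out)


def cvt_field(strain: StrainField, density, params: StrainCVParams = StrainCVParams(),
              cv_long: float = 0.6) -> CVField:
    """Evaluate CV_T = cvt_ref * fact * g(eps) per node.

    ``density`` is an InfarctDensityField or a bare fact array; CV_T is
    exactly zero wherever fact is zero (non-viable core).
    """
    fact = np.asarray(getattr(density, "fact", density), float)
    if fact.shape != strain.eps.shape:
        raise ValidationError("strain and density fields have different lengths")
    cvt = params.cvt_ref * fact * g_strain(strain.eps, params)
    cvt[fact == 0.0] = 0.0
    return CVField(cvt, cv_long=cv_long)


@dataclass
class FitDiagnostics:
    r_squared: float          # of the linear regression through the samples
    slope: float
    intercept: float
    residual_rms: float       # of the sigmoid fit [m/s]


def fit_strain_cv(eps_samples, cv_samples, fixed: dict | None = None, *,
                  objective: str = "line"
                  ) -> tuple[StrainCVParams, FitDiagnostics]:
    """Fit alpha and eps_ref of the strain-CV relation.

    With ``objective="line"`` (how the published parameters were obtained)
    an ordinary least-squares line is put through the (eps, cv) samples
    first and the sigmoid is then least-squares fitted to that line over the
    sampled strain range; ``objective="points"`` fits the sigmoid to the raw
    samples directly.  ``fixed`` may override cvt_ref / cvt_var (held fixed).
    """
    eps = np.asarray(eps_samples, float)
    cv = np.asarray(cv_samples, float)
    if eps.shape != cv.shape or eps.size < 2:
        raise FitError("need >= 2 matching (eps, cv) samples")
    if np.ptp(eps) < 1e-12:
        raise FitError("zero strain variance: cannot fit the relation")
    fixed = fixed or {}
    cvt_ref = float(fixed.get("cvt_ref", 0.30))
    cvt_var = float(fixed.get("cvt_var", 0.44))

    slope, intercept = np.polyfit(eps, cv, 1)
    pred = slope * eps + intercept
    ss_res = float(np.sum((cv - pred) ** 2))
    ss_tot = float(np.sum((cv - cv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if objective == "line":
        x = np.linspace(eps.min(), eps.max(), 200)
        y = slope * x + intercept
    elif objective == "points":
        x, y = eps, cv
    else:
        raise ValidationError("objective must be 'line' or 'points'")

    def model(p, xv):
        alpha, eps_ref = p
        return cvt_ref + cvt_var / 2.0 * np.tanh(alpha * (xv - eps_ref))

    alpha0 = max(2.0 * abs(slope) / cvt_var, 1e-3) if cvt_var > 0 else 1.0
    eps_ref0 = ((cvt_ref - intercept) / slope if abs(slope) > 1e-12
                else float(eps.mean()))
    sol = least_squares(lambda p: model(p, x) - y, [alpha0, eps_ref0],
                        bounds=([1e-6, -np.inf], [np.inf, np.inf]))
    if not sol.success:
        raise FitError(f"sigmoid fit failed: {sol.message}")
    alpha, eps_ref = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    params = StrainCVParams(cvt_ref=cvt_ref, cvt_var=cvt_var,
                            alpha=float(alpha), eps_ref=float(eps_ref))
    return params, FitDiagnostics(r2, float(slope), float(intercept), rms)


def discretize_cvt(field: CVField, n_levels: int = 9) -> CVField:
    """Bin the nonzero CV_T values into ``n_levels`` equal-width bins over
    [min positive, max] and impose each bin's center value; exact zeros (the
    core level) are preserved, so the full field carries n_levels + 1 values.
    """
    if n_levels < 1:
        raise ValidationError("n_levels must be >= 1")
    cvt = np.asarray(field.cvt, float)
    pos = cvt > 0
    if not np.any(pos):
        warnings.warn("all-zero CV_T field: nothing to discretize", stacklevel=2)
        return CVField(cvt.copy(), field.cv_long)
    lo, hi = cvt[pos].min(), cvt[pos].max()
    out = cvt.copy()
    if hi - lo < 1e-15:
        return CVField(out, field.cv_long)
    width = (hi - lo) / n_levels
    idx = np.minimum(((cvt[pos] - lo) / width).astype(int), n_levels - 1)
    out[pos] = lo + (idx + 0.5) * width
    return CVField(out, field.cv_long)


def interpolate_field(coarse_mesh: Mesh, field, fine_mesh: Mesh,
                      max_outside: float | None = None) -> np.ndarray:
    """Linear interpolation of a per-node field from a coarse mesh onto a
    fine mesh (mechanics -> electrophysiology resolution transfer).

    Inside the coarse support the interpolation is barycentric-linear;
    points outside fall back to the nearest coarse node provided they lie
    within ``max_outside`` (default: 1.5 coarse edge lengths), else a
    ProjectionError is raised.
    """
    values = np.asarray(field, float)
    if values.shape[0] != coarse_mesh.n_nodes:
        raise ValidationError("field length does not match the coarse mesh")
    if max_outside is None:
        max_outside = 1.5 * coarse_mesh.edge_length()

    cpts, fpts = coarse_mesh.nodes, fine_mesh.nodes
    # drop coordinates with no extent so 1D/2D meshes use the right dimension
    span = np.ptp(cpts, axis=0)
    active = span > 1e-12
    ndim = int(active.sum())
    if ndim <= 1:
        axis = int(np.argmax(span))
        order = np.argsort(cpts[:, axis])
        out = np.interp(fpts[:, axis], cpts[order, axis], values[order])
        d = np.maximum(cpts[:, axis].min() - fpts[:, axis],
                       fpts[:, axis] - cpts[:, axis].max())
        if np.any(d > max_outside):
            raise ProjectionError("fine nodes lie outside the coarse cable")
        return out

    interp = LinearNDInterpolator(cpts[:, active], values)
    out = interp(fpts[:, active])
    miss = ~np.isfinite(out)
    if np.any(miss):
        tree = cKDTree(cpts[:, active])
        d, j = tree.query(fpts[np.nonzero(miss)[0]][:, active], k=1)
        if np.any(d > max_outside):
            raise ProjectionError(
                f"{int((d > max_outside).sum())} fine nodes lie more than "
                f"{max_outside:.3g} mm outside the coarse mesh")
        out[miss] = values[j]
    return out
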