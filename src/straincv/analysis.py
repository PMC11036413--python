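"""Arrhythmogenic-substrate metrics.

Repolarization-time (RT) maps are taken from the last S1 beat (RT = first
downward -70 mV crossing after that beat's activation).  Their spatial
gradient magnitude (RTG, ms/mm) is recovered element-wise from linear shape
functions and volume-averaged onto nodes; the summary metrics are

    RTG_vol  [mL]    tissue volume with RTG >= 10 ms/mm (conduction-block
                     prone substrate),
    RTG_mean [ms/mm] volume-weighted mean RTG within that volume.

Also here: the tissue volume with severe conduction slowing
(CV_T <= 0.1 m/s) and volume-weighted CV_T histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import Mesh, REGION_CODES
from .monodomain import SolutionRecord
from .strain_cv import CVField

__all__ = [
    "RTGMap", "RTGMetrics", "repolarization_map", "element_gradients",
    "rtg_map", "rtg_metrics", "slow_cv_volume", "cvt_histogram",
]


@dataclass
class RTGMap:
    """Per-node repolarization-time-gradient magnitude [ms/mm] (NaN where
    undefined) with lumped node volumes [mm^3]."""

    magnitudes: np.ndarray
    node_volumes: np.ndarray


@dataclass
class RTGMetrics:
    rtg_vol: float    # [mL]
    rtg_mean: float   # [ms/mm]; 0 with empty=True when nothing exceeds
    empty: bool


def repolarization_map(record: SolutionRecord, beat: str = "last_s1"
                       ) -> np.ndarray:
    """Per-node repolarization time [ms] of the last S1 beat.

    For each node: the first -70 mV downward crossing after the node's
    first activation following the last S1 stimulus onset.  Nodes that
    never activate in that beat (e.g. the infarct core) are NaN.
    """
    if beat != "last_s1":
        raise ValidationError("only the last S1 beat is supported")
    if not record.stim_onsets:
        raise ValidationError("record contains no stimuli: no S1 beat found")
    t_on = record.stim_onsets[-1]
    act = record.first_activation(t_on, record.t_end)
    rt = np.full(record.n_nodes, np.nan)
    ok = np.isfinite(act)
    # first repolarization event after each node's activation
    order = np.lexsort((record.rep_times, record.rep_nodes))
    rn, rt_ev = record.rep_nodes[order], record.rep_times[order]
    for i in np.nonzero(ok)[0]:
        lo = np.searchsorted(rn, i, side="left")
        hi = np.searchsorted(rn, i, side="right")
        cand = rt_ev[lo:hi]
        cand = cand[cand > act[i]]
        if cand.size:
            rt[i] = cand[0]
    return rt


def element_gradients(mesh: Mesh, values: np.ndarray) -> np.ndarray:
    """Per-element constant gradient (3-vector) of a nodal field from
    linear shape functions; rows are NaN for elements touching NaN nodes."""
    vals = np.asarray(values, float)
    x = mesh.nodes[mesh.elements]
    v = vals[mesh.elements]
    m = mesh.n_elements
    grad = np.full((m, 3), np.nan)
    valid = np.all(np.isfinite(v), axis=1)
    if mesh.element_type == "line":
        t = x[:, 1] - x[:, 0]
        L = np.linalg.norm(t, axis=1)
        g = (v[:, 1] - v[:, 0])[:, None] / L[:, None] * (t / L[:, None])
        grad[valid] = g[valid]
    elif mesh.element_type == "triangle":
        e1 = x[:, 1] - x[:, 0]
        e2v = x[:, 2] - x[:, 0]
        nrm = np.cross(e1, e2v)
        a2 = np.linalg.norm(nrm, axis=1)  # 2*area
        u1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        un = nrm / a2[:, None]
        u2 = np.cross(un, u1)
        # local coordinates of the three vertices
        p = np.einsum("mkj,mji->mki", x - x[:, :1],
                      np.stack([u1, u2], axis=2))
        det = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
               - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        gx = ((v[:, 1] - v[:, 0]) * (p[:, 2, 1] - p[:, 0, 1])
              - (v[:, 2] - v[:, 0]) * (p[:, 1, 1] - p[:, 0, 1])) / det
        gy = ((v[:, 2] - v[:, 0]) * (p[:, 1, 0] - p[:, 0, 0])
              - (v[:, 1] - v[:, 0]) * (p[:, 2, 0] - p[:, 0, 0])) / det
        g = gx[:, None] * u1 + gy[:, None] * u2
        grad[valid] = g[valid]
    else:  # tetra
        J = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0],
                      x[:, 3] - x[:, 0]], axis=1)
        Jinv = np.linalg.inv(J)
        dv = v[:, 1:] - v[:, :1]
        # grad v = sum_i dv_i * (column i of J^{-1})
        g = np.einsum("mij,mj->mi", Jinv, dv)
        grad[valid] = g[valid]
    return grad


def rtg_map(rt: np.ndarray, mesh: Mesh) -> RTGMap:
    """Volume-weighted nodal RTG magnitudes from element-wise gradients.

    Elements touching nodes with missing RT are excluded; nodes with no
    valid adjacent element get NaN.
    """
    grad = element_gradients(mesh, rt)
    valid = np.all(np.isfinite(grad), axis=1)
    ev = mesh.element_volumes()
    k = mesh.elements.shape[1]
    # volume-weighted average of the gradient *vectors*: one-sided
    # cross-components of simplex gradients cancel at the node, which a
    # magnitude average would instead accumulate as positive bias
    acc = np.zeros((mesh.n_nodes, 3))
    wsum = np.zeros(mesh.n_nodes)
    conn = mesh.elements[valid]
    w = np.repeat(ev[valid], k)
    np.add.at(acc, conn.ravel(), w[:, None] * np.repeat(grad[valid], k, axis=0))
    np.add.at(wsum, conn.ravel(), w)
    out = np.full(mesh.n_nodes, np.nan)
    has = wsum > 0
    out[has] = np.linalg.norm(acc[has] / wsum[has, None], axis=1)
    return RTGMap(out, mesh.node_volumes())


def rtg_metrics(rtgmap: RTGMap, threshold: float = 10.0) -> RTGMetrics:
    """RTG_vol [mL] and RTG_mean [ms/mm] over nodes with RTG >= threshold."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    mag = rtgmap.magnitudes
    sel = np.isfinite(mag) & (mag >= threshold)
    if not sel.any():
        return RTGMetrics(0.0, 0.0, True)
    w = rtgmap.node_volumes[sel]
    return RTGMetrics(float(w.sum()) / 1000.0,
                      float(np.sum(w * mag[sel]) / w.sum()), False)


def slow_cv_volume(cvt, mesh: Mesh, threshold: float = 0.1, *,
                   include_core: bool = True) -> float:
    """Tissue volume [mL] with severe conduction slowing
    (0 < CV_T <= threshold), plus the non-conducting core volume when
    ``include_core`` (default, matching how scar volume is reported)."""
    vals = np.asarray(getattr(cvt, "cvt", cvt), float)
    nv = mesh.node_volumes()
    sel = (vals > 0) & (vals <= threshold)
    if include_core:
        sel |= vals == 0
    return float(nv[sel].sum()) / 1000.0


def cvt_histogram(cvt, mesh: Mesh, bins=None) -> tuple[np.ndarray, np.ndarray]:
    """Volume-weighted CV_T histogram: (bin_edges [m/s], volumes [mL]).

    By default the bin edges bracket the field's distinct (discretization)
    levels, one bin per level.
    """
    vals = np.asarray(getattr(cvt, "cvt", cvt), float)
    nv = mesh.node_volumes() / 1000.0
    if bins is None:
        uniq = np.unique(vals)
        if uniq.size == 1:
            bins = np.array([uniq[0] - 0.5, uniq[0] + 0.5])
        else:
            mid = 0.5 * (uniq[1:] + uniq[:-1])
            lo = uniq[0] - (mid[0] - uniq[0])
            hi = uniq[-1] + (uniq[-1] - mid[-1])
            bins = np.concatenate([[lo], mid, [hi]])
    volumes, edges = np.histogram(vals, bins=bins, weights=nv)
    return edges, volumes
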