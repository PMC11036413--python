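"""Virtual stress test: S1-S2 pacing, vulnerable-window scanning, VT
detection and exit-point localization.

A drive train of S1 stimuli (default 6 at 600 ms cycle length) is followed
by one premature stimulus (S2) whose coupling interval is scanned in 5 ms
increments from the earliest electrical capture to 15 ms after the latest
induced VT.  VT is defined as electrical activity sustained for at least
800 ms after S2; "activity" is operationalized as new activation upstrokes
occurring in every 100 ms sub-window.  The exit point of an induced VT is
the node with the earliest second activation after S2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MeasurementError, ProtocolError, ValidationError
from .geometry import Mesh, REGION_CODES
from .monodomain import (CellAssignment, SolutionRecord, StimulusSpec,
                         TissueParams, solve_monodomain)

__all__ = [
    "StressTestSpec", "VulnerableWindow", "TissueModel", "StressTest",
    "find_s2_bounds", "detect_vt", "locate_exit_point",
    "scan_vulnerable_window", "place_pacing_sites",
]


@dataclass
class TissueModel:
    """Runnable electrophysiology model: geometry + conductivity + cells."""

    mesh: Mesh
    params: TissueParams
    cells: CellAssignment

    def simulate(self, stimuli, duration, *, states=None, t0=0.0,
                 **kw) -> SolutionRecord:
        cells = self.cells
        if states is not None:
            cells = CellAssignment(self.cells.base, self.cells.scales, states)
        return solve_monodomain(self.mesh, self.params, cells, stimuli,
                                duration, t0=t0, **kw)


@dataclass
class StressTestSpec:
    """Protocol parameters of the virtual stress test."""

    pacing_sites: list | None = None   # coordinates; None -> placed around BZ
    n_s1: int = 6
    s1_bcl: float = 600.0       # [ms]
    s2_step: float = 5.0        # [ms]
    vt_sustain: float = 800.0   # [ms] activity needed after S2 to call VT
    stim_diameter: float = 3.0  # [mm]
    stim_amplitude: float = 40.0
    stim_duration: float = 2.0
    s2_min: float = 150.0       # [ms] start of the capture scan
    s2_max: float = 450.0       # [ms] cap when no VT bounds the scan
    capture_window: float = 150.0  # [ms] window to detect propagated capture
    activity_window: float = 100.0  # [ms] sub-window for "ongoing activity"

    def __post_init__(self) -> None:
        if self.n_s1 < 1:
            raise ValidationError("n_s1 must be >= 1")
        if self.s2_step <= 0:
            raise ValidationError("s2_step must be > 0")


@dataclass
class VulnerableWindow:
    """Outcome per (pacing site, S1-S2 interval) plus exit points."""

    sites: list
    s2_step: float
    outcomes: dict = field(default_factory=dict)   # (site_i, interval) -> str
    exit_points: dict = field(default_factory=dict)  # (site_i, interval) -> node

    def width(self, site_i: int) -> float:
        """VT-positive interval count x s2_step [ms]."""
        n = sum(1 for (s, _), o in self.outcomes.items()
                if s == site_i and o == "VT")
        return n * self.s2_step

    def total_width(self) -> float:
        return sum(self.width(i) for i in range(len(self.sites)))

    def to_frame(self) -> pd.DataFrame:
        """Matrix layout: rows = sites A.., columns = S2 intervals [ms]."""
        intervals = sorted({iv for (_, iv) in self.outcomes})
        letters = [chr(ord("A") + i) for i in range(len(self.sites))]
        data = {iv: [self.outcomes.get((i, iv), "") for i in range(len(self.sites))]
                for iv in intervals}
        return pd.DataFrame(data, index=letters)


def detect_vt(record: SolutionRecord, s2_onset: float, sustain: float = 800.0,
              window: float = 100.0) -> bool:
    """True iff new activations occur in every ``window``-ms sub-window of
    [s2_onset, s2_onset + sustain] (ongoing propagation, not residual
    plateau)."""
    if record.t_end + 1e-9 < s2_onset + sustain:
        raise ValidationError(
            f"record ends at {record.t_end} ms; needs {s2_onset + sustain}")
    n_win = int(np.ceil(sustain / window))
    for k in range(n_win):
        t0 = s2_onset + k * window
        t1 = min(s2_onset + sustain, t0 + window)
        if record.activations_in(t0, t1) == 0:
            return False
    return True


def locate_exit_point(record: SolutionRecord, s2_onset: float) -> int:
    """Node with the earliest second activation after S2 onset; ties break
    to the lowest node index."""
    second = record.second_activation(t0=s2_onset)
    if not np.any(np.isfinite(second)):
        raise MeasurementError("no node has a second activation after S2")
    return int(np.argmin(np.where(np.isfinite(second), second, np.inf)))


def place_pacing_sites(mesh: Mesh, n: int = 6) -> list:
    """Endocardial sites around the BZ: nodes near the minimum transmural
    coordinate at the BZ's mean height, spread evenly in circumferential
    angle.  On BZ-free fixtures the sites ring the domain centroid."""
    u = mesh.transmural if mesh.transmural is not None else np.zeros(mesh.n_nodes)
    endo = u <= np.quantile(u, 0.05) + 1e-9
    cand = np.nonzero(endo)[0]
    bz = mesh.region_label == REGION_CODES["structural_bz"]
    if bz.any() and mesh.height is not None:
        h0 = float(mesh.height[bz].mean())
        dh = np.abs(mesh.height[cand] - h0)
        cand = cand[dh <= np.quantile(dh, 0.1) + 1e-9]
    c = mesh.nodes[cand].mean(axis=0)
    ang = np.arctan2(mesh.nodes[cand, 1] - c[1], mesh.nodes[cand, 0] - c[0])
    order = np.argsort(ang)
    picks = order[np.linspace(0, order.size - 1, n, dtype=int)]
    return [mesh.nodes[cand[p]].copy() for p in picks]


class StressTest:
    """Stateful S1-S2 scanner with per-site drive-train snapshots.

    The S1 train is simulated once per site and its state saved at the last
    S1 onset; every S2 branch restarts from that snapshot, so scanning many
    coupling intervals costs one short simulation each.  Capture is judged
    against a no-S2 reference branch of the same length (activations beyond
    the stimulus patch that the reference does not show).
    """

    def __init__(self, model: TissueModel, spec: StressTestSpec):
        self.model = model
        self.spec = spec
        self._snap: dict[int, tuple[np.ndarray, float]] = {}
        self._ref: dict[tuple, SolutionRecord] = {}
        self._branch: dict[tuple, SolutionRecord] = {}
        self.sites = (spec.pacing_sites if spec.pacing_sites is not None
                      else place_pacing_sites(model.mesh))

    # -- internals ----------------------------------------------------------

    def _stim(self, site_i: int, onset: float) -> StimulusSpec:
        s = self.spec
        return StimulusSpec(center=self.sites[site_i], onset=onset,
                            diameter=s.stim_diameter,
                            amplitude=s.stim_amplitude,
                            duration=s.stim_duration)

    def _snapshot(self, site_i: int) -> tuple[np.ndarray, float]:
        """States at the last S1 onset, after n_s1 - 1 drive beats."""
        if site_i not in self._snap:
            s = self.spec
            t_last = (s.n_s1 - 1) * s.s1_bcl
            stims = [self._stim(site_i, k * s.s1_bcl) for k in range(s.n_s1 - 1)]
            if t_last > 0:
                rec = self.model.simulate(stims, t_last, keep_final_states=True)
                patch = self._stim(site_i, 0.0).node_mask(self.model.mesh)
                outside = np.setdiff1d(np.nonzero(
                    np.isfinite(rec.first_activation()))[0],
                    np.nonzero(patch)[0])
                if outside.size == 0:
                    raise ProtocolError("S1 drive train failed to capture")
                self._snap[site_i] = (rec.final_states, t_last)
            else:
                self._snap[site_i] = (self.model.cells.states.copy(), 0.0)
        states, t_last = self._snap[site_i]
        return states.copy(), t_last

    def _reference(self, site_i: int, duration: float) -> SolutionRecord:
        """Last-S1-only branch (no S2) of at least ``duration`` ms."""
        key = (site_i, round(duration, 6))
        if key not in self._ref:
            states, t_last = self._snapshot(site_i)
            stim = self._stim(site_i, t_last)
            self._ref[key] = self.model.simulate(
                [stim], duration, states=states, t0=t_last)
        return self._ref[key]

    def branch(self, site_i: int, interval: float,
               full: bool = True) -> tuple[SolutionRecord, float]:
        """Simulate last S1 + S2 at the given coupling interval.

        Returns (record, s2_onset).  ``full=False`` runs only long enough
        for the capture test.
        """
        s = self.spec
        key = (site_i, round(interval, 6), full)
        if key not in self._branch:
            states, t_last = self._snapshot(site_i)
            s2_on = t_last + interval
            margin = 100.0
            dur = interval + (s.vt_sustain + margin if full
                              else s.capture_window + 20.0)
            stims = [self._stim(site_i, t_last), self._stim(site_i, s2_on)]
            self._branch[key] = self.model.simulate(
                stims, dur, states=states, t0=t_last)
        _, t_last = self._snap[site_i]
        return self._branch[key], t_last + interval

    def captures(self, site_i: int, interval: float) -> bool:
        """Did S2 elicit a propagated response beyond the stimulus patch?"""
        s = self.spec
        rec, s2_on = self.branch(site_i, interval, full=False)
        ref = self._reference(site_i, interval + s.capture_window + 20.0)
        patch = self._stim(site_i, 0.0).node_mask(self.model.mesh)
        t0, t1 = s2_on + s.stim_duration, s2_on + s.capture_window

        def outside_acts(r):
            sel = (r.act_times >= t0) & (r.act_times < t1)
            return np.count_nonzero(~patch[r.act_nodes[sel]])

        return outside_acts(rec) > outside_acts(ref)

    # -- protocol operations ------------------------------------------------

    def find_s2_bounds(self, site_i: int) -> tuple[float, float]:
        """(earliest capturing interval, latest VT interval + 15 ms); the
        upper bound falls back to the configured s2_max when no VT occurs."""
        s = self.spec
        lo = None
        iv = s.s2_min
        while iv <= s.s2_max + 1e-9:
            if self.captures(site_i, iv):
                lo = iv
                break
            iv += s.s2_step
        if lo is None:
            raise ProtocolError("no S2 interval captured up to s2_max")
        hi = None
        iv = lo
        while iv <= s.s2_max + 1e-9:
            rec, s2_on = self.branch(site_i, iv, full=True)
            if detect_vt(rec, s2_on, s.vt_sustain, s.activity_window):
                hi = iv
            iv += s.s2_step
        return lo, (hi + 15.0 if hi is not None else s.s2_max)

    def scan(self) -> VulnerableWindow:
        """Full vulnerable-window scan over all sites."""
        s = self.spec
        vw = VulnerableWindow(sites=list(self.sites), s2_step=s.s2_step)
        for site_i in range(len(self.sites)):
            lo, hi = self.find_s2_bounds(site_i)
            captured: list[tuple[float, bool]] = []
            iv = lo
            while iv <= min(hi, s.s2_max) + 1e-9:
                cap = self.captures(site_i, iv)
                captured.append((iv, cap))
                if not cap:
                    vw.outcomes[(site_i, iv)] = "no_capture"
                else:
                    rec, s2_on = self.branch(site_i, iv, full=True)
                    if detect_vt(rec, s2_on, s.vt_sustain, s.activity_window):
                        vw.outcomes[(site_i, iv)] = "VT"
                        vw.exit_points[(site_i, iv)] = locate_exit_point(rec, s2_on)
                    else:
                        vw.outcomes[(site_i, iv)] = "no_VT"
                iv += s.s2_step
            # monotone-capture sanity: once capturing, later intervals should too
            seen_cap = False
            for iv, cap in captured:
                if seen_cap and not cap:
                    warnings.warn(
                        f"protocol anomaly: interval {iv} lost capture after "
                        f"an earlier interval captured (site {site_i})",
                        stacklevel=2)
                seen_cap = seen_cap or cap
        return vw


def find_s2_bounds(site, spec: StressTestSpec, model: TissueModel
                   ) -> tuple[float, float]:
    """Functional wrapper around :meth:`StressTest.find_s2_bounds`."""
    spec2 = StressTestSpec(**{**spec.__dict__, "pacing_sites": [site]})
    return StressTest(model, spec2).find_s2_bounds(0)


def scan_vulnerable_window(spec: StressTestSpec, model: TissueModel
                           ) -> VulnerableWindow:
    """Functional wrapper around :meth:`StressTest.scan`."""
    return StressTest(model, spec).scan()
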