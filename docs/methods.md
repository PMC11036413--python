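# Methods

## Scope and model overview

`straincv` implements a ventricular electrophysiology model in which the
transverse conduction velocity (CV_T, the propagation speed across the
myofiber direction) is remodeled by the recurring mechanical load of the
tissue, expressed as the fiber-strain amplitude ε_a over a cardiac cycle.
The coupling is *weak and static*: a strain-amplitude field (here produced
by a synthetic generator; in general by any mechanics model) is mapped once
to a CV_T field, which then parameterizes monodomain electrophysiology
simulations — S1 drive trains, premature S2 stimuli, vulnerable-window
scans — and substrate metrics based on repolarization-time gradients (RTG).

The core law is

    CV_T(x) = CV_T,ref · f_act(x) · g(ε_a(x)),
    g(ε)    = 1 + (CV_T,var / 2 CV_T,ref) · tanh(α (ε − ε_ref)),

with defaults CV_T,ref = 0.30 m/s, CV_T,var = 0.44 m/s, α = 20.6,
ε_ref = 0.1665. f_act ∈ [0, 1] is the infarct-density factor (1 in healthy
tissue, 0 in the scar core, linear across the structural border zone), so
CV_T is exactly zero in the non-conducting core and spans
[0.08, 0.52] m/s in viable tissue. The *reference* model variant instead
uses the conventional image-based piecewise-constant field: 0.3 m/s remote,
0.08 m/s in the structural BZ, 0 in the core.

## Ionic model and its calibration

Cells follow the 2006 ten Tusscher–Panfilov human ventricular formulation,
implemented in full (19 states) with Rush–Larsen updates for the twelve
Hodgkin–Huxley gates and forward-Euler updates for concentrations and the
RyR adaptation gate. The base cell is the epicardial variant. Transmural
heterogeneity is introduced *only* through the slow delayed-rectifier
conductance G_Ks, scaled per layer: endo ×2.10, sub-endo ×0.95, mid ×1.30,
epi ×2.45. Structural-BZ cells additionally carry post-infarct remodeling
(G_Na ×0.38, G_CaL ×0.31, G_Kr ×0.30, G_Ks ×0.20), composed
multiplicatively with the layer factor by default; a
`bz_layer_gradient=False` switch gives a layer-independent BZ phenotype
instead.

One base-cell parameter is calibrated: base G_Kr = 0.13005 nS/pF
(0.85 × the published 0.392-family epicardial value of 0.153). With the
published G_Kr, all four layer APDs at BCL 600 ms after a 500-beat train
came out a uniform ~6 ms short of the target set
(242 / 294 / 274 / 232 ms, −70 mV repolarization from maximum upstroke);
a uniform offset is the signature of a small I_Kr difference, and the
0.85 factor restores all four within 1.5 ms while keeping every gating
formulation published. Integrator step size and the two published τ_f2
variants were excluded as causes before touching the conductance.

Single cells are integrated with the same fixed-step (20 µs) Rush–Larsen
scheme as tissue rather than an adaptive stiff solver, so the intrinsic
APDs that anchor the tissue calibration carry no cross-integrator bias.
APD is defined as the time from maximum dV/dt to the following downward
−70 mV crossing (linearly interpolated), matching the tissue
repolarization-time definition; APD90 is not used anywhere.

## Tissue model and numerics

The monodomain equation
β C_m ∂V/∂t + I_ion − ∇·(σ_m ∇V) = β I_ext is solved with operator
splitting at Δt = 20 µs: one reaction step (Rush–Larsen, per node) followed
by one implicit (backward-Euler) diffusion step using linear finite
elements with a lumped mass matrix, prefactorized once per run
(zero-flux boundaries are the natural boundary condition). Per-element
tensors are transversely isotropic,
D = d_L e_f e_fᵀ + d_T (I − e_f e_fᵀ), stored as the scaled diffusivity
D = σ_m/(β C_m) in mm²/ms (β = 0.14 µm⁻¹, C_m = 1 µF/cm² are carried for
unit conversion but never enter the dynamics separately).

For tissue runs the reaction term uses voltage-tabulated gate steady
states, Rush–Larsen multipliers and current coefficients (0.05 mV grid,
linear interpolation); the direct-evaluation kernel remains the reference,
and a test pins the two to sub-millisecond APD agreement over a full
action potential.

**Conductivity calibration.** Diffusivity eigenvalues are never taken from
literature; each required CV level is calibrated by simulating a planar
wave on a thin slab (20×2×1 mm) at the *working mesh resolution* and
adjusting d until the measured CV matches the target within 1%. Because
numerical CV depends on element size (and, near the discrete
propagation-block threshold, far more steeply on d than the continuum
√d law), the search brackets the target and then uses a log-space
regula-falsi with bisection safeguard; the lookup is cached per
(target, resolution, Δt, cell). The longitudinal target is a region-uniform
0.6 m/s; transverse targets are the discretized CV_T levels.

**Activation/repolarization markers.** Activation events are upward
crossings of −40 mV, repolarization events downward crossings of −70 mV,
both time-interpolated. The −40 mV crossing stands in for the
maximum-upstroke time (they differ by a fraction of the upstroke, which
cancels in CV and APD-difference measurements); "second activation"
(for VT exit points) is a node's second −40 mV upcrossing after S2.

**Discretization of CV_T.** Nonzero CV_T values are binned into 9
equal-width bins over [min positive, max] and replaced by bin centers;
exact zeros (the core) form their own level, so the field carries 9+1
distinct values. Element values are the nodal mean snapped to the nearest
calibrated level, with an exact zero whenever any vertex lies in the core
(which widens the blocked region by at most one element ring and keeps the
core strictly non-conducting).

## Synthetic strain generator

The generator emulates the *outputs* of a weakly-coupled mechanics model —
not the mechanics itself. It reproduces four reported features of
post-infarct strain-amplitude fields:

1. a transmural increase from epicardium to endocardium in remote tissue
   (linear in the transmural coordinate, defaults ε_epi = 0.143,
   ε_endo = 0.230 — chosen so the induced healthy CV_T spans 0.20–0.49 m/s,
   the reported healthy range, rather than digitizing any figure);
2. depressed amplitudes on a plateau of 0.15 in the structural BZ, whose
   contraction is impaired;
3. elevated amplitudes (default 0.25) in the passively bulging core;
4. a minimum of `halo_amplitude` (default 0.08) at the BZ outer boundary,
   held over a flat shelf of `halo_width` (3 mm) into remote tissue before
   recovering linearly over `transition_width` (5 mm).

Feature 4 deserves emphasis: mechanical tethering to the stiff scar
depresses strain in the *adjacent remote tissue* below the BZ-interior
plateau. This is what creates the "functional border zone" — without it,
remote tissue would only interpolate between 0.15 and its healthy profile,
the induced CV_T would never drop near 0.1 m/s outside the structural BZ,
and the extension would have nothing to add over the reference model. The
defaults are pinned by the reported slow-conduction volumes: severe
slowing (CV_T ≤ 0.1 m/s) extends several millimetres beyond the
structural BZ, and through the law this requires local strain at or below
≈ 0.0925 (where 0.3 · g(ε) crosses 0.1 m/s) over a multi-mm band — hence
a shelf at 0.08, comfortably inside the reported critical low-strain
range. On the paired infarct-sheet fixture these defaults give an
extended-to-reference slow-volume ratio of ≈ 1.5, bracketing the reported
+35% (transmural) and +66% (non-transmural) expansions.

Distribution metrics (the slow-CV volume and CV_T histograms) are always
computed on the *continuous* law output; the 9-level discretization exists
only for imposing conductivities on the solver and would bias
threshold-crossing metrics by up to half a bin width.

Optional Gaussian noise (per node, one neighbor-averaging smoothing pass)
is seeded and bitwise reproducible. The generator does **not** emulate
PV-loops, stroke volumes, ejection fractions, beat-resolved strain traces
or any stress computation; passing tests therefore demonstrate the
electrophysiological consequences of the assumed strain *pattern*, not the
validity of a mechanics model.

## Protocols

The virtual stress test paces n_S1 = 6 drive beats at 600 ms from an
endocardial site (2 ms, 40 µA/cm², 3 mm patch), then one premature S2
scanned in 5 ms steps from the earliest electrical capture to 15 ms after
the latest VT. The drive train is simulated once per site and snapshotted
at the last S1 onset, so each S2 interval costs one short branch
simulation. Capture is judged against a no-S2 reference branch
(activations beyond the stimulus patch not present in the reference), which
is robust when the last S1 wave still traverses slow regions at S2 time.
VT is "electrical activity sustained ≥ 800 ms after S2", operationalized as
at least one activation event in every 100 ms sub-window; the exit point is
the node with the earliest second activation after S2 (ties → lowest node
index). Capture non-monotonicity across intervals is logged as a protocol
anomaly, not an error.

## Substrate metrics

Repolarization-time maps are taken on the last S1 beat (first −70 mV
downcrossing after that beat's activation; unactivated nodes missing).
Gradients are element-constant from linear shape functions,
volume-averaged onto nodes (elements touching missing nodes excluded);
node volumes are the lumped 1/k share of adjacent element volumes.
RTG_vol is the node-integrated volume with RTG ≥ 10 ms/mm and RTG_mean the
volume-weighted mean over that set (0 with an `empty` flag when nothing
exceeds threshold). The slow-conduction volume counts 0 < CV_T ≤ 0.1 m/s
plus, by default, the core. Whether to node- or element-integrate these
volumes is not standardized; node-lumped integration was chosen and is
used consistently.

## Geometry

The idealized LV is a truncated prolate-ellipsoid shell: inner and outer
surfaces share a uniform wall thickness, with the inner long/short
semi-axis ratio fixed at 2 and the basal plane at half the outer long
semi-axis above the equator; the two free dimensions are solved so the
cavity and wall integrate to the requested 44 and 136 mL. The structured
parametric grid (transmural × meridional × circumferential) is split into
tetrahedra; a sub-resolution apical puncture (radius = resolution/2,
missing volume O(resolution⁴)) avoids the degenerate pole. At 1 mm
resolution the integrated wall volume is within 0.06% of the target.

Fibers follow a rule-based helix: the angle varies linearly across the
wall from +60° (endo) to −60° (epi) in the local
circumferential–longitudinal plane. Four transmural layers use
configurable thickness fractions, default (0.25, 0.25, 0.25, 0.25); the
single-cell APD anchors are layer-geometry independent and the manifested
transmural APD range proved insensitive to the exact fractions, so the
uniform default was kept. The infarct core spans 14–51% of the ventricle
height at configurable transmurality with a 9 mm structural BZ (Euclidean
distance to the core node set — adequate at the 9 mm scale on a smooth
shell); its circumferential extent is not derivable from the stated
volumes alone, so the default (0.20 rad) was calibrated once so the
transmural case's core+BZ volume integrates to ≈ 15 mL.

## Desk-scale experiment design

The full-resolution system (≈10⁶ degrees of freedom plus finite-element
mechanics) is out of scope; the qualitative claims are reproduced on
fixtures whose sizes keep the whole suite within minutes on one CPU:

- **Transmural cable** (14 mm ≈ the solved wall thickness, 0.5 mm
  elements, transverse coupling calibrated to 0.3 m/s, 6 S1 beats):
  manifested APD range across the four layers.
- **Paired infarct sheet** (25×25 mm, 0.5 mm, circular core r = 3 mm with
  a 6 mm BZ, fibers perpendicular to propagation so the wave crosses the
  infarct transversely, 2 S1 beats): reference vs extended RTG metrics and
  slow-CV volume. Cross-fiber propagation is essential — along-fiber waves
  barely feel CV_T.
- **Reentry ring** (80 mm circumference, 0.5 mm, a 20 mm ionically
  remodeled BZ arc at CV_T 0.08 m/s, optionally flanked by 6 mm halo arcs
  at 0.12 m/s, fibers perpendicular to the loop): S1–S2 vulnerable-window
  scans. The one-dimensional circuit makes unidirectional block and
  sustained circulation robust and cheap where a small 2D sheet could not
  sustain a spiral (the wavelength CV·APD ≈ 180 mm exceeds any desk-scale
  sheet).
- **Healthy sheet / slabs** for negative controls, isochrone circularity
  (checkerboard-split triangulation keeps grid anisotropy under 3%), CV
  calibration and the √σ oracle.

## Known limitations

- The strain generator's spatial structure is idealized (radial/transmural
  ramps); real mechanics produce asymmetric fields shaped by fiber
  architecture, which matters for exit-site prediction but not for the
  mechanisms tested here.
- Numerical CV at 0.5 mm exceeds the continuum value for fast waves
  (under-resolved upstroke); calibration absorbs this by construction, but
  the √σ scaling oracle is therefore checked at 0.25 mm.
- Diffusion-tensor deformation by mechanics, bidomain effects,
  stretch-activated channels and beat-resolved mechano-electric feedback
  are outside the weak-coupling design.
- The vulnerable-window fixture is a ring, so VT "morphology" reduces to
  circulation direction and exit point; multi-morphology VT classification
  needs the full 3D geometry.
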