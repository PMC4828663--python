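# Methods

This note documents the models, numerical choices and design decisions
behind `rotorlab`, and what its synthetic test-bed does and does not
establish about real atria.

## Synthetic left-atrial surface

The package operates on a triangulated monolayer stand-in for a
patient-derived left atrium (LA): a 50 x 50 mm sheet (flat by default,
optionally lifted into a gentle dome) with

* four circular pulmonary-vein (PV) ostium holes (radius 4 mm), two per
  posterior/anterior half, each surrounded by a 3 mm PV "sleeve" annulus;
* a mitral boundary (the outer rim) and a small appendage (LAA) patch;
* a per-triangle fiber field: uniform in the LA body, rotated by 90
  degrees inside each PV sleeve with a 2 mm linear transition band just
  outside the rim.  The abrupt rotation is the substrate feature that
  produces conduction block of paced PV beats, so the band is kept
  narrower than a wavelength but wider than two elements;
* eight analysis subdivisions: posterior half 1-4 and anterior half 5-8
  by x-quartile, mirroring the 4 + 4 regional layout used in noninvasive
  phase-mapping studies.  The exact clinical subdivision borders are not
  published; the 2 x 4 grid is an approximation, not asserted equivalent.

The mesh is a structured grid with alternating diagonals; interior nodes
are jittered by +/-15 % of the grid spacing (seeded) so edge lengths are
continuously distributed - this matters for the fibrosis cluster-length
calibration, which targets a median with sub-edge resolution.  The grid
spacing is chosen so the *mean* edge length hits the configured target
(default 0.5 mm; the reference atlas used 0.333 mm, which remains
available via configuration).  Units are mm and ms throughout.

The enhancement-likelihood (LGE) field is a seeded sum of Gaussian bumps
rescaled per subdivision so that normalized per-subdivision densities
(subdivision mean / max over subdivisions) match configured targets to
within +/-0.02.  The default targets are the printed population-averaged
fibrosis densities (0.84, 0.28, 1.0, 0.57, 0.42, 0.35, 0.25, 0.20).
The densest subdivision gets an absolute mean likelihood of 0.45 so the
field stays in [0, 1] with realistic contrast.

## Interstitial fibrosis

Each mesh edge draws u ~ U(0,1) and is selected as fibrotic iff

    alpha * (4 cos^2 theta + sin^2 theta) * L > u,

with theta the acute angle between edge and local fiber (sign-aligned
average of the two adjacent triangles' fibers), and L the edge's LGE
likelihood (mean of adjacent triangles).  The comparison is implemented
literally (no clipping of the product at 1).  Parallel edges are exactly
4x more likely to be selected than perpendicular ones, the signature of
interstitial (fiber-tract) fibrosis.

`calibrate_alpha` bisects alpha (in log space) until the median total
length of connected selected-edge components, averaged over 20 seeded
realizations, is 670 +/- 50 um - the reported scale of interstitial
collagen in aging atrial bundles.  Components are maximal sets of
selected edges connected through shared nodes; this connectivity rule is
an implementation decision, as is averaging over seeds (a single
realization's median is a step function of alpha on a finite mesh).

Selected edges become no-flux clefts by node duplication: around every
node the fan of incident triangles is cut at each selected interior
edge and every resulting sector keeps its own copy of the node.  At a
cleft tip (one cut in a cyclic fan) the fan is divided geometrically by
the cleft line, making clefts open at both ends; an isolated interior
split edge therefore duplicates both endpoints and fully decouples its
two triangles.  Selected edges that would close a loop - sealing off an
island of tissue - are left un-split (and logged) so no tissue is
silently disconnected.  Triangles with all three edges selected are
removed outright.  Coordinates never change, so surface area is
conserved exactly, and the finite-element assembly needs no special
treatment: lost adjacency is a natural no-flux boundary.

## Ionic model

Membrane kinetics are the Courtemanche-Ramirez-Nattel human atrial
model (21 states; mV, ms, mM, pA/pF).  On top of the published baseline
the tissue variant applies, in order:

| modifier | value | purpose |
|---|---|---|
| gNa | x 2 | realistic upstroke velocity at tissue scale |
| gK1 | x 0.8 | match clinically measured rate adaptation |
| Ito, IKur, ICaL | x 0.5, x 0.5, x 0.3 | chronic-AF electrical remodeling |
| PV sleeve | gto x 0.75, gCaL x 0.75, gKr x 2.4, gKs x 1.87, gK1 x 0.67 | shorter PV action potentials |
| appendage | LA gKr = 1.6 x RA gKr | left/right appendage gradient |

The AF-remodeling multipliers are the standard chronic-remodeling values
from the modeling literature and are exposed in configuration.  The
finer per-region repolarization-gradient tables used by the reference
atlas are not published in the main text; only the main-text region
classes are asserted, with a configuration hook for custom per-region
multiplier tables.  Large IK1 increases seen in some AF models are
deliberately absent.  With these settings the single-cell APD90 at
700 ms cycle length is ~176 ms (LA body) vs ~106 ms (PV); the
remodeled cell is ~33 % shorter than baseline.

Integration is Rush-Larsen for the 12 voltage-dependent gates (exact
exponential relaxation to the tabulated steady state), analytic
relaxation for the calcium gates, forward Euler for concentrations.
For tissue runs the gate steady states, relaxation factors exp(-dt/tau)
and five voltage-only current factors are pre-tabulated on a 0.05 mV
grid over [-100, 70] mV with linear interpolation; this removes ~50
transcendental evaluations per node-step.  Time-step convergence is
first order: halving dt moves steady-state APD90 by ~1.4 ms at the
20 us operating step and ~0.7 ms at 10 us (both checked in the suite).

## Monodomain solver

The tissue equation dV/dt = div(D grad V) - I_ion with anisotropic
per-triangle diffusivity D = D_l f f^T + D_t (I - f f^T) is discretized
with P1 surface finite elements and a lumped mass matrix; no-flux
boundaries are natural.  Conductivities sigma (S/m) convert to
diffusivities via D = sigma / (beta C_m) with beta = 1400 /cm and
C_m = 1 uF/cm^2.  The reference atlas does not publish tissue conductivities,
so the default longitudinal sigma_l = 0.25 S/m was calibrated once so a
planar wave in remodeled LA-body tissue at 0.5 mm resolution conducts at
~70 cm/s (physiological atrial CV); sigma_t = sigma_l / 4 gives a ~2:1
velocity ratio.  Ablated or non-conducting elements are floored at
0.001 S/m in both directions - non-conducting but non-zero, avoiding a
singular tensor.

Time stepping is operator splitting (ionic step, then explicit
diffusion) at dt = 20 us (default; 25 us for the long reentry runs -
well inside the explicit stability bound h^2/4D ~ 200 us).  Recordings
sample every node at 1-2 ms, matching the 1 ms granularity of the phase
analysis.  Stimuli are 2 ms transmembrane current injections of
-40 pA/pF (~2x diastolic threshold) on disc or edge-strip footprints.
An optional second, node-matched layer can be coupled resistively per
node (`couple_layers`); with strong coupling the bilayer reproduces
monolayer conduction to within 2 %, with zero coupling the layers are
independent.  Identical fibrosis is applied to both layers when the
two-layer mode is used.

Local activation times are upward -40 mV crossings, linearly
interpolated between frames, with a 5 ms blanking against double counts;
per-node mean cycle length is the mean interval between successive
crossings.

## Initiation protocols

Sinus rhythm is periodic pacing at 86 beats/min from an early-activation
surrogate site (the anterior-septal corner of the sheet; the true
right-atrial pathway is out of scope).  pAF initiation bursts a superior
PV sleeve for five beats at CL 160 ms (configurable), starting one
coupling interval after the last sinus stimulus: 240 ms (RSPV) or 400 ms
(LSPV), measured from the sinus stimulus time (the source protocol is
ambiguous between stimulus time and local PV activation; the
stimulus-time reading keeps the schedule exact integer arithmetic).  Sustainment means
self-activation - upstrokes more than 50 ms after the last scheduled
stimulus - continues through the observation window with no silent gap
of 500 ms.  Desk-scale defaults shorten the sustainment and analysis
windows to 2 s and 3 s (full scale: 10 s and 8 s); every algorithm is
window-length independent.

### Reentry scenario (cross-field S1-S2)

The acceptance measurement of rotor cycle length uses a uniform
pAF-remodeled LA-body sheet, 50 x 50 mm at 0.5 mm, with fibers along y.
An S1 train (4 beats, CL 250 ms) paced from the left edge propagates
*across* fibers at ~28 cm/s; rate adaptation shortens the action
potential, and slow transverse conduction stretches the S1 repolarizing
tail so it stays inside the sheet long enough for a spiral to pivot
(with fibers along the S1 direction the tail leaves the 50 mm sheet in
~70 ms and every S2 timing either blocks or unrolls into a plane wave -
the anisotropy-rescaled domain is effectively twice as long when S1
runs transversely).  The S2 half-field stimulus (lower half-sheet) is
timed from a 1-D strip probe of the same substrate: the sheet-centre
-65 mV repolarization of the last S1 beat plus a fixed offset.  Probe
timing is computed at run time, so the protocol adapts to parameter,
seed or resolution changes rather than encoding a magic time.

The resulting rotor is measured over >= 2 s; the mean cycle length is
the average of inter-upstroke intervals at six sample points spread over
the sheet.  This scenario reduces the reference atlas (363 k nodes,
bilayer, patient anatomy, regional gradients) to a desk-scale twin, so
the cycle length is compared at a +/-15 % margin rather than the
published +/-4 ms.

## Phase mapping

Phase is the analytic-signal angle of the mean-subtracted voltage
(Hilbert transform over the whole analysis window; for sustained
reentry the signal is near-stationary, making the window choice
uncritical).  Numerically constant nodes are masked.  Phase
singularities are detected per triangle from the topological charge:
the wrapped phase differences around the oriented vertex loop sum to
+/-2 pi at a singularity; the detection tolerance is |sum| > pi, i.e.
the nearest multiple of 2 pi must be +/-2 pi, which is robust to
discretization noise.  The detector is verified against brute-force
perimeter integration of analytic vortex fields (100 random placements,
exact agreement in position count and chirality).

Tracking is greedy nearest-centroid matching between consecutive frames
(equal chirality, jump <= 5 mm per 1 ms frame - far above observed
meander per frame, far below inter-rotor distances; the cited tracking
method does not print its threshold).  Trajectories outliving 120 ms
(the minimum fibrillatory cycle length) are rotors.  Density maps count
PS occurrences per element, smooth them with inverse-distance-squared
weights inside a 5 mm radius (epsilon = mean edge length squared tames
the d -> 0 singularity) and normalize to a maximum of 1.  Regional
statistics report per-subdivision mean +/- SD of concurrent PS/rotor
counts per millisecond, per-vertex average cycle lengths (mean and
minimum), and normalized per-subdivision PS density (subdivision mean
of the smoothed map / max across subdivisions; normalizing by
subdivision max instead is exposed as an option).

## Lesion design

All lesions are triangle sets whose conductivity the solver floors to
0.001 S/m, applied instantaneously (not sequentially).  Band width
defaults to 2 mm, a clinical RFA lesion diameter; the sources specify
shapes only by diameter/length.

* **PVI rings** encircle each ostium just outside the PV sleeve;
  construction is verified by graph connectivity (no conducting path
  sleeve -> body).  **Roof** and **mitral** lines are shortest surface
  paths (Dijkstra on the edge graph, then Laplacian straightening -
  within 2 % of Euclidean on a flat sheet) rasterized into bands.
* **PS-guided shapes**: circles, perforated circles (4 symmetric 2 mm
  gaps - wide enough for wavefront passage, narrow enough to anchor
  rotors; the perforation geometry is unpublished and configurable),
  lines and crosses, 0.5-1.5 cm.  Placement is the centroid of the
  maximum-density element within a subdivision (ties break to the
  lowest element index; an all-zero map falls back to the subdivision
  centroid with a warning).  Placement at subdivision centers is also
  exposed, since the source text supports both readings.
* **Streamlining**: seeds evenly spaced *by arc length* along the
  isochrone 10 ms after the earliest activation, integrated along the
  normalized LAT gradient (first-order steps of 0.5 mm, barycentric
  gradient per triangle) until the mitral boundary; plateaus continue
  along the last direction and are logged.  On analytic fields the
  lines are straight/radial and never intersect.

## Outcome classification and statistics

After ablation: *sinus* if no self-activation in the final 1 s of the
analysis window; *AT* if activity persists with a time-median concurrent
rotor count of exactly 1 and periodic activation (pooled cycle-length
coefficient of variation < 10 %); *pAF* otherwise.  The median-count and
CV thresholds operationalize the conceptual definition of AT as "a
single rotor" and are configurable.  Success (termination) = sinus or
AT.  Pearson product-moment correlations (two-sided p, t distribution,
n-2 d.o.f.) relate binary per-subdivision outcome vectors to PS and
fibrosis densities normalized by their maximum over the eight
subdivisions; constant vectors have undefined r, rendered "-", and no
multiple-testing correction is applied, matching the conventional
tabulation.

## Problem sizes and determinism

Default problem sizes were chosen so the full test suite and the
acceptance script each run on a single desktop core: 50 x 50 mm at
0.5 mm (~13 k nodes), reentry analyzed over 2.4 s, fibrosis calibration
over 20 seeds on a ~36 k edge mesh.  All stochastic steps take explicit
integer seeds and are bit-reproducible for fixed inputs on the same
platform; the numerical kernels are JIT-compiled but single-threaded.

## What the synthetic test-bed does not show

The geometry is a monolayer sheet, not a patient anatomy: wall-thickness
variation, true bilayer dissociation, right atrium, fast-conducting
bundles and the published per-region repolarization gradients are all
absent.  Quantities that depend on them - the full activation-time
table, per-region cycle-length maps, the exact outcome grid of the
lesion-shape study - are reproduced only as qualitative properties
(ordering, connectivity, termination thresholds), not numbers.

One emergent behaviour of the reference atlas is not attained here: with
the main-text-only parameters the LA-body action potential restitutes
below the 160 ms burst cycle length, so PV burst pacing conducts 1:1
into the body and extinguishes instead of breaking into reentry (the
atlas's conduction block relies on its longer, regionally tuned LA
repolarization).  Late burst beats do block decrementally at the PV
exit, but no reentrant episode forms on the synthetic LA; sustained
reentry for rotor analysis is therefore produced by the cross-field
scenario.  Mechanical contraction and thermal lesion biophysics are out
of scope.
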