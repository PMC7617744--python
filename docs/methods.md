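# Methods

This note documents the models behind `roboulm`, the parameters that matter,
the numerical choices, and what the synthetic experiments do and do not show
about real robot-assisted ULM acquisitions.

## Phantom and stage kinematics

The phantom is a rigid body in a world frame (x lateral, y elevational,
z depth, mm) containing:

* two straight cylindrical channels of 200 µm lumen diameter (180 µm
  template wire plus a 2×10 µm coating) crossing at 30° in the z = 20 mm
  plane with a ±0.05 mm depth stagger so the axes pass within one radius
  without colliding.  The crossing angle and depth are not physically
  constrained; they are free parameters with these defaults.
* a 1 mm landmark ball filled with a deterministic grid of strong point
  scatterers, flanked by two ellipsoidal "supporting" lobes (±1.5 mm
  laterally, amplitude 0.6× the ball) — the structure the tracking loop
  locks onto.
* diffuse speckle: by default 400 uniformly placed scatterers with
  Rayleigh-distributed amplitudes in a 16×16×12 mm block.
* microbubbles parameterised in channel coordinates (arc length, radial
  offset, azimuth).  Bubble axial speed follows a parabolic Poiseuille
  profile, `v(r) = 2 v̄ (1 − (r/R)²)` with mean speed v̄ = 1 mm/s by default
  (the order of Q/A for ~1.5 µL/min through a 200 µm channel).  A bubble
  leaving the outlet is recycled at the inlet with a fresh radial position
  drawn from an RNG keyed on (scene seed, bubble index, lap), so the scene
  at time *t* is a pure function of *t* and the seed.

Stage motion is a sequence of trapezoidal segments: constant acceleration
(3 mm/s² for the stage protocols), optional cruise at the commanded speed,
symmetric deceleration; segments too short to reach the speed cap become
triangular with peak `√(a·d)`.  Two protocols are built in: `single_speed`
(out-and-back 20 mm legs at one speed, 1–5 mm/s, 1 s dwell between legs —
the dwell is not physically pinned; 1 s is our choice) and `mixed` (out at
4 mm/s, back at 2 mm/s).  Two stacked stages capped at 2.6 mm/s each bound
the protocol speed at 5.2 mm/s.  Motion direction is a unit vector in the
probe frame; `lateral`, `elevational` and `arbitrary` (45°, our default for
"arbitrary") are the named options.

## Forward imaging model

RF physics is out of scope.  A scatterer of amplitude *a* becomes an
anisotropic Gaussian blob with peak *a* and per-axis FWHMs of the point
spread function; blobs are summed on a regular voxel grid and white Gaussian
noise is added.  PSF defaults follow a diffraction heuristic at the 20 mm
working depth: lateral/elevational FWHM = λ·depth/aperture (≈ 0.41/0.37 mm),
axial = 2λ (≈ 0.39 mm) at 7.8 MHz and 1540 m/s (sound speed is an
assumption; the hardware value is not pinned).  Scatterers outside a
±7.5 mm lateral/elevational field of view contribute nothing; between the
physical footprint edge and the FoV edge amplitudes roll off with a 3 mm
Gaussian directivity factor.  Optional side-lobe replicas (two parallel
copies, 1.5 mm lateral offset, amplitude 0.1) are off by default.  Contrast
volumes render only bubbles plus a configurable tissue-leakage fraction
(perfect linear-echo cancellation at leakage 0).

The PSF is spatially invariant in this model.  Real matrix-array volumes
have position-dependent PSFs, element-directivity shading and speckle
decorrelation under rotation — none of which are emulated beyond the
amplitude roll-off.  Consequences: our online registration sees an easier
problem than the hardware's, and localisation accuracy figures are upper
bounds on what the same chain achieves on acquired data.

A toy delay-and-sum path (`das_point_roundtrip`) simulates per-element
Gaussian pulses at plane-wave two-way time of flight for ≤ 10 point targets
and beamforms them onto a small grid; it exists to validate the geometry
conventions, not to model image formation.

## Asynchronous closed loop

Acquisition emits frames at exactly 1/rate spacing (85 Hz default) no matter
how long processing takes.  Processing is sequential rounds of:

1. wait until the robot finished the previous round's move,
2. beamform the latest available frame on a ~12.5 mm, 0.4 mm-pitch crop
   around the landmark (≈ 3×10⁴ voxels; 0.4 mm is two wavelengths),
3. estimate the target translation relative to the **first** frame
   (translation-only SSD, two pyramid levels, warm-started from the
   previous estimate, cost subsampled to ≤ 6000 voxels for speed),
4. command the robot to the estimated absolute target displacement,
   zeroing the axial component (the probe must not chase depth motion) and
   withholding — not clipping — commands outside the ±50/±50/±5 mm safety
   box.

The robot executes straight-line trapezoidal moves at 250 mm/s² up to
50 mm/s; per-round corrections are ~0.05–2 mm, far below the ≈10 mm needed
to reach the cap, so every move is triangular (accelerate–decelerate, no
cruise).

Stage latencies lie in the measured ranges — beamforming 0.04 s,
registration 0.04–0.3 s, robot control 0.03–0.25 s — and by default are
**state-dependent**: registration time grows affinely with the offset being
registered (iteration count tracks initial misalignment, saturating at the
crop half-width) with small Gaussian jitter, and the robot-control stage
lasts as long as the commanded move, `max(0.03 s, 2√(d/250))`, which spans
exactly 0.03–0.25 s for 0.06–2 mm moves.  A `latency_model="uniform"`
variant draws both stages uniformly and independently from their ranges;
it degrades the loop noticeably (mean in-motion residual ~1.6 mm instead of
~1.1 mm at 5 mm/s) because long draws no longer coincide with easy cycles.
We treat the state-dependent model as the physical one and keep the uniform
variant for sensitivity studies.

The per-frame landmark residual logged by the loop is the ground-truth
displacement minus the probe pose (lateral+elevational magnitude).  The
image-based evaluation path re-renders the landmark neighbourhood at 0.1 mm,
localises it by weighted centroiding (ROI tracking the previous centroid,
background floor subtracted) and agrees with the analytic residual to within
a few hundredths of a millimetre; both grids (0.4 mm online, 0.1 mm
evaluation) therefore exist in every evaluated run.  Motion onset/offset is
the first/last excursion of the displacement magnitude above 0.1 mm; means
and standard deviations are over the flagged frames only.

## Registration

`RigidTransform` maps reference-frame coordinates to moving-frame
coordinates (`y = R(x−c) + c + t`, extrinsic XYZ angles in degrees, rotation
centre at the volume centre), so the estimated translation equals the
physical displacement of the content.  The 6-DoF estimator minimises SSD by
Levenberg–Marquardt with an analytic Jacobian on volumes pre-smoothed with a
0.5-voxel Gaussian; convergence tolerances: parameter step 1e-6, relative
cost decrease 1e-8, 200 residual evaluations, and the result is rejected in
favour of the initialisation if the cost ever ends above its starting value.
Warm starting from the previous frame's converged transform roughly halves
the iteration count on smooth motion sequences.  Gaussian pyramids smooth
with σ = 2 voxels before each 2× decimation; that width is what lets the
coarse level capture shifts of 10+ fine voxels on pure speckle.  Resampling
uses cubic B-splines with an out-of-support validity mask; Lagrangian
accumulation scatters frame voxels to reference coordinates with trilinear
weights and reduces by sum, mean or max (max uses nearest-voxel
assignment).

## ULM chain

Background suppression keeps a voxel only if it strictly exceeds both a
Gaussian-weighted 5³ local mean (centre excluded) and a fixed floor
(default 3× the early-frame background standard deviation; the hardware
value is empirical and unreported).  The PSF template averages ≥ 2
peak-normalised, centre-of-mass-aligned single-bubble patches; the pipeline
picks bright isolated peaks from the first suppressed frames, falling back
to the analytic PSF when fewer than two isolated bubbles exist.  NCC uses
`skimage.feature.match_template` (scores undefined within half a template of
the border).  Peaks are 26-neighbourhood maxima above 0.5 — ties count as
maxima, because exactly symmetric synthetic scenes produce exact score
plateaus, and duplicates within one voxel are merged keeping the higher
score.  Each peak's ±1-voxel neighbourhood is resampled at pitch/5 with
cubic interpolation (the "5× upsampling") and the maximum taken as the
sub-voxel position; mean localisation error on seeded off-grid bubbles is
below pitch/5.

The linker is a gated optimal-assignment tracker: constant-velocity
prediction once a track has two points, Hungarian assignment on predicted
distance, gate `max_speed/rate` per elapsed frame (default 10 mm/s, no gap
bridging).  It is a deliberately simple stand-in for feature-based
microbubble trackers; identity preservation through crossings relies purely
on the motion model.  Tracks shorter than 4 frames are discarded.  Maps
accumulate each track's densely sampled polyline once per voxel (trajectory
count), and the speed map averages per-track local speeds per voxel; display
smoothing is a 40 µm FWHM Gaussian (density) and a 60 µm-diameter spherical
mean filter restricted to covered voxels (speed).

## Fourier shell correlation

Tracks split by index parity give two independently accumulated density
maps.  FSC is the real part of the normalised cross-spectral sum per
shell of width one frequency bin (nearest-integer radius assignment,
cubic/isotropic grids only).  The 1/2-bit threshold is
`T(n) = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n)`.  Resolution is the
inverse of the first sub-threshold crossing, linearly interpolated between
shells, DC excluded; a curve that never crosses reports the grid Nyquist
wavelength (2× pitch, 40 µm at 0.02 mm) flagged as a better-than bound —
the search cannot go beyond Nyquist, so resolutions finer than 40 µm are
not representable on the default map pitch.  When a constructed cutoff
falls mid-shell the interpolated crossing may land up to ~1.5 bins past it.

## Problem sizes

The default study sizes are chosen so the full loop and chain run in
minutes on one CPU: closed-loop experiments use 2 round trips per seed
(1 for the speed sweep), a 31³ online crop, ~400 speckle scatterers and 20
bubbles; the registration property suite uses 36³ volumes at 0.1 mm with
±1.2 mm / ±5° motions; reconstruction demos use tens of frames at 10–20 Hz.
A hardware-scale acquisition (70 s at 85 Hz, ~69 GB RF) is far outside this
package's purpose; all statements it supports are about the desk-scale
configurations above.

## Known limitations

* Rigid phantom only: no elastic deformation, so registration always has a
  consistent optimum; real tissue deformation degrades both the online and
  offline estimates.
* Translation-only probe compensation; probe rotation is supported in the
  forward model (about depth) but the servo does not command it.
* No RF-domain effects: nonlinear bubble echoes, AM cancellation residue,
  reverberation and attenuation enter only as amplitude knobs
  (tissue leakage, noise sigma).
* The latency model is a two-parameter caricature of a real software stack;
  only its ranges are anchored to measurements.
* The linker has no appearance features; in dense bubble fields its switch
  rate will exceed that of feature-based trackers.
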