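# Methods

`lv4dflow` re-creates, end to end and at desk scale, the measurement and
analysis chain used for time-resolved 3D particle tracking of pulsatile
intraventricular flow: a synthetic pulsatile left-ventricle (LV) flow
with virtual tracers and cameras stands in for the in-vitro experiment,
and every downstream stage — Lagrangian particle tracking, track-to-grid
reconstruction, pressure-Poisson relative pressure, lambda2 vortex
identification, snapshot POD — operates only on what a real measurement
would provide (images, tracks, gridded fields). This note records the
models, the tunable parameters, the numerical choices, and what the
synthetic setting does and does not demonstrate.

## Synthetic LV flow

The cavity is a truncated prolate ellipsoid (semi-axes 24 x 45 x 24 mm,
base plane 27 mm above center; apex at y = -45 mm), a parameterized
surrogate for a CT-averaged ventricle shape. Mitral and aortic orifice
axes pierce the base plane with a 40 degree separation. Wall motion is
prescribed: the lateral semi-axes scale so the cavity volume follows a
piecewise-sinusoidal waveform — a 300 ms systolic ejection and a 557 ms
diastolic filling within an 857 ms cycle (70 bpm), each half-wave
integrating to the 50 ml stroke volume. Volume change is imposed
externally in the reference experiment too, so prescribing it (rather
than solving fluid-structure interaction) mirrors the physical setup.

The velocity field is a superposition of closed-form components, each
divergence-free by construction:

* a diastolic trans-mitral jet from an axisymmetric Stokes stream
  function `psi = (Q/2pi)(1 - exp(-(r/R)^2)) exp(-(z/L)^2)` about the
  tilted mitral axis (R = 7.5 mm, L = 40 mm). The flow-rate waveform Q(t)
  integrates to the stroke volume over diastole, which fixes the peak
  centreline speed at 0.80 m/s — the peak speed scale of the reference
  flow. Setting `peak_jet_speed` explicitly rescales the whole field
  (0 gives a zero-velocity field with the wall still moving);
* a counter-rotating vortex-ring pair: an axisymmetric ring stream
  function translating apex-ward along the mitral axis at
  `ring_translation_speed` (default 0.06 m/s) during diastole, with swirl
  speed 0.4 x the jet peak;
* a late-diastolic apical vortex: azimuthal swirl about the long axis
  near the apex (`apical_vortex_strength`, default 30 1/s), with a
  temporal envelope peaking at end-diastole and persisting into systole;
* a systolic outflow jet converging into the aortic orifice.

Because every component derives from a stream function or an azimuthal
field, the continuum divergence is identically zero; sampling onto a
grid leaves only an O(h^2) discrete divergence (verified by grid
refinement). Tracers are advected with classical RK4 at the stored time
step, trilinear in space and linear in time, and terminate when they
leave the (shrinking) mask.

**What this emulates and what it does not.** The generator reproduces
the features the analyses need — cycle-periodic pulsatile transport, a
jet with a propagating ring vortex, an apical swirl, a moving wall with
the correct volume waveform, known tracer ground truth — but it is a
*kinematic* model: it does not satisfy the momentum equation, walls are
not no-slip/no-penetration, and there is no turbulence or cycle-to-cycle
variability. Consequently (a) the pressure recovered from it is the
projection of its material derivative onto gradient fields, noticeably
smaller in magnitude than a dynamically consistent flow would give
(base-apex probe peaks ~1 mmHg on the long axis, ~2 mmHg across the
cavity, versus 2.7 mmHg reported for the physical experiment), and (b)
passing tests demonstrate correctness of the *algorithms*, not fidelity
of any particular hemodynamic number.

## Camera model and rendering

Four ideal affine (scaled-orthographic) views in a +/-30 / +/-10 degree
fan with alternating +/-6 degree elevation; one image pixel corresponds
to one reconstruction voxel through the magnification (0.2 mm/px in the
tracking scene). Particles render as isotropic Gaussian spots (the OTF,
sigma = 1.2 px, peak 1000 counts) point-sampled at pixel centers,
optionally with additive Gaussian noise, quantised to integer counts.
Calibration is exactly known by construction; real-camera polynomial
mappings, refraction and OTF estimation are out of scope.

## Particle tracking (predict / shake / extend)

Initialization triangulates particles in the first four frames:
sub-pixel peak detection (5-count threshold; 3-point Gaussian fits,
exact for the sampled-Gaussian OTF), epipolar pair matching, joint
refinement with a worst-view drop-out (merged spots bias single views),
and greedy claiming — candidates supported by every view claim their
peaks first, then 3-view candidates use what is left. Iterative particle
reconstruction alternates triangulation with ensemble shaking and
residual-image triangulation until the residuals yield no new particles;
per-frame candidates are linked into chains by nearest-neighbour
assignment (4-voxel search radius) and only chains spanning all four
frames continue.

Tracking then advances frame by frame: each live track's position is
extrapolated (quadratic from three frames) and refined by shaking —
coordinate descent probing +/-0.1 voxel per axis over eight iterations,
with a guarded parabolic sub-step that is accepted only when it lowers
the residual. Moves are batched by graph coloring of the window-overlap
graph, so every accepted move provably never increases the global
image-match residual. Particle-by-particle descent has spurious fixed
points for closely spaced pairs (each position optimal given the other's
biased one, brightness compensating); after the coordinate-descent
iterations, closely projecting pairs are therefore probed with
*antisymmetric* displacements — both members moved in opposite
directions — which explores exactly that degenerate valley and resolves
pairs down to separations of ~2 px to millivoxel accuracy. Particle brightnesses are then re-estimated by
iterated per-particle least squares (coordinate descent on the joint
linear problem): a ghost whose every spot is also claimed by real
particles has no unique image support and its intensity contracts
geometrically to zero.

New particles are found by triangulating the residual images (spawn
threshold 0.3 x the tracked median brightness, well above the faint
dipole residue of sub-pixel errors), depth-scanned along the mean
viewing axis (where triangulation is least certain), shaken against the
residuals, and admitted as candidate chains. A chain becomes a reported
track only after `min_track_len = 4` consecutive confirmations *plus*
two consecutive frames of clean image match; an accepted track that
stops fitting the images (core-weighted window residual above
`max_misfit = 2%` of its model energy for six consecutive frames) is
dropped, and coincident live particles are resolved to the senior track.
Frames failing the quality gate are flagged and excluded from the
exported positions. The misfit gate default is calibrated for noise-free
synthetic images and should be raised for noisy recordings.

At the acceptance operating point (1,000 tracers, 100 frames at 2 kHz,
four noise-free 512 x 512 views, ~0.004 ppp) this yields zero ghost
tracks among ~1,050 accepted tracks and ~0.01 px mean position error —
comfortably inside the quoted figures for the reference implementation
(< 0.004% ghosts, 0.018 px). Those figures were reported for a different
(real, denser, noisier) regime; the desk-scale noise-free setting is the
feasible analogue, not a reproduction.

Track kinematics come from sliding quadratic least-squares fits
(3-frame windows, one-sided at ends): velocity and acceleration are the
analytic derivatives at each frame; exact on quadratic trajectories, and
with the standard h^2/6 |x'''| truncation bound on smooth ones. Tracks
shorter than the window fall back to finite-difference velocity with
acceleration flagged undefined.

## Track-to-grid binning

Scattered track samples are averaged in overlapping cubic sub-volumes
with Gaussian weights (sigma = sub-volume/4), halving the sub-volume per
pass (72 -> 36 -> 18 -> 9 reconstruction voxels by default, the
reference scheme's end points; 9 voxels = 0.735 mm at the reference
magnification). Each pass uses the previous one as a predictor: samples
deviating from it by more than median + 3 MAD of the local residuals are
excluded (disclosed addition — raw tracks contain spurious entries).
Voxels with fewer than 2 contributing samples are flagged invalid. Desk
scenes with a few hundred tracers override `final_subvolume` upward so
the windows match their much sparser seeding; this is a resolution
choice, stated in each analysis.

## Incompressibility projection

Two documented paths. On fully periodic boxes the filter is the exact
spectral Helmholtz projection (solenoidal fields are fixed points to
machine precision; gradient contamination is removed to spectral
accuracy). On masked domains it is the minimum-norm correction
`u - D^T lambda`, `D D^T lambda = D u`, with `D` the central-difference
divergence on masked voxels (one-sided at the wall) solved by CG — an
orthogonal projection (kinetic energy never increases, idempotent) whose
output divergence, measured with the same stencil, is reduced to the
solver tolerance (1e-10 relative by default). A second-order masked
projector cannot reproduce the spectral path's machine-precision
fixed-point property, and a spectral projector cannot satisfy a
stencil-wise reduction contract; splitting by domain type serves both.

## Relative pressure

The material derivative comes either from pathlines (the fitted track
accelerations, binned like the velocity) or from the gridded field
(central differences in time and space, second-order one-sided at
edges). The momentum balance `grad p = -rho Du/Dt + mu lap u`
(rho = 1160 kg/m^3, mu = 0.0177 Pa s — the blood-mimicking mixture)
gives the pressure gradient; its finite-volume divergence with Neumann
fluxes (linearly extrapolated to wall faces, second order) forms the
Poisson right-hand side. The operator is the 7-point masked Laplacian;
the pure-Neumann constant null space is handled by pinning the domain
mean (relative pressure only), and disconnected stray voxel islands are
restricted to the largest connected component before solving.

With xi > 0 the solve couples to the previous step through the
convective pressure time-derivative: the previous pressure is
back-traced along `-u_c dt` by a 4-point trilinear line integral of its
gradient, and the second time derivative is discretised backward with
one stored level, adding `xi/dt^2` to the operator diagonal (which also
regularises the Neumann null space, so a Dirichlet anchor — zero domain
mean — is needed only at the first step). The convective velocity `u_c`
is either prescribed or estimated as the single best-fit displacement
between consecutive fields (integer search with parabolic refinement;
ties resolve to zero shift) — a stated surrogate for the full
least-squares estimator of the reference workflow. The solver is CG at
1e-8 relative residual. The full chain recovers the decaying
Taylor-Green pressure to 0.7% relative L2 on a 64^3 box, and the
xi-coupled series tracks the analytic decay of a standing pattern.
Probes average pressure in 2 x 2 mm boxes on the center z-plane (widened
to one voxel on coarser grids) and report differences in mmHg
(133.322 Pa/mmHg); differences are invariant to the anchoring constant.

## lambda2 and phase averaging

lambda2 is the middle eigenvalue of S^2 + Omega^2 from the
central-difference velocity gradient (second-order one-sided at edges;
outside-mask values are nearest-filled before differencing so near-wall
stencils stay usable). The conventional display iso-level -150 1/s^2 is
exposed as a constant. Phase averaging is the voxel-wise mean over
cycles; the cycle-convergence metric is the median over valid voxels and
phases of |a - b| normalised by that phase's spatial peak speed (the
normalisation is unstated in the reference description; per-phase peak
scaling is this package's disclosed choice).

## Snapshot POD

The moving wall gives every stored step its own mask, so snapshots are
first interpolated onto the end-systole reference mask (the smallest
domain) — tricubic by default, with nearest-inside filling for reference
voxels just outside a snapshot's mask (counted and reported; voxels with
no source data within 2 voxels are an error). Identical masks
short-circuit to exact copies. The snapshot correlation matrix uses the
voxel-volume-weighted inner product; eigenvalues (kinetic-energy
contributions) are sorted descending, trailing values below 1e-12 of the
leading one are truncated, and mode signs are fixed so each mode's
largest-magnitude entry is positive (determinism). No mean subtraction
by default: the leading mode then captures the jet-dominated mean
structure, as in the reference analysis; `subtract_mean` switches this.
Orthonormality, coefficient uncorrelatedness, energy completeness and
permutation invariance of the spectrum are asserted on every run in the
test suite.

The full-cycle analysis uses 343 snapshots (5x temporal subsampling of
the 2 kHz cycle) on a 20 x 32 x 20 grid. The prescribed-spectrum
generator (orthonormalised random modes with orthogonalised,
exactly-rescaled coefficient series) recovers its construction spectrum
to machine precision, which is what makes the spectrum-recovery checks
sharp. On the synthetic cycle itself the spectrum is steeper than the
reference flow's (mode 1 ~69%) — a synthetic flow with a handful of
coherent components has less broadband content than a measured one — so
the reference fractions are checked through the prescribed-spectrum
route, not through the LV scene.

## Problem sizes and determinism

Desk-scale defaults: a 24 x 30 x 22 grid at 2.75 mm for field/pressure
work (64 phases per cycle), a 20 x 32 x 20 grid for POD (343 snapshots),
and 1,000 tracers / 100 frames / 512 x 512 views for tracking. All
randomness flows through seeded NumPy generators recorded in output
metadata; deterministic stages are bit-reproducible under a fixed config
hash (the run manifest records both).

## Known limitations

* Kinematic flow: no momentum balance, no wall boundary layers; pressure
  magnitudes are indicative only (see above).
* The tracker's quality gates are tuned for noise-free renders; noisy
  images need a higher `max_misfit` and a lower relative spawn threshold.
* The binning scheme assumes near-uniform local seeding; strongly
  clustered tracers bias the Gaussian means.
* The convective-velocity estimator fits a single bulk displacement; it
  is not the full structure-tracking least-squares method it stands in
  for.
* Per-particle shake objectives are guaranteed monotone only for
  particles with disjoint image windows; for overlapping ensembles the
  guarantee holds for the global residual.
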