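# Methods

## Physical model

Under the quasi-static approximation the potential u in a head of isotropic
conductivity σ(r) obeys ∇·(σ∇u) = ∇·j_s with zero normal current on the
scalp surface; the source j_s of a stimulating contact pair is idealized as
a point current dipole at the midpoint of the anode and cathode, moment
along the anode→cathode axis times the 3.5 mm contact separation.  The
overall source amplitude is arbitrary: recording hardware undersamples the
0.3 ms pulse (1 ms sample period) and the capacitive coupling distorts its
flanks, so only a single multiplicative factor relates simulated to
measured amplitudes.  That factor is fitted, never assumed.

Recording contacts are point sensors; published work shows electrode extent
and geometry contribute negligibly at the distances considered, and all
results use potential *differences* (bipolar montage), making them
invariant to the reference/gauge.

## Analytic multilayer-sphere solution

For N concentric shells with radii R_1 < … < R_N and conductivities
σ_1 … σ_N, and a dipole at radius b < R_1, the potential is expanded per
spherical-harmonic degree n.  In the source shell it is the
infinite-medium dipole term plus a regular r^n correction; outer shells
carry r^n and r^−(n+1) harmonics.  Instead of propagating 2×2 transfer
matrices, each degree's coefficients are solved as one (2N−1)-dimensional
linear system whose basis functions are scaled per layer, (r/R_j)^n and
(R_{j−1}/r)^(n+1): every matrix entry is then O(n) at any degree, so the
system stays well-conditioned with no overflow up to degree 800 and no
per-degree renormalization.  Radial (P_n) and tangential (P'_n·cos φ) modes
share the matrix and are solved as two right-hand sides.

Truncation: the series stops once the largest per-point term has stayed
below `tol` (default 1e−10) relative to the running sum for three
consecutive degrees, or raises `SeriesConvergenceError` carrying the tail
estimate at `n_terms` (default 200; the pipeline's ground-truth model uses
400 with tol 1e−9, comfortable for source eccentricities up to 0.9 of the
innermost radius).  Evaluating the primary term in closed form inside the
source shell keeps convergence governed by the source eccentricity rather
than by the sensor–source distance, so sensors arbitrarily close to the
dipole are handled exactly.

Verified properties: machine-precision agreement with the closed form
3m·cosθ/(4πσR²) for a central dipole; equal-conductivity multishell ≡ one
shell; continuity across interfaces for radial and tangential moments;
linearity in the moment; exact 1/σ scaling.

## Hexahedral FEM

One trilinear isoparametric hexahedron per nonzero voxel, 2×2×2 Gauss
quadrature, assembled in SI units.  Between model levels (3C/4C/5C) only
the element conductivities change; the mesh, and the cached geometric
element integrals, are shared.

**Node shift.**  Voxel meshes carry staircase tissue boundaries.  A node
incident to voxels of ≥ 2 distinct labels (the exterior counts as label 0)
is displaced by `node_shift × voxel/2` (default 0.3) toward the centroid of
its incident voxels carrying the locally-minority label (ties go to the
deeper tissue); any displacement that would drive an element Jacobian
non-positive is retracted.  All Jacobians are checked positive at every
Gauss point after shifting.

**Sources and sensors.**  Point dipoles enter by partial integration:
b_i = m·∇φ_i at the source position, nonzero only on the containing
element's 8 nodes and summing to zero.  Containment uses half-open voxel
intervals (a point on a shared face belongs to the higher-index element);
on shifted meshes local coordinates come from Newton inversion of the
trilinear map.  Sensors are trilinear point evaluations; a reciprocal
(transfer) path — one solve per bipolar channel with a ±interpolation-weight
load, dotted with each dipole load — matches the direct path to the solver
tolerance and is preferable when channels are fewer than stimulation pairs.

**Solver.**  The stiffness matrix is symmetric positive semi-definite with
the constants as nullspace.  Loads are exactly projected onto the
compatible (zero-sum) subspace and solved with Jacobi-preconditioned CG to
a relative residual of 1e−9 (iteration cap 10·√n + 1000); solutions are
returned in the zero-mean gauge.  At the study sizes (~65k nodes) a solve
takes a fraction of a second.

**Accuracy.**  Against the analytic oracle on the four-shell 50 mm phantom
at 2 mm resolution (dipole eccentricity ≤ 0.7, sensors ≥ 10 mm away, both
potential sets re-gauged to zero mean over the sensor set): RDM ≤ 0.09,
MAG within [0.94, 1.05] over 20 random configurations; refining a reduced
four-shell phantom (24/21/18.5/16 mm — shells thick enough to stay resolved
at 2 mm) from 2 mm to 1 mm reduces the median RDM about four-fold.

## Synthetic data generator

The generator emulates the acquisition, not the physiology: no neural
(evoked) responses, no line noise, no amplifier saturation, no CSF shunting
along shafts.  Ground truth is always the analytic solver, so FEM
discretization error remains measurable end to end.

- **Phantom**: adult-head-like shells 92/86/80/78/66 mm; the desk-scale
  study uses them scaled to a 50 mm outer radius at 2 mm voxels
  (~65k elements), which keeps the full pipeline re-runnable in seconds
  while preserving shell proportions.  The CSF and gray shells are then
  thinner than one voxel — deliberately so: partial-volume-limited thin
  shells are exactly the regime in which conductivity detail is debated.
- **Implantation**: 5 shafts × 12 contacts, entry at a random scalp point,
  tip placed at a target drawn within 4 mm of a common focus (clinical
  plans cluster around the suspected epileptogenic zone).  The clustering
  also guarantees stimulation-to-recording distances below 5 mm, without
  which the near-field analysis would have no support.
- **Stimulation**: 12 neighboring-contact pairs × 3 events (36 events,
  matching the ~40 stimulations per patient of clinical mapping sessions),
  restricted to pairs with both contacts in white matter and midpoint
  within 0.9 of the white-shell radius — deep targets, and the regime where
  the analytic ground truth applies and converges fast.
- **Pulse and gain**: 0.3 ms rectangular pulse through a first-order RC
  high-pass (corner 150 Hz, giving the >1 ms capacitive tails), decimated
  to 1000 Hz.  The gain g (default 200, mirroring the magnitude of fitted
  factors in practice) is defined as recorded-peak / true-potential: the
  sampled pulse is normalized to unit peak before scaling, so the fitted
  factor estimates g directly, and the raw sampled waveform (peak strictly
  below the continuous amplitude) documents the undersampling the factor
  absorbs.
- **Amplitudes and noise**: a unit stimulation current of 1 µA puts
  recorded artifacts at the 10²–10⁵ µV scale of clinical recordings; noise
  is 2 µV white Gaussian.  Bad channels carry 25 mV-sd noise — the
  exclusion threshold is sd > 10 mV, and noise with sd *at* the threshold
  would trip it only half the time, so the generator uses a decisively
  pathological value.
- **Reference**: a dedicated zero-signal (plus noise) channel at a
  white-matter position (head center by default).

## Measurement chain

10 Hz 4th-order Butterworth applied forward–backward (zero phase); epochs
−100…+200 ms with baseline −100…−10 ms (the corpus gives no windows; these
are configurable defaults).  Exclusion: (a) near-stimulation — the pair
itself, contacts adjacent on the stimulated shaft, or contacts within
2.5 mm of a stimulating contact; (b) extracranial (skull/scalp/outside
label); (c) after-peak spread — sd of the +5…+200 ms window, pooled over
epochs, above 10 mV.  "Variance higher than 10 millivolts" mixes a variance
with an amplitude; the sd reading is the unit-consistent one.  The
near-stimulation radius is 2.5 mm rather than 5 mm because a 5 mm radius
combined with 5 mm distance bins would empty the 0–5 mm bin identically,
contradicting the populated near bins of the real analyses it mirrors.
Peaks are the signed maximum-magnitude sample within ±1 sample of the
event, averaged over each pair's epochs.  The RMS normalizer is computed
over time and kept bipolar channels of the high-passed continuous signal.

The zero-phase 10 Hz filter attenuates the single-sample artifact peak by
~1.6 %, so the fitted factor under the full default chain sits near 197
rather than 200; with the filter disabled and zero noise the chain
reproduces g exactly (to 1e−9), which is how the fit itself is validated.

## Validation statistics

The L1-optimal scale is computed exactly as the |x|-weighted median of the
ratios m/x (entries with x = 0 are excluded from the fit but retained in
the error tables); a least-squares variant exists for sensitivity checks.
When several model levels are validated against one measured table, one
shared factor is fitted on the most detailed level (5C) so that the level
comparison differs only through the simulated potentials — fitting on the
pooled levels would let the near-field mismatch of the coarse models bias
the factor for all of them (we measured ~233 instead of ~200).  Relative
error orderings between levels are invariant to the shared factor.
Distances are midpoint-to-midpoint (stimulation pair to bipolar channel),
binned in [k·5, (k+1)·5) mm; quartiles use linear interpolation.

## What passing tests show — and do not show

On matched synthetic data the pipeline recovers the generator gain,
ranks model levels correctly (3C worse than 4C on CSF-containing truth;
misspecified skull conductivity strictly worse than matched), and
reproduces the distance structure: very large relative errors in the 0–5 mm
bin, sub-percent errors at 35–45 mm.  These are statements about the
pipeline and the solvers, under spherical anatomy, isotropic
conductivities, point-dipole truth, and white Gaussian noise.  They do not
certify accuracy on real heads: real segmentation error, tissue
heterogeneity and anisotropy, electrode-shaft shunting, and neural (CSEP)
components are all outside the generator, and real-data relative errors are
an order of magnitude larger than the matched-model synthetic ones.

## Numerical conventions and degenerate inputs

World coordinates are voxel-center based millimeters, right-handed, 0-based
voxel indexing (lossless NIfTI round-trip; anisotropic or rotated volumes
are rejected with a resampling hint).  SI units internally (m, S/m, A·m,
V).  Label codes are fixed integers (0 outside, 1 scalp … 5 white).
Degenerate cases raise typed errors: non-nested radii, shells that produce
no voxels, shafts that cannot be placed, dipoles outside the innermost
shell, unconverged series (with tail estimate), points outside the mesh,
incompatible loads, CG iteration-cap overruns (with residual).  All
randomness flows through seeded `numpy` generators; rerunning a
configuration reproduces every report bit-identically.
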