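# Methods

## Physical model

The scattering medium above a planar object is represented as `N` thin
phase screens `phi_k(rho)` at heights `z_k` above the object plane, with
free space between them.  The model neglects absorption and intra-medium
back-reflection; this is the regime selected by time-gated detection,
where only light that makes the direct roundtrip to the object depth is
recorded, and it is carried in the code as matrix metadata (`time_gated`)
rather than as a temporal simulation.  The object is a single plane of
complex amplitude reflectance `O(rho)` with `|O| <= 1`.

One-way transmission from the surface to the object is
`T = T_1 ... T_N` with `T_k = P_{z_{k-1}, z_k} diag(exp(i phi_k))`, and
the roundtrip reflection matrix is `R = T^T diag(O) T`; the transpose on
the outgoing path expresses optical reciprocity.  Matrices couple
vectorized fields on a single square lattice: columns index illumination
points, rows detection points.

## Numerical propagation model

All planes share one lattice of `N0 x N0` samples at pitch `dx0 <=
lambda/2` (the focus-scanning interval).  Free-space propagation is the
angular-spectrum transfer function `exp(i k_z d)` with
`k_z = sqrt(k0^2 - k_par^2)` over the propagating band, applied on the
periodic computational domain, and `k_z` clipped to zero beyond the band:
every sampled spatial frequency is carried with unit modulus.  Three
consequences shape the whole package:

* the propagator is exactly unitary, exactly symmetric in the space basis
  (reciprocity) and composes exactly over split distances;
* each layer factor `T_k` is unitary, so the inverse of the identified
  stack is the reversed product of conjugated factors — a structural
  inverse, never a numerical matrix inversion — and correcting a
  synthetic matrix with its ground-truth stack is an identity to
  rounding error;
* scattered light wraps around the periodic boundary instead of leaving
  the field of view, so *all* clutter stays in the matrix.  This is the
  conservative direction relative to an open-boundary experiment, where
  part of the multiply scattered light walks off the detection ROI.

A hard pupil cutoff inside the propagators was deliberately rejected: a
phase screen scatters across any fixed cutoff, truncation makes the layer
factors non-unitary, and the structural inversion would then only hold
approximately.  The circular pupil `|k_par| <= NA k0` remains available as
grid metadata for passband projections and diagnostics.  Out-of-band
components are inert (no phase, no decay) rather than evanescent; for the
smooth screens studied here their population is negligible, and for sharp
binary targets they simply ride along unobserved.  An optional zero-padded
field propagator (`pad=True`) provides open-boundary point responses where
wrap-around would mislead.

## Synthetic media

Random screens are Gaussian-correlated: white noise filtered in the
spectral domain so the phase autocorrelation is `exp(-r^2 / l^2)`, then
normalized to a requested standard deviation; binary polygon/numeral
overlays can be superimposed as phase steps for visual bookkeeping.
Plate strength is never trusted from its parameterization: a stack is
calibrated in closed loop so that its *measured* one-way optical
thickness — `-ln` of the ballistic power fraction of the ground-truth
transmission matrix — hits the requested value (default tolerance 0.02
mean free paths), via a multiplicative fixed point on the expected
`OD ~ N sigma^2` law.

Two generator parameters have no uniquely "correct" value and were fixed
once, as follows:

* **Correlation length.**  The reference phantom regime is defined by how
  much of the stack's thickness lies beyond the resolvable band of the
  layer mapping (effective NA `L0 / (2 z_k)`); the reference study's
  observable residual after rectification (~0.42 of 3.3 mean free paths,
  about 13%) pins this at `l ~= 1.3 um` for the full-scale geometry
  (`L0 = 45 um`, plates at 35–100 um).  Because the band cutoff scales as
  `L0 / z`, scaled-down phantoms preserve the regime by scaling the
  correlation length with `1/L0`: `l = 1.3 um * (45 um / L0)`.
* **Per-plate strength.**  Plates share one standard deviation, set by the
  closed-loop calibration to the stack target (3.3 mean free paths
  one-way for the reference phantom).

## The tracing loop

One cycle = one sweep over all layers on the incoming path, then the same
sweep on the matrix transpose for the outgoing path.  A sweep visits
layers from the object outward by default (their mapping resolution is
highest, so they stabilize first; the order is configurable).  For layer
`k` the working matrix is the measured matrix with the outgoing path fully
corrected by the current accumulated estimates and the incoming path
corrected down to layer `k`; dividing each entry by the free-space point
response over the gap (the same band-limited kernel the propagators use;
entries where its magnitude falls below `1e-6` of the peak are masked, not
divided) leaves `S ~ o · exp(i phi_k_residual)^T` plus clutter `M'` from
everything unmodeled.

The residual phase is the angle of the dominant right singular vector of
`S`.  Three estimator details matter in the clutter-dominated regime that
deep phantoms start in:

* **Truncated power iteration** (default 3 steps from the all-ones
  start).  The early iterates equal the unbiased column-correlation
  average of the phase; running to convergence when the rank-1 term is
  subdominant locks onto the strongest clutter direction and the loop
  diverges.  With a dominant signal a few steps already reach the fixed
  point, so exact rank-1 inputs are recovered to numerical precision.
* **Band-limit projection.**  The ROI of side `L0` is the aperture of the
  mapping, so layer `k` is only resolvable up to spatial frequency
  `(L0 / 2 z_k) k0`.  The estimated vector is projected onto that band,
  removing estimation noise in modes the data cannot constrain.  Without
  this projection the noise injected per cycle exceeds the correction
  gain at desk scales and the loop does not bootstrap.
* **Spectral (Wiener) shrinkage.**  The out-of-band modes of the estimated
  vector carry no layer information, so their mean power is a direct
  noise-floor estimate; in-band modes are weighted by
  `max(0, 1 - floor/power)`.  For clean data the floor vanishes and the
  weight is unity.

Each increment is pinned to zero at the central reference point (falling
back to the strongest column if the reference carries no signal), wrapped,
restricted to the layer's circular recoverable field of view of diameter
`L_k = L0 + 2 z_k tan(asin(NA_eff))` (with the default cone `NA_eff`
chosen so the growth rate is 1.2 per unit depth, matching the reference
experimental geometry), and accumulated into `phi_k^c`.  The loop stops
when the largest per-layer RMS increment of a cycle falls below 0.01 rad
(default) or after `max_cycles` (default 20).  Per cycle the code records
the roundtrip enhancement `xi1` of the identified stack and the
image-domain enhancement `xi2`.

`alpha` (the ballistic share of the uncorrected confocal power, needed for
`xi2 = eta_c / alpha`) is estimated as the squared magnitude of the
normalized projection of `diag(R)` onto the reconstructed object
direction: the coherent component of the uncorrected confocal field that
matches the object is the ballistic part, the rest is clutter.  This
estimator is exact (`alpha = 1`) for an aberration-free medium and small
for a clutter-dominated diagonal; other decompositions of the same
quantity exist, which is why image-domain enhancements carry a wider
uncertainty than `xi1`.

## Problem sizes and what the phantoms show

Unit tests run on 16^2–32^2 lattices; the headline phantom study (four
plates at 35/50/70/100 um, 3.3 mean free paths one-way, wavelength
0.9 um, NA 1.0) runs at 64^2 with a 28.8 um ROI and single-precision
working arithmetic in the sweeps, three seeded realizations in the
acceptance script.  Estimation noise scales inversely with the pixel
count, so desk-scale runs carry a noise inflation of the identified
thickness (a few tenths of a mean free path) that a full-scale run would
reduce; the residual thickness after rectification is correspondingly a
slight overestimate.  The synthetic phantoms exercise the model the
algorithm assumes (thin screens, no absorption, no intra-medium
back-reflection, object-plane-only reflection).  Passing them demonstrates
correctness and robustness of the reconstruction machinery — including
robustness to object-uncorrelated clutter injected on top of the model —
but not performance on real tissue, where the medium is volumetric, gating
is imperfect, and detection noise exists.

## Degenerate inputs and numerical choices

* Plane transforms, basis changes and corrections validate plane/basis
  metadata and fail loudly on mismatch.
* An empty layer list is a valid model: the matrix is its own correction,
  `xi1 = 1`, converged in one cycle.
* A masked or signal-free reference column falls back to the
  largest-magnitude column for piston fixing; all-masked normalized
  matrices are an error.
* Calibration to an unreachable optical thickness raises rather than
  returning the closest achievable value.
* Complex matrices are stored in containers as paired real/imag float64
  datasets; phases are stored wrapped to (-pi, pi] (lossless for
  `exp(i phi)`) plus an unwrapped copy of the accumulated maps.

## Known limitations

* The periodic domain keeps all scattered light in view; clutter levels
  are therefore an upper bound on the open-boundary case at equal optical
  thickness.
* Layer depths are assumed, not estimated, except through the
  single-plate depth-scan recipe (`sweep-depth`), which localizes a
  dominant scattering layer by the peak of `xi2`.
* Phase-only screens: amplitude scattering and absorption are out of
  model.
* The object is a single plane; volumetric targets require one matrix per
  gated depth.
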