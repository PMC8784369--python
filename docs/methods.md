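# Methods

This note documents the models implemented in `otonav`, the assumptions
behind them, the defaults of the synthetic-data generator, and the design
choices made where the design was genuinely open.

## Coordinate conventions

All world coordinates are millimetres in a right-handed frame; volumes
carry an index→world affine with voxel centres at integer 0-based indices.
Synthetic CT volumes use an LPS-style axis-aligned affine. Rotations are
stored as proper orthonormal 3×3 matrices (orthonormality enforced to
1e-9, determinant +1); quaternions are accepted only at I/O boundaries
(tracking-stream CSVs, column order `t,qw,qx,qy,qz,x,y,z`) and normalised
on conversion. The registration transform maps patient (tracker) space
into image space.

## Rigid registration

`fit_rigid` is the closed-form least-squares alignment: demean both point
sets, take the SVD of the cross-covariance H = Σ (pᵢ−p̄)(qᵢ−q̄)ᵀ, and form
R = V·diag(1,1,det(VUᵀ))·Uᵀ. The determinant correction flips the smallest
singular direction whenever the unconstrained optimum is a reflection;
anatomy is never mirrored, so a reflection is corrected, not returned.
Configurations with fewer than 3 points, or whose second singular value is
below 1e-8 of the first (collinear), raise a degeneracy error.

FRE is reported as the RMS over fiducials, i.e. FRE² is the *mean* of the
squared residuals. Published FRE values are rarely explicit about RMS
versus mean-of-norms; RMS is used here because the expectation identity
⟨FRE²⟩ = (1 − 2/N)⟨FLE²⟩ is stated for squared quantities, and the
invariant `fre_rms² = mean(residuals²)` is enforced in tests.

`match_correspondence` resolves unknown labelling by evaluating every
permutation (N ≤ 8, at most 8!/(8−N)! closed-form fits, each O(N)). An
exhaustive search is exact at this scale, so no heuristic matcher is
needed. If the winning permutation beats the runner-up by less than a
configurable FRE margin (default 0.1 mm) the configuration is declared
ambiguous — a perfectly square marker arrangement is the canonical case —
and an error is raised rather than guessing.

## Error models

**FLE composition.** Independent localization error sources add in
quadrature: total² = Σ componentᵢ². The default composition is 0.1 mm for
image-space localization of the spherical markers and 0.7 mm for the
electromagnetic tracker, giving √0.50 ≈ 0.707 mm.

**FLE from FRE.** Inverting the expectation identity:
FLE = FRE/√(1 − 2/N), defined for N ≥ 3 (at N = 2 the factor diverges;
below that the rigid fit is underdetermined).

**Analytic TRE.** The first-order isotropic closed form
⟨TRE²(r)⟩ = (⟨FLE²⟩/N)(1 + ⅓ Σₖ dₖ²/fₖ²) is evaluated in the demeaned
principal-axis frame of the fiducial configuration: fₖ is the RMS distance
of the fiducials from principal axis k (fₖ² equals the sum of the other
two principal second moments) and dₖ the distance of the target from that
axis. It assumes isotropic, zero-mean, independent FLE and small errors
(first order); anisotropic FLE must use the covariance path, and the
closed form raises if asked otherwise.

**TRE covariance.** To first order the fitted transform's error decomposes
into a translation error dt (covariance σ²/N·I, σ² the per-axis FLE
variance) and a small rotation dθ about the centroid with
Cov(dθ) = σ²·A⁻¹, A = diag(N·fₖ²) in the principal frame. The error at a
target r (demeaned, principal frame) is dt + dθ×r, giving

Cov(TRE) = (σ²/N)·I + [r]ₓ σ²A⁻¹ [r]ₓᵀ,

rotated back to world axes. For isotropic FLE its trace equals the closed
form's ⟨TRE²⟩ exactly (asserted to 1e-6 relative in tests), so the two
analytic routes cross-validate each other, and both are checked against
the Monte-Carlo oracle (trace to 3%, full matrix to 5% Frobenius at 10⁵
reps).

**Confidence ellipses.** For a 2D marginal (the lateral display plane), the
level-p ellipse has semi-axes √(χ²₂(p)·λᵢ) along the covariance
eigenvectors, χ²₂(0.95) = 5.99146. Coverage is validated empirically to
±0.5 percentage points at 10⁵ samples.

**Monte-Carlo oracle.** `monte_carlo_tre` perturbs *both* point sets —
the total FLE is split evenly across the two spaces (per-set RMS =
total/√2, per-axis σ = per-set RMS/√3) so the summed localization error
across a correspondence equals the model total — refits the rigid
transform with a vectorised batch SVD, and records the displacement at the
target. The generator is `numpy.random.default_rng` seeded explicitly;
identical seeds reproduce identical samples.

## Pivot calibration

Stacking Rᵢ·t_tip − p_pivot = −pᵢ over all poses gives a 3n×6 linear
system solved by `lstsq`. Rotation diversity is checked through the
condition number of the design matrix (threshold 1e6): pivoting about a
single axis leaves one tip-offset component unconstrained, and the error
message names that component from the null-space vector. An algebraic
one-shot solve was chosen over an iterative sphere fit because it is
closed-form, has no initialisation, and its residual RMS is a direct
quality figure. No accuracy target is asserted beyond properties
(noiseless exactness, graceful noise scaling, invariance to a global rigid
motion of all poses): there is no published residual figure for this step.

## Fiducial detection

The phantom generator rasterizes spheres with partial-volume edge
weighting: voxels within one voxel-diagonal of the surface get the
fraction of 4³ sub-voxel sample points falling inside the sphere; interior
voxels get 1. Additive Gaussian noise is applied afterwards,
deterministically per seed. Sphere overlap and out-of-bounds centres are
rejected.

Detection thresholds at a user-set intensity or Otsu's threshold (titanium
at CT is far brighter than any tissue, so a bimodal histogram is a safe
assumption), labels 26-connected components, filters by voxel count
(default ≥ 4) and sphere-equivalent diameter (default 2–8 mm, bracketing
the physical 4 mm markers), excludes components touching the volume border
(their centroids would be truncated), and computes the centroid as the
intensity-weighted mean of background-subtracted intensities over the
component dilated by one voxel — the dilation captures the partial-volume
shell that carries the sub-voxel information. On phantoms at
0.43×0.43×0.6 mm voxels with 5% contrast noise the centroid RMS error is
≈0.03 voxel, comfortably inside the 0.2-voxel acceptance band and
consistent with an image-space FLE of ~0.1 mm.

Marker stability between two scans is measured as the per-fiducial
residual norms *after* a best-fit rigid alignment of one set onto the
other: raw coordinate differences would conflate head repositioning with
marker slippage, and rigid alignment removes exactly the repositioning
component.

## Targeting cues

The instrument triad has ẑ tip-forward along the tool axis; depth is the
signed component of (target − tip) along ẑ (positive = target ahead,
negative = overreached) and lateral its projection on the x–y plane.
Contracts, chosen where the display description leaves freedom:

- Range boundary: strict inequality (lateral distance > radius ⇒ out of
  range), ties in range. Deterministic, no hysteresis.
- Zero tolerance 0.05 mm: the depth circle "vanishes" and the lateral cues
  "overlap" within this band, making the on-target state reachable with
  floating-point streams.
- Blink is a boolean flag (blink ⇔ depth < −tolerance); no blink frequency
  is modelled.
- Out of range, only the arrow *direction* (atan2 of the lateral vector)
  is contracted; the arrow length is presentation.
- All cues are geometry (px offsets, diameters, radians), never pixels
  rendered; the error ellipse for display is the TRE covariance projected
  onto the instrument x–y plane.

Dwell capture scans windows in time order and accepts the earliest window
spanning ≥ dwell_time whose samples all lie within stability_radius of the
window mean (two-pass: mean, then membership). Defaults: 1.0 mm radius,
2.0 s dwell — "hold still for a couple of seconds" at surgical hand tremor
scales.

## Assessment

Placement error decomposes (achieved − planned) about a unit plane normal
n̂: depth = |Δ·n̂|, lateral = |Δ − (Δ·n̂)n̂|, so lateral² + depth² equals the
squared Euclidean distance identically. Summaries are mean ± sample SD
(n−1); missing measurements are excluded listwise before summarising.
Screw TRE reduces the (typically three) touch distances per screw by their
mean — the reduction is not standardised anywhere, and the mean is the
natural unbiased choice — then summarises over screws. Reports round half
away from zero to 2 decimals while JSON retains raw doubles.

## Synthetic sessions

`SessionSpec` defaults define the emulated conditions: 4 fiducials spread
through a 25 mm cluster (rejection-sampled for minimum pairwise separation
and non-collinearity), target 70 mm from the cluster centroid (the
cochlear-nucleus-to-nasopharynx distance scale), 8 check screws at
40–90 mm, image-space FLE 0.1 mm and tracking FLE 0.7 mm applied as
independent isotropic Gaussian noise (per-axis σ = RMS/√3) on the image
and patient sides respectively, and 20 Hz instrument streams at 2 mm/s.
Three trajectory kinds cover the behaviours the cue logic must classify:
a straight 10 mm approach, a jittered dwell at the target, and an
out-of-range lateral excursion that converges onto the target.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: electromagnetic field distortion near metal
(tracking noise is i.i.d. Gaussian, real EMT error is spatially
correlated), CT metal/beam-hardening artifacts around titanium, marker
migration between scans, tissue deformation and brainstem shift after
craniotomy, and human factors in instrument handling. The published
cadaver results (e.g. predicted TREs of 1.75/1.76 mm) depend on the actual
cadaver fiducial coordinates, which are not public, so they are validated
here only at the level of the model identities, not reproduced
numerically.

## Numerical choices

- Orthonormality/validation tolerances 1e-9; collinearity threshold 1e-8
  relative to the largest singular value.
- Monte-Carlo sizes: 10⁵ reps for model-validation comparisons (3%
  agreement band for RMS quantities, 5% Frobenius for covariances, 2% for
  the FRE/FLE ratio), smaller sizes for property sweeps. The acceptance
  script uses 10 random configurations at 10⁵ reps and 25 phantoms, sizes
  at which the Monte-Carlo standard error sits well inside every band.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  reports record it.
- The exhaustive correspondence search caps N at 8 (40320 fits, ~0.1 s);
  beyond that a combinatorial matcher would be needed, which is out of
  scope.

## Known limitations

- The closed-form TRE model is first-order: it underestimates slightly at
  very large FLE-to-cluster-size ratios. At the default 0.71 mm FLE on a
  25 mm cluster the analytic-vs-Monte-Carlo deviation is well under 1%.
- Anisotropic FLE is handled only through the covariance path, and only as
  a shared (configuration-wide) covariance, not per-fiducial weighting.
- The CLI's `navigate` replays recorded streams; it does not attempt
  real-time pacing.
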