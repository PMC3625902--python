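# Methods

## Signal model and angular interpolation

The diffusion-weighted signal at voxel `x` and unit gradient `g` is treated
as a function on the sphere, antipodally symmetric (`S(g) = S(-g)`) because
the ensemble-average propagator is real.  The synthetic generator uses the
Gaussian (tensor-mixture) closed form of the Stejskal-Tanner attenuation,

    S(x, g) = S0(x) * sum_f  f_f * exp(-b g^T D_f g),

with compartment tensors `D_f` (mm^2/s) and fractions summing to 1.  The
registration itself never assumes this model; it operates on raw volumes.

Under an orientation-preserving affine `A`, the tissue microstructure
reorients only through the rotational polar factor `R` of `A = R S`
(finite strain); strain changes region shapes, not fibre directions.
Sampling reoriented tissue with gradient `g_j` equals sampling unreoriented
tissue at a rotated direction, so a spatially warped dataset is corrected
by resampling its weighted volumes on the sphere at rotated directions.
The rotation that applies is the polar factor of the *local linear part of
the pull-back map* used to sample the image: for the affine cost
`I_test(A^-1 x, ·)` this is `polar(A^-1) = R^T`, reproducing the familiar
`R^T g_j`; for a deformation-field pull-back `x + u(x)` it is
`polar(I + J_u(x))`, computed per voxel.  The ground-truth warp generator,
the affine cost and the non-linear cost all apply this one rule, and the
convention is pinned by an oracle test: a rigid warp of a single-tensor
phantom must match the rotated-tensor closed form after correction.

### Angular kernel

Angular interpolation is a normalized weighted sum of the acquired weighted
volumes.  Weights are a truncated Gaussian in the geodesic angle
`theta_k = arccos |t . g_k|`:

    a_k = exp(-(theta_k / sigma)^2)   on the 4 nearest directions, else 0,

row-normalized to sum to 1, with `sigma = 0.7 x` the scheme's mean
nearest-neighbour angular spacing and a nearest-neighbour snap below 0.5
degrees (so resampling a scheme at its own directions is the identity).
The bandwidth and truncation were chosen by a bias analysis on the analytic
single-tensor signal: a wide kernel (sigma at or above the sample spacing)
over-smooths the exponential signal profile (mean relative errors of 10-20%
at 30-degree resampling), while a very narrow kernel degenerates to
nearest-neighbour sampling and inherits its discretization error; the
sub-spacing bandwidth balances the two, and truncation to the local
neighbourhood removes the residual far-field pull toward the spherical mean.
On a 64-direction scheme this yields ~4.6% mean relative error for
30-degree rotations of a prolate (FA 0.8) tensor signal at b = 1500 s/mm^2.
b0 volumes carry no direction and always pass through unchanged.

### Spherical-harmonics backend

The alternative intensity correction fits each voxel's weighted signal on
the real, even-degree, orthonormal SH basis (order 8 → 45 coefficients) by
regularized least squares, `(B^T B + lambda L) c = B^T s`, with `L` the
squared Laplace-Beltrami diagonal `(l(l+1))^2` and `lambda = 1e-4`.  That
weight conditions the near-null space of an order-8 fit on ~64 directions
while biasing a smooth single-shell signal by only ~0.1%; substantially
larger weights visibly shrink the high-degree terms (a weight of 6e-3
costs ~5% at 30-degree resampling with this basis normalization).  The SH
route serves as the unbiased corrector when generating ground-truth warped
datasets, so recovery experiments never favour the AI kernel being tested.

## Transform models

**Affine.**  12 parameters ordered as Euler rotations (xyz, radians),
translations (mm), log-scales, shears; the linear part is
`R * Shear * Scale` acting about the reference volume's world centre.
`dof` 6/9/12 selects the leading parameters.

**B-spline field.**  `u(x) = sum_k w_k B_k(x)` on a tensor-product cubic
lattice aligned with the reference grid, two extra control points per side
so every voxel has full 4x4x4 support.  Weights are world-mm displacements;
evaluation and analytic Jacobians are parameterized by reference voxel
coordinates and chained through the grid affine.  Default knot spacing is
10 mm at the finest level, doubled per coarser level.  Between levels the
field is transferred by sparse least-squares projection onto the finer
lattice, restricted to the masked voxels the cost reads (dyadic cubic
spline spaces nest, so the projection is exact there up to conditioning;
Tikhonov damping relative to the normal-matrix diagonal pins the
unsupported boundary controls).

## Optimization

**Affine stage** is derivative-free: Powell search over a scaled parameter
vector inside a coarse-to-fine pyramid (powers-of-2 downsampling with
Gaussian pre-smoothing), with a cheap six-point rotation multi-start at the
coarsest level.  The angular correction is recomputed from the full current
transform at every cost evaluation.  Metrics: mean per-volume
`1 - normalized cross-correlation` (default; intensity-scale invariant) or
SSD.  The cost is evaluated on the intersection of the reference support
(s0 above 5% of max), the warped field of view, and the pulled-back test
support — the last term matters for test images that themselves carry
zero-filled out-of-field regions.  The reported trace is the running best
cost, hence non-increasing by construction.

**Non-linear stage** is damped Gauss-Newton.  Residuals
`E = I_corrected(w) - I_ref` over masked voxels and all volumes give
`C = (1/mn) E^T E`; the per-volume Jacobian entry is the spatial gradient
of the warped-and-corrected volume at the pulled-back point times the
supporting basis value `B_k(x_i)`.  Two deliberate approximations follow
the small-deformation regime: the derivative of the angular correction
with respect to `w` is neglected (the correction is refreshed every
iteration instead), and the basis is evaluated at the unwarped voxel
position — the exact chain-rule location, since `u` is a function of `x`.
Spatial image gradients are central differences of the cubic-spline
interpolant with a step of 0.01 voxel, and warping clamps at the volume
edge, so `C(w)` is smooth in `w`; on isotropic phantoms (where the angular
correction is exactly constant in `w`) the assembled gradient matches
finite differences of `C` to better than 1e-3 relative.  The LM schedule
multiplies the damping by 10 on rejection and 0.1 on acceptance, solving
`(H + lambda diag H) d = -grad C` on the control points that have image
support (an absolute damping floor of `1e-8 max diag H` bounds the update
of weakly supported ones); accepted steps strictly decrease `C`.  Stopping:
relative cost decrease below 1e-5 or 20 iterations per level, 3 levels by
default.  Voxels with `det(I + J_u) <= 0` are zeroed out of the residual
and counted; the report warns when they exceed 0.1% of the mask.  No
bending-energy penalty is applied by default — the data term is pure, and
topology is monitored rather than enforced.

With one weighted volume and the angular correction disabled, the machinery
reduces to ordinary scalar-image B-spline registration (tested).

## Synthetic study conditions

The default phantom is 32x32x16 voxels at 2 mm isotropic, 30 gradient
directions (deterministic Fibonacci hemisphere) plus 3 b0s at
b = 1500 s/mm^2, S0 = 1000 with a smooth off-centre Gaussian S0 texture
(emulating receive-field/anatomy contrast and giving the b0 volumes spatial
structure): an off-centre ellipsoid of isotropic tissue
(0.7e-3 mm^2/s) containing a prolate-x region (diag(1.7, 0.3, 0.3)e-3,
FA 0.8) and a 50/50 prolate-x/prolate-y crossing region, with air outside.
Optional Rician noise uses the magnitude convention
`sqrt((S + n1)^2 + n2^2)`.

Random affines are `A = R S D + t`: uniform random axis, rotation angle
uniform in [min, max] (default max 12 degrees), unit-diagonal upper
triangular shear, diagonal scales, translation uniform within ±4 mm.
Random fields draw i.i.d. uniform control weights (default ±6 mm on a
24 mm lattice) and rescale the whole field by bisection until
`min det(I + J_u) > 0.1` on the grid — amplitude zero is the identity, so
a feasible scale always exists.  All generators are deterministic per seed.

`apply_ground_truth_warp` produces the test image whose registration back
onto the input recovers the warp: it reads the input at the pulled-back
point and corrects intensities at the locally rotated directions (SH by
default, so recovery experiments are not biased toward the AI kernel; AI
and uncorrected variants are available — the uncorrected variant leaves
fibre orientations inconsistent on anisotropic tissue, which is the
premise of intensity correction).

**What the phantoms do not emulate:** acquisition point-spread/partial
volume (region boundaries are voxel-sharp, which makes small-grid
registration landscapes harsher than real data), eddy-current and
susceptibility artifacts (assumed pre-corrected), multi-shell sampling,
spatially varying noise, and anatomical variability between subjects.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated model, not clinical-grade accuracy on scanner data.

## Evaluation metrics

`MSE = mean((I_test - I_ref) / I_max)^2 x 100` over masked voxels and all
volumes, normalized by the reference maximum intensity (the inner norm is
the per-element squared difference; under the double sum this coincides
with a per-voxel vector norm).  `foe = arccos |v_test . v_ref|` between
principal eigenvectors of log-linear least-squares tensor fits, reported
as mean ± sd in degrees (values like 14.5 are only plausible in degrees;
the absolute dot product absorbs the eigenvector sign ambiguity).  The
default foe mask is FA(ref) > 0.2 within the s0 support — a stand-in for
coherent-white-matter ROI masks that would otherwise require external
atlas data — intersected with Westin linear coefficient CL > 0.1: where
the first two eigenvalues tie (balanced crossings) the principal direction
is degenerate and its angle is numerical noise, not registration error.
The tensor fit is plain (unweighted) log-linear least squares; voxels with
non-positive signal are excluded and counted; eigenvalues are clamped at
zero before FA, so FA stays in [0, 1].

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 32x32x16 phantoms with
33 volumes for affine experiments, 24x24x12 for non-linear recovery
(16 mm finest knot spacing, 2 levels, 8 iterations per level), and an
8x8x4 isotropic phantom for the analytic-vs-finite-difference gradient
check.  Affine cost evaluations use linear spatial interpolation (the
optimizer is derivative-free); final resampling and the whole non-linear
stage use cubic splines.  Field recovery is measured as the RMS of the
composition residual `u_est(x) + u_true(x + u_est(x))` over the mask —
with pull-back conventions on both sides, the estimated field approximates
the inverse of the generating one, and this residual is zero exactly at
perfect registration.

## Known limitations

* The finite-strain rotation mis-handles pure shear of fibres by design
  (shear carries a rotational component that FS attributes to rotation);
  preservation-of-principal-directions reorientation is intentionally not
  implemented.  The `A g / ||A g||` direction variant is available for
  comparison only.
* The Gauss-Newton Jacobian ignores the w-dependence of the angular
  correction; on strongly anisotropic data with large local rotations the
  gradient is approximate (the LM accept/reject loop still guarantees
  monotone cost decrease).
* Mutual information is not implemented; SSD and cross-correlation only.
* No explicit field inversion or diffeomorphic parameterization; topology
  is monitored via the Jacobian determinant, not enforced.
* Single-shell angular interpolation only — no radial (multi-shell q-space)
  interpolation.
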