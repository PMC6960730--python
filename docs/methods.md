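# Methods

## Model and conventions

`fiberpol` treats light in the Stokes formalism: a beam is the 4-vector
`S = (s0, s1, s2, s3)` of total intensity and the horizontal/vertical,
±45°, and circular polarization differences, built from six projected
intensities as `S = (IH+IV, IH−IV, IP−IM, IR−IL)`. A sample is its 4×4
Mueller matrix with **row = output component, column = input component**
(`s_out = M s_in`); this convention is fixed by the reconstruction
arithmetic, in which `M[2,1] = HH − HV + VH − VV` is the output-s1
response to (effectively) unpolarized input. Phase information is outside
the formalism; no Jones/coherent modelling is attempted.

Frame rotations are counter-clockwise positive looking toward the source.
The Mueller rotation matrix carries the doubled angle in its (s1, s2)
block, so every angular quantity is axial: a rotation by 180° is the
identity, and orientation statistics use double-angle (axial) circular
formulas by default, with the plain n−1 sample standard deviation also
available.

## Acquisition

A measurement is a stack of intensity images, one per (generator,
analyzer) state pair. The over-determined scheme uses all 36 pairs from
{H, V, P, M, R, L}²; the minimal scheme uses the 16 pairs over
{H, V, P, R}² — a complete choice spanning both linear bases and one
circular state (the minimal subset is not canonical; this one is
configurable). Two reconstruction routes are provided, because either may
be preferred in practice:

* **Direct arithmetic**: each entry is a signed four-term sum of images
  (first letter = illumination). These sums equal `2·gain·M[i,j]`; the
  constant cancels when the result is normalized by `M[1,1]`, which also
  makes reconstructions invariant to overall detector gain.
* **Least squares**: the linear system `I(X,Y) = gain · a(Y)ᵀ M s(X)` is
  solved per pixel over all available pairs. With an ideal instrument and
  noiseless 36-image data it agrees with the direct route to 1e−9; with
  perturbed instrument states the 36-pair solve averages calibration
  error down and beats the 16-pair solve in median entry error.

Pixels whose `M[1,1]` falls at or below `epsilon = 1e−3` of the image
maximum are masked invalid rather than divided through. Region-of-interest
results are entrywise means with n−1 sample standard deviations over valid
pixels; homogeneous samples are averaged over the full frame.

## Polar decomposition

The Lu–Chipman factorization `M = M_Δ · M_R · M_D` proceeds
diattenuator-first: the diattenuation vector is the first row of the
normalized matrix; `M_D` has the 3×3 block
`√(1−D²) I + (1−√(1−D²)) d̂d̂ᵀ`; `M' = M M_D⁻¹` carries the polarizance
vector in its first column; the depolarizer block is
`sign(det m′) · (m′ m′ᵀ)^{1/2}` computed by eigendecomposition of the
symmetric product; the retarder block is `m_Δ⁻¹ m′` (a proper rotation by
construction). The general depolarizer (with polarizance vector and
non-diagonal block) is used; the diagonal summary `(a, b, c)` is reported
only when the off-diagonal block is below 1e−8, otherwise the block's
eigenvalues are reported. The decomposition is order-dependent, and the
implementation is deliberately asymmetric (a regression test reverses the
factor order and checks that the recovered diattenuation changes).

Numerical choices:

* `arccos` arguments are clamped to [−1, 1]; the fast axis is flagged
  undefined when `|sin R| < 1e−6`. Near `R = π` the axis is recovered as
  the retarder block's +1 eigenvector (sign fixed by the first significant
  component — for a half-wave retarder the fast/slow distinction is
  genuinely ambiguous).
* A perfect polarizer (`D → 1`) makes `M_D` singular: the retarder is set
  to the identity, the depolarizer absorbs the remainder through a
  pseudo-inverse, and the result is flagged `degenerate_polarizer`. A
  singular depolarizer block (e.g. an ideal diffuse scatterer) leaves the
  retarder as identity with NaN retardance and flag
  `singular_depolarizer`.
* Non-physical measured matrices are decomposed anyway and flagged by the
  separate physicality check (entry bounds plus output degree of
  polarization ≤ 1 on a fixed 26-state fully polarized probe grid); no
  Cloude-type filtering or projection is applied.
* The algorithm's depolarizer is always `±(PSD)`: a *mixed-sign* diagonal
  depolarizer composed with a retarder admits another factorization in
  which the sign flip migrates into an improper rotation, so such inputs
  are recovered with identical Δ and D but a different retarder split.
  Construct-then-decompose oracles therefore sample canonical (single
  global sign) depolarizers.

## Orientation and velocity inference

The fiber direction is the azimuth `θ = ½ atan2(a₂, a₁)` of the fast
axis, mapped to [0°, 180°); the circular component `a₃` is reported as an
out-of-plane diagnostic only. For images, the central estimate comes from
decomposing the ROI-averaged matrix and the quoted uncertainty is the
axial circular standard deviation of per-pixel azimuths.

Rotating a sample with alignment makes entries such as `M21` trace
`offset + A cos 2θ + B sin 2θ` (period fixed at 180°); the fit is linear
least squares, so **three measurements at distinct angles (mod 180°)
determine amplitude and phase exactly** in the noiseless case. In this
forward model `M21(θ) = a·d·cos(2(φ+θ))` with `a` the relevant
depolarizer coefficient and `d` the diattenuation, so the fitted phase
relates to the fiber azimuth as `φ = (−phase) mod 180°` — the sign
convention is fixed by this one documented reference case. Mounting the
sample rotated by 90° flips the sign of the `M12`/`M21` oscillation, while
the key figures Δ, R, P are rotation-insensitive for this model (P is
exactly constant under rotation), which is why they are the preferred
per-sample summaries.

The amplitude–velocity calibration is an isotonic (monotone
non-decreasing) fit with piecewise-linear interpolation on the rising
branch — a deliberate choice over a parametric saturating curve, since
only monotonicity up to a plateau is assumed. Inversion refuses
amplitudes below the calibrated range and maps amplitudes at/above the
plateau to the saturation velocity with a `saturated` flag. On noiseless
synthetic series the round trip recovers rising-branch velocities within
0.5 m/s.

## Synthetic data: what it emulates and what it does not

The generator composes exactly the factor structure the decomposition
recovers:

    M(q, φ) = Rot(φ) [ M_Δ(q) · M_R(q·δ_max) · M_D(q·d_max) ] Rot(−φ)

with alignment fraction `q ∈ [0, 1]` and fiber azimuth `φ`. The
depolarizer interpolates diagonally from isotropic at `q = 0` to
`depol_floor` at `q = 1`; its first two coefficients are kept equal so it
commutes with frame rotation and generated matrices stay exactly
factorizable at any φ. Collector velocity maps to alignment as
`q(v) = q_max (1 − e^{−v/v_sat})` with `v_sat = 7 m/s` (the observed
saturation scale) and `q_max = 0.95`.

Defaults `d_max = 0.3`, `delta_max = 0.6 rad`,
`depol_floor = (0.6, 0.6, 0.5)` are package plumbing chosen to give signal
magnitudes typical of strongly scattering fiber mats; they are **not**
measured constants (no printed matrix magnitudes exist to anchor them).
The virtual detector applies mean-one multiplicative gamma speckle (a
stand-in for time-modulated residual laser speckle), Poisson shot noise,
Gaussian read noise, clipping, and bit-depth quantization, all seeded; the
default is an ideal float detector so exactness tests are meaningful. The
default production series is 14 velocities from 0.4 to 10.7 m/s with 5
replicates, matching a realistic reproducibility design.

Passing tests on these data show the *pipeline* is correct, not that real
scaffolds follow the model: real measurements add instrument polarization
artifacts, mounting misalignment, sample inhomogeneity beyond orientation
jitter, reflection-mode non-sinusoidal angular behavior, and a
post-saturation amplitude *decrease* at high velocities — none of which
are modelled (the velocity map plateaus; reflection mode is limited to raw
scan I/O).

## Problem sizes

Default test and reproduction sizes are chosen for desk-scale runs:
500-matrix reconstruction oracles, 1000-product decomposition round trips,
1e4 random matrices for range bounds, 1e5 coefficient draws for the
depolarization-power extremum, 100 seeded noisy runs (16×16 px, 12-bit,
speckle contrast 0.1) for orientation recovery, and 200 draws for the
over-determination comparison.
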