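# fiberpol

Mueller-matrix imaging polarimetry for electrospun fiber scaffolds.

Electrospun polymer scaffolds collected on a rotating drum develop partial
fiber alignment that grows with the relative collector velocity and
saturates near 7 m/s. Because aligned polymer fibers are weakly
diattenuating and birefringent along the fiber axis, the scaffold's
polarization transfer — its 4×4 Mueller matrix **M** — encodes both the
fiber direction and the degree of alignment. `fiberpol` implements the
full measurement-analysis chain for such samples, plus a virtual
polarimeter and scaffold simulator so every stage is testable without
instrument data:

1. **Acquisition** — reconstruct a per-pixel Mueller matrix from a stack
   of 36 (or 16) intensity images taken with generator/analyzer state
   pairs drawn from {H, V, P, M, R, L}², either by the direct sum/difference
   arithmetic (e.g. `M[1,1] = HH + HV + VH + VV`) or by least squares
   against an instrument model, normalized by `M[1,1]`.
2. **Decomposition** — Lu–Chipman polar decomposition
   `M = M_Δ · M_R · M_D` (depolarizer · retarder · diattenuator) and the
   key figures

   - depolarization power `Δ = 1 − (|a|+|b|+|c|)/3 ∈ [0, 1]`,
   - total retardance `R = arccos(tr(M_R)/2 − 1) ∈ [0, π]`,
   - total polarizance `P = √(M₂₁² + M₃₁² + M₄₁²)/M₁₁ ∈ [0, 1]`,
   - the fast-axis Stokes vector `aᵢ = (1/2 sin R) Σ εᵢⱼₖ (m_R)ⱼₖ`.

3. **Orientation** — the fast-axis azimuth `θ = ½ atan2(a₂, a₁)` gives the
   fiber direction from a single measurement; rotating the sample makes
   anisotropic entries such as `M21` trace a 180°-periodic sinusoid whose
   amplitude calibrates against collector velocity (monotone up to the
   saturation plateau), so one amplitude measurement reads the production
   velocity back.

## Worked example

Simulate a scaffold spun at 5.2 m/s with fibers at 30°, image it through
the virtual polarimeter (12-bit detector, 5 % speckle contrast),
reconstruct, decompose, and read the orientation and velocity back:

```python
import numpy as np
import fiberpol as fp

q = fp.velocity_to_alignment(5.2)                   # alignment fraction
model = fp.ScaffoldModel(q=q, phi_deg=30.0)
noise = fp.NoiseModel(speckle_contrast=0.05, bit_depth=12, seed=1)
stack, _ = fp.generate_stack(model, fp.InstrumentModel.ideal(gain=1000.0),
                             noise, width=32, height=32)
mm = fp.reconstruct_table3(stack)
mean, std = fp.roi_average(mm, fp.Roi(0, 0, 32, 32))
res = fp.lu_chipman(mean.normalize())
est = fp.estimate_orientation(mm)

scan = fp.generate_angular_scan(model, [0.0, 30.0, 60.0])
fit = fp.fit_angular_scan(scan, "M21")
vels = np.array([0.4,1.2,2.0,2.8,3.6,4.4,5.2,6.0,6.7,7.5,8.3,9.1,9.9,10.7])
amps = [fp.fit_angular_scan(fp.generate_angular_scan(
            fp.ScaffoldModel(q=fp.velocity_to_alignment(v)), [0.,30.,60.]),
        "M21").amplitude for v in vels]
cal = fp.calibrate_alignment(vels, amps)
v_est = fp.infer_velocity(fit.amplitude, cal)
```

Output:

```
alignment q(5.2 m/s)     = 0.498
depolarization power Δ   = 0.434
total retardance R       = 0.300 rad
polarizance P            = 0.087
diattenuation D          = 0.149
fiber azimuth            = 30.07 deg (+/- 3.11 deg over 1024 px)
M21 sinusoid amplitude   = 0.0871
inferred velocity        = 5.20 m/s (ok)
```

The azimuth recovers the 30° ground truth to within the speckle-limited
uncertainty; the three-angle `M21` sinusoid fit plus the monotone
amplitude–velocity calibration recovers the 5.2 m/s collector velocity.

A `fiberpol` CLI wraps the same pipeline
(`simulate | reconstruct | decompose | orient | scanfit | calibrate`);
try `fiberpol --help`.

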