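"""Virtual polarimeter and fiber-scaffold forward model.

An electrospun scaffold collected on a rotating drum develops partial
fiber alignment that grows with the relative collector velocity and
saturates near 7 m/s. Optically, aligned polymer fibers act as a weak
linear diattenuator and linear retarder along the fiber axis, embedded in
strong diffuse depolarization. The forward model composes exactly the
factor structure the polar decomposition later recovers,

    M(q, phi) = Rot(phi) [ M_delta(q) M_R(q delta_max) M_D(q d_max) ] Rot(-phi),

with alignment fraction q in [0, 1] and fiber azimuth phi. The virtual
polarimeter projects these matrices onto generator/analyzer state pairs,
adds multiplicative speckle, shot and read noise, and quantizes to the
detector bit depth — so every pipeline stage can be tested against known
ground truth.

Anisotropy magnitudes (d_max, delta_max, depol_floor) are package
defaults chosen to give signal sizes typical of scattering fiber mats;
they are not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    MuellerMatrix,
    diagonal_depolarizer,
    linear_diattenuator,
    linear_retarder,
    rotate_frame,
)
from .acquisition import (
    FULL_PAIRS,
    MINIMAL_PAIRS,
    InstrumentModel,
    PolarizationImageStack,
)
from .orientation import AngularScan

#: Collector velocities (m/s) of the reference production series (batch 2 design).
DEFAULT_VELOCITIES = (
    0.4, 1.2, 2.0, 2.8, 3.6, 4.4, 5.2, 6.0, 6.7, 7.5, 8.3, 9.1, 9.9, 10.7,
)


@dataclass(frozen=True)
class ScaffoldModel:
    """Optical model of one scaffold: alignment, orientation, anisotropy.

    depol_floor is the diagonal depolarizer at full alignment; its first
    two coefficients are kept equal so the depolarizer commutes with frame
    rotation and generated matrices stay exactly factorizable at any phi.
    """

    q: float = 0.5
    phi_deg: float = 0.0
    d_max: float = 0.3
    delta_max: float = 0.6
    depol_floor: tuple = (0.6, 0.6, 0.5)
    heterogeneity_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"alignment q must be in [0, 1], got {self.q}")
        if not 0.0 <= self.d_max < 1.0:
            raise ValueError(f"d_max must be in [0, 1), got {self.d_max}")
        if self.delta_max < 0:
            raise ValueError("delta_max must be nonnegative")
        if any(abs(c) > 1 for c in self.depol_floor):
            raise ValueError("depol_floor coefficients must lie in [-1, 1]")
        if self.heterogeneity_deg < 0:
            raise ValueError("heterogeneity must be nonnegative")


@dataclass(frozen=True)
class NoiseModel:
    """Detector and illumination noise; the default is an ideal detector.

    ``bit_depth`` None keeps floating-point intensities (no quantization);
    an integer quantizes and clips to [0, 2**bit_depth - 1]. ``shot_scale``
    is photons per intensity unit (0 disables shot noise); speckle is a
    mean-one multiplicative gamma field of the given contrast.
    """

    read_noise: float = 0.0
    shot_scale: float = 0.0
    speckle_contrast: float = 0.0
    bit_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.speckle_contrast < 1.0:
            raise ValueError("speckle contrast must be in [0, 1)")
        if self.read_noise < 0 or self.shot_scale < 0:
            raise ValueError("noise scales must be nonnegative")


@dataclass(frozen=True)
class VelocityMap:
    """Saturating map from collector velocity to alignment fraction."""

    v_sat: float = 7.0
    q_max: float = 0.95
    shape: str = "exp_saturation"

    def __post_init__(self) -> None:
        if self.v_sat <= 0 or not 0 < self.q_max <= 1:
            raise ValueError("v_sat must be > 0 and q_max in (0, 1]")
        if self.shape != "exp_saturation":
            raise ValueError(f"unknown velocity-map shape {self.shape!r}")


def velocity_to_alignment(v: float, vmap: VelocityMap = VelocityMap()) -> float:
    """q(v) = q_max (1 - exp(-v / v_sat)): zero at rest, monotone, saturating."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("collector velocity must be nonnegative")
    out = vmap.q_max * (1.0 - np.exp(-v / vmap.v_sat))
    return float(out) if out.ndim == 0 else out


def scaffold_mueller(model: ScaffoldModel, phi_deg: float | None = None) -> MuellerMatrix:
    """Ground-truth Mueller matrix of a scaffold (optionally overriding phi)."""
    phi = model.phi_deg if phi_deg is None else phi_deg
    iso = float(np.mean(np.abs(model.depol_floor)))
    abc = [iso + model.q * (c - iso) for c in model.depol_floor]
    m = (
        diagonal_depolarizer(*abc).m
        @ linear_retarder(model.q * model.delta_max).m
        @ linear_diattenuator(model.q * model.d_max).m
    )
    return rotate_frame(MuellerMatrix(m, normalized=True), phi)


def simulate_intensities(m: np.ndarray, instrument: InstrumentModel, pairs=FULL_PAIRS) -> dict:
    """Noise-free detected intensity per state pair for matrices (..., 4, 4)."""
    return {(g, a): instrument.intensity(m, g, a) for g, a in pairs}


def _apply_noise(img: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(img, dtype=float)
    c = noise.speckle_contrast
    if c > 0:
        k = 1.0 / c**2
        out = out * rng.gamma(shape=k, scale=1.0 / k, size=out.shape)
    if noise.shot_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.shot_scale) / noise.shot_scale
    if noise.read_noise > 0:
        out = out + rng.normal(0.0, noise.read_noise, size=out.shape)
    out = np.clip(out, 0.0, None)
    if noise.bit_depth is not None:
        full = 2**noise.bit_depth - 1
        out = np.clip(np.round(out), 0, full)
    return out


def generate_stack(
    model: ScaffoldModel,
    instrument: InstrumentModel | None = None,
    noise: NoiseModel = NoiseModel(),
    width: int = 16,
    height: int = 16,
    mode: str = "36",
):
    """Simulate one polarization image stack plus its per-pixel ground truth.

    Returns ``(PolarizationImageStack, truth)`` where truth is the
    (height, width, 4, 4) array of sample matrices used per pixel.
    """
    if instrument is None:
        instrument = InstrumentModel.ideal()
    rng = np.random.default_rng(noise.seed)
    if model.heterogeneity_deg > 0:
        phis = model.phi_deg + rng.normal(0.0, model.heterogeneity_deg, (height, width))
        truth = np.empty((height, width, 4, 4))
        for y in range(height):
            for x in range(width):
                truth[y, x] = scaffold_mueller(model, phis[y, x]).m
    else:
        truth = np.broadcast_to(
            scaffold_mueller(model).m, (height, width, 4, 4)
        ).copy()
    pairs = FULL_PAIRS if mode == "36" else MINIMAL_PAIRS
    images = {}
    for pair, ideal in simulate_intensities(truth, instrument, pairs).items():
        images[pair] = _apply_noise(ideal, noise, rng)
    stack = PolarizationImageStack(
        images, bit_depth=noise.bit_depth, wavelength_nm=532.0
    )
    return stack, truth


def generate_angular_scan(
    model: ScaffoldModel,
    angles_deg,
    instrument: InstrumentModel | None = None,
    noise: NoiseModel | None = None,
    exact: bool = True,
    width: int = 8,
    height: int = 8,
) -> AngularScan:
    """Rotate the sample through the given angles and record its matrix.

    ``exact=True`` returns the analytic ground-truth matrices; otherwise
    each angle is imaged through the virtual polarimeter, reconstructed,
    and averaged over the full frame (imports deferred to avoid cycles).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if exact:
        mats = tuple(
            scaffold_mueller(model, model.phi_deg + th) for th in angles
        )
        return AngularScan(angles, mats)
    from .acquisition import Roi, reconstruct_table3, roi_average

    if noise is None:
        noise = NoiseModel()
    mats = []
    stds = []
    for k, th in enumerate(angles):
        rotated = ScaffoldModel(
            q=model.q,
            phi_deg=(model.phi_deg + th) % 360.0,
            d_max=model.d_max,
            delta_max=model.delta_max,
            depol_floor=model.depol_floor,
            heterogeneity_deg=model.heterogeneity_deg,
        )
        nz = NoiseModel(
            read_noise=noise.read_noise,
            shot_scale=noise.shot_scale,
            speckle_contrast=noise.speckle_contrast,
            bit_depth=noise.bit_depth,
            seed=noise.seed + 1000 * k,
        )
        stack, _ = generate_stack(rotated, instrument, nz, width, height)
        mmimg = reconstruct_table3(stack)
        mean, std = roi_average(mmimg, Roi(0, 0, width, height))
        mats.append(mean)
        stds.append(std)
    return AngularScan(angles, tuple(mats), tuple(stds))


def generate_velocity_series(
    velocities=DEFAULT_VELOCITIES,
    replicates: int = 5,
    vmap: VelocityMap = VelocityMap(),
    template: ScaffoldModel = ScaffoldModel(),
    instrument: InstrumentModel | None = None,
    noise: NoiseModel = NoiseModel(),
    batch_q_jitter: float = 0.0,
    exact: bool = True,
    width: int = 8,
    height: int = 8,
    seed: int = 0,
):
    """Production series: replicated samples over a velocity ladder.

    Mirrors a 14-velocity, n-replicate reproducibility design. Batch-to-
    batch variability enters as a seeded relative perturbation of q.
    Returns ``(samples, truth_table)``: samples maps (velocity, replicate)
    to a ground-truth MuellerMatrix (exact mode) or an image stack, and the
    truth table is a tidy DataFrame (velocity, replicate, q, phi_deg, seed).
    """
    rng = np.random.default_rng(seed)
    samples = {}
    rows = []
    for v in velocities:
        for rep in range(replicates):
            q = velocity_to_alignment(v, vmap)
            if batch_q_jitter > 0:
                q = float(np.clip(q * (1 + rng.normal(0, batch_q_jitter)), 0.0, 1.0))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            model = ScaffoldModel(
                q=q,
                phi_deg=template.phi_deg,
                d_max=template.d_max,
                delta_max=template.delta_max,
                depol_floor=template.depol_floor,
                heterogeneity_deg=template.heterogeneity_deg,
            )
            if exact:
                samples[(v, rep)] = scaffold_mueller(model)
            else:
                nz = NoiseModel(
                    read_noise=noise.read_noise,
                    shot_scale=noise.shot_scale,
                    speckle_contrast=noise.speckle_contrast,
                    bit_depth=noise.bit_depth,
                    seed=sub_seed,
                )
                samples[(v, rep)], _ = generate_stack(
                    model, instrument, nz, width, height
                )
            rows.append(
                {"velocity": v, "replicate": rep, "q": q,
                 "phi_deg": model.phi_deg, "seed": sub_seed}
            )
    return samples, pd.DataFrame(rows)
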