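"""Stokes/Mueller algebra: basis polarization states, frame rotation,
element constructors, and physicality checks.

Conventions
-----------
* Stokes vector ``(s0, s1, s2, s3)``: total intensity, horizontal/vertical
  linear, +45/-45 linear, right/left circular.
* Mueller matrix ``M[i, j]``: row ``i`` = output Stokes component, column
  ``j`` = input Stokes component, so ``s_out = M @ s_in``.
* Frame rotation angles are physical angles in degrees, counter-clockwise
  positive looking toward the source; the Mueller rotation matrix carries
  the doubled angle in its (s1, s2) block, so a 180 deg rotation is the
  identity (axial periodicity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHYSICALITY_TOL = 1e-9

#: The six-letter polarization-state alphabet: horizontal, vertical,
#: +45 deg, -45 deg, right circular, left circular.
STATE_LABELS = ("H", "V", "P", "M", "R", "L")

_BASIS = {
    "H": np.array([1.0, 1.0, 0.0, 0.0]),
    "V": np.array([1.0, -1.0, 0.0, 0.0]),
    "P": np.array([1.0, 0.0, 1.0, 0.0]),
    "M": np.array([1.0, 0.0, -1.0, 0.0]),
    "R": np.array([1.0, 0.0, 0.0, 1.0]),
    "L": np.array([1.0, 0.0, 0.0, -1.0]),
}


@dataclass(frozen=True)
class StokesVector:
    """Polarization state of a light beam in arbitrary linear detector units."""

    s0: float
    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError(f"s0 (total intensity) must be >= 0, got {self.s0}")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    @classmethod
    def from_array(cls, a) -> "StokesVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"Stokes vector needs 4 components, got shape {a.shape}")
        return cls(*a)

    @property
    def degree_of_polarization(self) -> float:
        """|(s1, s2, s3)| / s0; NaN for a dark beam (s0 == 0)."""
        pol = float(np.sqrt(self.s1**2 + self.s2**2 + self.s3**2))
        if self.s0 == 0:
            return float("nan") if pol > 0 else 0.0
        return pol / self.s0

    def is_physical(self, tol: float = PHYSICALITY_TOL) -> bool:
        pol = np.sqrt(self.s1**2 + self.s2**2 + self.s3**2)
        return bool(pol <= self.s0 * (1 + tol))


@dataclass(frozen=True)
class MuellerMatrix:
    """4x4 real polarization transfer matrix (row = output, column = input)."""

    m: np.ndarray
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"Mueller matrix must be 4x4, got shape {m.shape}")
        object.__setattr__(self, "m", m)
        if self.normalized:
            if not np.isclose(m[0, 0], 1.0, atol=1e-9):
                raise ValueError("normalized Mueller matrix requires M[1,1] == 1")

    @property
    def block(self) -> np.ndarray:
        """The lower-right 3x3 submatrix (rows/columns 2-4)."""
        return self.m[1:, 1:]

    def normalize(self) -> "MuellerMatrix":
        m00 = self.m[0, 0]
        if m00 <= 0:
            raise ValueError(f"cannot normalize: M[1,1] = {m00} <= 0")
        return MuellerMatrix(self.m / m00, normalized=True)

    def __matmul__(self, other: "MuellerMatrix") -> "MuellerMatrix":
        return MuellerMatrix(self.m @ other.m)


def stokes_from_six_intensities(
    i_h: float, i_v: float, i_p: float, i_m: float, i_r: float, i_l: float
) -> StokesVector:
    """Build a Stokes vector from the six polarization-projected intensities.

    ``S = (IH + IV, IH - IV, IP - IM, IR - IL)``.
    """
    for name, val in (("H", i_h), ("V", i_v), ("P", i_p),
                      ("M", i_m), ("R", i_r), ("L", i_l)):
        if val < 0:
            raise ValueError(f"negative intensity in channel {name}: {val}")
    return StokesVector(i_h + i_v, i_h - i_v, i_p - i_m, i_r - i_l)


def basis_state(label: str) -> StokesVector:
    """Unit-intensity fully polarized state for one of the six labels."""
    if label not in _BASIS:
        raise ValueError(f"unknown state label {label!r}; expected one of {STATE_LABELS}")
    return StokesVector.from_array(_BASIS[label])


def apply_mueller(m: MuellerMatrix, s: StokesVector) -> StokesVector:
    """Propagate a Stokes vector through a sample: ``s_out = M @ s_in``."""
    out = m.m @ s.array
    # the matrix may be non-physical; clamp only exact-zero drift on s0
    if out[0] < 0 and out[0] > -1e-300:
        out[0] = 0.0
    return StokesVector(*out)


def rotation_mueller(phi_deg: float) -> np.ndarray:
    """Mueller rotation matrix Rot(phi); doubled angle acts on (s1, s2)."""
    a = np.deg2rad(2.0 * phi_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def rotate_frame(m: MuellerMatrix, phi_deg: float) -> MuellerMatrix:
    """Express a sample rotated by ``phi_deg``: ``Rot(phi) @ M @ Rot(-phi)``."""
    r = rotation_mueller(phi_deg)
    rinv = rotation_mueller(-phi_deg)
    return MuellerMatrix(r @ m.m @ rinv, normalized=m.normalized)


def rotate_frame_stokes(s: StokesVector, phi_deg: float) -> StokesVector:
    """Rotate a Stokes vector's linear components by the doubled angle."""
    return StokesVector(*(rotation_mueller(phi_deg) @ s.array))


# ---------------------------------------------------------------------------
# Element constructors (building blocks for the forward model and tests)
# ---------------------------------------------------------------------------

def diattenuator_from_vector(d_vec) -> MuellerMatrix:
    """Pure diattenuator with diattenuation vector ``d_vec`` (|d| <= 1).

    M_D = [[1, d^T], [d, m_D]] with
    m_D = sqrt(1 - D^2) I + (1 - sqrt(1 - D^2)) d_hat d_hat^T.
    """
    d = np.asarray(d_vec, dtype=float)
    dd = float(np.linalg.norm(d))
    if dd > 1 + 1e-12:
        raise ValueError(f"diattenuation magnitude {dd} exceeds 1")
    if dd < 1e-300:
        return MuellerMatrix(np.eye(4), normalized=True)
    dhat = d / dd
    root = np.sqrt(max(1.0 - dd * dd, 0.0))
    md = root * np.eye(3) + (1.0 - root) * np.outer(dhat, dhat)
    m = np.eye(4)
    m[0, 1:] = d
    m[1:, 0] = d
    m[1:, 1:] = md
    return MuellerMatrix(m, normalized=True)


def linear_diattenuator(d: float, angle_deg: float = 0.0) -> MuellerMatrix:
    """Linear partial polarizer of diattenuation ``d`` with axis at ``angle_deg``."""
    base = diattenuator_from_vector([d, 0.0, 0.0])
    return rotate_frame(base, angle_deg) if angle_deg else base


def retarder_from_axis(axis, delta_rad: float) -> MuellerMatrix:
    """Elliptical retarder with fast-axis Stokes direction ``axis``, retardance delta.

    The 3x3 block is the rotation by ``delta_rad`` about ``axis`` with the sign
    chosen so that a horizontal linear fast axis gives the standard block
    [[1, 0, 0], [0, cos d, sin d], [0, -sin d, cos d]].
    """
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("retarder axis must be nonzero")
    a = a / n
    k = np.array(
        [[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]]
    )
    c, s = np.cos(delta_rad), np.sin(delta_rad)
    block = c * np.eye(3) - s * k + (1 - c) * np.outer(a, a)
    m = np.eye(4)
    m[1:, 1:] = block
    return MuellerMatrix(m, normalized=True)


def linear_retarder(delta_rad: float, angle_deg: float = 0.0) -> MuellerMatrix:
    """Linear retarder of retardance ``delta_rad`` with fast axis at ``angle_deg``."""
    phi = np.deg2rad(2.0 * angle_deg)
    return retarder_from_axis([np.cos(phi), np.sin(phi), 0.0], delta_rad)


def diagonal_depolarizer(a: float, b: float, c: float) -> MuellerMatrix:
    """Diagonal depolarizer diag(1, a, b, c) with |a|, |b|, |c| <= 1."""
    for name, v in (("a", a), ("b", b), ("c", c)):
        if abs(v) > 1 + 1e-12:
            raise ValueError(f"depolarizer coefficient {name} = {v} outside [-1, 1]")
    return MuellerMatrix(np.diag([1.0, a, b, c]), normalized=True)


def horizontal_polarizer() -> MuellerMatrix:
    """Ideal horizontal polarizer, 0.5 * [[1,1,0,0],[1,1,0,0],[0...],[0...]]."""
    m = np.zeros((4, 4))
    m[:2, :2] = 0.5
    return MuellerMatrix(m)


def ideal_diffuser() -> MuellerMatrix:
    """Fully depolarizing scatterer, diag(1, 0, 0, 0)."""
    return MuellerMatrix(np.diag([1.0, 0.0, 0.0, 0.0]), normalized=True)


# ---------------------------------------------------------------------------
# Physicality check
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform grid of n unit vectors on the sphere."""
    i = np.arange(n, dtype=float)
    golden = (1 + np.sqrt(5.0)) / 2
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _polarized_probe_grid() -> np.ndarray:
    """>= 26 fully polarized unit-intensity probe states (6 basis + sphere grid)."""
    basis = np.array([_BASIS[k] for k in STATE_LABELS])
    sphere = _fibonacci_sphere(20)
    extra = np.column_stack([np.ones(len(sphere)), sphere])
    return np.vstack([basis, extra])


_PROBE_GRID = _polarized_probe_grid()


@dataclass(frozen=True)
class PhysicalityVerdict:
    physical: bool
    diagnostics: tuple

    def __bool__(self) -> bool:
        return self.physical


def is_physical(m: MuellerMatrix, tol: float = PHYSICALITY_TOL) -> PhysicalityVerdict:
    """Necessary-condition check that M maps physical light to physical light.

    Checks M[1,1] > 0, entry bounds |M[i,j]| <= M[1,1], and that every state
    on a fixed grid of fully polarized probes leaves with degree of
    polarization <= 1. Measured noisy matrices that fail are flagged, never
    silently projected.
    """
    diags = []
    mm = m.m
    m00 = mm[0, 0]
    if m00 <= 0:
        diags.append(f"M[1,1] = {m00} is not positive")
        return PhysicalityVerdict(False, tuple(diags))
    bound = m00 * (1 + tol)
    over = np.argwhere(np.abs(mm) > bound)
    for i, j in over:
        diags.append(
            f"|M[{i + 1},{j + 1}]| = {abs(mm[i, j]):.6g} exceeds M[1,1] = {m00:.6g}"
        )
    out = _PROBE_GRID @ mm.T
    s0 = out[:, 0]
    pol = np.linalg.norm(out[:, 1:], axis=1)
    bad_dark = (s0 <= 0) & (pol > tol * m00)
    for idx in np.flatnonzero(bad_dark):
        diags.append(f"probe state {idx}: nonpositive output intensity {s0[idx]:.6g}")
    ok = (s0 > 0) | ~bad_dark
    with np.errstate(divide="ignore", invalid="ignore"):
        dop = np.where(s0 > 0, pol / np.where(s0 > 0, s0, 1.0), 0.0)
    bad_dop = ok & (dop > 1 + tol)
    for idx in np.flatnonzero(bad_dop):
        diags.append(
            f"probe state {idx}: output degree of polarization {dop[idx]:.6g} > 1"
        )
    return PhysicalityVerdict(len(diags) == 0, tuple(diags))
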