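"""Lu-Chipman polar decomposition and polarimetric key figures.

A measured Mueller matrix is factorized as M = M_delta * M_R * M_D
(depolarizer times retarder times diattenuator, in that order; the
factorization is order dependent). From the factors the key figures are
computed: depolarization power Delta in [0, 1], total retardance R in
[0, pi], total polarizance P in [0, 1], and the normalized Stokes vector
of the retarder's fast axis, whose equatorial azimuth encodes the fiber
orientation.

Non-physical measured matrices are decomposed anyway but flagged; no
filtering or projection is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MuellerMatrix, diattenuator_from_vector
from .acquisition import MMImage

#: |sin R| below this, the axis of rotation is not resolvable from the
#: antisymmetric part of the retarder block.
SIN_R_THRESHOLD = 1e-6

_POLARIZER_D_TOL = 1e-9


@dataclass(frozen=True)
class DecompositionResult:
    """Factors and key figures of one polar decomposition."""

    m_delta: MuellerMatrix
    m_r: MuellerMatrix
    m_d: MuellerMatrix
    diattenuation_vector: np.ndarray
    polarizance_vector: np.ndarray
    depol_diag: tuple
    delta: float
    r_total: float
    p_total: float
    fast_axis: np.ndarray
    fast_axis_defined: bool
    flags: tuple = ()

    @property
    def diattenuation(self) -> float:
        return float(np.linalg.norm(self.diattenuation_vector))

    @property
    def azimuth_deg(self) -> float:
        """Fast-axis azimuth in [0, 180) degrees; NaN when undefined."""
        if not self.fast_axis_defined:
            return float("nan")
        a1, a2 = self.fast_axis[0], self.fast_axis[1]
        return float(np.rad2deg(0.5 * np.arctan2(a2, a1)) % 180.0)

    def product(self) -> MuellerMatrix:
        return MuellerMatrix(self.m_delta.m @ self.m_r.m @ self.m_d.m)


def depolarization_power(m_delta: MuellerMatrix) -> float:
    """Delta = 1 - mean absolute eigenvalue of the depolarizer's 3x3 block.

    For the diagonal depolarizer diag(1, a, b, c) this is
    1 - (|a| + |b| + |c|) / 3.
    """
    block = m_delta.block
    if np.allclose(block, block.T, atol=1e-12):
        eig = np.linalg.eigvalsh(block)
    else:
        eig = np.linalg.eigvals(block)
    return float(1.0 - np.abs(eig).sum() / 3.0)


def total_retardance(m_r: MuellerMatrix) -> float:
    """R = arccos(tr(M_R)/2 - 1), clamped into [0, pi]."""
    arg = np.trace(m_r.m) / 2.0 - 1.0
    return float(np.arccos(np.clip(arg, -1.0, 1.0)))


def polarizance(m: MuellerMatrix) -> float:
    """P = |(M21, M31, M41)| / M11: degree of polarization given to
    unpolarized input."""
    m00 = m.m[0, 0]
    if m00 <= 0:
        raise ValueError(f"polarizance undefined: M[1,1] = {m00} <= 0")
    return float(np.linalg.norm(m.m[1:, 0]) / m00)


def fast_axis(m_r: MuellerMatrix, r_total: float):
    """Fast-axis unit Stokes 3-vector from the retarder block.

    a_i = 1 / (2 sin R) * sum_jk eps_ijk (m_R)_jk. When |sin R| is below
    threshold (R near 0 or pi) the antisymmetric part vanishes; for R near
    pi the axis is recovered as the block's +1 eigenvector, for R near 0 it
    is undefined. Returns ``(axis, defined)``.
    """
    mr = m_r.block
    s = np.sin(r_total)
    if np.isfinite(r_total) and abs(s) >= SIN_R_THRESHOLD:
        a = np.array(
            [mr[1, 2] - mr[2, 1], mr[2, 0] - mr[0, 2], mr[0, 1] - mr[1, 0]]
        ) / (2.0 * s)
        n = np.linalg.norm(a)
        if n > 0:
            return a / n, True
        return np.full(3, np.nan), False
    # R near 0: any axis fits; R near pi: axis is the +1 eigenvector.
    if np.isfinite(r_total) and r_total > np.pi / 2:
        w, v = np.linalg.eig(mr)
        idx = int(np.argmin(np.abs(w - 1.0)))
        if abs(w[idx] - 1.0) < 1e-6:
            a = np.real(v[:, idx])
            a = a / np.linalg.norm(a)
            # half-wave axis is sign ambiguous; fix by first significant component
            lead = a[np.argmax(np.abs(a) > 1e-12)]
            if lead < 0:
                a = -a
            return a, True
    return np.full(3, np.nan), False


def lu_chipman(m: MuellerMatrix) -> DecompositionResult:
    """Polar decomposition M = M_delta * M_R * M_D of a normalized matrix.

    Steps: the diattenuation vector is the first row; M_D is built from it;
    M' = M * M_D^-1 carries the polarizance vector in its first column; the
    depolarizer block is the signed matrix square root of m' m'^T (sign of
    det m'); the retarder block is m_delta^-1 m'.

    A perfect polarizer (D -> 1) makes M_D singular: the retarder is then
    set to the identity, the depolarizer absorbs the remainder via a
    pseudo-inverse, and the result is flagged "degenerate_polarizer".
    A singular depolarizer block leaves the retarder undefined: the
    retarder is reported as identity with NaN total retardance and the flag
    "singular_depolarizer".
    """
    m00 = m.m[0, 0]
    if m00 <= 0:
        raise ValueError(f"cannot decompose: M[1,1] = {m00} <= 0")
    mat = m.m / m00
    flags = []

    d_vec = mat[0, 1:].copy()
    d_mag = float(np.linalg.norm(d_vec))
    p_vec = mat[1:, 0].copy()

    if d_mag >= 1.0 - _POLARIZER_D_TOL:
        flags.append("degenerate_polarizer")
        m_d = diattenuator_from_vector(d_vec / max(d_mag, 1.0))
        m_r = MuellerMatrix(np.eye(4), normalized=True)
        m_delta = MuellerMatrix(mat @ np.linalg.pinv(m_d.m))
        delta = depolarization_power(m_delta)
        r_tot = 0.0
        axis, defined = np.full(3, np.nan), False
        depol_diag = _diag_summary(m_delta.block)
    else:
        m_d = diattenuator_from_vector(d_vec)
        m_prime = mat @ np.linalg.inv(m_d.m)
        p_delta = m_prime[1:, 0]
        mp = m_prime[1:, 1:]
        sym = mp @ mp.T
        w, v = np.linalg.eigh(sym)
        w = np.clip(w, 0.0, None)
        m_delta_block = (v * np.sqrt(w)) @ v.T
        det_mp = np.linalg.det(mp)
        if det_mp < 0:
            m_delta_block = -m_delta_block
        elif det_mp == 0:
            flags.append("singular_block_sign_fallback")
        m_delta_full = np.eye(4)
        m_delta_full[1:, 0] = p_delta
        m_delta_full[1:, 1:] = m_delta_block
        m_delta = MuellerMatrix(m_delta_full, normalized=True)

        if np.sqrt(w).min() < 1e-12:
            flags.append("singular_depolarizer")
            m_r = MuellerMatrix(np.eye(4), normalized=True)
            r_tot = float("nan")
            axis, defined = np.full(3, np.nan), False
        else:
            mr_block = np.linalg.solve(m_delta_block, mp)
            m_r_full = np.eye(4)
            m_r_full[1:, 1:] = mr_block
            m_r = MuellerMatrix(m_r_full, normalized=True)
            r_tot = total_retardance(m_r)
            axis, defined = fast_axis(m_r, r_tot)
        delta = depolarization_power(m_delta)
        depol_diag = _diag_summary(m_delta.block)

    return DecompositionResult(
        m_delta=m_delta,
        m_r=m_r,
        m_d=m_d,
        diattenuation_vector=d_vec,
        polarizance_vector=p_vec,
        depol_diag=depol_diag,
        delta=delta,
        r_total=r_tot,
        p_total=polarizance(MuellerMatrix(mat)),
        fast_axis=axis,
        fast_axis_defined=defined,
        flags=tuple(flags),
    )


def _diag_summary(block: np.ndarray) -> tuple:
    """(a, b, c) when the depolarizer block is diagonal, else its eigenvalues."""
    off = block - np.diag(np.diag(block))
    if np.abs(off).max() <= 1e-8:
        return tuple(np.diag(block))
    return tuple(np.linalg.eigvalsh(block))


def decompose_image(mm: MMImage) -> dict:
    """Per-pixel key-figure maps from a normalized Mueller-matrix image.

    Returns a dict of float maps ``delta``, ``retardance``, ``polarizance``,
    ``diattenuation``, ``azimuth_deg`` plus a boolean ``valid`` map; invalid
    or degenerate pixels carry NaN.
    """
    if not mm.normalized:
        raise ValueError("decompose_image expects a normalized MMImage")
    h, w = mm.shape
    maps = {
        k: np.full((h, w), np.nan)
        for k in ("delta", "retardance", "polarizance", "diattenuation", "azimuth_deg")
    }
    valid = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            if not mm.mask[y, x]:
                continue
            try:
                res = lu_chipman(MuellerMatrix(mm.m[y, x]))
            except (ValueError, np.linalg.LinAlgError):
                continue
            maps["delta"][y, x] = res.delta
            maps["retardance"][y, x] = res.r_total
            maps["polarizance"][y, x] = res.p_total
            maps["diattenuation"][y, x] = res.diattenuation
            maps["azimuth_deg"][y, x] = res.azimuth_deg
            valid[y, x] = True
    maps["valid"] = valid
    return maps
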