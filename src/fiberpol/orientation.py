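"""Fiber orientation and alignment inference from polarimetric results.

The fast-axis azimuth of the retarder factor tracks the fiber direction,
so one Mueller-matrix measurement yields the orientation. When a sample is
rotated, anisotropic matrix entries such as M21 trace a sinusoid with a
180 degree period whose amplitude grows with fiber alignment; three
measurements at distinct angles determine the sinusoid, and a monotone
calibration of amplitude against the collector velocity used during
electrospinning lets the production velocity be read back from a single
amplitude (up to the saturation plateau near 7 m/s).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .core import MuellerMatrix
from .acquisition import MMImage, Roi, roi_average
from .decomposition import lu_chipman, decompose_image


def parse_entry(entry) -> tuple:
    """Matrix entry spec: "M21" (1-based row, column) or an index pair."""
    if isinstance(entry, str):
        match = re.fullmatch(r"M\[?([1-4])[,]?([1-4])\]?", entry)
        if not match:
            raise ValueError(f"cannot parse Mueller entry {entry!r}")
        return int(match.group(1)) - 1, int(match.group(2)) - 1
    i, j = entry
    if not (0 <= i < 4 and 0 <= j < 4):
        raise ValueError(f"entry index {entry} out of range")
    return int(i), int(j)


@dataclass(frozen=True)
class AngularScan:
    """Mueller matrices of one sample measured at a series of rotation angles."""

    angles_deg: np.ndarray
    matrices: tuple
    stds: tuple | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or len(a) < 1:
            raise ValueError("angles must be a 1-D sequence")
        if np.any(np.diff(a) <= 0):
            raise ValueError("scan angles must be strictly increasing")
        if a[-1] - a[0] >= 360.0:
            raise ValueError("scan must stay within one full turn")
        if len(self.matrices) != len(a):
            raise ValueError("one matrix per angle required")
        object.__setattr__(self, "angles_deg", a)

    def entry_trace(self, entry) -> np.ndarray:
        i, j = parse_entry(entry)
        return np.array([m.m[i, j] for m in self.matrices])


@dataclass(frozen=True)
class SinusoidFit:
    """offset + amplitude * cos(2 (theta - phase)) fit of one entry's scan."""

    amplitude: float
    phase_deg: float
    offset: float
    rms_residual: float
    entry: tuple

    def predict(self, angles_deg) -> np.ndarray:
        th = np.deg2rad(np.asarray(angles_deg, dtype=float))
        return self.offset + self.amplitude * np.cos(
            2.0 * (th - np.deg2rad(self.phase_deg))
        )


def fit_angular_scan(scan: AngularScan, entry="M21") -> SinusoidFit:
    """Least-squares fit of a 180-degree-periodic sinusoid to one entry.

    Three measurements at distinct angles (mod 180) suffice to determine
    offset, amplitude, and phase exactly; the phase is the rotation angle
    maximizing the entry, reduced to [0, 180).
    """
    i, j = parse_entry(entry)
    th = np.deg2rad(scan.angles_deg)
    distinct = np.unique(np.round(scan.angles_deg % 180.0, 9))
    if len(distinct) < 3:
        raise ValueError(
            f"need >= 3 distinct angles modulo 180, got {len(distinct)}"
        )
    design = np.column_stack([np.ones_like(th), np.cos(2 * th), np.sin(2 * th)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate angle design: sinusoid parameters not identifiable")
    y = scan.entry_trace((i, j))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    offset, a, b = coef
    amplitude = float(np.hypot(a, b))
    phase = float(np.rad2deg(0.5 * np.arctan2(b, a)) % 180.0)
    resid = y - design @ coef
    return SinusoidFit(
        amplitude=amplitude,
        phase_deg=phase,
        offset=float(offset),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        entry=(i, j),
    )


def azimuth_from_fast_axis(axis, defined: bool = True) -> float:
    """Physical azimuth theta = atan2(a2, a1) / 2 in [0, 180) degrees.

    The circular component a3 is an out-of-plane diagnostic and does not
    enter the azimuth.
    """
    if not defined:
        raise ValueError("fast axis undefined; azimuth not available")
    a = np.asarray(axis, dtype=float)
    if not np.all(np.isfinite(a[:2])) or np.hypot(a[0], a[1]) == 0:
        raise ValueError("fast axis has no equatorial component; azimuth undefined")
    return float(np.rad2deg(0.5 * np.arctan2(a[1], a[0])) % 180.0)


@dataclass(frozen=True)
class OrientationEstimate:
    azimuth_deg: float
    uncertainty_deg: float
    n_pixels: int


def estimate_orientation(mm, roi: Roi | None = None) -> OrientationEstimate:
    """Fiber orientation from a single measurement.

    For a bare MuellerMatrix, the azimuth of its retarder fast axis is
    returned with zero quoted uncertainty. For an MMImage, the central
    estimate comes from the decomposition of the (ROI-)averaged matrix and
    the uncertainty is the axial circular standard deviation of the
    per-pixel azimuths.
    """
    if isinstance(mm, MuellerMatrix):
        res = lu_chipman(mm)
        theta = azimuth_from_fast_axis(res.fast_axis, res.fast_axis_defined)
        return OrientationEstimate(theta, 0.0, 1)
    if roi is None:
        h, w = mm.shape
        roi = Roi(0, 0, w, h)
    mean_m, _ = roi_average(mm, roi)
    res = lu_chipman(mean_m.normalize())
    theta = azimuth_from_fast_axis(res.fast_axis, res.fast_axis_defined)
    sy, sx = roi.slices(mm.shape)
    sub = MMImage(mm.m[sy, sx], mm.mask[sy, sx], normalized=mm.normalized)
    maps = decompose_image(sub)
    az = maps["azimuth_deg"][maps["valid"]]
    az = az[np.isfinite(az)]
    if len(az) == 0:
        raise ValueError("fast axis undefined everywhere in the ROI")
    return OrientationEstimate(theta, axial_dispersion(az), int(len(az)))


def angular_dispersion(values) -> float:
    """Plain sample standard deviation with the n - 1 denominator."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 values, got {v.size}")
    return float(np.std(v, ddof=1))


def axial_dispersion(angles_deg) -> float:
    """Circular standard deviation of axial (180-degree-periodic) angles.

    Angles are doubled, the circular std of the doubled angles is computed,
    and the result is halved — so 179 and 1 degree are 2 degrees apart, not
    178.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 2:
        raise ValueError(f"need at least 2 angles, got {a.size}")
    z = np.exp(1j * np.deg2rad(2.0 * a))
    rbar = np.abs(z.mean())
    rbar = min(rbar, 1.0)
    if rbar == 0:
        return 90.0  # isotropic axial distribution
    circ_std = np.sqrt(-2.0 * np.log(rbar))
    return float(np.rad2deg(circ_std) / 2.0)


@dataclass(frozen=True)
class AlignmentCalibration:
    """Monotone amplitude-versus-velocity calibration with a rising branch.

    ``knot_velocities`` / ``knot_amplitudes`` are the isotonic fit's knots
    on the rising branch (strictly increasing amplitude); above
    ``saturation_amplitude`` the curve is flat at ``saturation_velocity``.
    """

    knot_velocities: np.ndarray
    knot_amplitudes: np.ndarray
    saturation_velocity: float
    saturation_amplitude: float

    @property
    def amplitude_range(self) -> tuple:
        return float(self.knot_amplitudes[0]), float(self.saturation_amplitude)


@dataclass(frozen=True)
class VelocityEstimate:
    velocity: float
    flag: str  # "ok" | "saturated" | "below_range"


def calibrate_alignment(velocities, amplitudes) -> AlignmentCalibration:
    """Isotonic fit of sinusoid amplitude (or polarizance) against velocity.

    The rising branch is the maximal prefix of knots strictly below the
    fitted plateau; interpolation along it is piecewise linear.
    """
    v = np.asarray(velocities, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if v.size < 3:
        raise ValueError(f"need >= 3 calibration pairs, got {v.size}")
    if np.any(a < 0):
        raise ValueError("amplitudes must be nonnegative")
    if np.ptp(a) == 0:
        raise ValueError("all amplitudes equal: no alignment signal to calibrate")
    order = np.argsort(v)
    v, a = v[order], a[order]
    fitted = IsotonicRegression(increasing=True).fit(v, a).predict(v)
    peak = fitted.max()
    eps = 1e-12 * max(np.ptp(fitted), 1.0)
    sat_idx = int(np.argmax(fitted >= peak - eps))  # first knot at the plateau
    rising = slice(0, sat_idx + 1)
    kv, ka = v[rising], fitted[rising]
    # collapse isotonic ties so amplitude knots are strictly increasing
    _, first = np.unique(np.round(ka, 15), return_index=True)
    kv, ka = kv[np.sort(first)], ka[np.sort(first)]
    return AlignmentCalibration(
        knot_velocities=kv,
        knot_amplitudes=ka,
        saturation_velocity=float(v[sat_idx]),
        saturation_amplitude=float(peak),
    )


def infer_velocity(amplitude: float, cal: AlignmentCalibration) -> VelocityEstimate:
    """Invert the calibration: amplitude back to collector velocity.

    Amplitudes at or above the plateau return the saturation velocity with
    the "saturated" flag; amplitudes below the calibrated range are refused
    (NaN velocity, "below_range" flag) rather than extrapolated.
    """
    lo, hi = cal.amplitude_range
    if amplitude >= hi - 1e-12 * max(hi, 1.0):
        flag = "saturated" if amplitude > hi + 1e-12 * max(hi, 1.0) else "ok"
        return VelocityEstimate(cal.saturation_velocity, flag)
    if amplitude < lo:
        return VelocityEstimate(float("nan"), "below_range")
    vel = float(np.interp(amplitude, cal.knot_amplitudes, cal.knot_velocities))
    return VelocityEstimate(vel, "ok")
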