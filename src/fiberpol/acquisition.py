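"""Per-pixel Mueller-matrix reconstruction from polarization image stacks.

Two routes are provided: the direct sum/difference arithmetic over the 36
generator/analyzer intensity images (the classic table of four-term
combinations), and a general least-squares solve against an instrument
model that also handles the minimal 16-image scheme and over-determined
data with calibration errors.

The direct-arithmetic entries carry a constant factor (2 * gain) relative
to the sample matrix; it is harmless because every reconstruction is
normalized by M[1,1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .core import MuellerMatrix, STATE_LABELS, _BASIS

#: Generator states of the minimal (exactly determined) 16-image scheme.
MINIMAL_STATES = ("H", "V", "P", "R")

FULL_PAIRS = tuple(itertools.product(STATE_LABELS, STATE_LABELS))
MINIMAL_PAIRS = tuple(itertools.product(MINIMAL_STATES, MINIMAL_STATES))

# Signed two-state combinations indexed by Stokes component: summing the two
# labels with these signs projects out s0, s1, s2, s3 respectively.
_COMBO = (
    (("H", 1.0), ("V", 1.0)),
    (("H", 1.0), ("V", -1.0)),
    (("P", 1.0), ("M", -1.0)),
    (("R", 1.0), ("L", -1.0)),
)


@dataclass(frozen=True)
class PolarizationImageStack:
    """Raw intensity images keyed by (generator state, analyzer state).

    ``mode`` is "36" for the full six-by-six scheme or "16" for the minimal
    {H, V, P, R} x {H, V, P, R} scheme.
    """

    images: dict
    bit_depth: int | None = None
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        keys = set(self.images)
        if keys == set(FULL_PAIRS):
            mode = "36"
        elif keys == set(MINIMAL_PAIRS):
            mode = "16"
        else:
            missing36 = sorted(set(FULL_PAIRS) - keys)
            raise ValueError(
                "image stack key set is neither the 36-pair nor the 16-pair "
                f"scheme; missing from the 36 scheme: "
                f"{['%s%s' % p for p in missing36]}"
            )
        object.__setattr__(self, "_mode", mode)
        shapes = {np.asarray(v).shape for v in self.images.values()}
        if len(shapes) != 1 or len(next(iter(shapes))) != 2:
            raise ValueError(f"all images must share one 2-D shape, got {shapes}")
        imgs = {k: np.asarray(v, dtype=float) for k, v in self.images.items()}
        for k, v in imgs.items():
            if np.any(v < 0):
                raise ValueError(f"negative pixel values in image {''.join(k)}")
        object.__setattr__(self, "images", imgs)

    @property
    def mode(self) -> str:
        return self._mode

    @property
    def shape(self) -> tuple:
        return next(iter(self.images.values())).shape

    @property
    def pairs(self) -> tuple:
        return FULL_PAIRS if self.mode == "36" else MINIMAL_PAIRS

    def scaled(self, k: float) -> "PolarizationImageStack":
        """Overall detector-gain change; reconstructions are invariant to it."""
        return replace(self, images={p: im * k for p, im in self.images.items()})


@dataclass(frozen=True)
class MMImage:
    """Per-pixel Mueller-matrix field with a validity mask."""

    m: np.ndarray          # (height, width, 4, 4)
    mask: np.ndarray       # (height, width) bool
    normalized: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.ndim != 4 or m.shape[2:] != (4, 4):
            raise ValueError(f"MMImage array must be (H, W, 4, 4), got {m.shape}")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != m.shape[:2]:
            raise ValueError("mask shape must match image shape")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple:
        return self.m.shape[:2]


@dataclass(frozen=True)
class InstrumentModel:
    """Polarization state generator / analyzer model.

    ``generator_states`` maps each label to the Stokes vector the PSG
    prepares; ``analyzer_vectors`` maps each label to the 4-component row
    vector of the PSA projection (an ideal analyzer transmits
    0.5 * (s0 + u . (s1, s2, s3))).
    """

    generator_states: dict
    analyzer_vectors: dict
    gain: float = 1.0

    @classmethod
    def ideal(cls, gain: float = 1.0) -> "InstrumentModel":
        gens = {k: _BASIS[k].copy() for k in STATE_LABELS}
        anas = {k: 0.5 * _BASIS[k] for k in STATE_LABELS}
        return cls(gens, anas, gain)

    def perturbed(self, scale: float, rng: np.random.Generator) -> "InstrumentModel":
        """Additive state-vector error of the given scale on the polarization
        components (models PSG/PSA calibration error)."""
        gens = {}
        anas = {}
        for k in STATE_LABELS:
            dg = np.concatenate([[0.0], rng.normal(0.0, scale, 3)])
            da = np.concatenate([[0.0], rng.normal(0.0, scale, 3)])
            gens[k] = self.generator_states[k] + dg
            anas[k] = self.analyzer_vectors[k] + 0.5 * da
        return InstrumentModel(gens, anas, self.gain)

    def intensity(self, m: np.ndarray, gen: str, ana: str) -> np.ndarray:
        """Detected intensity for matrices ``m`` of shape (..., 4, 4)."""
        a = self.analyzer_vectors[ana]
        s = self.generator_states[gen]
        return self.gain * np.einsum("i,...ij,j->...", a, m, s)

    def design_matrix(self, pairs) -> np.ndarray:
        """Rows of the linear system I = gain * a^T M s, one per state pair;
        the 16 unknowns are M flattened row-major."""
        rows = [
            self.gain
            * np.outer(self.analyzer_vectors[a], self.generator_states[g]).ravel()
            for g, a in pairs
        ]
        return np.array(rows)


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest in pixel coordinates."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI origin must be nonnegative")

    def slices(self, shape: tuple) -> tuple:
        if self.x + self.width > shape[1] or self.y + self.height > shape[0]:
            raise ValueError(f"ROI {self} exceeds image bounds {shape}")
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)


def reconstruct_table3(
    stack: PolarizationImageStack, epsilon: float = 1e-3
) -> MMImage:
    """Direct per-pixel reconstruction from the 36-image scheme.

    Each entry M[i, j] is the signed four-term combination of intensity
    images whose generator labels project input component j and whose
    analyzer labels project output component i. The result is normalized
    by M[1,1].
    """
    if stack.mode != "36":
        missing = sorted(set(FULL_PAIRS) - set(stack.images))
        raise ValueError(
            "direct-arithmetic reconstruction needs the full 36-pair stack; "
            f"missing pairs: {['%s%s' % p for p in missing]}"
        )
    h, w = stack.shape
    m = np.zeros((h, w, 4, 4))
    for i, ana_combo in enumerate(_COMBO):
        for j, gen_combo in enumerate(_COMBO):
            acc = np.zeros((h, w))
            for g, sg in gen_combo:
                for a, sa in ana_combo:
                    acc += sg * sa * stack.images[(g, a)]
            m[:, :, i, j] = acc
    raw = MMImage(m, np.ones((h, w), dtype=bool), normalized=False)
    return normalize_m11(raw, epsilon)


def reconstruct_lsq(
    stack: PolarizationImageStack,
    instrument: InstrumentModel,
    epsilon: float = 1e-3,
) -> MMImage:
    """Least-squares reconstruction against an instrument model.

    Solves I(X, Y) = gain * a(Y)^T M s(X) for the 16 entries per pixel over
    all available state pairs: exactly determined for the 16-image scheme,
    over-determined (error compensating) for the 36-image scheme.
    """
    pairs = stack.pairs
    design = instrument.design_matrix(pairs)
    rank = np.linalg.matrix_rank(design)
    if rank < 16:
        cond = np.linalg.cond(design)
        raise ValueError(
            f"degenerate instrument states: design matrix rank {rank} < 16 "
            f"(condition number {cond:.3g})"
        )
    h, w = stack.shape
    rhs = np.stack([stack.images[p].ravel() for p in pairs])
    coeffs, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    m = coeffs.T.reshape(h, w, 4, 4)
    raw = MMImage(m, np.ones((h, w), dtype=bool), normalized=False)
    return normalize_m11(raw, epsilon)


def normalize_m11(mm: MMImage, epsilon: float = 1e-3) -> MMImage:
    """Divide each pixel's matrix by its M[1,1]; mask low-signal pixels.

    Pixels whose M[1,1] is at or below ``epsilon`` times the image maximum
    are marked invalid instead of producing unbounded entries.
    """
    m00 = mm.m[:, :, 0, 0]
    peak = m00.max(initial=0.0, where=mm.mask) if mm.mask.any() else 0.0
    valid = mm.mask & (m00 > epsilon * peak) & (m00 > 0)
    if not valid.any():
        raise ValueError("no signal: every pixel fell below the M[1,1] threshold")
    denom = np.where(valid, m00, 1.0)
    out = mm.m / denom[:, :, None, None]
    out[~valid] = np.nan
    return MMImage(out, valid, normalized=True)


def roi_average(mm: MMImage, roi: Roi):
    """Entrywise mean and sample standard deviation over the ROI's valid pixels.

    The std uses the n-1 denominator. Returns ``(MuellerMatrix, std)`` where
    ``std`` is a 4x4 array of per-entry standard deviations.
    """
    sy, sx = roi.slices(mm.shape)
    sub = mm.m[sy, sx]
    valid = mm.mask[sy, sx]
    n = int(valid.sum())
    if n < 2:
        raise ValueError(f"ROI contains {n} valid pixel(s); need at least 2")
    vals = sub[valid]  # (n, 4, 4)
    mean = vals.mean(axis=0)
    std = vals.std(axis=0, ddof=1)
    return MuellerMatrix(mean, normalized=bool(mm.normalized and np.isclose(mean[0, 0], 1.0))), std
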