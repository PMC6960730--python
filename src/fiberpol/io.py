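"""Readers and writers: image stacks with manifests, Mueller-matrix
images, result CSVs, and calibration files.

Stack layout on disk: one grayscale TIFF per state pair named
``<GEN><ANA>.tif`` (two-letter notation, first letter = illumination) plus
a ``manifest.yaml`` naming the state pairs, bit depth, wavelength and
dimensions; the manifest is authoritative over globbing.

Mueller-matrix images are stored as a 16-page float64 TIFF (lossless,
row-major entry order M11..M44) with a YAML sidecar header, a mask plane,
and sixteen 8-bit preview images using the affine display mapping
[-1, 1] -> [0, 255].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acquisition import MMImage, PolarizationImageStack
from .orientation import AlignmentCalibration, AngularScan, SinusoidFit
from .core import MuellerMatrix

MANIFEST_NAME = "manifest.yaml"

_ENTRY_NAMES = [f"M{i}{j}" for i in range(1, 5) for j in range(1, 5)]


def write_stack(stack: PolarizationImageStack, directory) -> Path:
    """Write one image per state pair plus the manifest; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stack.bit_depth is None:
        dtype = np.float64
    elif stack.bit_depth <= 8:
        dtype = np.uint8
    else:
        dtype = np.uint16
    for (g, a), img in stack.images.items():
        tifffile.imwrite(directory / f"{g}{a}.tif", img.astype(dtype))
    h, w = stack.shape
    manifest = {
        "state_pairs": [f"{g}{a}" for g, a in stack.pairs],
        "file_pattern": "{pair}.tif",
        "bit_depth": stack.bit_depth,
        "wavelength_nm": stack.wavelength_nm,
        "width": int(w),
        "height": int(h),
        "mode": stack.mode,
    }
    (directory / MANIFEST_NAME).write_text(yaml.safe_dump(manifest))
    return directory


def read_stack(directory) -> PolarizationImageStack:
    """Load a stack from a manifest directory, validating completeness."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    manifest = yaml.safe_load(manifest_path.read_text())
    pattern = manifest.get("file_pattern", "{pair}.tif")
    images = {}
    problems = []
    for pair in manifest["state_pairs"]:
        if len(pair) != 2 or any(c not in "HVPMRL" for c in pair):
            problems.append(f"unknown state-pair label {pair!r}")
            continue
        path = directory / pattern.format(pair=pair)
        if not path.exists():
            problems.append(f"missing image file for pair {pair}: {path.name}")
            continue
        images[(pair[0], pair[1])] = tifffile.imread(path)
    if problems:
        raise ValueError("inconsistent stack: " + "; ".join(problems))
    shapes = {v.shape for v in images.values()}
    if len(shapes) > 1:
        raise ValueError(f"image dimension mismatch across files: {shapes}")
    return PolarizationImageStack(
        images,
        bit_depth=manifest.get("bit_depth"),
        wavelength_nm=manifest.get("wavelength_nm"),
    )


def preview_u8(values: np.ndarray) -> np.ndarray:
    """Display mapping [-1, 1] -> [0, 255]: v -> round(255 (v + 1) / 2)."""
    v = np.clip(np.nan_to_num(values, nan=-1.0), -1.0, 1.0)
    return np.round((v + 1.0) / 2.0 * 255.0).astype(np.uint8)


def write_mm_image(mm: MMImage, directory) -> Path:
    """Write float planes, mask, previews and the sidecar header."""
    if not mm.normalized:
        raise ValueError("write_mm_image expects a normalized MMImage")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    h, w = mm.shape
    planes = mm.m.reshape(h, w, 16).transpose(2, 0, 1)
    tifffile.imwrite(
        directory / "planes.tif", planes.astype(np.float64),
        photometric="minisblack",
    )
    tifffile.imwrite(directory / "mask.tif", mm.mask.astype(np.uint8))
    for k, name in enumerate(_ENTRY_NAMES):
        tifffile.imwrite(directory / f"preview_{name}.tif", preview_u8(planes[k]))
    header = {
        "entry_order": _ENTRY_NAMES,
        "layout": "row-major, row = output Stokes component",
        "normalized": True,
        "width": int(w),
        "height": int(h),
        "preview_mapping": "value v in [-1,1] -> round(255*(v+1)/2)",
    }
    (directory / "header.yaml").write_text(yaml.safe_dump(header))
    return directory


def read_mm_image(directory) -> MMImage:
    directory = Path(directory)
    planes = tifffile.imread(directory / "planes.tif")
    mask = tifffile.imread(directory / "mask.tif").astype(bool)
    h, w = mask.shape
    m = planes.transpose(1, 2, 0).reshape(h, w, 4, 4)
    return MMImage(m, mask, normalized=True)


def write_scan_csv(scan: AngularScan, path, entry="M21") -> Path:
    from .orientation import parse_entry

    i, j = parse_entry(entry)
    rows = {"angle_deg": scan.angles_deg, "value": scan.entry_trace((i, j))}
    if scan.stds is not None:
        rows["std"] = [s[i, j] for s in scan.stds]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_scan_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "angle_deg" not in df or "value" not in df:
        raise ValueError("scan table needs 'angle_deg' and 'value' columns")
    return df


def write_decomposition_csv(rows, path) -> Path:
    """Per-ROI decomposition results, one row per ROI.

    Each row is (roi_id, DecompositionResult); columns follow the key
    figures plus the fast-axis vector and azimuth.
    """
    records = []
    for roi_id, res in rows:
        records.append(
            {
                "roi_id": roi_id,
                "delta": res.delta,
                "retardance_rad": res.r_total,
                "polarizance": res.p_total,
                "diattenuation": res.diattenuation,
                "a1": res.fast_axis[0],
                "a2": res.fast_axis[1],
                "a3": res.fast_axis[2],
                "azimuth_deg": res.azimuth_deg,
                "flags": ";".join(res.flags),
            }
        )
    path = Path(path)
    pd.DataFrame(records).to_csv(path, index=False)
    return path


def write_fit_csv(fit: SinusoidFit, path) -> Path:
    pd.DataFrame(
        [
            {
                "entry": f"M{fit.entry[0] + 1}{fit.entry[1] + 1}",
                "amplitude": fit.amplitude,
                "phase_deg": fit.phase_deg,
                "offset": fit.offset,
                "rms_residual": fit.rms_residual,
            }
        ]
    ).to_csv(path, index=False)
    return Path(path)


def write_calibration(cal: AlignmentCalibration, path) -> Path:
    payload = {
        "knot_velocities": [float(v) for v in cal.knot_velocities],
        "knot_amplitudes": [float(a) for a in cal.knot_amplitudes],
        "saturation_velocity": cal.saturation_velocity,
        "saturation_amplitude": cal.saturation_amplitude,
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload))
    return path


def read_calibration(path) -> AlignmentCalibration:
    payload = yaml.safe_load(Path(path).read_text())
    return AlignmentCalibration(
        knot_velocities=np.asarray(payload["knot_velocities"], dtype=float),
        knot_amplitudes=np.asarray(payload["knot_amplitudes"], dtype=float),
        saturation_velocity=float(payload["saturation_velocity"]),
        saturation_amplitude=float(payload["saturation_amplitude"]),
    )


def roi_matrix_to_csv(m: MuellerMatrix, std: np.ndarray, path) -> Path:
    rows = []
    for i in range(4):
        for j in range(4):
            rows.append(
                {"entry": f"M{i + 1}{j + 1}", "mean": m.m[i, j], "std": std[i, j]}
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
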