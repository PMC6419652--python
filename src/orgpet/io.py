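"""Readers/writers for the package's on-disk formats.

Images travel as NIfTI-1 with millimeter spacing in the header (RAS
orientation, axis 2 cranio-caudal); respiratory traces and tables as CSV.
Floats in tables are serialized at 9 significant digits for stable diffs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomImage, RespiratoryTrace

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_trace",
    "write_trace",
    "read_table",
    "write_table",
]

PathLike = Union[str, Path]

TRACE_COLUMNS = ("time_s", "amplitude_mm")
FLOAT_FORMAT = "%.9g"


def write_image(image: PhantomImage, path: PathLike) -> None:
    affine = np.diag(list(image.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.values.astype(np.float64), affine), str(path))


def read_image(path: PathLike) -> PhantomImage:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhantomImage(np.asarray(img.dataobj, dtype=np.float64), spacing)


def write_mask(mask: np.ndarray, spacing_mm, path: PathLike) -> None:
    affine = np.diag([float(s) for s in spacing_mm] + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def read_mask(path: PathLike, match_image: PhantomImage | None = None) -> np.ndarray:
    img = nib.load(str(path))
    if match_image is not None:
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if any(
            abs(a - b) > 1e-6 for a, b in zip(spacing, match_image.spacing_mm)
        ):
            raise ValueError(
                f"mask spacing {spacing} does not match image spacing "
                f"{match_image.spacing_mm}"
            )
        if img.shape[:3] != match_image.shape:
            raise ValueError("mask shape does not match image")
    return np.asarray(img.dataobj) > 0


def write_trace(trace: RespiratoryTrace, path: PathLike) -> None:
    df = pd.DataFrame({"time_s": trace.times_s, "amplitude_mm": trace.amplitudes_mm})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trace(path: PathLike) -> RespiratoryTrace:
    df = pd.read_csv(path)
    if tuple(df.columns) != TRACE_COLUMNS:
        raise ValueError(
            f"trace CSV must have header {','.join(TRACE_COLUMNS)}, got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        # +1 for the offending data row, +1 header line, +1 one-based
        raise ValueError(f"non-monotone time at CSV row {int(bad[0]) + 3}")
    return RespiratoryTrace(t, df["amplitude_mm"].to_numpy(dtype=float))


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
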