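"""Shared I/O: multi-page TIFF stacks/videos, CSV tables, result rows."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import IOFormatError, SchemaError
from .nuclei import ImageStack3D
from .stats import COHORT_COLUMNS, validate_cohort
from .tracking import FrameSequence

RESULT_COLUMNS = ["id", "n_repetitions", "velocity_m_s", "velocity_se",
                  "diameter_um", "density_g_cm3", "mass_ug",
                  "buoyant_weight_nN", "reynolds", "qc_flags"]

NUCLEI_COLUMNS = ["id", "count", "volume_um3", "density_per_um3",
                  "optical_density_per_um2"]


def _read_pages(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"{path}: file not found")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # truncated / non-TIFF
        raise IOFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise IOFormatError(f"{path}: expected a stack of 2D pages")
    return data.astype(float)


def read_stack(path, voxel_size, channel: str = "nuclear") -> ImageStack3D:
    """Read a multi-page TIFF as a (z, y, x) stack; voxel size from config."""
    return ImageStack3D(_read_pages(path), tuple(voxel_size), channel)


def write_stack(path, stack: ImageStack3D) -> None:
    tifffile.imwrite(path, stack.voxels.astype(np.float32))


def read_video(path, pixel_size: float, fps: float | None = None,
               timestamps=None, polarity: str = "dark") -> FrameSequence:
    """Read a multi-page TIFF as a time sequence (pages = frames).

    Timestamps are authoritative when supplied; otherwise derived from fps.
    """
    frames = _read_pages(path)
    if timestamps is None:
        if fps is None:
            raise SchemaError("either fps or timestamps is required")
        timestamps = np.arange(len(frames)) / fps
    return FrameSequence(frames=frames, timestamps=np.asarray(timestamps, float),
                         pixel_size=pixel_size, polarity=polarity)


def write_video(path, seq: FrameSequence) -> None:
    tifffile.imwrite(path, seq.frames.astype(np.float32))


def write_results(rows: list[dict], path, columns=None) -> None:
    """Write result rows as CSV with a fixed header order ('.' decimals, UTF-8)."""
    columns = columns or RESULT_COLUMNS
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)


def measurement_row(measurement, spheroid_id: str) -> dict:
    """Flatten a BiophysicalMeasurement into a result CSV row."""
    return {
        "id": spheroid_id,
        "n_repetitions": measurement.n_repetitions,
        "velocity_m_s": measurement.terminal_velocity,
        "velocity_se": measurement.velocity_se,
        "diameter_um": measurement.diameter,
        "density_g_cm3": measurement.mass_density,
        "mass_ug": measurement.mass,
        "buoyant_weight_nN": measurement.buoyant_weight,
        "reynolds": measurement.reynolds,
        "qc_flags": ";".join(measurement.qc_flags),
    }


def read_cohort(path) -> pd.DataFrame:
    """Read and schema-validate a long-format cohort CSV."""
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"{path}: file not found")
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return validate_cohort(table)


def write_cohort(table: pd.DataFrame, path) -> None:
    validate_cohort(table)
    table.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_standards(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("concentration", "fluorescence"):
        if col not in table.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return table
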