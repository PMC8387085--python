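"""Micrograph input/output and spatial calibration.

A *field* is one high-power brightfield photomicrograph of an
immunostained liver section, together with the pixel-to-µm calibration
factor of the optical train that produced it.  Calibration is supplied
explicitly (per manifest row or function argument); it is never guessed
from image content.

Coordinate convention: row-major arrays, origin at the top-left pixel,
0-based indices.  All physical quantities (µm, µm²) are produced at
measurement time from pixel counts and the scale factor; nothing
physical is stored per pixel.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Column layout of a batch manifest CSV.
MANIFEST_COLUMNS = [
    "path",
    "sample_id",
    "field_index",
    "group_label",
    "subgroup",
    "scale_um_per_px",
]


@dataclass(frozen=True)
class CalibratedField:
    """One RGB micrograph with physical calibration and batch identity.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` array of 8-bit intensities in ``[0, 255]``.
    scale:
        Side length of one pixel in µm (µm per pixel), strictly positive.
    sample_id:
        Opaque label of the biopsy/slide the field was captured from.
    field_index:
        1-based index of the field within its sample; unique per sample.
    group_label:
        Study arm, canonically ``"disease"`` or ``"control"``.
    subgroup:
        Optional clinical tag, canonically ``"clinical_liver_disease"``
        or ``"none"``.
    """

    pixels: np.ndarray
    scale: float
    sample_id: str
    field_index: int
    group_label: str
    subgroup: str = "none"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"field pixels must be (H, W, 3); got shape {px.shape}"
            )
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixels must be integer-typed, got {px.dtype}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be a positive µm/px factor, got {self.scale}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def load_field(
    path: str | os.PathLike,
    scale: float,
    sample_id: str,
    field_index: int,
    group_label: str,
    subgroup: str = "none",
) -> CalibratedField:
    """Read a TIFF/PNG raster and attach calibration and identity.

    Grayscale (single-channel) images are rejected; an alpha channel is
    dropped with a logged warning.
    """
    if not (np.isfinite(scale) and scale > 0):
        raise ValueError(f"scale must be a positive µm/px factor, got {scale}")
    raw = np.asarray(iio.imread(os.fspath(path)))
    if raw.ndim == 2 or (raw.ndim == 3 and raw.shape[2] == 1):
        n = 1
        raise ValueError(
            f"{path}: expected an RGB image, got {n} channel(s); "
            "stain separation needs color input"
        )
    if raw.ndim != 3 or raw.shape[2] not in (3, 4):
        raise ValueError(f"{path}: unsupported raster shape {raw.shape}")
    if raw.shape[2] == 4:
        logger.warning("%s: dropping alpha channel", path)
        raw = raw[:, :, :3]
    if raw.dtype != np.uint8:
        # 16-bit scanners: rescale to the 8-bit range the method is defined on
        raw = np.clip(np.rint(raw.astype(np.float64) / raw.max() * 255), 0, 255)
    return CalibratedField(
        pixels=raw.astype(np.uint8),
        scale=float(scale),
        sample_id=str(sample_id),
        field_index=int(field_index),
        group_label=str(group_label),
        subgroup=str(subgroup),
    )


def save_field(fld: CalibratedField, path: str | os.PathLike) -> None:
    """Write the raster of a field to TIFF (or PNG by extension)."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, fld.pixels.astype(np.uint8))
    else:
        iio.imwrite(path, fld.pixels.astype(np.uint8))


def load_batch(manifest_path: str | os.PathLike) -> list[CalibratedField]:
    """Load every field listed in a manifest CSV, in row order.

    The manifest has columns ``path,sample_id,field_index,group_label,
    subgroup,scale_um_per_px`` (``subgroup`` may be omitted).  Paths are
    resolved relative to the manifest's directory.  Duplicate
    ``(sample_id, field_index)`` pairs and inconsistent per-sample scales
    are validation errors.
    """
    manifest_path = os.fspath(manifest_path)
    df = pd.read_csv(manifest_path, comment="#")
    if df.empty:
        logger.warning("%s: empty manifest, no fields to load", manifest_path)
        return []
    missing = {"path", "sample_id", "field_index", "group_label", "scale_um_per_px"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "subgroup" not in df.columns:
        df["subgroup"] = "none"
    df["subgroup"] = df["subgroup"].fillna("none")

    dup = df.duplicated(subset=["sample_id", "field_index"])
    if dup.any():
        rows = df.loc[dup, ["sample_id", "field_index"]].to_records(index=False)
        raise ValueError(f"duplicate (sample_id, field_index) in manifest: {list(rows)}")
    scales = df.groupby("sample_id")["scale_um_per_px"].nunique()
    bad = scales[scales > 1]
    if not bad.empty:
        raise ValueError(
            f"inconsistent scale within sample(s): {list(bad.index)}"
        )

    base = os.path.dirname(manifest_path)
    fields = []
    for row in df.itertuples(index=False):
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        fields.append(
            load_field(
                p,
                scale=float(row.scale_um_per_px),
                sample_id=row.sample_id,
                field_index=int(row.field_index),
                group_label=row.group_label,
                subgroup=row.subgroup,
            )
        )
    return fields


def write_manifest(rows: list[dict], path: str | os.PathLike) -> None:
    """Write a manifest CSV with the canonical column order."""
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(os.fspath(path), index=False)


def with_pixels(fld: CalibratedField, pixels: np.ndarray) -> CalibratedField:
    """Copy of a field with a replaced raster (same calibration/identity)."""
    return replace(fld, pixels=pixels)
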