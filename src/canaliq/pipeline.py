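"""End-to-end measurement chain: field → stain mask → ROI table → thickness.

This is the library core behind the ``measure`` CLI command; each step
delegates to the dedicated module (stain separation, morphometry,
thickness).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import morphometry, stain, thickness
from .io import CalibratedField

logger = logging.getLogger(__name__)

FIELD_COLUMNS = [
    "sample_id", "field_index", "group_label", "subgroup", "scale_um_per_px",
    "threshold_used", "n_rois", "area", "perimeter", "feret", "pf_ratio",
    "solidity", "mgv", "cmgv", "thickness",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated knobs of one measurement/comparison run.

    ``threshold``: manual 8-bit cut (default 200, a generous cut that
    keeps every reconstructed-DAB pixel — extraction has already forced
    the background to 255) or ``"auto"`` (Otsu on sub-255 pixels, which
    splits strong staining from a weak halo population when one is
    present).  ``min_pixels``: artefact floor, components below it are
    discarded.  ``feret_mode``: ``"projection"`` (axis-projection mean,
    the method's definition) or ``"caliper"``.  ``thickness_filtered``:
    compute thickness on the artefact-filtered mask instead of the raw
    mask.  ``exclude_border``: drop ROIs touching the field border
    (kept by default).
    """

    threshold: int | str = 200
    min_pixels: int = 10
    feret_mode: str = "projection"
    aggregation_level: str = "patient"
    test: str = "student"
    seed: int = 0
    exclude_border: bool = False
    thickness_filtered: bool = False

    def __post_init__(self) -> None:
        if self.threshold != "auto":
            t = int(self.threshold)
            if not 0 <= t <= 255:
                raise ValueError(f"threshold must be in [0, 255] or 'auto', got {t}")
            object.__setattr__(self, "threshold", t)
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.feret_mode not in ("projection", "caliper"):
            raise ValueError(f"unknown feret_mode {self.feret_mode!r}")
        if self.aggregation_level not in ("patient", "field", "roi"):
            raise ValueError(f"unknown aggregation_level {self.aggregation_level!r}")
        if self.test not in ("student", "welch"):
            raise ValueError(f"unknown test {self.test!r}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def process_field(field: CalibratedField, config: RunConfig | None = None):
    """Run extract → 8-bit → threshold → label → filter → measure →
    thickness on one field.

    Returns ``(roi_records, field_row, stain_mask, thickness_map)``
    where ``field_row`` is a dict matching :data:`FIELD_COLUMNS`.
    """
    config = config or RunConfig()
    extracted = stain.extract_dab(field)
    gray = stain.to_8bit(extracted)
    try:
        sm = stain.threshold_mask(gray, config.threshold)
    except ValueError:
        logger.warning(
            "%s field %d: no IHC-positive signal; empty mask recorded",
            field.sample_id, field.field_index,
        )
        sm = stain.StainMask(
            dab_8bit=gray,
            mask=np.zeros(gray.shape, dtype=bool),
            threshold_used=0,
            method_tag="no-signal",
        )

    comps = morphometry.label_rois(sm)
    if config.exclude_border:
        h, w = gray.shape
        comps = [
            c for c in comps
            if c[:, 0].min() > 0 and c[:, 1].min() > 0
            and c[:, 0].max() < h - 1 and c[:, 1].max() < w - 1
        ]
    kept, _ = morphometry.filter_artefacts(comps, config.min_pixels)
    records = [
        morphometry.measure_roi(c, gray, field.scale, roi_id=i + 1,
                                feret_mode=config.feret_mode)
        for i, c in enumerate(kept)
    ]
    summary = morphometry.summarize_field(records)

    if config.thickness_filtered:
        tmask = np.zeros(gray.shape, dtype=bool)
        for c in kept:
            tmask[c[:, 0], c[:, 1]] = True
    else:
        tmask = sm.mask
    tmap = thickness.local_thickness(tmask, field.scale)

    field_row = {
        "sample_id": field.sample_id,
        "field_index": field.field_index,
        "group_label": field.group_label,
        "subgroup": field.subgroup,
        "scale_um_per_px": field.scale,
        "threshold_used": sm.threshold_used,
        "n_rois": summary.n_rois,
        "area": summary.area,
        "perimeter": summary.perimeter,
        "feret": summary.feret,
        "pf_ratio": summary.pf_ratio,
        "solidity": summary.solidity,
        "mgv": summary.mgv,
        "cmgv": summary.cmgv,
        "thickness": np.nan if tmap.mean_thickness is None else tmap.mean_thickness,
    }
    return records, field_row, sm, tmap


def measure_batch(fields: list[CalibratedField], config: RunConfig | None = None):
    """Measure every field; failures are logged and skipped.

    Returns ``(roi_table, field_table, n_failed)`` as DataFrames with
    the canonical column layouts.
    """
    config = config or RunConfig()
    roi_frames = []
    field_rows = []
    n_failed = 0
    for fld in fields:
        try:
            records, row, sm, _ = process_field(fld, config)
        except Exception:
            logger.exception(
                "field %s/%d failed; continuing", fld.sample_id, fld.field_index
            )
            n_failed += 1
            continue
        field_rows.append(row)
        roi_frames.append(
            morphometry.records_to_frame(
                records, fld.sample_id, fld.field_index, sm.threshold_used
            )
        )
    roi_table = (
        pd.concat(roi_frames, ignore_index=True)
        if roi_frames
        else morphometry.records_to_frame([])
    )
    field_table = pd.DataFrame(field_rows, columns=FIELD_COLUMNS)
    return roi_table, field_table, n_failed


def write_csv(df: pd.DataFrame, path, config: RunConfig, extra: dict | None = None) -> None:
    """Write a CSV with the provenance header block (deterministic)."""
    from . import __version__

    lines = [f"# canaliq {__version__}", f"# config_hash={config.config_hash()}"]
    cfg = asdict(config)
    lines.append("# " + " ".join(f"{k}={cfg[k]}" for k in sorted(cfg)))
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
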