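"""IHC-positive (DAB) signal isolation from RGB brightfield micrographs.

The pipeline mirrors the classical ImageJ workflow for DAB
quantification: (A) original RGB → (B) DAB-only RGB with everything else
forced to white → (C) 8-bit grayscale → (D) binary mask of IHC-positive
pixels.

Stain separation uses Beer–Lambert color deconvolution with the
Ruifrok–Johnston hematoxylin/DAB basis by default.  A pixel is
classified DAB-positive when the DAB fraction of its total optical
density exceeds a cutoff and the total optical density is above a
background floor; everything else is background and is rendered pure
white.

Sign convention (important for cMGV downstream): *stained pixels are
dark*.  The 8-bit channel has background at 255 and DAB at low values,
so the mask rule is ``gray <= threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb_from_hdx
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: Default stain basis: rows are unit optical-density vectors in RGB for
#: hematoxylin, DAB, and the orthogonal residual (Ruifrok & Johnston).
HDX_BASIS: np.ndarray = np.asarray(rgb_from_hdx, dtype=np.float64)

_OD_EPS = 1e-6  # floor on transmitted intensity before the log


@dataclass(frozen=True)
class StainMask:
    """Binary IHC-positive mask plus the 8-bit channel it came from.

    ``dab_8bit`` has background forced to white (255); ``mask`` is true
    where the pixel is IHC-positive, i.e. ``dab_8bit <= threshold_used``.
    """

    dab_8bit: np.ndarray
    mask: np.ndarray
    threshold_used: int
    method_tag: str = "hdx-deconvolution"

    def __post_init__(self) -> None:
        if self.dab_8bit.shape != self.mask.shape:
            raise ValueError("dab_8bit and mask must have identical shape")
        if not 0 <= self.threshold_used <= 255:
            raise ValueError("threshold_used must lie in [0, 255]")


def _check_basis(basis: np.ndarray) -> np.ndarray:
    basis = np.asarray(basis, dtype=np.float64)
    if basis.shape != (3, 3):
        raise ValueError(f"stain basis must be 3x3, got {basis.shape}")
    if np.linalg.cond(basis) > 1e8:
        raise ValueError("stain basis is singular or near-singular")
    return basis


def optical_density(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density, ``-log10(I/255)``, white = 0."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return -np.log10(np.maximum(rgb, _OD_EPS) / 255.0)


def stain_concentrations(rgb: np.ndarray, stain_vectors: np.ndarray | None = None) -> np.ndarray:
    """Unmix RGB into per-stain optical densities.

    Returns an ``(..., 3)`` array of concentrations in the order of the
    basis rows (hematoxylin, DAB, residual for the default basis).
    """
    basis = _check_basis(HDX_BASIS if stain_vectors is None else stain_vectors)
    od = optical_density(rgb)
    return od @ np.linalg.inv(basis)


def dab_od(rgb: np.ndarray, stain_vectors: np.ndarray | None = None) -> np.ndarray:
    """DAB optical density per pixel (row 1 of the stain basis)."""
    return stain_concentrations(rgb, stain_vectors)[..., 1]


def render_stains(
    concentrations: np.ndarray, stain_vectors: np.ndarray | None = None
) -> np.ndarray:
    """Forward Beer–Lambert render: concentrations → float RGB in [0, 255].

    Inverse of :func:`stain_concentrations` (up to the intensity floor).
    Used both to reconstruct the DAB-only image and by the synthetic
    generator, so extraction is testable to numerical precision.
    """
    basis = _check_basis(HDX_BASIS if stain_vectors is None else stain_vectors)
    od = np.asarray(concentrations, dtype=np.float64) @ basis
    return 255.0 * 10.0 ** (-od)


def extract_dab(
    rgb_or_field,
    stain_vectors: np.ndarray | None = None,
    od_fraction_cutoff: float = 0.5,
    od_floor: float = 0.05,
) -> np.ndarray:
    """Suppress everything but DAB to white; keep DAB as its pure color.

    Accepts a :class:`~canaliq.io.CalibratedField` or a raw ``(H, W, 3)``
    array in ``[0, 255]``.  A pixel counts as DAB when

    * total optical density (sum of positive stain concentrations) is
      above ``od_floor`` (it is not blank background), and
    * the DAB share of that total is at least ``od_fraction_cutoff``.

    DAB pixels are re-rendered from their DAB concentration alone, so
    the output contains exactly two populations: pure white and pure
    DAB color.  Consequently the operation is idempotent.  Integer input
    yields ``uint8`` output; float input stays float (full precision).
    """
    rgb = getattr(rgb_or_field, "pixels", rgb_or_field)
    rgb = np.asarray(rgb)
    was_int = np.issubdtype(rgb.dtype, np.integer)
    conc = stain_concentrations(rgb, stain_vectors)
    pos = np.clip(conc, 0.0, None)
    total = pos.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, pos[..., 1] / np.where(total > 0, total, 1.0), 0.0)
    is_dab = (total >= od_floor) & (frac >= od_fraction_cutoff)

    out = np.full(rgb.shape, 255.0)
    if is_dab.any():
        dab_only = np.zeros(conc.shape)
        dab_only[..., 1] = np.where(is_dab, conc[..., 1], 0.0)
        rendered = render_stains(dab_only, stain_vectors)
        out[is_dab] = rendered[is_dab]
    if was_int:
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def to_8bit(rgb: np.ndarray, weights: tuple[float, float, float] | None = None) -> np.ndarray:
    """RGB → 8-bit grayscale by the unweighted channel mean.

    This matches the default RGB→8-bit conversion of the reference
    ImageJ workflow: ``round((R + G + B) / 3)``.  Pass ITU-R BT.601 luma
    ``weights`` for the perceptual alternative.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB, got {rgb.shape}")
    if weights is None:
        gray = rgb.mean(axis=-1)
    else:
        w = np.asarray(weights, dtype=np.float64)
        gray = rgb @ (w / w.sum())
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def threshold_mask(
    gray_8bit: np.ndarray,
    threshold: int | str = "auto",
    method_tag: str = "hdx-deconvolution",
) -> StainMask:
    """Threshold the extracted 8-bit channel into an IHC-positive mask.

    ``mask = gray <= threshold`` (positive = dark).  With
    ``threshold="auto"``, Otsu's criterion is evaluated on the sub-255
    pixels only — the forced-white background would otherwise dominate
    the histogram — and the chosen value is logged.  The threshold
    actually applied is always recorded in the returned
    :class:`StainMask` for provenance.
    """
    gray = np.asarray(gray_8bit)
    if gray.ndim != 2:
        raise ValueError(f"expected 2-D 8-bit image, got shape {gray.shape}")
    if threshold == "auto":
        fg = gray[gray < 255]
        if fg.size == 0:
            raise ValueError("no foreground signal: image is entirely white")
        if fg.min() == fg.max():
            thr = int(fg.min())
            logger.warning("auto threshold: single-valued foreground, using %d", thr)
        else:
            thr = int(threshold_otsu(fg, nbins=256))
        logger.info("auto (Otsu, sub-255) threshold = %d", thr)
    else:
        thr = int(threshold)
        if not 0 <= thr <= 255:
            raise ValueError(f"threshold must lie in [0, 255], got {thr}")
    return StainMask(
        dab_8bit=gray, mask=gray <= thr, threshold_used=thr, method_tag=method_tag
    )
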