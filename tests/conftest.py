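"""Shared fixtures and independent oracle implementations.

The oracle functions here are deliberately naive (brute-force
enumeration, textbook formulas) and share no code with the package
internals they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest


def disk_mask(radius: int, pad: int = 2) -> np.ndarray:
    """Digitized disk: pixels whose centre lies within ``radius``."""
    n = radius + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return xx * xx + yy * yy <= radius * radius


def random_blob_mask(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """Random smooth blob mask (thresholded filtered noise)."""
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.standard_normal(shape), sigma=rng.uniform(2, 6))
    mask = field > np.quantile(field, rng.uniform(0.55, 0.85))
    return mask


# ---------------------------------------------------------------- oracles

def otsu_bruteforce(values: np.ndarray) -> int:
    """Otsu's threshold by exhaustive search over all 256 cut points.

    Maximizes between-class variance of the split ``v <= t`` / ``v > t``.
    Returns the best integer cut point.
    """
    values = np.asarray(values).ravel()
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = 1.0 - w0
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def local_thickness_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Largest-inscribed-disk thickness by exhaustive pairwise search.

    Candidate radius at centre c is the distance to the nearest
    background pixel centre (image border counts as background),
    computed directly from pairwise distances — independent of any
    distance-transform code.  A pixel's thickness is ``2r - 1`` for the
    largest candidate disk covering it.  All arithmetic on integer
    squared distances.
    """
    mask = np.asarray(mask, bool)
    padded = np.pad(mask, 1)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    if fg.size == 0:
        return np.zeros(mask.shape)
    # r²(c) = min over background centres of |c - b|²
    d2_bg = ((fg[:, None, :] - bg[None, :, :]) ** 2).sum(-1)
    r2 = d2_bg.min(axis=1)
    # thickness(p) = max over c of r²(c) where |p - c|² <= r²(c)
    d2_fg = ((fg[:, None, :] - fg[None, :, :]) ** 2).sum(-1)
    covered = d2_fg <= r2[None, :]
    best = np.where(covered, r2[None, :], 0).max(axis=1)
    out = np.zeros(padded.shape)
    out[tuple(fg.T)] = 2.0 * np.sqrt(best) - 1.0
    return out[1:-1, 1:-1]


def pooled_t_oracle(a, b) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t-test (two-sided)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return float(t), float(p)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210306)
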