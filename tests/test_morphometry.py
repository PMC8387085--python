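"""ROI labeling, artefact filtering, and shape parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canaliq.morphometry import (
    filter_artefacts,
    label_rois,
    measure_roi,
    records_to_frame,
    summarize_field,
)
from conftest import disk_mask


def _measure_mask(mask, scale=1.0, gray_value=55, **kw):
    px = np.column_stack(np.nonzero(mask))
    gray = np.full(mask.shape, gray_value, dtype=np.uint8)
    return measure_roi(px, gray, scale, **kw)


class TestLabelRois:
    def test_diagonal_pixels_are_one_component(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert len(label_rois(m)) == 1

    def test_separated_blobs_are_two_components(self):
        m = np.zeros((6, 6), bool)
        m[0:2, 0:2] = True
        m[4:6, 4:6] = True
        assert len(label_rois(m)) == 2

    def test_empty_mask(self):
        assert label_rois(np.zeros((5, 5), bool)) == []

    def test_deterministic_topleft_rowmajor_order(self):
        m = np.zeros((8, 8), bool)
        m[5:7, 0:2] = True   # lower-left blob
        m[0:2, 5:7] = True   # upper-right blob: first in row-major order
        comps = label_rois(m)
        firsts = [tuple(c[np.lexsort((c[:, 1], c[:, 0]))][0]) for c in comps]
        assert firsts == [(0, 5), (5, 0)]


class TestFilterArtefacts:
    def test_nine_pixel_component_removed_ten_kept(self):
        """The artefact rule is exclusive: <10 px removed, ==10 kept."""
        comps = [np.argwhere(np.ones((3, 3), bool)),        # 9 px
                 np.argwhere(np.ones((2, 5), bool))]        # 10 px
        kept, n_removed = filter_artefacts(comps)
        assert n_removed == 1
        assert len(kept) == 1 and len(kept[0]) == 10

    def test_empty_input(self):
        assert filter_artefacts([]) == ([], 0)

    def test_min_pixels_validated(self):
        with pytest.raises(ValueError):
            filter_artefacts([], min_pixels=0)


class TestMeasureRoi:
    def test_filled_square_analytic(self):
        r = _measure_mask(np.ones((5, 5), bool), gray_value=55)
        assert r.area == 25.0
        assert r.feret_x == 5.0 and r.feret_y == 5.0 and r.feret == 5.0
        assert r.solidity == 1.0
        assert r.mgv == 55.0 and r.cmgv == 200.0
        assert abs(r.pf_ratio - 4.0) / 4.0 < 0.05

    def test_horizontal_bar_projections(self):
        m = np.zeros((3, 22), bool)
        m[1, 1:21] = True
        r = _measure_mask(m)
        assert r.feret_x == 20.0 and r.feret_y == 1.0 and r.feret == 10.5
        assert r.pf_ratio == pytest.approx(r.perimeter / 10.5)

    def test_digitized_disk_pf_near_pi(self):
        """P/F ≈ π for a disk is the perimeter calibration anchor."""
        r = _measure_mask(disk_mask(40))
        assert abs(r.pf_ratio - np.pi) / np.pi < 0.05

    def test_comb_branches_raise_pf_over_bounding_rectangle(self):
        """Side branches lengthen the outline much faster than the
        projections: a comb scores higher than its filled bounding box."""
        comb = np.zeros((12, 21), bool)
        comb[9:12, :] = True                   # spine
        for c0 in (0, 9, 18):                  # three teeth
            comb[0:9, c0:c0 + 3] = True
        rect = np.ones((12, 21), bool)
        r_comb, r_rect = _measure_mask(comb), _measure_mask(rect)
        assert r_comb.feret == r_rect.feret
        assert r_comb.pf_ratio > r_rect.pf_ratio

    def test_concavity_strictly_lowers_solidity(self):
        full = np.ones((9, 9), bool)
        notched = full.copy()
        notched[0:4, 3:6] = False
        assert _measure_mask(notched).solidity < _measure_mask(full).solidity == 1.0

    def test_caliper_feret_exceeds_projection_for_diagonal(self):
        m = np.zeros((20, 20), bool)
        np.fill_diagonal(m, True)
        m |= np.roll(m, 1, axis=1)  # 2-px wide diagonal band, stays 8-connected
        proj = _measure_mask(m).feret
        cal = _measure_mask(m, feret_mode="caliper").feret
        assert cal > proj

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.05, 10.0),
        dr=st.integers(0, 30),
        dc=st.integers(0, 30),
        seed=st.integers(0, 500),
    )
    def test_scale_equivariance_and_translation_invariance(self, scale, dr, dc, seed):
        """Lengths scale by s, areas by s²; P/F and solidity are
        scale- and translation-invariant."""
        rng = np.random.default_rng(seed)
        m = np.zeros((12, 12), bool)
        m[2:10, 2:10] = rng.random((8, 8)) < 0.7
        comps = label_rois(m)
        if not comps:
            return
        px = max(comps, key=len)
        gray = np.full((64, 64), 100, dtype=np.uint8)
        a = measure_roi(px, gray, 1.0)
        b = measure_roi(px, gray, scale)
        c = measure_roi(px + [dr, dc], gray, 1.0)
        assert b.area == pytest.approx(a.area * scale**2)
        assert b.perimeter == pytest.approx(a.perimeter * scale)
        assert b.feret == pytest.approx(a.feret * scale)
        assert b.pf_ratio == pytest.approx(a.pf_ratio)
        assert b.solidity == pytest.approx(a.solidity)
        for name in ("area", "perimeter", "feret", "pf_ratio", "solidity"):
            assert getattr(c, name) == pytest.approx(getattr(a, name))

    def test_quarter_turn_preserves_pf_and_solidity(self):
        m = np.zeros((15, 25), bool)
        m[2:6, 1:24] = True
        m[2:14, 4:8] = True
        a = _measure_mask(m)
        b = _measure_mask(np.rot90(m).copy())
        assert b.pf_ratio == pytest.approx(a.pf_ratio)
        assert b.solidity == pytest.approx(a.solidity)
        assert b.feret == pytest.approx(a.feret)  # X/Y mean is symmetric

    def test_one_pixel_wide_component_is_legal(self):
        m = np.zeros((1, 12), bool)
        m[0, :] = True
        r = _measure_mask(m)
        assert r.feret_y == 1.0
        assert r.feret > 0


class TestSummarizeField:
    def _rec(self, area):
        m = np.ones((5, int(area / 5)), bool)
        px = np.column_stack(np.nonzero(m))
        return measure_roi(px, np.full((5, 50), 10, np.uint8), 1.0)

    def test_single_roi_mean_is_identity(self):
        r = self._rec(10)
        s = summarize_field([r])
        assert s.n_rois == 1 and s.area == r.area and s.pf_ratio == r.pf_ratio

    def test_two_rois_arithmetic_mean(self):
        s = summarize_field([self._rec(10), self._rec(20)])
        assert s.area == 15.0

    def test_empty_field_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            s = summarize_field([])
        assert s.is_empty and s.n_rois == 0
        assert np.isnan(s.area)

    def test_records_frame_columns(self):
        df = records_to_frame([self._rec(10)], "s1", 2, 200)
        assert list(df.columns)[:5] == [
            "sample_id", "field_index", "roi_id", "pixel_count", "area_um2"
        ]
        assert df.loc[0, "threshold_used"] == 200


def test_cmgv_identity_on_random_rois(rng):
    """cmgv + mgv == 255 exactly for every measured ROI."""
    gray = rng.integers(0, 256, (40, 40)).astype(np.uint8)
    m = rng.random((40, 40)) < 0.4
    comps, _ = filter_artefacts(label_rois(m))
    for i, c in enumerate(comps):
        r = measure_roi(c, gray, 0.3, roi_id=i)
        assert r.cmgv + r.mgv == 255.0
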