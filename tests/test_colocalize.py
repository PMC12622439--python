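import numpy as np
import pytest

from psht.colocalize import (
    ColocalizationCurve,
    binarize_fluorescence_mip,
    binarize_ri_mip,
    default_ri_grid,
    manders,
    select_ri_th,
    sweep_ri_threshold,
)
from psht.volumes import Mask2D


class TestManders:
    def test_identical_masks(self):
        m = Mask2D(np.eye(8, dtype=bool))
        assert manders(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert manders(Mask2D(a), Mask2D(b)) == (0.0, 0.0)

    def test_hand_counted_case(self):
        # |ref| = 10, |test| = 5, overlap = 4 -> (0.4, 0.8)
        ref = np.zeros((5, 5), dtype=bool)
        test = np.zeros((5, 5), dtype=bool)
        ref.flat[:10] = True
        test.flat[6:11] = True
        m1, m2 = manders(Mask2D(ref), Mask2D(test))
        assert (m1, m2) == (0.4, 0.8)

    def test_random_masks_match_pixel_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.random((16, 16)) > 0.6
            b = rng.random((16, 16)) > 0.6
            overlap = sum(
                1 for i in range(16) for j in range(16) if a[i, j] and b[i, j]
            )
            m1, m2 = manders(Mask2D(a), Mask2D(b))
            assert m1 == (overlap / a.sum() if a.sum() else np.isnan(m1))
            assert m2 == (overlap / b.sum() if b.sum() else np.isnan(m2))

    def test_empty_denominator_is_nan_not_zero(self):
        empty = Mask2D(np.zeros((4, 4), dtype=bool))
        full = Mask2D(np.ones((4, 4), dtype=bool))
        m1, m2 = manders(empty, full)
        assert np.isnan(m1) and m2 == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            manders(Mask2D(np.zeros((4, 4), bool)), Mask2D(np.zeros((5, 4), bool)))


class TestBinarize:
    def test_ri_mask_monotone_in_threshold(self, clean_phantom):
        _, pair, _, _ = clean_phantom
        m1 = binarize_ri_mip(pair.vertical, 1.370)
        m2 = binarize_ri_mip(pair.vertical, 1.376)
        assert np.all(m2.data <= m1.data)

    def test_ri_threshold_below_min_gives_full_mask(self, clean_phantom):
        _, pair, _, _ = clean_phantom
        assert binarize_ri_mip(pair.vertical, 1.30).data.all()

    def test_ri_threshold_separates_droplets_exactly(self, clean_phantom):
        # droplets at 1.380, everything else <= 1.370: threshold 1.375 is exact
        _, pair, _, truth = clean_phantom
        mask = binarize_ri_mip(pair.vertical, 1.375)
        assert np.array_equal(mask.data, np.max(truth.ld_mask.data, axis=0))

    def test_fluor_threshold_zero_gives_all_ones(self, clean_phantom):
        _, _, fluor, _ = clean_phantom
        assert binarize_fluorescence_mip(fluor, 0.0).data.all()

    def test_fluor_threshold_above_max_warns_empty(self, clean_phantom):
        _, _, fluor, _ = clean_phantom
        with pytest.warns(UserWarning, match="empty"):
            mask = binarize_fluorescence_mip(fluor, fluor.data.max() + 1)
        assert mask.count() == 0

    def test_fluor_half_peak_overlaps_truth(self, clean_phantom):
        _, _, fluor, truth = clean_phantom
        thr = fluor.data.min() + 0.5 * np.ptp(fluor.data)
        mask = binarize_fluorescence_mip(fluor, thr)
        t = np.max(truth.ld_mask.data, axis=0)
        jaccard = (mask.data & t).sum() / (mask.data | t).sum()
        assert jaccard >= 0.5


class TestSweep:
    def test_truth_reference_perfect_plateau(self, clean_phantom):
        """Non-LD MIP <= 1.3700, droplets >= 1.3760: the plateau onset lies in
        (1.3700, 1.3760] and reaches perfect colocalization."""
        _, pair, _, truth = clean_phantom
        ref = Mask2D(np.max(truth.ld_mask.data, axis=0))
        curve = sweep_ri_threshold(pair.vertical, ref)
        assert 1.3700 < curve.ri_th <= 1.3760
        assert curve.m1_at_th == 1.0 and curve.m2_at_th == 1.0
        assert curve.plateau_found
        # M2 constant at maximum above the confounder level
        above = curve.ri[(curve.ri > 1.3701) & (curve.ri <= 1.3790)]
        sel = np.isin(curve.ri, above)
        assert np.all(curve.m2[sel] == np.nanmax(curve.m2))

    def test_blurred_reference_m2_exceeds_m1(self, clean_phantom):
        _, pair, fluor, _ = clean_phantom
        thr = fluor.data.min() + 0.2 * np.ptp(fluor.data)
        ref = binarize_fluorescence_mip(fluor, thr)
        curve = sweep_ri_threshold(pair.vertical, ref)
        assert curve.m2_at_th > curve.m1_at_th
        assert curve.m1_at_th >= 0.9 and curve.m2_at_th >= 0.9

    def test_curve_matches_independent_mask_count_oracle(self, clean_phantom):
        _, pair, _, truth = clean_phantom
        ref = Mask2D(np.max(truth.ld_mask.data, axis=0))
        grid = default_ri_grid(1.3650, 1.3850, 0.001)  # coarse for the loop oracle
        curve = sweep_ri_threshold(pair.vertical, ref, grid=grid)
        proj = pair.vertical.data.max(axis=0)
        for i, t in enumerate(grid):
            test = proj >= t
            n_ref, n_test = ref.data.sum(), test.sum()
            ov = np.logical_and(ref.data, test).sum()
            assert curve.m1[i] == (ov / n_ref)
            if n_test:
                assert curve.m2[i] == (ov / n_test)
            else:
                assert np.isnan(curve.m2[i])

    def test_empty_reference_rejected(self, clean_phantom):
        _, pair, _, _ = clean_phantom
        with pytest.raises(ValueError, match="empty"):
            sweep_ri_threshold(pair.vertical, Mask2D(np.zeros(pair.vertical.shape[1:], bool)))


def make_curve(m2, ri=None):
    ri = default_ri_grid() if ri is None else ri
    m2 = np.asarray(m2, dtype=float)
    dm2 = np.gradient(m2, ri)
    return ColocalizationCurve(ri, m2.copy(), m2, dm2)


class TestSelectRITh:
    def test_perfect_step_selects_step_index(self):
        ri = default_ri_grid()
        k = 80
        m2 = np.where(np.arange(len(ri)) >= k, 0.95, 0.2)
        curve = select_ri_th(make_curve(m2, ri))
        assert curve.ri_th == ri[k]
        assert curve.plateau_found

    def test_constant_m2_selects_grid_minimum(self):
        ri = default_ri_grid()
        curve = select_ri_th(make_curve(np.full(len(ri), 0.8), ri))
        assert curve.ri_th == ri[0]

    def test_noisy_plateau_stays_close_to_clean_answer(self):
        ri = default_ri_grid()
        k = 100
        clean = np.where(np.arange(len(ri)) >= k, 0.95, 0.3)
        rng = np.random.default_rng(42)
        noisy = np.clip(clean + rng.normal(0, 0.01, len(ri)), 0, 1)
        sel_clean = select_ri_th(make_curve(clean, ri))
        sel_noisy = select_ri_th(make_curve(noisy, ri))
        step = ri[1] - ri[0]
        assert abs(sel_noisy.ri_th - sel_clean.ri_th) <= 5 * step + 1e-12

    def test_no_plateau_flagged(self):
        ri = default_ri_grid()
        rising = np.linspace(0.1, 0.9, len(ri))  # still rising at the end
        with pytest.warns(UserWarning, match="plateau"):
            curve = select_ri_th(make_curve(rising, ri), window=10)
        assert not curve.plateau_found
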