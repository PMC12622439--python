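import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psht.birefringence import (
    BirefringenceVolume,
    birefringence_histogram,
    birefringent_volume,
    compute_birefringence,
    line_profile,
)
from psht.masks import CleanupParams
from psht.register import PolarizationPair
from psht.volumes import ROI, Volume3D


def make_pair(a, b, spacing=(0.2, 0.1, 0.1)):
    return PolarizationPair(
        Volume3D(a, spacing, "ri_vertical"),
        Volume3D(b, spacing, "ri_horizontal"),
        state="fully_aligned",
    )


class TestComputeBirefringence:
    def test_identical_volumes_give_zero(self):
        a = np.full((8, 8, 8), 1.36)
        assert np.all(compute_birefringence(make_pair(a, a.copy())).volume.data == 0)

    def test_constant_offset(self):
        a = np.full((4, 4, 4), 1.36)
        b = np.full((4, 4, 4), 1.34)
        out = compute_birefringence(make_pair(a, b)).volume.data
        assert np.allclose(out, 0.02)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bruteforce_oracle_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = 1.33 + 0.1 * rng.random((16, 16, 16))
        b = 1.33 + 0.1 * rng.random((16, 16, 16))
        out = compute_birefringence(make_pair(a, b)).volume.data
        expected = np.empty_like(a)
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    expected[i, j, k] = abs(a[i, j, k] - b[i, j, k])
        assert np.array_equal(out, expected)
        swapped = compute_birefringence(make_pair(b, a)).volume.data
        assert np.array_equal(out, swapped)

    def test_unaligned_pair_rejected(self):
        a = np.full((4, 4, 4), 1.36)
        pair = PolarizationPair(
            Volume3D(a, channel="ri_vertical"), Volume3D(a, channel="ri_horizontal")
        )
        with pytest.raises(ValueError, match="aligned"):
            compute_birefringence(pair)


class TestHistogram:
    def _bvol(self, data, spacing=(0.2, 0.1, 0.1)):
        return BirefringenceVolume(Volume3D(data, spacing, "birefringence"))

    def test_zero_volume_all_in_first_bin(self):
        h = birefringence_histogram(self._bvol(np.zeros((4, 4, 4))))
        assert h.counts[0] == 64
        assert h.counts[1:].sum() == 0

    def test_counts_conserved_with_overflow(self):
        rng = np.random.default_rng(0)
        data = 0.1 * rng.random((6, 6, 6))  # some values above the 0.05 default range
        h = birefringence_histogram(self._bvol(data))
        assert h.counts.sum() == 216
        assert h.counts[-1] > 0  # overflow bin in use

    def test_roi_restriction(self):
        data = np.zeros((4, 4, 4))
        h = birefringence_histogram(self._bvol(data), roi=ROI((0, 2), (0, 4), (0, 4)))
        assert h.counts.sum() == 32

    def test_shell_counts_match_truth(self, clean_phantom):
        _, pair, _, truth = clean_phantom
        bvol = compute_birefringence(pair)
        h = birefringence_histogram(bvol)
        n_above_003 = h.counts_above(0.03)
        assert n_above_003 == pytest.approx(truth.masks["ld_shell"].count(), rel=0.10)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            birefringence_histogram(self._bvol(np.zeros((2, 2, 2))), edges=np.array([0.0, 0.0, 1.0]))


class TestBirefringentVolume:
    def _bvol(self, data):
        return BirefringenceVolume(Volume3D(data, (0.2, 0.1, 0.1), "birefringence"))

    def test_threshold_above_max_gives_zero(self):
        assert birefringent_volume(self._bvol(np.full((4, 4, 4), 0.005)), threshold=0.01) == 0

    def test_all_above_no_cleanup_counts_everything(self):
        bv = birefringent_volume(self._bvol(np.full((4, 4, 4), 0.02)), cleanup=None)
        assert bv == pytest.approx(64 * 0.002)

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(3)
        bvol = self._bvol(0.05 * rng.random((8, 8, 8)))
        vols = [birefringent_volume(bvol, threshold=t, cleanup=None) for t in (0.0, 0.01, 0.02, 0.04)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_phantom_droplet_volume_within_10pct(self):
        from psht.phantom import LDRecord, PhantomSpec, generate_cell

        spec = PhantomSpec(
            shape=(48, 96, 96), spacing=(0.2, 0.1, 0.1), noise_sigma=0.0,
            nucleolus_count=0, ld_sampling=None,
            lds=(LDRecord((4.8, 4.8, 4.8), 1.0),),  # core/shell dn both above 0.01
        )
        pair, _, truth = generate_cell(spec)
        bvol = compute_birefringence(pair)
        bv = birefringent_volume(bvol, threshold=0.01, cleanup=CleanupParams())
        expected = truth.ld_mask.count() * 0.002
        assert bv == pytest.approx(expected, rel=0.10)


class TestLineProfile:
    def test_constant_volume_constant_profile(self):
        v = Volume3D(np.full((8, 8, 8), 1.36))
        p = line_profile(v, (0, 0, 0), (7, 7, 7), n=20)
        assert np.allclose(p, 1.36)

    def test_out_of_bounds_endpoint_rejected(self):
        v = Volume3D(np.full((8, 8, 8), 1.36))
        with pytest.raises(ValueError, match="out of bounds"):
            line_profile(v, (0, 0, 0), (8, 0, 0))

    def test_droplet_double_peak_in_birefringence_single_peak_in_ri(self, clean_phantom):
        """Across a droplet centre the birefringence profile is double-peaked
        (ordered shell > core) while the RI profile has a single maximum."""
        spec, pair, _, truth = clean_phantom
        ld = truth.lds[0]  # radius 1.2 µm at (4.8, 3.2, 3.2) µm
        dz, dy, dx = spec.spacing
        cz, cy, cx = ld.center_um[0] / dz, ld.center_um[1] / dy, ld.center_um[2] / dx
        r_vox = ld.radius_um / dx
        a = (cz, cy, cx - r_vox - 5)
        b = (cz, cy, cx + r_vox + 5)
        bvol = compute_birefringence(pair)
        prof_b = line_profile(bvol.volume, a, b, n=101)
        prof_ri = line_profile(pair.vertical, a, b, n=101)

        center = 50
        # birefringence: local minimum at the centre flanked by two maxima
        left_peak = prof_b[:center].max()
        right_peak = prof_b[center + 1 :].max()
        assert prof_b[center] < left_peak
        assert prof_b[center] < right_peak
        assert prof_b[center] > 0  # core still birefringent
        # RI: flat-topped single maximum, no central dip
        assert prof_ri[center] == pytest.approx(prof_ri.max(), abs=1e-9)
        top = prof_ri >= prof_ri.max() - 1e-9
        runs = np.diff(np.where(top)[0])
        assert np.all(runs == 1)  # the maximal region is contiguous
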