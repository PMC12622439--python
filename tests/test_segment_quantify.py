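import numpy as np
import pytest

from psht.birefringence import compute_birefringence
from psht.phantom import LDRecord, PhantomSpec, generate_cell
from psht.segment_quantify import (
    LDQuantification,
    OrganelleThresholds,
    dry_mass,
    quantify_cell,
    segment_organelles,
    volume_of,
)
from psht.volumes import Mask3D, Volume3D


class TestVolumeOf:
    def test_single_voxel(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 2, 3] = True
        assert volume_of(Mask3D(m, (0.2, 0.1, 0.1))) == pytest.approx(0.002)

    def test_empty_mask(self):
        assert volume_of(Mask3D(np.zeros((4, 4, 4), bool), (0.2, 0.1, 0.1))) == 0

    def test_digitized_sphere_close_to_analytic(self):
        # radius 10 voxels at isotropic 0.1 µm: (4/3)π(1 µm)³ = 4.18879 µm³
        z, y, x = np.ogrid[-16:16, -16:16, -16:16]
        sphere = (z**2 + y**2 + x**2) <= 10**2
        v = volume_of(Mask3D(sphere, (0.1, 0.1, 0.1)))
        assert v == pytest.approx(4.18879, rel=0.05)


class TestDryMass:
    def test_empty_mask_zero_mass(self):
        ri = Volume3D(np.full((4, 4, 4), 1.36), (0.2, 0.1, 0.1))
        assert dry_mass(ri, Mask3D(np.zeros((4, 4, 4), bool), (0.2, 0.1, 0.1))) == 0

    def test_uniform_region_closed_form(self):
        # Δn = 0.037 over 100 µm³ at α = 0.185 µm³/pg -> 20 pg
        shape = (10, 100, 100)  # 100000 voxels × 0.001 µm³ = 100 µm³
        ri = Volume3D(np.full(shape, 1.337 + 0.037), (0.1, 0.1, 0.1))
        mask = Mask3D(np.ones(shape, bool), (0.1, 0.1, 0.1))
        m = dry_mass(ri, mask, n_medium=1.337, alpha=0.185)
        assert m == pytest.approx(20.0, rel=0.01)

    def test_linearity_in_dn_exact(self):
        shape = (4, 8, 8)
        mask = Mask3D(np.ones(shape, bool), (0.2, 0.1, 0.1))
        m1 = dry_mass(Volume3D(np.full(shape, 1.337 + 0.01), (0.2, 0.1, 0.1)), mask)
        m2 = dry_mass(Volume3D(np.full(shape, 1.337 + 0.02), (0.2, 0.1, 0.1)), mask)
        assert m2 == pytest.approx(2 * m1, rel=1e-12)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(0)
        shape = (6, 8, 8)
        ri = Volume3D(1.34 + 0.02 * rng.random(shape), (0.2, 0.1, 0.1))
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        a[:3] = True
        b[3:] = rng.random((3, 8, 8)) > 0.5
        total = dry_mass(ri, Mask3D(a | b, ri.spacing))
        assert total == pytest.approx(
            dry_mass(ri, Mask3D(a, ri.spacing)) + dry_mass(ri, Mask3D(b, ri.spacing))
        )

    def test_below_medium_clipped_with_warning(self):
        shape = (2, 2, 2)
        ri = Volume3D(np.full(shape, 1.33), (0.2, 0.1, 0.1))
        with pytest.warns(UserWarning, match="clipped"):
            m = dry_mass(ri, Mask3D(np.ones(shape, bool), ri.spacing), n_medium=1.337)
        assert m == 0

    def test_bad_alpha(self):
        ri = Volume3D(np.full((2, 2, 2), 1.36))
        with pytest.raises(ValueError):
            dry_mass(ri, Mask3D(np.ones((2, 2, 2), bool), ri.spacing), alpha=0)


class TestSegmentOrganelles:
    def test_exact_generative_thresholds_recover_truth(self, clean_phantom):
        spec, pair, _, truth = clean_phantom
        thresholds = OrganelleThresholds(
            cytosol=(1.340, 1.350),
            nucleus=(1.350, 1.365),
            extra={"nucleolus": (1.368, 1.372)},
            ld=(1.375, np.inf),
        )
        masks = segment_organelles(pair.vertical, thresholds, cleanup=None)
        assert np.array_equal(masks["cytosol"].data, truth.masks["cytosol"].data)
        assert np.array_equal(masks["nucleus"].data, truth.masks["nucleus"].data)
        assert np.array_equal(masks["nucleolus"].data, truth.masks["nucleolus"].data)
        assert np.array_equal(masks["ld"].data, truth.ld_mask.data)

    def test_exclusive_thresholds_warn_empty(self, clean_phantom):
        _, pair, _, _ = clean_phantom
        t = OrganelleThresholds(cytosol=(1.30, 1.301), nucleus=(1.301, 1.302), ld=(1.44, np.inf))
        with pytest.warns(UserWarning, match="empty"):
            masks = segment_organelles(pair.vertical, t, cleanup=None)
        assert all(m.count() == 0 for m in masks.values())

    def test_nucleolus_confounder_leaks_into_ld_mask(self):
        """With nucleolar RI inside the droplet interval and no ROI exclusion,
        nucleolus voxels are misclassified as droplets — the documented
        failure mode of RI-only segmentation that birefringence avoids."""
        spec = PhantomSpec(
            shape=(48, 96, 96), spacing=(0.2, 0.1, 0.1), noise_sigma=0.0,
            texture_amplitude=0.0, nucleolus_count=2, nucleolus_ri=1.378, ld_sampling=None,
            lds=(LDRecord((4.8, 3.2, 3.2), 1.0),),
        )
        pair, _, truth = generate_cell(spec)
        masks = segment_organelles(pair.vertical, OrganelleThresholds(), cleanup=None)
        nucleolus = truth.masks["nucleolus"].data
        assert np.all(masks["ld"].data[nucleolus])
        # the birefringence channel does not share the confusion
        biref = compute_birefringence(pair).volume.data
        assert biref[nucleolus].max() == 0

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            OrganelleThresholds(cytosol=(1.335, 1.355), nucleus=(1.350, 1.365))


class TestQuantifyCell:
    def test_noise_free_phantom_matches_truth(self, clean_phantom):
        spec, pair, _, truth = clean_phantom
        bvol = compute_birefringence(pair)
        q = quantify_cell(pair.vertical, bvol, OrganelleThresholds(), cleanup=None)
        truth_cell = truth.cell_mask
        assert q.cell_volume_um3 == pytest.approx(volume_of(truth_cell), rel=0.10)
        assert q.ld_volume_um3 == pytest.approx(
            truth.ld_mask.count() * 0.002, rel=0.10
        )
        expected_mass = dry_mass(pair.vertical, truth.ld_mask)
        assert q.ld_dry_mass_pg == pytest.approx(expected_mass, rel=0.10)
        assert q.ld_count == len(truth.lds)
        expected_mean = pair.vertical.data[truth_cell.data].mean()
        assert q.mean_cell_ri == pytest.approx(expected_mean, abs=0.001)

    def test_zero_droplet_cell(self):
        spec = PhantomSpec(
            shape=(32, 64, 64), spacing=(0.2, 0.1, 0.1), noise_sigma=0.0,
            texture_amplitude=0.0, nucleolus_count=0, ld_sampling=None, lds=(),
            cytosol_semiaxes_um=(2.4, 2.6, 2.2), nucleus_semiaxes_um=(1.0, 1.2, 0.9),
            nucleus_center_offset_um=(0.1, 0.3, -0.3),
        )
        pair, _, _ = generate_cell(spec)
        bvol = compute_birefringence(pair)
        q = quantify_cell(pair.vertical, bvol, OrganelleThresholds(), cleanup=None)
        assert q.ld_volume_um3 == 0
        assert q.ld_dry_mass_pg == 0
        assert q.birefringent_volume_um3 == 0
        assert q.ld_count == 0

    def test_tripling_droplet_count_triples_ld_volume(self):
        def cell(lds):
            spec = PhantomSpec(
                shape=(48, 96, 96), spacing=(0.2, 0.1, 0.1), noise_sigma=0.0,
                texture_amplitude=0.0, nucleolus_count=0, ld_sampling=None, lds=lds,
            )
            pair, _, _ = generate_cell(spec)
            bvol = compute_birefringence(pair)
            return quantify_cell(pair.vertical, bvol, OrganelleThresholds(), cleanup=None)

        one = cell((LDRecord((4.8, 3.2, 3.2), 0.8),))
        three = cell((
            LDRecord((4.8, 3.2, 3.2), 0.8),
            LDRecord((4.8, 6.4, 6.0), 0.8),
            LDRecord((3.4, 5.0, 2.9), 0.8),
        ))
        ratio = three.ld_volume_um3 / one.ld_volume_um3
        assert 2.5 <= ratio <= 3.5

    def test_mean_ri_within_cell_range(self, clean_phantom):
        _, pair, _, _ = clean_phantom
        q = quantify_cell(pair.vertical, None, OrganelleThresholds(), cleanup=None)
        cell = pair.vertical.data >= 1.340
        assert pair.vertical.data[cell].min() <= q.mean_cell_ri <= pair.vertical.data[cell].max()

    def test_ld_volume_bounded_by_cell_volume(self):
        with pytest.raises(ValueError, match="exceed"):
            LDQuantification(
                cell_volume_um3=1.0, mean_cell_ri=1.35, ld_volume_um3=2.0,
                ld_dry_mass_pg=0.1, ld_mass_density_pg_um3=0.05,
                birefringent_volume_um3=0.0, ld_count=1,
            )
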