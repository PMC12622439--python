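import pytest

from psht.phantom import LDRecord, PhantomSpec, generate_cell
from psht.register import register_pair


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, aligned phantom with three droplets and a nucleolus
    confounder at exactly RI 1.3700 (non-LD MIP <= 1.3700, LD >= 1.3760)."""
    spec = PhantomSpec(
        shape=(48, 96, 96),
        spacing=(0.2, 0.1, 0.1),
        noise_sigma=0.0,
        texture_amplitude=0.0,
        nucleolus_count=2,
        nucleolus_ri=1.370,
        ld_sampling=None,
        lds=(
            LDRecord((4.8, 3.2, 3.2), 1.2),
            LDRecord((4.8, 6.5, 6.2), 1.0),
            LDRecord((3.2, 5.0, 2.8), 0.7),
        ),
        seed=0,
    )
    pair, fluor, truth = generate_cell(spec)
    return spec, pair, fluor, truth


@pytest.fixture(scope="session")
def misaligned_phantom():
    """Noise-free phantom displaced by 2 deg rotation, (3, -2) voxel
    translation and +4 slices between the two polarization acquisitions."""
    spec = PhantomSpec(
        shape=(64, 128, 128),
        spacing=(0.2, 0.1, 0.1),
        noise_sigma=0.0,
        texture_amplitude=0.0,
        nucleolus_count=2,
        ld_sampling=None,
        lds=(
            LDRecord((6.4, 4.0, 4.0), 1.0),
            LDRecord((6.4, 8.5, 8.0), 0.8),
            LDRecord((4.0, 6.4, 6.4), 0.6),
        ),
        misalign_rotation_deg=2.0,
        misalign_translation_vox=(3.0, -2.0),
        misalign_axial_slices=4,
        seed=0,
    )
    pair, fluor, truth = generate_cell(spec)
    return spec, pair, fluor, truth


@pytest.fixture(scope="session")
def registered_pair(misaligned_phantom):
    _, pair, _, _ = misaligned_phantom
    return register_pair(pair, seed=3)
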