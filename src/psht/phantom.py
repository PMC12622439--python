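"""Seeded digital-phantom generator for polarization-resolved cell volumes.

The phantom emulates the structures a polarization-sensitive holotomogram
of an adherent cell contains: a cytosol ellipsoid of low refractive index
(RI ~1.345) in aqueous medium, a nucleus of intermediate RI, optional
nucleoli whose RI overlaps the lipid-droplet range (the classic confounder
of RI-only segmentation), and spherical lipid droplets (LDs) of high RI
with a core-shell anisotropy structure: under one polarization the LD RI
is lowered by a polarization-dependent decrement Δn that is larger in the
thin phospholipid shell than in the neutral-lipid core.  The voxelwise
absolute difference of the two polarization volumes therefore recovers the
Δn map — near zero everywhere except LDs, shell-dominant within each LD.

Volumes are sampled from a *continuous* scene description.  The horizontal
(moving) volume is sampled at rigidly transformed coordinates rather than
warped after rasterization, mimicking a physically displaced sample: the
misaligned volume contains no interpolation artefacts, so any interpolation
halo in downstream results is attributable to the registration step alone.

Ground truth (organelle masks, per-LD records, applied misalignment, the
lowest RI assigned to any LD voxel) is returned alongside the data, which
makes every downstream stage testable without a microscope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .register import AxialShift, PolarizationPair, RigidTransform2D
from .volumes import Mask3D, Volume3D

__all__ = [
    "LDRecord",
    "LDSampling",
    "PhantomSpec",
    "PhantomTruth",
    "LabeledCell",
    "generate_cell",
    "generate_cohort",
    "rasterize_lds",
    "healthy_spec",
    "cancer_spec",
]


@dataclass(frozen=True)
class LDRecord:
    """One lipid droplet: geometry plus its polarization-dependent RI decrements."""

    center_um: Tuple[float, float, float]  # (z, y, x)
    radius_um: float
    core_ri: float = 1.380
    core_dn: float = 0.015
    shell_dn: float = 0.035
    shell_thickness_um: float = 0.15
    birefringent: bool = True

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("LD radius must be positive")
        if not (self.shell_dn >= self.core_dn > 0):
            raise ValueError("require shell_dn >= core_dn > 0 (shell-dominant anisotropy)")


@dataclass(frozen=True)
class LDSampling:
    """Sampling law for per-cell LD populations.

    ``birefringent_fraction`` is the probability that a droplet carries the
    full (ordered, strongly anisotropic) decrements; the remainder receive
    the weak decrements, modelling droplets whose lipid ordering is too low
    to register above the fixed birefringence threshold.
    """

    count_range: Tuple[int, int] = (3, 6)
    diameter_range_um: Tuple[float, float] = (0.5, 5.0)
    core_ri_range: Tuple[float, float] = (1.378, 1.390)
    core_dn: float = 0.015
    shell_dn: float = 0.035
    weak_core_dn: float = 0.003
    weak_shell_dn: float = 0.007
    shell_thickness_um: float = 0.15
    birefringent_fraction: float = 1.0

    def __post_init__(self):
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi):
            raise ValueError("invalid diameter range")
        if not (0 <= self.birefringent_fraction <= 1):
            raise ValueError("birefringent_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of one synthetic cell."""

    shape: Tuple[int, int, int] = (64, 128, 128)
    spacing: Tuple[float, float, float] = (0.2, 0.1, 0.1)
    medium_ri: float = 1.337
    cytosol_semiaxes_um: Tuple[float, float, float] = (5.0, 5.8, 4.6)
    cytosol_ri: float = 1.345
    nucleus_semiaxes_um: Tuple[float, float, float] = (2.0, 2.4, 1.8)
    nucleus_center_offset_um: Tuple[float, float, float] = (0.4, 0.9, -0.7)
    nucleus_ri: float = 1.358
    nucleolus_count: int = 2
    nucleolus_radius_range_um: Tuple[float, float] = (0.4, 0.7)
    nucleolus_ri: float = 1.376
    lds: Optional[Tuple[LDRecord, ...]] = None
    ld_sampling: Optional[LDSampling] = field(default_factory=LDSampling)
    ld_overlap_tolerance: float = 0.0
    texture_amplitude: float = 0.002
    texture_wavelength_um: Tuple[float, float] = (0.6, 2.4)
    texture_components: int = 32
    noise_sigma: float = 0.002
    fluor_sigma_lateral_um: float = 0.2
    fluor_sigma_axial_um: float = 1.0
    fluor_background: float = 0.05
    fluor_photons: Optional[int] = 200
    misalign_rotation_deg: float = 0.0
    misalign_translation_vox: Tuple[float, float] = (0.0, 0.0)
    misalign_axial_slices: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (self.cytosol_ri < self.nucleus_ri < min(self.nucleolus_ri, 1.45)):
            raise ValueError("require cytosol RI < nucleus RI < nucleolus RI")
        if self.medium_ri >= self.cytosol_ri:
            raise ValueError("medium RI must be below cytosol RI")
        if self.lds is not None:
            object.__setattr__(self, "lds", tuple(self.lds))

    @property
    def center_um(self) -> Tuple[float, float, float]:
        dz, dy, dx = self.spacing
        nz, ny, nx = self.shape
        return ((nz - 1) / 2 * dz, (ny - 1) / 2 * dy, (nx - 1) / 2 * dx)

    @property
    def nucleus_center_um(self) -> Tuple[float, float, float]:
        return tuple(c + o for c, o in zip(self.center_um, self.nucleus_center_offset_um))

    @property
    def misalignment(self) -> RigidTransform2D:
        return RigidTransform2D(self.misalign_rotation_deg, tuple(self.misalign_translation_vox))

    @property
    def is_misaligned(self) -> bool:
        return (
            self.misalign_rotation_deg != 0
            or any(t != 0 for t in self.misalign_translation_vox)
            or self.misalign_axial_slices != 0
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one generated cell (defined on the reference grid)."""

    masks: Dict[str, Mask3D]  # cytosol, nucleus, nucleolus, ld_core, ld_shell
    lds: Tuple[LDRecord, ...]
    misalign_lateral: RigidTransform2D
    misalign_axial: AxialShift
    ld_ri_threshold: float  # lowest RI assigned to any LD voxel
    birefringence: Volume3D  # noiseless Δn map on the reference grid

    @property
    def ld_mask(self) -> Mask3D:
        core, shell = self.masks["ld_core"], self.masks["ld_shell"]
        return Mask3D(core.data | shell.data, core.spacing)

    @property
    def cell_mask(self) -> Mask3D:
        m = None
        for v in self.masks.values():
            m = v.data if m is None else (m | v.data)
        return Mask3D(m, next(iter(self.masks.values())).spacing)


@dataclass(frozen=True)
class LabeledCell:
    label: str
    pair: PolarizationPair
    fluorescence: Volume3D
    truth: PhantomTruth
    seed: int


# ---------------------------------------------------------------------------
# scene evaluation
# ---------------------------------------------------------------------------


class _FourierTexture:
    """Band-limited random field as a finite cosine series.

    Real RI maps show smooth intracellular heterogeneity; a sum of random
    plane waves reproduces it while remaining an analytic function of
    position, so the displaced (misaligned) acquisition samples the *same*
    texture rigidly moved — exactly like a physical specimen.  The texture
    is common to both polarizations and therefore cancels in the
    birefringence map of a perfectly aligned pair.
    """

    def __init__(self, amplitude, wavelength_range, n, rng):
        self.amplitude = amplitude
        if amplitude <= 0 or n < 1:
            self.k = np.zeros((0, 3))
            self.phase = np.zeros(0)
            self.a = np.zeros(0)
            return
        wl = rng.uniform(*wavelength_range, size=n)
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        self.k = (2 * np.pi / wl)[:, None] * d
        self.phase = rng.uniform(0, 2 * np.pi, size=n)
        a = rng.normal(size=n)
        a *= amplitude / np.sqrt(np.sum(a**2) / 2.0)  # field std = amplitude
        self.a = a

    def __call__(self, zc, yc, xc):
        out = np.zeros(zc.shape)
        for (kz, ky, kx), ph, a in zip(self.k, self.phase, self.a):
            out += a * np.cos(kz * zc + ky * yc + kx * xc + ph)
        return out


def _ellipsoid_value(zc, yc, xc, center, semiaxes):
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return ((zc - cz) / az) ** 2 + ((yc - cy) / ay) ** 2 + ((xc - cx) / ax) ** 2


def _evaluate_scene(spec: PhantomSpec, lds, nucleoli, zc, yc, xc, texture=None, with_labels=False):
    """Evaluate the continuous scene at physical coordinates (µm).

    Returns (ri, dn) and, if requested, the organelle label map with codes
    1=cytosol, 2=nucleus, 3=nucleolus, 4=ld_core, 5=ld_shell.  Later
    structures overwrite earlier ones, so labels are disjoint by
    construction.
    """
    ri = np.full(zc.shape, spec.medium_ri, dtype=np.float64)
    dn = np.zeros(zc.shape, dtype=np.float64)
    labels = np.zeros(zc.shape, dtype=np.uint8) if with_labels else None

    cell = _ellipsoid_value(zc, yc, xc, spec.center_um, spec.cytosol_semiaxes_um) <= 1.0
    ri[cell] = spec.cytosol_ri
    if with_labels:
        labels[cell] = 1
    m = _ellipsoid_value(zc, yc, xc, spec.nucleus_center_um, spec.nucleus_semiaxes_um) <= 1.0
    ri[m] = spec.nucleus_ri
    if with_labels:
        labels[m] = 2
    for center, radius in nucleoli:
        m = _ellipsoid_value(zc, yc, xc, center, (radius,) * 3) <= 1.0
        ri[m] = spec.nucleolus_ri
        if with_labels:
            labels[m] = 3
    for ld in lds:
        v = _ellipsoid_value(zc, yc, xc, ld.center_um, (ld.radius_um,) * 3)
        inside = v <= 1.0
        r_core = max(ld.radius_um - ld.shell_thickness_um, 0.0)
        core = _ellipsoid_value(zc, yc, xc, ld.center_um, (max(r_core, 1e-9),) * 3) <= 1.0
        core &= inside
        shell = inside & ~core
        ri[inside] = ld.core_ri
        dn[core] = ld.core_dn
        dn[shell] = ld.shell_dn
        if with_labels:
            labels[core] = 4
            labels[shell] = 5
    if texture is not None and texture.amplitude > 0:
        ri[cell] += texture(zc, yc, xc)[cell]
    if with_labels:
        return ri, dn, labels
    return ri, dn


def _reference_coords(shape, spacing):
    dz, dy, dx = spacing
    z = np.arange(shape[0], dtype=np.float64) * dz
    y = np.arange(shape[1], dtype=np.float64) * dy
    x = np.arange(shape[2], dtype=np.float64) * dx
    return np.meshgrid(z, y, x, indexing="ij")


def _misaligned_coords(spec: PhantomSpec):
    """Physical coordinates at which the moved sample is observed.

    The misaligned volume M satisfies M(p) = scene(T^-1(p)) for the rigid
    content transform T plus the integer axial content shift, i.e. the same
    convention as warping with :func:`psht.register.apply_rigid_to_volume`.
    """
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    if abs(dy - dx) > 1e-12 and spec.misalign_rotation_deg != 0:
        raise ValueError("in-plane rotation requires isotropic lateral spacing")
    zi = np.arange(nz, dtype=np.float64) - spec.misalign_axial_slices
    yi, xi = np.meshgrid(
        np.arange(ny, dtype=np.float64), np.arange(nx, dtype=np.float64), indexing="ij"
    )
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    sy, sx = spec.misalignment.source_coords(yi, xi, (cy, cx))
    zc = (zi * dz)[:, None, None] * np.ones((1, ny, nx))
    yc = (sy * dy)[None, :, :] * np.ones((nz, 1, 1))
    xc = (sx * dx)[None, :, :] * np.ones((nz, 1, 1))
    return zc, yc, xc


# ---------------------------------------------------------------------------
# organelle placement
# ---------------------------------------------------------------------------


def _fits_inside(center, radius, ell_center, semiaxes, margin=0.0):
    shrunk = tuple(max(a - radius - margin, 1e-6) for a in semiaxes)
    return _ellipsoid_value(
        np.array(center[0]), np.array(center[1]), np.array(center[2]), ell_center, shrunk
    ) <= 1.0


def _outside(center, radius, ell_center, semiaxes, margin=0.0):
    grown = tuple(a + radius + margin for a in semiaxes)
    return _ellipsoid_value(
        np.array(center[0]), np.array(center[1]), np.array(center[2]), ell_center, grown
    ) > 1.0


def _sample_nucleoli(spec: PhantomSpec, rng) -> List[Tuple[Tuple[float, float, float], float]]:
    out = []
    lo, hi = spec.nucleolus_radius_range_um
    for _ in range(spec.nucleolus_count):
        for _attempt in range(500):
            r = rng.uniform(lo, hi)
            c = tuple(
                rng.uniform(cc - aa, cc + aa)
                for cc, aa in zip(spec.nucleus_center_um, spec.nucleus_semiaxes_um)
            )
            if not _fits_inside(c, r, spec.nucleus_center_um, spec.nucleus_semiaxes_um, margin=0.1):
                continue
            if all(
                np.linalg.norm(np.subtract(c, c2)) >= r + r2 + 0.1 for c2, r2 in out
            ):
                out.append((c, r))
                break
        else:
            raise ValueError("could not place nucleolus inside the nucleus")
    return out


def _sample_lds(spec: PhantomSpec, rng) -> Tuple[LDRecord, ...]:
    law = spec.ld_sampling
    if law is None:
        return ()
    lo_n, hi_n = law.count_range
    n = int(rng.integers(lo_n, hi_n + 1))
    placed: List[LDRecord] = []
    for _ in range(n):
        for _attempt in range(500):
            d = rng.uniform(*law.diameter_range_um)
            r = d / 2.0
            c = tuple(
                rng.uniform(cc - aa, cc + aa)
                for cc, aa in zip(spec.center_um, spec.cytosol_semiaxes_um)
            )
            if not _fits_inside(c, r, spec.center_um, spec.cytosol_semiaxes_um, margin=0.1):
                continue
            if not _outside(c, r, spec.nucleus_center_um, spec.nucleus_semiaxes_um, margin=0.05):
                continue
            if not all(
                np.linalg.norm(np.subtract(c, ld.center_um)) >= r + ld.radius_um + 0.1
                for ld in placed
            ):
                continue
            strong = rng.uniform() < law.birefringent_fraction
            placed.append(
                LDRecord(
                    center_um=c,
                    radius_um=r,
                    core_ri=float(rng.uniform(*law.core_ri_range)),
                    core_dn=law.core_dn if strong else law.weak_core_dn,
                    shell_dn=law.shell_dn if strong else law.weak_shell_dn,
                    shell_thickness_um=law.shell_thickness_um,
                    birefringent=strong,
                )
            )
            break
        else:
            raise ValueError(
                f"could not place LD {len(placed) + 1}/{n}: organelle does not fit in the grid"
            )
    return tuple(placed)


def _validate_explicit_lds(spec: PhantomSpec) -> Tuple[LDRecord, ...]:
    dz, dy, dx = spec.spacing
    extent = (spec.shape[0] * dz, spec.shape[1] * dy, spec.shape[2] * dx)
    for ld in spec.lds:
        for c, e in zip(ld.center_um, extent):
            if c - ld.radius_um < 0 or c + ld.radius_um > e:
                raise ValueError(f"LD at {ld.center_um} does not fit in the grid")
    tol = spec.ld_overlap_tolerance
    for i, a in enumerate(spec.lds):
        for b in spec.lds[i + 1 :]:
            gap = np.linalg.norm(np.subtract(a.center_um, b.center_um))
            if gap < (a.radius_um + b.radius_um) * (1.0 - tol):
                raise ValueError("overlapping LDs beyond the configured tolerance")
    return spec.lds


def rasterize_lds(
    lds: Sequence[LDRecord],
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
) -> Tuple[Mask3D, Mask3D]:
    """Voxelize per-LD records into (core, shell) masks on the reference grid.

    This is the same evaluation used during generation, so truth masks are
    reproducible from the records alone.
    """
    zc, yc, xc = _reference_coords(shape, spacing)
    core = np.zeros(shape, dtype=bool)
    shell = np.zeros(shape, dtype=bool)
    for ld in lds:
        inside = _ellipsoid_value(zc, yc, xc, ld.center_um, (ld.radius_um,) * 3) <= 1.0
        r_core = max(ld.radius_um - ld.shell_thickness_um, 1e-9)
        c = _ellipsoid_value(zc, yc, xc, ld.center_um, (r_core,) * 3) <= 1.0
        core |= c & inside
        shell |= inside & ~c
    core &= ~shell  # paint order: shell wins at shared voxels (there are none)
    return Mask3D(core, spacing), Mask3D(shell, spacing)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_cell(spec: PhantomSpec) -> Tuple[PolarizationPair, Volume3D, PhantomTruth]:
    """Generate one synthetic cell: polarization pair, fluorescence volume,
    and ground truth.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nucleoli = _sample_nucleoli(spec, rng) if spec.nucleolus_count else []
    lds = _validate_explicit_lds(spec) if spec.lds is not None else _sample_lds(spec, rng)
    texture = _FourierTexture(
        spec.texture_amplitude, spec.texture_wavelength_um, spec.texture_components, rng
    )

    zc, yc, xc = _reference_coords(spec.shape, spec.spacing)
    ri_ref, dn_ref, labels = _evaluate_scene(
        spec, lds, nucleoli, zc, yc, xc, texture=texture, with_labels=True
    )

    if spec.is_misaligned:
        zm, ym, xm = _misaligned_coords(spec)
        ri_m, dn_m = _evaluate_scene(spec, lds, nucleoli, zm, ym, xm, texture=texture)
        ri_h = ri_m - dn_m
    else:
        ri_h = ri_ref - dn_ref
    ri_v = ri_ref.copy()

    if spec.noise_sigma > 0:
        ri_v = ri_v + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        ri_h = ri_h + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        np.clip(ri_v, 1.30, 1.45, out=ri_v)
        np.clip(ri_h, 1.30, 1.45, out=ri_h)

    vertical = Volume3D(ri_v, spec.spacing, "ri_vertical")
    horizontal = Volume3D(ri_h, spec.spacing, "ri_horizontal")
    state = "raw" if spec.is_misaligned else "fully_aligned"
    pair = PolarizationPair(
        vertical,
        horizontal,
        state=state,
        lateral_transform=None if spec.is_misaligned else RigidTransform2D.identity(),
        axial_shift=None if spec.is_misaligned else AxialShift(0),
    )

    # fluorescence: blurred LD mask + diffuse background (+ shot noise)
    dz, dy, dx = spec.spacing
    ld_mask = (labels >= 4).astype(np.float64)
    sig = (
        spec.fluor_sigma_axial_um / dz,
        spec.fluor_sigma_lateral_um / dy,
        spec.fluor_sigma_lateral_um / dx,
    )
    fl = ndimage.gaussian_filter(ld_mask, sigma=sig) + spec.fluor_background
    if spec.fluor_photons and spec.noise_sigma > 0:
        fl = rng.poisson(fl * spec.fluor_photons).astype(np.float64) / spec.fluor_photons
    fluorescence = Volume3D(fl, spec.spacing, "fluorescence")

    masks = {
        "cytosol": Mask3D(labels == 1, spec.spacing),
        "nucleus": Mask3D(labels == 2, spec.spacing),
        "nucleolus": Mask3D(labels == 3, spec.spacing),
        "ld_core": Mask3D(labels == 4, spec.spacing),
        "ld_shell": Mask3D(labels == 5, spec.spacing),
    }
    ld_voxels = labels >= 4
    ld_ri_threshold = float(ri_ref[ld_voxels].min()) if ld_voxels.any() else math.nan
    truth = PhantomTruth(
        masks=masks,
        lds=tuple(lds),
        misalign_lateral=spec.misalignment,
        misalign_axial=AxialShift(spec.misalign_axial_slices),
        ld_ri_threshold=ld_ri_threshold,
        birefringence=Volume3D(dn_ref, spec.spacing, "birefringence"),
    )
    return pair, fluorescence, truth


def generate_cohort(
    spec_a: PhantomSpec,
    spec_b: PhantomSpec,
    n_per_class: int,
    seed: int = 0,
    labels: Tuple[str, str] = ("class_a", "class_b"),
) -> List[LabeledCell]:
    """Generate ``2 * n_per_class`` labeled cells with per-cell seed jitter.

    Each cell re-draws its LD count, sizes and positions from its class
    sampling law, so class-conditional features vary cell to cell.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    cells: List[LabeledCell] = []
    for label, spec in zip(labels, (spec_a, spec_b)):
        for _ in range(n_per_class):
            child = int(rng.integers(0, 2**31 - 1))
            pair, fluor, truth = generate_cell(replace(spec, seed=child))
            cells.append(LabeledCell(label, pair, fluor, truth, child))
    return cells


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------


def healthy_spec(**overrides) -> PhantomSpec:
    """Preset emulating a healthy (low lipid-ordering) cell.

    Few, small droplets; only ~20% of them carry decrements above the fixed
    0.01 birefringence threshold.  Combined with :func:`cancer_spec` this
    yields roughly 3-fold total LD volume and roughly 17-fold birefringent
    volume between the two classes.
    """
    base = dict(
        shape=(48, 96, 96),
        spacing=(0.2, 0.1, 0.1),
        cytosol_semiaxes_um=(3.4, 4.2, 3.4),
        nucleus_semiaxes_um=(1.5, 1.8, 1.4),
        nucleus_center_offset_um=(0.2, 0.5, -0.4),
        nucleolus_count=1,
        nucleolus_radius_range_um=(0.3, 0.5),
        ld_sampling=LDSampling(
            count_range=(6, 10),
            diameter_range_um=(0.6, 1.2),
            birefringent_fraction=0.2,
        ),
    )
    base.update(overrides)
    return PhantomSpec(**base)


def cancer_spec(**overrides) -> PhantomSpec:
    """Preset emulating a lipid-loaded cancer cell: more and larger droplets,
    all strongly birefringent."""
    base = dict(
        shape=(48, 96, 96),
        spacing=(0.2, 0.1, 0.1),
        cytosol_semiaxes_um=(3.4, 4.2, 3.4),
        nucleus_semiaxes_um=(1.5, 1.8, 1.4),
        nucleus_center_offset_um=(0.2, 0.5, -0.4),
        nucleolus_count=1,
        nucleolus_radius_range_um=(0.3, 0.5),
        ld_sampling=LDSampling(
            count_range=(9, 13),
            diameter_range_um=(0.8, 1.6),
            birefringent_fraction=1.0,
        ),
    )
    base.update(overrides)
    return PhantomSpec(**base)
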