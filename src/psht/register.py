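"""Alignment of the two polarization volumes.

The two refractive-index volumes of a polarization pair are acquired a few
seconds apart, during which the sample holder can drift: an in-plane rigid
displacement (rotation + translation, no scaling) plus a possible integer
slice offset along the optical axis.  Alignment proceeds in two stages:

1. *Lateral*: a 2-D rigid transform is estimated between the z-axis
   maximum-intensity projections of the two volumes (restricted to an ROI
   around the cell) and applied uniformly to every slice of the moving
   volume.  Rotation is found by exhaustive coarse-to-fine search scored
   with normalized mutual information (or mean squares); at each candidate
   rotation the translation is recovered by subpixel phase correlation.
2. *Axial*: a handful of randomly sampled reference slices are matched
   against candidate moving slices by mutual information; the mean best
   shift, rounded to the nearest integer, is the axial offset.

The vertical-polarization volume is the reference throughout; the
horizontal volume is moved.  Recovered transforms follow the *inverse*
convention: if the moving content was displaced by ``+t``, the recovered
translation is ``-t`` (the correction to apply).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.metrics import normalized_mutual_information
from skimage.registration import phase_cross_correlation

from .volumes import ROI, Volume3D, mip

__all__ = [
    "RigidTransform2D",
    "AxialShift",
    "PolarizationPair",
    "RegistrationError",
    "align_lateral",
    "align_axial",
    "register_pair",
    "apply_rigid_2d",
    "apply_rigid_to_volume",
    "apply_alignment",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid transform: rotate content by ``rotation`` degrees about
    the lateral image centre, then translate content by ``(ty, tx)`` voxels.

    No scaling or shear.  ``identity()`` is the do-nothing transform.
    """

    rotation: float = 0.0
    translation: Tuple[float, float] = (0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, (0.0, 0.0))

    def matrix(self) -> np.ndarray:
        """Rotation matrix acting on (y, x) offsets."""
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])

    def inverse(self) -> "RigidTransform2D":
        rinv = RigidTransform2D(-self.rotation).matrix()
        t = np.asarray(self.translation)
        return RigidTransform2D(-self.rotation, tuple(-(rinv @ t)))

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``first`` then ``self``."""
        t = self.matrix() @ np.asarray(first.translation) + np.asarray(self.translation)
        return RigidTransform2D(self.rotation + first.rotation, tuple(t))

    def source_coords(self, yy: np.ndarray, xx: np.ndarray, center: Tuple[float, float]):
        """Map output voxel coords to input coords (inverse mapping).

        For output point p the warped image takes the value of the input at
        ``R^-1 (p - t - c) + c``.
        """
        cy, cx = center
        ty, tx = self.translation
        rinv = RigidTransform2D(-self.rotation).matrix()
        dy = yy - cy - ty
        dx = xx - cx - tx
        sy = rinv[0, 0] * dy + rinv[0, 1] * dx + cy
        sx = rinv[1, 0] * dy + rinv[1, 1] * dx + cx
        return sy, sx


@dataclass(frozen=True)
class AxialShift:
    """Integer slice offset of the moving volume relative to the reference."""

    shift: int

    def __post_init__(self):
        if int(self.shift) != self.shift:
            raise ValueError("axial shift must be integer-valued")
        object.__setattr__(self, "shift", int(self.shift))


@dataclass(frozen=True)
class PolarizationPair:
    """The vertical/horizontal RI volumes of one cell plus registration state."""

    vertical: Volume3D
    horizontal: Volume3D
    state: str = "raw"
    lateral_transform: Optional[RigidTransform2D] = None
    axial_shift: Optional[AxialShift] = None
    crop: Optional[ROI] = None

    def __post_init__(self):
        if self.state not in ("raw", "laterally_aligned", "fully_aligned"):
            raise ValueError(f"unknown registration state {self.state!r}")
        if self.vertical.spacing != self.horizontal.spacing:
            raise ValueError("polarization volumes must share voxel spacing")
        if self.state == "fully_aligned" and self.vertical.shape != self.horizontal.shape:
            raise ValueError("fully aligned pair must have identical shapes")


# ---------------------------------------------------------------------------
# transform application
# ---------------------------------------------------------------------------


def _lateral_center(shape_yx: Tuple[int, int]) -> Tuple[float, float]:
    return ((shape_yx[0] - 1) / 2.0, (shape_yx[1] - 1) / 2.0)


def apply_rigid_2d(
    image: np.ndarray, transform: RigidTransform2D, fill: float = 0.0
) -> np.ndarray:
    """Apply an in-plane rigid transform to a 2-D image (linear interpolation)."""
    yy, xx = np.meshgrid(
        np.arange(image.shape[0], dtype=float),
        np.arange(image.shape[1], dtype=float),
        indexing="ij",
    )
    sy, sx = transform.source_coords(yy, xx, _lateral_center(image.shape))
    return ndimage.map_coordinates(
        image.astype(float), [sy, sx], order=1, mode="constant", cval=fill
    )


def _valid_region_2d(shape_yx: Tuple[int, int], transform: RigidTransform2D) -> np.ndarray:
    """Boolean 2-D map of pixels whose warped value uses only in-field data."""
    ones = np.ones(shape_yx)
    w = apply_rigid_2d(ones, transform, fill=0.0)
    return w > 1.0 - 1e-9


def _largest_valid_box(valid: np.ndarray) -> Tuple[int, int, int, int]:
    """Greedy shrink of the bounding box until every pixel inside is valid."""
    y0, y1, x0, x1 = 0, valid.shape[0], 0, valid.shape[1]
    while y1 - y0 > 1 and x1 - x0 > 1:
        box = valid[y0:y1, x0:x1]
        if box.all():
            break
        borders = {
            "top": np.count_nonzero(~box[0, :]),
            "bottom": np.count_nonzero(~box[-1, :]),
            "left": np.count_nonzero(~box[:, 0]),
            "right": np.count_nonzero(~box[:, -1]),
        }
        worst = max(borders, key=borders.get)
        if borders[worst] == 0:
            # invalid pixels strictly interior: cannot happen for rigid warps
            raise RegistrationError("no valid rectangular crop found")
        if worst == "top":
            y0 += 1
        elif worst == "bottom":
            y1 -= 1
        elif worst == "left":
            x0 += 1
        else:
            x1 -= 1
    if not valid[y0:y1, x0:x1].all():
        raise RegistrationError("no valid rectangular crop found")
    return y0, y1, x0, x1


def apply_rigid_to_volume(
    volume: Volume3D, transform: RigidTransform2D, fill: Optional[float] = None
) -> Volume3D:
    """Apply one 2-D rigid transform uniformly to every slice of a volume."""
    dz, dy, dx = volume.spacing
    if abs(dy - dx) > 1e-9:
        raise RegistrationError("in-plane rotation requires isotropic lateral spacing")
    if fill is None:
        fill = float(np.min(volume.data))
    out = np.empty_like(volume.data, dtype=float)
    for iz in range(volume.shape[0]):
        out[iz] = apply_rigid_2d(volume.data[iz], transform, fill=fill)
    return volume.with_data(out)


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------


def _score(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if metric == "nmi":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return -np.inf  # a constant image carries no mutual information
        return float(normalized_mutual_information(a, b, bins=100))
    if metric == "ms":
        return -float(np.mean((a - b) ** 2))
    raise ValueError(f"unknown metric {metric!r}; use 'nmi' or 'ms'")


# ---------------------------------------------------------------------------
# lateral alignment
# ---------------------------------------------------------------------------


def align_lateral(
    reference: Volume3D,
    moving: Volume3D,
    roi: Optional[ROI] = None,
    metric: str = "nmi",
    rotation_range: float = 5.0,
    coarse_step: float = 0.5,
    fine_step: float = 0.05,
    upsample: int = 50,
    denoise_sigma: float = 1.0,
) -> Tuple[RigidTransform2D, Volume3D, ROI]:
    """Estimate and apply the in-plane rigid transform aligning ``moving``
    to ``reference``.

    The transform is estimated on the two z-MIPs restricted to ``roi`` and
    applied identically to every slice.  Both volumes are lightly Gaussian
    smoothed in 3-D (``denoise_sigma`` voxels) before projection: maximum
    projection amplifies voxel noise into an extreme-value bias, and on
    noise-free piecewise-constant volumes intensity metrics are biased
    toward near-integer warps (which interpolate less); pre-smoothing
    removes both effects without moving edges.  The transform itself is
    applied to the raw volume.  Returns the recovered transform, the warped
    moving volume (uncropped), and the lateral ROI of the mutually valid
    region after warping.
    """
    if reference.shape != moving.shape:
        raise RegistrationError(
            f"shape mismatch: {reference.shape} vs {moving.shape}"
        )
    if reference.spacing != moving.spacing:
        raise RegistrationError("spacing mismatch between polarization volumes")
    if roi is None:
        roi = ROI.full(reference.shape)
    roi.validate(reference.shape)
    if denoise_sigma > 0:
        ref_s = reference.with_data(ndimage.gaussian_filter(reference.data, denoise_sigma))
        mov_s = moving.with_data(ndimage.gaussian_filter(moving.data, denoise_sigma))
    else:
        ref_s, mov_s = reference, moving
    ref_mip = mip(ref_s, "z", roi)
    mov_mip = mip(mov_s, "z", roi)
    if ref_mip.size < 16:
        raise RegistrationError("degenerate ROI: too few pixels for registration")
    fill = float(np.min(mov_mip))

    def evaluate(rot: float) -> Tuple[float, Tuple[float, float]]:
        rotated = apply_rigid_2d(mov_mip, RigidTransform2D(rot), fill=fill)
        shift, _, _ = phase_cross_correlation(
            ref_mip, rotated, upsample_factor=upsample, normalization=None
        )
        cand = RigidTransform2D(rot, (float(shift[0]), float(shift[1])))
        warped = apply_rigid_2d(mov_mip, cand, fill=fill)
        return _score(ref_mip, warped, metric), cand.translation

    best_rot, best_score, best_t = 0.0, -np.inf, (0.0, 0.0)
    coarse = np.arange(-rotation_range, rotation_range + 1e-9, coarse_step)
    for rot in coarse:
        s, t = evaluate(float(rot))
        if s > best_score:
            best_rot, best_score, best_t = float(rot), s, t
    if abs(abs(best_rot) - rotation_range) < 1e-9 and rotation_range > 0:
        raise RegistrationError(
            f"lateral registration did not converge: best rotation {best_rot:.2f} deg "
            f"at search boundary (metric={best_score:.4f})"
        )
    fine = np.arange(best_rot - coarse_step, best_rot + coarse_step + 1e-9, fine_step)
    for rot in fine:
        s, t = evaluate(float(rot))
        if s > best_score:
            best_rot, best_score, best_t = float(rot), s, t

    transform = RigidTransform2D(best_rot, best_t)
    aligned = apply_rigid_to_volume(moving, transform)
    valid = _valid_region_2d(reference.shape[1:], transform)
    y0, y1, x0, x1 = _largest_valid_box(valid)
    crop = ROI((0, reference.shape[0]), (y0, y1), (x0, x1))
    return transform, aligned, crop


# ---------------------------------------------------------------------------
# axial alignment
# ---------------------------------------------------------------------------


def align_axial(
    reference: Volume3D,
    moving: Volume3D,
    n_slices: int = 5,
    seed: int = 0,
    max_shift: int = 15,
    metric: str = "nmi",
) -> AxialShift:
    """Estimate the integer slice offset of ``moving`` relative to
    ``reference``.

    ``n_slices`` reference slices are drawn without replacement (seeded)
    from the central 80% of the z range, restricted to slices that actually
    contain structure (an empty medium-only slice scores every candidate
    shift equally well up to noise and would contribute a random shift);
    for each, the best-matching moving slice within ``±max_shift`` is found
    by mutual information.  The mean per-slice shift is rounded to the
    nearest integer (half away from zero).
    """
    nz = reference.shape[0]
    if nz < n_slices:
        raise RegistrationError(f"volume has {nz} slices, fewer than n_slices={n_slices}")
    lo = int(math.floor(0.1 * nz))
    hi = int(math.ceil(0.9 * nz))
    candidates = np.arange(lo, hi)
    if len(candidates) < n_slices:
        candidates = np.arange(nz)
    # structure score: std of the lightly smoothed slice; medium-only slices
    # retain only attenuated voxel noise and fall well below cell slices
    scores = np.array(
        [float(np.std(ndimage.gaussian_filter(reference.data[iz], 1.0))) for iz in candidates]
    )
    informative = scores >= 0.3 * scores.max()
    if informative.any():
        candidates = candidates[informative]
    rng = np.random.default_rng(seed)
    order = rng.permutation(candidates)

    shifts = []
    for iz in order:
        if len(shifts) >= n_slices:
            break
        if np.ptp(reference.data[iz]) == 0:
            continue  # empty (constant) slice carries no alignment information
        best_s, best_score = 0, -np.inf
        # scan from zero outward: exact score ties (possible on noise-free
        # piecewise-constant slices) resolve to the smallest displacement
        for s in sorted(range(-max_shift, max_shift + 1), key=lambda v: (abs(v), v < 0)):
            jz = iz + s
            if jz < 0 or jz >= moving.shape[0]:
                continue
            sc = _score(reference.data[iz], moving.data[jz], metric)
            if sc > best_score:
                best_s, best_score = s, sc
        if not np.isfinite(best_score):
            continue
        shifts.append(best_s)
    if not shifts:
        raise RegistrationError("no informative slices found for axial alignment")
    mean = float(np.mean(shifts))
    # round half away from zero, e.g. mean 3.5 -> 4, -3.5 -> -4
    rounded = int(math.copysign(math.floor(abs(mean) + 0.5), mean))
    return AxialShift(rounded)


def round_half_away(mean_shift: float) -> int:
    """Rounding rule used for the mean axial shift (half away from zero)."""
    return int(math.copysign(math.floor(abs(mean_shift) + 0.5), mean_shift))


# ---------------------------------------------------------------------------
# full procedure
# ---------------------------------------------------------------------------


def _axial_overlap(nz: int, shift: int) -> Tuple[int, int]:
    """Corrected-frame z range where moving slice ``z + shift`` exists."""
    z0 = max(0, -shift)
    z1 = nz - max(0, shift)
    if z1 <= z0:
        raise RegistrationError(f"axial shift {shift} leaves no overlapping slices")
    return z0, z1


def apply_alignment(
    moving: Volume3D,
    lateral_transform: RigidTransform2D,
    axial_shift: AxialShift,
    crop: ROI,
) -> Volume3D:
    """Apply recorded transforms (lateral warp, crop, axial shift) to a raw
    moving volume.  ``register_pair`` uses exactly this function, so replaying
    the recorded transforms on the raw volume reproduces the aligned volume
    bit-for-bit.
    """
    warped = apply_rigid_to_volume(moving, lateral_transform)
    cropped = crop.extract(warped.data)
    z0, z1 = _axial_overlap(cropped.shape[0], axial_shift.shift)
    shifted = cropped[z0 + axial_shift.shift : z1 + axial_shift.shift]
    return moving.with_data(shifted)


def reference_crop(reference: Volume3D, axial_shift: AxialShift, crop: ROI) -> Volume3D:
    """Crop the (unmoved) reference volume to the mutually valid region."""
    cropped = crop.extract(reference.data)
    z0, z1 = _axial_overlap(cropped.shape[0], axial_shift.shift)
    return reference.with_data(cropped[z0:z1])


def register_pair(
    pair: PolarizationPair,
    roi: Optional[ROI] = None,
    seed: int = 0,
    metric: str = "nmi",
    rotation_range: float = 5.0,
    max_axial_shift: int = 15,
) -> PolarizationPair:
    """Full registration: vertical volume is the reference; the horizontal
    volume is laterally then axially aligned; both are cropped to the
    mutually valid region.
    """
    if pair.state != "raw":
        raise RegistrationError(f"pair already in state {pair.state!r}")
    if pair.vertical.shape != pair.horizontal.shape:
        raise RegistrationError(
            f"shape mismatch: vertical {pair.vertical.shape} vs "
            f"horizontal {pair.horizontal.shape}"
        )
    transform, h_warped, crop = align_lateral(
        pair.vertical, pair.horizontal, roi=roi, metric=metric,
        rotation_range=rotation_range,
    )
    v_crop = pair.vertical.with_data(crop.extract(pair.vertical.data))
    h_crop = h_warped.with_data(crop.extract(h_warped.data))
    shift = align_axial(
        v_crop, h_crop, seed=seed, max_shift=max_axial_shift, metric=metric
    )
    vertical = reference_crop(pair.vertical, shift, crop)
    horizontal = apply_alignment(pair.horizontal, transform, shift, crop)
    return PolarizationPair(
        vertical=vertical,
        horizontal=horizontal,
        state="fully_aligned",
        lateral_transform=transform,
        axial_shift=shift,
        crop=crop,
    )
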