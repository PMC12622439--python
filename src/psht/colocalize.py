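"""RI-threshold optimization by mask colocalization against fluorescence.

RI-only droplet segmentation needs a cell-line- and condition-specific
threshold.  That threshold is calibrated here against a labeled reference:
binary maximum-intensity projections (MIPs) of the fluorescence droplet
channel and of the RI volume are compared with Manders overlap
coefficients while the RI threshold is swept over a fine grid
(1.3650 … 1.3850 in steps of 0.0001 by default),

    M1 = |N_ref ∩ N_ri| / |N_ref|     (fraction of labeled droplet pixels
                                        recovered by the RI mask)
    M2 = |N_ref ∩ N_ri| / |N_ri|      (fraction of RI-mask pixels confirmed
                                        by the label).

As the threshold rises, non-droplet high-RI structures (e.g. nucleoli)
drop out of the RI mask and M2 climbs to a plateau; the smallest grid RI
at the plateau onset is the optimal threshold ``RI_th``.  The sweep
operates on MIPs, which consolidate the droplet content of the stack into
a single frame and suppress the axial blur of wide-field fluorescence.

Thresholding is inclusive (a pixel with MIP value equal to the threshold
is classified as droplet), so a structure at RI exactly t drops out of the
mask only once the threshold passes t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .volumes import ROI, Mask2D, Volume3D, mip

__all__ = [
    "DEFAULT_RI_GRID",
    "ColocalizationCurve",
    "binarize_fluorescence_mip",
    "binarize_ri_mip",
    "manders",
    "sweep_ri_threshold",
    "select_ri_th",
    "default_ri_grid",
]


def default_ri_grid(start: float = 1.3650, stop: float = 1.3850, step: float = 0.0001):
    n = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, n), 10)


DEFAULT_RI_GRID = default_ri_grid()


@dataclass(frozen=True)
class ColocalizationCurve:
    """M1/M2 versus the RI-threshold grid plus the selected threshold.

    Grid points where a Manders denominator was empty hold NaN (flagged
    missing, never zero).  ``plateau_found`` is False when no plateau
    satisfied the selection rule and the grid maximum of M2 was returned
    instead.
    """

    ri: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    dm2_dri: np.ndarray
    ri_th: float = np.nan
    m1_at_th: float = np.nan
    m2_at_th: float = np.nan
    plateau_found: bool = True

    def __post_init__(self):
        ri = np.asarray(self.ri, dtype=float)
        if len(ri) < 2:
            raise ValueError("grid must have at least 2 points")
        steps = np.diff(ri)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("RI grid must be strictly increasing with uniform step")
        for name in ("m1", "m2", "dm2_dri"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != ri.shape:
                raise ValueError(f"{name} must match the grid length")
            object.__setattr__(self, name, arr)
        finite = self.m1[np.isfinite(self.m1)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("M1 out of [0, 1]")
        finite = self.m2[np.isfinite(self.m2)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("M2 out of [0, 1]")
        object.__setattr__(self, "ri", ri)

    def with_selection(self, ri_th: float, flagged: bool) -> "ColocalizationCurve":
        i = int(np.argmin(np.abs(self.ri - ri_th)))
        return ColocalizationCurve(
            self.ri, self.m1, self.m2, self.dm2_dri,
            ri_th=float(self.ri[i]), m1_at_th=float(self.m1[i]),
            m2_at_th=float(self.m2[i]), plateau_found=not flagged,
        )


def binarize_fluorescence_mip(
    fluor: Volume3D,
    intensity_threshold: float,
    roi: Optional[ROI] = None,
) -> Mask2D:
    """Threshold the z-MIP of the fluorescence volume into the droplet
    reference mask.  An empty result is reported with a warning, not fatal."""
    proj = mip(fluor, "z", roi)
    lo, hi = float(proj.min()), float(proj.max())
    if not (lo <= intensity_threshold <= hi) and intensity_threshold > hi:
        warnings.warn(
            f"fluorescence threshold {intensity_threshold} above image maximum {hi}: empty mask"
        )
    mask = proj >= intensity_threshold
    if not mask.any():
        warnings.warn("fluorescence reference mask is empty")
    return Mask2D(mask)


def binarize_ri_mip(
    ri: Volume3D,
    ri_threshold: float,
    roi: Optional[ROI] = None,
) -> Mask2D:
    """Binary mask of the z-MIP of the RI volume at an inclusive threshold."""
    if not (1.30 <= ri_threshold <= 1.45):
        raise ValueError(f"RI threshold {ri_threshold} outside plausible range [1.30, 1.45]")
    proj = mip(ri, "z", roi)
    return Mask2D(proj >= ri_threshold)


def manders(reference: Mask2D, test: Mask2D) -> Tuple[float, float]:
    """Manders overlap coefficients of two binary masks.

    Returns ``(M1, M2)``; an undefined coefficient (empty denominator) is
    returned as NaN.
    """
    if reference.shape != test.shape:
        raise ValueError(f"mask shape mismatch: {reference.shape} vs {test.shape}")
    n_ref = reference.count()
    n_test = test.count()
    overlap = int(np.count_nonzero(reference.data & test.data))
    m1 = overlap / n_ref if n_ref else np.nan
    m2 = overlap / n_test if n_test else np.nan
    return m1, m2


def sweep_ri_threshold(
    ri: Volume3D,
    reference: Mask2D,
    grid: Optional[np.ndarray] = None,
    roi: Optional[ROI] = None,
    rel_eps: float = 0.05,
    window: int = 10,
) -> ColocalizationCurve:
    """Compute M1/M2 over the RI-threshold grid and select ``RI_th``.

    dM2/dRI uses central differences (one-sided at the grid ends).
    """
    if grid is None:
        grid = DEFAULT_RI_GRID
    grid = np.asarray(grid, dtype=float)
    if reference.count() == 0:
        raise ValueError("reference mask is empty")
    proj = mip(ri, "z", roi)
    if proj.shape != reference.shape:
        raise ValueError("reference mask shape does not match the RI MIP")
    ref = reference.data
    n_ref = reference.count()
    m1 = np.empty(len(grid))
    m2 = np.empty(len(grid))
    for i, t in enumerate(grid):
        test = proj >= t
        n_test = int(np.count_nonzero(test))
        overlap = int(np.count_nonzero(ref & test))
        m1[i] = overlap / n_ref
        m2[i] = overlap / n_test if n_test else np.nan
    dm2 = _gradient_with_nan(m2, grid)
    curve = ColocalizationCurve(grid, m1, m2, dm2)
    return select_ri_th(curve, rel_eps=rel_eps, window=window)


def _gradient_with_nan(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """np.gradient on the finite prefix; NaN propagated elsewhere."""
    out = np.full_like(y, np.nan)
    finite = np.isfinite(y)
    if finite.sum() >= 2:
        idx = np.where(finite)[0]
        # the sweep produces NaN only where the mask is empty (high thresholds),
        # i.e. a contiguous suffix; gradient over the finite run is well defined
        lo, hi = idx[0], idx[-1]
        out[lo : hi + 1] = np.gradient(y[lo : hi + 1], x[lo : hi + 1])
    return out


def select_ri_th(
    curve: ColocalizationCurve, rel_eps: float = 0.05, window: int = 10
) -> ColocalizationCurve:
    """Select the smallest grid RI at the onset of the M2 plateau.

    A grid point qualifies when (a) its M2 is within ``rel_eps`` (relative)
    of the grid maximum of M2 and (b) |dM2/dRI| stays below
    ``rel_eps * max|dM2/dRI|`` for the next ``window`` grid points — i.e.
    the curve has stopped rising.  If no point qualifies, the M2 argmax is
    returned with the ``plateau_found`` flag cleared.
    """
    m2, dm2 = curve.m2, curve.dm2_dri
    finite = np.isfinite(m2)
    if not finite.any():
        raise ValueError("M2 undefined everywhere: empty masks at all thresholds")
    m2_max = np.nanmax(m2)
    d_max = np.nanmax(np.abs(dm2)) if np.isfinite(dm2).any() else 0.0
    # absolute floor: float rounding of the grid leaves ~1e-13 jitter in the
    # gradient of an exactly flat curve, which a purely relative tolerance chases
    d_tol = max(rel_eps * d_max, 1e-9)
    n = len(m2)
    for i in range(n):
        if not finite[i] or m2[i] < m2_max * (1 - rel_eps):
            continue
        upper = min(i + window, n - 1)
        future = dm2[i + 1 : upper + 1]
        future = future[np.isfinite(future)]
        if future.size == 0:
            continue  # no lookahead left: a plateau cannot be established here
        if np.any(np.abs(future) > d_tol):
            continue
        return curve.with_selection(float(curve.ri[i]), flagged=False)
    warnings.warn("no M2 plateau found; returning the grid maximum of M2 (flagged)")
    i = int(np.nanargmax(m2))
    return curve.with_selection(float(curve.ri[i]), flagged=True)
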