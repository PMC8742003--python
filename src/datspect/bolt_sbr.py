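"""Bolt (Southampton) specific binding ratio analysis.

The SBR deliberately uses a striatal VOI much larger than the striatum so
that blurred (partial-volume) striatal counts are captured in full:

    SBR = (Cs_total / Cr - Vs_VOI) / Vs

where ``Cs_total`` is the total count in the striatal VOI, ``Cr`` the mean
count concentration (counts/cm3) in a reference region, ``Vs_VOI`` the VOI
volume and ``Vs`` the assumed striatal volume.  The reference region is
grown automatically: voxels outside both striatal VOIs whose (masked-
smoothed) value reaches half of the non-striatal maximum, pulled 20 mm
inward from the region borders to avoid partial-volume margins.

The nominal bilateral VOI and striatal volumes (141.56 and 17.92 cm3) are
split evenly between the sides since each side is analysed separately and
the two SBRs are averaged.  In the SBR formula the per-side ``Vs_VOI`` is
the achieved (voxelised) VOI volume, so the identity SBR = 0 on a uniform
image holds exactly on a discrete grid; the nominal volume serves as the
placement target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .atrophy import erode_mask
from .fbp_recon import ReconVolume

__all__ = [
    "AnalysisParams",
    "StriatalVOI",
    "BoltResult",
    "place_striatal_vois",
    "build_reference_region",
    "smooth_within_mask",
    "compute_sbr",
    "analyze",
    "striatal_centroids_mm",
]


class PlacementError(ValueError):
    """A striatal VOI does not fit inside the image."""


class AnalysisError(RuntimeError):
    """Reference region construction failed."""


@dataclass(frozen=True)
class AnalysisParams:
    """Bolt analysis parameters (volumes are bilateral totals in cm3)."""

    vs_voi_cm3: float = 141.56
    vs_cm3: float = 17.92
    reference_threshold: float = 0.5
    margin_mm: float = 20.0
    smoothing_fwhm_mm: float = 8.0
    #: the "striatal area" kept out of the reference region and its
    #: threshold search: the striatal VOIs dilated by this margin, so that
    #: striatal counts spilled just outside the boxes (system resolution is
    #: of order 13 mm FWHM) cannot inflate the 50%-of-maximum threshold
    spill_margin_mm: float = 20.0
    #: relative edge lengths (x, y, z) of the box-shaped striatal VOI.
    #: The default follows the large-VOI principle: the box must enclose
    #: the striatum (about 23 x 49 x 24 mm per side) with roughly equal
    #: margins for partial-volume spill in every direction, which at the
    #: nominal per-side volume gives edges near 34 x 60 x 35 mm.
    voi_aspect: tuple[float, float, float] = (1.0, 1.75, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.reference_threshold < 1:
            raise ValueError("reference threshold must lie in (0, 1)")
        if self.vs_cm3 >= self.vs_voi_cm3:
            raise ValueError("striatal volume must be smaller than the VOI volume")
        if self.margin_mm < 0 or self.smoothing_fwhm_mm < 0:
            raise ValueError("margin and smoothing width must be non-negative")

    @property
    def vs_voi_per_side_cm3(self) -> float:
        return self.vs_voi_cm3 / 2.0

    @property
    def vs_per_side_cm3(self) -> float:
        return self.vs_cm3 / 2.0


@dataclass
class StriatalVOI:
    """Fixed-volume box VOI over one striatum."""

    side: str
    mask: np.ndarray
    volume_cm3: float


@dataclass
class BoltResult:
    """Per-side and averaged Bolt quantities for one reconstruction."""

    cs_total: dict            # side -> total VOI counts
    cs: dict                  # side -> mean counts per VOI voxel
    cr: dict                  # side-independent, stored per side for symmetry
    sbr: dict                 # side -> SBR
    cs_total_mean: float
    cs_mean: float
    cr_mean: float
    sbr_mean: float
    reference_volume_cm3: float
    vs_voi_used_cm3: dict     # side -> achieved VOI volume
    replicate_index: int = 0


def _image_and_spacing(image, spacing=None):
    if isinstance(image, ReconVolume):
        return np.asarray(image.image, dtype=np.float64), (image.voxel_mm,) * 3
    if spacing is None:
        raise ValueError("spacing is required when passing a bare array")
    return np.asarray(image, dtype=np.float64), tuple(float(s) for s in spacing)


def _box_half_extents(params: AnalysisParams, spacing) -> tuple[int, int, int]:
    """Integer box dimensions (voxels per axis) matching the per-side VOI volume.

    Dimensions are kept odd so a box centres exactly on its centroid voxel
    and mirrored centroids produce mirror-symmetric VOIs.
    """
    target_mm3 = params.vs_voi_per_side_cm3 * 1000.0
    aspect = np.asarray(params.voi_aspect, dtype=float)
    c = (target_mm3 / np.prod(aspect)) ** (1.0 / 3.0)
    raw = c * aspect / np.asarray(spacing)
    dims = np.maximum(1, (2 * np.round((raw - 1) / 2) + 1).astype(int))
    # trim/grow one axis at a time (odd steps of 2) toward the target volume
    vox_mm3 = float(np.prod(spacing))
    for _ in range(4):
        best = dims.copy()
        best_err = abs(np.prod(dims) * vox_mm3 - target_mm3)
        for ax in range(3):
            for step in (-2, 2):
                trial = dims.copy()
                trial[ax] += step
                if trial[ax] < 1:
                    continue
                err = abs(np.prod(trial) * vox_mm3 - target_mm3)
                if err < best_err:
                    best, best_err = trial, err
        if np.array_equal(best, dims):
            break
        dims = best
    return tuple(int(d) for d in dims)


def place_striatal_vois(
    image,
    truth_centroids: Mapping[str, Sequence[float]],
    params: AnalysisParams | None = None,
    spacing: Sequence[float] | None = None,
) -> tuple[StriatalVOI, StriatalVOI]:
    """Place the two fixed-volume box VOIs on the true striatal centroids.

    ``truth_centroids`` maps ``"left"``/``"right"`` to world coordinates in
    mm relative to the volume centre (the phantoms are generated
    pre-aligned, so no re-orientation is needed).
    """
    if params is None:
        params = AnalysisParams()
    img, spc = _image_and_spacing(image, spacing)
    dims = _box_half_extents(params, spc)
    vox_cm3 = float(np.prod(spc)) / 1000.0
    vois = []
    for side in ("left", "right"):
        world = np.asarray(truth_centroids[side], dtype=float)
        center = np.round(world / np.asarray(spc) + (np.asarray(img.shape) - 1) / 2.0).astype(int)
        lo = center - (np.asarray(dims) - 1) // 2
        hi = lo + np.asarray(dims)
        if (lo < 0).any() or (hi > np.asarray(img.shape)).any():
            raise PlacementError(f"{side} striatal VOI exceeds the image bounds")
        mask = np.zeros(img.shape, dtype=bool)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        vois.append(StriatalVOI(side=side, mask=mask, volume_cm3=mask.sum() * vox_cm3))
    left, right = vois
    if (left.mask & right.mask).any():
        raise PlacementError("left and right striatal VOIs overlap")
    return left, right


def smooth_within_mask(
    image,
    mask: np.ndarray,
    fwhm_mm: float,
    spacing: Sequence[float] | None = None,
) -> np.ndarray:
    """Normalised masked Gaussian smoothing.

    Values outside the mask neither contribute to nor receive smoothed
    values; within the mask the kernel is renormalised to the in-mask
    support, so a constant field is exactly preserved.  ``fwhm_mm = 0``
    returns the masked values unchanged.
    """
    img, spc = _image_and_spacing(image, spacing)
    out = np.zeros_like(img)
    if fwhm_mm == 0:
        out[mask] = img[mask]
        return out
    sigma = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / s for s in spc]
    num = ndimage.gaussian_filter(np.where(mask, img, 0.0), sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma, mode="constant")
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def _filled_silhouette(mask: np.ndarray) -> np.ndarray:
    """Solid outer silhouette of a mask.

    Holes are filled per axial slice first so that central low-count regions
    that leak out through the poles (uncorrected attenuation depresses the
    deep brain) are still treated as interior, then in 3D.
    """
    out = mask.copy()
    for k in range(out.shape[2]):
        if out[:, :, k].any():
            out[:, :, k] = ndimage.binary_fill_holes(out[:, :, k])
    return ndimage.binary_fill_holes(out)


def build_reference_region(
    image,
    vois: Sequence[StriatalVOI],
    params: AnalysisParams | None = None,
    spacing: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-grown reference region and its masked-smoothed values.

    The threshold is ``reference_threshold`` times the maximum of the
    masked-smoothed values outside the striatal area — both VOIs dilated by
    ``spill_margin_mm``, so striatal counts spilled just outside the boxes
    (system resolution is of order 13 mm FWHM) cannot inflate the maximum.

    The threshold delineates the whole-brain outline: the filled silhouette
    of the above-threshold region.  The reference region is that outline
    pulled ``margin_mm`` inward (3D distance transform) minus the striatal
    VOIs — interior low-count structures such as the ventricles stay
    inside it, which is what makes the reference mean sensitive to brain
    atrophy.  Returns ``(mask, smoothed)``.
    """
    if params is None:
        params = AnalysisParams()
    img, spc = _image_and_spacing(image, spacing)
    boxes = np.zeros(img.shape, dtype=bool)
    for voi in vois:
        boxes |= voi.mask
    candidate = ~boxes
    if params.spill_margin_mm > 0:
        dist = ndimage.distance_transform_edt(~boxes, sampling=spc)
        max_search = dist > params.spill_margin_mm
    else:
        max_search = candidate
    smoothed = smooth_within_mask(img, candidate, params.smoothing_fwhm_mm, spacing=spc)
    threshold = params.reference_threshold * smoothed[max_search].max()
    outline = _filled_silhouette((candidate & (smoothed >= threshold)) | boxes)
    if params.smoothing_fwhm_mm > 0:
        # the margin is measured from the VOI boundary, a segmentation
        # surface: regularise the voxelwise outline (0.5 level set of its
        # smoothed indicator, same width as the reference smoothing) so
        # noise raggedness does not cut channels into the margin erosion
        sigma = [
            params.smoothing_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / s
            for s in spc
        ]
        level = ndimage.gaussian_filter(outline.astype(np.float32), sigma, mode="nearest")
        outline = _filled_silhouette((level >= 0.5) | boxes)
    mask = erode_mask(outline, params.margin_mm, spc) & candidate
    if not mask.any():
        raise AnalysisError(
            "reference region is empty after the inward margin; reduce margin_mm"
        )
    return mask, smoothed


def compute_sbr(cs_total: float, cr: float, vs_voi_cm3: float, vs_cm3: float) -> float:
    """Specific binding ratio ``(Cs_total/Cr - Vs_VOI) / Vs`` (one side)."""
    if cr <= 0:
        raise ZeroDivisionError("reference concentration Cr must be positive")
    return (cs_total / cr - vs_voi_cm3) / vs_cm3


def analyze(
    image,
    truth_centroids: Mapping[str, Sequence[float]],
    params: AnalysisParams | None = None,
    spacing: Sequence[float] | None = None,
    replicate_index: int = 0,
) -> BoltResult:
    """Full Bolt analysis of one volume.

    ``Cs_total`` sums the raw image over each striatal VOI; ``Cr`` is the
    mean masked-smoothed value in the reference region divided by the voxel
    volume (counts/cm3); per-side SBRs are averaged into the output measure.
    """
    if params is None:
        params = AnalysisParams()
    img, spc = _image_and_spacing(image, spacing)
    vox_cm3 = float(np.prod(spc)) / 1000.0
    left, right = place_striatal_vois(img, truth_centroids, params, spacing=spc)
    ref_mask, smoothed = build_reference_region(img, (left, right), params, spacing=spc)
    cr_value = float(smoothed[ref_mask].mean()) / vox_cm3

    cs_total, cs, cr, sbr, vs_voi_used = {}, {}, {}, {}, {}
    for voi in (left, right):
        total = float(img[voi.mask].sum())
        n_vox = int(voi.mask.sum())
        cs_total[voi.side] = total
        cs[voi.side] = total / n_vox
        cr[voi.side] = cr_value
        vs_voi_used[voi.side] = voi.volume_cm3
        sbr[voi.side] = compute_sbr(total, cr_value, voi.volume_cm3, params.vs_per_side_cm3)

    return BoltResult(
        cs_total=cs_total,
        cs=cs,
        cr=cr,
        sbr=sbr,
        cs_total_mean=float(np.mean(list(cs_total.values()))),
        cs_mean=float(np.mean(list(cs.values()))),
        cr_mean=cr_value,
        sbr_mean=float(np.mean(list(sbr.values()))),
        reference_volume_cm3=float(ref_mask.sum()) * vox_cm3,
        vs_voi_used_cm3=vs_voi_used,
        replicate_index=replicate_index,
    )


def striatal_centroids_mm(mask_left: np.ndarray, mask_right: np.ndarray, spacing) -> dict:
    """World-centred centroids (mm) of the two striatal truth masks."""
    spc = np.asarray(spacing, dtype=float)
    out = {}
    for side, mask in (("left", mask_left), ("right", mask_right)):
        idx = np.argwhere(mask).mean(axis=0)
        out[side] = tuple((idx - (np.asarray(mask.shape) - 1) / 2.0) * spc)
    return out
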