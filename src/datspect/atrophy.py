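"""Brain atrophy model (BAM) series.

Atrophy is emulated morphologically: the background (reference parenchyma)
region is eroded inward so that ventricles and sulci enlarge, exactly as the
brain parenchyma recedes in atrophic patients.  Atrophy level ``k`` erodes
the background by ``(k - 1) * 0.5`` in-plane pixels; level 1 is the
unprocessed phantom.

Sub-voxel erosion distances are realised by thresholding the Euclidean
distance transform in physical units: a voxel survives if its distance to
the mask complement exceeds the erosion distance.  The complement is
treated as a region of voxel cubes, not a set of centre points, so the
distance carries a half-voxel surface offset; with that convention a
0.5-pixel erosion removes the face-connected boundary layer and a
1.0-pixel erosion additionally the diagonal layer, matching the classic
rank-filter erosions at those radii while remaining well defined at any
fractional distance.  Erosion is three-dimensional by default (anisotropic
spacing respected); a slice-wise 2D mode is available as a switch.

The striatum is part of the background mask, interior to it, so erosion at
the levels used here never touches it; the striatal voxels are re-labelled
as their own class when the model is assembled, identical at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .phantom import LabelVolume, SegmentSet, region_volume

__all__ = [
    "AtrophyLevel",
    "BrainAtrophyModel",
    "BAM_LEGEND",
    "erode_mask",
    "build_bam",
    "bam_series",
]

#: in-plane pixels of erosion per level step
EROSION_STEP_PIXELS = 0.5

#: reference in-plane pixel (mm) defining the physical size of one erosion
#: pixel; kept fixed so the atrophy severity does not depend on the grid
#: resolution a phantom happens to be sampled on
REFERENCE_PIXEL_MM = 1.1

#: Label values of an assembled brain atrophy model.
BAM_LEGEND = {
    0: "air",
    1: "skull",
    2: "gray_matter",      # background (reference parenchyma)
    4: "ventricle_csf",    # original ventricles + voxels removed by erosion
    5: "striatum_left",
    6: "striatum_right",
}

BACKGROUND_LABEL = 2
CSF_GAP_LABEL = 4


class DegenerateModelError(RuntimeError):
    """Erosion removed the entire background region."""


@dataclass(frozen=True)
class AtrophyLevel:
    """Severity of simulated atrophy; level 1 = no processing."""

    level: int
    pixel_mm: float = REFERENCE_PIXEL_MM   # converts erosion pixels -> mm

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("atrophy level must be >= 1")
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def erosion_pixels(self) -> float:
        return (self.level - 1) * EROSION_STEP_PIXELS

    @property
    def erosion_mm(self) -> float:
        return self.erosion_pixels * self.pixel_mm


@dataclass
class BrainAtrophyModel:
    """A labelled head model at one atrophy level.

    ``background_volume_cm3`` is the volume of the eroded background region
    including the striatal voxels it encloses — the whole-brain reference
    volume plotted on the x-axis of the experiment's trend figures.
    """

    labels: LabelVolume
    level: AtrophyLevel
    background_volume_cm3: float
    masks: dict = field(repr=False, default_factory=dict)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.labels.spacing


def erode_mask(
    mask: np.ndarray,
    distance_mm: float,
    spacing: Sequence[float],
    mode: str = "3d",
) -> np.ndarray:
    """Erode a boolean mask by a physical distance (mm).

    Keeps the voxels whose Euclidean distance to the mask complement —
    treated as a region of voxel cubes, i.e. the centre-to-centre distance
    minus half a voxel — exceeds ``distance_mm``.  ``distance_mm = 0``
    returns the mask unchanged.  With ``mode="2d"`` the erosion is applied
    independently per axial slice.
    """
    if distance_mm < 0:
        raise ValueError("erosion distance must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if distance_mm == 0:
        return mask.copy()
    spacing = tuple(float(s) for s in spacing)
    if mode == "3d":
        # pad so the array border counts as complement
        dist = ndimage.distance_transform_edt(np.pad(mask, 1), sampling=spacing)
        dist = dist[1:-1, 1:-1, 1:-1]
        return dist > distance_mm + 0.5 * min(spacing)
    if mode == "2d":
        out = np.zeros_like(mask)
        for k in range(mask.shape[2]):
            sl = mask[:, :, k]
            if not sl.any():
                continue
            dist = ndimage.distance_transform_edt(np.pad(sl, 1), sampling=spacing[:2])
            out[:, :, k] = dist[1:-1, 1:-1] > distance_mm + 0.5 * min(spacing[:2])
        return out
    raise ValueError(f"unknown erosion mode {mode!r}")


def build_bam(
    segments: SegmentSet,
    level: AtrophyLevel | int,
    mode: str = "3d",
) -> BrainAtrophyModel:
    """Assemble the atrophy model at one level from a segment set.

    The background region (which contains the striatum) is eroded by the
    level's physical distance; the voxels it loses join the CSF class
    together with the original ventricles; bone and striatum are carried
    over unchanged.
    """
    if isinstance(level, int):
        level = AtrophyLevel(level)
    eroded = erode_mask(segments.background, level.erosion_mm, segments.spacing, mode=mode)
    if not eroded.any():
        raise DegenerateModelError(
            f"erosion by {level.erosion_mm:.2f} mm removed the whole background region"
        )
    striatum_l = segments.striatum_left
    striatum_r = segments.striatum_right
    csf_gap = (segments.background & ~eroded) | segments.ventricles

    grid = np.zeros(eroded.shape, dtype=np.int16)
    grid[segments.bone] = 1
    grid[csf_gap] = CSF_GAP_LABEL
    grid[eroded] = BACKGROUND_LABEL
    grid[striatum_l] = 5
    grid[striatum_r] = 6
    labels = LabelVolume(grid=grid, spacing=segments.spacing, legend=dict(BAM_LEGEND))
    background_mask = eroded | striatum_l | striatum_r
    return BrainAtrophyModel(
        labels=labels,
        level=level,
        background_volume_cm3=region_volume(background_mask, segments.spacing),
        masks={
            "background": eroded & ~(striatum_l | striatum_r),
            "background_with_striatum": background_mask,
            "striatum_left": striatum_l,
            "striatum_right": striatum_r,
            "csf_gap": csf_gap,
            "bone": segments.bone,
        },
    )


def bam_series(
    segments: SegmentSet,
    levels: Sequence[int] = (1, 2, 3),
    mode: str = "3d",
) -> list[BrainAtrophyModel]:
    """Build one atrophy model per level (levels sorted ascending)."""
    if list(levels) != sorted(levels):
        raise ValueError("levels must be sorted ascending")
    return [build_bam(segments, lvl, mode=mode) for lvl in levels]
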