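"""Labelled digital head phantoms.

This module provides the anatomical ground truth for the SPECT simulation
pipeline: a voxelised head volume labelled with tissue classes (skull, gray
and white matter, ventricular/sulcal CSF, left and right striatum).  Two
sources are supported:

* :func:`load_zubal` reads the MRI-derived Zubal head phantom distributed by
  Yale University as a headerless byte volume (256 x 256 x 128 voxels,
  1.1 x 1.1 x 1.4 mm), given a label legend;
* :func:`generate_synthetic_head` builds a fully synthetic head with the same
  gross anatomy (skull shell, folded brain parenchyma, lateral/third/fourth
  ventricles, bilateral caudate + putamen) so the whole pipeline runs without
  any external download.

Anatomical segments used downstream (bone, striatum, ventricles, parenchyma,
and the background/reference region = parenchyma minus ventricles) are
extracted with :func:`extract_segments`.

Coordinate convention: voxel indices are 0-based with axis order
(x = width, y = height, z = slice); physical lengths in mm, volumes in cm3;
the world origin sits at the volume centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import BinaryIO, Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "TISSUE_CLASSES",
    "DEFAULT_ZUBAL_LEGEND",
    "LabelVolume",
    "SegmentSet",
    "SyntheticHeadParams",
    "load_zubal",
    "generate_synthetic_head",
    "extract_segments",
    "region_volume",
    "save_label_volume",
    "load_label_volume",
]

#: Recognised tissue classes for a labelled head volume.
TISSUE_CLASSES = frozenset(
    {
        "air",
        "skull",
        "gray_matter",
        "white_matter",
        "ventricle_csf",
        "striatum_left",
        "striatum_right",
        "striatum",  # side-unsplit striatum (split at the midline on extraction)
        "other",
    }
)

#: Default spacing of the Zubal head phantom in mm.
ZUBAL_SPACING = (1.1, 1.1, 1.4)
ZUBAL_SHAPE = (256, 256, 128)

# Best-effort legend for the Zubal head phantom ("head" distribution).
# Label ids differ between distributions; treat this as configuration and
# override with the legend shipped alongside your copy of the phantom.
DEFAULT_ZUBAL_LEGEND: dict[int, str] = {
    0: "air",
    1: "other",        # skin
    2: "ventricle_csf",  # cerebral fluid
    3: "other",        # spinal cord handled below if present
    4: "skull",
    5: "other",        # spine
    6: "white_matter",
    7: "gray_matter",
    8: "striatum",     # caudate nucleus (both sides)
    9: "striatum",     # putamen (both sides)
    10: "ventricle_csf",  # lateral ventricles
    11: "ventricle_csf",  # third ventricle
    12: "ventricle_csf",  # fourth ventricle / aqueduct
}


class MalformedFileError(ValueError):
    """Raw phantom stream does not match the declared geometry."""


class ConfigurationError(ValueError):
    """Missing or inconsistent legend/parameter configuration."""


class GenerationError(RuntimeError):
    """Synthetic phantom targets could not be realised."""


class ExtractionError(ValueError):
    """A tissue class required for segmentation is absent."""


@dataclass
class LabelVolume:
    """Integer-labelled 3D voxel grid with physical spacing.

    Parameters
    ----------
    grid : ndarray of int
        Label volume, axis order (x, y, z).
    spacing : tuple of float
        Voxel size (dx, dy, dz) in mm.
    legend : dict
        Mapping label value -> tissue class (see :data:`TISSUE_CLASSES`).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = ZUBAL_SPACING
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not self.legend:
            raise ConfigurationError("legend must not be empty")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        unknown = set(self.legend.values()) - TISSUE_CLASSES
        if unknown:
            raise ConfigurationError(f"unknown tissue classes in legend: {sorted(unknown)}")
        present = set(np.unique(self.grid).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ConfigurationError(f"grid labels missing from legend: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def labels_for(self, *classes: str) -> list[int]:
        return sorted(k for k, v in self.legend.items() if v in classes)

    def mask_of(self, *classes: str) -> np.ndarray:
        """Boolean mask of all voxels whose label maps to any of *classes*."""
        labels = self.labels_for(*classes)
        if not labels:
            return np.zeros(self.grid.shape, dtype=bool)
        return np.isin(self.grid, labels)

    def classes_present(self) -> set[str]:
        present = np.unique(self.grid)
        return {self.legend[int(v)] for v in present}


@dataclass
class SegmentSet:
    """Anatomical segments shared by one phantom (boolean masks, one spacing).

    ``background`` is the reference parenchyma: parenchyma with the
    ventricular CSF removed.  The striatum is part of the parenchyma and
    therefore also of the background mask.
    """

    bone: np.ndarray
    striatum_left: np.ndarray
    striatum_right: np.ndarray
    ventricles: np.ndarray
    parenchyma: np.ndarray
    background: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def striatum(self) -> np.ndarray:
        return self.striatum_left | self.striatum_right

    def validate(self) -> None:
        if (self.striatum_left & self.striatum_right).any():
            raise ValueError("left and right striatal masks overlap")
        if not self.striatum_left.any() or not self.striatum_right.any():
            raise ValueError("each striatal side must be non-empty")
        if (self.bone & self.parenchyma).any():
            raise ValueError("bone intersects parenchyma")
        if (self.striatum & ~self.parenchyma).any():
            raise ValueError("striatum is not contained in parenchyma")
        if not np.array_equal(self.background, self.parenchyma & ~self.ventricles):
            raise ValueError("background must equal parenchyma minus ventricles")


@dataclass
class SyntheticHeadParams:
    """Geometry and volume targets for the synthetic head generator.

    Default targets mirror the reference anatomy the pipeline is calibrated
    against: a background (whole-brain reference) region of 1387.41 cm3 and a
    bilateral striatum of 17.92 cm3.
    """

    shape: tuple[int, int, int] = ZUBAL_SHAPE
    spacing: tuple[float, float, float] = ZUBAL_SPACING
    #: outer head (scalp) ellipsoid semi-axes, mm
    head_semiaxes_mm: tuple[float, float, float] = (79.0, 104.0, 80.0)
    #: brain ellipsoid semi-axes before volume calibration, mm
    brain_semiaxes_mm: tuple[float, float, float] = (66.0, 92.0, 60.0)
    skull_gap_mm: float = 2.0
    skull_thickness_mm: float = 7.0
    #: sulcal grooves: two orthogonal families of parallel clefts confined to
    #: the cortical shell (outer ``sulcus_depth_frac`` of the brain radius)
    sulcus_spacing_mm: float = 36.0
    sulcus_width_mm: float = 1.8
    sulcus_depth_frac: float = 0.30
    white_frac: float = 0.78
    striatum_target_cm3: float = 17.92   # bilateral total
    background_target_cm3: float = 1387.41
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("head_semiaxes_mm", "brain_semiaxes_mm", "spacing"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be strictly positive")
        if self.striatum_target_cm3 <= 0 or self.background_target_cm3 <= 0:
            raise ValueError("volume targets must be positive")
        if not 0 < self.sulcus_depth_frac < 1:
            raise ValueError("sulcus_depth_frac must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticHeadParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("shape", "spacing", "head_semiaxes_mm", "brain_semiaxes_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def scaled(self, factor: float) -> "SyntheticHeadParams":
        """Coarser copy: same physical head, voxel size scaled by *factor*."""
        shape = tuple(max(8, int(round(n / factor))) for n in self.shape)
        spacing = tuple(s * factor for s in self.spacing)
        return replace(self, shape=shape, spacing=spacing)


# ----------------------------------------------------------------------------
# I/O

def load_zubal(
    stream: bytes | BinaryIO,
    legend: Mapping[int, str] | None = None,
    spacing: Sequence[float] = ZUBAL_SPACING,
    shape: Sequence[int] = ZUBAL_SHAPE,
) -> LabelVolume:
    """Read a raw Zubal-format label volume.

    The format is a headerless stream of unsigned 8-bit labels, x fastest
    varying, slice-major.  *legend* maps byte values to tissue classes;
    values absent from the legend are mapped to ``"other"``.
    """
    if legend is None:
        legend = DEFAULT_ZUBAL_LEGEND
    legend = dict(legend)
    if not legend:
        raise ConfigurationError("legend must not be empty")
    data = stream if isinstance(stream, (bytes, bytearray)) else stream.read()
    nx, ny, nz = (int(n) for n in shape)
    expected = nx * ny * nz
    if len(data) != expected:
        raise MalformedFileError(
            f"stream has {len(data)} bytes, expected {expected} for shape {tuple(shape)}"
        )
    grid = np.frombuffer(bytes(data), dtype=np.uint8).reshape(nz, ny, nx).transpose(2, 1, 0)
    full_legend = dict(legend)
    for value in np.unique(grid):
        full_legend.setdefault(int(value), "other")
    return LabelVolume(grid=grid.copy(), spacing=tuple(spacing), legend=full_legend)


def save_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI-1 with a JSON legend sidecar."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.grid.astype(np.int16), affine), str(path))
    sidecar = path.with_suffix("").with_suffix(".legend.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in vol.legend.items()}, indent=1))


def load_label_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = path.with_suffix("").with_suffix(".legend.json")
    legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    grid = np.asarray(img.dataobj).astype(np.int16)
    return LabelVolume(grid=grid, spacing=spacing, legend=legend)


# ----------------------------------------------------------------------------
# Synthetic generator

#: Label values used by the synthetic generator.
SYNTH_LEGEND = {
    0: "air",
    1: "skull",
    2: "white_matter",
    3: "gray_matter",
    4: "ventricle_csf",
    5: "striatum_left",
    6: "striatum_right",
}


def _coord_grids(shape, spacing):
    """World coordinates (mm, origin at volume centre) on the voxel grid."""
    axes = [
        (np.arange(n, dtype=np.float32) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_rho(coords, center, semiaxes):
    x, y, z = coords
    cx, cy, cz = center
    a, b, c = semiaxes
    return np.sqrt(((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2)


def _ventricle_mask(coords) -> np.ndarray:
    """Lateral + third + fourth ventricles as a union of ellipsoids."""
    parts = [
        ((+15.0, 6.0, 8.0), (7.5, 32.0, 10.5)),   # right lateral
        ((-15.0, 6.0, 8.0), (7.5, 32.0, 10.5)),   # left lateral
        ((0.0, 2.0, -2.0), (2.5, 18.0, 10.0)),    # third
        ((0.0, -28.0, -24.0), (3.5, 9.0, 9.0)),   # fourth + aqueduct
    ]
    mask = np.zeros(np.broadcast_shapes(*(c.shape for c in coords)), dtype=bool)
    for center, semi in parts:
        mask |= _ellipsoid_rho(coords, center, semi) <= 1.0
    return mask


def _fissure_mask(coords, rho_brain, brain_scale: float) -> np.ndarray:
    """Major deep CSF fissures: interhemispheric and bilateral sylvian.

    The interhemispheric fissure is a midsagittal cleft running the whole
    anteroposterior extent, complete above the corpus callosum and confined
    to the outer brain below it; the sylvian fissures are oblique lateral
    clefts superior to the insula.  Their walls lie deep inside the brain,
    so atrophy widens CSF spaces well beyond the cortical shell — as it
    does in real brains.
    """
    x, y, z = coords
    interhemispheric = (np.abs(x) <= 1.2) & ((z >= 14.0) | (rho_brain >= 0.62 * brain_scale))
    sylvian = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape), dtype=bool)
    for side in (-1.0, 1.0):
        lateral = side * x
        plane = z - (-4.0 + 0.25 * (lateral - 40.0))
        sylvian |= (np.abs(plane) <= 1.2) & (lateral >= 40.0) & (y > -50.0) & (y < 30.0)
    return (interhemispheric | sylvian) & (rho_brain <= brain_scale)


def _striatum_rho(coords, side: int):
    """Per-side minimum ellipsoid rho for caudate head + putamen (side = +-1)."""
    caudate = _ellipsoid_rho(coords, (side * 17.0, 20.0, 7.0), (5.5, 14.0, 9.0))
    putamen = _ellipsoid_rho(coords, (side * 27.0, 2.0, 2.0), (7.0, 17.0, 10.0))
    return np.minimum(caudate, putamen)


def generate_synthetic_head(params: SyntheticHeadParams | None = None) -> LabelVolume:
    """Generate a synthetic labelled head phantom.

    The brain is an ellipsoid with two orthogonal families of narrow sulcal
    clefts carved into the cortical shell, ventricles as a union of
    ellipsoids, and mirrored caudate + putamen striata lateral to the lateral
    ventricles.  The brain scale and the striatal scale are each calibrated
    by bisection so that the achieved background and bilateral striatal
    volumes land within 3% of their targets.  The construction is fully
    deterministic for a fixed parameter set.
    """
    if params is None:
        params = SyntheticHeadParams()
    coords = _coord_grids(params.shape, params.spacing)
    voxel_cm3 = float(np.prod(params.spacing)) / 1000.0

    rho_brain = _ellipsoid_rho(coords, (0.0, 0.0, 0.0), params.brain_semiaxes_mm)
    vent = _ventricle_mask(coords)

    # Sulcal cleft pattern: two families of parallel planes; a voxel is in a
    # cleft if it lies within half a cleft width of a plane.  Slight tilts
    # de-align the pattern from the voxel grid.
    x, y, z = coords
    p = params.sulcus_spacing_mm
    w = params.sulcus_width_mm
    u1 = x + 0.35 * z + 0.31 * p
    u2 = y + 0.25 * z + 0.47 * p
    near_plane = (np.abs(u1 - p * np.round(u1 / p)) < w / 2) | (
        np.abs(u2 - p * np.round(u2 / p)) < w / 2
    )

    def csf_clefts(scale: float) -> np.ndarray:
        brain = rho_brain <= scale
        shell = rho_brain > (1.0 - params.sulcus_depth_frac) * scale
        return (brain & shell & near_plane) | _fissure_mask(coords, rho_brain, scale)

    def background_mask(scale: float) -> np.ndarray:
        return (rho_brain <= scale) & ~vent & ~csf_clefts(scale)

    def background_volume(scale: float) -> float:
        return float(np.count_nonzero(background_mask(scale))) * voxel_cm3

    lo, hi = 0.5, 1.6
    if background_volume(hi) < params.background_target_cm3:
        raise GenerationError(
            "background target volume "
            f"{params.background_target_cm3} cm3 is not achievable within the brain ellipsoid"
        )
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if background_volume(mid) < params.background_target_cm3:
            lo = mid
        else:
            hi = mid
    brain_scale = 0.5 * (lo + hi)
    achieved_bg = background_volume(brain_scale)
    if abs(achieved_bg - params.background_target_cm3) > 0.03 * params.background_target_cm3:
        raise GenerationError(
            f"background volume {achieved_bg:.1f} cm3 missed target "
            f"{params.background_target_cm3} cm3 by more than 3%"
        )

    brain = rho_brain <= brain_scale
    sulci = csf_clefts(brain_scale)
    white = (rho_brain <= params.white_frac * brain_scale) & ~vent & ~sulci

    # Striatum: bisect a common scale factor on the union of the two sides.
    rho_l = _striatum_rho(coords, -1)
    rho_r = _striatum_rho(coords, +1)

    def striatum_volume(t: float) -> float:
        n = np.count_nonzero(rho_l <= t) + np.count_nonzero(rho_r <= t)
        return float(n) * voxel_cm3

    lo, hi = 0.3, 1.8
    if striatum_volume(hi) < params.striatum_target_cm3:
        raise GenerationError("striatal target volume not achievable")
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if striatum_volume(mid) < params.striatum_target_cm3:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    achieved_str = striatum_volume(t)
    if abs(achieved_str - params.striatum_target_cm3) > 0.03 * params.striatum_target_cm3:
        raise GenerationError(
            f"striatal volume {achieved_str:.2f} cm3 missed target "
            f"{params.striatum_target_cm3} cm3 by more than 3%"
        )
    str_l = rho_l <= t
    str_r = rho_r <= t
    if not (str_l <= brain).all() or not (str_r <= brain).all():
        raise GenerationError("striatum does not fit inside the brain ellipsoid")

    # Skull: shell at a fixed physical offset outside the brain surface,
    # approximated by scaled ellipsoids (offset converted to rho units of the
    # smallest semi-axis so the shell is at least the nominal thickness).
    a_min = min(params.brain_semiaxes_mm) * brain_scale
    gap_rho = params.skull_gap_mm / a_min
    thick_rho = params.skull_thickness_mm / a_min
    inner = brain_scale * (1.0 + gap_rho)
    outer = brain_scale * (1.0 + gap_rho + thick_rho)
    skull = (rho_brain > inner) & (rho_brain <= outer)
    head = _ellipsoid_rho(coords, (0.0, 0.0, 0.0), params.head_semiaxes_mm) <= 1.0
    skull &= head

    grid = np.zeros(params.shape, dtype=np.int16)
    grid[skull] = 1
    grid[brain] = 3                      # gray matter by default
    grid[white] = 2
    grid[brain & (vent | sulci)] = 4     # ventricular + sulcal CSF
    grid[str_l] = 5
    grid[str_r] = 6

    return LabelVolume(grid=grid, spacing=params.spacing, legend=dict(SYNTH_LEGEND))


# ----------------------------------------------------------------------------
# Segmentation

_REQUIRED_FOR_SEGMENTS = ("skull", "ventricle_csf")


def extract_segments(vol: LabelVolume) -> SegmentSet:
    """Split a labelled head volume into the segments the atrophy model uses.

    The background (reference) region is the brain parenchyma with the
    ventricular/sulcal CSF removed.  Parenchyma is gray + white matter plus
    the striatum.  If the legend carries a side-unsplit ``striatum`` class it
    is split into left/right halves at the mid-sagittal plane.
    """
    present = vol.classes_present()
    if not ({"gray_matter", "white_matter"} & present):
        raise ExtractionError("no parenchymal (gray/white matter) class present")
    for cls in _REQUIRED_FOR_SEGMENTS:
        if cls not in present:
            raise ExtractionError(f"required tissue class {cls!r} absent from volume")
    if "striatum" in present:
        both = vol.mask_of("striatum")
        half = vol.shape[0] // 2
        left = both.copy()
        left[half:, :, :] = False
        right = both & ~left
        left |= vol.mask_of("striatum_left")
        right |= vol.mask_of("striatum_right")
    else:
        left = vol.mask_of("striatum_left")
        right = vol.mask_of("striatum_right")
        if not left.any() or not right.any():
            raise ExtractionError("both striatal sides are required")

    bone = vol.mask_of("skull")
    ventricles = vol.mask_of("ventricle_csf")
    parenchyma = vol.mask_of("gray_matter", "white_matter") | left | right
    segments = SegmentSet(
        bone=bone,
        striatum_left=left,
        striatum_right=right,
        ventricles=ventricles,
        parenchyma=parenchyma,
        background=parenchyma & ~ventricles,
        spacing=vol.spacing,
    )
    segments.validate()
    return segments


def region_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Volume of a boolean mask in cm3 (voxel count x voxel volume)."""
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError("spacing must be three positive lengths in mm")
    return float(np.count_nonzero(mask)) * spacing[0] * spacing[1] * spacing[2] / 1000.0
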