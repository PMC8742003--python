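"""NIfTI/JSON persistence for projection sets and reconstructions."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fbp_recon import ReconstructionParams, ReconVolume
from .spect_sim import AcquisitionGeometry, ProjectionSet

__all__ = [
    "save_projection_set",
    "load_projection_set",
    "save_recon_volume",
    "load_recon_volume",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json")


def save_projection_set(proj: ProjectionSet, path: str | Path) -> None:
    """Write counts as NIfTI (views as slices) plus a JSON geometry sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(proj.counts, 0, -1).astype(np.int32), np.eye(4))
    nib.save(img, str(path))
    meta = {
        "geometry": dataclasses.asdict(proj.geometry),
        "seed": proj.seed,
        "replicate_index": proj.replicate_index,
        "expectation_total": float(proj.expectation.sum()),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_projection_set(path: str | Path) -> ProjectionSet:
    path = Path(path)
    counts = np.moveaxis(np.asarray(nib.load(str(path)).dataobj), -1, 0)
    meta = json.loads(_sidecar(path).read_text())
    geo = meta["geometry"]
    geo["energy_window_kev"] = tuple(geo["energy_window_kev"])
    geometry = AcquisitionGeometry(**geo)
    expectation = np.full(counts.shape, meta["expectation_total"] / counts.size)
    return ProjectionSet(
        counts=counts.astype(np.int64),
        expectation=expectation,
        geometry=geometry,
        seed=meta["seed"],
        replicate_index=meta["replicate_index"],
    )


def save_recon_volume(recon: ReconVolume, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag([recon.voxel_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(recon.image.astype(np.float32), affine), str(path))
    meta = {"params": dataclasses.asdict(recon.params), "provenance": recon.provenance}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_recon_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(_sidecar(path).read_text())
    return ReconVolume(
        image=np.asarray(img.dataobj, dtype=np.float64),
        voxel_mm=float(img.header.get_zooms()[0]),
        params=ReconstructionParams(**meta["params"]),
        provenance=meta.get("provenance", ""),
    )
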