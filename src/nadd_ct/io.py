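"""On-disk formats: HDF5 sinogram containers, NIfTI/TIFF slices, manifests.

Sinograms live in an HDF5 container with the full scan geometry, the role
tag and RNG provenance stored as attributes; noise-realization sets add
``/realizations/r{n}`` (sinograms) and ``/realizations/h{n}`` (images)
groups with the dose configuration attached. Image slices can be written as
single-slice NIfTI volumes (pixel size in the affine) or 32-bit TIFF.
A cohort manifest is a JSON index of (subject_id, slice path, role, split).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .containers import ImageSlice, Sinogram
from .geometry import ScanGeometry
from .noise import DoseConfig, NoiseRealizationSet

_GEOM_PREFIX = "geometry."


def save_sinogram(path, sinogram: Sinogram, provenance: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sinogram", data=sinogram.values.astype(np.float32))
        ds.attrs["role"] = sinogram.role
        for key, val in sinogram.geometry.to_dict().items():
            ds.attrs[_GEOM_PREFIX + key] = val
        for key, val in (provenance or {}).items():
            ds.attrs[f"provenance.{key}"] = val


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        ds = f["sinogram"]
        geom = ScanGeometry.from_dict(
            {k[len(_GEOM_PREFIX):]: v for k, v in ds.attrs.items() if k.startswith(_GEOM_PREFIX)}
        )
        return Sinogram(values=ds[()], geometry=geom, role=str(ds.attrs.get("role", "clean")))


def save_realizations(path, rset: NoiseRealizationSet) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("realizations")
        for key, val in asdict(rset.config).items():
            grp.attrs[f"dose.{key}"] = val
        grp.attrs["source_role"] = rset.source_role
        grp.attrs["N"] = len(rset)
        for n, (r, h) in enumerate(zip(rset.sinograms, rset.images)):
            grp.create_dataset(f"r{n}", data=r.values.astype(np.float32))
            grp.create_dataset(f"h{n}", data=h.pixels.astype(np.float32))
        if rset.sinograms:
            for key, val in rset.sinograms[0].geometry.to_dict().items():
                grp.attrs[_GEOM_PREFIX + key] = val


def load_realizations(path) -> NoiseRealizationSet:
    with h5py.File(path, "r") as f:
        grp = f["realizations"]
        geom = ScanGeometry.from_dict(
            {k[len(_GEOM_PREFIX):]: v for k, v in grp.attrs.items() if k.startswith(_GEOM_PREFIX)}
        )
        dose_fields = {k[len("dose."):]: v for k, v in grp.attrs.items() if k.startswith("dose.")}
        if "N" in dose_fields:
            dose_fields["N"] = int(dose_fields["N"])
        for key in ("max_realizations", "seed"):
            if key in dose_fields:
                dose_fields[key] = int(dose_fields[key])
        cfg = DoseConfig(**{k: v for k, v in dose_fields.items() if k in DoseConfig.__dataclass_fields__})
        n = int(grp.attrs["N"])
        sinos = [Sinogram(values=grp[f"r{i}"][()], geometry=geom, role="noise_only") for i in range(n)]
        images = [
            ImageSlice(pixels=grp[f"h{i}"][()], pixel_size=geom.pixel_size, role="noise_only")
            for i in range(n)
        ]
        return NoiseRealizationSet(
            sinograms=sinos, images=images, source_role=str(grp.attrs.get("source_role", "noisy")), config=cfg
        )


def save_slice(path, image: ImageSlice) -> None:
    """Write a slice as NIfTI (.nii/.nii.gz) or 32-bit TIFF (.tif/.tiff)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels.astype(np.float32))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([image.pixel_size, image.pixel_size, 1.0, 1.0])
        img = nib.Nifti1Image(image.pixels.astype(np.float32)[..., None], affine)
        img.header.set_zooms((image.pixel_size, image.pixel_size, 1.0))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported slice format {path.suffix!r} (use .nii[.gz] or .tif[f])")


def load_slice(path, role: str = "ground_truth") -> ImageSlice:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
        return ImageSlice(pixels=pixels, pixel_size=1.0, role=role)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim == 3:
            data = data[..., 0]
        return ImageSlice(pixels=data, pixel_size=float(img.header.get_zooms()[0]), role=role)
    raise ValueError(f"unsupported slice format {path.suffix!r}")


def write_manifest(path, entries: list[dict]) -> None:
    """Cohort manifest: list of {subject_id, path, role, split} records."""
    with open(path, "w") as fh:
        json.dump({"schema": "nadd-ct/cohort-manifest/v1", "slices": entries}, fh, indent=2)


def read_manifest(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)["slices"]
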