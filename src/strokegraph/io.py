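"""Cohort readers/writers: NIfTI volumes, 16-bit PNG pairs, CSV manifests.

A cohort on disk is a manifest CSV plus per-patient NIfTI image/mask volumes
(axial slices along the last axis) or per-slice 16-bit PNG pairs.  PNG
intensities are stored with a fixed +1024 offset so that the negative
out-of-window values CT data can contain survive the unsigned encoding;
integer-valued HU images round-trip exactly.
"""

from __future__ import annotations

import csv
import os

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .errors import InputError
from .phantom import SliceSample

__all__ = [
    "save_cohort_nifti",
    "save_cohort_png",
    "load_volume",
    "load_cohort",
    "PNG_OFFSET",
]

PNG_OFFSET = 1024


def save_cohort_nifti(samples: list[SliceSample], out_dir: str) -> str:
    """Write one image + mask NIfTI volume per patient; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    by_patient: dict[str, list[SliceSample]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "image_path", "mask_path",
                         "slice_count", "format"])
        for pid in sorted(by_patient):
            stack = sorted(by_patient[pid], key=lambda s: s.slice_index)
            img = np.stack([s.image for s in stack], axis=-1)
            msk = np.stack([s.mask for s in stack], axis=-1).astype(np.uint8)
            img_path = os.path.join(out_dir, f"{pid}_img.nii")
            msk_path = os.path.join(out_dir, f"{pid}_msk.nii")
            nib.save(nib.Nifti1Image(img, affine=np.eye(4)), img_path)
            nib.save(nib.Nifti1Image(msk, affine=np.eye(4)), msk_path)
            writer.writerow([pid, os.path.basename(img_path),
                             os.path.basename(msk_path), len(stack), "nifti"])
    return manifest


def save_cohort_png(samples: list[SliceSample], out_dir: str) -> str:
    """Write per-slice 16-bit PNG image/mask pairs; returns manifest path.

    Images are rounded to integers and shifted by ``PNG_OFFSET``.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "slice_index", "image_path",
                         "mask_path", "format", "offset"])
        for s in samples:
            stem = f"{s.patient_id}_{s.slice_index:03d}"
            img_path = os.path.join(out_dir, f"{stem}_img.png")
            msk_path = os.path.join(out_dir, f"{stem}_msk.png")
            enc = np.round(s.image).astype(np.int64) + PNG_OFFSET
            if enc.min() < 0 or enc.max() > 65535:
                raise InputError("image intensities out of 16-bit PNG range")
            iio.imwrite(img_path, enc.astype(np.uint16))
            iio.imwrite(msk_path, s.mask.astype(np.uint16))
            writer.writerow([s.patient_id, s.slice_index,
                             os.path.basename(img_path),
                             os.path.basename(msk_path), "png", PNG_OFFSET])
    return manifest


def load_volume(path: str, mask_path: str | None = None,
                patient_id: str | None = None,
                require_mask: bool = True) -> list[SliceSample]:
    """Slice a NIfTI volume (last axis = axial) into SliceSamples."""
    vol = np.asanyarray(nib.load(path).dataobj).astype(np.float64)
    if vol.ndim != 3:
        raise InputError(f"expected a 3-D volume, got shape {vol.shape}")
    if mask_path is None:
        if require_mask:
            raise InputError(f"no mask volume given for {path}")
        msk = np.zeros_like(vol, dtype=np.uint8)
    else:
        msk = np.asanyarray(nib.load(mask_path).dataobj)
        if msk.shape != vol.shape:
            raise InputError(
                f"mask shape {msk.shape} != volume shape {vol.shape}")
    pid = patient_id or os.path.basename(path).split(".")[0].removesuffix("_img")
    return [SliceSample(image=vol[..., i], mask=msk[..., i].astype(np.uint8),
                        patient_id=pid, slice_index=i)
            for i in range(vol.shape[-1])]


def load_cohort(manifest_path: str) -> list[SliceSample]:
    """Load a cohort written by :func:`save_cohort_nifti` / :func:`save_cohort_png`."""
    base = os.path.dirname(manifest_path)
    with open(manifest_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise InputError(f"empty manifest: {manifest_path}")
    samples: list[SliceSample] = []
    for row in rows:
        if row["format"] == "nifti":
            samples.extend(load_volume(os.path.join(base, row["image_path"]),
                                       os.path.join(base, row["mask_path"]),
                                       patient_id=row["patient_id"]))
        elif row["format"] == "png":
            img = iio.imread(os.path.join(base, row["image_path"]))
            img = img.astype(np.float64) - float(row["offset"])
            msk = iio.imread(os.path.join(base, row["mask_path"]))
            samples.append(SliceSample(image=img, mask=msk.astype(np.uint8),
                                       patient_id=row["patient_id"],
                                       slice_index=int(row["slice_index"])))
        else:
            raise InputError(f"unknown cohort format {row['format']!r}")
    return samples
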