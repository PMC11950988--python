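"""Readers and writers for the formats the tool exchanges.

Readers return :class:`~aspectscore.preprocess.HUImage` with Hounsfield
rescaling applied:

- DICOM (``.dcm``): ``RescaleSlope * stored + RescaleIntercept``; missing
  rescale tags are an error instructing the user to supply an explicit
  rescale, never a silent assumption.
- NIfTI (``.nii`` / ``.nii.gz``): values taken as HU after the header's
  scl_slope/scl_inter (handled by nibabel's ``get_fdata``).
- 16-bit grayscale PNG (``.png``): requires an explicit (slope, intercept)
  pair, since PNG carries no intensity semantics.

Writers persist phantoms and label maps as NIfTI (HU as signed 16-bit,
scale 1) and cohort manifests/truth as CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError
from .phantom import LEVELS, REGIONS, CohortRecord
from .preprocess import HUImage

SUPPORTED_EXTENSIONS = (".dcm", ".nii", ".nii.gz", ".png")


def read_dicom(path, level: str = "unknown") -> HUImage:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
        raise FormatError(
            f"{path}: DICOM lacks RescaleSlope/RescaleIntercept; supply an "
            "explicit HU rescale in the run configuration"
        )
    hu = float(ds.RescaleSlope) * ds.pixel_array.astype(np.float64) + float(
        ds.RescaleIntercept
    )
    spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (0.5, 0.5)))
    return HUImage(hu, spacing=spacing, level=level)


def read_nifti(path, level: str = "unknown") -> HUImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.get_fdata(), dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single 2D slice, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    spacing = (float(zooms[0]) or 0.5, float(zooms[1]) or 0.5)
    return HUImage(data, spacing=spacing, level=level)


def read_png16(
    path, rescale: tuple[float, float], level: str = "unknown",
    spacing: tuple[float, float] = (0.5, 0.5),
) -> HUImage:
    from PIL import Image

    slope, intercept = rescale
    arr = np.asarray(Image.open(str(path)), dtype=np.float64)
    return HUImage(slope * arr + intercept, spacing=spacing, level=level)


def read_inputs(
    paths: Sequence, *, levels: Sequence[str] | None = None,
    png_rescale: tuple[float, float] | None = None,
) -> list[HUImage]:
    """Read a list of slice files, dispatching on extension."""
    out = []
    for i, p in enumerate(paths):
        p = Path(p)
        level = levels[i] if levels else "unknown"
        name = p.name.lower()
        if name.endswith(".dcm"):
            out.append(read_dicom(p, level))
        elif name.endswith((".nii", ".nii.gz")):
            out.append(read_nifti(p, level))
        elif name.endswith(".png"):
            if png_rescale is None:
                raise FormatError(
                    f"{p}: PNG input requires an explicit (slope, intercept) rescale"
                )
            out.append(read_png16(p, png_rescale, level))
        else:
            raise FormatError(
                f"{p}: unsupported format; supported extensions: "
                + ", ".join(SUPPORTED_EXTENSIONS)
            )
    return out


def write_nifti(path, pixels: np.ndarray, spacing=(0.5, 0.5), dtype=np.int16) -> None:
    """Write a 2D array as NIfTI; HU stored as signed 16-bit with scale 1."""
    arr = np.asarray(pixels)
    if np.issubdtype(dtype, np.integer):
        arr = np.rint(arr).astype(dtype)
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_cohort(cohort: Iterable[CohortRecord], out_dir) -> Path:
    """Persist a synthetic cohort: NIfTI slices plus a CSV manifest.

    Manifest columns: patient_id, category, laterality, region, side, truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        for level in LEVELS:
            img = rec.slices[level]
            write_nifti(out_dir / f"{rec.patient_id}_{level}.nii",
                        img.pixels, img.spacing)
        for region in REGIONS:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "category": rec.category,
                    "laterality": rec.laterality,
                    "region": region,
                    "side": rec.laterality,
                    "truth": bool(rec.truth[region]),
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(out_dir) -> list[CohortRecord]:
    """Reload a cohort written by :func:`write_cohort`."""
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "manifest.csv")
    records = []
    for pid, grp in df.groupby("patient_id", sort=True):
        slices = {
            level: read_nifti(out_dir / f"{pid}_{level}.nii", level)
            for level in LEVELS
        }
        truth = dict(zip(grp["region"], grp["truth"].astype(bool)))
        records.append(
            CohortRecord(
                patient_id=str(pid),
                category=str(grp["category"].iloc[0]),
                laterality=str(grp["laterality"].iloc[0]),
                slices=slices,
                truth={r: bool(truth.get(r, False)) for r in REGIONS},
            )
        )
    return records


def write_label_map(path, labels: np.ndarray, table: dict, spacing=(0.5, 0.5)) -> None:
    """Integer label map as NIfTI with a JSON sidecar mapping label->(region, side)."""
    import json

    write_nifti(path, labels, spacing, dtype=np.int16)
    sidecar = Path(str(path)).with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {str(k): list(v) for k, v in sorted(table.items())},
            fh, indent=2, sort_keys=True,
        )
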