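"""Readers and writers for slices, masks and phantom datasets.

Slices travel as 16-bit unsigned PNG/TIFF with HU offset by +1024 (spacing
in a JSON sidecar next to the image) or as NIfTI with spacing in the
header. Masks are 8-bit {0, 255} images; any nonzero pixel reads as true.
HU values are kept signed inside the package; the +1024 offset exists only
at the unsigned-format boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .phantom import PhantomGroundTruth
from .types import BinaryMask, CTSlice, HU_MAX, HU_MIN

__all__ = [
    "read_slice",
    "write_slice",
    "read_mask",
    "write_mask",
    "save_sample",
    "load_sample",
    "load_dataset",
]

_UNSIGNED_OFFSET = 1024
_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_slice(ct: CTSlice, path) -> None:
    """Write a slice; integer HU values round-trip losslessly."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([ct.spacing_mm[0], ct.spacing_mm[1], 1.0, 1.0])
        img = nib.Nifti1Image(ct.pixels[:, :, None], affine)
        img.header.set_zooms((ct.spacing_mm[0], ct.spacing_mm[1], 1.0))
        nib.save(img, path)
        return
    if path.suffix.lower() not in _IMAGE_EXTS:
        raise ValueError(f"unsupported slice format: {path.suffix!r}")
    raw = np.clip(np.rint(ct.pixels), HU_MIN, HU_MAX).astype(np.int32)
    iio.imwrite(path, (raw + _UNSIGNED_OFFSET).astype(np.uint16))
    _sidecar(path).write_text(json.dumps({"spacing_mm": list(ct.spacing_mm)}))


def read_slice(path) -> CTSlice:
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 3:
            if data.shape[2] != 1:
                raise ValueError("volume has multiple slices; iterate explicitly")
            data = data[:, :, 0]
        zooms = img.header.get_zooms()
        return CTSlice(data, (float(zooms[0]), float(zooms[1])))
    if path.suffix.lower() not in _IMAGE_EXTS:
        raise ValueError(f"unsupported slice format: {path.suffix!r}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing spacing sidecar {sidecar.name} next to {path.name}: "
            "PNG/TIFF slices carry no pixel spacing"
        )
    spacing = json.loads(sidecar.read_text())["spacing_mm"]
    raw = iio.imread(path).astype(np.float64) - _UNSIGNED_OFFSET
    return CTSlice(raw, (float(spacing[0]), float(spacing[1])))


def write_mask(mask: BinaryMask, path) -> None:
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> BinaryMask:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty mask file: {path}")
    return iio.imread(path) != 0


# -- phantom dataset layout -------------------------------------------------
# <stem>.tif + <stem>.tif.json   slice and spacing sidecar
# <stem>_mask.png                lesion mask {0,255}
# <stem>_tissue.png              tissue-class labels (uint8)
# <stem>.json                    ground-truth metadata


def save_sample(out_dir, stem: str, ct: CTSlice, gt: PhantomGroundTruth) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_slice(ct, out_dir / f"{stem}.tif")
    write_mask(gt.lesion_mask, out_dir / f"{stem}_mask.png")
    iio.imwrite(out_dir / f"{stem}_tissue.png", gt.tissue_map.astype(np.uint8))
    meta = {
        "group": gt.group,
        "skin_thickness_mm": gt.skin_thickness_mm,
        "body_radius_mm": gt.body_radius_mm,
        "fascia_thickness_mm": gt.fascia_thickness_mm,
        "hu_params": {k: list(v) for k, v in gt.hu_params.items()},
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=1))


def load_sample(data_dir, stem: str) -> tuple[CTSlice, PhantomGroundTruth]:
    data_dir = Path(data_dir)
    ct = read_slice(data_dir / f"{stem}.tif")
    lesion = read_mask(data_dir / f"{stem}_mask.png")
    tissue = iio.imread(data_dir / f"{stem}_tissue.png").astype(np.uint8)
    meta = json.loads((data_dir / f"{stem}.json").read_text())
    gt = PhantomGroundTruth(
        tissue_map=tissue,
        lesion_mask=lesion,
        skin_thickness_mm=float(meta["skin_thickness_mm"]),
        hu_params={k: tuple(v) for k, v in meta["hu_params"].items()},
        group=meta["group"],
        body_radius_mm=float(meta["body_radius_mm"]),
        fascia_thickness_mm=float(meta["fascia_thickness_mm"]),
    )
    return ct, gt


def load_dataset(data_dir) -> list[tuple[str, CTSlice, PhantomGroundTruth]]:
    """All samples in a directory, sorted by stem."""
    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise FileNotFoundError(f"data directory not found: {data_dir}")
    stems = sorted(p.name[: -len(".json")] for p in data_dir.glob("*.json")
                   if not p.name.endswith(".tif.json"))
    out = []
    for stem in stems:
        ct, gt = load_sample(data_dir, stem)
        out.append((stem, ct, gt))
    if not out:
        raise FileNotFoundError(f"no samples found in {data_dir}")
    return out
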