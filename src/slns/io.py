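"""Reading and writing slices and masks (8-bit grayscale PNG, NIfTI)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .image import LabelMask, MRImage

__all__ = ["load_image", "save_image", "load_mask", "save_mask"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def load_image(path: str | Path) -> MRImage:
    """Load an 8-bit grayscale PNG or a single-slice NIfTI volume.

    Higher bit depths raise with a conversion hint; NIfTI volumes are
    squeezed to 2-D (single slice) and keep their affine in metadata.
    """
    path = Path(path)
    if _is_nifti(path):
        vol = nib.load(str(path))
        data = np.squeeze(np.asanyarray(vol.dataobj)).astype(np.float64)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-slice volume, got shape {data.shape}")
        return MRImage(np.clip(data, 0, 255), metadata={"path": str(path), "affine": vol.affine.tolist()})
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "F"):
            raise ValueError(
                f"{path}: unsupported bit depth {im.mode!r}; convert to 8-bit grayscale first"
            )
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return MRImage(arr, metadata={"path": str(path)})


def save_image(img: MRImage, path: str | Path) -> None:
    path = Path(path)
    data = np.clip(np.round(img.data), 0, 255).astype(np.uint8)
    if _is_nifti(path):
        affine = np.array(img.metadata.get("affine", np.eye(4)))
        nib.save(nib.Nifti1Image(data[..., None].astype(np.int16), affine), str(path))
    else:
        Image.fromarray(data, mode="L").save(path)


def load_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    if _is_nifti(path):
        data = np.squeeze(np.asanyarray(nib.load(str(path)).dataobj)).astype(np.int64)
    else:
        with Image.open(path) as im:
            data = np.asarray(im, dtype=np.int64)
    return LabelMask(data)


def save_mask(mask: LabelMask, path: str | Path) -> None:
    """Write labels losslessly (palette PNG or int16 NIfTI single slice)."""
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.labels[..., None].astype(np.int16), np.eye(4)), str(path))
    else:
        im = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
        # small fixed palette so the five labels are visually distinct
        palette = [0, 0, 0, 128, 128, 128, 80, 160, 80, 220, 40, 40, 250, 200, 40]
        im.putpalette(palette + [0] * (768 - len(palette)))
        im.save(path)
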