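"""File input/output: images, seed maps, masks and probability rasters.

Grayscale rasters come in as PNG/TIFF, single-slice NIfTI, or single DICOM
slices (rescale slope/intercept applied, pixel spacing honoured).  Seed maps
come in as integer label rasters (0 = unseeded) or CSV with header
``row,col,label``.  Outputs are PNG label masks, float32 TIFF probability
rasters, and JSON run summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .rw_core import GridImage, SeedMap


def load_image(path) -> GridImage:
    path = Path(path)
    suffix = "".join(path.suffixes[-2:]).lower() if path.name.endswith(".nii.gz") else path.suffix.lower()
    if suffix in (".nii", ".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.squeeze(np.asanyarray(img.dataobj)).astype(np.float64)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single 2D slice, got shape {data.shape}")
        zooms = img.header.get_zooms()[:2]
        return GridImage(data.T, spacing=(float(zooms[1]), float(zooms[0])))
    if suffix == ".dcm":
        import pydicom

        ds = pydicom.dcmread(str(path))
        data = ds.pixel_array.astype(np.float64)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single 2D DICOM slice")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        data = data * slope + intercept
        spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
        return GridImage(data, spacing=(float(spacing[0]), float(spacing[1])))
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    else:
        from PIL import Image

        with Image.open(path) as im:
            if im.mode not in ("I", "I;16", "F", "L"):
                im = im.convert("L")
            data = np.asarray(im, dtype=np.float64)
    if data.ndim == 3:  # collapse an RGB(A) raster to luminance
        data = data[..., :3].mean(axis=-1)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale raster, got shape {data.shape}")
    return GridImage(data)


def load_seeds(path, shape: tuple[int, int]) -> SeedMap:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        seeds = SeedMap.from_csv(path)
    else:
        raster = load_image(path).pixels
        seeds = SeedMap.from_raster(np.rint(raster).astype(np.int64))
    seeds.validate_shape(shape)
    return seeds


def load_mask(path) -> np.ndarray:
    return load_image(path).pixels > 0


def save_mask_png(path, mask: np.ndarray) -> None:
    from PIL import Image

    arr = np.asarray(mask)
    Image.fromarray(arr.astype(np.uint8), mode="L").save(str(path))


def save_float_tiff(path, raster: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(raster, dtype=np.float32))


def save_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
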