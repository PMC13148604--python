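"""Frame I/O: single-plane TIFF, HDF5 datasets and NPY arrays.

Mask convention: masked-out pixels are stored as NaN and restored as
masked-out on read, so a write -> read round trip is lossless for values and
mask.  Pixel size travels as an HDF5 attribute when the container supports
attributes, and otherwise must be supplied by the caller (TIFF/NPY).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .imaging_core import Image2D

__all__ = ["read_frame", "write_frame"]

_TIFF = {".tif", ".tiff"}
_HDF5 = {".h5", ".hdf5", ".hdf"}


def _infer_format(path: Path, format: str | None) -> str:
    if format:
        return format.lower()
    suffix = path.suffix.lower()
    if suffix in _TIFF:
        return "tiff"
    if suffix in _HDF5:
        return "hdf5"
    if suffix == ".npy":
        return "npy"
    raise ValueError(f"cannot infer format of {path}: unknown suffix {suffix!r}")


def read_frame(path, format: str | None = None, *, dataset: str = "data",
               pixel_size: float | None = None) -> Image2D:
    """Read a 2D frame; NaN pixels become masked-out."""
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "tiff":
            values = np.asarray(tifffile.imread(path), dtype=float)
        elif fmt == "hdf5":
            with h5py.File(path, "r") as fh:
                if dataset not in fh:
                    raise ValueError(f"dataset {dataset!r} not found")
                ds = fh[dataset]
                values = np.asarray(ds[...], dtype=float)
                if pixel_size is None and "pixel_size" in ds.attrs:
                    pixel_size = float(ds.attrs["pixel_size"])
        elif fmt == "npy":
            values = np.asarray(np.load(path), dtype=float)
        else:
            raise ValueError(f"unsupported format {fmt!r}")
    except (OSError, ValueError) as exc:
        raise ValueError(f"failed to read frame from {path}: {exc}") from exc
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D plane, got shape {values.shape}")
    mask = np.isfinite(values)
    return Image2D(values, pixel_size if pixel_size is not None else 1.0, mask)


def write_frame(img: Image2D, path, format: str | None = None, *,
                dataset: str = "data") -> None:
    """Write a frame; masked-out pixels are stored as NaN (float32 for TIFF)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    out = img.values.copy()
    out[~img.mask] = np.nan
    if fmt == "tiff":
        tifffile.imwrite(path, out.astype(np.float32))
    elif fmt == "hdf5":
        with h5py.File(path, "a") as fh:
            if dataset in fh:
                del fh[dataset]
            ds = fh.create_dataset(dataset, data=out)
            ds.attrs["pixel_size"] = img.pixel_size
    elif fmt == "npy":
        np.save(path, out)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
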