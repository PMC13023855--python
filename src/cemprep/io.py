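"""Raster and manifest I/O.

Every reader funnels into :class:`GrayImage`, a thin wrapper around a 2-D
numpy array with an explicit bit-depth tag.  DICOM quirks (rescale
slope/intercept, MONOCHROME1 inversion) are normalized at read time so the
rest of the pipeline never has to know where an image came from.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

Depth = Literal["u8", "u16", "unit_float"]

VALID_LABELS = ("malignant", "benign_negative")
MANIFEST_COLUMNS = (
    "image_id",
    "patient_id",
    "view",
    "laterality",
    "label",
    "image_path",
    "mask_path",
)

_DEPTH_DTYPE = {"u8": np.uint8, "u16": np.uint16, "unit_float": np.float64}
_DEPTH_MAX = {"u8": 255, "u16": 65535, "unit_float": 1.0}


class FormatError(ValueError):
    """Raised when an input file violates the supported-format contract."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster at a declared bit depth.

    ``u8`` and ``u16`` hold integers in [0, 255] / [0, 65535]; ``unit_float``
    holds reals in [0.0, 1.0].  NaN/Inf are rejected at construction.
    """

    pixels: np.ndarray
    depth: Depth

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got shape {px.shape}")
        if self.depth not in _DEPTH_DTYPE:
            raise ValueError(f"unknown depth {self.depth!r}")
        if self.depth == "unit_float":
            px = px.astype(np.float64, copy=False)
            if not np.all(np.isfinite(px)):
                raise ValueError("GrayImage contains NaN/Inf")
            if px.size and (px.min() < 0.0 or px.max() > 1.0):
                raise ValueError("unit_float pixels outside [0, 1]")
        else:
            if not np.issubdtype(px.dtype, np.integer):
                if not np.all(np.isfinite(px)):
                    raise ValueError("GrayImage contains NaN/Inf")
                if not np.all(px == np.round(px)):
                    raise ValueError(f"{self.depth} pixels must be integral")
            if px.size and (px.min() < 0 or px.max() > _DEPTH_MAX[self.depth]):
                raise ValueError(f"{self.depth} pixels outside [0, {_DEPTH_MAX[self.depth]}]")
            px = px.astype(_DEPTH_DTYPE[self.depth])
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def to_unit_float(self) -> "GrayImage":
        """Explicit conversion to the internal working depth."""
        if self.depth == "unit_float":
            return self
        scale = float(_DEPTH_MAX[self.depth])
        return GrayImage(self.pixels.astype(np.float64) / scale, "unit_float")


def read_gray_png(path: str | os.PathLike) -> GrayImage:
    """Read an 8- or 16-bit grayscale PNG."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise FormatError(f"{path}: expected grayscale PNG, got {arr.shape[2]} channels")
    if arr.dtype == np.uint8:
        return GrayImage(arr, "u8")
    if arr.dtype == np.uint16:
        return GrayImage(arr, "u16")
    raise FormatError(f"{path}: unsupported PNG dtype {arr.dtype}")


def write_gray_png(img: GrayImage, path: str | os.PathLike) -> None:
    if img.depth == "unit_float":
        raise ValueError("convert unit_float to u8/u16 before writing PNG")
    iio.imwrite(path, img.pixels)


def read_gray_dicom(path: str | os.PathLike) -> GrayImage:
    """Read a single-frame grayscale DICOM into a u16 GrayImage.

    Applies RescaleSlope/Intercept, inverts MONOCHROME1 so that brighter
    always means more signal, and shifts the minimum to zero so the result
    fits the unsigned 16-bit contract.
    """
    ds = pydicom.dcmread(path)
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise FormatError(f"{path}: multi-frame DICOM not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise FormatError(f"{path}: color DICOM not supported")
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise FormatError(f"{path}: unsupported photometric interpretation {photometric}")
    try:
        arr = ds.pixel_array.astype(np.float64)
    except Exception as exc:  # pragma: no cover - codec availability
        raise FormatError(f"{path}: cannot decode pixel data ({exc})") from exc
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if photometric == "MONOCHROME1":
        arr = arr.max() - arr
    if arr.size and arr.min() < 0:  # shift only signed data; preserve stored values
        arr = arr - arr.min()
    if arr.max() > 65535:
        arr = arr / arr.max() * 65535.0
    return GrayImage(np.round(arr).astype(np.uint16), "u16")


def write_gray_dicom(img: GrayImage, path: str | os.PathLike) -> None:
    """Write a minimal single-frame secondary-capture DICOM (test fixture writer)."""
    if img.depth != "u16":
        raise ValueError("DICOM writer expects u16")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = img.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = img.pixels.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_gray(path: str | os.PathLike) -> GrayImage:
    """Dispatch on extension: ``.dcm`` → DICOM, otherwise PNG."""
    if str(path).lower().endswith((".dcm", ".dicom")):
        return read_gray_dicom(path)
    return read_gray_png(path)


def _validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c != "mask_path" and c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing mandatory column(s): {missing}")
    if "mask_path" not in df.columns:
        df = df.assign(mask_path="")
    df = df.copy()
    df["mask_path"] = df["mask_path"].fillna("")
    if len(df) == 0:
        raise ValueError("manifest is empty")
    dup = df["image_id"][df["image_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate image_id in manifest: {sorted(set(dup))}")
    bad = sorted(set(df["label"]) - set(VALID_LABELS))
    if bad:
        raise ValueError(f"unknown label token(s): {bad}; expected one of {VALID_LABELS}")
    return df


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Unknown columns are preserved; a missing/blank ``mask_path`` is legal
    (masks are generated later in the pipeline).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: manifest file is empty") from exc
    return _validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    _validate_manifest(manifest).to_csv(path, index=False)
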