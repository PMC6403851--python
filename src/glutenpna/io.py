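"""Image and table input/output.

Micrographs are single-channel 8-bit images (TIFF or PNG).  The default
physical calibration is the confocal setting of 4.76 pixel/µm, stored as
its reciprocal in µm per pixel.  Attribute tables are plain CSV with a
fixed header so they round-trip losslessly through pandas.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

#: µm per pixel side at the study's calibration of 4.76 pixel/µm.
DEFAULT_PIXEL_SIZE_UM: float = 1.0 / 4.76

#: Fixed column order of the attribute CSV.
ATTRIBUTE_COLUMNS = [
    "source_id",
    "lacunarity",
    "branching_rate",
    "endpoint_rate",
    "avg_protein_length_um",
    "protein_width_um",
    "protein_area_um2",
    "n_components",
]

MIN_IMAGE_DIM = 64


class FormatError(ValueError):
    """Raised for images whose bit depth or layout is unsupported."""


@dataclass(frozen=True)
class Micrograph:
    """A 2D grayscale fluorescence micrograph with physical pixel size.

    Parameters
    ----------
    intensities
        2D uint8 array of intensities in [0, 255].
    pixel_size_um
        Physical size of one pixel side in µm; must be positive.
    source_id
        Free-text identifier (usually the file stem).
    """

    intensities: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise FormatError(f"expected a 2D image, got ndim={arr.ndim}")
        if arr.shape[0] < MIN_IMAGE_DIM or arr.shape[1] < MIN_IMAGE_DIM:
            raise ValueError(
                f"image dimensions {arr.shape} below minimum of {MIN_IMAGE_DIM} px"
            )
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise FormatError("intensities outside [0, 255]")
            arr = arr.astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


def read_micrograph(
    path: str | os.PathLike,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel: int = 0,
) -> Micrograph:
    """Read an 8-bit grayscale TIFF or PNG as a :class:`Micrograph`.

    Multi-channel images are reduced by taking ``channel`` (default 0;
    Rhodamine B protein staining is single-channel).  Bit depths other
    than 8 raise :class:`FormatError` naming the depth.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # channel-last (H, W, C) or channel-first (C, H, W)
        if arr.shape[-1] <= 4:
            arr = arr[..., channel]
        else:
            arr = arr[channel]
    if arr.dtype != np.uint8:
        raise FormatError(
            f"unsupported bit depth: {arr.dtype.itemsize * 8}-bit "
            f"({arr.dtype}); expected 8-bit"
        )
    source_id = os.path.splitext(os.path.basename(path))[0]
    return Micrograph(arr, pixel_size_um=pixel_size_um, source_id=source_id)


def write_micrograph(micro: Micrograph, path: str | os.PathLike) -> None:
    """Write the intensities as an 8-bit TIFF or PNG depending on suffix."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, micro.intensities)
    else:
        iio.imwrite(path, micro.intensities)


def write_attribute_table(profiles: list, path: str | os.PathLike) -> None:
    """Write attribute profiles to CSV with the fixed schema.

    One row per profile; comma separator, '.' decimal, UTF-8, no index.
    Round-trips through :func:`read_attribute_table` to within 1e-9.
    """
    if not profiles:
        raise ValueError("profile list is empty")
    rows = [{c: getattr(p, c) for c in ATTRIBUTE_COLUMNS} for p in profiles]
    df = pd.DataFrame(rows, columns=ATTRIBUTE_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_attribute_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an attribute CSV written by :func:`write_attribute_table`."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"attribute table missing columns: {missing}")
    return df[ATTRIBUTE_COLUMNS]
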