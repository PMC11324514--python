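"""File I/O: TIFF stacks with pixel-size metadata, CSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_image", "write_image", "write_table", "read_table"]


def write_image(
    path: str | Path, stack: np.ndarray, pixel_size: float | None = None
) -> None:
    """Write a 2D image or 3D stack as (multi-page) TIFF.

    Float data is stored as float32, integer data as the smallest
    sufficient unsigned integer type. ``pixel_size`` (um per pixel) is
    recorded in the TIFF resolution tags and survives a round trip
    through `read_image`.
    """
    arr = np.asarray(stack)
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    elif np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0:
            arr = arr.astype(np.int32)
        elif arr.max() <= np.iinfo(np.uint16).max:
            arr = arr.astype(np.uint16)
        else:
            arr = arr.astype(np.uint32)
    kwargs: dict[str, Any] = {"photometric": "minisblack"}
    if pixel_size is not None:
        kwargs["resolution"] = (1.0 / pixel_size, 1.0 / pixel_size)
        kwargs["metadata"] = {"unit": "um", "pixel_size_um": pixel_size}
    tifffile.imwrite(str(path), arr, **kwargs)


def read_image(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a (multi-page) TIFF; returns (array, pixel_size or None)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            pixel_size = None
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_size = den / num
    except Exception as exc:  # pragma: no cover - passthrough with path
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    return arr, pixel_size


def write_table(
    records: Sequence[dict] | pd.DataFrame, path: str | Path
) -> None:
    """Write homogeneous records as CSV: documented header, '.' decimals,
    deterministic row and column order (insertion order of the first
    record). An empty record list produces a header-only file only if a
    DataFrame with columns is given; otherwise an empty file with no
    rows."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
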