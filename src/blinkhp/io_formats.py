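"""Readers and writers for the stack and table formats used by the package.

Stacks travel as multi-page grayscale TIFF (uint16 or float32 accepted on
read; float32 written), with the pixel size carried in the image description
as a small JSON record.  Localization and ground-truth tables are plain CSV
with fixed, validated headers -- diff-able and readable by any downstream
tool.  Experiment configuration files are YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .localize import LOC_COLUMNS
from .simulate import TRUTH_COLUMNS
from .stack import DEFAULT_PIXEL_SIZE_NM, DataError, ImageStack

__all__ = [
    "StackMetadata",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "read_yaml",
]

log = logging.getLogger(__name__)

#: Known table schemas: name -> (required columns, integer columns)
TABLE_SCHEMAS = {
    "localizations": (LOC_COLUMNS, ("frame",)),
    "ground_truth": (TRUTH_COLUMNS, ("frame", "emitter_id")),
}


@dataclass
class StackMetadata:
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    frame_interval: float | None = None
    dtype: str = "float32"
    source: str = ""


def read_stack(path) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack.

    Accepts uint16 and float32 pages; all pages must share one shape.  Pixel
    size is taken from the JSON image description written by
    :func:`write_stack` when present, else the documented default (160 nm)
    is applied with a logged notice.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
            description = tif.pages[0].description or ""
    except (tifffile.TiffFileError, ValueError) as exc:
        raise DataError(f"{path} is not a readable TIFF: {exc}") from exc
    if not pages:
        raise DataError(f"{path} contains no image pages")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        bad = next(i for i, p in enumerate(pages) if p.shape != pages[0].shape)
        raise DataError(
            f"{path}: inconsistent page shapes (page {bad} is {pages[bad].shape}, "
            f"page 0 is {pages[0].shape})"
        )
    data = np.stack(pages).astype(np.float64)
    pixel_size = None
    frame_interval = None
    if description:
        try:
            meta = json.loads(description)
            pixel_size = meta.get("pixel_size_nm")
            frame_interval = meta.get("frame_interval_ms")
        except (json.JSONDecodeError, AttributeError):
            pass
    if pixel_size is None:
        pixel_size = DEFAULT_PIXEL_SIZE_NM
        log.info("%s: no pixel size metadata, assuming %.0f nm", path, pixel_size)
    return ImageStack(data, pixel_size=pixel_size, frame_interval=frame_interval)


def write_stack(stack: ImageStack, path) -> None:
    """Write an ImageStack as a float32 multi-page TIFF with JSON metadata."""
    meta = {"pixel_size_nm": stack.pixel_size}
    if stack.frame_interval is not None:
        meta["frame_interval_ms"] = stack.frame_interval
    tifffile.imwrite(
        Path(path),
        stack.data.astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def write_table(table: pd.DataFrame, path, kind: str) -> None:
    """Write a localization or ground-truth table as CSV (schema ``kind``)."""
    columns, _ = _schema(kind)
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise DataError(f"table is missing column(s): {', '.join(missing)}")
    table[list(columns)].to_csv(Path(path), index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a CSV table of schema ``kind``.

    ``kind`` is one of ``"localizations"`` or ``"ground_truth"``.  Raises a
    descriptive error naming any missing column or non-numeric field.
    """
    columns, int_columns = _schema(kind)
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    table = pd.read_csv(path)
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise DataError(f"{path} is missing column(s): {', '.join(missing)}")
    for c in columns:
        if not pd.api.types.is_numeric_dtype(table[c]):
            if len(table):
                raise DataError(f"{path}: column {c!r} is not numeric")
            table[c] = table[c].astype(float)
    for c in int_columns:
        table[c] = table[c].astype(int)
    return table[list(columns)]


def read_yaml(path) -> dict:
    """Load a YAML config file as a plain dict."""
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise DataError(f"{path}: expected a YAML mapping at top level")
    return loaded


def _schema(kind: str):
    try:
        return TABLE_SCHEMAS[kind]
    except KeyError:
        raise DataError(
            f"unknown table kind {kind!r}; expected one of {sorted(TABLE_SCHEMAS)}"
        ) from None
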