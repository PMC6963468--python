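"""Reading and writing 8-bit grayscale images and feature tables.

Images are plain 2-D ``uint8`` numpy arrays (origin top-left, row-major);
PGM (P5) and PNG are the supported carriers and round-trip bit-exactly.
Feature tables are CSV files with one row per image: the eight features in
canonical order followed by a ``label`` column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, SchemaError

#: Canonical per-image feature order used everywhere (CSV schema, subset encoding).
CANONICAL_FEATURES: tuple[str, ...] = (
    "entropy",
    "mean",
    "variance",
    "sd",
    "range",
    "minimum",
    "maximum",
    "rms",
)


def as_gray_image(pixels) -> np.ndarray:
    """Validate and coerce an array to a 2-D uint8 grayscale image."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D grayscale raster, got ndim={arr.ndim}")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise FormatError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PGM/PNG image; colour inputs are luminance-converted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as img:
        if img.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise FormatError(
                f"unsupported bit depth (mode {img.mode!r}); only 8-bit grayscale is supported"
            )
        if img.mode != "L":
            img = img.convert("L")
        return np.asarray(img, dtype=np.uint8)


def write_image(image, path: str | Path) -> None:
    """Write a uint8 grayscale image as PGM (.pgm) or PNG (.png)."""
    arr = as_gray_image(image)
    path = Path(path)
    fmt = {".pgm": "PPM", ".png": "PNG"}.get(path.suffix.lower())
    if fmt is None:
        raise FormatError(f"unsupported image extension {path.suffix!r}")
    Image.fromarray(arr, mode="L").save(path, format=fmt)


def write_features(rows: Iterable[tuple[Sequence[float], str | int]], path: str | Path) -> None:
    """Write (feature_vector, label) rows to CSV with the canonical header.

    Each feature vector must supply the eight canonical features, either as a
    sequence in canonical order or as a mapping/NamedTuple with those names.
    """
    records = []
    for fv, label in rows:
        if hasattr(fv, "_asdict"):
            d = fv._asdict()
        elif isinstance(fv, dict):
            d = dict(fv)
        else:
            vals = list(fv)
            if len(vals) != len(CANONICAL_FEATURES):
                raise SchemaError(
                    f"expected {len(CANONICAL_FEATURES)} features, got {len(vals)}"
                )
            d = dict(zip(CANONICAL_FEATURES, vals))
        if set(d) != set(CANONICAL_FEATURES):
            raise SchemaError(
                f"feature names {sorted(d)} differ from canonical {sorted(CANONICAL_FEATURES)}"
            )
        rec = {name: float(d[name]) for name in CANONICAL_FEATURES}
        rec["label"] = label
        records.append(rec)
    df = pd.DataFrame(records, columns=list(CANONICAL_FEATURES) + ["label"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV back; validates the canonical schema."""
    df = pd.read_csv(path)
    expected = list(CANONICAL_FEATURES) + ["label"]
    if list(df.columns) != expected:
        raise SchemaError(f"columns {list(df.columns)} != expected {expected}")
    return df
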