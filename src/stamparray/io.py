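"""Reading and writing image stacks and tables.

Image series are stored as a single multi-page TIFF with (T, C, Y, X)
axes plus a JSON sidecar carrying pixel size, channel roles and
acquisition-day stamps; intensities are written as 16-bit counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .series import ImageSeries


def save_image_series(series: ImageSeries, path) -> Path:
    """Write a TIFF stack and its JSON sidecar; returns the TIFF path."""
    path = Path(path)
    data = np.clip(np.rint(series.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"axes": "TCYX"})
    sidecar = {
        "pixel_size_um": series.pixel_size_um,
        "channel_roles": series.channel_roles,
        "days": [int(d) for d in series.days],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_image_series(path) -> ImageSeries:
    """Load a TIFF stack written by :func:`save_image_series`."""
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if data.ndim == 3:  # single-channel stack
        data = data[:, None]
    return ImageSeries(
        data=data.astype(float),
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
        pixel_size_um=float(meta["pixel_size_um"]),
        days=[int(d) for d in meta["days"]],
    )


def save_labels(labels: np.ndarray, path) -> Path:
    """Write a ground-truth/segmentation label stack as TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32), metadata={"axes": "TYX"})
    return path


def load_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
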