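"""File formats: 16-bit TIFF images, trace CSVs, annotations and configs.

Conventions: TIFF for images (multi-page, one page per channel, 16-bit);
CSV for traces and scores (human-diffable); JSON for configurations and
ground truth.  The trace CSV dialect has columns ``time_s, roi,
whole_cell`` (``whole_cell`` optional) preceded by comment header rows
``# pre_index=<int>`` and ``# bleach_index=<int>``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from nvjquant.photobleach import IntensityTrace

__all__ = [
    "read_tiff",
    "write_tiff",
    "rgb_to_16bit",
    "write_trace_csv",
    "read_trace_csv",
    "read_scanlines",
]


def write_tiff(pixels: np.ndarray, path: str | Path) -> None:
    """Write a (channels, rows, cols) or (rows, cols) uint16 image.

    Channels are written as separate pages so the file round-trips exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    arr = np.asarray(pixels)
    if arr.dtype != np.uint16:
        raise ValueError(f"expected uint16 pixels, got {arr.dtype}")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D (channel-first) array, got ndim={arr.ndim}")
    tifffile.imwrite(path, arr)


def read_tiff(path: str | Path, allow_rgb: bool = False) -> np.ndarray:
    """Read a TIFF as a (channels, rows, cols) array, pixel-exact.

    Only 8/16-bit grayscale multi-page TIFFs are accepted; an RGB TIFF is
    converted to 16-bit luminance only when ``allow_rgb`` is set, otherwise
    it is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        if not allow_rgb:
            raise ValueError(
                f"{path} is an RGB image; pass allow_rgb to convert to 16-bit luminance"
            )
        return rgb_to_16bit(arr)[None]
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def rgb_to_16bit(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an RGB(A) image, rescaled to the 16-bit range."""
    rgb = np.asarray(rgb, dtype=float)[..., :3]
    lum = rgb @ np.array([0.299, 0.587, 0.114])
    if lum.max() > 0:
        lum = lum / lum.max() * 65535.0
    return np.rint(lum).astype(np.uint16)


def write_trace_csv(trace: IntensityTrace, path: str | Path) -> None:
    """Write an intensity trace in the trace CSV dialect."""
    path = Path(path)
    lines = [f"# pre_index={trace.pre_index}", f"# bleach_index={trace.bleach_index}"]
    if trace.whole_cell is not None:
        lines.append("time_s,roi,whole_cell")
        for t, r, w in zip(trace.times, trace.roi, trace.whole_cell):
            lines.append(f"{t:.10g},{r:.10g},{w:.10g}")
    else:
        lines.append("time_s,roi")
        for t, r in zip(trace.times, trace.roi):
            lines.append(f"{t:.10g},{r:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_trace_csv(path: str | Path) -> IntensityTrace:
    """Read a trace CSV written by :func:`write_trace_csv`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trace file: {path}")
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = int(val)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    for key in ("pre_index", "bleach_index"):
        if key not in meta:
            raise ValueError(f"trace file {path} lacks the '# {key}=' header")
    return IntensityTrace(
        times=df["time_s"].to_numpy(),
        roi=df["roi"].to_numpy(),
        whole_cell=df["whole_cell"].to_numpy() if "whole_cell" in df else None,
        pre_index=meta["pre_index"],
        bleach_index=meta["bleach_index"],
    )


def read_scanlines(path: str | Path) -> tuple[list[dict], float | None]:
    """Read scan-line annotations from JSON (ground-truth sidecar) or CSV.

    The CSV dialect has columns ``cell_id, x0, y0, x1, y1, side`` with side
    in {nvj, opposite}; both lines of a cell must be present.  Returns the
    per-cell records plus the pixel size when the file declares one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such annotation file: {path}")
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return data["cells"], data.get("pixel_size_um")
    df = pd.read_csv(path)
    required = {"cell_id", "x0", "y0", "x1", "y1", "side"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    cells = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        rec = {"cell_id": cell_id}
        for side, key in (("nvj", "scanline_nvj"), ("opposite", "scanline_opposite")):
            row = sub[sub["side"] == side]
            if len(row) != 1:
                raise ValueError(f"cell {cell_id!r} needs exactly one {side!r} line")
            r = row.iloc[0]
            rec[key] = [[float(r.x0), float(r.y0)], [float(r.x1), float(r.y1)]]
        cells.append(rec)
    return cells, None
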