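"""NVJ partitioning index from nuclear-envelope line scans.

The partitioning index of a cell is the ratio of background-subtracted
fluorescence (area under the line-scan profile) at the nucleus--vacuole
junction to that at the antipodal nuclear-envelope region.  A cell whose
ratio strictly exceeds the classification threshold (default 2.0) is
classified as NVJ-partitioned; a field of view is summarised as the
percentage of partitioned cells.

Processing follows the standard Fiji workflow: subtract a Gaussian-blurred
duplicate (sigma 5 px) from the image, take five-pixel-wide line scans
across the nuclear envelope, sum the profile as the AUC, and form the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import profile_line

__all__ = [
    "QuantConfig",
    "LineScan",
    "PartitionScore",
    "background_subtract",
    "line_profile",
    "partition_ratio",
    "summarize_field",
    "quantify_image",
]


@dataclass(frozen=True)
class QuantConfig:
    """Parameters of the partitioning quantification.

    ``blur_sigma`` is the sigma (in pixels) of the Gaussian blur used for
    background subtraction; ``scan_width`` the perpendicular averaging width
    of line scans in pixels (odd); ``scan_length`` the default scan-line
    length in micrometres; ``partition_threshold`` the strict classification
    boundary on the NVJ/opposite AUC ratio.
    """

    blur_sigma: float = 5.0  # px
    scan_width: int = 5  # px, odd
    scan_length: float = 1.5  # um
    partition_threshold: float = 2.0
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise ValueError(f"blur_sigma must be > 0, got {self.blur_sigma}")
        if self.scan_width < 1 or self.scan_width % 2 == 0:
            raise ValueError(
                f"scan_width must be an odd positive integer, got {self.scan_width}"
            )
        if self.partition_threshold <= 0:
            raise ValueError(
                f"partition_threshold must be > 0, got {self.partition_threshold}"
            )


@dataclass(frozen=True)
class LineScan:
    """A width-averaged intensity profile along a line.

    ``sample_positions`` are micrometres along the line, ``profile`` the
    width-averaged intensity at each position, and ``auc`` the sum of
    profile values times the sample spacing.
    """

    sample_positions: np.ndarray  # um
    profile: np.ndarray  # a.u.
    auc: float  # a.u. * um


@dataclass(frozen=True)
class PartitionScore:
    """Per-cell partitioning ratio and its classification."""

    ratio: float
    partitioned: bool


def background_subtract(image: np.ndarray, cfg: QuantConfig = QuantConfig()) -> np.ndarray:
    """Subtract a Gaussian-blurred duplicate of the image from itself.

    Output = input - Gaussian(input, ``blur_sigma``); negative values are
    clamped to zero when ``clamp_negative`` (matching Fiji's behaviour on
    unsigned images).  Returns float64 with the input's shape.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got ndim={img.ndim}")
    if np.isnan(img).any():
        raise ValueError("image contains NaN pixels")
    out = img - ndimage.gaussian_filter(img, sigma=cfg.blur_sigma)
    if cfg.clamp_negative:
        out = np.clip(out, 0.0, None)
    return out


def line_profile(
    image: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    cfg: QuantConfig = QuantConfig(),
    pixel_size: float = 0.1,
) -> LineScan:
    """Width-averaged intensity profile along a line given in micrometres.

    The line is sampled at pixel-spacing steps; at each step the intensity
    is the mean over ``scan_width`` samples taken perpendicular to the line
    with bilinear interpolation.  Endpoints are (x, y) in micrometres with
    x = col * pixel_size.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={img.ndim}")
    (x0, y0), (x1, y1) = line
    src = (y0 / pixel_size, x0 / pixel_size)  # (row, col)
    dst = (y1 / pixel_size, x1 / pixel_size)
    rows, cols = img.shape
    for name, (r, c) in (("start", src), ("end", dst)):
        if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
            raise ValueError(
                f"scan-line {name} point (row={r:.2f}, col={c:.2f}) lies outside "
                f"the {rows}x{cols} image"
            )
    if np.hypot(dst[0] - src[0], dst[1] - src[1]) == 0:
        raise ValueError("zero-length scan line")
    prof = profile_line(
        img, src, dst, linewidth=cfg.scan_width, order=1, mode="constant", cval=0.0
    )
    positions = np.arange(prof.size, dtype=float) * pixel_size
    auc = float(prof.sum() * pixel_size)
    return LineScan(sample_positions=positions, profile=prof, auc=auc)


def partition_ratio(
    scan_nvj: LineScan, scan_opposite: LineScan, cfg: QuantConfig = QuantConfig()
) -> PartitionScore:
    """NVJ partitioning index: AUC at the NVJ over AUC opposite the NVJ.

    Classification is strict: ``partitioned`` iff ratio > threshold, so a
    cell sitting exactly at the threshold is not counted as partitioned.
    """
    if not (np.isfinite(scan_nvj.auc) and np.isfinite(scan_opposite.auc)):
        raise ValueError("line-scan AUCs must be finite")
    if scan_opposite.auc <= 0:
        raise ValueError(
            f"opposite-side AUC is {scan_opposite.auc}; degenerate background "
            "subtraction (no NE signal opposite the NVJ)"
        )
    ratio = scan_nvj.auc / scan_opposite.auc
    return PartitionScore(ratio=float(ratio), partitioned=bool(ratio > cfg.partition_threshold))


def summarize_field(scores: list[PartitionScore]) -> dict:
    """Field-of-view summary: percentage of partitioned cells and n."""
    if not scores:
        raise ValueError("summarize_field requires at least one PartitionScore")
    n = len(scores)
    k = sum(s.partitioned for s in scores)
    return {"n": n, "n_partitioned": k, "percent_partitioned": 100.0 * k / n}


def quantify_image(
    image: np.ndarray,
    cells: list[dict],
    cfg: QuantConfig = QuantConfig(),
    pixel_size: float = 0.1,
) -> list[dict]:
    """Run the full pipeline on one image and scan-line annotations.

    ``cells`` is a list of records with ``cell_id``, ``scanline_nvj`` and
    ``scanline_opposite`` (endpoints in um), as written by the synthetic
    generator or read from annotation files.  Returns one result dict per
    cell with both AUCs, the ratio and the classification.
    """
    sub = background_subtract(image, cfg)
    results = []
    for cell in cells:
        scan_n = line_profile(sub, cell["scanline_nvj"], cfg, pixel_size)
        scan_o = line_profile(sub, cell["scanline_opposite"], cfg, pixel_size)
        score = partition_ratio(scan_n, scan_o, cfg)
        results.append(
            {
                "cell_id": cell.get("cell_id"),
                "auc_nvj": scan_n.auc,
                "auc_opposite": scan_o.auc,
                "ratio": score.ratio,
                "partitioned": score.partitioned,
            }
        )
    return results
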