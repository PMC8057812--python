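"""Synthetic two-channel yeast microscopy images with ground truth.

Renders a GFP-like nuclear-envelope (NE) ring whose angular intensity
profile carries an enriched arc at the nucleus--vacuole junction (NVJ),
plus a second channel with a filled vacuole disc (an FM4-64 stand-in).
Every rendered cell comes with a ground-truth record holding the arc
geometry and the two NE-crossing scan lines (NVJ side and antipodal side)
that the partitioning quantification consumes, so the partitioning index
can be tested against a known enrichment factor.

Model: the NE signal is a radial Gaussian around the nuclear circle with
an angle-dependent amplitude -- ``base_intensity`` outside the NVJ arc and
``enrichment_factor * base_intensity`` inside it.  The image is optionally
convolved with an isotropic Gaussian PSF, Poisson photon noise and Gaussian
read noise are applied, and the result is clipped and quantized to 16-bit.

Coordinates: physical coordinates are (x, y) in micrometres with
x = col * pixel_size and y = row * pixel_size; pixel indices are 0-based
(row, col).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CellSpec",
    "ImagingConfig",
    "SyntheticImage",
    "ring_profile",
    "analytic_arc_mean_ratio",
    "render_cell",
    "render_field",
]


@dataclass(frozen=True)
class CellSpec:
    """Geometric and photometric ground truth for one synthetic cell.

    The NVJ arc is centred at the point of the nuclear circle nearest the
    vacuole centre and spans ``nvj_arc_halfwidth`` radians to either side.
    ``enrichment_factor = 1`` gives a rotationally uniform ring.
    """

    nucleus_center: tuple[float, float]  # (x, y) um
    nucleus_radius: float  # um
    vacuole_center: tuple[float, float]  # (x, y) um
    vacuole_radius: float  # um
    # the NVJ expands to ~2 um of apposition under glucose restriction;
    # 1.0 rad on a ~1 um nucleus matches that span
    nvj_arc_halfwidth: float = 1.0  # radians, in (0, pi/2]
    enrichment_factor: float = 1.0  # >= 1
    ne_ring_sigma: float = 0.1  # um, radial Gaussian thickness of the NE signal
    base_intensity: float = 2000.0  # a.u.
    cytoplasm_intensity: float = 100.0  # a.u.

    def __post_init__(self) -> None:
        if self.nucleus_radius <= 0:
            raise ValueError(f"nucleus_radius must be > 0, got {self.nucleus_radius}")
        if self.vacuole_radius <= 0:
            raise ValueError(f"vacuole_radius must be > 0, got {self.vacuole_radius}")
        if not (0 < self.nvj_arc_halfwidth <= math.pi / 2):
            raise ValueError(
                f"nvj_arc_halfwidth must lie in (0, pi/2], got {self.nvj_arc_halfwidth}"
            )
        if self.enrichment_factor < 1:
            raise ValueError(
                f"enrichment_factor must be >= 1, got {self.enrichment_factor}"
            )
        if self.ne_ring_sigma <= 0:
            raise ValueError(f"ne_ring_sigma must be > 0, got {self.ne_ring_sigma}")
        if self.base_intensity <= 0:
            raise ValueError(f"base_intensity must be > 0, got {self.base_intensity}")
        if self.cytoplasm_intensity < 0:
            raise ValueError(
                f"cytoplasm_intensity must be >= 0, got {self.cytoplasm_intensity}"
            )

    @property
    def nvj_angle(self) -> float:
        """Angle (radians) of the NVJ arc centre on the nuclear circle."""
        dx = self.vacuole_center[0] - self.nucleus_center[0]
        dy = self.vacuole_center[1] - self.nucleus_center[1]
        return math.atan2(dy, dx)


@dataclass(frozen=True)
class ImagingConfig:
    """Rendering configuration: sampling, optics surrogate, camera noise.

    With identical ``rng_seed`` and configuration, rendering is
    bit-identical.  Output pixel values lie in ``[0, 2**bit_depth - 1]``.
    """

    pixel_size: float = 0.1  # um / px
    image_shape: tuple[int, int] = (128, 128)  # (rows, cols)
    psf_sigma: float = 0.1  # um, isotropic Gaussian PSF; 0 disables
    poisson_noise: bool = True
    read_noise_sigma: float = 5.0  # a.u.
    bit_depth: int = 16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.psf_sigma < 0:
            raise ValueError(f"psf_sigma must be >= 0, got {self.psf_sigma}")
        if self.read_noise_sigma < 0:
            raise ValueError(
                f"read_noise_sigma must be >= 0, got {self.read_noise_sigma}"
            )
        if self.bit_depth != 16:
            raise ValueError(f"only bit_depth=16 is supported, got {self.bit_depth}")


@dataclass
class SyntheticImage:
    """A rendered 2-channel image plus the per-cell ground-truth table.

    ``pixels`` has shape (2, rows, cols), dtype uint16: channel 0 is the NE
    ring (GFP-like), channel 1 the vacuole disc.  ``ground_truth`` is a list
    of per-cell records with the arc geometry and scan-line endpoints (um).
    """

    pixels: np.ndarray
    pixel_size: float
    ground_truth: list[dict] = field(default_factory=list)

    def save(self, tiff_path: str | Path, json_path: str | Path | None = None) -> None:
        from nvjquant.io import write_tiff

        write_tiff(self.pixels, tiff_path)
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps({"pixel_size_um": self.pixel_size, "cells": self.ground_truth}, indent=2)
            )


def ring_profile(spec: CellSpec, theta: np.ndarray) -> np.ndarray:
    """Analytic angular amplitude of the NE ring at angles ``theta``.

    This is the pre-rasterization ground truth: ``base_intensity`` outside
    the NVJ arc, ``enrichment_factor * base_intensity`` inside it.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.angle(np.exp(1j * (theta - spec.nvj_angle)))
    inside = np.abs(delta) <= spec.nvj_arc_halfwidth
    return np.where(inside, spec.enrichment_factor * spec.base_intensity, spec.base_intensity)


def analytic_arc_mean_ratio(spec: CellSpec, n_samples: int = 4096) -> float:
    """Ratio of the analytic profile's mean over the NVJ arc to its mean
    over the antipodal arc; equals ``enrichment_factor`` exactly."""
    half = spec.nvj_arc_halfwidth
    th = np.linspace(-half, half, n_samples)
    nvj_mean = ring_profile(spec, spec.nvj_angle + th).mean()
    opp_mean = ring_profile(spec, spec.nvj_angle + math.pi + th).mean()
    return float(nvj_mean / opp_mean)


def _scanline(spec: CellSpec, angle: float, length: float) -> list[list[float]]:
    """Radial scan line of ``length`` um centred on the NE crossing at ``angle``."""
    cx, cy = spec.nucleus_center
    ux, uy = math.cos(angle), math.sin(angle)
    r0 = spec.nucleus_radius - length / 2
    r1 = spec.nucleus_radius + length / 2
    return [[cx + r0 * ux, cy + r0 * uy], [cx + r1 * ux, cy + r1 * uy]]


def _cell_extent(spec: CellSpec, scanline_length: float) -> float:
    """Radius (um) of the disc around the nucleus centre that the rendered
    cell (ring + scan lines + vacuole) can touch."""
    d = math.hypot(
        spec.vacuole_center[0] - spec.nucleus_center[0],
        spec.vacuole_center[1] - spec.nucleus_center[1],
    )
    return max(
        spec.nucleus_radius + scanline_length / 2 + 3 * spec.ne_ring_sigma,
        d + spec.vacuole_radius,
    )


def _check_in_bounds(spec: CellSpec, cfg: ImagingConfig, scanline_length: float) -> None:
    rows, cols = cfg.image_shape
    width = cols * cfg.pixel_size
    height = rows * cfg.pixel_size
    ext = _cell_extent(spec, scanline_length)
    cx, cy = spec.nucleus_center
    for name, val, lim in (
        ("x_min", cx - ext, 0.0),
        ("y_min", cy - ext, 0.0),
    ):
        if val < lim:
            raise ValueError(
                f"cell geometry extends outside image: {name}={val:.3f} um < {lim}"
            )
    if cx + ext > width:
        raise ValueError(
            f"cell geometry extends outside image: x_max={cx + ext:.3f} um > {width:.3f}"
        )
    if cy + ext > height:
        raise ValueError(
            f"cell geometry extends outside image: y_max={cy + ext:.3f} um > {height:.3f}"
        )


def _render_expected(specs: list[CellSpec], cfg: ImagingConfig) -> np.ndarray:
    """Noise-free expected-photon image (2, rows, cols), before PSF."""
    rows, cols = cfg.image_shape
    y = (np.arange(rows, dtype=float) * cfg.pixel_size)[:, None]
    x = (np.arange(cols, dtype=float) * cfg.pixel_size)[None, :]
    ch_ring = np.zeros((rows, cols))
    ch_vac = np.zeros((rows, cols))
    for spec in specs:
        cx, cy = spec.nucleus_center
        dx = x - cx
        dy = y - cy
        r = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        amp = ring_profile(spec, theta)
        ring = amp * np.exp(-0.5 * ((r - spec.nucleus_radius) / spec.ne_ring_sigma) ** 2)
        # cytoplasmic haze: uniform disc standing in for the cell body
        body = r <= 1.8 * spec.nucleus_radius
        ch_ring += ring + spec.cytoplasm_intensity * body
        vx, vy = spec.vacuole_center
        rv = np.hypot(x - vx, y - vy)
        ch_vac += spec.base_intensity * (rv <= spec.vacuole_radius)
    return np.stack([ch_ring, ch_vac])


def _finalize(expected: np.ndarray, cfg: ImagingConfig) -> np.ndarray:
    out = expected.copy()
    if cfg.psf_sigma > 0:
        sig_px = cfg.psf_sigma / cfg.pixel_size
        for c in range(out.shape[0]):
            out[c] = ndimage.gaussian_filter(out[c], sigma=sig_px)
    rng = np.random.default_rng(cfg.rng_seed)
    if cfg.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if cfg.read_noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sigma, size=out.shape)
    vmax = 2**cfg.bit_depth - 1
    return np.clip(np.rint(out), 0, vmax).astype(np.uint16)


def render_cell(
    spec: CellSpec, cfg: ImagingConfig, scanline_length: float = 1.5
) -> SyntheticImage:
    """Render a single cell into a fresh 2-channel image.

    Channel 0 carries the NE ring (NVJ-enriched arc), channel 1 the vacuole
    disc.  The ground-truth record stores the enrichment factor, the arc
    geometry and the two radial scan lines (``scanline_nvj`` crossing the NE
    at the NVJ, ``scanline_opposite`` at the antipodal point), each of
    ``scanline_length`` um centred on the NE crossing.
    """
    _check_in_bounds(spec, cfg, scanline_length)
    expected = _render_expected([spec], cfg)
    pixels = _finalize(expected, cfg)
    record = _ground_truth_record(spec, cell_id=0, scanline_length=scanline_length)
    return SyntheticImage(pixels=pixels, pixel_size=cfg.pixel_size, ground_truth=[record])


def _ground_truth_record(spec: CellSpec, cell_id: int, scanline_length: float) -> dict:
    return {
        "cell_id": cell_id,
        "center": list(spec.nucleus_center),
        "radius": spec.nucleus_radius,
        "enrichment": spec.enrichment_factor,
        "nvj_angle": spec.nvj_angle,
        "nvj_arc_halfwidth": spec.nvj_arc_halfwidth,
        "scanline_nvj": _scanline(spec, spec.nvj_angle, scanline_length),
        "scanline_opposite": _scanline(spec, spec.nvj_angle + math.pi, scanline_length),
    }


def render_field(
    specs: list[CellSpec],
    cfg: ImagingConfig,
    scanline_length: float = 1.5,
    margin: float = 0.5,
) -> SyntheticImage:
    """Render a field of non-overlapping cells into one image.

    Cells must be pairwise separated by more than the sum of their extents
    plus ``margin`` (um).  The ground-truth table has one row per cell.
    """
    if not specs:
        raise ValueError("render_field requires at least one CellSpec")
    exts = [_cell_extent(s, scanline_length) for s in specs]
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            d = math.hypot(
                specs[i].nucleus_center[0] - specs[j].nucleus_center[0],
                specs[i].nucleus_center[1] - specs[j].nucleus_center[1],
            )
            if d <= exts[i] + exts[j] + margin:
                raise ValueError(
                    f"cells {i} and {j} overlap: center distance {d:.3f} um <= "
                    f"{exts[i] + exts[j] + margin:.3f} um"
                )
    for spec in specs:
        _check_in_bounds(spec, cfg, scanline_length)
    expected = _render_expected(specs, cfg)
    pixels = _finalize(expected, cfg)
    records = [
        _ground_truth_record(s, cell_id=i, scanline_length=scanline_length)
        for i, s in enumerate(specs)
    ]
    return SyntheticImage(pixels=pixels, pixel_size=cfg.pixel_size, ground_truth=records)


def grid_field_specs(
    enrichments: Sequence[float],
    n_cols: int = 5,
    pitch: float = 7.0,
    origin: float = 4.0,
) -> tuple[list[CellSpec], tuple[int, int]]:
    """Lay one cell per enrichment factor on a regular grid.

    Returns the specs plus the (rows, cols) image shape (at the default
    0.1 um pixel size) that contains them all.  Cells are standard demo
    geometry (1.05 um nucleus, vacuole apposed from the +x side) spaced
    ``pitch`` um apart, comfortably beyond the non-overlap margin.
    """
    specs = []
    for i, e in enumerate(enrichments):
        r, c = divmod(i, n_cols)
        cx = origin + c * pitch
        cy = origin + r * pitch
        specs.append(
            CellSpec(
                nucleus_center=(cx, cy),
                nucleus_radius=1.05,
                vacuole_center=(cx + 2.1, cy),
                vacuole_radius=1.0,
                enrichment_factor=e,
            )
        )
    n_rows_cells = -(-len(enrichments) // n_cols)
    width = origin + (min(len(enrichments), n_cols) - 1) * pitch + origin
    height = origin + (n_rows_cells - 1) * pitch + origin
    shape = (int(round(height / 0.1)), int(round(width / 0.1)))
    return specs, shape


def spec_to_dict(spec: CellSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> CellSpec:
    d = dict(d)
    d["nucleus_center"] = tuple(d["nucleus_center"])
    d["vacuole_center"] = tuple(d["vacuole_center"])
    return CellSpec(**d)
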