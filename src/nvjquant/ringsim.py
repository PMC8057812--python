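"""Photobleaching kinetics on a 1-D nuclear-envelope ring.

Mechanistic ground-truth generator for FRAP/FLIP traces: a fluorophore
diffuses on a periodic 1-D ring (the nuclear-envelope circumference) and
binds reversibly inside a contiguous NVJ domain.  Free molecules diffuse
with coefficient D; inside the NVJ they convert to an immobile bound pool
at rate ``k_on`` and return at ``k_off`` -- the minimal mechanism for
selective retention at the junction.  Bleach events multiply both pools
inside a region of interest by a survival fraction, and traces record the
ROI-integrated total (free + bound) signal at the acquisition frames.

The PDE is integrated deterministically by operator splitting: explicit
finite-difference diffusion (time step automatically kept below the
0.5 dx^2 / D stability bound) alternating with an exact local update of the
linear binding exchange.  Optional Gaussian measurement noise can be added
to the emitted traces, seeded.

Default acquisition schedules mirror spinning-disk photobleaching protocols:
FRAP is one pre-bleach frame, a single bleach, then frames every 500 ms for
a 25 s movie; FLIP is 50 bleach cycles (pre-bleach frame, bleach, four
post-bleach frames 500 ms apart) padded to a 6 s period, i.e. a 300 s movie.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from nvjquant.photobleach import (
    IntensityTrace,
    flip_normalize,
    fit_flip_decay,
)

__all__ = [
    "RingParams",
    "Protocol",
    "simulate",
    "default_protocols",
    "calibrate_demo",
    "DEMO_RETAINED",
    "DEMO_FREE",
]

BLEACH_ROI_AREA_UM2 = 0.77  # circular bleach spot area (metadata)
# arc length subtended on the ring by a disc of that area (its diameter)
BLEACH_ARC_UM = 2.0 * math.sqrt(BLEACH_ROI_AREA_UM2 / math.pi)


@dataclass(frozen=True)
class RingParams:
    """Ring geometry, transport and binding parameters.

    ``nvj_span`` is the arc length (um) of the contiguous NVJ binding
    domain, centred at ring coordinate 0.  ``k_on`` acts only inside that
    domain; the bound pool is immobile.
    """

    circumference: float = 6.4  # um (yeast nucleus, radius ~1.02 um)
    n_sites: int = 128
    D: float = 0.45  # um^2/s
    nvj_span: float = 1.2  # um
    k_on: float = 0.0  # 1/s, free -> bound inside the NVJ
    k_off: float = 1.0  # 1/s, bound -> free
    initial_density: float = 1000.0  # a.u. / um

    def __post_init__(self) -> None:
        if self.circumference <= 0:
            raise ValueError(f"circumference must be > 0, got {self.circumference}")
        if self.n_sites < 32:
            raise ValueError(f"n_sites must be >= 32, got {self.n_sites}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if not (0 <= self.nvj_span < self.circumference):
            raise ValueError(
                f"nvj_span must lie in [0, circumference), got {self.nvj_span}"
            )
        if self.k_on < 0:
            raise ValueError(f"k_on must be >= 0, got {self.k_on}")
        if self.k_on > 0 and self.k_off <= 0:
            raise ValueError("k_off must be > 0 when k_on > 0")
        if self.initial_density <= 0:
            raise ValueError(f"initial_density must be > 0, got {self.initial_density}")

    @property
    def dx(self) -> float:
        return self.circumference / self.n_sites


@dataclass(frozen=True)
class Protocol:
    """A timed bleach/acquisition schedule on the ring.

    ``bleach_events`` are (time s, roi name, survival fraction) triples;
    ``roi_definitions`` maps names to arc intervals (start, end) in um on
    the ring (wrapping allowed), and must include "whole" for the entire
    ring.  ``roi_area_label`` records the nominal 2-D bleach-spot area and
    is metadata only.
    """

    kind: str  # "frap" or "flip"
    frame_times: np.ndarray  # s
    bleach_events: list[tuple[float, str, float]]
    roi_definitions: dict[str, tuple[float, float]] = field(default_factory=dict)
    roi_area_label: float = BLEACH_ROI_AREA_UM2

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, dtype=float))
        if self.kind not in ("frap", "flip"):
            raise ValueError(f"kind must be 'frap' or 'flip', got {self.kind!r}")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        for t, roi, s in self.bleach_events:
            if roi not in self.roi_definitions:
                raise ValueError(f"bleach event references unknown ROI {roi!r}")
            if not (0 <= s < 1):
                raise ValueError(f"survival fraction must lie in [0, 1), got {s}")
        if "whole" not in self.roi_definitions:
            raise ValueError("roi_definitions must include 'whole'")

    @property
    def pre_index(self) -> int:
        """Index of the last frame before the first bleach (0 if no bleach)."""
        if not self.bleach_events:
            return 0
        first_bleach = min(t for t, _, _ in self.bleach_events)
        idx = np.nonzero(self.frame_times < first_bleach)[0]
        if idx.size == 0:
            raise ValueError("no pre-bleach frame before the first bleach event")
        return int(idx[-1])

    @property
    def bleach_index(self) -> int:
        """Index of the first frame at/after the first bleach (1 if no bleach)."""
        if not self.bleach_events:
            return 1
        first_bleach = min(t for t, _, _ in self.bleach_events)
        idx = np.nonzero(self.frame_times >= first_bleach)[0]
        if idx.size == 0:
            raise ValueError("no frame after the first bleach event")
        return int(idx[0])


def default_protocols(params: RingParams = RingParams()) -> tuple[Protocol, Protocol]:
    """Default FRAP and FLIP schedules sized to ``params``' ring.

    FRAP: pre-bleach frame at t=0, one bleach of the NVJ spot, then frames
    every 0.5 s out to 25 s.  FLIP: 50 cycles of (pre frame, bleach of a
    spot antipodal to the NVJ, four post frames 0.5 s apart) on a 6 s
    period, closed by a terminal frame at 300 s.
    """
    L = params.circumference
    half_nvj = params.nvj_span / 2 if params.nvj_span > 0 else BLEACH_ARC_UM / 2
    rois = {
        "nvj": (-half_nvj, half_nvj),
        "opposite_ne": (L / 2 - BLEACH_ARC_UM / 2, L / 2 + BLEACH_ARC_UM / 2),
        "whole": (0.0, L),
    }
    frap_frames = np.concatenate([[0.0], np.arange(0.5, 25.0 + 1e-9, 0.5)])
    frap = Protocol(
        kind="frap",
        frame_times=frap_frames,
        bleach_events=[(0.25, "nvj", 0.1)],
        roi_definitions=rois,
    )
    cycle_frames = []
    bleaches = []
    for c in range(50):
        t0 = 6.0 * c
        cycle_frames.extend([t0, t0 + 0.5, t0 + 1.0, t0 + 1.5, t0 + 2.0])
        bleaches.append((t0 + 0.25, "opposite_ne", 0.1))
    cycle_frames.append(300.0)
    flip = Protocol(
        kind="flip",
        frame_times=np.array(cycle_frames),
        bleach_events=bleaches,
        roi_definitions=rois,
    )
    return frap, flip


def _roi_mask(params: RingParams, interval: tuple[float, float]) -> np.ndarray:
    """Boolean site mask for an arc interval (start, end) um, with wrap."""
    a, b = interval
    span = b - a
    if span <= 0 or span > params.circumference + 1e-12:
        raise ValueError(f"ROI interval {interval} does not lie on the ring")
    x = (np.arange(params.n_sites) + 0.5) * params.dx
    rel = np.mod(x - a, params.circumference)
    return rel < span - 1e-12 * params.circumference


def _roi_weights(params: RingParams, interval: tuple[float, float]) -> np.ndarray:
    """Partial-volume weights in [0, 1]: fraction of each grid cell covered
    by the arc interval (start, end) um, with wrap.  Edge cells get
    fractional weight so ROI totals converge smoothly with n_sites."""
    a, b = interval
    span = b - a
    L = params.circumference
    if span <= 0 or span > L + 1e-12:
        raise ValueError(f"ROI interval {interval} does not lie on the ring")
    span = min(span, L)
    dx = params.dx
    start = np.mod(np.arange(params.n_sites) * dx - a, L)  # cell start, arc frame
    direct = np.clip(np.minimum(start + dx, span) - start, 0.0, dx)
    wrapped = np.clip(np.minimum(start + dx - L, span), 0.0, dx)
    return (direct + wrapped) / dx


def simulate(
    params: RingParams,
    protocol: Protocol,
    seed: int | None = None,
    noise_sigma: float = 0.0,
    dt: float | None = None,
    return_state: bool = False,
    initial_free: np.ndarray | None = None,
) -> dict[str, IntensityTrace] | tuple[dict[str, IntensityTrace], np.ndarray, np.ndarray]:
    """Integrate the ring model under a bleaching protocol.

    Returns one :class:`IntensityTrace` per ROI in the protocol, each with
    the ROI-integrated total (free + bound) signal at the frame times and
    the whole-ring signal as its ``whole_cell`` channel.  The initial state
    is the binding equilibrium (uniform free density; bound = k_on/k_off
    times free inside the NVJ), so pre-bleach frames are stationary.

    ``dt`` overrides the automatic time step; it must satisfy the explicit
    diffusion stability bound dt <= 0.5 dx^2 / D.  ``initial_free``
    replaces the uniform initial free density (bound still starts at local
    binding equilibrium); with ``return_state`` the final (free, bound)
    site arrays are returned alongside the traces.
    """
    dx = params.dx
    dt_stable = 0.5 * dx * dx / params.D
    if dt is not None and dt > dt_stable:
        raise ValueError(
            f"time step {dt:g} s violates the diffusion stability bound; "
            f"use dt <= {dt_stable:g} s"
        )
    dt_max = dt if dt is not None else 0.8 * dt_stable
    rate = params.k_on + params.k_off
    if rate > 0:
        dt_max = min(dt_max, 0.2 / rate)

    weights = {
        name: _roi_weights(params, iv) for name, iv in protocol.roi_definitions.items()
    }
    nvj_w = (
        _roi_weights(params, (-params.nvj_span / 2, params.nvj_span / 2))
        if params.nvj_span > 0
        else np.zeros(params.n_sites)
    )
    # per-site on-rate: edge cells of the NVJ domain bind at reduced rate
    kon_i = params.k_on * nvj_w

    if initial_free is not None:
        free = np.asarray(initial_free, dtype=float).copy()
        if free.shape != (params.n_sites,):
            raise ValueError("initial_free must have n_sites entries")
    else:
        free = np.full(params.n_sites, params.initial_density)
    bound = np.zeros(params.n_sites)
    if params.k_on > 0:
        bound = kon_i / params.k_off * free

    # merge frames and bleaches into one event schedule
    events: list[tuple[float, str, object]] = [
        (t, "frame", i) for i, t in enumerate(protocol.frame_times)
    ]
    events += [(t, "bleach", (roi, s)) for t, roi, s in protocol.bleach_events]
    events.sort(key=lambda e: (e[0], 0 if e[1] == "frame" else 1))

    alpha = params.D / (dx * dx)
    kon, koff = params.k_on, params.k_off
    rate_i = kon_i + koff  # per-site total exchange rate
    frac_free_i = np.where(rate_i > 0, koff / np.where(rate_i > 0, rate_i, 1.0), 1.0)

    n_frames = protocol.frame_times.size
    signals = {name: np.empty(n_frames) for name in weights}

    t_now = min(0.0, events[0][0]) if events else 0.0
    for t_ev, etype, payload in events:
        span = t_ev - t_now
        if span > 1e-12:
            n_steps = max(1, int(math.ceil(span / dt_max)))
            h = span / n_steps
            lam = alpha * h
            decay = np.exp(-rate_i * h) if kon > 0 else None
            for _ in range(n_steps):
                free = free + lam * (np.roll(free, 1) + np.roll(free, -1) - 2.0 * free)
                if kon > 0:
                    # exact local relaxation of the linear exchange
                    tot = free + bound
                    feq = frac_free_i * tot
                    free = feq + (free - feq) * decay
                    bound = tot - free
        t_now = t_ev
        if etype == "frame":
            total = free + bound
            for name, w in weights.items():
                signals[name][payload] = float(total @ w) * dx
        else:
            roi, s = payload
            # a cell covered by fraction w of the bleach spot keeps
            # (1 - w) + w * s of its content
            keep = 1.0 - weights[roi] * (1.0 - s)
            free = free * keep
            bound = bound * keep

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        for name in signals:
            scale = noise_sigma * signals[name][protocol.pre_index]
            signals[name] = np.clip(
                signals[name] + rng.normal(0.0, scale, n_frames), 0.0, None
            )

    whole = signals["whole"]
    traces = {}
    for name in signals:
        traces[name] = IntensityTrace(
            times=protocol.frame_times.copy(),
            roi=signals[name],
            whole_cell=whole.copy(),
            pre_index=protocol.pre_index,
            bleach_index=protocol.bleach_index,
        )
    if return_state:
        return traces, free, bound
    return traces


# Documented demo parameter sets for the retention demonstration: identical
# rings, with and without NVJ binding.  With binding (k_on/k_off = 20, so
# ~95% of the NVJ pool is immobile at any instant) the NVJ signal outlives
# repeated distal bleaching with a halftime of a few hundred seconds;
# without binding the NE pool is depleted with a halftime of tens of
# seconds, limited by the bleach-cycle rate and diffusion to the spot.
DEMO_RETAINED = RingParams(k_on=1.0, k_off=0.05)
DEMO_FREE = RingParams(k_on=0.0, k_off=1.0)


def calibrate_demo(
    params_retained: RingParams = DEMO_RETAINED,
    params_free: RingParams = DEMO_FREE,
) -> dict:
    """FLIP retention demonstration: NVJ halftime with vs without binding.

    Runs the default FLIP schedule on both parameter sets, fits one-phase
    decays to the NVJ-ROI traces, and reports the fitted halftimes together
    with qualitative checks: the retained halftime should exceed 100 s and
    the free halftime sit near 25 s for the documented demo parameters.
    This is a calibrated qualitative demonstration, not an inference of
    in vivo rate constants.
    """
    report: dict = {}
    for label, params in (("retained", params_retained), ("free", params_free)):
        _, flip = default_protocols(params)
        traces = simulate(params, flip)
        fit = fit_flip_decay(flip_normalize(traces["nvj"]))
        if not fit.converged:
            raise RuntimeError(f"FLIP decay fit did not converge for the {label} set")
        report[f"halftime_{label}_s"] = fit.halftime
        report[f"rate_{label}_per_s"] = fit.rate_k
    report["ordering_ok"] = report["halftime_retained_s"] > report["halftime_free_s"]
    report["retained_gt_100s"] = report["halftime_retained_s"] > 100.0
    report["free_near_25s"] = abs(report["halftime_free_s"] - 25.0) <= 10.0
    return report
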