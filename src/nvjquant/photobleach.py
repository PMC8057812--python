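"""FRAP/FLIP trace normalization and one-phase exponential halftime fits.

FRAP traces are normalized with the double-normalization method,

    I_norm(t) = (I_wc(pre) / I_wc(t)) * (I_roi(t) / I_roi(pre)),

which corrects the bleached-ROI signal for the fluorescence lost from the
whole cell during monitoring.  Full normalization then rescales the curve
between its pre-bleach and bleach values so pre-bleach reads 1 and the
bleach frame reads 0.  FLIP traces are normalized simply to the pre-bleach
ROI intensity, I_FLIP(t) = I_roi(t) / I_roi(pre).

Halftimes come from one-phase exponential fits with the bleach frame as
time origin:

    association (FRAP recovery):  y(t') = Y_inf * (1 - exp(-k t'))
    decay (FLIP loss):            y(t') = y0 * exp(-k t') + c,  c = 0 by default

with t' measured from the bleach frame and halftime = ln 2 / k.  Fits are
deterministic: the rate is initialized from a log-linear regression and
refined by bounded least squares, with no random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "IntensityTrace",
    "NormalizedTrace",
    "ExpFitResult",
    "OnePhaseModel",
    "frap_double_normalize",
    "frap_full_normalize",
    "flip_normalize",
    "fit_one_phase",
    "fit_frap_recovery",
    "fit_flip_decay",
    "halftime_summary",
]

K_BOUNDS = (1e-6, 1e3)  # 1/s


@dataclass(frozen=True)
class IntensityTrace:
    """A photobleaching intensity time series.

    ``roi`` holds the bleached/monitored ROI intensity per frame (I_frap for
    FRAP, I_NVJ for FLIP); ``whole_cell`` the whole-cell intensity (optional
    for FLIP).  ``pre_index`` is the frame preceding the (first) bleach;
    ``bleach_index`` the frame at/immediately after photobleaching.
    """

    times: np.ndarray  # s, strictly increasing
    roi: np.ndarray  # a.u.
    whole_cell: np.ndarray | None = None  # a.u.
    pre_index: int = 0
    bleach_index: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "roi", np.asarray(self.roi, dtype=float))
        if self.whole_cell is not None:
            object.__setattr__(self, "whole_cell", np.asarray(self.whole_cell, dtype=float))
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-D array with at least two frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.roi.shape != self.times.shape:
            raise ValueError("roi and times must have equal length")
        if self.whole_cell is not None and self.whole_cell.shape != self.times.shape:
            raise ValueError("whole_cell and times must have equal length")
        if np.any(self.roi < 0) or (
            self.whole_cell is not None and np.any(self.whole_cell < 0)
        ):
            raise ValueError("intensities must be non-negative")
        if not (0 <= self.pre_index < self.bleach_index < self.times.size):
            raise ValueError(
                f"need 0 <= pre_index < bleach_index < n_frames, got "
                f"pre_index={self.pre_index}, bleach_index={self.bleach_index}, "
                f"n_frames={self.times.size}"
            )


@dataclass(frozen=True)
class NormalizedTrace:
    """A dimensionless normalized trace of kind frap_double, frap_full or flip."""

    times: np.ndarray  # s
    values: np.ndarray
    kind: Literal["frap_double", "frap_full", "flip"]
    pre_index: int = 0
    bleach_index: int = 1


def frap_double_normalize(trace: IntensityTrace) -> NormalizedTrace:
    """Double normalization of a FRAP trace.

    value(t) = (whole_cell(pre) / whole_cell(t)) * (roi(t) / roi(pre)).
    The pre-bleach frame normalizes to exactly 1.
    """
    if trace.whole_cell is None:
        raise ValueError("FRAP double normalization requires a whole_cell trace")
    roi_pre = trace.roi[trace.pre_index]
    if roi_pre <= 0:
        raise ValueError(f"roi at pre_index={trace.pre_index} must be > 0, got {roi_pre}")
    zero = np.nonzero(trace.whole_cell <= 0)[0]
    if zero.size:
        raise ValueError(f"whole_cell is non-positive at frame {zero[0]}")
    wc_pre = trace.whole_cell[trace.pre_index]
    values = (wc_pre / trace.whole_cell) * (trace.roi / roi_pre)
    return NormalizedTrace(
        times=trace.times,
        values=values,
        kind="frap_double",
        pre_index=trace.pre_index,
        bleach_index=trace.bleach_index,
    )


def frap_full_normalize(trace: IntensityTrace | NormalizedTrace) -> NormalizedTrace:
    """Full normalization: rescale the double-normalized curve so the
    pre-bleach frame reads 1 and the bleach frame reads 0.

    v_full(t) = (v(t) - v(bleach)) / (v(pre) - v(bleach)), where v is the
    double-normalized curve.  Accepts either a raw trace (double
    normalization is applied first) or an already double-normalized trace;
    re-application changes nothing.
    """
    if isinstance(trace, IntensityTrace):
        dn = frap_double_normalize(trace)
    elif trace.kind in ("frap_double", "frap_full"):
        dn = trace
    else:
        raise ValueError(f"cannot fully normalize a trace of kind {trace.kind!r}")
    v = dn.values
    v_pre = v[dn.pre_index]
    v_bleach = v[dn.bleach_index]
    if v_pre == v_bleach:
        raise ValueError(
            "no bleach depth: double-normalized values at pre and bleach frames are equal"
        )
    values = (v - v_bleach) / (v_pre - v_bleach)
    return NormalizedTrace(
        times=dn.times,
        values=values,
        kind="frap_full",
        pre_index=dn.pre_index,
        bleach_index=dn.bleach_index,
    )


def flip_normalize(trace: IntensityTrace) -> NormalizedTrace:
    """FLIP normalization: value(t) = roi(t) / roi(pre_index).

    The whole-cell channel is ignored; the pre-bleach frame reads 1.
    """
    roi_pre = trace.roi[trace.pre_index]
    if roi_pre <= 0:
        raise ValueError(
            f"roi at pre_index={trace.pre_index} must be > 0, got {roi_pre}"
        )
    return NormalizedTrace(
        times=trace.times,
        values=trace.roi / roi_pre,
        kind="flip",
        pre_index=trace.pre_index,
        bleach_index=trace.bleach_index,
    )


@dataclass(frozen=True)
class ExpFitResult:
    """Fitted one-phase exponential and derived halftime.

    For association, ``amplitude`` is the plateau Y_inf and ``offset`` 0;
    for decay, ``amplitude`` is y0 and ``offset`` the (default-zero) floor.
    ``halftime = ln 2 / rate_k`` always.
    """

    kind: Literal["association", "decay"]
    rate_k: float  # 1/s
    amplitude: float
    offset: float
    halftime: float  # s
    rmse: float
    converged: bool
    n_points: int = 0
    rate_k_stderr: float = float("nan")
    message: str = ""

    def summary(self) -> str:
        lines = [
            f"One-phase exponential {self.kind} fit",
            "-" * 40,
            f"n points        {self.n_points}",
            f"rate k          {self.rate_k:.6g} 1/s (SE {self.rate_k_stderr:.3g})",
            f"halftime        {self.halftime:.6g} s",
            f"amplitude       {self.amplitude:.6g}",
            f"offset          {self.offset:.6g}",
            f"rmse            {self.rmse:.3g}",
            f"converged       {self.converged}",
        ]
        if self.message:
            lines.append(f"note            {self.message}")
        return "\n".join(lines)


class OnePhaseModel:
    """One-phase exponential association/decay model for a normalized trace.

    Parameters
    ----------
    times, values
        Post-bleach samples; times in seconds.  The first time point is the
        fit's origin (t' = 0), i.e. the bleach frame by convention.
    kind
        ``"association"`` fits y = Y_inf * (1 - exp(-k t')); ``"decay"``
        fits y = y0 * exp(-k t') + c.
    free_offset
        Decay only: if True, the floor c is a free parameter; by default it
        is fixed at 0.
    """

    def __init__(
        self,
        times: Sequence[float],
        values: Sequence[float],
        kind: Literal["association", "decay"],
        free_offset: bool = False,
    ):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if kind not in ("association", "decay"):
            raise ValueError(f"kind must be 'association' or 'decay', got {kind!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 5:
            raise ValueError(
                f"need at least 5 post-bleach points, got {self.times.size}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.kind = kind
        self.free_offset = free_offset and kind == "decay"

    # deterministic initialization: rate from a log-linear regression on the
    # exponentially transformed curve, amplitude/plateau from endpoints
    def _initial_guess(self) -> list[float]:
        t = self.times - self.times[0]
        y = self.values
        if self.kind == "association":
            plateau = max(y[-1], 1e-6)
            resid = plateau - y
            mask = resid > 1e-3 * max(abs(plateau), 1.0)
            if mask.sum() >= 2:
                slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
                k0 = max(-slope, K_BOUNDS[0])
            else:
                k0 = 1.0 / max(t[-1], 1e-6)
            return [plateau, min(max(k0, K_BOUNDS[0]), K_BOUNDS[1])]
        y0 = max(y[0], 1e-6)
        floor = min(y[-1], y0) if self.free_offset else 0.0
        resid = y - floor
        mask = resid > 1e-3 * max(y0, 1.0)
        if mask.sum() >= 2:
            slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
            k0 = max(-slope, K_BOUNDS[0])
        else:
            k0 = 1.0 / max(t[-1], 1e-6)
        guess = [y0, min(max(k0, K_BOUNDS[0]), K_BOUNDS[1])]
        if self.free_offset:
            guess.append(floor)
        return guess

    def fit(self) -> ExpFitResult:
        t = self.times - self.times[0]
        y = self.values
        if self.kind == "association":
            model = lambda tt, a, k: a * (1.0 - np.exp(-k * tt))
            lo, hi = [-np.inf, K_BOUNDS[0]], [np.inf, K_BOUNDS[1]]
        elif self.free_offset:
            model = lambda tt, a, k, c: a * np.exp(-k * tt) + c
            lo, hi = [-np.inf, K_BOUNDS[0], -np.inf], [np.inf, K_BOUNDS[1], np.inf]
        else:
            model = lambda tt, a, k: a * np.exp(-k * tt)
            lo, hi = [-np.inf, K_BOUNDS[0]], [np.inf, K_BOUNDS[1]]
        p0 = self._initial_guess()
        try:
            popt, pcov = curve_fit(
                model, t, y, p0=p0, bounds=(lo, hi), maxfev=10000
            )
        except (RuntimeError, ValueError) as exc:
            return ExpFitResult(
                kind=self.kind,
                rate_k=float("nan"),
                amplitude=float("nan"),
                offset=float("nan"),
                halftime=float("nan"),
                rmse=float("nan"),
                converged=False,
                n_points=t.size,
                message=f"least-squares failure: {exc}",
            )
        amp, k = popt[0], popt[1]
        offset = popt[2] if self.free_offset else 0.0
        resid = y - model(t, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        k_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
        # a rate pinned to a bound means the data carry no rate information
        at_bound = not (K_BOUNDS[0] * 1.01 < k < K_BOUNDS[1] * 0.99)
        converged = bool(k > 0 and not at_bound)
        return ExpFitResult(
            kind=self.kind,
            rate_k=float(k),
            amplitude=float(amp),
            offset=float(offset),
            halftime=float(np.log(2.0) / k),
            rmse=rmse,
            converged=converged,
            n_points=int(t.size),
            rate_k_stderr=k_se,
            message="rate at bound" if at_bound else "",
        )


def fit_one_phase(
    times: Sequence[float],
    values: Sequence[float],
    kind: Literal["association", "decay"],
    free_offset: bool = False,
) -> ExpFitResult:
    """Fit a one-phase exponential to post-bleach data (see OnePhaseModel)."""
    return OnePhaseModel(times, values, kind, free_offset=free_offset).fit()


def fit_frap_recovery(norm: NormalizedTrace) -> ExpFitResult:
    """Association fit to a fully normalized FRAP curve from the bleach frame on."""
    if norm.kind != "frap_full":
        raise ValueError("FRAP recovery is fitted on a fully normalized trace")
    sl = slice(norm.bleach_index, None)
    return fit_one_phase(norm.times[sl], norm.values[sl], "association")


def fit_flip_decay(norm: NormalizedTrace, free_offset: bool = False) -> ExpFitResult:
    """Decay fit to a FLIP curve from the first post-bleach frame onward."""
    if norm.kind != "flip":
        raise ValueError("FLIP decay is fitted on a flip-normalized trace")
    sl = slice(norm.bleach_index, None)
    return fit_one_phase(norm.times[sl], norm.values[sl], "decay", free_offset=free_offset)


def halftime_summary(
    fits: Sequence[ExpFitResult], groups: Sequence[str]
) -> pd.DataFrame:
    """Per-group halftime summary over converged fits.

    Returns a DataFrame indexed by group with n, median/mean/std of the
    halftimes and the count of excluded (non-converged) fits.  A group with
    no converged fit is an error.
    """
    if len(fits) != len(groups):
        raise ValueError("fits and groups must have equal length")
    if not fits:
        raise ValueError("halftime_summary requires at least one fit")
    df = pd.DataFrame(
        {
            "group": list(groups),
            "halftime": [f.halftime for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    rows = []
    for g, sub in df.groupby("group", sort=True):
        ok = sub[sub["converged"]]
        if ok.empty:
            raise ValueError(f"group {g!r} has no converged fits")
        rows.append(
            {
                "group": g,
                "n": len(ok),
                "median_halftime_s": float(ok["halftime"].median()),
                "mean_halftime_s": float(ok["halftime"].mean()),
                "std_halftime_s": float(ok["halftime"].std(ddof=1)) if len(ok) > 1 else 0.0,
                "excluded_count": int((~sub["converged"]).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
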