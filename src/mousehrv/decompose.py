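"""Median-based nonlinear decomposition of an RR-interval series.

Conventional spectral HRV bands assume stationary, gap-free data and do not
transfer to the mouse, where respiration drives a beat-to-beat alternation of
the RR interval (about two beats per breath).  Instead the series is split
into three additive components:

* ``sd_fast`` — the respiratory-coupled fast component.  A running median of
  the +/-k nearest-neighbour intervals (excluding the interval itself) is
  subtracted from each RRI; the remainder after a short box smoother is the
  fast component.  It is closely related to the successive-differences metric
  but preserves the shape of the fast variation.
* ``rr_vslow`` — the slow trend (drug responses, behavioural state), from a
  hybrid median/box smoother: the mean of the middle 50 % (interquartile
  mean) of the fast-smoothed intervals over a +/-k_vslow-beat window.
* ``sd_slow`` — everything in between, defined by subtraction so that
  rr_orig = sd_fast + sd_slow + rr_vslow holds exactly at every beat.

All windows are in beats, shrink at edges (no padding), and the fast/local
steps never bridge gaps, while the very-slow trend spans them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._utils import box_smooth, rms
from .detect import RRISequence


@dataclass
class RRComponents:
    """Per-beat decomposition aligned to the valid intervals of a sequence.

    The sum identity rr_orig = sd_fast + sd_slow + rr_vslow holds exactly at
    every row.  ``defined`` is False where the fast residual could not be
    formed (runs shorter than 3 beats); those rows carry sd_fast = 0 and are
    excluded from epoch statistics.
    """

    time_s: np.ndarray
    rr_orig: np.ndarray
    sd_fast: np.ndarray
    sd_slow: np.ndarray
    rr_vslow: np.ndarray
    defined: np.ndarray

    def __len__(self) -> int:
        return self.time_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "rr_orig_ms": self.rr_orig,
                "sd_fast_ms": self.sd_fast,
                "sd_slow_ms": self.sd_slow,
                "rr_vslow_ms": self.rr_vslow,
                "defined": self.defined,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RRComponents":
        return cls(
            time_s=df["time_s"].to_numpy(float),
            rr_orig=df["rr_orig_ms"].to_numpy(float),
            sd_fast=df["sd_fast_ms"].to_numpy(float),
            sd_slow=df["sd_slow_ms"].to_numpy(float),
            rr_vslow=df["rr_vslow_ms"].to_numpy(float),
            defined=df["defined"].to_numpy(bool),
        )


def _runs_of(rri: RRISequence) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Valid-row indices and the contiguous runs among them.

    A run breaks at gap-flagged rows, at invalid rows, and wherever the
    stored rows are not adjacent in the original sequence.
    """
    vidx = np.nonzero(rri.valid)[0]
    runs: list[tuple[int, int]] = []
    start = 0
    for j in range(1, vidx.size + 1):
        if (
            j == vidx.size
            or vidx[j] != vidx[j - 1] + 1
            or rri.gap[vidx[j]]
        ):
            runs.append((start, j))
            start = j
    return vidx, runs


def _median_excluding_self(values: np.ndarray, k: int) -> np.ndarray:
    """median(values[i-k..i+k] \\ {values[i]}) with edge-shrunk windows."""
    n = values.size
    out = np.empty(n)
    w = 2 * k + 1
    if n >= w:
        windows = sliding_window_view(values, w)  # (n-w+1, w)
        excl = np.delete(windows, k, axis=1)
        out[k : n - k] = np.median(excl, axis=1)
    for i in list(range(min(k, n))) + list(range(max(n - k, k), n)):
        lo, hi = max(0, i - k), min(n, i + k + 1)
        neigh = np.delete(values[lo:hi], i - lo)
        out[i] = np.median(neigh) if neigh.size else values[i]
    return out


def neighbor_median_detrend(rri: RRISequence, k: int = 4) -> np.ndarray:
    """Fast residual per valid interval: RRI minus the +/-k neighbour median.

    Returned array is aligned with the valid rows of ``rri`` (see
    :func:`_runs_of`); NaN where a run is shorter than 3 beats, in which
    case the residual is undefined.  Windows shrink at run edges and never
    bridge gaps.
    """
    vidx, runs = _runs_of(rri)
    vals = rri.rri_ms[vidx]
    out = np.full(vals.size, np.nan)
    for a, b in runs:
        seg = vals[a:b]
        if seg.size < 3:
            continue
        out[a:b] = seg - _median_excluding_self(seg, k)
    return out


def _iqr_mean_sliding(values: np.ndarray, k: int) -> np.ndarray:
    """Mean of the middle 50 % of values over +/-k, windows shrinking at edges.

    The middle 50 % of an m-sample window is the sorted slice
    ``[floor(m/4) : m - floor(m/4)]`` (the interquartile mean).
    """
    n = values.size
    out = np.empty(n)
    w = 2 * k + 1

    def iqm(seg: np.ndarray) -> float:
        m = seg.size
        cut = int(0.25 * m)
        s = np.sort(seg)
        return float(np.mean(s[cut : m - cut]))

    if n >= w:
        sw = np.sort(sliding_window_view(values, w), axis=1)
        cut = int(0.25 * w)
        out[k : n - k] = sw[:, cut : w - cut].mean(axis=1)
        edge = range(k)
        tail = range(n - k, n)
    else:
        edge = range(n)
        tail = range(0)
    for i in edge:
        out[i] = iqm(values[max(0, i - k) : i + k + 1])
    for i in tail:
        out[i] = iqm(values[max(0, i - k) : i + k + 1])
    return out


def split_components(
    rri: RRISequence,
    k_fast: int = 4,
    box_fast: int = 7,
    k_vslow: int = 100,
) -> RRComponents:
    """Three-way decomposition of the valid RR intervals.

    Step 1 (fast): subtract the +/-``k_fast`` neighbour median, remove the
    residual's remaining jitter with a ``box_fast``-beat box smoother, and
    recompute sd_fast as rr minus this double-smoothed series.  Local; never
    bridges gaps.

    Step 2 (trend): rr_vslow is the interquartile mean of the double-smoothed
    series over +/-``k_vslow`` beats.  The window is in beats over the whole
    valid series and spans gaps (the trend persists through dropped data).

    Step 3: sd_slow = rr - sd_fast - rr_vslow, so the sum identity is exact
    by construction.
    """
    vidx, runs = _runs_of(rri)
    t = rri.time_s[vidx]
    rr = rri.rri_ms[vidx]
    n = rr.size
    if n == 0:
        e = np.empty(0)
        return RRComponents(e, e.copy(), e.copy(), e.copy(), e.copy(),
                            np.empty(0, bool))
    sd_fast = np.zeros(n)
    defined = np.zeros(n, dtype=bool)
    double = rr.copy()  # double-smoothed series; short runs pass through
    for a, b in runs:
        seg = rr[a:b]
        if seg.size < 3:
            continue
        resid = seg - _median_excluding_self(seg, k_fast)
        smoothed = seg - resid
        dbl = box_smooth(smoothed, box_fast)
        double[a:b] = dbl
        sd_fast[a:b] = seg - dbl
        defined[a:b] = True
    rr_vslow = _iqr_mean_sliding(double, k_vslow)
    sd_slow = rr - sd_fast - rr_vslow
    return RRComponents(
        time_s=t, rr_orig=rr, sd_fast=sd_fast, sd_slow=sd_slow,
        rr_vslow=rr_vslow, defined=defined,
    )


# ---------------------------------------------------------------------------
# epoch metrics
# ---------------------------------------------------------------------------

EPOCH_COLUMNS = [
    "start_s", "mean_rr_orig_ms", "mean_rr_vslow_ms",
    "rms_sd_slow_ms", "rms_sd_fast_ms",
    "log10_rms_sd_slow", "log10_rms_sd_fast",
    "n_beats", "valid",
]


def epoch_metrics(
    components: RRComponents,
    epoch_len_s: float = 15.0,
    min_beats: int = 8,
    t0: float = 0.0,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Per-epoch summary statistics from valid component rows.

    Non-overlapping epochs of ``epoch_len_s`` starting at ``t0`` (session
    start).  Each epoch reports the mean of rr_orig and rr_vslow and the RMS
    of sd_slow and sd_fast over its valid beats, plus base-10 logs of the RMS
    values (NaN when the RMS is 0).  Epochs with fewer than ``min_beats``
    valid beats are flagged invalid.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    sel = components.defined
    t = components.time_s[sel]
    if t_end is None:
        t_end = float(t.max()) + epoch_len_s if t.size else t0 + epoch_len_s
    n_epochs = max(1, int(np.ceil((t_end - t0) / epoch_len_s)))
    idx = np.floor((t - t0) / epoch_len_s).astype(int)
    keep = (idx >= 0) & (idx < n_epochs)
    idx = idx[keep]

    def _sum(x):
        return np.bincount(idx, weights=x, minlength=n_epochs)

    counts = np.bincount(idx, minlength=n_epochs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rr = _sum(components.rr_orig[sel][keep]) / counts
        mean_vs = _sum(components.rr_vslow[sel][keep]) / counts
        rms_ss = np.sqrt(_sum(components.sd_slow[sel][keep] ** 2) / counts)
        rms_sf = np.sqrt(_sum(components.sd_fast[sel][keep] ** 2) / counts)
        log_ss = np.where(rms_ss > 0, np.log10(np.where(rms_ss > 0, rms_ss, 1.0)),
                          np.nan)
        log_sf = np.where(rms_sf > 0, np.log10(np.where(rms_sf > 0, rms_sf, 1.0)),
                          np.nan)
    return pd.DataFrame(
        {
            "start_s": t0 + epoch_len_s * np.arange(n_epochs),
            "mean_rr_orig_ms": mean_rr,
            "mean_rr_vslow_ms": mean_vs,
            "rms_sd_slow_ms": rms_ss,
            "rms_sd_fast_ms": rms_sf,
            "log10_rms_sd_slow": log_ss,
            "log10_rms_sd_fast": log_sf,
            "n_beats": counts,
            "valid": counts >= min_beats,
        }
    )


# ---------------------------------------------------------------------------
# rate conversions
# ---------------------------------------------------------------------------

_UNITS = {"rri_ms", "period_s", "bpm", "per_min", "beats_per_cycle"}


def convert_rate(
    value: float,
    from_unit: str,
    to_unit: str,
    rri_ms: float | None = None,
) -> float:
    """Convert between RR interval, heart rate, and oscillation-rate units.

    * rri_ms <-> bpm:            bpm = 60000 / rri_ms
    * period_s <-> per_min:      per_min = 60 / period_s
    * period_s -> beats_per_cycle: period_s * 1000 / rri_ms  (needs ``rri_ms``)

    Values must be positive.  No display rounding is applied here; use
    :func:`display_rate` for the conventional integer-bpm / one-decimal
    formatting.
    """
    if from_unit not in _UNITS or to_unit not in _UNITS:
        raise ValueError(f"units must be one of {sorted(_UNITS)}")
    if value <= 0:
        raise ValueError("value must be positive")
    if from_unit == to_unit:
        return float(value)
    pair = (from_unit, to_unit)
    if pair == ("rri_ms", "bpm") or pair == ("bpm", "rri_ms"):
        return 60000.0 / value
    if pair == ("period_s", "per_min") or pair == ("per_min", "period_s"):
        return 60.0 / value
    if pair == ("rri_ms", "period_s"):
        return value / 1000.0
    if pair == ("period_s", "rri_ms"):
        return value * 1000.0
    if pair == ("period_s", "beats_per_cycle"):
        if rri_ms is None or rri_ms <= 0:
            raise ValueError("beats_per_cycle conversion requires rri_ms > 0")
        return value * 1000.0 / rri_ms
    if pair == ("beats_per_cycle", "period_s"):
        if rri_ms is None or rri_ms <= 0:
            raise ValueError("beats_per_cycle conversion requires rri_ms > 0")
        return value * rri_ms / 1000.0
    raise ValueError(f"unsupported conversion {from_unit} -> {to_unit}")


def display_rate(value: float, unit: str) -> float:
    """Round a rate for display: integer bpm / per-minute, one decimal otherwise."""
    if unit in ("bpm", "per_min"):
        return float(round(value))
    return float(round(value, 1))


def component_rms(components: RRComponents) -> dict[str, float]:
    """Whole-series RMS of the two zero-centered components (defined rows)."""
    sel = components.defined
    return {
        "sd_fast": rms(components.sd_fast[sel]),
        "sd_slow": rms(components.sd_slow[sel]),
    }
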