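"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def box_smooth(x: np.ndarray, size: int) -> np.ndarray:
    """Centered moving average whose window shrinks symmetrically at the edges.

    ``size`` is the nominal (odd) window length in samples; even values are
    rounded up to the next odd length so the window stays centered.  Near the
    edges the radius is limited by the distance to the nearest edge, which
    keeps the average unbiased for locally linear signals and never pads or
    reflects data.
    """
    x = np.asarray(x, dtype=float)
    if size <= 1 or x.size == 0:
        return x.copy()
    n = x.size
    half = size // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    r = np.minimum(np.minimum(i, n - 1 - i), half)
    lo = i - r
    hi = i + r
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def rms(x: np.ndarray) -> float:
    """Root mean square of a 1-D array (nan for empty input)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(np.square(x))))


def contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open ``(start, stop)`` index ranges of True runs in a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    stops = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))
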