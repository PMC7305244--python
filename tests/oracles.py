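"""Brute-force reference implementations used only as test oracles.

Everything here follows the written definitions directly, with explicit
loops and library primitives (scipy trim_mean), independent of the
package's vectorized code paths.
"""

import numpy as np
from scipy import stats


def oracle_runs(valid, gap):
    """Contiguous runs of valid intervals (indices into the valid subset)."""
    vidx = [i for i in range(len(valid)) if valid[i]]
    runs = []
    current = []
    for j, i in enumerate(vidx):
        if current and (i != vidx[j - 1] + 1 or gap[i]):
            runs.append(current)
            current = []
        current.append(j)
    if current:
        runs.append(current)
    return vidx, runs


def oracle_split(time_s, rr_ms, valid, gap, k_fast=4, box_fast=7, k_vslow=100):
    """Direct windowed-median / box / interquartile-mean decomposition."""
    vidx, runs = oracle_runs(valid, gap)
    rr = np.array([rr_ms[i] for i in vidx], float)
    n = rr.size
    sd_fast = np.zeros(n)
    defined = np.zeros(n, bool)
    double = rr.copy()
    for run in runs:
        seg = rr[run]
        m = seg.size
        if m < 3:
            continue
        resid = np.empty(m)
        for i in range(m):
            neigh = [seg[j] for j in range(max(0, i - k_fast),
                                           min(m, i + k_fast + 1)) if j != i]
            resid[i] = seg[i] - np.median(neigh)
        smoothed = seg - resid
        half = box_fast // 2
        dbl = np.empty(m)
        for i in range(m):
            r = min(i, m - 1 - i, half)
            dbl[i] = np.mean(smoothed[i - r : i + r + 1])
        for local, j in enumerate(run):
            double[j] = dbl[local]
            sd_fast[j] = seg[local] - dbl[local]
            defined[j] = True
    vslow = np.empty(n)
    for i in range(n):
        window = double[max(0, i - k_vslow) : i + k_vslow + 1]
        vslow[i] = stats.trim_mean(window, 0.25)
    sd_slow = rr - sd_fast - vslow
    return {
        "rr": rr, "sd_fast": sd_fast, "sd_slow": sd_slow,
        "rr_vslow": vslow, "defined": defined,
    }


def oracle_welch(a, b):
    """Textbook Welch statistic with Satterthwaite degrees of freedom."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p
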