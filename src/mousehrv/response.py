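"""Pharmacological response windows and group statistics.

Epoch metrics are summarized into named analysis windows around the
injection time — a pre-injection baseline, the brief isoproterenol
tachycardia peak (minimum-RR epoch over the first 1.25 min), the Iso
recovery plateau, and the carbachol maximal-slowing and partial-recovery
windows — and the per-animal summaries are compared across groups with
two-tailed Welch t-tests plus within-group paired t-tests against baseline.
RMS HRV measures are analysed on a log10 scale and back-calculated to ms
for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ["mean_rr_orig_ms", "log10_rms_sd_slow", "log10_rms_sd_fast"]


@dataclass(frozen=True)
class Window:
    label: str
    start_min: float  # minutes relative to injection
    end_min: float
    rule: str = "mean"  # "mean" or "min_epoch"


DEFAULT_WINDOWS = {
    "ISO": [
        Window("baseline", -29.0, 0.0, "mean"),
        Window("iso_1", 0.0, 1.25, "min_epoch"),
        Window("iso_10_15", 10.0, 15.0, "mean"),
    ],
    "CCH": [
        Window("baseline", -29.0, 0.0, "mean"),
        Window("cch_2_6", 2.0, 6.0, "mean"),
        Window("cch_6_10", 6.0, 10.0, "mean"),
    ],
}


@dataclass
class SessionDesign:
    """Injection timing and the named analysis windows for one session."""

    injection_time_s: float
    agent: str  # "ISO" or "CCH"
    windows: list[Window] = field(default_factory=list)

    def __post_init__(self) -> None:
        agent = self.agent.upper()
        if agent not in ("ISO", "CCH", "NONE"):
            raise ValueError(f"unknown agent {self.agent!r}")
        self.agent = agent
        if not self.windows and agent in DEFAULT_WINDOWS:
            self.windows = list(DEFAULT_WINDOWS[agent])
        labels = [w.label for w in self.windows]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate window labels")

    def window(self, label: str) -> Window:
        for w in self.windows:
            if w.label == label:
                return w
        raise KeyError(f"window {label!r} not defined for agent {self.agent}")


def summarize_period(
    epochs: pd.DataFrame,
    design: SessionDesign,
    label: str,
) -> dict:
    """One animal's summary of a named window from its epoch metrics.

    Valid epochs whose start time falls inside the window are aggregated by
    the window's rule: ``mean`` averages each measure; ``min_epoch`` picks
    the single epoch with the lowest mean RR (fastest heart rate), as used
    for the isoproterenol peak.  A window with zero valid epochs yields NaNs
    and ``missing=True``.
    """
    w = design.window(label)
    t0 = design.injection_time_s + 60.0 * w.start_min
    t1 = design.injection_time_s + 60.0 * w.end_min
    sel = epochs[
        (epochs["start_s"] >= t0) & (epochs["start_s"] < t1) & epochs["valid"]
    ]
    out = {"window": label, "rule": w.rule, "n_valid_epochs": int(len(sel)),
           "missing": len(sel) == 0}
    if len(sel) == 0:
        for m in MEASURES:
            out[m] = np.nan
        out["equiv_ihr_bpm"] = np.nan
        return out
    if w.rule == "min_epoch":
        row = sel.loc[sel["mean_rr_orig_ms"].idxmin()]
        vals = {m: float(row[m]) if m in row else np.nan for m in MEASURES}
    elif w.rule == "mean":
        vals = {m: float(sel[m].mean()) for m in MEASURES}
    else:
        raise ValueError(f"unknown rule {w.rule!r}")
    out.update(vals)
    out["equiv_ihr_bpm"] = 60000.0 / vals["mean_rr_orig_ms"]
    return out


def summarize_sessions(
    manifest: pd.DataFrame,
    epochs_by_subject: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-animal window summaries for every session in a manifest.

    ``manifest`` needs columns subject, group, agent, injection_time_s.
    Returns one row per subject x window with the measures of
    :data:`MEASURES` plus equivalent IHR.
    """
    rows = []
    for _, s in manifest.iterrows():
        design = SessionDesign(
            injection_time_s=float(s["injection_time_s"]), agent=str(s["agent"])
        )
        epochs = epochs_by_subject[s["subject"]]
        for w in design.windows:
            row = summarize_period(epochs, design, w.label)
            row["subject"] = s["subject"]
            row["group"] = s["group"]
            row["agent"] = design.agent
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def welch_ttest(
    mean_a=None, sem_a=None, n_a=None,
    mean_b=None, sem_b=None, n_b=None,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> dict:
    """Two-tailed unpaired unequal-variance (Welch) t-test.

    Accepts either raw per-animal vectors ``a``/``b`` or printed summary
    statistics (mean, SEM, n per group).  Uses the Welch-Satterthwaite
    degrees of freedom.  If both groups have zero variance and equal means,
    p = 1 by convention.
    """
    if a is not None or b is not None:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        mean_a, mean_b = a.mean(), b.mean()
        n_a, n_b = a.size, b.size
        sem_a = a.std(ddof=1) / np.sqrt(n_a) if n_a > 1 else 0.0
        sem_b = b.std(ddof=1) / np.sqrt(n_b) if n_b > 1 else 0.0
    if n_a is None or n_b is None or n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = sem_a**2, sem_b**2  # = variance / n
    denom = va + vb
    if denom == 0.0:
        if mean_a == mean_b:
            return {"t": 0.0, "df": float(n_a + n_b - 2), "p": 1.0}
        warnings.warn("zero variance with unequal means", stacklevel=2)
        return {"t": np.inf if mean_a > mean_b else -np.inf,
                "df": float(n_a + n_b - 2), "p": 0.0}
    t = (mean_a - mean_b) / np.sqrt(denom)
    df = denom**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(min(p, 1.0))}


def paired_ttest(values: np.ndarray, baselines: np.ndarray) -> dict:
    """Two-tailed paired t-test of window summaries against baseline.

    Implemented as a one-sample t-test on the paired differences (the
    pairing makes a separate unequal-variance treatment moot).  Pairs with
    a missing member are dropped; fewer than 2 complete pairs is an error.
    Zero-variance nonzero-mean differences are degenerate: p is reported at
    the machine floor with a warning.
    """
    values = np.asarray(values, float)
    baselines = np.asarray(baselines, float)
    if values.shape != baselines.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(values) & np.isfinite(baselines)
    d = values[ok] - baselines[ok]
    if d.size < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return {"t": 0.0, "df": float(d.size - 1), "p": 1.0}
        warnings.warn(
            "paired differences have zero variance and nonzero mean; "
            "p at machine floor", stacklevel=2,
        )
        return {"t": np.inf if d.mean() > 0 else -np.inf,
                "df": float(d.size - 1), "p": float(np.nextafter(0.0, 1.0))}
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), d.size - 1)
    return {"t": float(t), "df": float(d.size - 1), "p": float(min(p, 1.0))}


def holm_adjust(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment (off by default in the pipeline)."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj.tolist()


# ---------------------------------------------------------------------------
# group table
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Group means +/- SEM per window with between- and within-group tests.

    ``table`` has one row per group x window with mean, SEM and n for every
    measure (plus equivalent IHR and back-calculated RMS in ms for display);
    ``tests`` has one row per window x measure with the Welch between-group
    test and per-group paired tests against baseline, flagged at p < .05.
    """

    table: pd.DataFrame
    tests: pd.DataFrame
    alpha: float = 0.05

    def summary(self) -> str:
        lines = ["Group summary (mean +/- SEM)", "=" * 72]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['group']:>10s} {r['window']:>10s}  "
                f"RR {r['mean_rr_orig_ms_mean']:7.1f} +/- {r['mean_rr_orig_ms_sem']:5.2f} ms"
                f"  (IHR {r['equiv_ihr_bpm']:5.0f} bpm, n={int(r['n'])})"
            )
        lines.append("")
        lines.append("Tests (Welch between groups; paired vs baseline)")
        lines.append("=" * 72)
        for _, r in self.tests.iterrows():
            flag = " *" if r["significant"] else ""
            lines.append(
                f"{r['window']:>10s} {r['measure']:>20s}  "
                f"t={r['t']:6.2f} df={r['df']:5.1f} p={r['p']:.4g}{flag}"
            )
        return "\n".join(lines)


def build_table(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> GroupComparison:
    """Build the full group-comparison grid from per-animal window summaries.

    ``summaries`` is the output of :func:`summarize_sessions`.  Groups with a
    single animal are excluded with a warning.  The grid reports, per group
    and window, mean +/- SEM of mean RR (with equivalent IHR), and of the
    log10 RMS slow/fast measures (back-calculated to ms via 10**mean).
    Between-group Welch tests and within-group paired tests versus baseline
    are run per window x measure; identical inputs produce byte-identical
    output (fixed ordering).
    """
    summaries = summaries[~summaries["missing"]].copy()
    counts = summaries.groupby("group")["subject"].nunique()
    small = sorted(counts[counts < 2].index)
    if small:
        warnings.warn(f"excluding groups with a single animal: {small}",
                      stacklevel=2)
        summaries = summaries[~summaries["group"].isin(small)]
    groups = sorted(summaries["group"].unique())
    windows = list(dict.fromkeys(summaries["window"]))  # keep design order

    rows = []
    for g in groups:
        for w in windows:
            sel = summaries[(summaries["group"] == g) & (summaries["window"] == w)]
            if len(sel) == 0:
                continue
            row: dict = {"group": g, "window": w, "n": len(sel)}
            for m in MEASURES:
                vals = sel[m].to_numpy(float)
                vals = vals[np.isfinite(vals)]
                row[f"{m}_mean"] = vals.mean() if vals.size else np.nan
                row[f"{m}_sem"] = (
                    vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
                )
            row["equiv_ihr_bpm"] = float(
                np.mean(60000.0 / sel["mean_rr_orig_ms"].to_numpy(float))
            )
            row["equiv_rr_sd_slow_ms"] = 10.0 ** row["log10_rms_sd_slow_mean"]
            row["equiv_rr_sd_fast_ms"] = 10.0 ** row["log10_rms_sd_fast_mean"]
            rows.append(row)
    table = pd.DataFrame(rows)

    tests = []
    for w in windows:
        for m in MEASURES:
            per_group = {}
            for g in groups:
                sel = summaries[
                    (summaries["group"] == g) & (summaries["window"] == w)
                ][["subject", m]].dropna()
                per_group[g] = sel.set_index("subject")[m]
            if len(groups) == 2:
                a, b = (per_group[g] for g in groups)
                if a.size >= 2 and b.size >= 2:
                    res = welch_ttest(a=a.to_numpy(), b=b.to_numpy())
                    tests.append(
                        {"window": w, "measure": m, "comparison": "between_groups",
                         **res}
                    )
            if w != "baseline":
                for g in groups:
                    base = summaries[
                        (summaries["group"] == g)
                        & (summaries["window"] == "baseline")
                    ][["subject", m]].dropna().set_index("subject")[m]
                    vals = per_group[g]
                    common = vals.index.intersection(base.index)
                    if common.size >= 2:
                        res = paired_ttest(
                            vals.loc[common].to_numpy(), base.loc[common].to_numpy()
                        )
                        tests.append(
                            {"window": w, "measure": m,
                             "comparison": f"{g}_vs_baseline", **res}
                        )
    tests_df = pd.DataFrame(tests)
    if len(tests_df):
        if holm:
            tests_df["p_adj"] = holm_adjust(tests_df["p"].tolist())
            tests_df["significant"] = tests_df["p_adj"] < alpha
        else:
            tests_df["significant"] = tests_df["p"] < alpha
    return GroupComparison(table=table, tests=tests_df, alpha=alpha)
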