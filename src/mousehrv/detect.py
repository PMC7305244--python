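"""R-wave detection across three simultaneously recorded ECG channels.

The normalized complex channels are cross-correlated with one or more
complex-valued beat templates; the locally normalized correlation magnitude
("match signal") varies between 0 and about 1 and peaks where the ECG best
matches the template.  Candidate beats from the three channels are merged,
one source channel is chosen per segment with a stickiness rule so the
detector does not bounce between channels of nearly equal quality, and the
accepted beat set is refined iteratively using median-smoothed RR intervals
from the previous pass to reject implausibly short intervals.  Regions where
no channel is of sufficient quality yield invalid beats, and RR intervals are
never fabricated across them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from ._utils import contiguous_runs
from .preprocess import AnalyticChannel, EnvelopeSet

# physiological RR-interval bounds for mouse (configurable everywhere below)
MIN_RRI_MS = 60.0
MAX_RRI_MS = 250.0

CHANNEL_LABELS = np.array(["A", "B", "C"])


@dataclass
class BeatTemplate:
    """Unit-energy complex reference waveform spanning one QRS complex.

    ``peak_scale`` is the typical envelope-normalized peak magnitude of a
    genuine beat, recorded at extraction time; matching multiplies the shape
    similarity by the local magnitude relative to this scale, which keeps the
    match near 1 at real beats but pushes it toward 0 both in low-amplitude
    stretches (dropouts) and on noise, whose peaks stay well below a QRS
    peak after envelope normalization.  Pure cosine similarity separates
    neither: it is scale-free, and band-limited noise is as smooth as the
    template.
    """

    waveform: np.ndarray  # complex, unit L2 norm
    fs: float
    source_span: tuple[float, float] | None = None
    peak_scale: float | None = None

    @property
    def length_ms(self) -> float:
        return 1000.0 * self.waveform.size / self.fs

    def __post_init__(self) -> None:
        e = np.linalg.norm(self.waveform)
        if e == 0:
            raise ValueError("template has zero energy")
        self.waveform = self.waveform / e


@dataclass
class MatchSignal:
    """Per-sample template-match magnitude for one channel, nominally in [0, 1].

    Values may slightly exceed 1 on over-matching; they are never clipped
    for comparison purposes.
    """

    values: np.ndarray
    fs: float


@dataclass
class BeatSeries:
    """Detected beats: time, winning channel, match quality, validity."""

    time_s: np.ndarray
    channel: np.ndarray  # int in {0,1,2}
    quality: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def valid_times(self) -> np.ndarray:
        return self.time_s[self.valid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "channel": CHANNEL_LABELS[self.channel],
                "quality": self.quality,
                "valid": self.valid,
            }
        )


@dataclass
class RRISequence:
    """RR intervals between consecutive valid beats.

    ``time_s`` is the onset beat time of each interval, ``rri_ms`` its
    duration.  ``valid`` is False for intervals outside the physiological
    bounds; ``gap`` marks intervals whose onset follows an excluded region
    (invalid beats or missing signal).  Intervals are never formed across
    invalid beats.
    """

    time_s: np.ndarray
    rri_ms: np.ndarray
    valid: np.ndarray
    gap: np.ndarray

    def __len__(self) -> int:
        return self.time_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "rri_ms": self.rri_ms,
                "valid": self.valid,
                "gap": self.gap,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RRISequence":
        return cls(
            time_s=df["time_s"].to_numpy(dtype=float),
            rri_ms=df["rri_ms"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy(dtype=bool),
            gap=df["gap"].to_numpy(dtype=bool),
        )


@dataclass
class DetectorParams:
    """Tunable detection parameters with mouse defaults."""

    threshold: float = 0.5          # match-magnitude acceptance cut
    candidate_floor: float = 0.25   # weaker peaks become (invalid) candidates
    min_rri_ms: float = MIN_RRI_MS
    max_rri_ms: float = MAX_RRI_MS
    stickiness_margin: float = 0.05
    stickiness_sustain: int = 5
    cluster_tol_ms: float = 20.0
    max_iterations: int = 3
    rri_band_k: float = 3.0         # predicted band: median +/- max(k*MAD, 25 ms)
    rri_band_floor_ms: float = 25.0  # beat-to-beat changes frequently exceed 25 ms
    template_ms: float = 16.0
    template_min_beats: int = 10


# ---------------------------------------------------------------------------
# template extraction
# ---------------------------------------------------------------------------

def _peak_candidates(mag: np.ndarray, fs: float, min_rri_ms: float,
                     height: float) -> np.ndarray:
    dist = max(1, int(round(min_rri_ms / 1000.0 * fs)))
    peaks, _ = signal.find_peaks(mag, height=height, distance=dist)
    return peaks


def _auto_seed_window(
    normalized: AnalyticChannel,
    params: DetectorParams,
    seed_len_s: float = 5.0,
) -> tuple[float, float]:
    """Pick the most rhythmically stable stretch as template seed window.

    Scans overlapping windows, requires mostly usable samples and at least
    ``template_min_beats`` candidate peaks, and ranks windows by the relative
    spread (MAD/median) of their candidate RR intervals.
    """
    fs = normalized.fs
    n = normalized.n
    win = int(seed_len_s * fs)
    hop = max(1, win // 2)
    usable = normalized.usable_mask()
    best: tuple[float, tuple[float, float]] | None = None
    for start in range(0, max(1, n - win + 1), hop):
        stop = min(n, start + win)
        if np.mean(usable[start:stop]) < 0.9:
            continue
        seg = normalized.magnitude[start:stop]
        height = 0.5 * np.percentile(seg, 95)
        if height <= 0:
            continue
        peaks = _peak_candidates(seg, fs, params.min_rri_ms, height)
        if peaks.size < params.template_min_beats + 1:
            continue
        rri = np.diff(peaks) / fs * 1000.0
        inb = (rri >= params.min_rri_ms) & (rri <= params.max_rri_ms)
        if np.mean(inb) < 0.8:
            continue
        med = np.median(rri[inb])
        mad = np.median(np.abs(rri[inb] - med))
        score = mad / med
        if best is None or score < best[0]:
            best = (score, (start / fs, stop / fs))
    if best is None:
        raise ValueError(
            "no seed window with enough clean beats was found automatically; "
            "pass seed_window=(start_s, stop_s) over a visually clean stretch"
        )
    return best[1]


def extract_template(
    normalized: AnalyticChannel,
    seed_window: tuple[float, float] | None = None,
    params: DetectorParams | None = None,
) -> BeatTemplate:
    """Average aligned beat-centered complex snippets into a reference beat.

    Snippets are centered on magnitude peaks inside the seed window, phase
    rotated so their center sample is real-positive (the analytic phase is
    arbitrary), averaged, and normalized to unit energy.  Raises if the seed
    window does not contain at least ``template_min_beats`` mutually
    consistent beats.
    """
    params = params or DetectorParams()
    fs = normalized.fs
    if seed_window is None:
        seed_window = _auto_seed_window(normalized, params)
    t0, t1 = seed_window
    i0, i1 = int(t0 * fs), int(t1 * fs)
    seg = normalized.magnitude[i0:i1]
    if seg.size == 0:
        raise ValueError("seed window is empty")
    height = 0.5 * np.percentile(seg, 95)
    peaks = _peak_candidates(seg, fs, params.min_rri_ms, height) + i0
    half = max(2, int(round(params.template_ms / 1000.0 * fs / 2)))
    peaks = peaks[(peaks >= half) & (peaks < normalized.n - half)]
    if peaks.size < params.template_min_beats:
        raise ValueError(
            f"seed window contains only {peaks.size} candidate beats "
            f"(need {params.template_min_beats}); select a cleaner window"
        )
    snippets = []
    peak_mags = []
    for p in peaks:
        s = normalized.z[p - half : p + half + 1].astype(complex)
        c = s[half]
        if np.abs(c) > 0:
            s = s * np.exp(-1j * np.angle(c))
        e = np.linalg.norm(s)
        if e > 0:
            snippets.append(s / e)
            peak_mags.append(float(normalized.magnitude[p]))
    snippets = np.array(snippets)
    mean = snippets.mean(axis=0)
    me = np.linalg.norm(mean)
    if me == 0:
        raise ValueError("seed window produced a degenerate template")
    mean /= me
    # consistency check: each snippet should resemble the average beat.
    # Genuine beats agree at ~0.999; band-limited noise snippets still reach
    # ~0.85 after phase alignment, so the gate sits at 0.9.
    sims = np.abs(snippets @ mean.conj())
    if float(np.mean(sims)) < 0.9:
        raise ValueError(
            "seed window beats are too dissimilar (noise?); "
            "select a cleaner seed window manually"
        )
    return BeatTemplate(
        waveform=mean, fs=fs, source_span=(t0, t1),
        peak_scale=float(np.median(peak_mags)),
    )


# ---------------------------------------------------------------------------
# matched filtering
# ---------------------------------------------------------------------------

def match_signal(
    normalized: AnalyticChannel,
    templates: BeatTemplate | list[BeatTemplate],
    env: EnvelopeSet | None = None,
) -> MatchSignal:
    """Locally normalized complex cross-correlation against the templates.

    The match combines three envelope-normalized factors:

    * shape similarity — ``|sum_k conj(T[k]) z[t-L//2+k]|`` divided by the
      local signal norm over the same window (bounded by 1, Cauchy-Schwarz),
      squared to sharpen the contrast;
    * an amplitude factor (when the template carries a ``peak_scale``) —
      the envelope-normalized magnitude relative to half a genuine beat
      peak's, saturating at 1, which kills faint filter ringing inside
      dropouts that similarity alone would accept;
    * a sparsity factor (when ``env`` is given) — ``(1 - mid)^2`` with
      ``mid`` the middle envelope's position inside the lower-upper spread.
      A real ECG channel is sparse (middle envelope near the noise floor,
      mid ~ 0.03) while band-limited noise is not (mid ~ 0.4), and this is
      the only scale-free cue that separates the two.

    The product typically varies between 0 and 1, peaking where the ECG
    best matches the reference; values may slightly exceed 1 on
    over-matching and are never clipped for comparison.  Multiple templates
    combine by a per-sample maximum; unusable samples get a match of 0.
    """
    if isinstance(templates, BeatTemplate):
        templates = [templates]
    z = normalized.z
    n = z.size
    out = np.zeros(n)
    sparsity = 1.0
    if env is not None:
        spread = np.maximum(env.upper - env.lower, 1e-30)
        mid = (env.middle - env.lower) / spread
        sparsity = np.clip(1.0 - mid, 0.0, 1.0) ** 2
    energy = None
    for tpl in templates:
        w = tpl.waveform
        if w.size > n:
            raise ValueError("template longer than the signal")
        if energy is None or energy[1] != w.size:
            # local signal energy over the template support, centered
            power = np.abs(z) ** 2
            loc = signal.fftconvolve(power, np.ones(w.size), mode="same")
            energy = (np.sqrt(np.maximum(loc, 0.0)), w.size)
        num = np.abs(signal.fftconvolve(z, np.conj(w[::-1]), mode="same"))
        e = energy[0]
        floor = 1e-6 * max(float(np.median(e)), 1e-30)
        cos = np.where(e > floor, num / np.maximum(e, floor), 0.0)
        if tpl.peak_scale is not None and tpl.peak_scale > 0:
            amp = np.clip(
                normalized.magnitude / (0.5 * tpl.peak_scale), 0.0, 1.0
            )
            m = cos**2 * amp * sparsity
        else:
            m = cos  # bare template: pure normalized correlation
        out = np.maximum(out, m)
    usable = normalized.usable_mask()
    out[~usable] = 0.0
    return MatchSignal(values=out, fs=normalized.fs)


# ---------------------------------------------------------------------------
# candidate clustering and channel arbitration
# ---------------------------------------------------------------------------

def _channel_candidates(match: MatchSignal, params: DetectorParams):
    peaks = _peak_candidates(
        match.values, match.fs, params.min_rri_ms, params.candidate_floor
    )
    return peaks / match.fs, match.values[peaks]


def _cluster_candidates(times, quals, chans, tol_s, n_channels=3):
    """Merge per-channel candidates into beat clusters within ``tol_s``."""
    order = np.argsort(times, kind="stable")
    t, q, c = times[order], quals[order], chans[order]
    clusters_t = []
    clusters_q = []
    start = 0
    for i in range(1, t.size + 1):
        if i == t.size or t[i] - t[i - 1] > tol_s:
            qs = np.zeros(n_channels)
            ts = np.full(n_channels, np.nan)
            for j in range(start, i):
                if q[j] > qs[c[j]]:
                    qs[c[j]] = q[j]
                    ts[c[j]] = t[j]
            clusters_t.append(ts)
            clusters_q.append(qs)
            start = i
    return np.array(clusters_t), np.array(clusters_q)


def arbitrate_channels(
    cluster_times: np.ndarray,
    cluster_quals: np.ndarray,
    stickiness_margin: float = 0.05,
    sustain: int = 5,
    threshold: float = 0.5,
) -> BeatSeries:
    """Choose one source channel per beat with a sticky segment rule.

    The incumbent channel is kept as long as no other channel exceeds its
    quality by more than ``stickiness_margin`` for ``sustain`` consecutive
    beats; when a challenger sustains that margin, the switch is applied
    retroactively from the start of the challenger's run, so the output
    switches exactly once at a genuine quality crossover.  Beats whose chosen
    quality falls below ``threshold`` are marked invalid.
    """
    nclu = cluster_quals.shape[0]
    chosen = np.zeros(nclu, dtype=int)
    if nclu == 0:
        return BeatSeries(
            time_s=np.empty(0), channel=np.empty(0, dtype=int),
            quality=np.empty(0), valid=np.empty(0, dtype=bool),
        )
    incumbent = int(np.argmax(cluster_quals[0]))
    challenger = -1
    run_start = 0
    run_len = 0
    for i in range(nclu):
        qs = cluster_quals[i]
        best = int(np.argmax(qs))
        if best != incumbent and qs[best] > qs[incumbent] + stickiness_margin:
            if best == challenger:
                run_len += 1
            else:
                challenger, run_start, run_len = best, i, 1
            if run_len >= sustain:
                chosen[run_start:i + 1] = challenger
                incumbent = challenger
                challenger, run_len = -1, 0
                continue
        else:
            challenger, run_len = -1, 0
        chosen[i] = incumbent
    quality = cluster_quals[np.arange(nclu), chosen]
    time = cluster_times[np.arange(nclu), chosen]
    # fall back to the best-channel time where the chosen channel had no peak
    missing = ~np.isfinite(time)
    if np.any(missing):
        alt = np.nanmax(np.where(np.isfinite(cluster_times), cluster_times, np.nan),
                        axis=1)
        time[missing] = alt[missing]
    valid = quality >= threshold
    order = np.argsort(time, kind="stable")
    return BeatSeries(
        time_s=time[order], channel=chosen[order],
        quality=quality[order], valid=valid[order],
    )


def _enforce_refractory(beats: BeatSeries, min_rri_s: float) -> None:
    """Invalidate the weaker of any valid pair closer than the refractory bound."""
    changed = True
    while changed:
        changed = False
        idx = np.nonzero(beats.valid)[0]
        if idx.size < 2:
            return
        dt = np.diff(beats.time_s[idx])
        for j in np.nonzero(dt < min_rri_s)[0]:
            a, b = idx[j], idx[j + 1]
            if not (beats.valid[a] and beats.valid[b]):
                continue
            drop = a if beats.quality[a] <= beats.quality[b] else b
            beats.valid[drop] = False
            changed = True


def _prune_pass(beats: BeatSeries, params: DetectorParams, widen: float) -> bool:
    """One iteration of RRI-guided rejection.

    Uses the median of the +/-4 surrounding intervals and their MAD to
    predict the plausible local RRI band; a valid pair implying an interval
    shorter than the band's lower edge loses its weaker member.
    """
    idx = np.nonzero(beats.valid)[0]
    if idx.size < 3:
        return False
    t = beats.time_s[idx]
    rri = np.diff(t) * 1000.0
    k = 4
    changed = False
    for j in range(rri.size):
        lo_n, hi_n = max(0, j - k), min(rri.size, j + k + 1)
        neigh = np.delete(rri[lo_n:hi_n], j - lo_n)
        if neigh.size < 2:
            continue
        med = np.median(neigh)
        mad = np.median(np.abs(neigh - med))
        band = max(params.rri_band_k * mad, params.rri_band_floor_ms) * widen
        lower = max(med - band, params.min_rri_ms)
        if rri[j] < lower and rri[j] < med - band:
            a, b = idx[j], idx[j + 1]
            if beats.valid[a] and beats.valid[b]:
                drop = a if beats.quality[a] <= beats.quality[b] else b
                beats.valid[drop] = False
                changed = True
    return changed


def detect_beats_iterative(
    matches: list[MatchSignal],
    params: DetectorParams | None = None,
) -> BeatSeries:
    """Joint beat detection from up to three match signals.

    Candidate peaks above ``candidate_floor`` are found per channel, merged
    into beat clusters, arbitrated to one channel per segment, and then
    refined for up to ``max_iterations`` passes: each pass recomputes locally
    median-smoothed RRIs and their variability from the previous accepted set
    and rejects the weaker beat of pairs implying an impossibly short
    interval.  Iteration stops at a fixed point.  If nothing is found an
    empty series is returned with a warning rather than an exception.
    """
    params = params or DetectorParams()
    all_t, all_q, all_c = [], [], []
    for ci, m in enumerate(matches):
        t, q = _channel_candidates(m, params)
        all_t.append(t)
        all_q.append(q)
        all_c.append(np.full(t.size, ci, dtype=int))
    times = np.concatenate(all_t) if all_t else np.empty(0)
    if times.size == 0:
        warnings.warn("no beats found on any channel", stacklevel=2)
        return BeatSeries(
            time_s=np.empty(0), channel=np.empty(0, dtype=int),
            quality=np.empty(0), valid=np.empty(0, dtype=bool),
        )
    quals = np.concatenate(all_q)
    chans = np.concatenate(all_c)
    ct, cq = _cluster_candidates(
        times, quals, chans, params.cluster_tol_ms / 1000.0, len(matches)
    )
    beats = arbitrate_channels(
        ct, cq,
        stickiness_margin=params.stickiness_margin,
        sustain=params.stickiness_sustain,
        threshold=params.threshold,
    )
    _enforce_refractory(beats, params.min_rri_ms / 1000.0)
    widen = 1.0
    for _ in range(params.max_iterations):
        if not _prune_pass(beats, params, widen):
            break
        widen *= 1.5
    if not np.any(beats.valid):
        warnings.warn("no valid beats detected", stacklevel=2)
    return beats


# ---------------------------------------------------------------------------
# RR intervals and yield
# ---------------------------------------------------------------------------

def rr_sequence(
    beats: BeatSeries,
    min_rri_ms: float = MIN_RRI_MS,
    max_rri_ms: float = MAX_RRI_MS,
) -> RRISequence:
    """Form RR intervals between consecutive valid beats only.

    An interval is emitted only for beats that are adjacent in the detected
    series and both valid; stretches containing invalid beats produce no
    interval, and the first interval after such a stretch carries the gap
    flag.  Out-of-bounds intervals are kept but marked invalid.
    """
    n = len(beats)
    if np.count_nonzero(beats.valid) < 2:
        e = np.empty(0)
        return RRISequence(e, e.copy(), np.empty(0, bool), np.empty(0, bool))
    order = np.argsort(beats.time_s, kind="stable")
    t = beats.time_s[order]
    v = beats.valid[order]
    times, rri, valid, gap = [], [], [], []
    after_gap = False
    for i in range(n - 1):
        if v[i] and v[i + 1]:
            d = (t[i + 1] - t[i]) * 1000.0
            times.append(t[i])
            rri.append(d)
            valid.append(min_rri_ms <= d <= max_rri_ms)
            gap.append(after_gap)
            after_gap = False
        else:
            after_gap = True
    return RRISequence(
        time_s=np.array(times), rri_ms=np.array(rri),
        valid=np.array(valid, dtype=bool), gap=np.array(gap, dtype=bool),
    )


def estimate_yield(
    rri: RRISequence,
    window: tuple[float, float],
) -> float | None:
    """Fraction of the window's estimated total heartbeats actually measured.

    yield = (# valid RRIs in window) / (window duration / median valid RRI).
    Returns None when the window contains no valid intervals (undefined).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    sel = (rri.time_s >= t0) & (rri.time_s < t1) & rri.valid
    n_valid = int(np.count_nonzero(sel))
    if n_valid == 0:
        return None
    med = float(np.median(rri.rri_ms[sel])) / 1000.0
    expected = (t1 - t0) / med
    return float(min(n_valid / expected, 1.0))


# ---------------------------------------------------------------------------
# high-level driver
# ---------------------------------------------------------------------------

def run_detection(
    channels: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 168.0),
    notch: float | None = 60.0,
    params: DetectorParams | None = None,
    seed_window: tuple[float, float] | None = None,
) -> tuple[BeatSeries, RRISequence]:
    """Condition three raw channels, build a template, and detect beats.

    The template is extracted from the channel whose auto-selected seed
    window scores best; channels on which no seed window exists still
    contribute to matching and arbitration.
    """
    params = params or DetectorParams()
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    from .preprocess import preprocess_channel

    normed = []
    envs = []
    for ch in channels:
        an, env = preprocess_channel(ch, fs, band=band, notch=notch)
        normed.append(an)
        envs.append(env)
    template = None
    err: Exception | None = None
    for an in normed:
        try:
            template = extract_template(an, seed_window=seed_window, params=params)
            break
        except ValueError as exc:  # try the next channel
            err = exc
    if template is None:
        raise ValueError(f"could not extract a beat template from any channel: {err}")
    matches = [
        match_signal(an, template, env) for an, env in zip(normed, envs)
    ]
    beats = detect_beats_iterative(matches, params)
    rri = rr_sequence(beats, params.min_rri_ms, params.max_rri_ms)
    return beats, rri
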