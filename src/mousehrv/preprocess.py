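"""Per-channel ECG conditioning.

Each of the three foot-contact ECG channels is conditioned independently:

1. zero-phase band-pass + mains-notch filtering,
2. analytic (Hilbert) transform into a complex stream whose magnitude tracks
   instantaneous ECG amplitude independently of waveform shape,
3. robust (rank-based) lower / middle / upper amplitude envelopes,
4. envelope-based normalization so that R-wave peaks sit near 1 regardless of
   channel gain, with flat or dead stretches flagged unusable instead of being
   divided toward infinity.

All filters are applied forward-backward, so beat times are never shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._utils import box_smooth

DEFAULT_BAND = (1.0, 168.0)  # amplifier bandwidth, Hz
DEFAULT_NOTCH = 60.0         # US mains, Hz


@dataclass
class AnalyticChannel:
    """Complex-valued (analytic) representation of one ECG channel.

    ``z`` carries the filtered signal in its real part and the 90-degree
    shifted counterpart in its imaginary part; ``magnitude`` is the amplitude
    proxy used for envelopes and matching.  After :func:`normalize_channel`
    the magnitude is dimensionless (R peaks near 1) and ``usable`` marks the
    samples where the channel carried enough dynamic range to be trusted.
    """

    z: np.ndarray
    magnitude: np.ndarray
    fs: float
    usable: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.z.shape != self.magnitude.shape:
            raise ValueError("z and magnitude must have the same shape")

    @property
    def n(self) -> int:
        return self.z.size

    def usable_mask(self) -> np.ndarray:
        if self.usable is None:
            return np.ones(self.n, dtype=bool)
        return self.usable


@dataclass
class EnvelopeSet:
    """Smoothed lower/middle/upper amplitude envelopes of one channel.

    Rank-based running summaries (10th/50th/90th percentile over
    ``window_s``), box-smoothed over ``smooth_s``.  The ordering
    lower <= middle <= upper is enforced pointwise.
    """

    lower: np.ndarray
    middle: np.ndarray
    upper: np.ndarray
    fs: float
    window_s: float = 2.0
    smooth_s: float = 10.0
    percentiles: tuple[float, float, float] = field(default=(10.0, 50.0, 90.0))


def bandpass_notch_filter(
    raw: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    notch: float | None = DEFAULT_NOTCH,
    order: int = 2,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase band-pass plus optional mains notch.

    Parameters
    ----------
    raw : array
        One sampled ECG channel.
    fs : float
        Sampling rate in Hz; must exceed twice the upper band edge.
    band : (lo, hi)
        Pass band in Hz.
    notch : float or None
        Mains frequency to reject (None disables the notch).

    The band-pass is a Butterworth section applied with ``sosfiltfilt`` and
    the notch an IIR notch applied with ``filtfilt``; both are therefore
    zero-phase, so R-wave times are not shifted.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("expected a 1-D channel")
    if not np.all(np.isfinite(raw)):
        raise ValueError("channel contains non-finite samples")
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band edges must satisfy lo < hi, got {band}")
    if fs <= 2.0 * hi:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the upper band edge {hi} Hz"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, raw)
    if notch is not None:
        if not 0.0 < notch < fs / 2.0:
            raise ValueError(f"notch frequency {notch} outside (0, fs/2)")
        b, a = signal.iirnotch(notch, notch_q, fs=fs)
        out = signal.filtfilt(b, a, out)
    return out


def analytic_transform(filtered: np.ndarray, fs: float) -> AnalyticChannel:
    """Build the complex analytic stream of a band-limited channel.

    The magnitude of the analytic signal is a phase-independent amplitude
    envelope: for a pure in-band sinusoid it is constant, and for an ECG it
    peaks once per QRS complex regardless of the waveform's polarity or
    exact shape.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.size == 0:
        raise ValueError("empty input")
    z = signal.hilbert(filtered)
    return AnalyticChannel(z=z, magnitude=np.abs(z), fs=fs)


def build_envelopes(
    magnitude: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    smooth_s: float = 10.0,
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0),
    hop_fraction: float = 0.05,
) -> EnvelopeSet:
    """Running-percentile amplitude envelopes, box-smoothed.

    Percentiles are evaluated on a coarse grid (hop = ``hop_fraction`` of the
    window) and linearly interpolated back to full rate, which makes the
    rank filters affordable at 5 kHz without changing their slow behaviour.
    Windows shrink symmetrically at the recording edges.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    n = magnitude.size
    win = int(round(window_s * fs))
    if win > n:
        raise ValueError("envelope window longer than the recording")
    win = max(win, 1)
    half = win // 2
    hop = max(1, int(round(win * hop_fraction)))
    centers = np.arange(0, n, hop)
    if centers[-1] != n - 1:
        centers = np.append(centers, n - 1)
    qs = np.asarray(percentiles, dtype=float)
    grid = np.empty((3, centers.size))
    for j, c in enumerate(centers):
        r = min(min(c, n - 1 - c), half)  # symmetric shrink at edges
        seg = magnitude[c - r : c + r + 1]
        grid[:, j] = np.percentile(seg, qs)
    idx = np.arange(n)
    smooth_n = max(1, int(round(smooth_s * fs)))
    envs = [
        box_smooth(np.interp(idx, centers, grid[k]), smooth_n) for k in range(3)
    ]
    lower, middle, upper = np.sort(np.vstack(envs), axis=0)
    return EnvelopeSet(
        lower=lower, middle=middle, upper=upper, fs=fs,
        window_s=window_s, smooth_s=smooth_s, percentiles=tuple(qs),
    )


def normalize_channel(
    analytic: AnalyticChannel,
    env: EnvelopeSet,
    floor_fraction: float = 0.01,
) -> AnalyticChannel:
    """Envelope-normalize a channel; gain-invariant and flat-channel safe.

    normalized magnitude = (magnitude - lower) / max(upper - lower, floor)
    with floor = ``floor_fraction`` of the channel's global median magnitude.
    The complex stream is divided by the same denominator so that matching
    downstream is amplitude-invariant.  Samples where the envelope spread is
    at or below the floor (flat or dead channel) are flagged unusable; no
    NaNs are ever emitted.
    """
    mag = analytic.magnitude
    spread = env.upper - env.lower
    floor = floor_fraction * float(np.median(mag))
    usable = spread > floor
    denom = np.maximum(spread, floor)
    denom = np.where(denom > 0.0, denom, 1.0)  # dead channel: keep finite
    norm_mag = (mag - env.lower) / denom
    norm_z = analytic.z / denom
    if analytic.usable is not None:
        usable = usable & analytic.usable
    return AnalyticChannel(z=norm_z, magnitude=norm_mag, fs=analytic.fs, usable=usable)


def preprocess_channel(
    raw: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    notch: float | None = DEFAULT_NOTCH,
    envelope_window_s: float = 2.0,
    envelope_smooth_s: float = 10.0,
    floor_fraction: float = 0.01,
) -> tuple[AnalyticChannel, EnvelopeSet]:
    """Full conditioning chain for one channel: filter, analytic, envelopes, normalize.

    Returns the normalized analytic channel and the envelope set it was
    normalized with.
    """
    filtered = bandpass_notch_filter(raw, fs, band=band, notch=notch)
    an = analytic_transform(filtered, fs)
    env = build_envelopes(
        an.magnitude, fs, window_s=envelope_window_s, smooth_s=envelope_smooth_s
    )
    return normalize_channel(an, env, floor_fraction=floor_fraction), env
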