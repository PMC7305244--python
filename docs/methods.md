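# Methods

This note documents the models, parameter choices, and numerical behaviour of
`mousehrv`, and what the synthetic-data tests do and do not establish.

## Signal model and preprocessing

Input is three simultaneously recorded ECG channels from foot-contact
electrodes on a freely moving mouse (typically 5 kHz, 16-bit, 1–168 Hz
amplifier bandwidth). Because the animal moves, the best channel switches
frequently, channels fade as feet reposition, and long stretches are
unusable.

Each channel is conditioned independently:

1. **Filtering** — Butterworth band-pass (default 1–168 Hz, the amplifier
   bandwidth, order 2) applied forward-backward (`sosfiltfilt`), plus an IIR
   notch (default 60 Hz, Q 30, `filtfilt`). Both are zero-phase so beat
   times are not shifted; the test suite asserts zero cross-correlation lag
   on an impulse train. The notch frequency and orders are package defaults,
   configurable; they are not dictated by the recording hardware.
2. **Analytic transform** — the channel plus its Hilbert transform as a
   complex stream. Its magnitude is a phase-independent amplitude proxy:
   constant for an in-band sinusoid, one peak per QRS regardless of
   polarity or morphology.
3. **Envelopes** — running 10th/50th/90th percentiles of the magnitude over
   a 2-s window, box-smoothed over 10 s. Percentiles are evaluated on a
   coarse grid (1/20 window hop) and interpolated; windows shrink
   symmetrically at the recording edges (no padding — edges reflect real,
   shorter windows). Rank statistics make the envelopes immune to brief
   artifact bursts (asserted: a 100× single-sample spike moves the lower and
   middle envelopes by < 5 %).
4. **Normalization** — `(magnitude − lower) / max(upper − lower, floor)`
   with floor = 1 % of the channel's global median magnitude. This is
   gain-invariant by construction (all terms scale together) and safe on
   flat channels: where the envelope spread is at or below the floor the
   samples are flagged unusable instead of being divided toward infinity.

**Edge warm-up.** The 1-Hz high-pass transient and envelope smoothing windows
distort roughly the first and last second of a recording; the match signal is
depressed there and beats inside a ~1 s margin can be missed. All closed-loop
accuracy figures therefore exclude a 2-s margin per edge. For the intended
2-hour sessions this is negligible; for very short records it is not.

## Beat detection

A **beat template** is the unit-energy average of phase-aligned complex
snippets (default 16 ms) centered on magnitude peaks inside a seed window —
either user-supplied or auto-selected as the 5-s window whose candidate
intervals are most regular (lowest MAD/median). Snippets must agree with
their average at mean similarity ≥ 0.9; genuine beats sit near 0.999 while
phase-aligned band-limited noise reaches ~0.85, so a noise seed window raises
an error rather than producing a junk template.

The **match signal** per channel is the product of three factors, each in
envelope-normalized units:

* squared cosine similarity between the local complex window and the
  template (locally normalized matched filter);
* an amplitude factor: the normalized magnitude relative to half the seed
  beats' median peak, saturated at 1;
* a sparsity factor `(1 − mid)²`, where `mid` is the middle envelope's
  position inside the lower–upper spread.

The product typically varies between 0 and 1 and peaks at genuine beats.
Similarity alone is scale-free and fires on faint filter ringing inside
dropouts; amplitude alone cannot tell a QRS from noise that its own
envelopes have normalized to order 1. The sparsity factor encodes the one
scale-free difference: an ECG channel is sparse (middle envelope near the
noise floor, `mid` ≈ 0.03) while broadband noise is not (`mid` ≈ 0.4).
Measured on synthetic data: clean beats score ~0.94 (≥ 0.66 at amplitude
SNR 4), the white-noise null's 99th percentile is ~0.25, and all-channel
dropouts contain zero detections. The acceptance threshold default is 0.5
(mid-scale); candidate peaks down to 0.25 are kept as invalid markers.

**Channel arbitration** merges per-channel candidates within 20 ms into beat
clusters and keeps the incumbent channel until a challenger exceeds its
quality by more than 0.05 for 5 consecutive beats; the switch is then applied
retroactively from the start of the challenger's run, so a genuine quality
crossover produces exactly one switch at the crossover. Beats whose chosen
quality is below threshold are kept but invalid.

**Iterative acceptance**: up to 3 passes (or a fixed point). Each pass
estimates the local plausible interval from the median of the ±4 surrounding
intervals ± max(3 × MAD, 25 ms) — mouse beat-to-beat changes routinely exceed
25 ms — widened ×1.5 per retry, and rejects the weaker beat of any pair
implying an impossibly short interval. A refractory bound (60 ms minimum,
250 ms maximum interval — 1000 to 240 bpm) is enforced throughout.

**RR intervals** are formed only between adjacent valid beats; stretches
containing invalid beats produce no interval, and the first interval after
an exclusion carries a gap flag. Out-of-bounds intervals are kept but marked
invalid. The **yield** of a window is (# valid intervals) / (window duration
/ median valid interval), capped at 1; undefined (None) when no valid
interval exists.

## HRV decomposition

Operating on the valid intervals, in beat units (not seconds):

1. **Fast residual**: `rr[i] − median(rr[i−4..i+4] \ {rr[i]})`, windows
   truncated at run edges and never bridging gaps; runs shorter than 3 beats
   are flagged undefined (their `sd_fast` is 0 and they are excluded from
   epoch statistics). Subtracting the residual and applying a centered
   7-beat box smoother (shrinking at edges) gives the double-smoothed
   series; `sd_fast = rr − double-smoothed`.
2. **Trend**: `rr_vslow[i]` is the interquartile mean — the mean of the
   sorted middle 50 %, cutting `floor(m/4)` from each end of an m-sample
   window — of the double-smoothed series over ±100 beats. This window
   spans gaps: the trend persists through dropped data, whereas the fast
   step is strictly local.
3. `sd_slow = rr − sd_fast − rr_vslow`, so the sum identity is exact at
   every beat by construction (asserted to 1e-9 ms on 10,000-beat gapped
   sequences, and element-for-element against a brute-force loop
   implementation of the definitions).

Properties worth knowing: the decomposition is offset-equivariant (adding a
constant moves only `rr_vslow`); a strict ±a alternation is recovered in
`sd_fast` exactly; a 50-beat oscillation of amplitude 4 ms appears in
`sd_slow` with RMS ≈ 12 % below 4/√2 (the 7-beat box and the neighbour
median each shave a few percent — within the 15 % recovery band the tests
assert); the ±100-beat interquartile mean tracks a linear trend to < 2 ms
away from the first/last ~100 beats.

**Epoch metrics**: non-overlapping 15-s epochs from session start; per epoch
the mean of `rr_orig` and `rr_vslow`, the RMS of `sd_slow` and `sd_fast`,
and their base-10 logs (RMS values are roughly log-normal across epochs).
Epochs with fewer than 8 valid beats are invalid — at 3 % yield and ~730 bpm
a 15-s epoch holds about 5 beats, so 8 keeps only epochs with at least ~5 %
yield. `log10` of a zero RMS is reported as NaN, not −inf.

## Response windows and statistics

Windows are defined relative to the injection: baseline (−29–0 min, mean of
valid epochs), isoproterenol peak (0–1.25 min, the single epoch with minimum
mean RR — the response is too brief to average), Iso recovery plateau
(10–15 min), carbachol maximal slowing (2–6 min) and partial recovery
(6–10 min). RR statistics use `rr_orig`; RMS measures are analysed as log10
and back-calculated (10^mean) for display only. Equivalent instantaneous
heart rate is 60000 / RR(ms), averaged per animal then across animals.

Between groups: two-tailed unpaired Welch t-test (Satterthwaite df),
accepting either raw per-animal vectors or printed summary statistics
(mean, SEM, n). Within group vs baseline: a standard paired t-test
(one-sample on differences) — a "paired unequal-variance" test is not a
coherent object, and pairing subsumes the variance question. Degenerate
cases have explicit conventions: both groups constant and equal → p = 1;
zero-variance nonzero-mean differences → p at the machine floor with a
warning. No multiple-testing correction by default (a Holm option exists,
off by default). Significance is flagged at p < .05.

## Synthetic data: the stated world

`simulate_rri` draws `rr[i] = base + trend(t_i) + slow + fast + noise` with
beat times solved by fixed-point iteration so `t[i+1] − t[i] = rr[i]/1000`
exactly. Defaults: base 82 ms (~730 bpm); fast component a strict
beat-to-beat alternation of 3 ms scaled by 2/(beats per breath) — the
saw-tooth respiratory coupling at its typical two beats per breath; slow
oscillation 1.5 ms over 50 beats; per-beat noise 0–1 ms. Drug trends are
phenomenological closed forms: isoproterenol, a −6 ms deflection peaking at
40 s and decaying within ~2 min plus a +3 ms rebound (τ 300 s); carbachol, a
+63 ms rise (τ 25 s, plateau within 2 min) times a recovery factor that
passes half-way back to baseline at 10 min. Amplitudes sit at the heart
rates the recordings show (~730 bpm baseline, ~790 bpm Iso peak, ~420 bpm
CCh plateau); they are scenario defaults, not empirical claims.

`simulate_ecg` renders beats as a Ricker-wavelet QRS (8 ms wide) into three
channels with piecewise-constant gain schedules (foot repositioning), white
and 1/f noise, optional 60 Hz mains, and dropout intervals that zero the
affected channels. `simulate_cohort` adds between-animal variability
(base ~ N(82, 3) ms, CCh plateau ~ N(63, 8) ms, jittered HRV amplitudes) and
optional group-level window offsets with smooth ramps.

What the generator does **not** emulate: real QRS morphology changes,
electrode pop and movement artifacts with ECG-like spectra, arrhythmic
beats, respiration-rate drift, or amplitude modulation of the ECG by
respiration. A green closed-loop test therefore establishes that the
pipeline recovers the structure it models — not performance on artifacts it
has never seen. Conversely the Monte-Carlo calibration of the group
statistics (type-I error 0.05 over 500 null cohorts; a +25 ms recovery
offset detected in ≥ 90 % of replicates) uses epoch metrics computed from
the simulator's ground-truth components, which tests the statistics layer at
realistic between-animal variability, not the decomposition (covered
separately); those cohort sessions are also shortened (4 min baseline,
12 min post) since window means do not depend on session length.

## Numerical choices and degenerate inputs

* All smoothing windows shrink at edges; nothing is padded or reflected.
* Box smoothers use cumulative sums (O(n)); sliding medians and
  interquartile means are vectorized with stride tricks, with explicit loops
  only at edges; even box sizes round up to the next odd length.
* The interquartile mean of an m-window cuts `int(0.25·m)` from each end
  (identical to `scipy.stats.trim_mean(x, 0.25)`, which the tests use as an
  independent oracle).
* Dead channels: everything flagged unusable, denominators floored, no NaNs.
* Empty detection: a warning and an empty beat series, not an exception.
* Determinism: identical seeds give bit-identical simulations, detection is
  deterministic, and the analysis table is a pure function of its inputs.

## Known limitations

* The first/last ~2 s of a recording are unreliable (filter and envelope
  warm-up).
* Template extraction assumes at least one channel holds ≥ 10 clean beats
  somewhere; fully pathological recordings need a manual seed window.
* The sticky arbitration can hold a marginally worse channel for up to the
  sustain run-length after a true quality crossover (by design).
* `rr_vslow` is biased within ~100 beats of the sequence ends (asymmetric
  windows), so trend values there should not be interpreted.
* File I/O is plain CSV only.
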