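"""Template extraction, matched filtering, arbitration, beats, RRIs, yield."""

import numpy as np
import pytest

import mousehrv as mh
from mousehrv.detect import (
    BeatSeries,
    BeatTemplate,
    DetectorParams,
    arbitrate_channels,
    detect_beats_iterative,
    estimate_yield,
    rr_sequence,
)
from mousehrv.preprocess import AnalyticChannel
from mousehrv.synth import qrs_waveform

from conftest import match_stats


class TestTemplate:
    def test_matches_generating_shape(self, clean_channel, clean_sim):
        an, _ = clean_channel
        tpl = mh.extract_template(an)
        # reference: analytic form of the generator's QRS after the same band
        shape = qrs_waveform(5000.0, 8.0)
        pad = np.zeros(5000)
        emb = np.concatenate([pad, shape, pad])
        filt = mh.bandpass_notch_filter(emb, 5000.0)
        ref = mh.analytic_transform(filt, 5000.0).z
        c = int(pad.size + shape.size // 2)
        half = tpl.waveform.size // 2
        snip = ref[c - half : c + half + 1]
        snip = snip / np.linalg.norm(snip)
        corr = np.abs(np.vdot(snip, tpl.waveform))
        assert corr > 0.99

    def test_noise_seed_window_raises(self):
        rng = np.random.default_rng(3)
        an, env = mh.preprocess_channel(rng.standard_normal(50000), 5000.0)
        with pytest.raises(ValueError):
            mh.extract_template(an, seed_window=(2.0, 7.0))

    def test_two_seed_windows_agree(self, clean_channel):
        an, _ = clean_channel
        t1 = mh.extract_template(an, seed_window=(5.0, 10.0))
        t2 = mh.extract_template(an, seed_window=(18.0, 23.0))
        corr = np.abs(np.vdot(t1.waveform, t2.waveform))
        assert corr > 0.98


class TestMatchSignal:
    def _embedded(self):
        fs = 5000.0
        shape = qrs_waveform(fs, 8.0)
        x = np.zeros(20000)
        c = 10000
        x[c - shape.size // 2 : c - shape.size // 2 + shape.size] = shape
        an = mh.analytic_transform(x, fs)
        half = 40
        w = an.z[c - half : c + half + 1]
        tpl = BeatTemplate(waveform=w.copy(), fs=fs)  # bare: no peak scale
        return an, tpl, c

    def test_self_match_peak_at_embedding(self):
        an, tpl, c = self._embedded()
        ms = mh.match_signal(an, tpl)
        assert abs(int(np.argmax(ms.values)) - c) <= 1
        assert ms.values.max() == pytest.approx(1.0, abs=1e-6)
        # single dominant peak: nothing else comes close
        away = np.r_[ms.values[: c - 100], ms.values[c + 100 :]]
        assert away.max() < 0.9

    def test_amplitude_invariance_with_envelopes(self, clean_sim, clean_channel):
        an, env = clean_channel
        tpl = mh.extract_template(an)
        rec = clean_sim["rec"]
        an2, env2 = mh.preprocess_channel(2.0 * rec.channels[0], rec.fs)
        m1 = mh.match_signal(an, tpl, env).values
        m2 = mh.match_signal(an2, tpl, env2).values
        idx = (clean_sim["beats"].time_s * rec.fs).astype(int)
        idx = idx[(idx > 10000) & (idx < m1.size - 10000)]
        p1 = np.array([m1[i - 10 : i + 11].max() for i in idx])
        p2 = np.array([m2[i - 10 : i + 11].max() for i in idx])
        assert np.abs(p2 - p1).max() < 0.02
        # near 1 at beats (the sparsity factor costs ~6 % on a clean channel)
        assert np.median(p2) > 0.9

    def test_white_noise_null_below_threshold(self, clean_channel):
        an, _ = clean_channel
        tpl = mh.extract_template(an)
        rng = np.random.default_rng(0)
        noise_an, noise_env = mh.preprocess_channel(
            rng.standard_normal(150000), 5000.0
        )
        ms = mh.match_signal(noise_an, tpl, noise_env)
        assert np.percentile(ms.values, 99) < DetectorParams().threshold

    def test_template_longer_than_signal(self):
        an, tpl, _ = self._embedded()
        short = AnalyticChannel(z=an.z[:10], magnitude=an.magnitude[:10], fs=an.fs)
        with pytest.raises(ValueError, match="longer"):
            mh.match_signal(short, tpl)


class TestDetection:
    def test_clean_constant_rate(self, clean_sim, clean_detection):
        beats, rri = clean_detection
        truth = clean_sim["beats"].time_s
        sens, fp, err = match_stats(truth, beats.valid_times, 2.0, 28.0)
        assert sens == 1.0
        assert fp == 0.0
        assert err <= 1.0
        v = rri.rri_ms[rri.valid & (rri.time_s > 2.0) & (rri.time_s < 28.0)]
        # design: 83.3 ms base +/- 3 ms alternation + 0.3 ms noise
        assert np.all(np.abs(v - 1000 * 60 / 720) < 5.0)

    def test_iteration_fixed_point(self, clean_sim, clean_detection):
        beats1, _ = clean_detection
        beats2, _ = mh.run_detection(clean_sim["rec"].channels,
                                     clean_sim["rec"].fs)
        assert np.array_equal(beats1.time_s, beats2.time_s)
        assert np.array_equal(beats1.valid, beats2.valid)

    def test_refractory_never_violated(self, clean_detection):
        beats, _ = clean_detection
        assert np.all(np.diff(beats.valid_times) >= 0.060)

    def test_all_channel_dropout_is_a_gap(self):
        design = mh.RRIDesign(noise_sd_ms=0.3, seed=9)
        seq, _ = mh.simulate_rri(design, 30.0)
        rec, truth = mh.simulate_ecg(
            seq, mh.ECGDesign(fs=5000.0, noise_white=0.02,
                              dropouts=[(12.0, 17.0, "all")], seed=10)
        )
        beats, rri = mh.run_detection(rec.channels, rec.fs)
        vt = beats.valid_times
        assert np.count_nonzero((vt > 12.05) & (vt < 16.95)) == 0
        ok = rri.valid
        spans = (rri.time_s[ok] > 12.0) & (rri.time_s[ok] + rri.rri_ms[ok] / 1000 < 17.0)
        assert spans.sum() == 0  # nothing fabricated across the dropout
        # tracking resumes within 3 beats of signal return
        resumed = vt[vt >= 16.95]
        truth_after = truth.time_s[truth.time_s >= 17.0]
        assert resumed.size and np.searchsorted(truth_after, resumed[0]) <= 3

    def test_sawtooth_alternation_recovered(self):
        design = mh.RRIDesign(base_rri_ms=105.0, fast_amp_ms=10.0,
                              slow_amp_ms=0.0, noise_sd_ms=0.0, seed=4)
        seq, _ = mh.simulate_rri(design, 30.0)
        rec, truth = mh.simulate_ecg(
            seq, mh.ECGDesign(fs=5000.0, noise_white=0.02, seed=5)
        )
        beats, rri = mh.run_detection(rec.channels, rec.fs)
        sens, fp, _ = match_stats(truth.time_s, beats.valid_times, 2.0, 28.0)
        assert sens >= 0.99
        v = rri.rri_ms[rri.valid & (rri.time_s > 2.0) & (rri.time_s < 28.0)]
        # strict 95/115 alternation: successive differences flip sign
        assert np.all(np.abs(np.abs(np.diff(v)) - 20.0) < 2.0)

    def test_mains_with_notch(self, clean_sim):
        seq = clean_sim["seq"]
        rec, truth = mh.simulate_ecg(
            seq, mh.ECGDesign(fs=5000.0, noise_white=0.02, mains_amp=0.5, seed=8)
        )
        beats, _ = mh.run_detection(rec.channels, rec.fs)
        sens, _, _ = match_stats(truth.time_s, beats.valid_times, 2.0, 28.0)
        assert sens >= 0.99

    def test_no_signal_warns_not_raises(self):
        quiet = [mh.detect.MatchSignal(values=np.zeros(10000), fs=5000.0)] * 3
        with pytest.warns(UserWarning, match="no beats"):
            beats = detect_beats_iterative(quiet)
        assert len(beats) == 0


class TestArbitration:
    @staticmethod
    def _clusters(quals):
        quals = np.asarray(quals, float)
        n = quals.shape[0]
        times = np.tile(np.arange(n)[:, None] * 0.1, (1, quals.shape[1]))
        return times, quals

    def test_sticky_with_sub_margin_differences(self):
        t, q = self._clusters(np.tile([0.90, 0.89, 0.88], (50, 1)))
        beats = arbitrate_channels(t, q)
        assert np.all(beats.channel == 0)

    def test_single_switch_at_crossover(self):
        q = np.tile([0.9, 0.6, 0.5], (100, 1)).astype(float)
        q[50:] = [0.6, 0.9, 0.5]  # channel B takes over by > margin
        t, q = self._clusters(q)
        beats = arbitrate_channels(t, q)
        switches = np.nonzero(np.diff(beats.channel))[0]
        assert switches.size == 1
        assert switches[0] == 49  # switch applied at the crossover cluster

    def test_all_below_threshold_marked_invalid(self):
        t, q = self._clusters(np.tile([0.3, 0.2, 0.1], (20, 1)))
        beats = arbitrate_channels(t, q, threshold=0.5)
        assert not np.any(beats.valid)
        assert len(beats) == 20

    def test_gain_switching_bounded(self):
        design = mh.RRIDesign(fast_amp_ms=2.0, noise_sd_ms=0.3, seed=6)
        seq, _ = mh.simulate_rri(design, 30.0)
        sched = [(0.0, (1.0, 0.2, 0.1)), (10.0, (0.2, 1.0, 0.1)),
                 (20.0, (0.1, 0.2, 1.0))]
        rec, _ = mh.simulate_ecg(
            seq, mh.ECGDesign(fs=5000.0, noise_white=0.05,
                              gain_schedule=sched, seed=7)
        )
        beats, _ = mh.run_detection(rec.channels, rec.fs)
        ch = beats.channel[beats.valid]
        assert np.count_nonzero(np.diff(ch)) <= 3


class TestRRSequence:
    @staticmethod
    def _beats(times, valid=None):
        times = np.asarray(times, float)
        valid = np.ones(times.size, bool) if valid is None else np.asarray(valid)
        return BeatSeries(time_s=times, channel=np.zeros(times.size, int),
                          quality=np.ones(times.size), valid=valid)

    def test_simple_intervals(self):
        rri = rr_sequence(self._beats([0.0, 0.1, 0.2]))
        assert np.allclose(rri.rri_ms, [100.0, 100.0])
        assert rri.valid.all() and not rri.gap.any()

    def test_no_interval_across_invalid_beat(self):
        rri = rr_sequence(self._beats([0.0, 0.1, 0.22, 0.35],
                                      [True, True, False, True]))
        assert np.allclose(rri.rri_ms, [100.0])  # no fabricated 250 ms
        assert rri.valid.all()

    def test_out_of_bounds_interval_invalidated(self):
        rri = rr_sequence(self._beats([0.0, 0.1, 0.5]))
        assert np.allclose(rri.rri_ms, [100.0, 400.0])
        assert list(rri.valid) == [True, False]

    def test_random_deletions_never_bridge(self):
        design = mh.RRIDesign(noise_sd_ms=1.0, seed=21)
        seq, _ = mh.simulate_rri(design, 120.0)
        truth_t = np.concatenate(
            (seq.time_s, [seq.time_s[-1] + seq.rri_ms[-1] / 1000])
        )
        rng = np.random.default_rng(5)
        keep = rng.random(truth_t.size) > 0.2
        beats = self._beats(truth_t, keep)
        rri = rr_sequence(beats)
        # every emitted interval is a true adjacent pair of surviving beats
        kept_t = truth_t[keep]
        pos = np.searchsorted(kept_t, rri.time_s)
        implied = (kept_t[pos + 1] - kept_t[pos]) * 1000.0
        assert np.allclose(rri.rri_ms, implied)
        # and no interval spans a deleted beat
        full_pos = np.searchsorted(truth_t, rri.time_s)
        assert np.all(keep[full_pos] & keep[full_pos + 1])

    def test_fewer_than_two_valid_beats(self):
        rri = rr_sequence(self._beats([0.0, 0.1], [True, False]))
        assert len(rri) == 0


class TestYield:
    def test_fully_detected_window(self):
        design = mh.RRIDesign(seed=0)
        seq, _ = mh.simulate_rri(design, 60.0)
        y = estimate_yield(seq, (5.0, 55.0))
        assert y == pytest.approx(1.0, abs=0.02)

    def test_ten_percent_detectable(self):
        design = mh.RRIDesign(noise_sd_ms=0.5, detectable_fraction=0.1, seed=3)
        seq, _ = mh.simulate_rri(design, 600.0)
        y = estimate_yield(seq, (0.0, 600.0))
        assert y == pytest.approx(0.10, abs=0.02)

    def test_empty_window_is_missing(self):
        design = mh.RRIDesign(seed=0, dropouts=[(10.0, 20.0)])
        seq, _ = mh.simulate_rri(design, 30.0)
        assert estimate_yield(seq, (11.0, 19.0)) is None
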