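"""RR-interval decomposition: fast residual, three-way split, epochs, units."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mousehrv as mh
from mousehrv.decompose import component_rms, display_rate
from mousehrv.detect import RRISequence

from oracles import oracle_split


def make_seq(rr, valid=None, gap=None):
    rr = np.asarray(rr, float)
    n = rr.size
    t = np.concatenate(([0.0], np.cumsum(rr[:-1]))) / 1000.0
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    gap = np.zeros(n, bool) if gap is None else np.asarray(gap, bool)
    return RRISequence(time_s=t, rri_ms=rr, valid=valid, gap=gap)


class TestNeighborMedianDetrend:
    def test_constant_sequence_zero_residual(self):
        res = mh.neighbor_median_detrend(make_seq(np.full(30, 100.0)))
        assert np.allclose(res, 0.0)

    def test_alternating_residual(self):
        rr = np.where(np.arange(40) % 2 == 0, 100.0, 110.0)
        res = mh.neighbor_median_detrend(make_seq(rr))
        # interior: 8 neighbours, 4 of each value -> median 105
        assert np.allclose(res[6:34], np.where(np.arange(6, 34) % 2 == 0, -5.0, 5.0))

    def test_single_outlier_isolated(self):
        rr = np.full(30, 100.0)
        rr[15] = 150.0
        res = mh.neighbor_median_detrend(make_seq(rr))
        assert res[15] == pytest.approx(50.0)
        mask = np.ones(30, bool)
        mask[15] = False
        assert np.allclose(res[mask], 0.0)

    def test_short_runs_flagged(self):
        valid = np.array([True, True, False, True, True, True, True])
        res = mh.neighbor_median_detrend(make_seq(np.full(7, 100.0), valid))
        # first run has 2 beats -> undefined; second run (4 beats) defined
        assert np.isnan(res[:2]).all()
        assert np.isfinite(res[2:]).all()


class TestSplitComponents:
    def test_constant_sequence(self):
        comp = mh.split_components(make_seq(np.full(400, 100.0)))
        assert np.allclose(comp.sd_fast, 0.0, atol=1e-12)
        assert np.allclose(comp.sd_slow, 0.0, atol=1e-12)
        assert np.allclose(comp.rr_vslow, 100.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sum_identity_random_with_gaps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 400))
        rr = 100.0 + rng.normal(0.0, 10.0, n)
        valid = rng.random(n) > 0.15
        gap = rng.random(n) < 0.05
        comp = mh.split_components(make_seq(rr, valid, gap))
        resid = comp.rr_orig - (comp.sd_fast + comp.sd_slow + comp.rr_vslow)
        assert np.abs(resid).max() <= 1e-9 if len(comp) else True

    def test_offset_equivariance(self):
        rng = np.random.default_rng(7)
        rr = 100.0 + rng.normal(0.0, 5.0, 500)
        a = mh.split_components(make_seq(rr))
        b = mh.split_components(make_seq(rr + 40.0))
        assert np.allclose(b.rr_vslow - a.rr_vslow, 40.0, atol=1e-9)
        assert np.allclose(b.sd_fast, a.sd_fast, atol=1e-9)
        assert np.allclose(b.sd_slow, a.sd_slow, atol=1e-9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        rr = 100.0 + 5.0 * (-1.0) ** np.arange(300) + rng.normal(0, 2, 300)
        valid = rng.random(300) > 0.1
        gap = rng.random(300) < 0.03
        seq = make_seq(rr, valid, gap)
        comp = mh.split_components(seq)
        ref = oracle_split(seq.time_s, seq.rri_ms, seq.valid, seq.gap)
        assert np.array_equal(comp.defined, ref["defined"])
        for mine, theirs in (
            (comp.sd_fast, ref["sd_fast"]),
            (comp.rr_vslow, ref["rr_vslow"]),
            (comp.sd_slow, ref["sd_slow"]),
        ):
            assert np.allclose(mine, theirs, atol=1e-10)

    def test_component_recovery(self):
        # saw-tooth 5 ms + 50-beat oscillation (4 ms) + linear trend
        i = np.arange(3000)
        rr = 105.0 + 5.0 * (-1.0) ** i + 4.0 * np.sin(2 * np.pi * i / 50) + 0.004 * i
        comp = mh.split_components(make_seq(rr))
        core = slice(150, -150)
        assert np.sqrt(np.mean(comp.sd_fast[core] ** 2)) == pytest.approx(5.0, rel=0.10)
        assert np.sqrt(np.mean(comp.sd_slow[core] ** 2)) == pytest.approx(
            4.0 / np.sqrt(2.0), rel=0.15
        )
        trend = 105.0 + 0.004 * i
        assert np.abs(comp.rr_vslow[core] - trend[core]).max() < 2.0

    def test_empty_input(self):
        comp = mh.split_components(make_seq(np.array([]), np.array([], bool),
                                            np.array([], bool)))
        assert len(comp) == 0


class TestEpochMetrics:
    def test_constant_epoch(self):
        rr = np.full(120, 100.0)
        comp = mh.split_components(make_seq(rr))
        ep = mh.epoch_metrics(comp, epoch_len_s=15.0, min_beats=8)
        first = ep.iloc[0]
        assert first["mean_rr_orig_ms"] == pytest.approx(100.0)
        assert 60000.0 / first["mean_rr_orig_ms"] == pytest.approx(600.0)

    def test_rms_and_log(self):
        comp = mh.RRComponents(
            time_s=np.arange(100) * 0.1,
            rr_orig=np.full(100, 100.0),
            sd_fast=3.0 * (-1.0) ** np.arange(100),
            sd_slow=np.zeros(100),
            rr_vslow=np.full(100, 100.0) - 3.0 * (-1.0) ** np.arange(100),
            defined=np.ones(100, bool),
        )
        ep = mh.epoch_metrics(comp, epoch_len_s=15.0, min_beats=8)
        assert ep.iloc[0]["rms_sd_fast_ms"] == pytest.approx(3.0)
        assert ep.iloc[0]["log10_rms_sd_fast"] == pytest.approx(0.477, abs=1e-3)

    def test_sparse_epoch_invalid(self):
        comp = mh.RRComponents(
            time_s=np.array([0.0, 0.1]), rr_orig=np.full(2, 100.0),
            sd_fast=np.zeros(2), sd_slow=np.zeros(2),
            rr_vslow=np.full(2, 100.0), defined=np.ones(2, bool),
        )
        ep = mh.epoch_metrics(comp, epoch_len_s=15.0, min_beats=8)
        assert not ep.iloc[0]["valid"]

    def test_bad_epoch_length(self):
        comp = mh.split_components(make_seq(np.full(10, 100.0)))
        with pytest.raises(ValueError):
            mh.epoch_metrics(comp, epoch_len_s=0.0)


class TestConvertRate:
    def test_rri_to_bpm(self):
        assert mh.convert_rate(100.0, "rri_ms", "bpm") == pytest.approx(600.0)

    @pytest.mark.parametrize(
        "period_s, rri_ms, per_min, beats",
        [(0.60, 105.0, 100, 5.7), (0.82, 99.0, 73, 8.3)],
    )
    def test_oscillation_rate_conversions(self, period_s, rri_ms, per_min, beats):
        pm = mh.convert_rate(period_s, "period_s", "per_min")
        bc = mh.convert_rate(period_s, "period_s", "beats_per_cycle", rri_ms=rri_ms)
        assert display_rate(pm, "per_min") == per_min
        assert display_rate(bc, "beats_per_cycle") == beats

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mh.convert_rate(0.0, "rri_ms", "bpm")
        with pytest.raises(ValueError):
            mh.convert_rate(-1.0, "period_s", "per_min")

    def test_beats_per_cycle_needs_rri(self):
        with pytest.raises(ValueError, match="rri_ms"):
            mh.convert_rate(0.6, "period_s", "beats_per_cycle")


def test_component_rms_uses_defined_rows_only():
    rr = np.full(200, 100.0)
    valid = np.ones(200, bool)
    valid[50:150] = False
    comp = mh.split_components(make_seq(rr, valid))
    out = component_rms(comp)
    assert out["sd_fast"] == pytest.approx(0.0, abs=1e-12)
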