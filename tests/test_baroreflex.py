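import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barovar import (
    Ramp,
    BaroSequence,
    SequenceConfig,
    analyze_baroreflex,
    find_ramps,
    fit_sequence_slope,
    match_sequences,
    simulate_beats,
    summarize_baroreflex,
)
from barovar.errors import DegenerateFit
from .conftest import beats_from_arrays, clean_sim


class TestFindRamps:
    @pytest.mark.parametrize(
        "sbp, expected",
        [
            ([100, 101, 102, 103, 102], [(0, 1, 4)]),
            ([110, 108, 106, 104, 102, 100], [(0, -1, 6)]),
            ([100, 101, 100, 101, 100], []),
        ],
        ids=["up-ramp", "down-ramp", "alternating"],
    )
    def test_examples(self, sbp, expected):
        ramps = find_ramps(np.asarray(sbp, float))
        assert [(r.start_index, r.direction, r.length) for r in ramps] == expected

    def test_maximal_run_is_one_ramp(self):
        ramps = find_ramps(np.r_[np.linspace(100, 106, 7), 105.0])
        assert len(ramps) == 1 and ramps[0].length == 7

    def test_per_step_threshold(self):
        sbp = np.array([100.0, 100.5, 101.0, 101.5, 102.0])
        assert len(find_ramps(sbp)) == 1
        assert find_ramps(sbp, SequenceConfig(delta_sbp=0.8)) == []


class TestFitSlope:
    def test_exact_line(self):
        slope, intercept, r = fit_sequence_slope([100, 101, 102, 103], [150, 152, 154, 156])
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(-50.0)
        assert r == pytest.approx(1.0)

    def test_constant_pi_gives_zero_slope_and_r(self):
        slope, _, r = fit_sequence_slope([100, 101, 102, 103], [150, 150, 150, 150])
        assert slope == 0.0 and r == 0.0

    def test_degenerate_sbp(self):
        with pytest.raises(DegenerateFit):
            fit_sequence_slope([100, 100, 100], [150, 151, 152])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(90, 150, allow_nan=False), st.floats(120, 220, allow_nan=False)
    ), min_size=4, max_size=4))
    def test_matches_normal_equation_oracle(self, points):
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        if np.ptp(x) < 1e-3 or np.ptp(y) < 1e-9:
            return
        slope, intercept, _ = fit_sequence_slope(x, y)
        # brute-force normal equations on the mean-centred design
        xc, yc = x - x.mean(), y - y.mean()
        oracle_slope = float(np.linalg.solve(np.atleast_2d(xc @ xc), np.atleast_1d(xc @ yc))[0])
        oracle_intercept = y.mean() - oracle_slope * x.mean()
        assert slope == pytest.approx(oracle_slope, abs=1e-10)
        assert intercept == pytest.approx(oracle_intercept, abs=1e-8)


class TestMatchSequences:
    def test_perfect_linear_response(self):
        sbp = np.array([100.0, 101, 102, 103, 103, 102, 101, 102, 103, 104])
        pi = np.full(20, 150.0)
        pi[3:7] = [150, 152, 154, 156]  # lag-3 response to the first ramp
        ramps = find_ramps(sbp)
        seqs, n_eval = match_sequences(ramps[:1], pi)
        assert len(seqs) == 1
        assert seqs[0].lag == 3
        assert seqs[0].slope == pytest.approx(2.0) and seqs[0].r == pytest.approx(1.0)

    def test_no_monotone_response_at_any_lag(self):
        sbp = np.array([100.0, 101, 102, 103])
        pi = np.array([150.0, 151, 150, 151, 150, 151, 150, 151, 150])
        seqs, n_eval = match_sequences(find_ramps(sbp), pi)
        assert seqs == [] and n_eval == 1

    def test_edge_ramp_skipped_not_counted(self):
        sbp = np.array([100.0, 101, 102, 103])
        pi = np.array([150.0, 152, 154, 156])  # too short for any lag window
        seqs, n_eval = match_sequences(find_ramps(sbp), pi)
        assert seqs == [] and n_eval == 0

    def test_fully_coupled_simulation_recovers_gain_everywhere(self):
        beats, _ = simulate_beats(clean_sim(gain=1.5, lag=3, seed=3))
        ramps = find_ramps(beats.sbp)
        seqs, n_eval = match_sequences(ramps, beats.pi)
        assert n_eval > 100 and len(seqs) == n_eval
        slopes = np.array([s.slope for s in seqs])
        np.testing.assert_allclose(slopes, 1.5, rtol=1e-6)
        # cross-check one slope with an independent least-squares solve
        s = seqs[0]
        design = np.c_[s.ramp.sbp_values, np.ones(len(s.pi_values))]
        lsq = np.linalg.lstsq(design, s.pi_values, rcond=None)[0][0]
        assert s.slope == pytest.approx(lsq, abs=1e-9)


def _fake_sequences(sbp_points, pi_points):
    ramp = Ramp(0, 1, len(sbp_points), np.asarray(sbp_points, float))
    return [BaroSequence(ramp, 3, np.asarray(pi_points, float), 1.0, 0.0, 1.0)]


class TestSummarize:
    @pytest.mark.parametrize("n_seq,n_ramps,expected", [(10, 10, 1.0), (2, 5, 0.4)])
    def test_bei_ratio(self, n_seq, n_ramps, expected):
        seqs = _fake_sequences(np.arange(4.0) + 100, np.arange(4.0) + 150) * n_seq
        res = summarize_baroreflex(seqs[:n_seq], n_ramps)
        assert res.bei == pytest.approx(expected)

    def test_degenerate_identical_points(self):
        seqs = _fake_sequences([120.0] * 4, [160.0] * 4)
        res = summarize_baroreflex(seqs, 1)
        assert res.sbp_span == 0 and res.pi_span == 0 and res.operating_range_area == 0
        assert res.set_point_sbp == 120.0 and res.set_point_pi == 160.0

    def test_percentile_rectangle_against_sorting_oracle(self):
        sbp = np.arange(100.0, 140.0)  # 40 points
        pi = sbp + 30.0
        res = summarize_baroreflex(_fake_sequences(sbp, pi), 1)

        def interp_quantile(values, q):
            v = np.sort(values)
            h = (len(v) - 1) * q
            lo, hi = int(math.floor(h)), int(math.ceil(h))
            return v[lo] + (h - lo) * (v[hi] - v[lo])

        span = interp_quantile(sbp, 0.975) - interp_quantile(sbp, 0.025)
        assert res.sbp_span == pytest.approx(span)
        assert res.pi_span == pytest.approx(span)
        assert res.operating_range_area == pytest.approx(span * span)
        assert res.set_point_sbp == pytest.approx(np.sort(sbp)[len(sbp) // 2 - 1 : len(sbp) // 2 + 1].mean())

    def test_area_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(5)
        sbp = rng.uniform(100, 140, 400)
        pi = rng.uniform(140, 200, 400)
        base = summarize_baroreflex(_fake_sequences(sbp, pi), 1)
        perm = rng.permutation(400)
        shuffled = summarize_baroreflex(_fake_sequences(sbp[perm], pi[perm]), 1)
        doubled = summarize_baroreflex(_fake_sequences(np.r_[sbp, sbp], np.r_[pi, pi]), 1)
        assert shuffled.operating_range_area == pytest.approx(base.operating_range_area)
        # interpolated percentiles shift by under half an inter-point gap on duplication
        assert doubled.operating_range_area == pytest.approx(base.operating_range_area, rel=0.01)

    def test_no_sequences_leaves_fields_missing(self):
        res = summarize_baroreflex([], 7)
        assert res.n_sequences == 0 and res.n_ramps == 7
        assert res.bei == 0.0
        assert math.isnan(res.brs) and math.isnan(res.operating_range_area)


class TestAnalyze:
    def test_noise_free_gain_and_full_effectiveness(self):
        beats, _ = simulate_beats(clean_sim(gain=2.0, seed=4))
        res = analyze_baroreflex(beats)
        assert res.brs == pytest.approx(2.0, rel=1e-6)
        assert res.bei == 1.0

    def test_partial_coupling_bei_in_binomial_interval(self):
        beats, _ = simulate_beats(clean_sim(gain=2.0, coupling_prob=0.5, seed=6))
        res = analyze_baroreflex(beats)
        assert res.n_ramps >= 200
        assert 0.35 <= res.bei <= 0.65  # 99% binomial interval around 0.5

    def test_constant_sbp_yields_no_sequences(self):
        beats, _ = simulate_beats(clean_sim(components=(), gain=0.0, seed=7))
        res = analyze_baroreflex(beats)
        assert res.n_sequences == 0 and math.isnan(res.brs)

    def test_bei_non_decreasing_in_coupling_probability(self):
        means = []
        for p in (0.2, 0.5, 0.8):
            vals = [
                analyze_baroreflex(
                    simulate_beats(clean_sim(duration=200.0, coupling_prob=p, seed=40 + s))[0]
                ).bei
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_gain_recovery_across_gains_and_lags(self):
        for gain in (0.5, 5.0):
            for lag in (3, 4, 5):
                beats, _ = simulate_beats(clean_sim(duration=120.0, gain=gain, lag=lag, seed=8))
                res = analyze_baroreflex(beats)
                assert res.brs == pytest.approx(gain, rel=1e-6), (gain, lag)
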