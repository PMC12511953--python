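import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereotrack.episodes import (
    EpisodeConfig,
    Segment,
    _segment_costs,
    acf,
    assemble_report,
    fft_cycle,
    is_periodic,
    segment_series,
)
from stereotrack.errors import InvalidArgumentError, UndefinedStatisticError

FPS = 25.0


def sine(period_s, duration_s, amp=0.2, base=0.8, fps=FPS, noise=0.0, seed=0):
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    y = base + amp * np.sin(2 * np.pi * t / period_s)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, size=n)
    return y


def brute_force_single_split(y, min_len):
    """Exhaustive search over all single split points with the same cost."""
    cost = _segment_costs(np.asarray(y, float))
    n = len(y)
    best_s, best_gain = None, -np.inf
    for s in range(min_len, n - min_len + 1):
        gain = cost(0, n) - cost(0, s) - cost(s, n)
        if gain > best_gain:
            best_s, best_gain = s, gain
    return best_s, best_gain


class TestSegmentation:
    def test_iid_noise_single_segment(self, make_series, rng):
        series = make_series(0.8 + rng.normal(0, 0.03, 800))
        segs = segment_series(series)
        assert len(segs) == 1

    def test_mean_shift_split_matches_exhaustive_oracle(self, make_series, rng):
        y = np.concatenate([rng.normal(0, 0.05, 100), rng.normal(1, 0.05, 100)])
        series = make_series(y)
        segs = segment_series(series, min_len_s=0.4)
        boundary = segs[0].end_idx
        oracle, _ = brute_force_single_split(y, min_len=10)
        assert abs(boundary - oracle) <= 2
        assert abs(boundary - 100) <= 2

    def test_quiescent_oscillating_quiescent_boundaries(self, make_series, rng):
        quiet = lambda n: 0.8 + rng.normal(0, 0.03, n)
        y = np.concatenate(
            [quiet(500), sine(2.0, 10.0, noise=0.03, seed=1), quiet(500)]
        )
        series = make_series(y)
        segs = segment_series(series)
        assert len(segs) >= 3
        cuts = sorted({s.start_idx for s in segs} | {s.end_idx for s in segs})
        assert any(abs(c - 500) <= 0.5 * FPS for c in cuts)
        assert any(abs(c - 750) <= 0.5 * FPS for c in cuts)

    def test_partition_exact(self, make_series, rng):
        series = make_series(np.concatenate([rng.normal(0, 1, 120), rng.normal(3, 1, 130)]))
        segs = segment_series(series, min_len_s=0.4)
        assert segs[0].start_idx == 0
        assert segs[-1].end_idx == len(series)
        for a, b in zip(segs, segs[1:]):
            assert a.end_idx == b.start_idx

    def test_short_series_single_segment(self, make_series):
        series = make_series(np.ones(10) * 0.8)
        assert len(segment_series(series, min_len_s=2.0)) == 1


class TestACF:
    def test_lag_zero_is_one(self, rng):
        y = rng.normal(size=50)
        assert acf(y, 0) == pytest.approx(1.0)

    def test_hand_example(self):
        assert acf([1, 2, 3, 4, 5], 1) == pytest.approx(0.4, abs=1e-12)

    def test_sinusoid_local_max_at_period(self):
        y = sine(period_s=20 / FPS, duration_s=8.0)
        period = 20
        values = [acf(y, k) for k in range(period + 3)]
        k_star = int(np.argmax(values[period - 2 : period + 3])) + period - 2
        assert abs(k_star - period) <= 1

    def test_constant_series_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            acf(np.ones(10), 1)

    def test_bad_lag(self):
        with pytest.raises(InvalidArgumentError):
            acf(np.arange(5.0), 5)

    def test_matches_statsmodels(self, rng):
        """Independent oracle: the same statistic as statsmodels' ACF
        (full-series mean and denominator)."""
        statsmodels = pytest.importorskip("statsmodels.tsa.stattools")
        y = rng.normal(size=120)
        reference = statsmodels.acf(y, nlags=20, adjusted=False, fft=False)
        ours = [acf(y, k) for k in range(21)]
        assert np.allclose(ours, reference, atol=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_bounded_by_one(self, seed):
        y = np.random.default_rng(seed).normal(size=40)
        for k in (0, 1, 5, 20, 39):
            assert abs(acf(y, k)) <= 1.0 + 1e-12


class TestIsPeriodic:
    def test_flat_segment_not_periodic(self, make_series):
        series = make_series(np.full(300, 0.8))
        ev = is_periodic(Segment(series, 0, 300))
        assert not ev
        assert "variance" in ev.reason

    def test_clean_sinusoid_detected_with_correct_lag(self, make_series):
        series = make_series(sine(period_s=2.0, duration_s=20.0))
        ev = is_periodic(Segment(series, 0, len(series)))
        assert ev.periodic
        assert ev.lag_s == pytest.approx(2.0, abs=1.5 / FPS)
        assert ev.acf_value >= 0.3

    def test_white_noise_rarely_flagged(self):
        """|ACF| of white noise stays far below 0.3 for n = 500."""
        flagged = 0
        for seed in range(100):
            y = 0.8 + np.random.default_rng(seed).normal(0, 0.1, 500)
            series = AmplitudeSeriesFactory(y)
            if is_periodic(Segment(series, 0, 500)).periodic:
                flagged += 1
        assert flagged <= 1

    def test_too_short_segment_is_false_not_error(self, make_series):
        series = make_series(sine(2.0, 0.4))  # 10 samples: below the smallest lag
        ev = is_periodic(Segment(series, 0, len(series)))
        assert not ev.periodic
        assert "short" in ev.reason


def AmplitudeSeriesFactory(y, fps=FPS):
    from stereotrack.amplitude import AmplitudeSeries

    return AmplitudeSeries(track_id=1, fps=fps, t=np.arange(len(y)) / fps, r=np.asarray(y, float))


class TestFFTCycle:
    def test_exact_when_period_divides_length(self):
        y = sine(period_s=0.5, duration_s=5.0, fps=30.0)  # 15-frame period, n=150
        assert fft_cycle(y, fps=30.0) == pytest.approx(0.5, abs=1e-12)

    def test_noise_keeps_estimate_within_a_bin(self, rng):
        y = sine(period_s=0.5, duration_s=5.0, fps=30.0) + rng.normal(0, 0.02, 150)
        # 150 samples at 30 fps: bin spacing 0.2 Hz around the 2 Hz peak
        est = fft_cycle(y, fps=30.0)
        assert 1.0 / 2.2 <= est <= 1.0 / 1.8

    def test_dominant_component_wins(self):
        t = np.arange(300) / FPS
        y = 1.0 * np.sin(2 * np.pi * t / 2.0) + 0.3 * np.sin(2 * np.pi * t / 0.75)
        assert fft_cycle(y, fps=FPS) == pytest.approx(2.0, rel=0.05)

    def test_minimum_length(self):
        with pytest.raises(InvalidArgumentError):
            fft_cycle(np.ones(7), fps=FPS)

    def test_degenerate_spectrum(self):
        with pytest.raises(UndefinedStatisticError):
            fft_cycle(np.full(16, 0.8), fps=FPS)

    def test_accepts_segment(self, make_series):
        series = make_series(sine(period_s=2.0, duration_s=10.0))
        assert fft_cycle(Segment(series, 0, len(series))) == pytest.approx(2.0, rel=0.02)


class TestAssembleReport:
    def test_embedded_episode_recovered(self, make_series, rng):
        quiet = lambda n, s: 0.8 + np.random.default_rng(s).normal(0, 0.03, n)
        y = np.concatenate(
            [quiet(625, 1), sine(2.0, 10.0, noise=0.03, seed=2), quiet(625, 3)]
        )
        series = make_series(y)
        report = assemble_report([series])
        eps = report.episodes[1]
        assert len(eps) == 1
        assert eps[0].cycle_time_s == pytest.approx(2.0, abs=0.2)
        assert eps[0].duration_s == pytest.approx(10.0, abs=1.0)
        assert eps[0].start_s == pytest.approx(25.0, abs=1.0)

    def test_all_quiescent_is_none(self, make_series, rng):
        series = make_series(0.8 + rng.normal(0, 0.03, 1500))
        report = assemble_report([series])
        assert report.episodes[1] == []
        assert report.summary()[1] is None
        assert report.summary_frame().iloc[0]["cycle_time_s"] == "None"

    def test_two_separated_episodes_not_merged(self, make_series):
        quiet = lambda n, s: 0.8 + np.random.default_rng(s).normal(0, 0.03, n)
        y = np.concatenate(
            [
                quiet(250, 1),
                sine(1.5, 8.0, noise=0.03, seed=2),
                quiet(250, 3),
                sine(3.0, 8.0, noise=0.03, seed=4),
                quiet(250, 5),
            ]
        )
        series = make_series(y)
        report = assemble_report([series])
        eps = report.episodes[1]
        assert len(eps) == 2
        assert eps[0].cycle_time_s == pytest.approx(1.5, abs=0.25)
        assert eps[1].cycle_time_s == pytest.approx(3.0, abs=0.45)

    def test_episode_invariants(self, make_series):
        y = np.concatenate(
            [
                0.8 + np.random.default_rng(0).normal(0, 0.03, 300),
                sine(2.0, 12.0, noise=0.03, seed=1),
                0.8 + np.random.default_rng(2).normal(0, 0.03, 300),
            ]
        )
        report = assemble_report([make_series(y)])
        for e in report.episodes[1]:
            assert e.duration_s > 0
            assert 0 < e.cycle_time_s <= e.duration_s
            assert e.n_cycles == pytest.approx(e.duration_s / e.cycle_time_s)

    def test_config_validation(self):
        with pytest.raises(InvalidArgumentError):
            EpisodeConfig(theta_acf=1.5)
        with pytest.raises(InvalidArgumentError):
            EpisodeConfig(lag_range_s=(2.0, 1.0))
        with pytest.raises(InvalidArgumentError):
            EpisodeConfig(min_len_s=0.0)
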