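"""R/R0 quantification pipeline tests."""

import numpy as np
import pytest

from cyclosim.errors import (CorruptFrameError, InsufficientBaselineError,
                             MissingEventError, NoPlateauError)
from cyclosim.traces import (
    RatioSeries, RawTrace, background_subtract_and_ratio, detrend_baseline,
    extract_plateau_delta, find_plateau, normalize_to_baseline, read_trace,
    saturation_headroom, write_trace,
)


def make_series(values, events=None, stim=None):
    values = np.asarray(values, float)
    series = RatioSeries(time_s=np.arange(len(values)) * 10.0, ratio=values,
                         events=events or {})
    if stim is not None:
        series = normalize_to_baseline(series, stim)
    return series


def step_trace(baseline=1.0, levels=(), n_base=12, n_level=20):
    """Piecewise-constant normalized-ratio profile."""
    parts = [np.full(n_base, baseline)]
    for level in levels:
        parts.append(np.full(n_level, level))
    return np.concatenate(parts)


class TestBackgroundAndRatio:
    def test_arithmetic(self):
        trace = RawTrace(time_s=np.arange(10) * 10.0,
                         donor_480=np.full(10, 300.0), acceptor_545=np.full(10, 200.0),
                         background_480=100.0, background_545=100.0)
        series = background_subtract_and_ratio(trace)
        assert np.allclose(series.ratio, 2.0)

    def test_zero_background_is_plain_ratio(self):
        trace = RawTrace(time_s=np.arange(10) * 10.0,
                         donor_480=np.full(10, 330.0), acceptor_545=np.full(10, 300.0))
        assert np.allclose(background_subtract_and_ratio(trace).ratio, 1.1)

    def test_corrupt_frame_named(self):
        acceptor = np.full(10, 200.0)
        acceptor[5] = 100.0  # equals background
        trace = RawTrace(time_s=np.arange(10) * 10.0,
                         donor_480=np.full(10, 300.0), acceptor_545=acceptor,
                         background_480=100.0, background_545=100.0)
        with pytest.raises(CorruptFrameError) as err:
            background_subtract_and_ratio(trace)
        assert err.value.frame == 5


class TestNormalization:
    def test_constant_trace(self):
        series = make_series(np.full(30, 1.7), stim=10)
        assert series.r0 == pytest.approx(1.7)
        assert np.allclose(series.normalized, 1.0)

    def test_plateau_scaling_arithmetic(self):
        values = np.concatenate([np.full(10, 2.0), np.full(20, 2.5)])
        series = make_series(values, stim=10)
        assert series.normalized[-1] == pytest.approx(1.25)

    def test_baseline_window_mean_exactly_one(self, rng):
        values = 1.5 * (1 + rng.normal(0, 0.01, 60))
        series = make_series(values, stim=20)
        window = series.normalized[12:20]
        assert np.mean(window) == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_baseline(self):
        with pytest.raises(InsufficientBaselineError):
            make_series(np.ones(30), stim=5)


class TestDetrend:
    def test_drift_free_unchanged(self):
        series = make_series(np.full(40, 1.4), stim=10)
        out = detrend_baseline(series, "linear")
        assert np.allclose(out.ratio, series.ratio, atol=1e-12)

    def test_multiplicative_drift_removed(self):
        t = np.arange(60, dtype=float)
        values = 1.5 * (1 + 0.001 * t)
        series = make_series(values, stim=20)
        out = detrend_baseline(series, "linear")
        slope = np.polyfit(t[:20], out.ratio[:20], 1)[0]
        assert abs(slope) < 1e-6

    def test_mode_none_is_identity(self):
        series = make_series(np.linspace(1, 2, 30), stim=10)
        assert detrend_baseline(series, "none") is series


class TestPlateauDelta:
    def test_step_delta(self):
        values = step_trace(1.0, [1.2])
        series = make_series(values, events={"stim": 12}, stim=12)
        assert extract_plateau_delta(series, "stim") == pytest.approx(0.2, abs=1e-12)

    def test_ramp_has_no_plateau(self):
        values = np.concatenate([np.ones(12), 1.0 + 0.01 * np.arange(30)])
        series = make_series(values, events={"stim": 12}, stim=12)
        with pytest.raises(NoPlateauError):
            extract_plateau_delta(series, "stim")

    def test_chained_deltas_use_previous_plateau(self):
        # stimulus to 1.15, then inhibitor on the stimulated background to 1.25
        values = step_trace(1.0, [1.15, 1.25])
        series = make_series(values, events={"stim": 12, "inh": 32}, stim=12)
        assert extract_plateau_delta(series, "stim") == pytest.approx(0.15, abs=1e-9)
        assert extract_plateau_delta(series, "inh") == pytest.approx(0.10, abs=1e-9)

    def test_chained_deltas_recovered_under_noise(self, rng):
        values = step_trace(1.0, [1.15, 1.25], n_level=30)
        values = values * (1 + rng.normal(0, 0.004, len(values)))
        series = make_series(values, events={"stim": 12, "inh": 42}, stim=12)
        assert extract_plateau_delta(series, "stim") == pytest.approx(0.15, abs=0.01)
        assert extract_plateau_delta(series, "inh") == pytest.approx(0.10, abs=0.01)

    def test_latest_window_is_used(self):
        # slow approach then flat: the plateau must reflect the final level
        approach = 1.2 - 0.2 * np.exp(-np.arange(40) / 6.0)
        values = np.concatenate([np.ones(12), approach, np.full(10, 1.2)])
        series = make_series(values, events={"stim": 12}, stim=12)
        assert extract_plateau_delta(series, "stim") == pytest.approx(0.2, abs=1e-3)


class TestHeadroom:
    def test_positive_headroom(self):
        values = step_trace(1.0, [1.2, 1.5])
        series = make_series(values, events={"stim": 12, "sat": 32}, stim=12)
        assert saturation_headroom(series, "sat") == pytest.approx(0.3, abs=1e-9)

    def test_equal_plateaus_zero_headroom(self):
        values = step_trace(1.0, [1.2, 1.2])
        series = make_series(values, events={"stim": 12, "sat": 32}, stim=12)
        assert saturation_headroom(series, "sat") == pytest.approx(0.0, abs=1e-9)

    def test_missing_event(self):
        series = make_series(step_trace(1.0, [1.2]), events={"stim": 12}, stim=12)
        with pytest.raises(MissingEventError):
            saturation_headroom(series, "sat")


class TestPlateauRule:
    def test_noiseless_ramp_rejected_by_strict_tolerance(self):
        ramp = 1.0 + 0.002 * np.arange(30)
        with pytest.raises(NoPlateauError):
            find_plateau(ramp, 0, 30, plateau_len=6, slope_tol=1e-3)

    def test_flat_window_found_after_transient(self):
        values = np.concatenate([np.linspace(1.0, 1.3, 20), np.full(10, 1.3)])
        window = find_plateau(values, 0, 30)
        assert np.allclose(window, 1.3)


class TestRoundTrip:
    def test_trace_csv_round_trip(self, tmp_path, rng):
        trace = RawTrace(time_s=np.arange(20) * 10.0,
                         donor_480=1000 + rng.normal(0, 5, 20),
                         acceptor_545=800 + rng.normal(0, 5, 20),
                         background_480=90.0, background_545=110.0,
                         events={"stim": 10, "sat": 15},
                         meta={"cell_id": "c1", "genotype": "control"})
        path = tmp_path / "c1.csv"
        write_trace(trace, path)
        back = read_trace(path)
        assert np.allclose(back.donor_480, trace.donor_480, atol=5e-6)
        assert back.events == {"stim": 10, "sat": 15}
        assert back.meta["genotype"] == "control"

    def test_writer_is_deterministic(self, tmp_path):
        trace = RawTrace(time_s=np.arange(12) * 10.0,
                         donor_480=np.linspace(900, 1000, 12),
                         acceptor_545=np.linspace(800, 850, 12))
        write_trace(trace, tmp_path / "a.csv")
        write_trace(trace, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
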