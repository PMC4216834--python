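"""Stimulus-locking-index metrics and synchrony read-outs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tcloop import (
    SLISeries,
    SpecificationError,
    integrate_full,
    max_sli,
    mean_field,
    noise_floor,
    peak_frequency,
    sli,
    sli_timeseries,
    sync_duration,
)
from tcloop.model import LorentzSpec, NetworkSpec, PopulationSpec, StimulusSpec, Trajectory
from tcloop.networks import two_population_network
from tcloop.sli import locked_median_frequency, median_oscillator_frequency


class TestSLI:
    @pytest.mark.parametrize("phases,expected", [
        (np.full(7, 2.0), 1.0),
        (np.array([0.0, np.pi]), 0.0),
        (np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3]), 0.0),
    ])
    def test_examples(self, phases, expected):
        assert np.isclose(sli(phases), expected, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(SpecificationError):
            sli(np.array([]))

    @given(st.floats(-10.0, 10.0), st.integers(0, 2**31 - 1))
    def test_invariance_under_global_shift(self, shift, seed):
        ph = np.random.default_rng(seed).uniform(0, 2 * np.pi, 64)
        assert np.isclose(sli(ph + shift), sli(ph), atol=1e-9)

    def test_matches_mean_field_amplitude(self, rng):
        ph = rng.uniform(0, 2 * np.pi, 256)
        assert np.isclose(sli(ph), mean_field(ph).amplitude, atol=1e-14)


def _synthetic_trajectory(times, y_by_pop, net=None):
    names = tuple(y_by_pop)
    mf = np.column_stack([y_by_pop[k] for k in names])
    return Trajectory(
        times_ms=times, mean_fields=mf, pop_names=names, net=net,
        dt_ms=float(times[1] - times[0]), seed=0, freq_mode="quantile",
        frequencies=[],
    )


class TestSeries:
    def test_uniform_initialised_run_sits_at_noise_floor_prestimulus(self):
        net = two_population_network(k_c=1.2, k_t=5.5, n=1000,
                                     stimulus=StimulusSpec(100.0, 200.0, 50.0))
        traj = integrate_full(net, (0.0, 200.0), dt_ms=0.1, seed=8)
        series = sli_timeseries(traj)
        for name in ("thalamus", "theta"):
            assert np.all(series.sli[name] < 0.1)

    def test_synchronized_trajectory_has_unit_sli(self):
        t = np.arange(0.0, 100.0, 1.0)
        traj = _synthetic_trajectory(t, {"a": np.exp(1j * 0.04 * t)})
        series = sli_timeseries(traj)
        assert np.allclose(series.sli["a"], 1.0)

    def test_max_sli_of_constant_series(self):
        t = np.arange(0.0, 100.0, 1.0)
        series = SLISeries(t, {"a": np.full_like(t, 0.42)})
        assert max_sli(series, "a", (10.0, 90.0)) == pytest.approx(0.42)
        with pytest.raises(SpecificationError):
            max_sli(series, "a", (200.0, 300.0))


class TestSyncDuration:
    def _step_series(self, level=1.0, drop_at=300.0):
        t = np.arange(0.0, 1000.0, 1.0)
        x = np.where(t < drop_at + 50.0, level, 0.0)  # offset at 50
        return SLISeries(t, {"a": x})

    def test_never_locked_gives_zero(self):
        t = np.arange(0.0, 500.0, 1.0)
        series = SLISeries(t, {"a": np.full_like(t, 0.05)})
        assert sync_duration(series, "a", 0.5) == 0.0

    def test_step_series_duration(self):
        assert sync_duration(self._step_series(), "a", 0.5) == pytest.approx(300.0)

    def test_late_locking_counted_from_offset(self):
        # locking only develops 100 ms after offset, collapses at 400 ms
        t = np.arange(0.0, 1000.0, 1.0)
        x = np.where((t >= 150.0) & (t < 450.0), 0.8, 0.0)
        series = SLISeries(t, {"a": x})
        assert sync_duration(series, "a", 0.5) == pytest.approx(400.0)

    def test_monotone_nonincreasing_in_threshold(self):
        t = np.arange(0.0, 800.0, 1.0)
        x = np.exp(-(t - 50.0) / 200.0) * (t >= 50.0)
        series = SLISeries(t, {"a": x})
        durations = [sync_duration(series, "a", thr)
                     for thr in (0.1, 0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(durations, durations[1:]))

    def test_brief_dips_ride_through_guard(self):
        t = np.arange(0.0, 1000.0, 1.0)
        x = np.where(t < 650.0, 0.8, 0.0)
        x[(t >= 200) & (t < 220)] = 0.1  # 20 ms dip < 50 ms guard
        series = SLISeries(t, {"a": x})
        assert sync_duration(series, "a", 0.5) == pytest.approx(600.0)


class TestFrequencies:
    def _pure_tone_traj(self, f_hz=6.0, dt=1.0, t_end=1000.0):
        t = np.arange(0.0, t_end, dt)
        y = 0.5 * np.exp(2j * np.pi * f_hz * t / 1000.0)
        net = two_population_network(1.2, 5.5, n=10)
        traj = _synthetic_trajectory(t, {"thalamus": y, "theta": y}, net=net)
        return traj

    @pytest.mark.parametrize("f", [4.0, 6.0, 9.4, 12.0])
    def test_pure_tone_recovered_within_a_bin(self, f):
        traj = self._pure_tone_traj(f_hz=f)
        est = peak_frequency(traj, "theta", (0.0, 999.0))
        bin_hz = 1000.0 / (999.0 * 4)
        assert abs(est - f) <= bin_hz + 1e-9

    def test_window_too_short_rejected(self):
        traj = self._pure_tone_traj()
        with pytest.raises(SpecificationError):
            peak_frequency(traj, "theta", (0.0, 100.0))  # < 2 periods at 6 Hz

    def test_median_oscillator_frequency_of_linear_drift(self):
        t = np.arange(0.0, 500.0, 1.0)
        f_hz = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
        ph = np.mod(np.outer(t, 2 * np.pi * f_hz / 1000.0), 2 * np.pi)
        net = two_population_network(1.2, 5.5, n=5)
        traj = Trajectory(
            times_ms=t, mean_fields=np.zeros((t.size, 2), complex),
            pop_names=("thalamus", "theta"), net=net, dt_ms=1.0, seed=0,
            freq_mode="quantile", frequencies=[], phases=[ph, ph],
        )
        assert median_oscillator_frequency(traj, "theta", (0.0, 499.0)) == pytest.approx(6.0, abs=1e-9)

    def test_locked_median_frequency_limits(self):
        # no drive: the median is the natural center
        assert locked_median_frequency(6.0, 0.5, 0.0, 9.0) == pytest.approx(6.0, abs=0.01)
        # overwhelming drive: everyone is entrained to the collective rhythm
        assert locked_median_frequency(6.0, 0.5, 50.0, 9.0) == pytest.approx(9.0, abs=0.05)

    def test_noise_floor_scaling(self):
        assert noise_floor(1000) == pytest.approx(np.sqrt(np.pi / 4000.0))
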