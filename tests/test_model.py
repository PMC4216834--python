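"""Full-model unit tests: sampling, stimulus, mean field, integration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from tcloop import (
    ANGULAR_PER_HZ_MS,
    LorentzSpec,
    NetworkSpec,
    PopulationSpec,
    SpecificationError,
    StimulusSpec,
    integrate_full,
    mean_field,
    sample_initial_phases,
    sample_natural_frequencies,
    stimulus_value,
)
from tcloop.model import full_rhs
from tcloop.networks import two_population_network

C = ANGULAR_PER_HZ_MS


def pop(n=101, center=6.0, width=0.5, seed=7, name="p"):
    return PopulationSpec(name, n, LorentzSpec(center, width), seed=seed)


class TestFrequencySampling:
    def test_quantile_median_is_center(self):
        w = sample_natural_frequencies(pop(n=101), mode="quantile")
        assert np.isclose(w[50], C * 6.0)
        assert np.all(np.diff(w) > 0)

    def test_random_mode_is_seeded(self):
        a = sample_natural_frequencies(pop(), mode="random")
        b = sample_natural_frequencies(pop(), mode="random")
        assert np.array_equal(a, b)

    def test_random_sample_median_near_center(self):
        # Cauchy has no mean; the median is the meaningful location check
        w = sample_natural_frequencies(pop(n=10**5, seed=11), mode="random")
        med_hz = np.median(w) / C
        assert abs(med_hz - 6.0) < 0.05

    @pytest.mark.parametrize("bad", [
        dict(center=-1.0), dict(width=0.0), dict(width=-0.5),
    ])
    def test_invalid_law_rejected(self, bad):
        with pytest.raises(SpecificationError):
            LorentzSpec(bad.get("center", 6.0), bad.get("width", 0.5))


class TestInitialPhases:
    def test_uniform_phases_sit_at_noise_floor(self):
        ph = sample_initial_phases(1000, seed=3)
        assert np.abs(np.mean(np.exp(1j * ph))) < 0.1
        assert ph.min() >= 0.0 and ph.max() < 2 * np.pi

    def test_seed_determinism_and_bounds(self):
        assert np.array_equal(sample_initial_phases(10, 5), sample_initial_phases(10, 5))
        assert 0.0 <= sample_initial_phases(1, 0)[0] < 2 * np.pi
        with pytest.raises(SpecificationError):
            sample_initial_phases(0, 0)


class TestStimulus:
    @pytest.mark.parametrize("t,expected", [
        (25.0, 100.0),   # mid-pulse
        (-10.0, 0.0),    # pre-stimulus
        (50.0, 0.0),     # half-open right endpoint
        (0.0, 100.0),    # closed left endpoint
    ])
    def test_window_convention(self, t, expected):
        assert stimulus_value(t, StimulusSpec(100.0, 0.0, 50.0)) == expected


class TestMeanField:
    @pytest.mark.parametrize("phases,amp,phase", [
        (np.full(5, 1.3), 1.0, 1.3),
        (np.array([0.0, np.pi]), 0.0, None),
        (np.array([0.0, np.pi / 2]), np.sqrt(2) / 2, np.pi / 4),
    ])
    def test_examples(self, phases, amp, phase):
        mf = mean_field(phases)
        assert np.isclose(mf.amplitude, amp, atol=1e-12)
        if phase is not None:
            assert np.isclose(mf.phase, phase)

    def test_empty_rejected(self):
        with pytest.raises(SpecificationError):
            mean_field(np.array([]))


class TestFullRHS:
    def setup_method(self):
        self.net = two_population_network(k_c=0.0, k_t=0.0, n=4,
                                          stimulus=StimulusSpec(0.0, 0.0, 0.0))
        self.freqs = [sample_natural_frequencies(p, "quantile")
                      for p in self.net.populations]

    def test_uncoupled_velocity_is_natural_frequency(self):
        ph = [np.array([0.1, 1.0, 2.0, 3.0])] * 2
        out = full_rhs(ph, 10.0, self.net, self.freqs)
        for d, w in zip(out, self.freqs):
            assert np.allclose(d, w)

    def test_stimulus_term_vanishes_at_quarter_phase(self):
        net = two_population_network(k_c=0.0, k_t=0.0, n=4,
                                     stimulus=StimulusSpec(100.0, 0.0, 50.0))
        ph = [np.full(4, np.pi / 2), np.full(4, 0.0)]
        out = full_rhs(ph, 10.0, net, self.freqs)
        assert np.allclose(out[0], self.freqs[0])  # cos(pi/2) = 0

    def test_synchronized_thalamus_exerts_no_force_at_zero_lag(self):
        net = two_population_network(k_c=0.0, k_t=8.0, n=4,
                                     stimulus=StimulusSpec(0.0, 0.0, 0.0))
        ph = [np.zeros(4), np.zeros(4)]  # Theta_T = phi_C = 0 -> sin(0) = 0
        out = full_rhs(ph, 10.0, net, self.freqs)
        assert np.allclose(out[1], self.freqs[1])

    def test_size_mismatch_rejected(self):
        with pytest.raises(SpecificationError):
            full_rhs([np.zeros(3), np.zeros(4)], 0.0, self.net, self.freqs)


class TestIntegration:
    def test_uncoupled_oscillators_drift_linearly(self):
        net = two_population_network(k_c=0.0, k_t=0.0, n=2,
                                     stimulus=StimulusSpec(0.0, 0.0, 0.0))
        traj = integrate_full(net, (0.0, 100.0), dt_ms=0.1, seed=0,
                              freq_mode="quantile", store_phases=True,
                              initial_phases=[np.array([0.0, 1.0])] * 2)
        for p_idx in range(2):
            w = traj.frequencies[p_idx]
            expect = np.mod(np.array([0.0, 1.0]) + w * 100.0, 2 * np.pi)
            assert np.allclose(traj.final_phases[p_idx], expect, atol=1e-8)

    def test_bitwise_determinism(self):
        net = two_population_network(k_c=1.2, k_t=5.5, n=50)
        a = integrate_full(net, (0.0, 50.0), dt_ms=0.1, seed=9)
        b = integrate_full(net, (0.0, 50.0), dt_ms=0.1, seed=9)
        assert np.array_equal(a.mean_fields, b.mean_fields)

    def test_mean_field_amplitude_bounded(self):
        net = two_population_network(k_c=1.2, k_t=16.0, n=200)
        traj = integrate_full(net, (0.0, 300.0), dt_ms=0.1, seed=2)
        assert np.all(np.abs(traj.mean_fields) <= 1.0 + 1e-12)

    def test_stored_mean_fields_recomputable_from_phases(self):
        net = two_population_network(k_c=1.2, k_t=5.5, n=100)
        traj = integrate_full(net, (0.0, 100.0), dt_ms=0.1, seed=4,
                              store_phases=True)
        for a, (name, y) in enumerate(traj.iter_populations()):
            recomputed = np.mean(np.exp(1j * traj.phases[a]), axis=1)
            assert np.allclose(recomputed, y, atol=1e-12)

    def test_lorentzian_dephasing_matches_exponential_decay(self):
        # synchronized start, no coupling: |Y(t)| = exp(-Delta * t) exactly
        # in the infinite-N limit; quantile sampling at N = 4e4 tracks it
        n = 40_000
        net = NetworkSpec(
            thalamus=PopulationSpec("thalamus", n, LorentzSpec(6.0, 0.5)),
            cortical=(PopulationSpec("c", 2, LorentzSpec(6.0, 0.5)),),
            k_thal_to_cortex=(0.0,),
            k_cortex_to_thal=(0.0,),
            stimulus=StimulusSpec(0.0, 0.0, 0.0),
        )
        delta = C * 0.5  # rad/ms
        t_max = 3.0 / delta
        # uncoupled phases drift linearly, so RK4 is exact at any step size
        traj = integrate_full(
            net, (0.0, t_max), dt_ms=0.5, seed=0, freq_mode="quantile",
            store_every=20,
            initial_phases=[np.zeros(n), np.zeros(2)],
        )
        amp = np.abs(traj.mean_fields[:, 0])
        expect = np.exp(-delta * traj.times_ms)
        rel = np.abs(amp - expect) / expect
        assert rel.max() < 0.02

    def test_strong_stimulus_resets_phases_to_attracting_angle(self):
        # oracle: each oscillator follows the 1-D ODE dphi = omega + c*I*cos(phi)
        n = 200
        net = two_population_network(k_c=0.0, k_t=0.0, n=n,
                                     stimulus=StimulusSpec(100.0, 0.0, 50.0))
        traj = integrate_full(net, (0.0, 50.0), dt_ms=0.1, seed=5,
                              freq_mode="quantile")
        w = traj.frequencies[0]
        phi0 = integrate_full(net, (0.0, 0.5), dt_ms=0.1, seed=5,
                              freq_mode="quantile", store_phases=True
                              ).phases[0][0]

        def rhs(t, phi):
            return w + C * 100.0 * np.cos(phi)

        sol = solve_ivp(rhs, (0.0, 50.0), phi0, rtol=1e-10, atol=1e-10)
        oracle_final = np.mod(sol.y[:, -1], 2 * np.pi)
        # the half-open stimulus window makes the last RK4 step's later
        # stages see I = 0, a small O(dt) boundary mismatch vs the oracle
        assert np.allclose(
            np.sort(traj.final_phases[0]), np.sort(oracle_final), atol=1e-2
        )
        near = np.abs(np.angle(np.exp(1j * (traj.final_phases[0] - np.pi / 2))))
        assert np.mean(near < 0.3) >= 0.95

    def test_nonfinite_state_raises_with_time(self):
        from tcloop import IntegrationError
        net = two_population_network(k_c=1.2, k_t=5.5, n=10)
        bad = [np.full(10, np.nan), np.zeros(10)]
        with pytest.raises(IntegrationError):
            integrate_full(net, (0.0, 1.0), dt_ms=0.1, initial_phases=bad)


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_phase_sampling_always_in_range(seed):
    ph = sample_initial_phases(50, seed)
    assert np.all((ph >= 0.0) & (ph < 2 * np.pi))
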