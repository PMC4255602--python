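"""Izhikevich Class-1 neurons, LFSR noise, gain calibration, populations."""

import numpy as np
import pytest

from spindlesim.errors import CalibrationError, ConfigError
from spindlesim.neurons import (IzhikevichParams, NeuronConfig, NeuronState,
                                NoiseStream, SpikeRaster, _advance32,
                                _lfsr_step_scalar, _seed_states, calibrate_gain,
                                izhikevich_step, lfsr_noise, measure_fi_curve,
                                rate_to_epsc, run_population)

PARAMS = IzhikevichParams()


class TestIzhikevichStep:
    def test_rest_without_input_stays_silent(self):
        st = NeuronState(v=-60.0, u=PARAMS.b * -60.0)
        vs = []
        for _ in range(500):
            st, spiked = izhikevich_step(st, 0.0, 0.0, 1.0, PARAMS)
            assert not spiked
            vs.append(st.v)
        assert abs(vs[-1] - vs[-2]) < 1e-6  # converged to rest

    def test_constant_drive_fires_periodically(self):
        st = NeuronState()
        spikes = []
        for t in range(3000):
            st, spiked = izhikevich_step(st, 20.0, 0.0, 1.0, PARAMS)
            if spiked:
                spikes.append(t)
        isis = np.diff(spikes[5:])
        assert isis.size > 50
        # deterministic quasi-periodic firing: small jitter from the 1 ms grid
        assert isis.std() / isis.mean() < 0.2

    def test_rate_close_to_fine_dt_reference(self):
        """The 1 ms two-half-step update tracks a 0.05 ms reference
        simulation of the same model to within 15%."""
        for current in (10.0, 30.0, 60.0):
            coarse = measure_fi_curve(PARAMS, [current], dt_ms=1.0)[0]
            fine = measure_fi_curve(PARAMS, [current], dt_ms=0.05)[0]
            assert coarse == pytest.approx(fine, rel=0.15)

    def test_class1_fi_curve_continuous_and_monotone(self):
        """Class-1 excitability: rate grows continuously from zero, with no
        finite jump at onset beyond one resolvable step."""
        currents = np.linspace(0.0, 30.0, 61)
        rates = measure_fi_curve(PARAMS, currents)
        assert np.all(np.diff(rates) >= -0.5)
        onset = rates[rates > 0]
        assert onset[0] < 10.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            IzhikevichParams(a=-0.1)
        with pytest.raises(ConfigError):
            IzhikevichParams(c=40.0)


class TestLfsrNoise:
    def test_jump_table_matches_naive_stepping(self):
        """The byte-table 32-tick jump is bit-exact with serial stepping."""
        for seed in (1, 0xDEADBEEF, 0x7FFFFFFF, 0x80000000):
            naive = seed
            for _ in range(32):
                naive = _lfsr_step_scalar(naive)
            assert int(_advance32(np.asarray(seed, dtype=np.uint32))[()]) == naive

    def test_deterministic_sequence(self):
        a = NoiseStream(lfsr_state=12345)
        b = NoiseStream(lfsr_state=12345)
        for _ in range(1000):
            sa, a = lfsr_noise(a)
            sb, b = lfsr_noise(b)
            assert sa == sb

    def test_sample_statistics(self):
        """Pooled samples are zero-mean uniform within the +/-2.5 mV bounds."""
        states = _seed_states(99, 16)
        samples = np.empty((62_500, 16))
        s = states.copy()
        for i in range(samples.shape[0]):
            s = _advance32(s)
            samples[i] = s * (5.0 / 2.0 ** 32) - 2.5
        assert abs(samples.mean()) < 0.02
        assert samples.min() >= -2.5
        assert samples.max() <= 2.5
        # distinct streams are uncorrelated
        corr = np.corrcoef(samples[:, 0], samples[:, 1])[0, 1]
        assert abs(corr) < 0.02

    def test_zero_seed_rejected(self):
        with pytest.raises(ValueError):
            NoiseStream(lfsr_state=0)

    def test_seed_states_never_zero(self):
        assert np.all(_seed_states(0, 4096) != 0)


class TestCalibration:
    def test_round_trip_within_twenty_percent(self, gain):
        """rate -> current -> simulated rate closes to within 20%."""
        for target in (40.0, 100.0, 160.0, 220.0, 300.0):
            current = rate_to_epsc(target, gain)
            measured = measure_fi_curve(PARAMS, [current])[0]
            assert measured == pytest.approx(target, rel=0.20)

    def test_monotonic_map(self, gain):
        rates = np.linspace(0.0, 300.0, 301)
        currents = rate_to_epsc(rates, gain)
        assert np.all(np.diff(currents) >= 0)

    def test_zero_rate_is_subthreshold(self, gain):
        """A silent spindle leaves a noise-free neuron silent."""
        current = rate_to_epsc(0.0, gain)
        assert measure_fi_curve(PARAMS, [current], measure_ms=2000.0)[0] == 0.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_gain(PARAMS, (0.0, 0.0))

    def test_deterministic(self, gain):
        again = calibrate_gain(PARAMS, (0.0, 300.0))
        assert np.array_equal(again.currents, gain.currents)
        assert np.array_equal(again.rates, gain.rates)

    def test_negative_rate_rejected(self, gain):
        with pytest.raises(ValueError):
            rate_to_epsc(-1.0, gain)

    def test_linear_method_also_monotone(self):
        g = calibrate_gain(PARAMS, (0.0, 300.0), method="linear")
        rates = np.linspace(0.0, 300.0, 301)
        assert np.all(np.diff(rate_to_epsc(rates, g)) >= 0)


class TestRunPopulation:
    def test_bit_identical_given_seed(self, neuron_cfg):
        trace = np.full(2000, 80.0)
        a = run_population(trace, 16, "Ia", 42, neuron_cfg)
        b = run_population(trace, 16, "Ia", 42, neuron_cfg)
        assert np.array_equal(a.times_ms, b.times_ms)
        assert np.array_equal(a.neuron_ids, b.neuron_ids)
        c = run_population(trace, 16, "Ia", 43, neuron_cfg)
        assert not (np.array_equal(a.times_ms, c.times_ms)
                    and np.array_equal(a.neuron_ids, c.neuron_ids))

    def test_zero_rate_with_noise_stays_near_silent(self, neuron_cfg):
        ras = run_population(np.zeros(5000), 64, "Ia", 3, neuron_cfg)
        assert ras.n_spikes <= 5  # membrane noise alone is subthreshold

    def test_constant_rate_tracked_by_population(self, neuron_cfg):
        ras = run_population(np.full(5000, 50.0), 64, "Ia", 9, neuron_cfg)
        mean_rate = ras.n_spikes / 64 / 5.0
        assert mean_rate == pytest.approx(50.0, rel=0.25)

    def test_noise_raises_isi_variability(self, gain):
        """Membrane noise makes firing irregular; without it the 1 ms grid
        leaves only a small deterministic quantization jitter."""
        trace = np.full(12000, 100.0)
        cvs = {}
        for amp in (0.0, 5.0):
            cfg = NeuronConfig(noise_amplitude_mv=amp, gain=gain)
            ras = run_population(trace, 1, "Ia", 5, cfg)
            st = ras.spike_times(0)
            isis = np.diff(st[st > 2000])
            cvs[amp] = isis.std() / isis.mean()
        assert cvs[5.0] > cvs[0.0]
        assert cvs[0.0] < 0.15

    def test_population_coding_improves_with_size(self, neuron_cfg):
        """Binned population counts track the driving rate better as the
        population grows."""
        from scipy import stats as sstats
        from spindlesim import stimuli
        wf = stimuli.filtered_white_noise(20.0, 5.0, 1.0, seed=7)
        rate = 20.0 + 130.0 * (wf.samples - 1.0)
        rs = []
        for n in (8, 32, 128):
            ras = run_population(rate, n, "Ia", 11, neuron_cfg)
            _, counts = ras.binned_counts(20.0, float(rate.size))
            model = rate[: counts.size * 20].reshape(-1, 20).mean(axis=1)
            rs.append(sstats.pearsonr(counts, model)[0])
        assert rs[0] < rs[1] < rs[2]

    def test_bad_population_size_rejected(self, neuron_cfg):
        with pytest.raises(ConfigError):
            run_population(np.zeros(10), 0, "Ia", 1, neuron_cfg)


class TestSpikeRaster:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            SpikeRaster(times_ms=[3.0, 1.0], neuron_ids=[0, 0], n_neurons=1)
        with pytest.raises(ValueError):
            SpikeRaster(times_ms=[1.0], neuron_ids=[5], n_neurons=2)

    def test_binned_counts(self):
        ras = SpikeRaster(times_ms=[1.0, 2.0, 25.0], neuron_ids=[0, 1, 0],
                          n_neurons=2)
        _, counts = ras.binned_counts(20.0, 40.0)
        assert counts.tolist() == [2.0, 1.0]
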