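"""Intrafusal fiber dynamics and afferent-rate combination."""

import math
from dataclasses import replace

import numpy as np
import pytest

from spindlesim import stimuli
from spindlesim.errors import ConfigError
from spindlesim.spindle import (AfferentRates, FiberState, SpindleConfig,
                                SpindleInput, combine_afferents, default_bag1,
                                default_bag2, fiber_derivatives,
                                fiber_equilibrium, fusimotor_activation_derivative,
                                fusimotor_drive, intrafusal_tensions, simulate,
                                spindle_equilibrium, step_fiber, step_spindle)

BAG1 = default_bag1()
BAG2 = default_bag2()


class TestFusimotorActivation:
    def test_zero_drive_zero_activation_is_fixed_point(self):
        assert fusimotor_activation_derivative(0.0, 0.0, BAG1) == 0.0

    def test_half_activation_at_omega(self):
        """gamma = omega saturates the drive at exactly one half."""
        d = fusimotor_activation_derivative(0.0, BAG1.omega, BAG1)
        assert d == pytest.approx(0.5 / BAG1.tau)

    def test_hand_evaluated_derivative(self):
        # (80^2/(80^2+60^2) - 0.2) / 0.149, evaluated independently
        d = fusimotor_activation_derivative(0.2, 80.0, BAG1)
        assert d == pytest.approx(2.953020134228188, rel=1e-12)

    def test_instantaneous_fiber_has_no_derivative(self):
        from spindlesim.spindle import default_chain
        with pytest.raises(ConfigError):
            fusimotor_activation_derivative(0.0, 10.0, default_chain())

    def test_negative_tau_rejected(self):
        with pytest.raises(ConfigError):
            replace(BAG1, tau=-0.1)


class TestIntrafusalTensions:
    def test_sensory_spring_at_rest_length(self):
        st = FiberState(x0=0.0, x1=1.0 - BAG1.l0_sr, x2=0.0)
        t_sr, _, _ = intrafusal_tensions(st, 1.0, BAG1)
        assert t_sr == pytest.approx(0.0, abs=1e-12)

    def test_damping_vanishes_at_zero_velocity(self):
        st = FiberState(x0=0.5, x1=0.9, x2=0.0)
        assert intrafusal_tensions(st, 1.0, BAG1)[1] == 0.0

    def test_hand_evaluated_tensions(self):
        # independent evaluation at L=1.05, x0=0.3, x1=0.98, x2=0.5 (bag1)
        st = FiberState(x0=0.3, x1=0.98, x2=0.5)
        t_sr, t_b, t_pr = intrafusal_tensions(st, 1.05, BAG1)
        assert t_sr == pytest.approx(0.313947, rel=1e-9)
        assert t_b == pytest.approx(0.058397048486510825, rel=1e-9)
        assert t_pr == pytest.approx(0.033, rel=1e-9)

    def test_damping_opposes_shortening(self):
        """Negative polar velocity flips the damping sign and uses the
        shortening asymmetry coefficient."""
        up = intrafusal_tensions(FiberState(0.3, 0.98, 0.5), 1.05, BAG1)[1]
        down = intrafusal_tensions(FiberState(0.3, 0.98, -0.5), 1.05, BAG1)[1]
        assert down == pytest.approx(-up * BAG1.c_shorten / BAG1.c_lengthen)

    def test_fpga_mode_close_to_exact(self):
        st = FiberState(x0=0.3, x1=0.98, x2=0.5)
        p25 = replace(BAG1, a_exp=0.25)
        exact = intrafusal_tensions(st, 1.05, p25)
        fpga = intrafusal_tensions(st, 1.05, p25, arith="fpga_faithful")
        for e, f in zip(exact, fpga):
            assert f == pytest.approx(e, rel=5e-3)


class TestFiberDerivatives:
    def test_dx1_is_polar_velocity(self):
        st = FiberState(x0=0.2, x1=0.95, x2=0.371)
        inp = SpindleInput(length=1.1, gamma_dyn=20.0)
        assert fiber_derivatives(st, inp, BAG1)[1] == st.x2

    def test_equilibrium_is_fixed_point(self):
        st = fiber_equilibrium(1.0, 0.0, BAG1)
        dx0, dx1, dx2 = fiber_derivatives(st, SpindleInput(1.0), BAG1)
        assert dx0 == pytest.approx(0.0, abs=1e-12)
        assert dx1 == 0.0
        assert dx2 == pytest.approx(0.0, abs=1e-6)

    def test_hand_evaluated_acceleration(self):
        # chained through the hand-evaluated tensions above
        st = FiberState(x0=0.3, x1=0.98, x2=0.5)
        inp = SpindleInput(length=1.05, gamma_dyn=0.0)
        dx2 = fiber_derivatives(st, inp, BAG1)[2]
        assert dx2 == pytest.approx(1069.399757567449, rel=1e-9)


class TestStepFiber:
    def test_single_euler_substep_matches_hand_update(self):
        st = FiberState(x0=0.1, x1=0.95, x2=0.2)
        inp = SpindleInput(length=1.02, gamma_dyn=30.0)
        h = 1e-4
        out = step_fiber(st, inp, BAG1, dt_s=h, integrator="euler", substeps=1)
        drive = 30.0 ** 2 / (30.0 ** 2 + BAG1.omega ** 2)
        x0_new = drive + (st.x0 - drive) * math.exp(-h / BAG1.tau)
        dx2 = fiber_derivatives(FiberState(x0_new, st.x1, st.x2), inp, BAG1)[2]
        assert out.x0 == pytest.approx(x0_new, rel=1e-12)
        assert out.x1 == pytest.approx(st.x1 + h * st.x2, rel=1e-12)
        assert out.x2 == pytest.approx(st.x2 + h * dx2, rel=1e-12)

    def test_equilibrium_is_stationary(self):
        """The analytic force balance holds to integrator tolerance; the
        non-smooth damping term limits a fixed-step explicit scheme to a
        ~1e-5 L0 numerical offset around it."""
        st = fiber_equilibrium(1.0, 0.0, BAG1)
        out = step_fiber(st, SpindleInput(1.0), BAG1, dt_s=0.1, substeps=1000)
        assert out.x1 == pytest.approx(st.x1, abs=5e-5)
        assert abs(out.x2) < 1e-2

    def test_relaxation_to_equilibrium(self):
        """A second of constant input drives any start to force balance."""
        st = FiberState(x0=0.0, x1=0.93, x2=0.0)
        inp = SpindleInput(1.0)
        for _ in range(1000):
            st = step_fiber(st, inp, BAG1, dt_s=1e-3)
        eq = fiber_equilibrium(1.0, 0.0, BAG1)
        assert st.x1 == pytest.approx(eq.x1, abs=1e-4)
        assert abs(st.x2) < 1e-2

    def test_activation_clipped_to_unit_interval(self):
        st = FiberState(x0=1.0, x1=0.95, x2=0.0)
        out = step_fiber(st, SpindleInput(1.0, gamma_dyn=1e4), BAG1, dt_s=1e-3)
        assert 0.0 <= out.x0 <= 1.0


class TestCombineAfferents:
    CFG = SpindleConfig.default()

    def _tensions(self, b1=0.0, b2=0.0, ch=0.0):
        """Sensory-region tensions giving chosen primary components (Hz)."""
        out = {}
        for name, comp in (("bag1", b1), ("bag2", b2), ("chain", ch)):
            p = getattr(self.CFG, name)
            out[name] = p.k_sr * (comp / p.g_primary + p.threshold_strain)
        return out

    def test_all_zero_components(self):
        rates = combine_afferents(1.0, self._tensions(), self.CFG)
        assert rates.ia_rate == 0.0

    def test_occlusion_of_zero(self):
        rates = combine_afferents(0.9, self._tensions(b1=100.0), self.CFG)
        assert rates.ia_rate == pytest.approx(100.0, rel=1e-9)

    def test_partial_occlusion_rule(self):
        """Winner takes all, loser contributes the occlusion fraction."""
        rates = combine_afferents(0.9, self._tensions(b1=50.0, b2=60.0, ch=60.0),
                                  self.CFG)
        expected = 120.0 + self.CFG.occlusion_factor * 50.0
        assert rates.ia_rate == pytest.approx(expected, rel=1e-9)

    def test_bag1_does_not_feed_group_ii(self):
        rates = combine_afferents(0.9, self._tensions(b1=200.0), self.CFG)
        assert rates.ii_rate == 0.0


class TestStepSpindle:
    def test_constant_input_keeps_baseline_rates(self):
        """After a short numerical settling, constant input gives constant
        baseline rates."""
        cfg = SpindleConfig.default()
        state = spindle_equilibrium(1.0, 0.0, 0.0, cfg)
        inp = SpindleInput(1.0)
        for _ in range(2500):
            state, r0 = step_spindle(state, inp, 1e-3, cfg)
        for _ in range(500):
            state, r = step_spindle(state, inp, 1e-3, cfg)
        assert r.ia_rate == pytest.approx(r0.ia_rate, abs=0.05)
        assert r.ii_rate == pytest.approx(r0.ii_rate, abs=0.05)


@pytest.fixture(scope="module")
def ramp_traces():
    cfg = SpindleConfig.default()
    wf = stimuli.ramp_hold(1.0, 0.368, 200, 800, pre_ms=200)
    return {
        "wf": wf,
        "plain": simulate(wf, 0.0, 0.0, cfg),
        "tonic": simulate(wf, 50.0, 50.0, cfg),
    }


class TestRampResponses:
    def test_rates_nonnegative(self, ramp_traces):
        for tr in (ramp_traces["plain"], ramp_traces["tonic"]):
            assert np.all(tr.ia_rate >= 0)
            assert np.all(tr.ii_rate >= 0)

    def test_phasic_tonic_differentiation(self, ramp_traces):
        """Ia overshoots during the ramp and adapts; II is dominated by the
        sustained length response."""
        tr = ramp_traces["plain"]
        ramp = slice(200, 401)
        ia_di = tr.ia_rate[ramp].max() - tr.ia_rate[900]
        ii_di = tr.ii_rate[ramp].max() - tr.ii_rate[900]
        assert ia_di > 0
        assert ia_di > ii_di

    def test_tonic_gamma_facilitates_both_groups(self, ramp_traces):
        plain, tonic = ramp_traces["plain"], ramp_traces["tonic"]
        assert np.all(tonic.ia_rate >= plain.ia_rate - 1e-9)
        assert np.all(tonic.ii_rate >= plain.ii_rate - 1e-9)
        assert tonic.ia_rate.mean() > plain.ia_rate.mean()
        assert tonic.ii_rate.mean() > plain.ii_rate.mean()

    def test_peak_rate_nondecreasing_in_ramp_speed(self):
        cfg = SpindleConfig.default()
        peaks = []
        for ramp_ms in (800, 400, 200, 100):
            wf = stimuli.ramp_hold(1.0, 0.368, ramp_ms, 300, pre_ms=100)
            tr = simulate(wf, 0.0, 0.0, cfg)
            peaks.append(tr.ia_rate.max())
        assert np.all(np.diff(peaks) >= 0)

    def test_release_stop_produces_transient_burst(self):
        """An abruptly ending shortening acts like a momentary fast stretch."""
        cfg = SpindleConfig.default()
        wf = stimuli.release_ramp(1.2, 0.2, 100, pre_ms=300, post_ms=600)
        tr = simulate(wf, 0.0, 0.0, cfg)
        during = tr.ia_rate[300:395].mean()
        burst = tr.ia_rate[400:550].max()
        settled = tr.ia_rate[-1]
        assert burst > during + 50.0
        assert burst > settled + 50.0

    def test_exact_and_fpga_traces_agree(self, ramp_traces):
        """Single-precision datapath with the 0.25 exponent stays within 5%
        RMS of the double-precision 0.3-exponent reference."""
        tr = ramp_traces["plain"]
        cfg_f = SpindleConfig.default("fpga_faithful")
        tr_f = simulate(ramp_traces["wf"], 0.0, 0.0, cfg_f)
        rms = np.sqrt(np.mean((tr.ia_rate - tr_f.ia_rate) ** 2))
        dyn_range = tr.ia_rate.max() - tr.ia_rate.min()
        assert rms < 0.05 * dyn_range


class TestFusimotorSelectivity:
    def test_sinusoid_gamma_routing(self):
        """gamma-dynamic boosts Ia modulation depth; gamma-static boosts the
        cycle-mean rate more than gamma-dynamic does."""
        cfg = SpindleConfig.default()
        wf = stimuli.sinusoid(1.0, 0.026, 3.0, 6)
        t = wf.times_ms
        step = np.where(t >= 1000.0, 80.0, 0.0)

        base = simulate(wf, 0.0, 0.0, cfg)
        dyn = simulate(wf, step, 0.0, cfg)
        stat = simulate(wf, 0.0, step, cfg)

        def cycle_stats(tr, c):
            sel = slice(int(c * 1000 / 3), int((c + 1) * 1000 / 3))
            seg = tr.ia_rate[sel]
            return seg.max() - seg.min(), seg.mean()

        d_base, m_base = cycle_stats(base, 5)
        d_dyn, m_dyn = cycle_stats(dyn, 5)
        d_stat, m_stat = cycle_stats(stat, 5)
        assert d_dyn > d_base
        assert m_stat > m_base
        assert m_stat - m_base > m_dyn - m_base
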