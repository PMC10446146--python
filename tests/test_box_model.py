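"""Well-mixed compartment balance: closed form, oracle agreement, limits."""

import math

import numpy as np
import pytest

from nanorelease.boxmodel import (
    Compartment,
    NoSteadyStateError,
    SourceSinkSet,
    closed_chamber_profile,
    solve_profile,
    solve_profile_numeric,
    steady_state,
    total_loss_rate,
)


class TestTotalLossRate:
    def test_ventilation_only(self):
        comp = Compartment(volume_m3=20.0, flow_m3_h=10.0)
        assert total_loss_rate(comp) == pytest.approx(0.5)

    def test_sealed_chamber_is_zero(self):
        comp = Compartment(volume_m3=0.22, flow_m3_h=0.0)
        assert total_loss_rate(comp) == 0.0

    def test_deposition_and_sink_add(self):
        comp = Compartment(volume_m3=20.0, flow_m3_h=10.0, lambda_dep_h=0.1)
        sinks = SourceSinkSet(extra_sink_flows_m3_h=(10.0,))  # 20 m3/h at eta 0.5
        assert total_loss_rate(comp, sinks) == pytest.approx(1.1)  # (10+2+10)/20


class TestSteadyState:
    def test_no_source_no_supply(self):
        comp = Compartment(volume_m3=20.0, flow_m3_h=10.0)
        assert steady_state(comp) == 0.0

    def test_reference_room_level(self):
        comp = Compartment(volume_m3=20.0, flow_m3_h=10.0)
        sinks = SourceSinkSet(source_rate=0.1998)
        assert steady_state(comp, sinks) == pytest.approx(0.01998, rel=1e-12)

    def test_doubling_flow_halves_level(self):
        sinks = SourceSinkSet(source_rate=1.0)
        c1 = steady_state(Compartment(volume_m3=20.0, flow_m3_h=10.0), sinks)
        c2 = steady_state(Compartment(volume_m3=20.0, flow_m3_h=20.0), sinks)
        assert c1 == pytest.approx(2 * c2, rel=1e-12)

    def test_strictly_increasing_in_source(self):
        comp = Compartment(volume_m3=20.0, flow_m3_h=10.0)
        levels = [steady_state(comp, SourceSinkSet(source_rate=g)) for g in (0.1, 0.2, 0.5)]
        assert levels == sorted(levels) and len(set(levels)) == 3

    def test_sealed_compartment_has_no_steady_state(self):
        comp = Compartment(volume_m3=0.22, flow_m3_h=0.0)
        with pytest.raises(NoSteadyStateError):
            steady_state(comp, SourceSinkSet(source_rate=1.0))


class TestSolveProfile:
    comp = Compartment(volume_m3=20.0, flow_m3_h=10.0)
    sinks = SourceSinkSet(source_rate=0.1998)

    def test_fixed_point_stays_constant(self):
        c_ss = steady_state(self.comp, self.sinks)
        prof = solve_profile(self.comp, self.sinks, c_ss, np.linspace(0, 10, 11))
        assert np.allclose(prof.concentrations, c_ss, rtol=1e-12)

    def test_reference_room_after_10h(self):
        prof = solve_profile(self.comp, self.sinks, 0.0, np.linspace(0, 10, 241))
        expected = 0.01998 * (1 - math.exp(-5.0))
        assert prof.concentrations[-1] == pytest.approx(expected, rel=1e-10)

    def test_monotone_approach_to_steady_state(self):
        prof = solve_profile(self.comp, self.sinks, 0.0, np.linspace(0, 30, 301))
        assert np.all(np.diff(prof.concentrations) > 0)
        assert np.all(prof.concentrations <= prof.steady_state)

    def test_long_time_limit_reaches_steady_state(self):
        k = total_loss_rate(self.comp, self.sinks)
        prof = solve_profile(self.comp, self.sinks, 0.0, np.array([0.0, 20.0 / k]))
        assert abs(prof.concentrations[-1] - prof.steady_state) < 1e-8 * prof.steady_state

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(ValueError):
            solve_profile(self.comp, self.sinks, -1.0, np.array([0.0, 1.0]))

    def test_time_grid_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            solve_profile(self.comp, self.sinks, 0.0, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            solve_profile(self.comp, self.sinks, 0.0, np.array([0.0, 2.0, 1.0]))


class TestNumericalOracleAgreement:
    def test_closed_form_matches_integrator_on_random_parameters(self):
        rng = np.random.default_rng(20260919)
        times = np.linspace(0.0, 12.0, 49)
        for _ in range(100):
            comp = Compartment(
                volume_m3=rng.uniform(1.0, 200.0),
                flow_m3_h=rng.uniform(0.0, 50.0),
                penetration=rng.uniform(0.0, 1.0),
                lambda_dep_h=rng.uniform(0.0, 1.0),
                outdoor_conc=rng.uniform(0.0, 10.0),
            )
            sinks = SourceSinkSet(
                source_rate=rng.uniform(0.0, 5.0),
                extra_sink_flows_m3_h=(rng.uniform(0.0, 20.0),),
            )
            c0 = rng.uniform(0.0, 10.0)
            closed = solve_profile(comp, sinks, c0, times).concentrations
            numeric = solve_profile_numeric(comp, sinks, c0, times).concentrations
            scale = max(np.max(np.abs(closed)), 1e-30)
            assert np.max(np.abs(closed - numeric)) / scale < 1e-9

    def test_oracle_handles_time_varying_supply(self):
        comp = Compartment(volume_m3=20.0, flow_m3_h=10.0, outdoor_conc=0.0)
        sinks = SourceSinkSet()
        times = np.linspace(0.0, 4.0, 9)
        prof = solve_profile_numeric(
            comp, sinks, 0.0, times, outdoor_conc=lambda th: 1.0 + 0.5 * math.sin(th)
        )
        assert np.all(prof.concentrations[1:] > 0)


class TestClosedChamber:
    def test_no_source_stays_at_initial(self):
        t = np.array([0.0, 10.0, 1000.0])
        assert np.allclose(closed_chamber_profile(220e3, 0.0, 5.0, t), 5.0)

    def test_slope_from_chamber_test_parameters(self):
        # 4400 1/s into 220 L -> dC/dt = 0.02 1/(cm3 s)
        v_cm3 = 0.22 * 1e6
        c1 = closed_chamber_profile(v_cm3, 4400.0, 0.0, 1.0)
        assert c1 == pytest.approx(0.02, rel=1e-12)
        assert closed_chamber_profile(v_cm3, 4400.0, 0.0, 60.0) == pytest.approx(1.2)

    def test_mass_conservation_is_exact(self):
        v_cm3 = 0.22 * 1e6
        g = 4400.0
        t = np.linspace(0.0, 259200.0, 97)
        c = closed_chamber_profile(v_cm3, g, 8.0, t)
        assert np.allclose(v_cm3 * (c - 8.0), g * t, rtol=1e-12, atol=1e-9)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            closed_chamber_profile(0.0, 1.0, 0.0, 1.0)
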