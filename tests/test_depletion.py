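import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flashtod import (
    Exposure,
    KineticParams,
    OxygenEnvironment,
    concentration_to_pressure,
    mmhg_to_percent,
    percent_to_mmhg,
    pressure_to_concentration,
    simulate_depletion,
)
from flashtod.errors import DomainError

from .oracles import euler_end_state


class TestUnitConversions:
    def test_zero_percent(self):
        assert percent_to_mmhg(0.0) == 0.0

    def test_half_percent(self):
        assert percent_to_mmhg(0.5) == pytest.approx(3.8)

    def test_air(self):
        assert percent_to_mmhg(21.0) == pytest.approx(159.6)

    def test_negative_percent_rejected(self):
        with pytest.raises(DomainError):
            percent_to_mmhg(-1.0)

    def test_zero_pressure_concentration(self, kinetic):
        assert pressure_to_concentration(0.0, kinetic) == 0.0

    def test_concentration_example(self):
        params = KineticParams(solubility=1.295e-3)
        assert pressure_to_concentration(100.0, params) == pytest.approx(0.1295)

    def test_negative_pressure_rejected(self, kinetic):
        with pytest.raises(DomainError):
            pressure_to_concentration(-5.0, kinetic)

    @given(p=st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
    def test_pressure_round_trip(self, p):
        params = KineticParams()
        c = pressure_to_concentration(p, params)
        assert concentration_to_pressure(c, params) == pytest.approx(p, rel=1e-12)

    @given(pct=st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_percent_round_trip(self, pct):
        assert mmhg_to_percent(percent_to_mmhg(pct)) == pytest.approx(pct, rel=1e-12)


class TestTypes:
    def test_exposure_duration(self):
        assert Exposure(20.0, 2000.0).duration == pytest.approx(0.01)

    def test_zero_dose_duration(self):
        assert Exposure(0.0, 0.1).duration == 0.0

    def test_negative_dose_rejected(self):
        with pytest.raises(DomainError):
            Exposure(-1.0, 1.0)

    def test_zero_dose_rate_rejected(self):
        with pytest.raises(DomainError):
            Exposure(1.0, 0.0)

    def test_ambient_defaults_to_initial(self):
        env = OxygenEnvironment(initial_pO2=3.8)
        assert env.ambient_pO2 == 3.8

    def test_kinetic_invariants(self):
        with pytest.raises(DomainError):
            KineticParams(solubility=0.0)
        with pytest.raises(DomainError):
            KineticParams(k_capture=0.0)
        with pytest.raises(DomainError):
            KineticParams(g_consumption=-1e-4)


class TestSimulate:
    def test_zero_dose_constant(self, kinetic):
        env = OxygenEnvironment(initial_pO2=3.8)
        trace = simulate_depletion(env, Exposure(0.0, 0.1), kinetic)
        assert trace.end_pO2 == 3.8
        assert np.all(trace.pO2 == 3.8)
        assert np.all(trace.radical_conc == 0.0)

    def test_capture_dominated_mass_balance(self):
        # Every radical generated is captured: consumed O2 -> g*D = 6e-3.
        params = KineticParams(
            g_consumption=3e-4, k_decay=0.0, recovery_rate=0.0, metabolic_rate=0.0
        )
        env = OxygenEnvironment(initial_pO2=100.0)  # [O2]0 = 0.1295 >> g*D
        trace = simulate_depletion(env, Exposure(20.0, 2000.0), params)
        consumed = (100.0 - trace.end_pO2) * params.solubility
        assert consumed == pytest.approx(6e-3, rel=0.01)

    def test_conv_depletion_negligible(self, kinetic):
        # 0.1 Gy/s with default recovery: net end depletion ~ 0.
        env = OxygenEnvironment(initial_pO2=percent_to_mmhg(0.5))
        trace = simulate_depletion(env, Exposure(20.0, 0.1), kinetic)
        assert env.initial_pO2 - trace.end_pO2 == pytest.approx(0.0, abs=0.02)

    def test_trace_shape_and_positivity(self, kinetic):
        env = OxygenEnvironment(initial_pO2=3.8)
        trace = simulate_depletion(env, Exposure(20.0, 2000.0), kinetic)
        assert len(trace.times) >= 200
        assert trace.times[0] == 0.0
        assert trace.times[-1] == pytest.approx(0.01)
        assert np.all(np.diff(trace.times) > 0)
        assert np.all(trace.pO2 >= 0)
        assert np.all(trace.radical_conc >= 0)

    def test_no_recovery_monotone_decreasing(self):
        params = KineticParams(recovery_rate=0.0, metabolic_rate=0.0)
        env = OxygenEnvironment(initial_pO2=3.8)
        trace = simulate_depletion(env, Exposure(20.0, 100.0), params)
        assert np.all(np.diff(trace.pO2) <= 1e-12)

    def test_monotone_in_dose(self, kinetic):
        env = OxygenEnvironment(initial_pO2=3.8)
        ends = [
            simulate_depletion(env, Exposure(d, 2000.0), kinetic).end_pO2
            for d in (5.0, 10.0, 20.0, 40.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ends, ends[1:]))

    def test_scale_invariance(self):
        # Doubling solubility and halving initial pressure: same concentrations.
        base = KineticParams(recovery_rate=0.0)
        scaled = dataclasses.replace(base, solubility=2 * base.solubility)
        exposure = Exposure(20.0, 1000.0)
        t1 = simulate_depletion(OxygenEnvironment(initial_pO2=7.6), exposure, base)
        t2 = simulate_depletion(OxygenEnvironment(initial_pO2=3.8), exposure, scaled)
        c1 = t1.end_pO2 * base.solubility
        c2 = t2.end_pO2 * scaled.solubility
        assert c1 == pytest.approx(c2, rel=1e-6)

    def test_conservation_with_decay(self):
        # generated = captured + decayed + still-alive radicals.
        params = KineticParams(recovery_rate=0.0, metabolic_rate=0.0)
        env = OxygenEnvironment(initial_pO2=3.8)
        exposure = Exposure(20.0, 100.0)
        trace = simulate_depletion(env, exposure, params, n_points=4001)
        c0 = env.initial_pO2 * params.solubility
        captured = c0 - trace.end_pO2 * params.solubility
        decayed = params.k_decay * np.trapezoid(trace.radical_conc, trace.times)
        pending = trace.radical_conc[-1]
        generated = params.g_consumption * exposure.dose
        assert captured + decayed + pending == pytest.approx(generated, rel=1e-3)

    def test_qss_matches_full_when_relaxation_fast(self, kinetic):
        # Radical relaxation time < 1% of duration -> within 2% end depletion.
        env = OxygenEnvironment(initial_pO2=3.8)
        for rate in (1.0, 10.0, 100.0):
            exposure = Exposure(20.0, rate)
            relax = 1.0 / (kinetic.k_decay)  # worst case (anoxia)
            assert relax < 0.01 * exposure.duration
            full = simulate_depletion(env, exposure, kinetic)
            qss = simulate_depletion(env, exposure, kinetic, method="qss")
            d_full = env.initial_pO2 - full.end_pO2
            d_qss = env.initial_pO2 - qss.end_pO2
            assert d_qss == pytest.approx(d_full, rel=0.02, abs=1e-9)

    def test_invalid_solver_options(self, kinetic):
        env = OxygenEnvironment(initial_pO2=3.8)
        with pytest.raises(DomainError):
            simulate_depletion(env, Exposure(1.0, 1.0), kinetic, rtol=-1.0)
        with pytest.raises(DomainError):
            simulate_depletion(env, Exposure(1.0, 1.0), kinetic, method="magic")

    def test_trace_csv_columns(self, kinetic, tmp_path):
        env = OxygenEnvironment(initial_pO2=3.8)
        trace = simulate_depletion(env, Exposure(5.0, 100.0), kinetic)
        path = tmp_path / "trace.csv"
        trace.write_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time_s,pO2_mmHg,radical_mol_m3"


class TestEulerOracle:
    @pytest.mark.parametrize(
        "oxygen_percent,dose,rate",
        [
            (0.25, 5.0, 500.0),
            (0.25, 10.0, 1000.0),
            (0.25, 20.0, 2000.0),
            (0.5, 5.0, 1000.0),
            (0.5, 10.0, 2000.0),
            (0.5, 20.0, 500.0),
            (1.0, 5.0, 2000.0),
            (1.0, 10.0, 500.0),
            (1.0, 20.0, 1000.0),
            (0.5, 40.0, 2000.0),
        ],
    )
    def test_adaptive_matches_euler(self, kinetic, oxygen_percent, dose, rate):
        p0 = percent_to_mmhg(oxygen_percent)
        trace = simulate_depletion(
            OxygenEnvironment(initial_pO2=p0), Exposure(dose, rate), kinetic
        )
        end_euler, _ = euler_end_state(p0, dose, rate, kinetic)
        depletion = p0 - trace.end_pO2
        depletion_euler = p0 - end_euler
        assert depletion == pytest.approx(depletion_euler, rel=5e-3, abs=1e-6)


@settings(max_examples=25, deadline=None)
@given(
    dose=st.floats(min_value=1.0, max_value=40.0),
    rate=st.floats(min_value=1.0, max_value=2000.0),
    p0=st.floats(min_value=0.5, max_value=160.0),
)
def test_end_pO2_never_negative_or_above_ambient(dose, rate, p0):
    kinetic = KineticParams()
    trace = simulate_depletion(
        OxygenEnvironment(initial_pO2=p0), Exposure(dose, rate), kinetic
    )
    assert 0.0 <= trace.end_pO2 <= p0 + 1e-9
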