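"""Turnover ODE core: right-hand side, integration, steady states, units."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ttrkin import (DomainError, TTRParameters, TTRState, TTRTrajectory,
                    mass_to_molar, mean_separation, molar_to_mass,
                    simulate_ttr, steady_state_numeric, ttr_rhs)

from conftest import KA, KD, KREM_T, TST


class TestRhs:
    def test_empty_system_produces_only_synthesis(self):
        p = TTRParameters(r=0.37, kd=0.01, ka=1e5, krem_T=0.02, krem_M=5.0)
        assert ttr_rhs(TTRState(0.0, 0.0), p) == (0.37, 0.0)

    def test_direct_substitution_at_reference_state(self):
        # frozen oracle: hand substitution of T=6.44, M=0.014393, r=0.1,
        # krem_M=0 into the two balance equations
        p = TTRParameters(r=0.1, kd=KD, ka=KA, krem_T=KREM_T, krem_M=0.0)
        dT, dM = ttr_rhs(TTRState(6.44, 0.014393), p)
        assert dT == pytest.approx(-3.046735722849178e-3, rel=1e-12)
        assert dM == pytest.approx(2.6942891396743163e-5, rel=1e-12)

    @given(T=st.floats(0, 50), M=st.floats(0, 1),
           kd=st.floats(0, 1), ka=st.floats(0, 1e6))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_monomer_equivalent_conservation_structure(self, T, M, kd, ka):
        # with no synthesis/removal, 4·dT + dM = 0 identically
        p = TTRParameters(r=0.0, kd=kd, ka=ka, krem_T=0.0, krem_M=0.0)
        dT, dM = ttr_rhs(TTRState(T, M), p)
        assert 4.0 * dT + dM == pytest.approx(0.0, abs=1e-9 * max(1.0, 4 * abs(dT)))

    def test_negative_state_rejected(self):
        with pytest.raises(DomainError):
            TTRState(-1.0, 0.0)
        with pytest.raises(DomainError):
            TTRParameters(r=-0.1, kd=KD, ka=KA, krem_T=KREM_T, krem_M=0.0)


class TestSimulate:
    def test_pure_exponential_decay(self):
        p = TTRParameters(r=0.0, kd=0.0, ka=0.0, krem_T=0.05, krem_M=0.0)
        t = np.linspace(0.0, 200.0, 41)
        traj = simulate_ttr(p, TTRState(3.0, 0.0), t)
        np.testing.assert_allclose(traj.T, 3.0 * np.exp(-0.05 * t), rtol=1e-7)

    def test_converges_to_reference_steady_state(self, reference_params):
        traj = simulate_ttr(reference_params, TTRState(0.0, 0.0),
                            np.linspace(0.0, 2000.0, 81))
        assert traj.T[-1] == pytest.approx(TST, rel=1e-3)

    def test_closed_system_conserves_monomer_equivalents(self):
        p = TTRParameters(r=0.0, kd=KD, ka=KA, krem_T=0.0, krem_M=0.0)
        traj = simulate_ttr(p, TTRState(5.0, 0.5), np.linspace(0.0, 1e4, 101))
        total = 4.0 * traj.T + traj.M
        assert np.max(np.abs(total / total[0] - 1.0)) < 1e-8

    def test_nonnegative_from_nonnegative_start(self, reference_params):
        traj = simulate_ttr(reference_params, TTRState(20.0, 0.5),
                            np.linspace(0.0, 5000.0, 51))
        assert np.all(traj.T >= 0.0) and np.all(traj.M >= 0.0)

    def test_bad_time_grid_rejected(self, reference_params):
        with pytest.raises(ValueError):
            simulate_ttr(reference_params, TTRState(0, 0), [1.0, 2.0])
        with pytest.raises(ValueError):
            simulate_ttr(reference_params, TTRState(0, 0), [0.0, 2.0, 2.0])


class TestSteadyState:
    def test_reassociation_closed_form_oracle(self, reference_params):
        ss = steady_state_numeric(reference_params)
        assert ss.T == pytest.approx(TST, rel=1e-12)
        assert ss.M == pytest.approx((KD * TST / KA) ** 0.25, rel=1e-10)

    def test_no_dissociation_means_no_monomers(self):
        p = TTRParameters(r=0.2, kd=0.0, ka=KA, krem_T=0.01, krem_M=1.0)
        ss = steady_state_numeric(p)
        assert ss.M == 0.0
        assert ss.T == pytest.approx(20.0, rel=1e-14)

    def test_residual_is_tiny(self, degradation_params):
        ss = steady_state_numeric(degradation_params)
        dT, dM = ttr_rhs(ss, degradation_params)
        assert abs(dT) < 1e-10 * degradation_params.r
        assert abs(dM) < 1e-10 * degradation_params.r

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_long_time_ode_limit(self, seed):
        r = np.random.default_rng(seed + 11)
        p = TTRParameters(r=float(10 ** r.uniform(-1.5, 0)),
                          kd=float(10 ** r.uniform(-3.5, -1.5)),
                          ka=float(10 ** r.uniform(3, 6)),
                          krem_T=float(10 ** r.uniform(-2, -1)),
                          krem_M=float([0.0, 10 ** r.uniform(-2, 2)][seed % 2]))
        ss = steady_state_numeric(p)
        horizon = 60.0 / p.krem_T
        traj = simulate_ttr(p, TTRState(0.0, 0.0),
                            np.linspace(0.0, horizon, 31))
        assert traj.T[-1] == pytest.approx(ss.T, rel=1e-6)
        assert traj.M[-1] == pytest.approx(ss.M, rel=1e-6)


class TestUnits:
    @pytest.mark.parametrize("mass, mw, uM", [
        (0.055, 55000.0, 1.0),
        (3.0811e-4, 308.11, 1.0),
        (0.3542, 55000.0, 6.44),
    ])
    def test_mass_to_molar(self, mass, mw, uM):
        assert mass_to_molar(mass, mw) == pytest.approx(uM, rel=1e-3)

    @given(c=st.floats(1e-6, 1e3), mw=st.floats(1.0, 1e6))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_conversion_round_trip(self, c, mw):
        assert molar_to_mass(mass_to_molar(c, mw), mw) == pytest.approx(c, rel=1e-14)

    def test_mean_separation_values(self):
        assert mean_separation(1.0) == pytest.approx(1.18)
        # inverse of the relation at 15 nm
        assert mean_separation(1.18 ** 3 / 15.0 ** 3) == pytest.approx(15.0, rel=1e-12)

    @given(c1=st.floats(1e-9, 1.0), c2=st.floats(1e-9, 1.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_mean_separation_monotone_decreasing(self, c1, c2):
        lo, hi = sorted([c1, c2])
        if lo < hi:
            assert mean_separation(lo) > mean_separation(hi)

    def test_domain_errors(self):
        for bad in (0.0, -1.0):
            with pytest.raises(DomainError):
                mass_to_molar(bad, 55000.0)
            with pytest.raises(DomainError):
                mean_separation(bad)


class TestIO:
    def test_parameter_file_round_trip(self, tmp_path, degradation_params):
        f = tmp_path / "params.yaml"
        degradation_params.to_file(f)
        assert TTRParameters.from_file(f) == degradation_params
        j = tmp_path / "params.json"
        degradation_params.to_file(j)
        assert TTRParameters.from_file(j) == degradation_params

    def test_trajectory_csv_round_trip(self, tmp_path, reference_params):
        traj = simulate_ttr(reference_params, TTRState(0.0, 0.0),
                            np.linspace(0.0, 100.0, 11))
        f = tmp_path / "traj.csv"
        traj.to_csv(f)
        assert f.read_text().splitlines()[0] == "time_h,T_uM,M_uM"
        back = TTRTrajectory.from_csv(f)
        np.testing.assert_allclose(back.T, traj.T)
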