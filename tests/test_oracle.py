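"""Steady-state gas-exchange simulator: component and whole-model physics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from gastwin.cohort import OUTPUT_COLUMNS, generate_cohort
from gastwin.oracle import (
    DEFAULT_CONSTANTS,
    OracleConstants,
    PhysiologicRangeError,
    alveolar_ventilation,
    blood_co2_content,
    blood_o2_content,
    co2_pressure_from_content,
    compartment_weights,
    effective_shunt,
    o2_pressure_from_content,
    saturation,
    simulate,
    simulate_batch,
    solve_acid_base,
    solve_compartment,
)


class TestSaturation:
    def test_reference_point(self):
        assert saturation(100.0) == pytest.approx(0.9775, abs=5e-4)

    def test_half_saturation_pressure(self):
        # independent root-finding oracle: p^3 + 150 p = 23400 at S = 0.5
        p50 = brentq(lambda p: p ** 3 + 150 * p - 23400, 1, 100)
        assert saturation(p50) == pytest.approx(0.5, abs=1e-3)
        assert p50 == pytest.approx(26.9, abs=0.1)

    def test_limits_and_monotonicity(self):
        p = np.linspace(0.5, 600, 500)
        s = saturation(p)
        assert np.all(np.diff(s) > 0)
        assert saturation(1e-3) < 1e-4
        assert saturation(5000.0) > 0.999

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(PhysiologicRangeError):
            saturation(0.0)


class TestBloodContents:
    def test_o2_content_reference(self):
        # Hb 9.31 mmol/L = 15.0 g/dL: 1.34*15*0.9775 + 0.003*100 = 19.95
        assert blood_o2_content(100.0, 9.31) == pytest.approx(19.95, abs=0.05)

    def test_anaemic_limit_dissolved_only(self):
        assert blood_o2_content(80.0, 0.0) == pytest.approx(0.003 * 80.0)

    def test_o2_content_invertible(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(5, 600, 50)
        Hb = rng.uniform(6, 12, 50)
        C = blood_o2_content(P, Hb)
        back = o2_pressure_from_content(C, Hb)
        np.testing.assert_allclose(back, P, rtol=1e-6, atol=1e-4)

    @pytest.mark.parametrize("P,expected", [(40.0, 48.0), (50.0, 55.0)])
    def test_co2_content_linear_curve(self, P, expected):
        assert blood_co2_content(P) == pytest.approx(expected)

    def test_co2_inverse_identity(self):
        assert co2_pressure_from_content(48.0) == pytest.approx(40.0)
        P = np.linspace(10, 120, 23)
        np.testing.assert_allclose(
            co2_pressure_from_content(blood_co2_content(P)), P, rtol=1e-12)


class TestVentilationAndShunt:
    def test_alveolar_ventilation_reference(self, healthy_state):
        va = alveolar_ventilation(healthy_state)
        assert va == pytest.approx(4.2)
        # ideal-compartment PACO2 = 863 * (RQ*VO2) / VA
        assert 863 * 0.2 / va == pytest.approx(41.1, abs=0.1)

    def test_deadspace_floor(self, healthy_state):
        s = dict(healthy_state, Vt=220.0, VD_phys=0.30, RR=15.0)
        assert alveolar_ventilation(s) == pytest.approx(15 * 0.2 * 0.22)

    def test_source_mean_state_ventilation(self, healthy_state):
        s = dict(healthy_state, RR=20.83, Vt=463.80, VD_phys=0.15)
        assert alveolar_ventilation(s) == pytest.approx(6.54, abs=0.01)

    @pytest.mark.parametrize("asht,v_nc,peep,expected", [
        (0.0, 0, 0.0, 0.0),
        (0.05, 10, 0.0, 0.15),
        (0.05, 10, 20.0, 0.05),
    ])
    def test_effective_shunt_rule(self, healthy_state, asht, v_nc, peep,
                                  expected):
        s = dict(healthy_state, asht=asht, v_nc=v_nc, PEEP=peep)
        assert effective_shunt(s) == pytest.approx(expected)

    def test_shunt_bounded(self, healthy_state):
        s = dict(healthy_state, asht=0.9, v_nc=90, PEEP=0.0)
        assert effective_shunt(s) == 0.95


class TestCompartmentWeights:
    def test_constant_resistance_gives_uniform_weights(self, healthy_state):
        s = dict(healthy_state, v_sR=0.0, v_inR=1.3, v_nc=20)
        v, q = compartment_weights(s, N=100)
        assert len(v) == 80
        np.testing.assert_allclose(v, 1 / 80, rtol=1e-12)

    def test_hand_normalised_two_compartments(self, healthy_state):
        s = dict(healthy_state, v_inR=1.0, v_sR=1.0, v_inVR=1.0, v_sVR=1.0,
                 v_nc=0)
        v, q = compartment_weights(s, N=2)
        np.testing.assert_allclose(v, [0.571428571, 0.428571429], rtol=1e-8)

    def test_weights_normalised_for_random_states(self):
        t = generate_cohort(200, seed=19)
        for _, row in t.iterrows():
            v, q = compartment_weights(row)
            assert v.sum() == pytest.approx(1.0, abs=1e-12)
            assert q.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(v > 0) and np.all(q > 0)

    def test_degenerate_lung_rejected(self, healthy_state):
        with pytest.raises(PhysiologicRangeError, match="degenerate"):
            compartment_weights(dict(healthy_state, v_nc=100), N=100)


class TestSolveCompartment:
    def test_high_vq_approaches_inspired_gas(self):
        PAO2, PACO2, _, _ = solve_compartment(
            100.0, (15.0, 52.0), FiO2=21.0, RQ=0.8, Hb=9.0)
        assert PACO2 < 4.0
        assert PAO2 == pytest.approx(0.21 * 713 - PACO2 / 0.8, abs=0.1)

    def test_mass_balance_residual(self):
        rng = np.random.default_rng(1)
        vaq = 10 ** rng.uniform(-2, 1.5, 1000)
        CvCO2 = rng.uniform(45, 60, 1000)
        _, PACO2, _, _ = solve_compartment(vaq, (15.0, CvCO2), 40.0, 0.8, 9.0)
        residual = vaq - 8.63 * (CvCO2 - blood_co2_content(PACO2)) / PACO2
        assert np.max(np.abs(residual / vaq)) < 1e-6

    def test_alveolar_o2_below_inspired(self):
        PAO2, _, _, _ = solve_compartment(1.0, (15.0, 52.0), 40.0, 0.8, 9.0)
        assert 0 < PAO2 < 0.40 * 713


class TestAcidBase:
    def test_normal_reference_point(self):
        # independent bisection oracle on the two constituent relations
        def be(ph, paco2=40.0):
            hco3 = 0.03 * paco2 * 10 ** (ph - 6.1)
            return 0.9287 * (hco3 - 24.4 + 14.83 * (ph - 7.4))
        ph_oracle = brentq(lambda p: be(p), 6.5, 7.9, xtol=1e-10)
        ph, hco3 = solve_acid_base(40.0, 0.0)
        assert ph == pytest.approx(ph_oracle, abs=1e-6)
        assert ph == pytest.approx(7.407, abs=1e-3)
        assert hco3 == pytest.approx(24.3, abs=0.05)

    def test_henderson_hasselbalch_identity(self):
        rng = np.random.default_rng(2)
        paco2 = rng.uniform(20, 90, 200)
        be = rng.uniform(-12, 12, 200)
        ph, hco3 = solve_acid_base(paco2, be)
        np.testing.assert_allclose(
            ph, 6.1 + np.log10(hco3 / (0.03 * paco2)), atol=1e-6)

    def test_ph_decreases_with_rising_paco2(self):
        grid = np.linspace(20, 100, 33)
        ph, _ = solve_acid_base(grid, np.zeros_like(grid))
        assert np.all(np.diff(ph) < 0)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(PhysiologicRangeError):
            solve_acid_base(300.0, 0.0)
        with pytest.raises(PhysiologicRangeError):
            solve_acid_base(40.0, 40.0)


class TestSimulate:
    def test_healthy_reference_envelope(self, healthy_state):
        gas = simulate(healthy_state)
        assert 85 <= gas.PaO2 <= 105
        assert 35 <= gas.PaCO2 <= 45
        assert 7.35 <= gas.pH <= 7.45

    def test_zero_shunt_single_compartment_equals_alveolar(self, healthy_state):
        constants = OracleConstants(N_comp=1)
        s = dict(healthy_state, asht=0.0, v_nc=0)
        gas = simulate(s, constants)
        va = alveolar_ventilation(s)
        vaq = va / s["CO"]
        CvCO2 = blood_co2_content(gas.PaCO2) + 100 * s["RQ"] * s["VO2"] / s["CO"]
        PAO2, PACO2, _, _ = solve_compartment(vaq, (0.0, CvCO2), s["FiO2"],
                                              s["RQ"], s["Hb"])
        assert gas.PaO2 == pytest.approx(PAO2, abs=2 * constants.tol_P)
        assert gas.PaCO2 == pytest.approx(PACO2, abs=2 * constants.tol_P)

    def test_pao2_strictly_increases_with_fio2(self, healthy_state):
        pao2 = [simulate(dict(healthy_state, FiO2=f)).PaO2
                for f in np.linspace(21, 100, 9)]
        assert np.all(np.diff(pao2) > 0)

    def test_pao2_nonincreasing_in_shunt(self, healthy_state):
        rng = np.random.default_rng(5)
        for _ in range(20):
            base = dict(healthy_state, FiO2=rng.uniform(21, 60),
                        SvO2=rng.uniform(50, 80))
            pao2 = [simulate(dict(base, asht=a)).PaO2
                    for a in np.linspace(0.0, 0.4, 6)]
            assert np.all(np.diff(pao2) <= 1e-9)

    def test_paco2_falls_with_rising_ventilation(self, healthy_state):
        paco2 = [simulate(dict(healthy_state, RR=rr)).PaCO2
                 for rr in np.linspace(8, 30, 8)]
        assert np.all(np.diff(paco2) < 0)

    def test_aggregation_one_vs_many_uniform_compartments(self, healthy_state):
        s = dict(healthy_state, v_sR=0.0, v_sVR=0.0, v_nc=0)
        g1 = simulate(s, OracleConstants(N_comp=1))
        g100 = simulate(s, OracleConstants(N_comp=100))
        assert g1.PaO2 == pytest.approx(g100.PaO2, abs=2 * DEFAULT_CONSTANTS.tol_P)
        assert g1.PaCO2 == pytest.approx(g100.PaCO2, abs=2 * DEFAULT_CONSTANTS.tol_P)

    def test_simulate_is_deterministic(self, healthy_state):
        a = simulate(healthy_state)
        b = simulate(healthy_state)
        assert a == b

    def test_o2_and_co2_bookkeeping(self, healthy_state):
        gas, diag = simulate(healthy_state, full_output=True)
        # compartmental O2 uptake equals the arterial Fick computation exactly
        assert diag["o2_uptake_comp"] == pytest.approx(
            diag["o2_uptake_art"], rel=1e-9)
        # metabolic CO2 production is eliminated across compartments within 2%
        assert diag["co2_output"] == pytest.approx(
            diag["vco2_target"], rel=0.02)


class TestSimulateBatch:
    def test_labelled_schema(self, labelled_cohort):
        assert labelled_cohort.shape[1] == 23
        assert list(labelled_cohort.columns[-4:]) == list(OUTPUT_COLUMNS)
        assert not labelled_cohort.isna().any().any()

    def test_henderson_hasselbalch_on_every_row(self, labelled_cohort):
        hh = 6.1 + np.log10(labelled_cohort["HCO3"]
                            / (0.03 * labelled_cohort["PaCO2"]))
        np.testing.assert_allclose(hh, labelled_cohort["pH"], atol=1e-6)

    def test_outputs_within_physical_invariants(self, labelled_cohort):
        pio2 = labelled_cohort["FiO2"] / 100 * 713
        assert np.all(labelled_cohort["PaO2"] > 0)
        assert np.all(labelled_cohort["PaO2"] <= pio2 + 1e-6)
        assert np.all(labelled_cohort["PaCO2"] > 0)
        assert labelled_cohort["pH"].between(6.5, 7.9).all()

    def test_worker_count_does_not_change_results(self, small_cohort):
        a = simulate_batch(small_cohort, workers=1)
        b = simulate_batch(small_cohort, workers=4)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_empty_table_gives_empty_labelled_table(self, small_cohort):
        out = simulate_batch(small_cohort.iloc[:0])
        assert len(out) == 0
        assert out.shape[1] == 23

    def test_row_order_preserved(self, small_cohort, labelled_cohort):
        # the input columns of surviving rows appear in original order
        merged = small_cohort.merge(labelled_cohort, how="inner")
        np.testing.assert_array_equal(
            merged[small_cohort.columns].to_numpy(),
            labelled_cohort[small_cohort.columns].to_numpy())
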