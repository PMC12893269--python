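import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ictalmea import ephys as E
from ictalmea.errors import ConfigError, DomainError, EstimationError
from ictalmea.synthetic import PatchConfig, generate_patch_fixtures

from _reference import reference_ghk_anion, reference_two_ion_henderson


class TestBicarbonate:
    @pytest.mark.parametrize(
        "ph_i, ph_o, hco3_o, expected",
        [
            (7.2, 7.4, 26.0, 26.0 * 10 ** (-0.2)),  # ~16.41, the standard intracellular value
            (7.4, 7.4, 26.0, 26.0),
            (6.4, 7.4, 26.0, 2.6),
        ],
    )
    def test_known_values(self, ph_i, ph_o, hco3_o, expected):
        assert E.hh_bicarbonate(ph_i, ph_o, hco3_o) == pytest.approx(expected, rel=1e-12)

    def test_matches_printed_physiological_value(self):
        """The constant-pCO2 bicarbonate at pH_i 7.2 / pH_o 7.4 is ~16.4 mmol/L."""
        assert E.hh_bicarbonate(7.2, 7.4, 26.0) == pytest.approx(16.41, abs=0.01)

    @given(hco3=st.floats(1.0, 60.0), scale=st.floats(0.5, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_multiplicative_in_extracellular_bicarbonate(self, hco3, scale):
        a = E.hh_bicarbonate(7.2, 7.4, hco3)
        b = E.hh_bicarbonate(7.2, 7.4, hco3 * scale)
        assert b == pytest.approx(a * scale, rel=1e-9)

    def test_rejects_unphysical_ph(self):
        with pytest.raises(ConfigError):
            E.hh_bicarbonate(-1.0, 7.4, 26.0)


class TestGHK:
    def test_symmetric_concentrations_give_zero(self):
        c = E.IonConditions(cl_i_mM=100, cl_o_mM=100, hco3_i_mM=26, hco3_o_mM=26)
        assert E.ghk_reversal(c) == pytest.approx(0.0, abs=1e-12)

    def test_nernst_limit(self):
        c = E.IonConditions(cl_i_mM=13, cl_o_mM=130, perm_ratio=0.0, temperature_K=305.15)
        assert E.ghk_reversal(c) == pytest.approx(-60.5, abs=0.1)

    def test_agrees_with_independent_point_evaluation(self):
        c = E.IonConditions(cl_i_mM=19, cl_o_mM=133.5, hco3_i_mM=16.38, hco3_o_mM=26.0, perm_ratio=0.3)
        expected = reference_ghk_anion(19, 133.5, 16.38, 26.0, 0.3, 305.15)
        assert E.ghk_reversal(c) == pytest.approx(expected, abs=1e-9)

    @given(
        cl_i=st.floats(2.0, 60.0),
        cl_o=st.floats(100.0, 160.0),
        r=st.floats(0.0, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_intracellular_chloride(self, cl_i, cl_o, r):
        c1 = E.IonConditions(cl_i_mM=cl_i, cl_o_mM=cl_o, perm_ratio=r)
        c2 = E.IonConditions(cl_i_mM=cl_i * 1.1, cl_o_mM=cl_o, perm_ratio=r)
        assert E.ghk_reversal(c2) > E.ghk_reversal(c1)

    @given(cl_i=st.floats(2.0, 80.0), r=st.floats(0.0, 0.6))
    @settings(max_examples=50, deadline=None)
    def test_invert_forward_identity(self, cl_i, r):
        c = E.IonConditions(cl_i_mM=cl_i, cl_o_mM=133.5, perm_ratio=r)
        e = E.ghk_reversal(c)
        assert E.invert_ghk_cl(e, c) == pytest.approx(cl_i, abs=1e-9)

    def test_invert_pure_chloride_closed_form(self):
        c = E.IonConditions(cl_i_mM=10, cl_o_mM=130, perm_ratio=0.0)
        vt = E.thermal_voltage_mv(c.temperature_K)
        e = -40.0
        assert E.invert_ghk_cl(e, c) == pytest.approx(130 * math.exp(e / vt), rel=1e-12)

    def test_invert_domain_error_reports_bound(self):
        c = E.IonConditions(cl_i_mM=10, cl_o_mM=130, hco3_i_mM=16.41, hco3_o_mM=26, perm_ratio=0.3)
        with pytest.raises(DomainError, match="bounds"):
            E.invert_ghk_cl(-120.0, c)


class TestReversalFromIV:
    def test_two_point_line(self):
        iv = E.IVCurve(points=[(-70.0, -10.0), (-50.0, 10.0)])
        est = E.estimate_reversal_from_iv(iv, v_rest_mV=-70.0)
        assert est.e_gaba_mV == pytest.approx(-60.0)
        assert est.slope_nS == pytest.approx(1.0)
        assert est.df_mV == pytest.approx(10.0)

    def test_noiseless_line_recovers_exactly(self):
        v = np.array([-78.4, -68.4, -58.4, -48.4, -38.4])
        iv = E.IVCurve(points=[(float(vv), float(1.3 * (vv + 48.4))) for vv in v])
        est = E.estimate_reversal_from_iv(iv)
        assert est.e_gaba_mV == pytest.approx(-48.4, abs=1e-9)

    def test_unbiased_under_noise(self):
        """OLS zero-crossing bias stays below 1 mV at sigma = 2 pA, 5 voltages."""
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(1000):
            fx = generate_patch_fixtures(
                PatchConfig(e_true_mV=-55.0, iv_noise_sd_pA=2.0), seed=int(rng.integers(2**31))
            )
            errs.append(E.estimate_reversal_from_iv(fx["iv"]).e_gaba_mV - (-55.0))
        assert abs(np.mean(errs)) < 1.0

    def test_flat_curve_is_estimation_error(self):
        iv = E.IVCurve(points=[(-70.0, 5.0), (-50.0, 5.0)])
        with pytest.raises(EstimationError):
            E.estimate_reversal_from_iv(iv)

    def test_negative_slope_is_flagged(self):
        iv = E.IVCurve(points=[(-70.0, 10.0), (-50.0, -10.0)])
        assert E.estimate_reversal_from_iv(iv).flagged_negative_slope


class TestLJP:
    def test_identical_solutions_zero(self):
        s = E.SolutionComposition(species=[("K", 1, 150), ("Cl", -1, 150)])
        assert E.ljp_henderson(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_two_salt_dilution_matches_closed_form(self):
        s1 = E.SolutionComposition(species=[("K", 1, 150), ("Cl", -1, 150)])
        s2 = E.SolutionComposition(species=[("K", 1, 15), ("Cl", -1, 15)])
        got = E.ljp_henderson(s1, s2)
        want = reference_two_ion_henderson(
            E.RELATIVE_MOBILITIES["K"], E.RELATIVE_MOBILITIES["Cl"], 150, 15, 305.15
        )
        assert got == pytest.approx(want, abs=0.01)

    def test_antisymmetry(self):
        a = E.SolutionComposition(species=[("K", 1, 135), ("gluconate", -1, 125), ("Cl", -1, 10)])
        b = E.SolutionComposition(species=[("Na", 1, 150), ("Cl", -1, 150)])
        assert E.ljp_henderson(a, b) == pytest.approx(-E.ljp_henderson(b, a), abs=1e-12)

    def test_gluconate_pipette_has_positive_double_digit_ljp(self):
        """Low-mobility anion in the pipette -> +10..+17 mV correction, the
        familiar whole-cell magnitude."""
        pip = E.SolutionComposition(
            species=[("K", 1, 135), ("gluconate", -1, 130), ("Cl", -1, 5), ("Na", 1, 4), ("Mg", 2, 2)]
        )
        bath = E.SolutionComposition(
            species=[("Na", 1, 151), ("K", 1, 2.5), ("Cl", -1, 133.5), ("HCO3", -1, 26), ("Ca", 2, 2), ("Mg", 2, 1.3)]
        )
        assert 10.0 < E.ljp_henderson(pip, bath) < 17.0

    def test_unknown_species_named_in_error(self):
        s1 = E.SolutionComposition(species=[("K", 1, 150), ("unobtainium", -1, 150)])
        s2 = E.SolutionComposition(species=[("K", 1, 15), ("Cl", -1, 15)])
        with pytest.raises(KeyError, match="unobtainium"):
            E.ljp_henderson(s1, s2)


class TestRCTransient:
    def test_ideal_rc_recovered_within_one_percent(self):
        fx = generate_patch_fixtures(PatchConfig(rs_MOhm=10.0, cap_pF=150.0, step_mV=-10.0), seed=0)
        cap, rs = E.rc_from_transient(fx["transient_pA"], 10_000.0, -10.0)
        assert cap == pytest.approx(150.0, rel=0.01)
        assert rs == pytest.approx(10.0, rel=0.01)
        assert fx["transient_pA"][0] == pytest.approx(-1000.0)  # -1 nA peak

    def test_capacitance_scaling_property(self):
        f1 = generate_patch_fixtures(PatchConfig(cap_pF=100.0), seed=0)
        f2 = generate_patch_fixtures(PatchConfig(cap_pF=200.0), seed=0)
        c1, r1 = E.rc_from_transient(f1["transient_pA"], 10_000.0, -10.0)
        c2, r2 = E.rc_from_transient(f2["transient_pA"], 10_000.0, -10.0)
        assert c2 == pytest.approx(2 * c1, rel=0.01)
        assert r2 == pytest.approx(r1, rel=0.01)

    def test_zero_trace_errors(self):
        with pytest.raises(EstimationError):
            E.rc_from_transient(np.zeros(100), 10_000.0, -10.0)


class TestSeriesResistanceQC:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([10.0, 11.0], True),  # 10% change
            ([10.0, 12.5], False),  # 25% change
            ([10.0, 8.0], True),  # exactly 20%: "exceeded" is strict
            ([10.0, 10.5, 12.1], False),
        ],
    )
    def test_threshold(self, series, expected):
        assert E.qc_series_resistance(series) is expected

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            E.qc_series_resistance([10.0])
        with pytest.raises(ConfigError):
            E.qc_series_resistance([0.0, 10.0])


class TestTonicHistogram:
    def test_identical_traces_zero(self):
        rng = np.random.default_rng(0)
        tr = -200 + 5 * rng.standard_normal(120_000)
        res = E.tonic_from_histogram(tr, tr, 10_000.0)
        assert res.tonic_pA == pytest.approx(0.0, abs=1e-9)

    def test_clean_gaussian_shift(self):
        rng = np.random.default_rng(1)
        before = -200 + 5 * rng.standard_normal(120_000)
        during = -170 + 5 * rng.standard_normal(120_000)
        res = E.tonic_from_histogram(before, during, 10_000.0, capacity_pF=150.0)
        assert res.tonic_pA == pytest.approx(30.0, abs=1.0)
        assert res.density_pA_per_pF == pytest.approx(res.tonic_pA / 150.0)

    def test_mode_robust_to_synaptic_event_tail(self):
        """Inward synaptic deflections skew the mean but not the histogram peak."""
        fx = generate_patch_fixtures(
            PatchConfig(tonic_shift_pA=30.0, synaptic_rate_hz=8.0), seed=2
        )
        res = E.tonic_from_histogram(fx["holding_before_pA"], fx["holding_during_pA"], 10_000.0)
        assert res.tonic_pA == pytest.approx(30.0, abs=2.0)
        mean_shift = fx["holding_during_pA"].mean() - fx["holding_before_pA"].mean()
        assert abs(res.tonic_pA - 30.0) < abs(mean_shift - 30.0) + 1.0

    def test_equivariant_under_constant_offset(self):
        rng = np.random.default_rng(3)
        before = -150 + 4 * rng.standard_normal(110_000)
        during = before.copy()
        r0 = E.tonic_from_histogram(before, during, 10_000.0)
        r1 = E.tonic_from_histogram(before, during + 17.0, 10_000.0)
        assert r1.tonic_pA - r0.tonic_pA == pytest.approx(17.0, abs=0.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ConfigError):
            E.tonic_from_histogram(np.zeros(1000), np.zeros(1000), 10_000.0)

    def test_bimodal_histogram_warns(self):
        rng = np.random.default_rng(4)
        half = 60_000
        before = np.concatenate([-200 + 2 * rng.standard_normal(half), -150 + 2 * rng.standard_normal(half)])
        during = -150 + 2 * rng.standard_normal(2 * half)
        with pytest.warns(UserWarning, match="competing modes"):
            res = E.tonic_from_histogram(before, during, 10_000.0)
        assert res.ambiguous_before
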