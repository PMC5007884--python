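"""Nested ANOVA precision, pooling, bias, budget, linearity, LOD/LOQ."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dropval.validation import (
    CertifiedLevel,
    assay_variability,
    bias_assessment,
    combined_uncertainty,
    linearity_fit,
    lod_experimental,
    loq_assess,
    one_way_anova,
    pool_rms,
    precision_from_runs,
    robustness_compare,
    threshold_variability,
)
from dropval.records import WellResult


def _brute_force_anova(groups):
    """Independent oracle: explicit sums of squares, no shared code."""
    flat = [x for g in groups for x in g]
    grand = sum(flat) / len(flat)
    ssw = ssb = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ssw += sum((x - m) ** 2 for x in g)
        ssb += len(g) * (m - grand) ** 2
    return ssw / (len(flat) - len(groups)), ssb / (len(groups) - 1)


class TestAnova:
    def test_hand_computed_example(self):
        a = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert a.ms_within == pytest.approx(1.0)
        assert a.ms_between == pytest.approx(1.5)
        assert a.n_bar == 3 and a.grand_mean == 2.5

    def test_identical_groups_no_between_variance(self):
        a = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert a.ms_between == pytest.approx(0.0)

    def test_matches_brute_force_oracle_unbalanced(self, rng):
        for _ in range(100):
            k = rng.integers(2, 6)
            groups = [
                rng.normal(10, 2, size=rng.integers(2, 9)).tolist()
                for _ in range(k)
            ]
            a = one_way_anova(groups)
            msw, msb = _brute_force_anova(groups)
            assert a.ms_within == pytest.approx(msw, rel=1e-10)
            assert a.ms_between == pytest.approx(msb, rel=1e-10)

    def test_f_ratio_matches_scipy(self, rng):
        groups = [rng.normal(5, 1, size=7) for _ in range(4)]
        a = one_way_anova(groups)
        f = stats.f_oneway(*groups)
        assert a.ms_between / a.ms_within == pytest.approx(f.statistic, rel=1e-10)

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1], [2], [3]])


class TestPrecision:
    def test_hand_computed_example(self):
        pe = precision_from_runs([[1, 2, 3], [2, 3, 4]])
        assert pe.s_repeat_rel == pytest.approx(0.40)
        assert pe.s_run_rel == pytest.approx(0.16329932)
        assert pe.u_precision_rel == pytest.approx(0.20)

    def test_run_component_clamped_to_zero(self):
        # groups whose between-run scatter is below the within-run scatter
        pe = precision_from_runs([[1.0, 5.0, 3.0], [2.9, 3.1, 3.0]])
        assert pe.run_sd_clamped and pe.s_run_rel == 0.0

    def test_published_unbalanced_design_magnitude(self):
        """s_repeat 7.7 %, s_run 0 over 3 runs of ~13.3 gives u_precision 1.2 %."""
        # synthetic groups engineered to the published summary statistics
        n_bar = 40 / 3
        u = math.sqrt(0.077**2 / (n_bar * 3))
        assert u == pytest.approx(0.012, abs=5e-4)


class TestPoolRms:
    def test_published_repeatability_column(self):
        assert pool_rms([4.7, 5.6, 4.8, 7.7, 7.3]) == pytest.approx(6.1, abs=0.05)

    def test_published_run_column_with_clamped_zero(self):
        assert pool_rms([1.4, 5.3, 2.7, 0, 2.0]) == pytest.approx(2.9, abs=0.05)

    def test_singleton_identity(self):
        assert pool_rms([3.3]) == pytest.approx(3.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_rms([])

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=10))
    def test_rms_dominates_mean(self, values):
        assert pool_rms(values) >= np.mean(values) - 1e-9


class TestBias:
    CERT = [
        CertifiedLevel("a", 1.08e6, 0.13e6),
        CertifiedLevel("b", 1.08e5, 0.11e5),
        CertifiedLevel("c", 1.03e4, 0.10e4),
        CertifiedLevel("d", 1.02e3, 0.09e3),
        CertifiedLevel("e", 1.04e2, 0.10e2),
    ]
    MEASURED = {"a": 0.97e6, "b": 0.93e5, "c": 0.94e4, "d": 0.93e3, "e": 0.97e2}

    def test_per_level_and_mean_bias(self):
        be = bias_assessment(self.MEASURED, self.CERT, 0.019)
        assert 100 * be.bias_rel["a"] == pytest.approx(-10.2, abs=0.05)
        assert 100 * be.mean_bias_rel == pytest.approx(-9.7, abs=0.1)

    def test_bias_uncertainty_from_certificates(self):
        be = bias_assessment(self.MEASURED, self.CERT, 0.019)
        assert 100 * be.u_bias_rel == pytest.approx(5.4, abs=0.1)
        assert not be.significant  # |−9.7| < 2·5.4

    def test_zero_bias_never_significant(self):
        measured = {c.level_id: c.c_cert for c in self.CERT}
        be = bias_assessment(measured, self.CERT, 0.019)
        assert be.mean_bias_rel == 0.0 and not be.significant

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            bias_assessment({"zz": 1.0}, self.CERT, 0.01)


class TestAssayAndThreshold:
    def test_assay_component_hand_example(self):
        s = assay_variability([[10, 11, 12], [13, 14, 15]])
        assert s == pytest.approx(0.16329932, rel=1e-6)

    def test_identical_assays_zero(self):
        assert assay_variability([[5, 6], [5, 6]]) == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            assay_variability([[1, 2]])

    def test_threshold_component_hand_example(self):
        s = threshold_variability([[100, 102, 98, 100]])
        assert s == pytest.approx(math.sqrt(8 / 3) / 100, rel=1e-9)

    def test_identical_variants_zero(self):
        assert threshold_variability([[7, 7, 7], [9, 9, 9]]) == 0.0

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError):
            threshold_variability([[100]])


class TestCombinedUncertainty:
    def test_working_range_budget(self):
        U = combined_uncertainty(0.061, 0.029, 0.018, 0.054, n_meas=4, n_run=1)
        assert 100 * U == pytest.approx(14.2, abs=0.1)

    def test_quantification_limit_budget(self):
        u_bias = math.sqrt(0.050**2 + 0.075**2)
        assert 100 * 2 * u_bias == pytest.approx(18.0, abs=0.1)
        U = combined_uncertainty(
            0.170, 0.0, 0.018, u_bias, n_meas=4, n_run=1, s_thres_rel=0.072
        )
        assert 100 * U == pytest.approx(28.9, abs=0.1)

    def test_all_zero_components(self):
        assert combined_uncertainty(0, 0, 0, 0, n_meas=4) == 0.0

    def test_run_term_readings_agree_for_single_run(self):
        a = combined_uncertainty(0.1, 0.05, 0.01, 0.02, n_meas=3, n_run=1)
        b = combined_uncertainty(
            0.1, 0.05, 0.01, 0.02, n_meas=3, n_run=1, run_term="ratio"
        )
        assert a == b

    @given(
        s=st.floats(min_value=0, max_value=0.5),
        n=st.integers(min_value=1, max_value=50),
    )
    def test_monotone_in_components_and_replicates(self, s, n):
        base = combined_uncertainty(0.05, 0.02, 0.018, 0.05, n_meas=n)
        assert combined_uncertainty(0.05 + s, 0.02, 0.018, 0.05, n_meas=n) >= base
        assert combined_uncertainty(0.05, 0.02, 0.018, 0.05 + s, n_meas=n) >= base
        assert combined_uncertainty(0.05, 0.02, 0.018, 0.05, n_meas=n + 1) <= base


class TestLinearity:
    def test_exact_line(self):
        slope, r2 = linearity_fit([1, 2, 3], [2, 4, 6])
        assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_single_point(self):
        slope, r2 = linearity_fit([10], [8.7])
        assert slope == pytest.approx(0.87) and r2 == pytest.approx(1.0)

    def test_noisy_five_decade_series(self, rng):
        x = np.array([2.5, 26, 255, 2575, 5400, 25500])
        y = 0.87 * x * rng.normal(1, 0.01, size=x.size)
        slope, r2 = linearity_fit(x, y)
        assert slope == pytest.approx(0.87, abs=0.02)
        assert r2 > 0.995


def _result(P, A=15_000, c=None, well="w"):
    r = WellResult(well_id=well, P=P, A=A)
    r.c_pcr = c
    return r


class TestLodLoq:
    def test_all_replicates_positive(self):
        results = [_result(3, c=0.5, well=f"w{i}") for i in range(60)]
        s = lod_experimental(results)
        assert s.all_positive and s.n_valid == 60

    def test_one_blank_replicate_breaks_detection_claim(self):
        results = [_result(3, c=0.5), _result(0, c=0.0)]
        assert not lod_experimental(results).all_positive

    def test_low_level_relative_sd_matches_poisson_regime(self, rng):
        """60 replicates at 0.56 cp/uL scatter with rel SD ~ 1/sqrt(T_A) ~ 35 %."""
        from dropval.quantify import concentration_from_counts
        from dropval.simulate import SimulationConfig, simulate_well

        cfg = SimulationConfig(0.56, droplet_count_mean=17_000,
                               droplet_count_sd=500, emit_amplitudes=False)
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            cs = []
            for _ in range(60):
                w = simulate_well(cfg, r)
                cs.append(concentration_from_counts(w.positives, w.accepted)[0])
            rel_sd = np.std(cs, ddof=1) / np.mean(cs)
            hits += 0.25 <= rel_sd <= 0.45
        assert hits >= 4

    def test_loq_chain_on_synthetic_groups(self):
        cert = CertifiedLevel("f", 10.0, 1.5)
        runs = [[3.3, 3.5, 3.2, 3.4], [3.4, 3.2, 3.5, 3.3]]
        la = loq_assess(runs, cert, s_thres_rel=0.072, n_meas=4)
        assert la.meets_loq  # tight groups: U well below 30 %
        assert la.U_meas_rel >= 2 * math.hypot(0.018, la.u_bias_rel)

    def test_noisy_level_fails_acceptance(self):
        cert = CertifiedLevel("f", 10.0, 1.5)
        # engineered ~40 % repeatability
        runs = [[1.0, 2.0, 4.0, 3.0], [2.0, 4.0, 1.0, 3.0]]
        la = loq_assess(runs, cert, s_thres_rel=0.0, n_meas=4)
        assert not la.meets_loq


class TestRobustness:
    def test_published_primer_probe_block(self):
        rows = robustness_compare(
            {"optimal": [279] * 3, "plus": [273] * 3, "minus": [285] * 3},
            "optimal",
            0.142,
        )
        assert not any(r.significant for r in rows)

    def test_identical_groups_zero_delta(self):
        rows = robustness_compare({"a": [5, 5], "b": [5, 5]}, "a", 0.1)
        assert all(r.delta_vs_reference == 0 for r in rows)

    def test_large_shift_flagged(self):
        rows = robustness_compare(
            {"ref": [100.0] * 4, "shifted": [130.0] * 4}, "ref", 0.142
        )
        flagged = {r.condition: r.significant for r in rows}
        assert flagged["shifted"] and not flagged["ref"]
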