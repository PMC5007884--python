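"""Cluster estimation, thresholds, classification, rain and well QC."""
import numpy as np
import pytest

from dropval.partitions import (
    ClusterStats,
    classify,
    estimate_clusters,
    make_thresholds,
    qc_well,
    selectivity_metrics,
)
from dropval.records import DropletWell
from dropval.simulate import SimulationConfig, simulate_well


def _well(amplitudes, **kw):
    a = np.asarray(amplitudes, dtype=float)
    return DropletWell(well_id=kw.pop("well_id", "T01"), accepted=a.size,
                       amplitudes=a, **kw)


class TestEstimateClusters:
    def test_exact_small_case(self):
        cs = estimate_clusters([1000, 1000, 6000, 6000])
        assert cs.neg_mean == 1000 and cs.pos_mean == 6000
        assert make_thresholds(cs).midpoint == 3500

    def test_identical_amplitudes_give_one_cluster(self):
        cs = estimate_clusters([2000.0] * 10)
        assert cs.single_cluster
        with pytest.raises(ValueError):
            make_thresholds(cs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_clusters([])

    def test_recovers_generating_means(self, rng, cluster_params):
        n = 10_000
        neg = rng.normal(*cluster_params["neg"], size=int(n * 0.8))
        pos = rng.normal(*cluster_params["pos"], size=int(n * 0.2))
        cs = estimate_clusters(np.concatenate([neg, pos]))
        assert cs.neg_mean == pytest.approx(cluster_params["neg"][0], rel=0.01)
        assert cs.pos_mean == pytest.approx(cluster_params["pos"][0], rel=0.01)

    def test_simulator_output_recovery(self, rng):
        well = simulate_well(SimulationConfig(250.0), rng)
        cs = estimate_clusters(well.amplitudes)
        se_neg = 135 / np.sqrt(cs.n_neg)
        se_pos = 212 / np.sqrt(cs.n_pos)
        assert abs(cs.neg_mean - 1764) < 3 * se_neg
        assert abs(cs.pos_mean - 5418) < 3 * se_pos


class TestMakeThresholds:
    def test_observed_cluster_stats(self):
        ts = make_thresholds(ClusterStats(1764, 135, 5418, 212, 100, 100))
        assert ts.midpoint == pytest.approx(3591)
        assert ts.low == pytest.approx(2304)
        assert ts.high == pytest.approx(4570)

    def test_symmetric_unit_clusters(self):
        ts = make_thresholds(ClusterStats(0, 1, 10, 1, 5, 5))
        assert (ts.midpoint, ts.low, ts.high) == (5, 4, 6)

    def test_zero_width_clusters(self):
        ts = make_thresholds(ClusterStats(1000, 0, 6000, 0, 5, 5))
        assert ts.low == 1000 and ts.high == 6000


class TestClassify:
    def test_simple_counts(self):
        res = classify(_well([1, 2, 10]), threshold=5)
        assert (res.P, res.A) == (1, 3)

    def test_tie_counts_positive(self):
        res = classify(_well([5, 5, 1]), threshold=5)
        assert res.P == 2

    def test_rain_free_well_threshold_invariant(self):
        well = _well([1000] * 50 + [6000] * 20)
        ts = make_thresholds(ClusterStats(1000, 10, 6000, 10, 50, 20))
        counts = {classify(well, t).P for t in (ts.low, ts.midpoint, ts.high)}
        assert counts == {20}

    def test_rain_removal_counts(self):
        well = _well([1764.0] * 100 + [3500.0] * 10 + [5418.0] * 50)
        bounds = make_thresholds(ClusterStats(1764, 135, 5418, 212, 100, 50))
        res = classify(well, bounds.midpoint, rain_removal=True, bounds=bounds)
        assert (res.P, res.A, res.rain) == (50, 150, 10)

    def test_rain_removal_requires_bounds(self):
        with pytest.raises(ValueError):
            classify(_well([1, 2]), 1.5, rain_removal=True)

    def test_monotonicity_and_variant_ordering(self, rng):
        """P never increases with the threshold; low/mid/high order holds."""
        for _ in range(20):
            amps = rng.uniform(0, 7000, size=rng.integers(10, 500))
            well = _well(amps)
            thresholds = np.sort(rng.uniform(0, 7000, size=8))
            ps = [classify(well, t).P for t in thresholds]
            assert np.all(np.diff(ps) <= 0)

    def test_rain_removal_never_inflates_accepted(self, rng):
        cfg = SimulationConfig(300.0, droplet_count_mean=3000,
                               droplet_count_sd=0, rain_fraction=0.01)
        well = simulate_well(cfg, rng)
        bounds = make_thresholds(ClusterStats(1764, 135, 5418, 212, 1, 1))
        plain = classify(well, bounds.midpoint, bounds=bounds)
        removed = classify(well, bounds.midpoint, rain_removal=True, bounds=bounds)
        assert removed.A <= plain.A
        p_low = classify(well, bounds.low, bounds=bounds).P
        p_high = classify(well, bounds.high, bounds=bounds).P
        assert p_low >= plain.P >= p_high


class TestQC:
    def test_min_droplet_rule_is_exact_on_count(self):
        w = DropletWell("A1", accepted=9_999, positives=10)
        rep = qc_well(w)
        assert "min_droplets" in rep.failed_rules
        w2 = DropletWell("A2", accepted=10_000, positives=10)
        assert qc_well(w2).passed

    def test_low_amplitude_tail_rule(self, rng):
        amps = np.concatenate([
            np.full(60, 500.0),                      # 6 % far below the cluster
            rng.normal(1764, 135, 840),
            rng.normal(5418, 212, 100),
        ])
        w = _well(amps)
        rep = qc_well(w, reference=ClusterStats(1764, 135, 5418, 212, 840, 100),
                      min_droplets=100)
        assert "low_amplitude_tail" in rep.failed_rules

    def test_counts_only_rules_not_evaluated(self):
        rep = qc_well(DropletWell("A1", accepted=15_000, positives=100))
        assert rep.passed
        assert rep.details["low_amplitude_tail"] == "not evaluated"

    def test_clean_simulated_well_passes(self, rng):
        cfg = SimulationConfig(250.0, droplet_count_mean=17_000)
        well = simulate_well(cfg, rng)
        assert qc_well(well).passed

    def test_amplitude_outlier_against_plate(self, rng):
        cfg = SimulationConfig(250.0, droplet_count_mean=2_000, droplet_count_sd=0)
        wells = [simulate_well(cfg, rng, well_id=f"W{i}") for i in range(6)]
        shifted = simulate_well(cfg, rng, well_id="bad")
        shifted.amplitudes = shifted.amplitudes + 2_000.0
        plate = wells + [shifted]
        stats = [estimate_clusters(w.amplitudes) for w in plate]
        rep = qc_well(shifted, stats, min_droplets=100)
        assert "amplitude_outlier" in rep.failed_rules
        assert qc_well(wells[0], stats, min_droplets=100).passed


class TestSelectivity:
    def test_published_pooled_counts(self):
        blanks = [DropletWell("B1", accepted=61_275, positives=0)]
        controls = [DropletWell("P1", accepted=57_895, positives=57_895 - 33)]
        fp, fn = selectivity_metrics(blanks, controls)
        assert fp == 0.0
        assert fn == pytest.approx(33 / 57_895)
        assert round(100 * fn, 3) == 0.057

    def test_single_false_positive(self):
        blanks = [DropletWell("B1", accepted=10_000, positives=1)]
        controls = [DropletWell("P1", accepted=10_000, positives=10_000 - 1)]
        fp, _ = selectivity_metrics(blanks, controls)
        assert fp == pytest.approx(1e-4)

    def test_zero_droplets_rejected(self):
        with pytest.raises(ValueError):
            selectivity_metrics([], [DropletWell("P", accepted=10, positives=5)])
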