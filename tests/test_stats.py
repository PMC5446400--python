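"""Partition fractions, recovery sums, log depletion, viability, gating."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clusterdld import stats as St
from clusterdld import synthio as S


def table(rows):
    return pd.DataFrame(rows, columns=list(St.STREAMS)).rename_axis("class")


class TestPartitionFractions:
    def test_single_replicate_fractions(self):
        t = table({"large_cluster": [90, 7, 3]}).T
        t = pd.DataFrame({"large_cluster": [90, 7, 3]},
                         index=St.STREAMS).T
        out = St.partition_fractions([t])
        assert out.loc["large_cluster", "stage1_product_mean"] == \
            pytest.approx(90.0)
        assert out.loc["large_cluster", "stage2_product_mean"] == \
            pytest.approx(7.0)
        assert out.loc["large_cluster", "waste_mean"] == pytest.approx(3.0)

    def test_fractions_sum_to_100_per_class(self):
        tables = S.make_count_table(
            {"single": (0.2, 0.3, 0.5), "small_cluster": (0.3, 0.5, 0.2)},
            {"single": 400, "small_cluster": 300}, n_replicates=4, seed=9)
        out = St.partition_fractions(tables)
        sums = (out["stage1_product_mean"] + out["stage2_product_mean"]
                + out["waste_mean"])
        assert np.allclose(sums, 100.0)

    def test_multinomial_parameter_recovery(self):
        # generator probabilities from the whole-blood large-cluster split
        p = (0.778, 0.209, 0.013)
        tables = S.make_count_table({"large_cluster": p},
                                    {"large_cluster": 500},
                                    n_replicates=5, seed=123)
        out = St.partition_fractions(tables)
        for stream, target in zip(St.STREAMS, p):
            mean = out.loc["large_cluster", f"{stream}_mean"]
            sd = out.loc["large_cluster", f"{stream}_sd"]
            se = max(sd / math.sqrt(5), 1e-3)
            assert abs(mean - 100 * target) <= \
                max(2 * sd, 3 * 100 * math.sqrt(target * (1 - target) / 500))

    def test_zero_total_class_flagged_nan(self):
        t = pd.DataFrame({"single": [0, 0, 0]}, index=St.STREAMS).T
        out = St.partition_fractions([t])
        assert np.isnan(out.loc["single", "stage1_product_mean"])


class TestRecovery:
    def test_buffer_large_cluster_worked_example(self):
        rec, sd = St.total_recovery(91.8, 7.5, 9.5, 8.8)
        assert rec == pytest.approx(99.3)
        assert sd == pytest.approx(math.hypot(9.5, 8.8))

    def test_blood_large_cluster_worked_example(self):
        rec, _ = St.total_recovery(77.8, 20.9)
        assert rec == pytest.approx(98.7)

    def test_all_waste_gives_zero(self):
        assert St.total_recovery(0.0, 0.0)[0] == 0.0

    def test_recovery_is_complement_of_waste(self):
        tables = S.make_count_table({"small_cluster": (0.3, 0.45, 0.25)},
                                    {"small_cluster": 400},
                                    n_replicates=3, seed=4)
        frac = St.partition_fractions(tables)
        rec = St.recovery_by_replicate(tables)
        assert rec.loc["small_cluster", "recovery_mean"] == pytest.approx(
            100.0 - frac.loc["small_cluster", "waste_mean"], abs=1e-9)


class TestDepletion:
    def test_million_to_ten_is_five_logs(self):
        assert St.log10_depletion(1e6, 10).log10_depletion == \
            pytest.approx(5.0)

    def test_equal_counts_zero_depletion(self):
        assert St.log10_depletion(12345, 12345).log10_depletion == \
            pytest.approx(0.0)

    def test_volume_scale_invariance(self):
        c_in, c_out = 5.1e6, 320.0
        d1 = St.log10_depletion(St.counts_from_concentration(c_in, 2.0),
                                St.counts_from_concentration(c_out, 2.0))
        d2 = St.log10_depletion(St.counts_from_concentration(c_in, 4.0),
                                St.counts_from_concentration(c_out, 4.0))
        assert d1.log10_depletion == pytest.approx(d2.log10_depletion)

    def test_zero_output_reported_censored_not_infinite(self):
        d = St.log10_depletion(1e6, 0)
        assert d.censored and d.log10_depletion == pytest.approx(6.0)
        assert str(d) == "> 6.00"

    def test_additive_over_serial_stages(self):
        a = St.log10_depletion(1e6, 1e3).log10_depletion
        b = St.log10_depletion(1e3, 20).log10_depletion
        total = St.log10_depletion(1e6, 20).log10_depletion
        assert a + b == pytest.approx(total)

    def test_wbc_from_paired_channels(self):
        assert St.wbc_from_channels(150, 30) == 120
        with pytest.raises(ValueError):
            St.wbc_from_channels(10, 30)


def viability_pair(mean, sd, n=2, total=2000, condition="x"):
    """Two replicates realizing the reported mean ± SD."""
    vals = [mean - sd / math.sqrt(2), mean + sd / math.sqrt(2)]
    return [St.ViabilityRecord.from_percent(condition, v, total)
            for v in vals[:n]]


class TestViability:
    def test_identical_groups_not_significant(self):
        a = viability_pair(93.0, 1.5)
        out = St.viability_compare(a, a)
        assert not out.significant
        assert out.ci_low <= 0.0 <= out.ci_high

    def test_low_rate_viability_not_distinguishable_from_control(self):
        treated = viability_pair(93.8, 0.7)
        control = viability_pair(93.0, 1.5)
        out = St.viability_compare(treated, control)
        assert not out.significant

    def test_high_rate_viability_significantly_reduced(self):
        treated = viability_pair(73.8, 3.4)
        control = viability_pair(93.0, 1.5)
        out = St.viability_compare(treated, control)
        assert out.significant and out.p_value < 0.05
        assert out.difference_pct < 0
        assert out.ci_high < 0

    def test_fewer_than_200_cells_rejected(self):
        with pytest.raises(ValueError, match="200"):
            St.ViabilityRecord("x", live=100, total=150)


class TestCytometry:
    def test_reference_gating_examples(self):
        hi, lo = 200.0, 10.0
        viable = St.CytometryEvent(nuclear=hi, viability=hi, apoptosis=lo,
                                   epithelial=hi, leukocyte=lo)
        assert St.cytometry_classify(viable) == "viable_cancer"
        caspase_pos = St.CytometryEvent(nuclear=hi, viability=hi,
                                        apoptosis=hi, epithelial=hi,
                                        leukocyte=lo)
        assert St.cytometry_classify(caspase_pos) == "nonviable_cancer"
        anucleate = St.CytometryEvent(nuclear=lo, viability=hi, apoptosis=lo,
                                      epithelial=hi, leukocyte=lo)
        assert St.cytometry_classify(anucleate) == "excluded"

    def test_calcein_negative_is_nonviable(self):
        e = St.CytometryEvent(nuclear=200, viability=10, apoptosis=10,
                              epithelial=200, leukocyte=10)
        assert St.cytometry_classify(e) == "nonviable_cancer"

    def test_every_event_lands_in_exactly_one_bin(self):
        cats = {"excluded", "viable_cancer", "nonviable_cancer", "leukocyte"}
        for bits in itertools.product((10.0, 200.0), repeat=5):
            e = St.CytometryEvent(*bits)
            assert St.cytometry_classify(e) in cats
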