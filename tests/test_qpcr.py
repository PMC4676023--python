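"""Percent-input, ddCt, occupancy-ratio, methylation and t-test arithmetic,
checked against direct formula oracles and the synthetic Ct generator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rdnachip import qpcr, synthetic
from oracles import student_ttest, welch_ttest


class TestPercentInput:
    def test_equal_template_is_100(self):
        # adjusted input Ct for 10% input is ct_input - log2(10)
        assert qpcr.percent_input(20.0, 20.0 + math.log2(10), 0.1) == pytest.approx(100.0)

    def test_one_cycle_halves(self):
        adjusted = 20.0 + math.log2(10)
        assert qpcr.percent_input(21.0, adjusted, 0.1) == pytest.approx(50.0)

    def test_one_percent_input_example(self):
        # equivalent closed form: 100 * input_fraction * 2^(ct_input - ct_ip)
        assert qpcr.percent_input(22.0, 25.0, 0.01) == pytest.approx(8.0, abs=1e-9)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(200):
            ct_ip = float(rng.uniform(15, 35))
            ct_in = float(rng.uniform(15, 35))
            f = float(rng.uniform(0.005, 1.0))
            oracle = 100.0 * f * 2.0 ** (ct_in - ct_ip)
            assert qpcr.percent_input(ct_ip, ct_in, f) == pytest.approx(oracle, rel=1e-12)

    @given(
        st.floats(10, 35),
        st.floats(10, 35),
        st.floats(-5, 5),
    )
    def test_invariant_to_common_ct_offset(self, ct_ip, ct_in, delta):
        a = qpcr.percent_input(ct_ip, ct_in, 0.1)
        b = qpcr.percent_input(ct_ip + delta, ct_in + delta, 0.1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            qpcr.percent_input(20.0, 25.0, 0.0)
        with pytest.raises(ValueError):
            qpcr.percent_input(-1.0, 25.0, 0.1)


def tidy_table(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "assay", "target", "ct", "input_fraction"]
    )


class TestDdctFoldChange:
    def test_no_shift_gives_fold_one(self):
        rows = []
        for cond in ("control", "treatment"):
            for i in (1, 2, 3):
                rows.append((f"{cond}_{i}", cond, "rt", "geneA", 24.0, None))
                rows.append((f"{cond}_{i}", cond, "rt", "GAPDH", 18.0, None))
        est = qpcr.ddct_fold_change(tidy_table(rows), "geneA")
        assert est.point == pytest.approx(1.0)

    def test_one_cycle_shift_gives_half(self):
        rows = []
        for cond, shift in (("control", 0.0), ("treatment", 1.0)):
            for i in (1, 2):
                rows.append((f"{cond}_{i}", cond, "rt", "geneA", 24.0 + shift, None))
                rows.append((f"{cond}_{i}", cond, "rt", "GAPDH", 18.0, None))
        est = qpcr.ddct_fold_change(tidy_table(rows), "geneA")
        assert est.point == pytest.approx(0.5)

    def test_inverts_generator_exactly_at_zero_noise(self):
        params = synthetic.QpcrSimParams(
            true_fold={"pre-rRNA_5ETS": 0.8}, noise_sd=0.0, n_reps=3, seed=0
        )
        table = synthetic.simulate_qpcr(params)
        est = qpcr.ddct_fold_change(table, "pre-rRNA_5ETS")
        assert est.point == pytest.approx(0.8, abs=1e-12)

    def test_monte_carlo_recovery_of_20_percent_knockdown(self):
        folds = []
        for seed in range(200):
            params = synthetic.QpcrSimParams(
                true_fold={"t": 0.8}, noise_sd=0.1, n_reps=6, seed=seed
            )
            folds.append(qpcr.ddct_fold_change(synthetic.simulate_qpcr(params), "t").point)
        assert 0.78 <= float(np.mean(folds)) <= 0.82

    def test_missing_condition_rejected(self):
        rows = [
            ("a", "control", "rt", "geneA", 24.0, None),
            ("a", "control", "rt", "GAPDH", 18.0, None),
        ]
        with pytest.raises(ValueError):
            qpcr.ddct_fold_change(tidy_table(rows), "geneA")


class TestOccupancyRatio:
    def test_equal_percents_unity(self):
        assert qpcr.occupancy_ratio(3.7, 3.7) == 1.0

    def test_halved_occupancy(self):
        assert qpcr.occupancy_ratio(2.0, 4.0) == 0.5

    def test_replicates_match_elementwise_oracle(self, rng):
        kd = rng.uniform(0.5, 5.0, 3)
        ctrl = rng.uniform(0.5, 5.0, 3)
        est = qpcr.occupancy_ratios(kd, ctrl)
        assert est.point == pytest.approx(np.mean(kd / ctrl))
        assert est.dispersion == pytest.approx(np.std(kd / ctrl, ddof=1))
        assert est.n == 3

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            qpcr.occupancy_ratio(1.0, 0.0)


class TestMethylationFraction:
    def test_equal_cts_fully_resistant(self):
        res = qpcr.methylation_fraction(25.0, 25.0)
        assert res.value == 1.0 and not res.censored and not res.clipped

    def test_three_cycles_later_is_one_eighth(self):
        assert qpcr.methylation_fraction(28.0, 25.0).value == pytest.approx(0.125)

    def test_no_amplification_is_detection_censored(self):
        res = qpcr.methylation_fraction(None, 25.0, max_cycles=40.0)
        assert res.censored
        assert res.value == pytest.approx(2.0 ** (25.0 - 40.0))
        assert str(res).startswith("<")

    def test_impossible_fraction_clipped(self):
        res = qpcr.methylation_fraction(24.0, 25.0)
        assert res.value == 1.0 and res.clipped


class TestTwoSampleTtest:
    def test_identical_groups_null(self):
        res = qpcr.two_sample_ttest([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_welch_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a = rng.normal(10, rng.uniform(0.5, 3), int(rng.integers(3, 9)))
            b = rng.normal(rng.uniform(9, 12), rng.uniform(0.5, 3), int(rng.integers(3, 9)))
            t0, p0, df0 = welch_ttest(a, b)
            res = qpcr.two_sample_ttest(a, b)
            assert res.t == pytest.approx(t0, abs=1e-10)
            assert res.p == pytest.approx(p0, abs=1e-10)
            assert res.df == pytest.approx(df0, abs=1e-10)

    def test_classical_variant_matches_pooled_formula(self, rng):
        a = rng.normal(10, 1, 5)
        b = rng.normal(11, 1, 7)
        t0, p0, df0 = student_ttest(a, b)
        res = qpcr.two_sample_ttest(a, b, equal_var=True)
        assert res.t == pytest.approx(t0, abs=1e-10)
        assert res.p == pytest.approx(p0, abs=1e-10)
        assert res.df == df0

    def test_degenerate_zero_variance(self):
        same = qpcr.two_sample_ttest([2.0, 2.0], [2.0, 2.0])
        assert (same.t, same.p) == (0.0, 1.0) and not same.degenerate
        diff = qpcr.two_sample_ttest([2.0, 2.0], [3.0, 3.0])
        assert diff.p == 0.0 and diff.degenerate

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            qpcr.two_sample_ttest([1.0], [1.0, 2.0])


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,label",
        [(0.005, "**"), (0.03, "*"), (0.5, ""), (0.01, ""), (0.05, ""), (0.0, "**"), (1.0, "")],
    )
    def test_legend_convention(self, p, label):
        assert qpcr.significance_stars(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qpcr.significance_stars(1.5)


class TestTables:
    def test_load_primer_panel(self):
        df = qpcr.load_primer_table()
        assert {"H4", "H8", "H13", "H18", "H28", "H42", "H42.9", "GAPDH"} <= set(df["name"])
        h28 = df[df["name"] == "H28"].iloc[0]
        assert h28["forward"].strip("ACGT") == "" and h28["unit_kb"] == 28

    def test_percent_input_summary_pairs_samples(self):
        rows = []
        for cond, base in (("control", 22.0), ("knockdown", 23.0)):
            for i in (1, 2, 3):
                rows.append((f"{cond}_{i}", cond, "chip_ip", "H28", base + 0.05 * i, 0.1))
                rows.append((f"{cond}_{i}", cond, "chip_input", "H28", 21.0 + 0.05 * i, 0.1))
        df = qpcr.percent_input_summary(tidy_table(rows))
        assert set(df["condition"]) == {"control", "knockdown"}
        ctrl = df[df["condition"] == "control"].iloc[0]
        oracle = 100 * 0.1 * 2.0 ** (21.0 - 22.0)
        assert ctrl["percent_input_mean"] == pytest.approx(oracle)
        assert ctrl["n"] == 3 and np.isfinite(ctrl["p_vs_other"])

    def test_qpcr_table_loading_roundtrip(self, tmp_path):
        params = synthetic.QpcrSimParams(seed=1)
        table = synthetic.simulate_qpcr(params)
        path = tmp_path / "ct.csv"
        table.to_csv(path, index=False)
        back = qpcr.load_qpcr_table(path)
        assert list(back.columns) == qpcr.QPCR_COLUMNS
        assert len(back) == len(table)
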