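import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from functionome.gsr import Functionome, build_functionome
from functionome.stats import (
    bh_adjust,
    call_degs,
    call_dysregulated,
    ihc_score,
    mann_whitney_set,
    summarize_histogram,
)
from functionome.synthetic import SyntheticConfig, generate_cohort, generate_collection

from .conftest import random_cohort_frame
from .oracles import enumerate_mw_p


def functionome_of(frame: pd.DataFrame) -> Functionome:
    return Functionome(
        gsr=frame, skipped=pd.DataFrame(columns=["set_id", "n_measured_genes", "reason"])
    )


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        r = mann_whitney_set([0.1, 0.2, 0.3], [0.7, 0.8, 0.9], set_id="S")
        assert r.u_statistic == 0
        assert r.p_raw == pytest.approx(0.1)  # 2/20 rank assignments as extreme
        assert r.direction == -1

    def test_identical_groups_p_one(self):
        r = mann_whitney_set([0.5, 0.5], [0.5, 0.5])
        assert r.p_raw == pytest.approx(1.0)

    def test_two_vs_two_separated(self):
        r = mann_whitney_set([1, 2], [3, 4])
        assert r.u_statistic == 0
        assert r.p_raw == pytest.approx(1 / 3)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_set([], [1.0])

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        st.integers(1, 6),
        st.integers(1, 6),
        st.integers(0, 2**31 - 1),
    )
    def test_exact_branch_matches_full_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1, n + m + 1)).astype(float)  # no ties
        x, y = pooled[:n], pooled[n:]
        r = mann_whitney_set(x, y)
        u_oracle, p_oracle = enumerate_mw_p(x, y)
        assert r.u_statistic == pytest.approx(u_oracle)
        assert r.p_raw == pytest.approx(p_oracle)


class TestBhAdjust:
    def test_hand_worked_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_tied_inputs_unchanged(self):
        assert bh_adjust([0.5] * 10) == pytest.approx([0.5] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_qs_dominate_ps_and_sorted_monotone(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert q.max() <= 1.0
        q_sorted = bh_adjust(sorted(ps))
        assert np.all(np.diff(q_sorted) >= -1e-12)


class TestCallDysregulated:
    def test_planted_reversal_is_detected(self):
        cfg = SyntheticConfig(
            n_case=30, n_control=30, n_genes=500, n_sets=20, planted_fraction=0.1,
            scramble_strength=1.0, noise_sd=0.2, seed=2,
        )
        coll = generate_collection(cfg)
        mat, truth = generate_cohort(cfg, coll)
        f = build_functionome(mat, coll)
        results = {r.set_id: r for r in call_dysregulated(f, mat.groups)}
        for sid in truth.planted_set_ids:
            assert results[sid].significant
            assert results[sid].q < 1e-6

    def test_alpha_zero_interval_excludes_everything(self):
        rng = np.random.default_rng(1)
        gsr = pd.DataFrame(rng.uniform(size=(10, 5)),
                           index=[f"s{i}" for i in range(10)],
                           columns=[f"S{i}" for i in range(5)])
        labels = pd.Series(["case"] * 5 + ["control"] * 5, index=gsr.index)
        results = call_dysregulated(functionome_of(gsr), labels, alpha=1e-12)
        assert not any(r.significant for r in results)

    def test_one_group_functionome_is_error(self):
        gsr = pd.DataFrame(np.ones((4, 3)), index=[f"s{i}" for i in range(4)],
                           columns=["a", "b", "c"])
        labels = pd.Series(["case"] * 4, index=gsr.index)
        with pytest.raises(ValueError):
            call_dysregulated(functionome_of(gsr), labels)

    def test_raw_p_flag_thresholds_unadjusted_values(self):
        rng = np.random.default_rng(7)
        gsr = pd.DataFrame(rng.uniform(size=(20, 40)),
                           index=[f"s{i}" for i in range(20)],
                           columns=[f"S{i}" for i in range(40)])
        labels = pd.Series(["case"] * 10 + ["control"] * 10, index=gsr.index)
        raw = call_dysregulated(functionome_of(gsr), labels, use_raw_p=True)
        adj = call_dysregulated(functionome_of(gsr), labels, use_raw_p=False)
        assert sum(r.significant for r in raw) >= sum(r.significant for r in adj)
        for r in raw:
            assert r.significant == (r.p_raw < 0.05)


class TestCallDegs:
    def test_separated_gene_significant_identical_gene_null(self):
        rng = np.random.default_rng(3)
        n = 10
        values = pd.DataFrame(
            {
                f"s{i}": [
                    (i < n) * 10 + rng.uniform(0, 1),  # disjoint case/control ranges
                    5.0,                                # constant gene
                ]
                for i in range(2 * n)
            },
            index=["sep", "flat"],
        )
        labels = pd.Series(["case"] * n + ["control"] * n, index=values.columns)
        from functionome.data_io import ExpressionMatrix

        degs = {r.gene_id: r for r in call_degs(ExpressionMatrix(values=values, groups=labels))}
        assert degs["sep"].significant
        assert degs["flat"].p_raw == pytest.approx(1.0)

    def test_alpha_one_boundary(self):
        rng = np.random.default_rng(4)
        from functionome.data_io import ExpressionMatrix

        values = pd.DataFrame(rng.normal(size=(5, 8)),
                              index=[f"g{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["case"] * 4 + ["control"] * 4, index=values.columns)
        degs = call_degs(ExpressionMatrix(values=values, groups=labels),
                         alpha=1.0, use_raw_p=True)
        for r in degs:
            assert r.significant == (r.p_raw < 1.0)


class TestHistogram:
    def test_all_ones_mass_in_last_bin(self):
        gsr = pd.DataFrame(np.ones((4, 3)), index=[f"s{i}" for i in range(4)],
                           columns=["a", "b", "c"])
        labels = pd.Series(["case", "case", "control", "control"], index=gsr.index)
        h = summarize_histogram(functionome_of(gsr), labels, n_bins=10)
        assert h.case_counts.tolist() == [0] * 9 + [6]
        assert h.control_counts.tolist() == [0] * 9 + [6]

    def test_bin_arithmetic(self):
        gsr = pd.DataFrame([[0.05, 0.15]], index=["s0"], columns=["a", "b"])
        gsr = pd.concat([gsr, pd.DataFrame([[0.5, 0.5]], index=["s1"], columns=["a", "b"])])
        labels = pd.Series({"s0": "case", "s1": "control"})
        h = summarize_histogram(functionome_of(gsr), labels, n_bins=10)
        assert h.case_counts.tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_summary_matches_group_mean(self, tiny_matrix, tiny_collection):
        from functionome.gsr import corrected_group_mean

        f = build_functionome(tiny_matrix, tiny_collection)
        h = summarize_histogram(f, tiny_matrix.groups, n_bins=10)
        mean, sd = corrected_group_mean(f, tiny_matrix.case_ids)
        assert h.case_mean == pytest.approx(mean)
        assert h.case_sd == pytest.approx(sd)
        assert h.case_counts.sum() == f.gsr.loc[tiny_matrix.case_ids].size


class TestIhcScore:
    @pytest.mark.parametrize(
        "intensity,percent,expected",
        [(3, 100.0, 300.0), (0, 73.0, 0.0), (2, 45.0, 90.0)],
    )
    def test_product_rule(self, intensity, percent, expected):
        assert ihc_score(intensity, percent) == expected

    @pytest.mark.parametrize("intensity,percent", [(4, 50), (-1, 50), (2, 101), (2, -5)])
    def test_out_of_range_rejected(self, intensity, percent):
        with pytest.raises(ValueError):
            ihc_score(intensity, percent)
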