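import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from functionome.data_io import ExpressionMatrix, GeneSet, GeneSetCollection
from functionome.gsr import (
    build_functionome,
    build_template,
    corrected_group_mean,
    gsr_index,
    pair_orders,
)

from .conftest import random_cohort_frame
from .oracles import brute_gsr

GENES = ("A", "B", "C")


def _pov(values, gene_set=None, universe=GENES):
    gene_set = gene_set or GeneSet("SET_ABC", "abc", GENES)
    return pair_orders(pd.Series(values), gene_set, universe)


class TestPairOrders:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ({"A": 1, "B": 2, "C": 3}, [1, 1, 1]),   # fully increasing
            ({"A": 3, "B": 2, "C": 1}, [0, 0, 0]),   # fully decreasing
            ({"A": 1, "B": 3, "C": 2}, [1, 1, 0]),   # pairs (A,B),(A,C),(B,C)
        ],
    )
    def test_three_gene_encodings(self, values, expected):
        assert _pov(values).bits.tolist() == expected

    def test_ties_resolve_by_gene_symbol_order(self):
        # equal values: "A" < "B" lexicographically, so bit("A","B") = 1
        assert _pov({"A": 5, "B": 5, "C": 5}).bits.tolist() == [1, 1, 1]

    def test_unmeasured_genes_dropped(self):
        pov = _pov({"A": 1, "B": 2, "C": 3}, universe=("A", "C"))
        assert pov.genes == ("A", "C")
        assert pov.bits.tolist() == [1]

    def test_single_measured_gene_not_retained(self):
        assert _pov({"A": 1}, universe=("A",)) is None


class TestTemplate:
    def test_unanimous_controls(self, tiny_matrix, abc_set):
        t = build_template(tiny_matrix, abc_set)
        assert t.template_bits.tolist() == [1, 1, 1]
        assert t.support.tolist() == [1.0, 1.0, 1.0]

    def test_majority_vote(self, abc_set):
        values = pd.DataFrame(
            {"c1": [1.0, 2.0, 3.0], "c2": [1.0, 2.0, 3.0], "c3": [2.0, 1.0, 3.0]},
            index=list(GENES),
        )
        t = build_template(values, abc_set)
        assert t.support[0] == pytest.approx(2 / 3)
        assert t.template_bits.tolist() == [1, 1, 1]

    def test_split_support_half_votes_one(self, abc_set):
        values = pd.DataFrame(
            {"c1": [1.0, 2.0, 3.0], "c2": [2.0, 1.0, 3.0]}, index=list(GENES)
        )
        t = build_template(values, abc_set)
        assert t.support[0] == 0.5
        assert t.template_bits[0] == 1

    def test_no_controls_is_error(self, abc_set):
        values = pd.DataFrame(index=list(GENES))
        with pytest.raises(ValueError, match="no control samples"):
            build_template(values, abc_set)


class TestGsrIndex:
    def test_match_mismatch_and_partial(self, tiny_matrix, abc_set):
        t = build_template(tiny_matrix, abc_set)
        same = _pov({"A": 5, "B": 6, "C": 7})
        rev = _pov({"A": 7, "B": 6, "C": 5})
        partial = _pov({"A": 1, "B": 3, "C": 2})  # bits (1,1,0) vs (1,1,1)
        assert gsr_index(same, t) == 1.0
        assert gsr_index(rev, t) == 0.0
        assert gsr_index(partial, t) == pytest.approx(2 / 3)

    def test_pair_list_mismatch_is_error(self, tiny_matrix, abc_set):
        t = build_template(tiny_matrix, abc_set)
        other = pair_orders(
            pd.Series({"A": 1, "B": 2}), GeneSet("SET_ABC", "ab", ("A", "B")), ("A", "B")
        )
        with pytest.raises(ValueError, match="mismatch"):
            gsr_index(other, t)


class TestFunctionome:
    def test_identity_cohort_scores_one(self, tiny_matrix, tiny_collection):
        f = build_functionome(tiny_matrix, tiny_collection)
        assert f.gsr.loc["case_same", "SET_ABC"] == 1.0
        assert f.gsr.loc["case_rev", "SET_ABC"] == 0.0
        # identically ordered controls all score 1 against their own consensus
        assert (f.gsr.loc[["ctrl_0", "ctrl_1", "ctrl_2"]] == 1.0).all().all()

    def test_all_entries_in_unit_interval(self):
        rng = np.random.default_rng(11)
        matrix = random_cohort_frame(rng, n_genes=30, n_samples=12, n_controls=6)
        sets = [
            GeneSet(f"S{k}", f"s{k}", tuple(rng.choice(matrix.gene_ids, 6, replace=False)))
            for k in range(10)
        ]
        f = build_functionome(matrix, GeneSetCollection(sets=sets))
        assert ((f.gsr >= 0) & (f.gsr <= 1)).all().all()

    def test_unretained_sets_logged_not_raised(self, tiny_matrix):
        coll = GeneSetCollection(
            sets=[
                GeneSet("OK", "ok", ("A", "B")),
                GeneSet("TOO_SMALL", "x", ("A", "ZZZ_ABSENT")),
            ]
        )
        f = build_functionome(tiny_matrix, coll)
        assert f.set_ids == ["OK"]
        assert f.skipped["set_id"].tolist() == ["TOO_SMALL"]

    def test_no_retained_sets_is_error(self, tiny_matrix):
        coll = GeneSetCollection(sets=[GeneSet("S", "s", ("NOPE1", "NOPE2"))])
        with pytest.raises(ValueError, match="no gene set retained"):
            build_functionome(tiny_matrix, coll)

    def test_single_control_scores_itself_one(self):
        rng = np.random.default_rng(5)
        matrix = random_cohort_frame(rng, n_genes=10, n_samples=3, n_controls=1)
        sets = [GeneSet("S", "s", tuple(matrix.gene_ids[:6]))]
        f = build_functionome(matrix, GeneSetCollection(sets=sets))
        assert f.gsr.loc[matrix.control_ids[0], "S"] == 1.0

    def test_scrambled_case_column_depressed_and_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        n_controls, n_cases = 4, 2
        matrix = random_cohort_frame(rng, 12, n_controls + n_cases, n_controls)
        genes = list(matrix.gene_ids[:5])
        # scramble the set's genes in case samples only (full reversal of values)
        vals = matrix.values.copy()
        for s in matrix.case_ids:
            vals.loc[genes, s] = vals.loc[genes, s].to_numpy()[::-1]
        matrix = ExpressionMatrix(values=vals, groups=matrix.groups)
        coll = GeneSetCollection(sets=[GeneSet("S", "s", tuple(genes))])
        f = build_functionome(matrix, coll)
        case_mean = f.gsr.loc[matrix.case_ids, "S"].mean()
        ctrl_mean = f.gsr.loc[matrix.control_ids, "S"].mean()
        assert case_mean < ctrl_mean
        controls = [matrix.values[c].to_dict() for c in matrix.control_ids]
        for s in matrix.sample_ids:
            expected = brute_gsr(matrix.values[s].to_dict(), controls, genes)
            assert f.gsr.loc[s, "S"] == pytest.approx(expected)


class TestGroupMean:
    def test_constant_and_mixed(self, tiny_matrix, tiny_collection):
        f = build_functionome(tiny_matrix, tiny_collection)
        mean, sd = corrected_group_mean(f, tiny_matrix.control_ids)
        assert (mean, sd) == (1.0, 0.0)

    def test_hand_computed_mean_sd(self, tiny_matrix, tiny_collection):
        f = build_functionome(tiny_matrix, tiny_collection)
        f.gsr = pd.DataFrame(
            [[0.2, 0.4], [0.6, 0.8]], index=["s1", "s2"], columns=["x", "y"]
        )
        mean, sd = corrected_group_mean(f, ["s1", "s2"])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.sqrt(0.2 / 3))  # n-1 denominator by hand

    def test_empty_group_is_error(self, tiny_matrix, tiny_collection):
        f = build_functionome(tiny_matrix, tiny_collection)
        with pytest.raises(ValueError, match="empty"):
            corrected_group_mean(f, [])


class TestOrdinalProperties:
    """Invariances that follow from the purely ordinal definition."""

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_leaves_functionome_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_cohort_frame(rng, n_genes=15, n_samples=8, n_controls=4)
        sets = [
            GeneSet(f"S{k}", f"s{k}", tuple(rng.choice(matrix.gene_ids, 5, replace=False)))
            for k in range(4)
        ]
        coll = GeneSetCollection(sets=sets)
        base = build_functionome(matrix, coll)
        transforms = [np.exp, lambda v: v**3, lambda v: 2 * v + 7, np.arctan]
        vals = matrix.values.copy()
        for i, s in enumerate(matrix.sample_ids):
            vals[s] = transforms[i % len(transforms)](vals[s])
        warped = build_functionome(
            ExpressionMatrix(values=vals, groups=matrix.groups), coll
        )
        pd.testing.assert_frame_equal(base.gsr, warped.gsr)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_reversal_antisymmetry(self, seed):
        # complementing a sample's bits maps GSR -> 1 - GSR
        rng = np.random.default_rng(seed)
        genes = tuple(sorted(f"g{i}" for i in range(5)))
        gs = GeneSet("S", "s", genes)
        controls = pd.DataFrame(
            rng.normal(size=(5, 4)), index=list(genes), columns=[f"c{i}" for i in range(4)]
        )
        t = build_template(controls, gs)
        sample = pd.Series(rng.normal(size=5), index=list(genes))
        pov = pair_orders(sample, gs, genes)
        flipped = type(pov)(set_id=pov.set_id, genes=pov.genes, bits=1 - pov.bits)
        assert gsr_index(flipped, t) == pytest.approx(1.0 - gsr_index(pov, t))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_gene_order_within_set_definition_irrelevant(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_cohort_frame(rng, n_genes=12, n_samples=6, n_controls=3)
        genes = list(rng.choice(matrix.gene_ids, 5, replace=False))
        shuffled = list(genes)
        rng.shuffle(shuffled)
        f1 = build_functionome(
            matrix, GeneSetCollection(sets=[GeneSet("S", "s", tuple(genes))])
        )
        f2 = build_functionome(
            matrix, GeneSetCollection(sets=[GeneSet("S", "s", tuple(shuffled))])
        )
        pd.testing.assert_frame_equal(f1.gsr, f2.gsr)
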