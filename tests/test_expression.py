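"""Expression flags, grouping, Venn regions and ddCt fold-changes."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famscan.expression import (ddct_fold_change, expression_flags,
                                group_expression, venn_membership)
from famscan.io import ExpressionMatrix


def mat(values, genes=None, tissues=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=tissues))


class TestFlags:
    def test_thresholds_inclusive(self):
        m = mat([[1.0, 1.0], [0.99, 5.0], [2.0, 1.9]])
        constitutive, expressed = expression_flags(m)
        assert constitutive.tolist() == [True, False, True]
        assert expressed["t0"] == {"g2"}
        assert expressed["t1"] == {"g1"}

    def test_tissue_specific_gene_in_single_set(self):
        m = mat([[9.0, 0.1, 0.1], [3.0, 3.0, 3.0]])
        _, expressed = expression_flags(m)
        assert {t for t, s in expressed.items() if "g0" in s} == {"t0"}


class TestGroups:
    def test_three_constant_levels(self):
        m = mat([[20.0] * 4, [6.0] * 4, [1.0] * 4])
        groups = group_expression(m, 3, seed=0)
        assert [g.members for g in groups] == [["g0"], ["g1"], ["g2"]]
        assert [g.mean_fpkm for g in groups] == [20.0, 6.0, 1.0]

    def test_identical_genes_degenerate_warning(self):
        m = mat([[5.0, 5.0]] * 4)
        with pytest.warns(UserWarning, match="single group"):
            groups = group_expression(m, 3, seed=0)
        assert len(groups) == 1

    def test_k_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            group_expression(mat([[1.0, 2.0]]), 3, seed=0)

    def test_planted_partition_recovered(self, family_bundle):
        _, out, truth = family_bundle
        frame = pd.read_csv(out / "fpkm.tsv", sep="\t", index_col=0)
        groups = group_expression(ExpressionMatrix(frame), 3, seed=0)
        got = {g: grp.label for grp in groups for g in grp.members}
        assert got == truth["expression"]["group_of"]
        assert [len(g.members) for g in groups] == \
            truth["expression"]["group_sizes"]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        m = mat(rng.uniform(0.1, 30, size=(15, 6)))
        g1 = group_expression(m, 3, seed=9)
        g2 = group_expression(m, 3, seed=9)
        assert [g.members for g in g1] == [g.members for g in g2]


small_sets = st.dictionaries(
    st.sampled_from(["A", "B", "C", "D"]),
    st.sets(st.integers(min_value=0, max_value=12), max_size=8),
    min_size=2, max_size=4)


class TestVenn:
    def test_identical_sets(self):
        counts = venn_membership({"A": {1, 2}, "B": {1, 2}})
        assert counts[("A", "B")] == 2
        assert counts[("A",)] == counts[("B",)] == 0

    def test_disjoint_sets(self):
        counts = venn_membership({"A": {1}, "B": {2, 3}})
        assert counts[("A",)] == 1 and counts[("B",)] == 2
        assert counts[("A", "B")] == 0

    def test_too_many_sets_rejected(self):
        with pytest.raises(ValueError):
            venn_membership({c: set() for c in "ABCDEF"})

    @given(small_sets)
    def test_region_counts_sum_to_union(self, sets):
        counts = venn_membership(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_planted_venn_truth(self, family_bundle):
        cfg, out, truth = family_bundle
        frame = pd.read_csv(out / "fpkm.tsv", sep="\t", index_col=0)
        _, expressed = expression_flags(
            ExpressionMatrix(frame), venn_tissues=list(cfg.venn_tissues))
        counts = venn_membership(expressed)
        all_five = counts[tuple(sorted(cfg.venn_tissues))]
        assert all_five == truth["expression"]["n_expressed_all_venn"]
        spec = truth["expression"]["tissue_specific"]
        for gene, tissue in spec.items():
            tissues_with = {t for t, s in expressed.items() if gene in s}
            assert tissues_with == {tissue}


def qpcr_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "condition", "replicate",
                                       "ct_target", "ct_reference"])


class TestDdct:
    def _rows(self, treat_dct, ctrl_dct, ref=20.0):
        rows = []
        for i, d in enumerate(ctrl_dct):
            rows.append(("g", "control", i, ref + d, ref))
        for i, d in enumerate(treat_dct):
            rows.append(("g", "ABA", i, ref + d, ref))
        return qpcr_frame(rows)

    def test_equal_dct_is_unity_ns(self):
        res = ddct_fold_change(self._rows([5, 5, 5], [5, 5, 5]), "g", "ABA")
        assert res.fold_change == pytest.approx(1.0)
        assert res.call == "ns"

    def test_one_cycle_shift_doubles(self):
        res = ddct_fold_change(self._rows([4, 4, 4], [5, 5, 5]), "g", "ABA")
        assert res.fold_change == pytest.approx(2.0)

    def test_call_rules(self):
        up = ddct_fold_change(self._rows([2.0, 2.01, 1.99],
                                         [5.0, 5.01, 4.99]), "g", "ABA")
        assert up.call == "up" and up.fold_change > 1 and up.p_value <= 0.05
        down = ddct_fold_change(self._rows([7.0, 7.01, 6.99],
                                           [5.0, 5.01, 4.99]), "g", "ABA")
        assert down.call == "down" and down.fold_change < 1

    def test_missing_control_rejected(self):
        rows = qpcr_frame([("g", "ABA", i, 25.0, 20.0) for i in range(3)])
        with pytest.raises(ValueError, match="control"):
            ddct_fold_change(rows, "g", "ABA")

    @given(st.floats(min_value=-3, max_value=3))
    def test_invariance_to_replicate_wide_ct_shift(self, shift):
        """Adding a constant to all Ct values of a replicate (target and
        reference together) leaves the fold-change unchanged."""
        base = self._rows([3.0, 3.2, 2.8], [5.0, 5.2, 4.8])
        shifted = base.copy()
        first = shifted.index[shifted.condition == "ABA"][0]
        shifted.loc[first, ["ct_target", "ct_reference"]] += shift
        r1 = ddct_fold_change(base, "g", "ABA")
        r2 = ddct_fold_change(shifted, "g", "ABA")
        assert r2.fold_change == pytest.approx(r1.fold_change, rel=1e-9)

    def test_zero_noise_recovers_planted_folds_exactly(self):
        from conftest import small_config

        from famscan.synthetic import SynthConfig, generate_qpcr
        cfg = small_config()
        cfg = SynthConfig(**{**cfg.__dict__, "ct_noise_sd": 0.0})
        genes = [f"m{i}" for i in range(8)]
        table, truth = generate_qpcr(cfg, genes, seed=3)
        for key, planted in truth["fold_changes"].items():
            gene, cond = key.split("|")
            res = ddct_fold_change(table, gene, cond)
            assert res.fold_change == pytest.approx(planted, rel=1e-9)

    def test_noisy_showcase_recovered_and_called(self, family_bundle):
        _, out, truth = family_bundle
        table = pd.read_csv(out / "qpcr.csv")
        show = truth["qpcr"]["showcase"]
        res = ddct_fold_change(table, show["aba_up"], "ABA")
        assert res.fold_change == pytest.approx(88.0, rel=0.25)
        assert res.call == "up"
        res = ddct_fold_change(table, show["aba_down"], "ABA")
        assert res.fold_change == pytest.approx(1 / 17, rel=0.25)
        assert res.call == "down"
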