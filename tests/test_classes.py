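import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import egranule as eg
from egranule.classes import OverlapStats


def class_table(rpm, excluded=None, soma=None):
    genes = list(rpm)
    return pd.DataFrame(
        {
            "rpm": [rpm[g] for g in genes],
            "excluded_biotype": [g in (excluded or set()) for g in genes],
            "soma_specific": [g in (soma or set()) for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestFoldChange:
    @pytest.mark.parametrize(
        "mut,wt,eps,expected",
        [(5, 10, 0.0, 0.5), (0, 10, 0.1, 0.1 / 10.1), (7.3, 7.3, 0.1, 1.0), (0, 0, 0.1, 1.0)],
    )
    def test_values(self, mut, wt, eps, expected):
        assert eg.fold_change(mut, wt, eps) == pytest.approx(expected)

    def test_zero_over_zero_without_pseudocount_raises(self):
        with pytest.raises(ValueError):
            eg.fold_change(0.0, 0.0, 0.0)

    @given(st.floats(0.01, 1e4), st.floats(0.001, 10))
    def test_identity(self, x, eps):
        assert eg.fold_change(x, x, eps) == pytest.approx(1.0)


class TestDepletedGenes:
    def test_wt_floor_and_exclusions(self):
        wt = class_table({"a": 9.0, "b": 20.0, "mir": 100.0, "som": 50.0},
                         excluded={"mir"}, soma={"som"})
        mut = class_table({"a": 0.0, "b": 9.0, "mir": 1.0, "som": 1.0},
                          excluded={"mir"}, soma={"som"})
        params = eg.ContrastParams(pseudocount=0.0)
        got = eg.depleted_genes(mut, wt, params)
        assert got == {"b"}  # a fails the 10 RPM floor; mir/som are excluded

    def test_mismatched_universe_raises(self):
        wt = class_table({"a": 10.0})
        mut = class_table({"b": 1.0})
        with pytest.raises(ValueError, match="universe"):
            eg.depleted_genes(mut, wt, eg.ContrastParams())

    def test_up_direction_floors_the_mutant_table(self):
        wt = class_table({"a": 0.5, "b": 0.5})
        mut = class_table({"a": 50.0, "b": 5.0})
        got = eg.depleted_genes(mut, wt, eg.ContrastParams(direction="up", pseudocount=0.0))
        assert got == {"a"}  # b is >2-fold up but below the mutant floor

    def test_up_down_symmetry_without_pseudocount(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        a = class_table(dict(zip(genes, rng.uniform(0, 40, 50))))
        b = class_table(dict(zip(genes, rng.uniform(0, 40, 50))))
        down = eg.ContrastParams(direction="down", pseudocount=0.0)
        up = eg.ContrastParams(direction="up", pseudocount=0.0)
        assert eg.depleted_genes(b, a, down) == eg.depleted_genes(a, b, up)

    @given(st.integers(0, 30))
    def test_raising_wt_floor_never_adds_genes(self, floor):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        wt = class_table(dict(zip(genes, rng.uniform(0, 40, 40))))
        mut = class_table(dict(zip(genes, rng.uniform(0, 40, 40))))
        lo = eg.depleted_genes(mut, wt, eg.ContrastParams(wt_min_rpm=float(floor)))
        hi = eg.depleted_genes(mut, wt, eg.ContrastParams(wt_min_rpm=float(floor + 5)))
        assert hi <= lo


class TestSetMachinery:
    @pytest.mark.parametrize(
        "a,b,expected",
        [({"a", "b", "c"}, {"b", "c", "d"}, {"b", "c"}), ({"a"}, set(), set()),
         ({"a", "b"}, {"a", "b"}, {"a", "b"})],
    )
    def test_consensus_is_intersection(self, a, b, expected):
        assert eg.consensus_targets(a, b) == expected

    def test_e_class_union_from_printed_counts(self):
        shared = {f"g{i}" for i in range(1192)}
        egc1 = shared | {f"e{i}" for i in range(1504 - 1192)}
        elli1 = shared | {f"l{i}" for i in range(1282 - 1192)}
        assignment = eg.define_classes(egc1, elli1, mut16_targets=set())
        assert len(assignment.e_class) == 1594

    def test_empty_inputs_give_empty_classes(self):
        a = eg.define_classes(set(), set(), set())
        assert not (a.e_class | a.m_class | a.up_class)

    def test_overlap_percentages(self):
        o = OverlapStats.from_counts(1504, 1282, 1192)
        assert o.size_union == 1594
        assert o.pct_of_b_shared == pytest.approx(100 * 1192 / 1282)
        assert round(o.pct_of_b_shared) == 93
        assert eg.overlap_stats({"a"}, {"b"}).pct_of_a_shared == 0.0
        sub = eg.overlap_stats({"a", "b"}, {"a", "b", "c"})
        assert sub.pct_of_a_shared == 100.0

    @given(st.sets(st.integers(0, 60)), st.sets(st.integers(0, 60)))
    def test_inclusion_exclusion_exact(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        o = eg.overlap_stats(a, b)
        assert o.size_union == o.size_a + o.size_b - o.size_intersection
        assert o.size_union == len(a | b)
        assert 0 <= o.pct_of_a_shared <= 100 and 0 <= o.pct_of_b_shared <= 100


class TestMrnaDe:
    def test_clear_4fold_change_is_called(self):
        # many unchanged genes keep the library-size normalization stable
        genes = ["down4"] + [f"flat{i}" for i in range(20)]
        wt_counts = [4000] + [1000] * 20
        mut_counts = [1000] + [1005] * 20
        wt = pd.DataFrame({"r1": wt_counts, "r2": [c + 10 for c in wt_counts]}, index=genes)
        mut = pd.DataFrame({"r1": mut_counts, "r2": [c - 5 for c in mut_counts]}, index=genes)
        up, down = eg.mrna_de_genes(mut, wt)
        assert down == {"down4"} and not up

    def test_silenced_genes_recovered_in_seeded_monte_carlo(self, tiny_genome):
        silenced = tiny_genome.truth_genes("NEUTRAL")[:2]
        hit = 0
        for i in range(100):
            wt = eg.simulate_mrna_counts(tiny_genome, "WT", 2e5, 0.05, seed=100 + i)
            mut = eg.simulate_mrna_counts(
                tiny_genome, "egc1", 2e5, 0.05, seed=9100 + i,
                silenced_genes=silenced, silencing_factor=4.0,
            )
            _, down = eg.mrna_de_genes(mut, wt)
            hit += set(silenced) <= down
        assert hit >= 95

    def test_zero_depth_condition_raises(self):
        wt = pd.DataFrame({"r1": [0, 0]}, index=["a", "b"])
        mut = pd.DataFrame({"r1": [5, 5]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero total"):
            eg.mrna_de_genes(mut, wt)


class TestDdct:
    @pytest.mark.parametrize("ddct_value,expected", [(1.0, 0.5), (0.0, 1.0), (-2.0, 4.0)])
    def test_closed_form(self, ddct_value, expected):
        rows = []
        for sample, tgt_ct in (("control", 10.0), ("treated", 10.0 + ddct_value)):
            for b in (1, 2, 3):
                rows.append(("g", sample, b, 1, tgt_ct))
                rows.append(("eft-3", sample, b, 1, 5.0))
        tab = pd.DataFrame(rows, columns=["gene", "sample", "bio_rep", "tech_rep", "ct"])
        res = eg.ddct(tab, control_sample="control")
        assert res.summary.loc[("g", "treated"), "mean_level"] == pytest.approx(expected)

    def test_technical_replicates_are_averaged_first(self):
        rows = [("g", "s", 1, 1, 9.0), ("g", "s", 1, 2, 11.0), ("eft-3", "s", 1, 1, 5.0)]
        tab = pd.DataFrame(rows, columns=["gene", "sample", "bio_rep", "tech_rep", "ct"])
        res = eg.ddct(tab, control_sample="s")
        assert res.per_replicate["relative_level"].iloc[0] == pytest.approx(1.0)

    def test_missing_reference_rows_raise(self):
        tab = pd.DataFrame(
            [("g", "s", 1, 1, 9.0)], columns=["gene", "sample", "bio_rep", "tech_rep", "ct"]
        )
        with pytest.raises(ValueError, match="reference"):
            eg.ddct(tab, control_sample="s")
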