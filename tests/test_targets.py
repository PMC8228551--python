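"""Target selection: evidence filter, brain-expression filter, set algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirnet_pd.curation import ConsolidatedDESets
from mirnet_pd.targets import (
    BRAIN_TISSUES,
    ExpressionMatrix,
    Interaction,
    brain_expression_filter,
    classify_brain_expression,
    derive_target_sets,
    filter_interactions,
    intersect_sets,
    load_expression,
    load_interactions,
)


def expr_matrix(values: dict[str, list[float]], tissues=None) -> ExpressionMatrix:
    tissues = tissues or list(BRAIN_TISSUES)
    return ExpressionMatrix(pd.DataFrame(values, index=tissues).T)


def test_13_brain_tissues():
    assert len(BRAIN_TISSUES) == 13
    assert "substantia_nigra" in BRAIN_TISSUES and "putamen" in BRAIN_TISSUES


class TestFilterInteractions:
    def test_keeps_requested_level_only(self):
        table = [Interaction("m1", "G1", "strong"), Interaction("m1", "G2", "weak")]
        assert filter_interactions(table, "strong") == [table[0]]

    def test_empty_table(self):
        assert filter_interactions([], "strong") == []

    def test_duplicates_collapsed_order_preserved(self):
        table = [
            Interaction("m1", "G2", "strong"),
            Interaction("m1", "G1", "strong"),
            Interaction("m1", "G2", "strong", source="dup"),
        ]
        out = filter_interactions(table, "strong")
        assert [(i.mirna_id, i.gene) for i in out] == [("m1", "G2"), ("m1", "G1")]

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            filter_interactions([], "medium")

    def test_evidence_validated_on_construction(self):
        with pytest.raises(ValueError):
            Interaction("m1", "G1", "hearsay")


class TestLoadInteractions:
    def test_dialect_mapping(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text(
            "mirna_id\tgene\tevidence\n"
            "hsa-miR-1\tfoxo3\tFunctional MTI\n"
            "hsa-miR-1\tMYC\tFunctional MTI (Weak)\n"
        )
        table = load_interactions(p)
        assert [(i.mirna_id, i.gene, i.evidence) for i in table] == [
            ("hsa-mir-1", "FOXO3", "strong"),
            ("hsa-mir-1", "MYC", "weak"),
        ]

    def test_unknown_evidence_label(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("mirna_id\tgene\tevidence\nm1\tG1\trumor\n")
        with pytest.raises(ValueError, match="rumor"):
            load_interactions(p)


class TestBrainExpressionFilter:
    def test_zero_everywhere_excluded(self):
        expr = expr_matrix({"G1": [0.0] * 13})
        assert brain_expression_filter({"G1"}, expr) == set()

    def test_boundary_exactly_one_excluded(self):
        vals = [5.0] * 13
        vals[4] = 1.0
        expr = expr_matrix({"G1": vals, "G2": [5.0] * 13})
        assert brain_expression_filter({"G1", "G2"}, expr) == {"G2"}

    def test_absent_genes_excluded_and_reported(self):
        expr = expr_matrix({"G1": [5.0] * 13})
        retained, below, absent = classify_brain_expression({"G1", "GX"}, expr)
        assert retained == {"G1"} and absent == {"GX"}

    def test_missing_tissue_named(self):
        expr = expr_matrix({"G1": [5.0, 5.0]}, tissues=["putamen", "cortex"])
        with pytest.raises(KeyError, match="substantia_nigra"):
            brain_expression_filter({"G1"}, expr, tissues=["putamen", "substantia_nigra"])

    def test_synthetic_planted_fraction(self):
        from mirnet_pd.simulate import simulate_expression

        genes = [f"G{i}" for i in range(200)]
        expr, planted = simulate_expression(genes, expressed_fraction=0.6, seed=5)
        assert len(planted) == 120
        assert brain_expression_filter(genes, expr) == planted

    @given(st.integers(0, 40))
    def test_antitone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        genes = {f"G{i}": list(rng.uniform(0, 4, 13)) for i in range(12)}
        expr = expr_matrix(genes)
        lo = brain_expression_filter(set(genes), expr, threshold=0.5)
        hi = brain_expression_filter(set(genes), expr, threshold=1.5)
        assert hi <= lo


class TestExpressionIO:
    def test_plain_tsv_roundtrip(self, tmp_path):
        from mirnet_pd.targets import write_expression

        expr = expr_matrix({"G1": [2.0] * 13, "G2": [0.5] * 13})
        p = tmp_path / "e.tsv"
        write_expression(expr, p)
        back = load_expression(p)
        pd.testing.assert_frame_equal(back.frame, expr.frame.sort_index())

    def test_gct_header_accepted(self, tmp_path):
        p = tmp_path / "e.gct"
        p.write_text(
            "#1.2\n2\t2\nName\tDescription\tputamen\tcortex\n"
            "g1\tdesc\t2.0\t3.0\nG2\tdesc\t0.1\t0.2\n"
        )
        expr = load_expression(p)
        assert expr.genes == ["G1", "G2"]
        assert expr["G1", "cortex"] == 3.0

    def test_duplicate_genes_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\tputamen\nG1\t1.0\nG1\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_expression(p)


def _desets(up=(), down=(), sn=(), putamen=()):
    up, down = frozenset(up), frozenset(down)
    return ConsolidatedDESets(
        up=up, down=down, sn=frozenset(sn), putamen=frozenset(putamen),
        conflicts=up & down, multi_study=frozenset(),
    )


class TestDeriveTargetSets:
    def setup_method(self):
        self.expr = expr_matrix({"G1": [5.0] * 13, "G2": [5.0] * 13, "G3": [0.1] * 13})
        self.inter = [
            Interaction("mir-1", "G1", "strong"),
            Interaction("mir-1", "G3", "strong"),  # not brain-expressed
            Interaction("mir-2", "G2", "strong"),
            Interaction("mir-2", "G1", "weak"),  # weak evidence
        ]

    def test_union_of_member_targets_within_universe(self):
        sets = _desets(up=["mir-1", "mir-2"], down=["mir-2"], sn=["mir-1"])
        ts = derive_target_sets(sets, self.inter, self.expr)
        assert ts.up_targets == {"G1", "G2"}
        assert ts.down_targets == {"G2"}
        assert ts.sn_targets == {"G1"}
        assert ts.putamen_targets == frozenset()

    def test_empty_mirna_set_yields_empty_not_error(self):
        ts = derive_target_sets(_desets(), self.inter, self.expr)
        assert ts.union == frozenset()

    def test_monotone_in_mirna_set(self):
        small = derive_target_sets(_desets(up=["mir-1"]), self.inter, self.expr)
        large = derive_target_sets(_desets(up=["mir-1", "mir-2"]), self.inter, self.expr)
        assert small.up_targets <= large.up_targets

    def test_generator_strong_count_matches(self):
        from mirnet_pd.simulate import simulate_interactions

        table, truth = simulate_interactions(10, 30, density=0.2, seed=3)
        strong = [i for i in table if i.evidence == "strong"]
        assert len(strong) == truth.strong_edge_count
        assert len(filter_interactions(table, "strong")) == len(strong)


class TestIntersectSets:
    def test_fixture_all_four(self, packaged_targets):
        rep = intersect_sets(packaged_targets.as_dict())
        assert rep.intersection("up", "down", "sn", "putamen") == {
            "CCND1", "FOXO3", "SIRT1",
        }

    def test_fixture_sn_putamen(self, packaged_targets):
        rep = intersect_sets(packaged_targets.as_dict())
        assert rep.intersection("sn", "putamen") == {
            "BCL2", "CCND1", "FOXO3", "MYC", "SIRT1",
        }

    def test_fixture_counts_partition_the_union(self, packaged_targets):
        rep = intersect_sets(packaged_targets.as_dict())
        assert sum(rep.bar_counts.values()) == rep.union_size == 135

    def test_disjoint_sets(self):
        rep = intersect_sets({"a": {"X"}, "b": {"Y", "Z"}})
        assert rep.intersection("a", "b") == set()
        assert rep.bar_counts == {("a",): 1, ("b",): 2}

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            intersect_sets([("a", {"X"}), ("a", {"Y"})])

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            intersect_sets({"a": {"X"}})

    @given(st.integers(0, 30))
    def test_patterns_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(15)]
        names = ["s1", "s2", "s3", "s4", "s5"][: int(rng.integers(2, 6))]
        sets = {n: set(rng.choice(genes, size=int(rng.integers(0, 10)))) for n in names}
        rep = intersect_sets(sets)
        union = set().union(*sets.values())
        # brute force over all membership patterns
        expected = {}
        for r in range(1, len(names) + 1):
            for combo in itertools.combinations(names, r):
                inside = set.intersection(*(sets[n] for n in combo)) if combo else union
                outside = set().union(*(sets[n] for n in names if n not in combo), set())
                exact = inside - outside
                if exact:
                    expected[tuple(combo)] = len(exact)
        assert rep.bar_counts == expected
        assert sum(rep.bar_counts.values()) == len(union)
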