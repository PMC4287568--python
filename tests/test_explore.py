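"""The exploration driver: exhaustive/sampled scoring and summaries."""
import numpy as np
import pandas as pd
import pytest

from treealign import (
    GuideTree,
    SequenceRecord,
    SimulationConfig,
    compare_strategies,
    count_distinct_labelings,
    count_labeled_trees,
    enumerate_labeled_trees,
    enumerate_shapes,
    exhaustive_exploration,
    find_best,
    min_rf_to,
    sample_exploration,
    simulate_family,
    summarize_by_shape,
)
from treealign.explore import ExplorationError, ScoreTable
from treealign.scoring import NoCoreColumnsError


@pytest.fixture(scope="module")
def small_family():
    return simulate_family(SimulationConfig(
        n_sequences=4, root_length=60, branch_length_mean=0.5,
        indel_rate=0.08, seed=13,
    ))


@pytest.fixture(scope="module")
def small_table(small_family):
    return exhaustive_exploration(small_family)


class TestExhaustiveExploration:
    def test_record_count_is_double_factorial(self, small_table):
        assert len(small_table) == count_labeled_trees(4) == 15

    @pytest.mark.parametrize("n", [5, 6])
    def test_record_counts_for_larger_n(self, n):
        fam = simulate_family(SimulationConfig(
            n_sequences=n, root_length=40, branch_length_mean=0.3, seed=n,
        ))
        table = exhaustive_exploration(fam)
        assert len(table) == count_labeled_trees(n)
        assert table.records["tc"].between(0, 1).all()
        assert table.records["sp"].between(0, 1).all()

    def test_identical_sequences_score_identically_everywhere(self):
        recs = [SequenceRecord(f"s{i}", "MKVAWEQRNDLI") for i in range(4)]
        from treealign import ProteinFamily, ReferenceAlignment
        from treealign.aligner import Profile

        ref = ReferenceAlignment.from_profile(
            Profile([(r.id, r.residues) for r in recs]))
        fam = ProteinFamily(name="const", sequences=recs, reference=ref)
        table = exhaustive_exploration(fam)
        assert table.records["tc"].nunique() == 1

    def test_no_core_columns_flagged(self):
        from treealign import ProteinFamily, ReferenceAlignment
        from treealign.aligner import Profile

        aln = Profile([("a", "MK-"), ("b", "-KV")])
        fam = ProteinFamily(
            name="hollow",
            sequences=[SequenceRecord("a", "MK"), SequenceRecord("b", "KV")],
            reference=ReferenceAlignment(alignment=aln,
                                         core_mask=np.zeros(3, dtype=bool)),
        )
        with pytest.raises(NoCoreColumnsError):
            exhaustive_exploration(fam)

    def test_checkpoint_resume_no_duplicates(self, small_family, tmp_path):
        ck = tmp_path / "ck.tsv"
        full = exhaustive_exploration(small_family, checkpoint=ck)
        resumed = exhaustive_exploration(small_family, checkpoint=ck)
        assert len(full) == len(resumed) == 15
        assert sorted(full.records["tree"]) == sorted(resumed.records["tree"])


class TestFindBest:
    def test_count_of_tied_optima(self, small_table):
        best_tc, best_trees, count = find_best(small_table)
        assert best_tc == small_table.records["tc"].max()
        assert count == len(best_trees)
        assert count == int((small_table.records["tc"] == best_tc).sum())

    def test_all_equal_table_counts_everything(self):
        records = pd.DataFrame({
            "tree": [f"t{i};" for i in range(15)],
            "shape_id": 0, "tc": 0.7, "sp": 0.8,
        })
        table = ScoreTable(family="x", records=records)
        assert find_best(table)[2] == 15

    def test_injective_scores_give_unique_best(self):
        records = pd.DataFrame({
            "tree": [f"t{i};" for i in range(10)],
            "shape_id": 0, "tc": np.linspace(0, 0.9, 10), "sp": 0.5,
        })
        assert find_best(ScoreTable(family="x", records=records))[2] == 1


class TestMinRF:
    def test_reference_in_best_set_gives_zero(self, small_family, small_table):
        _, best_trees, _ = find_best(small_table)
        some_best = sorted(best_trees)[0]
        from treealign.io import parse_newick

        assert min_rf_to(best_trees, parse_newick(some_best)) == 0

    def test_all_trees_include_reference(self, small_family):
        all_trees = list(enumerate_labeled_trees(small_family.ids))
        assert min_rf_to(all_trees, small_family.true_tree) == 0

    def test_maximally_distant_best_set(self):
        from treealign import chained_tree_from_order, rooted_rf_distance

        cat = chained_tree_from_order("12345678")
        far = GuideTree.from_nested(
            ((("1", "5"), ("2", "6")), (("3", "7"), ("4", "8"))))
        assert rooted_rf_distance(cat, far) == 12
        assert min_rf_to([far, far.copy()], cat) == 12


class TestSummarizeByShape:
    def test_one_row_per_shape_sorted_by_imbalance(self, small_table):
        summary = summarize_by_shape(small_table)
        assert len(summary) == len(enumerate_shapes(4)) == 2
        assert summary["colless"].is_monotonic_increasing
        assert summary.iloc[-1]["n_trees"] == 12  # chained shape

    def test_constant_scores_collapse_quantiles(self):
        records = pd.DataFrame({
            "tree": ["((a,b),(c,d));", "(((a,b),c),d);"],
            "shape_id": [0, 1], "tc": 0.6, "sp": 0.6,
        })
        summary = summarize_by_shape(ScoreTable(family="x", records=records))
        assert (summary["tc_min"] == summary["tc_median"]).all()
        assert (summary["tc_median"] == summary["tc_max"]).all()

    def test_quartiles_match_percentile_oracle(self, small_table):
        summary = summarize_by_shape(small_table)
        for _, row in summary.iterrows():
            group = small_table.records.loc[
                small_table.records["shape_id"] == row["shape_id"], "tc"
            ].to_numpy()
            assert row["tc_q1"] == pytest.approx(np.percentile(group, 25))
            assert row["tc_q3"] == pytest.approx(np.percentile(group, 75))

    def test_weighted_shape_means_recover_global_mean(self, small_table):
        summary = summarize_by_shape(small_table)
        weighted = (summary["tc_mean"] * summary["n_trees"]).sum()
        weighted /= summary["n_trees"].sum()
        assert weighted == pytest.approx(small_table.records["tc"].mean())


class TestSampleExploration:
    def test_full_coverage_equals_exhaustive(self):
        fam = simulate_family(SimulationConfig(
            n_sequences=5, root_length=50, branch_length_mean=0.4, seed=21,
        ))
        exhaustive = exhaustive_exploration(fam)
        max_labelings = max(count_distinct_labelings(s)
                            for s in enumerate_shapes(5))
        with pytest.warns(UserWarning):
            sampled = sample_exploration(fam, labelings_per_shape=max_labelings,
                                         seed=4)
        assert set(sampled.records["tree"]) == set(exhaustive.records["tree"])
        merged = sampled.records.merge(exhaustive.records, on="tree")
        assert (merged["tc_x"] == merged["tc_y"]).all()

    def test_same_seed_reproducible(self, small_family):
        t1 = sample_exploration(small_family, labelings_per_shape=3, seed=7)
        t2 = sample_exploration(small_family, labelings_per_shape=3, seed=7)
        assert t1.records.equals(t2.records)

    def test_shape_size_mismatch_rejected(self, small_family):
        with pytest.raises(ExplorationError):
            sample_exploration(small_family, shapes=enumerate_shapes(5),
                               labelings_per_shape=2)


class TestCompareStrategies:
    def test_true_tree_perfect_on_easy_families(self):
        fams = [simulate_family(SimulationConfig(
            n_sequences=5, root_length=60, branch_length_mean=0.02,
            indel_rate=0.0, seed=s)) for s in (31, 32)]
        summary, detail = compare_strategies(fams, ["true_tree"])
        assert summary.loc[0, "mean_tc"] == 1.0

    def test_duplicate_strategy_names_give_identical_means(self, small_family):
        summary, _ = compare_strategies(
            [small_family], {"u1": lambda f, p: _upgma(f, p),
                             "u2": lambda f, p: _upgma(f, p)})
        assert summary["mean_tc"].nunique() == 1

    def test_failing_strategy_recorded_as_missing(self, small_family):
        fam = small_family
        fam2 = simulate_family(SimulationConfig(n_sequences=4, seed=77))
        fam2.true_tree = None
        with pytest.warns(UserWarning):
            summary, detail = compare_strategies([fam, fam2],
                                                 ["upgma", "true_tree"])
        missing = detail[(detail["family"] == fam2.name)
                         & (detail["strategy"] == "true_tree")]
        assert missing["tc"].isna().all()
        row = summary[summary["strategy"] == "true_tree"].iloc[0]
        assert row["n_families"] == 1

    def test_rerun_determinism_through_public_operations(self, small_family):
        from treealign import progressive_align, tc_score
        from treealign.explore import resolve_strategy
        from treealign.aligner import DEFAULT_PARAMS

        names = ["upgma", "single", "chained:len/a"]
        summary, detail = compare_strategies([small_family], names)
        for name in names:
            tree = resolve_strategy(name)(small_family, DEFAULT_PARAMS)
            aln = progressive_align(small_family, tree)
            expected = tc_score(aln, small_family.reference)
            got = detail[(detail["strategy"] == name)]["tc"].iloc[0]
            assert got == expected


def _upgma(family, params):
    from treealign import build_distance_matrix, cluster_guide_tree

    return cluster_guide_tree(
        build_distance_matrix(family, method="aligned_identity", params=params),
        "upgma",
    )
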