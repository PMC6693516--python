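"""Gene-level transformation scoring: change sets, TS, ranks, bootstraps."""

import numpy as np
import pandas as pd
import pytest

from ctxmetanet.expression_states import DE_COLUMNS, discretize_states
from ctxmetanet.imat import IMATParams, imat_solve, map_states_to_reactions, reference_flux
from ctxmetanet.mta import (
    MTAParams,
    MTARunResult,
    TargetChangeSets,
    aggregate_scores,
    bootstrap_gene_sets,
    bootstrap_runs,
    derive_change_sets,
    mta_all_genes,
    mta_run_set,
    mta_score_knockout,
    overall_score,
    rank_normalize,
    remove_genes,
)


@pytest.fixture(scope="module")
def source_state(scenario):
    """Oracle-verified source context (MYb71@L4): branch A active."""
    model = scenario.model
    de = scenario.de_tables["transcriptome"]
    states = discretize_states(de, scenario.design)
    sets = map_states_to_reactions(model, states.context_slice("MYb71", "L4"))
    net = imat_solve(model, sets, context="MYb71@L4")
    v_ref = reference_flux(model, net, sets)
    return de, v_ref


@pytest.fixture(scope="module")
def change(scenario, source_state):
    de, v_ref = source_state
    return derive_change_sets(
        de, ("MYb71", "L4"), ("OP50", "L4"), scenario.model, v_ref
    )


class TestDeriveChangeSets:
    def test_diamond_scenario_partition(self, change):
        assert change.r_forward_up == {"R_b1", "R_b2"}
        assert change.r_forward_down == {"R_a1", "R_a2"}
        assert "R_amb" in change.r_steady  # gX is not differential
        assert change.r_steady == frozenset(
            ["EX_up", "R_join", "R_sec", "R_amb"]
        )

    def test_no_significant_genes_all_steady(self, scenario, source_state):
        de, v_ref = source_state
        null_de = de.assign(padj=0.9)
        sets = derive_change_sets(
            null_de, ("MYb71", "L4"), ("OP50", "L4"), scenario.model, v_ref
        )
        assert sets.n_forward == 0
        assert sets.r_steady == frozenset(scenario.model.reaction_ids())

    def test_conflicting_marks_go_steady(self, scenario, source_state):
        """A reaction touched by one up-gene and one down-gene is held
        steady (the diamond's cross reaction under gX/gB conflict)."""
        de, v_ref = source_state
        rows = pd.DataFrame(
            [
                ("gX", "OP50@L4", "MYb71@L4", 2.0, 0.001),
                ("gB", "OP50@L4", "MYb71@L4", 2.0, 0.001),
            ],
            columns=DE_COLUMNS,
        )
        # make gX both up (its own row) and force a conflict on R_amb by
        # planting a second model with R_amb gated by "gX and gA" instead:
        # simpler here — mark gX up and gA down; R_amb depends only on gX
        rows2 = pd.DataFrame(
            [("gA", "OP50@L4", "MYb71@L4", -2.0, 0.001)], columns=DE_COLUMNS
        )
        de2 = pd.concat([rows, rows2], ignore_index=True)
        sets = derive_change_sets(
            de2, ("MYb71", "L4"), ("OP50", "L4"), scenario.model, v_ref
        )
        # gX up marks R_amb up; no conflict there, so it must be in up
        assert "R_amb" in sets.r_forward_up
        # but a gene marked both up and down on the same reaction conflicts:
        de3 = pd.concat(
            [
                de2,
                pd.DataFrame(
                    [("gX", "MYb71@L4", "OP50@L4", 2.0, 0.001)],
                    columns=DE_COLUMNS,
                ),
            ],
            ignore_index=True,
        )
        sets3 = derive_change_sets(
            de3, ("MYb71", "L4"), ("OP50", "L4"), scenario.model, v_ref
        )
        assert "R_amb" in sets3.r_steady

    def test_low_reference_down_marks_dropped(self, scenario, source_state):
        """Down-marked reactions already below epsilon_change stay steady
        (branch B carries no reference flux)."""
        de, v_ref = source_state
        sets = derive_change_sets(
            de, ("MYb71", "L4"), ("OP50", "L4"), scenario.model, v_ref,
            epsilon_change=2.0,  # above the reference flux of 1
        )
        assert sets.r_forward_down == frozenset()

    def test_missing_comparison_raises(self, scenario, source_state):
        de, v_ref = source_state
        with pytest.raises(KeyError):
            derive_change_sets(
                de, ("MYb71", "L2"), ("OP50", "L2"), scenario.model, v_ref
            )


class TestScoreKnockout:
    def test_null_knockout_scores_zero(self, scenario, source_state, change):
        _, v_ref = source_state
        ts_null = mta_score_knockout(scenario.model, v_ref, change, set())
        assert ts_null == pytest.approx(0.0, abs=1e-9)

    def test_mediator_beats_null(self, scenario, source_state, change):
        _, v_ref = source_state
        ts = mta_score_knockout(
            scenario.model, v_ref, change, {"R_a1", "R_a2"}
        )
        assert ts == pytest.approx(1.0, abs=1e-6)  # full reroute, no drift

    def test_join_knockout_penalized(self, scenario, source_state, change):
        """Blocking the join kills throughput: both down-changes succeed
        but the steady set deviates, giving 0.5 - 3/4 = -0.25."""
        _, v_ref = source_state
        ts = mta_score_knockout(scenario.model, v_ref, change, {"R_join"})
        assert ts == pytest.approx(0.5 - 0.75, abs=1e-6)

    def test_steady_zero_blocked_reactions_score_null(
        self, scenario, source_state, change
    ):
        """Blocking only a steady reaction with zero reference flux
        changes nothing (the gX knockout case)."""
        _, v_ref = source_state
        ts = mta_score_knockout(scenario.model, v_ref, change, {"R_amb"})
        assert ts == pytest.approx(0.0, abs=1e-9)

    def test_optimistic_policy_never_beats_null(
        self, scenario, source_state, change
    ):
        """The best-case two-stage score is maximal for the null knockout
        (blocking can only shrink the polytope)."""
        _, v_ref = source_state
        params = MTAParams(policy="optimistic")
        ts_null = mta_score_knockout(
            scenario.model, v_ref, change, set(), params
        )
        for blocked in [{"R_a1", "R_a2"}, {"R_join"}, {"R_b1", "R_b2"}]:
            ts = mta_score_knockout(
                scenario.model, v_ref, change, blocked, params
            )
            assert ts <= ts_null + 1e-9

    def test_unknown_blocked_reaction_raises(
        self, scenario, source_state, change
    ):
        _, v_ref = source_state
        with pytest.raises(KeyError):
            mta_score_knockout(scenario.model, v_ref, change, {"ghost"})


class TestAllGenes:
    def test_mediator_has_maximal_score(self, scenario, source_state, change):
        _, v_ref = source_state
        run = mta_all_genes(scenario.model, v_ref, change)
        assert set(run.scores) == set(scenario.model.genes)
        assert max(run.scores, key=run.scores.get) == "gA"

    def test_orphan_gene_scores_threshold(self, scenario, source_state, change):
        _, v_ref = source_state
        run = mta_all_genes(scenario.model, v_ref, change)
        assert run.scores["gU"] == run.threshold

    def test_identical_blocked_sets_identical_scores(
        self, scenario, source_state, change
    ):
        _, v_ref = source_state
        run = mta_all_genes(scenario.model, v_ref, change)
        # gU and gX both leave the reference state untouched
        assert run.scores["gU"] == run.scores["gX"]


class TestRankNormalize:
    def test_formula_forced_example(self):
        run = MTARunResult(scores={"a": 5, "b": 3, "c": 1}, threshold=2)
        assert rank_normalize(run) == {"a": 1.0, "b": 0.5, "c": 0.0}

    def test_all_below_threshold_all_zero(self):
        run = MTARunResult(scores={"a": 1, "b": 0}, threshold=2)
        assert rank_normalize(run) == {"a": 0.0, "b": 0.0}

    def test_average_rank_for_ties(self):
        run = MTARunResult(scores={"a": 4, "b": 4, "c": 3}, threshold=0)
        out = rank_normalize(run)
        assert out["a"] == pytest.approx(2.5 / 3)
        assert out["b"] == pytest.approx(2.5 / 3)
        assert out["c"] == pytest.approx(1 / 3)

    def test_outputs_in_unit_interval_and_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = {f"g{i}": float(rng.normal()) for i in range(15)}
            thr = float(rng.normal(scale=0.5))
            out = rank_normalize(MTARunResult(scores=scores, threshold=thr))
            assert all(0.0 <= v <= 1.0 for v in out.values())
            for g1, v1 in scores.items():
                for g2, v2 in scores.items():
                    if v1 > v2 and out[g2] > 0:
                        assert out[g1] >= out[g2]
            for g, v in scores.items():
                if v <= thr:
                    assert out[g] == 0.0


class TestAggregation:
    def test_single_run_identity_up_to_rescaling(self):
        run = {"a": 0.5, "b": 1.0, "c": 0.0}
        assert aggregate_scores([run]) == {"a": 0.5, "b": 1.0, "c": 0.0}

    def test_consistent_top_gene_stays_at_one(self):
        runs = [{"a": 1.0, "b": 0.2}, {"a": 1.0, "b": 0.6}]
        assert aggregate_scores(runs)["a"] == 1.0

    def test_all_zero_gene_stays_zero(self):
        runs = [{"a": 1.0, "b": 0.0}, {"a": 0.5, "b": 0.0}]
        assert aggregate_scores(runs)["b"] == 0.0


class TestOverall:
    def test_forward_minus_reverse_arithmetic(self):
        fwd = {"t": {"g": 0.8}, "p": {"g": 0.6}}
        rev = {"t": {"g": 0.1}, "p": {"g": 0.0}}
        assert overall_score(fwd, rev)["g"] == pytest.approx(1.3)

    def test_antisymmetry_under_direction_swap(self):
        rng = np.random.default_rng(1)
        fwd = {"t": {f"g{i}": float(rng.random()) for i in range(10)}}
        rev = {"t": {f"g{i}": float(rng.random()) for i in range(10)}}
        o1 = overall_score(fwd, rev)
        o2 = overall_score(rev, fwd)
        assert all(o1[g] == -o2[g] for g in o1)

    def test_gene_absent_from_all_maps_scores_zero(self):
        out = overall_score({"t": {"a": 1.0}}, {"t": {"b": 0.3}})
        assert out["a"] == 1.0 and out["b"] == -0.3


class TestBootstraps:
    def test_removed_gene_sets_deterministic_and_sized(self, scenario):
        de = scenario.de_tables["transcriptome"]
        params = MTAParams()
        sets1 = bootstrap_gene_sets(de, params, seed=3)
        sets2 = bootstrap_gene_sets(de, params, seed=3)
        assert sets1 == sets2
        n_genes = de["gene"].nunique()
        expected = max(1, int(round(params.bootstrap_fraction * n_genes)))
        assert all(len(s) == expected for s in sets1)

    def test_ten_percent_of_hundred_genes_removes_ten(self):
        de = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(100)],
                "side_a": "MYb71@L4",
                "side_b": "OP50@L4",
                "log2fc": 0.0,
                "padj": 1.0,
            }
        )
        sets = bootstrap_gene_sets(de, MTAParams(), seed=0)
        assert all(len(s) == 10 for s in sets)

    def test_removing_irrelevant_genes_leaves_scores_unchanged(
        self, scenario
    ):
        """Dropping genes outside all GPRs and without significant rows
        does not move any transformation score."""
        de = scenario.de_tables["transcriptome"]
        model, design = scenario.model, scenario.design
        full = bootstrap_runs(
            model, de, design, ("MYb71", "L4"), ("OP50", "L4"),
            include_full=True, seed=0,
        )[0]
        pruned_de = remove_genes(de, {"gU"})
        pruned = bootstrap_runs(
            model, pruned_de, design, ("MYb71", "L4"), ("OP50", "L4"),
            include_full=True, seed=0,
        )[0]
        assert full.scores == pruned.scores

    def test_run_count_and_labels(self, scenario):
        de = scenario.de_tables["transcriptome"]
        runs = bootstrap_runs(
            scenario.model, de, scenario.design,
            ("MYb71", "L4"), ("OP50", "L4"), seed=1,
        )
        assert len(runs) == 1 + MTAParams().bootstrap_runs
        assert runs[0].metadata["bootstrap"] == 0
        assert [r.metadata["bootstrap"] for r in runs[1:]] == [1, 2, 3, 4, 5]


class TestMediatorRecovery:
    def test_planted_mediator_ranks_first_overall(self, scenario):
        model = scenario.model
        de = scenario.de_tables["transcriptome"]
        fwd, _ = mta_run_set(model, de, scenario.design, "forward", seed=11)
        rev, _ = mta_run_set(model, de, scenario.design, "reverse", seed=12)
        overall = overall_score({"t": fwd}, {"t": rev})
        assert max(overall, key=overall.get) == "gA"
        assert min(overall, key=overall.get) == "gB"

    def test_gene_order_invariance(self, scenario, source_state, change):
        """Scores do not depend on gene enumeration order."""
        _, v_ref = source_state
        model = scenario.model
        run1 = mta_all_genes(model, v_ref, change)
        from ctxmetanet.model_core import MetabolicModel

        reordered = MetabolicModel(
            model.metabolites, model.reactions, list(reversed(model.genes)),
            id=model.id,
        )
        run2 = mta_all_genes(reordered, v_ref, change)
        assert run1.scores == run2.scores
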