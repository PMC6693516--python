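"""Toy-model construction, DE-table simulation, and planted-truth checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog
from scipy.stats import binom

from ctxmetanet.model_core import OFF, ON, UNKNOWN
from ctxmetanet.synthetic_data import (
    DEFAULT_DESIGN,
    PlantedTruth,
    StudyDesign,
    SyntheticBundle,
    make_bundle,
    make_fold_change_matrix,
    make_planted_truth,
    make_toy_model,
    plant_transformation_scenario,
    simulate_de_tables,
)


class TestStudyDesign:
    def test_defaults_match_study_layout(self):
        d = DEFAULT_DESIGN
        assert d.conditions == ("OP50", "MYb71", "MYb237")
        assert d.timepoint_labels == ("L2", "L3", "L4", "Ad1", "Ad3", "Ad7")
        assert dict(d.timepoints)["Ad7"] == 216.0
        assert d.replicates == 3

    def test_comparison_count_formula(self):
        # (|C| choose 2) * |T|  +  |C| * (|T| - 1) comparisons per gene
        d = DEFAULT_DESIGN
        n_cond, n_tp = len(d.conditions), len(d.timepoints)
        expected = n_cond * (n_cond - 1) // 2 * n_tp + n_cond * (n_tp - 1)
        assert len(d.comparisons()) == expected == 33

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"conditions": ("OP50",)},
            {"timepoints": (("L2", 6.0),)},
            {"replicates": 1},
        ],
    )
    def test_degenerate_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StudyDesign(**kwargs)


class TestToyModels:
    def test_diamond_is_fixed_and_seed_independent(self, diamond):
        again = make_toy_model("diamond", seed=123)
        assert [r.id for r in again.reactions] == [r.id for r in diamond.reactions]
        assert len(diamond.reactions) == 8
        assert len(diamond.metabolites) == 5
        assert len(diamond.genes) == 6

    def test_toy_models_validate_and_have_structure(self):
        for variant in ("diamond", "two_pathway", "random"):
            m = make_toy_model(variant, size=12, seed=3)
            m.validate()
            assert len({r.subsystem for r in m.reactions}) >= 2
            exchanges = [r for r in m.reactions if r.is_exchange]
            assert any(sum(r.stoichiometry.values()) > 0 for r in exchanges)
            assert any(sum(r.stoichiometry.values()) < 0 for r in exchanges)
            internal = [r for r in m.reactions if not r.is_exchange]
            assert all(not r.gpr.is_empty() for r in internal)

    def test_random_model_deterministic_under_seed(self):
        a = make_toy_model("random", 20, seed=1)
        b = make_toy_model("random", 20, seed=1)
        assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
        assert all(
            ra.gpr.to_string() == rb.gpr.to_string()
            for ra, rb in zip(a.reactions, b.reactions)
        )

    def test_random_model_reactions_can_all_carry_flux(self):
        """LP oracle: every internal reaction admits nonzero steady flux."""
        m = make_toy_model("random", 20, seed=1)
        S = m.stoichiometric_matrix()
        for j, rxn in enumerate(m.reactions):
            if rxn.is_exchange:
                continue
            c = np.zeros(len(m.reactions))
            c[j] = -1.0  # maximize v_j
            res = linprog(
                c,
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=[(r.lower_bound, r.upper_bound) for r in m.reactions],
                method="highs",
            )
            assert res.status == 0
            assert -res.fun > 1e-6, f"{rxn.id} cannot carry flux"

    def test_size_guard(self):
        with pytest.raises(ValueError):
            make_toy_model("random", size=3)


class TestSimulateDETables:
    def test_every_required_comparison_emitted_once_per_gene(self):
        truth = make_planted_truth([f"g{i}" for i in range(10)], seed=0)
        de = simulate_de_tables(DEFAULT_DESIGN, truth, seed=1)
        per_gene = de.groupby("gene").size()
        assert (per_gene == len(DEFAULT_DESIGN.comparisons())).all()
        assert not de.duplicated(["gene", "side_a", "side_b"]).any()

    def test_determinism_under_seed(self):
        truth = make_planted_truth([f"g{i}" for i in range(10)], seed=0)
        a = simulate_de_tables(DEFAULT_DESIGN, truth, seed=5)
        b = simulate_de_tables(DEFAULT_DESIGN, truth, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_difference_yields_significant_signed_rows(self):
        """An ON-vs-OFF comparison at effect 3, noise 0.3 is called
        significant with the right sign in >= 99% of draws."""
        design = StudyDesign(
            conditions=("OP50", "MYb71"),
            timepoints=(("L4", 48.0), ("Ad1", 72.0)),
        )
        genes = [f"g{i}" for i in range(2000)]
        states = {}
        for g in genes:  # ON in MYb71, OFF in OP50, at every timepoint
            for t in design.timepoint_labels:
                states[(g, "MYb71", t)] = ON
                states[(g, "OP50", t)] = OFF
        truth = PlantedTruth(genes=genes, gene_states=states)
        de = simulate_de_tables(design, truth, seed=2)
        cross = de[de["side_a"] == "MYb71@L4"]
        ok = (cross["padj"] < 0.05) & (cross["log2fc"] > 0)
        assert ok.mean() >= 0.99

    def test_all_unknown_truth_gives_false_positive_rate(self):
        genes = [f"g{i}" for i in range(300)]
        truth = PlantedTruth(genes=genes, gene_states={})
        de = simulate_de_tables(DEFAULT_DESIGN, truth, seed=3)
        n = len(de)
        hits = int((de["padj"] < 0.05).sum())
        lo, hi = binom.ppf([0.0005, 0.9995], n, truth.false_positive_rate)
        assert lo <= hits <= hi

    def test_sign_points_toward_the_on_side(self):
        design = StudyDesign(
            conditions=("OP50", "MYb71"),
            timepoints=(("L4", 48.0), ("Ad1", 72.0)),
        )
        states = {}
        for t in design.timepoint_labels:  # OFF in MYb71, ON in OP50
            states[("g0", "MYb71", t)] = OFF
            states[("g0", "OP50", t)] = ON
        truth = PlantedTruth(genes=["g0"], gene_states=states)
        de = simulate_de_tables(design, truth, seed=4)
        cross = de[(de["side_a"] == "MYb71@L4") & (de["side_b"] == "OP50@L4")]
        assert (cross["log2fc"] < 0).all()


class TestBundles:
    def test_bundle_model_validates_and_regeneration_is_identical(self):
        b1 = make_bundle(seed=9)
        b2 = make_bundle(seed=9)
        b1.model.validate()
        pd.testing.assert_frame_equal(
            b1.de_tables["transcriptome"], b2.de_tables["transcriptome"]
        )
        assert b1.truth.gene_states == b2.truth.gene_states

    def test_bundle_round_trips_through_disk(self, tmp_path, scenario):
        scenario.write(tmp_path / "bundle")
        back = SyntheticBundle.read(tmp_path / "bundle")
        assert back.design == scenario.design
        assert back.truth.gene_states == scenario.truth.gene_states
        assert back.truth.mediator_genes == ["gA"]
        pd.testing.assert_frame_equal(
            back.de_tables["transcriptome"],
            scenario.de_tables["transcriptome"],
        )

    def test_scenario_plants_branch_states(self, scenario):
        t = scenario.truth
        assert t.state("gA", "MYb71", "L4") == ON
        assert t.state("gA", "OP50", "L4") == OFF
        assert t.state("gB", "MYb71", "L4") == OFF
        assert t.state("gB", "OP50", "L4") == ON
        assert t.state("gU", "OP50", "L4") == UNKNOWN

    def test_knockout_of_mediator_leaves_feasible_secretion(self, scenario):
        """LP oracle: with branch A blocked the diamond still secretes."""
        m = scenario.model
        S = m.stoichiometric_matrix()
        bounds = []
        for r in m.reactions:
            if r.id in ("R_a1", "R_a2"):
                bounds.append((0.0, 0.0))
            elif r.id == "R_sec":
                bounds.append((1.0, r.upper_bound))  # demand secretion
            else:
                bounds.append((r.lower_bound, r.upper_bound))
        res = linprog(
            np.zeros(len(m.reactions)),
            A_eq=S,
            b_eq=np.zeros(S.shape[0]),
            bounds=bounds,
            method="highs",
        )
        assert res.status == 0


class TestFoldChangeMatrix:
    def test_shape_labels_and_determinism(self):
        fc, assign = make_fold_change_matrix(seed=2)
        assert fc.shape == (400, 12)
        assert set(assign.values()) == set(range(1, 9))
        fc2, _ = make_fold_change_matrix(seed=2)
        pd.testing.assert_frame_equal(fc, fc2)

    def test_cluster_centres_are_separated(self):
        fc, assign = make_fold_change_matrix(seed=0)
        means = {
            k: fc.loc[[g for g, a in assign.items() if a == k]].mean(axis=0)
            for k in range(1, 9)
        }
        for i in range(1, 9):
            for j in range(i + 1, 9):
                dist = np.linalg.norm(means[i] - means[j])
                assert dist > 5 * 0.3  # >= 5 noise SDs apart
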