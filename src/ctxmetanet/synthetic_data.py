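"""Synthetic study generator with planted ground truth.

Emulates the structure of a host-microbiota colonization study: three
bacterial conditions (an *E. coli* OP50 control plus the two *Ochrobactrum*
isolates MYb71 and MYb237) sampled at six time points spanning larval
development and adult life, with 2-3 replicates per cell.  The generator
does not simulate reads or counts; it emits the differential-expression
summary statistics (log2 fold-change, FDR-adjusted p-value) that the
downstream pipeline consumes, with planted per-context gene activity
states, planted fold-change cluster structure, and a planted metabolic
"mediator" gene whose knockout reroutes a toy network from one dietary
state to the other.

Planted activity patterns differ between conditions (and may invert once
along the time axis), mirroring the kinds of state changes the
discretization step is built to detect; genes whose state never differs
between the two sides of any comparison are indistinguishable from
unknowns at the summary-statistic level and are planted as UNKNOWN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import json

import numpy as np
import pandas as pd

from .model_core import (
    EMPTY_GPR,
    OFF,
    ON,
    UNKNOWN,
    MetabolicModel,
    Metabolite,
    Reaction,
    load_model,
    parse_gpr,
    save_model_json,
)

__all__ = [
    "StudyDesign",
    "PlantedTruth",
    "SyntheticBundle",
    "DEFAULT_DESIGN",
    "make_toy_model",
    "make_planted_truth",
    "simulate_de_tables",
    "make_fold_change_matrix",
    "make_bundle",
    "plant_transformation_scenario",
]

DE_COLUMNS = ["gene", "side_a", "side_b", "log2fc", "padj"]

_STATE_NAMES = {ON: "ON", OFF: "OFF", UNKNOWN: "UNKNOWN"}
_STATE_VALUES = {v: k for k, v in _STATE_NAMES.items()}


@dataclass(frozen=True)
class StudyDesign:
    """Factorial design: bacterial conditions x developmental time points."""

    conditions: tuple[str, ...] = ("OP50", "MYb71", "MYb237")
    timepoints: tuple[tuple[str, float], ...] = (
        ("L2", 6.0),
        ("L3", 24.0),
        ("L4", 48.0),
        ("Ad1", 72.0),
        ("Ad3", 120.0),
        ("Ad7", 216.0),
    )
    replicates: int = 3

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")

    @property
    def timepoint_labels(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.timepoints)

    def contexts(self) -> list[tuple[str, str]]:
        """All (condition, timepoint label) cells, row-major by condition."""
        return [
            (c, t) for c in self.conditions for t in self.timepoint_labels
        ]

    def comparisons(self) -> list[tuple[tuple[str, str], tuple[str, str]]]:
        """All (side_a, side_b) context pairs the DE tables must cover.

        Cross-condition pairs at each time point (side_a is the condition
        listed later, so *Ochrobactrum* vs the OP50 control has its
        conventional orientation) plus adjacent-timepoint pairs within each
        condition (side_a is the later time point).
        """
        out: list[tuple[tuple[str, str], tuple[str, str]]] = []
        for t in self.timepoint_labels:
            for c1, c2 in combinations(self.conditions, 2):
                out.append(((c2, t), (c1, t)))
        labels = self.timepoint_labels
        for c in self.conditions:
            for t1, t2 in zip(labels, labels[1:]):
                out.append(((c, t2), (c, t1)))
        return out


DEFAULT_DESIGN = StudyDesign()


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic bundle."""

    genes: list[str]
    gene_states: dict[tuple[str, str, str], int]
    cluster_assignment: dict[str, int] = field(default_factory=dict)
    mediator_genes: list[str] = field(default_factory=list)
    effect_size: float = 3.0
    noise_sd: float = 0.3
    false_positive_rate: float = 0.01

    def state(self, gene: str, condition: str, timepoint: str) -> int:
        return self.gene_states.get((gene, condition, timepoint), UNKNOWN)


@dataclass
class SyntheticBundle:
    model: MetabolicModel
    design: StudyDesign
    de_tables: dict[str, pd.DataFrame]
    truth: PlantedTruth
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_model_json(self.model, outdir / "model.json")
        for layer, table in self.de_tables.items():
            table.to_csv(outdir / f"de_{layer}.tsv", sep="\t", index=False)
        truth = {
            "genes": self.truth.genes,
            "gene_states": [
                [g, c, t, _STATE_NAMES[s]]
                for (g, c, t), s in sorted(self.truth.gene_states.items())
            ],
            "cluster_assignment": self.truth.cluster_assignment,
            "mediator_genes": self.truth.mediator_genes,
            "effect_size": self.truth.effect_size,
            "noise_sd": self.truth.noise_sd,
            "false_positive_rate": self.truth.false_positive_rate,
            "design": {
                "conditions": list(self.design.conditions),
                "timepoints": [list(t) for t in self.design.timepoints],
                "replicates": self.design.replicates,
            },
            "seed": self.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))

    @classmethod
    def read(cls, outdir: str | Path) -> "SyntheticBundle":
        outdir = Path(outdir)
        meta = json.loads((outdir / "truth.json").read_text())
        design = StudyDesign(
            conditions=tuple(meta["design"]["conditions"]),
            timepoints=tuple(
                (str(lbl), float(h)) for lbl, h in meta["design"]["timepoints"]
            ),
            replicates=int(meta["design"]["replicates"]),
        )
        truth = PlantedTruth(
            genes=list(meta["genes"]),
            gene_states={
                (g, c, t): _STATE_VALUES[s]
                for g, c, t, s in meta["gene_states"]
            },
            cluster_assignment={
                g: int(k) for g, k in meta["cluster_assignment"].items()
            },
            mediator_genes=list(meta["mediator_genes"]),
            effect_size=float(meta["effect_size"]),
            noise_sd=float(meta["noise_sd"]),
            false_positive_rate=float(meta["false_positive_rate"]),
        )
        de_tables = {
            p.stem[3:]: pd.read_csv(p, sep="\t")
            for p in sorted(outdir.glob("de_*.tsv"))
        }
        model = load_model(outdir / "model.json", "json")
        return cls(
            model=model,
            design=design,
            de_tables=de_tables,
            truth=truth,
            seed=int(meta["seed"]),
        )


# ---------------------------------------------------------------------------
# Toy metabolic models
# ---------------------------------------------------------------------------

_BOUND = 1000.0


def _rxn(rid, stoich, gpr, subsystem, genes, lb=0.0, ub=_BOUND):
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        subsystem=subsystem,
        gpr=parse_gpr(gpr, genes) if gpr else EMPTY_GPR,
    )


def _diamond_model() -> MetabolicModel:
    """Fixed 8-reaction diamond: uptake -> branch A | branch B -> join ->
    secretion.

    Branch A is gated entirely by gene gA and branch B by gB, so knocking
    out gA blocks exactly the branch-A reactions and forces all feasible
    throughput onto branch B (and vice versa).  gX gates only the
    reversible cross reaction between the branches (zero in every
    reference state) and gU is associated with no reaction at all.
    """
    genes = ["gA", "gB", "gJ", "gS", "gU", "gX"]
    mets = [
        Metabolite("m_in"),
        Metabolite("m_a"),
        Metabolite("m_b"),
        Metabolite("m_mid"),
        Metabolite("m_out"),
    ]
    reactions = [
        _rxn("EX_up", {"m_in": 1.0}, "", "uptake", genes),
        _rxn("R_a1", {"m_in": -1.0, "m_a": 1.0}, "gA", "branch_a", genes),
        _rxn("R_a2", {"m_a": -1.0, "m_mid": 1.0}, "gA", "branch_a", genes),
        _rxn("R_b1", {"m_in": -1.0, "m_b": 1.0}, "gB", "branch_b", genes),
        _rxn("R_b2", {"m_b": -1.0, "m_mid": 1.0}, "gB", "branch_b", genes),
        _rxn("R_join", {"m_mid": -1.0, "m_out": 1.0}, "gJ", "core", genes),
        _rxn(
            "R_amb",
            {"m_a": -1.0, "m_b": 1.0},
            "gX",
            "core",
            genes,
            lb=-_BOUND,
        ),
        _rxn("R_sec", {"m_out": -1.0}, "gS", "secretion", genes),
    ]
    return MetabolicModel(
        metabolites=mets, reactions=reactions, genes=genes, id="diamond"
    )


DIAMOND_BRANCH_A = ("R_a1", "R_a2")
DIAMOND_BRANCH_B = ("R_b1", "R_b2")


def _two_pathway_model() -> MetabolicModel:
    """Two parallel three-step pathways between shared uptake and export."""
    genes = ["p1a", "p1b", "p2a", "p2b", "exp1", "exp2"]
    mets = [Metabolite(m) for m in ["m0", "m1", "m2", "m3"]]
    reactions = [
        _rxn("EX_in", {"m0": 1.0}, "", "exchange", genes),
        _rxn("P1_s1", {"m0": -1.0, "m1": 1.0}, "p1a", "pathway_1", genes),
        _rxn("P1_s2", {"m1": -1.0, "m2": 1.0}, "p1b", "pathway_1", genes),
        _rxn("P2_s1", {"m0": -1.0, "m3": 1.0}, "p2a", "pathway_2", genes),
        _rxn("P2_s2", {"m3": -1.0, "m2": 1.0}, "p2b", "pathway_2", genes),
        _rxn("EX_out", {"m2": -1.0}, "exp1 or exp2", "exchange", genes),
    ]
    return MetabolicModel(
        metabolites=mets, reactions=reactions, genes=genes, id="two_pathway"
    )


def make_toy_model(
    variant: str, size: int = 8, seed: int = 0
) -> MetabolicModel:
    """Build a toy metabolic model.

    ``diamond`` and ``two_pathway`` are fixed, seed-independent fixtures;
    ``random`` builds a connected chain-plus-shortcuts network with
    ``size`` reactions (>= 4), every internal reaction GPR-annotated and
    able to carry steady-state flux from uptake to secretion.
    """
    if variant == "diamond":
        return _diamond_model()
    if variant == "two_pathway":
        return _two_pathway_model()
    if variant != "random":
        raise ValueError(f"unknown toy-model variant {variant!r}")
    if size < 4:
        raise ValueError("random toy model needs size >= 4 reactions")

    rng = np.random.default_rng(seed)
    n_internal = size - 2
    n_chain = max(2, n_internal - n_internal // 3)
    n_extra = n_internal - n_chain
    n_genes = max(3, size // 2)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    mets = [Metabolite(f"m{i:02d}") for i in range(n_chain + 1)]

    def random_gpr() -> str:
        kind = rng.integers(0, 3)
        g1, g2 = rng.choice(n_genes, size=2, replace=False)
        if kind == 0:
            return genes[g1]
        op = "and" if kind == 1 else "or"
        return f"{genes[g1]} {op} {genes[g2]}"

    half = n_chain // 2
    reactions = [_rxn("EX_in", {mets[0].id: 1.0}, "", "exchange", genes)]
    for i in range(n_chain):
        sub = "upper_pathway" if i < half else "lower_pathway"
        reactions.append(
            _rxn(
                f"R{i:02d}",
                {mets[i].id: -1.0, mets[i + 1].id: 1.0},
                random_gpr(),
                sub,
                genes,
            )
        )
    for j in range(n_extra):
        i1 = int(rng.integers(0, n_chain))
        i2 = int(rng.integers(i1 + 1, n_chain + 1))
        reactions.append(
            _rxn(
                f"S{j:02d}",
                {mets[i1].id: -1.0, mets[i2].id: 1.0},
                random_gpr(),
                "shortcuts",
                genes,
            )
        )
    reactions.append(
        _rxn("EX_out", {mets[-1].id: -1.0}, "", "exchange", genes)
    )
    return MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        id=f"random_{size}_{seed}",
    )


# ---------------------------------------------------------------------------
# Planted truth and DE-table simulation
# ---------------------------------------------------------------------------


def make_planted_truth(
    genes: list[str],
    design: StudyDesign = DEFAULT_DESIGN,
    responsive_fraction: float = 0.5,
    switch_fraction: float = 0.3,
    effect_size: float = 3.0,
    noise_sd: float = 0.3,
    false_positive_rate: float = 0.01,
    seed: int = 0,
) -> PlantedTruth:
    """Plant per-context activity states.

    A ``responsive_fraction`` of genes receives a non-constant ON/OFF
    pattern across conditions (constant over time, or inverting once at a
    random interior time point for a ``switch_fraction`` of them); the
    remaining genes are UNKNOWN in every context.
    """
    rng = np.random.default_rng(seed)
    n_cond = len(design.conditions)
    tlabels = design.timepoint_labels
    states: dict[tuple[str, str, str], int] = {}
    for g in genes:
        if rng.random() >= responsive_fraction:
            continue  # UNKNOWN everywhere (left out of the map)
        # Non-constant ON/OFF pattern over conditions.
        while True:
            pattern = rng.integers(0, 2, size=n_cond)
            if 0 < pattern.sum() < n_cond:
                break
        switch_at = None
        if rng.random() < switch_fraction:
            switch_at = int(rng.integers(1, len(tlabels)))
        for ti, t in enumerate(tlabels):
            flip = switch_at is not None and ti >= switch_at
            for ci, c in enumerate(design.conditions):
                on = bool(pattern[ci]) ^ flip
                states[(g, c, t)] = ON if on else OFF
    return PlantedTruth(
        genes=list(genes),
        gene_states=states,
        effect_size=effect_size,
        noise_sd=noise_sd,
        false_positive_rate=false_positive_rate,
    )


def simulate_de_tables(
    design: StudyDesign, truth: PlantedTruth, seed: int
) -> pd.DataFrame:
    """Simulate one DE summary table covering every required comparison.

    For a comparison whose two planted states differ (ON vs OFF), the
    log2 fold-change is drawn from Normal(+-effect_size, noise_sd) with the
    sign toward the ON side and padj from Uniform(0, 0.01).  Comparisons
    with agreeing or UNKNOWN states are null: log2fc ~ Normal(0, noise_sd)
    and padj ~ Uniform(0.2, 1), except that a ``false_positive_rate``
    fraction of them receives padj ~ Uniform(0, 0.05).
    """
    rng = np.random.default_rng(seed)
    comparisons = design.comparisons()
    rows = []
    for g in truth.genes:
        for (ca, ta), (cb, tb) in comparisons:
            sa = truth.state(g, ca, ta)
            sb = truth.state(g, cb, tb)
            if sa != sb and UNKNOWN not in (sa, sb):
                sign = 1.0 if sa == ON else -1.0
                lfc = rng.normal(sign * truth.effect_size, truth.noise_sd)
                padj = rng.uniform(0.0, 0.01)
            else:
                lfc = rng.normal(0.0, truth.noise_sd)
                if rng.random() < truth.false_positive_rate:
                    padj = rng.uniform(0.0, 0.05)
                else:
                    padj = rng.uniform(0.2, 1.0)
            rows.append((g, f"{ca}@{ta}", f"{cb}@{tb}", lfc, padj))
    return pd.DataFrame(rows, columns=DE_COLUMNS)


def simulate_nb_counts(
    design: StudyDesign,
    truth: PlantedTruth,
    seed: int,
    base_mean: float = 200.0,
    dispersion: float = 0.1,
) -> pd.DataFrame:
    """Optional negative-binomial count emitter (interface demos only).

    Emits raw counts per (gene, condition, timepoint, replicate) whose
    means follow the planted ON/OFF states; no test is performed on them —
    the pipeline consumes DE summary tables, not counts.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in truth.genes:
        for c, t in design.contexts():
            s = truth.state(g, c, t)
            mu = base_mean * 2.0 ** (s * truth.effect_size / 2.0)
            n = 1.0 / dispersion
            p = n / (n + mu)
            for rep in range(design.replicates):
                rows.append((g, c, t, rep + 1, int(rng.negative_binomial(n, p))))
    return pd.DataFrame(
        rows, columns=["gene", "condition", "timepoint", "replicate", "count"]
    )


def make_fold_change_matrix(
    n_clusters: int = 8,
    genes_per_cluster: int = 50,
    design: StudyDesign = DEFAULT_DESIGN,
    profile_scale: float = 3.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gene x contrast log2 fold-change matrix with planted clusters.

    Contrasts are the microbiota-vs-control comparisons (every non-control
    condition vs the first condition, per time point).  Cluster mean
    profiles are mutually orthogonal with norm ``profile_scale`` (log2
    units), so any two cluster centres are ``profile_scale * sqrt(2)``
    apart — well separated relative to ``noise_sd`` at the defaults.
    """
    rng = np.random.default_rng(seed)
    control = design.conditions[0]
    contrasts = [
        f"{c}_vs_{control}@{t}"
        for c in design.conditions[1:]
        for t in design.timepoint_labels
    ]
    d = len(contrasts)
    if n_clusters > d:
        raise ValueError(
            f"cannot plant {n_clusters} orthogonal profiles in {d} contrasts"
        )
    # Random orthonormal profiles via QR, scaled to profile_scale.
    raw = rng.normal(size=(d, d))
    q, _ = np.linalg.qr(raw)
    profiles = q[:n_clusters] * profile_scale

    genes, assignment, rows = [], {}, []
    for k in range(n_clusters):
        for i in range(genes_per_cluster):
            g = f"c{k + 1}_g{i:03d}"
            genes.append(g)
            assignment[g] = k + 1
            rows.append(profiles[k] + rng.normal(0.0, noise_sd, size=d))
    fc = pd.DataFrame(np.asarray(rows), index=genes, columns=contrasts)
    return fc, assignment


def make_bundle(
    n_genes: int = 80,
    design: StudyDesign = DEFAULT_DESIGN,
    seed: int = 0,
    model: MetabolicModel | None = None,
    **truth_kwargs,
) -> SyntheticBundle:
    """Default synthetic bundle: a random toy model plus DE tables with
    planted activity states over ``n_genes`` genes (the model's genes
    first, padded with non-metabolic filler genes)."""
    if model is None:
        model = make_toy_model("random", size=14, seed=seed)
    genes = list(model.genes)
    genes += [f"x{i:03d}" for i in range(max(0, n_genes - len(genes)))]
    truth = make_planted_truth(genes, design, seed=seed, **truth_kwargs)
    de = simulate_de_tables(design, truth, seed=seed + 1)
    return SyntheticBundle(
        model=model,
        design=design,
        de_tables={"transcriptome": de},
        truth=truth,
        seed=seed,
    )


def plant_transformation_scenario(
    variant: str = "diamond", seed: int = 7
) -> SyntheticBundle:
    """Two-condition scenario with a planted metabolic mediator gene.

    In the *Ochrobactrum* (MYb71) contexts branch A carries the flux
    (gA ON, gB OFF); in the OP50 contexts branch B does.  By construction
    knocking out gA blocks exactly the branch-A reactions and forces all
    feasible throughput onto branch B, so gA is the planted mediator of
    the MYb71 -> OP50 transition (and gB of the reverse).
    """
    if variant != "diamond":
        raise ValueError(f"unsupported scenario variant {variant!r}")
    model = _diamond_model()
    design = StudyDesign(
        conditions=("OP50", "MYb71"),
        timepoints=(("L4", 48.0), ("Ad1", 72.0)),
        replicates=3,
    )
    states: dict[tuple[str, str, str], int] = {}
    for t in design.timepoint_labels:
        for gene, on_in_myb71 in (("gA", True), ("gB", False)):
            states[(gene, "MYb71", t)] = ON if on_in_myb71 else OFF
            states[(gene, "OP50", t)] = OFF if on_in_myb71 else ON
        for gene in ("gJ", "gS"):  # housekeeping: active on both diets
            states[(gene, "MYb71", t)] = ON
            states[(gene, "OP50", t)] = ON
    truth = PlantedTruth(
        genes=list(model.genes),
        gene_states=states,
        mediator_genes=["gA"],
    )
    de = simulate_de_tables(design, truth, seed=seed)
    return SyntheticBundle(
        model=model,
        design=design,
        de_tables={"transcriptome": de},
        truth=truth,
        seed=seed,
    )
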