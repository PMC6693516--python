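"""Steps 3-4: gene-level metabolic transformation scoring (MTA).

Given a source context network (with its reference flux ``v_ref``) and a
target expression state, every metabolic gene's knockout is scored for
its ability to shift the source flux state toward the target.  Knockouts
act through the GPR rules: a knockout blocks the reactions left without
a catalyst, and the blocked reactions are pinned to zero flux.

Scoring policies
----------------
``moma`` (default)
    The network's response to the knockout is predicted as the feasible
    flux closest to ``v_ref`` in L1 norm (a MOMA-style LP).  The
    transformation score TS is the fraction of required flux changes the
    response achieves minus a normalized penalty for deviation of the
    reactions required to stay steady.  The null (empty) knockout leaves
    the network at ``v_ref`` and scores exactly 0, which serves as the
    significance threshold: a positive TS means the knockout *forces* the
    network toward the target.

``optimistic``
    A best-case two-stage variant: a MILP first maximizes the number of
    achievable required changes over the knockout-constrained flux
    polytope, then an LP minimizes the steady-set deviation at that
    optimum.  Because blocking reactions can only shrink the polytope,
    this score can never exceed the null score; it is provided for
    sensitivity analysis, not for ranking (the ranking contract needs
    knockouts to be able to beat the threshold).

Per run, scores at or below the threshold are zeroed and the rest are
replaced by their ascending rank divided by the number of positive genes
(ties get the average rank), so the top gene scores 1.  Robustness comes
from bootstrap runs that each remove a random 10% of genes from the DE
table before the whole pipeline (discretization, iMAT, scoring) is
recomputed.  Rank-normalized scores are averaged across all runs of a
set and rescaled to [0, 1]; the overall score of a gene is the sum of
its aggregated forward-direction scores across omics layers minus the
reverse-direction sum, hence positive for mediators of the forward
transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, linprog, milp
from scipy.stats import rankdata

from .expression_states import discretize_states
from .imat import (
    ContextNetwork,
    IMATParams,
    InfeasibleError,
    imat_solve,
    map_states_to_reactions,
    reference_flux,
)
from .model_core import MetabolicModel, blocked_reactions_by_knockout

__all__ = [
    "TargetChangeSets",
    "MTAParams",
    "MTARunResult",
    "derive_change_sets",
    "mta_score_knockout",
    "mta_all_genes",
    "rank_normalize",
    "bootstrap_runs",
    "aggregate_scores",
    "overall_score",
    "mta_run_set",
]

_TOL = 1e-6


@dataclass(frozen=True)
class TargetChangeSets:
    """Partition of the reactions into required-change and steady sets."""

    r_forward_up: frozenset[str]
    r_forward_down: frozenset[str]
    r_steady: frozenset[str]

    def __post_init__(self) -> None:
        if (
            self.r_forward_up & self.r_forward_down
            or self.r_forward_up & self.r_steady
            or self.r_forward_down & self.r_steady
        ):
            raise ValueError("change sets must be disjoint")

    @property
    def n_forward(self) -> int:
        return len(self.r_forward_up) + len(self.r_forward_down)


@dataclass(frozen=True)
class MTAParams:
    epsilon_change: float = 0.5  # minimum required |flux| change
    lambda_steady: float = 1.0  # weight of the steady-deviation penalty
    bootstrap_fraction: float = 0.10
    bootstrap_runs: int = 5
    alpha: float = 0.05
    policy: str = "moma"  # or "optimistic"

    def __post_init__(self) -> None:
        if not 0 < self.bootstrap_fraction < 1:
            raise ValueError("bootstrap_fraction must be in (0, 1)")
        if self.bootstrap_runs < 1:
            raise ValueError("bootstrap_runs must be >= 1")
        if self.epsilon_change <= 0:
            raise ValueError("epsilon_change must be positive")
        if self.policy not in ("moma", "optimistic"):
            raise ValueError(f"unknown scoring policy {self.policy!r}")


@dataclass
class MTARunResult:
    scores: dict[str, float]  # gene -> raw TS
    threshold: float  # TS of the null (empty) knockout
    metadata: dict = field(default_factory=dict)


def derive_change_sets(
    de: pd.DataFrame,
    source: tuple[str, str],
    target: tuple[str, str],
    model: MetabolicModel,
    v_ref: Mapping[str, float],
    alpha: float = 0.05,
    epsilon_change: float = 0.5,
) -> TargetChangeSets:
    """Derive the target state from the source-vs-target DE comparison.

    Genes significantly higher in the target context mark every reaction
    whose GPR mentions them for increased flux; significantly lower genes
    mark theirs for decreased flux.  A reaction marked in both directions
    is a conflict and stays steady, as does any down-marked reaction whose
    reference flux is already below ``epsilon_change``.
    """
    src = f"{source[0]}@{source[1]}"
    tgt = f"{target[0]}@{target[1]}"
    fwd = (de["side_a"] == tgt) & (de["side_b"] == src)
    rev = (de["side_a"] == src) & (de["side_b"] == tgt)
    if not (fwd | rev).any():
        raise KeyError(
            f"DE table has no comparison between {source} and {target}"
        )
    sig = de["padj"] < alpha
    up_in_target = set(de.loc[fwd & sig & (de["log2fc"] > 0), "gene"])
    up_in_target |= set(de.loc[rev & sig & (de["log2fc"] < 0), "gene"])
    down_in_target = set(de.loc[fwd & sig & (de["log2fc"] < 0), "gene"])
    down_in_target |= set(de.loc[rev & sig & (de["log2fc"] > 0), "gene"])

    up_marks, down_marks = set(), set()
    for rxn in model.reactions:
        leaves = rxn.gpr.genes()
        if leaves & up_in_target:
            up_marks.add(rxn.id)
        if leaves & down_in_target:
            down_marks.add(rxn.id)
    conflict = up_marks & down_marks
    up = up_marks - conflict
    down = {
        r
        for r in down_marks - conflict
        if abs(v_ref.get(r, 0.0)) >= epsilon_change
    }
    steady = frozenset(model.reaction_ids()) - up - down
    return TargetChangeSets(
        r_forward_up=frozenset(up),
        r_forward_down=frozenset(down),
        r_steady=frozenset(steady),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _moma_response(
    model: MetabolicModel,
    v_ref: Mapping[str, float],
    blocked: set[str],
) -> np.ndarray:
    """L1-closest feasible flux to v_ref with the blocked reactions at 0."""
    rids = model.reaction_ids()
    n = len(rids)
    lb = np.array(
        [0.0 if r.id in blocked else r.lower_bound for r in model.reactions]
    )
    ub = np.array(
        [0.0 if r.id in blocked else r.upper_bound for r in model.reactions]
    )
    ref = np.array([v_ref.get(r, 0.0) for r in rids])
    S = model.stoichiometric_matrix()
    # Variables [v, t], t_i >= |v_i - ref_i|; minimize sum t.
    c = np.concatenate([np.zeros(n), np.ones(n)])
    eye = np.eye(n)
    A_ub = np.vstack(
        [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
    )
    b_ub = np.concatenate([ref, -ref])
    A_eq = np.hstack([S, np.zeros_like(S)])
    bounds = [(lb[i], ub[i]) for i in range(n)] + [(0.0, None)] * n
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise InfeasibleError(f"knockout response LP failed: {res.message}")
    return res.x[:n]


def _score_flux(
    v: np.ndarray,
    rids: Sequence[str],
    v_ref: Mapping[str, float],
    sets: TargetChangeSets,
    params: MTAParams,
) -> float:
    ridx = {r: i for i, r in enumerate(rids)}
    n_succ = 0
    for r in sets.r_forward_up:
        if abs(v[ridx[r]]) >= abs(v_ref.get(r, 0.0)) + params.epsilon_change - _TOL:
            n_succ += 1
    for r in sets.r_forward_down:
        floor = max(abs(v_ref.get(r, 0.0)) - params.epsilon_change, 0.0)
        if abs(v[ridx[r]]) <= floor + _TOL:
            n_succ += 1
    dev = sum(abs(v[ridx[r]] - v_ref.get(r, 0.0)) for r in sets.r_steady)
    norm = sum(abs(v_ref.get(r, 0.0)) for r in sets.r_steady) + 1.0
    penalty = params.lambda_steady * dev / norm
    if sets.n_forward == 0:
        return -penalty
    return n_succ / sets.n_forward - penalty


def _optimistic_response(
    model: MetabolicModel,
    v_ref: Mapping[str, float],
    sets: TargetChangeSets,
    blocked: set[str],
    params: MTAParams,
) -> np.ndarray:
    """Two-stage best-case response: maximize achieved changes (MILP),
    then minimize steady deviation holding the achieved set fixed (LP)."""
    rids = model.reaction_ids()
    ridx = {r: i for i, r in enumerate(rids)}
    n = len(rids)
    lb = np.array(
        [0.0 if r.id in blocked else r.lower_bound for r in model.reactions]
    )
    ub = np.array(
        [0.0 if r.id in blocked else r.upper_bound for r in model.reactions]
    )
    S = model.stoichiometric_matrix()
    up = sorted(sets.r_forward_up)
    down = sorted(sets.r_forward_down)
    h, l = len(up), len(down)
    nvar = n + 2 * h + l
    c = np.zeros(nvar)
    c[n:] = -1.0
    rows, los, his = [], [], []
    A_eq = np.zeros((S.shape[0], nvar))
    A_eq[:, :n] = S
    rows.append(A_eq)
    los.append(np.zeros(S.shape[0]))
    his.append(np.zeros(S.shape[0]))
    ind = np.zeros((3 * h + 2 * l, nvar))
    ind_lo = np.empty(ind.shape[0])
    ind_hi = np.empty(ind.shape[0])
    row = 0
    for k, rid in enumerate(up):
        j = ridx[rid]
        thr = abs(v_ref.get(rid, 0.0)) + params.epsilon_change
        # b_plus = 1 => v_j >= thr ; b_minus = 1 => v_j <= -thr
        ind[row, j] = 1.0
        ind[row, n + k] = -(thr - lb[j])
        ind_lo[row], ind_hi[row] = lb[j], np.inf
        row += 1
        ind[row, j] = 1.0
        ind[row, n + h + k] = ub[j] + thr
        ind_lo[row], ind_hi[row] = -np.inf, ub[j]
        row += 1
        ind[row, n + k] = 1.0
        ind[row, n + h + k] = 1.0
        ind_lo[row], ind_hi[row] = -np.inf, 1.0
        row += 1
    for k, rid in enumerate(down):
        j = ridx[rid]
        u = max(abs(v_ref.get(rid, 0.0)) - params.epsilon_change, 0.0)
        # d = 1 => -u <= v_j <= u
        ind[row, j] = 1.0
        ind[row, n + 2 * h + k] = ub[j] - u
        ind_lo[row], ind_hi[row] = -np.inf, ub[j]
        row += 1
        ind[row, j] = 1.0
        ind[row, n + 2 * h + k] = lb[j] + u
        ind_lo[row], ind_hi[row] = lb[j], np.inf
        row += 1
    rows.append(ind)
    los.append(ind_lo)
    his.append(ind_hi)
    res = milp(
        c,
        constraints=LinearConstraint(
            np.vstack(rows), np.concatenate(los), np.concatenate(his)
        ),
        bounds=Bounds(
            np.concatenate([lb, np.zeros(2 * h + l)]),
            np.concatenate([ub, np.ones(2 * h + l)]),
        ),
        integrality=np.concatenate([np.zeros(n), np.ones(2 * h + l)]),
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleError(f"optimistic MILP failed: {res.message}")
    x = res.x
    # Stage 2: pin the achieved directions, minimize steady deviation.
    lb2, ub2 = lb.copy(), ub.copy()
    for k, rid in enumerate(up):
        j = ridx[rid]
        thr = abs(v_ref.get(rid, 0.0)) + params.epsilon_change
        if x[n + k] > 0.5:
            lb2[j] = max(lb2[j], thr)
        elif x[n + h + k] > 0.5:
            ub2[j] = min(ub2[j], -thr)
    for k, rid in enumerate(down):
        j = ridx[rid]
        u = max(abs(v_ref.get(rid, 0.0)) - params.epsilon_change, 0.0)
        if x[n + 2 * h + k] > 0.5:
            lb2[j] = max(lb2[j], -u)
            ub2[j] = min(ub2[j], u)
    steady = sorted(sets.r_steady)
    m = len(steady)
    c2 = np.concatenate([np.zeros(n), np.ones(m)])
    sel = np.zeros((m, n))
    ref_s = np.empty(m)
    for k, rid in enumerate(steady):
        sel[k, ridx[rid]] = 1.0
        ref_s[k] = v_ref.get(rid, 0.0)
    A_ub = np.vstack(
        [
            np.hstack([sel, -np.eye(m)]),
            np.hstack([-sel, -np.eye(m)]),
        ]
    )
    b_ub = np.concatenate([ref_s, -ref_s])
    res2 = linprog(
        c2,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=np.hstack([S, np.zeros((S.shape[0], m))]),
        b_eq=np.zeros(S.shape[0]),
        bounds=[(lb2[i], ub2[i]) for i in range(n)] + [(0.0, None)] * m,
        method="highs",
    )
    if res2.status != 0:
        raise InfeasibleError(f"optimistic stage-2 LP failed: {res2.message}")
    return res2.x[:n]


def mta_score_knockout(
    model: MetabolicModel,
    v_ref: Mapping[str, float],
    sets: TargetChangeSets,
    blocked: Iterable[str],
    params: MTAParams = MTAParams(),
) -> float:
    """Transformation score of one knockout (its blocked reaction set)."""
    blocked = set(blocked)
    unknown = blocked - set(model.reaction_ids())
    if unknown:
        raise KeyError(f"blocked set names unknown reactions: {sorted(unknown)}")
    if params.policy == "moma":
        v = _moma_response(model, v_ref, blocked)
    else:
        v = _optimistic_response(model, v_ref, sets, blocked, params)
    return _score_flux(v, model.reaction_ids(), v_ref, sets, params)


def mta_all_genes(
    model: MetabolicModel,
    v_ref: Mapping[str, float],
    sets: TargetChangeSets,
    params: MTAParams = MTAParams(),
    metadata: dict | None = None,
) -> MTARunResult:
    """Score every model gene; identical blocked sets share one solve.

    Genes blocking no reaction are assigned the null score (= threshold)
    by construction.
    """
    threshold = mta_score_knockout(model, v_ref, sets, set(), params)
    cache: dict[frozenset[str], float] = {frozenset(): threshold}
    scores: dict[str, float] = {}
    for gene in sorted(model.genes):
        blocked = frozenset(blocked_reactions_by_knockout(model, gene))
        if blocked not in cache:
            cache[blocked] = mta_score_knockout(
                model, v_ref, sets, blocked, params
            )
        scores[gene] = cache[blocked]
    return MTARunResult(
        scores=scores, threshold=threshold, metadata=metadata or {}
    )


def rank_normalize(run: MTARunResult) -> dict[str, float]:
    """Zero at-or-below-threshold scores, rank the rest ascending, divide
    by the count of positive genes so the best gene scores 1."""
    genes = sorted(run.scores)
    above = [g for g in genes if run.scores[g] > run.threshold]
    out = {g: 0.0 for g in genes}
    if not above:
        return out
    ranks = rankdata([run.scores[g] for g in above], method="average")
    m = len(above)
    for g, r in zip(above, ranks):
        out[g] = float(r) / m
    return out


def aggregate_scores(
    normalized_runs: Sequence[Mapping[str, float]],
) -> dict[str, float]:
    """Per-gene mean over all runs of a set, rescaled to a max of 1."""
    if not normalized_runs:
        raise ValueError("need at least one run to aggregate")
    genes = sorted({g for run in normalized_runs for g in run})
    means = {
        g: float(np.mean([run.get(g, 0.0) for run in normalized_runs]))
        for g in genes
    }
    top = max(means.values(), default=0.0)
    if top > 0:
        means = {g: s / top for g, s in means.items()}
    return means


def overall_score(
    forward: Mapping[str, Mapping[str, float]],
    reverse: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """Signed overall score: sum of forward-layer scores minus reverse.

    ``forward`` and ``reverse`` map omics-layer name -> aggregated score
    map; genes missing from a map contribute 0.  Antisymmetric under
    exchanging the two arguments.
    """
    genes = {
        g
        for layer in list(forward.values()) + list(reverse.values())
        for g in layer
    }
    return {
        g: sum(layer.get(g, 0.0) for layer in forward.values())
        - sum(layer.get(g, 0.0) for layer in reverse.values())
        for g in sorted(genes)
    }


# ---------------------------------------------------------------------------
# Run orchestration: bootstraps and run sets
# ---------------------------------------------------------------------------


def remove_genes(de: pd.DataFrame, genes: Iterable[str]) -> pd.DataFrame:
    drop = set(genes)
    return de.loc[~de["gene"].isin(drop)].reset_index(drop=True)


def bootstrap_gene_sets(
    de: pd.DataFrame, params: MTAParams, seed: int
) -> list[frozenset[str]]:
    """The per-bootstrap-run sets of genes removed from the DE table."""
    rng = np.random.default_rng(seed)
    genes = sorted(de["gene"].unique())
    n_remove = int(round(params.bootstrap_fraction * len(genes)))
    n_remove = min(max(n_remove, 1), len(genes) - 1)
    return [
        frozenset(rng.choice(genes, size=n_remove, replace=False))
        for _ in range(params.bootstrap_runs)
    ]


def _single_run(
    model: MetabolicModel,
    de: pd.DataFrame,
    design,
    source: tuple[str, str],
    target: tuple[str, str],
    params: MTAParams,
    imat_params: IMATParams,
    metadata: dict,
) -> MTARunResult:
    states = discretize_states(de, design, alpha=params.alpha)
    slice_ = states.context_slice(*source)
    evidence = map_states_to_reactions(model, slice_)
    net = imat_solve(
        model, evidence, imat_params, context=f"{source[0]}@{source[1]}"
    )
    v_ref = reference_flux(model, net, evidence, imat_params)
    change = derive_change_sets(
        de,
        source,
        target,
        model,
        v_ref,
        alpha=params.alpha,
        epsilon_change=params.epsilon_change,
    )
    return mta_all_genes(model, v_ref, change, params, metadata=metadata)


def bootstrap_runs(
    model: MetabolicModel,
    de: pd.DataFrame,
    design,
    source: tuple[str, str],
    target: tuple[str, str],
    params: MTAParams = MTAParams(),
    imat_params: IMATParams = IMATParams(),
    seed: int = 0,
    include_full: bool = True,
) -> list[MTARunResult]:
    """Full-data run plus bootstrap runs for one source -> target pair.

    Each bootstrap removes a random ``bootstrap_fraction`` of the genes
    (all their DE rows) and recomputes discretization, the source network,
    the target change sets, and all knockout scores.
    """
    runs: list[MTARunResult] = []
    base_meta = {
        "source": f"{source[0]}@{source[1]}",
        "target": f"{target[0]}@{target[1]}",
    }
    if include_full:
        runs.append(
            _single_run(
                model, de, design, source, target, params, imat_params,
                {**base_meta, "bootstrap": 0},
            )
        )
    for b, removed in enumerate(
        bootstrap_gene_sets(de, params, seed), start=1
    ):
        runs.append(
            _single_run(
                model,
                remove_genes(de, removed),
                design,
                source,
                target,
                params,
                imat_params,
                {**base_meta, "bootstrap": b, "removed": sorted(removed)},
            )
        )
    return runs


def mta_run_set(
    model: MetabolicModel,
    de: pd.DataFrame,
    design,
    direction: str,
    params: MTAParams = MTAParams(),
    imat_params: IMATParams = IMATParams(),
    seed: int = 0,
    control: str | None = None,
    include_full: bool = True,
) -> tuple[dict[str, float], list[MTARunResult]]:
    """All runs of one direction's set, aggregated.

    ``direction`` is ``"forward"`` (each microbiota condition as source,
    the control as target — the transition *to* growth on the control) or
    ``"reverse"`` (control as source, each microbiota condition as
    target).  The set spans every time point, every microbiota condition,
    and the full-data run plus bootstraps; aggregation averages the
    rank-normalized scores and rescales to [0, 1].
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    control = control if control is not None else design.conditions[0]
    others = [c for c in design.conditions if c != control]
    all_runs: list[MTARunResult] = []
    rng = np.random.default_rng(seed)
    for tp in design.timepoint_labels:
        for cond in others:
            if direction == "forward":
                source, target = (cond, tp), (control, tp)
            else:
                source, target = (control, tp), (cond, tp)
            run_seed = int(rng.integers(0, 2**31 - 1))
            all_runs.extend(
                bootstrap_runs(
                    model, de, design, source, target, params, imat_params,
                    seed=run_seed, include_full=include_full,
                )
            )
    aggregated = aggregate_scores([rank_normalize(r) for r in all_runs])
    return aggregated, all_runs
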