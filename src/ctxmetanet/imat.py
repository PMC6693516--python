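"""Step 2: context-specific network extraction (iMAT).

Given tri-valued reaction evidence — reactions whose enzymes are ON
(``r_high``) or OFF (``r_low``) in a context — iMAT picks a steady-state
flux distribution that maximizes the number of satisfied evidence labels:
a high reaction is satisfied when it carries at least ``epsilon`` flux in
either direction, a low reaction when it carries none.  The optimization
is a mixed-integer linear program; indicator constraints are expressed as
big-M inequalities with M taken from the flux bounds.

A brute-force oracle (`imat_bruteforce`) enumerates evidence-satisfaction
assignments and checks each by LP feasibility; it is exact on small
models and serves as the independent check of the MILP formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model_core import MetabolicModel, OFF, ON, evaluate_gpr_state

__all__ = [
    "ReactionStateSets",
    "IMATParams",
    "ContextNetwork",
    "InfeasibleError",
    "map_states_to_reactions",
    "imat_solve",
    "imat_bruteforce",
    "reference_flux",
]


class InfeasibleError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReactionStateSets:
    """Reactions with ON (+1) and OFF (-1) expression evidence."""

    r_high: frozenset[str]
    r_low: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.r_high & self.r_low
        if overlap:
            raise ValueError(f"reactions in both r_high and r_low: {overlap}")

    @property
    def total_evidence(self) -> int:
        return len(self.r_high) + len(self.r_low)


@dataclass(frozen=True)
class IMATParams:
    epsilon: float = 1.0  # minimum |flux| for a reaction to count as used
    delta: float = 1e-6  # |flux| below this is "zero" when classifying
    time_limit: float | None = None  # seconds, per MILP
    mip_gap: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.delta < self.epsilon:
            raise ValueError("need 0 < delta < epsilon")


@dataclass
class ContextNetwork:
    context: str
    active_reactions: frozenset[str]
    flux: dict[str, float]
    objective: int


def map_states_to_reactions(
    model: MetabolicModel, states: Mapping[str, int]
) -> ReactionStateSets:
    """Lift gene states to reaction evidence through the GPR rules."""
    high, low = set(), set()
    for rxn in model.reactions:
        ev = evaluate_gpr_state(rxn.gpr, states)
        if ev == ON:
            high.add(rxn.id)
        elif ev == OFF:
            low.add(rxn.id)
    return ReactionStateSets(r_high=frozenset(high), r_low=frozenset(low))


def _check_finite_bounds(model: MetabolicModel) -> None:
    for rxn in model.reactions:
        if not (np.isfinite(rxn.lower_bound) and np.isfinite(rxn.upper_bound)):
            raise ValueError(f"reaction {rxn.id}: bounds must be finite")


def imat_solve(
    model: MetabolicModel,
    sets: ReactionStateSets,
    params: IMATParams = IMATParams(),
    context: str = "",
    blocked: Iterable[str] = (),
) -> ContextNetwork:
    """Solve the iMAT MILP and return one optimal context network.

    ``blocked`` reactions are pinned to zero flux before solving (used for
    knockout analyses).  The returned ``active_reactions`` are those with
    |flux| > delta in the single returned optimum.
    """
    _check_finite_bounds(model)
    unknown = set(sets.r_high | sets.r_low | set(blocked)) - set(
        model.reaction_ids()
    )
    if unknown:
        raise KeyError(f"evidence for unknown reactions: {sorted(unknown)}")

    rids = model.reaction_ids()
    ridx = {r: i for i, r in enumerate(rids)}
    n = len(rids)
    high = sorted(sets.r_high)
    low = sorted(sets.r_low)
    eps = params.epsilon
    blocked = set(blocked)

    lb = np.array(
        [0.0 if r.id in blocked else r.lower_bound for r in model.reactions]
    )
    ub = np.array(
        [0.0 if r.id in blocked else r.upper_bound for r in model.reactions]
    )

    # Variables: [v (n), y_plus (h), y_minus (h), z (l)]
    h, l = len(high), len(low)
    nvar = n + 2 * h + l
    c = np.zeros(nvar)
    c[n:] = -1.0  # maximize satisfied evidence

    S = model.stoichiometric_matrix()
    A_rows, lo_rows, hi_rows = [], [], []

    A_eq = np.zeros((S.shape[0], nvar))
    A_eq[:, :n] = S
    A_rows.append(A_eq)
    lo_rows.append(np.zeros(S.shape[0]))
    hi_rows.append(np.zeros(S.shape[0]))

    ind = np.zeros((2 * h + h + 2 * l, nvar))
    ind_lo = np.empty(ind.shape[0])
    ind_hi = np.empty(ind.shape[0])
    row = 0
    for k, rid in enumerate(high):
        j = ridx[rid]
        # y_plus = 1  =>  v_j >= eps
        ind[row, j] = 1.0
        ind[row, n + k] = -(eps - lb[j])
        ind_lo[row], ind_hi[row] = lb[j], np.inf
        row += 1
        # y_minus = 1  =>  v_j <= -eps
        ind[row, j] = 1.0
        ind[row, n + h + k] = ub[j] + eps
        ind_lo[row], ind_hi[row] = -np.inf, ub[j]
        row += 1
    for k in range(h):
        ind[row, n + k] = 1.0
        ind[row, n + h + k] = 1.0
        ind_lo[row], ind_hi[row] = -np.inf, 1.0
        row += 1
    for k, rid in enumerate(low):
        j = ridx[rid]
        # z = 1  =>  v_j = 0
        ind[row, j] = 1.0
        ind[row, n + 2 * h + k] = ub[j]
        ind_lo[row], ind_hi[row] = -np.inf, ub[j]
        row += 1
        ind[row, j] = 1.0
        ind[row, n + 2 * h + k] = lb[j]
        ind_lo[row], ind_hi[row] = lb[j], np.inf
        row += 1
    A_rows.append(ind)
    lo_rows.append(ind_lo)
    hi_rows.append(ind_hi)

    A = np.vstack(A_rows)
    constraint = LinearConstraint(
        A, np.concatenate(lo_rows), np.concatenate(hi_rows)
    )
    var_lb = np.concatenate([lb, np.zeros(2 * h + l)])
    var_ub = np.concatenate([ub, np.ones(2 * h + l)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * h + l)])

    options: dict = {"mip_rel_gap": params.mip_gap}
    if params.time_limit is not None:
        options["time_limit"] = params.time_limit
    res = milp(
        c,
        constraints=constraint,
        bounds=Bounds(var_lb, var_ub),
        integrality=integrality,
        options=options,
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleError(
            f"iMAT MILP did not solve to optimality: {res.message}"
        )
    v = res.x[:n]
    flux = {rid: float(v[i]) for i, rid in enumerate(rids)}
    active = frozenset(r for r, f in flux.items() if abs(f) > params.delta)
    return ContextNetwork(
        context=context,
        active_reactions=active,
        flux=flux,
        objective=int(round(-res.fun)),
    )


def _lp_feasible(
    model: MetabolicModel,
    lb: np.ndarray,
    ub: np.ndarray,
) -> np.ndarray | None:
    """Feasibility LP for S v = 0 within [lb, ub]; returns a flux or None."""
    if np.any(lb > ub + 1e-12):
        return None
    S = model.stoichiometric_matrix()
    res = linprog(
        c=np.zeros(len(lb)),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.x if res.status == 0 else None


def imat_bruteforce(
    model: MetabolicModel,
    sets: ReactionStateSets,
    params: IMATParams = IMATParams(),
    context: str = "",
    blocked: Iterable[str] = (),
    max_evidence: int = 16,
) -> ContextNetwork:
    """Exhaustive iMAT oracle for small evidence sets.

    Enumerates every satisfaction assignment over the evidence reactions
    (including flux direction for satisfiable-in-both-directions high
    reactions), checks each by LP feasibility, and returns a maximal
    feasible assignment.  Refuses inputs with more than ``max_evidence``
    evidence labels.
    """
    if sets.total_evidence > max_evidence:
        raise ValueError(
            f"brute force refused: {sets.total_evidence} evidence labels "
            f"exceeds the guard of {max_evidence}"
        )
    _check_finite_bounds(model)
    rids = model.reaction_ids()
    ridx = {r: i for i, r in enumerate(rids)}
    eps = params.epsilon
    blocked = set(blocked)
    base_lb = np.array(
        [0.0 if r.id in blocked else r.lower_bound for r in model.reactions]
    )
    base_ub = np.array(
        [0.0 if r.id in blocked else r.upper_bound for r in model.reactions]
    )

    evidence = [(rid, "high") for rid in sorted(sets.r_high)]
    evidence += [(rid, "low") for rid in sorted(sets.r_low)]
    m = len(evidence)

    masks = sorted(
        range(2**m), key=lambda b: -bin(b).count("1")
    )  # try the largest satisfied subsets first
    for mask in masks:
        chosen = [evidence[i] for i in range(m) if mask >> i & 1]
        dir_options = []
        for rid, kind in chosen:
            j = ridx[rid]
            if kind == "low":
                dir_options.append(("zero",))
            else:
                opts = []
                if base_ub[j] >= eps:
                    opts.append("fwd")
                if base_lb[j] <= -eps:
                    opts.append("rev")
                if not opts:
                    opts = ["impossible"]
                dir_options.append(tuple(opts))
        for dirs in product(*dir_options):
            if "impossible" in dirs:
                continue
            lb, ub = base_lb.copy(), base_ub.copy()
            for (rid, _), d in zip(chosen, dirs):
                j = ridx[rid]
                if d == "zero":
                    lb[j] = ub[j] = 0.0
                elif d == "fwd":
                    lb[j] = max(lb[j], eps)
                else:
                    ub[j] = min(ub[j], -eps)
            v = _lp_feasible(model, lb, ub)
            if v is not None:
                flux = {rid: float(v[i]) for i, rid in enumerate(rids)}
                active = frozenset(
                    r for r, f in flux.items() if abs(f) > params.delta
                )
                return ContextNetwork(
                    context=context,
                    active_reactions=active,
                    flux=flux,
                    objective=len(chosen),
                )
    raise InfeasibleError("no feasible assignment found (not even v = 0)")


def reference_flux(
    model: MetabolicModel,
    context: ContextNetwork,
    sets: ReactionStateSets,
    params: IMATParams = IMATParams(),
) -> dict[str, float]:
    """L1-norm-minimal flux supporting a context network.

    Minimizes sum |v| subject to steady state, bounds, and |v_r| >= epsilon
    (in the direction the iMAT optimum chose) for every high-evidence
    reaction the optimum satisfied.  This is the deterministic source
    state handed to the transformation scoring stage.
    """
    _check_finite_bounds(model)
    rids = model.reaction_ids()
    n = len(rids)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    eps = params.epsilon
    for i, rid in enumerate(rids):
        if rid not in sets.r_high or rid not in context.active_reactions:
            continue
        f = context.flux.get(rid, 0.0)
        if f >= eps - params.delta:
            lb[i] = max(lb[i], eps)
        elif f <= -eps + params.delta:
            ub[i] = min(ub[i], -eps)

    # Variables [v, t] with t >= |v|; minimize sum t.
    S = model.stoichiometric_matrix()
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros_like(S)])
    eye = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([eye, -eye]),  # v - t <= 0
            np.hstack([-eye, -eye]),  # -v - t <= 0
        ]
    )
    b_ub = np.zeros(2 * n)
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
        raise InfeasibleError(
            f"reference-flux LP infeasible: {res.message}"
        )
    v = res.x[:n]
    v[np.abs(v) <= params.delta] = 0.0
    return {rid: float(v[i]) for i, rid in enumerate(rids)}
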