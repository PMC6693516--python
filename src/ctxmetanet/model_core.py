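"""Genome-scale metabolic model container, GPR logic, and model I/O.

The model object is deliberately small: stoichiometry, flux bounds, a
pathway (subsystem) label per reaction, and a boolean gene-protein-reaction
(GPR) rule per reaction.  Everything downstream — context-specific network
extraction and knockout scoring — only needs these four ingredients.

GPR rules are evaluated over the tri-valued gene-state lattice
OFF = -1 < UNKNOWN = 0 < ON = +1 with AND = min and OR = max, the standard
conservative extension of boolean logic: restricted to {-1, +1} it coincides
with boolean AND/OR.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ON",
    "OFF",
    "UNKNOWN",
    "GPRExpression",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "GPRParseError",
    "parse_gpr",
    "evaluate_gpr_state",
    "blocked_reactions_by_knockout",
    "load_model",
    "save_model_json",
    "save_model_sbml",
]

ON = 1
UNKNOWN = 0
OFF = -1

JSON_SCHEMA_VERSION = "ctxmetanet-model-v1"


class ModelValidationError(ValueError):
    """A model violates a structural invariant (duplicate/unknown ids)."""


class GPRParseError(ValueError):
    """A GPR rule string could not be parsed; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene ids.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``, ``"empty"``.  The empty
    expression is a distinct value meaning "no gene association"; it
    evaluates to UNKNOWN and is never blocked by a knockout.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = ()

    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        """All gene ids appearing as leaves."""
        if self.op == "empty":
            return frozenset()
        if self.op == "gene":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: frozenset[str] = frozenset()
        for child in self.children:
            out |= child.genes()
        return out

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return str(self.gene)
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            text = child.to_string()
            if child.op in ("and", "or") and child.op != self.op:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)


EMPTY_GPR = GPRExpression(op="empty")

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str, genes: Iterable[str] | None = None) -> GPRExpression:
    """Parse a GPR rule string into a boolean tree.

    Grammar: gene ids, parentheses, case-insensitive ``and`` / ``or``
    (``or`` binds looser than ``and``).  Empty or whitespace-only text
    yields the empty expression.  If ``genes`` is given, every leaf must be
    a member of it.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses, dangling operators, or (when ``genes``
        is provided) a leaf id not in the known gene list.
    """
    if text is None or not text.strip():
        return EMPTY_GPR
    known = set(genes) if genes is not None else None
    tokens = _tokenize(text)
    idx = 0

    def peek() -> tuple[str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def parse_or() -> GPRExpression:
        nonlocal idx
        children = [parse_and()]
        while True:
            nxt = peek()
            if nxt is not None and nxt[0].lower() == "or":
                idx += 1
                children.append(parse_and())
            else:
                break
        if len(children) == 1:
            return children[0]
        return GPRExpression(op="or", children=tuple(children))

    def parse_and() -> GPRExpression:
        nonlocal idx
        children = [parse_atom()]
        while True:
            nxt = peek()
            if nxt is not None and nxt[0].lower() == "and":
                idx += 1
                children.append(parse_atom())
            else:
                break
        if len(children) == 1:
            return children[0]
        return GPRExpression(op="and", children=tuple(children))

    def parse_atom() -> GPRExpression:
        nonlocal idx
        nxt = peek()
        if nxt is None:
            raise GPRParseError("unexpected end of rule", len(text))
        tok, pos = nxt
        if tok == "(":
            idx += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parenthesis", pos)
            idx += 1
            return inner
        if tok == ")":
            raise GPRParseError("unbalanced parenthesis", pos)
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"dangling operator {tok!r}", pos)
        if known is not None and tok not in known:
            raise GPRParseError(f"unknown gene id {tok!r}", pos)
        idx += 1
        return GPRExpression(op="gene", gene=tok)

    expr = parse_or()
    trailing = peek()
    if trailing is not None:
        raise GPRParseError(f"unexpected token {trailing[0]!r}", trailing[1])
    return expr


def evaluate_gpr_state(gpr: GPRExpression, states: Mapping[str, int]) -> int:
    """Evaluate a GPR over tri-valued gene states.

    AND nodes take the minimum of their children, OR nodes the maximum;
    genes absent from ``states`` default to UNKNOWN (0), and the empty
    expression evaluates to UNKNOWN.  Total function, returns -1, 0 or +1.
    """
    if gpr.op == "empty":
        return UNKNOWN
    if gpr.op == "gene":
        return int(states.get(gpr.gene, UNKNOWN))  # type: ignore[arg-type]
    values = [evaluate_gpr_state(c, states) for c in gpr.children]
    return min(values) if gpr.op == "and" else max(values)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry (metabolite id -> signed coefficient),
    flux bounds, subsystem label, and a GPR rule."""

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    subsystem: str = "unassigned"
    gpr: GPRExpression = EMPTY_GPR

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction: touches a single metabolite."""
        return len(self.stoichiometry) <= 1


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str]
    id: str = "model"

    # Lookup caches, built lazily.
    _reaction_index: dict[str, Reaction] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()
        self._reaction_index = {r.id: r for r in self.reactions}

    # -- queries ----------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        try:
            return self._reaction_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def stoichiometric_matrix(self):
        """Dense S matrix (metabolites x reactions) as a numpy array."""
        import numpy as np

        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_index[met], j] = coef
        return S

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            problems.append(f"duplicate metabolite ids: {dupes}")
        if any(not m for m in met_ids):
            problems.append("empty metabolite id")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            problems.append(f"duplicate reaction ids: {dupes}")
        gene_set = set(self.genes)
        met_set = set(met_ids)
        for rxn in self.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                problems.append(f"reaction {rxn.id}: lower_bound > upper_bound")
            if not rxn.subsystem:
                problems.append(f"reaction {rxn.id}: empty subsystem")
            unknown_mets = sorted(set(rxn.stoichiometry) - met_set)
            if unknown_mets:
                problems.append(
                    f"reaction {rxn.id}: undeclared metabolites {unknown_mets}"
                )
            unknown_genes = sorted(rxn.gpr.genes() - gene_set)
            if unknown_genes:
                problems.append(
                    f"reaction {rxn.id}: GPR references undeclared genes "
                    f"{unknown_genes}"
                )
            if not rxn.stoichiometry and not rxn.is_exchange:
                problems.append(f"reaction {rxn.id}: empty stoichiometry")
        if problems:
            raise ModelValidationError("; ".join(problems))


def blocked_reactions_by_knockout(model: MetabolicModel, gene: str) -> set[str]:
    """Reactions whose catalyst is lost when ``gene`` is knocked out.

    A reaction is blocked exactly when its GPR, evaluated with the knocked
    out gene OFF and every other gene ON, is false — i.e. no isozyme route
    remains.  Reactions without a gene association are never blocked.
    """
    if gene not in set(model.genes):
        raise KeyError(f"unknown gene id {gene!r}")
    blocked: set[str] = set()
    for rxn in model.reactions:
        if rxn.gpr.is_empty() or gene not in rxn.gpr.genes():
            continue
        states = {g: ON for g in rxn.gpr.genes()}
        states[gene] = OFF
        if evaluate_gpr_state(rxn.gpr, states) == OFF:
            blocked.add(rxn.id)
    return blocked


# ---------------------------------------------------------------------------
# I/O — native JSON dialect and SBML (via cobra)
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema": JSON_SCHEMA_VERSION,
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gpr": r.gpr.to_string(),
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    genes = list(data["genes"])
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
        )
        for m in data["metabolites"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            subsystem=r.get("subsystem", "unassigned"),
            gpr=parse_gpr(r.get("gpr", ""), genes),
        )
        for r in data["reactions"]
    ]
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        id=data.get("id", "model"),
    )


def save_model_json(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1))


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        rule = r.gpr.to_string()
        if rule:
            cr.gene_reaction_rule = rule
    # Declare GPR-less genes too so the gene list round-trips.
    declared = {g.id for g in cm.genes}
    for g in model.genes:
        if g not in declared:
            cm.genes.add(cobra.Gene(g))
    # Subsystems travel as SBML groups (the L3 convention cobra reads back).
    by_subsystem: dict[str, list] = {}
    for r in model.reactions:
        by_subsystem.setdefault(r.subsystem, []).append(
            cm.reactions.get_by_id(r.id)
        )
    cm.add_groups(
        [
            cobra.core.Group(sub, name=sub, members=members, kind="partonomy")
            for sub, members in sorted(by_subsystem.items())
        ]
    )
    return cm


def _from_cobra(cm) -> MetabolicModel:
    genes = sorted(g.id for g in cm.genes)
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            subsystem=r.subsystem or "unassigned",
            gpr=parse_gpr(r.gene_reaction_rule, genes),
        )
        for r in cm.reactions
    ]
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, genes=genes, id=cm.id
    )


def save_model_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write SBML Level 3 with fbc gene associations and group subsystems."""
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(path))


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from the native JSON dialect or from SBML (fbc).

    ``format`` is ``"json"`` or ``"sbml"``; when omitted it is inferred
    from the file suffix (.json vs .xml/.sbml).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON: {exc}") from exc
        if data.get("schema") not in (None, JSON_SCHEMA_VERSION):
            raise ValueError(
                f"{path}: unsupported schema {data.get('schema')!r}"
            )
        return _model_from_dict(data)
    if format == "sbml":
        from cobra.io import read_sbml_model

        return _from_cobra(read_sbml_model(str(path)))
    raise ValueError(f"unknown model format {format!r}")
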