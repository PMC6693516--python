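"""Step 1 of the network analysis: tri-valued gene activity states.

Differential-expression summary tables (gene, comparison sides, log2
fold-change, FDR-adjusted p-value) are turned into a per-context activity
call: ON, OFF, or UNKNOWN for every (gene, condition, timepoint) cell of
the study design.  Only genes with at least one comparison significant at
``alpha`` (strictly below) are eligible for a call; the state of all other
genes is left open (UNKNOWN), as is the state of any eligible gene whose
significant comparisons cast a tied or empty vote for a context.

Each significant comparison with |log2fc| >= ``lfc_min`` casts one ON vote
for its higher-expressed side and one OFF vote for the lower side; a
context's comparisons are the cross-condition ones at its time point plus
the adjacent-time ones within its condition.  Majority vote decides the
state.  The rule is sign-symmetric: negating every fold-change swaps
ON and OFF and leaves UNKNOWN fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .model_core import OFF, ON, UNKNOWN

__all__ = [
    "DE_COLUMNS",
    "GeneStateTable",
    "read_de_table",
    "write_de_table",
    "parse_side",
    "eligible_genes",
    "discretize_states",
]

DE_COLUMNS = ["gene", "side_a", "side_b", "log2fc", "padj"]

_STATE_NAMES = {ON: "ON", OFF: "OFF", UNKNOWN: "UNKNOWN"}
_STATE_VALUES = {v: k for k, v in _STATE_NAMES.items()}


def parse_side(side: str) -> tuple[str, str]:
    """Split a ``condition@timepoint`` side label."""
    cond, sep, tp = side.partition("@")
    if not sep or not cond or not tp:
        raise ValueError(f"malformed side label {side!r}")
    return cond, tp


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE summary TSV and validate its schema.

    Columns: gene, side_a, side_b (``condition@timepoint`` labels),
    log2fc (positive when higher on side_a), padj in [0, 1].
    """
    de = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    de = de[DE_COLUMNS].copy()
    for col in ("log2fc", "padj"):  # empty files parse as object dtype
        de[col] = pd.to_numeric(de[col], errors="coerce")
    bad = de.index[(de["padj"] < 0) | (de["padj"] > 1) | de["padj"].isna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # 1-based incl. header
        raise ValueError(f"{path}: padj outside [0, 1] at file row(s) {rows}")
    bad = de.index[~np.isfinite(de["log2fc"])]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise ValueError(f"{path}: non-finite log2fc at file row(s) {rows}")
    same = de.index[de["side_a"] == de["side_b"]]
    if len(same):
        rows = ", ".join(str(i + 2) for i in same[:5])
        raise ValueError(f"{path}: side_a equals side_b at file row(s) {rows}")
    for col in ("side_a", "side_b"):
        de[col].map(parse_side)  # raises on malformed labels
    return de


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def eligible_genes(de: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes with at least one comparison strictly below ``alpha``."""
    if not len(de):
        return set()
    return set(de.loc[de["padj"] < alpha, "gene"])


@dataclass
class GeneStateTable:
    """Tri-valued activity state per (gene, condition, timepoint)."""

    states: dict[tuple[str, str, str], int]
    alpha: float
    lfc_min: float
    genes: tuple[str, ...] = ()
    contexts: tuple[tuple[str, str], ...] = ()

    def state(self, gene: str, condition: str, timepoint: str) -> int:
        return self.states.get((gene, condition, timepoint), UNKNOWN)

    def context_slice(self, condition: str, timepoint: str) -> dict[str, int]:
        """Gene -> state map for one (condition, timepoint) context."""
        return {
            g: s
            for (g, c, t), s in self.states.items()
            if c == condition and t == timepoint
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, c, t, _STATE_NAMES[self.state(g, c, t)])
            for g in self.genes
            for c, t in self.contexts
        ]
        return pd.DataFrame(
            rows, columns=["gene", "condition", "timepoint", "state"]
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"alpha": self.alpha, "lfc_min": self.lfc_min})
        )

    @classmethod
    def read(cls, path: str | Path) -> "GeneStateTable":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", dtype=str)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text()
        )
        states = {
            (r.gene, r.condition, r.timepoint): _STATE_VALUES[r.state]
            for r in frame.itertuples()
            if r.state != "UNKNOWN"
        }
        genes = tuple(dict.fromkeys(frame["gene"]))
        contexts = tuple(
            dict.fromkeys(zip(frame["condition"], frame["timepoint"]))
        )
        return cls(
            states=states,
            alpha=float(meta["alpha"]),
            lfc_min=float(meta["lfc_min"]),
            genes=genes,
            contexts=contexts,
        )


def _majority(on_votes: int, off_votes: int) -> int:
    if on_votes > off_votes:
        return ON
    if off_votes > on_votes:
        return OFF
    return UNKNOWN


def discretize_states(
    de: pd.DataFrame,
    design,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    vote_policy: Callable[[int, int], int] = _majority,
) -> GeneStateTable:
    """Derive the most likely activity state of each gene in each context.

    ``design`` provides the (condition, timepoint) grid; ``vote_policy``
    maps (ON votes, OFF votes) to a state and defaults to strict majority
    with ties left UNKNOWN.
    """
    contexts = set(design.contexts())
    tlabels = list(design.timepoint_labels)
    conditions = set(design.conditions)

    sides_a = de["side_a"].map(parse_side)
    sides_b = de["side_b"].map(parse_side)
    for side in list(sides_a) + list(sides_b):
        if side[0] not in conditions or side[1] not in tlabels:
            raise ValueError(
                f"comparison context {side[0]}@{side[1]} absent from design"
            )

    elig = eligible_genes(de, alpha)
    sig = (de["padj"] < alpha) & (de["log2fc"].abs() >= lfc_min)
    sig &= de["log2fc"] != 0.0  # a directionless change casts no vote

    votes: dict[tuple[str, str, str], list[int]] = {}
    for row, sa, sb in zip(de.loc[sig].itertuples(), sides_a[sig], sides_b[sig]):
        hi, lo = (sa, sb) if row.log2fc > 0 else (sb, sa)
        votes.setdefault((row.gene, *hi), [0, 0])[0] += 1
        votes.setdefault((row.gene, *lo), [0, 0])[1] += 1

    states: dict[tuple[str, str, str], int] = {}
    for (gene, cond, tp), (on_n, off_n) in votes.items():
        if gene not in elig:
            continue
        s = vote_policy(on_n, off_n)
        if s != UNKNOWN:
            states[(gene, cond, tp)] = s

    genes = tuple(dict.fromkeys(de["gene"]))
    return GeneStateTable(
        states=states,
        alpha=alpha,
        lfc_min=lfc_min,
        genes=genes,
        contexts=tuple(design.contexts()),
    )
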