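"""Pathway-level summaries of context-specific networks.

Each reaction of the reconstruction carries a subsystem (pathway) label;
a context network's activity profile is the count of its active reactions
per subsystem.  Between-diet shifts are the differences of mean counts
between two groups of contexts, ranked by absolute size; the ordination
view is a PCA of the binary reaction-activity matrix across contexts.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .imat import ContextNetwork
from .model_core import MetabolicModel

__all__ = [
    "count_active_by_subsystem",
    "pathway_differences",
    "activity_matrix",
    "activity_pca",
]


def count_active_by_subsystem(
    model: MetabolicModel, networks: Sequence[ContextNetwork]
) -> pd.DataFrame:
    """Subsystem x context matrix of active-reaction counts.

    Column sums equal the active-set sizes, so every active reaction is
    counted exactly once.
    """
    known = set(model.reaction_ids())
    subsystems = sorted({r.subsystem for r in model.reactions})
    sub_of = {r.id: r.subsystem for r in model.reactions}
    table = pd.DataFrame(
        0,
        index=pd.Index(subsystems, name="subsystem"),
        columns=[net.context for net in networks],
        dtype=int,
    )
    for net in networks:
        stray = set(net.active_reactions) - known
        if stray:
            raise ValueError(
                f"context {net.context!r} has active reactions absent from "
                f"the model: {sorted(stray)}"
            )
        for rid in net.active_reactions:
            table.loc[sub_of[rid], net.context] += 1
    return table


def pathway_differences(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    top_k: int = 8,
) -> tuple[pd.Series, list[str]]:
    """Per-subsystem signed difference of mean counts (group_a - group_b)
    and the ``top_k`` subsystems by |difference|.

    Ties in |difference| are broken lexicographically by subsystem name.
    Antisymmetric under swapping the groups.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    for label in group_a + group_b:
        if label not in table.columns:
            raise KeyError(f"unknown context label {label!r}")
    diff = table[group_a].mean(axis=1) - table[group_b].mean(axis=1)
    order = sorted(diff.index, key=lambda s: (-abs(diff[s]), s))
    return diff, order[: min(top_k, len(order))]


def activity_matrix(
    model: MetabolicModel, networks: Sequence[ContextNetwork]
) -> pd.DataFrame:
    """Binary contexts x reactions activity matrix."""
    rids = model.reaction_ids()
    data = [
        [1.0 if rid in net.active_reactions else 0.0 for rid in rids]
        for net in networks
    ]
    return pd.DataFrame(
        data, index=[net.context for net in networks], columns=rids
    )


def activity_pca(
    networks: Sequence[ContextNetwork],
    model: MetabolicModel | None = None,
    use_counts: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of context networks: 2-D scores per context + explained variance.

    The ordinated objects are the binary reaction-activity profiles
    (set ``use_counts=True`` to ordinate subsystem count profiles
    instead).  All-identical networks yield zero coordinates and a
    degeneracy warning.
    """
    if len(networks) < 3:
        raise ValueError("PCA needs at least 3 context networks")
    if model is None:
        rids = sorted({r for net in networks for r in net.active_reactions})
        X = np.array(
            [[1.0 if r in net.active_reactions else 0.0 for r in rids]
             for net in networks]
        )
        if X.shape[1] == 0:
            X = np.zeros((len(networks), 1))
    elif use_counts:
        X = count_active_by_subsystem(model, networks).T.to_numpy(float)
    else:
        X = activity_matrix(model, networks).to_numpy(float)

    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc**2).sum())
    labels = [net.context for net in networks]
    if total_var <= 1e-12:
        warnings.warn("all context networks identical; PCA is degenerate")
        coords = pd.DataFrame(
            np.zeros((len(networks), 2)), index=labels, columns=["PC1", "PC2"]
        )
        return coords, np.zeros(2)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :2] * s[:2]
    if scores.shape[1] < 2:  # fewer than 2 non-trivial components
        scores = np.pad(scores, ((0, 0), (0, 2 - scores.shape[1])))
        s = np.pad(s, (0, 2 - len(s)))
    explained = (s[:2] ** 2) / total_var
    coords = pd.DataFrame(scores, index=labels, columns=["PC1", "PC2"])
    return coords, explained
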