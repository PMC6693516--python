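"""Transcriptome-side summaries: fold-change clustering, signature overlap,
cross-omics concordance, and expression PCA.

The clustering stage groups genes by their log2 fold-change profiles
(microbiota vs control, per strain and time point) with K-means, choosing
the cluster number by the Akaike information criterion under a Gaussian
model with a shared spherical variance, treating each gene profile as
one observation:

    AIC(k) = n * ln(RSS / n) + 2 * k * d

with n genes, d contrasts, RSS the total within-cluster sum of squares
and k * d estimated mean parameters.  BIC (replacing the 2 with ln(n))
is available as an alternative.  The signature stage reports Venn overlap counts of two
differentially-expressed gene sets, and the concordance stage compares
protein and transcript fold-changes (Pearson correlation plus
consistent-direction counts among significantly changed proteins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cluster import KMeans

__all__ = [
    "ClusteringResult",
    "kmeans_aic",
    "core_overlap",
    "omics_concordance",
    "expression_pca",
]


@dataclass
class ClusteringResult:
    k: int
    assignment: dict[str, int]  # gene -> cluster id in 1..k
    criterion_by_k: dict[int, float]
    centers: np.ndarray
    row_order: list[str] = field(default_factory=list)

    def ordered_matrix(self, fc: pd.DataFrame) -> pd.DataFrame:
        """Heatmap export: rows reordered so clusters are contiguous."""
        return fc.loc[self.row_order]


_RSS_FLOOR = 1e-12


def _aic(rss: float, n: int, d: int, k: int) -> float:
    return n * float(np.log(max(rss, _RSS_FLOOR) / n)) + 2.0 * k * d


def _bic(rss: float, n: int, d: int, k: int) -> float:
    return n * float(np.log(max(rss, _RSS_FLOOR) / n)) + k * d * float(
        np.log(n)
    )


def kmeans_aic(
    fc: pd.DataFrame,
    k_range: Iterable[int] = range(2, 16),
    restarts: int = 25,
    seed: int = 0,
    criterion: str = "aic",
) -> ClusteringResult:
    """Best-of-restarts Lloyd K-means per k; keep the k of lowest AIC.

    ``fc`` is the gene x contrast log2 fold-change matrix.  Rows that are
    all identical collapse to a single cluster (k = 1) with a warning.
    Within each cluster, genes are ordered by correlation with their
    cluster mean profile (heatmap row order).
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range is empty")
    X = fc.to_numpy(float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    score = _aic if criterion == "aic" else _bic

    # Degenerate input short-circuits before the k-range sanity check.
    if np.allclose(X, X[0]):
        warnings.warn("all fold-change rows identical; returning k = 1")
        genes = list(fc.index)
        return ClusteringResult(
            k=1,
            assignment={g: 1 for g in genes},
            criterion_by_k={1: score(0.0, n, d, 1)},
            centers=X[:1].copy(),
            row_order=genes,
        )

    if max(k_range) >= n:
        raise ValueError("k_range maximum must be below the gene count")

    by_k: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in k_range:
        km = KMeans(
            n_clusters=k,
            n_init=restarts,
            algorithm="lloyd",
            random_state=seed,
        ).fit(X)
        by_k[k] = score(float(km.inertia_), n, d, k)
        fits[k] = km
    best_k = min(by_k, key=lambda k: (by_k[k], k))
    km = fits[best_k]
    genes = list(fc.index)
    assignment = {g: int(lbl) + 1 for g, lbl in zip(genes, km.labels_)}

    # Heatmap row order: clusters contiguous; within a cluster, genes
    # sorted by decreasing correlation with the cluster mean profile.
    order: list[str] = []
    for cid in range(1, best_k + 1):
        members = [g for g in genes if assignment[g] == cid]
        center = km.cluster_centers_[cid - 1]
        c_sd = center.std()

        def corr(g: str) -> float:
            row = X[genes.index(g)]
            if c_sd == 0 or row.std() == 0:
                return 0.0
            return float(np.corrcoef(row, center)[0, 1])

        order.extend(sorted(members, key=lambda g: (-corr(g), g)))
    return ClusteringResult(
        k=best_k,
        assignment=assignment,
        criterion_by_k=by_k,
        centers=km.cluster_centers_.copy(),
        row_order=order,
    )


def core_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> dict[str, int]:
    """Venn counts for two differentially-expressed gene sets."""
    a, b = set(set_a), set(set_b)
    both = len(a & b)
    return {
        "only_a": len(a) - both,
        "only_b": len(b) - both,
        "both": both,
        "union": len(a | b),
    }


def omics_concordance(
    transcript_fc: Mapping[str, float],
    protein_fc: Mapping[str, float],
    significant_proteins: Iterable[str] | None = None,
) -> dict[str, float]:
    """Transcript/protein fold-change agreement.

    Pearson correlation over the shared genes, plus consistent-direction
    counts among the significantly changed proteins (defaulting to all
    shared proteins): a protein counts as consistent when its transcript
    fold-change has the same sign.  Percentages are relative to the
    up- and down-regulated protein counts.
    """
    shared = sorted(set(transcript_fc) & set(protein_fc))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes for concordance")
    t = np.array([transcript_fc[g] for g in shared])
    p = np.array([protein_fc[g] for g in shared])
    r, _ = pearsonr(t, p)

    sig = set(significant_proteins) if significant_proteins is not None else set(shared)
    sig &= set(shared)
    up = [g for g in sig if protein_fc[g] > 0]
    down = [g for g in sig if protein_fc[g] < 0]
    n_up = sum(1 for g in up if transcript_fc[g] > 0)
    n_down = sum(1 for g in down if transcript_fc[g] < 0)
    return {
        "pearson_r": float(r),
        "r_squared": float(r) ** 2,
        "n_protein_up": len(up),
        "n_protein_down": len(down),
        "n_consistent_up": n_up,
        "n_consistent_down": n_down,
        "pct_consistent_up": 100.0 * n_up / len(up) if up else float("nan"),
        "pct_consistent_down": (
            100.0 * n_down / len(down) if down else float("nan")
        ),
    }


def expression_pca(
    expr: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of sample expression profiles (genes x samples input).

    Sample profiles are centered (input is assumed already on a log-like
    scale); returns per-sample scores on the first ``n_components``
    components and their explained-variance fractions.  With fewer
    samples than requested components the count is reduced with a
    warning.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    X = expr.to_numpy(float).T  # samples x genes
    n = X.shape[0]
    if n_components > n - 1:
        warnings.warn(
            f"only {n - 1} non-trivial components available; reducing"
        )
        n_components = n - 1
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float((Xc**2).sum())
    k = n_components
    scores = U[:, :k] * s[:k]
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    coords = pd.DataFrame(
        scores,
        index=expr.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return coords, explained
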