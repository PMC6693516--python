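#!/usr/bin/env python
"""Transcriptome-side analyses: K-means fold-change clustering with
AIC-based cluster-number choice, signature-set overlap counts, and
transcript-protein concordance.

The clustering runs on a synthetic fold-change matrix with 8 planted
profile clusters; the overlap and concordance stages run on the
published set sizes of the microbiota-response signature (65 and 71
genes, 50 shared) and of the proteome comparison (40 of 50 up- and 67
of 73 down-regulated proteins transcript-consistent).

Writes cluster_assignment.tsv, cluster_criterion.tsv, venn_counts.json
and concordance.json under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ctxmetanet.clustering_signature import (
    core_overlap,
    kmeans_aic,
    omics_concordance,
)
from ctxmetanet.synthetic_data import make_fold_change_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fc, planted = make_fold_change_matrix(seed=args.seed)
    result = kmeans_aic(fc, seed=args.seed)
    pd.DataFrame(
        {"gene": list(result.assignment), "cluster": list(result.assignment.values())}
    ).to_csv(args.out / "cluster_assignment.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"k": list(result.criterion_by_k), "aic": list(result.criterion_by_k.values())}
    ).to_csv(args.out / "cluster_criterion.tsv", sep="\t", index=False)
    result.ordered_matrix(fc).to_csv(
        args.out / "cluster_heatmap_matrix.tsv", sep="\t"
    )
    purity = sum(
        1
        for cid in set(planted.values())
        if len({result.assignment[g] for g, a in planted.items() if a == cid}) == 1
    )
    print(
        f"K-means + AIC on {fc.shape[0]} genes x {fc.shape[1]} contrasts: "
        f"chose k = {result.k} (8 planted); {purity}/8 planted clusters "
        "mapped one-to-one"
    )

    shared = {f"s{i}" for i in range(50)}
    counts = core_overlap(
        shared | {f"a{i}" for i in range(15)},
        shared | {f"b{i}" for i in range(21)},
    )
    (args.out / "venn_counts.json").write_text(json.dumps(counts, indent=1))
    print(
        f"signature overlap: {counts['both']} shared, "
        f"{counts['only_a']} + {counts['only_b']} exclusive, "
        f"{counts['union']} total"
    )

    protein, transcript = {}, {}
    for i in range(50):
        protein[f"up{i}"] = 1.0
        transcript[f"up{i}"] = 1.0 if i < 40 else -1.0
    for i in range(73):
        protein[f"dn{i}"] = -1.0
        transcript[f"dn{i}"] = -1.0 if i < 67 else 1.0
    conc = omics_concordance(transcript, protein)
    (args.out / "concordance.json").write_text(json.dumps(conc, indent=1))
    print(
        f"transcript-protein concordance: "
        f"{conc['n_consistent_up']}/{conc['n_protein_up']} up "
        f"({conc['pct_consistent_up']:.1f}%), "
        f"{conc['n_consistent_down']}/{conc['n_protein_down']} down "
        f"({conc['pct_consistent_down']:.1f}%)"
    )


if __name__ == "__main__":
    main()
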