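#!/usr/bin/env python
"""Summarize the context networks at pathway level: active-reaction
counts per subsystem, the top pathways shifted between diets, and a PCA
of the binary reaction-activity profiles.

Reads results/context_networks.json (03), writes pathway_counts.tsv,
pathway_differences.tsv and activity_pca.tsv under results/.
"""

import argparse
import json
from pathlib import Path

from ctxmetanet.imat import ContextNetwork
from ctxmetanet.pathway_activity import (
    activity_pca,
    count_active_by_subsystem,
    pathway_differences,
)
from ctxmetanet.synthetic_data import SyntheticBundle


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundles", type=Path, default=Path("results/bundles"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = SyntheticBundle.read(args.bundles / "diamond")
    records = json.loads(
        (args.results / "context_networks.json").read_text()
    )
    nets = [
        ContextNetwork(
            context=r["context"],
            active_reactions=frozenset(r["active_reactions"]),
            flux=r["flux"],
            objective=r["objective"],
        )
        for r in records
    ]

    counts = count_active_by_subsystem(bundle.model, nets)
    counts.to_csv(args.results / "pathway_counts.tsv", sep="\t")
    print("active reactions per subsystem and context:")
    print(counts.to_string())

    control = bundle.design.conditions[0]
    group_b = [
        n.context for n in nets if n.context.startswith(f"{control}@")
    ]
    group_a = [n.context for n in nets if n.context not in group_b]
    diff, top = pathway_differences(counts, group_a, group_b)
    frame = diff.rename("mean_diff").to_frame()
    frame["top"] = [s in top for s in frame.index]
    frame.to_csv(args.results / "pathway_differences.tsv", sep="\t")
    print(
        "\nlargest microbiota-vs-control shifts: "
        + ", ".join(f"{s} ({diff[s]:+.1f})" for s in top if diff[s] != 0)
    )

    coords, explained = activity_pca(nets, bundle.model)
    coords.to_csv(args.results / "activity_pca.tsv", sep="\t")
    print(
        f"\nactivity PCA: PC1 {100 * explained[0]:.0f}% / "
        f"PC2 {100 * explained[1]:.0f}% of variance; "
        "coordinates -> results/activity_pca.tsv"
    )


if __name__ == "__main__":
    main()
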