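#!/usr/bin/env python
"""Generate the synthetic study bundles every later stage consumes.

Writes two bundles under results/bundles/:

* ``diamond`` — the two-condition transformation scenario: branch A of a
  small diamond-shaped network carries flux on the microbiota diet
  (MYb71), branch B on the *E. coli* OP50 control, and gene gA is the
  planted mediator whose knockout reroutes the network.
* ``state_recovery`` — the full 3-condition x 6-timepoint design with
  planted per-context ON/OFF activity states over 80 genes, used to
  quantify discretization accuracy.
"""

import argparse
from pathlib import Path

from ctxmetanet.pipeline import simulate_bundle
from ctxmetanet.synthetic_data import make_bundle


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=Path("results/bundles"))
    args = ap.parse_args()

    diamond_dir = args.outdir / "diamond"
    config = simulate_bundle(
        diamond_dir, variant="diamond", seed=args.seed, force=True
    )
    print(f"wrote transformation scenario -> {diamond_dir}")
    print(f"  pipeline config: {diamond_dir / 'config.yaml'}")

    recovery_dir = args.outdir / "state_recovery"
    bundle = make_bundle(n_genes=80, seed=args.seed)
    bundle.write(recovery_dir)
    n_planted = len(bundle.truth.gene_states)
    print(f"wrote state-recovery bundle -> {recovery_dir}")
    print(
        f"  {len(bundle.truth.genes)} genes, "
        f"{n_planted} planted ON/OFF states, "
        f"{len(bundle.de_tables['transcriptome'])} DE rows"
    )


if __name__ == "__main__":
    main()
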