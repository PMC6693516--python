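"""End-to-end orchestration: discretize -> iMAT -> pathway activity ->
MTA -> overall scores, with optional clustering, from one configuration.

Each stage writes plain-text artifacts (TSV/JSON) under the output
directory; a manifest JSON records the effective parameters, the global
seed, and a SHA-256 content hash of every artifact so a re-run can be
checked for byte-identical reproduction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression_states import discretize_states, read_de_table
from .imat import IMATParams, imat_solve, map_states_to_reactions
from .model_core import load_model
from .mta import MTAParams, mta_run_set, overall_score
from .pathway_activity import (
    activity_pca,
    count_active_by_subsystem,
    pathway_differences,
)
from .clustering_signature import kmeans_aic
from .synthetic_data import StudyDesign, plant_transformation_scenario

__all__ = ["PipelineConfig", "run_pipeline", "simulate_bundle"]


@dataclass
class PipelineConfig:
    model_path: str
    de_paths: dict[str, str]  # omics layer -> DE TSV path
    output_dir: str
    conditions: list[str] = field(
        default_factory=lambda: ["OP50", "MYb71", "MYb237"]
    )
    timepoints: list[list] = field(
        default_factory=lambda: [
            ["L2", 6.0], ["L3", 24.0], ["L4", 48.0],
            ["Ad1", 72.0], ["Ad3", 120.0], ["Ad7", 216.0],
        ]
    )
    replicates: int = 3
    alpha: float = 0.05
    lfc_min: float = 0.0
    epsilon: float = 1.0
    delta: float = 1e-6
    epsilon_change: float = 0.5
    lambda_steady: float = 1.0
    bootstrap_fraction: float = 0.10
    bootstrap_runs: int = 5
    k_range: list[int] = field(default_factory=lambda: list(range(2, 16)))
    kmeans_restarts: int = 25
    seed: int = 0
    run_networks: bool = True
    run_mta: bool = True
    run_clustering: bool = False

    def design(self) -> StudyDesign:
        return StudyDesign(
            conditions=tuple(self.conditions),
            timepoints=tuple((str(l), float(h)) for l, h in self.timepoints),
            replicates=self.replicates,
        )

    def imat_params(self) -> IMATParams:
        return IMATParams(epsilon=self.epsilon, delta=self.delta)

    def mta_params(self) -> MTAParams:
        return MTAParams(
            epsilon_change=self.epsilon_change,
            lambda_steady=self.lambda_steady,
            bootstrap_fraction=self.bootstrap_fraction,
            bootstrap_runs=self.bootstrap_runs,
            alpha=self.alpha,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the configured stages and return the run manifest.

    With ``resume=True`` a stage whose artifacts already exist is not
    recomputed.  Any stage error aborts the run after writing a partial
    manifest naming the failed stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    artifacts: list[Path] = []
    manifest_path = out / "manifest.json"

    def stage_done(paths: list[Path]) -> bool:
        return resume and all(p.exists() for p in paths)

    current_stage = "setup"
    try:
        model = load_model(config.model_path)
        layer_tables = {
            layer: read_de_table(path)
            for layer, path in sorted(config.de_paths.items())
        }

        # -- discretization -------------------------------------------
        current_stage = "discretize"
        states_by_layer = {}
        for layer, de in layer_tables.items():
            p = out / f"states_{layer}.tsv"
            states = discretize_states(
                de, design, alpha=config.alpha, lfc_min=config.lfc_min
            )
            states_by_layer[layer] = states
            if not stage_done([p]):
                states.write(p)
            artifacts += [p, p.with_suffix(p.suffix + ".meta.json")]

        networks_by_layer: dict[str, list] = {}
        if config.run_networks:
            current_stage = "imat"
            for layer, states in states_by_layer.items():
                nets = []
                for cond, tp in design.contexts():
                    evidence = map_states_to_reactions(
                        model, states.context_slice(cond, tp)
                    )
                    nets.append(
                        imat_solve(
                            model,
                            evidence,
                            config.imat_params(),
                            context=f"{cond}@{tp}",
                        )
                    )
                networks_by_layer[layer] = nets
                p = out / f"networks_{layer}.json"
                if not stage_done([p]):
                    _write_json(
                        p,
                        [
                            {
                                "context": n.context,
                                "objective": n.objective,
                                "active_reactions": sorted(
                                    n.active_reactions
                                ),
                                "flux": {
                                    k: round(v, 9)
                                    for k, v in sorted(n.flux.items())
                                },
                            }
                            for n in nets
                        ],
                    )
                artifacts.append(p)

            current_stage = "pathways"
            control = design.conditions[0]
            for layer, nets in networks_by_layer.items():
                counts = count_active_by_subsystem(model, nets)
                p_counts = out / f"pathway_counts_{layer}.tsv"
                counts.to_csv(p_counts, sep="\t")
                group_b = [
                    f"{control}@{t}" for t in design.timepoint_labels
                ]
                group_a = [
                    f"{c}@{t}"
                    for c in design.conditions[1:]
                    for t in design.timepoint_labels
                ]
                diff, top = pathway_differences(counts, group_a, group_b)
                p_diff = out / f"pathway_differences_{layer}.tsv"
                frame = diff.rename("mean_diff").to_frame()
                frame["top8"] = [s in top for s in frame.index]
                frame.to_csv(p_diff, sep="\t")
                coords, explained = activity_pca(nets, model)
                p_pca = out / f"activity_pca_{layer}.tsv"
                coords.assign().to_csv(p_pca, sep="\t")
                artifacts += [p_counts, p_diff, p_pca]

        if config.run_mta and config.run_networks:
            current_stage = "mta"
            forward_by_layer, reverse_by_layer = {}, {}
            for li, (layer, de) in enumerate(sorted(layer_tables.items())):
                fwd, _ = mta_run_set(
                    model, de, design, "forward",
                    config.mta_params(), config.imat_params(),
                    seed=config.seed + 1000 * li,
                )
                rev, _ = mta_run_set(
                    model, de, design, "reverse",
                    config.mta_params(), config.imat_params(),
                    seed=config.seed + 1000 * li + 500,
                )
                forward_by_layer[layer] = fwd
                reverse_by_layer[layer] = rev
            overall = overall_score(forward_by_layer, reverse_by_layer)
            p = out / "mta_overall.tsv"
            rows = []
            for g in sorted(overall):
                row = {"gene": g, "overall": overall[g]}
                for layer in forward_by_layer:
                    row[f"forward_{layer}"] = forward_by_layer[layer].get(
                        g, 0.0
                    )
                    row[f"reverse_{layer}"] = reverse_by_layer[layer].get(
                        g, 0.0
                    )
                rows.append(row)
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            artifacts.append(p)

        if config.run_clustering:
            current_stage = "clustering"
            de = layer_tables[sorted(layer_tables)[0]]
            fc = fold_change_matrix_from_de(de, design)
            result = kmeans_aic(
                fc,
                k_range=config.k_range,
                restarts=config.kmeans_restarts,
                seed=config.seed,
            )
            p_assign = out / "cluster_assignment.tsv"
            pd.DataFrame(
                {
                    "gene": list(result.assignment),
                    "cluster": list(result.assignment.values()),
                }
            ).to_csv(p_assign, sep="\t", index=False)
            p_aic = out / "cluster_criterion.tsv"
            pd.DataFrame(
                {
                    "k": list(result.criterion_by_k),
                    "aic": list(result.criterion_by_k.values()),
                }
            ).to_csv(p_aic, sep="\t", index=False)
            artifacts += [p_assign, p_aic]
    except Exception as exc:
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "status": "failed",
            "failed_stage": current_stage,
            "error": str(exc),
            "artifacts": {
                str(p.relative_to(out)): _sha256(p)
                for p in artifacts
                if p.exists()
            },
        }
        _write_json(manifest_path, manifest)
        raise

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "status": "ok",
        "parameters": asdict(config),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in artifacts
        },
    }
    _write_json(manifest_path, manifest)
    return manifest


def fold_change_matrix_from_de(de: pd.DataFrame, design) -> pd.DataFrame:
    """Gene x contrast matrix of microbiota-vs-control fold-changes taken
    from the cross-condition rows of a DE table."""
    control = design.conditions[0]
    rows = []
    for c in design.conditions[1:]:
        for t in design.timepoint_labels:
            sel = (de["side_a"] == f"{c}@{t}") & (
                de["side_b"] == f"{control}@{t}"
            )
            sub = de.loc[sel, ["gene", "log2fc"]].set_index("gene")["log2fc"]
            rows.append(sub.rename(f"{c}_vs_{control}@{t}"))
    fc = pd.concat(rows, axis=1)
    return fc.dropna()


def simulate_bundle(
    outdir: str | Path,
    variant: str = "diamond",
    seed: int = 7,
    force: bool = False,
) -> PipelineConfig:
    """Write a ready-to-run synthetic bundle plus a matching config."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"{outdir} exists and is not empty (pass force=True)"
        )
    bundle = plant_transformation_scenario(variant=variant, seed=seed)
    bundle.write(outdir)
    config = PipelineConfig(
        model_path=str(outdir / "model.json"),
        de_paths={
            layer: str(outdir / f"de_{layer}.tsv")
            for layer in bundle.de_tables
        },
        output_dir=str(outdir / "results"),
        conditions=list(bundle.design.conditions),
        timepoints=[list(t) for t in bundle.design.timepoints],
        replicates=bundle.design.replicates,
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return config
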