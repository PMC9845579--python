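"""End-to-end pipeline orchestration from a structured config file.

Stages run in a fixed order — synthetic generation (or loading), variable
standardization, the univariate Kendall screen, ensemble network fitting,
consensus/subnetwork/phenotype-parent reporting, counterfactual dose-
response, and quartile/SNP association tables — each writing its artifacts
into the output directory and recording seeds, input hashes, and durations
in a JSON manifest.  A single global seed fans out deterministically to
per-stage seeds (SeedSequence(global_seed, stage_index)) so any stage can
be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, counterfactual, search, synthetic
from .datasets import PanomicDataset, class_map, load_dataset, standardize
from .model import PanomicNetworkModel
from .scoring import PenaltyConfig
from .search import ConstraintSet

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = [
    "data",
    "standardize",
    "screen",
    "network",
    "consensus_reports",
    "counterfactual",
    "association",
]


@dataclass
class PipelineConfig:
    """Validated settings for a full pipeline run."""

    output_dir: str
    seed: int
    # data source: synthetic mode or matrix/meta paths
    synthetic_mode: bool = True
    synthetic_n: int = 600
    n_nuisance_per_class: int = 1
    matrix_path: str | None = None
    meta_path: str | None = None
    ground_truth_path: str | None = None
    # network settings
    n_networks: int = 50
    resample: str = "bootstrap"
    restarts: int = 2
    threshold: float = 0.05
    penalty_style: str = "per_term"
    gamma: float = 0.5
    max_parents: int = 3
    root_classes: tuple = ("genetics",)
    tiers: tuple = ()
    # analysis focus
    phenotype_node: str = "ASCAD"
    focus_node: str = "LDL_TG"
    dose_grid_points: int = 5
    stages: tuple = tuple(_STAGES)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory when stochastic stages are enabled")
        if not self.synthetic_mode:
            if not self.matrix_path or not self.meta_path:
                raise ValueError("matrix_path and meta_path required outside synthetic mode")
            for p in (self.matrix_path, self.meta_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)


def _stage_seed(global_seed: int, stage_index: int) -> int:
    return int(
        np.random.SeedSequence([global_seed, stage_index]).generate_state(1)[0] % (2**31)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
    }

    def record(stage, t0, artifacts: dict):
        entry = {
            "stage": stage,
            "seconds": round(time.perf_counter() - t0, 3),
            "seed": _stage_seed(config.seed, _STAGES.index(stage)),
        }
        manifest["stages"].append(entry)
        for name, path in artifacts.items():
            manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    try:
        # -- stage: data -----------------------------------------------------
        t0 = time.perf_counter()
        if config.synthetic_mode:
            if config.ground_truth_path:
                spec = synthetic.GroundTruthSpec.from_yaml(config.ground_truth_path)
            else:
                spec = synthetic.default_ground_truth(config.n_nuisance_per_class)
            dataset = synthetic.sample_dataset(
                spec, config.synthetic_n, seed=_stage_seed(config.seed, 0)
            )
            spec.to_yaml(out / "ground_truth.yaml")
            edges_path = out / "true_edges.tsv"
            with open(edges_path, "w") as fh:
                fh.write("from\tto\n")
                for u, v in sorted(synthetic.true_edges(spec)):
                    fh.write(f"{u}\t{v}\n")
            truth = spec
        else:
            dataset = load_dataset(config.matrix_path, config.meta_path)
            truth = None
        dataset.save(out / "matrix.tsv", out / "meta.tsv")
        artifacts = {"matrix": out / "matrix.tsv", "meta": out / "meta.tsv"}
        if truth is not None:
            artifacts.update(
                {"ground_truth": out / "ground_truth.yaml", "true_edges": out / "true_edges.tsv"}
            )
        record("data", t0, artifacts)

        # -- stage: standardize ----------------------------------------------
        t0 = time.perf_counter()
        analysis_ds = standardize(dataset) if "standardize" in config.stages else dataset
        analysis_ds.save(out / "matrix_standardized.tsv", out / "meta_standardized.tsv")
        record("standardize", t0, {"matrix_standardized": out / "matrix_standardized.tsv"})

        # -- stage: screen ---------------------------------------------------
        t0 = time.perf_counter()
        pheno = config.phenotype_node
        continuous = [m.name for m in dataset.meta if m.kind == "continuous"]
        taus, ps, kept = association.kendall_screen(
            dataset.values[continuous], dataset.values[[pheno]]
        )
        screen = taus.join(ps, lsuffix="_tau", rsuffix="_p")
        screen["kept"] = [c in kept for c in screen.index]
        screen.to_csv(out / "kendall_screen.tsv", sep="\t")
        record("screen", t0, {"kendall_screen": out / "kendall_screen.tsv"})

        # -- stage: network --------------------------------------------------
        t0 = time.perf_counter()
        penalty = PenaltyConfig(
            class_map=class_map(analysis_ds), style=config.penalty_style, gamma=config.gamma
        )
        constraints = ConstraintSet(
            tiers=tuple(tuple(t) for t in config.tiers),
            root_classes=tuple(config.root_classes),
            max_parents=config.max_parents,
        )
        model = PanomicNetworkModel(analysis_ds, penalty, constraints)
        results = model.fit(
            n_networks=config.n_networks,
            seed=_stage_seed(config.seed, 3),
            resample=config.resample,
            restarts=config.restarts,
            threshold=config.threshold,
        )
        record("network", t0, {})

        # -- stage: consensus reports ----------------------------------------
        t0 = time.perf_counter()
        results.consensus.to_tsv(out / "consensus.tsv")
        results.consensus.to_graphml(out / "consensus.graphml")
        results.consensus.to_dot(out / "consensus.dot")
        sub = results.subnetwork(config.focus_node, degree=1)
        sub.to_tsv(out / "subnetwork.tsv")
        results.phenotype_parents(pheno).to_csv(
            out / "phenotype_parents.tsv", sep="\t", index=False
        )
        record(
            "consensus_reports",
            t0,
            {
                "consensus": out / "consensus.tsv",
                "consensus_graphml": out / "consensus.graphml",
                "consensus_dot": out / "consensus.dot",
                "subnetwork": out / "subnetwork.tsv",
                "phenotype_parents": out / "phenotype_parents.tsv",
            },
        )

        # -- stage: counterfactual -------------------------------------------
        t0 = time.perf_counter()
        focus = analysis_ds.column(config.focus_node)
        grid = np.linspace(focus.min(), focus.max(), config.dose_grid_points)
        dose = counterfactual.population_dose_response(
            results.ensemble, analysis_ds, config.focus_node, grid, pheno
        )
        dose.to_csv(out / "dose_response.tsv", sep="\t", index=False)
        record("counterfactual", t0, {"dose_response": out / "dose_response.tsv"})

        # -- stage: association ----------------------------------------------
        t0 = time.perf_counter()
        quart = association.quartile_logistic(
            dataset.column(config.focus_node), dataset.column(pheno)
        )
        quart.to_csv(out / "quartile_or.tsv", sep="\t")
        artifacts = {"quartile_or": out / "quartile_or.tsv"}
        genos = [m.name for m in dataset.meta if m.kind == "genotype_additive"]
        snp_rows = []
        for gname in genos:
            try:
                r = association.snp_association(
                    dataset.column(gname),
                    dataset.column(config.focus_node),
                    snp_name=gname,
                    outcome_name=config.focus_node,
                )
                snp_rows.append(
                    (r.exposure, r.outcome, r.kind, r.estimate, r.se, r.ci_lower, r.ci_upper, r.p)
                )
            except ValueError:
                logger.warning("skipping monomorphic genotype %r", gname)
        if snp_rows:
            import pandas as pd

            pd.DataFrame(
                snp_rows,
                columns=["snp", "outcome", "kind", "estimate", "se", "ci_lower", "ci_upper", "p"],
            ).to_csv(out / "snp_association.tsv", sep="\t", index=False)
            artifacts["snp_association"] = out / "snp_association.tsv"
        curve = association.cumulative_incidence_curve(
            dataset.column(config.focus_node), dataset.column(pheno)
        )
        curve.to_csv(out / "cumulative_incidence.tsv", sep="\t", index=False)
        artifacts["cumulative_incidence"] = out / "cumulative_incidence.tsv"
        record("association", t0, artifacts)

    except Exception:
        manifest["status"] = "failed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
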