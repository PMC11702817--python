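"""Configuration-driven orchestration of the full analysis.

Stages: simulate a synthetic cohort from the ground-truth network ->
one-hot encode and select features -> learn the network with family
blacklists -> evaluate (held-out AUC, cross-validation, rare-scenario
subsets) -> answer scenario risk queries with bootstrap intervals.
Every stage is deterministic given the config's seeds, and each output
bundle is stamped with a config hash so stale artifacts are detectable.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, risk, synthetic
from .bayesnet import (
    BayesNet,
    blacklist_from_families,
    fit_parameters,
    learn_structure,
    terminal_node_blacklist,
)
from .cohort import Cohort, expand_families, summarize
from .evaluation import SplitSpec, auc_with_ci, cross_validate, split, unique_scenarios
from .inference import predict_batch
from .risk import BACKGROUND, Scenario, estimate_risk

log = logging.getLogger("contextrisk")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: str = "results/pipeline"
    n: int = 20_000
    seeds: dict = field(
        default_factory=lambda: {
            "simulation": 11,
            "split": 22,
            "structure": 33,
            "bootstrap": 44,
            "selection": 55,
        }
    )
    missingness: dict = field(default_factory=lambda: {"efw": 0.064, "bp_high": 0.049})
    feature_selection: dict = field(
        default_factory=lambda: {
            "m": 12,
            "k": 8,
            "mode": "greedy",
            "jaccard_threshold": 0.8,
            "forced_includes": ["hdp", "ga_term", "efw_lt3", "efw_p3to9"],
        }
    )
    network: dict = field(
        default_factory=lambda: {"restarts": 5, "method": "bayes", "alpha": 1.0}
    )
    bootstrap_b: int = 200
    folds: int = 5
    scenarios: list = field(
        default_factory=lambda: [
            {"label": "background", "evidence": {}},
            {"label": "EFW 3-9th percentile", "evidence": {"efw_p3to9": "present"}},
            {
                "label": "EFW 3-9th + diabetes + female",
                "evidence": {
                    "efw_p3to9": "present",
                    "diabetes": "present",
                    "female": "present",
                },
            },
        ]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise PipelineError("config", f"unknown config key {key!r}")
            setattr(cfg, key, value)
        if cfg.bootstrap_b < 2:
            raise PipelineError("config", "bootstrap_b must be at least 2")
        return cfg

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _out(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _stamp(config: PipelineConfig, stage: str, extra: Mapping[str, Any] | None = None) -> None:
    out = _out(config)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest[stage] = {"config_hash": config.hash(), "seeds": config.seeds, **(extra or {})}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _check_stage(config: PipelineConfig, stage: str) -> None:
    manifest_path = _out(config) / "manifest.json"
    if not manifest_path.exists():
        return
    manifest = json.loads(manifest_path.read_text())
    if stage in manifest and manifest[stage]["config_hash"] != config.hash():
        log.warning("stale upstream artifact for stage %s (config hash mismatch)", stage)


def stage_simulate(config: PipelineConfig) -> dict:
    out = _out(config)
    truth_cfg = synthetic.TruthConfig(
        n=config.n, seed=config.seeds["simulation"], missingness=config.missingness
    )
    net, cohort = synthetic.simulate(truth_cfg)
    cohort.to_csv(out / "cohort.csv", out / "cohort.schema.json")
    net.to_json(out / "truth_network.json")
    summarize(cohort).to_csv(out / "summary.csv", index=False)
    _stamp(config, "simulate", {"n": cohort.n})
    return {"cohort": str(out / "cohort.csv"), "truth_network": str(out / "truth_network.json")}


def _load_cohort(config: PipelineConfig) -> Cohort:
    out = _out(config)
    path = out / "cohort.csv"
    if not path.exists():
        raise PipelineError("select", f"missing upstream cohort {path}; run simulate first")
    return Cohort.from_csv(path, out / "cohort.schema.json")


def stage_select(config: PipelineConfig) -> dict:
    _check_stage(config, "simulate")
    out = _out(config)
    cohort = _load_cohort(config)
    encoded = expand_families(cohort)
    fs = config.feature_selection
    ranking = features.rank_features(encoded)
    retained = features.prune_redundant(ranking, encoded, fs.get("jaccard_threshold", 0.8))
    ranked = [v for v in ranking.top(len(ranking.table)) if v in retained]
    top_m = ranked[: fs["m"]]
    best = features.search_combinations(
        encoded,
        top_m,
        fs["k"],
        mode=fs.get("mode", "greedy"),
        seed=config.seeds.get("selection", 0),
    )
    final = features.assemble_pgm_features(
        encoded, best.feature_set, fs.get("forced_includes", [])
    )
    ranking.table.to_csv(out / "ranking.csv")
    (out / "selected_features.json").write_text(
        json.dumps(
            {
                "top_m": top_m,
                "best_subset": list(best.feature_set),
                "best_subset_auc": best.auc,
                "n_evaluated": best.n_evaluated,
                "final_features": final,
            },
            indent=2,
        )
    )
    _stamp(config, "select", {"n_features": len(final)})
    return {"selected_features": str(out / "selected_features.json")}


def _pipeline_blacklist(cohort: Cohort):
    """Family blacklists (mutually exclusive one-hot siblings) plus the
    clinical constraint that the composite outcome is terminal."""
    return blacklist_from_families(cohort.specs).union(
        terminal_node_blacklist(cohort.variables, cohort.outcome)
    )


def _selected_cohort(config: PipelineConfig) -> Cohort:
    out = _out(config)
    sel_path = out / "selected_features.json"
    if not sel_path.exists():
        raise PipelineError("learn", f"missing upstream artifact {sel_path}; run select first")
    final = json.loads(sel_path.read_text())["final_features"]
    cohort = expand_families(_load_cohort(config))
    return cohort.select(final)


def stage_learn(config: PipelineConfig) -> dict:
    _check_stage(config, "select")
    out = _out(config)
    cohort = _selected_cohort(config)
    blacklist = _pipeline_blacklist(cohort)
    dag = learn_structure(
        cohort,
        blacklist=blacklist,
        seed=config.seeds["structure"],
        restarts=config.network.get("restarts", 5),
    )
    net = fit_parameters(
        dag,
        cohort,
        method=config.network.get("method", "bayes"),
        alpha=config.network.get("alpha", 1.0),
    )
    net.to_json(out / "network.json")
    _stamp(config, "learn", {"n_edges": len(dag.edges)})
    return {"network": str(out / "network.json")}


def stage_evaluate(config: PipelineConfig) -> dict:
    _check_stage(config, "learn")
    out = _out(config)
    cohort = _selected_cohort(config)
    derivation, validation = split(cohort, SplitSpec(seed=config.seeds["split"]))
    blacklist = _pipeline_blacklist(cohort)
    builder = evaluation.pgm_model_builder(
        blacklist=blacklist,
        restarts=config.network.get("restarts", 5),
        method=config.network.get("method", "bayes"),
        alpha=config.network.get("alpha", 1.0),
    )
    scorer = builder(derivation, config.seeds["structure"])
    scores = scorer(validation)
    labels = (validation.records[validation.outcome] == "present").astype(int).to_numpy()
    report = auc_with_ci(scores, labels, b=config.bootstrap_b, seed=config.seeds["bootstrap"])
    cv = cross_validate(
        derivation, folds=config.folds, model_builder=builder, seed=config.seeds["split"]
    )
    rare = unique_scenarios(
        cohort, validation, 1, scores=scores, b=config.bootstrap_b, seed=config.seeds["bootstrap"]
    )
    payload = {
        "validation": report.as_dict(),
        "cross_validation": cv,
        "n_of_1": {
            "n": rare.n,
            "fraction_of_validation_pct": round(100 * rare.fraction_of_validation, 1),
            "report": rare.report.as_dict() if rare.report else None,
            "reason": rare.reason,
        },
    }
    (out / "evaluation.json").write_text(json.dumps(payload, indent=2))
    _stamp(config, "evaluate", {"validation_auc": report.auc})
    return {"evaluation": str(out / "evaluation.json")}


def stage_query(config: PipelineConfig) -> dict:
    _check_stage(config, "learn")
    out = _out(config)
    net_path = out / "network.json"
    if not net_path.exists():
        raise PipelineError("query", f"missing network artifact {net_path}; run learn first")
    net = BayesNet.from_json(net_path)
    cohort = _selected_cohort(config)
    scenarios = config.scenarios
    if isinstance(scenarios, str):
        path = Path(scenarios)
        if not path.exists():
            raise PipelineError("query", f"scenario file {path} not found")
        scenarios = yaml.safe_load(path.read_text())
    rows = []
    for i, sc in enumerate(scenarios):
        scenario = Scenario(sc["label"], dict(sc.get("evidence", {})))
        est = estimate_risk(
            net,
            cohort,
            net.dag,
            scenario,
            sc.get("target", cohort.outcome),
            b=config.bootstrap_b,
            seed=config.seeds["bootstrap"] + i,
            method=config.network.get("method", "bayes"),
            alpha=config.network.get("alpha", 1.0),
        )
        rows.append(est.as_row())
    table = pd.DataFrame(rows)
    table.to_csv(out / "scenario_risks.csv", index=False)
    _stamp(config, "query", {"n_scenarios": len(rows)})
    return {"scenario_risks": str(out / "scenario_risks.csv")}


STAGES = {
    "simulate": stage_simulate,
    "select": stage_select,
    "learn": stage_learn,
    "evaluate": stage_evaluate,
    "query": stage_query,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; any failure aborts with the stage name."""
    artifacts: dict = {}
    for name in ("simulate", "select", "learn", "evaluate", "query"):
        log.info("running stage %s", name)
        try:
            artifacts.update(STAGES[name](config))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(name, str(exc)) from exc
    return artifacts
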