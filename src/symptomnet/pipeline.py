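"""Configuration-driven end-to-end orchestration.

Stages: simulate (optional fixture generation) -> screen -> estimate ->
centrality/report -> stability -> layout/figure. Each stage consumes
the previous stage's serialized outputs, so stages can be re-run
individually from the CLI; a manifest records every artifact with its
SHA-256 hash, the effective config, and the per-stage seeds derived
from the single global seed.

Every analysis constant (screening cutoffs, EBIC gamma, fold count,
bootstrap iterations, CI level) lives in the config, not in code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import screening as scr
from .association import ItemResponseMatrix
from .centrality import centrality_table
from .ggm import (
    NetworkModel,
    SelectionConfig,
    cross_community_edges,
    gamma_sensitivity,
    select_network,
)
from .layout import fruchterman_reingold, render_network
from .reporting import make_table1, write_table1
from .screening import NODE_LABELS
from .simulate import (
    SimulationConfig,
    inject_missingness,
    make_ground_truth,
    make_roster,
    sample_ordinal,
    write_roster,
)
from .stability import (
    BootstrapConfig,
    bootstrap_edges,
    case_drop_bootstrap,
    difference_test_centrality,
    difference_test_edges,
    make_estimator,
)

logger = logging.getLogger(__name__)

COMMUNITY_OF = {lab: ("anxiety" if lab.startswith("GAD") else "depression")
                for lab in NODE_LABELS}

STAGES = ("simulate", "screen", "estimate", "stability", "report")


@dataclass
class RunConfig:
    """Validated run configuration; serializable to/from YAML."""

    out_dir: str = "symptomnet_out"
    roster: str | None = None  # input roster; None -> simulate stage provides it
    column_map: dict[str, str] | None = None
    seed: int = 20170101
    log_level: str = "INFO"
    # simulate stage
    simulate_n: int = 2477
    simulate_stage_counts: tuple[int, int, int] | None = (318, 120, 87)
    # estimation
    gamma: float = 0.5
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    selection_mode: str = "direct_ebic"
    sensitivity_gammas: tuple[float, ...] = (0.1, 0.5, 0.9)
    # screening cutoffs (reported, also used for prevalence flags)
    gad_cutoff: int = 5
    cesd_cutoff: int = 10
    # stability
    n_boot: int = 1000
    ci_level: float = 0.95
    drop_proportions: tuple[float, ...] = tuple(
        np.round(np.arange(0.10, 0.76, 0.05), 2)
    )
    cs_correlation: float = 0.7
    cs_probability: float = 0.95
    # layout
    layout_iterations: int = 500

    def stage_seeds(self) -> dict[str, int]:
        """One deterministic sub-seed per stage from the global seed."""
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGES))
        return {stage: int(s % (2**31)) for stage, s in zip(STAGES, state)}

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            gamma=self.gamma, n_folds=self.n_folds, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            seed=self.stage_seeds()["estimate"], mode=self.selection_mode,
        )

    def bootstrap_config(self) -> BootstrapConfig:
        return BootstrapConfig(
            n_boot=self.n_boot, seed=self.stage_seeds()["stability"],
            ci_level=self.ci_level,
            drop_proportions=tuple(self.drop_proportions),
            cs_correlation=self.cs_correlation,
            cs_probability=self.cs_probability,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("simulate_stage_counts", "sensitivity_gammas",
                    "drop_proportions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = [float(x) if isinstance(x, (float, np.floating)) else x
                        for x in v]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(stage, f"missing upstream artifact {path}")
    return path


def stage_simulate(config: RunConfig, out: Path) -> Path:
    """Generate a synthetic roster with planted network + screening flow."""
    seed = config.stage_seeds()["simulate"]
    truth = make_ground_truth(seed=seed)
    sim = SimulationConfig(n=config.simulate_n, seed=seed,
                           stage_counts=config.simulate_stage_counts)
    data = sample_ordinal(truth, n=config.simulate_n, seed=seed)
    roster = make_roster(data, seed=seed)
    roster = inject_missingness(roster, sim)
    roster_path = out / "roster.csv"
    write_roster(roster, roster_path)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps({
        "node_labels": truth.node_labels,
        "communities": truth.communities,
        "bridge_edges": truth.bridge_edges,
        "partials": truth.partials.tolist(),
    }, indent=2))
    return roster_path


def stage_screen(config: RunConfig, out: Path) -> dict[str, Path]:
    roster_path = Path(config.roster) if config.roster else out / "roster.csv"
    _require(roster_path, "screen")
    records = scr.parse_roster(roster_path, config.column_map)
    retained, report = scr.apply_exclusions(records)
    if not retained:
        raise PipelineError("screen", "no records survived screening")
    report_path = out / "screening_report.json"
    report.to_json(report_path)
    retained_path = out / "retained.csv"
    scr.records_to_frame(retained).to_csv(retained_path, index=False)
    desc = scr.descriptives(retained)
    desc_path = out / "descriptives.csv"
    desc.to_csv(desc_path)
    prev_path = out / "prevalences.json"
    prev_path.write_text(json.dumps(scr.flag_prevalences(retained), indent=2))
    return {"report": report_path, "retained": retained_path,
            "descriptives": desc_path, "prevalences": prev_path}


def _load_retained(out: Path, stage: str) -> ItemResponseMatrix:
    frame = pd.read_csv(_require(out / "retained.csv", stage))
    return ItemResponseMatrix.from_frame(frame, NODE_LABELS, COMMUNITY_OF)


def stage_estimate(config: RunConfig, out: Path) -> dict[str, Path]:
    data = _load_retained(out, "estimate")
    model, path = select_network(data, config.selection_config())
    paths = {
        "model": out / "network_model.json",
        "weights": out / "network_weights.csv",
        "edges": out / "edge_list.csv",
        "path": out / "regularization_path.csv",
    }
    model.to_json(paths["model"])
    model.to_csv(paths["weights"])
    model.edge_list().to_csv(paths["edges"], index=False)
    pd.DataFrame({
        "lambda": path.lambda_grid,
        "ebic": path.ebic_values,
        "n_edges": [m.n_edges for m in path.models],
    }).to_csv(paths["path"], index=False)
    if config.sensitivity_gammas:
        sens = gamma_sensitivity(data, tuple(config.sensitivity_gammas),
                                 config.selection_config())
        sens_path = out / "gamma_sensitivity.json"
        sens_path.write_text(json.dumps({
            "edge_counts": {str(g): m.n_edges for g, m in sens["models"].items()},
            "comparisons": sens["comparisons"],
        }, indent=2))
        paths["gamma_sensitivity"] = sens_path
    return paths


def stage_stability(config: RunConfig, out: Path) -> dict[str, Path]:
    data = _load_retained(out, "stability")
    _require(out / "network_model.json", "stability")
    estimator = make_estimator(config.selection_config())
    bconf = config.bootstrap_config()
    boot = bootstrap_edges(data, estimator, bconf)
    cs = case_drop_bootstrap(data, estimator, bconf)
    paths = {
        "edge_cis": out / "edge_cis.csv",
        "edge_diff": out / "difference_test_edges.csv",
        "ei_diff": out / "difference_test_ei.csv",
        "bei_diff": out / "difference_test_bei.csv",
        "cs": out / "cs_coefficients.json",
        "cs_curves": out / "cs_curves.csv",
    }
    boot.edge_table().to_csv(paths["edge_cis"], index=False)
    difference_test_edges(boot).to_csv(paths["edge_diff"])
    difference_test_centrality(boot, "EI").to_csv(paths["ei_diff"])
    difference_test_centrality(boot, "BEI").to_csv(paths["bei_diff"])
    paths["cs"].write_text(json.dumps({
        "cs": cs.cs,
        "interpretation": cs.interpretation(),
        "n_boot": bconf.n_boot,
        "skipped_proportions": cs.skipped_proportions,
    }, indent=2))
    cs.curves.to_csv(paths["cs_curves"], index=False)
    return paths


def stage_report(config: RunConfig, out: Path) -> dict[str, Path]:
    model = NetworkModel.from_json(_require(out / "network_model.json", "report"))
    desc = pd.read_csv(_require(out / "descriptives.csv", "report"), index_col=0)
    cent = centrality_table(model)
    paths = {
        "centrality": out / "centrality.csv",
        "table1": out / "table1.csv",
        "cross_edges": out / "cross_community_edges.csv",
    }
    cent.to_csv(paths["centrality"])
    write_table1(make_table1(desc, cent, decimals=2), paths["table1"])
    pd.DataFrame(
        cross_community_edges(model), columns=["node_a", "node_b", "weight"]
    ).to_csv(paths["cross_edges"], index=False)
    coords = fruchterman_reingold(model, seed=config.stage_seeds()["report"],
                                  n_iter=config.layout_iterations)
    written = render_network(model, coords, out / "network")
    paths.update({f"figure_{k}": v for k, v in written.items()})
    return paths


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages and write a manifest; returns the manifest dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    artifacts: dict[str, str] = {"config": str(out / "config.yaml")}

    def record(stage: str, produced: dict[str, Path] | Path) -> None:
        if isinstance(produced, Path):
            produced = {stage: produced}
        artifacts.update({f"{stage}.{k}": str(v) for k, v in produced.items()})

    manifest_path = out / "manifest.json"
    try:
        if config.roster is None:
            record("simulate", stage_simulate(config, out))
            record("simulate.truth", {"ground_truth": out / "ground_truth.json"})
        record("screen", stage_screen(config, out))
        record("estimate", stage_estimate(config, out))
        record("stability", stage_stability(config, out))
        record("report", stage_report(config, out))
    except Exception as exc:
        manifest = {
            "status": "failed",
            "error": str(exc),
            "artifacts": {k: {"path": v} for k, v in artifacts.items()},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise
    manifest = {
        "status": "ok",
        "seed": config.seed,
        "stage_seeds": config.stage_seeds(),
        "n_boot": config.n_boot,
        "artifacts": {
            k: {"path": v, "sha256": _sha256(Path(v))}
            for k, v in sorted(artifacts.items())
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
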