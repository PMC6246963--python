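"""End-to-end analysis pipeline and its report bundle.

Stages: load quiz -> (simulate or read responses) -> QC -> error metrics ->
crowd aggregation -> bias models -> error-correlation network.  Every stage
writes its artifact under the output directory, and ``manifest.json`` records
the configuration, master seed, QC report and a SHA-256 checksum per artifact,
so every number in ``report.json`` is traceable to a file.  The same
configuration and seed reproduce the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias_models import REGISTERED_MODELS, density_bias_curve, density_mass_correlation, fit_bias_model
from .crowd_consensus import bootstrap_crowd_test, convergence_curve, crowd_estimate, expert_comparison
from .error_metrics import compute_metrics, participant_summaries, per_food_summary
from .error_network import build_graph, cluster_foods, error_correlation_matrix
from .qc_filters import apply_qc
from .quiz_model import QuizSpec, load_quiz, read_responses, responses_to_frame, write_responses
from .synthetic_cohort import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``responses_source`` (a CSV to analyze) and ``simulation``
    (a cohort to generate) must be given.
    """

    out_dir: str | Path
    quiz_source: str = "table1"
    responses_source: str | Path | None = None
    demographics_source: str | Path | None = None
    simulation: SimulationConfig | None = None
    seed: int = 0
    k_grid: list[int] = field(default_factory=lambda: [1, 2, 5, 10, 20, 50, 100])
    n_draws: int = 100
    bootstrap_k1: int = 10
    bootstrap_k2: int | None = None  # default: min(1000, available participants)
    bootstrap_B: int = 500
    aggregator: str = "mean"
    bias_model_names: list[str] = field(default_factory=lambda: list(REGISTERED_MODELS))
    network_threshold: float = 0.3
    cluster_cut: float = 0.7
    expert_k_max: int = 20
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.responses_source is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of responses_source and simulation must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in data and isinstance(data["simulation"], dict):
            data["simulation"] = SimulationConfig(**data["simulation"])
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        if self.responses_source is not None:
            d["responses_source"] = str(self.responses_source)
        if self.demographics_source is not None:
            d["demographics_source"] = str(self.demographics_source)
        return d


def _stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the consolidated report dict.

    Artifacts written under ``config.out_dir``: the (possibly simulated)
    response table, QC report, metrics and summary CSVs, convergence curve,
    bootstrap test, expert comparison (when experts are present), bias-model
    fits, correlation matrix/edge list/GraphML/clusters, ``report.json`` and
    ``manifest.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        artifacts.append(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        _write_json(obj, path)
        artifacts.append(path)

    # -- stage: load ------------------------------------------------------
    try:
        quiz = load_quiz(config.quiz_source)
    except Exception as exc:
        raise RuntimeError(f"stage 'load_quiz' failed: {exc}") from exc

    # -- stage: acquire responses ----------------------------------------
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation.to_dict(), "seed": config.seed})
        participants, responses = simulate_cohort(quiz, sim)
        write_responses(participants, responses, out / "responses.csv",
                        demographics_path=out / "participants.csv")
        artifacts += [out / "responses.csv", out / "participants.csv"]
    else:
        try:
            participants, responses = read_responses(
                config.responses_source, config.demographics_source, quiz=quiz
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'read_responses' failed: {exc}") from exc

    # -- stage: QC --------------------------------------------------------
    participants, responses, qc_report = apply_qc(participants, responses, quiz)
    save_json(qc_report.to_dict(), "qc_report.json")
    if not responses:
        raise RuntimeError("stage 'qc' failed: no responses retained")

    # -- stage: metrics ---------------------------------------------------
    metrics = compute_metrics(responses, quiz)
    save_csv(metrics, "metrics.csv")
    psumm = participant_summaries(metrics)
    save_csv(psumm, "participant_summaries.csv")
    save_csv(per_food_summary(metrics, quiz), "per_food_summary.csv")

    expert_ids = {p.participant_id for p in participants if p.is_expert}
    nonexp_metrics = metrics[~metrics["participant_id"].isin(expert_ids)]
    exp_metrics = metrics[metrics["participant_id"].isin(expert_ids)]
    n_nonexpert = nonexp_metrics["participant_id"].nunique()

    # -- stage: crowd -----------------------------------------------------
    k_grid = [k for k in config.k_grid if k <= n_nonexpert]
    curve = convergence_curve(
        nonexp_metrics, quiz, k_grid, n_draws=config.n_draws,
        aggregator=config.aggregator, seed=_stage_seed(config.seed, 1),
    )
    save_csv(curve, "convergence_curve.csv")

    consensus = crowd_estimate(
        nonexp_metrics, quiz, k=n_nonexpert, aggregator=config.aggregator,
        seed=_stage_seed(config.seed, 2),
    )
    save_json(consensus.to_dict(), "crowd_consensus.json")

    k2 = config.bootstrap_k2 or min(1000, n_nonexpert)
    k1 = min(config.bootstrap_k1, n_nonexpert)
    boot = bootstrap_crowd_test(
        nonexp_metrics, quiz, k1=k1, k2=k2, B=config.bootstrap_B,
        aggregator=config.aggregator, seed=_stage_seed(config.seed, 3),
    )
    save_json(boot.to_dict(), "bootstrap_test.json")

    expert_cmp = None
    if expert_ids:
        cmp_result = expert_comparison(
            nonexp_metrics, exp_metrics, quiz, k_max=config.expert_k_max,
            n_draws=config.n_draws, aggregator=config.aggregator,
            seed=_stage_seed(config.seed, 4),
        )
        save_csv(cmp_result.table, "expert_comparison.csv")
        expert_cmp = cmp_result.to_dict()
        expert_cmp.pop("table")
        save_json(expert_cmp, "expert_comparison.json")

    # -- stage: bias models ----------------------------------------------
    fits = {}
    for name in config.bias_model_names:
        try:
            fits[name] = fit_bias_model(metrics, participants, quiz, name).to_dict()
        except Exception as exc:
            raise RuntimeError(f"stage 'bias_models' failed on {name!r}: {exc}") from exc
    save_json(fits, "bias_fits.json")
    save_csv(density_bias_curve(metrics, quiz), "density_bias_curve.csv")

    # -- stage: network ---------------------------------------------------
    corr = error_correlation_matrix(metrics)
    path = out / "error_correlation_matrix.csv"
    corr.to_csv(path)
    artifacts.append(path)
    graph = build_graph(corr, threshold=config.network_threshold)
    graph.clusters = cluster_foods(corr, distance_cut=config.cluster_cut)
    save_csv(graph.edge_frame(), "error_network_edges.csv")
    graph.write_graphml(out / "error_network.graphml")
    artifacts.append(out / "error_network.graphml")
    graph.write_clusters_json(out / "error_network_clusters.json")
    artifacts.append(out / "error_network_clusters.json")

    # -- report and manifest ---------------------------------------------
    report = {
        "seed": config.seed,
        "quiz": {
            "source": str(config.quiz_source),
            "n_foods": len(quiz),
            "density_mass_correlation": density_mass_correlation(quiz),
        },
        "qc": qc_report.to_dict(),
        "accuracy": {
            "n_participants": int(psumm.shape[0]),
            "mean_D": float(psumm["D"].mean()),
            "mean_abs_e_kcal": float(metrics["abs_e"].mean()),
            "mean_abs_eta": float(metrics["eta"].abs().mean()),
            "median_e_kcal": float(metrics["e"].median()),
        },
        "crowd": {
            "consensus_D": consensus.crowd_D,
            "consensus_mean_abs_e_kcal": consensus.crowd_mean_abs_e_kcal,
            "bootstrap": boot.to_dict(),
            "expert_comparison": expert_cmp,
        },
        "bias_models": fits,
        "network": {
            "threshold": config.network_threshold,
            "n_edges": len(graph.edges),
            "n_clusters": len(set(graph.clusters.values())),
            "clusters": {k: int(v) for k, v in graph.clusters.items()},
        },
    }
    save_json(report, "report.json")

    config_record = _jsonable(config.to_dict())
    config_record.pop("out_dir")  # keep the bundle byte-identical across directories
    manifest = {
        "package": "crowdcal",
        "version": __version__,
        "seed": config.seed,
        "config": config_record,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    _write_json(manifest, out / "manifest.json")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
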