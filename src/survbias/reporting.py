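"""Run configuration, experiment orchestration, and table rendering.

A RunConfig captures everything a run needs — cohort source (path or generator
parameters), outcome, model families, perturbation settings, cross-validation
plan, composite weights, output directory and master seed — and round-trips to
YAML, so an echoed config reproduces the run (up to floating-point
non-associativity in the network's training).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import build_default_schema, generate_cohort, load_schema, read_cohort, write_cohort
from .metrics import CompositeWeights
from .models import FAMILIES, default_spec
from .perturb import PerturbationConfig
from .pipeline import CVPlan, compare_robustness, feature_sensitivity

__all__ = ["RunConfig", "load_config", "save_config", "render_metrics_table", "run_experiment"]

logger = logging.getLogger(__name__)

# Column order of the human-readable metrics table.
TABLE_COLUMNS = [
    ("accuracy", "Accuracy"),
    ("recall", "Recall"),
    ("f1_weighted", "F1 Weighted"),
    ("cohens_kappa", "Cohen's Kappa"),
    ("positive_precision", "Positive Precision"),
    ("negative_precision", "Negative Precision"),
    ("error_rate", "Error Rate"),
    ("loss", "Loss"),
    ("computing_time_s", "Computing Time (s)"),
]

_DEFAULTS = {
    "cohort": None,          # CSV path; None -> generate synthetically
    "schema": None,          # sidecar path; None -> default schema
    "n": 4184,
    "outcome": "MDD",
    "models": sorted(FAMILIES),
    "p": 0.2,
    "target_features": None,
    "exclude_original": False,
    "folds": 10,
    "stratified": True,
    "w1": 2.0,
    "w2": 0.25,
    "sensitivity": False,
    "epochs": None,          # CNN epochs override; None -> family default
    "output_dir": "survbias_out",
    "seed": 0,
}


@dataclass
class RunConfig:
    cohort: str | None = None
    schema: str | None = None
    n: int = 4184
    outcome: str = "MDD"
    models: list = field(default_factory=lambda: sorted(FAMILIES))
    p: float = 0.2
    target_features: list | None = None
    exclude_original: bool = False
    folds: int = 10
    stratified: bool = True
    w1: float = 2.0
    w2: float = 0.25
    sensitivity: bool = False
    epochs: int | None = None
    output_dir: str = "survbias_out"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} outside [0,1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = set(self.models) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")

    def weights(self) -> CompositeWeights:
        return CompositeWeights(self.w1, self.w2)

    def plan(self) -> CVPlan:
        return CVPlan(k=self.folds, seed=self.seed, stratified=self.stratified)

    def perturbation(self) -> PerturbationConfig:
        targets = tuple(self.target_features) if self.target_features else None
        return PerturbationConfig(p=self.p, target_features=targets,
                                  exclude_original=self.exclude_original, seed=self.seed)


def load_config(path) -> RunConfig:
    """Parse a YAML run config; unknown keys or out-of-range values are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    return RunConfig(**merged)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def render_metrics_table(aggregates: dict):
    """Render per-family aggregates as (long-form CSV DataFrame, human-readable text).

    aggregates: family -> {metric -> {"mean": m, "sd": s}}. The CSV frame keeps
    full precision (columns model, metric, mean, sd); the text table shows
    'mean ± sd' at two decimals in the conventional column order.
    """
    if not aggregates:
        raise ValueError("no aggregate reports to render")
    rows = []
    for family, agg in aggregates.items():
        for metric, ms in agg.items():
            rows.append({"model": family, "metric": metric, "mean": ms["mean"], "sd": ms["sd"]})
    csv_frame = pd.DataFrame(rows)

    header = ["Model"] + [label for _, label in TABLE_COLUMNS]
    lines = ["\t".join(header)]
    for family, agg in aggregates.items():
        cells = [family]
        for key, _ in TABLE_COLUMNS:
            ms = agg.get(key, {"mean": float("nan"), "sd": float("nan")})
            cells.append(f"{ms['mean']:.2f} ± {ms['sd']:.2f}")
        lines.append("\t".join(cells))
    return csv_frame, "\n".join(lines)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: RunConfig) -> Path:
    """Full protocol: load-or-generate cohort, paired original/perturbed CV evaluation,
    optional per-feature sensitivity, rendered outputs and a checksummed manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("survbias")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest = {"package_version": __version__, "config": asdict(config), "outputs": {}}
    try:
        logger.info("config: %s", asdict(config))
        if config.cohort:
            schema = load_schema(config.schema) if config.schema else build_default_schema()
            table = read_cohort(config.cohort, schema)
        else:
            schema = load_schema(config.schema) if config.schema else build_default_schema()
            table = generate_cohort(schema, n=config.n, seed=config.seed)
            write_cohort(table, out / "cohort.csv", out / "schema.yaml")

        specs = [default_spec(f, seed=config.seed) for f in config.models]
        report = compare_robustness(specs, table, config.outcome, config.perturbation(),
                                    config.plan(), config.weights(), epochs=config.epochs)
        for arm in ("original", "perturbed"):
            aggs = {fam: res[arm] for fam, res in report.results.items()}
            csv_frame, text = render_metrics_table(aggs)
            csv_frame.to_csv(out / f"metrics_{arm}.csv", index=False)
            (out / f"metrics_{arm}.txt").write_text(text + "\n")

        if config.sensitivity:
            spec = specs[0]
            sens = feature_sensitivity(spec, table, config.outcome, p=config.p,
                                       plan=config.plan(), weights=config.weights(),
                                       seed=config.seed, epochs=config.epochs)
            sens.to_csv(out / "sensitivity.csv")

        save_config(config, out / "config_echo.yaml")
        manifest["fold_fingerprint"] = report.fold_fingerprint
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        _write_manifest(out, manifest)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    manifest["status"] = "complete"
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
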