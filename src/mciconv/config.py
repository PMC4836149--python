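"""YAML experiment configuration and the end-to-end experiment runner.

An experiment config either points at a feature/label TSV pair or embeds a
synthetic-cohort block (possibly several, one per diagnostic pair).  A single
master seed expands deterministically into per-stage seeds via
``numpy.random.SeedSequence`` spawning, so stages re-run in isolation
reproduce the full run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import SVMConfig
from .data import ALL_CATEGORIES
from .model import MCIConversionModel, MCIConversionResults
from .selection import StabilityConfig
from .synthetic import SynthConfig, generate_cohort

__all__ = ["ExperimentConfig", "ResultsBundle", "run_experiment", "sweep_top_k"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Schema-checked experiment description (see ``default_config()``)."""

    features_path: str | None = None
    labels_path: str | None = None
    synth: list[SynthConfig] = field(default_factory=list)
    categories: tuple[str, ...] = ALL_CATEGORIES
    kernel_alpha: float = 0.01
    cost: float | str = 0.18
    cost_grid_start: float = 0.08
    cost_grid_stop: float = 0.40
    cost_grid_step: float = 0.01
    top_k: int = 10
    sweep_ks: tuple[int, ...] = tuple(range(1, 31))
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.features_path is None and not self.synth:
            raise ValueError("config needs either input paths or a synth block")
        if self.features_path is not None and self.labels_path is None:
            raise ValueError("features_path requires labels_path")
        for p in (self.features_path, self.labels_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        unknown = set(self.categories) - set(ALL_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")

    @property
    def cost_grid(self) -> np.ndarray:
        n = int(round((self.cost_grid_stop - self.cost_grid_start) / self.cost_grid_step))
        return np.round(
            self.cost_grid_start + self.cost_grid_step * np.arange(n + 1), 10
        )

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        synth = raw.pop("synth", [])
        if isinstance(synth, dict):
            synth = [synth]
        raw["synth"] = [s if isinstance(s, SynthConfig) else SynthConfig(**s) for s in synth]
        if "stability" in raw and isinstance(raw["stability"], dict):
            raw["stability"] = StabilityConfig(**raw["stability"])
        if "svm" in raw and isinstance(raw["svm"], dict):
            svm = dict(raw["svm"])
            for key in ("C_grid", "sigma2_grid"):
                if key in svm and svm[key] is not None:
                    svm[key] = np.asarray(svm[key], dtype=float)
            raw["svm"] = SVMConfig(**svm)
        for key in ("categories", "sweep_ks"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "features_path": self.features_path,
            "labels_path": self.labels_path,
            "synth": [s.to_dict() for s in self.synth],
            "categories": list(self.categories),
            "kernel_alpha": self.kernel_alpha,
            "cost": self.cost,
            "cost_grid_start": self.cost_grid_start,
            "cost_grid_stop": self.cost_grid_stop,
            "cost_grid_step": self.cost_grid_step,
            "top_k": self.top_k,
            "sweep_ks": list(self.sweep_ks),
            "stability": {
                "n_subsamples": self.stability.n_subsamples,
                "subsample_fraction": self.stability.subsample_fraction,
                "n_lambdas": self.stability.n_lambdas,
                "lambda_min_ratio": self.stability.lambda_min_ratio,
                "lambda_grid": None
                if self.stability.lambda_grid is None
                else [float(v) for v in self.stability.lambda_grid],
                "top_k_per_combination": self.stability.top_k_per_combination,
                "bootstrap": self.stability.bootstrap,
                "cd_tol": self.stability.cd_tol,
                "cd_max_sweeps": self.stability.cd_max_sweeps,
            },
            "svm": {
                "C_grid": [float(v) for v in self.svm.C_grid],
                "sigma2_grid": None
                if self.svm.sigma2_grid is None
                else [float(v) for v in self.svm.sigma2_grid],
                "inner_folds": self.svm.inner_folds,
                "class_weight": self.svm.class_weight,
            },
            "outdir": self.outdir,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_config(**overrides) -> ExperimentConfig:
    """Config pre-filled with the pipeline defaults and one synthetic pair."""
    base = {"synth": [SynthConfig()]}
    base.update(overrides)
    return ExperimentConfig(**base)


@dataclass
class ResultsBundle:
    """Everything one experiment wrote: metrics, ROC, selection report, echo."""

    metrics: "object"
    results: dict[str, MCIConversionResults]
    outdir: Path


def _build_models(config: ExperimentConfig) -> dict[str, MCIConversionModel]:
    seeds = np.random.SeedSequence(config.seed).spawn(max(len(config.synth), 1))
    models: dict[str, MCIConversionModel] = {}
    common = dict(
        categories=config.categories,
        cost=config.cost,
        cost_grid=config.cost_grid,
        kernel_alpha=config.kernel_alpha,
        top_k=config.top_k,
        stability=config.stability,
        svm=config.svm,
    )
    if config.features_path is not None:
        models["input"] = MCIConversionModel.from_tables(
            config.features_path, config.labels_path, seed=config.seed, **common
        )
    for sc, ss in zip(config.synth, seeds):
        stage_seed = int(ss.generate_state(1)[0] % (2**31))
        cohort, _ = generate_cohort(sc)
        models[sc.pair_tag] = MCIConversionModel(cohort, seed=stage_seed, **common)
    return models


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Run every configured diagnostic pair and write the results bundle."""
    import pandas as pd

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, MCIConversionResults] = {}
    rows = []
    for name, model in _build_models(config).items():
        logger.info("fitting pair %s (n=%d)", name, len(model.cohort))
        res = model.fit()
        results[name] = res
        rows.append(res.metrics_row(pair=f"MCInc vs. MCIc_{name}"))
        res.roc_points.to_csv(outdir / f"roc_{name}.tsv", sep="\t", index=False)
        res.selection_report().to_csv(
            outdir / f"selection_{name}.tsv", sep="\t", index=False
        )
        res.predictions.to_csv(outdir / f"predictions_{name}.tsv", sep="\t", index=False)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config_echo.yaml")
    return ResultsBundle(metrics, results, outdir)


def sweep_top_k(config: ExperimentConfig) -> "object":
    """Per-K AUC table for every configured pair (one fit, SVM refits per K)."""
    import pandas as pd

    if not config.sweep_ks:
        raise ValueError("sweep_ks must be non-empty")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for name, model in _build_models(config).items():
        res = model.fit()
        df = res.sweep_top_k(config.sweep_ks)
        df.insert(0, "diagnostic_pair", f"MCInc vs. MCIc_{name}")
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "sweep_k.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config_echo.yaml")
    return table
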