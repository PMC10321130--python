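"""End-to-end orchestration: data -> preprocess -> cluster -> features ->
classify -> evaluate, driven by a single YAML-serializable config.

A run writes, under its output directory: one consolidated benchmark CSV
per clusterer, the entropy separability report, optional MSE
hyperparameter-search tables, figure-source exports, structured logs and a
resolved-config echo that reproduces the run byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import features as feat
from .bonn_io import LabeledDataset, load_labeled_dataset
from .classify import ClassifierSpec, default_specs, mse_hyperparam_search
from .evaluate import run_kfold_benchmark
from .preprocess import standardize_dataset
from .synthetic import SynthParams, generate_dataset

logger = logging.getLogger("eegclust")

DEFAULT_CLUSTERERS = ("kmeans", "fcm", "cuckoo", "dragonfly", "firefly", "modified_firefly")


@dataclass
class PipelineConfig:
    """Everything one experiment needs, seedable and echoable as YAML."""

    # data: either a manifest path or synthetic parameters
    manifest: str | None = None
    synthetic: dict = field(default_factory=lambda: {"n_per_class": 100})
    # preprocessing
    standardize: bool = True
    # clustering / features
    clusterers: tuple[str, ...] = DEFAULT_CLUSTERERS
    k: int = 10
    # entropy
    entropy: dict = field(default_factory=dict)  # m, r, bins
    # classification / evaluation
    classifiers: list[str] | None = None  # None: all ten registry kinds
    folds: int = 10
    positive_label: str | None = None  # None: E if present, else "ictal"
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.clusterers = tuple(cfg.clusterers)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {**self.__dict__, "clusterers": list(self.clusterers)}
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _load_data(config: PipelineConfig) -> LabeledDataset:
    if config.manifest is not None:
        return load_labeled_dataset(config.manifest)
    params = {k: v for k, v in config.synthetic.items() if k != "n_per_class"}
    n_per_class = config.synthetic.get("n_per_class", 100)
    if "normal_rhythm_hz" in params:
        params["normal_rhythm_hz"] = tuple(params["normal_rhythm_hz"])
    return generate_dataset(n_per_class, SynthParams(**params), seed=config.seed)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(name)s %(message)s")

    t0 = time.time()
    dataset = _load_data(config)
    logger.info("loaded %d segments (%s)", len(dataset), ",".join(dataset.labels))
    if config.standardize:
        dataset = standardize_dataset(dataset)

    positive = config.positive_label
    if positive is None:
        positive = "E" if "E" in dataset.labels else "ictal"

    specs = (
        default_specs(seed=config.seed)
        if config.classifiers is None
        else [ClassifierSpec(kind, seed=config.seed) for kind in config.classifiers]
    )

    entropy_params = feat.EntropyParams(**config.entropy)
    feature_tables: dict[str, object] = {}
    summary: dict[str, dict] = {}
    for ci, name in enumerate(config.clusterers):
        t_stage = time.time()
        sub_seed = int(
            np.random.SeedSequence(config.seed, spawn_key=(1000 + ci,)).generate_state(1)[0]
            % (2**31)
        )
        table = feat.dataset_feature_matrix(dataset, name, k=config.k, seed=sub_seed)
        feature_tables[name] = table
        table.to_csv(out / f"features_{name}.csv", index=False)
        _, bench = run_kfold_benchmark(
            table,
            table["label"].to_numpy(),
            specs,
            positive_label=positive,
            K=config.folds,
            seed=config.seed,
        )
        bench.to_csv(out / f"benchmark_{name}.csv")
        summary[name] = bench["accuracy"].to_dict()
        logger.info("clusterer %s done in %.1fs", name, time.time() - t_stage)

    report = feat.entropy_report(feature_tables, entropy_params)
    report.to_csv(out / "entropy_report.csv")

    labels = dataset.labels
    if len(labels) == 2 and len(config.clusterers) >= 1:
        name = config.clusterers[0]
        table = feature_tables[name]
        feat.export_cluster_views(
            table[table["label"] == labels[0]],
            table[table["label"] == labels[1]],
            out / "figure_data",
        )

    config.to_yaml(out / "resolved_config.yaml")
    with (out / "summary.json").open("w") as fh:
        json.dump(
            {"accuracy_by_clusterer": summary, "elapsed_s": round(time.time() - t0, 2)},
            fh,
            indent=2,
        )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return out


def run_mse_search(
    feature_table,
    kind: str,
    grid,
    param_name: str | None,
    out_path: str | Path,
    seed: int = 0,
):
    """Run one MSE-vs-iterations search and write its table as CSV."""
    X = feature_table[[c for c in feature_table.columns if c.startswith("f")]].to_numpy(float)
    y = feature_table["label"].to_numpy()
    table, chosen = mse_hyperparam_search(
        ClassifierSpec(kind, seed=seed), grid, X, y, param_name=param_name, seed=seed
    )
    table.to_csv(out_path)
    return table, chosen
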