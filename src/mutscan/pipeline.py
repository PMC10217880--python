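"""End-to-end orchestration: data -> features -> models -> ensemble -> evaluation.

A run is described by a :class:`RunConfig` (YAML-serializable).  Exactly one
input source must be given: either file inputs (a reference FASTA plus a
mutation table, or a normal/mutated FASTA pair) or a synthetic-cohort
configuration.  Every run writes, under its output directory:

- ``features.csv`` and ``feature_layout.json``
- ``report.json``  (per protocol: weights, per-model metrics, confusion
  matrices, per-fold details)
- ``summary.csv``  (one flat row per protocol x model)
- ``manifest.json`` (config echo, seed, package version)

Identical config + seed produce byte-identical ``summary.csv`` and
``report.json``; wall-clock timings go to the log only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datagen import (
    SyntheticCohortConfig,
    build_labeled_dataset,
    deduplicate,
    generate_mutated_sequences,
    generate_synthetic_cohort,
    parse_mutation_records,
    read_fasta,
    write_fasta,
    write_mutation_table,
)
from .errors import ConfigError
from .evaluation import PROTOCOLS, run_protocol
from .features import HahnParams, MomentFeaturizer, write_features_csv
from .models import MODEL_NAMES, default_spec

logger = logging.getLogger("mutscan")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    seed: int
    output_dir: str
    # input source A: files
    reference_fasta: str | None = None
    mutation_table: str | None = None
    mutated_fasta: str | None = None  # optional pre-built mutated set
    mutation_mode: str = "per_record"  # per_record | combined
    # input source B: synthetic cohort
    synthetic: dict | None = None
    # feature / model / protocol settings
    hahn_a: int = 0
    hahn_b: int = 0
    input_mode: str = "token_sequence"
    epochs: int | None = None
    batch_size: int | None = None
    learning_rate: float | None = None
    ensemble_mode: str = "accuracy"
    protocols: list[str] = field(default_factory=lambda: list(PROTOCOLS))
    dedup: bool = True

    def __post_init__(self):
        has_files = self.reference_fasta is not None or self.mutated_fasta is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ConfigError(
                "exactly one input source required: file inputs XOR synthetic"
            )
        if has_files and self.reference_fasta is None:
            raise ConfigError("file input requires reference_fasta")
        if has_files and self.mutation_table is None and self.mutated_fasta is None:
            raise ConfigError(
                "file input requires mutation_table and/or mutated_fasta"
            )
        unknown = set(self.protocols) - set(PROTOCOLS)
        if unknown:
            raise ConfigError(f"unknown protocol(s) {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config {path}: {exc}") from exc


def _build_dataset(config: RunConfig):
    """Assemble the labeled dataset from whichever input source is configured."""
    if config.synthetic is not None:
        synth = SyntheticCohortConfig(**{**config.synthetic, "seed": config.seed})
        dataset, records = generate_synthetic_cohort(synth)
        return dataset, records
    references = read_fasta(config.reference_fasta)
    if config.mutated_fasta is not None:
        mutateds = read_fasta(config.mutated_fasta)
        records = []
    else:
        records = parse_mutation_records(config.mutation_table)
        mutateds = generate_mutated_sequences(
            references, records, mode=config.mutation_mode
        )
    if config.dedup:
        references = deduplicate(references)
        mutateds = deduplicate(mutateds)
    return build_labeled_dataset(references, mutateds), records


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict it also writes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    logger.info("stage=data start")
    dataset, records = _build_dataset(config)
    logger.info(
        "stage=data done n=%d counts=%s dt=%.2fs",
        len(dataset), dataset.class_counts, time.perf_counter() - t0,
    )
    if config.synthetic is not None:
        normals = [s for s in dataset.sequences if s.label == "normal"]
        mutateds = [s for s in dataset.sequences if s.label == "mutated"]
        write_fasta(normals, out / "normal.fasta")
        write_fasta(mutateds, out / "mutated.fasta")
        write_mutation_table(records, out / "mutations.tsv")

    t1 = time.perf_counter()
    hahn = HahnParams(config.hahn_a, config.hahn_b)
    feats = MomentFeaturizer(hahn.a, hahn.b).fit_transform(dataset.sequences)
    write_features_csv(
        (s.id for s in dataset.sequences), feats,
        out / "features.csv", out / "feature_layout.json",
    )
    logger.info("stage=features done shape=%s dt=%.2fs",
                feats.shape, time.perf_counter() - t1)

    spec_kwargs: dict = {"seed": config.seed, "input_mode": config.input_mode}
    if config.batch_size is not None:
        spec_kwargs["batch_size"] = config.batch_size
    if config.learning_rate is not None:
        spec_kwargs["learning_rate"] = config.learning_rate
    if config.epochs is not None:
        spec_kwargs["epochs"] = config.epochs
    specs = [
        default_spec(name, **{**spec_kwargs, "seed": config.seed + i})
        for i, name in enumerate(MODEL_NAMES)
    ]

    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "class_counts": dict(dataset.class_counts),
        "protocols": {},
    }
    rows = []
    for protocol in config.protocols:
        t2 = time.perf_counter()
        logger.info("stage=evaluate protocol=%s start", protocol)
        result = run_protocol(
            protocol, dataset, specs=specs, seed=config.seed, hahn_params=hahn
        )
        report["protocols"][protocol] = {
            "weights": result.weights,
            "reports": [r.to_dict() for r in result.reports],
            "per_fold": [r.to_dict() for r in result.per_fold],
        }
        for r in result.reports:
            rows.append(
                {
                    "protocol": protocol,
                    "model": r.model,
                    "acc": round(r.acc, 6),
                    "sn": round(r.sn, 6),
                    "sp": round(r.sp, 6),
                    "mcc": round(r.mcc, 6),
                    "auc": round(r.auc, 6) if r.auc is not None else "",
                }
            )
        logger.info("stage=evaluate protocol=%s done dt=%.2fs",
                    protocol, time.perf_counter() - t2)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "package_version": __version__,
        "n_sequences": len(dataset),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete out=%s total=%.2fs", out, time.perf_counter() - t0)
    return report
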