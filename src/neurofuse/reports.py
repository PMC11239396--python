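"""Interpretability reports and the end-to-end pipeline runner.

Turns selection results into human-readable tables — ranked FNC
connections annotated with their component pair and intrinsic-network
domains, and ranked SNPs by rs-identifier — and orchestrates the full run:
cohort (synthetic or on-disk) -> morphological encoding -> per-modality
relevance selection -> fusion -> cross-validated classification -> report
files, with a manifest and a structured stage log.
"""

from __future__ import annotations

import csv
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig, read_cohort, simulate_cohort, write_cohort
from .densenet import EncoderConfig, build_encoder, extract_features
from .fusion import DEFAULT_GRID, cross_validate
from .selectors import (
    ConnectionIndexMap,
    FNC_THRESHOLD,
    SNP_TOP_K,
    SelectionResult,
    rank_features,
    select_features,
    train_modality_cnn,
    vectorize_fnc_stack,
)

__all__ = [
    "ConnectionReport",
    "RunConfig",
    "connection_report",
    "snp_report",
    "write_selection_csv",
    "run_pipeline",
]


@dataclass
class ConnectionReport:
    """Ranked FNC connections resolved to components and domains."""

    rows: list  # dicts: rank, component_i/j, domain_i/j, score
    n_top: int

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "rank", "component_i", "component_j",
                    "domain_i", "domain_j", "score",
                ],
            )
            writer.writeheader()
            writer.writerows(self.rows)

    @classmethod
    def from_csv(cls, path):
        with open(path, newline="") as fh:
            rows = []
            for row in csv.DictReader(fh):
                rows.append(
                    {
                        "rank": int(row["rank"]),
                        "component_i": int(row["component_i"]),
                        "component_j": int(row["component_j"]),
                        "domain_i": row["domain_i"],
                        "domain_j": row["domain_j"],
                        "score": float(row["score"]),
                    }
                )
        return cls(rows=rows, n_top=len(rows))


def connection_report(
    selection: SelectionResult, index_map: ConnectionIndexMap, n_top=25
) -> ConnectionReport:
    """Resolve the top ``n_top`` selected connections to component pairs
    and domain labels (e.g. the top 25 of a 249-connection selection)."""
    if selection.modality and selection.modality != "fnc":
        raise ValueError("connection reports require an FNC selection")
    rows = []
    for rank, flat_idx in enumerate(selection.selected_indices[:n_top], start=1):
        info = index_map.describe(int(flat_idx))
        rows.append(
            {
                "rank": rank,
                **info,
                "score": float(selection.relevance.scores[int(flat_idx)]),
            }
        )
    return ConnectionReport(rows=rows, n_top=len(rows))


def snp_report(selection: SelectionResult, snp_ids):
    """Rank-ordered (rank, rs-identifier, score) table for selected SNPs."""
    snp_ids = list(snp_ids)
    if len(snp_ids) != len(selection.ranked_indices):
        raise ValueError(
            f"{len(snp_ids)} identifiers for "
            f"{len(selection.ranked_indices)} SNP features"
        )
    if len(set(snp_ids)) != len(snp_ids):
        warnings.warn("duplicate rs identifiers in SNP metadata", stacklevel=2)
    return [
        {
            "rank": rank,
            "rs_id": snp_ids[int(idx)],
            "score": float(selection.relevance.scores[int(idx)]),
        }
        for rank, idx in enumerate(selection.selected_indices, start=1)
    ]


def write_selection_csv(selection: SelectionResult, path, index_map=None):
    """Full ranked-selection export (one row per selected feature)."""
    fields = ["rank", "feature_index", "score"]
    if index_map is not None:
        fields += ["component_i", "component_j", "domain_i", "domain_j"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rank, idx in enumerate(selection.selected_indices, start=1):
            row = {
                "rank": rank,
                "feature_index": int(idx),
                "score": float(selection.relevance.scores[int(idx)]),
            }
            if index_map is not None:
                row.update(index_map.describe(int(idx)))
            writer.writerow(row)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort: dict = field(default_factory=dict)  # CohortConfig fields
    input_dir: str | None = None  # load an on-disk cohort instead
    encoder: dict = field(default_factory=dict)  # EncoderConfig fields
    modalities: tuple = ("smri", "fnc", "snp")
    fnc_rule: tuple = ("threshold", FNC_THRESHOLD)
    snp_rule: tuple = ("top_k", SNP_TOP_K)
    k: int = 5
    n_top_connections: int = 25
    seed: int = 0
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    out_dir: str = "neurofuse_run"

    def validate(self):
        if bool(self.cohort) == bool(self.input_dir):
            raise ValueError(
                "exactly one of a synthetic cohort config or an input "
                "directory must be supplied"
            )
        if not self.modalities:
            raise ValueError("at least one modality must be enabled")
        for m in self.modalities:
            if m not in ("smri", "fnc", "snp"):
                raise ValueError(f"unknown modality {m!r}")
        return self

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh)

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.modalities = tuple(cfg.modalities)
        cfg.fnc_rule = tuple(cfg.fnc_rule)
        cfg.snp_rule = tuple(cfg.snp_rule)
        return cfg


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig):
    """Execute the full pipeline; returns the output directory path.

    Stage outputs (cohort, morphological features, FNC selection, SNP
    selection, cross-validation report, interpretability reports) are all
    written under ``config.out_dir`` and indexed by ``manifest.json``; a
    structured log records each stage with wall time.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    manifest, log = {}, []

    def stage(name):
        log.append({"stage": name, "time": time.time(), "seed": config.seed})

    # 1. cohort
    stage("cohort")
    if config.input_dir:
        cohort = read_cohort(config.input_dir)
        manifest["cohort"] = str(config.input_dir)
    else:
        cohort = simulate_cohort(CohortConfig(**config.cohort))
        cohort_dir = out / "cohort"
        write_cohort(cohort, cohort_dir)
        manifest["cohort"] = str(cohort_dir)
    labels = np.asarray(cohort.labels, dtype=int)

    data = {}
    # 2. morphological encoding
    stage("encode")
    if "smri" in config.modalities:
        encoder = build_encoder(EncoderConfig(**config.encoder))
        morph = extract_features(encoder, cohort.volumes, cohort.subject_ids)
        np.savetxt(out / "morph_features.csv", morph.matrix, delimiter=",")
        manifest["morph_features"] = str(out / "morph_features.csv")
        data["smri"] = morph.matrix

    # 3-4. cohort-level relevance selection reports (per-fold selection is
    # re-done inside cross_validate; these rankings feed the report tables)
    index_map = None
    for modality, rule, stage_name in (
        ("fnc", config.fnc_rule, "select-fnc"),
        ("snp", config.snp_rule, "select-snp"),
    ):
        if modality not in config.modalities:
            continue
        stage(stage_name)
        if modality == "fnc":
            features, index_map = vectorize_fnc_stack(cohort.fnc, cohort.domain_map)
        else:
            features = np.asarray(cohort.snps, dtype=float)
        data[modality] = features
        net = train_modality_cnn(features, labels, seed=config.seed)
        selection = select_features(rank_features(net, features), tuple(rule))
        selection.modality = modality
        path = out / f"selection_{modality}.csv"
        write_selection_csv(
            selection, path, index_map if modality == "fnc" else None
        )
        manifest[f"selection_{modality}"] = str(path)
        if modality == "fnc":
            report = connection_report(
                selection, index_map, config.n_top_connections
            )
            report.to_csv(out / "top_connections.csv")
            manifest["top_connections"] = str(out / "top_connections.csv")
        else:
            rows = snp_report(selection, cohort.snp_ids)
            with open(out / "top_snps.csv", "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=["rank", "rs_id", "score"])
                writer.writeheader()
                writer.writerows(rows)
            manifest["top_snps"] = str(out / "top_snps.csv")

    # 5. fusion + cross-validated classification
    stage("classify")
    cv = cross_validate(
        data,
        labels,
        modalities=config.modalities,
        k=config.k,
        seed=config.seed,
        fnc_rule=tuple(config.fnc_rule),
        snp_rule=tuple(config.snp_rule),
        grid=config.grid,
    )
    cv.to_json(out / "cv_report.json")
    manifest["cv_report"] = str(out / "cv_report.json")

    # 6. manifest + log
    stage("finalize")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out
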