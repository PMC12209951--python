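"""Configuration, orchestration and manifests for end-to-end runs.

Two entry points chain the stages on synthetic (or user) data:

* :func:`run_benchmark` — simulate (or read) a dilution series, pivot,
  then precision (complete-case CVs, abundance summaries), accuracy
  (error tables, summaries, CDFs) and ID-propagation stratification.
* :func:`run_covariation` — simulate (or read) single cells, fit cell size
  versus median intensity, normalize, correlate, filter, cluster and score
  complex recovery.

Every run writes delimited-text tables plus a ``manifest.json`` recording
the master seed, a hash of the resolved configuration and the table list,
so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accuracy, covariation, precision, propagation, report_io, synthetic
from .errors import ConfigError, DataError
from .synthetic import ComplexSpec, NoiseConfig

logger = logging.getLogger("scpqb")

__all__ = [
    "RunConfig",
    "CatalogConfig",
    "DilutionConfig",
    "CellsConfig",
    "CovariationConfig",
    "load_config",
    "config_hash",
    "run_benchmark",
    "run_covariation",
]


def _from_dict(cls, data: Mapping[str, Any]):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class CatalogConfig:
    n_proteins: int = 800
    peptides_per_protein: tuple[int, int] = (1, 3)
    dynamic_range_log10: float = 4.0
    distribution: str = "log-uniform"


@dataclass(frozen=True)
class DilutionConfig:
    """Dilution-series design: union of the low-range (100 pg reference,
    targets down to 10 pg) and high-range (50 pg reference, targets up to
    500 pg = 10x libraries) benchmark designs, in triplicate."""

    loads: tuple[float, ...] = (10, 20, 30, 40, 50, 100, 150, 200, 250, 500)
    replicates: int = 3
    reference_load: float = 100.0
    target_loads: tuple[float, ...] = (50, 40, 30, 20, 10)
    library_reference_load: float = 50.0
    library_loads: tuple[float, ...] = (50, 100, 150, 200, 250, 500)
    thresholds: tuple[float, ...] = (20.0, 25.0, 50.0)
    fwhm_constant: float = 2.634
    quant_level: str = "MS1"
    adjacent_pairs: tuple[tuple[float, float], ...] = ((40, 20), (20, 10))


@dataclass(frozen=True)
class CellsConfig:
    n_cells: int = 100
    cell_load_pg: float = 25.0
    fsc_low: float = 500.0
    fsc_high: float = 1500.0
    log2_size_per_fsc: float = 0.002
    complex_sizes: tuple[int, ...] = (6, 8)
    complex_strengths: tuple[float, ...] = (0.9, 0.9)


@dataclass(frozen=True)
class CovariationConfig:
    rho_threshold: float = 0.6
    min_partners: int = 1
    min_obs: int = 10
    k: int = 3
    n_perm: int = 999
    cluster_scope: str = "all"  # "all" or "filtered"
    normalize: bool = True
    quant_level: str = "MS1"


@dataclass(frozen=True)
class RunConfig:
    master_seed: int = 0
    output_dir: str = "scpqb_out"
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    dilution: DilutionConfig = field(default_factory=DilutionConfig)
    cells: CellsConfig = field(default_factory=CellsConfig)
    covariation: CovariationConfig = field(default_factory=CovariationConfig)

    def resolved_noise(self) -> NoiseConfig:
        """Noise config with the master seed folded in."""
        return dataclasses.replace(self.noise, seed=self.master_seed)


_SECTION_TYPES = {
    "catalog": CatalogConfig,
    "noise": NoiseConfig,
    "dilution": DilutionConfig,
    "cells": CellsConfig,
    "covariation": CovariationConfig,
}

_TUPLE_KEYS = {
    "peptides_per_protein", "loads", "target_loads", "library_loads",
    "thresholds", "adjacent_pairs", "complex_sizes", "complex_strengths",
}


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(x) for x in obj]
    return obj


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(x) for x in obj)
    return obj


def load_config(path: str | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected.

    ``overrides`` (e.g. from CLI flags) are applied on top: top-level keys
    or ``section.key`` dotted names.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path!r} is not a mapping")
        data = loaded
    for key, value in (overrides or {}).items():
        if "." in key:
            section, sub = key.split(".", 1)
            data.setdefault(section, {})[sub] = value
        else:
            data[key] = value

    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, Mapping):
                raise ConfigError(f"config section {key!r} must be a mapping")
            value = {k: _tuplify(v) if k in _TUPLE_KEYS else v for k, v in value.items()}
            kwargs[key] = _from_dict(_SECTION_TYPES[key], value)
        elif key in ("master_seed", "output_dir"):
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)


def config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=_listify))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config_dict(config), sort_keys=True, default=_listify)
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_manifest(out: Path, config: RunConfig, tables: Sequence[str]) -> None:
    manifest = {
        "config_hash": config_hash(config),
        "master_seed": config.master_seed,
        "tables": sorted(tables),
        "config": config_dict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _write(out: Path, name: str, df: pd.DataFrame, written: list[str]) -> None:
    df.to_csv(out / name, sep="\t", index=False)
    written.append(name)


class _Stage:
    """Context manager adding stage names to failures and timing to the log."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        from .errors import ScpqbError

        if exc is not None:
            logger.error("stage %s failed: %s", self.name, exc)
            if isinstance(exc, ScpqbError):
                return False  # keep the precise error type
            raise DataError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", self.name, time.perf_counter() - self.t0)


def run_benchmark(config: RunConfig, report: pd.DataFrame | None = None) -> Path:
    """Simulate (or take) a dilution report and run the full benchmark chain.

    Writes the report, CV table, abundance summary, error table, error
    summary, CDF table, library-origin table and tier-fraction table plus a
    manifest; returns the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    cfg = config.resolved_noise()
    dil = config.dilution

    with _Stage("simulate"):
        if report is None:
            catalog = synthetic.simulate_catalog(
                config.catalog.n_proteins,
                config.catalog.peptides_per_protein,
                config.catalog.dynamic_range_log10,
                seed=config.master_seed,
                distribution=config.catalog.distribution,
            )
            report = synthetic.simulate_dilution_series(
                catalog, dil.loads, dil.replicates, cfg
            )
        report_io.write_report(report, str(out / "report.tsv"))
        written.append("report.tsv")

    with _Stage("pivot"):
        matrix = report_io.pivot_matrix(report, quant_level=dil.quant_level)

    with _Stage("precision"):
        low_runs = matrix.run_meta.index[
            matrix.run_meta["load_pg"].isin([dil.reference_load, *dil.target_loads])
        ]
        complete = precision.complete_case_filter(matrix, list(low_runs))
        cv = precision.peptide_cv(complete, "load_pg")
        _write(out, "cv_table.tsv", cv, written)
        summaries = precision.abundance_summary(complete, "load_pg")
        _write(
            out,
            "abundance_summary.tsv",
            pd.DataFrame(
                [
                    {
                        "group": s.group, "n_values": s.n_values,
                        "median_log2": s.median_log2,
                        "q05_log2": s.q05_log2, "q95_log2": s.q95_log2,
                    }
                    for s in summaries
                ]
            ),
            written,
        )

    with _Stage("accuracy"):
        design = accuracy.DilutionDesign(dil.reference_load, tuple(dil.target_loads))
        error_frames, summary_rows, cdf_frames = [], [], []
        for target in dil.target_loads:
            errors = accuracy.observed_ratios(complete, design, target)
            error_frames.append(errors)
            s = accuracy.error_summary(errors, dil.thresholds, dil.fwhm_constant)
            row = {
                "target": s.target, "n_values": s.n_values, "n_peptides": s.n_peptides,
                "mean_replicate_sd": s.mean_replicate_sd,
                "sigma_fit": s.sigma_fit, "fwhm": s.fwhm,
            }
            row.update({f"fraction_below_{t:g}": f for t, f in s.fraction_below.items()})
            summary_rows.append(row)
            cdf = s.cdf.copy()
            cdf.insert(0, "target", target)
            cdf_frames.append(cdf)
        _write(out, "error_table.tsv", pd.concat(error_frames, ignore_index=True), written)
        _write(out, "error_summary.tsv", pd.DataFrame(summary_rows), written)
        _write(out, "cdf_table.tsv", pd.concat(cdf_frames, ignore_index=True), written)

    with _Stage("propagation"):
        id_sets = propagation.id_sets_from_report(
            report, dil.library_reference_load, dil.library_loads, dil.quant_level
        )
        origins = propagation.annotate_library_origin(
            id_sets, dil.library_reference_load, dil.library_loads
        )
        _write(out, "origin_table.tsv", origins, written)
        lib_design = accuracy.DilutionDesign(
            dil.library_reference_load, tuple(dil.library_loads)
        )
        # the 1:2 (reference : 2x reference) comparison on the full matrix,
        # so propagated-only quantities are part of the evaluation
        two_x = 2.0 * dil.library_reference_load
        lib_errors = accuracy.observed_ratios(matrix, lib_design, two_x)
        lib_errors = lib_errors[
            lib_errors["peptide_id"].isin(origins["peptide_id"])
        ].reset_index(drop=True)
        tiers, tier_fractions = propagation.stratify_tiers(lib_errors, origins)
        _write(out, "tier_table.tsv", tiers, written)
        _write(out, "tier_fractions.tsv", tier_fractions, written)

    _write_manifest(out, config, written)
    return out


def run_covariation(
    config: RunConfig,
    report: pd.DataFrame | None = None,
    cell_meta: pd.DataFrame | None = None,
    complexes: Sequence[ComplexSpec] | None = None,
) -> Path:
    """Simulate (or take) single-cell data and run the covariation chain."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    cfg = config.resolved_noise()
    cc = config.cells
    cov = config.covariation

    with _Stage("simulate-cells"):
        if report is None:
            catalog = synthetic.simulate_catalog(
                config.catalog.n_proteins,
                config.catalog.peptides_per_protein,
                config.catalog.dynamic_range_log10,
                seed=config.master_seed,
                distribution=config.catalog.distribution,
            )
            cells = synthetic.make_cell_specs(
                cc.n_cells, seed=config.master_seed,
                fsc_low=cc.fsc_low, fsc_high=cc.fsc_high,
                log2_size_per_fsc=cc.log2_size_per_fsc,
            )
            complexes = synthetic.make_complexes(
                catalog, cc.complex_sizes, cc.complex_strengths, seed=config.master_seed
            )
            report, cell_meta = synthetic.simulate_single_cells(
                catalog, cells, complexes, cfg, cell_load_pg=cc.cell_load_pg
            )
        if cell_meta is None:
            raise ConfigError("cell metadata is required when a report is supplied")
        if complexes is None:
            raise ConfigError("complex membership sets are required (gene-set file)")
        report_io.write_report(report, str(out / "cells_report.tsv"))
        written.append("cells_report.tsv")
        cell_meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False)
        written.append("cell_meta.tsv")
        covariation.write_gene_sets(
            {c.complex_name: list(c.member_proteins) for c in complexes},
            str(out / "complexes.gmt"),
        )
        written.append("complexes.gmt")

    with _Stage("pivot-cells"):
        pep_matrix = report_io.pivot_matrix(
            report, quant_level=cov.quant_level, row_unit="peptide"
        )
        prot_matrix = report_io.pivot_matrix(
            report, quant_level=cov.quant_level, row_unit="protein"
        )

    with _Stage("cell-size-fit"):
        protein_of = dict(
            report[["peptide_id", "protein_id"]].drop_duplicates().to_numpy()
        )
        fit = covariation.cell_size_fit(pep_matrix, cell_meta, protein_of=protein_of)
        per_cell = fit.per_cell.copy()
        per_cell["slope"] = fit.slope
        per_cell["intercept"] = fit.intercept
        per_cell["r"] = fit.r
        _write(out, "cell_fit.tsv", per_cell, written)

    with _Stage("covariation"):
        mat = covariation.normalize_cells(prot_matrix) if cov.normalize else prot_matrix
        result = covariation.pairwise_spearman(mat, min_obs=cov.min_obs)
        retained = covariation.filter_correlated(
            result, cov.rho_threshold, cov.min_partners
        )
        scope = result.proteins if cov.cluster_scope == "all" else retained
        clustered = covariation.cluster_modules(result, cov.k, proteins=scope)
        rho_out = clustered.rho.round(6)
        rho_out.index.name = "protein_id"
        rho_out.reset_index().to_csv(out / "rho_matrix.tsv", sep="\t", index=False)
        written.append("rho_matrix.tsv")
        module_table = pd.DataFrame(
            {
                "protein_id": clustered.proteins,
                "module": clustered.module_label.loc[clustered.proteins].to_numpy(),
                "markedly_correlated": [p in set(retained) for p in clustered.proteins],
                "leaf_position": pd.Series(
                    {p: i for i, p in enumerate(clustered.leaf_order)}
                ).loc[clustered.proteins].to_numpy(),
            }
        )
        _write(out, "module_table.tsv", module_table, written)
        recovery = covariation.complex_recovery(
            result, complexes, n_perm=cov.n_perm, seed=config.master_seed
        )
        _write(out, "recovery_table.tsv", recovery, written)

    _write_manifest(out, config, written)
    return out
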