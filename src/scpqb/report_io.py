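"""Reading/writing peptide report tables and pivoting to abundance matrices.

Report tables are long-format delimited text: one row per (run, peptide,
quant level) with an intensity and identification provenance. Two vendor-ish
dialects (Spectronaut- and DIA-NN-style column names) are supported next to
the package's own "native" dialect; the column maps live in a YAML config
(``dialects.yaml``), not in code, so a new export format needs no code
change.

Missingness contract: a peptide that was not detected in a run is an absent
row / an empty matrix cell — never a zero. Rows with non-positive or
non-numeric intensities are dropped on read with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, InputError
from .synthetic import REPORT_COLUMNS

logger = logging.getLogger("scpqb")

__all__ = [
    "AbundanceMatrix",
    "load_dialects",
    "read_report",
    "write_report",
    "pivot_matrix",
    "melt_matrix",
]

_DUPLICATE_RULES = ("max", "min", "sum", "mean", "first", "error")


def load_dialects(path: str | None = None) -> dict:
    """Load dialect column maps; default to the packaged ``dialects.yaml``."""
    if path is None:
        text = resources.files("scpqb").joinpath("dialects.yaml").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return yaml.safe_load(text)


_DIALECTS = load_dialects()


@dataclass
class AbundanceMatrix:
    """Peptides-or-proteins × runs intensity grid with explicit missingness.

    ``values`` is a DataFrame (rows = unit ids, columns = run ids, ``NaN`` =
    missing); ``run_meta`` is indexed by run id and carries ``load_pg``,
    ``replicate`` and any cell annotations. ``is_log2`` marks matrices whose
    values are log2-transformed (e.g. after per-cell normalization), where
    the positivity invariant does not apply.
    """

    values: pd.DataFrame
    run_meta: pd.DataFrame
    row_unit: str = "peptide"
    quant_level: str = "MS1"
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise DataError("duplicate row or column keys in abundance matrix")
        if not self.is_log2:
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) <= 0:
                raise DataError("non-positive intensities in abundance matrix")

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_rows(self, rows) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.loc[list(rows)], self.run_meta, self.row_unit,
            self.quant_level, self.is_log2,
        )


def _parse_load(series: pd.Series) -> pd.Series:
    """Coerce a load column that may read '50pg' / '50 pg' / 50.0."""
    s = series.astype("string").str.replace(r"\s*pg$", "", regex=True)
    return pd.to_numeric(s, errors="coerce")


def read_report(
    path: str,
    dialect: str = "native",
    dialects: Mapping | None = None,
) -> pd.DataFrame:
    """Read a report table into the canonical long format.

    Returns a DataFrame with :data:`scpqb.synthetic.REPORT_COLUMNS`. Unknown
    dialects raise :class:`ConfigError`; a missing mandatory column raises
    :class:`DataError` naming the column. Rows with non-positive or
    non-numeric intensity are dropped (count logged).
    """
    maps = dict(dialects if dialects is not None else _DIALECTS)
    if dialect not in maps:
        raise ConfigError(f"unknown report dialect {dialect!r}; known: {sorted(maps)}")
    spec = maps[dialect]
    raw = pd.read_csv(path, sep=spec.get("separator", "\t"))

    colmap = spec["columns"]
    wide = "intensity_columns" in spec
    needed = [colmap[c] for c in spec.get("mandatory", [])]
    if wide:
        needed += list(spec["intensity_columns"].values())
    for col in needed:
        if col not in raw.columns:
            raise DataError(f"report file {path!r} is missing mandatory column {col!r}")

    out = pd.DataFrame(index=raw.index)
    for canon in REPORT_COLUMNS:
        if canon in ("quant_level", "intensity") and wide:
            continue
        src = colmap.get(canon)
        out[canon] = raw[src] if src in raw.columns else pd.NA

    if wide:
        frames = []
        for level, col in spec["intensity_columns"].items():
            part = out.copy()
            part["quant_level"] = level
            part["intensity"] = raw[col]
            frames.append(part)
        out = pd.concat(frames, ignore_index=True)

    if "id_source_values" in spec:
        out["id_source"] = out["id_source"].map(spec["id_source_values"])
    out["id_source"] = out["id_source"].fillna("direct")
    out["load_pg"] = _parse_load(out["load_pg"]) if out["load_pg"].notna().any() else np.nan
    out["replicate"] = pd.to_numeric(out["replicate"], errors="coerce")

    out["intensity"] = pd.to_numeric(out["intensity"], errors="coerce")
    keep = out["intensity"] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_report: dropped %d rows with missing/non-positive intensity", n_dropped)
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out[REPORT_COLUMNS]


def write_report(report: pd.DataFrame, path: str) -> None:
    """Write a canonical long-format table in the native dialect (TSV, UTF-8)."""
    report[REPORT_COLUMNS].to_csv(path, sep="\t", index=False)


def pivot_matrix(
    measurements: pd.DataFrame,
    quant_level: str = "MS1",
    row_unit: str = "peptide",
    duplicate_rule: str = "max",
    rollup: str = "sum",
) -> AbundanceMatrix:
    """Pivot long measurements into an :class:`AbundanceMatrix`.

    ``row_unit="protein"`` rolls peptides up per protein (sum of peptide
    intensities by default). Duplicate (unit, run) entries are resolved by
    ``duplicate_rule`` (default ``"max"``, mirroring multi-charge-state
    report rows); rule ``"error"`` raises instead.
    """
    if len(measurements) == 0:
        raise InputError("measurements are empty")
    if duplicate_rule not in _DUPLICATE_RULES:
        raise InputError(f"duplicate_rule must be one of {_DUPLICATE_RULES}")
    if row_unit not in ("peptide", "protein"):
        raise InputError("row_unit must be 'peptide' or 'protein'")

    df = measurements[measurements["quant_level"] == quant_level]
    if len(df) == 0:
        raise InputError(f"no rows at quant level {quant_level!r}")

    key = "peptide_id"
    dup = df.duplicated([key, "run_id"])
    if dup.any():
        if duplicate_rule == "error":
            raise DataError(f"{int(dup.sum())} duplicate (peptide, run) entries")
        agg = "first" if duplicate_rule == "first" else duplicate_rule
        df = df.groupby([key, "run_id"], as_index=False).agg(
            intensity=("intensity", agg),
            protein_id=("protein_id", "first"),
            load_pg=("load_pg", "first"),
            replicate=("replicate", "first"),
        )
    if row_unit == "protein":
        df = df.groupby(["protein_id", "run_id"], as_index=False).agg(
            intensity=("intensity", rollup),
            load_pg=("load_pg", "first"),
            replicate=("replicate", "first"),
        )
        key = "protein_id"

    values = df.pivot(index=key, columns="run_id", values="intensity")
    values = values.sort_index().sort_index(axis=1)
    run_meta = (
        df[["run_id", "load_pg", "replicate"]]
        .drop_duplicates("run_id")
        .set_index("run_id")
        .loc[values.columns]
    )
    return AbundanceMatrix(values, run_meta, row_unit=row_unit, quant_level=quant_level)


def melt_matrix(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Inverse of :func:`pivot_matrix`: long (unit, run, intensity) rows."""
    long = (
        matrix.values.rename_axis(index="unit_id", columns="run_id")
        .stack(future_stack=True)
        .rename("intensity")
        .dropna()
        .reset_index()
    )
    return long
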