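"""Complete-case filtering, CV analysis and abundance-distribution summaries.

Precision of replicate DIA measurements is summarized as the coefficient of
variation per peptide within a group of runs (typically the replicates of
one load), computed on raw, non-normalized intensities with the sample
(n−1) standard deviation — the convention for triplicate dilution designs.
Abundance distributions are summarized on the log2 scale (median, 0.05 and
0.95 quantiles, histogram), mirroring how low-input dilution series are
inspected for downward intensity scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .report_io import AbundanceMatrix

logger = logging.getLogger("scpqb")

__all__ = [
    "complete_case_filter",
    "peptide_cv",
    "abundance_summary",
    "intersect_units",
    "AbundanceSummary",
]


def _run_groups(matrix: AbundanceMatrix, group_by: str | Mapping) -> pd.Series:
    """Resolve the run→group assignment from a metadata column or mapping."""
    if isinstance(group_by, str):
        if group_by not in matrix.run_meta.columns:
            raise InputError(f"run metadata has no column {group_by!r}")
        return matrix.run_meta[group_by].reindex(matrix.values.columns)
    groups = pd.Series(dict(group_by))
    missing = set(matrix.values.columns) - set(groups.index)
    if missing:
        raise InputError(f"runs without a group: {sorted(missing)}")
    return groups.loc[matrix.values.columns]


def complete_case_filter(
    matrix: AbundanceMatrix, runs: Sequence[str] | None = None
) -> AbundanceMatrix:
    """Keep only the rows with a present value in every listed run.

    ``runs`` defaults to all columns. This is the filter applied before
    comparing precision and accuracy across a whole dilution series: only
    peptides found in all the loads with no missing values survive.
    """
    runs = list(matrix.values.columns) if runs is None else list(runs)
    if len(runs) == 0:
        raise InputError("complete_case_filter needs a non-empty run set")
    unknown = set(runs) - set(matrix.values.columns)
    if unknown:
        raise InputError(f"runs not in matrix: {sorted(unknown)}")
    keep = matrix.values[runs].notna().all(axis=1)
    return matrix.subset_rows(matrix.values.index[keep])


def peptide_cv(matrix: AbundanceMatrix, group_by: str | Mapping = "load_pg") -> pd.DataFrame:
    """Per-unit CV% within each run group.

    ``cv_percent = 100 * sample SD / mean`` on raw (linear) intensities.
    Units with fewer than two present values in a group are skipped for
    that group, never imputed. Returns columns ``unit_id``, ``group``,
    ``cv_percent``, ``n_obs``.
    """
    groups = _run_groups(matrix, group_by)
    records = []
    for g, cols in matrix.values.columns.to_series().groupby(groups.values):
        sub = matrix.values[list(cols)]
        n_obs = sub.notna().sum(axis=1)
        ok = n_obs >= 2
        mean = sub[ok].mean(axis=1)
        sd = sub[ok].std(axis=1, ddof=1)
        rec = pd.DataFrame(
            {
                "unit_id": mean.index,
                "group": g,
                "cv_percent": (100.0 * sd / mean).to_numpy(),
                "n_obs": n_obs[ok].to_numpy(),
            }
        )
        records.append(rec)
    if not records:
        return pd.DataFrame(columns=["unit_id", "group", "cv_percent", "n_obs"])
    return pd.concat(records, ignore_index=True)


@dataclass
class AbundanceSummary:
    """Log2-scale distribution summary of one run group."""

    group: object
    n_values: int
    median_log2: float
    q05_log2: float
    q95_log2: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    @property
    def empty(self) -> bool:
        return self.n_values == 0


def abundance_summary(
    matrix: AbundanceMatrix,
    group_by: str | Mapping = "load_pg",
    bin_width_log2: float = 0.25,
) -> list[AbundanceSummary]:
    """Median / 0.05 / 0.95 quantiles and histogram of log2 intensities per group.

    Quantiles use linear interpolation between order statistics and are
    computed on present values only. An all-missing group yields a flagged
    empty summary (``n_values == 0``, NaN statistics).
    """
    if matrix.is_log2:
        raise InputError("abundance_summary expects a linear-scale matrix")
    groups = _run_groups(matrix, group_by)
    out: list[AbundanceSummary] = []
    for g, cols in matrix.values.columns.to_series().groupby(groups.values):
        vals = matrix.values[list(cols)].to_numpy(dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("abundance_summary: group %r has no present values", g)
            out.append(
                AbundanceSummary(g, 0, np.nan, np.nan, np.nan, np.array([]), np.array([]))
            )
            continue
        log2v = np.log2(vals)
        q05, med, q95 = np.quantile(log2v, [0.05, 0.5, 0.95])
        lo = np.floor(log2v.min() / bin_width_log2) * bin_width_log2
        hi = np.ceil(log2v.max() / bin_width_log2) * bin_width_log2
        nbins = max(1, int(round((hi - lo) / bin_width_log2)))
        counts, edges = np.histogram(log2v, bins=nbins, range=(lo, hi))
        out.append(AbundanceSummary(g, vals.size, float(med), float(q05), float(q95), edges, counts))
    return out


def intersect_units(
    a: AbundanceMatrix, b: AbundanceMatrix
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Restrict two matrices (e.g. MS1 vs MS2) to their shared unit set.

    Used when comparing CV distributions across quant levels so both levels
    are evaluated on the same peptides.
    """
    shared = a.values.index.intersection(b.values.index)
    if len(shared) == 0:
        raise InputError("matrices share no units")
    return a.subset_rows(shared), b.subset_rows(shared)
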