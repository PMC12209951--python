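"""Reference-vs-target ratio accuracy for dilution-series designs.

A dilution design fixes one reference load and a set of target loads; the
expected peptide ratio for a target is ``target_load / reference_load``.
Within each replicate the observed ratio is ``target intensity / reference
intensity`` per peptide, and the error is the percentile difference between
observed and expected:

    relative_error% = 100 * (observed − expected) / expected

Distribution summaries follow the conventions of low-input DIA accuracy
benchmarking: the mean over replicates of the per-replicate error SD; a
Gaussian fit to the central peak of the relative-error histogram, reported
as a full width at half maximum ``fwhm = fwhm_constant * sigma`` (default
constant 2.634, with the standard Gaussian constant 2.3548 available);
empirical CDFs of the absolute error; and fractions of peptides below given
absolute-error thresholds (strict inequality, so counts are reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, InputError
from .report_io import AbundanceMatrix

logger = logging.getLogger("scpqb")

__all__ = [
    "DilutionDesign",
    "ErrorSummary",
    "observed_ratios",
    "error_summary",
    "cdf_absolute_error",
    "cdf_at",
    "adjacent_ratio_comparison",
    "GAUSSIAN_FWHM_CONSTANT",
]

#: FWHM of a unit-variance Gaussian; the benchmarking constant 2.634 is the
#: package default in :func:`error_summary` (kept configurable on purpose).
GAUSSIAN_FWHM_CONSTANT = 2.3548


@dataclass(frozen=True)
class DilutionDesign:
    """Reference load, target loads and replicate pairing of a dilution design."""

    reference_load: float
    target_loads: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.reference_load <= 0 or any(t <= 0 for t in self.target_loads):
            raise InputError("loads must be positive")

    def expected_ratio(self, target: float) -> float:
        return float(target) / float(self.reference_load)


def _runs_at(matrix: AbundanceMatrix, load: float) -> pd.DataFrame:
    meta = matrix.run_meta
    return meta[np.isclose(meta["load_pg"].astype(float), load)]


def observed_ratios(
    matrix: AbundanceMatrix, design: DilutionDesign, target: float
) -> pd.DataFrame:
    """Per-peptide observed/expected ratio errors for one target load.

    Runs are paired by replicate index within (reference, target). Peptides
    missing in either run of a pair are excluded; the excluded count is kept
    in ``result.attrs["n_excluded"]``. Returns columns ``peptide_id``,
    ``target``, ``replicate``, ``observed_ratio``, ``expected_ratio``,
    ``relative_error_percent``, ``absolute_error_percent``.
    """
    if not any(np.isclose(target, t) for t in design.target_loads):
        raise InputError(f"target {target} is not part of the design")
    ref_runs = _runs_at(matrix, design.reference_load)
    tgt_runs = _runs_at(matrix, target)
    reps = sorted(set(ref_runs["replicate"]) & set(tgt_runs["replicate"]))
    if not reps:
        raise DataError(
            f"no paired runs for reference {design.reference_load} vs target {target}"
        )
    expected = design.expected_ratio(target)
    frames = []
    n_excluded = 0
    for rep in reps:
        ref_id = ref_runs.index[ref_runs["replicate"] == rep][0]
        tgt_id = tgt_runs.index[tgt_runs["replicate"] == rep][0]
        ref_col = matrix.values[ref_id]
        tgt_col = matrix.values[tgt_id]
        both = ref_col.notna() & tgt_col.notna()
        n_excluded += int((~both).sum() - (ref_col.isna() & tgt_col.isna()).sum())
        observed = tgt_col[both] / ref_col[both]
        rel = 100.0 * (observed - expected) / expected
        frames.append(
            pd.DataFrame(
                {
                    "peptide_id": observed.index,
                    "target": target,
                    "replicate": rep,
                    "observed_ratio": observed.to_numpy(),
                    "expected_ratio": expected,
                    "relative_error_percent": rel.to_numpy(),
                    "absolute_error_percent": np.abs(rel.to_numpy()),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_excluded"] = n_excluded
    if n_excluded:
        logger.info(
            "observed_ratios %g:%g pg: excluded %d half-missing peptide pairs",
            target, design.reference_load, n_excluded,
        )
    return out


@dataclass
class ErrorSummary:
    """Distributional summary of one target's ratio errors."""

    target: float
    n_values: int
    n_peptides: int
    mean_replicate_sd: float
    sigma_fit: float | None
    fwhm: float | None
    fwhm_constant: float
    fraction_below: dict[float, float]
    cdf: pd.DataFrame


def _gaussian_core_sigma(
    relative_errors: np.ndarray,
    central_fraction: float = 0.90,
    n_bins: int = 41,
) -> float | None:
    """Least-squares Gaussian fit to the histogram of the central errors.

    The central ``central_fraction`` of the relative errors is histogrammed
    and a single Gaussian is fitted to the bin counts; restricting to the
    core makes the width estimate robust to the heavy tails that appear at
    low loads. Returns ``None`` when there are fewer than 10 values or the
    fit fails.
    """
    x = np.asarray(relative_errors, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        return None
    tail = (1.0 - central_fraction) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    core = x[(x >= lo) & (x <= hi)]
    if core.size < 10 or hi <= lo:
        return None
    counts, edges = np.histogram(core, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(t, a, mu, sigma):
        return a * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    p0 = (counts.max(), float(np.median(core)), float(np.std(core)) or 1.0)
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError):
        logger.warning("Gaussian core fit failed (n=%d)", x.size)
        return None
    return float(abs(popt[2]))


def error_summary(
    errors: pd.DataFrame,
    thresholds: Sequence[float] = (20.0, 25.0, 50.0),
    fwhm_constant: float = 2.634,
    central_fraction: float = 0.90,
) -> ErrorSummary:
    """Summarize an error table: replicate SDs, Gaussian-core width, CDF, fractions.

    ``fraction_below[t]`` counts strictly ``absolute_error_percent < t``.
    ``mean_replicate_sd`` is the mean over replicates of each replicate's
    relative-error SD. ``fwhm = fwhm_constant * sigma_fit``.
    """
    if len(errors) == 0:
        raise InputError("error table is empty")
    rel = errors["relative_error_percent"].to_numpy(dtype=float)
    abse = errors["absolute_error_percent"].to_numpy(dtype=float)
    per_rep_sd = errors.groupby("replicate")["relative_error_percent"].std(ddof=1)
    sigma = _gaussian_core_sigma(rel, central_fraction=central_fraction)
    fraction_below = {float(t): float(np.mean(abse < t)) for t in thresholds}
    target = float(errors["target"].iloc[0]) if "target" in errors else np.nan
    return ErrorSummary(
        target=target,
        n_values=len(errors),
        n_peptides=int(errors["peptide_id"].nunique()),
        mean_replicate_sd=float(per_rep_sd.mean()),
        sigma_fit=sigma,
        fwhm=None if sigma is None else fwhm_constant * sigma,
        fwhm_constant=fwhm_constant,
        fraction_below=fraction_below,
        cdf=cdf_absolute_error(errors),
    )


def cdf_absolute_error(errors: pd.DataFrame) -> pd.DataFrame:
    """Right-continuous empirical CDF of the absolute error (percent).

    Returns sorted ``absolute_error_percent`` with ``cum_fraction``; tied
    values collapse into one step whose height is their multiplicity / n.
    """
    if len(errors) == 0:
        raise InputError("error table is empty")
    vals = np.sort(errors["absolute_error_percent"].to_numpy(dtype=float))
    n = vals.size
    cum = np.arange(1, n + 1) / n
    df = pd.DataFrame({"absolute_error_percent": vals, "cum_fraction": cum})
    # keep the last (highest) cumulative fraction at each distinct value
    return df.groupby("absolute_error_percent", as_index=False).max()


def cdf_at(cdf: pd.DataFrame, t: float) -> float:
    """Evaluate the empirical CDF at ``t`` (fraction of errors ≤ t)."""
    vals = cdf["absolute_error_percent"].to_numpy()
    cum = cdf["cum_fraction"].to_numpy()
    idx = np.searchsorted(vals, t, side="right") - 1
    return 0.0 if idx < 0 else float(cum[idx])


def adjacent_ratio_comparison(
    matrix: AbundanceMatrix,
    pairs: Sequence[tuple[float, float]],
    thresholds: Sequence[float] = (20.0, 25.0, 50.0),
    fwhm_constant: float = 2.634,
) -> dict[tuple[float, float], ErrorSummary]:
    """Error summaries for (load_a, load_b) pairs at small dynamic range.

    Reuses the ratio machinery with ``expected = load_b / load_a`` so that
    neighboring low loads (e.g. 20:40 pg, 10:20 pg) can be compared without
    the wide dynamic range that dominates errors against a high reference.
    """
    out: dict[tuple[float, float], ErrorSummary] = {}
    for load_a, load_b in pairs:
        design = DilutionDesign(reference_load=load_a, target_loads=(load_b,))
        errors = observed_ratios(matrix, design, load_b)
        out[(load_a, load_b)] = error_summary(
            errors, thresholds=thresholds, fwhm_constant=fwhm_constant
        )
    return out
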