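"""Library ID-propagation annotation and accuracy-tier stratification.

When low-input runs are searched together with higher-load "library" runs,
identifications propagate from the libraries into the low-input files and
the peptide list grows — at the cost of quantifying ions near or below the
direct detection limit. This module annotates each peptide by the smallest
library (expressed as a multiple of the reference load: direct, 1×, 2×, …)
that first enabled its identification, quantifies the fractional ID gains,
and stratifies quantities into accuracy tiers by absolute ratio error:

    tier I:  error < 25 %       tier II: 25 % ≤ error ≤ 50 %       tier III: error > 50 %

(the 25 % and 50 % boundaries fall into tier II, reading "between 25 and
50 %" as a closed interval, so counts are reproducible).

Identification sets are *inputs* — from report-file ID columns or from the
synthetic generator; no search engine is re-run here. The generator-side
construction (:func:`id_sets_from_report`) defines: *direct* = directly
detected in every reference run; the *m×* search additionally admits
peptides quantifiable above the propagated threshold in all reference runs
and directly detected in at least one run of load ≤ m × reference — so the
sets are cumulative in the library multiple.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger("scpqb")

__all__ = [
    "origin_label",
    "annotate_library_origin",
    "fractional_increase",
    "stratify_tiers",
    "id_sets_from_report",
    "TIER_BOUNDS",
]

TIER_BOUNDS = (25.0, 50.0)  # percent absolute error: I < 25, II ≤ 50, III above


def origin_label(library_load: float, reference_load: float) -> str:
    """Render a library load as a multiple of the reference (1x, 2x, 2.5x...)."""
    m = float(library_load) / float(reference_load)
    if np.isclose(m, round(m)):
        return f"{int(round(m))}x"
    return f"{m:.1f}x"


def annotate_library_origin(
    id_sets: Mapping[object, set],
    reference_load: float,
    library_loads: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Assign each peptide the smallest library that first identified it.

    ``id_sets`` maps ``"direct"`` plus library loads (pg) to peptide-id
    sets; the direct set is mandatory. Origin is ``"direct"`` for peptides
    in the direct set, otherwise the label of the smallest library load
    whose set contains the peptide; peptides in no set are absent from the
    result. Non-nested sets (a peptide present at a smaller library but
    absent at a larger one) are tolerated with a logged warning — the
    smallest containing set still wins. Returns columns ``peptide_id``,
    ``origin``.
    """
    if "direct" not in id_sets:
        raise InputError('id_sets must contain a "direct" entry')
    loads = [k for k in id_sets if k != "direct"]
    if library_loads is not None:
        unknown = set(loads) - {float(x) for x in library_loads}
        if unknown:
            raise InputError(f"id_sets contain loads not in library_loads: {sorted(unknown)}")
    if not loads:
        raise InputError("id_sets must contain at least one library search")
    loads = sorted(float(x) for x in loads)

    rows: list[tuple[str, str]] = []
    assigned = set(id_sets["direct"])
    rows.extend((p, "direct") for p in sorted(assigned))
    seen = set(assigned)
    n_non_nested = 0
    for i, load in enumerate(loads):
        current = set(id_sets[load])
        for bigger in loads[i + 1 :]:
            n_non_nested += len((current - set(id_sets[bigger])))
        new = current - seen
        label = origin_label(load, reference_load)
        rows.extend((p, label) for p in sorted(new))
        seen |= current
    if n_non_nested:
        logger.warning(
            "annotate_library_origin: %d non-nested peptide memberships across "
            "cumulative searches; smallest containing set used", n_non_nested,
        )
    return pd.DataFrame(rows, columns=["peptide_id", "origin"])


def fractional_increase(n_base: int, n_augmented: int) -> float:
    """Percent gain in identifications: ``100 * (n_augmented − n_base) / n_base``."""
    if n_base <= 0:
        raise InputError("n_base must be > 0")
    return 100.0 * (n_augmented - n_base) / n_base


def _tier(abs_error: np.ndarray) -> np.ndarray:
    lo, hi = TIER_BOUNDS
    return np.where(abs_error < lo, "I", np.where(abs_error <= hi, "II", "III"))


def stratify_tiers(
    errors: pd.DataFrame,
    origins: pd.DataFrame,
    aggregate_first: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tier each error row by absolute error and tabulate fractions per origin.

    ``errors`` is an error table (per-replicate rows by default; with
    ``aggregate_first`` the absolute error is averaged per peptide before
    tiering); ``origins`` comes from :func:`annotate_library_origin` and
    must cover every peptide in ``errors``. Returns ``(tier_table,
    fraction_table)``; in the fraction table each origin's tier fractions
    sum to one.
    """
    df = errors[["peptide_id", "absolute_error_percent"]].copy()
    if aggregate_first:
        df = df.groupby("peptide_id", as_index=False)["absolute_error_percent"].mean()
    merged = df.merge(origins, on="peptide_id", how="left")
    if merged["origin"].isna().any():
        missing = merged.loc[merged["origin"].isna(), "peptide_id"].unique()
        raise InputError(f"{len(missing)} error peptides lack a library origin")
    merged["tier"] = _tier(merged["absolute_error_percent"].to_numpy(dtype=float))

    counts = (
        merged.groupby(["origin", "tier"]).size().unstack(fill_value=0)
        .reindex(columns=["I", "II", "III"], fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0).reset_index()
    fractions["n"] = counts.sum(axis=1).to_numpy()
    return merged[["peptide_id", "origin", "tier", "absolute_error_percent"]], fractions


def id_sets_from_report(
    report: pd.DataFrame,
    reference_load: float,
    library_loads: Sequence[float],
    quant_level: str = "MS1",
) -> dict[object, set]:
    """Build cumulative identification sets from a generator report table.

    See the module docstring for the construction; ``library_loads`` must
    include the reference load itself (the 1× peer-propagation search).
    """
    df = report[report["quant_level"] == quant_level]
    ref = df[np.isclose(df["load_pg"].astype(float), reference_load)]
    if len(ref) == 0:
        raise InputError(f"no rows at reference load {reference_load}")
    ref_runs = ref["run_id"].unique()
    n_ref = len(ref_runs)

    present_counts = ref.groupby("peptide_id")["run_id"].nunique()
    present_all = set(present_counts.index[present_counts == n_ref])
    direct_counts = (
        ref[ref["id_source"] == "direct"].groupby("peptide_id")["run_id"].nunique()
    )
    direct_all = set(direct_counts.index[direct_counts == n_ref])

    sets: dict[object, set] = {"direct": direct_all}
    loads = sorted(float(x) for x in library_loads)
    if not any(np.isclose(x, reference_load) for x in loads):
        raise InputError("library_loads must include the reference load (1x search)")
    cumulative_direct: set = set()
    for load in loads:
        at_load = df[np.isclose(df["load_pg"].astype(float), load)]
        cumulative_direct |= set(at_load.loc[at_load["id_source"] == "direct", "peptide_id"])
        sets[load] = direct_all | (present_all & cumulative_direct)
    return sets
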