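"""Single-cell protein covariation: Spearman networks, modules, complex recovery.

Protein–protein covariation across single cells carries information about
stable assemblies: subunits of a complex are produced and degraded together
and so correlate cell-to-cell. The analysis chain is

1. per-cell median centering of log2 intensities (removes the cell-size
   driven common mode that would correlate *everything*),
2. pairwise-complete Spearman correlation with a minimum-overlap guard,
3. filtering to proteins with at least one markedly correlated partner,
4. average-linkage hierarchical clustering on distance ``1 − ρ``,
5. permutation-based recovery scoring of annotated complexes
   (within-complex mean ρ versus complex-to-background mean ρ),
6. an ordinary least-squares fit of per-cell median log2 intensity on the
   sorter's FSC-A readout (cell size), on pre-normalization intensities —
   it measures exactly what the normalization removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DataError, InputError
from .report_io import AbundanceMatrix
from .synthetic import ComplexSpec

logger = logging.getLogger("scpqb")

__all__ = [
    "CovariationResult",
    "ComplexRecovery",
    "CellFit",
    "normalize_cells",
    "pairwise_spearman",
    "filter_correlated",
    "cluster_modules",
    "complex_recovery",
    "cell_size_fit",
    "read_gene_sets",
    "write_gene_sets",
]


def normalize_cells(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-cell median centering of log2 intensities.

    Returns a log2-scale matrix in which every cell (column) has median 0;
    idempotent on an already-centered matrix.
    """
    if matrix.is_log2:
        vals = matrix.values.copy()
    else:
        vals = np.log2(matrix.values)
    centered = vals - vals.median(axis=0)
    return AbundanceMatrix(
        centered, matrix.run_meta, matrix.row_unit, matrix.quant_level, is_log2=True
    )


@dataclass
class CovariationResult:
    """Protein-wise rank-correlation matrix and (optional) module structure."""

    proteins: list[str]
    rho: pd.DataFrame
    n_obs: pd.DataFrame
    module_label: pd.Series | None = None
    leaf_order: list[str] | None = None


def pairwise_spearman(matrix: AbundanceMatrix, min_obs: int = 10) -> CovariationResult:
    """Pairwise-complete Spearman ρ between proteins across cells.

    Each pair uses only the cells where both proteins are present; pairs
    with fewer than ``min_obs`` shared cells are set missing. Ties receive
    average ranks (the pandas/scipy convention).
    """
    cells_by_protein = matrix.values.T  # cells × proteins
    if cells_by_protein.shape[0] < 3:
        raise InputError("need >= 3 cells for correlation")
    rho = cells_by_protein.corr(method="spearman", min_periods=max(2, min_obs))
    present = cells_by_protein.notna().astype(float)
    n_obs = present.T @ present
    rho = rho.where(n_obs >= min_obs)
    np.fill_diagonal(rho.values, np.where(np.diag(n_obs) > 0, 1.0, np.nan))
    return CovariationResult(list(rho.index), rho, n_obs.astype(int))


def filter_correlated(
    result: CovariationResult,
    rho_threshold: float = 0.6,
    min_partners: int = 1,
) -> list[str]:
    """Proteins with at least ``min_partners`` partners at ``|ρ| ≥ rho_threshold``."""
    if not 0 <= rho_threshold <= 1:
        raise InputError("rho_threshold must be in [0, 1]")
    rho = result.rho.abs().copy()
    np.fill_diagonal(rho.values, np.nan)
    n_partners = (rho >= rho_threshold).sum(axis=1)
    return list(rho.index[n_partners >= min_partners])


def cluster_modules(
    result: CovariationResult,
    k: int,
    proteins: Sequence[str] | None = None,
) -> CovariationResult:
    """Average-linkage clustering on ``1 − ρ`` cut into ``k`` modules.

    ``proteins`` restricts the clustering (e.g. to a filtered subset);
    missing ρ entries are imputed as 0 (the null correlation) with a logged
    count because average linkage needs a complete matrix. Deterministic:
    same input gives the same labels and leaf order. Returns a new
    :class:`CovariationResult` with ``module_label`` and ``leaf_order``.
    """
    keep = list(result.proteins) if proteins is None else list(proteins)
    if k < 1 or k > len(keep):
        raise InputError(f"k must be in [1, {len(keep)}]")
    rho = result.rho.loc[keep, keep].copy()
    n_missing = int(rho.isna().to_numpy().sum())
    if n_missing:
        logger.info("cluster_modules: imputed %d missing rho entries as 0", n_missing)
        rho = rho.fillna(0.0)
    dist = 1.0 - rho.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)  # guard symmetry against fp asymmetry
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(z)
    return CovariationResult(
        proteins=keep,
        rho=rho,
        n_obs=result.n_obs.loc[keep, keep],
        module_label=pd.Series(labels, index=keep, name="module"),
        leaf_order=[keep[i] for i in leaves],
    )


@dataclass
class ComplexRecovery:
    """Permutation-tested covariation excess of one annotated complex."""

    complex_name: str
    n_members_present: int
    mean_within_rho: float
    mean_background_rho: float
    delta: float
    permutation_p: float


def _mean_within(rho: np.ndarray, idx: np.ndarray) -> float:
    sub = rho[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.nanmean(sub[iu]))


def _mean_between(rho: np.ndarray, idx: np.ndarray, other: np.ndarray) -> float:
    return float(np.nanmean(rho[np.ix_(idx, other)]))


def complex_recovery(
    result: CovariationResult,
    complexes: Sequence[ComplexSpec] | Mapping[str, Sequence[str]],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each complex: ``delta = mean within-ρ − mean member-to-background ρ``.

    The null distribution shuffles member labels over the retained proteins
    (random member sets of the same size); ``permutation_p`` uses +1
    smoothing: ``(1 + #{null ≥ observed}) / (n_perm + 1)``. Complexes with
    fewer than two members present yield a flagged NaN row.
    """
    if isinstance(complexes, Mapping):
        complexes = [
            ComplexSpec(name, tuple(members), 0.0) for name, members in complexes.items()
        ]
    rng = np.random.default_rng(seed)
    proteins = np.array(result.proteins)
    rho = result.rho.to_numpy(dtype=float)
    rows = []
    for cx in complexes:
        member_idx = np.flatnonzero(np.isin(proteins, list(cx.member_proteins)))
        if len(member_idx) < 2:
            logger.warning(
                "complex_recovery: %r has <2 members among retained proteins", cx.complex_name
            )
            rows.append(
                ComplexRecovery(cx.complex_name, len(member_idx), np.nan, np.nan, np.nan, np.nan)
            )
            continue
        other_idx = np.setdiff1d(np.arange(len(proteins)), member_idx)
        within = _mean_within(rho, member_idx)
        background = _mean_between(rho, member_idx, other_idx) if len(other_idx) else 0.0
        delta = within - background
        null = np.empty(n_perm)
        all_idx = np.arange(len(proteins))
        for i in range(n_perm):
            perm = rng.choice(all_idx, size=len(member_idx), replace=False)
            perm_other = np.setdiff1d(all_idx, perm)
            w = _mean_within(rho, perm)
            b = _mean_between(rho, perm, perm_other) if len(perm_other) else 0.0
            null[i] = w - b
        p = (1.0 + np.sum(null >= delta)) / (n_perm + 1.0)
        rows.append(
            ComplexRecovery(cx.complex_name, len(member_idx), within, background, delta, float(p))
        )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class CellFit:
    """OLS fit of per-cell median log2 intensity on FSC-A."""

    slope: float
    intercept: float
    r: float
    ok: bool
    per_cell: pd.DataFrame


def cell_size_fit(
    matrix: AbundanceMatrix,
    cell_meta: pd.DataFrame,
    protein_of: Mapping[str, str] | None = None,
    peptide_set: str = "shared",
) -> CellFit:
    """Regress per-cell median log2 intensity on the FSC-A size readout.

    Uses pre-normalization intensities. ``peptide_set="shared"`` (default)
    takes the median over the peptides present in *every* cell, so that
    abundance-dependent missingness cannot truncate small cells' medians
    differently from large cells'; ``"observed"`` uses each cell's own
    present values (the reading used for real single-cell scatter plots).
    Attaches per-cell protein-group counts (from ``protein_of`` if given,
    else row-unit counts). A constant FSC-A makes the fit undefined: the
    result is flagged ``ok=False`` with NaN slope.
    """
    if matrix.is_log2:
        raise InputError("cell_size_fit expects pre-normalization (linear) intensities")
    if peptide_set not in ("shared", "observed"):
        raise InputError("peptide_set must be 'shared' or 'observed'")
    meta = cell_meta.set_index("cell_id") if "cell_id" in cell_meta.columns else cell_meta
    cells = [c for c in matrix.values.columns if c in meta.index]
    if len(cells) < 3:
        raise InputError("need >= 3 cells with fsc_a")
    vals = matrix.values[cells]
    if peptide_set == "shared":
        vals_for_median = vals[vals.notna().all(axis=1)]
        if len(vals_for_median) == 0:
            raise DataError("no peptides shared by all cells; use peptide_set='observed'")
    else:
        vals_for_median = vals
    median_log2 = np.log2(vals_for_median).median(axis=0, skipna=True)

    if protein_of is not None:
        present = vals.notna()
        prot = pd.Series({u: protein_of.get(u, u) for u in vals.index})
        n_groups = {
            c: int(prot[present.index[present[c]]].nunique()) for c in cells
        }
    else:
        n_groups = vals.notna().sum(axis=0).astype(int).to_dict()

    per_cell = pd.DataFrame(
        {
            "cell_id": cells,
            "fsc_a": meta.loc[cells, "fsc_a"].to_numpy(dtype=float),
            "median_log2_intensity": median_log2.to_numpy(),
            "n_protein_groups": [n_groups[c] for c in cells],
        }
    )
    x = per_cell["fsc_a"].to_numpy()
    y = per_cell["median_log2_intensity"].to_numpy()
    if np.allclose(x, x[0]):
        logger.warning("cell_size_fit: constant FSC-A, fit undefined")
        return CellFit(np.nan, np.nan, np.nan, False, per_cell)
    fit = stats.linregress(x, y)
    return CellFit(float(fit.slope), float(fit.intercept), float(fit.rvalue), True, per_cell)


# ---------------------------------------------------------------------------
# gene-set-style complex membership files (name <tab> description <tab> members...)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str) -> dict[str, list[str]]:
    """Read tab-delimited membership sets (GMT-style: name, description, members)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [p for p in parts[2:] if p]
    if not sets:
        raise DataError(f"no membership sets found in {path!r}")
    return sets


def write_gene_sets(sets: Mapping[str, Sequence[str]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
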