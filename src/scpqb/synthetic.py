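"""Synthetic DIA report-table generator for dilution series and single cells.

The generator produces long-format peptide report tables with the statistical
structure that low-input DIA measurements exhibit, so that every downstream
analysis stage (precision, accuracy, ID-propagation stratification, protein
covariation) can be exercised against a known ground truth:

* signal proportional to the injected load (pg), with an optional small
  sub-proportional loss bias at low load (``intensity ∝ load**e``, e ≥ 1);
* a chemical-background term that scales with the input amount and is added
  to the expected signal before ion sampling;
* multiplicative log-normal technical noise shared between the MS1 and MS2
  readouts of the same peptide in the same run;
* shot noise from Poisson ion counting, so the relative noise grows as
  ``1/sqrt(expected ions)`` toward low loads;
* missing-not-at-random detection: a peptide is reported only when its
  sampled ion count clears a detection threshold, with a lower threshold for
  identifications that a higher-load library could propagate.

Randomness discipline: one master seed; every (stage, run) pair draws from
its own ``numpy`` ``SeedSequence`` substream via a fixed ``spawn_key``, so
adding a stage or a run never perturbs another stage's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "NoiseConfig",
    "CellSpec",
    "ComplexSpec",
    "simulate_catalog",
    "simulate_dilution_series",
    "simulate_single_cells",
    "make_cell_specs",
    "make_complexes",
    "true_size_slope",
]

# spawn-key stage ids (never reorder: they define the substream layout)
_STAGE_CATALOG = 0
_STAGE_DILUTION = 1
_STAGE_CELLS = 2
_STAGE_CELLSPECS = 3
_STAGE_RESPONSE = 4

#: canonical long-format report columns (the "native" dialect of report_io)
REPORT_COLUMNS = [
    "run_id",
    "load_pg",
    "replicate",
    "peptide_id",
    "protein_id",
    "quant_level",
    "intensity",
    "id_source",
    "library_origin",
]


def _rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage, index)))


@dataclass(frozen=True)
class NoiseConfig:
    """Noise and detection model of the generator.

    Parameters
    ----------
    technical_cv
        Coefficient of variation (fraction) of the multiplicative log-normal
        technical scatter. ``0`` disables it.
    ions_per_signal
        Conversion from signal units to expected ion counts. Shot noise is
        Poisson on ``expected_signal * ions_per_signal``; ``math.inf``
        disables shot noise (and makes every peptide directly detectable).
    background_per_pg
        Additive chemical-background signal per pg of load, applied to every
        peptide's expected signal before ion sampling. The background scales
        with the input amount, as observed for low-input DIA runs.
    detection_threshold
        Minimum sampled ion count for a direct identification.
    propagated_threshold
        Lower ion-count threshold at which a peptide is still quantifiable
        when an external library supplies the identification. Must not
        exceed ``detection_threshold``.
    loss_bias_exponent
        ``e ≥ 1`` in ``expected ∝ load**e``; values slightly above 1 give the
        sub-proportional low-load medians seen in real dilution series
        (small losses between vial and instrument).
    response_exponent_sd
        Per-peptide scatter (SD) around ``loss_bias_exponent``: peptide ``p``
        responds as ``load**(e + δ_p)`` with ``δ_p ~ N(0, sd)`` drawn once
        per simulation. This models peptide-specific response nonlinearity
        (adsorptive losses, detector/interference effects), making ratio
        errors widen with the log dynamic range of the compared loads even
        when ion counts are large — counting noise alone cannot produce
        that behavior. ``0`` disables it.
    ms2_ion_fraction
        Multiplier on effective ions for the MS2 readout. MS1 and MS2 share
        the technical-noise draw but take independent shot-noise draws; the
        default ``2.0`` gives MS2 more effective ions so that MS1 shows the
        broader CV distribution, matching precursor-level interference.
    seed
        Master seed for all generator randomness.
    """

    technical_cv: float = 0.05
    ions_per_signal: float = 0.1
    background_per_pg: float = 0.5
    detection_threshold: float = 50.0
    propagated_threshold: float = 5.0
    loss_bias_exponent: float = 1.05
    response_exponent_sd: float = 0.05
    ms2_ion_fraction: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technical_cv < 0:
            raise InputError("technical_cv must be >= 0")
        if self.ions_per_signal <= 0:
            raise InputError("ions_per_signal must be > 0 (use math.inf to disable)")
        if self.background_per_pg < 0:
            raise InputError("background_per_pg must be >= 0")
        if not 0 < self.propagated_threshold <= self.detection_threshold:
            raise InputError("need 0 < propagated_threshold <= detection_threshold")
        if self.loss_bias_exponent < 1:
            raise InputError("loss_bias_exponent must be >= 1")
        if self.response_exponent_sd < 0:
            raise InputError("response_exponent_sd must be >= 0")
        if self.ms2_ion_fraction <= 0:
            raise InputError("ms2_ion_fraction must be > 0")


@dataclass(frozen=True)
class CellSpec:
    """One sorted cell: sorter size readout and its total-signal multiplier."""

    cell_id: str
    fsc_a: float
    size_factor: float

    def __post_init__(self) -> None:
        if self.fsc_a <= 0 or self.size_factor <= 0:
            raise InputError("fsc_a and size_factor must be > 0")


@dataclass(frozen=True)
class ComplexSpec:
    """A protein complex whose members covary cell-to-cell.

    ``covariation_strength`` is the loading of a shared per-cell latent
    factor: member signal is multiplied by ``exp(strength * z_cell)`` with
    ``z_cell ~ N(0, 1)`` drawn once per (cell, complex).
    """

    complex_name: str
    member_proteins: tuple[str, ...]
    covariation_strength: float

    def __post_init__(self) -> None:
        if len(set(self.member_proteins)) < 2:
            raise InputError(f"complex {self.complex_name!r} needs >= 2 distinct members")
        if not 0 <= self.covariation_strength <= 1:
            raise InputError("covariation_strength must be in [0, 1]")


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def simulate_catalog(
    n_proteins: int,
    peptides_per_protein: tuple[int, int] = (1, 3),
    dynamic_range_log10: float = 4.0,
    seed: int = 0,
    distribution: str = "log-uniform",
) -> pd.DataFrame:
    """Draw a latent peptide catalog.

    Returns a DataFrame with columns ``peptide_id``, ``protein_id``,
    ``base_abundance`` (signal units per pg of load) and ``ionizability``.
    Base abundances span ``dynamic_range_log10`` decades, drawn log-uniform
    (default) or log-normal with a 4-sigma span over the requested decades.
    Deterministic given ``seed``.
    """
    if n_proteins < 1:
        raise InputError("n_proteins must be >= 1")
    lo, hi = peptides_per_protein
    if lo < 1 or hi < lo:
        raise InputError("peptides_per_protein must be a (low, high) range with low >= 1")
    if dynamic_range_log10 <= 0:
        raise InputError("dynamic_range_log10 must be > 0")
    if distribution not in ("log-uniform", "log-normal"):
        raise InputError(f"unknown base-abundance distribution {distribution!r}")

    rng = _rng(seed, _STAGE_CATALOG)
    n_pep = rng.integers(lo, hi + 1, size=n_proteins)
    protein_ids = np.repeat(
        np.array([f"PROT{i:05d}" for i in range(n_proteins)]), n_pep
    )
    counters = np.concatenate([np.arange(1, k + 1) for k in n_pep])
    peptide_ids = np.array(
        [f"{p}_pep{c}" for p, c in zip(protein_ids, counters)]
    )
    n_total = len(peptide_ids)
    if distribution == "log-uniform":
        log10_base = rng.uniform(0.0, dynamic_range_log10, size=n_total)
    else:
        log10_base = rng.normal(
            dynamic_range_log10 / 2.0, dynamic_range_log10 / 4.0, size=n_total
        )
    ionizability = np.exp(rng.normal(0.0, 0.25, size=n_total))
    return pd.DataFrame(
        {
            "peptide_id": peptide_ids,
            "protein_id": protein_ids,
            "base_abundance": 10.0 ** log10_base,
            "ionizability": ionizability,
        }
    )


# ---------------------------------------------------------------------------
# shared measurement machinery
# ---------------------------------------------------------------------------

def _response_exponents(catalog: pd.DataFrame, cfg: NoiseConfig) -> np.ndarray:
    """Per-peptide load-response exponents, drawn once per simulation."""
    if cfg.response_exponent_sd == 0:
        return np.full(len(catalog), cfg.loss_bias_exponent)
    rng = _rng(cfg.seed, _STAGE_RESPONSE)
    return cfg.loss_bias_exponent + rng.normal(0.0, cfg.response_exponent_sd, len(catalog))


def _expected_signal(
    catalog: pd.DataFrame, load: float, cfg: NoiseConfig, exponents: np.ndarray
) -> np.ndarray:
    base = catalog["base_abundance"].to_numpy()
    ioniz = catalog["ionizability"].to_numpy()
    return base * load**exponents * ioniz + cfg.background_per_pg * load


def _technical_factor(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    # mean-one log-normal so technical noise never shifts the expected signal
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _sample_level(
    rng: np.random.Generator,
    expected_with_tech: np.ndarray,
    cfg: NoiseConfig,
    ion_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (intensity, ions) for one quant level of one run."""
    ions_per_signal = cfg.ions_per_signal * ion_fraction
    if math.isinf(cfg.ions_per_signal):
        intensity = expected_with_tech.copy()
        ions = np.full_like(intensity, np.inf)
        return intensity, ions
    lam = expected_with_tech * ions_per_signal
    ions = rng.poisson(lam).astype(float)
    intensity = ions / ions_per_signal
    return intensity, ions


def _emit_run_rows(
    catalog: pd.DataFrame,
    cfg: NoiseConfig,
    rng: np.random.Generator,
    expected: np.ndarray,
    run_id: str,
    load_pg: float,
    replicate: int,
) -> list[pd.DataFrame]:
    """Sample both quant levels for one run and keep rows above threshold."""
    tech = _technical_factor(rng, len(catalog), cfg.technical_cv)
    expected_tech = expected * tech
    frames = []
    for quant_level, ion_fraction in (("MS1", 1.0), ("MS2", cfg.ms2_ion_fraction)):
        intensity, ions = _sample_level(rng, expected_tech, cfg, ion_fraction)
        detected = ions >= cfg.propagated_threshold
        if not detected.any():
            continue
        direct = ions >= cfg.detection_threshold
        frame = pd.DataFrame(
            {
                "run_id": run_id,
                "load_pg": load_pg,
                "replicate": replicate,
                "peptide_id": catalog["peptide_id"].to_numpy()[detected],
                "protein_id": catalog["protein_id"].to_numpy()[detected],
                "quant_level": quant_level,
                "intensity": intensity[detected],
                "id_source": np.where(direct[detected], "direct", "propagated"),
                "library_origin": pd.Series(
                    [pd.NA] * int(detected.sum()), dtype="string"
                ),
            }
        )
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# dilution series
# ---------------------------------------------------------------------------

def simulate_dilution_series(
    catalog: pd.DataFrame,
    loads: Sequence[float],
    replicates: int = 3,
    cfg: NoiseConfig = NoiseConfig(),
) -> pd.DataFrame:
    """Simulate a dilution-series report table.

    One run is emitted per (load, replicate); each run carries MS1 and MS2
    intensities as two correlated noise realizations of the same underlying
    signal. Peptides whose sampled ion count stays below the propagated
    threshold are absent from the table (missing, never zero). Rows with
    ion counts between the propagated and the direct detection threshold are
    flagged ``id_source == "propagated"``: quantifiable only when a library
    supplies the identification.
    """
    if len(catalog) == 0:
        raise InputError("catalog is empty")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    loads = [float(x) for x in loads]
    if any(x <= 0 for x in loads):
        raise InputError("loads must be positive")

    frames: list[pd.DataFrame] = []
    run_index = 0
    exponents = _response_exponents(catalog, cfg)
    for load in loads:
        expected = _expected_signal(catalog, load, cfg, exponents)
        for rep in range(1, replicates + 1):
            rng = _rng(cfg.seed, _STAGE_DILUTION, run_index)
            run_index += 1
            run_id = f"dil_{load:g}pg_r{rep}"
            frames.extend(
                _emit_run_rows(catalog, cfg, rng, expected, run_id, load, rep)
            )
    if not frames:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[REPORT_COLUMNS]


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

def make_cell_specs(
    n_cells: int,
    seed: int = 0,
    fsc_low: float = 500.0,
    fsc_high: float = 1500.0,
    log2_size_per_fsc: float = 0.002,
) -> list[CellSpec]:
    """Draw cell specs with size factor exponential in the FSC-A readout.

    ``size_factor = 2 ** (log2_size_per_fsc * (fsc_a - fsc_mid))`` with
    ``fsc_mid`` the midpoint of the FSC range, so total signal is log-linear
    in cell size and ``log2_size_per_fsc`` is the ground-truth slope of
    log2 signal versus FSC-A (before the loss-bias exponent).
    """
    if n_cells < 2:
        raise InputError("need >= 2 cells")
    rng = _rng(seed, _STAGE_CELLSPECS)
    fsc = rng.uniform(fsc_low, fsc_high, size=n_cells)
    mid = 0.5 * (fsc_low + fsc_high)
    return [
        CellSpec(
            cell_id=f"cell{i:04d}",
            fsc_a=float(f),
            size_factor=float(2.0 ** (log2_size_per_fsc * (f - mid))),
        )
        for i, f in enumerate(fsc)
    ]


def make_complexes(
    catalog: pd.DataFrame,
    sizes: Sequence[int],
    strengths: Sequence[float],
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> list[ComplexSpec]:
    """Pick disjoint member sets from the catalog's proteins."""
    if len(sizes) != len(strengths):
        raise InputError("sizes and strengths must have equal length")
    proteins = catalog["protein_id"].unique()
    if sum(sizes) > len(proteins):
        raise InputError("not enough proteins in catalog for the requested complexes")
    rng = _rng(seed, _STAGE_CELLSPECS, 1)
    chosen = rng.choice(proteins, size=sum(sizes), replace=False)
    out, start = [], 0
    for i, (k, s) in enumerate(zip(sizes, strengths)):
        name = names[i] if names is not None else f"complex{i + 1}"
        out.append(
            ComplexSpec(
                complex_name=name,
                member_proteins=tuple(sorted(chosen[start : start + k])),
                covariation_strength=float(s),
            )
        )
        start += k
    return out


def simulate_single_cells(
    catalog: pd.DataFrame,
    cells: Sequence[CellSpec],
    complexes: Sequence[ComplexSpec] = (),
    cfg: NoiseConfig = NoiseConfig(),
    cell_load_pg: float = 25.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate single-cell report rows plus a cell metadata table.

    Each cell behaves like a dilution run at effective load
    ``cell_load_pg * size_factor``; members of a complex share a per-cell
    latent factor ``exp(strength * z)`` so their (normalized) quantities
    covary cell-to-cell, while all other proteins carry independent noise
    only. Detection is missing-not-at-random exactly as in the dilution
    simulation. Returns ``(report, cell_meta)`` where ``cell_meta`` has
    columns ``cell_id``, ``fsc_a``, ``size_factor``.
    """
    if len(catalog) == 0:
        raise InputError("catalog is empty")
    if len(cells) < 2:
        raise InputError("need >= 2 cells")
    known = set(catalog["protein_id"])
    for cx in complexes:
        missing = set(cx.member_proteins) - known
        if missing:
            raise InputError(
                f"complex {cx.complex_name!r} members absent from catalog: {sorted(missing)}"
            )
    sizes = np.array([c.size_factor for c in cells])
    fscs = np.array([c.fsc_a for c in cells])
    order = np.argsort(fscs)
    if np.any(np.diff(sizes[order]) < 0):
        raise InputError("size_factor must be monotone in fsc_a")

    protein_arr = catalog["protein_id"].to_numpy()
    member_masks = [np.isin(protein_arr, list(cx.member_proteins)) for cx in complexes]

    frames: list[pd.DataFrame] = []
    meta_rows = []
    exponents = _response_exponents(catalog, cfg)
    for i, cell in enumerate(cells):
        rng = _rng(cfg.seed, _STAGE_CELLS, i)
        eff_load = cell_load_pg * cell.size_factor
        expected = _expected_signal(catalog, eff_load, cfg, exponents)
        # one latent factor per complex per cell, shared by all member peptides
        for cx, mask in zip(complexes, member_masks):
            z = rng.normal()
            if cx.covariation_strength > 0:
                expected = np.where(
                    mask, expected * math.exp(cx.covariation_strength * z), expected
                )
        frames.extend(
            _emit_run_rows(
                catalog, cfg, rng, expected, cell.cell_id, float("nan"), i + 1
            )
        )
        meta_rows.append(
            {"cell_id": cell.cell_id, "fsc_a": cell.fsc_a, "size_factor": cell.size_factor}
        )
    report = (
        pd.concat(frames, ignore_index=True)[REPORT_COLUMNS]
        if frames
        else pd.DataFrame(columns=REPORT_COLUMNS)
    )
    return report, pd.DataFrame(meta_rows)


def true_size_slope(cells: Sequence[CellSpec], cfg: NoiseConfig = NoiseConfig()) -> float:
    """Ground-truth OLS slope of log2 signal versus FSC-A for given cells.

    A fixed peptide observed without noise in cell ``c`` has log2 intensity
    ``const + e * log2(eff_load_c)`` with ``e`` the loss-bias exponent, so the
    ground truth is the OLS slope of ``e * log2(size_factor)`` on ``fsc_a``.
    """
    x = np.array([c.fsc_a for c in cells])
    y = cfg.loss_bias_exponent * np.log2([c.size_factor for c in cells])
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
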