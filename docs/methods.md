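# Methods

This note documents the models, conventions and design choices behind
`scpqb`: what the synthetic generator simulates (and what it deliberately
does not), how each statistic is defined, and where the design was
genuinely open.

## The generator's measurement model

Each peptide *p* carries a latent base abundance *a_p* (signal units per pg
of load, drawn log-uniform over a configurable number of decades, 4 by
default) and an ionizability factor *i_p* (log-normal, σ = 0.25). For a run
at load *L* pg the expected signal is

    μ_p(L) = a_p · L^(e + δ_p) · i_p + b·L

with four noise/bias channels layered on top:

- **Loss bias** `e = loss_bias_exponent` (default 1.05). Real dilution
  series show medians falling slightly faster than proportionally at low
  load (losses on the path from vial to instrument); a single exponent
  e ≥ 1 reproduces this monotonically and invertibly.
- **Response scatter** δ_p ~ N(0, `response_exponent_sd`), default 0.05,
  drawn once per simulation. This models peptide-specific response
  nonlinearity (adsorptive losses, interference, detector effects). It is
  what makes ratio-error distributions widen with the *log dynamic range*
  of the compared loads even when ion counts are large — pure counting
  noise cannot produce that behavior, yet it is the dominant feature of
  measured error distributions at high loads, and it is why comparing two
  adjacent low loads (20:40, 10:20 pg) gives much narrower errors than
  comparing against a distant reference.
- **Background** `b = background_per_pg` (default 0.5 signal/pg) is added
  to every peptide's expectation *before* ion sampling. Chemical background
  scales with the injected amount, so it cancels exactly in expected ratios
  (it biases neither the dilution design nor the noise-free tests) while
  setting a detection floor that scales with load.
- **Technical noise**: one mean-one log-normal factor per (peptide, run)
  with CV = `technical_cv` (default 5%, the scale of replicate CVs at high
  load in triplicate DIA designs), shared between the MS1 and MS2 readouts
  of that run.
- **Shot noise**: observed ions ~ Poisson(μ·tech·`ions_per_signal`),
  intensity = ions / `ions_per_signal` (default 0.1 ions per signal unit).
  This yields the familiar CV ∝ 1/√(expected ions) ∝ L^(−1/2) growth toward
  low load. `ions_per_signal = inf` disables counting noise entirely.

MS1 and MS2 are two realizations of the same underlying signal: they share
the technical-noise draw but take independent Poisson draws, MS2 with
`ms2_ion_fraction` (default 2.0) times the effective ions. The default
direction gives MS1 the broader CV distribution, consistent with
precursor-level quantities suffering co-eluting background interference
that fragment-level extraction deconvolutes.

**Detection (MNAR)**: a peptide row is emitted only if its sampled ion
count reaches `propagated_threshold` (default 5 ions); it is flagged
`direct` if it also reaches `detection_threshold` (default 50 ions), else
`propagated` — quantifiable only when a library supplies the
identification. The 10× gap reflects that integrating a known precursor's
signal needs far less evidence than an unassisted identification. Missing
measurements are absent rows, never zeros. Detection probability is
non-decreasing in abundance and load by construction.

**Randomness discipline**: one master seed; each (stage, run) pair draws
from its own `SeedSequence` substream with a fixed spawn key, so adding a
stage or a run never perturbs any other stage's draws, and identical
configurations are byte-identical on rerun.

### Single cells

Cell *c* behaves like a dilution run at effective load
`cell_load_pg · size_factor_c` (default 25 pg — single-cell signal in
practice sits well below the 250 pg proxy commonly used). The helper
`make_cell_specs` draws FSC-A uniformly over [500, 1500] sorter units and
sets `size_factor = 2^(s·(FSC−1000))` with `s = log2_size_per_fsc`
(default 0.002), so log2 total signal is linear in FSC-A with a known
slope — the regression target of `cell_size_fit`; `true_size_slope`
returns the ground truth (e·s for the exponential size model).

Members of an annotated complex share one latent factor per (cell,
complex): member signal is multiplied by `exp(λ·z_c)`, `z_c ~ N(0,1)`,
λ = `covariation_strength`. Proteins outside complexes receive independent
noise only, so any background correlation is driven by the cell-size
common mode, which per-cell normalization removes.

### What the generator does not emulate

No spectra, chromatographic peak shapes, charge states, modifications,
FAIMS transmission, interference structure between specific peptides, or
search-engine FDR behavior. Its parameters are plausible for low-input DIA
but are not calibrated to any deposited instrument dataset. Passing tests
therefore demonstrate that the *analysis chain* is correct and recovers
known structure under realistic noise — not that any particular instrument
achieves these numbers.

## Statistical definitions and numerical choices

- **CV**: 100·SD/mean on raw (non-normalized, linear) intensities, sample
  (n−1) SD — the right convention for triplicate designs. Units with <2
  observations in a group are skipped, never imputed. When MS1 and MS2 CV
  distributions are compared, `intersect_units` restricts both levels to
  the shared peptide set first.
- **Quantiles**: linear interpolation between order statistics
  (`numpy.quantile` default), stated because conventions differ across
  ecosystems.
- **Ratio errors** are computed on linear-scale ratios within replicate
  pairs (replicates paired by index); a pooled mode and log2-ratio mode
  exist but are off by default. Self-comparison yields exactly zero.
- **Gaussian-core width**: the central 90% of relative errors is
  histogrammed (41 bins) and a single Gaussian fitted to bin counts by
  least squares; this is robust to the heavy tails that appear at low
  loads. FWHM = `fwhm_constant`·σ with default 2.634 — the constant used
  in the benchmarking literature this pipeline follows — while the exact
  Gaussian constant 2·√(2·ln 2) ≈ 2.3548 is available; the package
  supports both and does not silently "correct" either.
- **Threshold fractions** count strictly below (error < t), so integer
  counts are reproducible; the empirical CDF is right-continuous (≤ t).
  The two coincide for continuous data and differ only at atoms.
- **Tiers**: I below 25%, II from 25 to 50% inclusive (a closed interval,
  so the boundary values 25 and 50 are tier II), III above 50%.
- **Library origins**: `id_sets` are inputs — no search engine is re-run.
  The generator-side construction defines *direct* as directly detected in
  every reference run; the *m×* search additionally admits peptides
  quantifiable (above the propagated threshold) in all reference runs and
  directly detected in ≥1 run at load ≤ m·reference. Sets are cumulative
  in m; non-nested inputs are tolerated with a warning and the smallest
  containing set wins. Per-replicate error rows are tiered independently
  by default (`aggregate_first` averages per peptide first).
- **Spearman correlation**: pairwise-complete cells, average ranks for
  ties, entries with fewer than `min_obs` (default 10) shared cells set
  missing. Computed after per-cell median centering of log2 intensities by
  default — the paper-style normalization question is genuinely open (some
  exports arrive MaxLFQ-normalized, some with cross-run normalization
  off), so both modes are exposed (`normalize` switch).
- **"Markedly correlated"** is not a standard quantity; the default filter
  keeps proteins with ≥1 partner at |ρ| ≥ 0.6, all three knobs exposed in
  config.
- **Clustering**: average linkage on 1 − ρ, cut with `maxclust` into k
  modules; k is a required user choice (dendrogram granularity is a
  judgment call). Missing ρ entries are imputed as 0 (the null
  correlation) with a logged count, because average linkage needs a
  complete matrix. The pipeline clusters the full protein set by default
  (`cluster_scope: all`): when the marked-correlation filter retains
  little beyond a few tight complexes, cutting only that subset at k
  forces a split straight through a complex, whereas on the full map the
  diffuse background absorbs the extra clusters and tight blocks stay
  intact. `cluster_scope: filtered` reproduces the filter-then-cluster
  reading.
- **Complex recovery**: Δ = mean within-complex ρ − mean
  member-to-background ρ; the null re-draws member sets of the same size
  uniformly from the retained proteins, and p = (1 + #{Δ_null ≥ Δ}) /
  (n_perm + 1) (add-one smoothing, so p is never 0).
- **Cell-size fit**: OLS of per-cell median log2 intensity on FSC-A, on
  pre-normalization intensities (the fit measures exactly what
  normalization removes). The median is taken over the peptides shared by
  all cells by default: under MNAR detection, each cell's *observed*
  median is truncated differentially by cell size (small cells lose more
  of their faint peptides, pushing their observed median up), which
  inflates the slope; a fixed peptide set removes that bias. The
  `observed` mode mirrors how real single-cell scatter plots are usually
  drawn.

## Problem sizes

Default study conditions: dilution series over
10/20/30/40/50/100/150/200/250/500 pg in triplicate (the union of a
low-range design with a 100 pg reference and a library design with a 50 pg
reference and up to 10× libraries), catalogs of 800 proteins with 1–3
peptides each (~1600 peptides); single-cell runs with 100 cells, 200
proteins, two annotated complexes of 6 and 8 members at strength 0.9.
These sizes give stable Monte-Carlo behavior for every recovery check
while keeping any full run in the seconds-to-minutes range.

## Known limitations

- The generator's CV–load law is shot-noise + technical floor; real
  instruments may deviate (e.g. detector saturation at high load is not
  modeled).
- Library-origin semantics are a simplified, threshold-based stand-in for
  search-engine ID transfer; FDR effects of propagated identifications are
  out of scope.
- The permutation null for complex recovery treats proteins as
  exchangeable; strong mean-abundance structure in real data may warrant
  abundance-matched nulls.
- Protein rollup is a plain peptide-intensity sum; MaxLFQ-style rollup is
  out of scope.
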