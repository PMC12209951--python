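# scpqb — quantitative-accuracy benchmarking for low-input and single-cell DIA proteomics

Single-cell proteomics by mass spectrometry (scp-MS) measures peptide signal
at the very edge of instrument sensitivity, where ion-counting statistics,
load-scaled chemical background and abundance-dependent missingness all
degrade the measured quantities. Before trusting single-cell protein
abundances, one wants to know *how accurately* known ratios are recovered at
single-cell-level loads (tens of pg), what it costs to borrow
identifications from higher-load library runs, and whether the resulting
matrices still carry biology (e.g. covariation of protein-complex
subunits across cells).

`scpqb` is a reusable pipeline for exactly these questions. It consumes
long-format peptide report tables (Spectronaut- or DIA-NN-style exports, or
its own native dialect) and computes:

- **Precision** — complete-case filtering and per-peptide coefficients of
  variation, CV% = 100·SD/mean (sample SD, raw non-normalized intensities),
  plus log2 abundance-distribution summaries (median, 5/95% quantiles).
- **Accuracy** — dilution-design ratio errors per peptide,
  `relative error% = 100·(observed − expected)/expected` with
  `expected = target load / reference load`; summaries include the mean
  over replicates of the per-replicate error SD, a robust Gaussian-core
  width σ reported as FWHM = 2.634·σ (the standard Gaussian constant
  2.3548 is also supported), empirical CDFs of the absolute error and
  strict-inequality threshold fractions.
- **ID propagation** — annotation of each peptide with the smallest library
  (as a multiple of the reference load: direct, 1×, 2×, …) that first
  enabled its identification, fractional identification gains, and
  stratification of quantities into accuracy tiers
  (I: error < 25%, II: 25–50%, III: > 50%).
- **Covariation** — per-cell median-centered log2 matrices, pairwise-complete
  Spearman correlation with a minimum-overlap guard, hierarchical module
  clustering on distance 1 − ρ, permutation-tested recovery of annotated
  protein complexes (Δ = mean within-complex ρ − mean member-to-background
  ρ), and an OLS fit of per-cell median log2 intensity on FSC-A cell size.

A **synthetic report-table generator** emulates the statistical structure of
such data — load-proportional signal with a small sub-proportional low-load
loss bias (intensity ∝ load^e, e ≥ 1), Poisson shot noise, shared log-normal
technical noise across MS1/MS2, load-scaled additive background,
peptide-specific response nonlinearity, missing-not-at-random detection with
a lower threshold for library-assisted identifications, and single-cell
matrices with cell-size scaling and latent-factor complex covariation — so
the whole pipeline runs against known ground truth with no downloads.

## Worked example

Run the end-to-end synthetic dilution benchmark (800 proteins, loads
10–500 pg in triplicate, 100 pg reference for the low-load accuracy design,
50 pg reference for the library-propagation design):

```python
from scpqb.pipeline import RunConfig, CatalogConfig, run_benchmark
import pandas as pd

cfg = RunConfig(master_seed=1, catalog=CatalogConfig(n_proteins=800),
                output_dir="demo_out")
out = run_benchmark(cfg)

cv = pd.read_csv(out / "cv_table.tsv", sep="\t")
print(cv.groupby("group")["cv_percent"].median().round(2))
```

```
group
10.0     7.23
20.0     6.36
30.0     5.84
40.0     5.52
50.0     5.45
100.0    5.00
...
500.0    4.36
```

Median peptide CVs fall from ~7% at 10 pg toward the 5% technical floor at
high load — shot noise dominating at single-cell-level inputs. The accuracy
summary (`error_summary.tsv`) shows the same trend as widening ratio-error
distributions when the target load drops away from the 100 pg reference:

```
 target  n_peptides  sigma_fit   fwhm  fraction_below_20
   50.0        1300      8.838 23.279              0.935
   30.0        1300      9.936 26.171              0.878
   20.0        1300     11.472 30.216              0.818
   10.0        1300     15.147 39.898              0.671
```

i.e. >90% of complete-case peptides recover the expected 1:2 ratio within
20%, degrading to ~67% for the 1:10 ratio. The tier table
(`tier_fractions.tsv`) stratifies library-propagated identifications: direct
IDs are almost all tier I (<25% error), peer 1× transfers remain good, and
quantities first identified through ≥2× libraries carry an increasing share
of tier-III (>50% error) values:

```
origin     I    II   III    n
direct 0.969 0.031 0.001 3636
    1x 0.703 0.267 0.030  165
    2x 0.712 0.201 0.088  399
    4x 0.507 0.327 0.167  150
   10x 0.417 0.444 0.139   36
```

The single-cell covariation chain is run analogously with
`scpqb.pipeline.run_covariation` (or the `scpqb covariation` CLI), yielding
the Spearman matrix, module labels, complex-recovery scores and the
cell-size fit.

A command-line interface mirrors the library:

```bash
scpqb simulate dilution --seed 1 --out sim/
scpqb accuracy --report sim/report.tsv --reference 100 --targets 50,20,10 --out acc/
scpqb benchmark --seed 1 --out bench/
```

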