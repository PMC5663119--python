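# dysregdir

Identify subject-level factors associated with the **direction and
significance** of paired tumor–normal expression differences, per tumor
site. The pipeline:

1. **Scale normalization** — each sample is multiplied by
   (median of all samples' 75th percentiles) / (that sample's 75th
   percentile), so every sample's 75th percentile matches the global
   median.
2. **Multimodality screen** — Hartigan's dip statistic on each feature's
   tumor−normal difference distribution (exact zeros retained), with
   add-one Monte-Carlo p-values against the uniform null and Hommel
   family-wise error control at 0.05 per site. Only multimodal features
   proceed.
3. **Stratified signed-rank testing** — a one-sided Wilcoxon signed-rank
   test (zeros dropped, mid-ranks under ties; exact enumeration for small
   effective n, tie-corrected normal approximation otherwise) overall and
   within each binary factor's levels, whenever both levels have at least
   10 subjects at the site.
4. **One-sided FDR adjustment** — per site and per test arm (overall /
   level 0 / level 1): tail pairs are folded to two-sided p-values,
   Benjamini–Hochberg adjusted at 0.05, and unfolded to a single one-sided
   value in [0, 1].
5. **Classification & colors** — adjusted one-sided p-values map to
   Down (&lt; .05/2), Up (&gt; 1 − .05/2), NS (inside (.15/2, 1 − .15/2)),
   or inconclusive; each (overall, level-0, level-1) triple receives one of
   five color categories (blue / green / orange / purple / yellow) or none.

A first-class synthetic-data module generates paired studies with a
planted mixture structure — exact-zero spike, null spread, directional
modes with factor-dependent weights, missingness, per-sample scale
factors — plus ground truth for recovery and error-rate testing.

## Tests

```sh
python -m pytest tests/
```

The suite includes independent brute-force oracles (an LP-based
unimodal-fit minimizer for the dip statistic, full 2^n sign enumeration
for the signed-rank test, closed-testing Simes for Hommel, quadratic
step-up for BH) plus error-rate and planted-color recovery simulations.
`tests/test_acceptance.py` holds one test per acceptance criterion.

## CLI

```sh
# generate a synthetic study (one scenario per color category)
dysregdir simulate --scenario yellow --seed 7 --n-subjects 500 --out sim/

# run the full analysis
dysregdir run --expression sim/expression.tsv --metadata sim/metadata.tsv \
              --config config.yaml --out out/

# triptych histogram (overall / level 0 / level 1) for one feature
dysregdir plot --expression sim/expression.tsv --metadata sim/metadata.tsv \
               --site proximal --feature plant000 --factor DRIVER --out fig.png
```

`run` writes `results.csv` (one row per site/factor/feature with sample
sizes, adjusted one-sided p-values, labels and color), per-site screen
TSVs, a color-annotated cross-tabulation, the scale-factor audit table,
a config echo and a log of every skipped test.

The YAML config mirrors `dysregdir.RunConfig`; all fields are optional.
Defaults: `transform: log2p1`, `dip_B: 10000`, `fwer_alpha: 0.05`,
`fdr_alpha: 0.05`, `band: 0.15`, `min_n: 10`, `exact_cutoff: 20`,
`family_mode: pooled`.

Note: the multimodality screen's Monte-Carlo p-values have floor
1/(dip_B + 1), and Hommel's adjustment multiplies the smallest p-value by
up to the family size m, so `dip_B` must exceed roughly `m / fwer_alpha`
for the screen to be able to select anything.

## Library use

```python
from dysregdir import (default_scenarios, generate_study, run_study, RunConfig)

scenario = default_scenarios(n_subjects_per_site=500)["orange"]
study, truth = generate_study(scenario, seed=1)
results = run_study(study, RunConfig(dip_B=20000, seed=0))
print(results.screened_counts())
print(results.color_totals())
```
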