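# telburden

Population burden attribution for genetically predicted telomere length (gTL):
a tested, reusable pipeline that turns per-SD disease odds ratios from
Mendelian-randomization (MR) studies and registry burden rates into **excess
incidence and excess DALYs per 100,000 persons per SD of gTL**, with
confidence bounds, definition mapping, sensitivity analyses, and
LD-based counting of independent telomere-length-associated variants.

## The science

Telomeres shorten with each cell division; both inherited variation and ageing
affect their length. MR studies using telomere-length-associated SNPs as
instruments report odds ratios per standard deviation of genetically predicted
telomere length — longer gTL raises the risk of several cancers (the
proliferative-advantage side), while shorter gTL raises the risk of
degenerative conditions such as coronary heart disease and interstitial lung
disease.

An odds ratio alone says nothing about how much disease a population would
accrue. This package computes the simple excess-burden statistic

```
excess = (OR − 1) × rate
```

where `rate` is an age-standardized incidence or DALY rate per 100,000
persons. With rare-disease ORs approximating risk ratios, `(OR − 1) × rate`
estimates the burden in excess of baseline per SD of gTL. Confidence bounds
propagate the OR's CI against the point rate:
`((OR_lower − 1) × rate, (OR_upper − 1) × rate)`; group totals sum values and
like bounds across diseases. See `docs/methods.md` for the conventions and
their caveats.

Around that statistic the package provides the full pipeline:

- **`tables_io`** — validated dataclass records and readers/writers for OR
  tables (combined `"5.27 (3.02–9.18)"` cells or separate columns), registry
  burden exports (simple and GBD-results dialects), SNP panels, and
  per-chromosome LD matrices (triangular input mirrored, `NA` = MISSING).
- **`harmonization`** — direction tracking (`per_sd_longer` /
  `per_sd_shorter`), exact OR inversion `OR′ = 1/OR` with CI
  `(1/upper, 1/lower)`, significance filtering, and weighted collapsing of
  multiple ORs for one disease.
- **`definition_mapping`** — proportional allocation of broad registry burden
  onto narrow MR case definitions by case-count fractions, and sub-condition
  subtraction for sensitivity analyses.
- **`burden_attribution`** — the excess statistic, per-measure exclusion
  bookkeeping (a disease with a MISSING incidence still contributes its DALY
  row), and totals with summed or root-sum-square bounds.
- **`ld_analysis`** — thresholded LD clustering (R² ≥ 0.5) with two rules:
  transitive connected components and greedy sentinel claiming; sentinel =
  lowest chromosomal position.
- **`synthetic_data`** — seeded generators for complete synthetic studies and
  block-structured LD with exact ground truth, so the pipeline is testable
  end-to-end without downloads.
- **`cli`** — `telburden harmonize | allocate | attribute | ld-cluster |
  simulate | reproduce`.

Transcribed fixture tables from two published studies ship with the package
(`telburden.datasets`), including a 106-SNP panel on 18 chromosomes with its
LD matrices.

## Worked example

```python
>>> import telburden as tb
>>> report = tb.reproduce_study("haycock")
>>> glioma = next(r for r in report.rows
...               if r.cause_name == "Glioma" and r.measure == "incidence")
>>> round(glioma.value, 2)            # (5.27 - 1) x 8.39
35.83
>>> total = report.totals[("incidence", "per_sd_longer")]
>>> round(total.value, 2), round(total.ci_lower, 2), round(total.ci_upper, 2)
(94.05, 45.5, 168.87)
```

Sensitivity analysis — remove the idiopathic-pulmonary-fibrosis share (26.8%)
of the interstitial-lung-disease excess from the short-gTL totals:

```python
>>> from telburden import datasets
>>> from telburden.definition_mapping import subtract_subcondition
>>> ild = next(r for r in report.rows
...            if r.cause_name == "Interstitial lung disease"
...            and r.measure == "incidence")
>>> adj = subtract_subcondition(report.totals[("incidence", "per_sd_shorter")],
...                             ild, datasets.ipf_fraction().fraction)
>>> round(adj.value, 2)
109.42
```

Count independent variants in the bundled SNP panel:

```console
$ telburden ld-cluster --method both
method=connected_components: 106 SNPs on 18 chromosomes -> 68 independent variants (r^2 cutoff 0.5); 63 SNPs in known telomere-maintenance genes
method=greedy_sentinel: 106 SNPs on 18 chromosomes -> 71 independent variants (r^2 cutoff 0.5); 63 SNPs in known telomere-maintenance genes
```

Generate and analyze a synthetic study:

```console
$ telburden simulate --seed 3 --out sim/
$ telburden attribute --or-table sim/or_table.csv --burden-table sim/burden_table.csv --out-dir sim/out
```

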