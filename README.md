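# rdspectrum

`rdspectrum` characterizes the **rare-disorder (RD) spectrum**: the range of
disorders running from *borderline-common* (point prevalence 6–9 or 1–5 per
10,000) through *rare* (1–9 per 100,000 or per 1,000,000) to *ultra-rare*
(< 1 per 1,000,000). It is aimed at researchers in rare-disease epidemiology
and diagnostics who work with Orphadata-style registry exports (disorder
classifications, interval prevalence classes, HPO phenotype annotations with
occurrence categories, gene associations) and want a reproducible, tested
pipeline for:

- **Spectrum classification** — resolve each disorder's point-prevalence
  class (worldwide records prioritized over continent records; modal class
  among continent records, deterministic tie-break) and map it to a spectrum
  category.
- **Population burden** — a fictive-cohort model: for category *c* with
  disorder classes *k*, the expected share of a randomly selected population
  living with a category-*c* disorder is
  `P_c = Σ_k π_k · n_k · 100` (percent), where `π_k` is the representative
  (midpoint) point prevalence of class *k* and `n_k` the number of disorders
  in it; expected patients in a population of *N* are `P_c/100 · N`.
- **Phenotypic expressivity** — per-disorder ratios over non-excluded HPO
  annotations: `r_high = n_(obligate ∪ very frequent)/n_total` (lower ⇒ more
  variable expressivity) and `r_low = n_(occasional ∪ very rare)/n_total`
  (higher ⇒ more variable), plus per-category term rankings, term-by-term
  co-occurrence matrices, and category term-overlap (Venn) sets.
- **Category statistics** — a from-scratch kernel: two-sided Fisher's exact
  test, Benjamini–Hochberg FDR, tie-corrected Kruskal–Wallis, exact/
  approximate two-sided Wilcoxon rank-sum, binomial proportion SEs — driving
  the category-comparison tables (disorder types, linearisation parents,
  inheritance, natural history, top HPO terms, count/ratio distributions).
- **Pathway over-representation** — hypergeometric/Fisher enrichment of each
  category's gene universe against a GMT annotation with BH-FDR and a
  minimum of 10 annotated query genes for a pathway to count as enriched.
- **Synthetic registries** — a seeded generator of Orphadata-like bundles
  (plus a co-generated GMT with a known enrichment positive control) so the
  whole pipeline runs and is tested fully offline.

Real Orphadata product XML (2020-era dialects) can be ingested through
`rdspectrum.orphadata`; the canonical interchange format is a directory of
plain TSV files ("registry bundle").

## Worked example

```python
from rdspectrum.simulate import default_config, generate
from rdspectrum.registry import filter_spectrum
from rdspectrum.classification import classify_registry, cohort_expectation

config = default_config(seed=1, scale=1.0)   # 3,524-disorder study conditions
registry, manifest = generate(config)
filtered, report = filter_spectrum(registry)
result = classify_registry(filtered)
print({c.value: n for c, n in result.category_counts.items()})
print({c.value: round(v, 1) for c, v in result.shares_percent().items()})

estimate = cohort_expectation(result.class_counts, population_size=500)
for c, b in estimate.per_category.items():
    print(c.value, round(b.population_prevalence_percent, 2), b.expected_patients)
print("total", estimate.total_expected, "-> 1 in", estimate.one_in_n)
```

prints

```
{'borderline_common': 145, 'rare': 412, 'ultra_rare': 2967}
{'borderline_common': 4.1, 'rare': 11.7, 'ultra_rare': 84.2}
borderline_common 6.51 33
rare 0.34 2
ultra_rare 0.3 1
total 36 -> 1 in 14
```

i.e. borderline-common disorders are only ~4% of the spectrum's disorders,
yet in a random population of 500 people about 33 of the 36 expected RD
patients (≈92%) carry one — the common end of the "rare" spectrum dominates
the patient population, while the ultra-rare end dominates the disorder
catalogue.

The same pipeline is available from the shell:

```sh
rdspectrum simulate --seed 1 --scale 0.1 --out run/bundle
rdspectrum classify --bundle run/bundle --out run/classify
rdspectrum characterize --bundle run/bundle \
    --assignments run/classify/assignments.tsv --out run/characterize
rdspectrum stats --bundle run/bundle \
    --assignments run/classify/assignments.tsv --out run/stats
rdspectrum enrich --bundle run/bundle \
    --assignments run/classify/assignments.tsv \
    --gmt run/bundle/pathways.gmt --out run/enrich
```

or end-to-end via `rdspectrum report --config config.yaml` (keys: `seed`,
`scale`, `out_dir`, `population_size`, `top_k`).

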