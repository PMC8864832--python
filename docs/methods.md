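# Methods

## Scope and data model

`rdspectrum` analyzes a registry of rare disorders keyed by Orphacode. Each
record carries: classification labels (disorder group: disorder / group of
disorders / subtype; disorder type; a single linearisation parent — the
monohierarchical classification branch), interval prevalence records (kind:
point / birth / annual incidence; one of six interval classes or "unknown";
geographic scope), inheritance types (nine closed labels), interval average
age-of-onset and age-of-death labels, HPO phenotype annotations with one of
six occurrence categories (obligate 100%, very frequent 99–80%, frequent
79–30%, occasional 29–5%, very rare <4–1%, excluded 0%), and gene
associations (disease-causing / modifier / susceptibility / other).

The canonical on-disk form is a TSV bundle (one file per facet) chosen over
a nested single file because it is diffable and language-neutral; rows are
written in deterministic order so equal registries produce byte-identical
bundles. An adapter ingests 2020-era Orphadata product XML; element
vocabularies drift between releases, so the adapter extracts what it
recognizes and counts skipped elements rather than failing.

## Spectrum filter

Records enter the spectrum when they (1) have at least one known prevalence
record, (2) are true disorders (not groups or subtypes), (3) do not belong
to the linearisation parents "rare disorder due to toxic effects", "rare
infectious disease" or "rare neoplastic disease", and (4) carry at least one
point prevalence of known class at worldwide or continent scope (restricting
to these scopes avoids founder/consanguinity effects that dominate country
and region records). A record failing several rules is attributed to the
first failing rule in the fixed order above so removal counts are
reproducible; removal counts plus survivors always equal the input size.

## Class resolution and categories

Worldwide point prevalence is prioritized over continent point prevalence;
with only continent records the modal class is assigned. Modal ties are
resolved by a configurable deterministic policy — default "rarer"
(conservative toward rarity) — and flagged on the assignment; a manual
per-case resolution is not reproducible, so it is not offered. Categories:
borderline-common (6–9/10,000, 1–5/10,000), rare (1–9/100,000,
1–9/1,000,000), ultra-rare (<1/1,000,000). The class >1/1,000 lies outside
the rare spectrum and maps to `excluded_common`.

## Fictive-cohort burden model

Each interval class gets a representative per-person point prevalence: the
interval midpoint (6–9/10,000 → 7.5e-4; 1–5/10,000 → 3e-4; 1–9/100,000 →
5e-5; 1–9/1,000,000 → 5e-6) except the open-ended rarest class, which uses
its upper bound 1e-6 (a literal midpoint does not exist; the upper bound
reproduces the published ultra-rare burden and is the conservative choice).
The map is user-overridable. Category population prevalence (percent) is
`Σ_k π_k · n_k · 100`; expected patients in a population of N (default 500)
are `percent/100 · N`, rounded half-up, which is also the printed-table
convention used throughout (shares to 1 d.p., sub-1% prevalences to 2
d.p.). The "1 in N" summary divides the population by the total of the
rounded per-category patient counts.

## Expressivity and term analytics

"Excluded (0%)" annotations are omitted from every count; a disorder holds
phenotypic information iff it has ≥1 non-excluded annotation, and
excluded-only disorders are treated as unphenotyped (no ratio profile, not
zero-filled). The two per-disorder ratios are exact rational divisions; by
construction `r_high + n_frequent/n_total + r_low = 1`. Term rankings use
the number of phenotyped disorders in the scope as denominator, count a term
once per disorder regardless of occurrence class, and break proportion ties
lexicographically by HPO id for determinism. Co-occurrence matrices count,
for every term pair, the disorders annotated (non-excluded, any occurrence
class — no frequency weighting) with both terms; the diagonal is the
per-term disorder count, and `counts(i,j) ≤ min(counts(i,i), counts(j,j))`
always holds. Category term-overlap sets are compared either on full
vocabularies or on each category's top-k terms (ranked by proportion, the
same convention as the rankings). Heatmap/chord rendering is out of scope;
the module emits matrices, edge lists and Venn region counts for external
plotting tools.

## Statistical kernel

Implemented from first principles for cross-platform reproducibility, with
scipy used only for chi-square/normal tail probabilities:

- **Fisher's exact test (two-sided)**: sum of hypergeometric probabilities
  of all tables with the observed margins whose probability is ≤ the
  observed table's, with a 1e-7 relative tolerance on the comparison (the
  same guard R uses) so floating-point noise cannot flip the inclusion of an
  equal-probability table.
- **BH-FDR**: step-up `adj_i = min_{j ≥ rank(i)} p_(j)·m/j`, capped at 1,
  input order preserved. Adjustment families are declared explicitly (one
  per comparison table/axis/run) and recorded in the output for audit; raw
  p-values are always emitted alongside.
- **Kruskal–Wallis**: midranks, tie correction `1 − Σ(t³−t)/(N³−N)`,
  chi-square reference with (groups − 1) df; all-identical data yields H=0,
  p=1.
- **Wilcoxon rank-sum (two-sided)**: exact when both samples have ≤ 25
  observations and the pooled data is tie-free, via the full null rank-sum
  distribution (dynamic programming over subsets); otherwise a normal
  approximation with continuity and tie corrections. Both modes are
  selectable; the n≤25 cutoff keeps the exact path fast while covering the
  sample sizes where the approximation is least reliable.
- **Proportion SE**: `sqrt(p(1−p)/n)`.

Category comparisons test borderline-common and rare against the ultra-rare
reference. Denominators are all category disorders for disorder type /
linearisation / inheritance / natural history, and phenotyped disorders for
HPO-term features. Multi-valued features (e.g. two inheritance types on one
disorder) count once per value with the category size as denominator, so
columns may sum to more than 100%. The direction column is the sign of
(ultra-rare proportion − borderline-common proportion), reported only when
at least one of the feature's comparisons is significant (BH-adjusted
p < 0.05). Pairwise Wilcoxon tests run only when the Kruskal–Wallis omnibus
is significant, BH-adjusted within the pairwise family.

## Over-representation analysis

A category's gene universe is the deduplicated union of its disorders' gene
associations (all association types by default — registries associate
modifier and susceptibility genes as well as causative ones). Each GMT
pathway is tested against a background defaulting to all annotation genes
(configurable); pathway gene sets are intersected with the background, and
query genes missing from it are an error in strict mode. The default test
is two-sided Fisher, with a one-sided (upper-tail hypergeometric) option
since ORA tools commonly use it. A pathway is *enriched* iff BH-adjusted
p < 0.05 **and** at least 10 query genes are annotated to it — the
minimum-gene rule reads "annotated genes associated with the category" as
query genes in the pathway (k), not pathway size (K). Enriched-set overlaps
are reported as exclusive Venn region cardinalities, which always partition
the union.

## Synthetic study conditions

The generator's defaults define the study conditions and are not tuned per
run. Per-class disorder counts total 145 / 412 / 2,967 across the three
categories (3,524 disorders); the within-category split (48 + 97 and
30 + 382) is reconstructed so the implied cohort prevalences (6.51%, 0.34%,
0.30%) match the category-level burden this spectrum composition produces.
Inheritance mixtures are independent per-type Bernoulli draws with
autosomal-recessive probability 0.20 / 0.398 / 0.425 and
multigenic/multifactorial 0.145 / 0.063 / 0.003 across the three categories;
disorder-type and linearisation-parent mixtures follow the same per-category
margins pattern. Phenotyped fractions are 131/145, 387/412 and 1912/2967.
HPO term counts are shifted negative-binomial (r=2, mean ≈ 18/25/20 + 1);
occurrence mixtures are parameterized so the conditional (non-excluded)
obligate∪very-frequent share is 0.22 / 0.25 / 0.33 and the
occasional∪very-rare share 0.44 / 0.36 / 0.18, with a 4% excluded rate.
Gene counts are geometric (p = 0.21 / 0.55 / 0.85, medians 3 / 1 / 1) with a
25% chance of no gene associations. Onset/death level mixtures give the
rarer categories earlier onset and death; availability is 96.3% (onset) and
64.2% (death). A noise block gives 30% of disorders continent-only
prevalence records (2–3 records; with probability 0.1 an extra minority
record of a neighboring class, exercising the modal resolution without
changing the resolved class) and 10% an additional birth-prevalence record.
Each category samples HPO terms from a biased window of the 400-term
synthetic vocabulary (bias 3×) so term rankings and overlap sets have
structure. The GMT co-generator partitions a 2,000-gene pool into 50
pathways of 40 core genes plus 10 random overlap genes; ultra-rare gene
draws come from pathway SPW0000 with probability 0.3, a known positive
control.

Randomness is split per disorder from the root seed
(`SeedSequence(seed, spawn_key=(1, i))`), making generation
order-independent and byte-deterministic.

What the generator does **not** emulate: real HPO ontology structure
(terms are opaque ids; no ancestor closure), correlation between inheritance
type and expressivity (blocks are drawn independently), country/region
founder-effect prevalences, gene–pathway biology beyond the single injected
signal, and the long-tailed real-world linearisation vocabulary. Passing
recovery tests therefore demonstrates that the *pipeline's estimators are
consistent for the quantities the generator controls* — not that real
registry data would yield the same margins; headline registry counts from
any real snapshot depend on that snapshot and its curation.

## Numerical and design choices

- Rounding of reported values is half-up at the printed precision (1 d.p.
  for shares, 2 d.p. for sub-1% prevalences, integers for patient counts);
  TSV outputs keep full precision.
- Ranking and tie-break rules are deterministic everywhere (lexicographic by
  id); repeated runs on identical inputs are byte-identical.
- Degenerate inputs: empty registries produce empty (header-only) outputs;
  a category with no phenotyped disorders yields an empty term table with an
  explicit zero denominator; an all-identical rank test returns H=0, p=1;
  a zero expected-patient total leaves the "1 in N" summary undefined rather
  than infinite.
- The acceptance script reports values at the scales used by the printed
  conventions (percentages as percentages, medians to 2 d.p.) and runs the
  full 3,524-disorder study, 1,000-replicate null calibration and the
  enrichment control in a few seconds on one CPU.

## Known limitations

- The exact FDR family behind any externally printed adjusted p-value is
  generally unknowable; this package therefore treats adjusted p-values as
  family-relative quantities and always records the family label.
- The Orphadata XML adapter targets the 2020-era product structure; newer
  dialects may need mapping extensions (unknown elements are skipped and
  counted, never guessed).
- Expressivity ratios are proxies built from occurrence categories; they do
  not measure penetrance and inherit the curation granularity of the source
  annotations.
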