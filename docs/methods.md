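# Methods

## The index

For one sample with total classified read count *N* (the root row of the
taxonomy table) and a guild *G* of genera linked to hydrocarbon
biodegradation, the ecological index of hydrocarbon exposure is

EIHE = Σ_{g∈G} 100 · c_g / N,

with c_g the reads assigned to genus *g* (0 when absent). Two conventions
matter and are fixed here:

* **Denominator.** *N* is the root count — all classified reads — not the
  sum of genus-level rows. Reads classified only to higher ranks therefore
  dilute the index. This matches the definition "percentage of the total
  reads" and makes the index a true community fraction, so
  0 ≤ EIHE ≤ 100, EIHE is invariant to uniform rescaling of a sample's
  counts, and disjoint guilds contribute additively.
* **Aggregation.** The same genus label can occur under several parents
  (classifiers emit many `unclassified` rows); genus-level counts are
  summed by label before percentages are taken. `unclassified` never
  matches a guild genus, so it contributes to the denominator only.

### Genus-name matching

Classifier output labels vary in casing and decoration. Matching against
the guild is exact on a normalized token: optional case folding (default
on), optional synonym lists from the guild file (default on), and optional
decoration stripping (default on: surrounding quotes, a leading
`Candidatus` marker, trailing `[...]`/`(...)` qualifiers). There is
deliberately no substring or edit-distance matching — a label like
"Oleispira-like organism" must not silently count as *Oleispira*. If two
distinct table labels normalize onto one guild genus the computation stops
with an ambiguity error rather than picking one.

## The default guild

The packaged guild (`eihe/data/hydrocarbon_guild.tsv`) holds 63 genera —
45 Proteobacteria (71.4%), 12 Actinobacteria (19.0%), 3 Bacteroidetes
(4.8%), 3 Firmicutes (4.8%) — each with at least one described
hydrocarbon-degrading strain or strong environmental evidence of a role in
hydrocarbon degradation, spanning marine obligate hydrocarbonoclastic
genera (*Alcanivorax*, *Cycloclasticus*, *Oleispira*, *Oleiphilus*,
*Thalassolituus*), generalist degraders (*Pseudomonas*, *Rhodococcus*,
*Mycobacterium*), anaerobic degraders (*Thauera*, *Desulfobacula*,
*Desulfatibacillum*) and others. Curation notes sit in the file header; the
per-genus isolation-environment and evidence columns are descriptive
metadata and never affect computation. The guild is intentionally a
replaceable data asset: `load_guild_list` accepts any TSV with a genus
column, and `extend_guild` derives a version-bumped definition without
mutating the original. Genus names are unique case-insensitively and
synonyms may not shadow another member.

## Statistics

**Unreplicated two-sample designs** (one sample per condition, the common
situation for deep-sequenced composite sediment samples) compare read
proportions k/n between two samples:

* *p-value*: Fisher's exact test, the conditional/permutation-exact view of
  the 2×2 table. The two-sided p sums hypergeometric probabilities of all
  tables with the observed margins whose probability is at most that of the
  observed table (the minimum-likelihood convention, not doubling).
  Degenerate margins give p = 1. A seeded Monte-Carlo permutation mode
  (`permutation_two_proportions`) exists purely as a cross-check.
* *Interval*: the Newcombe hybrid score interval for p1 − p2, combining the
  two per-sample Wilson score intervals (l, u):
  low = d − √((p1−l1)² + (u2−p2)²), high = d + √((u1−p1)² + (p2−l2)²). It
  never degenerates at k = 0 or k = n, unlike the Wald interval. The normal
  quantile comes from the inverse standard-normal CDF, so any confidence
  level is supported (default 0.95).

These run per guild genus (`per_genus_screen`, 2×2 of genus reads vs other
reads) and for the whole guild dichotomy guild-vs-others
(`guild_level_test`). By construction the guild-level proportions times 100
equal the two samples' EIHE values — an identity the test suite asserts.
Multiple testing across the guild is uncorrected by default (each raw p
compared to α, mirroring a per-genus screening read-out), with
Benjamini-Hochberg available via `correction="bh"`.

**Replicated designs** use Welch's unequal-variance *t* (two groups;
Welch-Satterthwaite degrees of freedom) or Kruskal-Wallis with tie
correction (≥3 groups; chi-square approximation, requiring a total n ≥ 5),
with Dunn's z pairwise comparisons, Bonferroni-adjusted, as the post-hoc.
Degenerate inputs are defined, not errors: both variances zero with equal
means → p = 1; zero variances with distinct means → infinite statistic,
p = 0; all values identical across groups → H = 0, p = 1.

## Diversity estimators

Inputs are per-sample OTU count vectors (clustering is upstream). With f1
singletons, f2 doubletons, S_obs observed OTUs and N reads:

* Good's coverage: 100 · (1 − f1/N).
* Chao1: bias-corrected S_obs + f1(f1−1)/(2(f2+1)) by default (defined for
  all inputs); classic S_obs + f1²/(2f2) behind a flag (errors without
  doubletons). The CI is the standard log-normal construction on
  T = estimate − S_obs: K = exp(z√(ln(1 + var/T²))),
  CI = [S_obs + T/K, S_obs + T·K], guaranteeing the lower bound ≥ S_obs;
  T = 0 collapses the CI to [S_obs, S_obs]. The variance formula follows
  the chosen form (with the separate f2 = 0 variant); the form used is
  recorded in the report (`chao1_form`) because published pipelines differ.
* Shannon: H = −Σ pᵢ ln pᵢ, natural log by default — the conventional scale
  on which communities with thousands of OTUs score ≈5–7 — with base 2 (or
  any base) behind a flag. CI: H ± z√var with
  var = (Σ pᵢ(ln pᵢ)² − H²)/N + (S_obs − 1)/(2N²).
* Rarefaction: a single fixed-depth multivariate hypergeometric subsample
  (without replacement), seeded and deterministic, applied before all
  metrics when a depth is given so samples of unequal depth are comparable.
  A standard choice of depth for deep pyrotag datasets is 25,000 reads.

## The simulator

`simulate_two_group_study` emulates the design the index targets: one base
genus composition drawn from a symmetric Dirichlet (default concentration
0.5 over 500 genera, giving realistically skewed rank-abundance curves), a
designated guild (default 50 genera), multiplicative guild enrichment by
`enrichment_fold` (default 4, the polluted-vs-pristine regime of interest)
followed by renormalization, and multinomial sampling at `depth` reads
(default 25,000, a typical per-sample pyrotag depth). Because of
compositional closure the realized enrichment is f·g/(1 + (f−1)·g) for
baseline guild proportion g, not f; the recorded `truth` always carries the
exact post-renormalization proportions and expected index values.
`guild_baseline_proportion` pins g exactly (e.g. 0.01 for a 1% baseline
guild) when a controlled effect size is needed. An optional
`overdispersion` parameter redraws each sample's composition from a
Dirichlet around its condition's composition, producing
Dirichlet-multinomial counts that deliberately violate the plain-proportion
assumption of the exact test — useful for robustness checks.

What the simulator does *not* emulate: sequencing error, chimeras, primer
and copy-number bias, classifier misassignment, or spatial correlation
between samples. Passing tests on simulated data therefore demonstrate the
correctness and calibration of the computations under multinomial sampling,
not robustness to those real-data artifacts.

`simulate_otu_vector` feeds the diversity module: uniform or log-series
OTU abundance models with known true richness.

## Verification choices and problem sizes

* Exact-test correctness is checked against exhaustive hypergeometric
  enumeration over every 2×2 table with both sample sizes ≤ 12 (8,100
  tables, tolerance 1e-10).
* Wilson and Newcombe intervals are checked to 1e-10 against independent
  transcriptions of the closed forms on 1,000 random configurations, and
  against statsmodels; empirical coverage is measured over 10,000 simulated
  binomials (n = 100, p = 0.3 for Wilson; n = 200, p = 0.05 per arm for
  Newcombe).
* Calibration of the guild-level test uses 1,000 null studies (500 genera,
  depth 25,000); effect recovery uses 200 studies at 1% baseline guild and
  fold 4. The per-genus screen's null calibration is probed on a
  near-uniform 50-genus community (concentration 50) so every genus has
  enough expected reads for the exact test to sit near its nominal level;
  on skewed communities the conditional exact test is conservative for rare
  genera, which is a property of the test, not a defect of the screen.
* The richness-recovery demonstration samples 6,000 reads from 5,000
  equally probable OTUs — a depth at which observed richness underestimates
  truth by ~30% while bias-corrected Chao1 recovers it within 15%. At much
  deeper sampling both statistics converge and the contrast disappears.
* Chao1 and Shannon point estimates are cross-checked against scikit-bio;
  the intervals are this package's own, as scikit-bio does not provide
  them.

## Known limitations

* The index is presence-weighted by abundance only; it cannot distinguish
  active degraders from dormant or dead cells, nor genera whose strains
  lack the catabolic pathways (a DNA-based indicator's usual caveats).
* Guild membership is a curated, literature-driven list. Differences
  between taxonomies (SILVA versions, classifier versions) change genus
  labels and hence matched membership; the matching policy surfaces, but
  cannot resolve, such drift.
* The exact test treats reads as independent draws; overdispersion between
  biological replicates makes the unreplicated two-sample test
  anti-conservative at the guild level. With replicates available, use the
  replicated design instead.
* No beta diversity, rarefaction curves, phylogenetic metrics, or
  OTU-level index variants.
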