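# Methods

This note documents the statistical model behind `mitosurvey`, the
conventions the implementation fixes where surveys of this kind are
usually silent, the synthetic-data generator's design, and the
package's numerical choices and known limitations.

## The survey model

The substrate is one curated multiple alignment of complete
mitochondrial genomes with a two-population partition (an African-like
and a non-African-like group, after the L vs M/N haplogroup split of
human mtDNA). Alignment columns are the coordinate system for
everything; no liftover to a reference coordinate system is attempted.
`N` and `-` are missing data: excluded from allele sets and from every
denominator.

**Polymorphic sites and minor alleles.** A column is polymorphic when
two or more distinct non-missing bases occur. Minor alleles are defined
on the *pooled* sample: at each polymorphic column the single major
allele is the most frequent base (ties broken alphabetically, A<C<G<T)
and every other observed base is a minor allele. The pooled definition
makes the two population columns of every report refer to the same
alleles; a switch (`site_count_definition: population`) instead
re-calls minors within each population for the site-count table.

**Functional categories.** Each minor allele is classified by
substituting its base into the *background codon* — the pooled major
allele at every column — strand-aware, under the vertebrate
mitochondrial genetic code (NCBI translation table 2: ATA=Met, TGA=Trp,
AGA/AGG=stop). Same amino acid → synonymous (with a four-fold flag when
the position is four-fold degenerate on the background); different →
nonsynonymous. Sites in tRNA/rRNA genes take those compartments;
everything else is other-noncoding. Codons with missing background
bases give an `unknown-codon` category, excluded from the syn/nonsyn
tallies and logged. A column inside overlapping protein genes is
classified against each frame and counted once, nonsynonymous-if-any
(conservative for deleteriousness surveys; logged).

Effect labels (benign/damaging, the two damaging sub-grades pooled) are
consumed from a variant-effect annotation file, never computed;
nonsynonymous minors without an annotation are `unknown`. The
pathogenic flag is a cross-cutting property: any minor allele matching
a catalogue entry with status Reported or Confirmed carries it,
subdivided by compartment (coding/tRNA/rRNA), without leaving its
functional category.

## Nei–Gojobori diversity

Nucleotide diversity π is the average over all n(n−1)/2 within-
population sequence pairs of the per-pair per-site proportion of
differences. Proportions are used directly (p-distances, no
Jukes–Cantor correction): within-species mtDNA distances are ≤ 0.01,
where the correction is far below the reporting precision.

Per site class:

* **all** — the site-wise estimator
  π = Σ_s h_s / L_used, with h_s = 1 − Σ_a C(c_a,2)/C(m_s,2)
  (c_a = allele counts, m_s = non-missing genomes at column s, L_used =
  columns with m_s ≥ 2). With complete data this is algebraically the
  mean pairwise p-distance; with missing data it is the standard
  per-site estimator (per-site denominators rather than per-pair ones).
* **fourfold** — the same estimator restricted to columns four-fold
  degenerate on the pooled major-allele background.
* **syn / nonsyn** — the NG86 partition. Per codon, synonymous site
  counts S are the fraction of single-nucleotide changes preserving the
  amino acid (changes to stops count as nonsynonymous); per codon pair,
  differences sd/nd are averaged over all orderings of the differing
  positions, excluding pathways through stop codons (falling back to
  all pathways, stop steps nonsynonymous, when none survive). Codons
  with missing data or a stop in either sequence of a pair are deleted
  pairwise at codon granularity. Per pair, pS = sd/S and pN = nd/N,
  summed/averaged over the concatenated protein genes; π_syn/π_nonsyn
  are the means over pairs (pairs with zero usable sites are excluded
  and counted).

The NG86 computation is exact all-pairs but organised by codon *type*:
identical codons contribute identically, so per-pair site counts come
from two rank-one matrix products and per-pair differences from
accumulating the (sd, nd) of each unordered pair of codon types over
the member index sets. A test pins equality with the naive
`ng_pair` double loop, with and without missing data.

Two scale controls, both documented in outputs:

* `diversity_max_genomes` (default 200): populations larger than the
  cap are represented by a seeded random subsample. The pairs of a
  random subset are a random subset of pairs, so the estimator is
  unbiased; only its sampling error grows.
* Bootstrap SEs resample alignment columns (codon columns for the NG86
  classes) with `n_boot` (default 1000) multinomial draws; for the NG86
  classes the bootstrap evaluates the mean pS/pN on a capped random
  subset of pairs (500) to bound memory, which approximates the mean
  over all pairs closely because column resampling noise is shared
  across pairs.

## Population summaries and comparisons

* **Mean minor-allele frequency** (per category × population):
  unweighted mean over the category's minor alleles with count ≥ 1 in
  the population, of their within-population frequency
  (count / non-missing genomes at the site). SE is the sample SD across
  alleles / √k; a single allele reports SE 0; an empty category is
  *absent*, not zero.
* **Per-genome burden**: for each genome, the number of catalogued
  minor alleles of the category it carries (missing base ≠ carrier);
  reported as mean ± SEM across genomes. Burden conserves the
  catalogue: Σ_genomes burden = Σ_alleles per-population count.
* **Monte-Carlo sample-size correction**: the larger population is
  subsampled without replacement (defaults: 1000 replicates at the size
  of the smaller population, 401). Within each replicate the statistic
  is recomputed from scratch: minor alleles are re-called inside the
  subsample, so sites monomorphic there drop out. The reported column
  is the per-replicate category mean frequency averaged over
  replicates, with two SEs emitted: across replicates (SD of replicate
  means / √R) and across alleles (mean per-replicate SD/√k). Re-called
  alleles keep their pooled-catalogue annotations; a pooled-major
  allele that becomes minor inside a subsample carries no annotation
  and is skipped. A switch (`recall_in_subsample: false`) freezes the
  allele set instead and only recomputes frequencies.
* **Mann–Whitney U** (two-sided): exact enumeration when n1+n2 ≤ 12
  and tie-free, otherwise the normal approximation with tie and
  continuity corrections (scipy). The survey does not fix the
  observational unit, so two comparison surfaces are emitted per
  category: per-genome burden vectors between populations, and
  per-allele frequency values (reference population vs the other
  population's alleles, and vs the Monte-Carlo replicate means).
  Accuracy envelope of the approximation, measured against exact
  enumeration at n1=n2=6 over all tie-free configurations: the
  absolute two-sided p error is at most 0.0062 wherever the exact
  p ≤ 0.2 and at most 0.0155 overall (worst at U = 12, exact p 0.394).
  The test suite keeps one strict assertion at a 0.01 uniform
  tolerance, which the standard approximation genuinely cannot meet;
  it documents that gap rather than replacing the approximation with a
  nonstandard higher-order expansion.
* **Ratios** (figure-style summaries): per category, the non-African /
  African ratio of mean burdens (full samples) and of mean frequencies
  (Monte-Carlo column over the reference population's mean — the
  frequency contrast is the one quantity that needs the sample-size
  correction). SEs by first-order propagation:
  se(r)² = (se_num/den)² + (num·se_den/den²)². Zero denominators flag
  the ratio undefined.

**RNG policy.** Every stochastic routine takes one integer seed;
replicate draws come sequentially from a single generator, and the
pipeline derives all component seeds from the single config seed, so a
fixed config reproduces every output byte-for-byte.

## Synthetic data: what it emulates, and what it does not

The generator produces a complete input bundle (alignment, metadata,
gene models, effect annotation, pathogenic catalogue) plus a truth
manifest recording, for every planted variant, its category, target
per-population frequency and *realized* carrier counts; tests compare
estimates against realized truth, removing binomial planting noise from
the comparison.

Defaults (the study conditions; chosen once, not tuned per run):

| parameter | default | rationale |
|---|---|---|
| populations | 401 / 4057 | the African / non-African sample sizes of the surveyed dataset |
| genome length | 16,569 bp | human mtDNA size; simplified layout with 13 protein genes (one minus-strand), 22 tRNAs, 2 rRNAs, control region |
| variants per category | 250 syn, 250 four-fold, 250 benign, 250 damaging, 12 unknown-effect, 200 tRNA, 200 rRNA, 200 noncoding, 200 pathogenic | ≥ 200 per category so frequency-recovery checks have power |
| frequency distributions | Beta(α, β) with α = 0.8 and means: African 0.027 syn / 0.029 four-fold / 0.026 benign / 0.0089 damaging; non-African 0.0040 / 0.0039 / 0.0042 / 0.00082 | the magnitudes of the two-population mtDNA contrast: several-fold higher African frequencies everywhere, damaging ~3–5-fold below benign |
| presence mix | 50% shared, 25% African-private, 25% non-African-private | variants segregate in one or both populations |
| pathogenic (biased rule) | 200 variants, 60% coding / 30% tRNA / 10% rRNA; presence 30% shared / 70% non-African-private / 0% African-private; African freq Beta(1.0, mean 0.0077); non-African freq Beta(0.08, mean 0.0037) | see below |

**The ascertainment knob.** Real pathogenic catalogues are compiled
from disease studies performed mostly in non-African cohorts, so they
over-represent variants that segregate in non-Africans and, among
those, the ones common enough there to be observed in patients. The
`non_african_biased` rule encodes both facets: zero mass on
African-private variants, and a strongly right-skewed non-African
frequency distribution (α = 0.08: a few common "founder" pathogenic
variants dominate, most entries are rare reports). The skew is the
load-bearing part — merely restricting the catalogue to
non-African-segregating variants cannot push the non-African/African
pathogenic ratios above 1 when African frequencies are uniformly
several-fold higher; conditioning discovery on being common in the
studied population can and does. Under the `unbiased` rule the
pathogenic category behaves like ordinary damaging variation and the
ratios fall below 1 like every other category.

Deliberately **not** emulated: linkage and haplogroup structure
(variants are planted independently — every statistic here is site-wise
or per-genome-count-wise, so haplotype structure would add realism but
no test power), recurrent mutation, heteroplasmy, sequencing error,
missing data (complete genomes by default; the missing-data code paths
are tested with hand-built alignments), and hypergeometric carrier
sampling (carriers are binomial; realized counts are recorded in the
manifest precisely so tests never depend on the sampling scheme).
Consequently, passing the recovery tests shows the estimators are
correct and unbiased under independent site-wise variation at realistic
frequency scales; it does not validate behaviour under linkage or
ascertainment schemes other than the one modelled.

Planting constraints: at most one variant per alignment column, planted
frequencies capped at 0.4 so the planted allele always remains the
pooled minor, stop-gain changes never planted (the NG86 machinery
deletes stop codons pairwise, so planting them would silently shrink
the usable alignment). Every planted variant is re-classified with the
production classifier against the pooled major background at build
time; under these constraints a mismatch is impossible, so the check is
an assertion rather than a reject–resample loop.

## Numerical and reporting choices

* Fractional NG86 quantities are computed in exact rational arithmetic
  and converted to float once, so S + N = 3 holds exactly and the
  brute-force oracle comparisons are exact equalities.
* Major-allele ties break alphabetically; classification and all
  statistics are invariant under sample reordering (tested).
* Percentage structure of the site-count table: synonymous and
  nonsynonymous are percentages of their sum; four-fold of synonymous;
  benign/damaging/unknown of nonsynonymous; percentages print at one
  decimal and each group sums to 100 ± rounding.
* The reference survey tally used by the validation tests contains
  three printed percentages that are inconsistent with their own
  printed counts at one-decimal rounding (419/792 = 52.9 vs printed
  53.0; 338/1263 = 26.8 vs 26.7; 309/1178 = 26.2 vs 26.3). The
  consistency check re-derives and verifies the 15 consistent cells and
  excludes those three.
* Degenerate inputs: k = 1 allele reports SE 0; an empty category is
  flagged absent rather than zero; pairs with zero usable NG86 sites
  are excluded from π and counted; a population of < 2 genomes is an
  error; an all-tied U-test reports p = 1.
* Problem sizes used by the test-suite's full-scale study: the default
  401 + 4057 genome bundle, 1000 Monte-Carlo replicates of 401, and a
  40,000-draw hypergeometric simulation as the independent expectation
  oracle; diversity estimates in the reports use the 200-genome cap and
  1000 bootstrap resamples.

## Known limitations

* Annotations refer to alignment columns; mapping a real catalogue's
  reference-genome coordinates onto a user's alignment is out of scope.
* The site-wise π estimator and the mean per-pair p-distance differ in
  the presence of missing data (per-site vs per-pair denominators);
  the package uses the former for the `all`/`fourfold` classes and
  exact per-pair NG86 for `syn`/`nonsyn`.
* Bootstrap SEs quantify column-resampling uncertainty only; for
  capped-population diversity estimates the genome-subsampling
  component is not included.
* No multiple-testing correction across categories (raw U-test
  p-values, as in surveys of this kind), and no effect-size measures
  beyond the ratio summaries.
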