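# Methods

## The mapping problem

A dominant, (near-)fully penetrant mutation segregating from one or two
founder sires produces a distinctive signature: every affected
descendant carries one copy of a founder haplotype, unaffected
descendants carry none, and a family-based association scan shows a
single extreme peak at the locus. `domscan` implements the three
analyses that exploit this signature — a family-based genome scan, rule
filters over sequence-variant panels, and windowed haplotype
association — plus generators that produce truth-known data of exactly
this shape.

## Family-based scan statistic

The pedigree is decomposed into disjoint scoring clusters:

* **Trio** — offspring with both parents genotyped. For each
  heterozygous parent of an affected offspring the transmitted allele
  is deduced from the trio; the cluster accumulates O += alt copies
  transmitted, E += 1/2, V += 1/4 per informative transmission. When
  both parents and the offspring are heterozygous, the two consistent
  phase assignments are equally likely; the cluster contributes their
  expectation (O += 1, E += 1, V += 1/2 across the two parents), which
  preserves exact equivalence with the classic transmission count.
  Mendelian-inconsistent trios are skipped at that marker only and
  counted in the scan output. Unaffected trio offspring contribute
  nothing to the trio component (the classic TDT conditions on affected
  offspring); they can still appear in sibship clusters.

* **Sibship** — ≥2 offspring sharing a sire whose dams are not
  genotyped (paternal half-sib families). With n genotyped sibs of
  dosages g_j, mean ḡ, and a affected, the cluster uses the
  finite-population moments of the affected-label permutation null:
  O = Σ_affected g_j, E = a·ḡ, V = a(n−a)/(n−1) · (1/n)Σ(g_j−ḡ)².
  A sibship with all labels equal or all dosages equal has V = 0 and is
  uninformative. Half-sib groups are scored this way even when the
  shared sire's genotype is known: with the maternal allele unknown,
  individual transmissions are not deducible, whereas the permutation
  null requires no parental genotypes. The sire's own genotype enters
  the analysis only through the variant filters.

Per marker, clusters with V_i > 0 combine into the stratified 1-df
chi-square X = (Σ(O_i−E_i))² / ΣV_i, with the p-value from the upper
tail. This construction reduces exactly to the classic TDT
(b−c)²/(b+c) on trio-only data and to a sib-TDT on pure sibship data;
the named DFAM procedure it emulates is not published as a formula, so
this definition is the package's own, validated by the trio
equivalence, by null calibration (empirical type-I error within
binomial error of α over ≥1000 unlinked null markers dropped through
the study-shaped pedigree), and by power on fully concordant simulated
markers. Tests of a marker are two-sided; p-values are floored at the
smallest positive double and additionally reported in log10 space, so a
scan never reports p = 0.

**Bonferroni accounting.** The scan threshold is α/m with m = all
tested markers by default (matching the convention of counting every
test attempted, e.g. 0.05/628,278 ≈ 7.96×10⁻⁸ genome-wide); a flag
restricts m to informative markers. The haplotype scan divides α by the
number of haplotype tests actually performed, since which haplotypes
clear the carrier minimum is data-dependent.

## Genotype QC

Samples with genotype call rate < 0.90 are removed first; marker minor
allele frequencies are then recomputed on surviving samples from
non-missing chromosomes only, and markers with MAF < 0.01 removed. The
defaults are the thresholds standard for SNP-chip family studies;
sample-before-marker ordering follows common GWAS practice. The filter
is idempotent and each exclusion is reported with its reason.

## Variant filtering

Genotypes are classed hom-ref / het / hom-alt / missing per variant
(multi-allelic VCF records are decomposed per ALT; indel keys are exact
(chrom, pos, ref, alt) matches and inputs are assumed consistently
normalized). The dominant-candidate filter requires het status in every
obligate carrier, hom-ref in every obligate non-carrier, and absence
from every supplied previously-observed variant set; the breed-contrast
filter requires carriage (het or hom-alt) in every in-group sample and
hom-ref in every out-group sample. Missing-genotype semantics are
asymmetric by design: *presence must be proven* (a missing call in a
required carrier or in-group sample disqualifies), while *absence is
presumed but flagged* (`unconfirmed_absence`); a strict mode makes
missing calls disqualifying everywhere. The audit trail assigns each
removed variant exactly one first-failing rule, so the filter's outcome
is fully accountable. Consequence annotation is deliberately minimal —
one transcript per gene, no splice classes — distinguishing
missense/nonsense/synonymous (by codon translation when a reference
sequence is supplied), frameshift vs in-frame indels, UTR, intronic and
intergenic placement; this is sufficient for an
exonic/protein-changing triage of a short candidate list.

## Haplotype phasing and windowed association

Windows of 6 markers advancing by 3 tile the interval; if trailing
markers would be uncovered, one extra window anchored at the last
possible start is appended so coverage is complete (the tiling
convention for the final window is otherwise arbitrary). Each window is
phased by an Excoffier–Slatkin EM: all genotype-compatible haplotype
pairs are enumerated exactly (practical for ≤8 markers), the E-step
weights ordered pairs by f_a·f_b, and the M-step re-estimates
frequencies; initialization is uniform over haplotypes appearing in any
compatible pair, making the fit deterministic, and iteration stops at
max |Δf| < 1e-6 or 500 iterations. Individuals with any missing
genotype in a window are excluded from that window. Each individual's
modal (highest-posterior) pair defines carrier status — carrying ≥1
copy of a haplotype — with posterior ties broken by lexicographic
haplotype order. Haplotypes with ≥5 carriers and ≥2 phenotyped
non-carriers are tested by a two-sided two-sample t-test
(pooled-variance by default; Welch available — the choice is
unspecified in the emulated design and pooled is the classic default).
This windowed EM deliberately replaces genome-wide phasing tools: for
short windows in a cohort of ~82, exact-enumeration EM is accurate,
dependency-free and reproducible.

## Synthetic data generators

All generators take a seed and are byte-deterministic.

* **Mapping cohort** (`simulate_cohort`): two founder sires, both
  heterozygous carriers of a causal allele private to them (father and
  carrier son in the emulated design), sharing the carrier haplotype
  over a configurable genetic block (default ±20 cM). 22 nuclear trios
  (fathers are the two sires, dams genotyped) and 55 half-sib offspring
  (28/27 per sire; dams simulated but not genotyped, matching a
  half-sib sibship analysis). Founder haplotypes draw alleles at
  frequencies uniform on [0.05, 0.5]; gametes recombine via the Haldane
  map r = (1−e^(−2d/100))/2 with no interference; chromosomes assort
  independently. Affection is carrier-with-probability-penetrance
  (default 1.0) with no phenocopies, then flipped at the misassignment
  rate (default 0). The default marker set is 200 markers over 5
  chromosomes at 2.5 cM spacing — a deliberately desk-scale stand-in
  for a genome-wide chip; the scan's power and calibration properties
  do not depend on the marker count, only the Bonferroni denominator
  does.
* **Crossbred coat-score cohort** (`simulate_crossbred_slick`): 82
  animals over 25 interval markers, 43 carriers bearing one copy of a
  contiguous founder haplotype (default 6 markers ≈ the associated
  block's span at 40-kb marker spacing). Scores are 1 for carriers and
  integer 2–4 for non-carriers (optionally jittered, clamped to the
  1–4 scale); by default two carriers are scored 2 and one non-carrier
  scored 1, reproducing the emulated cohort's 42 slick-coded cases, 40
  controls and 79/82 concordance with three discordant animals.
* **Multi-breed panels** (`simulate_variant_panels`): ten breed groups
  totalling 115 animals (9 in the target breed) plus a 50-animal
  population-database group. Background variants are a mix of shared
  and breed-private polymorphisms, constructed to be genuinely
  "previously observed" (listed in the dbSNP-like set or carried in
  the database group) and never fixed within the target breed; the
  planted variant is het in every target-breed animal, absent
  elsewhere and unseen. This makes clean-genotype filter recovery exact
  by construction, which is the property the emulated discovery design
  relies on.

What the generators do **not** emulate: population-level LD and breed
admixture tracts (founder haplotypes are drawn independently per
marker; LD arises only through co-segregation within the pedigree and
the planted founder blocks), genotyping error, coalescent founder
history, and sequencing-read-level noise. Passing recovery tests on
these data therefore demonstrates correctness of the statistics and
filters under the stated inheritance model, not robustness to
real-world artefacts such as batch effects or miscalled genotypes.

## Numerical and interface choices

* Coordinates are 1-based inclusive everywhere (VCF convention);
  intervals are closed.
* PED input orientation: the first allele seen per marker is taken as
  the alt allele unless an allele-reference table is supplied; the
  writer emits hets alt-first so write∘read round-trips. The scan
  statistic is invariant to ref/alt relabelling, so orientation cannot
  change a scan.
* The 2×2 genotypic dominance test is the 1-df Pearson chi-square on
  the carrier × phenotype table, N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
  without continuity correction by default (correction and Fisher's
  exact test are flags). Zero-margin tables are uninformative (p = 1).
* Covariate residualization fits ordinary least squares with an
  intercept always included, one-hot encoding categoricals with the
  first level dropped; constant columns are absorbed by the intercept
  and a rank-deficient design is an error naming the collinear columns.
* The pipeline runs six stages (acquire/simulate, QC, family scan,
  variant filters, concordance, haplotype scan) single-threaded,
  records input/output hashes and wall time per stage in a JSON-lines
  manifest, and suffixes outputs of a failed stage with `.partial`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `maf_min` | 0.01 | marker minor-allele-frequency floor |
| `call_rate_min` | 0.90 | per-sample genotype call-rate floor |
| `alpha` | 0.05 | per-experiment significance level |
| window `size`/`step` | 6 / 3 | haplotype window tiling (50% overlap) |
| `min_carriers` | 5 | minimum carriers for a haplotype test |
| `penetrance` | 1.0 | P(affected \| carrier) in the cohort generator |
| `misassignment_rate` | 0.0 | phenotype label-flip probability |
| `shared_block_cm` | 20 | sire-shared carrier-haplotype half-width, cM |

## Known limitations

* Hard genotype calls only; no dosage/imputation input.
* No X-chromosome, parent-of-origin or covariate-adjusted family tests;
  no permutation-based genome-wide p-values.
* Consequence annotation ignores splice sites and multiple transcripts.
* EM phasing is per-window (≤8 markers) and unrelated-individual; it is
  not a substitute for pedigree-aware or genome-wide phasing when long
  haplotypes are needed.
* The sibship variance is a large-sample chi-square approximation; for
  very small sibships with rare alleles the test is conservative-to-
  anticonservative within the usual bounds of 1-df score tests (the
  null-calibration test bounds this empirically for the target design).
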