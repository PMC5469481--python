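# Methods

## Problem setting

Large genotype repositories accumulate samples from the same person —
and from close relatives — across many studies, often genotyped on
different platforms with different marker sets and unknown DNA strand
orientations. `kinprint` detects identical samples and classifies close
pairwise relationships (parent-offspring, full sibling, second and
third degree) directly from genotype mismatch rates, without estimating
identity-by-descent probabilities or kinship coefficients, and checks
submitted pedigree files against the genotype evidence.

## Fingerprint panel

All comparisons run over a fixed, ordered panel of fingerprint SNPs.
Panel members must be bi-allelic autosomal SNPs, common (MAF > 0.17),
well spaced (≥ 50,000 bp apart within a chromosome, so that treating
SNPs as independent is a reasonable approximation), present on most
genotyping platforms (≥ 80% by default), and never strand-ambiguous
(no A/T or G/C allele pairs). The last rule is what makes
cross-platform harmonization deterministic: a non-complementary allele
pair can be matched to a dataset's alleles in exactly one of four
orientations (same, swapped, flipped, swapped-flipped) or declared
incompatible, with no need to know which strand was reported.
`select_panel` applies these rules with greedy left-to-right spacing
enforcement; the spacing scan keeps the leftmost SNP of any
too-close run, which is deterministic and order-independent.

Marker matching across datasets prefers the rsID and falls back to
(chromosome, position); positions vary by genome build, identifiers do
not. Monomorphic or half-missing allele columns ("0" alleles) are
treated as incompatible and encoded missing.

## Bit packing

Genotypes are stored two bits per SNP in paired 64-bit words with the
code table (hi, lo) = 00 hom-allele1, 01 het, 10 hom-allele2,
11 missing. The assignment is deliberate: "is homozygous" is the
complement of the low bit and "is missing" is `hi AND lo`, so the whole
pairwise comparison reduces to a handful of word-wide operations:

    valid    = NOT(hiA AND loA) AND NOT(hiB AND loB)
    mismatch = ((hiA XOR hiB) OR (loA XOR loB)) AND valid
    bothhom  = (NOT loA) AND (NOT loB) AND valid
    DO       = bothhom AND (hiA XOR hiB)

followed by popcounts. Pad bits beyond the panel size are set to
missing so no length masking is ever needed. Correctness is checked in
the test suite against a scalar per-SNP oracle, exhaustively over all
4×4 genotype-code combinations and on random 10,000-SNP fixtures.

## Mismatch statistics

For a pair compared at `n_compared` jointly non-missing SNPs:

* **AGMR** (all-genotype mismatch rate) = fraction of compared SNPs
  with different genotypes, i.e. the rate of IBS < 2 sites.
* **HGMR** (homozygous-genotype mismatch rate) = N_DO / (N_DO + N_SO),
  where DO counts opposite homozygotes (AA|BB) and SO same homozygotes.

HGMR with a zero denominator is reported as undefined (`None`) rather
than zero, so downstream consumers can skip it explicitly; on realistic
panels the denominator is never zero.

Under a homogeneous random-mating population in Hardy-Weinberg
equilibrium, the expectation of each statistic for a relationship with
IBD-state profile (P(Z=0), P(Z=1), P(Z=2)) is a polynomial in the
allele frequency p, averaged over the frequency distribution. With
p ~ U(0.1, 0.9) all integrands are polynomials, so `theory` computes
the expectations by exact polynomial integration (antiderivative
evaluation), which is bit-stable and faster than quadrature; explicit
per-SNP frequency lists use the arithmetic mean. The expected HGMR uses
the ratio-of-expectations form E[P(DO)]/E[P(DO)+P(SO)] — the
denominator's coefficient of variation is small, so the quotient of
expectations approximates the expected quotient well. Its predicted SD
treats the DO count as the dominant binomial noise term:
sqrt(P_DO(1−P_DO)/S) / E[P(DO)+P(SO)]. The printed SD tables correspond
to a panel of S = 10,000 SNPs.

## Duplicate detection

Three scanners report pairs whose full-panel AGMR is below a cutoff
(default 20%, a value that cleanly separates the identical-pair mode
near the genotyping error rate from the full-sibling mode near 33%):

* **naive** — O(n²S); every pair over the whole panel. Reference oracle.
* **quadratic** — O(n²); per pair, words are compared until at least
  m = 64 non-null comparisons accumulate (block-aligned: the screen
  stops at the word that carries the count past m), the pair is
  abandoned if k = 8 or more mismatches are seen by then, and survivors
  are verified over the full panel. Verification makes specificity 1 by
  construction; the false-negative rate is the upper binomial tail
  P(X ≥ k), X ~ Bin(m, ε) with ε the pair's per-genotype mismatch rate.
  Because the screen is word-aligned, slightly more than m comparisons
  can enter the mismatch count when genotypes are missing; with low
  missingness the screen uses exactly 64.
* **sub-quadratic** — O(n log n) per round; SNPs are ranked by missing
  rate, each round draws m = 20 SNPs from the low-missingness pool
  (the ≤ 20th-percentile missing-rate SNPs, widened to at least 10·m so
  draws vary between rounds while sentinel exclusions stay rare), packs
  each sample's genotypes at those SNPs into a 2m-bit integer key,
  sorts, and reads equal-key runs as putative pairs (all within-run
  pairs, so duplicate clusters are covered). Samples with any missing
  genotype among the drawn SNPs sit the round out with a sentinel key.
  Putative pairs are verified over the full panel; the loop ends after
  c = 10 consecutive rounds without a new confirmed pair. Per-round
  sensitivity for a pair with per-SNP missing-or-mismatch rate δ is
  ≈ e^(−mδ), and the residual false-negative rate after r rounds is
  (1 − e^(−mδ))^r; the scanner is intended for low-missingness data.

## Relationship classification

Classification is staged. AGMR below the identical cutoff → ID. HGMR
above the unrelated cutoff → UN; the default cutoff is the midpoint of
the analytic third-degree and unrelated HGMR expectations (≈ 0.188),
symmetric between the most distant modelled class and unrelated — the
exact value is configurable and not critical given the ≈ 9σ separation.
Remaining pairs get a posterior over T = {PO, FS, D2, D3} with equal
priors by default:

    P(R | x, y) = P(x, y | R) / Σ_t P(x, y | t)

where x = HGMR, y = AGMR. FS/D2/D3 use a bivariate normal density with
correlation ρ; PO uses an exponential density k·e^(−kx) for HGMR (PO
homozygous mismatches come only from genotyping error, and the observed
distribution decays roughly exponentially) times an independent normal
for AGMR. Ties in the argmax break toward the closer relationship
(PO > FS > D2 > D3) — a probability-zero event for continuous inputs but
reachable with rational mismatch rates.

Default parameters are pooled empirical values from a large repository
(stored as fractions; reports print percent). The default PO rate is
k = 1/0.0004 = 2500 — the reciprocal of the pooled mean PO HGMR —
and classification is insensitive to k over a wide range because PO sits
far from every other class. `fit_model` re-estimates parameters from
labelled pairs by sample moments (exponential rate by method of
moments, capped at 10⁵ when every PO HGMR is zero, to keep the density
finite); classes with fewer than 30 labelled pairs keep their previous
values. Means can alternatively be taken from the closed-form
expectations (`mu_source="analytic"`) while SDs and correlations stay
empirical, for studies with genotypes but few labelled pairs.

`decision_boundaries` returns the equal-posterior loci between adjacent
classes by linear interpolation of log-density differences on a grid;
they are for report plots and are not used in classification.

## Pedigree QC

Expected relationships come from the recursive kinship coefficient
φ with founders unrelated and no inbreeding: φ = 1/4 marks first degree
(split into PO vs FS by parent edges), 1/8 second degree, 1/16 third
degree. MZ twins must be annotated explicitly (PED files cannot express
them); same-subject pairs come from the subject-sample mapping.
Compound relationships (e.g. double first cousins) are classified by
total φ with a warning. `qc_report` emits one record per pair that is
reported related or predicted related, categorized as confirmed,
type_mismatch, unreported_related, reported_but_unrelated or
duplicate_unreported, and annotates two recurrent patterns: pairs
reported identical/MZ whose AGMR sits at the full-sibling expectation
(likely DZ twins) or at the unrelated expectation (likely sample
mix-ups). Unmappable samples are listed as orphans, not fatal.

## Simulator

The generator draws per-SNP alternate-allele frequencies once from the
frequency spec (default U(0.1, 0.9)), founders under HWE, and offspring
by gene dropping, independently across SNPs. Genotyping error replaces
a genotype with one of the other two uniformly; this makes the realized
mismatch rate of a duplicate pair equal the error rate applied to the
copy, which is the parameterization the screening false-negative
formula expects. Duplicates copy the source's realized (post-error)
genotypes and then receive their own errors; missingness is applied
last, and an optional platform mask blanks whole SNP columns to emulate
cross-platform gaps. Family templates (nuclear, three-generation,
half-sib, cousin) provide PO, FS, D2 and D3 pairs with known truth.

What the simulator does **not** emulate: linkage disequilibrium between
panel SNPs (real panels enforce spacing precisely to approximate this),
population structure and admixture, platform-specific cluster-calling
artifacts, non-random missingness, and sex chromosomes. Passing tests
therefore demonstrate correctness of the algorithms under the model's
own assumptions; on real data the empirical SDs of the mismatch rates
are wider than the binomial predictions (which is why the classifier
defaults to pooled empirical SDs rather than analytic ones).

## Numerical and design choices

* Uniform-interval expectations: exact polynomial integration.
* HGMR undefined (not 0) at zero denominator; such pairs classify as UN
  with a warning.
* Pairs sharing no compared SNPs are flagged incomparable, not errors.
* Sub-quadratic keys require m ≤ 32 (2m bits in a 64-bit key).
* All randomized components take explicit seeds and are reproducible
  bit-for-bit for a fixed seed.
* Default problem sizes in the test suite (panels of 2,000–10,000 SNPs,
  hundreds of samples, 500 planted duplicate pairs per Monte-Carlo
  condition, 40–50 simulated families per classification study) were
  chosen so the statistical checks have 3-SE resolution well inside the
  effects being tested while the whole suite runs in well under a
  minute of compute.

## Known limitations

* Relationships beyond third degree are not distinguished from
  unrelated; inbreeding and admixture are out of scope.
* The exponential PO model is a rough fit; it suffices because PO is
  far from other classes in the (HGMR, AGMR) plane.
* The quadratic screen's word alignment makes its realized
  false-negative rate differ slightly from the exact-m binomial tail
  when missingness is high.
* The naive and quadratic scanners are vectorized per anchor sample but
  still O(n²); they are practical to a few thousand samples in pure
  Python/NumPy, not to repository scale.
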