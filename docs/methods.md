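# Methods

`germcsg` re-implements, as a tested library, the analysis pipeline used to
estimate the prevalence of pathogenic germline variants in cancer
susceptibility genes (CSGs) in an unselected renal cell carcinoma (RCC)
cohort: short-variant prioritization, Bayesian ACMG/AMP classification,
structural-variant (SV) gene overlap, per-gene carrier burden testing,
diagnostic-yield estimation, and mutational-signature screening. This note
records the models, the defaults and why, and what the synthetic data do
and do not establish.

## Coordinate and encoding conventions

All genomic intervals are 1-based and inclusive at both ends (the VCF/HGVS
convention); BED-style half-open sources must be converted at the parsing
boundary. Missing annotation scores are sentinel-encoded (`.` in files,
`None` in memory) and are never coerced to zero: a MODERATE-impact variant
with a missing SIFT, PolyPhen or CADD value fails the in-silico retention
clause, mirroring the requirement that all three predictions support
deleteriousness. The population set for allele frequencies is column-driven
(`af_<pop>`), so a gnomAD-style popmax is computable without hard-coding
population names.

## Variant prioritization cascade

A short-variant observation is retained iff, in fixed order:

1. **panel** — the gene is on the 121-gene CSG panel (18 genes flagged as
   established RCC-CSGs);
2. **rarity** — popmax allele frequency `< 0.005` (strict inequality);
   a variant with no frequency annotation is treated as novel (popmax 0),
   the standard convention for variants absent from gnomAD;
3. **consequence** — VEP HIGH impact (stop gained/lost, frameshift, splice
   disruption, start lost), or a missense call that is SIFT-deleterious,
   PolyPhen possibly/probably damaging **and** CADD Phred `>= 20`
   (inclusive), or an inframe indel with CADD `>= 20`.

The inequality directions (strict `<` for frequency, inclusive `>=` for
CADD) follow the published thresholds exactly and are boundary-tested.
Start-lost is included in the HIGH set because VEP rates it HIGH, although
the published LoF enumeration lists only stop/frameshift/splice events.
Zygosity is deliberately not a filter: the observation that reported P/LP
variants were all heterozygous is a finding, not a rule. Each variant
carries an ordered trace of rule outcomes; evaluation stops at the first
failure, the filter is idempotent and monotone in its thresholds.

## Bayesian classification engine

Evidence codes (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7) carry an
applied strength mapped to points: supporting 1, moderate 2, strong 4,
very strong 8; benign codes count negatively. With combined points `p`,

    odds = 350 ** (p / 8)
    posterior = odds * prior / ((odds - 1) * prior + 1),  prior = 0.10

Five-tier classes follow the point bands P `>= 10`, LP `6..9`, VUS `0..5`,
LB `-6..-1`, B `<= -7`; BA1 is a stand-alone override forcing B regardless
of other codes. Within the VUS band the ACGS temperature grades map
one-to-one onto points (0 ice-cold … 5 hot); the equivalent posterior band
edges (0.10, 0.19, 0.32, 0.50, 0.68, 0.81) are exposed for users who prefer
the posterior formulation. The two formulations coincide under the default
prior and odds, which is why the point mapping is the primitive. Note the
6-point LP edge evaluates to 0.89991, i.e. 0.900 at the framework's printed
precision — band-edge assertions therefore compare at 3 significant
figures.

The engine is deterministic from the supplied codes. Expert curation enters
only through the codes; no automatic code derivation (PVS1 decision trees,
PM2 from frequency, …) is attempted.

**CNV scoring.** Copy-number evidence is scored with the 2020 ACMG/ClinGen
dosage rubric: signed per-section scores are summed and classified on the
thresholds P `>= 0.99`, LP `0.90..0.98`, VUS `-0.89..0.89`, LB
`-0.98..-0.90`, B `<= -0.99`. Allowed per-section ranges are table-driven
from a packaged rubric file, so gene-specific or updated rubrics can be
swapped in without code changes. Pipeline-level classification of panel
deletions supports both routes: rubric scoring, or (default) direct
assignment of P to deletions removing at least one exon of an RCC-CSG,
matching how the published VHL/CHEK2 deletions were judged.

## SV-gene overlap

A gene is hit when at least one breakpoint lies inside its interval; for
deletions, genes wholly contained in the deleted span are also reported
(default on) even when both breakpoints fall outside the gene — required to
represent a deletion that starts upstream and removes the gene body. An
exon partially overlapped by a deletion counts as removed: a disrupted exon
is functionally lost. Retention filtering is declarative — named predicates
over caller-supplied quality fields; the relaxed mode drops a configured
subset of the stringent predicates, so stringent-retained ⊆
relaxed-retained by construction. **The default predicate set is a
placeholder**: the original caller-specific filter definitions were not
published in the main text, so defaults must be replaced per call set.

## Cohort statistics

* **Diagnostic yield** — exact Clopper–Pearson binomial intervals in
  beta-quantile form. This method was chosen because it is the only
  standard interval that reproduces all three published CIs at 1-decimal
  rounding (the normal approximation does not). Reported percentages round
  half-up to one decimal, matching the published tables.
* **Fisher's exact test** — two-sided, hypergeometric-sum definition
  (scipy); the sample odds ratio `ad/bc` is reported (documented choice).
* **Carrier burden** — per gene, a carrier is a participant with `>= 1`
  filter-retained variant in that gene, counted once (carriers, not
  alleles); Fisher on carriers vs non-carriers restricted to one ancestry
  label (default `EUR`, labels are inputs, never inferred); multiplicity by
  Benjamini–Hochberg step-up across the tested gene family ("FDR" was
  unspecified; BH is the documented assumption). The FDR family defaults to
  all panel genes, with an option to restrict to genes with at least one
  case carrier.
* **Welch's t-test** — unequal variances, Satterthwaite degrees of freedom,
  two-sided.
* **Age-cutoff sweep** — for each cutoff `c`: carriers with age `< c`
  (testing sensitivity) and the cohort share under `c`; monotone in `c`.

Null calibration of the burden test is checked under label permutation.
Because carrier counts are small and Fisher p-values discrete, null
p-values are *conservative* (they stochastically dominate the uniform);
the calibration property tested is therefore empirical type-I error at
`alpha = 0.05` not exceeding nominal, not distributional uniformity —
a Kolmogorov–Smirnov test against the uniform would reject any discrete
exact test and is not a meaningful check here.

## Mutational signatures

Somatic catalogs are raw counts over the standard 96 trinucleotide channels
(6 pyrimidine substitution classes × 16 contexts, alphabetical within
class). Exposures are fit by non-negative least squares on counts
(active-set solver); fitting on counts rather than frequencies weights
high-burden samples naturally, and the frequency alternative is a one-line
renormalization of the input. MMR deficiency is flagged when signatures
6/15/20/26 jointly reach a minimum exposure proportion, POLE exonuclease
deficiency when signature 10 does; the "presence" threshold was never
quantified in the source analysis, so it defaults to 0.05 and is
configurable.

The packaged signature matrix is a **deterministic synthetic stand-in**
(`signature_matrix_v2_subset_synthetic.tsv`): ten probability columns with
hand-placed peaks mimicking the well-known spectral features of the named
COSMIC v2 signatures (e.g. signature 10's T[C>A]T peak) plus five
backgrounds. It supports recovery and flagging tests; analyses of real
tumours should load the genuine matrix from TSV.

## Synthetic cohorts and what they establish

The generator draws, per gene, case and control carriers as independent
binomials at configured frequencies (defaults follow the published case
carrier counts; control frequencies are order-of-magnitude configuration
guesses, clearly not estimates, because control counts were never
published). Each simulated variant gets a truth class from a configurable
mix over {P, LP, six VUS temperatures, LB, B}, realised two ways at once:
a canonical evidence-code set whose points land in the class band, and
annotations drawn conditional on the class so the filter cascade behaves
predictably (pathogenic truth looks rare and damaging; benign truth looks
common, tolerated or sub-threshold with probability `benign_look_rate`).
Annotation noise adds independently missing in-silico scores. Phenotypes
follow the published marginals: age truncated-normal (mean 61.3, SD 12,
range 13–88, by rejection sampling), 64% male, the published
histology/stage/ancestry mixes. Controls carry no tumour fields and are
emulated solely through lower carrier frequencies — no pedigree,
population-structure or read-level modelling. Every consumer draws from a
named RNG stream derived from the master seed, so outputs are bit-identical
for identical configs and stable under unrelated draws.

With zero annotation noise, planted codes pushed through the engine
reproduce truth classes at 100%; this validates the engine's band
arithmetic, **not** real-world curation accuracy. Likewise the burden power
property (≥ 80% BH-adjusted detection of a 2% vs 0.3% carrier contrast at
1336 vs 5834) validates the testing machinery at the study's sample sizes,
not the unpublished control counts behind the reported CHEK2 result.

## Demo cohort from the published tables

The published per-variant tables are packaged as data and expanded into a
fully specified 1336-case cohort: 88 P/LP observations (85 short variants +
3 deletions) across 85 carriers, including the two multilocus carriers
(CHEK2+ATM; CHEK2+2×MSH6). Multilocus carriers count once in
participant-level yield but once per gene in tallies — the only counting
scheme that reconciles 85 participants with 88 variants, verified by a
dedicated test. Carrier ages are planted to match the published age-cutoff
figures (18 carriers, 14 of 60 RCC-CSG carriers under 46 years); filler
ages are drawn from the age model. Gene coordinates in the packaged panel
are synthetic except that VHL's exon structure is anchored to the published
deletion breakpoints so both VHL deletions remove two of three exons and
the CHEK2 deletion removes exactly the fifth exon.

## Numerical choices and degenerate inputs

* Percentages: decimal half-up rounding at 1 d.p. (2 d.p. for p-values).
* Fisher on a table with an empty margin: p = 1, odds ratio undefined
  (NaN); `b*c = 0` with signal gives an infinite sample OR.
* NNLS residual agreement with an independent solver is required to 1e-8
  on fixtures; exposures are exactly homogeneous under catalog scaling.
* Empty evidence profile classifies as VUS ice-cold (posterior = prior).
* Zero-mutation catalogs yield all-zero exposures and no flags.
* Problem sizes in the checks were chosen to keep the full suite in a few
  minutes: burden power uses 500 replicates of binomially drawn carrier
  counts over 121 genes; calibration uses 300 label permutations of 20
  genes; signature recovery uses 50 000-mutation catalogs.

## Known limitations

* Evidence codes are inputs; the package does not derive them from
  annotations, so classification fidelity on real data depends entirely on
  upstream curation.
* The SV module consumes calls; no calling, genotyping or read-level
  validation, and translocations get gene hits only (no fusion annotation).
* One consequence per variant row is assumed; transcript-level consequence
  disagreement must be resolved upstream (canonical transcript choice).
* Burden testing is unadjusted Fisher per gene — no covariates, no
  kernel/collapsing tests, no ancestry inference.
* The stage-contrast p-value implied by the published counts (0.34) differs
  from the published 0.24; the package reports what the counts imply.
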