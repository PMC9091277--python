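# Methods

## The SELV statistic

For a locus — one (contig, 1-based position) pair on a stated genome
build — a population frequency resource reports a vector of alternate
allele frequencies (F₁, …, Fₙ). SELV is the Shannon entropy of that
vector,

    SELV = − Σᵢ Fᵢ log(Fᵢ),

computed over the reported frequencies *as reported*:

- **No renormalization.** The Fᵢ need not sum to one and the reference
  allele contributes no term. SELV is a property of the recorded
  variability, not of a probability distribution over alleles.
- **Boundary conventions.** 0·log 0 = 0 and 1·log 1 = 0, so SELV is
  finite and non-negative everywhere; the empty vector (no reported
  variant) gives 0.
- **Log base.** Natural log by default; any base b > 0, b ≠ 1 is
  accepted and rescales the value by 1/ln b. Ranking, ROC/PR curves and
  Youden calibration are invariant to base, so the choice only affects
  raw reported values.
- **Zero-frequency records** are accepted on input but dropped (and
  counted) before vector construction: a frequency of zero carries no
  entropy and such rows are usually artifacts of export pipelines.

A query variant receives the SELV of its locus; its own alternate allele
is never added to the vector, so a novel variant cannot raise its own
score, and a position absent from the resource scores 0 — the minimal
observed variability, hence maximally suspicious under the
selective-pressure interpretation. Mitochondrial contig spellings
(`chrM`, `chrMT`, `MT`, `M`) are pooled under one canonical name because
they denote the same molecule; genome builds, by contrast, are opaque
tags that never mix, and no coordinate conversion is attempted. Only
SNVs are scored; indels and MNVs are rejected with counts. Duplicate
(contig, position, ref, alt, population) records are a hard error rather
than a silent merge, since a merged duplicate would corrupt the vector.

Per-ancestry stratification is supported by tagging frequency records
with a population label: each stratum yields its own vectors and SELV,
reported alongside the combined score, so the sensitivity of SELV to
ancestry composition can be inspected directly.

## Orientation and decision rule

Constrained loci have low SELV, so SELV flags pathogenicity at *low*
values while most competitor predictors flag it at high values. Every
API that consumes scores takes an explicit orientation
(`lower_is_pathogenic` / `higher_is_pathogenic`); nothing auto-detects
direction, because silent auto-flipping masks sign bugs.

Classification uses the inclusive rule: with the default orientation a
variant is pathogenic iff SELV ≤ threshold. Inclusivity matters at the
boundary — variants at never-variable positions (SELV = 0) must classify
as pathogenic at any positive threshold, which a strict inequality would
violate at threshold 0.

## Benchmarking

- **ROC.** One threshold per distinct score value (all tied scores move
  together); AUC by the trapezoid, which equals the Mann–Whitney
  probability that a pathogenic variant out-ranks a neutral one with
  ties counting ½. Flipping orientation complements the AUC exactly.
- **PR.** Step-wise area (average precision): precision is held over
  each recall increment. Linear interpolation in PR space is known to
  over-estimate and is not offered; the interpolation rule is recorded
  in report metadata.
- **Paired AUC comparison.** DeLong placement values per observation
  give both AUCs and the covariance of the paired estimates;
  D = (AUC_a − AUC_b)/√var(diff) is referred two-sided to the standard
  normal. The paired form (both scores on the same variants) is used
  throughout; variants missing either score are dropped from that
  comparison only, and dropped counts are always reported. Zero variance
  with equal AUCs yields D = 0, p = 1; zero variance with unequal AUCs
  is flagged as degenerate rather than reported as ±∞.
- **KS and Fisher.** The two-sample Kolmogorov–Smirnov test uses the
  asymptotic p-value (the intended sample sizes are thousands of
  variants; exact small-sample p is out of scope). Fisher's exact test
  reports the conditional maximum-likelihood odds ratio, with complete
  separation reported as infinite.

## Youden calibration

Candidate cut-offs are the midpoints between consecutive distinct scores
plus ∓∞ sentinels — the ROC-consistent grid on which every achievable
confusion matrix appears exactly once. J = sensitivity + specificity − 1
is evaluated at each candidate; ties on J break toward higher
sensitivity (in a prioritization setting a missed pathogenic variant
costs more than a false alarm), then toward the lower threshold. The
reported sensitivity and specificity are resubstitution values on the
calibration data and are labelled as such in the serialized calibration,
which also carries a hash of the calibration set so classification runs
are auditable. Calibrations are per genomic context (splice-site,
nuclear non-coding, mitochondrial non-coding, …) because each context
draws its frequencies from a different resource and needs its own
cut-off.

## Synthetic data

The generator emulates the statistical premise under test: pathogenic
variants concentrate at positions under selective constraint.

- A resource of `n_loci` positions (default 5,000; spaced 100 bp on one
  contig) draws 0–3 alternate alleles per locus from a configurable
  distribution (default (0.35, 0.40, 0.17, 0.08), i.e. about a third of
  positions with no reported variant) and per-allele frequencies from a
  heavy-tailed family, by default log-uniform on (10⁻⁴, 0.5) to mimic
  the shape of a population allele-frequency spectrum. Frequencies are
  canonicalized through single precision at generation time because VCF
  `Type=Float` INFO fields are 32-bit on disk; this is what makes the
  VCF round trip bit-exact.
- A labeled cohort (default 2,000 pathogenic + 2,000 neutral) places
  pathogenic variants at loci with probability ∝ exp(−β·SELV)
  (default β = 4) and neutral variants uniformly. The bias acts on the
  true locus SELV, not on labels, so synthetic cohorts exercise the full
  resource → vectors → scores → benchmark pipeline. Placement is
  without replacement over (locus, alt) slots so cohorts have unique
  variant keys; resources are kept large relative to cohorts so this is
  statistically indistinguishable from independent draws.
- The *two-point design* (10% of loci with no variant, 90% with two
  balanced alleles at frequency 0.5, β = 8, 20,000 loci) admits a
  closed-form AUC from the two categorical SELV distributions, used as
  the analytic oracle for end-to-end signal recovery; with β = 0 the
  expected AUC is ½ exactly.
- Optional ancestry strata perturb each combined frequency by log-normal
  noise of configurable scale.
- Seeds are mandatory; identical seed and config reproduce outputs
  byte-identically.

What the generator does **not** emulate: mutation-rate heterogeneity and
sequence-context (k-mer) effects, linkage, frequency estimation noise at
small sample sizes, database ascertainment bias, and any correlation
between competitor scores and sequence features. Passing tests therefore
demonstrate that the machinery is correct and recovers planted signal —
not that SELV attains any particular performance on real cohorts, which
depends entirely on the frequency resource and benchmark sets supplied
by the user. SELV is also expected to be weak in protein-coding regions,
where pathogenicity is dominated by amino-acid effects rather than locus
variability; the tool scores such variants but claims nothing for them.

## Numerical choices and edge cases

- Frequency domain errors name the offending value; frequencies are
  validated to [0, 1] at record construction.
- ROC/PR require both classes and at least one observation per class;
  the DeLong test requires two per class to estimate a variance.
- The VCF annotator works line-wise on the text so that every byte it
  does not add is preserved; the added INFO key is declared
  `Number=1,Type=Float` and values are printed with `%.6g`.
- Scored tables print floats at 6 decimals; `NA` denotes missing on
  write, with empty cells and `NA` both accepted on read. Missing
  competitor scores are never coerced to 0.
- Plain-gzip (non-BGZF) VCFs are decompressed to a temporary file before
  parsing, since htslib cannot seek in them.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
oracle checks use up to 1,000 random vectors and a few hundred
observations per instance; end-to-end checks use 20,000-locus resources
with 4,000-variant cohorts, chosen to keep Monte-Carlo error on an AUC
near ±0.01 while the whole suite completes in well under a minute of
compute.
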