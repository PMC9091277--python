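# selv — Shannon Entropy of Locus Variability

`selv` scores single-nucleotide variants by how variable their genomic
position is in the population, and turns that score into a practical
variant-prioritization workflow: benchmarking against competitor
predictors, Youden-index threshold calibration, and reclassification of
variants of uncertain significance (VUS). It is aimed at the genomic
contexts where supervised pathogenicity predictors are weakest —
splice-site dinucleotides, nuclear non-coding DNA, and the non-coding
mitochondrial genome — and at anyone who has a population frequency
resource (a gnomAD-style VCF or a helixMTdb-style frequency table) and a
set of SNVs to rank.

## The statistic

At a locus (one genomic position on a stated build) a frequency resource
reports *n* alternate alleles with population frequencies
*F₁, …, Fₙ*. The Shannon Entropy of Locus Variability is

    SELV = − Σᵢ Fᵢ · log(Fᵢ)

with the conventions 0·log 0 = 0 and 1·log 1 = 0, natural log by default.
Frequencies are used exactly as reported — no renormalization, no
reference-allele term — so SELV ≥ 0, SELV = 0 for a position with no
reported variability, and SELV grows with the number and balance of
segregating alleles. The biological premise is selective pressure:
positions that tolerate variation accumulate it, positions under
constraint do not. A *low* SELV therefore flags a suspicious position, and
every function in the package carries an explicit orientation
(`lower_is_pathogenic` for SELV) rather than guessing directions.

Around the score the package provides:

- **io** — gnomAD-style VCF and tab-separated frequency readers (gzip
  accepted, multi-allelic sites split per allele, per-ancestry INFO keys
  supported), variant-table I/O, scored-table output, and byte-preserving
  VCF annotation with a `SELV` INFO field.
- **benchmark** — ROC and precision-recall curves with explicit tie
  handling, paired DeLong D-statistic tests between correlated AUCs,
  two-sample Kolmogorov–Smirnov and Fisher's exact tests.
- **calibrate** — Youden-index (J = sensitivity + specificity − 1)
  threshold selection per genomic context, inclusive-rule classification,
  serializable calibrations.
- **simulate** — synthetic frequency resources and labeled cohorts whose
  pathogenic variants are placed at low-entropy loci with probability
  ∝ exp(−β·SELV), for pipeline testing with known ground truth.

## Worked example

Score three query variants against a tiny mitochondrial resource:

```python
from selv import FrequencyRecord, LabeledVariant, build_locus_table, score_variants

records = [
    FrequencyRecord("chrM", 152, "T", "C", 0.23),
    FrequencyRecord("chrM", 152, "T", "G", 0.004),
    FrequencyRecord("chrM", 263, "A", "G", 0.51),
]
table = build_locus_table(records, build="rCRS")
queries = [
    LabeledVariant("chrM", 152, "T", "A"),   # busy locus
    LabeledVariant("chrM", 263, "A", "C"),   # one common allele
    LabeledVariant("chrM", 4300, "A", "G"),  # never-variable locus
]
for variant, score in score_variants(queries, table):
    print(f"{variant.contig}:{variant.position} {variant.ref}>{variant.alt}  "
          f"SELV={score.value:.6f}  n={score.n_variants}")
```

```
chrM:152 T>A  SELV=0.360111  n=2
chrM:263 A>C  SELV=0.343406  n=1
chrM:4300 A>G  SELV=0.000000  n=0
```

The query's own allele never joins the vector — a novel variant cannot
inflate its own score — so the T>A query at 152 is scored from the two
*database* alleles, and the variant at the never-variable position 4300
gets SELV = 0, the most suspicious value.

The same workflow from the shell, on simulated data:

```sh
selv simulate demo --seed 5 --n-loci 2000 --n-pathogenic 300 --n-neutral 300 --bias 25
selv score demo/resource.vcf demo/cohort.tsv demo/scored.tsv --build GRCh38
selv benchmark demo/scored.tsv demo/report.json
selv calibrate demo/scored.tsv demo/cal.json
```

which prints (seed 5):

```
{"mean_selv_pathogenic": 0.005190579253503098, "mean_selv_neutral": 0.10631645132248456, "selv_gap": 0.10112587206898146}
scored 600 variants (0 non-SNV rows rejected; resource: 1944 records kept, 0 zero-frequency dropped)
score         orientation   n  n_dropped      auc   pr_auc  d_vs_selv  p_vs_selv
 selv lower_is_pathogenic 600          0 0.731761 0.654616        NaN        NaN
nuclear_noncoding: threshold=0.0369845 J=0.4200 sens=0.9733 spec=0.4467
```

The simulated allele-frequency spectrum is heavy-tailed, so most loci
already sit near SELV = 0 and even a strong placement bias yields moderate
separation (AUC 0.73) — on a two-point resource design with distinct
SELV strata the same pipeline reaches AUC ≈ 0.93 (see below). The
calibration line reports the Youden-optimal cut-off with its
resubstitution sensitivity and specificity; `selv classify` then applies
such cut-offs per genomic context.

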