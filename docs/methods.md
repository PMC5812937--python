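# Methods

## Scope and model

`homeologdiv` analyzes homeolog-specific expression in a hybrid
(allopolyploid) transcriptome: a gene universe of A:B homeolog pairs
(~7% diverged), groups of 100%-identical genes created by loss of
heterozygosity, and unpaired singletons. The pipeline has four stages —
simulate, count, normalize, ratios — each usable on its own; user count
matrices enter at the normalize stage.

## Synthetic data generator

The generator exists so every downstream stage is testable without external
data; its defaults describe a 2-condition × 2-time-point × 3-replicate bulk
RNA-seq experiment.

**Catalogue.** Sequences are uniform ACGT. The A member of each pair is
drawn first; the B member is derived by per-site substitution at the
requested divergence (default 0.07), always to a different base, with no
indels — so observed mismatch fraction equals the substitution fraction and
exact-match mapping semantics are well defined. Identity-group members share
one sequence byte for byte. Gene length is a constant or uniform range
(default 1500 bp, typical of yeast coding genes).

**Expression ratios.** For each pair and sample group, the A-share ratio is
drawn from Beta(c·m, c·(1−m)) with mean bias m (default 0.5, no subgenome
preference) and concentration c per condition: 60 under control, 12 under
stress. The beta family is a modeling choice, not an inference from data;
it is the simplest two-parameter family on [0, 1] whose spread is
controlled independently of its mean. The default concentrations give ratio
SDs of 0.064 (control) and 0.139 (stress), bracketing the magnitudes
reported for hybrid yeast under acid stress, so "stress widens divergence"
is planted by construction and parameter-recovery tests have a known truth.
Ratios are drawn independently per (condition, time point) group, the unit
of all downstream summaries.

**Counts.** Per-pair abundances are lognormal(0, 1); a gene's expected
count in a sample is proportional to abundance × ratio share × length,
scaled to the target library size (default 2 × 10⁶ fragments). Counts are
negative binomial with var = μ + φμ² (default φ = 0.05, a typical
replicate-level RNA-seq dispersion). φ = 0 is the deterministic limit:
counts equal rounded expectations, which gives exact-recovery fixtures.
A fraction of genes can be made condition-specific (zero abundance in the
other condition) to exercise the expression filter; one control replicate
can be dropped to mirror a discarded low-depth library.

**Reads.** Single fragments (not read pairs — counting operates per
fragment either way): uniform start positions within the gene, fixed read
length (default 100 nt), per-base substitution errors at a configurable
rate, truth labels retained, FASTA/FASTQ output with constant Phred-40
qualities. Not modeled, and therefore not evidenced by passing tests:
splicing, UTRs, strand chemistry, GC or positional bias, paired-end insert
sizes, indels, quality-dependent errors. Real libraries also violate the
independence of counts across genes (shared technical factors), which the
NB model ignores.

## Assignment and counting

A read is assigned to every gene containing it as an exact full-length
substring (a seed-and-verify index: prefix k-mer lookup, k = min(read
length, 31), then substring verification — results provably equal a
brute-force scan, which the tests also assert). This emulates zero-mismatch
alignment stringency; reads carrying any sequencing error in a diagnostic
position simply go unaligned, which is the intended behavior of the
high-stringency design. Hit sets are exhaustive; no cap on the number of
reported alignments is applied (with realistically small identity groups a
cap of ~10 never binds).

Counting never uses the randomly chosen representative alignment (that
field exists only for the SAM-like dump), so both count flavors are
seed-independent and deterministic:

* **full**: count(g) = reads with hit set exactly {g};
* **duplicated**: count(G) = multimapped reads whose entire hit set lies
  within one identity group G. Multimappers touching genes outside a single
  group are discarded — pooled signal must stay within one 100%-identity
  set. (The alternative convention — crediting the randomly chosen member —
  would make duplicated counts stochastic; pooling per group is both
  deterministic and the quantity actually interpretable for identical
  genes.)

Every read is exactly one of: unique, within-group multimapped, discarded,
unaligned; the partition audit is written per sample.

## Normalization and filtering

TMM follows the published definition exactly: M- and A-values on
library-size-scaled counts over genes positive in both sample and
reference, double trim (30% of M, 5% of A, rank-based), inverse
delta-method-variance weights, factors rescaled to geometric mean 1;
automatic reference = sample whose 75th-percentile count fraction is
closest to the mean of those fractions. The implementation agrees with
edgeR's `calcNormFactors` to ≥ 6 digits on test matrices (asserted in the
suite via Rscript) and with an independent from-definition reimplementation
within 2%.

CPM uses TMM-effective library sizes by default (flag for raw sizes);
RPKM = CPM × 10³ / length. Full and duplicated matrices are normalized
independently — the duplicated flavor is a composite signal and is never
mixed into the full analysis.

Expression evidence: a gene is expressed in a condition iff ≥ `min_samples`
(default 3) of that condition's samples reach ≥ `min_cpm` (default 1),
pooling time points by default (per-group filtering behind a flag).
"No evidence" means expressed in neither condition. The filter sentence
this rule operationalizes could also be read as "≥ 3 low samples in a
condition ⇒ discard the gene globally", but that reading would erase
condition-specific genes, which the categorization explicitly reports;
requiring positive evidence per condition reproduces the
expressed/condition-specific/no-evidence partition.

## Ratio statistics

Ratio r = avgRPKM_A / (avgRPKM_A + avgRPKM_B), replicate-averaged
(arithmetic mean) within each (condition, time point) group. Pairs in which
neither homeolog ever shows expression evidence are excluded from the table
entirely; a group where both averages are zero yields an undefined ratio in
that group only (dropped from that group's summary, with the count
reported). Numerically, r is computed by dividing the smaller average and
complementing the larger, which makes r(A,B) + r(B,A) = 1 hold bit-exactly
(the naive two-division form misses by one ulp for ~15% of inputs).

Balance: r ≥ 0.6 unbalanced toward A, r ≤ 0.4 toward B, thresholds
inclusive and configurable. Ab/aB counts use strict inequalities around
0.5; exact ties count toward neither and are reported.

Subgenome-bias test: two-sided exact binomial P for n_Ab successes in
n_Ab + n_aB trials at p = ½, using the minimum-likelihood two-sided
convention (sum of all outcome probabilities ≤ that of the observed
outcome), Bonferroni-multiplied by the family size (default 4, the number
of sample groups) and capped at 1. The suite checks it against an
exhaustive pmf summation.

Variance divergence: Fligner–Killeen median-centered, normal-scores rank
test (via `scipy.stats.fligner`), all defined ratios per group (an
intersection-of-pairs mode is a documented alternative; with near-complete
tables the two coincide). The suite verifies type-I error calibration
(rejection rate in [0.03, 0.07] at α = 0.05 over 2000 null replicates) and
power (P < 1e-10 for Beta(6,6) vs Beta(30,30) at n = 4000).

Skewness defaults to the type-3 moment estimator
g₁·((n−1)/n)^{3/2}, matching the convention of the standard
descriptive-statistics packages; types 1 and 2 are selectable.

## Pipeline and reproducibility

One root seed feeds named substreams (catalogue / ratios / abundance /
counts / reads / assignment), so identical config + seed reproduces every
intermediate byte for byte (asserted on file digests). The count-level
entry mode skips read simulation so statistical stages run in milliseconds;
read mode is exercised at small scale. Stage metadata (flavor, stage) is
written in JSON sidecars, and the `ratios` CLI refuses a matrix whose
sidecar marks it as raw counts.

Problem sizes in the default suite and analysis scripts — 30–2000 pairs,
libraries of 10⁵–3×10⁶ fragments, 20 replicate recovery runs, 2000 null
simulations — were chosen so each property is measured at a scale where its
expected effect dominates sampling noise (e.g. ratio-recovery RMSE and FK
power are asserted at mean pair depth ≥ 500, where the estimator noise
floor sits well below the planted between-condition contrast).

## Known limitations

* Transcript-level exact matching, not genome alignment: no introns,
  indels, clipping, or quality-aware mismatches. Divergence between
  homeologs is pure substitution by construction.
* The duplicated-count convention (pool per identity group, discard
  boundary-crossers) is one of two defensible readings of MAPQ-0 recounting
  for identical genes; the alternative (random-member crediting) is noted
  above and deliberately not used.
* With NB dispersion > 0, the per-pair ratio estimate carries a noise floor
  (≈ 0.046 SD at mean pair depth 1000 and φ = 0.05); group-level variance
  comparisons are unaffected in direction but absolute SDs include this
  component.
* Differential expression modeling, GO enrichment, and phylogenetic
  analyses are out of scope; the package stops at counts, normalized
  expression, and ratio statistics.
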