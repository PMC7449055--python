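# Methods

## Read classification at a junction

All intervals are 0-based half-open internally; GTF/VCF/FASTA keep their
native 1-based inclusive convention at the file boundary and BED its 0-based
half-open one.  A gene model is the exon union over transcripts of one gene
(overlaps merged with a logged warning); introns are exactly the gaps
between consecutive union exons, numbered in transcription order (reversed
genomic order on the minus strand).

An aligned read is reduced to its reference blocks; reference gaps of at
least 20 bp split blocks (splices), shorter gaps (deletions) do not.  The 20
bp cut-off mirrors the conventional aligner minimum intron size and is
configurable.  At a junction with intron *(s, e)*:

- **spliced** — some between-block gap equals *(s, e)* exactly and the
  flanking blocks overlap the donor- and acceptor-side exons by at least
  `min_anchor` bases (default 1; tests also exercise 6);
- **unspliced** — a single block covers the donor-side exon|intron boundary
  with at least `min_anchor` bases on each side.  Only the donor (5') side
  is counted by default because unspliced intermediates are defined by
  read-through at the boundary where the intron begins in transcription
  order; `both_boundaries=True` also accepts acceptor-side crossings;
- **other** — anything else touching the junction neighbourhood (the intron
  plus one exonic base on each side).

A read counts at most once per junction but may be spliced at several
junctions.  Mates of a pair are treated as independent reads; no
fragment-level deduplication is attempted.  Read orientation is ignored:
the phenotypes are strand-symmetric and libraries of mixed strandedness can
be pooled.

## Phenotypes

- Splicing efficiency `SE_j = (n_spliced + c)/(n_unspliced + c)`; the
  pseudocount `c = 0.5` keeps ratios finite at low depth, `c = 0` is the
  strict spliced:unspliced ratio (undefined when no unspliced read exists).
  Association runs use `log SE_j`, which symmetrises the ratio scale.
- Intron-read percentage: share of gene-span-overlapping reads with ≥1 base
  in the intron.  Read-level, no mapping-quality filter by default; both
  choices are logged rather than asserted, since neither is forced by the
  phenotype definition.
- PSI of an alternative 5' donor event: among reads spliced at either the
  reference or the alternative donor form of the affected junction,
  the percentage using the reference form.  The event stores the removed
  (“intronified”) span; a span not divisible by 3 sets a frameshift flag,
  otherwise the removed-codon count is reported (the exon-8 worked example
  removes 66 bp = 22 codons).
- Normalised expression: median-of-ratios size factors (genes containing a
  zero are excluded from the geometric means) and `log2(count/sf + 1)`,
  optionally followed by per-batch mean-centering to the grand mean.  This
  is a deliberate, documented simplification of count-model
  variance-stabilising transforms: downstream association only requires a
  variance-stabilised monotone transform, not the exact parametric VST.
  With a single gene (or sample) size factors stay at 1 — depth and
  expression are not separable from one gene.

## Association model

Per marker, ordinary least squares `y ~ intercept + covariates + dosage`
with dosage additive in the count of alternative alleles, two-sided t-test
on the dosage coefficient.  The scan residualises the phenotype and every
dosage column against the covariate design once (QR) and tests each marker
in the residual space — algebraically identical to the per-marker fit
(checked against it and against a normal-equations oracle at 1e-10).
Missing dosages fall back to pairwise deletion per marker.  Variance
explained is reported as `100 × (SSE_reduced − SSE_full)/SSE_reduced`, the
share of covariate-adjusted phenotypic variance removed by the marker; this
convention is stated because reduced-rank alternatives exist and the choice
matters when covariates are strong.

Relatedness-style structure is available as a single grouped random
intercept fitted by REML profiled over the variance ratio λ = σ²_group/σ²_e
(bounded 1-D optimisation with the λ = 0 boundary checked explicitly, so a
zero component reduces *exactly* to OLS).  This is a deliberate,
qualitative stand-in for full pedigree mixed models, which are out of
scope; it is cross-checked against an independent mixed-model
implementation in the tests.

Conditional scans append the focal marker's dosage to the covariates; the
focal marker itself is reported as missing ("conditioned"), and a marker
whose residual dosage variance vanishes (perfect LD with the conditioned
dosage) is reported as missing ("collinear") — there is no testable
variation left, which is the strongest form of non-significance.

LD is the squared Pearson correlation of dosages (pairwise-complete,
allele-flip invariant).  Genotype-class tests use Kruskal–Wallis with tie
correction and a χ²(k−1) reference; at very small n the χ² tail is accurate
in the significance region (checked against exhaustive permutation at n=9)
but mid-range p-values deviate — the implementation keeps the standard χ²
reference and the tests document where it is trusted.  Multiple testing
uses Bonferroni only (α/n_tests): 0.05/(3128 × 14) ≈ 1.14e-6 for a
14-junction scan over 3128 markers, 0.05/12 ≈ 0.0042 for the in-vitro
table, 0.05/3128 ≈ 1.60e-5 for a single-phenotype conditional scan.  The
marker count always comes from the input, never from a constant.

## ESE scanning

A panel is a set of hexamers; scanning slides a 6-base window (windows with
N never match).  For a same-length substitution (SNP/MNP; indels are
rejected), both alleles are scanned and only hits whose window intersects
the variant span are compared: the delta reports motifs lost and gained.
Scanning is strand-naive; the reverse complement is a separate explicit
call.  The packaged panel is a small synthetic fixture subset of
purine-rich enhancer hexamers (including AAGAAG and AGAAGG) for tests and
examples; real analyses should supply the published panel file.  The 23-nt
exon-8 context shipped with the generator reconstructs the printed motif
positions around the AA>GC variant with neutral flanking bases; it does not
claim the true genomic flanks.

## qPCR quantification

Each assay's serial-dilution wells (5× steps) define a standard curve of Cq
on log10 concentration; amplification efficiency is `10^(−1/slope) − 1`
with validity flags (negative slope, efficiency in (0.7, 1.2)).
Quantities are back-calculated per well from the assay's own curve (the
standard-curve method rather than ΔΔCq, because per-assay dilution curves
are available and absorb efficiency differences), averaged over replicate
wells, and normalised by the geometric mean of the sample's reference
assays (endogenous control and transfection control both enter the
geometric mean by default; a separate-divisor mode is available).  The
per-sample splicing ratio is spliced/unspliced normalised quantity;
allele-level summaries are mean ± SD across samples, contrasted with a
pooled-variance Student's t-test by default (Welch by flag) and a
Bonferroni flag at α/n_tests.

## Synthetic cohort generator

The generator's defaults are the study conditions the package is validated
under: 375 animals; causal K-allele frequency 0.51 with Hardy–Weinberg
genotypes; 200 markers over a 1 Mbp interval centred on the causal MNP at
its reported position, each non-causal marker copying the causal haplotypes
with flip probability `min(0.5, 0.03 × distance-in-markers)` so the nearest
proxies reach r² ≈ 0.88 (the strongest observed proxy correlation) and
distant markers are unlinked; per-genotype (AA/AK/KK) intron-8 read
percentages 1.94/1.53/1.16 with smaller effects at junctions 2 and 7 and a
flat 1.5% elsewhere; reference-donor PSI 96.4/94.5/94.1; normalised
expression 9.244/9.436/9.628 (SD 0.25, consistent with class standard
errors of ~0.02–0.03 at class sizes near 100); three sampling cohorts at
proportions 21:183:171 with small additive expression offsets; Dirichlet
ancestry proportions and a Beta heterosis fraction.

Genotype class means map to animal-level probabilities on the logit scale
with biological spread 0.15 (retention) and 0.25 (PSI) logits — values
chosen once so that sampling noise at the default depth and biological
spread contribute comparably, keeping the causal signal strong but not
deterministic; degenerate class means (0 or 100%) bypass the logit map
exactly.  Read depth per animal is negative binomial (size 50) with mean
5000 scaled by 2^(expression − grand mean), linking the expression
phenotype to sequencing depth.  Per junction, spliced reads are
Binomial(depth, 0.02), intron-touching reads Binomial(depth, retention),
split 50:50 between donor-boundary-crossing and fully intronic reads;
alternative- vs reference-donor reads follow the animal's PSI.

Reads are single-end, fixed 100 bp — a deliberate simplification of
paired-end sequencing; fragment-level effects are out of scope.  Two
equivalent outputs exist: a read-level simulator emitting sorted RG-tagged
SAM plus a per-read truth table (every emitted junction-local read's true
class equals the classifier's output on it, exactly), and a count-level
fast path drawing the same binomial tallies directly, used for
cohort-scale replication studies.  qPCR plates simulate the same
standard-curve model that the analysis fits (efficiency 0.95, well noise
0.15 cycles, per-sample×assay biological CV 5% — together ≈10%
between-sample ratio CV, matching the printed in-vitro dispersion — and a
per-sample loading factor that the reference normalisation must cancel);
mini-gene allele ratios default to the printed per-junction values
(e.g. 28.49 vs 5.55 at intron 7).  Per-allele sample count defaults to 3
preparations × 3 wells.

All randomness flows from one master seed through named per-component
generators, so each sub-simulation is reproducible in isolation.

### What the generator does not emulate

No sequencing errors, base qualities or mapping ambiguity; no paired-end
fragments; no pedigree relatedness (the random-intercept model is validated
on generic groups); no isoform complexity beyond one alternative donor; no
real genomic sequence (the toy contig is random with the exon-8 context as
the only meaningful sequence).  Passing tests therefore demonstrate that
the estimators recover the generating process and that the statistical
machinery is calibrated — not that read classification is robust to
alignment artefacts in real BAMs, which should be assessed on real data
with the configurable anchor and flag filters.

## Problem sizes used in validation

Cohort-scale replication uses the count-level path: 100 cohorts of 375
animals × 200 markers for causal-rank recovery and conditional clearance.
The generator/classifier round trip materialises ~1.9 × 10⁵ reads (14
animals at depth 15 000) and checks every junction-local read exactly.
Null calibration uses 375 × 1000 independent markers × 5 phenotype draws;
qPCR replication uses 100 plates.  These sizes make the whole validation
suite run in well under a minute on one CPU while keeping Monte-Carlo
margins comfortable for the stated pass fractions.

## Numerical and degenerate-input choices

Division guards return NaN (missing) rather than raising: efficiency with
zero denominator and zero pseudocount, PSI with no informative read,
intron percentage with no gene read, LD with a monomorphic marker.
Monomorphic and covariate-collinear markers are reported with an explicit
reason instead of a fabricated statistic.  p-values are floored at the
smallest positive float to keep ranks well-defined.  Ranking breaks p-value
ties by genomic position then marker id, so results are deterministic
across runs and platforms.
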