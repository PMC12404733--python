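# Methods

## Reference model

An *isodecoder* is a mature tRNA transcript; isodecoders sharing an anticodon
form an *anticodon family* (isoacceptor pool).  Coordinates are 0-based and
half-open; the wobble position 34 is taken from the annotation (the index of
the anticodon's first base), never inferred from secondary structure.  The
internal alphabet is DNA (U→T on load); codons are rendered as RNA only in
exports.  Mitochondrial records are loaded and countable for QC but excluded
from ADAT-target classification and all I34 statistics, which concern
nuclear-encoded tRNAs.

ADAT targets are the families whose anticodon starts with A.  Decoded codons
of an I34 anticodon have bases 1–2 Watson–Crick-complementary to anticodon
bases 36–35 and base 3 ∈ {U, C, A}.  A decoded codon is *dependent* if no
other anticodon in the organism's table reads it under the wobble read-sets

| anticodon base 34 | reads codon base 3 |
|---|---|
| A (edited to I) | U, C, A |
| G | C, U |
| C | G |
| U | A, G, U |

The U34 read-set includes U (modified-uridine wobble in 4-codon boxes);
with the strict {A, G} set the U-ending codons of the ANN boxes would come
out dependent as well, contradicting the biological observation that only
the C-ending codons strictly require I34.  With the packaged standard
eukaryotic cytoplasmic anticodon table (45 anticodons) every one of the
eight ANN families has exactly one dependent codon: GCC, CGC, AUC, CUC,
CCC, UCC, ACC, GUC.

## Synthetic data

The simulator stands in for the study's sequencing libraries and records
every planted parameter (`GroundTruth`).  All randomness derives from a
mandatory seed; outputs are byte-reproducible.

* **Counts.** Isodecoder counts are negative-binomial with mean
  μ·sf (per-replicate lognormal size factors, geometric mean 1) and
  dispersion α (variance μ + αμ²; α=0 is Poisson).  Case-condition means are
  scaled by 2^log2FC.  Defaults: 3 replicates per condition, α=0.05 for the
  demo experiment (deep tRNA-seq libraries of cell lines are highly
  reproducible; dispersion at high counts is typically a few percent),
  depth 10⁶ reads per replicate (tests and the demo use 5–50 k to stay
  desk-sized; depth mainly scales coverage, not structure).
* **Reads.** The read model is full-length-biased, mirroring tRNA-seq RT
  chemistry: reads start at the 3'CCA and extend toward the 5' end.  Each
  annotated modification site stops the RT with probability 0.08 (first stop
  from the 3' side wins; the read then starts one base 3' of the site) or,
  if passed, misincorporates at rate 0.25.  The wobble base of an ANN read is
  G with probability θ (the planted I34 stoichiometry), else A.  Uniform
  substitution errors (rate 0.002) apply everywhere else; there are no
  indels, adapters or UMIs, and quality strings are constant.  With ~5 mod
  sites per demo reference this yields ~67% full-length reads and >99%
  CCA-tailed full-length reads, matching the QC ranges a real library of
  mature tRNAs shows.
* **Coupling.** Planted (ΔI34, Δabundance) pairs come from a Gaussian copula
  with Pearson correlation 2·sin(πρ/6), which gives Spearman ρ exactly.
* **Gene sets.** Background genes draw codons uniformly within each
  synonymous family; target-set genes multiply the odds of every
  ADAT-dependent codon by a configurable factor (default 1.5) and
  renormalize within the amino-acid family.  Gene lengths are uniform over
  150–500 codons; amino acids are uniform over the 20.  Real codon usage is
  neither uniform nor independent across positions — the generator tests the
  statistics, not genome realism.

## Read assignment

Reads are 3' suffixes of references in this protocol, so scoring is
3'-anchored: a read of length ℓ is compared with the terminal ℓ bases of each
reference and scored by its non-exempt mismatch count.  Mismatches at
annotated modification sites, and at the wobble position of ANN families, are
exempt (`mod_site_free`): the modification signal itself must not penalise
assignment.  The minimum score wins if ≤ `max_mismatch` (default 3; tRNAs are
~76 nt and the exemptions already absorb the expected signal).  Ties within
one family get equal fractional weights; ties across families are dropped as
`ambiguous_cross_family` — no expectation–maximization rescue is attempted.
If no reference scores within bound, a single terminal indel (read or
reference trimmed one base at the 3' end, cost 1) is tried; internal indels
are not modelled, matching the substitution-only error model.  Pileups
accumulate only from assigned reads, weighted by assignment fraction.

QC definitions: unique fraction over all reads; nuclear-mapped and
full-length (5' end reaches position 0) fractions over assigned reads; CCA
fraction over full-length reads.

## I34 quantification

θ̂ = G/(G+A) at the wobble position; C and T calls there are sequencing
error and excluded from the denominator (the editing proxy is G-vs-A).
Confidence intervals are Wilson 95% — stable at θ̂ near 0 and 1, where
control pools sit.  Units with informative coverage G+A < 20 are
`low_coverage` with no estimate.  Anticodon pools are coverage-weighted
means of member proportions, identical to calling on the summed counts;
pooling across replicates sums pileups first (counts are sufficient).
Condition deltas are reported in percentage points, and as
log2(θ̂_case/θ̂_control) (θ floored at 10⁻³) for the coupling stage.
Truncation at position 34 is not treated as an inosine signal.  In vitro
deamination curves are the same arithmetic on assay base-count tables:
editing fraction G/(G+A) per enzyme and concentration, relative activity as
the ratio to the reference enzyme at matched concentration.

## Differential abundance

Median-of-ratios size factors (median over all-positive units of
count/geometric mean).  Per-unit NB dispersion by method of moments pooled
within conditions — α̂ = Σ_c df_c(s²_c − m_c) / Σ_c df_c m_c², using
per-condition means so real condition effects do not inflate α — then shrunk
with weight w = 0.5 toward a parametric trend a₀ + a₁/m fitted across units.
Each unit is tested with a two-group NB GLM (log link, size-factor offsets;
statsmodels); the Wald statistic on the condition coefficient is referred to
a t distribution with df = df_residual/(1−w)² = 16 at 3 vs 3: shrinkage
scales the dispersion-estimate variance by (1−w)², and a plain normal
reference is measurably anticonservative at these replicate numbers.
Reported log2FC is the ratio of size-factor-normalized group means (exactly
level-invariant for single-member families; pseudocount 0.5 only when a
group mean is zero); BH adjustment across tested units; significance fixed
at padj < 0.05.  Fractional counts from tied assignments are kept exact for
normalization and rounded to integers only for the likelihood.  Calibration
and power are verified by simulation in the acceptance suite: type-I rate
≈ 0.045–0.056 under an α=0.1 null at 3 vs 3, and a planted 2-fold depletion
of the eight ANN families at depth 10⁵ and α=0.02 is recovered (≥6/8
families) in essentially every run.

## Coupling and enrichment

Spearman correlation between per-unit ΔI34(log2) and Δabundance(log2), both
case-minus-control, so a positive r means greater editing loss accompanies
greater abundance loss.  Significance by unit-label permutation,
p = (1 + #{|r*| ≥ |r|})/(1+B), never exactly zero.  Default B = 10,000.

Codon usage: per gene and ANN family, the dependent-codon count over all
codons of the family's decoded box (terminal stop codons excluded; genes
with frame violations or internal stops are skipped and reported).  The
enrichment statistic is the mean usage share over the gene set; the null is
B random same-size subsets of the background universe (optionally
length-matched by CDS-length decile), one-sided by default per the
directional hypothesis, with the add-one rule.  Bands are reported at
p < 0.05 (significant) and p < 0.1 (trending).

## Numerical and design notes

* Seeds: every stochastic routine takes an explicit seed or derives one from
  the run seed via `SeedSequence`; replicate FASTQ streams use a CRC of the
  replicate name so column order is irrelevant.
* Problem sizes in tests and the acceptance script (e.g. 500 repetitions of
  the stoichiometry grid at the pileup level rather than 500 full FASTQ
  simulations, 5–50 k reads per replicate, 20–50 simulation runs per
  calibration check) were chosen so the whole suite runs on one CPU in a few
  minutes; read-level recovery is exercised once end-to-end rather than
  inside every repetition.
* Degenerate inputs: empty references, constant delta vectors, gene sets
  < 5 genes, all-zero count rows and zero-coverage assay rows are rejected
  or excluded with explicit reporting rather than silently propagated.
* Known limitations: no indel or adapter/UMI modelling; no EM resolution of
  cross-family multi-mappers; dispersion trend is parametric (a₀ + a₁/m)
  rather than locally fitted; passing the simulation-based checks shows the
  estimators are correct under the generative model, not that real libraries
  meet its assumptions (uniform errors, substitution-only, annotation-exact
  modification sites).
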