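# Methods

`parpomics` re-implements, as a tested library, the pre-treatment
multi-omic biomarker analysis of germline-*BRCA*-mutant breast tumors
treated with a neoadjuvant PARP inhibitor: genomic "scar" statistics
from allele-specific copy number, consensus somatic-variant filtering
and tumor mutation burden (TMB), mutational-signature refitting,
preranked gene-set enrichment, and a composite resistance classifier.
The raw sequencing data behind such studies is controlled-access, so a
first-class synthetic-data module generates every input with attached
ground truth; this note records the models, the parameters that
matter, and the design choices made where the procedures left room.

## Response dichotomy

Pathologic response is graded by residual cancer burden (RCB).
`dichotomize_response` maps pCR and RCB-I to SENSITIVE and RCB-II/III
to RESISTANT; a `pcr_only` mode compares pCR against everything else.
Group contrasts (`group_compare`) use the unpaired two-sided Student's
t test with pooled variance and n1+n2−2 df; fold changes are reported
on the linear scale in both directions (so "2.2× lower in resistant
tumors" is mean(sensitive)/mean(resistant) = 2.2). Zero pooled
variance with unequal means is flagged degenerate (p = NaN) rather
than silently coerced.

## Copy-number scar scores

All scores operate on allele-specific segments (1-based inclusive,
`major_cn ≥ minor_cn ≥ 0`) and are restricted to autosomes 1–22; sex
chromosomes stay in the profile but never enter a score. The genome
build supplies chromosome lengths, centromere intervals and the
acrocentric set ({13, 14, 15, 22} in the hg19-like build).

**wGII.** The sample's reference level is the length-weighted median
total copy number over autosomal segments, with the *lower* median
taken when the weight splits evenly (a deterministic, documented tie
rule). Per autosome present in the profile, the altered fraction is
(segmented length with total CN ≠ median) / (segmented length); the
score is the unweighted mean of those fractions, so long chromosomes
do not dominate. The denominator is segmented length, not chromosome
length, because exome-derived segmentation leaves gaps.

**LST.** Per chromosome: merge consecutive segments with identical
(major, minor) profiles; drop segments shorter than 3 Mb entirely
(rather than smoothing them into neighbours); re-merge; then count
every segment ≥ 10 Mb whose adjacent neighbour is also ≥ 10 Mb, has a
different allele profile, and lies within a 3 Mb gap
(`start_next − end_prev − 1`). Both members of a qualifying pair
count; a segment with qualifying neighbours on both sides counts once.
Choices made where the procedure is under-specified: (i) counting is
per chromosome, not per arm — a `per_arm` flag splits segments at the
centromere for the arm-level variant; (ii) short segments are dropped
*after* the first merge and the list re-merged (`drop_before_merge`
exposes the other order); (iii) merging joins same-profile neighbours
across unsegmented gaps, which for capture data are small; (iv) a
surviving ≥ 3 Mb segment between two long segments blocks their
pairing, as under the original smoothing.

**TAI.** For each chromosome end — skipping p-termini of acrocentric
chromosomes, which have no capture coverage — take the maximal run of
consecutive segments, starting from the terminal segment, with
major ≠ minor. The end scores 1 if the run is non-empty and stops
strictly before the centromere; a run touching or crossing the
centromere scores 0 at both ends. The terminal segment of a profile is
treated as reaching the telomere (exome segmentation never reaches
literal chromosome ends; otherwise TAI would be identically 0). There
is no minimum run length.

Each score has an independent naive oracle (`parpomics.oracles`):
per-base expansion for wGII on small builds plus a separate
segment-walk for large ones, all-pairs enumeration for LST, and run
enumeration for TAI. Equivalence is asserted on hundreds of seeded
random profiles.

## Consensus variants, TMB, catalogs

Somatic SNVs carry support from up to six callers (MuSE, MuTect,
MuTect2, SomaticSniper, Strelka2, VarScan2 — configurable). The
consensus filter keeps records with ≥ 2 callers, depth ≥ 20 and
VAF ≥ 5%; the mutation-burden path additionally requires a
nonsynonymous consequence, while the signature path keeps all
consequence classes. The VAF used for thresholding is recomputed as
alt_reads/depth (callers disagree on VAF definitions); the stored
column is validated against it to 0.01. TMB is the surviving
nonsynonymous count divided by the unique targeted exome size in Mb,
computed as the merged-interval union of a standard BED (0-based
half-open, converted internally to 1-based inclusive).

Catalogs are 96-channel pyrimidine-centred trinucleotide counts in a
fixed lexicographic order over (substitution, 5' base, 3' base);
purine-reference SNVs are reverse-complemented into the pyrimidine
frame. The trinucleotide context is an input column — deriving it from
a reference FASTA is out of scope — and a context whose middle base
contradicts the reference base is an error naming the record.

## Signature refitting

Exposures are estimated by constrained least squares on the
96-simplex: the catalog (optionally multiplied channel-wise by a
96-vector context scaling, e.g. an exome-to-genome
trinucleotide-frequency correction; identity by default) is normalized
to sum 1 and approximated by a nonnegative combination of reference
profiles with total weight ≤ 1. The optimizer is greedy coordinate
descent: each iteration re-solves the single best signature weight in
closed form on its admissible interval and stops when the residual
norm improves by under `tol` (default 1e-3 on the norm scale, the
scale on which the reference tool's threshold operates). Weights below
0.06 are zeroed — exposures that small are indistinguishable from
noise at exome catalog sizes — and survivors are rescaled to the
pre-discard total. The procedure is deterministic, invariant to
reference ordering (ties broken by signature name), and its residual
never increases across iterations.

The bundled reference (`data/synthetic_signatures.tsv`) is
**synthetic**: four near-orthogonal profiles, each concentrating 95%
of its mass on ten peak channels over a flat background, mimicking the
sparsity of real single-base-substitution signatures. Real references
in COSMIC-v2-style TSV (channel column + one column per signature)
load through the same reader.

## Expression, ranking, GSEA

Counts convert to log2(TPM+1) with per-kilobase rates normalized per
sample. Genes are ranked by the Welch t statistic (SENSITIVE minus
RESISTANT) on log2 TPM — a deliberate replacement for a count-model
Wald statistic, whose dispersion machinery is out of scope; on the
synthetic data the two agree in rank direction. Zero-variance genes
rank 0 by convention. Ties break lexicographically by gene id, making
every ranking strictly deterministic.

The enrichment score is the classic weighted Kolmogorov–Smirnov
running sum (hit increments ∝ |statistic|^p, p = 1 by default; miss
decrements 1/(N−|S|)); ES is the signed value at maximal absolute
deviation, computed in closed form from hit positions. The null
permutes gene labels — the natural null for a preranked analysis;
n_perm (default 1000) and the seed are parameters, and one label
permutation per iteration is shared across sets. NES divides ES by the
mean |null ES| of matching sign; the nominal p is the matching-sign
tail frequency with +1 smoothing; Benjamini–Hochberg adjusts across
scored sets. Sets below `min_size` (5) after intersection are skipped
with a log line. The leading edge is the in-set genes at or before the
running-sum peak (positive ES) or at or after the trough (negative
ES). The ES implementation is cross-checked against the Bioconductor
reference implementation in the test suite. Because p-values of many
sets scored on one ranking share the permutation null, they are
correlated — calibration checks that assume independence must use
independent rankings.

Over-representation of a gene list against a background uses the
one-sided hypergeometric tail with BH adjustment. Per-sample signature
scores are the mean over set genes of row-wise z-scored expression
(sample sd; zero-variance rows contribute 0) — the simplest
transparent choice among unstated scoring schemes.

## Composite resistance classifier

Three per-sample flags feed a disjunction: shieldin loss (SHLD2
copy-number below the sample's median total CN at the configured
locus **and** expression z below −1 — concomitance is required),
hypoxia-high, and EMT/stem-high (signature score above a cutoff,
default 0, i.e. above the cohort mean). Predicted RESISTANT iff any
flag is set. An unresolved flag (e.g. no segment covering the SHLD2
locus) excludes the sample with a log line rather than guessing. The
score cutoffs are config knobs; the synthetic cohorts plant effects
(≥ 2 SD) robust to the default.

## Synthetic data

Generators are pure functions of (parameters, seed); truths are
re-verified against the naive oracles before return.

* **Profiles** (toy build: three 200 Mb chromosomes, centromere at
  90–100 Mb, chromosome 3 acrocentric — small enough for tractable
  oracles): diploid (1,1) baseline; each planted LST pair is two
  abutting 12 Mb segments with profiles (2,1)/(3,1) isolated by > 3 Mb
  unsegmented gaps (contributing exactly 2); each planted TAI run is a
  terminal copy-neutral LOH segment (2,0) ending before the
  centromere (contributing exactly 1). `random_profile` adds
  unstructured random segmentation for oracle-equivalence testing.
* **Catalogs**: multinomial draws from Σ wᵢ·profileᵢ.
* **Expression**: Gaussian on the log2 scale — per-gene baseline
  N(8, 2), noise sd 1 by default — with planted sets shifted by
  `effect_log2` (2 by default, i.e. 2 SD at the default noise) in the
  associated response group. A negative-binomial count layer is
  deliberately omitted: the analysis ranks log2 TPM, so Gaussian
  log-scale structure is the minimal model the method assumes. Passing
  tests therefore demonstrate correctness of the statistics, not
  robustness to count overdispersion, library-size artifacts or batch
  effects of real RNA-seq.
* **Variants**: six callers support independently (p = 0.5 default),
  depth ~ Poisson(40) floored at 1, latent VAF ~ Beta(2, 5) with
  alt_reads the rounded product, 70% nonsynonymous. The surviving
  fraction under the consensus filter has a closed-form independence
  product (`expected_survival_fraction`) evaluated with a
  rounding-aware Beta tail inside a Poisson sum over depth.
* **Biomarker cohorts** (default n = 13 with 6 resistant, matching a
  small neoadjuvant trial): each resistant sample receives one primary
  biomarker, cycling through the three so each has ≥ 2 carriers, plus
  occasional extra hypoxia/EMT flags (p = 0.25). Extra *shieldin*
  flags are never added: the single-gene z-score saturates once most
  of a small cohort loses the gene, and recurrent loss in a minority
  of resistant tumors is also the realistic pattern. Shieldin loss is
  planted as a (1,0) deletion spanning the SHLD2 locus plus a −4 log2
  expression shift; hypoxia/EMT as +2 log2 shifts of their 30-gene
  sets; measurement noise sd 0.5.

## Numerical and degenerate-input conventions

Coordinates: 1-based inclusive internally; BED read as 0-based
half-open. A gene set equal to the whole ranking has ES = 1 by
convention (no misses to decrement). A catalog with zero total cannot
be refit (error). "ER 5% weak" immunohistochemistry counts as ER+
(any nonzero positivity). Cohort percentages round to the nearest
integer, half away from zero. All randomness flows through
numpy `default_rng` seeds; fixed seeds give bit-identical outputs,
including GSEA p-values.

## Problem sizes

The test suite and the acceptance script run at the scales the
package's guarantees are stated at: 200 random profiles for scar-score
oracle equivalence, 50 multinomial catalogs (n = 2000) for refit
recovery, 20 seeded cohorts for planted-GSEA detection and for the
classifier's operating characteristics, n_perm = 1000 for permutation
nulls, and 5000 variants for the consensus-filter calibration.

## Known limitations

Copy-number inference, alignment, variant calling and annotation are
upstream and out of scope — consequence classes and allele-specific
segments are inputs. The refit does not model the sampling likelihood
(no multinomial deconvolution or confidence intervals); signature
scores are not purity-corrected. The GSEA null is gene-label
permutation, not sample permutation, and the adaptive multilevel
p-value refinement of modern implementations is not reproduced. The
composite classifier's cutoffs were chosen for transparency, not tuned
on real cohorts; on data without planted effects its operating point
depends on them.
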