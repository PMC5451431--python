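# Methods

## Overview

`kmergt` genotypes *previously known* bi-allelic SNVs directly from raw
FASTQ reads, without mapping.  Each marker is represented by up to three
k-mer pairs: two k-mers of length k (default 25) that are identical except
at the variant base, one carrying the reference allele (A) and one the
alternative allele (B).  If such a pair is unique in the genome, the
occurrence counts of its two members in a read set measure the number of
haplotype copies carrying each allele, and a probabilistic model of those
counts yields the genotype.  The package is a re-implementation of this
idea with its three components: database compilation, k-mer counting, and
empirical-Bayes calling, plus a read simulator that makes the whole stack
testable without external data.

## Marker database compilation

Given a reference genome and a variant list (VCF or TSV), markers are
selected in three steps.

1. **Neighborhood.**  An SNV is kept only if no other variant (SNV position
   or indel-occupied base) lies within k bases on either side.  This
   guarantees at least one k-window covering the SNV overlaps no other
   variant, and avoids enumerating combinations of neighboring alleles.
   With full flanks an SNV is covered by exactly k candidate pairs; near
   window boundaries fewer.

2. **Uniqueness.**  Candidate pairs are tested against the *expanded
   reference*: the multiset of all reference k-mers plus every alternative
   k-mer of every known SNV and indel.  A pair survives iff each member
   occurs at most once (its own locus).  All k-mer identity here — and
   everywhere in the package — is **canonical**: a k-mer is represented by
   the lexicographic minimum of itself and its reverse complement, packed
   two bits per base into a 64-bit word.  Reads come from both strands, so
   non-canonical counting would halve counts and miss reverse-complement
   collisions.  Surviving pairs are additionally flagged `mismatch_unique`
   when no *other* expanded-reference k-mer lies within Hamming distance 1
   of either member (the partner k-mer at the same locus, which is at
   distance 1 by construction, is discounted).  Such pairs are robust to a
   single sequencing error or point mutation creating a colliding k-mer.

3. **Panel (optional).**  When counts for a panel of sequenced individuals
   are available, markers are removed that (a) show chrY signal (any count
   > 3) in more than one woman, (b) show counts above 3x an individual's
   median autosomal depth in more than one individual, or (c) produce
   non-canonical genotypes in more than one individual.  These symptoms
   indicate loci unique in the reference but duplicated or deleted in real
   genomes.  The pipeline runs with steps 1-2 only when no panel exists.

Up to `max_pairs` (default 3) pairs are selected per marker,
deterministically: mismatch-unique pairs first (a soft preference, not a
hard filter), then by centering of the variant base in the k-mer
(|offset − (k−1)/2| ascending), ties broken toward the smaller offset.
Centered k-mers balance the flanking context on both sides; the rule is
a design choice — any deterministic rule over the candidate set works.
Multiple pairs guard against the loss of a single k-mer through a rare
neighboring mutation.

## Counting

The counter stores **only** database k-mers: a first-level index on the
first `min(14, k)` bases (prefix grouping over the sorted code array) and
sorted suffix ranges below it, with one 16-bit counter per distinct
canonical k-mer.  Memory is proportional to the database size and
independent of read-set size or coverage.  Counters saturate at 65535
rather than wrap; counts that large are orders of magnitude beyond any
genotyping-relevant depth (and would be removed by the 3x-median panel
criterion anyway).

Reads are streamed in batches; each batch is joined with `N` sentinels so
one vectorized rolling-encoding pass produces every window k-mer, windows
containing non-ACGT characters are dropped by a validity mask, lowercase
is upcased, and quality strings are ignored.  Counting is exactly
order-independent, invariant to splitting input across files and to
reverse-complementing reads (asserted against a naive
dictionary-of-substrings oracle in the tests).

## The genotype model

For one individual, the count x of a k-mer present in c haplotype copies
is modeled as negative binomial,

    x ~ NB(mu(c), alpha_c),   mu(c) = eps + c * lambda / 2,
    Var[x] = mu (1 + alpha_c mu),

with eight parameters:

| parameter | meaning | typical fitted value (30x) |
|---|---|---|
| `lambda_` | mean depth per locus (per-copy mean is lambda/2) | ~20.5 |
| `alpha`   | overdispersion, copies >= 1 | ~0.0-0.05 |
| `epsilon` | mean spurious count of a 0-copy allele (error leak) | ~0.03 |
| `alpha0`  | overdispersion of the 0-copy distribution | ~0.0-0.1 |
| `pi_AA, pi_AB, pi_BB` | priors of the canonical diploid classes | data-driven |
| `pi_NC`   | total prior of all non-canonical classes | small |

`lambda_` is the *effective* k-mer depth: nominal coverage C is attenuated
by the window factor (L−k+1)/L (a 25-mer must fit inside a 100-nt read)
and by (1−e)^k (an error anywhere in the window destroys the k-mer), about
0.67 overall at e = 0.005 — the model never needs to know C, it estimates
lambda from the data.

A genotype is a pair of allele copy numbers (cA, cB) with cA + cB <= 4 (15
classes), so mono-, tri- and tetra-allelic states — deletions and
duplications — are representable.  Canonical diploid classes are
AA = (2,0), AB = (1,1), BB = (0,2); the remaining 12 classes share `pi_NC`
uniformly.  The MAP class under Bayes' rule is reported; a non-canonical
MAP is printed as NC ("no call") in default output, with copy numbers and
full posteriors available in full output.  There is no posterior cutoff by
default (an optional `--min-posterior` adds one).

### Combining a marker's pairs

A marker's up-to-3 selected k-mer pairs all contain the same variant base
and are counted from the *same reads*: one read covering the SNV
increments every pair whose window it contains error-free.  Per-pair
counts are therefore near-duplicate observations, not independent ones —
treating them as independent multiplies the evidence of every single read
by the pair count, which audibly misbehaves at low coverage (a single
error read at the SNV position would flip a homozygous-reference marker to
AB).  The classifier therefore reduces the pairs to **one effective
observation per allele — the median of the per-pair counts, rounded to the
nearest integer** — and applies the model to that.  The median is also
robust to the loss of one k-mer through a rare flanking mutation, which is
the reason several pairs are kept at all.  A `pair_agreement` flag records
whether each pair alone supports the same class; disagreement indicates a
locally damaged locus.  The likelihood primitive
(`genotype_log_likelihood`) itself scores any supplied set of observations
as conditionally independent, which is exact for the single effective
observation fed to it.

### Empirical-Bayes estimation

All eight parameters are estimated per individual from its own counts at
up to 100,000 autosomal markers (subsampled deterministically when more
are available) by EM over the 15 copy-number classes:

* E-step: class responsibilities from the current parameters.
* M-step: `epsilon` = responsibility-weighted mean of 0-copy counts;
  `lambda` from a weighted regression of (x − eps) on copy number;
  `alpha`/`alpha0` by weighted method of moments on ((x − mu)² − mu)/mu²,
  clamped to [0, 10] and [0, 100]; priors = mean responsibilities, floored
  at 1e-10 and renormalized (the floor keeps log-priors finite when a
  class is absent, e.g. pi_AB in a homozygous-reference genome).
* Initialization: lambda = median marker depth, eps = 0.1,
  alpha = alpha0 = 0.05, priors (0.6, 0.2, 0.1, 0.1).  Convergence when
  the largest relative parameter change is < 1e-6, at most 200 iterations.

Parameter recovery on model-simulated counts is tested: lambda within 3%
at 50k markers, class priors within 0.02 absolute, across lambda 10-40.
Fitted parameters can be saved to a key=value text file and re-used.

### Sex and the haploid model

Sex is inferred from median(chrX marker depth) / median(autosomal marker
depth): one X copy halves the numerator, so the ratio sits near 0.5 for
males and 1.0 for females; the decision threshold 0.7 is the midpoint, and
ratios in [0.65, 0.75] log a warning.  At least 100 chrX and 100 autosomal
markers are required.  For males a haploid model (canonical classes
A = (1,0), B = (0,1); the heterozygote prior mass joins the non-canonical
pool) is fitted on up to 100,000 chrX markers and applied to chrX and chrY;
when too few chrX markers are available (< 1000 with signal) the pipeline
falls back to the diploid parameters with haploid class structure.
Females get no chrY calls at all.

## Read simulator

The simulator emulates whole-genome-shotgun benchmarking: uniform-random
ACGT reference; SNV markers placed on a jittered grid with spacing >= 2k
(so the whole marker set survives database compilation and every marker
has a full candidate-pair set); genotypes drawn i.i.d. from configurable
class frequencies (hemizygous chromosomes draw a single allele at the
implied allele frequency); paired 2 x 100 nt reads with fragment length
Normal(500, 50) truncated to >= 2 reads, fragments placed uniformly across
haplotype copies, and uniform per-base substitution errors at rate 0.005
(the error regime of the short-read instruments this method targets).

Deliberately **not** modeled: indel sequencing errors, quality-score
structure and miscalibration, GC/coverage bias, repeats and segmental
duplications, contamination, real linkage structure.  Consequently,
passing simulation tests demonstrates the correctness and the
coverage-behavior of the counting and calling machinery on a clean
genome; it does not bound error rates on real genomes, where repeat
structure (the reason for filter steps 2-3) and coverage bias dominate.
Random 2 Mb sequence is nearly repeat-free at k = 25, so the uniqueness
filter removes almost nothing here; its behavior is exercised by dedicated
repeat-construction tests instead.

## Study conditions and expected numbers

The packaged accuracy studies (`kmergt.experiments`,
`scripts/acceptance.py`) use a 2 Mb genome (two 900 kb autosomes, 150 kb
chrX, 50 kb chrY) with ~12,000 markers (>= 10,800 autosomal), k = 25, and
the 5/10/20/30/40x coverage series — sizes chosen so a full series runs
on a laptop-class single core in minutes while keeping >= 10^4 markers for
stable fractions.

Two regimes are measured:

* **Homozygous-reference individual** (genome == reference): the caller
  should invent nothing.  Across 5-40x the packaged study yields AA
  fractions >= 99.95% with zero BB calls and AB fractions at or near zero;
  because priors are estimated empirically from the same individual,
  pi_AB collapses to ~10^-3 or below and single error reads are absorbed.
* **Planted genotypes** (30% AB, 10% BB): sensitivity is coverage-limited
  below ~25x.  At the effective per-allele depth of 20x nominal coverage
  (~6.9) about 0.8% of heterozygotes yield an alternative-allele median of
  0 or 1; an alt median of 1 is *more* probable under AA-with-error-leak
  (P ~ 0.02) than under a heterozygote that produced a single read
  (P ~ 0.007), so the Bayes-optimal call for most of these is AA, and
  sensitivity lands near 99.5-99.6% at 20x, reaching ~99.98% at 30x.
  Pushing 20x sensitivity above 99.8% in this clean simulation would
  require calling alt-median-1 markers AB, which costs ~2% specificity —
  the two cannot be bought simultaneously at this depth.  Specificity
  stays above ~99.4% at 5x and above 99.9% from 20x.

## Numerical and formatting choices

* NB log-pmf via log-gamma, size r = 1/alpha, p = r/(r+mu); alpha = 0 is
  evaluated as the exact Poisson limit; mu = 0 is a point mass at zero.
* Effective counts: `floor(median + 0.5)` (median of 3 is already
  integral; the half-integer median of 2 pairs rounds half-up).
* Posterior normalization by log-sum-exp; class posteriors sum to 1 within
  1e-9 (tested).
* All text outputs are tab-separated with LF endings and fixed float
  formatting; database, counts, truth and calls files round-trip through
  their readers byte-identically, and pipeline re-runs with the same seed
  reproduce calls byte-for-byte.
* Every stochastic component takes an explicit integer seed;
  sub-seeds are derived arithmetically and kept below 2^31.

## Known limitations

* Known-variant genotyping only — no de novo variant discovery.
* Bi-allelic SNVs only; indels enter only as exclusion zones for k-mer
  selection.
* The candidate-pair selection rule and the exact eight-parameter form of
  the count model are this package's own design; other reasonable choices
  (e.g. different pair ranking, a posterior no-call cutoff) exist.
* The counter is single-process; throughput (~10-20 MB/s of FASTQ) is
  adequate for the packaged study sizes but not tuned for 100 GB read
  sets.
* Copy number is capped at 4 total; higher amplifications collapse onto
  the boundary classes.
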