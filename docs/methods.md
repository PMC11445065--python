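# Methods

## Problem and scope

The package surveys start-codon usage (ATG vs the alternatives GTG/TTG) at
specific regulator loci across bacterial genome cohorts, and implements the
arithmetic of in vivo competition experiments used to measure the fitness
consequence of a start-codon swap. Every stage is exercised on synthetic
genomes with planted ground truth; no external databases or aligner/gene-
finder binaries are invoked.

## Homology localization

Each reference gene (its full ORF, start through stop) is aligned to both
strands of every contig with an exact affine-gap Smith–Waterman
(Biopython `PairwiseAligner`, local mode). Scoring: match +2, mismatch −3,
gap open −5, gap extend −2; a gap of length L costs −5 −2(L−1); N is scored
as a mismatch against everything, including N. In place of an E-value the
reporter uses a score floor, by default 0.6 × match × |query| (≈ 70%
identity for an ungapped full-length hit). Only the optimal alignment per
strand is reported — downstream analysis consumes a single best hit per
(genome, gene), with ties broken by smaller subject start, then + strand,
then contig id. The best hit is excised with up to 75 nt of flanking
sequence on each side (clipped at contig edges) and reverse-complemented
for minus-strand hits so the gene always reads 5′→3′.

## Start + RBS model

Candidates are every in-frame ATG/GTG/TTG in the frame of the homology hit,
bounded above by the first in-frame stop at/after the hit start (the gene's
own stop) and below by any upstream in-frame stop inside the flank.

The scorer has two additive log-odds terms:

* **Start-codon prior** `w_start(c) = log( (n_c + 1)/(n + 3) / (1/3) )`
  over the annotated starts of one training genome (add-one smoothing
  against a uniform prior over the three codons).
* **RBS term**: for each Shine–Dalgarno-like k-mer (every 3..6-mer of the
  extended consensus AAGGAGGTGA) and each spacer bin
  ([3,5), [5,7), [7,9), [9,11), [11,13), [13,16) nt between motif 3′ end
  and start), the table stores
  `log( P(k-mer present in bin | annotated start) / P(present by chance) )`,
  with add-one smoothing and the chance term `1 − (1 − p_kmer)^width` from
  the training genome's base composition. A candidate's RBS score is the
  maximum table cell over all k-mer occurrences upstream of it; a candidate
  whose upstream window contains no vocabulary k-mer receives a fixed
  `no_motif_score` of −2.0. A trained "absent" log-odds was deliberately
  avoided: under smoothing it is unstable for rich vocabularies, while the
  constant guarantees such candidates fall below the RBS-presence threshold
  (default 0.0, i.e. motif evidence above background) deterministically.

Longer exact motif matches dominate short ones automatically because their
chance probability is smaller. Candidates with less upstream context than
the widest window (21 nt) are scored over what exists and flagged.

This scorer is a deliberately simple, fully specified stand-in for a
Prodigal-style start model: it reproduces the *structure* of such scoring
(codon prior + SD motif × spacer bin), not its numerics; percentage
thresholds are therefore calibrated on this model's own scale.

## Resolution and fractional counting

Three rules, applied to the scored candidates of one locus:

1. **Length**: ORF must span ≥ 90% of the best-hit length (shorter products
   are assumed non-functional fragments). Applied first; the order of rules
   1 and 2 is configurable and order-invariant on the default cohorts.
2. **Score**: retain candidates scoring within 80% of the best survivor.
   Log-odds scores can be negative, where a plain ratio is ill-defined, so
   all scores are shifted by −min(0, min score) + ε before the ratio test.
   This preserves the rule's intent (near-ties are retained) and reduces to
   the plain ratio when all scores are positive.
3. **RBS consistency**: if the top candidate has a predicted RBS, drop
   alternatives without one.

Each of the k retained candidates contributes 1/k (exact `Fraction`
arithmetic) to its codon class; {ATG, GTG, GTG} → 2/3 GTG + 1/3 ATG.
Human-readable reports truncate (never round) to two decimals — 0.66/0.33 —
while machine outputs keep full precision. Zero survivors yield an all-zero,
flagged call.

## Cohort aggregation and statistics

QC keeps a genome iff completeness ≥ 95, contamination ≤ 10 (the rule
excludes only values *larger than* 10), n_contigs ≤ 200, and genome size ≥
species median − 3 × MAD (raw median absolute deviation; the size rule
quantifies "exceptionally small for its species" deterministically).
Genus subsampling removes genera with < 10 genomes and uniformly downsamples
genera above 100 to exactly 100 (seeded, deterministic).

Usage aggregation averages per-genome fractional weights per gene
(optionally per gene × genus); every genome contributes equally. A
majority-call variant (each genome collapsed to its top class, ties split)
is available alongside, since headline "% non-ATG" figures can be defined
either way; the fraction-weighted definition is the default.

The Mann–Whitney U test is self-implemented: U from rank sums with midranks;
for n₁+n₂ ≤ 12 without ties the two-tailed p is exact by enumeration of all
C(n, n₁) rank arrangements (P(|U − μ| ≥ |u − μ|)); otherwise a tie-corrected
normal approximation with continuity correction (erfc-based tail). The suite
cross-checks it against both a from-scratch permutation oracle and
`scipy.stats.mannwhitneyu`.

Trees are consumed, never inferred. Input trees whose root has more than two
children are treated as unrooted and midpoint-rooted before any clade
reasoning (rooting affects monophyly; this choice is explicit), and
polytomies are resolved deterministically. Fitch small parsimony counts
union events on a postorder pass; monophyly of a state checks whether the
carriers' MRCA subtends exactly the carriers.

## Competition arithmetic

`cfu_WT = cfu_total − cfu_mutant` (a mutant count exceeding the total is an
error, never clamped); `C.I. = (cfu_mutant/cfu_WT) / (inoc_mutant/inoc_WT)`,
so 1 is fitness-neutral. A zero mutant count is reported as C.I. = 0 with a
below-detection flag (an optional pseudocount mode exists but is off by
default); a zero WT count is undefined and flagged. Group summaries use
medians, never raw-scale means. Barcode loads are qPCR fraction × selective-
plate cfu; reporter output is (fluorescence − autofluorescence)/OD, floored
at 0 with a flag. The autofluorescence control is an explicit input.

## Synthetic data generator

What it emulates: genome cohorts in which a shared ancestral regulator locus
— SD motif at a chosen spacer, chosen start codon, optional in-frame
secondary start within ten nucleotides, optional out-of-frame ATGTG overlap
whose ATG frame terminates at its second codon — diverges across genomes by
point substitutions, embedded in i.i.d. background at a configured GC.

Construction details that make planted truth exact: an in-frame TAA is
planted 24 nt upstream of the start so the candidate window is bounded; all
other in-frame triplets between that stop and the start are scrubbed of
start/stop codons; the first ~10% of the ORF (the span where a spurious
in-frame start would survive the length rule) is kept free of start codons.
Divergence masks the planted start/stop, SD motif and secondary-start bases
(switchable), and skips substitutions that would create an in-frame stop
inside a planted ORF — the purifying selection real regulator ORFs are
under; without it, a few percent divergence on a ~1 kb ORF truncates most
copies and the survey would measure ORF destruction rather than
start-calling accuracy. Genome 0 is always emitted undiverged and doubles
as the training/reference genome. Per-genome start-codon overrides allow
mixed-usage cohorts (e.g. 99.5% GTG / 0.5% ATG) around the shared ancestor.

What it does not emulate: indels, recombination, codon-usage bias, operon
structure, paralogy, or assembly artifacts. Passing tests therefore show
that the pipeline recovers planted signals under substitution noise — not
that its absolute accuracy transfers to real genomes.

Metadata defaults to passing QC (completeness 100, contamination 0, one
contig); failing genomes are produced only by explicit override, so QC is
tested deliberately rather than incidentally.

Competition simulation: the mutant:WT ratio in each sample is
true_C.I. × inoculum ratio, perturbed by multiplicative log-normal noise of
the configured CV with median 1 (σ = √ln(1+CV²)); total = mutant + WT, so
mutant ≤ total by construction, the noise-free C.I. recovers the truth
exactly, and the median over subjects is robust to noise.

## Study conditions (fixed designs in `survey.py`)

* Training genome: 80 genes, 120-nt ORFs, start usage 80/15/5 ATG/GTG/TTG,
  SD spacers uniform on 5–9 — E. coli-like initiation statistics at a size
  that trains the model in under a second.
* lacI-like cohort: 200 genomes, one 300-nt GTG regulator, AGGAGG at spacer
  7, divergence 0.03, 0.5% of genomes switched to ATG — the near-fixation
  regime reported for *lacI*-type loci, at desk-scale gene length.
* Category cohort: 20 carbohydrate regulators planted GTG vs 20
  carbohydrate-unrelated regulators planted ATG (150-nt ORFs, modes cycled
  negative/positive/bidirectional), surveyed over a genome panel and
  compared by Mann–Whitney on per-regulator non-ATG percentages.

ORF lengths and panel sizes are desk-scale choices — the calling logic is
length-agnostic and the statistics are computed from the generated cohorts
at run time.

## Numerical choices and edge cases

* Score-ratio ε = 1e-9; exact tie scores always co-retain (they
  fractionate).
* Fractions use rational arithmetic end to end; truncation to two decimals
  happens only at display.
* Alignment tie-breaks (start coordinate, strand, contig id) are a stated
  convention; the underlying data do not determine them.
* `align_local` refuses non-ACGTN symbols and empty sequences by name;
  hits with non-positive local score are unreportable and dropped.
* Exact MWU enumeration bound (n₁+n₂ ≤ 12) keeps worst-case enumeration at
  C(12,6) = 924 arrangements.

## Known limitations

* The start scorer is not Prodigal; its thresholds (80%/90%) operate on its
  own score scale and results are not numerically comparable to surveys run
  with Prodigal's internal scores.
* One best hit per (genome, gene): paralogs and pseudogenes beyond the best
  locus are logged, not analysed.
* Alignment reports one optimal local alignment per strand, not a full HSP
  list; for the single-locus surveys here that is the consumed information.
* Monophyly conclusions are conditional on the supplied rooting; midpoint
  rooting of unrooted inputs is a convention, not an inference.
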