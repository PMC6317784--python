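# Methods

This note records the models implemented in `retroquant`, the parameter
choices that matter, and what the synthetic-data tests do and do not
demonstrate about real data.

## Alignment model

Reads are aligned to a reference set (repeat-consensus library or genome)
on both strands with free end clipping.  The objective is an alignment
*score* — match +1, mismatch −2, insertion −3 per base, deletion −3 per
base (linear gap costs; no open/extend distinction) — and alignments are
canonical: they begin and end with an aligned base pair, so clips absorb
would-be terminal gaps.  `N` never counts as a match and is penalised as a
mismatch when aligned.

For every placement `(reference, strand, ref_start)` the representative
alignment is the lexicographic optimum: maximum score, then most aligned
read bases, then most matches, then fewest deleted bases.  Two filters are
evaluated on that representative, both inclusive:

* similarity = matches / (matches + mismatches + inserted + deleted bases) ≥ 0.9
* length fraction = aligned read bases / read length ≥ 0.9

The hit set is every accepted placement attaining the global maximum
score; a read is **unique** when that set has exactly one element,
**multi** otherwise.  `unique_only` mode discards multi reads (used for
consensus counting and locus mapping); `multi_random` mode assigns each
multi read uniformly at random among its best placements with a seeded
generator (used for the genome-mappable denominator).

Evaluating the filters on the best-scoring alignment, rather than
constraining the optimisation to filter-satisfying alignments, is the
behaviour of conventional read mappers: a read whose best alignment clips
11 of 100 bases *fails* the length-fraction filter even if a worse
alignment could stuff extra bases in as gaps.  This choice is what makes
the 90-vs-89-aligned-bases boundary sharp.

### Search and exactness

The DP scalarises the four-level lexicographic objective into one additive
`int64` value per cell (`value = (−score)·B³ − A·B² − M·B + D` with `B` a
power of two exceeding every component), runs in reversed coordinates so
per-start optima appear in single columns, and enters fresh starts only
through the diagonal transition (canonical ends).  Components decode
uniquely from the value; a cost cap prunes cells no accepted alignment can
pass through.

Two engines share these semantics.  The *exhaustive* engine scans entire
references.  The *seeded* engine (default above ~2 kb) finds candidate
windows by pigeonhole seeding — the read is cut into `⌊L/k⌋` non-overlapping
k-mers with `k` chosen so that any alignment passing both filters must
contain at least one exact k-mer match — prefilters windows with an
infix edit-distance bound (any accepted alignment has edit distance at most
`E_cap + C_max`, the mismatch-plus-gap budget plus the clip budget), and
runs the same DP inside merged windows with margins covering every
alignment of any candidate placement.  Both engines are therefore exact,
and the test suite asserts identity of both against an independently
implemented exhaustive numpy oracle on hundreds of randomized instances
(planted, mutated, reverse-complemented, N-containing and random reads).

## Quantification

* Per-consensus counts: unique reads only; reads ambiguous within or
  across consensuses are excluded.  Zero-count consensuses are retained.
* Normalisation: `count / total_mappable × 10⁶`, where `total_mappable`
  is the number of reads with any accepted genome placement
  (`multi_random` mode).  No length normalisation is applied.
* Region profiles: arithmetic mean of per-sample normalised vectors (mean
  of ratios).  Pairwise Spearman correlation uses average ranks; constant
  vectors yield NaN with a warning.
* Genomic context of a uniquely mapped read: exonic if its alignment
  overlaps any exon by ≥1 base, else intronic if inside a gene body, else
  intergenic.

## Locus analysis

Reads uniquely assigned to a family's consensuses are remapped to the
genome (unique matches only).  A read counts toward the annotated locus
containing its alignment midpoint — unambiguous for non-overlapping
annotations and insensitive to small boundary clips; unique reads whose
midpoint lies outside every locus are reported as off-annotation, not
dropped.  Overlapping annotation intervals are a validation error.

The transcription score is 0 below 3 reads and otherwise
`1 + min(4, ⌊log₁₀(count/3)⌋)` — log-decade bins anchored at the 3-read
detection floor (3–29 → 1, 30–299 → 2, … ≥30000 → 5), spanning the
three-orders-of-magnitude dynamic range typical of repeat-family
expression.  Bin edges are configurable.  The floor is applied to reads
pooled across the samples of one dataset (region).

Locus context is intronic (inside a gene body, no exon overlap, host gene
reported), intergenic, or exon-overlapping (flagged rather than forced
into the dichotomy).  Chromosome distributions report, per chromosome,
the fraction of annotated family bases and the fraction of uniquely
mapped family reads; chromosomes with reads but no content are reported —
that excess is the signature of locus-specific transcription.

## Group comparisons

Two-sided Mann–Whitney U; exact null distribution when `n_a·n_b ≤ 400`
and the pooled sample is tie-free, otherwise a normal approximation with
tie and continuity corrections plus an Edgeworth fourth-cumulant
refinement (closed form `κ₄ = −mn(N+1)(m²+n²+mn+m+n)/120`, tie-free
case).  The plain normal approximation deviates from the exact p by up to
~0.009 at n = 10+10; the refinement brings worst-case agreement to ~3×10⁻⁴
while converging to the plain approximation as n grows.  Significance is
declared at P < 0.05 and raw p-values are reported without
multiple-testing adjustment (the output records this caveat; a
Benjamini–Hochberg helper is available as an extension).  Compared
variables are the proportion of reads assigned to all repeat consensuses
and the normalised counts of each family of interest.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Genome**: uniform-random chromosomes (default 2 × 120 kb) with planted
  repeat copies and two-exon gene models, none overlapping.  Each copy is
  its family consensus mutated by per-base substitutions at the family's
  divergence rate (indels are not modelled), optionally truncated at one
  terminus (10–50% removed, floor at read length) — truncated copies are
  pseudoelements with the corresponding completeness flag cleared — and
  inserted on a random strand.  A configurable fraction of copies is
  embedded strictly within the intron of a host gene.
* **Expression**: each locus is transcribed with probability
  `fraction_transcribed`; transcribed loci draw a log-normal relative
  level (default log-sd 2.0, matching the several-orders-of-magnitude
  spread of real family expression).  Read origins are sampled
  proportionally to expression × locus length.
* **Mixture**: reads are a mixture of repeat transcripts, background gene
  transcripts (uniform over gene bodies, i.e. unspliced pre-mRNA; an
  exon-only switch exists) and genomic-DNA contamination (uniform over
  the genome).  At multiplier 1 the expected shares equal the configured
  `gdna_contamination` / `background_gene_fraction` / remainder; group
  multipliers scale family weights before renormalisation, so a 2×
  multiplier approximately doubles a small family's read share.  Host
  genes participate in background transcription, so intronic repeat loci
  can receive *gene-origin* readthrough reads — deliberate realism
  (pre-mRNA readthrough is a known source of intronic repeat signal);
  ground truth labels such reads by their gene origin.
* **Between-sample variability**: each sample draws a per-family
  log-normal factor (`expression_sample_sd`, default 0.3 on the log
  scale), so group comparisons face biological as well as sampling noise.
* **Reads**: fixed length (default 100 b), unstranded (either orientation
  with probability 0.5), per-base substitution errors at
  `sequencing_error_rate`, constant quality `I`; paired mode draws
  normal fragment lengths and emits synchronized mates.
* **Determinism**: one root seed; per-sample and per-purpose generators
  derive from it by CRC32 hashing of stable labels, so outputs are
  byte-identical across runs and adding samples does not perturb existing
  ones.

A counts-only cohort path (`simulate_cohort_counts`) draws per-sample
origin counts from the same origin-category distribution without emitting
sequences.  Statistical calibration (type-I error over 1000 null cohorts;
power over multiplier sweeps at 10⁵ reads × 30 samples) runs on this path —
the quantities under test are properties of the group-comparison statistics
on quantified values, and sequence-level simulation at that scale would add
nothing but alignment time.  Sequence-level fidelity of the full pipeline
is covered separately by the recovery, ambiguity and determinism tests.

### What the tests do and do not show

Passing tests demonstrate internal correctness — aligner exactness against
an oracle, filter boundary behaviour, normalisation identities, exact
recovery of planted transcription, calibrated type-I error, power, and
bit-level reproducibility — under the generator's assumptions: uniform
background genome, substitution-only divergence, non-overlapping loci,
no spliced reads, no quality-score structure, no library-preparation
biases.  Real repeat annotations contain nested and overlapping elements,
indel divergence and segmental duplications; absolute values from real
data (mappable fractions, repeat read shares, unique-mapping percentages)
will differ from synthetic ones, and the synthetic repeat share is
deliberately orders of magnitude higher than the ~0.1–0.2% observed in
real brain RNA-seq so that desk-scale simulations carry signal.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; BED is native,
  GTF is shifted on ingest.  Gene models are read from BED12 or a minimal
  GTF reader (exon features grouped by `gene_id`); a RepeatMasker `.out`
  converter is provided.
* Filter boundaries are inclusive, compared with a 10⁻⁹ epsilon so that
  exactly-0.9 ratios accept regardless of floating-point representation.
* Tie-breaks: hit lists are ordered by reference, strand (+ first), then
  start; multi-read choices use a seeded generator; Spearman uses average
  ranks; the traceback prefers diagonal over insertion over deletion
  transitions, deterministically.
* Degenerate inputs: empty extracted read sets give NaN unique-mapping
  fractions; a zero mappable-read denominator raises; constant profile
  vectors give NaN correlations with a warning; overlapping annotations
  raise naming the offending pair.
* Problem sizes in the test and acceptance suites (60 kb genomes, 3×20
  loci, a few thousand reads per sample, 10⁵-read counts-only cohorts)
  were chosen as the smallest scales at which the tested properties are
  non-trivial and stable under the fixed seeds.

## Known limitations

* No spliced alignment: reads crossing splice junctions of mature
  transcripts would be clipped or unmapped; the generator samples
  unspliced gene bodies by default for this reason.
* Reads ambiguous between overlapping or nested repeats are out of scope
  (the generator plants non-overlapping loci; user annotations are
  validated against overlap).
* Paired-end mates are aligned and counted as independent reads; no
  pairing constraint or fragment-level deduplication is applied.
* The Mann–Whitney Edgeworth refinement uses the tie-free fourth-cumulant
  formula; under heavy ties the tie-corrected variance is exact but the
  kurtosis term is an approximation.
* Quality scores are carried but ignored; no quality-aware alignment.
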