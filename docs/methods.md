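# Methods

## The problem

Small-RNA sequencing of human plasma yields millions of short reads
(~16–35 nt after trimming, averaging ~23 nt) of which a surprisingly small
fraction maps to the host: the rest, when screened against microbial and
food-species databases with exact matching, appears to be genuine exogenous
RNA (gut bacteria, fungi, dietary plants).  Defending that claim requires
three things beyond the classification itself: evidence that the mapping
procedure recovers essentially all genuine host reads despite sequencing
errors; a quantitative bound on how many "exogenous" calls mere chance
matching could produce; and a guard against cross-species misassignment
driven by ultra-conserved structural RNAs (rRNA/tRNA).  This package
implements the classification and all three defenses as one auditable,
fully synthetic-testable pipeline.

## The map-and-remove cascade

Reads are screened against an ordered list of reference tiers; a read with
at least one valid placement in the current tier is assigned that tier's
category and removed from the stream, so it is never tested against later
tiers.  The canonical order is:

1. host miRNA — exact match only
2. host transcripts — Strategy-controlled tolerance
3. host genome — Strategy-controlled tolerance
4. microbiome — exact
5. miRNA of other species — exact
6. nt collection (everything else) — exact

Survivors of the last tier are "unmapped", a first-class category.
*Strategy s ∈ {0, 1, 2}* is the Hamming-distance allowance applied to the
strategy-controlled host tiers only.  miRNA tiers are always exact because
mature miRNA family members differ by very few bases; exogenous tiers are
always exact because cross-species similarity makes tolerant matching
unreliable.  All three strategies are run on the identical processed-read
set, so strategy sweeps are comparable read-for-read.

Consequences that the suite tests as invariants: category counts always sum
to the processed-read count; raising the Strategy can only grow the
endogenous fraction and shrink (or leave unchanged) every exogenous and the
unmapped fraction; read order never matters.

## Matching: pigeonhole seeding, verified exactly

The matcher is deliberately not a heuristic aligner.  A read of length L
allowed m ≤ 2 mismatches is split into m + 1 contiguous segments whose
lengths differ by at most one; any placement with ≤ m mismatches must match
at least one segment exactly (pigeonhole).  Exact segment occurrences are
found by binary search in sorted 2-bit-packed k-mer tables (segments longer
than 32 bases are keyed by their 32-base prefix — harmless, since every
candidate is verified), and each candidate window is then verified by a
full Hamming comparison.  The result set therefore provably equals a naive
all-positions scan, and the suite enforces that equivalence against a
brute-force oracle, including a property test over arbitrary read/reference
content.

Only the sense strand is stored.  For genomic (double-stranded) tiers the
reverse-complemented read is additionally queried: a read matching the
minus strand of a window is exactly its reverse complement matching the
plus strand.  This halves index memory relative to indexing both strands
and yields the identical hit set; minus-strand hits are reported with
reference-forward coordinates.  `N` never matches anything, itself
included — in read or reference it simply counts as a mismatch, which makes
the exogenous exact-match policy conservative.

Because segment layout depends on read length, each (database, read length,
allowance) triple gets its own index, built lazily and cached; post-trim
libraries with mixed 16–35 nt lengths dispatch per length.  Reads longer
than every reference sequence yield no hits — there is no soft-clipping or
gapped alignment, since the Strategy definitions are pure mismatch counts.

## Preprocessing

Raw 35-cycle reads are `insert + 3' adapter (+ noise)`.  Trimming truncates
at the leftmost position where some adapter *prefix* of length
o ≥ `min_overlap` aligns with mismatch fraction ≤
`max_adapter_mismatch_rate`; testing all prefix lengths at each position
makes the rule idempotent (re-trimming a trimmed read is a no-op), which
the suite checks.  Rejection reasons are applied in fixed precedence —
adapter_only, too_short, too_long, polyA_only, low_quality — so summaries
are deterministic, and `kept + Σ rejected = input` always.

Defaults: `min_length` 16, `max_length` 35, `min_mean_quality` 20 (Phred),
`polyA_fraction` 0.9, `min_overlap` 5, `max_adapter_mismatch_rate` 0.1.
These thresholds are this package's declared operating point, chosen so
that realistic simulated 35-cycle libraries come out averaging ~23 nt
processed length (the `analysis/02` driver demonstrates 23.0 nt); "low
quality" and "polyA only" have no universal numeric definition.

## Taxonomy: best-hit-then-LCA, and the structural-RNA mask

A read's hits within its winning tier are first filtered to the minimal
mismatch count (for exogenous tiers this is vacuous — everything is at 0).
If the survivors agree on one taxon, the read is assigned to it at species
level; otherwise to the lowest common ancestor of the surviving taxa in a
simplified NCBI-style tree (taxid, parent, rank, name; ranks at least
species/genus/phylum/kingdom).  Best-hit-then-LCA rather than all-hit LCA
is a declared convention: it preserves species-level reporting for uniquely
placed reads while refusing to guess among equally good cross-species
placements.

Rollup to a rank walks each assignment's lineage; assignments whose lineage
lacks the rank (e.g. a cross-phylum LCA at kingdom level) are pooled under
`unranked`, so rollup totals are conserved.  Multi-sample figures use
unweighted arithmetic means of per-sample counts.

A read is flagged *structural RNA* iff any surviving hit overlaps an
annotated rRNA/tRNA interval by ≥ 1 base — deliberately the most
conservative rule, since the point of the mask is reliability.  Masking
drops flagged reads and re-rolls up; taxa detectable only through conserved
structural genes then disappear, which the suite reproduces on a
constructed fixture.

## The coincidence model

For a random read of length L, allowance m, against N searchable positions
(N = Σ strands × (sequence length − L + 1)), the per-position match
probability is the binomial mismatch tail
p = Σ_{i=0..m} C(L,i) q^i (1−q)^{L−i} with q the per-base mismatch
probability under the background composition (uniform: q = 3/4, so the
exact-match term is 4^−L).  Assuming independence across positions, the
chance of ≥ 1 hit is 1 − (1−p)^N, with 1 − exp(−Np) as the documented
Poisson approximation (agreeing to < 1% relative error whenever Np < 0.01).
Overlapping windows are weakly dependent, so this is the standard occupancy
approximation; the package validates it by running its own matcher on
random references and checking the empirical fraction against the closed
form (within binomial sampling error at the suite's settings).  Background
composition defaults to the reference's empirical base frequencies.

The practical conclusion the model licenses: at L = 23, m = 0, even 10^12
searchable positions give only ~1.4% chance of a hit per read, so
multi-percent exogenous fractions cannot be a sequencing-error artifact —
which is what the negative-control experiment then shows end-to-end.

## The synthetic-data generator

The generator emulates exactly the features the analysis depends on:

* **Tiered references with taxonomy.** Random sequences with configurable
  count, length range and GC per taxon; every sequence labelled with a
  species resolvable in an emitted root→kingdom→phylum→genus→species tree.
* **Conserved structural-RNA genes.** A master gene copied into several
  taxa, each copy independently mutated at a stated divergence (e.g. 2%),
  spliced into a host sequence and annotated as an rRNA/tRNA interval.
  This reproduces the cross-species multi-mapping that motivates the mask:
  at 2% per-copy divergence a 23-nt window is identical between two copies
  ~40% of the time.
* **Reads with per-cycle substitution errors.** Component counts are a
  multinomial draw over normalized mixture weights; start positions are
  uniform over eligible windows; transcript-type tiers are sampled sense
  strand only, genome-type tiers from either strand with p = 0.5; each
  cycle substitutes with its own probability, uniformly over the three
  alternative bases.  The default "Illumina-like" profile ramps linearly
  from 0.4× to 1.6× the mean rate across the read (3' end worst).  Every
  read carries a ground-truth record (source db/sequence/taxon, interval,
  strand, error cycles), so accuracy is scored exactly, not estimated.

The model is substitution-only (no indels or chimeras) because the
classification tolerances are pure mismatch counts — an indel-bearing read
would simply fail to map, which the recovery experiment already prices in.
It also omits amplification bias and biological between-sample variability;
passing tests therefore demonstrate the *procedure's* correctness and
calibration on sequences with realistic composition, error structure and
conservation — not performance against real databases' homology structure,
incompleteness, or contamination.

## Validation experiments and problem sizes

* **Mapping completeness** (`simulated_transcriptome_recovery`): 2,000
  random transcripts of 0.5–2 kb (~2.5 Mb), 10^5 reads of 23 nt at 1% mean
  per-cycle substitution, classified at Strategy 2 against the source
  transcriptome.  The expected mapped fraction is 1 − P(≥3 errors) =
  1 − 1.5×10⁻³ ≈ 99.85%, comfortably above the 98% requirement.
* **Negative control** (`negative_control_coincidence`): 2×10^5 reads
  (0.5% per-cycle rate) from a 12 Mb synthetic host genome, full cascade
  with exogenous tiers built from ~50 Mb of independent random genomes
  (20 Mb "bacteria", 18 Mb "fungi", 12 Mb "other"), host tier at
  Strategy 2, exogenous tiers exact.  Only ~2×10⁻⁴ of reads (≥3 errors)
  even reach the exogenous tiers, and each then has ~10⁻⁶ chance of a
  23-mer match in 10^8 positions; the measured exogenous fraction is 0%,
  far below the 0.15% bound.

These sizes are the package's chosen desk-scale study conditions: large
enough that the reported fractions are stable to well under a percentage
point, small enough to regenerate from scratch in minutes on one CPU.

## Numerical and design choices

* Seeds: every stochastic routine takes an explicit seed (NumPy
  `default_rng`); experiment drivers derive independent 31-bit sub-seeds
  from one master seed.  Identical seed + config ⇒ byte-identical FASTQ.
* Seed-table lookups pass `np.uint64` needles so `searchsorted` never
  falls back to casting the key table.
* Ties and determinism: hits are reported sorted by (sequence, start,
  strand); duplicate candidates from multiple segments are deduplicated;
  within-tier assignment depends only on hit existence, so result sets are
  independent of evaluation order.
* Degenerate inputs: empty tier databases, empty mixtures, zero-length
  sequence requests, allowance > read length, and zero processed reads all
  raise typed errors (`ConfigError`, `DataError`,
  `UndefinedFractionError`) rather than returning silent zeros; fold
  ratios refuse pseudocounts on a zero denominator.
* Reporting: percentages are rounded to 2 decimals only at the table edge;
  log-scale chart exports drop zero counts rather than emitting −∞;
  metazoan-style "other" hits are kept out of food tables by construction
  of the food tier.
* miRNA count tables collapse database entries with identical mature
  sequence into one multi-name row; a read contributes one count to each
  distinct identity group among its hits.

## Known limitations

* The matcher targets short reads and small-to-modest references (up to
  tens of Mb per tier); it is exact and memory-friendly at that scale but
  is not a BWT aligner and will not scale to full nt-collection sizes.
* LCA assignment ignores hit multiplicity within a taxon and does not
  model genome-size or copy-number bias in abundance (no correction is
  attempted, matching the read-count-based reporting).
* The coincidence model treats positions as independent; at chance-hit
  rates near saturation the clumping error grows, which is why the
  Monte-Carlo cross-check is part of the package rather than a one-off.
* Sequencing-quality strings are cosmetic output of the simulator; errors
  are governed solely by the per-cycle rates.
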