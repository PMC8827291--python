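# Methods

This note records the models implemented in `mutline`, their
assumptions, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate conventions and variant identity

All interval arithmetic inside the package is 0-based, half-open, on the
forward strand. Conversion happens only at I/O boundaries: VCF and GFF3
are 1-based inclusive, PAF and BED are already half-open. A single
arithmetic convention removes an entire class of off-by-one errors;
reader/writer pairs are lossless round trips on valid input.

Indels are left-normalized on VCF ingest when a reference genome is
supplied (trim shared trailing bases, extending left with the reference
base when an allele would empty; then trim shared leading bases).
Variant identity across lines is the normalized
`(sequence, position, REF, ALT)` tuple. Without normalization, "the same
deletion" called by independent runs at different anchors would defeat
the uniqueness filter.

## The filter cascade

Stage order is fixed: total → CDS → unique → biallelic → read depth →
alternate-allele frequency → cross-line evidence check. Counts are
non-increasing by construction, each filter is idempotent, and the
surviving set is invariant to input order (all property-tested).

Decisions that were open and how they were resolved:

* **CDS intersection.** A variant is coding when the reference interval
  it actually alters intersects a CDS interval. The shared anchor base
  of a left-anchored indel is *not* altered and does not count; a pure
  insertion counts when either base flanking the insertion point is
  coding.
* **Uniqueness granularity.** Default is per-variant (same position,
  different ALT in another line does not disqualify); a per-site mode is
  available (`per_site=True`), since published descriptions of such
  filters rarely state which was used.
* **Depth threshold.** `min_depth` defaults to 2 and the comparison is
  `>=` ("at least 2"); sources that say "greater than two" can set 3.
* **Missing evidence.** Records lacking DP fail the depth stage; records
  lacking AD fail the frequency stage. Both are counted and logged.
  This is the conservative reading: a record that cannot demonstrate
  homozygous support is not a candidate.
* **Cross-line check.** The manual genome-browser inspection of the
  original workflow is automated as a table of alt-supporting read
  counts per line at candidate sites; any other line exceeding
  `cross_line_max_alt_reads` (default 0) removes the candidate. The
  generator produces this table alongside the call sets; with real data
  it would be compiled from pileups of the other lines' alignments.

## Consequence classification

Gene models are single-transcript; the spliced CDS is the concatenation
of CDS intervals in transcription order (reverse-complemented for minus
strand). Classification rebuilds the mutant spliced CDS and translates
both alleles with the standard nuclear genetic code (stops TAA/TAG/TGA):

* equal-length substitutions: identical translation → synonymous; a stop
  arising before the reference stop → stop gain; the reference stop
  turned sense → stop loss; otherwise missense;
* indels overlapping CDS: net coding-length change mod 3 ≠ 0 →
  frameshift (taking precedence over any downstream stop it creates);
  otherwise in-frame deletion/insertion, with a `premature_stop` note if
  a new stop appears;
* REF/ALT are first reduced to a minimal replaced span by trimming
  shared prefix and suffix bases, so right-anchored records classify
  identically to their left-anchored equivalents (strand symmetry is
  property-tested by reverse-complementing the whole reference).

Indels that straddle an exon/intron junction are classified by the
coding part of their length change and flagged `splice_region`; splice
site strength is out of scope. Proteins are compared after truncation
at the first stop. A supplied domain interval (1-based amino-acid
coordinates on the reference protein) is reported lost when the mutant
protein no longer carries that exact amino-acid stretch at that
location — the appropriate notion for frameshifts, which destroy all
downstream sequence.

The test oracle is deliberately a different route: apply the variant to
the whole chromosome string, map the gene model's intervals through the
edit, re-splice, re-translate, and diff.

## Deletion scanning

Depth tracks are per-base integers (samtools-depth dialect). The scan
computes window means (default `depth_window_bp` = 1 kb) and per-track
whole-sequence medians. A window is a candidate when the mutant mean is
≤ `deletion_mutant_ceiling` (default 0.05) × mutant median **and** the
wild-type mean is ≥ `deletion_wt_floor` (default 0.5) × WT median — the
second condition excludes shared assembly gaps and N-runs, which
deplete every line. Candidate runs are merged across single-window gaps
and kept at ≥ `deletion_min_len` (default 5 kb). These thresholds are
this package's own: no published values exist for this step; the
defaults resolve a 35 kb event at ~20× comfortably and are all
configurable. Calls are invariant to uniform depth scaling of both
tracks, and a deletion seen in another mutant at ≥ 0.5 reciprocal
overlap clears `unique_to_line`.

Split-read refinement collects query-adjacent (gap ≤ 100 bp), same-
strand block pairs whose implied deleted interval (target-left block's
end to target-right block's start) overlaps the depth candidate. With
at least `min_support` (default 2) distinct reads, breakpoints become
the modal inner-edge pair, ties broken toward the widest interval
(deterministic, robust to soft-clipped stragglers); otherwise the call
is returned unchanged with a note. Spanning support counts contiguous
single blocks covering the interval ± 100 bp (intact allele) versus
split pairs (deleted allele).

The collinearity check walks one query's blocks in query order and
requires, per adjacent pair, one target, one orientation, monotone
target coordinates and an implied gap ≤ `max_gap` (default 100 kb);
violations are returned pairwise. Slicing any genuine alignment into
consecutive pieces can never produce a violation (property-tested).

## F2 linkage

The estimator is the direct gamete-counting rule, not maximum
likelihood: per plant with both genotypes present, same class → 0
recombinant gametes, heterozygote vs homozygote → 1, opposite
homozygotes → 2; divide by two gametes per scored plant. Double
heterozygotes are phase-ambiguous and scored parental, which makes the
estimator downward-biased with asymptotic expectation r(1 − r/2)
(exact enumeration over gamete pairs) — below half a centimorgan of
bias at the r ≤ 0.1 distances it is used for, and the test suite
asserts exactly this behaviour rather than pretending consistency at
large r.

Against a phenotype-defined locus with a dominant wild-type allele,
recessive-phenotype plants are inferred homozygous mutant and scored as
above; dominant-phenotype plants cannot reveal recombination and
contribute no events. The reported denominator remains two gametes per
scored plant — the published convention — while the statistically
defensible recessive-only denominator is carried alongside
(`informative_gametes` / `informative_frequency`), neither overriding
the other.

`segregation_check` is a Pearson chi-square against the 3:1 single-
recessive-locus expectation; with 0 df-correction and one degree of
freedom, (14, 5) gives χ² ≈ 0.018.

## The synthetic world

The generator emulates the *call-level* signature of the study design —
not reads. Variant calls are fabricated directly with DP/AD evidence;
read-level reality enters only through those fields, the depth tracks,
the split PAF blocks and the cross-line evidence table. Consequences:
a green end-to-end test establishes that the filter logic, coordinate
arithmetic and counting rules are correct on inputs with the stated
structure; it does not establish robustness to alignment artefacts,
mapping-quality pathologies or caller-specific representation quirks.

Defaults state the modelled world:

* reference: 1 × 500 kb, 50 four-exon genes on both strands, CDS =
  exons (no UTRs), every CDS ATG…stop with no internal stop;
* lines: one wild-type parent plus six mutants, one causal mutation
  each spanning the six classes (synonymous, missense, stop-gain SNVs;
  1-bp frameshift deletion; 3-bp in-frame deletion; multi-kb deletion);
  every causal coding mutation is re-verified by the consequence
  classifier at generation time;
* evidence: causal/background records are homozygous-like (DP ≥ 3 from
  Poisson around a 12× mean, alt fraction ≥ 0.9); per line ~70
  non-coding noise records, 16 records shared with a cyclic partner
  line, 10 multi-allelic sites, 10 low-depth, 5 missing-DP, 10
  low-frequency, 5 missing-AD and 5 cross-line-evidence records, so
  every stage removes at least one record and stage counts can be
  checked exactly by set arithmetic over the truth;
* depth tracks: Gaussian-rounded (mean 20×, sd 3) rather than Poisson —
  the tail is controllable for zero-run testing, and substituting a
  Poisson draw is a one-line change; deleted intervals are exactly
  zero by default (`edge_bleed_bp` adds noisy edges);
* F2: two independent gametes per plant, per-locus recombination with
  probability r, no interference, wild-type allele dominant.

Published printed values used as fixed inputs are encoded in
`mutline.datasets` (the 19-plant genotype table) and in the four-exon
gene fixture (`nin_like_gene_fixture`: 2889 nt spliced CDS — the
printed full-gene length of 3216 bp minus three 109 bp introns; the
printed CDS length of 2888 is not divisible by three and is treated as
including partial UTR or a typo — with the 1-bp CAA→CA_ deletion at
spliced position 2189 between an upstream RWP-RK-style and a
downstream PB1-style domain).

In the default 500 kb / 50-gene world the planted large deletion is the
widest interval containing exactly its target gene (≈19 kb for seed 0)
rather than the full 35 kb, which that gene density cannot accommodate;
the dedicated deletion-scan fixtures use a sparser 200 kb / 6-gene
world where the full 35 kb event fits.

## Degenerate inputs and tie-breaks

* `coverage_fold` rounds half away from zero (22.15 → 22, 28.37 → 28)
  and rejects non-positive inputs.
* Empty variant sets produce all-zero stage counts, not errors.
* Unknown sequence names in variants, mismatched track lengths, and
  illegal FASTA characters raise errors naming the offender.
* `refine_breakpoints` with fewer supporting reads than `min_support`
  returns the depth-only call annotated, never a partially refined one.
* A single alignment block is vacuously collinear.
* Plants with a missing genotype are excluded pairwise, not globally.

## Known limitations

* One transcript per gene; overlapping genes are resolved to the first
  model in coordinate order.
* Insertions exactly at exon boundaries are flagged rather than
  assigned to exon or intron.
* The deletion scanner targets homozygous events (depth ceiling 5% of
  median); heterozygous deletions (~50% depth) need a raised ceiling
  and are untested territory.
* No symbolic-ALT structural variant notation, no BAM/CRAM parsing, no
  multipoint mapping or map functions — inputs are the text formats of
  the surrounding toolchain, and the linkage module stops at two-point
  counting.
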