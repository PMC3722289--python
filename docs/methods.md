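# Methods

## Model and assumptions

`hlacall` types HLA genes by exhaustive comparison against a registry of
known allele sequences rather than by de novo variant calling.  The core
assumption is the one that makes registry-based typing work at all: within
a gene, the sample's two chromosome copies each match one registry allele
exactly over the assayed exons (novel variation is handled separately, as
deviations recorded during error correction).  Under this assumption,
sequencing errors can be removed by snapping each read to its closest
reference, perfect-overlap assembly of corrected reads reconstructs the two
exon haplotypes exactly, and the registry filter removes chimeric
assemblies that mix the two copies.

The pipeline further assumes reads are short relative to exons (a read
overlaps at most one exon; the default simulator geometry, 91 bp reads and
100 bp introns, guarantees it) and that both chromosome copies are captured
and sequenced at comparable efficiency — the zygosity ratio is only
meaningful when allelic coverage is roughly balanced.

## Reference matching and error correction

Each read (both orientations) is aligned against every allele of its gene
with edlib infix alignment.  A *discordance event* is one mismatched base
or one insertion/deletion run of any length.  Events are counted on a
minimum-edit-distance alignment, with one canonicalisation: a terminal
insertion run is rewritten as per-base substitutions whenever the reference
continues past the alignment end.  Without this, a read tail carrying
several errors could be written off as a single cheap "insertion" event and
survive the discordance budget; with it, placements are maximal-span and
deterministic.

The best reference is the one with the fewest events, ties broken by longer
aligned span, then lexicographic allele name, then lower exon number, then
lower offset.  Reads with more than `max_discordances` (default 2) events
everywhere, or whose aligned exon span is shorter than `min_span` (default
30 bp; spurious short matches otherwise pass for rescue-pool reads), are
discarded.  When alleles carry full (exon+intron) sequences, reads are
aligned to those and trimmed to the single exon they overlap most, so
exon-boundary reads contribute their exonic portion; for exon-only
databases an explicit overhang scan covers boundary reads, with
substitution-only scoring in the overhang.

A `MatchConfig(allow_indels=False)` mode restricts matching to gapless
(substitution-only) placements, implemented as a vectorised sliding-window
mismatch scan.  This mode has an exactly specifiable optimum, which the
test suite verifies against an independent exhaustive scan; the default
gapped mode is additionally exercised by deterministic insertion/deletion
fixtures.  Gapped event counts inherit one arbitrariness from alignment
theory: among co-optimal alignments the reported indel placement may shift
(left/right alignment ambiguity), so tests of gapped matching assert event
counts and event types, not exact co-optimal coordinates.

## Assembly

Corrected reads of one exon are chained wherever a read's prefix matches
the growing assembly's suffix over at least `min_overlap` bases (default
10) with zero mismatches.  All maximal chains are enumerated — every
consistent assembly, not a sampled subset, so the result is
order-independent — using a suffix-window memoisation: future extensions
depend only on the assembly's last `max-read-length` bases.  Duplicate read
sequences collapse to one graph node (multiplicity kept for depth); a
cycle guard and a 10 000-chain cap bound pathological repeat structures.
Assemblies that are substrings of others are dropped, then assemblies whose
sequence occurs in no database allele for that exon are filtered out as
artefacts.

Depth profiles count, per base, the read instances covering it (leftmost
occurrence); a read occurring in several maximal assemblies counts in each,
because each such assembly was genuinely constructed from it.  Depth
conservation across assemblies therefore holds exactly when the assemblies
partition the reads, which is how the conservation property is tested.

When low depth breaks an exon into fragments, every database exon sequence
on which two or more fragments place at non-overlapping positions is
emitted as a *bridged* candidate: the gap bases come from the database
exon, coverage counts only the fragment-covered bases, and depth evenness
is computed over covered bases only.

## Scores

For an assembly of length L with per-base depths Xᵢ (mean X̄), reads N and
coverage fraction C of its exon reference:

* dispersion `D = [Σ (Xᵢ − X̄)² / X̄] / (L − 1)` — a per-degree-of-freedom
  variance-to-mean index, zero for perfectly even depth;
* reliability `R = 1/(1 + D) ∈ (0, 1]`, maximal iff depth is uniform;
  profiles shorter than 2 bases have no measurable dispersion and score 1;
* haplotype score `S = C·R·ln(1 + N)` — bounded quality factors times
  diminishing-returns read support;
* type score `TScore = Σₑ Nₑ·Sₑ` over exons where the candidate allele has
  a compatible assembly (the best-S one per exon);
* confidence `AScore = (S₂ − S₁)/S₀`, clamped to [0, 1], with S₂ the final
  type's TScore, S₁ the best-ranked candidate outside the final call and
  S₀ = Σ S·N over all surviving assemblies of the gene; NaN (undefined)
  when S₀ ≤ 0.

All four are pluggable through `ScoringConfig`/`TypingConfig`, so
alternative functional forms can be swapped without touching callers.
Coverage C is measured against the shortest compatible exon reference, so
full-length matches score exactly 1.  N is the raw read-instance count
(not unique-start count).

## Zygosity and novel variants

A read *supports* an allele when its corrected sequence occurs in that
allele's exon; it is *unique* to a candidate when no higher-ranked
candidate also contains it.  The zygosity ratio is the runner-up's unique
support divided by the best type's support; a ratio strictly below 0.1
calls a homozygote, and the boundary value 0.1 itself calls a heterozygote.
Unique support is what discriminates a true second allele from an assembly
shadow: a spurious runner-up shares essentially all its reads with the
winner and scores near zero.

Ledger discordances become novel-variant calls when their read support
reaches `min_novel_support` (default 4, matching the depth floor commonly
used for variant calling from such data) and, for SNPs, the alternate base
occurs at that position in no allele of the gene — otherwise the
discordance is evidence of that other allele, not novelty.  Indel records
shift position between alleles and are only support-filtered.  Each novel
variant is linked to a called allele (the one it was recorded against when
called, else a called allele with the identical exon sequence, else the
dominant type).  Positional comparison across alleles assumes positionally
comparable exons; registries with length-variant exons would need an
alignment-based lift-over, a known limitation.

## Synthetic data

The generator emulates the diploid capture-sequencing setting at desk
scale.  A panel (default 3 genes × 8 alleles × 8 exons) is built from a
random per-gene template — 150 bp exons separated by 100 bp introns — with
each allele mutated from the template at 1% per-base divergence and
pairwise exonic distinctness enforced.  Allele *i* of every gene belongs to
panel haplotype *i*, mimicking a reference panel of sequenced homozygous
haplotypes; a diploid sample draws two haplotypes (distinct by default;
identical pairs for homozygote studies).  Reads are 2×91 bp pairs with
insert length Normal(500, 10) truncated to the template, uniform start
positions, and independent per-base substitution errors at the configured
rate (0–2% in the study grid); depths are sample-level (both haplotypes
together) over 20–100×.

What the simulator does not model: capture/probe bias and GC bias,
indel sequencing errors (substitution-only, matching the scalar error-rate
regime; a real sample adds indel errors the matcher tolerates as
single events), quality-score variation, intron-length variation between
alleles, and registry-scale allele counts (thousands per gene).  Passing
the simulation criteria therefore demonstrates the pipeline's logic —
correction, assembly, scoring, zygosity — under controlled conditions, not
clinical-grade accuracy on real capture data.

## Problem sizes and numerical choices

The accuracy grid runs 36 replicate diploids per condition over depths
{20, 50, 100}× and error rates {0, 1, 2}%, all on the default panel; the
acceptance script reports the same grid at 12 replicates per condition and
states each n alongside the value.  Exact-recovery checks use 10 diploids
at 100×/0%; homozygote recovery uses 40 identical-haplotype diploids at
50×.  Monotonicity of accuracy in error rate is asserted with a 95%
binomial confidence slack, since adjacent cells are finite-sample
estimates.

Tie-breaks are deterministic everywhere (lexicographic allele name after
score and support), so typing output is invariant to enumeration order.
Genes with no surviving assembly yield a structured `untypeable` result
rather than an exception, so a multi-gene run always completes.

## Design choices

* Registry matching replaces an external BLAST dependency with edlib-based
  infix alignment under the same best-hit contract; equivalence with an
  exhaustive scan is part of the test suite.
* "Random" assembly order in the original protocol cannot affect results
  here because *all* maximal consistent assemblies are enumerated; the
  seeded 10 000-chain cap exists only to bound adversarial repeat inputs.
* The unmapped-read rescue pool cannot be binned positionally, so it rides
  along with every gene and is resolved by the database matching step.
* Substring (not exact-equality) matching in the registry filter lets
  partial-coverage assemblies survive with C < 1; requiring full-length
  equality would make the coverage factor vacuous.
* Legacy run-together allele names (`B*0702`) are split into two-character
  fields so legacy and colon-separated names compare correctly at 4-digit
  resolution; expression suffix letters are preserved but ignored in
  comparisons.
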