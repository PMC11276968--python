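# Methods

## The problem

Ultraconserved elements (UCEs) are genomic segments that remain nearly
identical across distantly related species — in placental mammals, the
working definition is a stretch of at least 100 bp with at least 97%
sequence identity present in at least 50% of a panel of representative
genomes. `ucekit` implements a k-mer-seeded pipeline for discovering such
elements across multiple genome assemblies, together with the downstream
analyses a UCE study needs: tracing the discovered sequences into other
genomes with a glocal aligner, classifying their genomic context against a
gene annotation, and assessing synteny by flanking protein-coding genes.

## Discovery model

A UCE call is defined window-wise.  Given a genome set of Y species with a
designated reference, parameters L (minimum length, default 100), p
(minimum identity, default 0.97), f (minimum species fraction, default
0.5), and a multi-mapping cap C (default 100), a reference base belongs to
the output iff it lies in some reference window of length w in
[L, max_window] such that

* the window contains no N in the reference;
* at least ceil(f·Y) species — the reference counting as one — contain a
  gapless occurrence of the window, on either strand, with at most
  floor((1−p)·w) substitutions (N in a non-reference species counts as a
  mismatch for that species only, so one low-quality assembly cannot veto a
  window);
* the window's sequence occurs at most C times in every genome (both
  strands), the reference included.

The output is the union of all such windows, reported as merged intervals
(book-ended intervals merge).  Identity is gapless at this stage:
substitution-only divergence is the regime UCEs live in, and indels are the
tracer's job.

### The staged pipeline

1. **Core k-mer identification.** All canonical (strand-collapsed) N-free
   k-mers (k = 50) are hashed per genome; k-mers present exactly in at
   least ceil(core_fraction·Y) genomes, with at most `kmer_map_limit`
   (1,000) occurrences per genome, become core k-mers.
2. **Approximate mapping.** Each core k-mer is mapped to every position in
   every genome within the run's identity threshold (mismatch budget
   m = floor((1−p)·k)) by pigeonhole seeding: the k-mer is split into m+1
   disjoint exact seeds, one of which must match any window with ≤ m
   substitutions; candidates are verified by Hamming count.  This mapper is
   provably complete under the gapless model, so a single run suffices
   where a heuristic aligner would need the cumulative scan; the cumulative
   scan is still provided (and tested) as part of the method's contract.
3. **Candidate regions.** Reference hits of core k-mers are merged
   (book-ended included) into candidate regions carrying their per-species
   hit intervals.
4. **Extension and calling.** Each candidate neighbourhood is re-searched
   at full sensitivity: short exact seeds (length chosen by the pigeonhole
   bound below, 16 by default) discover every alignment diagonal between
   the reference and any oriented genome sequence; per-diagonal cumulative
   mismatch arrays then let the caller evaluate, for every candidate start,
   the maximal window satisfying the quorum, N and cap constraints.
   Re-seeding the extension stage (rather than extending only along
   stage-2 hits) is a deliberate design choice: it makes stage 4 exactly
   as sensitive as the window definition, so the only way the pipeline can
   miss a true window is if stage 1 finds no shared exact 50-mer in enough
   genomes — vanishingly unlikely at UCE-like divergence.

**Seed-length bound.** A window of length w with at most m substitutions
contains an exact run of at least ceil((w−m)/(m+1)) bases.  Minimized over
w in [L, max_window], this gives the longest seed guaranteed to detect
every qualifying occurrence (16 for p ≥ 0.95 at L = 100); the caller
refuses identity thresholds whose bound drops below 8.

**max_window.** Window search is capped at an explicit `max_window`
(default 1,000 bp).  Reported UCE length distributions concentrate in
100–200 bp with means near 180 bp, so 1 kb is a generous ceiling; it is a
shared part of the caller's and the oracle's window semantics, so the two
remain comparable base-for-base.

**Multimap cap semantics.** The cap is enforced per window during calling,
which is the definition the oracle checks.  Occurrence counts are not
monotone in window length (a longer window has a larger mismatch budget),
so a stricter re-check of each merged element's full sequence would drop
boundary cases the window definition admits; `apply_multimap_cap` is
therefore provided as a standalone post-filter for users who want the
full-sequence criterion, but the discovery driver does not re-apply it.
For the same reason the output is not strictly monotone in the identity
threshold at a high-copy locus: a looser threshold enlarges the mismatch
budget, more repeat copies match a boundary-straddling window, and the
cap can newly exclude bases that the stricter run emitted.  This is the
same strict-before-loose asymmetry that motivates the cumulative scan;
away from high-copy loci, monotonicity in identity (and everywhere in
species fraction and length) is exact.

**Reporting.** Merged intervals become UCE records ordered by position.
Per species, the reported hit is the longest sub-window of length ≥ L
meeting the identity threshold on the best diagonal (ties: longer span,
higher identity, lower coordinate, '+' strand); species without a passing
window are reported with their best full-length gapless hit for context
and do not count toward `n_species_passing`.  BED scores are per-mille mean
identity over the species with hits.

### The brute-force oracle

`oracle_find_uces` recomputes the same window definition by exhaustive
enumeration over every reference window start, refusing inputs above 1 Mb
aggregate.  It shares no candidate-generation machinery with the pipeline:
all diagonals sharing an exact seed (pigeonhole-safe length, as above) are
enumerated directly, and every start position admitted by a per-diagonal
feasibility scan is evaluated over every window length.  Exhaustive
seeding, rather than a literal cubic scan, is what makes enumeration
feasible at the 50–100 kb fixture scale; it is exact by the same pigeonhole
argument.  Acceptance testing asserts base-for-base equality between
pipeline and oracle on 20 seeded genome sets across a 12-point
(L, p, f) grid.

## Synthetic study conditions

The generator builds per-species genomes from i.i.d. background (default
GC 0.5) so that all cross-species conservation is attributable to
implanted elements.  Defaults: 24 elements of 150–300 bp per 80 kb genome
(background exceeds ten times the total element content, keeping chance
conservation negligible), copied from the reference into every species
with per-species Bernoulli substitution rates cycling through
0.4/0.8/1.2/1.6% — realized identities of roughly 98.4–99.6%, matching the
range reported when remapping placental-mammal UCEs across their
definition set.  Each element core carries 50 bp flanks diverged at 10%,
giving the characteristic core-versus-flank conservation step.  Element 0
is implanted 150 times (full unit, flanks included) in the first
non-reference species to exercise the multi-mapping cap.  Ground truth
records every realized copy with its exact substitution count.

What the generator does not emulate: phylogenetic (tree-shaped) descent,
indel-rich divergence in the discovery fixtures (a separate indel-bearing
configuration exercises only the tracer), assembly gaps, and realistic
repeat families.  Passing tests therefore demonstrate algorithmic
correctness under the stated model, not robustness to assembly artifacts.

## Tracing

Queries are aligned to target genomes global-in-query / local-in-target
(fit alignment) with affine gaps: match +5, mismatch −4, gap open −12,
gap extend −4 (a gap of length l costs 12 + 4(l−1)).  Both strands of
every target sequence are scanned and the single best hit per genome is
kept by bit-score (ties: longer alignment, lower target coordinate, '+'
strand).  Identity counts alignment columns including gaps in the
denominator.

Bit-scores and E-values use ungapped Karlin–Altschul statistics computed
numerically from the match/mismatch scores and the target base
composition: λ solves Σ p_s e^{λs} = 1, and K follows the classical
lattice series K = dλe^{−2σ}/(H(1−e^{−λd})) with
σ = Σ_j (1/j)[P(S_j ≥ 0) + E(e^{λS_j}; S_j < 0)] and d the lattice span of
the score values.  The implementation reproduces published ungapped
nucleotide values (+1/−2 → λ 1.33, K 0.62; +5/−4 → λ 0.192, K 0.176).
Applying ungapped statistics to gapped scores is an approximation; the
downstream filters (aligned length ≥ 30, E ≤ 0.01, 70% identity for
detection counting) dominate behaviour.  Detection counting and identity
summaries are filtered separately: a retained hit below 70% identity still
contributes to the mean identity, as in standard practice for these
summaries.

## Annotation and synteny

Context classification uses a fixed precedence: complex locus (irreducible
to one gene type, or straddling a gene/intergenic boundary) → CDS → UTRs →
exon/intron junction → intron → lncRNA exon → other-biotype gene →
intergenic.  "Wholly within" means every base inside the merged feature
union; junctions need ≥ 1 bp on each side.  Gene models are flattened
across transcripts (introns are intronic in all transcripts).  Two
documented fallbacks: an element wholly exonic but spanning a CDS/UTR
boundary is labelled by its coding overlap, and same-biotype containing
genes with conflicting verdicts become complex loci.

Synteny compares the nearest up- and downstream protein-coding genes
(all distance ties included; genes overlapping the element count on both
sides at distance zero) between the reference location and the element's
best trace hit (identity ≥ 70%) in the other species.  Matching is
case-insensitive on gene names and orientation-agnostic: any reference
flank gene matching any other-species flank gene, upstream or downstream,
makes the element syntenic.  Cross-species gene-nomenclature curation is
out of scope; non-syntenic records carry a reason flag instead.

## Numerical conventions

* All coordinates are 0-based half-open (BED); GTF converts on read.
* Mismatch budgets use floor((1−p)·w) with a 1e-9 epsilon so exact
  rational thresholds (e.g. 0.97·100) are not lost to binary floats;
  window comparisons carry a 1e-6 tolerance with true margins ≥ 0.01.
* `closest` reports gap distance (0 for overlap or book-ended abutment);
  tie sets are unaffected by this choice of distance scale.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and parameters produce
  byte-identical outputs, and `--deterministic` suppresses the only
  non-deterministic output content (header timestamps).

## Problem sizes

Validation runs use 3–8 species at 60–100 kb per genome with 20–30
implanted elements — the scale at which the exhaustive oracle is exact and
the full pipeline-versus-oracle grid completes in minutes.  The tracer's
divergence-recovery check uses 200 elements against a 60 kb target at 5%
substitution divergence with sparse indels, recovering mean identity
within two percentage points.  These sizes are the package's chosen study
conditions for exact validation; the pipeline itself has no such limits
(the oracle's 1 Mb guard applies only to the oracle).

## Known limitations

* Discovery is gapless by design; an element conserved only through an
  indel-bearing alignment is found by the tracer, not the caller.
* Species quorums below two (ceil(f·Y) < 2) degenerate to calling the
  entire reference and are rejected.
* Karlin–Altschul parameters are ungapped approximations applied to gapped
  scores.
* The annotation precedence resolves corner cases (e.g. a 3'UTR that is
  also a lncRNA exon) to complex locus by rule rather than by curation.
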