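# Methods

This note records the models, conventions and numerical choices behind
`scanmut`, and what the synthetic fixtures do and do not establish about
real data.

## Melting-temperature model

All temperatures come from the GC-fraction approximation
`Tm = 64.9 + 41·(n_GC − 16.4)/L` (°C), applied verbatim at any length — no
clamping for short or extreme-composition oligos, where the formula can
return values below 50 °C or even negative. The formula is deliberately not
a nearest-neighbour thermodynamic model: it is the empirical rule the
scanning-mutagenesis workflow was calibrated with, and the package treats
it as the definition of Tm rather than an approximation to be improved.
Salt correction, hairpin and homodimer energetics are out of scope; large
mutagenesis campaigns show no strong correlation between those quantities
and PCR failure, so they are not part of the feasibility rules.

For a mutagenic primer two Tm values are kept. `Tm_full` applies the
formula to the whole oligo (later PCR cycles, when the template already
carries the mutation). The annealing `Tm` models early cycles against the
original template: mismatched positions are **deleted** and the formula is
applied to the remaining bases (shorter effective length, reduced GC
count). The alternative one-line variant — counting mismatches as non-GC
positions at full length — was considered and rejected as it understates
the destabilisation; the deletion rule is isolated in
`seqcore.tm_pair_for_primer` so it can be swapped.

## Mutagenic pair enumeration

Geometry (top strand, 0-based internally; all user-facing coordinates are
1-based inclusive and converted only at the API boundary): an overlap
window `[s, s+k)` with `k ∈ [min_overlap, max_overlap]`; the forward primer
spans `[s, s+len_f)`; the reverse primer's annealing region spans
`[s+k−len_r, s+k)` and the oligo is its reverse complement. Both primers
therefore contain the whole overlap (`len_f, len_r ≥ k`). The mutated codon
is substituted wherever covered; a primer covering the codon only partially
is rejected outright, since it would prime an unintended codon. The codon
may sit in either primer, not necessarily in the overlap; when it lies
inside the overlap both primers carry identical mutated bases by
construction.

Constraints per primer: length in `[min_len, max_len]`; annealing Tm in
`[min_tm, max_tm]`; terminal G/C run ≥ `min_gc_clamp`; and, for
mutation-carrying primers, at least `min_anneal_len` bases between codon
and 3' end. Per pair: `|ΔTm| ≤ max_delta_tm`. Feasible pairs are ranked
lexicographically: (1) smallest max primer length, (2) smallest total
length, (3) smallest summed Tm excess over the (possibly relaxed) minimum,
(4) optionally largest summed clamp score, then leftmost overlap start,
shortest overlap, and forward length — a total order, so the designer is
fully deterministic and can be checked against an exhaustive search. The
published behaviour pins only "shortest primers" and "Tm as close to the
minimum"; the remaining tie-breaks are this package's declared convention.

Defaults: lengths 25–45 bp, Tm 58–70 °C, ΔTm ≤ 3 °C, annealing length
15 bp, overlap 13–15 bp, clamp run ≥ 1, one suggestion per residue. The
overlap bounds, annealing length and suggestion count are the workflow's
published defaults; the length/Tm/ΔTm/clamp values are this package's
choice of realistic practice values for ~50% GC templates (a 25-mer at 50%
GC sits near 58 °C under the formula above).

Adaptive Tm relaxes `min_tm` in 1 °C steps for positions that are
otherwise infeasible, stopping 10 °C below the nominal minimum
(`ADAPTIVE_TM_FLOOR`): unbounded relaxation produces useless primers, and
raising `max_len` is the better remedy. The relaxation applies only to the
affected position and is reported alongside the result.

Templates are treated as linear with flanks; the designer requires
`max_len − 3` bp of template on each side of the codon (hence the
recommendation to paste flanks at least `max_len` long). Circular
wrap-around arithmetic is used only where a product necessarily crosses
the origin: the in-silico PCR simulator and the two-fragment designer.

`simulate_mutagenesis` is the designer's own oracle: it builds the linear
product literally from the primer sequences (forward oligo, template around
the circle, reverse complement of the reverse oligo), verifies the two ends
share exactly the overlap, collapses them, and checks the result equals the
template with only the codon substituted. The two-fragment variant raises
both overlap bounds to ≥ 15 bp — the in-vitro assembly chemistries need
15 bp of terminal identity — and places a non-mutagenic anchor pair inside
a user-chosen span (typically the origin region, roughly opposite the
mutation), rejecting anchors that collide with the mutagenic footprint.

## Read checking

The alignment score at an offset is the number of window start positions
where all 7 aligned bases match. `N` never matches anything (a conservative
rule that stops N-rich read ends from inflating scores); overlaps shorter
than 7 score zero. Peaks are all offsets scoring at least 50% of the
maximum (`ambiguity_fraction`, configurable); two or more peaks mark the
read ambiguous, the signature of duplications and other rearrangements.
Argmax ties go to the smallest offset. Because the alignment is gapless, an
indel splits the profile into partial peaks or drops the score outright —
such reads surface as `ambiguous` or `no-overlap`, never as substitution
calls.

Calling compares aligned bases codon by codon. Only codons fully covered by
the read are called (a partially covered codon cannot be translated from
the read); read `N`s make their positions uncallable rather than mutated.
Every differing codon is reported with nucleotide- and amino-acid-level
detail plus a silent flag; the headline report filters to the region of
interest, and verdicts are `expected-mutation-present`, `clean`,
`unexpected`, `ambiguous` or `no-overlap`, with ambiguity taking
precedence. No quality trimming is done: inputs are base-called sequences,
not chromatograms.

## Cloning quartets

The target construct is `U + A5 + I + A3 + D` (upstream vector, optional
5' inclusion, insert, optional 3' inclusion, downstream vector). Annealing
cores are the shortest prefix/suffix oligos meeting the Tm/length/clamp
constraints (defaults 18–45 bp, 52–70 °C, clamp ≥ 1 — slightly looser than
the mutagenesis defaults because cores are anchored and cannot slide).
The vector amplicon is modelled as the linearised vector amplified outward
(pv5 anneals at the start of D pointing into the backbone, pv3 at the end
of U pointing the other way); collapsing the backbone to zero length in the
simulator preserves exactly the circular adjacency the real vector has, so
junction checks are unaffected.

At each junction the footprint is the inclusion plus `overlap_len` bases
(default 15) of identity. Strategy A places it on the vector primers, B on
the insert primers; C chooses the split that minimises the difference of
the two full primer lengths at that junction, achieving ≤ 1 nt whenever the
clamp of core lengths permits (the centred-vs-biased placement is a
declared convention — balance is the point of the strategy). Overhangs
longer than 60 nt raise an error, reflecting the practical synthesis limit
that motivates strategy C in the first place. `simulate_assembly` verifies
every emitted quartet end-to-end: both amplicons are generated from the
primers, terminal identities checked, and the joined circle compared
base-by-base with the intended construct.

## Synthetic fixtures

The generator emulates the study conditions of a scanning campaign: a
plasmid of 0.5–3 kb with one ORF (ATG start, no internal stops) centred
between random vector flanks at a chosen GC fraction (default 0.5), reads
of a codon ± 150 bp with optional uniform per-base substitution errors, and
ambiguity constructions with an 80 bp duplicated block. Identical seeds
give byte-identical output. What the fixtures do **not** model: real vector
sequence composition and repeats, chromatogram quality decay along a Sanger
read, indel errors, primer-synthesis errors, and the tandem-primer
insertions seen in real mutagenesis failures (the duplication construction
is a stylised stand-in that exercises the same ambiguity machinery).
Passing tests therefore establish the correctness of the algorithms under
controlled conditions, not wet-lab success rates.

Problem sizes used by the test suite — 500–600 bp templates for
oracle-equivalence checks (50 fixtures), 100 design→simulate→call round
trips, 100 ambiguity fixtures, 50 five-part cloning designs — were chosen
so the exhaustive oracles remain exact while the whole suite stays quick to
run during development.

## Known limitations

* The Tm model ignores sequence context, salt and concentration; it is a
  rule, not thermodynamics.
* The aligner cannot place indels; it only flags them indirectly.
* `Maxsuggestion > 1` returns the top-N *geometries* for the chosen codon,
  not alternative codons.
* Batch verdicts trust read naming; expected-mutation matching is exact
  string equality on labels like `A25D`.
* The original tool's binary project files are not readable; configuration
  round-trips through documented YAML instead.
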