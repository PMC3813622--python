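# scanmut

Primer design and sequencing-result checking for high-throughput scanning
mutagenesis, plus primer design for seamless (ligation-independent) cloning.

Scanning mutagenesis — substituting each residue of a protein in turn,
classically by alanine — needs hundreds of mutagenic primer pairs and then
hundreds of Sanger reads checked for the intended codon change. `scanmut`
automates the three desk-work steps of that campaign:

* **Mutagenic primer pairs** (`scanmut.mutprimer`) for whole-plasmid
  overlapping PCR: the plasmid is amplified with two primers that both carry
  the substitution, giving a linear product whose identical ends (13–15 bp)
  recircularise by in-cell end repair. The designer enumerates every
  primer-pair geometry around the target codon and returns the best pair
  under explicit, deterministic rules.
* **Mutant verification** (`scanmut.mutcheck`): a gapless offset-scan
  alignment of each read against the reference, scored by counting perfect
  7-base sliding windows; the score peak locates the alignment, multiple
  peaks flag rearranged (non-productive) clones, and aligned codons are
  compared to call changes such as `A25D`.
* **Seamless-cloning quartets** (`scanmut.clonedesign`): four primers
  (pv5/pv3 amplify the vector, pi5/pi3 the insert) whose 5' overhangs add
  optional inclusion sequences and ≥ 15 bp of shared terminal sequence at
  each junction, with three overhang-placement strategies (vector-side,
  insert-side, or split for balanced lengths).

## The rules at the core

Melting temperatures use the GC-fraction (Marmur-style) approximation

```
Tm = 64.9 °C + 41 °C · (n_GC − 16.4) / L
```

for a primer of length `L` with `n_GC` G/C bases. Two values are reported
per primer: `Tm` computed with mismatched (mutated) positions removed —
relevant in early PCR cycles against the original template — and `Tm_full`
for the full-length primer in later cycles. A pair is feasible when both
primers are within the length and Tm windows, their annealing-Tm difference
is at most `MaxDeltaTm`, each mutation-carrying primer keeps at least
`MinAnnealLen` bases between the codon and its 3' end, the end overlap is
within `[MinOverlap, MaxOverlap]`, and each 3' terminus ends in at least
`min_gc_clamp` consecutive G/C bases. The 3' clamp is also graded 0–3 from
the last three bases (S = G/C, W = A/T): `SSS`=0, `..W`=1, `.WS`=2, `WSS`=3.

The read aligner scores an offset as the number of window start positions
where all 7 aligned bases match; gaps are deliberately not modelled, so
insertions/deletions surface as split peaks or unalignable reads rather
than as spurious substitution calls.

## Worked example

```python
from scanmut import DesignParams, batch_design, io as scio
from scanmut.fixtures import FixtureSpec, generate_fixture

fixture = generate_fixture(FixtureSpec(seed=11, plasmid_length=600, orf_length_aa=80))
entries = batch_design(fixture.ctx, 40, 44, DesignParams())
print(scio.render_long2([p for e in entries for p in e.pairs]), end="")
```

prints (excerpt):

```
name	strand	length	tm_anneal	tm_full	gc_clamp_score	anneal_len_3prime	overlap_len	delta_tm	sequence
R40A_F	forward	28	59.32	62.85	2	22	14	1.11	GACGCTAAGGCGCACCTAAGTCATGTTC
R40A_R	reverse	30	58.22	61.62	2	19	14	1.11	TGCGCCTTAGCGTCATGTGTAAAGTCTAAC
A42G_F	forward	29	58.22	60.09	3	21	13	0.00	GAAAGGGTCACCTAAGTCATGTTCTAACC
A42G_R	reverse	29	58.22	60.09	2	21	13	0.00	AGGTGACCCTTTCTGTCATGTGTAAAGTC
```

Each row is one orderable oligo: residue 40 (Arg) is mutated to alanine by a
28/30-mer pair sharing a 14 bp end overlap, with annealing Tm just above the
58 °C minimum and a ΔTm of 1.11 °C; residue 42 is already alanine, so the
fallback substitution (glycine) is designed instead. The `examples/`
directory has one narrative script per capability (`design_scanning_primers`,
`check_sequencing_reads`, `clone_seamless`, `two_fragment_rescue`), and the
same functionality is scriptable from the shell via the `scanmut` command
(`scanmut design`, `scanmut check`, `scanmut clone`, `scanmut fixtures`).

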