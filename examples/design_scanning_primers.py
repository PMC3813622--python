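"""Design mutagenic primer pairs for an alanine scan of a small synthetic ORF.

Builds a seeded 600 bp plasmid carrying an 80-codon ORF, designs the best
primer pair for residues 40-44 at default constraints, and prints the
tabular (Long2) report: one row per oligo with its length, annealing Tm
(mismatches excluded, early PCR cycles), full-length Tm (later cycles),
3' GC-clamp score (0 worst - 3 best), distance from the mutated codon to
the 3' end, the end-overlap length of the pair, and the orderable sequence.
"""

from scanmut import DesignParams, batch_design, io as scio
from scanmut.fixtures import FixtureSpec, generate_fixture

fixture = generate_fixture(FixtureSpec(seed=11, plasmid_length=600, orf_length_aa=80))
params = DesignParams()  # 25-45 bp, Tm 58-70 degC, overlap 13-15 bp, clamp >= 1

entries = batch_design(fixture.ctx, 40, 44, params)
pairs = [pair for entry in entries for pair in entry.pairs]
print(scio.render_long2(pairs), end="")
print(f"\n# {len(pairs)} pairs designed; every residue is mutated to "
      f"{pairs[0].target_aa} (or the fallback when already alanine)")
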