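"""Rescue a difficult mutation with the two-fragment strategy.

When whole-plasmid PCR fails for a position, the plasmid is amplified as two
roughly half-size products: each mutagenic primer is paired with an anchor
primer in a region opposite the mutation (e.g. the origin).  The fragments
share >= 15 bp of terminal identity at both junctions and are joined in
vitro.  Here both PCRs and the assembly are simulated and the result is
compared base-by-base with the intended mutant plasmid.
"""

from scanmut import DesignParams, design_two_fragment
from scanmut.fixtures import FixtureSpec, generate_fixture
from scanmut.mutprimer import simulate_mutagenesis, simulate_two_fragment

fixture = generate_fixture(FixtureSpec(seed=23, plasmid_length=3000, orf_length_aa=120))
ctx = fixture.ctx

mut_pair, anchor_pair = design_two_fragment(ctx, 60, anchor_span=(2400, 2700),
                                            params=DesignParams())
assembled = simulate_two_fragment(ctx, mut_pair, anchor_pair)
expected = simulate_mutagenesis(ctx, mut_pair)

diffs = [i + 1 for i, (a, b) in enumerate(zip(assembled, ctx.plasmid)) if a != b]
print(f"mutation: {mut_pair.label}; mutagenic overlap {mut_pair.overlap_len} bp, "
      f"anchor overlap {anchor_pair.overlap_len} bp")
print(f"assembled == single-product simulation: {assembled == expected}")
print(f"positions differing from wild type: {diffs} "
      f"(codon of residue {mut_pair.aa_position})")
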