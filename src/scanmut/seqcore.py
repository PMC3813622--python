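"""Core sequence primitives shared by every designer and checker in the package.

All sequences are plain uppercase strings over the alphabet ``{A, C, G, T, N}``.
Melting temperatures use the GC-fraction (Marmur-style) approximation

    Tm = 64.9 + 41 * (n_GC - 16.4) / length   [degrees C]

applied verbatim at any length (no clamping for short oligos).  The 3' GC
clamp is characterised two ways: as the length of the terminal G/C run, and
as a 0-3 quality score determined by the last three bases (0 = worst,
3 = best).
"""

from __future__ import annotations

from Bio.Data import CodonTable

from .errors import (
    EmptySequence,
    FrameOutOfRange,
    IllegalCharacter,
    LengthMismatch,
    TooShort,
)

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_GC = frozenset("GC")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, stops rendered '*'
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TABLE.update({c: "*" for c in _STANDARD.stop_codons})


def normalize_sequence(raw: str) -> str:
    """Clean pasted sequence text into a bare uppercase ACGTN string.

    FASTA header lines (starting with ``>`` or ``;``) are dropped; whitespace
    and digits (line numbering) are removed; letters are uppercased.  Any
    remaining character outside the core alphabet raises
    :class:`~scanmut.errors.IllegalCharacter` with its position in the
    cleaned sequence.
    """
    bases = []
    for line in raw.splitlines():
        stripped = line.lstrip()
        if stripped.startswith(">") or stripped.startswith(";"):
            continue
        for ch in line:
            if ch.isspace() or ch.isdigit():
                continue
            bases.append(ch.upper())
    seq = "".join(bases)
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise IllegalCharacter(i + 1, ch)
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N; empty in, empty out."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate with the standard genetic code from a 0-based frame offset.

    Codons containing ``N`` give ``'X'``; stops give ``'*'``; a trailing
    partial codon is dropped.
    """
    if frame_offset >= len(seq):
        raise FrameOutOfRange(f"frame offset {frame_offset} >= length {len(seq)}")
    out = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def gc_count(seq: str) -> int:
    return sum(1 for b in seq if b in _GC)


def tm_basic(seq: str) -> float:
    """GC-fraction melting temperature of a mismatch-free oligo, in deg C."""
    if not seq:
        raise EmptySequence("Tm of an empty sequence")
    return 64.9 + 41.0 * (gc_count(seq) - 16.4) / len(seq)


def tm_pair_for_primer(primer: str, template_region: str) -> tuple[float, float]:
    """(tm_anneal, tm_full) for a primer aligned base-by-base on its template.

    ``tm_full`` treats the whole primer as matched (late PCR cycles, when the
    product itself is the template).  ``tm_anneal`` models the early cycles
    against the original template: positions where primer and template
    disagree are deleted, and the Tm formula is applied to the remaining
    bases (reduced length and GC count).
    """
    if len(primer) != len(template_region):
        raise LengthMismatch(
            f"primer length {len(primer)} != template region {len(template_region)}"
        )
    matched = "".join(p for p, t in zip(primer, template_region) if p == t)
    return tm_basic(matched), tm_basic(primer)


def gc_clamp_run(seq: str) -> int:
    """Length of the uninterrupted G/C run at the 3' (right) end."""
    if not seq:
        raise EmptySequence("GC clamp of an empty sequence")
    run = 0
    for b in reversed(seq):
        if b not in _GC:
            break
        run += 1
    return run


def gc_clamp_score(seq: str) -> int:
    """0-3 quality score of the 3' GC clamp from the last three bases.

    Patterns (S = G or C, W = A or T, . = any), scored worst to best:
    ``S S S`` = 0, ``. . W`` = 1, ``. W S`` = 2, ``W S S`` = 3.  The four
    patterns partition all 64 trinucleotides.
    """
    if len(seq) < 3:
        raise TooShort("GC clamp score needs at least 3 bases")
    a, b, c = (x in _GC for x in seq[-3:])
    if not c:
        return 1
    if not b:
        return 2
    # b and c are G/C
    return 0 if a else 3


def codon_mismatches(a: str, b: str) -> int:
    """Hamming distance between two codons."""
    if len(a) != 3 or len(b) != 3:
        raise LengthMismatch("codons must be length 3")
    return sum(1 for x, y in zip(a, b) if x != y)
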