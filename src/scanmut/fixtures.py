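"""Seeded synthetic fixtures: random plasmids with embedded ORFs, reads with
planted codon substitutions, and alignment-ambiguity constructions.

The generator emulates the study conditions of a scanning-mutagenesis
campaign: a plasmid of a few kb carrying one ORF with vector flanks, Sanger
reads of a few hundred bases around the mutated codon, optional per-base
read errors, and — for the ambiguity checks — references containing a
duplicated block such as a tandem primer insertion produces.  The same seed
always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqcore
from .errors import SpecInvalid
from .mutprimer import TemplateContext

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

#: codons per amino acid, alphabetical — deterministic planting choices
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(seqcore.CODON_TABLE.items()):
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic synthetic data set.

    ``planted_mutations`` lists (1-based residue, target amino acid) pairs;
    one read is generated per planted mutation plus ``n_clean_reads``
    mutation-free reads.  ``read_flank`` is how far each read extends beyond
    its codon on either side (clipped at the template ends).
    """

    seed: int
    plasmid_length: int = 3000
    orf_length_aa: int = 120
    gc_fraction: float = 0.5
    planted_mutations: tuple[tuple[int, str], ...] = ()
    read_error_rate: float = 0.0
    n_clean_reads: int = 0
    read_flank: int = 150

    def __post_init__(self):
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise SpecInvalid("gc_fraction must be within [0, 1]")
        if 3 * self.orf_length_aa + 120 > self.plasmid_length:
            raise SpecInvalid("ORF plus 60 bp flanks exceeds the plasmid length")
        for residue, aa in self.planted_mutations:
            if not 1 <= residue <= self.orf_length_aa:
                raise SpecInvalid(f"planted residue {residue} outside the ORF")
            if aa not in CODONS_FOR_AA or aa == "*":
                raise SpecInvalid(f"unknown target amino acid {aa!r}")


@dataclass
class Fixture:
    """Generated fixture: template context, ORF reference, reads, truth table."""

    ctx: TemplateContext
    reference: str  # the ORF sequence, first ATG onward
    reads: list[tuple[str, str]] = field(default_factory=list)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def random_orf(rng: np.random.Generator, n_aa: int, gc: float) -> str:
    """ATG followed by random sense (non-stop) codons."""
    codons = ["ATG"]
    while len(codons) < n_aa:
        c = _random_bases(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def planted_codon(wt_codon: str, target_aa: str) -> str:
    """Deterministic replacement codon: fewest mismatches, alphabetical ties."""
    return min(
        CODONS_FOR_AA[target_aa],
        key=lambda c: (seqcore.codon_mismatches(wt_codon, c), c),
    )


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the plasmid, reads and truth table described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    orf = random_orf(rng, spec.orf_length_aa, spec.gc_fraction)
    upstream = (spec.plasmid_length - len(orf)) // 2
    downstream = spec.plasmid_length - len(orf) - upstream
    plasmid = (
        _random_bases(rng, upstream, spec.gc_fraction)
        + orf
        + _random_bases(rng, downstream, spec.gc_fraction)
    )
    ctx = TemplateContext(
        plasmid=plasmid, orf_start=upstream + 1, orf_length_aa=spec.orf_length_aa
    )

    reads: list[tuple[str, str]] = []
    rows = []

    def with_errors(seq: str) -> str:
        if spec.read_error_rate <= 0:
            return seq
        arr = np.array(list(seq))
        hit = rng.random(len(arr)) < spec.read_error_rate
        for i in np.flatnonzero(hit):
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        return "".join(arr)

    for idx, (residue, target_aa) in enumerate(spec.planted_mutations, start=1):
        c0, c1 = ctx.codon_span0(residue)
        wt = plasmid[c0:c1]
        mut = planted_codon(wt, target_aa)
        mutant = plasmid[:c0] + mut + plasmid[c1:]
        a = max(0, c0 - spec.read_flank)
        b = min(len(plasmid), c1 + spec.read_flank)
        name = f"read_{idx}"
        reads.append((name, with_errors(mutant[a:b])))
        rows.append(
            {
                "read": name,
                "residue": residue,
                "ref_aa": seqcore.translate(wt),
                "obs_aa": target_aa,
                "label": f"{seqcore.translate(wt)}{residue}{target_aa}",
            }
        )
    n_planted = len(spec.planted_mutations)
    for j in range(spec.n_clean_reads):
        residue = int(rng.integers(1, spec.orf_length_aa + 1))
        c0, c1 = ctx.codon_span0(residue)
        a = max(0, c0 - spec.read_flank)
        b = min(len(plasmid), c1 + spec.read_flank)
        reads.append((f"read_{n_planted + j + 1}", with_errors(plasmid[a:b])))

    truth = pd.DataFrame(rows, columns=["read", "residue", "ref_aa", "obs_aa", "label"])
    return Fixture(ctx=ctx, reference=orf, reads=reads, truth=truth)


def duplication_fixture(
    seed: int, ref_length: int = 300, block_len: int = 80, gc: float = 0.5
) -> tuple[str, str]:
    """(reference, read) where the reference carries a duplicated block and
    the read comes from inside it — the alignment must be ambiguous."""
    rng = np.random.default_rng(seed)
    block = _random_bases(rng, block_len, gc)
    spacer = _random_bases(rng, max(10, (ref_length - 2 * block_len) // 2), gc)
    tail = _random_bases(rng, max(10, ref_length - 2 * block_len - len(spacer)), gc)
    ref = block + spacer + block + tail
    start = int(rng.integers(0, block_len // 4 + 1))
    read = block[start:]  # entirely inside the block: matches both copies
    return ref, read


def unique_fixture(
    seed: int, ref_length: int = 300, read_len: int = 60, gc: float = 0.5
) -> tuple[str, str]:
    """(reference, read) where the read is a unique slice — one peak only."""
    rng = np.random.default_rng(seed)
    ref = _random_bases(rng, ref_length, gc)
    start = int(rng.integers(0, ref_length - read_len + 1))
    return ref, ref[start : start + read_len]


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write plasmid FASTA, reads FASTA and truth TSV into ``outdir``."""
    from . import io as scio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plasmid": outdir / "plasmid.fasta",
        "reads": outdir / "reads.fasta",
        "truth": outdir / "truth.tsv",
    }
    scio.write_fasta([("plasmid", fixture.ctx.plasmid)], paths["plasmid"])
    scio.write_fasta(fixture.reads, paths["reads"])
    fixture.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
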