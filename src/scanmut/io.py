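"""FASTA reading/writing, the four primer output formats, and project config.

Output formats for designed mutagenic primer pairs:

* ``Long1`` — human-readable blocks: the primer rendered on the coding
  strand (template context lowercase, mutated codon capitalised, substituted
  bases shown as ``X``), its parameters (length, annealing Tm, full-length
  Tm, GC-clamp score, 3' annealing length), and the orderable sequence
  (reverse-complemented for reverse primers).
* ``Long2`` — the same fields as a tab-separated table, one row per primer.
* ``Short`` — ``name<TAB>sequence`` order-sheet lines.
* ``FASTA`` — the orderable sequences with the same names as headers.

Primer names follow ``<wtAA><position><mutAA>_F/_R`` (e.g. ``A25D_F``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import seqcore
from .errors import MalformedFasta
from .mutprimer import DesignParams, PrimerCandidate, PrimerPair

FORMATS = ("Long1", "Long2", "Short", "FASTA")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into an ordered list of (name, sequence)."""
    text = Path(path).read_text()
    if not text.lstrip().startswith(">"):
        raise MalformedFasta(f"{path}: not FASTA (no '>' header)")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedFasta(f"{path}: no FASTA records")
    return [(r.id, seqcore.normalize_sequence(str(r.seq))) for r in records]


def write_fasta(collection: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in collection
    ]
    SeqIO.write(records, str(path), "fasta")


def read_template(source: str | Path) -> str:
    """Load a template from a FASTA file, a raw-text file, or an inline string."""
    p = Path(str(source))
    if p.exists() and p.is_file():
        text = p.read_text()
        if text.lstrip().startswith(">"):
            return read_fasta(p)[0][1]
        return seqcore.normalize_sequence(text)
    return seqcore.normalize_sequence(str(source))


# ---------------------------------------------------------------------------
# renderers

def primer_name(pair: PrimerPair, cand: PrimerCandidate) -> str:
    base = pair.label or "primer"
    return f"{base}_{'F' if cand.strand == 'forward' else 'R'}"


def _iter_primers(
    pairs: Iterable[PrimerPair], separate_f_r: bool
) -> list[tuple[str, PrimerPair, PrimerCandidate]]:
    pairs = list(pairs)
    fwd = [(primer_name(p, p.forward), p, p.forward) for p in pairs]
    rev = [(primer_name(p, p.reverse), p, p.reverse) for p in pairs]
    if separate_f_r:
        return fwd + rev
    return [x for pair in zip(fwd, rev) for x in pair]


def _coding_strand_rendering(pair: PrimerPair, cand: PrimerCandidate) -> str:
    """Primer on the coding strand: lowercase, mutated codon capitalised,
    substituted bases shown as X."""
    top = (
        cand.sequence
        if cand.strand == "forward"
        else seqcore.reverse_complement(cand.sequence)
    )
    if not cand.carries_mutation or pair.aa_position is None:
        return top.lower()
    out = list(top.lower())
    # codon offset inside the span, recovered from the 3' annealing length
    if cand.strand == "forward":
        codon_off = len(top) - 3 - cand.anneal_len_3prime
    else:
        codon_off = cand.anneal_len_3prime
    for j in range(3):
        wt = pair.wt_codon[j]
        mut = pair.mutated_codon[j]
        out[codon_off + j] = "X" if wt != mut else mut.upper()
    return "".join(out)


def render_long1(pairs: Iterable[PrimerPair], separate_f_r: bool = False) -> str:
    blocks = []
    for name, pair, cand in _iter_primers(pairs, separate_f_r):
        anneal = "-" if cand.anneal_len_3prime is None else cand.anneal_len_3prime
        blocks.append(
            "\n".join(
                [
                    f"> {name}",
                    f"coding-strand: {_coding_strand_rendering(pair, cand)}",
                    (
                        f"length={len(cand)} Tm={cand.tm_anneal:.2f} "
                        f"Tm_full={cand.tm_full:.2f} GCclamp={cand.clamp_score} "
                        f"anneal3={anneal} overlap={pair.overlap_len}"
                    ),
                    f"order: {cand.sequence}",
                ]
            )
        )
    return "\n\n".join(blocks) + "\n"


LONG2_COLUMNS = (
    "name",
    "strand",
    "length",
    "tm_anneal",
    "tm_full",
    "gc_clamp_score",
    "anneal_len_3prime",
    "overlap_len",
    "delta_tm",
    "sequence",
)


def render_long2(pairs: Iterable[PrimerPair], separate_f_r: bool = False) -> str:
    lines = ["\t".join(LONG2_COLUMNS)]
    for name, pair, cand in _iter_primers(pairs, separate_f_r):
        anneal = "" if cand.anneal_len_3prime is None else str(cand.anneal_len_3prime)
        lines.append(
            "\t".join(
                [
                    name,
                    cand.strand,
                    str(len(cand)),
                    f"{cand.tm_anneal:.2f}",
                    f"{cand.tm_full:.2f}",
                    str(cand.clamp_score),
                    anneal,
                    str(pair.overlap_len),
                    f"{pair.delta_tm:.2f}",
                    cand.sequence,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def render_short(pairs: Iterable[PrimerPair], separate_f_r: bool = False) -> str:
    lines = [
        f"{name}\t{cand.sequence}"
        for name, _, cand in _iter_primers(pairs, separate_f_r)
    ]
    return "\n".join(lines) + "\n"


def render_fasta(pairs: Iterable[PrimerPair], separate_f_r: bool = False) -> str:
    lines = []
    for name, _, cand in _iter_primers(pairs, separate_f_r):
        lines.append(f">{name}")
        lines.append(cand.sequence)
    return "\n".join(lines) + "\n"


RENDERERS = {
    "Long1": render_long1,
    "Long2": render_long2,
    "Short": render_short,
    "FASTA": render_fasta,
}


def render(pairs: Iterable[PrimerPair], fmt: str, separate_f_r: bool = False) -> str:
    if fmt not in RENDERERS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    return RENDERERS[fmt](pairs, separate_f_r)


# ---------------------------------------------------------------------------
# project configuration (human-readable YAML)

@dataclasses.dataclass
class ProjectConfig:
    """A whole design setup: template, ORF coordinates, parameters, output.

    Saved as human-readable YAML and reloaded losslessly.
    """

    template: str
    orf_start: int
    orf_length_aa: int
    params: DesignParams = DesignParams()
    output_format: str = "Long2"
    separate_f_r: bool = False
    verbose: bool = False

    def __post_init__(self):
        if self.output_format not in FORMATS:
            raise ValueError(f"output_format must be one of {FORMATS}")


def save_config(config: ProjectConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> ProjectConfig:
    data = yaml.safe_load(Path(path).read_text())
    pdata = data.pop("params")
    for key in ("primary_codons", "fallback_codons"):
        pdata[key] = tuple(pdata[key])
    return ProjectConfig(params=DesignParams(**pdata), **data)
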