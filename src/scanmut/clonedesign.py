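"""Primer design for seamless (ligation-independent) cloning.

The target construct is the concatenation of five parts:

    upstream vector (U) + 5' inclusion (A5) + insert (I) + 3' inclusion (A3)
    + downstream vector (D)

Two PCRs produce it: the *vector* amplicon is the linearised vector
amplified outward from the insert site (pv5 anneals to the start of D
pointing into the backbone; pv3 anneals to the end of U pointing the other
way), and the *insert* amplicon is the insert amplified by pi5/pi3.
Non-annealing 5' overhangs on the primers add the inclusions and give the
two amplicons >= 15 bp of identical terminal sequence at each junction, so
homologous recombination joins them seamlessly.

Three overhang-placement strategies are supported: the junction sequence can
ride entirely on the vector primers (A — reuse one vector pair with many
inserts), entirely on the insert primers (B — reuse one insert with many
vectors), or be split between the two so their lengths are balanced
(C — avoids very long oligos when inclusions are large).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import seqcore
from .errors import InclusionTooLong, JunctionMismatch, NoFeasiblePrimer

LEFT = "left"
RIGHT = "right"

#: longest overhang that is still comfortable to synthesise
MAX_OVERHANG = 60


@dataclass(frozen=True)
class CloneParams:
    """Annealing-core constraints (a subset of the mutagenesis designer's)."""

    min_len: int = 18
    max_len: int = 45
    min_tm: float = 52.0
    max_tm: float = 70.0
    min_gc_clamp: int = 1


@dataclass(frozen=True)
class CloningDesign:
    """Five-part construct plus strategy and design constraints."""

    upstream_vector: str
    add5: str
    insert: str
    add3: str
    downstream_vector: str
    strategy: str = "A"
    params: CloneParams = CloneParams()
    overlap_len: int = 15

    def __post_init__(self):
        for name in ("upstream_vector", "add5", "insert", "add3", "downstream_vector"):
            object.__setattr__(self, name, seqcore.normalize_sequence(getattr(self, name)))
        if self.strategy not in ("A", "B", "C"):
            raise ValueError(f"strategy must be A, B or C, not {self.strategy!r}")
        for name in ("upstream_vector", "downstream_vector"):
            if len(getattr(self, name)) < self.overlap_len + self.params.min_len:
                raise ValueError(f"{name} shorter than overlap_len + min annealing length")


@dataclass(frozen=True)
class Oligo:
    """A cloning primer: optional non-annealing 5' overhang plus annealing core."""

    name: str
    overhang: str
    core: str
    core_tm: float

    @property
    def sequence(self) -> str:
        return self.overhang + self.core

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerQuartet:
    pv5: Oligo
    pi5: Oligo
    pv3: Oligo
    pi3: Oligo
    junction_overlaps: tuple[int, int]  # (5' junction, 3' junction)


def assemble_target(design: CloningDesign) -> str:
    """The intended final construct: plain concatenation of the five parts."""
    return (
        design.upstream_vector
        + design.add5
        + design.insert
        + design.add3
        + design.downstream_vector
    )


def design_anneal_core(template_part: str, end: str, params: CloneParams) -> str:
    """Shortest feasible annealing core anchored at one end of a part.

    ``end='left'`` returns the sense prefix (a forward primer amplifying the
    part rightwards); ``end='right'`` returns the reverse complement of the
    suffix (a reverse primer amplifying it leftwards).  Feasibility: length
    within bounds, Tm within bounds, 3' GC-clamp run at least
    ``min_gc_clamp``.  Lengths are scanned shortest-first, so the winner is
    minimal; equal-length candidates do not arise for a fixed anchor.
    """
    if len(template_part) < params.min_len:
        raise NoFeasiblePrimer("template part shorter than min_len")
    for length in range(params.min_len, min(params.max_len, len(template_part)) + 1):
        if end == LEFT:
            core = template_part[:length]
        elif end == RIGHT:
            core = seqcore.reverse_complement(template_part[-length:])
        else:
            raise ValueError(f"end must be 'left' or 'right', not {end!r}")
        tm = seqcore.tm_basic(core)
        if not params.min_tm <= tm <= params.max_tm:
            continue
        if seqcore.gc_clamp_run(core) < params.min_gc_clamp:
            continue
        return core
    raise NoFeasiblePrimer(
        f"no annealing core at the {end} end satisfies the Tm/length/clamp constraints"
    )


def _split_junction(
    strategy: str, inclusion_len: int, overlap_len: int, len_vec_core: int,
    len_ins_core: int,
) -> tuple[int, int]:
    """Lengths of (vector-side, insert-side) overhangs at one junction.

    The junction footprint is the inclusion plus ``overlap_len`` bases of
    identity; strategy A puts all of it on the vector primer, B on the
    insert primer, C splits it so the two full primer lengths differ by at
    most 1 nt where the clamp of core lengths permits.
    """
    total = inclusion_len + overlap_len
    if strategy == "A":
        vec = total
    elif strategy == "B":
        vec = 0
    else:  # C: balance len_vec_core + vec against len_ins_core + (total - vec)
        ideal = (len_ins_core + total - len_vec_core + 1) // 2
        vec = min(max(ideal, 0), total)
    return vec, total - vec


def design_quartet(design: CloningDesign) -> PrimerQuartet:
    """Design the pv5/pi5/pv3/pi3 quartet for a five-part construct."""
    target = assemble_target(design)
    u = len(design.upstream_vector)
    a5 = len(design.add5)
    d0 = u + a5 + len(design.insert) + len(design.add3)  # start of D in target

    core_pv3 = design_anneal_core(design.upstream_vector, RIGHT, design.params)
    core_pi5 = design_anneal_core(design.insert, LEFT, design.params)
    core_pi3 = design_anneal_core(design.insert, RIGHT, design.params)
    core_pv5 = design_anneal_core(design.downstream_vector, LEFT, design.params)

    vec5, ins5 = _split_junction(
        design.strategy, a5, design.overlap_len, len(core_pv3), len(core_pi5)
    )
    vec3, ins3 = _split_junction(
        design.strategy, len(design.add3), design.overlap_len, len(core_pv5),
        len(core_pi3),
    )
    for n in (vec5, ins5, vec3, ins3):
        if n > MAX_OVERHANG:
            raise InclusionTooLong(
                f"required overhang of {n} nt exceeds the {MAX_OVERHANG} nt synthesis limit"
            )

    # 5' junction: vector amplicon ends at e5 = u + vec5; insert amplicon
    # starts at s2 = (u + a5) - ins5; identity = e5 - s2 = a5 + overlap_len.
    pv3 = Oligo(
        name="pv3",
        overhang=seqcore.reverse_complement(target[u : u + vec5]),
        core=core_pv3,
        core_tm=seqcore.tm_basic(core_pv3),
    )
    pi5 = Oligo(
        name="pi5",
        overhang=target[u + a5 - ins5 : u + a5],
        core=core_pi5,
        core_tm=seqcore.tm_basic(core_pi5),
    )
    # 3' junction: insert amplicon ends at e3 = (d0 - a3) + a3 + ins3'... in
    # target coordinates the insert ends at v = d0 - len(add3); the insert
    # amplicon extends to v + a3_part; symmetric to the 5' junction.
    v = d0 - len(design.add3)
    pi3 = Oligo(
        name="pi3",
        overhang=seqcore.reverse_complement(target[v : v + ins3]),
        core=core_pi3,
        core_tm=seqcore.tm_basic(core_pi3),
    )
    pv5 = Oligo(
        name="pv5",
        overhang=target[d0 - vec3 : d0],
        core=core_pv5,
        core_tm=seqcore.tm_basic(core_pv5),
    )
    # terminal identity between the two amplicons at each junction:
    # (u + vec5) - (u + a5 - ins5) = overlap_len, and symmetrically in 3'
    junction5 = vec5 + ins5 - a5
    junction3 = vec3 + ins3 - len(design.add3)
    return PrimerQuartet(
        pv5=pv5, pi5=pi5, pv3=pv3, pi3=pi3,
        junction_overlaps=(junction5, junction3),
    )


def simulate_assembly(design: CloningDesign, quartet: PrimerQuartet) -> str:
    """Generate both amplicons, verify junction identity, join, and compare
    against the intended construct.

    The vector amplicon is modelled with its backbone collapsed (D joined
    directly to U), which is exactly the circular adjacency the real vector
    provides; the junction checks and the assembled product are unaffected.
    Raises :class:`JunctionMismatch` if any terminal identity fails or the
    joined product differs from :func:`assemble_target`.
    """
    target = assemble_target(design)
    n = len(target)
    u = len(design.upstream_vector)
    a5 = len(design.add5)
    d0 = n - len(design.downstream_vector)

    # spans on the (circular) target implied by the primers
    s2 = u + a5 - len(quartet.pi5.overhang)  # insert amplicon start
    e3 = (d0 - len(design.add3)) + len(quartet.pi3.overhang)  # insert amplicon end
    insert_amplicon = (
        quartet.pi5.sequence
        + target[u + a5 + len(quartet.pi5.core) : d0 - len(design.add3) - len(quartet.pi3.core)]
        + seqcore.reverse_complement(quartet.pi3.sequence)
    )
    vector_amplicon = (
        quartet.pv5.sequence
        + target[d0 + len(quartet.pv5.core) :]
        + target[: u - len(quartet.pv3.core)]
        + seqcore.reverse_complement(quartet.pv3.sequence)
    )
    e5 = u + len(quartet.pv3.overhang)  # vector amplicon end on the target
    s3 = d0 - len(quartet.pv5.overhang)  # vector amplicon start

    d5 = e5 - s2
    d3 = e3 - s3
    if d5 < design.overlap_len or d3 < design.overlap_len:
        raise JunctionMismatch("junction identity shorter than overlap_len")
    if insert_amplicon[:d5] != vector_amplicon[-d5:]:
        raise JunctionMismatch("5' junction ends differ")
    if vector_amplicon[:d3] != insert_amplicon[-d3:]:
        raise JunctionMismatch("3' junction ends differ")

    joined = insert_amplicon + vector_amplicon[d3 : len(vector_amplicon) - d5]
    if len(joined) != n:
        raise JunctionMismatch("assembled product has the wrong length")
    shift = (n - s2) % n
    assembled = joined[shift:] + joined[:shift]
    if assembled != target:
        raise JunctionMismatch("assembled product differs from the intended construct")
    return assembled
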