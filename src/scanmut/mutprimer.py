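"""Design of mutagenic primer pairs for whole-plasmid overlapping PCR.

The mutagenesis strategy: the whole plasmid is amplified with a forward and a
reverse primer that both sit around the target codon and carry the desired
substitution.  The linear product ends in a short identical sequence (the
*overlap*, 13-15 bp by default) on both ends; in-cell end repair then
recircularises it into the mutant plasmid.

Geometry convention used throughout this module (top strand = coding strand,
0-based half-open internally):

* an overlap window ``[s, s+k)`` with ``k`` between ``min_overlap`` and
  ``max_overlap`` is placed on the top strand;
* the forward primer starts at ``s`` and extends rightwards
  (span ``[s, s+len_f)``);
* the reverse primer's annealing region ends at the overlap's right edge
  (span ``[s+k-len_r, s+k)``) and the oligo is its reverse complement;
* the mutated codon is substituted wherever a primer covers it; a primer
  covering only part of the codon is rejected as a geometry.

Feasible pairs are ranked lexicographically: smallest maximum primer length,
then smallest total length, then annealing Tm closest to the (possibly
relaxed) minimum Tm, then — if requested — best combined GC-clamp score,
then leftmost overlap start, then shortest overlap.  The ranking is fully
deterministic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

from . import seqcore
from .errors import (
    AnchorOverlapsMutation,
    EndMismatch,
    JunctionMismatch,
    NoFeasiblePrimer,
    PositionOutOfRange,
    RangeInvalid,
)

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class TemplateContext:
    """A plasmid template plus the coordinates of the ORF being scanned.

    ``orf_start`` is the 1-based position of the A of the initiator ATG on
    the top strand (e.g. 49 if 48 bp of vector precede the coding sequence).
    """

    plasmid: str
    orf_start: int
    orf_length_aa: int
    circular: bool = True

    def __post_init__(self):
        object.__setattr__(self, "plasmid", seqcore.normalize_sequence(self.plasmid))
        if self.orf_start < 1:
            raise ValueError("orf_start is 1-based and must be >= 1")
        end = self.orf_start - 1 + 3 * self.orf_length_aa
        if end > len(self.plasmid):
            raise ValueError("ORF extends past the template end")
        if self.plasmid[self.orf_start - 1 : self.orf_start + 2] != "ATG":
            warnings.warn("ORF does not begin with ATG", stacklevel=2)

    def codon_span0(self, aa_position: int) -> tuple[int, int]:
        """0-based half-open top-strand span of the codon for residue ``aa_position``."""
        if not 1 <= aa_position <= self.orf_length_aa:
            raise PositionOutOfRange(
                f"residue {aa_position} outside ORF of {self.orf_length_aa} aa"
            )
        c0 = self.orf_start - 1 + 3 * (aa_position - 1)
        return c0, c0 + 3

    def wt_codon(self, aa_position: int) -> str:
        c0, c1 = self.codon_span0(aa_position)
        return self.plasmid[c0:c1]

    def protein(self) -> str:
        c0 = self.orf_start - 1
        return seqcore.translate(self.plasmid[c0 : c0 + 3 * self.orf_length_aa])


@dataclass(frozen=True)
class DesignParams:
    """Every numeric/boolean knob of the primer designer.

    Lengths in bp, temperatures in deg C.  ``min_anneal_len`` is the minimal
    distance from the mutated codon to a mutation-carrying primer's 3' end
    (15 bp recommended).  ``min_overlap``/``max_overlap`` bound the shared
    end sequence of the PCR product (default 13-15 bp; below 11 bp end
    repair becomes inefficient).  ``min_gc_clamp`` requires that many
    consecutive G/C bases at each primer's 3' terminus (0 disables the
    check).  ``adaptive_tm`` lets the designer relax ``min_tm`` in 1 deg C
    steps for positions that are otherwise infeasible.
    """

    min_len: int = 25
    max_len: int = 45
    min_tm: float = 58.0
    max_tm: float = 70.0
    max_delta_tm: float = 3.0
    min_anneal_len: int = 15
    min_gc_clamp: int = 1
    use_optimised_gc_clamp: bool = False
    min_overlap: int = 13
    max_overlap: int = 15
    max_suggestions: int = 1
    adaptive_tm: bool = False
    primary_codons: tuple[str, str] = ("GCT", "GCC")
    fallback_aa: str = "G"
    fallback_codons: tuple[str, str] = ("GGT", "GGC")

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.min_tm > self.max_tm:
            raise ValueError("min_tm > max_tm")
        if self.min_overlap > self.max_overlap:
            raise ValueError("min_overlap > max_overlap")
        if self.min_overlap < 11:
            warnings.warn(
                "overlaps shorter than 11 bp reduce end-repair efficiency",
                stacklevel=2,
            )
        aa = {seqcore.translate(c) for c in self.primary_codons}
        if len(aa) != 1:
            raise ValueError("primary codons encode different amino acids")
        for c in self.fallback_codons:
            if seqcore.translate(c) != self.fallback_aa:
                raise ValueError(f"fallback codon {c} does not encode {self.fallback_aa}")

    @property
    def primary_aa(self) -> str:
        return seqcore.translate(self.primary_codons[0])


@dataclass(frozen=True)
class PrimerCandidate:
    """One designed oligo, written 5'->3' (reverse primers already flipped)."""

    sequence: str
    template_span: tuple[int, int]  # 1-based inclusive on the top strand
    strand: str  # FORWARD or REVERSE
    tm_anneal: float
    tm_full: float
    clamp_run: int
    clamp_score: int
    anneal_len_3prime: Optional[int]  # only for mutation-carrying primers
    carries_mutation: bool

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A constrained forward/reverse pair for one substitution."""

    forward: PrimerCandidate
    reverse: PrimerCandidate
    overlap_len: int
    delta_tm: float
    mutated_codon: Optional[str]
    wt_codon: Optional[str]
    aa_position: Optional[int]
    target_aa: Optional[str]
    wt_aa: Optional[str]
    relaxed_min_tm: float

    @property
    def label(self) -> str:
        """Mutation label like ``A25D``; empty for non-mutagenic pairs."""
        if self.aa_position is None:
            return ""
        return f"{self.wt_aa}{self.aa_position}{self.target_aa}"


@dataclass
class BatchEntry:
    """Per-residue outcome of a batch design run."""

    aa_position: int
    pairs: list[PrimerPair] = field(default_factory=list)
    relaxed_min_tm: Optional[float] = None
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def choose_mutation_codon(template_codon: str, params: DesignParams) -> tuple[str, str]:
    """Pick the replacement codon for one template codon.

    If the template already encodes the primary target amino acid, the
    fallback choices are used instead (e.g. alanine positions are mutated to
    glycine in an alanine scan).  Among the two listed codons the one with
    the fewer mismatches to the template wins; ties go to the first listed.
    """
    template_aa = seqcore.translate(template_codon)
    if template_aa == params.primary_aa:
        choices, target = params.fallback_codons, params.fallback_aa
    else:
        choices, target = params.primary_codons, params.primary_aa
    best = min(choices, key=lambda c: seqcore.codon_mismatches(template_codon, c))
    return best, target


def _make_candidate(
    plasmid: str,
    mut_plasmid: str,
    c0: int,
    c1: int,
    a: int,
    b: int,
    strand: str,
) -> Optional[PrimerCandidate]:
    """Build a candidate for top-strand span [a, b), or None if it partially
    covers the codon or falls off the template."""
    if a < 0 or b > len(plasmid):
        return None
    covers = a <= c0 and b >= c1
    disjoint = b <= c0 or a >= c1
    if not covers and not disjoint:
        return None  # partial codon coverage would encode an unintended codon
    top = mut_plasmid[a:b]
    oligo = top if strand == FORWARD else seqcore.reverse_complement(top)
    tm_anneal, tm_full = seqcore.tm_pair_for_primer(top, plasmid[a:b])
    anneal_len = None
    if covers:
        anneal_len = (b - c1) if strand == FORWARD else (c0 - a)
    return PrimerCandidate(
        sequence=oligo,
        template_span=(a + 1, b),
        strand=strand,
        tm_anneal=tm_anneal,
        tm_full=tm_full,
        clamp_run=seqcore.gc_clamp_run(oligo),
        clamp_score=seqcore.gc_clamp_score(oligo),
        anneal_len_3prime=anneal_len,
        carries_mutation=covers,
    )


def _candidate_ok(
    cand: PrimerCandidate, params: DesignParams, min_tm_used: float, reject: dict
) -> bool:
    if not min_tm_used <= cand.tm_anneal <= params.max_tm:
        reject["tm_anneal outside [min_tm, max_tm]"] += 1
        return False
    if cand.clamp_run < params.min_gc_clamp:
        reject["3' GC clamp shorter than min_gc_clamp"] += 1
        return False
    if cand.carries_mutation and cand.anneal_len_3prime < params.min_anneal_len:
        reject["3' annealing length below min_anneal_len"] += 1
        return False
    return True


def _pair_sort_key(pair: PrimerPair, params: DesignParams, min_tm_used: float):
    f, r = pair.forward, pair.reverse
    key = [
        max(len(f), len(r)),
        len(f) + len(r),
        (f.tm_anneal - min_tm_used) + (r.tm_anneal - min_tm_used),
    ]
    if params.use_optimised_gc_clamp:
        key.append(-(f.clamp_score + r.clamp_score))
    # leftmost overlap start, shortest overlap, then forward length: with
    # these the key identifies the geometry uniquely, so order is total
    key.extend([pair.forward.template_span[0], pair.overlap_len, len(f)])
    return tuple(key)


def _enumerate(
    ctx: TemplateContext,
    aa_position: int,
    params: DesignParams,
    min_tm_used: float,
    truncate: bool = True,
) -> list[PrimerPair]:
    plasmid = ctx.plasmid
    c0, c1 = ctx.codon_span0(aa_position)
    if c0 - (params.max_len - 3) < 0 or c1 + (params.max_len - 3) > len(plasmid):
        raise PositionOutOfRange(
            f"residue {aa_position}: template flank shorter than max_len"
        )
    wt_codon = plasmid[c0:c1]
    mut_codon, target_aa = choose_mutation_codon(wt_codon, params)
    wt_aa = seqcore.translate(wt_codon)
    mut_plasmid = plasmid[:c0] + mut_codon + plasmid[c1:]

    reject: Counter = Counter()
    cache: dict[tuple[int, int, str], Optional[PrimerCandidate]] = {}

    def cand(a: int, b: int, strand: str) -> Optional[PrimerCandidate]:
        key = (a, b, strand)
        if key not in cache:
            c = _make_candidate(plasmid, mut_plasmid, c0, c1, a, b, strand)
            if c is not None and not _candidate_ok(c, params, min_tm_used, reject):
                c = None
            cache[key] = c
        return cache[key]

    pairs: list[PrimerPair] = []
    s_lo = c1 - params.max_len
    s_hi = c0 + params.max_len - params.min_overlap
    for s in range(s_lo, s_hi + 1):
        for k in range(params.min_overlap, params.max_overlap + 1):
            lo_len = max(params.min_len, k)
            for len_f in range(lo_len, params.max_len + 1):
                f = cand(s, s + len_f, FORWARD)
                if f is None:
                    continue
                for len_r in range(lo_len, params.max_len + 1):
                    r = cand(s + k - len_r, s + k, REVERSE)
                    if r is None:
                        continue
                    if not (f.carries_mutation or r.carries_mutation):
                        continue
                    delta = abs(f.tm_anneal - r.tm_anneal)
                    if delta > params.max_delta_tm:
                        reject["delta Tm above max_delta_tm"] += 1
                        continue
                    pairs.append(
                        PrimerPair(
                            forward=f,
                            reverse=r,
                            overlap_len=k,
                            delta_tm=delta,
                            mutated_codon=mut_codon,
                            wt_codon=wt_codon,
                            aa_position=aa_position,
                            target_aa=target_aa,
                            wt_aa=wt_aa,
                            relaxed_min_tm=min_tm_used,
                        )
                    )
    pairs.sort(key=lambda p: _pair_sort_key(p, params, min_tm_used))
    if not pairs:
        if reject:
            worst, n = reject.most_common(1)[0]
            detail = f"; tightest violated constraint: {worst} ({n} rejections)"
        else:
            detail = ""
        raise NoFeasiblePrimer(f"residue {aa_position}: no feasible pair{detail}")
    return pairs[: params.max_suggestions] if truncate else pairs


def enumerate_pairs(
    ctx: TemplateContext,
    aa_position: int,
    params: DesignParams,
    *,
    truncate: bool = True,
) -> list[PrimerPair]:
    """Exhaustively enumerate feasible primer pairs for one residue.

    Returns the ranked list truncated to ``params.max_suggestions`` (pass
    ``truncate=False`` for the full feasible set).  Raises
    :class:`NoFeasiblePrimer` with the most frequently violated constraint
    if nothing passes.
    """
    return _enumerate(ctx, aa_position, params, params.min_tm, truncate=truncate)


#: how far below min_tm the adaptive relaxation may go before giving up
ADAPTIVE_TM_FLOOR = 10.0


def design_with_adaptive_tm(
    ctx: TemplateContext, aa_position: int, params: DesignParams
) -> tuple[list[PrimerPair], float]:
    """Relax ``min_tm`` by 1 deg C steps until a pair exists.

    Stops ``ADAPTIVE_TM_FLOOR`` deg C below the nominal minimum; primers
    that far below the requested Tm are better obtained by raising
    ``max_len`` instead.
    """
    t = params.min_tm
    last_error: Optional[Exception] = None
    while t >= params.min_tm - ADAPTIVE_TM_FLOOR:
        try:
            return _enumerate(ctx, aa_position, params, t), t
        except NoFeasiblePrimer as exc:
            last_error = exc
            t -= 1.0
    raise NoFeasiblePrimer(
        f"residue {aa_position}: infeasible even at min_tm - "
        f"{ADAPTIVE_TM_FLOOR:g} degC ({last_error})"
    )


def batch_design(
    ctx: TemplateContext, aa_from: int, aa_to: int, params: DesignParams
) -> list[BatchEntry]:
    """Design primers for every residue in [aa_from, aa_to], 1-based inclusive.

    Failures are recorded per residue without aborting the batch; entries
    come back in residue order.
    """
    if not (1 <= aa_from <= aa_to <= ctx.orf_length_aa):
        raise RangeInvalid(
            f"range {aa_from}-{aa_to} invalid for ORF of {ctx.orf_length_aa} aa"
        )
    out = []
    for pos in range(aa_from, aa_to + 1):
        entry = BatchEntry(aa_position=pos)
        try:
            if params.adaptive_tm:
                entry.pairs, entry.relaxed_min_tm = design_with_adaptive_tm(
                    ctx, pos, params
                )
            else:
                entry.pairs = enumerate_pairs(ctx, pos, params)
                entry.relaxed_min_tm = params.min_tm
        except Exception as exc:  # recorded, not raised: fault isolation
            entry.error = f"{type(exc).__name__}: {exc}"
        out.append(entry)
    return out


def _circ_slice(seq: str, start: int, end: int) -> str:
    """Top-strand slice [start, end) walking rightwards, wrapping the origin."""
    n = len(seq)
    start %= n
    end %= n
    if end >= start:
        return seq[start:end]
    return seq[start:] + seq[:end]


def simulate_mutagenesis(ctx: TemplateContext, pair: PrimerPair) -> str:
    """In-silico whole-plasmid PCR plus end repair.

    Builds the linear product (forward oligo, template around the circle,
    reverse complement of the reverse oligo), checks that the two ends share
    exactly ``overlap_len`` identical bases, collapses them, and returns the
    circular mutant sequence in the template's frame.
    """
    n = len(ctx.plasmid)
    fa, fb = pair.forward.template_span[0] - 1, pair.forward.template_span[1]
    ra, rb = pair.reverse.template_span[0] - 1, pair.reverse.template_span[1]
    k = rb - fa
    if k != pair.overlap_len:
        raise EndMismatch("pair geometry inconsistent with its overlap length")
    # reverse annealing start (ra) is always left of the forward 3' end (fb),
    # so the product walks the whole circle: fb -> origin -> ra
    middle = ctx.plasmid[fb:] + ctx.plasmid[:ra]
    product = (
        pair.forward.sequence
        + middle
        + seqcore.reverse_complement(pair.reverse.sequence)
    )
    if len(product) != n + k:
        raise EndMismatch("simulated product has the wrong length")
    if product[:k] != product[-k:]:
        raise EndMismatch("product ends are not identical over the overlap")
    collapsed = product[:n]  # circular sequence starting at the forward 5' end
    shift = (n - fa) % n
    return collapsed[shift:] + collapsed[:shift]


def _design_anchor_pair(
    ctx: TemplateContext, anchor0: tuple[int, int], params: DesignParams
) -> list[PrimerPair]:
    """Non-mutagenic overlapping pair confined to the 0-based anchor span."""
    plasmid = ctx.plasmid
    a0, a1 = anchor0
    reject: Counter = Counter()
    pairs: list[PrimerPair] = []
    for k in range(params.min_overlap, params.max_overlap + 1):
        for s in range(a0, a1 - k + 1):
            lo_len = max(params.min_len, k)
            for len_f in range(lo_len, params.max_len + 1):
                if s + len_f > a1:
                    break
                f = _make_candidate(plasmid, plasmid, -1, -1, s, s + len_f, FORWARD)
                if f is None or not _candidate_ok(f, params, params.min_tm, reject):
                    continue
                for len_r in range(lo_len, params.max_len + 1):
                    if s + k - len_r < a0:
                        break
                    r = _make_candidate(
                        plasmid, plasmid, -1, -1, s + k - len_r, s + k, REVERSE
                    )
                    if r is None or not _candidate_ok(r, params, params.min_tm, reject):
                        continue
                    delta = abs(f.tm_anneal - r.tm_anneal)
                    if delta > params.max_delta_tm:
                        continue
                    pairs.append(
                        PrimerPair(
                            forward=f,
                            reverse=r,
                            overlap_len=k,
                            delta_tm=delta,
                            mutated_codon=None,
                            wt_codon=None,
                            aa_position=None,
                            target_aa=None,
                            wt_aa=None,
                            relaxed_min_tm=params.min_tm,
                        )
                    )
    pairs.sort(key=lambda p: _pair_sort_key(p, params, params.min_tm))
    if not pairs:
        raise NoFeasiblePrimer("no feasible anchor pair within the anchor span")
    return pairs


def design_two_fragment(
    ctx: TemplateContext,
    aa_position: int,
    anchor_span: tuple[int, int],
    params: DesignParams,
) -> tuple[PrimerPair, PrimerPair]:
    """Two-fragment fallback for positions recalcitrant to single-product PCR.

    The plasmid is amplified as two roughly half-plasmid products: each
    mutagenic primer is paired with a non-mutagenic *anchor* primer placed in
    a user-chosen region (typically the origin, roughly opposite the
    mutation).  The two products are later joined in vitro, which needs at
    least 15 bp of terminal identity at both junctions — so the mutagenic
    pair is designed with its overlap bounds raised to >= 15 bp, and the
    anchor primers overlap each other by >= 15 bp as well.

    Returns ``(mutagenic_pair, anchor_pair)``.
    """
    lo, hi = anchor_span
    if not (1 <= lo <= hi <= len(ctx.plasmid)):
        raise RangeInvalid(f"anchor span {anchor_span} outside template")
    a0, a1 = lo - 1, hi  # 0-based half-open
    c0, c1 = ctx.codon_span0(aa_position)
    if a0 < c1 and c0 < a1:
        raise AnchorOverlapsMutation(
            f"anchor span {anchor_span} overlaps the codon of residue {aa_position}"
        )
    p15 = replace(
        params,
        min_overlap=max(params.min_overlap, 15),
        max_overlap=max(params.max_overlap, 15),
    )
    mut_pair = _enumerate(ctx, aa_position, p15, p15.min_tm)[0]
    # the anchor must also clear the mutagenic primer footprint
    ma, mb = mut_pair.reverse.template_span[0] - 1, mut_pair.forward.template_span[1]
    if a0 < mb and ma < a1:
        raise AnchorOverlapsMutation(
            "anchor span overlaps the mutagenic primer region"
        )
    anchor_pair = _design_anchor_pair(ctx, (a0, a1), p15)[0]
    return mut_pair, anchor_pair


def simulate_two_fragment(
    ctx: TemplateContext, mut_pair: PrimerPair, anchor_pair: PrimerPair
) -> str:
    """Simulate the two half-plasmid PCRs and their in-vitro assembly.

    Fragment 1 runs from the mutagenic forward primer around the circle to
    the anchor reverse primer; fragment 2 from the anchor forward primer to
    the mutagenic reverse primer.  Terminal identities at both junctions are
    verified before joining; returns the assembled circular sequence in the
    template frame.
    """
    n = len(ctx.plasmid)
    wt = ctx.plasmid
    s_m = mut_pair.forward.template_span[0] - 1
    fb_m = mut_pair.forward.template_span[1]
    ra_m = mut_pair.reverse.template_span[0] - 1
    e_m = mut_pair.reverse.template_span[1]
    s_a = anchor_pair.forward.template_span[0] - 1
    fb_a = anchor_pair.forward.template_span[1]
    ra_a = anchor_pair.reverse.template_span[0] - 1
    e_a = anchor_pair.reverse.template_span[1]
    k_m, k_a = mut_pair.overlap_len, anchor_pair.overlap_len

    frag1 = (
        mut_pair.forward.sequence
        + _circ_slice(wt, fb_m, ra_a)
        + seqcore.reverse_complement(anchor_pair.reverse.sequence)
    )
    frag2 = (
        anchor_pair.forward.sequence
        + _circ_slice(wt, fb_a, ra_m)
        + seqcore.reverse_complement(mut_pair.reverse.sequence)
    )
    if frag1[-k_a:] != frag2[:k_a]:
        raise JunctionMismatch("anchor junction ends differ")
    if frag2[-k_m:] != frag1[:k_m]:
        raise JunctionMismatch("mutation junction ends differ")
    circ = frag1 + frag2[k_a : len(frag2) - k_m]
    if len(circ) != n:
        raise JunctionMismatch("assembled circle has the wrong length")
    shift = (n - s_m) % n
    return circ[shift:] + circ[:shift]
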