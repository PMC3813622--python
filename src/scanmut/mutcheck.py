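"""Verification of mutant sequencing reads by gapless offset-scan alignment.

A read is slid along the reference at every possible offset; at each offset
the score is the number of positions where a sliding window of 7 aligned
bases matches perfectly.  The score peak locates the alignment; two or more
comparable peaks indicate a rearranged (non-productive) clone, e.g. a
duplication.  Gaps are deliberately not modelled: the workflow looks for
substitutions, and indels surface as ambiguous or unalignable reads.

After alignment, aligned bases are compared position by position, grouped by
reference codon, and each differing codon is reported as an amino-acid
change (``A25D``; silent changes are flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import seqcore
from .errors import NoOverlap

#: number of consecutive matching bases required for a window to count
WINDOW = 7

AS_IS = "as_is"
REVERSE_COMPLEMENT = "reverse_complement"
AUTO = "auto"

_N = ord("N")


@dataclass(frozen=True)
class ReferenceContext:
    """Reference coding sequence (starting at the first ATG) plus the
    1-based residue interval used for headline reporting."""

    sequence: str
    region_of_interest: Optional[tuple[int, int]] = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", seqcore.normalize_sequence(self.sequence))
        if len(self.sequence) < 3:
            raise ValueError("reference shorter than one codon")
        n_aa = len(self.sequence) // 3
        region = self.region_of_interest or (1, n_aa)
        if not (1 <= region[0] <= region[1] <= n_aa):
            raise ValueError(f"region {region} outside translated length {n_aa}")
        object.__setattr__(self, "region_of_interest", region)


@dataclass
class AlignmentResult:
    best_offset: int
    profile: dict[int, int]
    peaks: list[int]
    ambiguous: bool
    oriented_read: str
    orientation: str
    max_score: int
    uncallable_nt: list[int] = field(default_factory=list)  # 1-based ref positions


@dataclass(frozen=True)
class MutationCall:
    """One codon-level difference between read and reference."""

    aa_position: int
    ref_aa: str
    obs_aa: str
    codon_ref: str
    codon_obs: str
    nt_changes: tuple[tuple[int, str, str], ...]  # (1-based nt pos, ref, obs)
    silent: bool
    in_region: bool

    @property
    def label(self) -> str:
        tag = f"{self.ref_aa}{self.aa_position}{self.obs_aa}"
        return tag + "(silent)" if self.silent else tag


def window_score(ref: str, read: str, offset: int) -> int:
    """Score of the read placed at ``offset`` on the reference.

    ``offset`` is the reference position aligned with the read's first base
    (negative values hang the read off the reference's left end).  The score
    counts window start positions where all 7 aligned bases match; a
    position involving ``N`` on either side never matches.  Overlaps shorter
    than the window score 0.
    """
    start = max(0, offset)
    end = min(len(ref), offset + len(read))
    n = end - start
    if n < WINDOW:
        return 0
    a = np.frombuffer(ref[start:end].encode(), dtype=np.uint8)
    b = np.frombuffer(read[start - offset : end - offset].encode(), dtype=np.uint8)
    m = (a == b) & (a != _N) & (b != _N)
    runs = np.convolve(m.astype(np.int32), np.ones(WINDOW, dtype=np.int32), "valid")
    return int(np.count_nonzero(runs == WINDOW))


def score_profile(
    ref: str, read: str, ambiguity_fraction: float = 0.5
) -> AlignmentResult:
    """Score every offset with >= 7 bp of overlap and locate the peak(s).

    Peaks are all offsets scoring at least ``ambiguity_fraction`` of the
    maximum; more than one peak marks the alignment ambiguous.  The best
    offset is the smallest argmax.  Raises :class:`NoOverlap` when no offset
    scores above zero.
    """
    if not ref or not read:
        raise NoOverlap("empty sequence")
    profile: dict[int, int] = {}
    for offset in range(WINDOW - len(read), len(ref) - WINDOW + 1):
        profile[offset] = window_score(ref, read, offset)
    max_score = max(profile.values(), default=0)
    if max_score <= 0:
        raise NoOverlap("no 7-base window matches at any offset")
    best = min(o for o, s in profile.items() if s == max_score)
    peaks = sorted(o for o, s in profile.items() if s >= ambiguity_fraction * max_score)
    return AlignmentResult(
        best_offset=best,
        profile=profile,
        peaks=peaks,
        ambiguous=len(peaks) > 1,
        oriented_read=read,
        orientation=AS_IS,
        max_score=max_score,
    )


def orient_read(ref: str, read: str, mode: str = AUTO) -> tuple[str, str]:
    """Return ``(oriented_read, orientation)`` for the requested mode.

    ``auto`` scores both orientations and keeps the higher-scoring one
    (ties prefer the read as given); the explicit modes mirror the
    reverse-complement checkbox for reads sequenced with reverse primers.
    """
    if mode == AS_IS:
        return read, AS_IS
    if mode == REVERSE_COMPLEMENT:
        return seqcore.reverse_complement(read), REVERSE_COMPLEMENT
    if mode != AUTO:
        raise ValueError(f"unknown orientation mode {mode!r}")
    rc = seqcore.reverse_complement(read)

    def best(seq: str) -> int:
        try:
            return score_profile(ref, seq).max_score
        except NoOverlap:
            return 0
    return (read, AS_IS) if best(read) >= best(rc) else (rc, REVERSE_COMPLEMENT)


def align_and_call(
    refctx: ReferenceContext,
    read: str,
    mode: str = AUTO,
    ambiguity_fraction: float = 0.5,
) -> tuple[AlignmentResult, list[MutationCall]]:
    """Orient and align a read, then call codon-level differences.

    Only codons fully covered by the read are called; read positions with
    ``N`` are recorded as uncallable reference positions instead of
    mutations.  All differing codons are returned, each flagged with
    ``in_region`` for headline filtering; if the alignment is ambiguous the
    calls are still made at the best offset and the result carries the flag.
    """
    ref = refctx.sequence
    read = seqcore.normalize_sequence(read)
    oriented, orientation = orient_read(ref, read, mode)
    result = score_profile(ref, oriented, ambiguity_fraction)
    result.oriented_read = oriented
    result.orientation = orientation

    offset = result.best_offset
    start = max(0, offset)
    end = min(len(ref), offset + len(oriented))
    lo_aa, hi_aa = refctx.region_of_interest
    calls: list[MutationCall] = []
    first_codon = (start + 2) // 3  # first codon fully covered
    last_codon = end // 3  # one past the last fully covered codon
    for ci in range(first_codon, last_codon):
        codon_ref = ref[3 * ci : 3 * ci + 3]
        codon_obs = oriented[3 * ci - offset : 3 * ci + 3 - offset]
        if codon_obs == codon_ref:
            continue
        if "N" in codon_obs:
            result.uncallable_nt.extend(
                3 * ci + j + 1 for j in range(3) if codon_obs[j] == "N"
            )
            continue
        nt_changes = tuple(
            (3 * ci + j + 1, codon_ref[j], codon_obs[j])
            for j in range(3)
            if codon_ref[j] != codon_obs[j]
        )
        ref_aa = seqcore.translate(codon_ref)
        obs_aa = seqcore.translate(codon_obs)
        calls.append(
            MutationCall(
                aa_position=ci + 1,
                ref_aa=ref_aa,
                obs_aa=obs_aa,
                codon_ref=codon_ref,
                codon_obs=codon_obs,
                nt_changes=nt_changes,
                silent=ref_aa == obs_aa,
                in_region=lo_aa <= ci + 1 <= hi_aa,
            )
        )
    return result, calls


def batch_check(
    refctx: ReferenceContext,
    reads: Iterable[tuple[str, str]],
    mode: str = AUTO,
    expected: Optional[Mapping[str, str]] = None,
    ambiguity_fraction: float = 0.5,
) -> pd.DataFrame:
    """Check a batch of named reads and tabulate one row per read.

    ``expected`` optionally maps read names to an expected mutation label
    (e.g. ``"A25D"``); matched reads get the verdict
    ``expected-mutation-present``.  Verdicts are otherwise ``clean``,
    ``unexpected``, ``ambiguous`` or ``no-overlap``.  Row order follows the
    input; duplicate read names are suffixed deterministically.
    """
    import warnings as _warnings

    rows = []
    seen: dict[str, int] = {}
    for name, seq in reads:
        if name in seen:
            seen[name] += 1
            unique = f"{name}_{seen[name]}"
            _warnings.warn(f"duplicate read name {name!r} renamed to {unique!r}",
                           stacklevel=2)
        else:
            seen[name] = 1
            unique = name
        row = {
            "read": unique,
            "best_offset": pd.NA,
            "max_score": 0,
            "ambiguous": False,
            "calls": "",
            "verdict": "",
        }
        try:
            result, calls = align_and_call(refctx, seq, mode, ambiguity_fraction)
        except NoOverlap:
            row["verdict"] = "no-overlap"
            rows.append(row)
            continue
        region_calls = [c for c in calls if c.in_region]
        row["best_offset"] = result.best_offset
        row["max_score"] = result.max_score
        row["ambiguous"] = result.ambiguous
        row["calls"] = ",".join(c.label for c in region_calls)
        want = expected.get(name) if expected else None
        if result.ambiguous:
            row["verdict"] = "ambiguous"
        elif want is not None and want in {c.label for c in region_calls}:
            row["verdict"] = "expected-mutation-present"
        elif not region_calls:
            row["verdict"] = "clean"
        else:
            row["verdict"] = "unexpected"
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["read", "best_offset", "max_score", "ambiguous", "calls", "verdict"]
    )


def profile_table(result: AlignmentResult) -> pd.DataFrame:
    """The score-vs-offset profile as a two-column table."""
    offsets = sorted(result.profile)
    return pd.DataFrame(
        {"offset": offsets, "score": [result.profile[o] for o in offsets]}
    )
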