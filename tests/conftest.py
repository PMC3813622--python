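"""Shared fixtures and independent oracles.

The oracles here re-derive every quantity from raw strings with their own
arithmetic — they deliberately share no code with the package so that a bug
in the implementation cannot hide in its own checker.
"""

from __future__ import annotations

import pytest

from scanmut import DesignParams, TemplateContext
from scanmut.fixtures import FixtureSpec, generate_fixture

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def tm_of(seq: str) -> float:
    gc = sum(1 for b in seq if b in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def clamp_run_of(seq: str) -> int:
    n = 0
    for b in reversed(seq):
        if b not in "GC":
            break
        n += 1
    return n


def clamp_score_of(seq: str) -> int:
    s = [b in "GC" for b in seq[-3:]]
    if s[0] and s[1] and s[2]:
        return 0
    if not s[2]:
        return 1
    if not s[1]:
        return 2
    return 3


def brute_force_window_score(ref: str, read: str, offset: int, w: int = 7) -> int:
    """Double-loop sliding-window score, the alignment oracle."""
    start, end = max(0, offset), min(len(ref), offset + len(read))
    score = 0
    for i in range(start, end - w + 1):
        ok = True
        for j in range(w):
            a, b = ref[i + j], read[i + j - offset]
            if a != b or a == "N" or b == "N":
                ok = False
                break
        if ok:
            score += 1
    return score


def oracle_candidate(
    plasmid: str,
    mut_plasmid: str,
    c0: int,
    a: int,
    b: int,
    strand: str,
    params: DesignParams,
    min_tm: float,
):
    """Independent per-primer feasibility check for span [a, b).

    Returns (tm_anneal, clamp_score, carries) or None.
    """
    if a < 0 or b > len(plasmid):
        return None
    covers = a <= c0 and b >= c0 + 3
    if not covers and not (b <= c0 or a >= c0 + 3):
        return None
    top = mut_plasmid[a:b]
    matched = "".join(
        ch for i, ch in zip(range(a, b), top) if plasmid[i] == ch
    )
    tm_anneal = tm_of(matched)
    if not min_tm <= tm_anneal <= params.max_tm:
        return None
    oligo = top if strand == "f" else rc(top)
    if clamp_run_of(oligo) < params.min_gc_clamp:
        return None
    if covers:
        anneal = b - (c0 + 3) if strand == "f" else c0 - a
        if anneal < params.min_anneal_len:
            return None
    return tm_anneal, clamp_score_of(oligo), covers


def oracle_feasible_geometries(
    plasmid: str, c0: int, mut_codon: str, params: DesignParams, min_tm: float
):
    """All feasible (s, k, len_f, len_r) geometries with their ranking keys."""
    mut_plasmid = plasmid[:c0] + mut_codon + plasmid[c0 + 3 :]
    out = []
    for s in range(c0 + 3 - params.max_len, c0 + params.max_len - params.min_overlap + 1):
        for k in range(params.min_overlap, params.max_overlap + 1):
            for len_f in range(max(params.min_len, k), params.max_len + 1):
                f = oracle_candidate(
                    plasmid, mut_plasmid, c0, s, s + len_f, "f", params, min_tm
                )
                if f is None:
                    continue
                for len_r in range(max(params.min_len, k), params.max_len + 1):
                    r = oracle_candidate(
                        plasmid, mut_plasmid, c0, s + k - len_r, s + k, "r",
                        params, min_tm,
                    )
                    if r is None:
                        continue
                    if not (f[2] or r[2]):
                        continue
                    if abs(f[0] - r[0]) > params.max_delta_tm:
                        continue
                    key = [
                        max(len_f, len_r),
                        len_f + len_r,
                        (f[0] - min_tm) + (r[0] - min_tm),
                    ]
                    if params.use_optimised_gc_clamp:
                        key.append(-(f[1] + r[1]))
                    key.extend([s + 1, k, len_f])  # s is 1-based in the key
                    out.append((tuple(key), (s, k, len_f, len_r)))
    return out


def oracle_best_geometry(plasmid, c0, mut_codon, params, min_tm):
    feas = oracle_feasible_geometries(plasmid, c0, mut_codon, params, min_tm)
    if not feas:
        return None
    return min(feas)[1]


def pair_geometry(pair):
    """(s, k, len_f, len_r) of a designed pair, 0-based overlap start."""
    s = pair.forward.template_span[0] - 1
    k = pair.reverse.template_span[1] - s
    return (s, k, len(pair.forward.sequence), len(pair.reverse.sequence))


def validate_pair(plasmid: str, c0: int, pair, params: DesignParams, min_tm: float):
    """Re-derive every constraint of an emitted pair from raw sequences;
    raises AssertionError on the first violation."""
    s, k, len_f, len_r = pair_geometry(pair)
    assert params.min_overlap <= k <= params.max_overlap
    mut_plasmid = plasmid[:c0] + pair.mutated_codon + plasmid[c0 + 3 :]
    fa, fb = pair.forward.template_span[0] - 1, pair.forward.template_span[1]
    ra, rb = pair.reverse.template_span[0] - 1, pair.reverse.template_span[1]
    assert pair.forward.sequence == mut_plasmid[fa:fb]
    assert pair.reverse.sequence == rc(mut_plasmid[ra:rb])
    assert params.min_len <= len_f <= params.max_len
    assert params.min_len <= len_r <= params.max_len
    tms = []
    for (a, b), strand, cand in (
        ((fa, fb), "f", pair.forward),
        ((ra, rb), "r", pair.reverse),
    ):
        got = oracle_candidate(plasmid, mut_plasmid, c0, a, b, strand, params, min_tm)
        assert got is not None, "emitted primer fails the independent validator"
        tm_anneal, _, covers = got
        assert abs(cand.tm_anneal - tm_anneal) < 1e-9
        assert covers == cand.carries_mutation
        tms.append(tm_anneal)
    assert abs(tms[0] - tms[1]) <= params.max_delta_tm
    assert abs(pair.delta_tm - abs(tms[0] - tms[1])) < 1e-9
    assert pair.forward.carries_mutation or pair.reverse.carries_mutation


@pytest.fixture(scope="session")
def small_fixture():
    """600 bp plasmid with an 80-codon ORF — the workhorse template."""
    return generate_fixture(
        FixtureSpec(seed=11, plasmid_length=600, orf_length_aa=80)
    )


@pytest.fixture(scope="session")
def default_params():
    return DesignParams()


@pytest.fixture(scope="session")
def kilobase_fixture():
    """3 kb plasmid with a 120-codon ORF for circular/two-fragment tests."""
    return generate_fixture(
        FixtureSpec(seed=23, plasmid_length=3000, orf_length_aa=120)
    )
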