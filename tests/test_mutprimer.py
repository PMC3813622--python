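"""Tests for the mutagenic primer designer: codon choice, oracle-checked
enumeration, adaptive Tm relaxation, batches, PCR simulation, two-fragment."""

from dataclasses import replace

import pytest

from scanmut import DesignParams, TemplateContext, mutprimer
from scanmut.errors import (
    AnchorOverlapsMutation,
    EndMismatch,
    NoFeasiblePrimer,
    PositionOutOfRange,
    RangeInvalid,
)
from scanmut.fixtures import FixtureSpec, generate_fixture

from conftest import (
    oracle_best_geometry,
    oracle_feasible_geometries,
    pair_geometry,
    validate_pair,
)


class TestChooseMutationCodon:
    @pytest.mark.parametrize(
        "template,expected_codon,expected_aa",
        [
            ("TCT", "GCT", "A"),  # Ser: GCT needs 1 mismatch, GCC needs 2
            ("GCA", "GGT", "G"),  # already Ala -> fallback Gly, tie -> first
            ("GAA", "GCT", "A"),  # tie 2-2 -> first listed
        ],
    )
    def test_examples(self, template, expected_codon, expected_aa):
        codon, aa = mutprimer.choose_mutation_codon(template, DesignParams())
        assert (codon, aa) == (expected_codon, expected_aa)


class TestEnumeratePairs:
    def test_top_pair_matches_exhaustive_oracle(self, default_params):
        """The designer's top choice equals the optimum of an independent
        exhaustive search under the documented ranking, across fixtures."""
        for seed in range(6):
            fx = generate_fixture(
                FixtureSpec(seed=100 + seed, plasmid_length=500, orf_length_aa=50)
            )
            residue = 10 + 5 * seed
            c0, _ = fx.ctx.codon_span0(residue)
            mut_codon, _ = mutprimer.choose_mutation_codon(
                fx.ctx.wt_codon(residue), default_params
            )
            expect = oracle_best_geometry(
                fx.ctx.plasmid, c0, mut_codon, default_params, default_params.min_tm
            )
            if expect is None:
                with pytest.raises(NoFeasiblePrimer):
                    mutprimer.enumerate_pairs(fx.ctx, residue, default_params)
                continue
            pair = mutprimer.enumerate_pairs(fx.ctx, residue, default_params)[0]
            assert pair_geometry(pair) == expect

    def test_emitted_pairs_pass_independent_validator(
        self, small_fixture, default_params
    ):
        params = replace(default_params, max_suggestions=10)
        pairs = mutprimer.enumerate_pairs(small_fixture.ctx, 40, params)
        c0, _ = small_fixture.ctx.codon_span0(40)
        for pair in pairs:
            validate_pair(
                small_fixture.ctx.plasmid, c0, pair, params, params.min_tm
            )

    def test_postconditions_on_returned_pair(self, small_fixture, default_params):
        pair = mutprimer.enumerate_pairs(small_fixture.ctx, 30, default_params)[0]
        assert default_params.min_overlap <= pair.overlap_len <= default_params.max_overlap
        assert pair.delta_tm <= default_params.max_delta_tm
        assert pair.forward.carries_mutation or pair.reverse.carries_mutation

    def test_mutation_in_overlap_carried_by_both(self, small_fixture):
        """When the codon sits inside the overlap window, both primers must
        carry identical mutated bases."""
        params = replace(DesignParams(), max_suggestions=500)
        pairs = mutprimer.enumerate_pairs(
            small_fixture.ctx, 40, params, truncate=False
        )
        c0, c1 = small_fixture.ctx.codon_span0(40)
        in_overlap = [
            p
            for p in pairs
            if p.forward.template_span[0] - 1 <= c0
            and c1 <= p.reverse.template_span[1]
        ]
        assert in_overlap, "expected at least one overlap-covering geometry"
        for p in in_overlap:
            assert p.forward.carries_mutation and p.reverse.carries_mutation
            # identical mutated bases: both sequences embed the same codon
            f_off = c0 - (p.forward.template_span[0] - 1)
            assert p.forward.sequence[f_off : f_off + 3] == p.mutated_codon

    def test_position_without_flank_raises(self, default_params):
        import numpy as np

        from scanmut.fixtures import _random_bases, random_orf

        rng = np.random.default_rng(5)
        # ORF starts 10 bp into the template: residue 1 lacks a max_len flank
        plasmid = _random_bases(rng, 10, 0.5) + random_orf(rng, 90, 0.5) + _random_bases(rng, 100, 0.5)
        ctx = TemplateContext(plasmid=plasmid, orf_start=11, orf_length_aa=90)
        with pytest.raises(PositionOutOfRange):
            mutprimer.enumerate_pairs(ctx, 1, default_params)

    def test_feasible_set_monotonicity(self, small_fixture, default_params):
        """Widening length/overlap windows or lowering min Tm never removes
        a feasible geometry."""
        c0, _ = small_fixture.ctx.codon_span0(35)
        mut_codon, _ = mutprimer.choose_mutation_codon(
            small_fixture.ctx.wt_codon(35), default_params
        )

        def feasible(params, min_tm):
            return {
                g
                for _, g in oracle_feasible_geometries(
                    small_fixture.ctx.plasmid, c0, mut_codon, params, min_tm
                )
            }

        base = feasible(default_params, default_params.min_tm)
        assert base
        wider_len = replace(default_params, max_len=default_params.max_len + 5)
        wider_ov = replace(default_params, min_overlap=12)
        lower_tm = default_params
        assert base <= feasible(wider_len, wider_len.min_tm)
        assert base <= feasible(wider_ov, wider_ov.min_tm)
        assert base <= feasible(lower_tm, default_params.min_tm - 2)

    def test_determinism(self, small_fixture, default_params):
        a = mutprimer.enumerate_pairs(small_fixture.ctx, 40, default_params)
        b = mutprimer.enumerate_pairs(small_fixture.ctx, 40, default_params)
        assert a == b


class TestAdaptiveTm:
    def test_no_relaxation_when_feasible(self, small_fixture, default_params):
        pairs, relaxed = mutprimer.design_with_adaptive_tm(
            small_fixture.ctx, 40, default_params
        )
        assert relaxed == default_params.min_tm
        assert pairs == mutprimer.enumerate_pairs(small_fixture.ctx, 40, default_params)

    def test_relaxes_on_gc_poor_region(self):
        """An AT-rich codon environment forces the Tm floor down; the result
        must equal direct enumeration at the relaxed threshold."""
        fx = generate_fixture(
            FixtureSpec(seed=42, plasmid_length=700, orf_length_aa=80, gc_fraction=0.30)
        )
        params = replace(DesignParams(), min_tm=62.0, adaptive_tm=True)
        for residue in range(20, 60):
            try:
                mutprimer.enumerate_pairs(fx.ctx, residue, params)
            except NoFeasiblePrimer:
                break
        else:
            pytest.skip("no infeasible residue in this AT-rich fixture")
        pairs, relaxed = mutprimer.design_with_adaptive_tm(fx.ctx, residue, params)
        assert relaxed < params.min_tm
        assert pairs == mutprimer._enumerate(fx.ctx, residue, params, relaxed)

    def test_floor_reached_on_poly_a(self):
        plasmid = "A" * 200 + "ATG" + "AAA" * 40 + "TAA" + "A" * 200
        ctx = TemplateContext(plasmid=plasmid, orf_start=201, orf_length_aa=42)
        params = replace(DesignParams(), adaptive_tm=True)
        with pytest.raises(NoFeasiblePrimer):
            mutprimer.design_with_adaptive_tm(ctx, 20, params)


class TestBatchDesign:
    def test_single_position_range_equals_single_design(
        self, small_fixture, default_params
    ):
        entries = mutprimer.batch_design(small_fixture.ctx, 30, 30, default_params)
        assert len(entries) == 1
        assert entries[0].pairs == mutprimer.enumerate_pairs(
            small_fixture.ctx, 30, default_params
        )

    def test_range_oracle_checked(self, small_fixture, default_params):
        entries = mutprimer.batch_design(small_fixture.ctx, 30, 49, default_params)
        assert [e.aa_position for e in entries] == list(range(30, 50))
        c0_of = lambda r: small_fixture.ctx.codon_span0(r)[0]
        for e in entries:
            if not e.ok:
                continue
            c0 = c0_of(e.aa_position)
            mut_codon = e.pairs[0].mutated_codon
            expect = oracle_best_geometry(
                small_fixture.ctx.plasmid, c0, mut_codon, default_params,
                default_params.min_tm,
            )
            assert pair_geometry(e.pairs[0]) == expect

    def test_infeasible_position_is_isolated(self, default_params):
        import numpy as np

        from scanmut.fixtures import _random_bases, random_orf

        rng = np.random.default_rng(77)
        # no upstream flank at all: early residues fail, later ones succeed
        plasmid = random_orf(rng, 100, 0.5) + _random_bases(rng, 120, 0.5)
        ctx = TemplateContext(plasmid=plasmid, orf_start=1, orf_length_aa=100)
        entries = mutprimer.batch_design(ctx, 1, 60, default_params)
        assert any(not e.ok for e in entries)
        assert any(e.ok and e.pairs for e in entries)

    def test_invalid_range(self, small_fixture, default_params):
        with pytest.raises(RangeInvalid):
            mutprimer.batch_design(small_fixture.ctx, 5, 4, default_params)
        with pytest.raises(RangeInvalid):
            mutprimer.batch_design(small_fixture.ctx, 1, 999, default_params)


class TestSimulateMutagenesis:
    def test_product_differs_only_inside_codon(self, small_fixture, default_params):
        for residue in (20, 40, 60):
            pair = mutprimer.enumerate_pairs(
                small_fixture.ctx, residue, default_params
            )[0]
            mutant = mutprimer.simulate_mutagenesis(small_fixture.ctx, pair)
            c0, c1 = small_fixture.ctx.codon_span0(residue)
            diffs = [
                i
                for i, (a, b) in enumerate(zip(mutant, small_fixture.ctx.plasmid))
                if a != b
            ]
            assert diffs
            assert all(c0 <= i < c1 for i in diffs)

    def test_protein_changes_exactly_at_position(self, small_fixture, default_params):
        residue = 33
        pair = mutprimer.enumerate_pairs(small_fixture.ctx, residue, default_params)[0]
        mutant = mutprimer.simulate_mutagenesis(small_fixture.ctx, pair)
        ctx = small_fixture.ctx
        mut_ctx = TemplateContext(
            plasmid=mutant, orf_start=ctx.orf_start, orf_length_aa=ctx.orf_length_aa
        )
        wt_prot, mut_prot = ctx.protein(), mut_ctx.protein()
        changed = [i + 1 for i, (a, b) in enumerate(zip(wt_prot, mut_prot)) if a != b]
        assert changed == [residue]
        assert mut_prot[residue - 1] == pair.target_aa

    def test_tampered_reverse_primer_raises(self, small_fixture, default_params):
        pair = mutprimer.enumerate_pairs(small_fixture.ctx, 40, default_params)[0]
        seq = pair.reverse.sequence
        # the reverse oligo's 5' end lies inside the overlap: flip its 5' base
        flipped = ("A" if seq[0] != "A" else "T") + seq[1:]
        bad = replace(pair, reverse=replace(pair.reverse, sequence=flipped))
        with pytest.raises(EndMismatch):
            mutprimer.simulate_mutagenesis(small_fixture.ctx, bad)


class TestTwoFragment:
    def test_assembly_reproduces_mutant_plasmid(self, kilobase_fixture):
        params = DesignParams()
        ctx = kilobase_fixture.ctx
        mut_pair, anchor_pair = mutprimer.design_two_fragment(
            ctx, 60, (2400, 2700), params
        )
        assert mut_pair.overlap_len >= 15
        assert anchor_pair.overlap_len >= 15
        assembled = mutprimer.simulate_two_fragment(ctx, mut_pair, anchor_pair)
        expected = mutprimer.simulate_mutagenesis(ctx, mut_pair)
        assert assembled == expected
        c0, c1 = ctx.codon_span0(60)
        diffs = [i for i, (a, b) in enumerate(zip(assembled, ctx.plasmid)) if a != b]
        assert diffs and all(c0 <= i < c1 for i in diffs)

    def test_anchor_overlapping_codon_raises(self, kilobase_fixture):
        ctx = kilobase_fixture.ctx
        c0, c1 = ctx.codon_span0(60)
        with pytest.raises(AnchorOverlapsMutation):
            mutprimer.design_two_fragment(
                ctx, 60, (c0 - 10, c1 + 50), DesignParams()
            )

    def test_junction_identity_lengths(self, kilobase_fixture):
        ctx = kilobase_fixture.ctx
        mut_pair, anchor_pair = mutprimer.design_two_fragment(
            ctx, 80, (2500, 2850), DesignParams()
        )
        # junction identities are exactly the overlap windows of the pairs
        assert mut_pair.overlap_len >= 15
        assert anchor_pair.overlap_len >= 15
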