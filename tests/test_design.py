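"""Design engine: the gap->strand rule, enumeration vs an exhaustive
oracle, bystander counting, scoring, swap symmetry, off-target scan."""

import pytest

from mitobe import (CircularGenome, DesignParams, EditRequest, GenomicInterval,
                    MUTH, MUTH_STAR, NT_BSPD6I_C, TaleArm,
                    bystanders_in_window, enumerate_designs, plant_motif,
                    predict_nick_strand, random_circular_genome, score_design,
                    tale_offtarget_scan)
from mitobe.design import ARM_STRAND, designs_to_table
from oracles import brute_enumerate_designs


def _signature(c):
    return (c.window.start, len(c.window),
            c.anchor_site.duplex_start if c.anchor_site else None,
            c.nickase_arm.side, len(c.nickase_arm.binding) if c.nickase_arm.side == "left"
            else len(c.deaminase_arm.binding),
            len(c.deaminase_arm.binding) if c.nickase_arm.side == "left"
            else len(c.nickase_arm.binding),
            c.nick_strand, c.edited_strand, c.gap)


class TestNickStrandRule:
    """Gap 0-4 nicks the strand opposite the nickase TALE, 5-9 the TALE's
    own recognition strand; left arms recognize top, right arms bottom."""

    @pytest.mark.parametrize("gap,side,expected", [
        (0, "left", "bottom"), (3, "left", "bottom"), (4, "left", "bottom"),
        (5, "left", "top"), (6, "left", "top"), (9, "left", "top"),
        (3, "right", "top"), (6, "right", "bottom"),
    ])
    def test_muth_rule_table(self, gap, side, expected):
        assert predict_nick_strand(gap, MUTH, side) == expected

    def test_gap_outside_table_unsupported(self):
        assert predict_nick_strand(10, MUTH, "left") == "unsupported"
        assert predict_nick_strand(12, MUTH, "left") == "unsupported"

    def test_sequence_unrestricted_nicks_tale_strand(self):
        for gap in (0, 3, 7, 30):
            assert predict_nick_strand(gap, NT_BSPD6I_C, "right") == "bottom"
            assert predict_nick_strand(gap, NT_BSPD6I_C, "left") == "top"

    def test_unvalidated_nickase_raises(self):
        from mitobe import get_nickase
        with pytest.raises(ValueError, match="uncharacterized"):
            predict_nick_strand(3, get_nickase("I-TevI"), "left")


class TestEnumeration:
    def _planted(self, seed=23, pos=100):
        g = random_circular_genome(240, gc=0.5, seed=seed)
        return plant_motif(g, "GATC", pos)

    def test_t_to_c_requests_edit_bottom_strand(self):
        """Knocking out an ATG start codon edits the A on the noncoding
        (bottom) strand, so every candidate must have edited_strand=bottom."""
        g = self._planted()
        t_pos = next(p for p in range(96, 110) if g.sequence[p] == "T") + 1
        req = EditRequest(position=t_pos, ref="T", desired="C")
        cands, _ = enumerate_designs(g, req, MUTH,
                                     DesignParams(require_preceding_t=False))
        assert cands and all(c.edited_strand == "bottom" for c in cands)
        assert all(c.nick_strand == "top" for c in cands)

    def test_no_motif_in_range_reason(self):
        g = random_circular_genome(300, seed=31)
        from oracles import brute_scan
        # pick a target far (>40bp) from every GATN duplex window
        sites = brute_scan(g.sequence, "GATN")
        far = [p for p in range(g.length)
               if all(min((p - s) % g.length, (s - p) % g.length) > 40
                      for s, _ in sites)]
        if not far:
            pytest.skip("random genome left no motif-free stretch")
        pos = far[0]
        ref = g.sequence[pos]
        desired = {"A": "G", "T": "C", "C": "T", "G": "A"}[ref]
        cands, reasons = enumerate_designs(
            g, EditRequest(pos + 1, ref, desired), MUTH_STAR,
            DesignParams(require_preceding_t=False))
        assert cands == []
        assert reasons["no_motif_in_range"] > 0

    def test_reference_mismatch_raises(self):
        g = self._planted()
        ref = g.sequence[49]
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="reference mismatch"):
            enumerate_designs(g, EditRequest(50, wrong, {"A": "G", "C": "T"}[wrong]),
                              MUTH)

    @pytest.mark.parametrize("seed,preceding_t", [(23, False), (41, True), (57, False)])
    def test_enumeration_equals_brute_force_oracle(self, seed, preceding_t):
        g = self._planted(seed=seed, pos=100)
        t_pos = next(p for p in range(96, 112) if g.sequence[p] == "T") + 1
        req = EditRequest(position=t_pos, ref="T", desired="C")
        params = DesignParams(require_preceding_t=preceding_t)
        cands, _ = enumerate_designs(g, req, MUTH, params)
        got = {_signature(c) for c in cands}
        expected = brute_enumerate_designs(
            g.sequence, t_pos, "T", "C", "GATC", palindromic=True,
            require_preceding_t=preceding_t)
        assert got == expected

    def test_enumeration_oracle_muth_star(self):
        g = random_circular_genome(300, gc=0.45, seed=77)
        g = plant_motif(g, "GATA", 150)
        t_pos = next(p for p in range(146, 162) if g.sequence[p] == "A") + 1
        req = EditRequest(position=t_pos, ref="A", desired="G")
        cands, _ = enumerate_designs(g, req, MUTH_STAR,
                                     DesignParams(require_preceding_t=False))
        got = {_signature(c) for c in cands}
        expected = brute_enumerate_designs(
            g.sequence, t_pos, "A", "G", "GATN", palindromic=False,
            require_preceding_t=False)
        assert got == expected

    def test_edited_strand_never_nicked(self):
        g = self._planted()
        for p in range(95, 112):
            ref = g.sequence[p]
            desired = {"A": "G", "T": "C", "C": "T", "G": "A"}[ref]
            cands, _ = enumerate_designs(
                g, EditRequest(p + 1, ref, desired), MUTH,
                DesignParams(require_preceding_t=False))
            assert all(c.edited_strand != c.nick_strand for c in cands)

    def test_nonpalindromic_nick_strand_is_motif_strand(self):
        g = random_circular_genome(300, seed=91)
        g = plant_motif(g, "GATG", 140)
        for p in range(136, 155):
            ref = g.sequence[p]
            desired = {"A": "G", "T": "C", "C": "T", "G": "A"}[ref]
            cands, _ = enumerate_designs(
                g, EditRequest(p + 1, ref, desired), MUTH_STAR,
                DesignParams(require_preceding_t=False))
            for c in cands:
                assert c.nick_strand == c.anchor_site.strand

    def test_swap_symmetry(self):
        """Exchanging the nickase and deaminase arms at fixed binding sites
        flips the edited strand exactly when the gap class flips."""
        g = self._planted()
        t_pos = next(p for p in range(96, 112) if g.sequence[p] == "T") + 1
        ref_cands, _ = enumerate_designs(
            g, EditRequest(t_pos, "T", "C"), MUTH,
            DesignParams(require_preceding_t=False))
        by_geom = {}
        for c in ref_cands:
            key = (c.window.start, len(c.window), c.anchor_site.duplex_start,
                   len(c.nickase_arm.binding) if c.nickase_side == "left"
                   else len(c.deaminase_arm.binding))
            by_geom.setdefault(key, {})[c.nickase_side] = c
        # the same geometry with the swapped assignment serves the opposite
        # edited strand, so it appears in the A->G enumeration instead;
        # verify directly via the rule:
        for c in ref_cands:
            other_side = "right" if c.nickase_side == "left" else "left"
            gap_other = (len(c.window) - 4 - c.gap)
            swapped = predict_nick_strand(gap_other, MUTH, other_side) \
                if 0 <= gap_other <= 9 else "unsupported"
            if swapped == "unsupported":
                continue
            same_class = (c.gap <= 4) == (gap_other <= 4)
            if same_class:
                assert swapped != c.nick_strand  # other arm, other strand
            else:
                assert swapped == c.nick_strand

    def test_widening_deaminase_side_preserves_edited_strand(self):
        """Growing the window only on the deaminase side keeps the gap, so
        the edited strand never changes — only the window widens."""
        g = self._planted()
        t_pos = next(p for p in range(96, 104) if g.sequence[p] == "T") + 1
        cands, _ = enumerate_designs(g, EditRequest(t_pos, "T", "C"), MUTH,
                                     DesignParams(require_preceding_t=False))
        by_gap_side = {}
        for c in cands:
            by_gap_side.setdefault((c.gap, c.nickase_side,
                                    c.anchor_site.duplex_start), set()).add(
                (len(c.window), c.edited_strand))
        for variants in by_gap_side.values():
            assert len({s for _, s in variants}) == 1


class TestBystanders:
    def test_counts_ts_on_top_for_bottom_strand_abe(self):
        # window TTGATCTT, edited strand bottom: bottom A's mirror top T's
        g = CircularGenome(name="w", sequence="CCCC" + "TTGATCTT" + "CCCC")
        window = GenomicInterval(4, 12)
        target = 5  # 1-based, a T
        bys = bystanders_in_window(g, window, "bottom", "A", target)
        tops = [i + 5 for i in range(8) if g.sequence[4 + i] == "T"]
        assert list(bys) == sorted(set(tops) - {target})
        assert len(bys) == 4  # five T's minus the target

    def test_motif_internal_bases_included(self):
        g = CircularGenome(name="m", sequence="AAAA" + "GATC" + "AAAA")
        window = GenomicInterval(4, 8)
        # edited strand bottom, ABE: bottom A's under top T at position 7
        bys = bystanders_in_window(g, window, "bottom", "A", target_position=999)
        assert list(bys) == [7]

    def test_cbe_empty_when_no_substrate(self):
        g = CircularGenome(name="c", sequence="ATATATATATAT")
        bys = bystanders_in_window(g, GenomicInterval(0, 8), "top", "C", 1)
        assert bys == ()


class TestScoring:
    def _cand(self, bystanders=(), gap=3, wlen=10, toff=5, nickase=MUTH):
        from mitobe.design import DesignCandidate
        from mitobe.registry import TADA8E_V106W
        left = TaleArm(side="left", binding=GenomicInterval(0, 15),
                       bound_seq="A" * 15, preceded_by_t=True)
        right = TaleArm(side="right", binding=GenomicInterval(25, 40, strand="bottom"),
                        bound_seq="A" * 15, preceded_by_t=True)
        return DesignCandidate(
            nickase_arm=left, deaminase_arm=right, nickase=nickase,
            deaminase=TADA8E_V106W, anchor_site=None, gap=gap,
            window=GenomicInterval(15, 15 + wlen), nick_strand="top",
            edited_strand="bottom", target_position=16 + toff,
            target_offset=toff, target_in_window=True,
            bystanders=tuple(bystanders))

    def test_bystander_penalty_monotone(self):
        assert score_design(self._cand(bystanders=())) > \
            score_design(self._cand(bystanders=(1, 2, 3)))

    def test_gap3_bonus(self):
        assert score_design(self._cand(gap=3)) > score_design(self._cand(gap=1))

    def test_class_prior(self):
        assert score_design(self._cand(nickase=MUTH)) > \
            score_design(self._cand(nickase=NT_BSPD6I_C))

    def test_centrality(self):
        centred = self._cand(wlen=11, toff=5)
        edge = self._cand(wlen=11, toff=0)
        assert score_design(centred) > score_design(edge)

    def test_deterministic(self):
        c = self._cand(bystanders=(3, 9), gap=4)
        assert score_design(c) == score_design(c)


class TestOfftargetScan:
    def test_unique_arm_has_no_offtargets(self):
        g = random_circular_genome(600, seed=3)
        arm_seq = g.fetch(GenomicInterval(100, 115))
        arm = TaleArm(side="left", binding=GenomicInterval(100, 115),
                      bound_seq=arm_seq, preceded_by_t=True)
        hits0 = tale_offtarget_scan(g, arm, max_mismatch=0)
        assert hits0 == []

    def test_planted_single_mismatch_copy(self):
        g = random_circular_genome(600, seed=49)
        probe = "ACGTACGTACGTACG"
        g = plant_motif(g, probe, 50, instance=probe)
        variant = "ACGTACGTACGTACC"  # one substitution at the 3' end
        g = plant_motif(g, variant, 300, instance=variant)
        arm = TaleArm(side="left", binding=GenomicInterval(50, 65),
                      bound_seq=probe, preceded_by_t=True)
        hits1 = [h for h in tale_offtarget_scan(g, arm, max_mismatch=1)]
        assert any(h[0] == 300 and h[2] == 1 for h in hits1)
        hits0 = tale_offtarget_scan(g, arm, max_mismatch=0)
        assert all(h[0] != 300 for h in hits0)

    def test_matches_naive_hamming_oracle(self):
        g = random_circular_genome(400, seed=8)
        probe = g.fetch(GenomicInterval(10, 25))
        arm = TaleArm(side="left", binding=GenomicInterval(10, 25),
                      bound_seq=probe, preceded_by_t=True)
        got = {(h[0], h[1], h[2]) for h in tale_offtarget_scan(g, arm, max_mismatch=2)}
        from oracles import rc
        doubled = g.sequence + g.sequence
        expected = set()
        for strand in ("top", "bottom"):
            for start in range(g.length):
                w = doubled[start:start + 15]
                text = w if strand == "top" else rc(w)
                mm = sum(a != b for a, b in zip(probe, text))
                if mm <= 2 and (start, strand) != (10, "top"):
                    expected.add((start, strand, mm))
        assert got == expected


def test_designs_table_round_trip():
    g = random_circular_genome(240, seed=23)
    g = plant_motif(g, "GATC", 100)
    t_pos = next(p for p in range(96, 112) if g.sequence[p] == "T") + 1
    cands, _ = enumerate_designs(g, EditRequest(t_pos, "T", "C"), MUTH,
                                 DesignParams(require_preceding_t=False))
    df = designs_to_table(cands)
    assert len(df) == len(cands)
    assert (df["edited_strand"] == "bottom").all()
    # sorted by score descending with deterministic ties
    assert list(df["score"]) == sorted(df["score"], reverse=True)
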