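import numpy as np
import pytest

from srna_seeker.annotation_io import revcomp
from srna_seeker.igr_extraction import IGRecord
from srna_seeker.signal_finder import (
    SPACER_OPT,
    TAIL_WEIGHTS,
    Pwm,
    TerminatorParams,
    TranscriptionSignal,
    call_unit,
    load_default_pwms,
    scan_promoters,
    scan_terminators,
)

PWM35, PWM10 = load_default_pwms()
MAX_SCORE = PWM35.max_score() + PWM10.max_score()


def rand_seq(rng, n, gc=0.5):
    return "".join(rng.choice(list("ACGT"), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]))


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain Python, no shared scanning code)

def oracle_promoters(seq, threshold):
    """Score every (-35 offset, spacer) pair directly with Pwm.score."""
    hits = []
    for i in range(len(seq)):
        for spacer in range(15, 20):
            j = i + 6 + spacer
            if j + 6 > len(seq):
                continue
            score = (PWM35.score(seq[i:i + 6]) + PWM10.score(seq[j:j + 6])
                     - 0.5 * abs(spacer - SPACER_OPT))
            if score >= threshold:
                hits.append((score, i, j + 6, j + 6))
    # greedy best-first non-overlap, written independently
    hits.sort(key=lambda h: (-h[0], h[1], h[2]))
    kept = []
    for h in hits:
        if all(h[2] <= k[1] or h[1] >= k[2] for k in kept):
            kept.append(h)
    return sorted((round(h[0], 9), h[3]) for h in kept)


PAIR = {("G", "C"): 2.0, ("C", "G"): 2.0, ("A", "T"): 1.0, ("T", "A"): 1.0,
        ("G", "T"): 0.5, ("T", "G"): 0.5}


def oracle_terminators(seq, p: TerminatorParams):
    """Exhaustive (pos, stem, loop) enumeration with naive loops."""
    cands = []
    for i in range(len(seq)):
        for s in range(p.stem_min, p.stem_max + 1):
            for l in range(p.loop_min, p.loop_max + 1):
                span = 2 * s + l
                if i + span > len(seq):
                    continue
                pairs = [PAIR.get((seq[i + k], seq[i + span - 1 - k]), -2.0)
                         for k in range(s)]
                mism = sum(1 for x in pairs if x == -2.0)
                if mism > p.max_mismatch:
                    continue
                hairpin = sum(pairs) - p.loop_penalty_per_nt * (l - p.loop_min)
                tail = sum(w for m, w in enumerate(TAIL_WEIGHTS)
                           if i + span + m < len(seq) and seq[i + span + m] == "T")
                if hairpin >= p.hairpin_min and tail >= p.tail_min:
                    cands.append((hairpin + 2 * tail, i,
                                  min(i + span + 8, len(seq)), i + span))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    kept = []
    for c in cands:
        if all(c[2] <= k[1] or c[1] >= k[2] for k in kept):
            kept.append(c)
    return sorted((round(c[0], 9), c[3]) for c in kept)


# ---------------------------------------------------------------------------

class TestPwm:
    def test_consensus_maximizes_score(self):
        assert PWM35.score("TTGACA") == pytest.approx(PWM35.max_score())
        assert PWM10.score("TATAAT") == pytest.approx(PWM10.max_score())

    def test_mismatch_lowers_score(self):
        assert PWM35.score("TTGACC") < PWM35.score("TTGACA")

    def test_matrix_shape_validation(self):
        with pytest.raises(ValueError):
            Pwm("bad", np.zeros((3, 6)))


class TestScanPromoters:
    def test_exact_consensus_with_canonical_spacer(self):
        rng = np.random.default_rng(0)
        plant = "TTGACA" + "G" * 17 + "TATAAT"
        seq = "GGGGGGGGGG" + plant + "GGGGGGGGGG"
        hits = scan_promoters(seq, "+", threshold=14.0)
        assert len(hits) == 1
        h = hits[0]
        assert h.score == pytest.approx(MAX_SCORE)  # spacer penalty 0 at 17
        assert h.details["spacer_len"] == 17
        assert h.position == 10 + len(plant)  # base after the -10 box

    def test_all_a_sequence_below_threshold(self):
        assert scan_promoters("A" * 100, "+", threshold=14.0) == []

    def test_planted_consensus_recovered_at_argmax(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            bg = rand_seq(rng, 300)
            offset = int(rng.integers(30, 240))
            plant = "TTGACA" + rand_seq(rng, 17) + "TATAAT"
            seq = bg[:offset] + plant + bg[offset + len(plant):]
            hits = scan_promoters(seq, "+", threshold=14.0)
            expected_tss = offset + len(plant)
            assert any(abs(h.position - expected_tss) <= 1 for h in hits)
            # brute force agrees on score set and positions
            assert oracle_promoters(seq, 14.0) == sorted(
                (round(h.score, 9), h.position) for h in hits
            )

    def test_minus_strand_maps_positions_back(self):
        plant = "TTGACA" + "C" * 17 + "TATAAT"
        fwd = "GGGGGGGGGG" + plant + "GGGGGGGGGG"
        seq = revcomp(fwd)
        hits = scan_promoters(seq, "-", threshold=14.0)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        # TSS proxy sits just left of the -10 box in forward coordinates
        assert hits[0].position == len(seq) - 1 - (10 + len(plant))

    def test_strand_symmetry_preserves_scores(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = rand_seq(rng, 150, gc=0.6)
            plus = scan_promoters(seq, "+", threshold=10.0)
            minus = scan_promoters(revcomp(seq), "-", threshold=10.0)
            assert sorted(round(h.score, 9) for h in plus) == sorted(
                round(h.score, 9) for h in minus
            )


GOOD_TERMINATOR = "GCCGGC" + "TTTT" + "GCCGGC" + "TTTTTTTT"


class TestScanTerminators:
    def test_worked_example_scores(self):
        # 6 bp all-GC stem, 4 nt loop, full 8 T tail, no flanking sequence
        params = TerminatorParams(hairpin_min=8.0, tail_min=2.5)
        hits = scan_terminators(GOOD_TERMINATOR, "+", params)
        assert hits
        best = max(hits, key=lambda h: h.score)
        assert best.details["hairpin_score"] == pytest.approx(11.5)  # 12 - 0.5
        assert best.details["tail_score"] == pytest.approx(5.9)
        assert best.score == pytest.approx(23.3)
        assert best.position == 16  # first base of the U-tract

    def test_poly_a_has_no_hits(self):
        assert scan_terminators("A" * 80, "+") == []

    def test_weak_tail_fails_threshold(self):
        seq = "A" * 10 + "GCCGGC" + "TTTT" + "GCCGGC" + "AAAAAAAA" + "A" * 10
        params = TerminatorParams(hairpin_min=8.0, tail_min=2.5)
        positions_16 = [h for h in scan_terminators(seq, "+", params)
                        if h.details.get("hairpin_start") == 10]
        assert positions_16 == []

    def test_one_mismatch_allowed_two_rejected(self):
        stem = "GGGGCCCC"
        loop = "GAAA"
        perfect = stem + loop + revcomp(stem) + "T" * 8
        one_mm = stem + loop + ("A" + revcomp(stem)[1:]) + "T" * 8
        params = TerminatorParams(hairpin_min=8.0, tail_min=2.5)
        assert scan_terminators("AA" + perfect + "AA", "+", params)
        hits1 = scan_terminators("AA" + one_mm + "AA", "+", params)
        assert any(h.details["hairpin_score"] >= 8 for h in hits1)

    def test_strand_symmetry(self):
        seq = "ATAT" + GOOD_TERMINATOR + "ATATAT"
        params = TerminatorParams(hairpin_min=8.0, tail_min=2.5)
        plus = scan_terminators(seq, "+", params)
        minus = scan_terminators(revcomp(seq), "-", params)
        assert sorted(round(h.score, 9) for h in plus) == sorted(
            round(h.score, 9) for h in minus
        )

    @pytest.mark.parametrize("gc", [0.4, 0.6])
    def test_matches_brute_force_oracle_on_short_fixtures(self, gc):
        rng = np.random.default_rng(17)
        params = TerminatorParams(hairpin_min=6.0, tail_min=1.0)
        fixtures = [rand_seq(rng, int(n), gc) for n in rng.integers(16, 26, size=60)]
        fixtures += ["GCGC" + "AAA" + "GCGC" + "TTTTTTTT",
                     GOOD_TERMINATOR[:25], "T" * 25, "GC" * 12]
        for seq in fixtures:
            got = sorted((round(h.score, 9), h.position)
                         for h in scan_terminators(seq, "+", params))
            assert got == oracle_terminators(seq, params), seq


def _sig(kind, pos, strand):
    return TranscriptionSignal(kind, pos, strand, 20.0)


class TestCallUnit:
    IGR = IGRecord("IGR-1", 0, 600, 40, 560, None, None)

    def test_promoter_before_terminator_plus(self):
        u = call_unit(self.IGR, [_sig("promoter", 100, "+")],
                      [_sig("terminator", 300, "+")])
        assert u.complete_unit and u.unit_strand == "+"

    def test_promoter_only_is_incomplete(self):
        u = call_unit(self.IGR, [_sig("promoter", 100, "+")], [])
        assert not u.complete_unit and u.has_promoter and not u.has_terminator

    def test_wrong_order_is_incomplete(self):
        u = call_unit(self.IGR, [_sig("promoter", 300, "+")],
                      [_sig("terminator", 100, "+")])
        assert not u.complete_unit

    def test_minus_strand_direction_reversed(self):
        u = call_unit(self.IGR, [_sig("promoter", 300, "-")],
                      [_sig("terminator", 100, "-")])
        assert u.complete_unit and u.unit_strand == "-"

    def test_both_strands_tie_goes_plus(self):
        u = call_unit(
            self.IGR,
            [_sig("promoter", 100, "+"), _sig("promoter", 300, "-")],
            [_sig("terminator", 300, "+"), _sig("terminator", 100, "-")],
        )
        assert u.unit_strand == "+"

    def test_mixed_strands_do_not_pair(self):
        u = call_unit(self.IGR, [_sig("promoter", 100, "+")],
                      [_sig("terminator", 300, "-")])
        assert not u.complete_unit
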