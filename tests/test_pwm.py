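"""PWM parsing, matrix similarity scoring against exhaustive enumeration,
strand-aware scanning, and SNP consequence calling."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from promsnp.pwm import (
    PWM,
    SNPContext,
    TransfacParseError,
    classify_consequence,
    parse_transfac,
    rsnp_filter,
    scan,
    write_transfac,
)
from promsnp.sequtils import reverse_complement

SAMPLE_TRANSFAC = """\
DE  P$TATA_01
P0      A      C      G      T
01      1      1      1     97
02     97      1      1      1
03      1      1      1     97
04     97      1      1      1
05     97      1      1      1
06     97      1      1      1
XX
//
DE  P$UNIFORM_01
P0      A      C      G      T
01      25     25     25     25
02      25     25     25     25
XX
//
"""


def naive_mss(pwm: PWM, window: str) -> float:
    """Independent plain-loop reimplementation of the scoring rule."""
    L = len(pwm)
    freqs = [[(pwm.counts[i][j] + pwm.pseudocount) for j in range(4)] for i in range(L)]
    freqs = [[v / sum(row) for v in row] for row in freqs]
    info = []
    for row in freqs:
        info.append(sum(f * math.log(4 * f) for f in row if f > 0))

    def score(w):
        return sum(info[i] * freqs[i]["ACGT".index(w[i])] for i in range(L))

    lo = sum(info[i] * min(freqs[i]) for i in range(L))
    hi = sum(info[i] * max(freqs[i]) for i in range(L))
    if hi - lo < 1e-12:
        return 1.0
    return (score(window) - lo) / (hi - lo)


class TestTransfacIO:
    def test_parse_sample(self):
        pwms = parse_transfac(SAMPLE_TRANSFAC)
        assert [p.name for p in pwms] == ["P$TATA_01", "P$UNIFORM_01"]
        assert len(pwms[0]) == 6
        assert pwms[0].consensus == "TATAAA"

    def test_uniform_matrix_degenerate(self):
        uniform = parse_transfac(SAMPLE_TRANSFAC)[1]
        np.testing.assert_allclose(uniform.information, 0.0, atol=1e-12)
        assert uniform.min_score == uniform.max_score
        assert uniform.mss("AC") == 1.0  # every window trivially optimal

    def test_write_parse_round_trip(self):
        pwms = parse_transfac(SAMPLE_TRANSFAC)
        back = parse_transfac(write_transfac(pwms))
        assert [p.name for p in back] == [p.name for p in pwms]
        for a, b in zip(pwms, back):
            np.testing.assert_allclose(a.counts, b.counts)

    def test_malformed_row_reports_line_number(self):
        bad = SAMPLE_TRANSFAC.replace("02     97      1      1      1", "02     97      oops")
        with pytest.raises(TransfacParseError, match="line 4"):
            parse_transfac(bad)

    def test_missing_terminator(self):
        with pytest.raises(TransfacParseError, match="terminator"):
            parse_transfac(SAMPLE_TRANSFAC.rstrip().rstrip("/"))


class TestMSS:
    @pytest.fixture()
    def tata(self):
        return parse_transfac(SAMPLE_TRANSFAC)[0]

    def test_consensus_scores_one(self, tata):
        assert tata.mss("TATAAA") == pytest.approx(1.0)

    def test_anti_consensus_scores_zero(self, tata):
        # the minimal base at every position (any non-consensus base here)
        assert tata.mss("CCCCCC") == pytest.approx(0.0)

    def test_window_length_mismatch(self, tata):
        with pytest.raises(ValueError):
            tata.mss("TATA")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("L", [2, 3, 4])
    def test_exhaustive_enumeration_oracle(self, seed, L):
        """All 4^L windows: scores in [0,1], extremes attained, and agreement
        with an independent plain-loop scorer."""
        rng = np.random.default_rng(seed)
        pwm = PWM("random", rng.integers(0, 50, size=(L, 4)), pseudocount=0.5)
        scores = []
        for window in itertools.product("ACGT", repeat=L):
            w = "".join(window)
            s = pwm.mss(w)
            assert s == pytest.approx(naive_mss(pwm, w), abs=1e-10)
            assert -1e-9 <= s <= 1 + 1e-9
            scores.append(s)
        assert min(scores) == pytest.approx(0.0, abs=1e-9)
        assert max(scores) == pytest.approx(1.0, abs=1e-9)

    def test_exhaustive_oracle_length_six(self):
        rng = np.random.default_rng(7)
        pwm = PWM("random6", rng.integers(0, 30, size=(6, 4)), pseudocount=0.25)
        best = worst = None
        for window in itertools.product("ACGT", repeat=6):
            w = "".join(window)
            s = pwm.mss(w)
            assert s == pytest.approx(naive_mss(pwm, w), abs=1e-10)
            best = s if best is None else max(best, s)
            worst = s if worst is None else min(worst, s)
        assert best == pytest.approx(1.0, abs=1e-9)
        assert worst == pytest.approx(0.0, abs=1e-9)


class TestScan:
    @pytest.fixture()
    def tata(self):
        return parse_transfac(SAMPLE_TRANSFAC)[0]

    def test_planted_consensus_found_on_plus_strand(self, tata):
        seq = "C" * 10 + "TATAAA" + "C" * 10
        hits = [h for h in scan([tata], seq, 0.95) if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].offset == 10 and hits[0].mss == pytest.approx(1.0)

    def test_planted_reverse_complement_found_on_minus_strand(self, tata):
        site = reverse_complement("TATAAA")
        seq = "C" * 8 + site + "C" * 6
        hits = [h for h in scan([tata], seq, 0.95) if h.strand == "-"]
        assert len(hits) == 1
        # the site occupies [8, 14) on the given sequence
        assert hits[0].offset == 8 and hits[0].mss == pytest.approx(1.0)

    def test_threshold_above_one_empty(self, tata):
        assert scan([tata], "TATAAA" * 4, threshold=1.01) == []

    @given(st.text(alphabet="ACGT", min_size=8, max_size=40))
    def test_reverse_complement_symmetry(self, seq):
        tata = parse_transfac(SAMPLE_TRANSFAC)[0]
        fwd = scan([tata], seq, 0.8)
        rev = scan([tata], reverse_complement(seq), 0.8)
        n, L = len(seq), 6
        mirrored = {
            (h.pwm_id, n - h.offset - L, "+-"["+-".index(h.strand) ^ 1], round(h.mss, 9))
            for h in rev
        }
        assert {(h.pwm_id, h.offset, h.strand, round(h.mss, 9)) for h in fwd} == mirrored


def make_context(ref_mid: str, alt_mid: str, flank_left: str, flank_right: str,
                 snp_id: str = "snp1") -> SNPContext:
    assert len(flank_left) == 25 - 0  # SNP at offset 25 of a 51-mer
    ref = flank_left + ref_mid + flank_right
    alt = flank_left + alt_mid + flank_right
    return SNPContext(snp_id, ref, alt)


class TestClassifyConsequence:
    @pytest.fixture()
    def tata(self):
        return parse_transfac(SAMPLE_TRANSFAC)[0]

    def left_right(self):
        # CC-rich flanks cannot spawn accidental TATA sites
        return "C" * 25, "C" * 25

    def test_reference_only_site_is_loss(self, tata):
        # ref: ...C TATAAA C... with SNP at the second motif base (offset 25)
        left = "C" * 21 + "TATA"[:4]
        ref = "C" * 21 + "TATA" + "AA" + "C" * 24
        alt = ref[:25] + "C" + ref[26:]
        ctx = SNPContext("s", ref, alt)
        calls = classify_consequence([tata], ctx, threshold=0.85)
        assert [c.type for c in calls] == ["loss"]
        assert calls[0].mss_alt is None and calls[0].mss_ref >= 0.85

    def test_alternate_only_site_is_gain(self, tata):
        alt = "C" * 21 + "TATA" + "AA" + "C" * 24
        ref = alt[:25] + "C" + alt[26:]
        ctx = SNPContext("s", ref, alt)
        calls = classify_consequence([tata], ctx, threshold=0.85)
        assert [c.type for c in calls] == ["gain"]

    def test_score_change_when_both_pass(self):
        # a permissive matrix: one strongly conserved position plus a SNP
        # column with unequal but non-vanishing weights keeps both alleles
        # above threshold at slightly different scores
        counts = np.array([[97, 1, 1, 1]] * 4 + [[60, 40, 1, 1]] + [[97, 1, 1, 1]])
        pwm = PWM("P$SOFT_01", counts, pseudocount=0.0)
        ref = "G" * 21 + "AAAA" + "A" + "A" + "G" * 24
        alt = ref[:25] + "C" + ref[26:]
        ctx = SNPContext("s", ref, alt)
        calls = classify_consequence([pwm], ctx, threshold=0.5)
        [site] = [c for c in calls if c.offset == 21 and c.strand == "+"]
        assert site.type == "score_change"
        assert site.mss_ref is not None and site.mss_alt is not None
        assert site.mss_ref != site.mss_alt

    def test_allele_swap_antisymmetry(self, tata):
        ref = "C" * 21 + "TATAAA" + "C" * 24
        alt = ref[:25] + "G" + ref[26:]
        fwd = classify_consequence([tata], SNPContext("s", ref, alt))
        rev = classify_consequence([tata], SNPContext("s", alt, ref))
        swap = {"loss": "gain", "gain": "loss", "score_change": "score_change",
                "no_effect": "no_effect"}
        assert sorted((c.pwm_id, c.offset, c.strand, swap[c.type]) for c in fwd) == sorted(
            (c.pwm_id, c.offset, c.strand, c.type) for c in rev
        )
        for f in fwd:
            [r] = [r for r in rev if (r.pwm_id, r.offset, r.strand) == (f.pwm_id, f.offset, f.strand)]
            assert r.mss_ref == f.mss_alt and r.mss_alt == f.mss_ref

    def test_sites_not_overlapping_snp_excluded(self, tata):
        # motif far from the SNP: present for both alleles, not reported
        ref = "TATAAA" + "C" * 19 + "A" + "C" * 25
        alt = ref[:25] + "G" + ref[26:]
        calls = classify_consequence([tata], SNPContext("s", ref, alt))
        assert calls == []
        # with overlap_only disabled the invariant site appears as no_effect
        all_calls = classify_consequence([tata], SNPContext("s", ref, alt), overlap_only=False)
        assert {c.type for c in all_calls} == {"no_effect"}

    def test_context_invariants_enforced(self):
        with pytest.raises(ValueError):
            SNPContext("s", "A" * 51, "A" * 51)  # no difference
        with pytest.raises(ValueError):
            SNPContext("s", "A" * 51, "A" * 20 + "C" + "A" * 30)  # wrong offset


class TestRsnpFilter:
    def mk(self, snp, typ):
        from promsnp.pwm import ConsequenceCall

        return ConsequenceCall(snp, "P$X_01", 0, "+", 0.9, 0.9, typ)

    def test_no_effect_only_excluded(self):
        assert rsnp_filter([self.mk("a", "no_effect")]) == []

    def test_single_gain_included(self):
        assert rsnp_filter([self.mk("a", "no_effect"), self.mk("b", "gain")]) == ["b"]

    def test_empty(self):
        assert rsnp_filter([]) == []
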