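import itertools
import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given
from hypothesis import strategies as st

from sugarminer.homology import (
    FRAMES,
    ScoringParams,
    SearchError,
    best_hit_confirm,
    bit_score,
    evalue,
    local_align,
    screen_transcriptome,
    six_frame_translate,
)
from sugarminer.simulate import back_translate

from oracles import batch_local_scores, enumerate_local_score, translate_oracle


class TestSixFrameTranslate:
    def test_forward_frame_standard_code(self):
        frames = {f.frame: f.sequence for f in six_frame_translate("ATGGCC")}
        assert frames[1] == "MA"

    def test_trailing_base_dropped(self):
        frames = {f.frame: f.sequence for f in six_frame_translate("ATGGCCA")}
        assert frames[1] == "MA"

    def test_exactly_six_frames(self):
        frames = six_frame_translate("ATGGCCTTT")
        assert [f.frame for f in frames] == list(FRAMES)

    def test_empty_gives_six_empty_frames(self):
        frames = six_frame_translate("")
        assert len(frames) == 6
        assert all(f.sequence == "" for f in frames)

    def test_illegal_character_rejected(self):
        with pytest.raises(SearchError, match="Z"):
            six_frame_translate("ATGZ")

    def test_stop_codon_rendered(self):
        frames = {f.frame: f.sequence for f in six_frame_translate("TAA")}
        assert frames[1] == "*"

    def test_reverse_frames_use_reverse_complement(self):
        # revcomp of ATGGCC is GGCCAT -> frame -1 translates GGC CAT = "GH"
        frames = {f.frame: f.sequence for f in six_frame_translate("ATGGCC")}
        assert frames[-1] == "GH"

    def test_matches_independent_codon_table_script(self):
        rng = random.Random(20240101)
        for trial in range(40):
            n = rng.randrange(0, 320)
            alpha = "ACGTN" if trial % 4 == 0 else "ACGT"
            nt = "".join(rng.choice(alpha) for _ in range(n))
            for fr in six_frame_translate(nt, "t"):
                assert fr.sequence == translate_oracle(nt, fr.frame), \
                    (nt, fr.frame)

    def test_frame_length_invariant(self):
        nt = "ACGTACGTACG"  # 11 nt
        for fr in six_frame_translate(nt):
            off = abs(fr.frame) - 1
            assert len(fr.sequence) == (len(nt) - off) // 3


class TestLocalAlign:
    def test_self_alignment_sums_diagonal(self):
        seq = "HEAGAWGHEE"
        mat = substitution_matrices.load("BLOSUM62")
        expected = sum(mat[c][c] for c in seq)
        hit = local_align(seq, seq)
        assert hit.score == expected
        assert hit.query_span == (1, len(seq))
        assert hit.subject_span == (1, len(seq))

    def test_empty_query_scores_zero(self):
        hit = local_align("", "ACDE")
        assert hit.score == 0.0
        assert hit.query_span == (0, 0)
        assert hit.subject_span == (0, 0)

    def test_spans_within_bounds(self):
        hit = local_align("MKVA", "AAMKVAAA")
        qs, qe = hit.query_span
        ss, se = hit.subject_span
        assert 1 <= qs <= qe <= 4
        assert 1 <= ss <= se <= 8

    def test_stop_symbol_blocks_readthrough(self):
        # the stop scores -1000 against residues, so the best local hit
        # stays on one side of it
        clean = local_align("MKVLAGHE", "MKVLAGHE").score
        split = local_align("MKVL*AGHE", "MKVLAGHE").score
        assert split < clean

    def test_dp_oracle_agrees_with_literal_enumeration(self):
        # validates the fast DP oracle itself against exhaustive
        # enumeration of every gapped local alignment on tiny strings
        mat = substitution_matrices.load("BLOSUM62")
        subd = {(a, b): float(mat[a][b]) for a in "ARN" for b in "ARN"}
        idx = {c: mat.alphabet.index(c) for c in "ARN"}
        arr = np.array(mat)
        strs = ["".join(p) for L in (1, 2)
                for p in itertools.product("ARN", repeat=L)]
        for q in strs:
            for s in strs:
                lit = enumerate_local_score(q, s, subd, 11, 1)
                Q = np.array([[idx[c] for c in q]])
                S = np.array([[idx[c] for c in s]])
                dp = batch_local_scores(Q, S, arr, 11, 1)[0]
                assert dp == pytest.approx(lit, abs=1e-9), (q, s)

    @pytest.mark.parametrize("matrix_name", ["BLOSUM62", "BLOSUM45"])
    def test_oracle_sample_every_shipped_matrix(self, matrix_name):
        mat = substitution_matrices.load(matrix_name)
        params = ScoringParams.for_matrix(matrix_name)
        idx = {c: mat.alphabet.index(c) for c in "ARN"}
        arr = np.array(mat)
        rng = random.Random(7)
        strs = ["".join(p) for L in range(1, 7)
                for p in itertools.product("ARN", repeat=L)]
        for _ in range(400):
            q, s = rng.choice(strs), rng.choice(strs)
            Q = np.array([[idx[c] for c in q]])
            S = np.array([[idx[c] for c in s]])
            want = batch_local_scores(Q, S, arr, params.gap_open,
                                      params.gap_extend)[0]
            assert local_align(q, s, params).score == pytest.approx(want), \
                (q, s)

    @given(st.text(alphabet="ARNDCQEGH", min_size=0, max_size=12),
           st.text(alphabet="ARNDCQEGH", min_size=0, max_size=12))
    def test_score_symmetry(self, a, b):
        assert local_align(a, b).score == local_align(b, a).score


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        p = ScoringParams()
        assert evalue(0.0, 100, 200, p) == pytest.approx(p.K * 100 * 200)

    def test_twelve_digit_reference_value(self):
        # E = 0.041 * 100 * 100 * exp(-0.267 * 30); independent arithmetic
        p = ScoringParams(K=0.041, lam=0.267)
        got = evalue(30.0, 100, 100, p)
        want = 0.041 * 1e4 * math.exp(-8.01)
        assert got == pytest.approx(want, rel=1e-12)

    def test_doubling_n_doubles_e(self):
        p = ScoringParams()
        assert evalue(25.0, 100, 400, p) == pytest.approx(
            2.0 * evalue(25.0, 100, 200, p))

    def test_strictly_decreasing_in_score(self):
        p = ScoringParams()
        es = [evalue(s, 100, 100, p) for s in range(0, 80, 5)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(SearchError):
            evalue(10.0, 0, 100, ScoringParams())

    def test_bit_score_formula(self):
        p = ScoringParams()
        want = (p.lam * 50.0 - math.log(p.K)) / math.log(2.0)
        assert bit_score(50.0, p) == pytest.approx(want, rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(SearchError):
            ScoringParams(lam=0.0)
        with pytest.raises(SearchError):
            ScoringParams(gap_open=-1.0)


BAIT = "MKVLAGHEWDETRNPQSICYFMKVLAGHEWDETRNPQSICYF"


def _transcript(protein: str) -> str:
    return back_translate(protein)


class TestScreenTranscriptome:
    def test_boundary_e_exactly_cutoff_kept(self):
        baits = [("bait", BAIT)]
        tx = [("t1", _transcript(BAIT))]
        probe = screen_transcriptome(baits, tx, ScoringParams(evalue_cutoff=1.0))
        e = probe["t1"]["hit"].evalue
        kept = screen_transcriptome(baits, tx, ScoringParams(evalue_cutoff=e))
        assert "t1" in kept
        excluded = screen_transcriptome(
            baits, tx, ScoringParams(evalue_cutoff=e * 0.999))
        assert "t1" not in excluded

    def test_unrelated_sequence_excluded(self):
        baits = [("bait", BAIT)]
        tx = [("junk", "ACGT" * 30)]
        assert screen_transcriptome(baits, tx) == {}

    def test_no_baits_is_error(self):
        with pytest.raises(SearchError):
            screen_transcriptome([], [("t", "ACGT")])

    def test_cutoff_monotonicity(self):
        baits = [("bait", BAIT)]
        tx = [("t1", _transcript(BAIT)),
              ("t2", _transcript(BAIT[:12])),
              ("t3", "ACGTACGTACGTACGTACGT")]
        strict = screen_transcriptome(baits, tx, ScoringParams(evalue_cutoff=1e-4))
        loose = screen_transcriptome(baits, tx, ScoringParams(evalue_cutoff=1e-3))
        assert set(strict) <= set(loose)

    def test_forward_gene_wins_forward_frame(self):
        baits = [("bait", BAIT)]
        tx = [("t1", "AC" + _transcript(BAIT) + "GT")]
        out = screen_transcriptome(baits, tx)
        assert out["t1"]["frame"] > 0

    def test_matched_region_is_substring_of_translation(self):
        baits = [("bait", BAIT)]
        tx = [("t1", "ACG" + _transcript(BAIT) + "TT")]
        rec = screen_transcriptome(baits, tx)["t1"]
        assert rec["matched_region"]
        assert rec["matched_region"] in rec["translation"]


class TestBestHitConfirm:
    def _candidates(self):
        baits = [("bait", BAIT)]
        tx = [("t1", _transcript(BAIT))]
        return screen_transcriptome(baits, tx)

    def test_family_best_hit_confirmed(self):
        cands = self._candidates()
        db = [("fam1", BAIT), ("dec1", "WWWWYYYYHHHHRRRRKKKK")]
        labels = {"fam1": "MST", "dec1": "decoy"}
        confirmed, audits = best_hit_confirm(cands, db, labels)
        assert "t1" in confirmed
        assert confirmed["t1"]["family"] == "MST"
        assert len(audits["t1"]) <= 50

    def test_decoy_best_hit_removed(self):
        cands = self._candidates()
        # the decoy is an exact copy, the family protein a weak relative
        db = [("fam1", BAIT[:14]), ("dec1", BAIT)]
        labels = {"fam1": "MST", "dec1": "decoy"}
        confirmed, _ = best_hit_confirm(cands, db, labels)
        assert confirmed == {}

    def test_empty_db_is_error(self):
        with pytest.raises(SearchError):
            best_hit_confirm(self._candidates(), [], {})

    def test_audit_k_respected(self):
        cands = self._candidates()
        db = [(f"p{i}", BAIT) for i in range(6)]
        labels = {f"p{i}": "MST" for i in range(6)}
        _, audits = best_hit_confirm(cands, db, labels, k=3)
        assert len(audits["t1"]) == 3
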