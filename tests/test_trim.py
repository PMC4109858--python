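"""Log-odds matrix estimation, gap penalties, and block trimming.

trim_block is checked against a brute-force oracle that applies the
trimming definitions literally on small blocks: choose the prefix cut
maximising the remaining score (ties -> longest cut), likewise the suffix,
then delete every non-positively scoring internal inter-gap segment and
repeat on the pieces until stable.
"""

import math

import numpy as np
import pytest

from selindel.alignio import extract_igs
from selindel.trim import (
    HALF_BIT_SCALE,
    ScoringMatrix,
    derive_gap_penalties,
    estimate_logodds_matrix,
    read_matrix_tsv,
    trim_block,
    trim_blocks,
    write_matrix_tsv,
)
from .conftest import BASES, make_block, random_block


def simple_matrix(match=2.0, mismatch=-3.0, gap_open=-4.0, gap_extend=-1.0):
    scores = np.full((4, 4), mismatch)
    np.fill_diagonal(scores, match)
    return ScoringMatrix(scores=scores, gap_open=gap_open, gap_extend=gap_extend)


class TestLogOddsMatrix:
    def test_independent_joint_gives_zero_scores(self):
        # all 16 ref/qry pairs equally often -> joint = product of marginals
        ref = "".join(a for a in BASES for _ in BASES) * 4
        qry = "".join(b for _ in BASES for b in BASES) * 4
        m = estimate_logodds_matrix([make_block(ref, qry)], pseudocount=1.0)
        assert np.allclose(m.scores, 0.0, atol=1e-12)

    def test_identity_alignment_sign_structure(self):
        ref = "ACGT" * 25
        m = estimate_logodds_matrix([make_block(ref, ref)], pseudocount=1.0)
        assert np.all(np.diag(m.scores) > 0)
        off = m.scores[~np.eye(4, dtype=bool)]
        assert np.all(off < 0)

    def test_matches_direct_formula_on_counted_block(self):
        rng = np.random.default_rng(5)
        ref = "".join(BASES[i] for i in rng.integers(0, 4, 100))
        qry = "".join(
            BASES[rng.integers(0, 4)] if rng.random() < 0.2 else c for c in ref
        )
        block = make_block(ref, qry)
        m = estimate_logodds_matrix([block], pseudocount=1.0)
        # independent recomputation of the odds ratio
        counts = np.zeros((4, 4))
        for a, b in zip(ref, qry):
            counts[BASES.index(a), BASES.index(b)] += 1
        f = (counts + 1.0) / (counts + 1.0).sum()
        expect = HALF_BIT_SCALE * np.log(
            f / np.outer(f.sum(axis=1), f.sum(axis=0))
        )
        assert np.allclose(m.scores, expect, atol=1e-12)

    def test_no_match_columns_is_error(self):
        with pytest.raises(ValueError, match="match columns"):
            estimate_logodds_matrix([make_block("----", "ACGT")])

    def test_tsv_roundtrip(self, tmp_path):
        m = simple_matrix()
        p = tmp_path / "m.tsv"
        write_matrix_tsv(m, p)
        m2 = read_matrix_tsv(p)
        assert np.allclose(m.scores, m2.scores)
        assert m2.gap_open == m.gap_open and m2.gap_extend == m.gap_extend


class TestGapPenalties:
    def test_counted_example(self):
        # 10 gap events, 40 gap columns, 1000 columns total
        blocks = []
        for _ in range(10):
            ref = "A" * 48 + "----" + "A" * 48
            qry = "A" * 48 + "CCCC" + "A" * 48
            blocks.append(make_block(ref, qry))
        gap_open, gap_extend = derive_gap_penalties(blocks)
        assert gap_open == pytest.approx(HALF_BIT_SCALE * math.log(10 / 1000))
        assert gap_extend == pytest.approx(HALF_BIT_SCALE * math.log(0.75))

    def test_all_length_one_gaps_hit_floor(self):
        b = make_block("AAAA-AAAA", "AAAACAAAA")
        _, gap_extend = derive_gap_penalties([b], extend_floor=-30.0)
        assert gap_extend == -30.0

    def test_longer_gaps_raise_extend_penalty(self):
        short = make_block("AAAA--AAAA", "AAAACCAAAA")
        long = make_block("AAAA----AAAA", "AAAACCCCAAAA")
        _, e_short = derive_gap_penalties([short])
        _, e_long = derive_gap_penalties([long])
        assert e_long > e_short

    def test_zero_gaps_warns_and_defaults(self):
        with pytest.warns(UserWarning):
            gap_open, gap_extend = derive_gap_penalties([make_block("ACGT", "ACGT")])
        assert gap_open <= 0 and gap_extend <= 0


# ---------------------------------------------------------------------------
# brute-force trimming oracle


def _column_scores_oracle(block, matrix):
    s = []
    prev_gap = False
    for r, q in zip(block.ref_text, block.qry_text):
        if r == "-" or q == "-":
            v = matrix.gap_extend + (0.0 if prev_gap else matrix.gap_open)
            prev_gap = True
        else:
            v = matrix.scores[BASES.index(r.upper()), BASES.index(q.upper())]
            prev_gap = False
        s.append(v)
    return s


def _oracle_trim(block, matrix):
    """Literal implementation of the trimming definitions by enumeration."""
    scores = _column_scores_oracle(block, matrix)
    n = len(scores)
    # prefix cut: maximise remaining total, ties -> longest cut
    best_p, best_val = 0, -math.inf
    for p in range(n + 1):
        val = sum(scores[p:])
        if val > best_val or (val == best_val):
            best_p, best_val = p, val
    if best_p == n:
        return []
    # suffix cut on the remainder, ties -> longest cut
    best_q, best_val = best_p, -math.inf
    for q in range(n, best_p, -1):
        val = sum(scores[best_p:q])
        if val > best_val or (val == best_val):
            best_q, best_val = q, val
    if best_val <= 0:
        return []
    piece = _sub(block, best_p, best_q)
    scores = scores[best_p:best_q]
    # internal inter-gap segments
    segs = []
    start = None
    for i, (r, q_) in enumerate(zip(piece.ref_text, piece.qry_text)):
        if r != "-" and q_ != "-":
            if start is None:
                start = i
        else:
            if start is not None:
                segs.append((start, i))
                start = None
    if start is not None:
        segs.append((start, len(piece.ref_text)))
    bad = [
        (s, e)
        for s, e in segs
        if s > 0 and e < piece.width and sum(scores[s:e]) <= 0
    ]
    if not bad:
        return [piece]
    out = []
    cuts = [0] + [c for se in bad for c in se] + [piece.width]
    for i in range(0, len(cuts), 2):
        if cuts[i + 1] > cuts[i]:
            out.extend(_oracle_trim(_sub(piece, cuts[i], cuts[i + 1]), matrix))
    return out


def _sub(block, s, e):
    ref_before = sum(1 for c in block.ref_text[:s] if c != "-")
    qry_before = sum(1 for c in block.qry_text[:s] if c != "-")
    return make_block(
        block.ref_text[s:e], block.qry_text[s:e],
        ref_start=block.ref_start + ref_before,
        qry_start=block.qry_start + qry_before,
    )


class TestTrimBlock:
    MATRIX = simple_matrix()

    def test_all_positive_block_unchanged(self):
        b = make_block("ACGTACGT", "ACGTACGT")
        (out,) = trim_block(b, self.MATRIX)
        assert out.ref_text == b.ref_text and out.ref_start == b.ref_start

    def test_all_nonpositive_block_removed(self):
        b = make_block("AAAA", "CCCC")
        assert trim_block(b, self.MATRIX) == []

    def test_negative_internal_segment_splits_block(self):
        # strong ends, one mildly negative internal inter-gap segment:
        # deleted and the block split, while the terminal cuts stay empty
        # because both prefixes/suffixes keep positive remaining score
        ref = "ACGTACGTAC" + "-" + "AA" + "-" + "ACGTACGTAC"
        qry = "ACGTACGTAC" + "A" + "CC" + "A" + "ACGTACGTAC"
        out = trim_block(make_block(ref, qry), self.MATRIX)
        assert len(out) == 2
        assert [p.ref_text for p in out] == ["ACGTACGTAC", "ACGTACGTAC"]
        assert out[1].ref_start == 12 and out[1].qry_start == 14

    def test_matches_bruteforce_oracle(self, rng):
        matrix = simple_matrix()
        for _ in range(60):
            b = random_block(rng, int(rng.integers(8, 40)), gap_rate=0.2, sub_rate=0.35)
            got = trim_block(b, matrix)
            want = _oracle_trim(b, matrix)
            assert [(p.ref_text, p.qry_text, p.ref_start, p.qry_start) for p in got] == [
                (p.ref_text, p.qry_text, p.ref_start, p.qry_start) for p in want
            ]

    def test_idempotent(self, rng):
        matrix = simple_matrix()
        for _ in range(40):
            b = random_block(rng, int(rng.integers(10, 60)), gap_rate=0.15, sub_rate=0.3)
            once = trim_block(b, matrix)
            twice = [p2 for p in once for p2 in trim_block(p, matrix)]
            assert [(p.ref_text, p.ref_start) for p in twice] == [
                (p.ref_text, p.ref_start) for p in once
            ]

    def test_emitted_blocks_have_positive_score_and_ends(self, rng):
        matrix = simple_matrix()
        for _ in range(40):
            b = random_block(rng, int(rng.integers(10, 60)), gap_rate=0.2, sub_rate=0.4)
            for p in trim_block(b, matrix):
                s = matrix.column_scores(p)
                assert s.sum() > 0
                assert s[0] > 0 and s[-1] > 0


class TestTrimOnRealisticBlocks:
    def _homologous_pair(self, rng, n, sub_rate=0.1):
        ref = "".join(BASES[i] for i in rng.integers(0, 4, n))
        qry = "".join(
            BASES[rng.integers(0, 4)] if rng.random() < sub_rate else c for c in ref
        )
        return ref, qry

    def test_random_flanks_are_removed_homology_kept(self, rng):
        """Unrelated flanking sequence scores at chance and is trimmed off;
        the homologous core survives nearly intact."""
        flank_cols = homol_cols = 0
        flank_kept = homol_lost = 0
        blocks = []
        n_flank, n_core = 120, 400
        for _ in range(10):
            core_r, core_q = self._homologous_pair(rng, n_core)
            fl_r = "".join(BASES[i] for i in rng.integers(0, 4, n_flank))
            fl_q = "".join(BASES[i] for i in rng.integers(0, 4, n_flank))
            fr_r = "".join(BASES[i] for i in rng.integers(0, 4, n_flank))
            fr_q = "".join(BASES[i] for i in rng.integers(0, 4, n_flank))
            blocks.append(make_block(fl_r + core_r + fr_r, fl_q + core_q + fr_q))
        matrix = estimate_logodds_matrix(blocks, pseudocount=1.0)
        for b in blocks:
            kept_cols = set()
            ref_pos = 0
            for p in trim_block(b, matrix):
                # map piece back to column offsets via ref_start (no ref gaps here)
                kept_cols.update(range(p.ref_start, p.ref_start + p.width))
                ref_pos += p.width
            flank_cols += 2 * n_flank
            homol_cols += n_core
            flank_kept += sum(
                1 for c in kept_cols if c < n_flank or c >= n_flank + n_core
            )
            homol_lost += n_core - sum(
                1 for c in kept_cols if n_flank <= c < n_flank + n_core
            )
        assert flank_kept / flank_cols <= 0.05
        assert homol_lost / homol_cols <= 0.05

    def test_trimming_does_not_increase_short_igs(self, rng):
        blocks = [
            random_block(rng, 400, gap_rate=0.08, sub_rate=0.25) for _ in range(8)
        ]
        matrix = estimate_logodds_matrix(blocks, pseudocount=1.0)
        before = sum(
            1 for b in blocks for r in extract_igs(b) if not r.censored and r.x < 10
        )
        trimmed = trim_blocks(blocks, matrix=matrix)
        after = sum(
            1 for b in trimmed for r in extract_igs(b) if not r.censored and r.x < 10
        )
        assert after <= before
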