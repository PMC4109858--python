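"""Log-odds rescoring and trimming of pairwise alignment blocks.

Whole-genome pairwise alignments carry a minority of spurious aligned
sequence, concentrated at block ends and in short inter-gap segments, which
inflates constraint estimates.  Following the rescoring idea of
Chiaromonte-style log-odds matrices, a substitution matrix is derived from
the alignment itself, gap penalties are derived from the observed gap
spectrum, and every block is trimmed: the maximal non-positively scoring
terminal segments are discarded, and any non-positively scoring internal
inter-gap segment is deleted (splitting the block).

The matrix is deliberately asymmetric: no symmetry across strand or species
is imposed, so compositional biases of either genome are scored as observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .alignio import AlignmentBlock, _GAP, _runs, _texts_u8

__all__ = [
    "ScoringMatrix",
    "estimate_logodds_matrix",
    "derive_gap_penalties",
    "trim_block",
    "trim_blocks",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

#: default scale: scores in half-bits
HALF_BIT_SCALE = 2.0 / math.log(2.0)

_BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0
GAP_EXTEND_FLOOR = -30.0


@dataclass
class ScoringMatrix:
    """4x4 substitution scores (ref base x query base) plus gap penalties.

    Scores are in units of ``scale`` per natural log of the odds ratio
    f(a,b) / (f_ref(a) * f_qry(b)).
    """

    scores: np.ndarray  # (4, 4), ref x qry, ACGT order
    gap_open: float
    gap_extend: float
    scale: float = HALF_BIT_SCALE

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (4, 4):
            raise ValueError("scores must be 4x4 in ACGT order")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def column_scores(self, block: AlignmentBlock) -> np.ndarray:
        """Per-column scores: substitution score at match columns (0 when a
        base is ambiguous), gap_extend per gap column with gap_open added at
        each gap-run start."""
        r, q = _texts_u8(block)
        gap = (r == _GAP) | (q == _GAP)
        ri = _BASE_INDEX[r]
        qi = _BASE_INDEX[q]
        s = np.zeros(block.width, dtype=float)
        known = ~gap & (ri >= 0) & (qi >= 0)
        s[known] = self.scores[ri[known], qi[known]]
        s[gap] = self.gap_extend
        runs = _runs(gap)
        if len(runs):
            s[runs[:, 0]] += self.gap_open
        return s


def _pair_counts(blocks: Iterable[AlignmentBlock]) -> np.ndarray:
    counts = np.zeros((4, 4), dtype=np.int64)
    for block in blocks:
        r, q = _texts_u8(block)
        ri = _BASE_INDEX[r]
        qi = _BASE_INDEX[q]
        ok = (ri >= 0) & (qi >= 0)
        np.add.at(counts, (ri[ok], qi[ok]), 1)
    return counts


def estimate_logodds_matrix(
    blocks: Sequence[AlignmentBlock],
    pseudocount: float = 1.0,
    scale: float = HALF_BIT_SCALE,
) -> ScoringMatrix:
    """Estimate the log-odds substitution matrix from the alignment itself.

    score(a,b) = scale * ln[ f(a,b) / (f_ref(a) f_qry(b)) ] with joint
    frequencies over non-gap columns (plus ``pseudocount`` per cell) and
    marginal frequencies from the joint.  Gap penalties come from
    :func:`derive_gap_penalties` on the same blocks.
    """
    raw = _pair_counts(blocks)
    if raw.sum() == 0:
        raise ValueError("no match columns in blocks; cannot estimate matrix")
    counts = raw.astype(float) + pseudocount
    f = counts / counts.sum()
    f_ref = f.sum(axis=1)
    f_qry = f.sum(axis=0)
    scores = scale * np.log(f / np.outer(f_ref, f_qry))
    gap_open, gap_extend = derive_gap_penalties(blocks, scale=scale)
    return ScoringMatrix(scores=scores, gap_open=gap_open, gap_extend=gap_extend, scale=scale)


def derive_gap_penalties(
    blocks: Sequence[AlignmentBlock],
    scale: float = HALF_BIT_SCALE,
    extend_floor: float = GAP_EXTEND_FLOOR,
) -> tuple[float, float]:
    """Gap penalties from the observed gap spectrum.

    gap_open = scale*ln(P_open) with P_open = gap events / columns;
    gap_extend = scale*ln(P_ext) with P_ext = 1 - 1/mean(gap length)
    (the geometric-law extension probability).  All events of length 1 drive
    P_ext to 0; the penalty is then floored at ``extend_floor``.
    """
    n_events = 0
    n_gap_cols = 0
    n_cols = 0
    for block in blocks:
        r, q = _texts_u8(block)
        gap = (r == _GAP) | (q == _GAP)
        n_cols += block.width
        n_gap_cols += int(gap.sum())
        n_events += len(_runs(gap))
    if n_events == 0:
        warnings.warn("no gap events observed; using default gap penalties")
        return DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND
    p_open = n_events / n_cols
    mean_len = max(n_gap_cols / n_events, 1.0 + 1e-9)
    p_ext = 1.0 - 1.0 / mean_len
    gap_open = scale * math.log(p_open)
    gap_extend = max(scale * math.log(p_ext), extend_floor) if p_ext > 0 else extend_floor
    return gap_open, gap_extend


# ---------------------------------------------------------------------------
# trimming


def _terminal_cut(scores: np.ndarray) -> tuple[int, int]:
    """Return (p, q): retained half-open column range after removing the
    maximal non-positively scoring prefix and suffix.

    p is the prefix cut maximising the remaining total (ties -> longest
    cut), then q likewise from the right.  Empty range when nothing scores
    positively.
    """
    n = len(scores)
    prefix = np.concatenate([[0.0], np.cumsum(scores)])  # prefix[p] = sum of first p
    # maximise total - prefix[p]  <=>  minimise prefix[p]; ties -> largest p
    p = int(np.flatnonzero(prefix == prefix.min())[-1])
    if p == n:
        return 0, 0
    tail = prefix[p:]  # tail[k] - tail[0] = score of columns p..p+k-1
    # choose q maximising sum over [p, q); ties -> smallest q (longest suffix cut)
    rel = tail - tail[0]
    best = rel.max()
    if best <= 0:
        return 0, 0
    q = p + int(np.flatnonzero(rel == best)[0])
    return p, q


def _subblock(block: AlignmentBlock, s: int, e: int, tag: str) -> AlignmentBlock:
    r, q = _texts_u8(block)
    ref_before = int((r[:s] != _GAP).sum())
    qry_before = int((q[:s] != _GAP).sum())
    return replace(
        block,
        ref_start=block.ref_start + ref_before,
        qry_start=block.qry_start + qry_before,
        ref_text=block.ref_text[s:e],
        qry_text=block.qry_text[s:e],
        block_id=f"{block.block_id}{tag}",
    )


def trim_block(block: AlignmentBlock, matrix: ScoringMatrix) -> list[AlignmentBlock]:
    """Trim one block; may return zero, one, or several sub-blocks.

    Terminal trims are applied first; then every remaining internal
    inter-gap segment is scored on its own (the delimiting gap events'
    costs belong to the block, not the segment) and any non-positive segment
    is deleted, splitting the block.  Newly exposed ends are re-trimmed, so
    the output is a fixed point: every emitted sub-block has positive total
    score and positively scoring ends.
    """
    out: list[AlignmentBlock] = []
    _trim_into(block, matrix, out, 0)
    return out


def _trim_into(
    block: AlignmentBlock, matrix: ScoringMatrix, out: list[AlignmentBlock], depth: int
) -> None:
    scores = matrix.column_scores(block)
    p, q = _terminal_cut(scores)
    if q <= p:
        return
    if p > 0 or q < block.width:
        block = _subblock(block, p, q, f"/t{depth}" if depth else "/t")
        scores = scores[p:q]
    r, qq = _texts_u8(block)
    gap = (r == _GAP) | (qq == _GAP)
    seg_runs = _runs(~gap)
    # internal segments: flanked by gap runs on both sides (terminal trim
    # guarantees the block starts/ends with match columns)
    bad = [
        (s, e)
        for s, e in seg_runs
        if s > 0 and e < block.width and scores[s:e].sum() <= 0
    ]
    if not bad:
        block.validate()
        out.append(block)
        return
    # delete non-positive internal segments, keep the complement pieces
    cuts = [0]
    for s, e in bad:
        cuts.extend((s, e))
    cuts.append(block.width)
    for i in range(0, len(cuts), 2):
        s, e = cuts[i], cuts[i + 1]
        if e > s:
            _trim_into(_subblock(block, s, e, f"/s{depth}.{i // 2}"), matrix, out, depth + 1)


def trim_blocks(
    blocks: Sequence[AlignmentBlock],
    matrix: ScoringMatrix | None = None,
    pseudocount: float = 1.0,
) -> list[AlignmentBlock]:
    """Estimate a matrix from ``blocks`` (unless given) and trim them all."""
    if matrix is None:
        matrix = estimate_logodds_matrix(blocks, pseudocount=pseudocount)
    out: list[AlignmentBlock] = []
    for b in blocks:
        out.extend(trim_block(b, matrix))
    return out


def write_matrix_tsv(matrix: ScoringMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("# gap_open\t%.10g\n# gap_extend\t%.10g\n# scale\t%.10g\n" % (
            matrix.gap_open, matrix.gap_extend, matrix.scale))
        fh.write("ref\\qry\t" + "\t".join(_BASES) + "\n")
        for i, a in enumerate(_BASES):
            fh.write(a + "\t" + "\t".join("%.10g" % v for v in matrix.scores[i]) + "\n")


def read_matrix_tsv(path) -> ScoringMatrix:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, val = line[1:].split("\t")
                meta[key.strip()] = float(val)
            elif not line.startswith("ref"):
                rows.append([float(v) for v in line.split("\t")[1:]])
    return ScoringMatrix(
        scores=np.array(rows),
        gap_open=meta["gap_open"],
        gap_extend=meta["gap_extend"],
        scale=meta.get("scale", HALF_BIT_SCALE),
    )
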