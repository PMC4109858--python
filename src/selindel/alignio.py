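"""Pairwise alignment I/O, inter-gap segment extraction and stratification.

The estimators in :mod:`selindel.nim` consume the distribution of distances
between neighbouring indel events ("inter-gap segments", IGSs) in a pairwise
whole-genome alignment.  This module reads alignments (MAF, AXT), extracts
IGSs, masks out annotated intervals, and stratifies segments into equally
populated G+C bins (the X chromosome is kept apart, since its mutational
spectrum differs from the autosomes).

Coordinate conventions: 0-based half-open everywhere, including BED I/O.
MAF/AXT native conventions are translated at the file boundary; query starts
are kept strand-relative (MAF-native) so that sub-block arithmetic is uniform
for both strands.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import AlignIO

__all__ = [
    "AlignmentBlock",
    "IGSRecord",
    "IGSHistogram",
    "BlockIntegrityError",
    "read_pairwise_alignment",
    "write_maf",
    "read_bed",
    "extract_igs",
    "count_indel_events",
    "excise_intervals",
    "assign_gc_bins",
    "write_histograms_tsv",
]

_GAP = ord("-")
# minimum run of N/n columns treated as an assembly gap, splitting the block
N_SPLIT_RUN = 10
# G+C is measured on a fixed-width ungapped-reference window centred on the
# segment (regional G+C).  A fixed width keeps the sampling variance of gc
# identical for all segments; measuring gc on the segment's own bases would
# couple gc spread to segment length and let gc-quantile binning distort the
# per-bin length distributions.
GC_WINDOW = 100


class BlockIntegrityError(ValueError):
    """An alignment block violates a structural invariant."""


@dataclass
class AlignmentBlock:
    """One gapped pairwise alignment block.

    ``ref_start``/``qry_start`` follow MAF conventions: 0-based, counted on
    the named strand.  ``ref_src_size``/``qry_src_size`` (chromosome lengths)
    are kept when known so strand conversions remain possible after
    splitting.
    """

    ref_chrom: str
    ref_start: int
    ref_strand: str
    ref_text: str
    qry_chrom: str
    qry_start: int
    qry_strand: str
    qry_text: str
    block_id: str = ""
    ref_src_size: int = 0
    qry_src_size: int = 0

    def __post_init__(self) -> None:
        if len(self.ref_text) != len(self.qry_text) or len(self.ref_text) < 1:
            raise BlockIntegrityError(
                f"block {self.block_id!r}: rows have unequal or zero length "
                f"({len(self.ref_text)} vs {len(self.qry_text)})"
            )

    @property
    def width(self) -> int:
        return len(self.ref_text)

    @property
    def ref_span(self) -> int:
        """Ungapped reference length."""
        return len(self.ref_text) - self.ref_text.count("-")

    @property
    def qry_span(self) -> int:
        return len(self.qry_text) - self.qry_text.count("-")

    def validate(self) -> None:
        r, q = _texts_u8(self)
        if np.any((r == _GAP) & (q == _GAP)):
            raise BlockIntegrityError(
                f"block {self.block_id!r}: column gapped in both species"
            )

    def qry_forward_interval(self) -> tuple[int, int]:
        """Query interval on the forward strand (requires qry_src_size for '-')."""
        if self.qry_strand == "+":
            return self.qry_start, self.qry_start + self.qry_span
        if not self.qry_src_size:
            raise ValueError("qry_src_size unknown; cannot convert '-' strand")
        end = self.qry_src_size - self.qry_start
        return end - self.qry_span, end


@dataclass(frozen=True)
class IGSRecord:
    """A gap-free run between two indel events, in reference bases."""

    x: int
    gc: float
    chrom_class: str  # "autosome" | "X"
    censored: bool
    ref_chrom: str = ""
    ref_start: int = 0
    annotations: frozenset = field(default_factory=frozenset)


@dataclass
class IGSHistogram:
    """Length histogram of internal IGSs for one stratum.

    ``counts`` holds internal (uncensored) segments only — these are what the
    neutral model is fitted to.  Censored (block-terminal) segments are
    tallied apart and contribute to ``total_aligned_bp`` but never to fits
    or excess sums.
    """

    bin_label: str
    counts: Counter
    censored_counts: Counter = field(default_factory=Counter)
    total_aligned_bp: int = 0

    @property
    def n_internal(self) -> int:
        return sum(self.counts.values())

    def lengths_counts(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.counts:
            return np.array([], int), np.array([], int)
        xs = np.array(sorted(self.counts), dtype=np.int64)
        cs = np.array([self.counts[int(x)] for x in xs], dtype=np.float64)
        return xs, cs


# ---------------------------------------------------------------------------
# reading / writing


_UNPLACED_TOKENS = ("Un", "random", "hap")


def _is_primary_chrom(name: str) -> bool:
    # strip an optional species prefix ("hg19.chr1" -> "chr1")
    name = name.split(".")[-1]
    if any(tok in name for tok in _UNPLACED_TOKENS):
        return False
    base = name[3:] if name.lower().startswith("chr") else name
    return base.isdigit() or base.upper() in {"X", "Y", "W", "Z", "M", "MT"}


def read_pairwise_alignment(
    path: str | Path,
    format: str = "maf",
    drop_unplaced: bool = False,
) -> Iterator[AlignmentBlock]:
    """Yield pairwise :class:`AlignmentBlock`\\ s from a MAF or AXT file.

    Blocks are yielded in file order.  With ``drop_unplaced``, blocks led by
    reference sequence not mapped to a primary chromosome (unlocalised,
    random, haplotype or bare-scaffold names) are skipped.
    """
    fmt = format.lower()
    if fmt == "maf":
        blocks = _read_maf(path)
    elif fmt == "axt":
        blocks = _read_axt(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    for block in blocks:
        if drop_unplaced and not _is_primary_chrom(block.ref_chrom):
            continue
        yield block


def _read_maf(path: str | Path) -> Iterator[AlignmentBlock]:
    for i, msa in enumerate(AlignIO.parse(str(path), "maf")):
        if len(msa) != 2:
            raise BlockIntegrityError(
                f"MAF block {i}: expected 2 rows for a pairwise alignment, "
                f"got {len(msa)}"
            )
        ref, qry = msa[0], msa[1]
        block = AlignmentBlock(
            ref_chrom=ref.id,
            ref_start=int(ref.annotations["start"]),
            ref_strand="+" if ref.annotations.get("strand", 1) in (1, "+") else "-",
            ref_text=str(ref.seq),
            qry_chrom=qry.id,
            qry_start=int(qry.annotations["start"]),
            qry_strand="+" if qry.annotations.get("strand", 1) in (1, "+") else "-",
            qry_text=str(qry.seq),
            block_id=f"maf:{i}",
            ref_src_size=int(ref.annotations.get("srcSize", 0)),
            qry_src_size=int(qry.annotations.get("srcSize", 0)),
        )
        _check_declared_span(block, int(ref.annotations["size"]), int(qry.annotations["size"]), i)
        block.validate()
        yield block


def _check_declared_span(block: AlignmentBlock, ref_size: int, qry_size: int, i: int) -> None:
    if block.ref_span != ref_size or block.qry_span != qry_size:
        raise BlockIntegrityError(
            f"block {i}: ungapped length disagrees with declared size "
            f"(ref {block.ref_span}!={ref_size} or qry {block.qry_span}!={qry_size})"
        )


def _read_axt(path: str | Path) -> Iterator[AlignmentBlock]:
    """AXT: header line `num tChrom tStart tEnd qChrom qStart qEnd strand score`
    with 1-based inclusive coordinates, followed by two sequence lines."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                return
            if not header.strip() or header.startswith("#"):
                continue
            parts = header.split()
            if len(parts) < 9:
                raise ValueError(f"{path}: malformed AXT header at line {lineno}")
            ref_text = fh.readline().strip()
            qry_text = fh.readline().strip()
            lineno += 2
            if not ref_text or not qry_text:
                raise ValueError(f"{path}: truncated AXT record at line {lineno}")
            blank = fh.readline()  # record separator
            lineno += 1 if blank else 0
            block = AlignmentBlock(
                ref_chrom=parts[1],
                ref_start=int(parts[2]) - 1,
                ref_strand="+",
                ref_text=ref_text,
                qry_chrom=parts[4],
                qry_start=int(parts[5]) - 1,
                qry_strand=parts[7],
                qry_text=qry_text,
                block_id=f"axt:{parts[0]}",
            )
            block.validate()
            yield block


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> int:
    """Write blocks as UCSC-dialect pairwise MAF. Returns block count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for b in blocks:
            fh.write("a\n")
            for chrom, start, strand, text, size, span in (
                (b.ref_chrom, b.ref_start, b.ref_strand, b.ref_text, b.ref_src_size, b.ref_span),
                (b.qry_chrom, b.qry_start, b.qry_strand, b.qry_text, b.qry_src_size, b.qry_span),
            ):
                fh.write(
                    f"s {chrom} {start} {span} {strand} {size or span} {text}\n"
                )
            fh.write("\n")
            n += 1
    return n


def read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read BED3/BED6 into {chrom: (n,2) int array}, merged and sorted."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            intervals.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return {c: merge_intervals(np.array(v, dtype=np.int64)) for c, v in intervals.items()}


def merge_intervals(ivals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent 0-based half-open intervals."""
    if len(ivals) == 0:
        return ivals.reshape(0, 2)
    ivals = ivals[np.argsort(ivals[:, 0], kind="stable")]
    out = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# IGS extraction


def _texts_u8(block: AlignmentBlock) -> tuple[np.ndarray, np.ndarray]:
    r = np.frombuffer(block.ref_text.encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(block.qry_text.encode("ascii"), dtype=np.uint8)
    return r, q


def _runs(mask: np.ndarray) -> np.ndarray:
    """(start, end) pairs of maximal True runs."""
    if mask.size == 0:
        return np.zeros((0, 2), dtype=np.int64)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.stack([starts, ends], axis=1)


def _column_classes(block: AlignmentBlock) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (gap_mask, break_mask, ref_u8).

    Gap columns are indel evidence; break columns are assembly-gap guards
    (runs of >= N_SPLIT_RUN 'N' columns in either row) that split the block
    without counting as indel events.
    """
    r, q = _texts_u8(block)
    gap = (r == _GAP) | (q == _GAP)
    is_n = ((r == ord("N")) | (r == ord("n")) | (q == ord("N")) | (q == ord("n"))) & ~gap
    brk = np.zeros_like(gap)
    for s, e in _runs(is_n):
        if e - s >= N_SPLIT_RUN:
            brk[s:e] = True
    return gap, brk, r


def count_indel_events(block: AlignmentBlock) -> int:
    """Number of indel events (maximal gap-column runs) in the block."""
    gap, _, _ = _column_classes(block)
    return len(_runs(gap))


def extract_igs(block: AlignmentBlock) -> list[IGSRecord]:
    """Extract inter-gap segments from one block.

    A maximal run of consecutive gap columns (in either row) is one indel
    event.  Gap-free runs flanked by indel events on both sides are internal
    IGSs; runs touching a block boundary (or an assembly-gap break) are
    emitted with ``censored=True`` and take no part in model fitting.
    Lengths are in reference bases; inside a gap-free run every column
    carries a reference base, so length equals the column count.
    """
    gap, brk, r = _column_classes(block)
    keep = ~(gap | brk)
    seg_runs = _runs(keep)
    if len(seg_runs) == 0:
        return []

    chrom_class = "X" if block.ref_chrom.split(".")[-1].rstrip().upper().endswith("X") else "autosome"

    # reference positions: number of ref bases strictly before each column
    ref_base = r != _GAP
    ref_before = np.concatenate([[0], np.cumsum(ref_base)])  # len width+1
    upper = np.frombuffer(block.ref_text.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (upper == ord("G")) | (upper == ord("C"))
    is_acgt = (
        (upper == ord("A")) | (upper == ord("C")) | (upper == ord("G")) | (upper == ord("T"))
    )

    # ungapped-reference cumulative composition for windowed regional G+C
    gc_ung = np.cumsum(np.r_[0, (is_gc & ref_base)[ref_base]])
    acgt_ung = np.cumsum(np.r_[0, (is_acgt & ref_base)[ref_base]])
    n_ref = int(ref_before[-1])

    width = block.width
    records: list[IGSRecord] = []
    for s, e in seg_runs:
        x = int(e - s)
        left_gap = s > 0 and gap[s - 1]
        right_gap = e < width and gap[e]
        censored = not (left_gap and right_gap)
        rs, re = int(ref_before[s]), int(ref_before[e])
        mid = (rs + re) // 2
        lo = max(0, mid - GC_WINDOW // 2)
        hi = min(n_ref, mid + GC_WINDOW // 2)
        denom = acgt_ung[hi] - acgt_ung[lo]
        num = gc_ung[hi] - gc_ung[lo]
        gc = float(num) / float(denom) if denom > 0 else 0.5
        records.append(
            IGSRecord(
                x=x,
                gc=gc,
                chrom_class=chrom_class,
                censored=censored,
                ref_chrom=block.ref_chrom,
                ref_start=block.ref_start + rs,
            )
        )
    return records


# ---------------------------------------------------------------------------
# interval excision


def excise_intervals(
    blocks: Iterable[AlignmentBlock],
    intervals: dict[str, np.ndarray],
    buffer: int = 0,
) -> list[AlignmentBlock]:
    """Remove reference positions inside ``intervals`` (widened by ``buffer``)
    from the blocks, splitting each block at the removals.

    Used to estimate constraint in a complement G\\S: segments abutting an
    excision become censored ends of the resulting sub-blocks.  Intervals on
    chromosomes absent from the blocks are ignored with a warning.
    """
    widened = {
        c: merge_intervals(np.stack([iv[:, 0] - buffer, iv[:, 1] + buffer], axis=1))
        for c, iv in intervals.items()
    }
    seen_chroms: set[str] = set()
    out: list[AlignmentBlock] = []
    for block in blocks:
        chrom = block.ref_chrom
        seen_chroms.add(chrom)
        ivals = widened.get(chrom)
        if ivals is None:
            ivals = widened.get(chrom.split(".")[-1])
        if ivals is None or len(ivals) == 0:
            out.append(block)
            continue
        out.extend(_excise_block(block, ivals))
    missing = set(widened) - {c.split(".")[-1] for c in seen_chroms} - seen_chroms
    if missing:
        warnings.warn(
            f"intervals on chromosomes absent from alignment ignored: {sorted(missing)}"
        )
    return out


def _excise_block(block: AlignmentBlock, ivals: np.ndarray) -> list[AlignmentBlock]:
    if block.ref_strand != "+":
        raise ValueError("excision requires forward-strand reference blocks")
    r, q = _texts_u8(block)
    ref_base = r != _GAP
    # genomic position of each column's ref base (undefined at ref gaps)
    pos = block.ref_start + np.cumsum(ref_base) - 1
    lo = np.searchsorted(ivals[:, 1], pos, side="right")
    inside = (lo < len(ivals)) & (pos >= ivals[np.minimum(lo, len(ivals) - 1), 0])
    remove = inside & ref_base  # ref-gap columns are kept with their segment
    if not remove.any():
        return [block]
    keep_runs = _runs(~remove)
    qry_base = q != _GAP
    ref_before = np.concatenate([[0], np.cumsum(ref_base)])
    qry_before = np.concatenate([[0], np.cumsum(qry_base)])
    pieces: list[AlignmentBlock] = []
    for i, (s, e) in enumerate(keep_runs):
        rt = block.ref_text[s:e]
        qt = block.qry_text[s:e]
        if len(rt) == 0 or rt.count("-") == len(rt) and qt.count("-") == len(qt):
            continue
        pieces.append(
            replace(
                block,
                ref_start=block.ref_start + int(ref_before[s]),
                qry_start=block.qry_start + int(qry_before[s]),
                ref_text=rt,
                qry_text=qt,
                block_id=f"{block.block_id}/x{i}",
            )
        )
    return pieces


# ---------------------------------------------------------------------------
# G+C binning


def assign_gc_bins(
    records: Sequence[IGSRecord], n_bins: int = 20
) -> list[IGSHistogram]:
    """Partition autosomal records into ``n_bins`` equally populated G+C bins
    (quantile binning; populations differ by at most 1); X-chromosome records
    form one extra histogram regardless of their G+C.

    Ties in G+C are broken by a stable sort on (gc, chromosome, position) so
    the partition is deterministic.
    """
    autosomal = [rec for rec in records if rec.chrom_class != "X"]
    x_recs = [rec for rec in records if rec.chrom_class == "X"]
    if len(autosomal) < n_bins:
        raise ValueError(
            f"{len(autosomal)} autosomal records < {n_bins} bins; use fewer bins"
        )
    order = sorted(range(len(autosomal)), key=lambda i: (
        autosomal[i].gc, autosomal[i].ref_chrom, autosomal[i].ref_start))
    histograms: list[IGSHistogram] = []
    for b, chunk in enumerate(np.array_split(np.array(order), n_bins)):
        histograms.append(_build_histogram(str(b + 1), [autosomal[i] for i in chunk]))
    if x_recs:
        histograms.append(_build_histogram("X", x_recs))
    return histograms


def _build_histogram(label: str, recs: Sequence[IGSRecord]) -> IGSHistogram:
    counts: Counter = Counter()
    censored: Counter = Counter()
    total = 0
    for rec in recs:
        total += rec.x
        (censored if rec.censored else counts)[rec.x] += 1
    return IGSHistogram(
        bin_label=label, counts=counts, censored_counts=censored, total_aligned_bp=total
    )


def write_histograms_tsv(histograms: Sequence[IGSHistogram], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_label\tlength\tcount\n")
        for h in histograms:
            xs, cs = h.lengths_counts()
            for x, c in zip(xs, cs):
                fh.write(f"{h.bin_label}\t{x}\t{c:g}\n")
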