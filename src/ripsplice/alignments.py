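"""SAM alignment reading, junction extraction, and coverage.

The shared substrate for expression counting, splicing quantification and
peak calling. Only uniquely mapped records pass the filter: not unmapped,
not secondary/supplementary, and either MAPQ >= ``min_mapq`` or an
explicit ``NH:i:1`` tag (the simulator's unique marker). Alignment blocks
come from the CIGAR: M/D/=/X runs extend the current block, N closes it
(one junction per N gap), I/S consume only the query.

Two access paths: :func:`read_alignments` streams ``SplicedAlignment``
records; :class:`AlignmentTable` loads a whole library into flat numpy
arrays for the vectorised operations.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pysam

from .annotation import SpliceJunction

log = logging.getLogger(__name__)

_REF_CONSUME_EXTEND = {0, 2, 7, 8}   # M, D, =, X
_SKIP = 3                            # N
_QUERY_ONLY = {1, 4}                 # I, S


class SplicedAlignment(NamedTuple):
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    unique: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclasses.dataclass
class FilterStats:
    kept: int = 0
    unmapped: int = 0
    secondary: int = 0
    low_mapq: int = 0
    malformed: int = 0


def _cigar_blocks(pos: int, cigartuples) -> list[tuple[int, int]]:
    if not cigartuples:
        raise ValueError("missing CIGAR")
    blocks = []
    cur = pos
    blk_start = pos
    open_block = False
    for op, ln in cigartuples:
        if op in _REF_CONSUME_EXTEND:
            if not open_block:
                blk_start = cur
                open_block = True
            cur += ln
        elif op == _SKIP:
            if open_block:
                blocks.append((blk_start, cur))
                open_block = False
            if ln < 1:
                raise ValueError("zero-length N gap")
            cur += ln
        elif op in _QUERY_ONLY or op in (5, 6):  # I, S, H, P
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if open_block:
        blocks.append((blk_start, cur))
    if not blocks:
        raise ValueError("alignment with no reference-consuming blocks")
    return blocks


def _record_passes(rec, min_mapq: int, stats: FilterStats) -> bool:
    if rec.is_unmapped:
        stats.unmapped += 1
        return False
    if rec.is_secondary or rec.is_supplementary:
        stats.secondary += 1
        return False
    unique_tag = rec.has_tag("NH") and rec.get_tag("NH") == 1
    if rec.mapping_quality < min_mapq and not unique_tag:
        stats.low_mapq += 1
        return False
    return True


def read_alignments(
    path: str | Path,
    min_mapq: int = 20,
    reverse_stranded: bool = False,
    stats: FilterStats | None = None,
) -> Iterator[SplicedAlignment]:
    """Stream uniquely mapped spliced alignments from a SAM/BAM file.

    Malformed CIGARs are logged and skipped (counted in ``stats``).
    """
    stats = stats if stats is not None else FilterStats()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if not _record_passes(rec, min_mapq, stats):
                continue
            strand = "-" if rec.is_reverse else "+"
            if reverse_stranded:
                strand = "-" if strand == "+" else "+"
            try:
                blocks = _cigar_blocks(rec.reference_start, rec.cigartuples)
            except ValueError as exc:
                stats.malformed += 1
                log.warning("skipping %s: %s", rec.query_name, exc)
                continue
            stats.kept += 1
            yield SplicedAlignment(rec.reference_name, strand, tuple(blocks))


class AlignmentTable:
    """Columnar store of one library's uniquely mapped alignments.

    Blocks are ragged: ``block_starts``/``block_ends`` are flat arrays and
    ``offsets[i]:offsets[i+1]`` indexes read *i*'s blocks. Single-chromosome
    per table; multi-reference files produce one table per reference via
    :meth:`from_sam_multi`.
    """

    def __init__(self, chrom: str, is_reverse: np.ndarray, offsets: np.ndarray,
                 block_starts: np.ndarray, block_ends: np.ndarray,
                 stats: FilterStats):
        self.chrom = chrom
        self.is_reverse = is_reverse
        self.offsets = offsets
        self.block_starts = block_starts
        self.block_ends = block_ends
        self.stats = stats

    def __len__(self) -> int:
        return len(self.is_reverse)

    @property
    def starts(self) -> np.ndarray:
        return self.block_starts[self.offsets[:-1]]

    @property
    def ends(self) -> np.ndarray:
        return self.block_ends[self.offsets[1:] - 1]

    @property
    def n_gapped(self) -> int:
        return int((np.diff(self.offsets) > 1).sum())

    @classmethod
    def from_sam(cls, path: str | Path, min_mapq: int = 20,
                 reverse_stranded: bool = False) -> "AlignmentTable":
        stats = FilterStats()
        rev: list[int] = []
        nblocks: list[int] = []
        bs: list[int] = []
        be: list[int] = []
        chrom = None
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if not _record_passes(rec, min_mapq, stats):
                    continue
                if chrom is None:
                    chrom = rec.reference_name
                elif rec.reference_name != chrom:
                    raise ValueError(
                        "AlignmentTable.from_sam expects a single reference; "
                        "use from_sam_multi"
                    )
                cig = rec.cigartuples
                try:
                    blocks = _cigar_blocks(rec.reference_start, cig)
                except ValueError as exc:
                    stats.malformed += 1
                    log.warning("skipping %s: %s", rec.query_name, exc)
                    continue
                stats.kept += 1
                r = rec.is_reverse
                if reverse_stranded:
                    r = not r
                rev.append(r)
                nblocks.append(len(blocks))
                for s, e in blocks:
                    bs.append(s)
                    be.append(e)
        offsets = np.zeros(len(rev) + 1, dtype=np.int64)
        np.cumsum(nblocks, out=offsets[1:])
        return cls(
            chrom or "", np.asarray(rev, dtype=bool), offsets,
            np.asarray(bs, dtype=np.int64), np.asarray(be, dtype=np.int64),
            stats,
        )

    @classmethod
    def from_alignments(cls, alignments: Iterable[SplicedAlignment]) -> "AlignmentTable":
        rev, nblocks, bs, be = [], [], [], []
        chrom = ""
        for aln in alignments:
            chrom = aln.chrom
            rev.append(aln.strand == "-")
            nblocks.append(len(aln.blocks))
            for s, e in aln.blocks:
                bs.append(s)
                be.append(e)
        offsets = np.zeros(len(rev) + 1, dtype=np.int64)
        np.cumsum(nblocks, out=offsets[1:])
        return cls(chrom, np.asarray(rev, dtype=bool), offsets,
                   np.asarray(bs, dtype=np.int64), np.asarray(be, dtype=np.int64),
                   FilterStats(kept=len(rev)))

    def strand_of(self, i: int) -> str:
        return "-" if self.is_reverse[i] else "+"

    def read_blocks(self, i: int) -> list[tuple[int, int]]:
        o0, o1 = self.offsets[i], self.offsets[i + 1]
        return list(zip(self.block_starts[o0:o1], self.block_ends[o0:o1]))


class JunctionCounts:
    """Supporting-read counts per splice junction for one sample.

    A read with k gaps contributes one count to each of its k junctions.
    """

    def __init__(self, counts: dict[SpliceJunction, int] | None = None):
        self.counts: dict[SpliceJunction, int] = dict(counts or {})

    def __getitem__(self, j: SpliceJunction) -> int:
        return self.counts.get(j, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self):
        return iter(self.counts.items())

    def add(self, other: "JunctionCounts") -> "JunctionCounts":
        out = dict(self.counts)
        for j, c in other.counts.items():
            out[j] = out.get(j, 0) + c
        return JunctionCounts(out)

    def to_frame(self, annotated: set[SpliceJunction] | None = None):
        import pandas as pd
        rows = [
            {"chrom": j.chrom, "strand": j.strand, "donor_end": j.donor_end,
             "acceptor_start": j.acceptor_start, "count": c,
             "known": (j in annotated) if annotated is not None else None}
            for j, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=[
            "chrom", "strand", "donor_end", "acceptor_start", "count", "known"])


def extract_junctions(
    alignments: AlignmentTable | Iterable[SplicedAlignment],
) -> JunctionCounts:
    """Count every inter-block gap as one junction observation."""
    if isinstance(alignments, AlignmentTable):
        t = alignments
        read_id = np.repeat(np.arange(len(t)), np.diff(t.offsets))
        same = read_id[1:] == read_id[:-1]
        donors = t.block_ends[:-1][same]
        acceptors = t.block_starts[1:][same]
        rev = t.is_reverse[read_id[:-1][same]]
        counts: dict[SpliceJunction, int] = {}
        if len(donors):
            arr = np.stack([donors, acceptors, rev.astype(np.int64)], axis=1)
            uniq, cnt = np.unique(arr, axis=0, return_counts=True)
            for (d, a, r), c in zip(uniq, cnt):
                j = SpliceJunction(t.chrom, "-" if r else "+", int(d), int(a))
                counts[j] = int(c)
        return JunctionCounts(counts)
    counts = {}
    for aln in alignments:
        for (_, d), (a, _) in zip(aln.blocks, aln.blocks[1:]):
            j = SpliceJunction(aln.chrom, aln.strand, d, a)
            counts[j] = counts.get(j, 0) + 1
    return JunctionCounts(counts)


def coverage(
    alignments: AlignmentTable | Iterable[SplicedAlignment],
    chrom: str,
    start: int,
    end: int,
    strand: str | None = None,
    chrom_length: int | None = None,
) -> np.ndarray:
    """Per-base depth of alignment blocks over [start, end) on a strand."""
    if start < 0 or end <= start or (chrom_length is not None and end > chrom_length):
        raise ValueError(f"region [{start},{end}) out of bounds")
    depth = np.zeros(end - start + 1, dtype=np.int64)
    if isinstance(alignments, AlignmentTable):
        t = alignments
        if t.chrom and t.chrom != chrom:
            return depth[:-1]
        bs, be = t.block_starts, t.block_ends
        if strand is not None:
            read_id = np.repeat(np.arange(len(t)), np.diff(t.offsets))
            keep = t.is_reverse[read_id] == (strand == "-")
            bs, be = bs[keep], be[keep]
        s = np.clip(bs, start, end) - start
        e = np.clip(be, start, end) - start
        ok = e > s
        np.add.at(depth, s[ok], 1)
        np.add.at(depth, e[ok], -1)
    else:
        for aln in alignments:
            if aln.chrom != chrom or (strand is not None and aln.strand != strand):
                continue
            for bs_, be_ in aln.blocks:
                s = max(bs_, start) - start
                e = min(be_, end) - start
                if e > s:
                    depth[s] += 1
                    depth[e] -= 1
    return np.cumsum(depth)[:-1]
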