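"""Gene annotation model: GTF parsing, feature classes, splice junctions.

Coordinates are 0-based half-open internally; GTF is read and written
1-based inclusive. Feature classes over a gene span are the six categories
used for read/peak distribution profiles: 5'UTR, CDS, 3'UTR, NC-exon
(exon of a noncoding transcript), intron, and intergenic. When transcripts
of one gene give a base conflicting labels the precedence is
CDS > 5'UTR > 3'UTR > NC-exon > intron (exonic always beats intronic;
translated sequence wins among exonic labels).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class GTFFormatError(ValueError):
    """Raised on malformed or wrong-dialect GTF input."""


class SpliceJunction(NamedTuple):
    """An intron: gap between the end of one exon and the start of the next.

    ``donor_end`` is the 0-based end (exclusive) of the upstream-in-genome
    exon block; ``acceptor_start`` the 0-based start of the downstream block.
    The intron occupies [donor_end, acceptor_start).
    """

    chrom: str
    strand: str
    donor_end: int
    acceptor_start: int

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end


@dataclasses.dataclass
class Transcript:
    id: str
    exons: list[Interval]                 # sorted, disjoint, 0-based half-open
    cds: Interval | None = None           # genomic span of coding sequence

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise GTFFormatError(f"transcript {self.id}: empty exon {s}-{e}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise GTFFormatError(f"transcript {self.id}: overlapping exons")
        if self.cds is not None:
            c1, c2 = self.cds
            if not (self.exons[0][0] <= c1 < c2 <= self.exons[-1][1]):
                raise GTFFormatError(f"transcript {self.id}: CDS outside exons")
            covered = any(s <= c1 < e for s, e in self.exons) and any(
                s < c2 <= e for s, e in self.exons
            )
            if not covered:
                raise GTFFormatError(f"transcript {self.id}: CDS ends not exonic")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def coding(self) -> bool:
        return self.cds is not None

    def junctions(self, chrom: str, strand: str) -> list[SpliceJunction]:
        return [
            SpliceJunction(chrom, strand, e1, s2)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclasses.dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GTFFormatError(f"gene {self.id}: bad strand {self.strand!r}")
        for t in self.transcripts:
            s, e = t.span
            if s < self.start or e > self.end:
                raise GTFFormatError(
                    f"gene {self.id}: transcript {t.id} outside gene span"
                )

    @property
    def coding(self) -> bool:
        return any(t.coding for t in self.transcripts)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def exon_union_length(self) -> int:
        """Length of the union of all exon bases across transcripts."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    def junctions(self) -> set[SpliceJunction]:
        out: set[SpliceJunction] = set()
        for t in self.transcripts:
            out.update(t.junctions(self.chrom, self.strand))
        return out


# ---------------------------------------------------------------------------
# GTF I/O


def parse_gtf(path: str | Path) -> list[Gene]:
    """Parse a GTF file into the hierarchical gene model.

    Requires the quoted ``gene_id``/``transcript_id`` attribute dialect.
    Recognised feature types: gene, transcript, exon, CDS. Other feature
    lines are ignored with a warning.
    """
    gene_rows: dict[str, dict] = {}
    tx_rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GTFFormatError(f"{path}:{lineno}: unparseable line: {exc}")
            ftype = feat.featuretype
            if ftype not in ("gene", "transcript", "exon", "CDS"):
                log.warning("%s:%d: ignoring feature type %r", path, lineno, ftype)
                continue
            attrs = feat.attributes
            if "gene_id" not in attrs:
                raise GTFFormatError(f"{path}:{lineno}: missing gene_id attribute")
            gid = attrs["gene_id"][0]
            start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
            if ftype == "gene":
                gene_rows[gid] = {
                    "chrom": feat.seqid, "strand": feat.strand,
                    "start": start0, "end": end0,
                }
                order.append(gid)
                continue
            if "transcript_id" not in attrs:
                raise GTFFormatError(
                    f"{path}:{lineno}: {ftype} line missing transcript_id"
                )
            tid = attrs["transcript_id"][0]
            row = tx_rows.setdefault(
                tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand,
                      "exons": [], "cds": []}
            )
            if row["gene_id"] != gid:
                raise GTFFormatError(f"transcript {tid} assigned to two genes")
            if ftype == "exon":
                row["exons"].append((start0, end0))
            elif ftype == "CDS":
                row["cds"].append((start0, end0))

    genes: list[Gene] = []
    tx_by_gene: dict[str, list[Transcript]] = {}
    for tid, row in tx_rows.items():
        if row["gene_id"] not in gene_rows:
            raise GTFFormatError(f"transcript {tid}: unknown parent {row['gene_id']}")
        cds = None
        if row["cds"]:
            cds = (min(s for s, _ in row["cds"]), max(e for _, e in row["cds"]))
        tx_by_gene.setdefault(row["gene_id"], []).append(
            Transcript(tid, row["exons"], cds)
        )
    for gid in order:
        row = gene_rows[gid]
        genes.append(
            Gene(gid, row["chrom"], row["strand"], row["start"], row["end"],
                 tx_by_gene.get(gid, []))
        )
    return genes


def write_gtf(genes: Sequence[Gene], path: str | Path, source: str = "ripsplice") -> None:
    """Emit the gene model as GTF (1-based inclusive, quoted attributes)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = f'gene_id "{g.id}"; transcript_id "{t.id}";'
                ts, te = t.span
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )
                if t.cds is not None:
                    c1, c2 = t.cds
                    for s, e in t.exons:
                        cs, ce = max(s, c1), min(e, c2)
                        if cs < ce:
                            fh.write(
                                f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                                f"{g.strand}\t0\t{tattrs}\n"
                            )


def annotated_junctions(genes: Iterable[Gene]) -> set[SpliceJunction]:
    """Union of consecutive-exon junctions over all transcripts, deduplicated."""
    out: set[SpliceJunction] = set()
    for g in genes:
        out.update(g.junctions())
    return out


# ---------------------------------------------------------------------------
# Feature index

FEATURE_CLASSES = ("5UTR", "CDS", "3UTR", "NC_exon", "intron", "intergenic")
# label codes: higher wins nothing -- precedence applied at build time
_CODE = {name: i for i, name in enumerate(FEATURE_CLASSES)}
_PRECEDENCE = ("CDS", "5UTR", "3UTR", "NC_exon", "intron")  # strongest first
INTERGENIC = _CODE["intergenic"]


def derive_features(gene: Gene) -> list[tuple[Interval, str]]:
    """Label every base of a gene span with one feature class.

    Coding-transcript exon bases split into 5'UTR / CDS / 3'UTR by the CDS
    span and strand; noncoding-transcript exon bases are NC-exon; gaps
    between exons are intron. Conflicts between transcripts resolve by
    CDS > 5'UTR > 3'UTR > NC-exon > intron. Returns merged, sorted
    (interval, class) tiles partitioning [gene.start, gene.end).
    """
    span_len = gene.end - gene.start
    # per-base class strength; 255 = unlabeled
    best = np.full(span_len, 255, dtype=np.uint8)
    strength = {name: i for i, name in enumerate(_PRECEDENCE)}

    def paint(s: int, e: int, cls: str) -> None:
        s, e = max(s, gene.start), min(e, gene.end)
        if s >= e:
            return
        sl = slice(s - gene.start, e - gene.start)
        st = strength[cls]
        np.minimum(best[sl], st, out=best[sl])

    for t in gene.transcripts:
        ts, te = t.span
        paint(ts, te, "intron")  # baseline inside transcript; exons overwrite
        for s, e in t.exons:
            if t.cds is None:
                paint(s, e, "NC_exon")
            else:
                c1, c2 = t.cds
                left, right = ("5UTR", "3UTR") if gene.strand == "+" else ("3UTR", "5UTR")
                paint(max(s, c1), min(e, c2), "CDS")
                if s < c1:
                    paint(s, min(e, c1), left)
                if e > c2:
                    paint(max(s, c2), e, right)
    # gene span outside any transcript counts as intron of the gene
    best[best == 255] = strength["intron"]

    tiles: list[tuple[Interval, str]] = []
    pos = 0
    while pos < span_len:
        code = best[pos]
        nxt = pos + 1
        while nxt < span_len and best[nxt] == code:
            nxt += 1
        tiles.append(((gene.start + pos, gene.start + nxt), _PRECEDENCE[code]))
        pos = nxt
    return tiles


class FeatureIndex:
    """Per-strand labelled feature map over one chromosome.

    Backed by a dense per-base uint8 array per strand (toy-genome scale);
    queries assign an interval the majority class of its bases, ties broken
    by the label precedence order.
    """

    def __init__(self, chrom: str, length: int, genes: Iterable[Gene]):
        self.chrom = chrom
        self.length = length
        self._labels = {
            "+": np.full(length, INTERGENIC, dtype=np.uint8),
            "-": np.full(length, INTERGENIC, dtype=np.uint8),
        }
        for g in genes:
            if g.chrom != chrom:
                continue
            arr = self._labels[g.strand]
            for (s, e), cls in derive_features(g):
                arr[s:e] = _CODE[cls]

    def classify(self, start: int, end: int, strand: str) -> str:
        """Majority feature class of [start, end) on a strand."""
        if start < 0 or end > self.length or start >= end:
            raise ValueError(f"interval [{start},{end}) outside chromosome")
        counts = np.bincount(self._labels[strand][start:end], minlength=6)
        top = counts.max()
        winners = [FEATURE_CLASSES[i] for i in np.nonzero(counts == top)[0]]
        if len(winners) == 1:
            return winners[0]
        for cls in _PRECEDENCE:  # deterministic tie-break by precedence
            if cls in winners:
                return cls
        return "intergenic"

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for strand in "+-":
                arr = self._labels[strand]
                boundaries = np.flatnonzero(np.diff(arr)) + 1
                edges = np.concatenate(([0], boundaries, [len(arr)]))
                for s, e in zip(edges[:-1], edges[1:]):
                    cls = FEATURE_CLASSES[arr[s]]
                    if cls == "intergenic":
                        continue
                    fh.write(f"{self.chrom}\t{s}\t{e}\t{cls}\t0\t{strand}\n")
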