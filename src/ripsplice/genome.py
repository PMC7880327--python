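"""Toy genome and annotation generator with planted signals.

One seeded call lays out the whole experiment: a random chromosome,
``n_genes`` non-overlapping multi-exon genes on both strands, and the three
classes of planted signal the downstream analysis is meant to recover —
fold-change genes, splicing-ratio shifts (one of ten event types per
alternative-splicing gene), and IP-enriched / shared-artifact peak
intervals (with a GC-rich motif embedded at motif-bearing peak centres).

Planted event grammar per type (delta = alternative splice-site offset):

====================  =====================================================
ES                    alt isoform skips one internal exon; only the
                      inclusion isoform is annotated (the skip is novel)
CE                    as ES but both isoforms annotated (cassette exon)
A5SS / A3SS           alternative donor/acceptor: one exon end moved
                      inward by delta (strand-aware)
IR                    alt isoform retains one intron (two exons merged)
MXE                   two adjacent internal exons, each isoform keeps one
5pMXE / 3pMXE         mutually exclusive first / last exons (strand-aware)
A5SS&ES / A3SS&ES     skip of one exon combined with an alternative
                      donor / acceptor on the flanking exon
====================  =====================================================

The "model" form is always the full base exon chain (or, for MXE-family
events, the form keeping the genomically left alternative exon); the
"alternative" form is the variant. Condition inclusion ratios for planted
genes are 0.5 -/+ ratio_shift/2.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .annotation import Gene, SpliceJunction, Transcript, write_gtf
from .config import SimulationConfig

EVENT_TYPES = (
    "ES", "A5SS", "A3SS", "IR", "MXE",
    "5pMXE", "3pMXE", "CE", "A3SS&ES", "A5SS&ES",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = dict(zip("ACGT", "TGCA"))

# structural bounds of generated genes
_MIN_EXONS, _MAX_EXONS = 5, 8
_EXON_LEN = (150, 400)
_INTRON_LEN = (200, 600)
_GENE_MARGIN = 100
_DELTA = 60  # alternative splice-site offset, bp
_MAX_SPAN = _MAX_EXONS * _EXON_LEN[1] + (_MAX_EXONS - 1) * _INTRON_LEN[1]


class SizingError(ValueError):
    """Genome too small to place the requested genes without overlap."""


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclasses.dataclass
class Isoform:
    id: str
    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclasses.dataclass
class PlantedEvent:
    gene_id: str
    event_type: str
    model_junctions: list[tuple[int, int]]
    alt_junctions: list[tuple[int, int]]     # empty for IR
    intron: tuple[int, int] | None           # IR only
    ratio_a: float
    ratio_b: float


@dataclasses.dataclass
class GeneDesign:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]             # base chain
    model: Isoform
    alt: Isoform | None
    annotate_alt: bool
    cds: tuple[int, int] | None              # nominal genomic CDS interval
    weight: float                            # relative expression
    is_deg: bool
    true_fold_change: float                  # condition B / condition A
    event: PlantedEvent | None

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class PeakPlan:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    enrichment: float
    has_motif: bool
    shared_with_input: bool


@dataclasses.dataclass
class GenomeDesign:
    config: SimulationConfig
    seq: np.ndarray                          # uint8 ASCII bases
    genes: list[GeneDesign]
    peaks: list[PeakPlan]

    @property
    def genome_str(self) -> str:
        return self.seq.tobytes().decode()

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        s = self.genome_str
        with open(path, "w") as fh:
            fh.write(f">{self.config.chrom}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")

    def to_genes(self) -> list[Gene]:
        """Annotation view: the gene model the GTF will contain."""
        out = []
        for g in self.genes:
            txs = [self._to_transcript(g, g.model)]
            if g.alt is not None and g.annotate_alt:
                txs.append(self._to_transcript(g, g.alt))
            out.append(Gene(g.id, g.chrom, g.strand, g.start, g.end, txs))
        return out

    @staticmethod
    def _to_transcript(g: GeneDesign, iso: Isoform) -> Transcript:
        cds = None
        if g.cds is not None:
            c1, c2 = g.cds
            segs = [(max(s, c1), min(e, c2)) for s, e in iso.exons
                    if min(e, c2) > max(s, c1)]
            if segs:
                cds = (segs[0][0], segs[-1][1])
        return Transcript(iso.id, [tuple(e) for e in iso.exons], cds)

    def write_gtf(self, path: str | Path) -> None:
        write_gtf(self.to_genes(), path, source="ripsplice_sim")


def _build_event(exons, etype, strand):
    """Return (model_exons, alt_exons, model_juncs, alt_juncs, intron)."""
    ex = [tuple(e) for e in exons]
    n = len(ex)
    k = n // 2
    d = _DELTA
    j = lambda a, b: (a, b)
    intron = None
    if etype in ("ES", "CE"):
        model = ex
        alt = ex[:k] + ex[k + 1:]
        mj = [j(ex[k - 1][1], ex[k][0]), j(ex[k][1], ex[k + 1][0])]
        aj = [j(ex[k - 1][1], ex[k + 1][0])]
    elif etype in ("A5SS", "A3SS"):
        # shrink-left: move donor end of exon k inward (genomic left side)
        left_side = (etype == "A5SS") == (strand == "+")
        model = ex
        if left_side:
            shrunk = (ex[k][0], ex[k][1] - d)
            alt = ex[:k] + [shrunk] + ex[k + 1:]
            mj = [j(ex[k][1], ex[k + 1][0])]
            aj = [j(ex[k][1] - d, ex[k + 1][0])]
        else:
            shrunk = (ex[k + 1][0] + d, ex[k + 1][1])
            alt = ex[:k + 1] + [shrunk] + ex[k + 2:]
            mj = [j(ex[k][1], ex[k + 1][0])]
            aj = [j(ex[k][1], ex[k + 1][0] + d)]
    elif etype == "IR":
        model = ex
        merged = (ex[k][0], ex[k + 1][1])
        alt = ex[:k] + [merged] + ex[k + 2:]
        mj = [j(ex[k][1], ex[k + 1][0])]
        aj = []
        intron = (ex[k][1], ex[k + 1][0])
    elif etype == "MXE":
        model = ex[:k + 1] + ex[k + 2:]          # keeps exon k
        alt = ex[:k] + ex[k + 1:]                # keeps exon k+1
        mj = [j(ex[k - 1][1], ex[k][0]), j(ex[k][1], ex[k + 2][0])]
        aj = [j(ex[k - 1][1], ex[k + 1][0]), j(ex[k + 1][1], ex[k + 2][0])]
    elif etype in ("5pMXE", "3pMXE"):
        left_terminal = (etype == "5pMXE") == (strand == "+")
        if left_terminal:
            model = [ex[0]] + ex[2:]             # first exon = ex0
            alt = ex[1:]                         # first exon = ex1
            mj = [j(ex[0][1], ex[2][0])]
            aj = [j(ex[1][1], ex[2][0])]
        else:
            model = ex[:n - 1]                   # last exon = ex[n-2]
            alt = ex[:n - 2] + [ex[n - 1]]       # last exon = ex[n-1]
            mj = [j(ex[n - 3][1], ex[n - 2][0])]
            aj = [j(ex[n - 3][1], ex[n - 1][0])]
    elif etype in ("A5SS&ES", "A3SS&ES"):
        left_side = (etype == "A5SS&ES") == (strand == "+")
        model = ex
        mj = [j(ex[k - 1][1], ex[k][0]), j(ex[k][1], ex[k + 1][0])]
        if left_side:
            shrunk = (ex[k - 1][0], ex[k - 1][1] - d)
            alt = ex[:k - 1] + [shrunk] + ex[k + 1:]
            aj = [j(ex[k - 1][1] - d, ex[k + 1][0])]
        else:
            shrunk = (ex[k + 1][0] + d, ex[k + 1][1])
            alt = ex[:k] + [shrunk] + ex[k + 2:]
            aj = [j(ex[k - 1][1], ex[k + 1][0] + d)]
    else:
        raise ValueError(f"unknown event type {etype!r}")
    return model, alt, mj, aj, intron


def generate_genome(config: SimulationConfig) -> GenomeDesign:
    """Build the seeded genome, gene structures, and all planted signals."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    L = config.genome_length
    slot = L // config.n_genes
    if slot < _MAX_SPAN + 2 * _GENE_MARGIN:
        raise SizingError(
            f"genome_length {L} cannot place {config.n_genes} genes without "
            f"overlap (need >= {(_MAX_SPAN + 2 * _GENE_MARGIN) * config.n_genes})"
        )
    seq = _BASES[rng.integers(0, 4, L)].copy()

    n = config.n_genes
    # planted-signal gene assignment (DEG and AS sets disjoint)
    perm = rng.permutation(n)
    n_deg = int(round(config.planted_deg_fraction * n))
    n_as = int(round(config.planted_as_fraction * n))
    if n_deg + n_as > n:
        raise SizingError("planted DEG + AS fractions exceed the gene count")
    deg_set = set(perm[:n_deg])
    as_list = list(perm[n_deg:n_deg + n_as])
    perm2 = rng.permutation(n)
    n_peak = int(round(config.planted_peak_fraction * n))
    n_art = int(round(config.planted_artifact_fraction * n))
    peak_set = set(perm2[:n_peak])
    artifact_set = set(perm2[n_peak:n_peak + n_art])

    genes: list[GeneDesign] = []
    peaks: list[PeakPlan] = []
    as_rank = {gi: r for r, gi in enumerate(as_list)}
    deg_rank = {gi: r for r, gi in enumerate(sorted(deg_set))}

    for i in range(n):
        gid = f"g{i + 1:04d}"
        n_ex = int(rng.integers(_MIN_EXONS, _MAX_EXONS + 1))
        ex_lens = rng.integers(_EXON_LEN[0], _EXON_LEN[1] + 1, n_ex)
        in_lens = rng.integers(_INTRON_LEN[0], _INTRON_LEN[1] + 1, n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        lo = slot * i + _GENE_MARGIN
        hi = slot * (i + 1) - _GENE_MARGIN - span
        start = int(lo + rng.integers(0, hi - lo + 1))
        exons = []
        pos = start
        for idx in range(n_ex):
            exons.append((pos, pos + int(ex_lens[idx])))
            pos += int(ex_lens[idx])
            if idx < n_ex - 1:
                pos += int(in_lens[idx])
        end = pos
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() < config.coding_fraction
        cds = None
        if coding:
            c1 = (exons[1][0] + exons[1][1]) // 2
            c2 = (exons[-2][0] + exons[-2][1]) // 2
            cds = (c1, c2)

        weight = float(rng.lognormal(0.0, config.expression_sigma))
        is_deg = i in deg_set
        fc = 1.0
        if is_deg:
            fc = config.fold_change if deg_rank[i] % 2 == 0 else 1.0 / config.fold_change

        event = None
        alt_iso = None
        annotate_alt = False
        if i in as_rank:
            etype = EVENT_TYPES[as_rank[i] % len(EVENT_TYPES)]
            m_ex, a_ex, mj, aj, intron = _build_event(exons, etype, strand)
            model_iso = Isoform(f"{gid}_t1", m_ex)
            alt_iso = Isoform(f"{gid}_t2", a_ex)
            annotate_alt = etype != "ES"   # novel skip: alt isoform unannotated
            event = PlantedEvent(gid, etype, mj, aj, intron,
                                 config.ratio_a, config.ratio_b)
        else:
            model_iso = Isoform(f"{gid}_t1", exons)

        genes.append(GeneDesign(
            gid, config.chrom, strand, start, end, exons, model_iso, alt_iso,
            annotate_alt, cds, weight, is_deg, fc, event,
        ))

        for pset, shared in ((peak_set, False), (artifact_set, True)):
            if i not in pset:
                continue
            w = config.peak_width
            if span <= w + 2 * config.rip_read_length:
                raise SizingError(f"gene {gid}: peak wider than gene span")
            off = int(rng.integers(config.rip_read_length,
                                   span - w - config.rip_read_length + 1))
            ps, pe = start + off, start + off + w
            has_motif = (not shared) and rng.random() < config.motif_fraction
            if has_motif:
                motif = config.motif if strand == "+" else revcomp(config.motif)
                mid = (ps + pe - len(motif)) // 2
                seq[mid:mid + len(motif)] = np.frombuffer(
                    motif.encode(), dtype=np.uint8)
            peaks.append(PeakPlan(gid, config.chrom, strand, ps, pe,
                                  config.enrichment, has_motif, shared))

    return GenomeDesign(config, seq, genes, peaks)
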