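"""Alternative-splicing event detection, quantification, and RASE calling.

Events are detected from splice-junction evidence laid against the gene
model and classified into ten types:

* skip family — an observed junction (D,A) bridging an annotated exon
  whose inclusion path (D,s),(e,A) is annotated. Pure skips are CE when
  the skip junction itself is annotated (a cassette exon the annotation
  knows) and ES when the skip is novel. If the bridging junction instead
  uses an alternative donor (A5SS&ES) or acceptor (A3SS&ES) on the
  flanking exon, the composite type is assigned (strand-aware naming).
* A5SS / A3SS — two junctions sharing one end whose variant ends fall on
  overlapping exon variants; named by which splice site (5' or 3' of the
  intron, strand-aware) moves. The model form is the shorter intron.
* MXE / 5pMXE / 3pMXE — two disjoint exons each spliced to common flanks
  and never to each other; internal (both flanks shared) is MXE, at the
  transcript 5'/3' terminus it is 5pMXE/3pMXE (strand-aware). The model
  form keeps the genomically left exon.
* IR — an annotated transcript exon spans another transcript's intron;
  retention evidence is contiguous (ungapped) reads crossing the
  exon-intron boundaries, competing with the spliced junction.

The AS ratio of an event in a sample is alt/(alt+model) where the model
and alternative counts are the mean supporting-read counts over the
form's junction(s) (boundary-crossing reads for IR retention); the ratio
is NA below ``min_support`` total informative reads. A regulated event
(RASE) is one whose per-replicate ratios differ between conditions by
Student's t-test p <= 0.05 with |mean ratio difference| >= 0.2; a
BH-adjusted column is reported alongside.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .alignments import AlignmentTable, JunctionCounts
from .annotation import Gene, SpliceJunction

log = logging.getLogger(__name__)

EVENT_TYPES = (
    "ES", "A5SS", "A3SS", "IR", "MXE",
    "5pMXE", "3pMXE", "CE", "A3SS&ES", "A5SS&ES",
)

Pair = tuple[int, int]


@dataclasses.dataclass(frozen=True)
class ASEvent:
    gene_id: str
    chrom: str
    strand: str
    etype: str
    model_junctions: tuple[Pair, ...]
    alt_junctions: tuple[Pair, ...]          # empty for IR
    intron: Pair | None                      # IR only
    known: bool

    @property
    def event_id(self) -> str:
        if self.etype == "IR":
            core = f"{self.intron[0]}-{self.intron[1]}"
        else:
            core = ",".join(f"{d}-{a}" for d, a in self.alt_junctions)
        return f"{self.gene_id}:{self.etype}:{core}"

    def junction_objects(self) -> list[SpliceJunction]:
        return [SpliceJunction(self.chrom, self.strand, d, a)
                for d, a in (*self.model_junctions, *self.alt_junctions)]


class _GeneContext:
    def __init__(self, gene: Gene, obs: dict[Pair, int]):
        self.gene = gene
        self.obs = obs
        self.annotated: set[Pair] = {
            (j.donor_end, j.acceptor_start) for j in gene.junctions()
        }
        self.universe: dict[Pair, int] = dict.fromkeys(self.annotated, 0)
        for p, c in obs.items():
            self.universe[p] = self.universe.get(p, 0) + c
        self.exons: set[Pair] = set()
        self.first_exons: set[Pair] = set()
        self.last_exons: set[Pair] = set()
        self.tx_exons: list[frozenset[Pair]] = []
        for t in gene.transcripts:
            exs = [tuple(e) for e in t.exons]
            self.exons.update(exs)
            self.first_exons.add(exs[0])
            self.last_exons.add(exs[-1])
            self.tx_exons.append(frozenset(exs))

    def support(self, pairs) -> int:
        return sum(self.obs.get(p, 0) for p in pairs)

    def exons_ending_at(self, d: int) -> list[Pair]:
        return [x for x in self.exons if x[1] == d]

    def exons_starting_at(self, a: int) -> list[Pair]:
        return [x for x in self.exons if x[0] == a]

    def left_variant(self, d_new: int, d_ref: int) -> bool:
        """Is d_new a plausible alternative donor-side end for exon(s) ending d_ref?"""
        if d_new == d_ref:
            return False
        for s0, e0 in self.exons_ending_at(d_ref):
            if s0 < d_new < e0:      # novel end inside the annotated exon
                return True
            for s1, e1 in self.exons_ending_at(d_new):
                if s1 < e0 and s0 < e1:  # annotated overlapping exon variants
                    return True
        return False

    def right_variant(self, a_new: int, a_ref: int) -> bool:
        if a_new == a_ref:
            return False
        for s0, e0 in self.exons_starting_at(a_ref):
            if s0 < a_new < e0:
                return True
            for s1, e1 in self.exons_starting_at(a_new):
                if s1 < e0 and s0 < e1:
                    return True
        return False

    def co_transcribed(self, x: Pair, y: Pair) -> bool:
        return any(x in t and y in t for t in self.tx_exons)


def _assign_junctions_to_genes(
    junctions: JunctionCounts, genes: Sequence[Gene]
) -> tuple[dict[str, dict[Pair, int]], int]:
    by_key: dict[tuple[str, str], list[Gene]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    index = {}
    for key, gs in by_key.items():
        gs.sort(key=lambda g: g.start)
        index[key] = (np.array([g.start for g in gs]),
                      np.array([g.end for g in gs]), gs)
    out: dict[str, dict[Pair, int]] = {g.id: {} for g in genes}
    intergenic = 0
    for j, c in junctions:
        key = (j.chrom, j.strand)
        if key not in index:
            intergenic += c
            continue
        starts, ends, gs = index[key]
        i = int(np.searchsorted(starts, j.donor_end, side="right")) - 1
        if i >= 0 and j.acceptor_start <= ends[i]:
            out[gs[i].id][(j.donor_end, j.acceptor_start)] = c
        else:
            intergenic += c
    return out, intergenic


def detect_events(
    junctions: JunctionCounts,
    genes: Sequence[Gene],
    min_total_support: int = 1,
) -> list[ASEvent]:
    """Classify splicing events from pooled junction counts and the gene model."""
    per_gene, intergenic = _assign_junctions_to_genes(junctions, genes)
    if intergenic:
        log.info("detect_events: %d junction reads outside genes", intergenic)
    events: list[ASEvent] = []
    for gene in genes:
        ctx = _GeneContext(gene, per_gene[gene.id])
        events.extend(_detect_gene_events(ctx, min_total_support))
    return events


def _detect_gene_events(ctx: _GeneContext, min_support: int) -> list[ASEvent]:
    g = ctx.gene
    A = ctx.annotated
    U = ctx.universe
    seen: set = set()
    consumed: set[Pair] = set()
    events: list[ASEvent] = []

    def emit(etype, model, alt, intron=None):
        model, alt = tuple(sorted(model)), tuple(sorted(alt))
        key = (etype, model, alt, intron)
        if key in seen:
            return
        pairs = model + alt
        if ctx.support(pairs) < min_support and intron is None:
            return
        if intron is not None and ctx.support(model) < min_support:
            return
        seen.add(key)
        known = all(p in A for p in pairs)
        events.append(ASEvent(g.id, g.chrom, g.strand, etype,
                              model, alt, intron, known))

    # --- intron retention: an exon spanning another isoform's intron
    for (d, a) in sorted(A):
        if any(s < d and e > a for s, e in ctx.exons):
            emit("IR", [(d, a)], [], intron=(d, a))

    # --- skip family
    for (D, Aj) in sorted(U):
        skipped = [x for x in ctx.exons if D <= x[0] and x[1] <= Aj]
        for (s, e) in sorted(skipped):
            j1s = [p for p in A if p[1] == s]
            j2s = [p for p in A if p[0] == e]
            for (D1, _) in sorted(j1s):
                for (_, A1) in sorted(j2s):
                    if (D1, s) == (D, Aj) or (e, A1) == (D, Aj):
                        continue
                    model = [(D1, s), (e, A1)]
                    if D1 == D and A1 == Aj:
                        etype = "CE" if (D, Aj) in A else "ES"
                    elif A1 == Aj and ctx.left_variant(D, D1):
                        etype = "A5SS&ES" if g.strand == "+" else "A3SS&ES"
                    elif D1 == D and ctx.right_variant(Aj, A1):
                        etype = "A3SS&ES" if g.strand == "+" else "A5SS&ES"
                    else:
                        continue
                    emit(etype, model, [(D, Aj)])
                    consumed.add((D, Aj))

    # --- mutually exclusive exons
    exlist = sorted(ctx.exons)
    for xi, x in enumerate(exlist):
        for y in exlist[xi + 1:]:
            if y[0] < x[1]:         # overlapping: splice-site variants, not MXE
                continue
            if ctx.co_transcribed(x, y):
                continue
            into_x = [p for p in U if p[1] == x[0]]
            into_y = [p for p in U if p[1] == y[0]]
            outof_x = [p for p in U if p[0] == x[1]]
            outof_y = [p for p in U if p[0] == y[1]]
            joined = (x[1], y[0]) in U
            if joined:
                continue
            donors = {p[0] for p in into_x} & {p[0] for p in into_y}
            acceptors = {p[1] for p in outof_x} & {p[1] for p in outof_y}
            if donors and acceptors:
                D, Ac = min(donors), min(a for a in acceptors if a >= y[1])
                emit("MXE", [(D, x[0]), (x[1], Ac)], [(D, y[0]), (y[1], Ac)])
                consumed.update({(D, x[0]), (x[1], Ac), (D, y[0]), (y[1], Ac)})
            elif acceptors and not into_x and not into_y:
                # alternative genomically-first exons
                if x in ctx.first_exons and y in ctx.first_exons:
                    Ac = min(a for a in acceptors if a >= y[1])
                    etype = "5pMXE" if g.strand == "+" else "3pMXE"
                    emit(etype, [(x[1], Ac)], [(y[1], Ac)])
                    consumed.update({(x[1], Ac), (y[1], Ac)})
            elif donors and not outof_x and not outof_y:
                if x in ctx.last_exons and y in ctx.last_exons:
                    D = min(donors)
                    etype = "3pMXE" if g.strand == "+" else "5pMXE"
                    emit(etype, [(D, x[0])], [(D, y[0])])
                    consumed.update({(D, x[0]), (D, y[0])})

    # --- alternative splice sites (shared-end junction pairs)
    pairs = sorted(U)
    by_acceptor: dict[int, list[int]] = {}
    by_donor: dict[int, list[int]] = {}
    for d, a in pairs:
        if (d, a) in consumed:
            continue
        by_acceptor.setdefault(a, []).append(d)
        by_donor.setdefault(d, []).append(a)
    for a, ds in by_acceptor.items():
        ds = sorted(ds)
        for i in range(len(ds)):
            for k in range(i + 1, len(ds)):
                d1, d2 = ds[i], ds[k]
                if ctx.left_variant(d1, d2) or ctx.left_variant(d2, d1):
                    etype = "A5SS" if g.strand == "+" else "A3SS"
                    emit(etype, [(d2, a)], [(d1, a)])  # model: shorter intron
    for d, as_ in by_donor.items():
        as_ = sorted(as_)
        for i in range(len(as_)):
            for k in range(i + 1, len(as_)):
                a1, a2 = as_[i], as_[k]
                if ctx.right_variant(a1, a2) or ctx.right_variant(a2, a1):
                    etype = "A3SS" if g.strand == "+" else "A5SS"
                    emit(etype, [(d, a1)], [(d, a2)])
    return events


# ---------------------------------------------------------------------------
# Quantification


def _boundary_crossers(table: AlignmentTable, strand: str, pos: int,
                       anchor: int) -> int:
    """Ungapped reads contiguously covering [pos-anchor, pos+anchor)."""
    single = np.diff(table.offsets) == 1
    on_strand = table.is_reverse == (strand == "-")
    m = single & on_strand
    starts = table.starts[m]
    ends = table.ends[m]
    return int(np.count_nonzero((starts <= pos - anchor) & (ends >= pos + anchor)))


def quantify_events(
    events: Sequence[ASEvent],
    samples: Sequence[tuple[str, JunctionCounts, AlignmentTable | None]],
    min_support: int = 10,
    anchor: int = 5,
) -> pd.DataFrame:
    """Per-sample model/alt counts and AS ratios for detected events.

    ``samples`` holds (name, junction counts, alignment table); the table
    is only required when IR events are present (boundary-read counting).
    Returns a long DataFrame (event_id, sample, model_count, alt_count,
    ratio) where ratio is NaN below ``min_support`` informative reads.
    """
    rows = []
    for name, juncs, table in samples:
        cache: dict = {}
        for ev in events:
            model = np.mean([
                juncs[SpliceJunction(ev.chrom, ev.strand, d, a)]
                for d, a in ev.model_junctions
            ])
            if ev.etype == "IR":
                if table is None:
                    raise ValueError("IR quantification needs alignment tables")
                d, a = ev.intron
                key = (ev.strand, d, a)
                if key not in cache:
                    cache[key] = 0.5 * (
                        _boundary_crossers(table, ev.strand, d, anchor)
                        + _boundary_crossers(table, ev.strand, a, anchor)
                    )
                alt = cache[key]
            else:
                alt = np.mean([
                    juncs[SpliceJunction(ev.chrom, ev.strand, d, a)]
                    for d, a in ev.alt_junctions
                ])
            tot = model + alt
            ratio = alt / tot if tot >= min_support else np.nan
            rows.append({
                "event_id": ev.event_id, "gene_id": ev.gene_id,
                "event_type": ev.etype, "sample": name,
                "model_count": float(model), "alt_count": float(alt),
                "ratio": ratio,
            })
    return pd.DataFrame(rows, columns=[
        "event_id", "gene_id", "event_type", "sample",
        "model_count", "alt_count", "ratio"])


def detect_rases(
    quantifications: pd.DataFrame,
    condition_of: dict[str, str],
    p_threshold: float = 0.05,
    delta_threshold: float = 0.2,
) -> pd.DataFrame:
    """Two-sample t-test on per-replicate AS ratios with both gates.

    Events lacking >=2 defined ratios per condition are untestable and
    dropped (logged). The ``significant`` flag uses the raw-p rule
    (p <= 0.05 and |delta| >= 0.2); a BH-adjusted column is also emitted.
    """
    rows = []
    skipped = 0
    for (event_id, gene_id, etype), sub in quantifications.groupby(
            ["event_id", "gene_id", "event_type"], sort=True):
        ra = sub.loc[[condition_of[s] == "A" for s in sub["sample"]], "ratio"].dropna()
        rb = sub.loc[[condition_of[s] == "B" for s in sub["sample"]], "ratio"].dropna()
        if len(ra) < 2 or len(rb) < 2:
            skipped += 1
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = sps.ttest_ind(rb, ra, equal_var=True)
        delta = float(abs(rb.mean() - ra.mean()))
        rows.append({
            "event_id": event_id, "gene_id": gene_id, "event_type": etype,
            "mean_ratio_a": float(ra.mean()), "mean_ratio_b": float(rb.mean()),
            "delta_ratio": delta, "t_stat": float(t), "pvalue": float(p),
        })
    if skipped:
        log.info("detect_rases: %d events untestable", skipped)
    out = pd.DataFrame(rows, columns=[
        "event_id", "gene_id", "event_type", "mean_ratio_a", "mean_ratio_b",
        "delta_ratio", "t_stat", "pvalue"])
    if len(out):
        tested = out["pvalue"].notna()
        out["fdr"] = np.nan
        if tested.any():
            out.loc[tested, "fdr"] = multipletests(
                out.loc[tested, "pvalue"], method="fdr_bh")[1]
        out["significant"] = (
            (out["pvalue"] <= p_threshold)
            & (out["delta_ratio"] >= delta_threshold)
        ).fillna(False)
    else:
        out["fdr"] = []
        out["significant"] = []
    return out.set_index("event_id")
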