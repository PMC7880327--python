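"""Simulated aligned-read libraries (SAM emission).

Fragments are emitted pre-aligned, one single-end SAM record per fragment,
at the pipeline's true input boundary (alignment itself is out of scope).
Per-gene fragment counts are Poisson with a gene-specific rate; for genes
carrying a planted splicing event the isoform of each fragment is
Bernoulli(inclusion ratio), with the ratio shifted between conditions.
Junction-spanning fragments get N-gapped CIGARs. Every record carries
MAPQ 50 and ``NH:i:1`` (the simulator's unique-mapping marker); reads are
on the transcript strand (stranded-kit convention).

RIP libraries: input fragments start uniformly within expressed gene
spans; IP fragments are additionally concentrated (enrichment-fold start
density) inside planted peak windows. Shared artifact peaks are enriched
in both IP and input.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from pathlib import Path

import numpy as np

from .config import SimulationConfig
from .genome import GeneDesign, GenomeDesign, Isoform
from .truth import TruthTable

CONDITIONS = ("A", "B")


@dataclasses.dataclass
class LibraryManifest:
    """Paths of the simulated libraries, keyed the way the analysis wants them."""
    rnaseq: dict[str, list[Path]]           # condition -> replicate SAMs
    rip_ip: list[Path]
    rip_input: list[Path]

    def all_rnaseq(self) -> list[tuple[str, int, Path]]:
        return [(cond, i + 1, p) for cond in CONDITIONS
                for i, p in enumerate(self.rnaseq[cond])]


def _sam_header(config: SimulationConfig) -> str:
    return (
        "@HD\tVN:1.6\tSO:coordinate\n"
        f"@SQ\tSN:{config.chrom}\tLN:{config.genome_length}\n"
        "@PG\tID:ripsplice_sim\tPN:ripsplice_sim\n"
    )


def _write_sam(path: Path, config: SimulationConfig, records) -> None:
    """records: list of (pos0, flag, cigar, seq) — sorted here by position."""
    records.sort(key=lambda r: r[0])
    chrom = config.chrom
    with open(path, "w") as fh:
        fh.write(_sam_header(config))
        lines = [
            f"r{i:07d}\t{flag}\t{chrom}\t{pos + 1}\t50\t{cigar}\t*\t0\t0\t"
            f"{seq}\t*\tNH:i:1"
            for i, (pos, flag, cigar, seq) in enumerate(records)
        ]
        if lines:
            fh.write("\n".join(lines) + "\n")


def _isoform_layout(iso: Isoform):
    lens = [e - s for s, e in iso.exons]
    cum = [0]
    for ln in lens:
        cum.append(cum[-1] + ln)
    return cum


def _spliced_records(gene: GeneDesign, iso: Isoform, starts, read_len: int,
                     genome: str, txseq_cache: dict) -> list:
    """Map transcript-coordinate fragment starts to SAM (pos, flag, cigar, seq)."""
    key = iso.id
    if key not in txseq_cache:
        txseq_cache[key] = (
            "".join(genome[s:e] for s, e in iso.exons), _isoform_layout(iso)
        )
    txseq, cum = txseq_cache[key]
    exons = iso.exons
    flag = 0 if gene.strand == "+" else 16
    out = []
    for t in starts:
        t = int(t)
        i = bisect_right(cum, t) - 1
        off = t - cum[i]
        pos = exons[i][0] + off
        remaining = read_len
        parts = []
        j = i
        while remaining > 0:
            s, e = exons[j]
            avail = e - s - (off if j == i else 0)
            take = min(avail, remaining)
            parts.append(take)
            remaining -= take
            j += 1
        if len(parts) == 1:
            cigar = f"{read_len}M"
        else:
            segs = [f"{parts[0]}M"]
            for idx, take in enumerate(parts[1:], start=i + 1):
                gap = exons[idx][0] - exons[idx - 1][1]
                segs.append(f"{gap}N{take}M")
            cigar = "".join(segs)
        out.append((pos, flag, cigar, txseq[t:t + read_len]))
    return out


def simulate_rnaseq(design: GenomeDesign, outdir: str | Path) -> LibraryManifest:
    """Write one SAM per RNA-seq library plus the truth tables."""
    config = design.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = design.genome_str
    L = config.read_length
    total_w = sum(g.weight for g in design.genes)
    paths: dict[str, list[Path]] = {c: [] for c in CONDITIONS}
    for ci, cond in enumerate(CONDITIONS):
        for rep in range(config.n_replicates_per_condition):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 101, ci, rep]))
            records: list = []
            cache: dict = {}
            for g in design.genes:
                mu = config.rnaseq_depth * g.weight / total_w
                if cond == "B" and g.is_deg:
                    mu *= g.true_fold_change
                n = int(rng.poisson(mu))
                if n == 0:
                    continue
                if g.alt is not None and g.event is not None:
                    r = g.event.ratio_b if cond == "B" else g.event.ratio_a
                    n_alt = int(rng.binomial(n, r))
                else:
                    n_alt = 0
                for iso, m in ((g.model, n - n_alt), (g.alt, n_alt)):
                    if m == 0 or iso is None:
                        continue
                    span = iso.length - L
                    if span < 0:
                        continue  # transcript shorter than a read
                    starts = rng.integers(0, span + 1, m)
                    records.extend(
                        _spliced_records(g, iso, starts, L, genome, cache))
            path = outdir / f"rnaseq_{cond}_rep{rep + 1}.sam"
            _write_sam(path, config, records)
            paths[cond].append(path)
    return LibraryManifest(paths, [], [])


class PlacementError(ValueError):
    """A planted peak does not fit inside its gene span."""


def _rip_gene_starts(rng, g: GeneDesign, n: int, windows, read_len: int):
    """Fragment start positions in one gene: uniform with enriched windows.

    Start-position weight is 1 outside windows and ``enrichment`` inside,
    so window read counts are enrichment-fold a matched control window.
    """
    lo, hi = g.start, g.end - read_len  # inclusive start range
    if hi < lo:
        raise PlacementError(f"gene {g.id} shorter than a read")
    win = []
    for (ps, pe, enr) in windows:
        ws, we = ps, pe - read_len  # starts keeping the read inside the peak
        if ws < lo or we > hi:
            raise PlacementError(f"peak {ps}-{pe} exceeds gene span of {g.id}")
        win.append((ws, we, enr))
    win.sort()
    # complementary uniform segments
    segs = []
    cur = lo
    for ws, we, _ in win:
        if ws > cur:
            segs.append((cur, ws - 1))
        cur = we + 1
    if cur <= hi:
        segs.append((cur, hi))
    comps = [(a, b, 1.0) for a, b in segs] + list(win)
    weights = np.array([(b - a + 1) * e for a, b, e in comps], dtype=float)
    probs = weights / weights.sum()
    which = rng.choice(len(comps), size=n, p=probs)
    starts = np.empty(n, dtype=np.int64)
    for idx, (a, b, _) in enumerate(comps):
        m = which == idx
        starts[m] = rng.integers(a, b + 1, int(m.sum()))
    return starts


def simulate_rip(design: GenomeDesign, outdir: str | Path) -> LibraryManifest:
    """Write IP and input SAMs for each RIP replicate."""
    config = design.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = design.genome_str
    L = config.rip_read_length
    total_w = sum(g.weight for g in design.genes)
    peaks_by_gene: dict[str, list] = {}
    for p in design.peaks:
        peaks_by_gene.setdefault(p.gene_id, []).append(p)
    ip_paths, input_paths = [], []
    for rep in range(config.n_rip_replicates):
        for ki, kind in enumerate(("ip", "input")):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 102, rep, ki]))
            records: list = []
            for g in design.genes:
                mu = config.rip_depth * g.weight / total_w
                n = int(rng.poisson(mu))
                if n == 0:
                    continue
                windows = [
                    (p.start, p.end, p.enrichment)
                    for p in peaks_by_gene.get(g.id, ())
                    if kind == "ip" or p.shared_with_input
                ]
                starts = _rip_gene_starts(rng, g, n, windows, L)
                flag = 0 if g.strand == "+" else 16
                cigar = f"{L}M"
                records.extend(
                    (int(s), flag, cigar, genome[s:s + L]) for s in starts)
            path = outdir / f"rip_{kind}_rep{rep + 1}.sam"
            _write_sam(path, config, records)
            (ip_paths if kind == "ip" else input_paths).append(path)
    return LibraryManifest({c: [] for c in CONDITIONS}, ip_paths, input_paths)


def simulate_dataset(config: SimulationConfig, outdir: str | Path):
    """Full synthetic dataset: FASTA + GTF + all SAMs + truth tables.

    Returns (design, truth, manifest). Byte-identical outputs for a given
    config (seed included).
    """
    from .genome import generate_genome
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = generate_genome(config)
    design.write_fasta(outdir / "genome.fa")
    design.write_gtf(outdir / "annotation.gtf")
    truth = TruthTable.from_design(design)
    truth.write(outdir)
    rna = simulate_rnaseq(design, outdir)
    rip = simulate_rip(design, outdir)
    manifest = LibraryManifest(rna.rnaseq, rip.rip_ip, rip.rip_input)
    config.to_yaml(outdir / "sim_config.yaml")
    return design, truth, manifest
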