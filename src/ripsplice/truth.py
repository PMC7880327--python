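"""Machine-readable record of every planted signal (the acceptance surface).

Three TSV tables: per-gene expression truth (weights, fold changes), the
planted splicing events with their defining junctions and condition
ratios, and the planted peak intervals with enrichment/motif/artifact
flags. Round-trips losslessly through :meth:`TruthTable.write` /
:meth:`TruthTable.read`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .genome import GenomeDesign


def _fmt_junctions(juncs) -> str:
    return ";".join(f"{d}-{a}" for d, a in juncs)


def parse_junctions(s: str) -> list[tuple[int, int]]:
    if not s or pd.isna(s):
        return []
    out = []
    for part in str(s).split(";"):
        d, a = part.split("-")
        out.append((int(d), int(a)))
    return out


@dataclasses.dataclass
class TruthTable:
    genes: pd.DataFrame
    events: pd.DataFrame
    peaks: pd.DataFrame

    @classmethod
    def from_design(cls, design: GenomeDesign) -> "TruthTable":
        gene_rows, event_rows, peak_rows = [], [], []
        for g in design.genes:
            gene_rows.append({
                "gene_id": g.id, "chrom": g.chrom, "strand": g.strand,
                "start": g.start, "end": g.end,
                "coding": g.cds is not None, "weight": g.weight,
                "is_deg": g.is_deg, "true_fold_change": g.true_fold_change,
                "event_type": g.event.event_type if g.event else "",
            })
            if g.event is not None:
                ev = g.event
                event_rows.append({
                    "gene_id": g.id, "event_type": ev.event_type,
                    "model_junctions": _fmt_junctions(ev.model_junctions),
                    "alt_junctions": _fmt_junctions(ev.alt_junctions),
                    "intron_start": ev.intron[0] if ev.intron else -1,
                    "intron_end": ev.intron[1] if ev.intron else -1,
                    "ratio_a": ev.ratio_a, "ratio_b": ev.ratio_b,
                    "alt_annotated": g.annotate_alt,
                })
        for p in design.peaks:
            peak_rows.append({
                "gene_id": p.gene_id, "chrom": p.chrom, "strand": p.strand,
                "start": p.start, "end": p.end, "enrichment": p.enrichment,
                "has_motif": p.has_motif, "shared_with_input": p.shared_with_input,
            })
        return cls(
            pd.DataFrame(gene_rows),
            pd.DataFrame(event_rows, columns=[
                "gene_id", "event_type", "model_junctions", "alt_junctions",
                "intron_start", "intron_end", "ratio_a", "ratio_b",
                "alt_annotated"]),
            pd.DataFrame(peak_rows, columns=[
                "gene_id", "chrom", "strand", "start", "end", "enrichment",
                "has_motif", "shared_with_input"]),
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
        self.peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthTable":
        outdir = Path(outdir)
        return cls(
            pd.read_csv(outdir / "truth_genes.tsv", sep="\t",
                        keep_default_na=False),
            pd.read_csv(outdir / "truth_events.tsv", sep="\t",
                        keep_default_na=False),
            pd.read_csv(outdir / "truth_peaks.tsv", sep="\t",
                        keep_default_na=False),
        )
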