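"""End-to-end analysis over a simulated (or equivalently formatted) dataset.

``simulate → expression → splice → peaks → integrate`` with every stage
reading its inputs from files (SAM/GTF/FASTA), plus recovery metrics
against the simulator's truth tables.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import expression, integrate, peaks as peakmod, splicing
from .alignments import AlignmentTable, extract_junctions
from .annotation import FeatureIndex, Gene, annotated_junctions, parse_gtf
from .config import SimulationConfig
from .reads import CONDITIONS, simulate_dataset
from .truth import TruthTable, parse_junctions

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    config: SimulationConfig
    genes: list[Gene]
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    correlation: pd.DataFrame
    degs: pd.DataFrame                 # all genes, with `significant`
    events: list[splicing.ASEvent]
    quantifications: pd.DataFrame
    rases: pd.DataFrame
    ip_peaks: list[list[peakmod.Peak]]       # per replicate, input-subtracted
    ip_called: list[list[peakmod.Peak]]      # per replicate, before subtraction
    input_peaks: list[list[peakmod.Peak]]
    final_peaks: list[peakmod.Peak]          # replicate-consistent, subtracted
    replicate_overlap: peakmod.OverlapSummary | None
    kmer_table: pd.DataFrame | None
    truth: TruthTable | None

    @property
    def condition_of(self) -> dict[str, str]:
        return {s: ("A" if s.startswith("A_") else "B")
                for s in self.counts.columns}


def run_pipeline(outdir: str | Path, n_sim: int = 500, seed: int = 0,
                 min_mapq: int = 20, kmer_k: int | None = None,
                 with_kmer: bool = True) -> PipelineResult:
    """Analyse a dataset directory written by :func:`simulate_dataset`."""
    outdir = Path(outdir)
    config = SimulationConfig.from_yaml(outdir / "sim_config.yaml")
    genes = parse_gtf(outdir / "annotation.gtf")
    truth = None
    if (outdir / "truth_genes.tsv").exists():
        truth = TruthTable.read(outdir)

    # --- expression
    sample_tables: dict[str, AlignmentTable] = {}
    sample_names: list[str] = []
    for cond in CONDITIONS:
        for rep in range(1, config.n_replicates_per_condition + 1):
            name = f"{cond}_rep{rep}"
            sample_tables[name] = AlignmentTable.from_sam(
                outdir / f"rnaseq_{cond}_rep{rep}.sam", min_mapq=min_mapq)
            sample_names.append(name)
    sample_counts = {
        name: expression.count_fragments(tbl, genes, stranded=config.stranded)
        for name, tbl in sample_tables.items()
    }
    counts = pd.DataFrame({n: sc.counts for n, sc in sample_counts.items()})
    lengths = expression.gene_lengths(genes)
    fpkm = expression.fpkm_matrix(sample_counts, lengths)
    corr, _ = expression.correlation_matrix(fpkm)
    condition_of = {n: n.split("_")[0] for n in sample_names}
    totals = {n: sc.total for n, sc in sample_counts.items()}
    degs = expression.detect_degs(counts, condition_of, totals=totals,
                                  return_all=True)

    # --- splicing
    per_sample_junctions = {
        n: extract_junctions(tbl) for n, tbl in sample_tables.items()
    }
    pooled = None
    for jc in per_sample_junctions.values():
        pooled = jc if pooled is None else pooled.add(jc)
    events = splicing.detect_events(pooled, genes)
    quants = splicing.quantify_events(
        events,
        [(n, per_sample_junctions[n], sample_tables[n]) for n in sample_names],
    )
    rases = splicing.detect_rases(quants, condition_of)

    # --- peaks
    ip_sub, ip_raw, input_called = [], [], []
    for rep in range(1, config.n_rip_replicates + 1):
        ip_tbl = AlignmentTable.from_sam(
            outdir / f"rip_ip_rep{rep}.sam", min_mapq=min_mapq)
        in_tbl = AlignmentTable.from_sam(
            outdir / f"rip_input_rep{rep}.sam", min_mapq=min_mapq)
        ip_called = peakmod.call_peaks(ip_tbl, genes, n_sim=n_sim,
                                       seed=seed * 10 + rep)
        in_called = peakmod.call_peaks(in_tbl, genes, n_sim=n_sim,
                                       seed=seed * 10 + rep + 1000)
        ip_sub.append(peakmod.subtract_input(ip_called, in_called))
        ip_raw.append(ip_called)
        input_called.append(in_called)
    overlap = None
    final = ip_sub[0] if ip_sub else []
    if len(ip_sub) >= 2:
        overlap = peakmod.replicate_overlap(ip_sub[0], ip_sub[1])
        final = [p for p in ip_sub[0]
                 if any(p.overlaps(q) for q in ip_sub[1])]

    # --- integration
    kmer_table = None
    if with_kmer and final:
        genome = str(Fasta(str(outdir / "genome.fa"))[config.chrom][:])
        kmer_table = integrate.peak_kmer_enrichment(
            genome, final, genes,
            k=kmer_k or len(config.motif), seed=seed)

    return PipelineResult(
        config, genes, counts, fpkm, corr, degs, events, quants, rases,
        ip_sub, ip_raw, input_called, final, overlap, kmer_table, truth,
    )


def simulate_and_run(config: SimulationConfig, outdir: str | Path,
                     n_sim: int = 500, **kwargs) -> PipelineResult:
    simulate_dataset(config, outdir)
    return run_pipeline(outdir, n_sim=n_sim, seed=config.seed, **kwargs)


# ---------------------------------------------------------------------------
# Truth-table recovery metrics


def _match_event(truth_row, detected: dict[tuple[str, str], list]) -> bool:
    key = (truth_row["gene_id"], truth_row["event_type"])
    if key not in detected:
        return False
    mj = set(parse_junctions(truth_row["model_junctions"]))
    aj = set(parse_junctions(truth_row["alt_junctions"]))
    for ev in detected[key]:
        if set(ev.model_junctions) == mj and (
                ev.etype == "IR" or set(ev.alt_junctions) == aj):
            return True
    return False


def recovery_metrics(result: PipelineResult) -> dict[str, float]:
    """Planted-signal recovery and artifact-removal rates vs the truth table."""
    truth = result.truth
    if truth is None:
        raise ValueError("dataset has no truth tables")
    out: dict[str, float] = {}

    # DEG recall: planted fold-change genes among significant calls
    planted = set(truth.genes.loc[truth.genes["is_deg"].astype(bool), "gene_id"])
    called = set(result.degs.index[result.degs["significant"]])
    if planted:
        out["deg_recall"] = len(planted & called) / len(planted)
        out["deg_precision"] = (
            len(planted & called) / len(called) if called else float("nan"))

    # event detection: every planted event present with the correct type
    by_key: dict[tuple[str, str], list] = {}
    for ev in result.events:
        by_key.setdefault((ev.gene_id, ev.etype), []).append(ev)
    ev_truth = truth.events
    if len(ev_truth):
        matched = ev_truth.apply(lambda r: _match_event(r, by_key), axis=1)
        out["event_detection_rate"] = float(matched.mean())

        # RASE recall: planted (shifted) events flagged as significant
        shifted = ev_truth[
            (ev_truth["ratio_b"] - ev_truth["ratio_a"]).abs() > 1e-9]
        if len(shifted):
            flagged = result.rases[result.rases["significant"]]
            fkeys = set(zip(flagged["gene_id"], flagged["event_type"]))
            hit = shifted.apply(
                lambda r: (r["gene_id"], r["event_type"]) in fkeys, axis=1)
            out["rase_recall"] = float(hit.mean())

    # peak recall / artifact removal on the final peak set
    pk_truth = truth.peaks
    if len(pk_truth):
        def recovered(row, peak_list) -> bool:
            return any(
                p.gene_id == row["gene_id"]
                and p.start < row["end"] and row["start"] < p.end
                for p in peak_list)
        ip_only = pk_truth[~pk_truth["shared_with_input"].astype(bool)]
        shared = pk_truth[pk_truth["shared_with_input"].astype(bool)]
        if len(ip_only):
            out["peak_recall"] = float(ip_only.apply(
                recovered, axis=1, peak_list=result.final_peaks).mean())
        if len(shared):
            out["artifact_removed"] = 1.0 - float(shared.apply(
                recovered, axis=1, peak_list=result.final_peaks).mean())
    if result.replicate_overlap is not None:
        out["replicate_peak_overlap"] = result.replicate_overlap.jaccard_like

    if result.kmer_table is not None:
        out["motif_rank"] = float(
            result.kmer_table.loc[result.config.motif, "rank"])
    return out


def null_fractions(result: PipelineResult) -> dict[str, float]:
    """Raw-p calibration fractions for a no-signal dataset."""
    out: dict[str, float] = {}
    degs = result.degs
    tested = degs["pvalue"].notna()
    if tested.any():
        out["deg_p_lt_05"] = float((degs.loc[tested, "pvalue"] < 0.05).mean())
        out["deg_n"] = int(tested.sum())
    rases = result.rases
    if len(rases):
        ok = rases["pvalue"].notna()
        out["rase_p_le_05"] = float((rases.loc[ok, "pvalue"] <= 0.05).mean())
        out["rase_n"] = int(ok.sum())
    return out
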