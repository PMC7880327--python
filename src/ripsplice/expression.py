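"""Gene-level fragment counting, FPKM, sample correlation, and DEG calling.

FPKM(g) = count(g) * 1e9 / (library_total * exon_union_length(g)) —
fragments per kilobase of transcript per million mapped fragments, with
gene length taken as the exon-union model length.

Differential expression uses the exact conditional rate-ratio test:
pooling replicate counts per condition, the condition-B count given the
total is Binomial with success probability equal to condition B's share of
the summed library sizes; the two-sided exact binomial p is then
BH-adjusted across genes. A gene is called differential when
|fold change| >= 2 (equivalently log2FC >= 1 in magnitude) and FDR <= 0.05.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .alignments import AlignmentTable
from .annotation import Gene

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SampleCounts:
    counts: pd.Series           # per-gene unique fragment count
    unassigned: int
    total: int                  # mapped fragments (assigned + unassigned)


def count_fragments(table: AlignmentTable, genes: Sequence[Gene],
                    stranded: bool = True) -> SampleCounts:
    """Assign each fragment to the unique gene containing all its blocks.

    A fragment is counted for a gene iff its full footprint (first block
    start to last block end) lies within the gene span on the matching
    strand; fragments contained in no gene, or touching more than one,
    are unassigned.
    """
    gene_ids = [g.id for g in genes]
    counts = pd.Series(0, index=gene_ids, dtype=np.int64)
    n = len(table)
    if n == 0:
        return SampleCounts(counts, 0, 0)
    starts, ends = table.starts, table.ends
    assigned_total = np.zeros(n, dtype=bool)
    for strand in ("+", "-"):
        strand_genes = sorted(
            (g for g in genes if g.strand == strand or not stranded),
            key=lambda g: g.start,
        )
        if not strand_genes:
            continue
        gs = np.array([g.start for g in strand_genes])
        ge = np.array([g.end for g in strand_genes])
        overlap_free = bool(np.all(gs[1:] >= ge[:-1]))
        if not overlap_free:
            raise ValueError("count_fragments requires non-overlapping genes")
        if stranded:
            mask = table.is_reverse == (strand == "-")
        else:
            mask = np.ones(n, dtype=bool) if strand == "+" else np.zeros(n, bool)
        idx = np.searchsorted(gs, starts[mask], side="right") - 1
        ok = idx >= 0
        ok &= ends[mask] <= ge[np.clip(idx, 0, None)]
        sel = np.flatnonzero(mask)
        per_gene = np.bincount(idx[ok], minlength=len(strand_genes))
        for gi, g in enumerate(strand_genes):
            counts[g.id] += int(per_gene[gi])
        assigned_total[sel[ok]] = True
    unassigned = int(n - assigned_total.sum())
    return SampleCounts(counts, unassigned, n)


def gene_lengths(genes: Sequence[Gene]) -> pd.Series:
    return pd.Series({g.id: g.exon_union_length() for g in genes})


def fpkm(sample: SampleCounts, lengths: pd.Series) -> pd.Series:
    """FPKM = count * 1e9 / (library_total * length_bp)."""
    if sample.total == 0:
        raise ValueError("zero mapped fragments: FPKM undefined")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return sample.counts * 1e9 / (sample.total * lengths.reindex(sample.counts.index))


def fpkm_matrix(samples: dict[str, SampleCounts], lengths: pd.Series) -> pd.DataFrame:
    return pd.DataFrame({name: fpkm(sc, lengths) for name, sc in samples.items()})


def correlation_matrix(matrix: pd.DataFrame):
    """Pearson correlation between samples + average-linkage leaf order.

    Returns (samples x samples correlation DataFrame, ordered sample list).
    Zero-variance samples give NaN correlations and are placed last.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need >=2 samples and >=2 genes")
    corr = matrix.corr(method="pearson")  # pairwise; NaN on zero variance
    valid = [c for c in corr.columns if matrix[c].std() > 0]
    order = list(corr.columns)
    if len(valid) >= 2:
        sub = corr.loc[valid, valid]
        dist = squareform(np.clip(1.0 - sub.values, 0.0, None), checks=False)
        leaves = leaves_list(average(dist))
        order = [valid[i] for i in leaves] + [c for c in corr.columns
                                              if c not in valid]
    return corr, order


def _rate_ratio_pvalue(a: int, b: int, na: float, nb: float) -> float:
    """Two-sided exact conditional test of equal rates (library-size offsets)."""
    tot = a + b
    if tot == 0:
        return 1.0
    p_b = nb / (na + nb)
    return float(sps.binomtest(b, tot, p_b, alternative="two-sided").pvalue)


def detect_degs(
    counts: pd.DataFrame,
    condition_of: dict[str, str],
    totals: dict[str, int] | None = None,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
    return_all: bool = False,
) -> pd.DataFrame:
    """Call differential genes between conditions A and B.

    ``counts``: genes x samples integer counts. ``condition_of`` maps sample
    name -> "A"/"B" (needs >=2 replicates each). Fold change is computed on
    library-size-normalised mean counts with an additive pseudocount.
    Returns the table of significant records (direction "up" meaning higher
    in B), or all tested genes when ``return_all``.
    """
    a_cols = [s for s in counts.columns if condition_of[s] == "A"]
    b_cols = [s for s in counts.columns if condition_of[s] == "B"]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >=2 replicates per condition")
    if totals is None:
        totals = {s: int(counts[s].sum()) for s in counts.columns}
    na = float(sum(totals[s] for s in a_cols))
    nb = float(sum(totals[s] for s in b_cols))
    mean_total = np.mean([totals[s] for s in counts.columns])
    norm = counts / pd.Series(totals) * mean_total
    mean_a = norm[a_cols].mean(axis=1)
    mean_b = norm[b_cols].mean(axis=1)

    nonzero = counts.sum(axis=1) > 0
    skipped = int((~nonzero).sum())
    if skipped:
        log.info("detect_degs: skipping %d all-zero genes", skipped)
    sub = counts[nonzero]
    pooled_a = sub[a_cols].sum(axis=1).to_numpy()
    pooled_b = sub[b_cols].sum(axis=1).to_numpy()
    pvals = np.array([
        _rate_ratio_pvalue(int(a), int(b), na, nb)
        for a, b in zip(pooled_a, pooled_b)
    ])
    fdr = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    log2fc = np.log2(
        (mean_b[nonzero] + pseudocount) / (mean_a[nonzero] + pseudocount))
    out = pd.DataFrame({
        "gene_id": sub.index,
        "log2_fold_change": log2fc.to_numpy(),
        "pvalue": pvals,
        "fdr": fdr,
        "direction": np.where(log2fc >= 0, "up", "down"),
    }).set_index("gene_id")
    out["significant"] = (
        (np.abs(out["log2_fold_change"]) >= np.log2(fc_threshold))
        & (out["fdr"] <= fdr_threshold)
    )
    return out if return_all else out[out["significant"]].copy()
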