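"""Binding/splicing integration: feature profiles, targets, motif enrichment.

* Feature distribution — each read or peak is assigned one genomic
  feature class (5'UTR, CDS, 3'UTR, NC-exon, intron, intergenic) by
  majority overlap on its strand; fractions sum to one per sample.
* Target genes — genes carrying >=1 retained (input-subtracted) peak.
* Gene-set overlap — bound genes intersected with genes holding a
  regulated splicing event, for Venn-style reporting.
* K-mer enrichment — motif stand-in: k-mer frequencies in strand-aware
  peak sequences against length-matched background windows resampled
  (seeded) from gene regions outside peaks; enrichment z-score uses the
  background resampling SD.
"""

from __future__ import annotations

import dataclasses
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import FEATURE_CLASSES, FeatureIndex, Gene
from .genome import revcomp
from .peaks import Peak


def feature_distribution(
    items: Iterable[tuple[int, int, str]],
    index: FeatureIndex,
) -> pd.DataFrame:
    """Count and fraction of items per feature class.

    ``items`` yields (start, end, strand) intervals — read footprints or
    peak intervals. Returns a DataFrame indexed by feature class.
    """
    counts = dict.fromkeys(FEATURE_CLASSES, 0)
    total = 0
    for start, end, strand in items:
        cls = index.classify(start, end, strand)
        counts[cls] += 1
        total += 1
    frac = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return pd.DataFrame({
        "count": pd.Series(counts), "fraction": pd.Series(frac)
    }).loc[list(FEATURE_CLASSES)]


def reads_as_items(table) -> Iterable[tuple[int, int, str]]:
    starts, ends = table.starts, table.ends
    rev = table.is_reverse
    for i in range(len(table)):
        yield int(starts[i]), int(ends[i]), "-" if rev[i] else "+"


def target_genes(peaks: Sequence[Peak]) -> set[str]:
    """Genes carrying at least one retained peak."""
    return {p.gene_id for p in peaks}


@dataclasses.dataclass
class GeneSetOverlap:
    bound: set[str]
    rase: set[str]

    @property
    def intersection(self) -> set[str]:
        return self.bound & self.rase

    def summary(self) -> dict[str, int]:
        return {
            "n_bound": len(self.bound),
            "n_rase": len(self.rase),
            "n_overlap": len(self.intersection),
        }


def overlap_with_rase(bound_genes: set[str], rase_genes: set[str]) -> GeneSetOverlap:
    return GeneSetOverlap(set(bound_genes), set(rase_genes))


# ---------------------------------------------------------------------------
# K-mer enrichment


def kmer_frequencies(sequences: Sequence[str], k: int) -> dict[str, float]:
    """Frequency of every observed k-mer over all k-length windows."""
    if any(len(s) < k for s in sequences):
        raise ValueError(f"k={k} exceeds the shortest sequence")
    counts: dict[str, int] = {}
    total = 0
    for s in sequences:
        s = s.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    return {kmer: c / total for kmer, c in counts.items()}


def extract_sequences(genome: str, intervals: Iterable[tuple[int, int, str]],
                      stranded: bool = True) -> list[str]:
    """Genome substrings; minus-strand intervals reverse-complemented."""
    out = []
    for s, e, strand in intervals:
        seq = genome[s:e]
        if stranded and strand == "-":
            seq = revcomp(seq)
        out.append(seq)
    return out


def sample_background_windows(
    genes: Sequence[Gene],
    peaks: Sequence[Peak],
    lengths: Sequence[int],
    rng: np.random.Generator,
) -> list[tuple[int, int, str]]:
    """Length-matched windows inside gene spans, avoiding peak intervals."""
    peak_ivs = [(p.start, p.end) for p in peaks]
    spans = [(g.start, g.end, g.strand) for g in genes]
    weights = np.array([e - s for s, e, _ in spans], dtype=float)
    probs = weights / weights.sum()
    out = []
    for ln in lengths:
        for _ in range(200):  # rejection sampling against peak overlap
            gi = int(rng.choice(len(spans), p=probs))
            gs, ge_, strand = spans[gi]
            if ge_ - gs <= ln:
                continue
            s = int(rng.integers(gs, ge_ - ln + 1))
            e = s + ln
            if not any(s < pe and ps < e for ps, pe in peak_ivs):
                out.append((s, e, strand))
                break
        else:
            raise RuntimeError("could not place a peak-free background window")
    return out


def kmer_enrichment(
    peak_sequences: Sequence[str],
    background_sequences: Sequence[Sequence[str]],
    k: int = 5,
) -> pd.DataFrame:
    """Rank k-mers by z = (f_obs - mean f_bg) / sd(f_bg).

    ``background_sequences`` is a list of resampled background sets; the
    per-set frequencies give the background mean and SD. All 4^k k-mers
    are reported, ranked by descending z (ties by k-mer string).
    """
    if not peak_sequences:
        raise ValueError("no peak sequences")
    if len(background_sequences) < 2:
        raise ValueError("need >=2 background resamples for an SD")
    all_kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    f_obs = kmer_frequencies(peak_sequences, k)
    bg = pd.DataFrame(
        [kmer_frequencies(bs, k) for bs in background_sequences],
        columns=all_kmers,
    ).fillna(0.0)
    mean_bg = bg.mean(axis=0)
    sd_bg = bg.std(axis=0, ddof=1)
    floor = 1.0 / max(sum(len(s) - k + 1 for s in peak_sequences), 1)
    sd = np.maximum(sd_bg, floor * 0.5)
    obs = pd.Series({km: f_obs.get(km, 0.0) for km in all_kmers})
    z = (obs - mean_bg) / sd
    out = pd.DataFrame({
        "kmer": all_kmers,
        "obs_freq": obs.values,
        "bg_freq": mean_bg.values,
        "zscore": z.values,
    })
    out = out.sort_values(["zscore", "kmer"], ascending=[False, True])
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("kmer")


def peak_kmer_enrichment(
    genome: str,
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    k: int = 5,
    seed: int = 0,
    n_resamples: int = 50,
    stranded: bool = True,
    summit_flank: int | None = 75,
) -> pd.DataFrame:
    """End-to-end k-mer enrichment of retained peaks against gene background.

    Sequences come from summit-centred windows (summit +/- ``summit_flank``,
    clipped to the peak interval) rather than whole clusters: binding-site
    sequence sits at the depth maximum, and deep clusters can span
    kilobases, which would dilute any short motif beyond recovery. Pass
    ``summit_flank=None`` to use full peak intervals.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    if summit_flank is None:
        ivs = [(p.start, p.end, p.strand) for p in peaks]
    else:
        ivs = [
            (max(p.start, p.summit - summit_flank),
             min(p.end, p.summit + summit_flank), p.strand)
            for p in peaks
        ]
    peak_seqs = extract_sequences(genome, ivs, stranded=stranded)
    lengths = [e - s for s, e, _ in ivs]
    bgs = []
    for _ in range(n_resamples):
        wins = sample_background_windows(genes, peaks, lengths, rng)
        bgs.append(extract_sequences(genome, wins, stranded=stranded))
    return kmer_enrichment(peak_seqs, bgs, k=k)
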