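"""Simulator contracts: determinism, annotation structure, truth fidelity."""

import hashlib
from pathlib import Path

import numpy as np
import pysam
import pytest
from scipy import stats as sps

from ripsplice import (
    ConfigError,
    SimulationConfig,
    SizingError,
    generate_genome,
    parse_gtf,
    simulate_dataset,
)
from ripsplice.genome import revcomp
from ripsplice.reads import simulate_rnaseq


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


SMALL = dict(n_genes=8, genome_length=100_000, rnaseq_depth=5_000,
             rip_depth=3_000)


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ConfigError):
            SimulationConfig(planted_as_fraction=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(ratio_shift=1.2)
        with pytest.raises(ConfigError):
            SimulationConfig(motif="GCN7")

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=3, **SMALL)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestGenomeGeneration:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=1, **SMALL)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg, a)
        simulate_dataset(SimulationConfig(seed=1, **SMALL), b)
        for name in sorted(p.name for p in a.iterdir()):
            assert _hash(a / name) == _hash(b / name), name

    def test_genes_disjoint_by_interval_scan(self):
        design = generate_genome(SimulationConfig(seed=2, n_genes=50,
                                                  genome_length=600_000))
        spans = sorted((g.start, g.end) for g in design.genes)
        assert len(spans) == 50
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_sizing_error_when_genome_too_small(self):
        with pytest.raises(SizingError):
            generate_genome(SimulationConfig(n_genes=100, genome_length=100_000))

    def test_cassette_gene_has_two_transcripts_differing_by_one_exon(self,
                                                                     tiny_dataset,
                                                                     tiny_result):
        truth = tiny_result.truth
        genes = {g.id: g for g in parse_gtf(tiny_dataset / "annotation.gtf")}
        ce = truth.events[truth.events["event_type"] == "CE"]
        es = truth.events[truth.events["event_type"] == "ES"]
        for gid in ce["gene_id"]:
            txs = genes[gid].transcripts
            assert len(txs) == 2
            e1, e2 = set(txs[0].exons), set(txs[1].exons)
            assert len(e1 ^ e2) == 1          # exactly one internal exon apart
        for gid in es["gene_id"]:
            assert len(genes[gid].transcripts) == 1   # the skip form is novel

    def test_gtf_is_valid_and_roundtrips(self, tiny_dataset):
        genes = parse_gtf(tiny_dataset / "annotation.gtf")
        assert len(genes) == 20
        for g in genes:
            for t in g.transcripts:
                assert t.exons == sorted(t.exons)


class TestRNASeq:
    def test_zero_depth_gives_header_only_sam(self, tmp_path):
        cfg = SimulationConfig(seed=1, rnaseq_depth=0, **{
            k: v for k, v in SMALL.items() if k != "rnaseq_depth"})
        design = generate_genome(cfg)
        man = simulate_rnaseq(design, tmp_path)
        sam = man.rnaseq["A"][0]
        lines = sam.read_text().splitlines()
        assert lines and all(l.startswith("@") for l in lines)
        with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
            assert sum(1 for _ in fh) == 0

    def test_sam_parses_and_cigar_reconstructs_footprint(self, tiny_dataset,
                                                         tiny_config):
        """Standard-compliant reader accepts the SAM; block arithmetic is exact."""
        n = 0
        with pysam.AlignmentFile(
                str(tiny_dataset / "rnaseq_A_rep1.sam")) as fh:
            for rec in fh:
                blocks = rec.get_blocks()
                assert sum(e - s for s, e in blocks) == tiny_config.read_length
                assert blocks[0][0] == rec.reference_start
                assert blocks[-1][1] == rec.reference_end
                assert rec.mapping_quality == 50 and rec.get_tag("NH") == 1
                n += 1
        assert n > 5000

    def test_planted_fold_change_recovered_by_independent_recount(
            self, tiny_dataset, tiny_result):
        """Mean count ratio B/A of a 4x gene is ~4 (independent pysam recount)."""
        truth = tiny_result.truth.genes
        spans = {r.gene_id: (r.strand, r.start, r.end)
                 for r in truth.itertuples()}

        def recount(path):
            counts = dict.fromkeys(spans, 0)
            with pysam.AlignmentFile(str(path)) as fh:
                for rec in fh:
                    strand = "-" if rec.is_reverse else "+"
                    for gid, (gs, s, e) in spans.items():
                        if (strand == gs and rec.reference_start >= s
                                and rec.reference_end <= e):
                            counts[gid] += 1
                            break
            return counts

        a = [recount(tiny_dataset / f"rnaseq_A_rep{i}.sam") for i in (1, 2, 3)]
        b = [recount(tiny_dataset / f"rnaseq_B_rep{i}.sam") for i in (1, 2, 3)]
        for r in truth.itertuples():
            if not r.is_deg:
                continue
            ma = np.mean([c[r.gene_id] for c in a])
            mb = np.mean([c[r.gene_id] for c in b])
            ratio = mb / ma
            # 3 relative-SE bounds from Poisson counting noise
            rel_se = np.sqrt(1 / (3 * ma) + 1 / (3 * mb))
            assert abs(np.log(ratio) - np.log(r.true_fold_change)) \
                <= 3 * rel_se + 0.05, (r.gene_id, ratio, r.true_fold_change)

    def test_balanced_ratio_converges_to_half(self, tmp_path):
        """ratio_shift=0: empirical junction inclusion ratio -> 0.5."""
        cfg = SimulationConfig(seed=5, ratio_shift=0.0, planted_as_fraction=1.0,
                               planted_deg_fraction=0.0, **SMALL)
        design = generate_genome(cfg)
        simulate_rnaseq(design, tmp_path)
        from ripsplice.alignments import AlignmentTable, extract_junctions
        from ripsplice.annotation import SpliceJunction
        juncs = extract_junctions(
            AlignmentTable.from_sam(tmp_path / "rnaseq_A_rep1.sam"))
        for g in design.genes:
            ev = g.event
            if ev is None or ev.event_type == "IR" or not ev.alt_junctions:
                continue
            m = np.mean([juncs[SpliceJunction(g.chrom, g.strand, d, a)]
                         for d, a in ev.model_junctions])
            al = np.mean([juncs[SpliceJunction(g.chrom, g.strand, d, a)]
                          for d, a in ev.alt_junctions])
            n = m + al
            if n < 30:
                continue
            assert abs(al / n - 0.5) <= 3 * np.sqrt(0.25 / n) + 0.03


class TestRIP:
    def test_motif_embedded_at_peak_centres(self, tiny_dataset, tiny_result,
                                            tiny_config):
        from pyfaidx import Fasta
        genome = str(Fasta(str(tiny_dataset / "genome.fa"))[tiny_config.chrom][:])
        motif = tiny_config.motif
        for r in tiny_result.truth.peaks.itertuples():
            if not r.has_motif:
                continue
            expected = motif if r.strand == "+" else revcomp(motif)
            mid = (r.start + r.end - len(motif)) // 2
            assert genome[mid:mid + len(motif)] == expected

    def test_peak_enrichment_by_independent_windowing(self, tiny_dataset,
                                                      tiny_result, tiny_config):
        """Planted-peak read counts ~ enrichment-fold matched control windows."""
        peaks = tiny_result.truth.peaks
        ip = tiny_dataset / "rip_ip_rep1.sam"
        starts = []
        with pysam.AlignmentFile(str(ip)) as fh:
            starts = np.array([rec.reference_start for rec in fh])
        genes = {r.gene_id: (r.start, r.end)
                 for r in tiny_result.truth.genes.itertuples()}
        in_peak, in_ctrl = 0, 0
        w = tiny_config.peak_width - tiny_config.rip_read_length
        for r in peaks.itertuples():
            if r.shared_with_input:
                continue
            in_peak += int(((starts >= r.start) & (starts <= r.start + w)).sum())
            gs, ge = genes[r.gene_id]
            cs = gs + 10 if r.start - gs > ge - r.end else ge - 10 - \
                tiny_config.peak_width
            in_ctrl += int(((starts >= cs) & (starts <= cs + w)).sum())
        ratio = in_peak / max(in_ctrl, 1)
        enr = tiny_config.enrichment
        rel_se = np.sqrt(1 / in_peak + 1 / max(in_ctrl, 1))
        assert abs(np.log(ratio) - np.log(enr)) <= 3 * rel_se + 0.15, \
            (in_peak, in_ctrl, ratio)

    def test_unit_enrichment_matches_input_law(self, tmp_path):
        """enrichment=1: IP and input per-window counts are indistinguishable."""
        cfg = SimulationConfig(seed=9, enrichment=1.0, planted_peak_fraction=0.5,
                               **SMALL)
        design = generate_genome(cfg)
        from ripsplice.reads import simulate_rip
        simulate_rip(design, tmp_path)

        def window_counts(path):
            with pysam.AlignmentFile(str(path)) as fh:
                s = np.array([r.reference_start for r in fh])
            return np.histogram(s, bins=np.arange(0, cfg.genome_length, 500))[0]

        ip = window_counts(tmp_path / "rip_ip_rep1.sam")
        inp = window_counts(tmp_path / "rip_input_rep1.sam")
        keep = (ip + inp) > 0
        p = sps.mannwhitneyu(ip[keep], inp[keep]).pvalue
        assert p > 0.01

    def test_truth_tables_roundtrip(self, tiny_dataset, tiny_result):
        from ripsplice.truth import TruthTable
        t2 = TruthTable.read(tiny_dataset)
        for name in ("genes", "events", "peaks"):
            a = getattr(tiny_result.truth, name)
            b = getattr(t2, name)
            assert a.astype(str).equals(b.astype(str)), name
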