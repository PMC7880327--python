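"""Shared fixtures: a small simulated dataset and hand-built event models."""

from __future__ import annotations

from pathlib import Path

import pytest

from ripsplice import SimulationConfig, simulate_dataset
from ripsplice.alignments import JunctionCounts
from ripsplice.annotation import Gene, SpliceJunction, Transcript
from ripsplice.pipeline import run_pipeline


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7, n_genes=20, genome_length=250_000,
        rnaseq_depth=20_000, rip_depth=10_000,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_config) -> Path:
    out = tmp_path_factory.mktemp("tiny_dataset")
    simulate_dataset(tiny_config, out)
    return out


@pytest.fixture(scope="session")
def tiny_result(tiny_dataset):
    return run_pipeline(tiny_dataset, n_sim=500, seed=7)


def _gene(chrom: str, strand: str, tx_exons: list[list[tuple[int, int]]],
          span=(0, 2000)) -> Gene:
    txs = [Transcript(f"{chrom}_t{i+1}", exs) for i, exs in enumerate(tx_exons)]
    return Gene(chrom, chrom, strand, span[0], span[1], txs)


def _counts(gene: Gene, obs: dict[tuple[int, int], int]) -> JunctionCounts:
    return JunctionCounts({
        SpliceJunction(gene.chrom, gene.strand, d, a): c
        for (d, a), c in obs.items()
    })


def build_grammar_fixtures() -> list[tuple[str, Gene, JunctionCounts]]:
    """Ten hand-built gene models, one per event type.

    Coordinates were enumerated by hand; each model plus its junction
    table realises exactly one event of the intended type.
    """
    out = []

    # ES: skip junction is novel (only the inclusion isoform is annotated)
    g = _gene("fx_es", "+", [[(100, 200), (400, 500), (800, 900)]])
    out.append(("ES", g, _counts(g, {(200, 400): 12, (500, 800): 11,
                                     (200, 800): 7})))

    # CE: cassette exon, the skip isoform is annotated too
    g = _gene("fx_ce", "+", [[(100, 200), (400, 500), (800, 900)],
                             [(100, 200), (800, 900)]])
    out.append(("CE", g, _counts(g, {(200, 400): 12, (500, 800): 11,
                                     (200, 800): 7})))

    # A5SS: two donors (exon-end variants) share one acceptor, plus strand
    g = _gene("fx_a5ss", "+", [[(100, 200), (500, 600)],
                               [(100, 170), (500, 600)]])
    out.append(("A5SS", g, _counts(g, {(200, 500): 10, (170, 500): 5})))

    # A3SS: two acceptors (exon-start variants) share one donor, plus strand
    g = _gene("fx_a3ss", "+", [[(100, 200), (500, 600)],
                               [(100, 200), (560, 600)]])
    out.append(("A3SS", g, _counts(g, {(200, 500): 10, (200, 560): 5})))

    # IR: second isoform's exon spans the intron
    g = _gene("fx_ir", "+", [[(100, 200), (500, 600)], [(100, 600)]])
    out.append(("IR", g, _counts(g, {(200, 500): 15})))

    # MXE: internal exons (400,500) and (600,700) never joined to each other
    g = _gene("fx_mxe", "+", [[(100, 200), (400, 500), (900, 1000)],
                              [(100, 200), (600, 700), (900, 1000)]])
    out.append(("MXE", g, _counts(g, {(200, 400): 9, (500, 900): 8,
                                      (200, 600): 7, (700, 900): 6})))

    # 5pMXE: mutually exclusive first exons, common downstream acceptor
    g = _gene("fx_5pmxe", "+", [[(100, 200), (600, 700), (1000, 1100)],
                                [(300, 400), (600, 700), (1000, 1100)]])
    out.append(("5pMXE", g, _counts(g, {(200, 600): 9, (400, 600): 8,
                                        (700, 1000): 20})))

    # 3pMXE: mutually exclusive last exons, common upstream donor
    g = _gene("fx_3pmxe", "+", [[(100, 200), (500, 600), (900, 1000)],
                                [(100, 200), (500, 600), (1200, 1300)]])
    out.append(("3pMXE", g, _counts(g, {(200, 500): 20, (600, 900): 9,
                                        (600, 1200): 8})))

    # A3SS&ES: skip of (400,500) combined with an alternative acceptor
    g = _gene("fx_a3es", "+", [[(100, 200), (400, 500), (800, 900)],
                               [(100, 200), (860, 900)]])
    out.append(("A3SS&ES", g, _counts(g, {(200, 400): 10, (500, 800): 9,
                                          (200, 860): 6})))

    # A5SS&ES: same genomic pattern on the minus strand (5'/3' names flip)
    g = _gene("fx_a5es", "-", [[(100, 200), (400, 500), (800, 900)],
                               [(100, 200), (860, 900)]])
    out.append(("A5SS&ES", g, _counts(g, {(200, 400): 10, (500, 800): 9,
                                          (200, 860): 6})))
    return out


@pytest.fixture(scope="session")
def grammar_fixtures():
    return build_grammar_fixtures()
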