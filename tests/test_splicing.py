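"""Event grammar, inclusion-ratio arithmetic, and RASE statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ripsplice.alignments import JunctionCounts
from ripsplice.annotation import Gene, SpliceJunction, Transcript
from ripsplice.splicing import (
    ASEvent,
    detect_events,
    detect_rases,
    quantify_events,
)
from ripsplice.truth import parse_junctions

from conftest import _counts, _gene


class TestEventGrammar:
    def test_each_fixture_yields_exactly_its_type(self, grammar_fixtures):
        """Grammar exactness: one event, correct label, per hand-built model."""
        for etype, gene, juncs in grammar_fixtures:
            events = detect_events(juncs, [gene])
            assert [e.etype for e in events] == [etype], (
                f"{gene.id}: expected one {etype}, got "
                f"{[(e.etype, e.model_junctions, e.alt_junctions) for e in events]}"
            )

    def test_three_exon_skip_definition_case(self):
        """Junctions E1-E2, E2-E3 and E1-E3 on a 3-exon gene: one exon skip."""
        g = _gene("sk", "+", [[(10, 20), (40, 50), (70, 80)]], span=(0, 100))
        juncs = _counts(g, {(20, 40): 5, (50, 70): 5, (20, 70): 3})
        events = detect_events(juncs, [g])
        assert len(events) == 1
        ev = events[0]
        assert ev.etype == "ES"          # the skip junction is unannotated
        assert set(ev.model_junctions) == {(20, 40), (50, 70)}
        assert ev.alt_junctions == ((20, 70),)
        assert not ev.known

    def test_two_donors_one_acceptor_is_a5ss(self):
        g = _gene("a5", "+", [[(100, 200), (500, 600)],
                              [(100, 230), (500, 600)]], span=(0, 1000))
        juncs = _counts(g, {(200, 500): 6, (230, 500): 6})
        events = detect_events(juncs, [g])
        assert [e.etype for e in events] == ["A5SS"]
        assert events[0].model_junctions == ((230, 500),)  # shorter intron
        assert events[0].known

    def test_known_flag_requires_all_junctions_annotated(self, grammar_fixtures):
        for etype, gene, juncs in grammar_fixtures:
            ev = detect_events(juncs, [gene])[0]
            assert ev.known == (etype != "ES")

    def test_unsupported_events_not_reported(self):
        """Annotated structure without observed junction reads stays silent."""
        g = _gene("ce0", "+", [[(100, 200), (400, 500), (800, 900)],
                               [(100, 200), (800, 900)]])
        assert detect_events(JunctionCounts(), [g]) == []

    def test_intergenic_junctions_excluded(self):
        g = _gene("ig", "+", [[(100, 200), (400, 500)]], span=(50, 600))
        juncs = JunctionCounts({
            SpliceJunction("ig", "+", 200, 400): 5,
            SpliceJunction("ig", "+", 5000, 6000): 9,   # outside any gene
            SpliceJunction("other", "+", 200, 400): 9,  # unknown chromosome
        })
        events = detect_events(juncs, [g])
        assert events == []  # a lone annotated junction is not an event


class TestQuantification:
    @staticmethod
    def _simple_event(model=((20, 40), (50, 70)), alt=((20, 70),)):
        return ASEvent("g", "c", "+", "CE", tuple(model), tuple(alt), None, True)

    @staticmethod
    def _sample(name, model_counts, alt_count,
                model=((20, 40), (50, 70)), alt=(20, 70)):
        counts = {SpliceJunction("c", "+", d, a): c
                  for (d, a), c in zip(model, model_counts)}
        counts[SpliceJunction("c", "+", *alt)] = alt_count
        return (name, JunctionCounts(counts), None)

    def test_ratio_arithmetic(self):
        ev = self._simple_event()
        q = quantify_events([ev], [self._sample("s1", (8, 8), 2)], min_support=5)
        assert q.loc[0, "ratio"] == pytest.approx(0.2)
        q = quantify_events([ev], [self._sample("s2", (10, 10), 0)], min_support=5)
        assert q.loc[0, "ratio"] == 0.0

    def test_low_support_gives_na(self):
        ev = self._simple_event()
        q = quantify_events([ev], [self._sample("s", (3, 3), 1)], min_support=10)
        assert np.isnan(q.loc[0, "ratio"])

    def test_model_count_is_mean_over_model_junctions(self):
        ev = self._simple_event()
        q = quantify_events([ev], [self._sample("s", (6, 10), 8)], min_support=1)
        assert q.loc[0, "model_count"] == pytest.approx(8.0)
        assert q.loc[0, "ratio"] == pytest.approx(0.5)

    def test_label_swap_symmetry(self):
        """Swapping model/alt maps ratio r to 1-r and preserves |delta| and p."""
        fwd = self._simple_event()
        swp = ASEvent("g", "c", "+", "CE", ((20, 70),),
                      ((20, 40), (50, 70)), None, True)
        rng = np.random.default_rng(0)
        samples = []
        cond = {}
        for i, c in enumerate(["A"] * 3 + ["B"] * 3):
            name = f"{c}{i}"
            cond[name] = c
            m = rng.integers(20, 40, 2)
            a = rng.integers(25 if c == "B" else 5, 45 if c == "B" else 15)
            samples.append(self._sample(name, tuple(m), int(a)))
        qf = quantify_events([fwd], samples, min_support=1)
        qs = quantify_events([swp], samples, min_support=1)
        assert np.allclose(qf["ratio"], 1.0 - qs["ratio"])
        rf = detect_rases(qf, cond)
        rs = detect_rases(qs, cond)
        assert rf["delta_ratio"].iloc[0] == pytest.approx(rs["delta_ratio"].iloc[0])
        assert rf["pvalue"].iloc[0] == pytest.approx(rs["pvalue"].iloc[0])

    def test_planted_ratio_recovered_within_binomial_error(self, tiny_result):
        """Estimated per-sample ratios sit within 3 binomial SEs of truth."""
        truth = tiny_result.truth.events
        q = tiny_result.quantifications
        checked = 0
        for _, row in truth.iterrows():
            sub = q[(q["gene_id"] == row["gene_id"])
                    & (q["event_type"] == row["event_type"])]
            for _, s in sub.iterrows():
                r_true = row["ratio_b"] if s["sample"].startswith("B") \
                    else row["ratio_a"]
                n = s["model_count"] + s["alt_count"]
                if np.isnan(s["ratio"]) or n < 20:
                    continue
                se = np.sqrt(r_true * (1 - r_true) / n)
                assert abs(s["ratio"] - r_true) <= max(3 * se, 0.12), (
                    row["gene_id"], s["sample"], s["ratio"], r_true, n)
                checked += 1
        assert checked >= 20


class TestRASE:
    @staticmethod
    def _quants(ra, rb):
        rows = []
        for i, r in enumerate(ra):
            rows.append({"event_id": "e", "gene_id": "g", "event_type": "CE",
                         "sample": f"A{i}", "model_count": 50.0,
                         "alt_count": 50.0, "ratio": r})
        for i, r in enumerate(rb):
            rows.append({"event_id": "e", "gene_id": "g", "event_type": "CE",
                         "sample": f"B{i}", "model_count": 50.0,
                         "alt_count": 50.0, "ratio": r})
        cond = {f"A{i}": "A" for i in range(len(ra))}
        cond.update({f"B{i}": "B" for i in range(len(rb))})
        return pd.DataFrame(rows), cond

    def test_hand_computed_t_statistic(self):
        """Pooled-variance t on (0.2,0.25,0.3) vs (0.6,0.65,0.7), df=4."""
        q, cond = self._quants([0.2, 0.25, 0.3], [0.6, 0.65, 0.7])
        out = detect_rases(q, cond)
        row = out.iloc[0]
        assert row["delta_ratio"] == pytest.approx(0.40)
        assert row["t_stat"] == pytest.approx(9.798, abs=0.005)
        # against the closed-form survival function at df=4
        assert row["pvalue"] == pytest.approx(2 * sps.t.sf(9.79796, df=4),
                                              rel=1e-6)
        assert row["pvalue"] < 0.001
        assert bool(row["significant"])

    def test_identical_ratios_not_significant(self):
        q, cond = self._quants([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        out = detect_rases(q, cond)
        assert out["delta_ratio"].iloc[0] == 0.0
        assert not out["significant"].iloc[0]

    def test_delta_gate_blocks_small_shifts(self):
        q, cond = self._quants([0.4, 0.5, 0.6], [0.45, 0.55, 0.65])
        out = detect_rases(q, cond)
        assert out["delta_ratio"].iloc[0] == pytest.approx(0.05)
        assert not out["significant"].iloc[0]

    def test_untestable_events_dropped(self):
        q, cond = self._quants([0.4, np.nan, np.nan], [0.5, 0.6, 0.7])
        out = detect_rases(q, cond)
        assert len(out) == 0

    def test_fdr_column_present_and_bh_monotone(self, tiny_result):
        r = tiny_result.rases
        assert {"fdr", "pvalue"} <= set(r.columns)
        ok = r["pvalue"].notna()
        assert (r.loc[ok, "fdr"] >= r.loc[ok, "pvalue"] - 1e-12).all()


def test_detected_events_match_truth_junctions(tiny_result):
    """Every planted event is found with its exact junction coordinates."""
    by_key = {}
    for ev in tiny_result.events:
        by_key.setdefault((ev.gene_id, ev.etype), []).append(ev)
    for _, row in tiny_result.truth.events.iterrows():
        key = (row["gene_id"], row["event_type"])
        assert key in by_key, key
        mj = set(parse_junctions(row["model_junctions"]))
        assert any(set(e.model_junctions) == mj for e in by_key[key])
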