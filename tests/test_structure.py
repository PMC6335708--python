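"""AS-mode classification, status overlap and novelty classification."""

import numpy as np
import pytest

from lncnet.exceptions import StructureError
from lncnet.records import HomologyHit, TranscriptModel
from lncnet.structure import (
    StatusSet,
    classify_all,
    classify_events,
    classify_novelty,
    event_mode_distribution,
    group_loci,
    specific_counts,
    status_overlap,
    transcript_key,
)
from lncnet.synthetic import SyntheticConfig, generate_sequences

from .oracles import brute_overlap_cells


def mk(tid, exons_1based, strand="+", chrom="chr1", offset=0):
    """Build a model from 1-based inclusive exon pairs (no sequence)."""
    exons = tuple((s - 1 + offset, e + offset) for s, e in exons_1based)
    return TranscriptModel(tid, f"g_{tid}", chrom, strand, exons)


FIXTURES = {
    "intron_retention": (
        [(1, 100), (201, 300)],
        [(1, 300)],
    ),
    "exon_skipping": (
        [(1, 100), (201, 300), (401, 500)],
        [(1, 100), (401, 500)],
    ),
    "alt_5_donor": (
        [(1, 100), (201, 300)],
        [(1, 130), (201, 300)],
    ),
    "alt_3_acceptor": (
        [(1, 100), (201, 300)],
        [(1, 100), (171, 300)],
    ),
    "mutually_exclusive_exon": (
        [(1, 100), (201, 250), (401, 500)],
        [(1, 100), (301, 350), (401, 500)],
    ),
}


class TestClassifyEvents:
    @pytest.mark.parametrize("mode", sorted(FIXTURES))
    def test_definition_forced_fixtures(self, mode):
        a, b = FIXTURES[mode]
        events = classify_events([mk("A", a), mk("B", b)])
        assert [e.mode for e in events] == [mode]

    @pytest.mark.parametrize("mode", sorted(FIXTURES))
    def test_invariant_under_translation_and_pair_order(self, mode):
        a, b = FIXTURES[mode]
        base = classify_events([mk("A", a), mk("B", b)])
        shifted = classify_events([mk("A", a, offset=5000), mk("B", b, offset=5000)])
        swapped = classify_events([mk("B", b), mk("A", a)])
        assert [e.mode for e in shifted] == [e.mode for e in base]
        assert {(e.transcript_a, e.transcript_b, e.mode) for e in swapped} == {
            (e.transcript_a, e.transcript_b, e.mode) for e in base
        }

    def test_intron_retention_direction_is_recorded(self):
        a, b = FIXTURES["intron_retention"]
        (event,) = classify_events([mk("A", a), mk("B", b)])
        # B's single exon spans A's intron, so B is the retaining isoform
        assert event.transcript_a == "B" and event.transcript_b == "A"

    def test_strand_law_swaps_donor_and_acceptor(self):
        a, b = FIXTURES["alt_5_donor"]
        plus = classify_events([mk("A", a, "+"), mk("B", b, "+")])
        minus = classify_events([mk("A", a, "-"), mk("B", b, "-")])
        assert [e.mode for e in plus] == ["alt_5_donor"]
        assert [e.mode for e in minus] == ["alt_3_acceptor"]
        a, b = FIXTURES["alt_3_acceptor"]
        minus = classify_events([mk("A", a, "-"), mk("B", b, "-")])
        assert [e.mode for e in minus] == ["alt_5_donor"]

    def test_mixed_strands_rejected(self):
        with pytest.raises(StructureError, match="strand"):
            classify_events([mk("A", [(1, 100)], "+"), mk("B", [(50, 150)], "-")])

    def test_identical_chains_yield_no_event(self):
        a = [(1, 100), (201, 300)]
        assert classify_events([mk("A", a), mk("B", a)]) == []


class TestDistribution:
    def test_single_event_proportion_one(self):
        a, b = FIXTURES["intron_retention"]
        events = classify_events([mk("A", a), mk("B", b)])
        dist = event_mode_distribution(events)
        assert dist.loc[0, "intron_retention"] == 1.0

    def test_injected_counts_give_exact_proportions(self):
        cfg = SyntheticConfig(
            n_coding=40, n_noncoding=0,
            as_pairs_per_mode={
                "intron_retention": 10, "exon_skipping": 5,
                "alt_3_acceptor": 5, "alt_5_donor": 5,
                "mutually_exclusive_exon": 0,
            },
            seed=0,
        )
        bundle = generate_sequences(cfg)
        events = classify_all(bundle.transcripts)
        dist = event_mode_distribution(events).iloc[0]
        assert dist["n_events"] == 25
        assert dist["intron_retention"] == pytest.approx(0.4)
        assert dist["exon_skipping"] == pytest.approx(0.2)
        assert dist["alt_3_acceptor"] == pytest.approx(0.2)
        assert dist["alt_5_donor"] == pytest.approx(0.2)
        assert dist["mutually_exclusive_exon"] == 0.0

    def test_zero_events_give_empty_table(self):
        dist = event_mode_distribution([])
        assert dist.empty
        assert not dist.isna().any().any()

    def test_proportions_sum_to_one_per_status(self):
        a, b = FIXTURES["exon_skipping"]
        ir_a, ir_b = FIXTURES["intron_retention"]
        groups = {
            "control_4h": classify_events([mk("A", a), mk("B", b)]),
            "infected_4h": classify_events([mk("A", ir_a), mk("B", ir_b)]),
        }
        dist = event_mode_distribution(groups)
        from lncnet.structure import AS_MODES

        assert np.allclose(dist[list(AS_MODES)].sum(axis=1), 1.0)


class TestLoci:
    def test_group_loci_by_exonic_overlap(self):
        t1 = mk("t1", [(1, 100)])
        t2 = mk("t2", [(50, 150)])
        t3 = mk("t3", [(500, 600)])
        t4 = mk("t4", [(50, 150)], strand="-")
        loci = group_loci([t1, t2, t3, t4])
        groups = sorted(sorted(t.transcript_id for t in locus) for locus in loci)
        assert groups == [["t1", "t2"], ["t3"], ["t4"]]

    def test_span_overlap_without_exon_overlap_is_not_a_locus(self):
        # t2 sits entirely inside t1's intron
        t1 = mk("t1", [(1, 100), (901, 1000)])
        t2 = mk("t2", [(300, 400)])
        assert len(group_loci([t1, t2])) == 2


class TestStatusOverlap:
    def _sets(self, mapping):
        out = []
        for (cond, time_h), keys in mapping.items():
            out.append(StatusSet((cond, time_h), frozenset(keys)))
        return out

    def test_two_set_example(self):
        cells = status_overlap(
            self._sets({("control", 4): {"a", "b"}, ("infected", 4): {"b", "c"}})
        )
        spec = specific_counts(cells)
        assert spec == {"control_4h": 1, "infected_4h": 1}
        shared = cells[(cells["control_4h"]) & (cells["infected_4h"])]["count"].sum()
        assert shared == 1

    def test_disjoint_sets_all_specific(self):
        mapping = {("control", t): {f"k{t}{i}" for i in range(3)} for t in (4, 12, 48)}
        mapping.update(
            {("infected", t): {f"j{t}{i}" for i in range(2)} for t in (4, 12, 48)}
        )
        cells = status_overlap(self._sets(mapping))
        assert sum(specific_counts(cells).values()) == cells["count"].sum() == 15

    def test_cells_match_brute_force_and_sum_to_union(self):
        rng = np.random.default_rng(3)
        universe = [f"k{i}" for i in range(200)]
        mapping = {
            ("control", 4): set(rng.choice(universe, 80, replace=False)),
            ("infected", 4): set(rng.choice(universe, 90, replace=False)),
            ("control", 12): set(rng.choice(universe, 50, replace=False)),
        }
        sets = self._sets(mapping)
        cells = status_overlap(sets)
        labels = [f"{c}_{t}h" for c, t in mapping]
        brute = brute_overlap_cells({lab: mapping[k] for lab, k in zip(labels, mapping)})
        for pattern, count in brute.items():
            row = cells
            for lab, flag in zip(labels, pattern):
                row = row[row[lab] == flag]
            assert row["count"].sum() == count
        union = set().union(*mapping.values())
        assert cells["count"].sum() == len(union)

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            status_overlap(self._sets({("control", 4): {"a"}}))


class TestTranscriptKey:
    def test_multi_exon_keyed_by_intron_chain(self):
        t1 = mk("x", [(1, 100), (201, 300)])
        t2 = mk("y", [(11, 100), (201, 290)])  # same introns, ragged ends
        assert transcript_key(t1) == transcript_key(t2)

    def test_mono_exon_keyed_by_coordinates(self):
        assert transcript_key(mk("x", [(1, 100)])) != transcript_key(mk("y", [(2, 100)]))


class TestNovelty:
    def _hit(self, q, e):
        return HomologyHit(q, "ref1", 95.0, 100, e, 300.0)

    def test_cutoff_semantics(self):
        labels = classify_novelty(
            ["a", "b", "c"], [self._hit("a", 1e-6), self._hit("b", 1e-4)]
        )
        assert labels == {"a": "known", "b": "novel", "c": "novel"}

    def test_random_queries_match_oracle_scan(self):
        rng = np.random.default_rng(9)
        queries = [f"q{i}" for i in range(100)]
        hits = [
            self._hit(f"q{int(rng.integers(0, 100))}", float(10.0 ** -rng.uniform(0, 12)))
            for _ in range(300)
        ]
        labels = classify_novelty(queries, hits, evalue_max=1e-5)
        for q in queries:
            best = min((h.evalue for h in hits if h.query_id == q), default=np.inf)
            assert labels[q] == ("known" if best <= 1e-5 else "novel")
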