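"""Determinism and truth-consistency of the synthetic study generator."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from lncnet.coexpression import log_expression, normalize_counts, pearson
from lncnet.exceptions import ConfigError
from lncnet.synthetic import (
    SyntheticConfig,
    generate_counts,
    generate_sequences,
    simulate_study,
    write_study,
)

from .oracles import brute_longest_orf


def _cfg(**overrides):
    base = dict(n_coding=60, n_noncoding=50, n_planted_pairs=10, n_planted_de=8,
                n_planted_de_pairs=2, seed=0)
    base.update(overrides)
    return SyntheticConfig(**base)


class TestDeterminism:
    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        cfg = _cfg(n_coding=30, n_noncoding=30, n_planted_pairs=5, n_planted_de=4,
                   n_planted_de_pairs=1)
        a = write_study(cfg, tmp_path / "a")
        b = write_study(cfg, tmp_path / "b")
        assert set(a) == set(b)
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key

    def test_different_seed_differs(self, tmp_path):
        a = write_study(_cfg(n_coding=20, n_noncoding=20, n_planted_pairs=3,
                             n_planted_de=2, n_planted_de_pairs=1,
                             as_pairs_per_mode={}, seed=1),
                        tmp_path / "a")
        b = write_study(_cfg(n_coding=20, n_noncoding=20, n_planted_pairs=3,
                             n_planted_de=2, n_planted_de_pairs=1,
                             as_pairs_per_mode={}, seed=2),
                        tmp_path / "b")
        assert Path(a["counts"]).read_bytes() != Path(b["counts"]).read_bytes()


class TestSequences:
    def test_no_noncoding_means_no_lncrna_truth(self):
        bundle = generate_sequences(_cfg(n_noncoding=0, as_pairs_per_mode={}))
        assert bundle.truth.true_lncrna_ids == set()

    def test_noncoding_orfs_below_100_by_oracle(self, small_study):
        lnc = sorted(small_study.truth.true_lncrna_ids)[:40]
        by_id = {t.transcript_id: t for t in small_study.transcripts}
        for tid in lnc:
            assert brute_longest_orf(by_id[tid].sequence) < 100
            assert by_id[tid].length >= 200

    def test_coding_design_is_separable(self, small_study):
        by_id = {t.transcript_id: t for t in small_study.transcripts}
        hit_ids = {h.query_id for h in small_study.sequences.homology_hits
                   if h.evalue <= 1e-6}
        for tid in sorted(small_study.truth.true_coding_ids)[:30]:
            assert brute_longest_orf(by_id[tid].sequence) >= 100
            assert tid in hit_ids
        for tid in sorted(small_study.truth.true_lncrna_ids):
            assert tid not in hit_ids

    def test_sequence_length_matches_exon_chain(self, small_study):
        for t in small_study.transcripts:
            assert len(t.sequence) == t.length

    def test_status_membership_covers_every_transcript(self, small_study):
        members = set(small_study.sequences.status_membership["transcript_id"])
        assert members == {t.transcript_id for t in small_study.transcripts}

    def test_truth_sets_consistent(self, small_study):
        truth = small_study.truth
        assert not truth.true_lncrna_ids & truth.true_coding_ids
        ids = set(truth.all_ids)
        for l, m in truth.planted_pairs:
            assert l in truth.true_lncrna_ids and m in truth.true_coding_ids
        assert set(truth.planted_de) <= ids

    def test_infeasible_noncoding_length_rejected(self):
        with pytest.raises(ConfigError, match="200"):
            SyntheticConfig(noncoding_length_range=(120, 400))

    def test_too_many_pairs_rejected(self):
        cfg = _cfg(n_planted_pairs=55)  # > n_noncoding
        bundle = generate_sequences(cfg)
        with pytest.raises(ConfigError, match="n_planted_pairs"):
            generate_counts(cfg, bundle.truth)


class TestCounts:
    def test_degenerate_limit_correlation_near_one(self):
        cfg = _cfg(planted_latent_correlation=1.0, nb_dispersion=1e-4,
                   n_planted_de=0, n_planted_de_pairs=0, as_pairs_per_mode={})
        study = simulate_study(cfg)
        _, norm = normalize_counts(study.counts)
        expr = log_expression(norm)
        for l, m in sorted(study.truth.planted_pairs):
            assert pearson(expr.loc[l], expr.loc[m]) >= 1.0 - 0.02

    def test_null_pair_tail_matches_t_distribution(self):
        cfg = SyntheticConfig(n_coding=120, n_noncoding=80, n_planted_pairs=0,
                              n_planted_de=0, n_planted_de_pairs=0,
                              as_pairs_per_mode={}, seed=0)
        study = simulate_study(cfg)
        _, norm = normalize_counts(study.counts)
        expr = log_expression(norm)
        lnc = expr.loc[sorted(study.truth.true_lncrna_ids)].to_numpy()
        mrna = expr.loc[sorted(study.truth.true_coding_ids)].to_numpy()
        zl = (lnc - lnc.mean(1, keepdims=True))
        zl /= np.sqrt((zl**2).sum(1, keepdims=True))
        zm = (mrna - mrna.mean(1, keepdims=True))
        zm /= np.sqrt((zm**2).sum(1, keepdims=True))
        r = (zl @ zm.T).ravel()
        n = expr.shape[1]
        for c in (0.3, 0.5):
            t = c * np.sqrt(n - 2) / np.sqrt(1 - c * c)
            p = 2 * stats.t.sf(t, df=n - 2)
            frac = float(np.mean(np.abs(r) >= c))
            se = np.sqrt(p * (1 - p) / r.size)
            assert abs(frac - p) <= 3 * se, (c, frac, p)

    def test_planted_de_all_down_at_minus_two(self):
        cfg = _cfg(planted_lfc=-2.0)
        study = simulate_study(cfg)
        de = study.de_table.set_index("transcript_id")
        for tid, direction in study.truth.planted_de.items():
            assert de.loc[tid, "direction"] == direction == "down"

    def test_planted_de_up_when_lfc_positive(self):
        cfg = _cfg(planted_lfc=2.0, de_pair_lfc=5.0)
        study = simulate_study(cfg)
        de = study.de_table.set_index("transcript_id")
        for tid in study.truth.planted_de:
            assert de.loc[tid, "direction"] == "up"

    def test_counts_match_truth_ids_and_layout(self, small_study):
        cm = small_study.counts
        assert set(cm.transcript_ids) == set(small_study.truth.all_ids)
        assert cm.n_libraries == 16
        layout = {(l.condition, l.time_h) for l in cm.libraries}
        assert layout == {(c, t) for c in ("control", "infected") for t in (4, 12, 48)}
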