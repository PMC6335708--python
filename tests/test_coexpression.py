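"""Normalization, correlation statistics, edge calling, permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lncnet.coexpression import (
    CoexpressionConfig,
    PermutationConfig,
    bh_adjust,
    call_edges,
    normalize_counts,
    pcc_pvalue,
    pearson,
    permutation_validate,
)
from lncnet.exceptions import ConstantVectorError

from .oracles import brute_bh, definitional_pearson


class TestNormalize:
    def test_identical_libraries_have_unit_factors(self):
        df = pd.DataFrame({"a": [10.0, 20, 5], "b": [10.0, 20, 5], "c": [10.0, 20, 5]})
        factors, norm = normalize_counts(df)
        assert np.allclose(factors, 1.0)
        assert np.allclose(norm, df)

    def test_doubled_library_hand_computation(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 500, size=40).astype(float)
        df = pd.DataFrame({"A": a, "B": 2 * a})
        factors, norm = normalize_counts(df)
        assert factors["A"] == pytest.approx(1 / np.sqrt(2))
        assert factors["B"] == pytest.approx(np.sqrt(2))
        assert np.allclose(norm["A"], norm["B"])

    def test_post_normalization_median_ratio_to_reference_is_one(self, small_study):
        raw = small_study.counts.counts.to_numpy()
        factors, norm = normalize_counts(small_study.counts)
        positive = np.all(raw > 0, axis=1)
        log_ref = np.mean(np.log(raw[positive]), axis=1)  # the original reference
        ratios = np.log(norm.to_numpy()[positive]) - log_ref[:, None]
        assert np.allclose(np.median(ratios, axis=0), 0.0, atol=1e-12)

    def test_no_all_positive_transcript_is_an_error(self):
        df = pd.DataFrame({"a": [0.0, 5.0], "b": [3.0, 0.0]})
        with pytest.raises(ValueError, match="positive"):
            normalize_counts(df)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
            ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-14)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert pearson(x, y) == pytest.approx(definitional_pearson(x, y), abs=1e-12)

    def test_constant_vector_is_signalled(self):
        with pytest.raises(ConstantVectorError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        st.integers(3, 12),
        st.floats(0.1, 50),
        st.floats(-100, 100),
        st.integers(0, 2**31 - 1),
    )
    def test_invariant_under_positive_affine_maps(self, n, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r = pearson(x, y)
        assert pearson(scale * x + shift, y) == pytest.approx(r, abs=1e-9)
        assert pearson(x, -y) == pytest.approx(-r, abs=1e-9)


class TestPvalue:
    def test_r_zero_is_one(self):
        for n in (3, 10, 16):
            assert pcc_pvalue(0.0, n) == pytest.approx(1.0)

    def test_df2_closed_form(self):
        # at n = 4 the two-sided tail has the closed form 1 - t / sqrt(2 + t^2)
        assert pcc_pvalue(0.8, 4) == pytest.approx(0.2, abs=1e-12)

    def test_perfect_correlation_is_zero(self):
        assert pcc_pvalue(1.0, 5) == 0.0
        assert pcc_pvalue(-1.0, 5) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pcc_pvalue(0.5, 2)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_adjusted_at_least_raw_and_matches_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            adj = bh_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            assert np.allclose(adj, brute_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _expr(rows, libs=16, seed=0, index=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(rows, libs)),
        index=index or [f"t{i}" for i in range(rows)],
    )


class TestCallEdges:
    def test_threshold_semantics(self):
        n = 16
        rng = np.random.default_rng(1)
        base = rng.normal(size=n)

        def noisy(target_r):
            # mix with independent noise to land near the target correlation
            eps = rng.normal(size=n)
            w = target_r
            return w * (base - base.mean()) / base.std() + np.sqrt(1 - w * w) * (
                eps - eps.mean()
            ) / eps.std()

        lnc = pd.DataFrame([base], index=["lnc1"])
        mrna = pd.DataFrame(
            [noisy(0.999), noisy(0.2)], index=["m_hi", "m_lo"]
        )
        edges, qc = call_edges(lnc, mrna, CoexpressionConfig())
        assert [e.mrna_id for e in edges] == ["m_hi"]
        assert all(abs(e.pcc) >= 0.95 and e.pvalue < 0.05 for e in edges)

    def test_high_r_but_failing_p_is_rejected(self):
        # n = 4 with |r| slightly above 0.95: p ~ 0.05-0.3, above nothing...
        # craft r ~ 0.96 at n = 4 -> p ~ 0.04? use threshold pvalue_max tiny instead
        lnc = pd.DataFrame([[1.0, 2.0, 3.1, 3.9]], index=["l"])
        mrna = pd.DataFrame([[1.1, 1.9, 3.2, 3.8]], index=["m"])
        strict = CoexpressionConfig(pvalue_max=1e-6)
        edges, _ = call_edges(lnc, mrna, strict)
        assert edges == []

    def test_constant_vectors_are_skipped_and_counted(self):
        lnc = pd.DataFrame([[1.0] * 16, list(range(16))], index=["flat", "ok"])
        mrna = _expr(5, seed=3)
        edges, qc = call_edges(lnc, mrna)
        assert qc["n_constant_lncrnas"] == 1
        assert qc["n_pairs_skipped_undefined"] == 5
        assert all(e.lncrna_id != "flat" for e in edges)

    def test_edge_set_shrinks_with_stricter_thresholds(self, small_study):
        from lncnet.coexpression import log_expression

        _, norm = normalize_counts(small_study.counts)
        expr = log_expression(norm)
        lnc = sorted(small_study.truth.true_lncrna_ids)
        mrna = sorted(small_study.truth.true_coding_ids)
        loose, _ = call_edges(
            expr.loc[lnc], expr.loc[mrna], CoexpressionConfig(pcc_threshold=0.9)
        )
        tight, _ = call_edges(
            expr.loc[lnc], expr.loc[mrna], CoexpressionConfig(pcc_threshold=0.97)
        )
        strict_p, _ = call_edges(
            expr.loc[lnc], expr.loc[mrna],
            CoexpressionConfig(pcc_threshold=0.9, pvalue_max=1e-9),
        )
        as_pairs = lambda edges: {(e.lncrna_id, e.mrna_id) for e in edges}
        assert as_pairs(tight) <= as_pairs(loose)
        assert as_pairs(strict_p) <= as_pairs(loose)

    def test_library_mismatch_rejected(self):
        lnc = _expr(2, seed=0)
        mrna = _expr(2, libs=12, seed=1)
        with pytest.raises(ValueError):
            call_edges(lnc, mrna)


class TestPermutationValidate:
    def test_threshold_zero_gives_proportion_one(self):
        s = permutation_validate(
            _expr(12), _expr(6, seed=5), PermutationConfig(10, 5, 0.0, seed=1)
        )
        assert s.proportion == 1.0

    def test_bitwise_reproducible_and_config_echoed(self):
        lnc, mrna = _expr(120, seed=6), _expr(30, seed=7)
        cfg = PermutationConfig(100, 50, 0.95, seed=3)
        a = permutation_validate(lnc, mrna, cfg)
        b = permutation_validate(lnc, mrna, cfg)
        assert a.to_dict() == b.to_dict()
        assert (a.n_lncrnas_sampled, a.n_repetitions, a.threshold) == (100, 50, 0.95)
        assert a.n_pooled == 50 * 100 * 30

    def test_proportion_non_increasing_in_threshold(self):
        lnc, mrna = _expr(60, seed=8), _expr(40, seed=9)
        props = [
            permutation_validate(
                lnc, mrna, PermutationConfig(50, 40, thr, seed=11)
            ).proportion
            for thr in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(props, props[1:]))

    def test_insufficient_lncrnas_rejected(self):
        with pytest.raises(ValueError, match="lncRNAs"):
            permutation_validate(_expr(5), _expr(5, seed=1), PermutationConfig(10, 5))
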