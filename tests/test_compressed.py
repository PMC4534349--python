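import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st

from aaparzen import (
    KernelParams,
    LabeledDataset,
    class_conditional_compressed,
    class_conditional_exact,
    class_conditional_truncated,
    compress_class,
    compression_error_report,
    fit_compressed,
    log_class_conditional_compressed,
)


class TestCompressClass:
    def test_single_prototype_statistics(self):
        # x = (1,0), lam = 0.75 => beta = e^{-ln 3} = 1/3
        p = KernelParams(lam=0.75, L=2)
        s = compress_class(np.array([[1, 0]]), p)
        assert s.n_omega == 1
        assert s.a == pytest.approx(1 / 3, rel=1e-14)
        assert np.array_equal(s.z, [1, 0])
        assert s.z_prime == pytest.approx([1 / 3, 0.0], rel=1e-14)
        np.testing.assert_allclose(s.Q.toarray(), [[1 / 3, 0], [0, 0]], rtol=1e-14)

    def test_all_zero_prototypes(self):
        p = KernelParams(lam=0.75, L=3)
        s = compress_class(np.zeros((4, 3), dtype=int), p)
        assert s.a == pytest.approx(4.0)
        assert np.array_equal(s.z, [0, 0, 0])
        assert s.Q.nnz == 0

    def test_duplicate_prototypes_double_everything(self, rng):
        p = KernelParams(lam=0.8, L=6)
        x = rng.integers(0, 2, (1, 6))
        s1 = compress_class(x, p)
        s2 = compress_class(np.vstack([x, x]), p)
        assert s2.a == pytest.approx(2 * s1.a, rel=1e-14)
        assert np.array_equal(s2.z, 2 * s1.z)
        assert s2.Q.toarray() == pytest.approx(2 * s1.Q.toarray(), rel=1e-14)

    def test_empty_prototype_set_rejected(self):
        p = KernelParams(lam=0.75, L=2)
        with pytest.raises(ValueError, match="at least one"):
            compress_class(np.empty((0, 2), dtype=int), p)

    def test_summary_invariants(self, rng):
        p = KernelParams(lam=0.7, L=12)
        P = rng.integers(0, 2, (30, 12))
        s = compress_class(P, p)
        assert 0 < s.a <= s.n_omega
        assert (s.z_prime <= s.z + 1e-12).all() and (s.z_prime >= 0).all()
        assert (s.z <= s.n_omega).all()
        Q = s.Q.toarray()
        assert Q == pytest.approx(Q.T)
        assert (np.diag(Q) <= s.z_prime + 1e-12).all()
        eigs = np.linalg.eigvalsh(Q)
        assert eigs.min() >= -1e-10  # positive semidefinite

    @given(st.integers(0, 10**9))
    def test_additivity_of_summaries(self, seed):
        rng = np.random.default_rng(seed)
        p = KernelParams(lam=0.75, L=10)
        P1 = rng.integers(0, 2, (rng.integers(1, 8), 10))
        P2 = rng.integers(0, 2, (rng.integers(1, 8), 10))
        merged = compress_class(P1, p) + compress_class(P2, p)
        direct = compress_class(np.vstack([P1, P2]), p)
        assert merged.n_omega == direct.n_omega
        assert merged.a == pytest.approx(direct.a, rel=1e-13)
        assert np.array_equal(merged.z, direct.z)
        assert merged.z_prime == pytest.approx(direct.z_prime, rel=1e-13)
        assert merged.Q.toarray() == pytest.approx(direct.Q.toarray(), rel=1e-13)

    def test_sparsity_scales_with_bit_support(self, rng):
        # nnz(Q) is bounded by the number of distinct co-occurring bit pairs
        p = KernelParams(lam=0.75, L=200)
        P = (rng.random((50, 200)) < 0.03).astype(int)
        s = compress_class(P, p)
        cooccur = set()
        for row in P:
            on = np.flatnonzero(row)
            for i in on:
                for j in on:
                    if i <= j:
                        cooccur.add((i, j))
        assert s.nnz <= len(cooccur)
        assert s.Q.nnz < 200 * 200 / 10  # far from dense

    def test_lambda_mismatch_rejected(self):
        p75 = KernelParams(lam=0.75, L=2)
        p80 = KernelParams(lam=0.80, L=2)
        s = compress_class(np.array([[1, 0]]), p75)
        with pytest.raises(ValueError, match="lambda"):
            class_conditional_compressed([1, 0], s, p80)
        with pytest.raises(ValueError, match="lambda"):
            compress_class(np.array([[1, 0]]), p75) + compress_class(
                np.array([[1, 0]]), p80
            )


class TestCompressedDensity:
    def test_single_prototype_exactness(self, rng):
        # with one prototype the factored tail is the full kernel series
        for lam in (0.55, 0.75, 0.95):
            for L in (4, 16, 64):
                p = KernelParams(lam=lam, L=L)
                proto = rng.integers(0, 2, (1, L))
                s = compress_class(proto, p)
                ds = LabeledDataset(proto, ["A"])
                for _ in range(5):
                    x = rng.integers(0, 2, L)
                    comp = class_conditional_compressed(x, s, p)
                    exact = class_conditional_exact(x, ds, "A", p)
                    assert comp == pytest.approx(exact, rel=1e-9)

    def test_zero_query_leaves_only_constant_term(self, rng):
        p = KernelParams(lam=0.75, L=6)
        P = rng.integers(0, 2, (7, 6))
        s = compress_class(P, p)
        val = class_conditional_compressed(np.zeros(6, dtype=int), s, p)
        assert val == pytest.approx(0.75**6 * s.a / 7, rel=1e-13)

    def test_nonnegative_everywhere(self, rng):
        p = KernelParams(lam=0.9, L=16)
        s = compress_class(rng.integers(0, 2, (25, 16)), p)
        for _ in range(50):
            assert class_conditional_compressed(rng.integers(0, 2, 16), s, p) >= 0

    def test_log_form_matches_linear_form(self, rng):
        p = KernelParams(lam=0.75, L=12)
        s = compress_class(rng.integers(0, 2, (10, 12)), p)
        for _ in range(20):
            x = rng.integers(0, 2, 12)
            lin = class_conditional_compressed(x, s, p)
            assert math.exp(log_class_conditional_compressed(x, s, p)) == pytest.approx(
                lin, rel=1e-12
            )

    def test_log_form_survives_large_mu(self, rng):
        # mu = 2 alpha x.z grows with class size; e^mu overflows linear doubles
        p = KernelParams(lam=0.95, L=40)
        P = (rng.random((500, 40)) < 0.8).astype(int)
        s = compress_class(P, p)
        x = np.ones(40, dtype=int)
        assert 2 * p.alpha * float(x @ s.z) > 700  # overflow regime for e^mu
        assert math.isfinite(log_class_conditional_compressed(x, s, p))


class TestTruncatedSeries:
    def test_order_zero_partial_sum(self, rng):
        p = KernelParams(lam=0.75, L=5)
        P = rng.integers(0, 2, (4, 5))
        x = rng.integers(0, 2, 5)
        s = compress_class(P, p)
        B = 0.75**5 * math.exp(-p.alpha * int(x @ x)) / 4
        assert class_conditional_truncated(x, P, p, 0) == pytest.approx(
            B * s.a, rel=1e-13
        )

    def test_monotone_nondecreasing_in_order(self, rng):
        p = KernelParams(lam=0.75, L=10)
        P = rng.integers(0, 2, (8, 10))
        x = rng.integers(0, 2, 10)
        vals = [class_conditional_truncated(x, P, p, r) for r in range(20)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_converges_to_exact_estimator(self, rng):
        p = KernelParams(lam=0.75, L=16)
        P = rng.integers(0, 2, (20, 16))
        ds = LabeledDataset(P, ["A"] * 20)
        for _ in range(10):
            x = rng.integers(0, 2, 16)
            trunc = class_conditional_truncated(x, P, p, 60)
            exact = class_conditional_exact(x, ds, "A", p)
            assert trunc == pytest.approx(exact, rel=1e-10)

    def test_first_order_matches_compressed_without_tail(self, rng):
        # the r = 0, 1 terms are exactly representable for any class size
        p = KernelParams(lam=0.8, L=14)
        P = rng.integers(0, 2, (30, 14))
        s = compress_class(P, p)
        for _ in range(20):
            x = rng.integers(0, 2, 14)
            no_tail = class_conditional_compressed(x, s, p, tail=False)
            first = class_conditional_truncated(x, P, p, 1)
            assert no_tail == pytest.approx(first, rel=1e-14)


class TestCompressionErrorReport:
    def test_single_prototype_classes_are_exact(self, rng):
        p = KernelParams(lam=0.75, L=8)
        ds = LabeledDataset(rng.integers(0, 2, (2, 8)), ["A", "B"])
        report = compression_error_report(ds, p, rng.integers(0, 2, (10, 8)))
        assert report.max_rel_error < 1e-9
        assert report.decision_agreement == 1.0

    def test_duplicated_prototypes_overshoot_is_measured(self, rng):
        # with N identical prototypes the tail term uses mu = 2 alpha (x.z)
        # where z sums the prototypes, so the r-th series term is inflated
        # by N^{r-2}: the compressed density overestimates, and the report
        # must surface that rather than hide it
        p = KernelParams(lam=0.75, L=8)
        proto = np.array([1, 1, 0, 1, 0, 0, 1, 0])
        P = np.tile(proto, (6, 1))
        ds = LabeledDataset(P, ["A"] * 6)
        queries = np.tile(proto, (3, 1))  # maximal-overlap queries
        report = compression_error_report(ds, p, queries)
        assert np.isfinite(report.table["rel_error"]).all()
        assert report.max_rel_error > 1.0  # overshoot, not round-off
        assert (
            report.table["compressed_density"] >= report.table["exact_density"]
        ).all()

    def test_general_classes_produce_finite_report(self, rng, toy_dataset):
        p = KernelParams(lam=0.75, L=4)
        report = compression_error_report(toy_dataset, p, rng.integers(0, 2, (5, 4)))
        assert len(report.table) == 5 * 2
        assert np.isfinite(report.table["rel_error"]).all()
        assert set(report.table.columns) >= {
            "query", "class", "exact_density", "compressed_density",
            "rel_error", "decision_agrees",
        }


class TestCompressedModel:
    def test_fit_builds_summary_per_class(self, toy_dataset):
        p = KernelParams(lam=0.75, L=4)
        model = fit_compressed(toy_dataset, p, prior_mode="empirical")
        assert model.classes == ("A", "B")
        assert model.summaries["A"].n_omega == 3
        assert model.priors.priors == {"A": 0.6, "B": 0.4}

    def test_model_size_independent_of_duplication(self, rng):
        p = KernelParams(lam=0.75, L=16)
        P = rng.integers(0, 2, (10, 16))
        s1 = compress_class(P, p)
        s10 = compress_class(np.tile(P, (10, 1)), p)
        assert s10.nnz == s1.nnz
        assert sp.triu(s10.Q).nnz == sp.triu(s1.Q).nnz
        assert s10.z.shape == s1.z.shape
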