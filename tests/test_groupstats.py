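"""Nonparametric group statistics: rank tests, BH adjustment, partitions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indentfit.groupstats import (
    bh_adjust,
    group_correlations,
    group_report,
    normality_p,
    partition_cohort,
    rank_test,
    spearman,
)

# ---------------------------------------------------------------------------
# brute-force enumeration oracles
# ---------------------------------------------------------------------------


def exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Enumerate all 2^n sign patterns of tie-free differences; returns the
    smaller signed-rank sum and the two-sided p = min(1, 2 P(W- <= w))."""
    d = np.asarray(d, dtype=float)
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_minus_obs = ranks[d < 0].sum()
    w_obs = min(w_minus_obs, ranks.sum() - w_minus_obs)
    dist = []
    for signs in itertools.product([1, -1], repeat=n):
        s = np.asarray(signs)
        dist.append(ranks[s < 0].sum())
    dist = np.asarray(dist)
    lo = np.mean(dist <= w_minus_obs + 1e-12)
    hi = np.mean(dist >= w_minus_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(lo, hi))


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Enumerate all C(n1+n2, n1) rank assignments of tie-free samples."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    dist = np.array([sum(c) for c in itertools.combinations(ranks, n1)])
    lo = np.mean(dist <= w_obs + 1e-12)
    hi = np.mean(dist >= w_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(lo, hi))


class TestRankTests:
    def test_rank_sum_worked_example(self):
        W, p = rank_test([1, 2, 3], [4, 5, 6], paired=False)
        assert W == pytest.approx(6.0)
        assert p == pytest.approx(0.1, rel=1e-12)  # 2/20 rank assignments

    def test_signed_rank_worked_example(self):
        W, p = rank_test([2, 4, 6], [1, 2, 3], paired=True)  # differences 1, 2, 3
        assert W == pytest.approx(0.0)
        assert p == pytest.approx(0.25, rel=1e-12)  # 2/8 sign patterns

    def test_paired_identical_degenerate(self):
        W, p = rank_test([1.0, 2.0], [1.0, 2.0], paired=True)
        assert p == 1.0

    def test_signed_rank_matches_enumeration(self, rng):
        """Exact p agrees with the 2^n sign-pattern oracle for all n <= 7."""
        for n in range(3, 8):
            for _ in range(5):
                d = rng.normal(0, 1, n)
                while np.any(d == 0) or len(np.unique(np.abs(d))) < n:
                    d = rng.normal(0, 1, n)
                x = rng.normal(0, 1, n)
                W, p = rank_test(x, x - d, paired=True)
                W_or, p_or = exact_signed_rank_p(d)
                assert W == pytest.approx(W_or)
                assert p == pytest.approx(p_or, rel=1e-10)

    def test_rank_sum_matches_enumeration(self, rng):
        """Exact p agrees with the combinatorial oracle for n1+n2 <= 10."""
        for n1, n2 in [(3, 3), (3, 4), (4, 4), (5, 5), (4, 6), (2, 8)]:
            for _ in range(4):
                pooled = rng.normal(0, 1, n1 + n2)
                while len(np.unique(pooled)) < n1 + n2:
                    pooled = rng.normal(0, 1, n1 + n2)
                x, y = pooled[:n1], pooled[n1:]
                W, p = rank_test(x, y, paired=False)
                W_or, p_or = exact_rank_sum_p(x, y)
                assert W == pytest.approx(W_or)
                assert p == pytest.approx(p_or, rel=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0], paired=False)


class TestNormality:
    def test_normal_draws_rarely_rejected(self):
        rej = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 50)
            rej += normality_p(x) < 0.05
        assert rej <= 10  # >= 90% of seeds pass

    def test_exponential_draws_usually_rejected(self):
        rej = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(1.0, 50)
            rej += normality_p(x) < 0.05
        assert rej >= 90

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            normality_p(np.ones(10))

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            normality_p(np.array([1.0, 2.0]))


class TestSpearman:
    def test_monotone_perfect(self):
        rho, _ = spearman([1, 2, 3], [2, 4, 9])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3], [9, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_identical_indicators(self):
        # two factors whose subgroups contain exactly the same specimens
        x = np.array([1, 1, 0, 0, 1, 0])
        rho, _ = spearman(x, x.copy())
        assert rho == pytest.approx(1.0)
        # at cohort size the association is also significant
        x33 = np.tile([1, 0, 1], 11)[:33]
        rho, p = spearman(x33, x33.copy())
        assert rho == pytest.approx(1.0) and p < 1e-6

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, 7)
        y = rng.normal(0, 1, 7)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_worked_example(self):
        adj = bh_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.02], rtol=1e-12)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_stepup_properties(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)  # never smaller
        assert np.all(adj <= 1.0 + 1e-15)
        # order preserved after sorting both by raw p
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


def make_cohort_frames(rng, n_pat=6, ages=None):
    ages = ages if ages is not None else [40, 45, 47, 55, 60, 65][:n_pat]
    rows, mod = [], []
    sid = 0
    for i, age in enumerate(ages):
        for _ in range(3):
            sid += 1
            rows.append({
                "specimen_id": f"S{sid:03d}", "patient_id": f"P{i}",
                "age_years": age, "bmi_kg_m2": 22.0 + 6 * (i % 2),
                "menopause": "post" if age >= 50 else "pre",
                "side": "right" if sid % 3 else "left", "thickness_mm": 10.0,
            })
            mod.append({"specimen_id": f"S{sid:03d}",
                        "E_first": rng.lognormal(-4.4, 0.2),
                        "E_second": rng.lognormal(-3.1, 0.2)})
    return pd.DataFrame(rows), pd.DataFrame(mod)


class TestPartitionsAndReport:
    def test_partition_sizes(self, rng):
        meta, mod = make_cohort_frames(rng, ages=[40, 60])
        parts = partition_cohort(meta, mod)
        age = next(p for p in parts if p.factor == "age")
        assert len(age.members["age_lt50"]) == 3
        assert len(age.members["age_gt50"]) == 3

    def test_all_premenopausal_flagged_untestable(self, rng):
        meta, mod = make_cohort_frames(rng, ages=[40, 45])
        recs = group_report(meta, mod)
        men = [r for r in recs if r.factor == "menopause"]
        assert all(r.test == "untestable" for r in men)

    def test_missing_metadata_names_specimen(self, rng):
        meta, mod = make_cohort_frames(rng)
        meta.loc[2, "bmi_kg_m2"] = np.nan
        with pytest.raises(ValueError, match=meta.loc[2, "specimen_id"]):
            partition_cohort(meta, mod)

    def test_age_menopause_identical_groups_correlate_perfectly(self, rng):
        meta, _ = make_cohort_frames(rng)
        corr = group_correlations(meta)
        row = corr[(corr.factor_a == "age") & (corr.factor_b == "menopause")]
        assert row.rho.iloc[0] == pytest.approx(1.0)

    def test_report_order_invariant(self, rng):
        meta, mod = make_cohort_frames(rng)
        recs1 = group_report(meta, mod)
        perm = rng.permutation(len(meta))
        recs2 = group_report(meta.iloc[perm].reset_index(drop=True), mod)
        for a, b in zip(recs1, recs2):
            assert a.factor == b.factor and a.region == b.region
            if a.p_raw is None:
                assert b.p_raw is None
            else:
                assert a.p_raw == pytest.approx(b.p_raw, rel=1e-12)

    def test_adjusted_ge_raw_and_flags(self, rng):
        meta, mod = make_cohort_frames(rng)
        recs = group_report(meta, mod)
        for r in recs:
            if r.p_raw is not None:
                assert r.p_adjusted >= r.p_raw - 1e-15

    def test_forced_signed_rank_routing(self, rng):
        meta, mod = make_cohort_frames(rng)
        recs = group_report(meta, mod, force_signed_rank=True)
        routed = [r for r in recs if r.factor in ("age", "bmi", "menopause")]
        assert all(r.test in ("signed-rank", "untestable") for r in routed)
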