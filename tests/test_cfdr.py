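import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condfdr.cfdr import (
    Lookup2D,
    build_lookup,
    cfdr_point,
    conditional_cdf,
    interpolate_fdr,
    summarize,
    uncond_fdr,
    uncond_fdr_vector,
)

P1 = np.array([0.01, 0.2, 0.5, 0.9])
P2 = np.array([0.001, 0.5, 0.02, 0.9])


def brute_force_cdf(p1, p2, pp, pc):
    """Independent double-loop counting oracle."""
    num = den = 0
    for a, b in zip(pp, pc):
        if b <= p2:
            den += 1
            if a <= p1:
                num += 1
    return np.nan if den == 0 else num / den


class TestConditionalCdf:
    def test_hand_counted_slice(self):
        # slice P2 <= 0.02 holds SNPs 1 and 3; only SNP 1 has P1 <= 0.2
        assert conditional_cdf(0.2, 0.02, P1, P2) == 0.5

    def test_full_p1_gives_one(self):
        assert conditional_cdf(1.0, 0.02, P1, P2) == 1.0

    def test_unit_p2_reduces_to_marginal_ecdf(self):
        assert conditional_cdf(0.2, 1.0, P1, P2) == 2 / 4

    def test_empty_slice_is_nan(self):
        assert np.isnan(conditional_cdf(0.5, 1e-9, P1, P2))


class TestCfdrPoint:
    def test_hand_counted_value(self):
        assert cfdr_point(0.2, 0.02, P1, P2) == pytest.approx(0.4)

    def test_uniform_independent_panel_is_uninformative(self):
        rng = np.random.default_rng(0)
        pp, pc = rng.uniform(size=20_000), rng.uniform(size=20_000)
        for q in (0.05, 0.2, 0.6):
            assert cfdr_point(q, 0.5, pp, pc) == pytest.approx(1.0, abs=0.1)

    def test_clipped_at_one(self):
        # F(0.6 | 0.2) = 1/2 on this panel, so the raw ratio 1.2 is clipped
        pp, pc = np.array([0.2, 0.9]), np.array([0.1, 0.1])
        assert cfdr_point(0.6, 0.2, pp, pc) == 1.0

    def test_empty_slice_maximally_conservative(self):
        assert cfdr_point(0.5, 1e-9, P1, P2) == 1.0

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        pp, pc = rng.uniform(size=n), rng.uniform(size=n)
        p1, p2 = rng.uniform(size=2)
        F = brute_force_cdf(p1, p2, pp, pc)
        expected = 1.0 if (np.isnan(F) or F == 0) else min(1.0, p1 / F)
        assert cfdr_point(p1, p2, pp, pc) == expected


class TestUncondFdr:
    def test_equals_degenerate_conditioning(self):
        for p1 in P1:
            assert uncond_fdr(p1, P1) == cfdr_point(p1, 1.0, P1, P2)

    def test_hand_counted_value(self):
        assert uncond_fdr(0.2, P1) == pytest.approx(0.4)

    def test_uniform_null_near_one(self):
        rng = np.random.default_rng(1)
        pp = rng.uniform(size=50_000)
        for q in (0.01, 0.1, 0.5):
            assert uncond_fdr(q, pp) == pytest.approx(1.0, abs=0.05)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(2)
        pp = rng.uniform(size=300)
        vec = uncond_fdr_vector(pp)
        for i in range(0, 300, 37):
            assert vec[i] == pytest.approx(uncond_fdr(pp[i], pp), rel=1e-12)


class TestBuildLookup:
    def test_origin_node_is_one(self):
        lk = build_lookup(P1, P2, grid_p1=[0.0, 1.0], grid_p2=[0.0, 1.0])
        assert lk.fdr[0, 0] == 1.0

    def test_all_nodes_match_pointwise_recomputation(self):
        rng = np.random.default_rng(3)
        pp, pc = rng.uniform(size=500), rng.uniform(size=500)
        g1 = np.arange(0.0, 4.01, 0.5)
        g2 = np.arange(0.0, 3.01, 1.0)
        lk = build_lookup(pp, pc, g1, g2)
        for i, a in enumerate(g1):
            for j, b in enumerate(g2):
                assert lk.fdr[i, j] == cfdr_point(10**-a, 10**-b, pp, pc)

    def test_base_row_reproduces_unconditional_curve(self):
        rng = np.random.default_rng(4)
        pp, pc = rng.uniform(size=400), rng.uniform(size=400)
        g1 = np.arange(0.0, 3.01, 0.25)
        lk = build_lookup(pp, pc, g1, [0.0, 0.0001])
        for i, a in enumerate(g1):
            assert lk.fdr[i, 0] == pytest.approx(uncond_fdr(10**-a, pp), rel=1e-12)

    def test_monotonization_running_minimum(self):
        rng = np.random.default_rng(5)
        pp, pc = rng.uniform(size=300), rng.uniform(size=300)
        lk = build_lookup(pp, pc, monotonize=True)
        assert np.all(np.diff(lk.fdr, axis=0) <= 1e-15)


class TestInterpolate:
    def test_exact_at_nodes(self):
        rng = np.random.default_rng(6)
        pp, pc = rng.uniform(size=1000), rng.uniform(size=1000)
        lk = build_lookup(pp, pc)
        for a, b in [(0.5, 1.0), (2.0, 3.5), (7.3, 0.0)]:
            i = np.searchsorted(lk.grid_p1, a)
            j = np.searchsorted(lk.grid_p2, b)
            assert interpolate_fdr(lk, 10.0**-a, 10.0**-b) == pytest.approx(
                lk.fdr[i, j], rel=1e-9
            )

    def test_bilinear_midpoint_closed_form(self):
        lk = Lookup2D(
            grid_p1=np.array([0.0, 2.0]),
            grid_p2=np.array([0.0, 2.0]),
            fdr=10.0 ** -np.array([[1.0, 1.0], [3.0, 3.0]]),
            n_at_node=np.array([4, 4]),
        )
        mid = interpolate_fdr(lk, 10.0**-1.0, 10.0**-1.0)
        assert -np.log10(mid) == pytest.approx(2.0, rel=1e-12)

    def test_queries_beyond_grid_clamp_to_boundary(self):
        rng = np.random.default_rng(7)
        pp, pc = rng.uniform(size=500), rng.uniform(size=500)
        lk = build_lookup(pp, pc)
        assert interpolate_fdr(lk, 1e-12, 1e-15) == pytest.approx(
            lk.fdr[-1, -1], rel=1e-9
        )

    def test_consistency_with_pointwise_estimator(self):
        # interpolated values track pointwise recomputation within the
        # resolution of the grid (checked against a 10x refined grid)
        rng = np.random.default_rng(8)
        pp, pc = np.sort(rng.uniform(size=2000)), rng.uniform(size=2000)
        coarse = build_lookup(pp, pc)
        fine = build_lookup(
            pp, pc,
            grid_p1=np.round(np.arange(0, 10.001, 0.01), 10),
            grid_p2=np.round(np.arange(0, 10.001, 0.05), 10),
        )
        q1 = rng.uniform(1e-6, 1, size=1000)
        q2 = rng.uniform(1e-4, 1, size=1000)
        coarse_v = -np.log10(interpolate_fdr(coarse, q1, q2))
        fine_v = -np.log10(interpolate_fdr(fine, q1, q2))
        # grid-induced bound: one coarse cell of slack in -log10 units
        assert np.max(np.abs(coarse_v - fine_v)) <= 1.0


class TestSummarize:
    def test_single_trait_min_is_that_trait(self, toy_panel):
        lk = build_lookup(toy_panel.p_primary, toy_panel.p_cond["t2"], trait="t2")
        out = summarize(toy_panel, {"t2": lk})
        np.testing.assert_allclose(out["min_cfdr"], out["cfdr_t2"])
        assert set(out["driving_trait"]) == {"t2"}

    def test_min_across_traits_and_threshold(self, toy_panel):
        lo = Lookup2D(
            grid_p1=np.array([0.0, 10.0]), grid_p2=np.array([0.0, 10.0]),
            fdr=np.full((2, 2), 0.004), n_at_node=np.array([4, 4]),
        )
        hi = Lookup2D(
            grid_p1=np.array([0.0, 10.0]), grid_p2=np.array([0.0, 10.0]),
            fdr=np.full((2, 2), 0.02), n_at_node=np.array([4, 4]),
        )
        toy_panel.p_cond["t3"] = toy_panel.p_cond["t2"].copy()
        out = summarize(toy_panel, {"t2": hi, "t3": lo}, threshold=0.01)
        assert np.allclose(out["min_cfdr"], 0.004)
        assert set(out["driving_trait"]) == {"t3"}
        assert out["significant"].all()

    def test_trait_mismatch_rejected(self, toy_panel):
        lk = build_lookup(toy_panel.p_primary, toy_panel.p_cond["t2"], trait="t2")
        with pytest.raises(KeyError):
            summarize(toy_panel, {"missing": lk})


def test_rectangle_estimate_is_conservative_for_fixed_thresholds():
    """For a FIXED rectangle {P1 <= p1, P2 <= p2} the estimator bounds the
    realized false-discovery proportion inside it from above on average
    (pi0 = 1 makes it conservative); checked on truth-labelled simulations."""
    from condfdr.simulate import SimConfig, simulate_panel

    p1s, p2s = 1e-4, 1e-2
    ests, fdps = [], []
    for seed in range(30):
        t1, t2, _, truth = simulate_panel(SimConfig(n_snps=50_000, seed=seed))
        p1 = t1["P"].to_numpy()
        p2 = t2["P"].to_numpy()
        nonnull = truth["component"].isin(["t1", "pleio"]).to_numpy()
        ests.append(cfdr_point(p1s, p2s, p1, p2))
        inside = (p1 <= p1s) & (p2 <= p2s)
        fdps.append((inside & ~nonnull).sum() / max(inside.sum(), 1))
    assert np.mean(fdps) <= np.mean(ests)
    assert np.mean(fdps) <= 0.015


def test_degenerate_conditioning_equals_unconditional():
    """cFDR conditioned on a trait that admits every SNP reduces to the
    unconditional FDR for every SNP."""
    rng = np.random.default_rng(9)
    pp = rng.uniform(size=2000)
    pc = np.full(2000, 1.0)
    for p1 in rng.uniform(size=50):
        assert cfdr_point(p1, 1.0, pp, pc) == pytest.approx(
            uncond_fdr(p1, pp), rel=1e-12
        )
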