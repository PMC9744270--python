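import math

import numpy as np
import pytest

from adscreen.genetics_prs import (
    DosageMatrix, PRSResult, ScoreType, VariantQCConfig, VariantWeight,
    centiles, compute_prs, hwe_exact_test, shift_nonnegative, variant_qc,
)


def matrix(grid, pids=None, vids=None):
    grid = np.asarray(grid, dtype=float)
    pids = pids or [f"P{i}" for i in range(grid.shape[0])]
    vids = vids or [f"v{j}" for j in range(grid.shape[1])]
    return DosageMatrix(pids, vids, grid)


def weights(*ws):
    return [VariantWeight(f"v{j}", "A", w) for j, w in enumerate(ws)]


class TestComputePRS:
    def test_hand_arithmetic(self):
        scores = compute_prs(matrix([[2, 1]]), weights(0.5, -1.0),
                             ScoreType.T2D_gePS)
        assert scores[0].raw_score == pytest.approx(0.0)

    def test_zero_weights_give_zero_scores(self):
        scores = compute_prs(matrix([[2, 1], [0, 2]]), weights(0.0, 0.0),
                             ScoreType.T1D_rsPS)
        assert all(s.raw_score == 0.0 for s in scores)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        grid = rng.uniform(0, 2, size=(50, 200))
        w = rng.normal(0, 0.1, size=200)
        m = matrix(grid)
        wts = [VariantWeight(f"v{j}", "A", float(w[j])) for j in range(200)]
        scores = compute_prs(m, wts, ScoreType.T2D_gePS)
        for i, s in enumerate(scores):
            expected = 0.0
            for j in range(200):
                expected += grid[i, j] * w[j]
            assert s.raw_score == pytest.approx(expected, rel=1e-12)

    def test_additive_over_disjoint_weight_subsets(self):
        rng = np.random.default_rng(1)
        grid = rng.uniform(0, 2, size=(10, 20))
        w = rng.normal(size=20)
        m = matrix(grid)
        wts = [VariantWeight(f"v{j}", "A", float(w[j])) for j in range(20)]
        full = compute_prs(m, wts, ScoreType.T2D_gePS)
        left = compute_prs(m, wts[:7], ScoreType.T2D_gePS)
        right = compute_prs(m, wts[7:], ScoreType.T2D_gePS)
        for f, l, r in zip(full, left, right):
            assert f.raw_score == pytest.approx(l.raw_score + r.raw_score)

    def test_missing_cells_use_cohort_mean_dosage(self):
        grid = [[2.0, 1.0], [np.nan, 1.0], [0.0, 1.0]]
        scores = compute_prs(matrix(grid), weights(1.0, 0.0),
                             ScoreType.T2D_gePS)
        assert scores[1].raw_score == pytest.approx(1.0)  # mean of 2 and 0

    def test_missing_policy_zero(self):
        grid = [[2.0], [np.nan]]
        scores = compute_prs(matrix(grid), weights(1.0), ScoreType.T2D_gePS,
                             missing_policy="zero")
        assert scores[1].raw_score == 0.0

    def test_empty_weights_and_unknown_variants_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_prs(matrix([[1.0]]), [], ScoreType.T2D_gePS)
        with pytest.raises(ValueError, match="absent"):
            compute_prs(matrix([[1.0]]),
                        [VariantWeight("nope", "A", 1.0)], ScoreType.T2D_gePS)


class TestShift:
    def test_min_becomes_zero_preserving_offsets(self):
        scores = [PRSResult(f"P{i}", ScoreType.T2D_gePS, raw)
                  for i, raw in enumerate((-2.0, 0.0, 3.0))]
        shifted = shift_nonnegative(scores)
        assert [s.transformed_score for s in shifted] == [0.0, 2.0, 5.0]

    def test_single_score_maps_to_zero(self):
        out = shift_nonnegative([PRSResult("P", ScoreType.T2D_gePS, 7.3)])
        assert out[0].transformed_score == 0.0

    def test_idempotent_and_rank_preserving(self):
        rng = np.random.default_rng(2)
        scores = [PRSResult(f"P{i}", ScoreType.T2D_gePS, float(v))
                  for i, v in enumerate(rng.normal(size=40))]
        once = shift_nonnegative(scores)
        twice = shift_nonnegative(once)
        assert [s.transformed_score for s in once] == \
               [s.transformed_score for s in twice]
        raw_order = np.argsort([s.raw_score for s in scores])
        new_order = np.argsort([s.transformed_score for s in once])
        assert list(raw_order) == list(new_order)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            shift_nonnegative([])


class TestCentiles:
    def ref(self):
        return list(range(1, 101))

    def score(self, v):
        return [PRSResult("P", ScoreType.T2D_gePS, float(v))]

    def test_below_reference_minimum_is_zero(self):
        assert centiles(self.score(0.5), self.ref())[0].centile == 0

    def test_at_reference_maximum(self):
        # ties count none of themselves: 99 of 100 strictly below
        assert centiles(self.score(100), self.ref())[0].centile == 99
        assert centiles(self.score(101), self.ref())[0].centile == 100

    def test_counting_oracle_mid_reference(self):
        assert centiles(self.score(50.5), self.ref())[0].centile == 50

    def test_monotone_in_score(self):
        rng = np.random.default_rng(3)
        ref = list(rng.normal(size=500))
        values = sorted(rng.normal(size=50))
        scored = centiles([PRSResult(f"P{i}", ScoreType.T2D_gePS, v)
                           for i, v in enumerate(values)], ref)
        cents = [s.centile for s in scored]
        assert cents == sorted(cents)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            centiles(self.score(1), [])


def hwe_oracle(n0, n1, n2):
    """Independent conditional-probability computation via math.comb."""
    n = n0 + n1 + n2
    n_rare = 2 * min(n0, n2) + n1

    # direct pmf: P(h) = 2^h * n! * n_rare! * (2n-n_rare)! / (h! hr! hc! (2n)!)
    def pmf(h):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        num = (2 ** h) * math.factorial(n) * math.factorial(n_rare) \
            * math.factorial(2 * n - n_rare)
        den = (math.factorial(h) * math.factorial(hr) * math.factorial(hc)
               * math.factorial(2 * n))
        return num / den
    hs = [h for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)]
    probs = {h: pmf(h) for h in hs}
    total = sum(probs.values())
    p_obs = probs[n1] / total
    return sum(p for p in (v / total for v in probs.values())
               if p <= p_obs * (1 + 1e-12))


class TestVariantQC:
    def test_high_missingness_dropped(self):
        grid = np.full((10, 1), np.nan)
        grid[:4, 0] = 1.0
        report = variant_qc(matrix(grid))
        assert report.dropped["v0"] == ["missingness"]

    def test_monomorphic_variant_dropped_for_maf(self):
        grid = np.zeros((50, 1))
        report = variant_qc(matrix(grid))
        assert "maf" in report.dropped["v0"]

    def test_all_heterozygote_variant_fails_hwe(self):
        grid = np.ones((200, 1))
        report = variant_qc(matrix(grid))
        assert "hwe" in report.dropped["v0"]

    def test_differential_missingness_needs_labels(self):
        grid = np.tile([[1.0, 1.0]], (100, 1)).astype(float)
        grid[:10, 0] = np.nan   # 20% missing among 50 cases, 0% in controls
        grid[:, 1] = np.linspace(0, 2, 100).round()
        labels = [True] * 50 + [False] * 50
        with_labels = variant_qc(matrix(grid), labels)
        assert "differential_missingness" in with_labels.dropped.get("v0", [])
        without = variant_qc(matrix(grid))
        assert "differential_missingness" not in without.dropped.get("v0", [])

    def test_clean_common_variant_kept(self):
        rng = np.random.default_rng(4)
        grid = rng.binomial(2, 0.3, size=(500, 1)).astype(float)
        report = variant_qc(matrix(grid))
        assert report.kept == ["v0"]

    def test_qc_matches_naive_reference_on_random_matrix(self):
        rng = np.random.default_rng(5)
        n, m = 120, 30
        grid = rng.binomial(2, rng.uniform(0.02, 0.5, size=m),
                            size=(n, m)).astype(float)
        mask = rng.random((n, m)) < rng.uniform(0, 0.1, size=m)
        grid[mask] = np.nan
        labels = rng.random(n) < 0.5
        config = VariantQCConfig()
        report = variant_qc(matrix(grid), labels, config)

        for j in range(m):
            col = grid[:, j]
            reasons = []
            if np.isnan(col).mean() > config.max_missing_rate:
                reasons.append("missingness")
            called = col[~np.isnan(col)]
            g = np.rint(called).astype(int)
            n0, n1, n2 = (g == 0).sum(), (g == 1).sum(), (g == 2).sum()
            af = (2 * n2 + n1) / (2 * len(g))
            if min(af, 1 - af) < config.maf_floor:
                reasons.append("maf")
            if hwe_oracle(int(n0), int(n1), int(n2)) < config.hwe_p_floor:
                reasons.append("hwe")
            diff = abs(np.isnan(col[labels]).mean()
                       - np.isnan(col[~labels]).mean())
            if diff > config.max_differential_missingness:
                reasons.append("differential_missingness")
            vid = f"v{j}"
            if reasons:
                assert report.dropped[vid] == reasons, vid
            else:
                assert vid in report.kept, vid


class TestHWEExact:
    @pytest.mark.parametrize("counts", [
        (0, 10, 0), (5, 5, 5), (10, 1, 10), (3, 0, 7), (50, 21, 29),
        (1, 1, 1), (0, 0, 25),
    ])
    def test_matches_direct_pmf_oracle(self, counts):
        got = hwe_exact_test(*counts)
        want = hwe_oracle(*counts)
        assert got == pytest.approx(want, rel=1e-9)

    def test_hw_equilibrium_counts_not_significant(self):
        # 0.25/0.5/0.25 genotype frequencies are exactly at equilibrium
        assert hwe_exact_test(25, 50, 25) > 0.5
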