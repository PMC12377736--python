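import itertools
import math

import numpy as np
import pytest

from els_mapper.stats import (
    ConstantInputError,
    QPCRMeasurement,
    bell_fit,
    dunn_posthoc,
    kruskal_wallis,
    pfaffl_fold_change,
    size_distribution,
    spearman,
)
import pandas as pd


# ---------------------------------------------------------------------------
# independent oracles (rank formulas, exhaustive enumeration)
# ---------------------------------------------------------------------------

def rank_avg(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), float)
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = rank_avg(x), rank_avg(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    return float((rxc * ryc).sum() / math.sqrt((rxc**2).sum() * (ryc**2).sum()))


def spearman_exact_p_oracle(x, y):
    rx, ry = rank_avg(x), rank_avg(y)
    obs = abs(spearman_oracle(x, y))
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = spearman_oracle(rx, np.asarray(perm))
        hits += abs(r) >= obs - 1e-12
        total += 1
    return hits / total


def kruskal_oracle(groups):
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = rank_avg(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = ranks[start : start + len(g)].sum()
        h += rsum**2 / len(g)
        start += len(g)
    h = 12 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n_tot**3 - n_tot)
    return h / correction


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        r, _ = spearman(x, [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)
        r, _ = spearman(x, [50, 40, 30, 20, 10])
        assert r == pytest.approx(-1.0)

    def test_worked_example_r_06(self):
        # 1 - 6*4 / (4*15) = 0.6
        r, p = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)
        assert p == pytest.approx(spearman_exact_p_oracle([1, 2, 3, 4], [2, 1, 4, 3]))

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle_small_n(self, seed):
        """r to 1e-12 and exact p for random small inputs, with ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        x = rng.integers(0, 5, n).astype(float)
        y = rng.integers(0, 5, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        r, p = spearman(x, y)
        assert r == pytest.approx(spearman_oracle(x, y), abs=1e-12)
        assert p == pytest.approx(spearman_exact_p_oracle(x, y), abs=1e-12)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.8, size=30)
        r, p = spearman(x, y)
        assert 0 < p < 0.05 and r > 0


class TestKruskalWallis:
    def test_worked_example_h_72(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert 0 < p < 0.05

    def test_all_tied_convention(self):
        h, p = kruskal_wallis([[5, 5, 5], [5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(i, 1, 6) for i in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_rank_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        groups = [rng.integers(0, 6, int(rng.integers(2, 5))).astype(float)
                  for _ in range(int(rng.integers(2, 4)))]
        if np.ptp(np.concatenate(groups)) == 0:
            pytest.skip("degenerate draw")
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_oracle(groups), abs=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0, 3.0]])


class TestDunnPosthoc:
    def test_extreme_groups_most_significant(self):
        groups = [[1, 2, 3, 4], [5, 6, 7, 8], [20, 21, 22, 23]]
        out = dunn_posthoc(groups, labels=["a", "b", "c"])
        assert len(out) == 3
        p = out.set_index(["group_i", "group_j"]).p_adj
        assert p[("a", "c")] < p[("a", "b")]
        assert ((out.p_adj >= out.p - 1e-12) & (out.p_adj <= 1)).all()

    def test_holm_sidak_adjustment_is_stepwise(self):
        # adjusted p for the smallest raw p equals 1-(1-p)^m
        groups = [[1, 2, 3], [10, 11, 12], [5, 6, 7]]
        out = dunn_posthoc(groups)
        smallest = out.sort_values("p").iloc[0]
        assert smallest.p_adj == pytest.approx(1 - (1 - smallest.p) ** 3, rel=1e-9)


class TestBellFit:
    def test_exact_quadratic_recovered(self):
        x = np.array([1, 4, 8, 12, 15, 18], float)
        y = 2 - 0.5 * x + 0.03 * x**2
        fit = bell_fit(x, y)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.params["a"] == pytest.approx(2, abs=1e-9)
        assert fit.params["b"] == pytest.approx(-0.5, abs=1e-9)
        assert fit.params["c"] == pytest.approx(0.03, abs=1e-9)
        assert fit.peak is None  # convex

    def test_constant_response_convention(self):
        fit = bell_fit([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.r_squared == 0.0

    def test_planted_bell_peak_recovered(self):
        """Peak location recovered across noisy replicates (seeded)."""
        ages = np.repeat([1.0, 12.0, 18.0], 8)
        rng = np.random.default_rng(42)
        peaks = []
        for _ in range(100):
            y = 30 - 0.18 * (ages - 12) ** 2 + rng.normal(0, 3, ages.size)
            fit = bell_fit(ages, y)
            assert fit.params["c"] < 0
            peaks.append(fit.peak)
        assert np.mean(peaks) == pytest.approx(12.0, abs=1.0)

    def test_gaussian_model_switch(self):
        x = np.linspace(0, 20, 30)
        y = 5 * np.exp(-((x - 11) ** 2) / (2 * 3.0**2)) + 1
        fit = bell_fit(x, y, model="gaussian")
        assert fit.r_squared > 0.999
        assert fit.peak == pytest.approx(11, abs=0.01)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            bell_fit([1, 1, 2], [1, 2, 3])


class TestPfaffl:
    def test_doubling_efficiency(self):
        m = QPCRMeasurement(e_target=2.0, delta_ct_target=3.0, e_ref=2.0, delta_ct_ref=0.0)
        assert pfaffl_fold_change(m) == pytest.approx(8.0)

    def test_identity_when_target_and_reference_cancel(self):
        m = QPCRMeasurement(e_target=1.8, delta_ct_target=2.5, e_ref=1.8, delta_ct_ref=2.5)
        assert pfaffl_fold_change(m) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        m = QPCRMeasurement(e_target=1.9, delta_ct_target=1.0, e_ref=2.0, delta_ct_ref=1.0)
        assert pfaffl_fold_change(m) == pytest.approx(0.95)

    @pytest.mark.parametrize("dct", [-2.0, 0.0, 1.5, 4.0])
    def test_multiplicative_in_delta_ct(self, dct):
        base = QPCRMeasurement(e_target=1.9, delta_ct_target=dct, e_ref=2.0, delta_ct_ref=1.0)
        plus = QPCRMeasurement(e_target=1.9, delta_ct_target=dct + 1, e_ref=2.0,
                               delta_ct_ref=1.0)
        assert pfaffl_fold_change(plus) == pytest.approx(1.9 * pfaffl_fold_change(base))

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            QPCRMeasurement(e_target=1.0, delta_ct_target=1, e_ref=2.0, delta_ct_ref=1)


class TestSizeDistribution:
    def test_median(self):
        df = pd.DataFrame({"age_group": ["12"] * 3, "area_um2": [1.0, 2.0, 3.0]})
        _, med = size_distribution(df)
        assert med.median_um2[0] == 2.0

    def test_empty(self):
        df = pd.DataFrame({"age_group": [], "area_um2": []})
        long, med = size_distribution(df)
        assert len(long) == 0 and len(med) == 0

    def test_pooling_order_invariant(self, rng):
        df = pd.DataFrame(
            {"age_group": rng.choice(["1", "12"], 20), "area_um2": rng.uniform(1, 9, 20)}
        )
        l1, m1 = size_distribution(df)
        shuffled = df.sample(frac=1, random_state=3).reset_index(drop=True)
        l2, m2 = size_distribution(shuffled)
        assert l1.equals(l2) and m1.equals(m2)
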