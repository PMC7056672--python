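import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microgdm.io_formats import OtuTable, TaxonomyMap
from microgdm.preprocess_diversity import (
    aggregate_to_rank,
    alpha_indices,
    alpha_table,
    compare_alpha,
    filter_rare_otus,
    rarefaction_curve,
    rarefy,
    _expected_observed,
)


def reference_ace(counts, cutoff=10):
    """Independent straightforward ACE implementation (loops, no vectorized
    shortcuts) used as a second-implementation oracle."""
    counts = [c for c in counts if c > 0]
    s_abund = sum(1 for c in counts if c > cutoff)
    rare = [c for c in counts if c <= cutoff]
    s_rare = len(rare)
    n_rare = sum(rare)
    f1 = sum(1 for c in rare if c == 1)
    c_ace = 1 - f1 / n_rare
    top = 0
    for i in range(1, cutoff + 1):
        fi = sum(1 for c in rare if c == i)
        top += i * (i - 1) * fi
    gamma = max(s_rare / c_ace * top / (n_rare * (n_rare - 1)) - 1, 0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma


class TestFilter:
    def test_strict_boundary(self):
        # grand total 100,000; threshold 0.005% = 5 reads: 4 removed, 5 kept
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [99991, 4, 5]
        t = OtuTable(["s1"], ["big", "four", "five"], counts)
        filtered, removed = filter_rare_otus(t, 0.00005)
        assert removed == ["four"]
        assert filtered.feature_ids == ["big", "five"]

    def test_zero_fraction_identity(self, tiny_table):
        filtered, removed = filter_rare_otus(tiny_table, 0.0)
        assert removed == []
        assert np.array_equal(filtered.counts, tiny_table.counts)

    def test_all_zero_feature_removed(self):
        t = OtuTable(["s1", "s2"], ["a", "z"], np.array([[5, 0], [5, 0]]))
        filtered, removed = filter_rare_otus(t, 1e-9)
        assert removed == ["z"]


class TestRarefy:
    def test_exact_depth_unchanged(self):
        t = OtuTable(["s1"], ["a", "b"], np.array([[30, 70]]))
        r = rarefy(t, 100, seed=0)
        assert np.array_equal(r.counts, t.counts)

    def test_row_sums_equal_depth(self, rng):
        t = OtuTable(
            [f"s{i}" for i in range(5)], [f"f{j}" for j in range(20)],
            rng.integers(0, 5000, size=(5, 20)),
        )
        depth = int(t.depths().min())
        r = rarefy(t, depth, seed=3)
        assert np.all(r.depths() == depth)

    def test_shallow_samples_dropped(self):
        t = OtuTable(["deep", "shallow"], ["a"], np.array([[100], [5]]))
        r = rarefy(t, 50, seed=0)
        assert r.sample_ids == ["deep"]

    def test_all_below_depth_errors(self):
        t = OtuTable(["s1"], ["a"], np.array([[5]]))
        with pytest.raises(ValueError):
            rarefy(t, 50)

    def test_hypergeometric_mean(self):
        # E[rarefied count] = depth * count/total
        counts = np.array([[40, 25, 35]])
        depth = 20
        total = 100
        expected = depth * counts[0] / total
        sims = np.zeros(3)
        n_rep = 1000
        for seed in range(n_rep):
            t = OtuTable(["s"], ["a", "b", "c"], counts)
            sims += rarefy(t, depth, seed=seed).counts[0]
        sims /= n_rep
        # hypergeometric variance for each feature
        var = depth * (counts[0] / total) * (1 - counts[0] / total) * (
            (total - depth) / (total - 1)
        )
        se = np.sqrt(var / n_rep)
        assert np.all(np.abs(sims - expected) < 3 * se + 1e-9)

    def test_idempotent_at_same_depth(self, rng):
        t = OtuTable(["s1"], [f"f{j}" for j in range(10)],
                     rng.integers(0, 100, size=(1, 10)))
        depth = int(t.depths()[0]) // 2
        r1 = rarefy(t, depth, seed=7)
        r2 = rarefy(r1, depth, seed=7)
        assert np.array_equal(r1.counts, r2.counts)


class TestAggregate:
    def test_same_genus_merged(self, tiny_table, tiny_taxonomy):
        g = aggregate_to_rank(tiny_table, tiny_taxonomy, "genus")
        assert g.feature_ids == ["GenusX"]
        assert np.array_equal(g.counts[:, 0], tiny_table.counts.sum(axis=1))

    def test_grand_total_preserved(self, rng):
        n, p = 4, 9
        t = OtuTable([f"s{i}" for i in range(n)], [f"o{j}" for j in range(p)],
                     rng.integers(0, 50, size=(n, p)))
        tax = TaxonomyMap({
            f"o{j}": ("Bacteria", f"P{j % 2}", "", "", "", f"G{j % 3}", "")
            for j in range(p)
        })
        g = aggregate_to_rank(t, tax, "genus")
        assert g.counts.sum() == t.counts.sum()

    def test_hand_phylum_aggregation(self):
        t = OtuTable(["s1"], ["o1", "o2", "o3"], np.array([[3, 4, 5]]))
        tax = TaxonomyMap({
            "o1": ("Bacteria", "Firmicutes"),
            "o2": ("Bacteria", "Bacteroidetes"),
            "o3": ("Bacteria", "Firmicutes"),
        })
        g = aggregate_to_rank(t, tax, "phylum")
        d = dict(zip(g.feature_ids, g.counts[0]))
        assert d == {"Firmicutes": 8, "Bacteroidetes": 4}

    def test_unassigned_pooled(self):
        t = OtuTable(["s1"], ["o1", "o2"], np.array([[3, 4]]))
        tax = TaxonomyMap({"o1": ("Bacteria",), "o2": ("Bacteria",)})
        g = aggregate_to_rank(t, tax, "genus")
        assert g.feature_ids == ["unassigned@genus"]
        assert g.counts[0, 0] == 7


class TestAlphaIndices:
    def test_uniform_closed_form(self):
        r = alpha_indices([25, 25, 25, 25])
        assert r.observed == 4
        assert r.shannon == pytest.approx(2.0)
        assert r.simpson == pytest.approx(0.75)
        assert r.dominance == pytest.approx(0.25)
        assert r.heip_e == pytest.approx(1.0)

    def test_chao1_hand_value(self):
        # F1=2, F2=1 -> chao1 = 5 + 4/2 = 7
        r = alpha_indices([10, 5, 2, 1, 1])
        assert r.chao1 == pytest.approx(7.0)

    def test_chao1_bias_corrected_when_no_doubletons(self):
        # F1=2, F2=0 -> S + F1(F1-1)/2 = 3 + 1 = 4
        r = alpha_indices([10, 1, 1])
        assert r.chao1 == pytest.approx(4.0)

    def test_ace_second_implementation(self):
        counts = [15, 5, 2, 1, 1]
        r = alpha_indices(counts)
        assert r.ace == pytest.approx(reference_ace(counts))

    @pytest.mark.parametrize("seed", range(5))
    def test_ace_random_vs_reference(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 40, size=20)
        counts[0] = 1  # ensure some rare structure
        r = alpha_indices(counts)
        if not math.isnan(r.ace):
            assert r.ace == pytest.approx(reference_ace(list(counts)))

    def test_ace_undefined_flagged(self):
        # all rare reads are singletons -> C_ace = 0 -> NaN
        r = alpha_indices([1, 1, 1])
        assert math.isnan(r.ace)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            alpha_indices([0, 0])

    def test_dominance_complement_and_bounds_random(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            c = rng.integers(0, 50, size=rng.integers(2, 30))
            if c.sum() == 0:
                continue
            r = alpha_indices(c)
            assert r.dominance == pytest.approx(1 - r.simpson, abs=1e-12)
            assert r.chao1 >= r.observed - 1e-9
            if not math.isnan(r.ace):
                assert r.ace >= r.observed - 1e-6
            assert r.shannon <= math.log2(max(r.observed, 1)) + 1e-9

    @given(st.lists(st.integers(min_value=0, max_value=200), min_size=2,
                    max_size=40).filter(lambda c: sum(c) > 0))
    @settings(max_examples=200, deadline=None)
    def test_permutation_invariance(self, counts):
        r1 = alpha_indices(counts)
        r2 = alpha_indices(list(reversed(counts)))
        for fld in ("observed", "chao1", "shannon", "simpson", "dominance"):
            a, b = getattr(r1, fld), getattr(r2, fld)
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestCompareAlpha:
    def test_identical_groups(self):
        t = OtuTable(
            [f"s{i}" for i in range(4)], ["a", "b"],
            np.array([[10, 5], [10, 5], [10, 5], [10, 5]]),
        )
        at = alpha_table(t)
        res = compare_alpha(at, ["case", "case", "control", "control"])
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_hand_t_statistic(self):
        import pandas as pd

        a = [1.0, 2.0, 3.0]
        b = [2.0, 4.0, 6.0]
        at = pd.DataFrame({"observed": a + b},
                          index=[f"s{i}" for i in range(6)])
        res = compare_alpha(at, ["case"] * 3 + ["control"] * 3)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t_hand = (ma - mb) / math.sqrt(va / 3 + vb / 3)
        assert res.loc["observed", "t"] == pytest.approx(t_hand)
        assert res.loc["observed", "higher_in"] == "control"

    def test_shifted_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        import pandas as pd

        a = rng.normal(0, 1, 70)
        b = rng.normal(5, 1, 70)
        at = pd.DataFrame({"observed": np.r_[a, b]},
                          index=[f"s{i}" for i in range(140)])
        res = compare_alpha(at, ["case"] * 70 + ["control"] * 70)
        assert res.loc["observed", "p"] < 1e-6

    def test_group_of_one_errors(self):
        import pandas as pd

        at = pd.DataFrame({"observed": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(Exception):
            compare_alpha(at, ["case", "control", "control"])


class TestRarefactionCurve:
    def test_depth_one(self):
        t = OtuTable(["s1"], ["a", "b"], np.array([[50, 50]]))
        df = rarefaction_curve(t, [1])
        assert df.iloc[0, 0] == pytest.approx(1.0)

    def test_full_depth_gives_richness(self):
        t = OtuTable(["s1"], ["a", "b", "c"], np.array([[5, 3, 2]]))
        df = rarefaction_curve(t, [10])
        assert df.iloc[0, 0] == pytest.approx(3.0)

    def test_monotone_in_depth(self, rng):
        t = OtuTable(["s1"], [f"f{j}" for j in range(30)],
                     rng.integers(0, 100, size=(1, 30)))
        total = int(t.depths()[0])
        depths = [total // 10, total // 4, total // 2, total]
        df = rarefaction_curve(t, depths)
        vals = df.iloc[0].to_numpy()
        assert np.all(np.diff(vals) >= -1e-9)

    def test_analytic_vs_monte_carlo(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 60, size=(1, 15))
        t = OtuTable(["s1"], [f"f{j}" for j in range(15)], counts)
        depth = int(t.depths()[0]) // 3
        exact = _expected_observed(counts[0], depth)
        reps = 600
        mc = rarefaction_curve(t, [depth], reps=reps, seed=0).iloc[0, 0]
        # per-draw variance of observed count is at most richness^2/4
        s_max = (counts > 0).sum()
        se = s_max / 2 / np.sqrt(reps)
        assert abs(mc - exact) < 3 * se

    def test_non_ascending_depths_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            rarefaction_curve(tiny_table, [10, 5])
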