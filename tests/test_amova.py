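"""AMOVA R_ST: QC filter, repeat distances, variance components against a
from-scratch enumeration oracle, permutation tests, and the full matrix."""

import itertools
import math

import numpy as np
import pytest

from ystrkit import (
    RstConfig,
    SimConfig,
    ValidationError,
    bonferroni_threshold,
    filter_for_rst,
    pairwise_rst,
    permutation_p,
    rst_distance,
    rst_matrix,
    simulate_populations,
)
from ystrkit.amova import variance_components

from conftest import hap, make_dataset


# ---------------------------------------------------------------------------
# independent oracle: variance components from explicit pairwise-distance sums
# ---------------------------------------------------------------------------

def brute_force_rst(records_a, records_b, loci):
    """Two-group R_ST from first principles: explicit SSD enumeration."""

    def dist(r1, r2):
        total = 0.0
        for ld in loci:
            for x, y in zip(sorted(r1.haplotype[ld.name]), sorted(r2.haplotype[ld.name])):
                total += (x.value - y.value) ** 2
        return total

    pooled = list(records_a) + list(records_b)
    n = len(pooled)
    n_a, n_b = len(records_a), len(records_b)
    ssd_total = sum(dist(a, b) for a, b in itertools.combinations(pooled, 2)) / n
    ssd_a = sum(dist(a, b) for a, b in itertools.combinations(records_a, 2)) / n_a
    ssd_b = sum(dist(a, b) for a, b in itertools.combinations(records_b, 2)) / n_b
    ssd_within = ssd_a + ssd_b
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n - 2)
    n_c = (n - (n_a**2 + n_b**2) / n)  # df_among = 1
    sigma_a = (ssd_among - sigma_w) / n_c
    if ssd_total == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


class TestFilter:
    def test_clean_dataset_unchanged(self, toy_dataset):
        out, log = filter_for_rst(toy_dataset)
        assert out.n == toy_dataset.n and log == []

    @pytest.mark.parametrize(
        "overrides,reason",
        [
            ({"DYS448": "0"}, "null"),
            ({"DYS385": ("16.2", 17)}, "intermediate"),
            ({"DYS385": (13, 14, 17)}, "copy_number_variant"),
        ],
    )
    def test_removal_reasons(self, overrides, reason):
        rows = [(f"s{i}", "p", {}) for i in range(3)] + [("bad", "p", overrides)]
        ds = make_dataset(rows)
        if reason == "copy_number_variant":
            from dataclasses import replace
            ds.records[-1] = replace(ds.records[-1], cnv_loci=frozenset({"DYS385"}))
        out, log = filter_for_rst(ds)
        assert ("bad", reason) in log
        assert out.n == 3

    def test_depleted_population_errors(self):
        rows = [("a", "tiny", {"DYS448": "0"}), ("b", "tiny", {}),
                ("c", "big", {}), ("d", "big", {})]
        with pytest.raises(ValidationError, match="tiny"):
            filter_for_rst(make_dataset(rows))


class TestRstDistance:
    def test_identical_is_zero(self):
        h = hap()
        assert rst_distance(h, h, make_dataset([("a", "p", {})]).loci) == 0.0

    def test_two_locus_arithmetic(self):
        loci = make_dataset([("a", "p", {})]).loci
        h1, h2 = hap(), hap(DYS19=15, DYS391=12)  # differs by 1 and 2 repeats
        assert rst_distance(h1, h2, loci) == 1 + 4

    def test_dys385_sorted_positional_pairing(self):
        loci = make_dataset([("a", "p", {})]).loci
        assert rst_distance(hap(DYS385=(13, 17)), hap(DYS385=(14, 17)), loci) == 1.0
        # input order of the pair is irrelevant
        assert rst_distance(hap(DYS385=(17, 13)), hap(DYS385=(17, 14)), loci) == 1.0

    def test_arity_mismatch_errors(self):
        loci = make_dataset([("a", "p", {})]).loci
        h1, h2 = hap(), hap()
        h2 = dict(h2)
        h2["DYS385"] = h2["DYS385"] + (h2["DYS385"][0],)
        with pytest.raises(ValidationError, match="arity"):
            rst_distance(h1, h2, loci)


class TestPairwiseRst:
    def test_identical_multisets_nonpositive(self):
        rows_a = [(f"a{i}", "A", {"DYS19": 14 + (i % 2)}) for i in range(4)]
        rows_b = [(f"b{i}", "B", {"DYS19": 14 + (i % 2)}) for i in range(4)]
        ds = make_dataset(rows_a + rows_b)
        pops = ds.by_population()
        assert pairwise_rst(pops["A"], pops["B"], ds.loci) <= 1e-12

    def test_internally_fixed_distinct_pops_give_one(self):
        rows = [(f"a{i}", "A", {}) for i in range(3)] + [
            (f"b{i}", "B", {"DYS19": 18}) for i in range(3)
        ]
        ds = make_dataset(rows)
        pops = ds.by_population()
        assert pairwise_rst(pops["A"], pops["B"], ds.loci) == 1.0

    def test_zero_total_variance_returns_zero(self):
        rows = [(f"{p}{i}", p, {}) for p in "AB" for i in range(3)]
        ds = make_dataset(rows)
        pops = ds.by_population()
        assert pairwise_rst(pops["A"], pops["B"], ds.loci) == 0.0

    def test_matches_brute_force_on_toy_data(self):
        rows = (
            [("a1", "A", {"DYS19": 14}), ("a2", "A", {"DYS19": 15}), ("a3", "A", {"DYS391": 11})]
            + [("b1", "B", {"DYS19": 17}), ("b2", "B", {"DYS19": 16, "DYS385": (13, 19)}),
               ("b3", "B", {})]
        )
        ds = make_dataset(rows)
        pops = ds.by_population()
        got = pairwise_rst(pops["A"], pops["B"], ds.loci)
        want = brute_force_rst(pops["A"], pops["B"], ds.loci)
        assert got == pytest.approx(want, abs=1e-12)

    def test_symmetry_and_order_invariance(self):
        ds = simulate_populations(SimConfig(n_pops=2, pop_sizes=(6, 5), seed=11))
        pops = ds.by_population()
        r_ab = pairwise_rst(pops["pop1"], pops["pop2"], ds.loci)
        r_ba = pairwise_rst(pops["pop2"], pops["pop1"], ds.loci)
        assert r_ab == pytest.approx(r_ba, abs=1e-12)
        r_shuffled = pairwise_rst(list(reversed(pops["pop1"])), pops["pop2"], ds.loci)
        assert r_ab == pytest.approx(r_shuffled, abs=1e-12)


class TestPermutation:
    def test_minimum_attainable_p(self):
        rows = [(f"a{i}", "A", {}) for i in range(14)] + [
            (f"b{i}", "B", {"DYS19": 19}) for i in range(14)
        ]
        ds = make_dataset(rows)
        pops = ds.by_population()
        _, p = permutation_p(pops["A"], pops["B"], ds.loci, n_permutations=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_reproducible_for_fixed_seed(self):
        ds = simulate_populations(SimConfig(n_pops=2, pop_sizes=(8, 8), seed=5))
        pops = ds.by_population()
        out1 = permutation_p(pops["pop1"], pops["pop2"], ds.loci, 199, seed=9)
        out2 = permutation_p(pops["pop1"], pops["pop2"], ds.loci, 199, seed=9)
        assert out1 == out2

    def test_too_few_permutations_rejected(self):
        ds = simulate_populations(SimConfig(n_pops=2, pop_sizes=(4, 4), seed=5))
        pops = ds.by_population()
        with pytest.raises(ValidationError):
            permutation_p(pops["pop1"], pops["pop2"], ds.loci, n_permutations=50)

    def test_split_panmictic_mean_rst_near_zero(self):
        """E[R_ST] ~ 0 when one population is split at random."""
        rng = np.random.default_rng(0)
        vals = []
        for rep in range(100):
            ds = simulate_populations(
                SimConfig(n_pops=1, pop_sizes=(20,), generations=0,
                          within_generations=150, mu=0.004, seed=3000 + rep)
            )
            recs = list(ds.records)
            perm = rng.permutation(len(recs))
            group_a = [recs[i] for i in perm[:10]]
            group_b = [recs[i] for i in perm[10:]]
            vals.append(pairwise_rst(group_a, group_b, ds.loci))
        assert abs(np.mean(vals)) < 0.01


class TestRstMatrix:
    def test_pair_count_and_shape(self):
        ds = simulate_populations(
            SimConfig(n_pops=4, pop_sizes=(6, 6, 6, 6), seed=21)
        )
        res = rst_matrix(ds, RstConfig(n_permutations=99, seed=1))
        assert res.n_comparisons == math.comb(4, 2)
        assert np.allclose(res.rst, res.rst.T) and np.allclose(res.pvals, res.pvals.T)
        assert np.all(np.diag(res.rst) == 0)
        assert res.bonferroni_threshold == pytest.approx(0.05 / 6)

    def test_bonferroni_override(self):
        ds = simulate_populations(SimConfig(n_pops=3, pop_sizes=(5, 5, 5), seed=2))
        res = rst_matrix(ds, RstConfig(n_permutations=99, seed=1, bonferroni_m=55))
        assert res.bonferroni_threshold == pytest.approx(0.05 / 55)

    def test_nineteen_population_threshold(self):
        assert round(bonferroni_threshold(19), 4) == 0.0003

    def test_filtered_counts_recorded(self):
        rows = [(f"a{i}", "A", {"DYS19": 14 + i % 3}) for i in range(5)] + [
            (f"b{i}", "B", {"DYS19": 16 + i % 3}) for i in range(5)
        ]
        rows.append(("dropme", "A", {"DYS448": "0"}))
        ds = make_dataset(rows)
        res = rst_matrix(ds, RstConfig(n_permutations=99, seed=0))
        assert res.filtered_counts == {"A": 1, "B": 0}
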