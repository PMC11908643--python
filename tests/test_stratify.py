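"""Stratification (CA / PP), apportionment and stratified sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ssblend.dataio import GenotypeMatrix, PhenotypeVector
from ssblend.exceptions import DegeneratePhenotypeError, SizeError
from ssblend.stratify import (
    StrataAssignment,
    StratifyConfig,
    largest_remainder,
    random_sample,
    stratified_sample,
    stratify_ca,
    stratify_pp,
)


def _geno(dosages):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(sample_ids=[f"S{i}" for i in range(n)],
                          marker_ids=[f"M{j}" for j in range(m)],
                          dosages=dosages)


def _pheno(values):
    values = np.asarray(values, dtype=float)
    return PhenotypeVector(sample_ids=[f"S{i}" for i in range(values.size)],
                           values=values)


class TestLargestRemainder:
    def test_proportional_example(self):
        # ideal shares (3.0, 2.0) -> exact
        np.testing.assert_array_equal(largest_remainder(5, np.array([0.6, 0.4])),
                                      [3, 2])

    def test_tie_breaks_to_lower_index(self):
        # ideal shares (4.5, 0.5): one leftover unit, equal remainders
        np.testing.assert_array_equal(largest_remainder(5, np.array([0.9, 0.1])),
                                      [5, 0])

    @settings(max_examples=60, deadline=None)
    @given(total=st.integers(0, 200),
           weights=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=12))
    def test_sums_to_total_and_stays_within_one_of_ideal(self, total, weights):
        w = np.asarray(weights)
        q = largest_remainder(total, w)
        assert q.sum() == total
        ideal = w / w.sum() * total
        assert np.all(np.abs(q - ideal) < 1.0)


class TestStratifyCA:
    def test_recovers_separated_blobs(self):
        dosages = np.vstack([np.zeros((6, 10)), np.full((4, 10), 2.0)])
        assignment = stratify_ca(_geno(dosages), StratifyConfig(strategy="ca", k=2, seed=0))
        labels = assignment.labels
        assert np.unique(labels[:6]).size == 1
        assert np.unique(labels[6:]).size == 1
        assert labels[0] != labels[-1]
        # proportional allocation: weights reflect the 6/4 split
        np.testing.assert_allclose(sorted(assignment.weights), [0.4, 0.6])

    def test_single_stratum_identity(self, rng):
        dosages = rng.integers(0, 3, size=(12, 5)).astype(float)
        assignment = stratify_ca(_geno(dosages), StratifyConfig(strategy="ca", k=1, seed=0))
        assert assignment.k == 1
        assert np.all(assignment.labels == 1)
        np.testing.assert_allclose(assignment.weights, [1.0])

    def test_eight_layers_partition_everyone(self, small_dataset):
        assignment = stratify_ca(small_dataset.G, StratifyConfig(strategy="ca", k=8, seed=1))
        assert 1 <= assignment.k <= 8
        assert assignment.occupied.sum() == small_dataset.G.n_samples
        assert np.all(assignment.occupied > 0)

    def test_more_strata_than_samples_rejected(self, rng):
        dosages = rng.integers(0, 3, size=(5, 4)).astype(float)
        with pytest.raises(SizeError):
            stratify_ca(_geno(dosages), StratifyConfig(strategy="ca", k=6, seed=0))

    def test_deterministic_under_seed(self, small_dataset):
        cfg = StratifyConfig(strategy="ca", k=4, seed=5)
        a = stratify_ca(small_dataset.G, cfg)
        b = stratify_ca(small_dataset.G, cfg)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_top_variance_filter_runs(self, small_dataset):
        cfg = StratifyConfig(strategy="ca", k=3, seed=2, ca_top_variance_markers=50)
        assignment = stratify_ca(small_dataset.G, cfg)
        assert assignment.occupied.sum() == small_dataset.G.n_samples


class TestStratifyPP:
    def test_equal_width_split_of_evenly_spaced_values(self):
        assignment = stratify_pp(_pheno(np.arange(10.0)),
                                 StratifyConfig(strategy="pp", k=2))
        np.testing.assert_array_equal(assignment.occupied, [5, 5])
        # intervals [0, 4.5) and [4.5, 9]
        np.testing.assert_array_equal(assignment.labels,
                                      [1, 1, 1, 1, 1, 2, 2, 2, 2, 2])

    def test_maximum_lands_in_last_interval(self):
        assignment = stratify_pp(_pheno([0.0, 1.0, 2.0, 3.0]),
                                 StratifyConfig(strategy="pp", k=4))
        assert assignment.labels[-1] == assignment.k

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=60, unique=True),
           st.integers(1, 8))
    def test_interval_probabilities_renormalized(self, values, k):
        assignment = stratify_pp(_pheno(values), StratifyConfig(strategy="pp", k=k))
        assert assignment.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(assignment.weights >= 0)
        assert assignment.occupied.sum() == len(values)

    def test_central_intervals_carry_most_mass_for_normal_trait(self):
        y = np.random.default_rng(21).standard_normal(2000)
        assignment = stratify_pp(_pheno(y), StratifyConfig(strategy="pp", k=8))
        k = assignment.k
        w = assignment.weights
        central = {np.argsort(w)[-1], np.argsort(w)[-2]}
        # the two heaviest intervals are the two middle ones
        assert central == {k // 2 - 1, k // 2}

    def test_integrated_mass_matches_quadrature_oracle(self):
        """Midpoint-rule masses agree with scipy quadrature of the same KDE."""
        from scipy.integrate import quad

        y = np.random.default_rng(3).normal(size=400)
        cfg = StratifyConfig(strategy="pp", k=4, pp_grid_points=4000)
        assignment = stratify_pp(_pheno(y), cfg)
        kde = stats.gaussian_kde(y, bw_method="silverman")
        edges = np.linspace(y.min(), y.max(), 5)
        oracle = np.array([quad(lambda x: float(kde(x)[0]),
                                edges[i], edges[i + 1])[0] for i in range(4)])
        oracle /= oracle.sum()
        np.testing.assert_allclose(assignment.weights, oracle, atol=1e-3)

    def test_empirical_count_mode(self):
        y = np.concatenate([np.zeros(8) + np.arange(8) * 0.01, [10.0, 10.1]])
        cfg = StratifyConfig(strategy="pp", k=2, pp_empirical_counts=True)
        assignment = stratify_pp(_pheno(y), cfg)
        np.testing.assert_allclose(assignment.weights, [0.8, 0.2])

    def test_constant_phenotype_rejected(self):
        with pytest.raises(DegeneratePhenotypeError):
            stratify_pp(_pheno(np.ones(10)), StratifyConfig(strategy="pp", k=3))


class TestStratifiedSample:
    def test_single_stratum_reduces_to_simple_random_sampling(self):
        assignment = StrataAssignment(labels=np.ones(10, dtype=int),
                                      weights=np.array([1.0]))
        picked = stratified_sample(assignment, 0.3, seed=4)
        assert picked.size == 3
        np.testing.assert_array_equal(picked, random_sample(10, 0.3, seed=4))

    def test_proportional_quotas(self):
        labels = np.array([1] * 6 + [2] * 4)
        assignment = StrataAssignment(labels=labels, weights=np.array([0.6, 0.4]))
        picked = stratified_sample(assignment, 0.5, seed=0)
        assert picked.size == 5
        assert (picked < 6).sum() == 3 and (picked >= 6).sum() == 2

    def test_quota_capped_and_redistributed(self):
        """A stratum with huge weight but tiny occupancy saturates; the
        overflow moves to the other stratum (quotas {2, 3})."""
        labels = np.array([1, 1] + [2] * 8)
        assignment = StrataAssignment(labels=labels, weights=np.array([0.9, 0.1]))
        picked = stratified_sample(assignment, 0.5, seed=0)
        assert picked.size == 5
        assert (picked < 2).sum() == 2 and (picked >= 2).sum() == 3

    @settings(max_examples=40, deadline=None)
    @given(occupied=st.lists(st.integers(1, 15), min_size=1, max_size=6),
           h_pct=st.integers(10, 90), seed=st.integers(0, 10_000))
    def test_exact_size_property(self, occupied, h_pct, seed):
        """|holdout| = round(H*n) for arbitrary assignments and rates."""
        rng = np.random.default_rng(seed)
        labels = np.concatenate([np.full(c, s + 1) for s, c in enumerate(occupied)])
        weights = rng.uniform(0.05, 1.0, size=len(occupied))
        assignment = StrataAssignment(labels=labels.astype(int), weights=weights)
        H = h_pct / 100
        n = labels.size
        T = int(round(H * n))
        if T < 1:
            return
        picked = stratified_sample(assignment, H, seed=seed)
        assert picked.size == T
        assert np.unique(picked).size == T

    def test_deterministic_under_seed(self):
        labels = np.array([1, 1, 1, 2, 2, 2, 2, 3, 3, 3])
        assignment = StrataAssignment(labels=labels, weights=np.array([0.3, 0.4, 0.3]))
        a = stratified_sample(assignment, 0.4, seed=77)
        b = stratified_sample(assignment, 0.4, seed=77)
        np.testing.assert_array_equal(a, b)

    def test_oversized_target_rejected(self):
        with pytest.raises((SizeError, ValueError)):
            random_sample(10, 1.2, seed=0)


class TestRandomSample:
    def test_size_contract(self):
        assert random_sample(20, 0.25, seed=0).size == 5

    def test_deterministic(self):
        np.testing.assert_array_equal(random_sample(30, 0.5, seed=3),
                                      random_sample(30, 0.5, seed=3))

    def test_all_subsets_reachable_uniformly(self):
        """n=8, H=0.5: all C(8,4)=70 subsets occur ~ uniformly (chi-square)."""
        from itertools import combinations

        index = {c: i for i, c in enumerate(combinations(range(8), 4))}
        counts = np.zeros(70)
        n_draws = 7000
        for seed in range(n_draws):
            counts[index[tuple(random_sample(8, 0.5, seed=seed))]] += 1
        assert counts.min() > 0
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3
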