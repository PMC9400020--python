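"""Ewens, Dirichlet-multinomial and joint MSN likelihood against
independent enumeration oracles."""

import itertools

import numpy as np
import pytest
from sympy.utilities.iterables import partitions

from nichedrift import (
    MetacommunitySample,
    dirmult_log_prob,
    ewens_log_prob,
    msn_log_likelihood,
)


def all_partitions(n):
    """Partitions of n as tuples of part sizes (ascending)."""
    for p in partitions(n):
        yield tuple(sorted(k for k, mult in p.items() for _ in range(mult)))


def crp_partition_probs(n, theta):
    """Brute-force CRP: enumerate every seating path of n customers and
    accumulate path probabilities by the resulting size multiset."""
    acc = {}

    def recurse(sizes, prob, i):
        if i == n:
            key = tuple(sorted(sizes))
            acc[key] = acc.get(key, 0.0) + prob
            return
        denom = theta + i
        for t in range(len(sizes)):
            recurse(sizes[:t] + [sizes[t] + 1] + sizes[t + 1:],
                    prob * sizes[t] / denom, i + 1)
        recurse(sizes + [1], prob * theta / denom, i + 1)

    recurse([], 1.0, 0)
    return acc


def polya_composition_prob(counts, props, I):
    """Brute-force Polya urn: sum sequential-draw probabilities over every
    ordered sequence realizing ``counts``."""
    counts = tuple(counts)
    J = sum(counts)
    S = len(counts)
    total = 0.0
    for seq in itertools.product(range(S), repeat=J):
        if tuple(seq.count(s) for s in range(S)) != counts:
            continue
        prob, seen = 1.0, [0] * S
        for pos, s in enumerate(seq):
            prob *= (I * props[s] + seen[s]) / (I + pos)
            seen[s] += 1
        total += prob
    return total


class TestEwens:
    def test_single_individual_is_certain(self):
        assert ewens_log_prob([1], 7.3) == pytest.approx(0.0)

    def test_three_singletons_theta_two(self):
        # sequential CRP construction: (2/2)(2/3)(2/4) = 1/3
        assert ewens_log_prob([1, 1, 1], 2.0) == pytest.approx(np.log(1 / 3))

    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_partition_probabilities_sum_to_one(self, n, theta):
        total = sum(np.exp(ewens_log_prob(p, theta)) for p in all_partitions(n))
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("theta", [1.5, 4.0])
    def test_matches_crp_enumeration(self, theta):
        oracle = crp_partition_probs(5, theta)
        for config, prob in oracle.items():
            assert ewens_log_prob(config, theta) == pytest.approx(
                np.log(prob), abs=1e-10
            )

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ewens_log_prob([], 1.0)
        with pytest.raises(ValueError):
            ewens_log_prob([2, 1], 0.0)
        with pytest.raises(ValueError):
            ewens_log_prob([2, 0], 1.0)


class TestDirichletMultinomial:
    def test_single_taxon_certain(self):
        assert dirmult_log_prob([3], [1.0], 5.0) == pytest.approx(0.0)

    def test_two_taxa_hand_computation(self):
        # Polya urn: 2 * Gamma(2)/Gamma(4) * (Gamma(2)/Gamma(1))^2 = 1/3
        assert dirmult_log_prob([1, 1], [0.5, 0.5], 2.0) == pytest.approx(
            np.log(1 / 3)
        )

    def test_large_I_approaches_multinomial(self):
        from scipy.stats import multinomial

        lp = dirmult_log_prob([5, 5], [0.5, 0.5], 1e6)
        assert lp == pytest.approx(multinomial.logpmf([5, 5], 10, [0.5, 0.5]),
                                   abs=1e-3)

    def test_zero_prop_with_count_impossible(self):
        assert dirmult_log_prob([1, 1], [1.0, 0.0], 2.0) == -np.inf

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            dirmult_log_prob([1, 1, 1], [0.5, 0.5], 2.0)

    @pytest.mark.parametrize("J,S", [(4, 2), (6, 3), (5, 3)])
    def test_compositions_sum_to_one(self, J, S):
        props = np.array([0.5, 0.3, 0.2])[:S]
        props = props / props.sum()
        total = 0.0
        for comp in itertools.product(range(J + 1), repeat=S):
            if sum(comp) == J:
                total += np.exp(dirmult_log_prob(list(comp), props, 1.7))
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("counts,props,I", [
        ((2, 1, 1), (0.5, 0.3, 0.2), 2.5),
        ((4, 0, 1), (0.2, 0.3, 0.5), 0.8),
    ])
    def test_matches_polya_enumeration(self, counts, props, I):
        oracle = polya_composition_prob(counts, props, I)
        assert dirmult_log_prob(counts, props, I) == pytest.approx(
            np.log(oracle), abs=1e-10
        )


class TestJointLikelihood:
    def test_additive_decomposition(self, tiny_sample):
        props = np.array([0.3, 0.4, 0.3])
        I = [2.0, 3.0]
        expected = ewens_log_prob(tiny_sample.species_totals(), 1.5)
        for i in range(2):
            expected += dirmult_log_prob(tiny_sample.counts[i], props, I[i])
        assert msn_log_likelihood(tiny_sample, 1.5, I, props) == pytest.approx(
            expected
        )

    def test_single_site_single_taxon(self):
        sample = MetacommunitySample(["a"], np.array([[4]]))
        lp = msn_log_likelihood(sample, 2.0, [3.0], [1.0])
        assert lp == pytest.approx(ewens_log_prob([4], 2.0))

    def test_matches_full_enumeration_oracle(self):
        """2 sites x 3 taxa, J=4 each: Ewens term from CRP path enumeration,
        local terms from Polya sequence enumeration."""
        counts = np.array([[2, 1, 1], [0, 3, 1]])
        sample = MetacommunitySample(["a", "b"], counts)
        props = np.array([0.25, 0.45, 0.30])
        I = [1.3, 2.6]
        theta = 1.9
        totals = tuple(sorted(counts.sum(axis=0)))  # (2, 4, 2) sorted
        oracle = np.log(crp_partition_probs(8, theta)[totals])
        for i in range(2):
            oracle += np.log(polya_composition_prob(tuple(counts[i]), props, I[i]))
        assert msn_log_likelihood(sample, theta, I, props) == pytest.approx(
            oracle, abs=1e-9
        )
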