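"""Niche-neutral hybrid model: expected SAD, octave binning, per-niche
fitting and the combined metacommunity test."""

import numpy as np
import pytest

from nichedrift import (
    NicheAssignment,
    fit_nnh_niche,
    nnh_expected_sad,
    nnh_meta_test,
    preston_octaves,
    simulate_neutral_metacommunity,
)


class TestExpectedSad:
    def test_phi1_is_theta_x(self):
        for gamma in (0.2, 1.3, 9.0):
            assert nnh_expected_sad(12.0, 0.8, gamma, 1) == pytest.approx(9.6)

    def test_log_series_limit(self):
        # gamma -> 0 recovers Fisher's log series theta x^n / n
        assert nnh_expected_sad(10.0, 0.5, 1e-8, 2) == pytest.approx(
            1.25, abs=1e-6
        )
        n = np.arange(1, 200)
        total = nnh_expected_sad(10.0, 0.5, 1e-8, n).sum()
        assert total == pytest.approx(-10.0 * np.log(0.5), abs=1e-3)

    def test_positive_and_monotone_in_theta_and_x(self):
        n = np.arange(1, 50)
        base = nnh_expected_sad(10.0, 0.7, 1.3, n)
        assert np.all(base > 0)
        np.testing.assert_allclose(
            nnh_expected_sad(20.0, 0.7, 1.3, n), 2 * base, rtol=1e-12
        )
        assert np.all(nnh_expected_sad(10.0, 0.75, 1.3, n) > base)

    def test_series_converges_for_x_below_one(self):
        n = np.arange(1, 20_000)
        phi = nnh_expected_sad(5.0, 0.97, 2.0, n)
        assert phi[-1] < 1e-12 * phi.sum()

    def test_rejects_divergent_x(self):
        with pytest.raises(ValueError):
            nnh_expected_sad(10.0, 1.0, 1.3, 1)


class TestOctaves:
    def test_examples_and_invariance(self):
        np.testing.assert_array_equal(preston_octaves([1]), [1])
        np.testing.assert_array_equal(
            preston_octaves([1, 2, 3, 4, 7, 8]), [1, 2, 2, 1]
        )
        rng = np.random.default_rng(0)
        ab = rng.integers(1, 300, size=40)
        np.testing.assert_array_equal(
            preston_octaves(ab), preston_octaves(rng.permutation(ab))
        )

    def test_conserves_species(self):
        ab = np.array([1, 1, 2, 9, 33, 260])
        assert preston_octaves(ab).sum() == ab.size

    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError):
            preston_octaves([1, 0, 2])


class TestNicheFit:
    def test_too_few_octaves_excluded(self):
        fit = fit_nnh_niche([1, 2, 3, 5])  # 3 occupied octaves
        assert not fit.included

    def test_self_consistency_on_model_octaves(self):
        """Octave counts equal to rounded model expectations are recovered
        nearly perfectly."""
        from nichedrift.nnh import _octave_log_expected

        expected = np.exp(_octave_log_expected(np.log(12.0), 0.8, 1.3, 8))
        obs = np.round(expected).astype(int)
        abundances = np.repeat(2 ** np.arange(8), obs)
        fit = fit_nnh_niche(abundances)
        assert fit.included
        assert fit.R2 >= 0.99
        assert fit.p > 0.05

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(8)
        ab = np.repeat(np.arange(1, 400),
                       rng.poisson(nnh_expected_sad(12.0, 0.8, 1.3,
                                                    np.arange(1, 400))))
        a, b = fit_nnh_niche(ab), fit_nnh_niche(ab)
        assert (a.theta, a.x, a.gamma) == (b.theta, b.x, b.gamma)

    def test_parameter_recovery(self):
        """x within +-0.1 (and theta within +-40%) in >= 7 of 10 seeds for
        Poisson samples of the expected SAD."""
        ok_x = ok_theta = 0
        n = np.arange(1, 3000)
        phi = nnh_expected_sad(12.0, 0.8, 1.3, n)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ab = np.repeat(n, rng.poisson(phi))
            fit = fit_nnh_niche(ab)
            if fit.included and abs(fit.x - 0.8) <= 0.1:
                ok_x += 1
            if fit.included and abs(fit.theta - 12.0) <= 0.4 * 12:
                ok_theta += 1
        assert ok_x >= 7
        assert ok_theta >= 5


class TestMetaTest:
    def test_additivity_and_pass_counts(self, neutral_sample):
        res = nnh_meta_test(neutral_sample)
        inc = [f for f in res.per_niche if f.included]
        assert res.chi2_total == pytest.approx(sum(f.chi2 for f in inc))
        assert res.df_total == sum(f.df for f in inc)
        assert res.N == len(inc)
        assert res.N_pass <= res.N

    def test_assignment_must_cover_sites(self, neutral_sample):
        with pytest.raises(ValueError):
            nnh_meta_test(neutral_sample, NicheAssignment({"site0": 0}))

    def test_neutral_bank_passes_nesting(self):
        """A purely neutral metacommunity is inside the hybrid family."""
        rng = np.random.default_rng(11)
        sample = simulate_neutral_metacommunity(
            30.0, np.full(10, 20.0), np.full(10, 2000), rng
        )
        assert nnh_meta_test(sample).pass_meta

    def test_grouped_assignment_pools_niches(self, neutral_sample):
        sites = neutral_sample.site_ids
        grouped = NicheAssignment({s: (0 if i < 3 else 1)
                                   for i, s in enumerate(sites)})
        res = nnh_meta_test(neutral_sample, grouped)
        assert len(res.per_niche) == 2
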