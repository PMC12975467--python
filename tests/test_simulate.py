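"""Synthetic taxonic/dimensional generators, matched pairs and presets."""

import numpy as np
import pytest
from scipy import stats

import taxometrics as tx


class TestSimulateTaxonic:
    def test_exact_taxon_count(self):
        spec = tx.SyntheticSpec("taxonic", n=600, k=3, base_rate=0.25)
        _, flags = tx.simulate_taxonic(spec, 0)
        assert flags.sum() == 150

    def test_same_seed_bitwise_identical(self, taxonic_spec):
        m1, f1 = tx.simulate_taxonic(taxonic_spec, 42)
        m2, f2 = tx.simulate_taxonic(taxonic_spec, 42)
        np.testing.assert_array_equal(m1.values, m2.values)
        np.testing.assert_array_equal(f1, f2)

    def test_realized_separation_matches_spec(self):
        spec = tx.SyntheticSpec("taxonic", n=2000, k=3, base_rate=0.25,
                                separation=2.0, within_r=0.1)
        ds = []
        for seed in range(20):
            m, flags = tx.simulate_taxonic(spec, seed)
            groups = tx.Membership(flags, int(flags.sum()))
            ds.append(tx.cohens_d(m, groups))
        np.testing.assert_allclose(np.mean(ds, axis=0), 2.0, atol=0.2)

    def test_zero_separation_groups_indistinguishable(self):
        # calibration: with d = 0 a location test between true groups
        # should reject at alpha = 0.01 only at the nominal rate
        spec = tx.SyntheticSpec("taxonic", n=600, k=3, base_rate=0.25,
                                separation=0.0, within_r=0.1)
        nonsig = 0
        for seed in range(20):
            m, flags = tx.simulate_taxonic(spec, seed)
            tax = m.values[flags == 1].sum(axis=1)
            comp = m.values[flags == 0].sum(axis=1)
            _, p = stats.ttest_ind(tax, comp)
            nonsig += p > 0.01
        assert nonsig >= 18

    def test_strong_separation_bimodal(self):
        # bimodality coefficient (g1^2+1)/(g2+3) exceeds the normal
        # unimodal reference value 1/3 when the mixture separates groups
        spec = tx.SyntheticSpec("taxonic", n=2000, k=3, base_rate=0.25,
                                separation=2.0, within_r=0.0)
        hits = 0
        for seed in range(20):
            m, _ = tx.simulate_taxonic(spec, seed)
            g1 = stats.skew(m.values, axis=0)
            g2 = stats.kurtosis(m.values, axis=0)
            bc = (g1**2 + 1) / (g2 + 3)
            hits += np.all(bc > 1 / 3)
        assert hits >= 18


class TestSimulateDimensional:
    def test_zero_loadings_uncorrelated(self):
        spec = tx.SyntheticSpec("dimensional", n=1000, k=3,
                                loadings=(0.0, 0.0, 0.0))
        m = tx.simulate_dimensional(spec, 1)
        R = np.corrcoef(m.values, rowvar=False)
        assert np.max(np.abs(R[np.triu_indices(3, 1)])) <= 0.1

    def test_loading_product_correlations(self):
        spec = tx.SyntheticSpec("dimensional", n=2000, k=3,
                                loadings=(0.7, 0.7, 0.7))
        m = tx.simulate_dimensional(spec, 2)
        R = np.corrcoef(m.values, rowvar=False)
        np.testing.assert_allclose(R[np.triu_indices(3, 1)], 0.49, atol=0.08)

    def test_requires_loadings(self):
        spec = tx.SyntheticSpec("dimensional", n=100, k=3)
        with pytest.raises(ValueError, match="loadings"):
            tx.simulate_dimensional(spec, 0)


class TestMatchedPair:
    def test_implied_loading_closed_form(self):
        # p=0.25, d=2, r=0: mixture correlation = 0.75/1.75 = 3/7
        spec = tx.SyntheticSpec("taxonic", n=600, k=3, base_rate=0.25,
                                separation=2.0, within_r=0.0)
        assert tx.mixture_correlation(0.25, 2.0, 2.0, 0.0) == \
            pytest.approx(3 / 7)
        np.testing.assert_allclose(tx.implied_loadings(spec),
                                   np.sqrt(3 / 7), atol=1e-12)

    def test_zero_separation_reduces_to_within_r(self):
        assert tx.mixture_correlation(0.25, 0.0, 0.0, 0.3) == \
            pytest.approx(0.3)

    def test_implied_loadings_verified_by_sampling(self):
        spec = tx.SyntheticSpec("taxonic", n=10_000, k=3, base_rate=0.25,
                                separation=2.0, within_r=0.0)
        m, _ = tx.simulate_taxonic(spec, 3)
        emp = np.corrcoef(m.values, rowvar=False)[np.triu_indices(3, 1)]
        np.testing.assert_allclose(emp, 3 / 7, atol=0.03)

    def test_pair_correlation_matrices_agree(self):
        spec = tx.SyntheticSpec("taxonic", n=2000, k=3, base_rate=0.25,
                                separation=2.0, within_r=0.1)
        tax, dim = tx.matched_pair(spec, 5)
        Rt = np.corrcoef(tax.values, rowvar=False)
        Rd = np.corrcoef(dim.values, rowvar=False)
        iu = np.triu_indices(3, 1)
        rmsr = np.sqrt(np.mean((Rt[iu] - Rd[iu]) ** 2))
        assert rmsr <= 0.05

    def test_infeasible_negative_correlation_rejected(self):
        spec = tx.SyntheticSpec("taxonic", n=600, k=3, base_rate=0.25,
                                separation=0.0, within_r=-0.3)
        with pytest.raises(ValueError, match="one-factor"):
            tx.implied_loadings(spec)


class TestPresets:
    @pytest.mark.parametrize(
        "name,n,means",
        [
            ("bss_like", 547, (7.12, 2.68, 2.00)),
            ("sidas_like", 989, (2.15, 4.01, 3.19)),
        ],
    )
    def test_sample_size_and_mean_targets(self, name, n, means):
        spec = tx.preset_spec(name)
        assert (spec.n, spec.k) == (n, 3)
        m, _ = tx.simulate_taxonic(spec, 1)
        np.testing.assert_allclose(m.values.mean(axis=0), means, atol=0.75)

    def test_sidas_like_bounded(self):
        m, _ = tx.simulate_taxonic(tx.preset_spec("sidas_like"), 1)
        assert m.values.min() >= 0 and m.values.max() <= 10

    def test_dimensional_preset_uses_implied_loadings(self):
        spec = tx.preset_spec("bss_like", structure="dimensional")
        assert spec.loadings is not None
        assert all(0 < v < 1 for v in spec.loadings)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            tx.preset_spec("nope")


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(structure="bogus", n=100),
            dict(structure="taxonic", n=10),
            dict(structure="taxonic", n=100, base_rate=0.0),
            dict(structure="taxonic", n=100, separation=-1.0),
            dict(structure="taxonic", n=100, within_r=1.0),
            dict(structure="dimensional", n=100, loadings=(1.5, 0.5, 0.5)),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tx.SyntheticSpec(**kwargs)
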