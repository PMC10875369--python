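"""Distribution-function contracts: closed forms, inverses, limits, modes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from nbpfweibull import (
    DomainError,
    FWParams,
    NBPFParams,
    ParameterError,
    fw_cdf,
    fw_pdf,
    fw_quantile,
    nbpf_cdf,
    nbpf_chf,
    nbpf_hf,
    nbpf_pdf,
    nbpf_quantile,
    nbpf_rvs,
    nbpf_sf,
)

P112 = NBPFParams(1.0, 1.0, 2.0)

valid_params = st.builds(
    NBPFParams,
    alpha=st.floats(0.3, 4.0),
    delta=st.floats(0.2, 2.5),
    beta=st.floats(0.45, 4.0),
)


class TestFWeibull:
    def test_parameter_validation(self):
        for bad in [(0, 1), (1, 0), (-1, 1), (np.nan, 1), (1, np.inf)]:
            with pytest.raises(ParameterError):
                FWParams(*bad)

    @pytest.mark.parametrize(
        "w, expected",
        [(0.0, 0.0), (-3.0, 0.0), (1.0, 1 - np.exp(-1)), (1e6, 1.0)],
    )
    def test_cdf_values(self, w, expected):
        assert fw_cdf(w, FWParams(1, 1)) == pytest.approx(expected, abs=1e-12)

    def test_quantile_closed_form(self):
        p = FWParams(1, 1)
        # c = 0 forces w = sqrt(alpha/delta) = 1
        assert fw_quantile(1 - np.exp(-1), p) == pytest.approx(1.0, abs=1e-12)
        assert fw_quantile(0.5, p) == pytest.approx(0.83339634, abs=1e-7)

    def test_quantile_roundtrip_grid(self):
        p = FWParams(0.7, 1.3)
        u = np.linspace(0.01, 0.99, 99)
        assert np.allclose(fw_cdf(fw_quantile(u, p), p), u, atol=1e-10)

    def test_quantile_domain_error(self):
        with pytest.raises(DomainError):
            fw_quantile(0.0, FWParams(1, 1))
        with pytest.raises(DomainError):
            fw_quantile(1.0, FWParams(1, 1))

    def test_extreme_tail_quantile_is_finite_positive(self):
        p = FWParams(2.0, 0.05)
        q = fw_quantile(np.array([1e-12, 1 - 1e-12]), p)
        assert np.all(np.isfinite(q)) and np.all(q > 0) and q[0] < q[1]


class TestNBPFFunctions:
    def test_cdf_sf_chf_frozen_values(self):
        # high-precision evaluations of the closed form at (1, 1, 2), w=1
        assert nbpf_cdf(1.0, P112) == pytest.approx(0.59098096, abs=1e-7)
        assert nbpf_sf(1.0, P112) == pytest.approx(0.40901904, abs=1e-7)
        assert nbpf_chf(1.0, P112) == pytest.approx(0.89399358, abs=1e-7)

    def test_boundary_limits(self):
        assert nbpf_cdf(0.0, P112) == 0.0
        assert nbpf_sf(0.0, P112) == 1.0
        assert nbpf_cdf(1e8, P112) == pytest.approx(1.0, abs=1e-12)
        assert nbpf_chf(1e-12, P112) == pytest.approx(0.0, abs=1e-12)

    def test_beta_one_collapses_to_fweibull(self):
        p1 = NBPFParams(1.3, 0.8, 1.0)
        base = FWParams(1.3, 0.8)
        w = np.geomspace(0.05, 20, 50)
        assert np.array_equal(nbpf_cdf(w, p1), fw_cdf(w, base))
        assert np.allclose(nbpf_pdf(w, p1), fw_pdf(w, base), rtol=1e-15)
        assert np.allclose(
            nbpf_pdf(w, p1, mode="as_printed"), fw_pdf(w, base), rtol=1e-15
        )
        assert np.allclose(nbpf_quantile(np.linspace(0.01, 0.99, 20), p1),
                           fw_quantile(np.linspace(0.01, 0.99, 20), base))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(valid_params)
    def test_complement_and_hazard_identities(self, p):
        w = np.geomspace(0.05, 15, 40)
        cdf, sf = nbpf_cdf(w, p), nbpf_sf(w, p)
        assert np.allclose(cdf + sf, 1.0, atol=1e-12)
        # restrict to where the survival function has not underflown: beyond
        # that the hazard saturates to +inf by design
        alive = sf > 1e-300
        with np.errstate(divide="ignore"):
            assert np.allclose(nbpf_chf(w, p)[alive], -np.log(sf[alive]), rtol=1e-12)
        f, h = nbpf_pdf(w, p), nbpf_hf(w, p)
        assert np.allclose((h * sf)[alive], f[alive], rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(valid_params)
    def test_cdf_monotone_nondecreasing(self, p):
        w = np.geomspace(0.01, 50, 200)
        assert np.all(np.diff(nbpf_cdf(w, p)) >= -1e-15)

    def test_hazard_saturates_not_crashes_in_far_tail(self):
        h = nbpf_hf(1e6, NBPFParams(1, 1, 2))
        assert h == np.inf or h > 0

    def test_pdf_rejects_bad_mode(self):
        with pytest.raises(DomainError):
            nbpf_pdf(1.0, P112, mode="bogus")


class TestDensityModes:
    @pytest.mark.parametrize("params", [(1.7, 0.9, 1.5), (1.5, 0.6, 1.1), (1.9, 0.4, 1.7)])
    def test_consistent_pdf_integrates_to_one(self, params):
        p = NBPFParams(*params)
        total, _ = quad(lambda w: nbpf_pdf(w, p), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("beta", [0.6, 1.5, 2.5])
    def test_as_printed_pdf_integrates_to_analytic_deficit(self, beta):
        # the variant bracket integrates to (1 + log(beta)/2)/beta, not 1
        p = NBPFParams(1.7, 0.9, beta)
        total, _ = quad(lambda w: nbpf_pdf(w, p, mode="as_printed"), 0, np.inf, limit=200)
        assert total == pytest.approx((1 + np.log(beta) / 2) / beta, abs=1e-6)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(valid_params)
    def test_consistent_pdf_is_cdf_derivative(self, p):
        w = np.geomspace(0.2, 8, 25)
        h = 1e-6 * w
        numeric = (nbpf_cdf(w + h, p) - nbpf_cdf(w - h, p)) / (2 * h)
        analytic = nbpf_pdf(w, p)
        mask = numeric > 1e-12
        assert np.allclose(analytic[mask], numeric[mask], rtol=1e-5)


class TestQuantileAndSampling:
    def test_quantile_frozen_value(self):
        # inner root G ~ 0.5435 of 2**G + G - 1 = 1, then base inversion
        assert nbpf_quantile(0.5, P112) == pytest.approx(0.885, abs=5e-4)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(valid_params)
    def test_quantile_cdf_roundtrip(self, p):
        u = np.concatenate([[0.001], np.linspace(0.01, 0.99, 30), [0.999]])
        assert np.allclose(nbpf_cdf(nbpf_quantile(u, p), p), u, atol=1e-8)

    def test_quantile_strictly_increasing(self):
        u = np.linspace(0.001, 0.999, 200)
        q = nbpf_quantile(u, NBPFParams(1.9, 0.4, 1.7))
        assert np.all(np.diff(q) > 0)

    def test_quantile_domain_error(self):
        with pytest.raises(DomainError):
            nbpf_quantile(1.5, P112)

    def test_rvs_deterministic_and_positive(self):
        a = nbpf_rvs(100, P112, seed=5)
        b = nbpf_rvs(100, P112, seed=5)
        assert np.array_equal(a, b)
        assert np.all(a > 0) and np.all(np.isfinite(a))
        with pytest.raises(DomainError):
            nbpf_rvs(0, P112, seed=1)

    def test_rvs_matches_cdf_distributionally(self):
        from scipy.stats import kstest

        p = NBPFParams(1.7, 0.9, 1.5)
        x = nbpf_rvs(5000, p, seed=42)
        assert kstest(x, lambda v: nbpf_cdf(v, p)).pvalue > 0.01

    def test_empirical_mean_matches_survival_integral(self):
        p = NBPFParams(1.7, 0.9, 1.5)
        x = nbpf_rvs(100_000, p, seed=99)
        mean_theory, _ = quad(lambda w: nbpf_sf(w, p), 0, np.inf, limit=200)
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - mean_theory) < 3 * se
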