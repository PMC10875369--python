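"""Likelihood, analytic score, MLE fitting and profile-likelihood contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbpfweibull import (
    DataValidationError,
    NBPFParams,
    Sample,
    fit_mle,
    log_likelihood,
    nbpf_pdf,
    nbpf_rvs,
    profile_loglik,
    score,
)


def numeric_gradient(w, p, mode, h=1e-6):
    out = []
    for name in ("alpha", "delta", "beta"):
        d = {"alpha": p.alpha, "delta": p.delta, "beta": p.beta}
        up, down = dict(d), dict(d)
        up[name] += h
        down[name] -= h
        out.append(
            (log_likelihood(w, NBPFParams(**up), mode) - log_likelihood(w, NBPFParams(**down), mode))
            / (2 * h)
        )
    return np.array(out)


class TestSample:
    def test_rejects_nonpositive_and_reports_rows(self):
        with pytest.raises(DataValidationError, match="rows"):
            Sample(np.array([1.0, -2.0, 3.0, 0.0]))
        with pytest.raises(DataValidationError):
            Sample(np.array([]))

    def test_len_and_values(self):
        s = Sample([3.0, 1.0, 2.0])
        assert len(s) == 3
        assert list(s.values) == [3.0, 1.0, 2.0]  # order preserved


class TestLogLikelihood:
    def test_equals_sum_of_log_densities(self):
        w = nbpf_rvs(40, NBPFParams(1.5, 0.6, 1.1), seed=2)
        for mode in ("consistent", "as_printed"):
            p = NBPFParams(1.4, 0.7, 1.3)
            direct = np.sum(np.log(nbpf_pdf(w, p, mode)))
            assert log_likelihood(w, p, mode) == pytest.approx(direct, abs=1e-10)

    def test_single_observation(self):
        p = NBPFParams(1.2, 0.9, 1.7)
        assert log_likelihood([2.0], p) == pytest.approx(float(np.log(nbpf_pdf(2.0, p))))

    def test_modes_coincide_at_beta_one(self):
        w = nbpf_rvs(30, NBPFParams(1.7, 0.9, 1.5), seed=3)
        p = NBPFParams(1.7, 0.9, 1.0)
        assert log_likelihood(w, p, "consistent") == pytest.approx(
            log_likelihood(w, p, "as_printed"), abs=1e-12
        )

    def test_permutation_invariance(self, medium_sample, rng):
        p = NBPFParams(1.6, 0.8, 1.4)
        shuffled = medium_sample[rng.permutation(medium_sample.size)]
        assert log_likelihood(shuffled, p) == pytest.approx(
            log_likelihood(medium_sample, p), abs=1e-9
        )


class TestScore:
    @pytest.mark.parametrize("mode", ["consistent", "as_printed"])
    def test_matches_numeric_gradient(self, mode):
        w = nbpf_rvs(50, NBPFParams(1.7, 0.9, 1.5), seed=11)
        p = NBPFParams(1.4, 0.8, 1.6)
        g = score(w, p, mode)
        num = numeric_gradient(w, p, mode)
        assert np.allclose(g, num, rtol=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        st.builds(NBPFParams, alpha=st.floats(0.5, 3.0), delta=st.floats(0.3, 2.0),
                  beta=st.floats(0.5, 3.0)),
        st.integers(0, 10_000),
    )
    def test_matches_numeric_gradient_property(self, p, seed):
        w = nbpf_rvs(40, NBPFParams(1.5, 0.6, 1.1), seed=seed)
        for mode in ("consistent", "as_printed"):
            g = score(w, p, mode)
            num = numeric_gradient(w, p, mode)
            scale = np.maximum(np.abs(num), 1.0)
            assert np.all(np.abs(g - num) / scale < 1e-5)

    def test_beta_score_vanishes_identically_at_beta_one(self):
        # the transform has zero first-order sensitivity to beta at beta=1,
        # so the beta component of the score is exactly 0 for any data
        w = nbpf_rvs(25, NBPFParams(1.9, 0.4, 1.7), seed=8)
        g = score(w, NBPFParams(1.9, 0.4, 1.0), "consistent")
        assert g[2] == pytest.approx(0.0, abs=1e-12)


class TestFitMLE:
    def test_recovers_truth_at_large_n(self):
        truth = NBPFParams(1.7, 0.9, 1.5)
        w = nbpf_rvs(3000, truth, seed=77)
        fit = fit_mle(w)
        assert fit.converged
        assert fit.estimates.alpha == pytest.approx(truth.alpha, abs=0.35)
        assert fit.estimates.delta == pytest.approx(truth.delta, abs=0.1)

    def test_score_small_at_interior_optimum(self, medium_sample):
        fit = fit_mle(medium_sample)
        assert fit.converged
        assert np.max(np.abs(score(medium_sample, fit.estimates))) < 1e-4

    def test_free_fit_at_least_submodel(self, medium_sample):
        from nbpfweibull.inference import fit_fweibull

        free = fit_mle(medium_sample)
        constrained = fit_fweibull(medium_sample)
        assert free.loglik_max >= constrained.loglik_max - 1e-9

    def test_deterministic(self, medium_sample):
        a = fit_mle(medium_sample)
        b = fit_mle(medium_sample)
        assert a.loglik_max == b.loglik_max
        assert a.estimates == b.estimates

    def test_degenerate_sample_flags_not_raises(self):
        fit = fit_mle(np.full(20, 2.0))
        assert not fit.converged

    def test_permutation_invariance(self, medium_sample, rng):
        a = fit_mle(medium_sample)
        b = fit_mle(medium_sample[rng.permutation(medium_sample.size)])
        assert a.loglik_max == pytest.approx(b.loglik_max, abs=1e-9)


class TestProfile:
    def test_profile_attains_full_maximum_and_never_exceeds(self, medium_sample):
        fit = fit_mle(medium_sample)
        for name in ("alpha", "beta"):
            mle_coord = getattr(fit.estimates, name)
            grid = np.linspace(0.7 * mle_coord, 1.3 * mle_coord, 9)
            grid = np.sort(np.append(grid, mle_coord))
            curve = profile_loglik(medium_sample, name, grid=grid)
            vals = curve.profile_loglik
            assert np.nanmax(vals) <= fit.loglik_max + 1e-6
            assert np.nanmax(vals) == pytest.approx(fit.loglik_max, abs=1e-6)

    def test_unimodal_on_bracketing_grid(self):
        w = nbpf_rvs(200, NBPFParams(3.239, 0.033, 0.410), seed=4)
        curve = profile_loglik(w, "delta")
        vals = curve.profile_loglik
        k = int(np.nanargmax(vals))
        assert np.all(np.diff(vals[: k + 1]) >= -1e-6)
        assert np.all(np.diff(vals[k:]) <= 1e-6)

    def test_rejects_unknown_parameter(self, medium_sample):
        from nbpfweibull import DomainError

        with pytest.raises(DomainError):
            profile_loglik(medium_sample, "gamma")
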