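"""Distribution families: invariants, closed forms, empirical estimation."""

import numpy as np
import pytest
from scipy import integrate, stats

from derangetropy import empirical_distribution, evaluation_grid, make_distribution
from derangetropy.distributions import read_samples
from derangetropy.exceptions import (
    DegenerateSampleError,
    InvalidInputError,
    InvalidParameterError,
    UnsupportedFamilyError,
)


class TestAnalyticFamilies:
    def test_pdf_nonnegative_and_cdf_monotone(self, family_dist):
        grid = evaluation_grid(family_dist, 2048)
        assert np.all(family_dist.pdf(grid) >= 0)
        F = family_dist.cdf(grid)
        assert np.all(np.diff(F) >= 0)
        assert np.all((F >= 0) & (F <= 1))

    def test_pdf_integrates_to_one(self, family_dist):
        lo, hi = family_dist.support
        mass, _ = integrate.quad(lambda t: float(family_dist.pdf(t)), lo, hi)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_cdf_limits_at_support_edges(self, family_dist):
        lo, hi = family_dist.support
        a = lo if np.isfinite(lo) else -1e9
        b = hi if np.isfinite(hi) else 1e9
        assert float(family_dist.cdf(a)) == pytest.approx(0.0, abs=1e-9)
        assert float(family_dist.cdf(b)) == pytest.approx(1.0, abs=1e-9)

    def test_cdf_of_median_is_half(self, family_dist):
        assert float(family_dist.cdf(family_dist.median)) == pytest.approx(
            0.5, abs=1e-9
        )

    @pytest.mark.parametrize(
        "name, params, expected_median",
        [
            ("uniform", (2.0, 6.0), 4.0),
            ("normal", (1.5, 2.0), 1.5),
            ("exponential", (2.0,), np.log(2) / 2.0),
            ("semicircle", (-3.0, 3.0), 0.0),
            ("arcsin", (0.0, 1.0), 0.5),
        ],
    )
    def test_median_matches_closed_form(self, name, params, expected_median):
        dist = make_distribution(name, params)
        assert dist.median == pytest.approx(expected_median, abs=1e-9)

    def test_pointwise_closed_forms(self):
        uni = make_distribution("uniform", (0.0, 1.0))
        assert float(uni.pdf(0.5)) == pytest.approx(1.0)
        norm = make_distribution("normal", (0.0, 1.0))
        assert float(norm.cdf(0.0)) == pytest.approx(0.5)
        arc = make_distribution("arcsin", (0.0, 1.0))
        assert float(arc.cdf(0.5)) == pytest.approx(
            (2 / np.pi) * np.arcsin(np.sqrt(0.5))
        )
        semi = make_distribution("semicircle", (-1.0, 1.0))
        # density ∝ sqrt(R² − x²): peak 2/(πR) at center
        assert float(semi.pdf(0.0)) == pytest.approx(2 / np.pi)

    def test_pdf_derivative_matches_central_difference(self, family_dist):
        grid = evaluation_grid(family_dist, 64)
        h = 1e-6 * max(1.0, np.ptp(grid))
        lo, hi = family_dist.support
        grid = grid[(grid - h > lo) & (grid + h < hi)]  # keep the stencil interior
        numeric = (family_dist.pdf(grid + h) - family_dist.pdf(grid - h)) / (2 * h)
        analytic = family_dist.pdf_deriv(grid)
        assert np.allclose(analytic, numeric, atol=1e-4, rtol=1e-4)

    def test_unknown_family_rejected(self):
        with pytest.raises(UnsupportedFamilyError):
            make_distribution("cauchy", (0.0, 1.0))

    @pytest.mark.parametrize(
        "name, params",
        [
            ("uniform", (1.0, 1.0)),
            ("uniform", (2.0, 1.0)),
            ("normal", (0.0, -1.0)),
            ("exponential", (0.0,)),
            ("arcsin", (3.0, 3.0)),
            ("semicircle", (1.0, -1.0)),
            ("normal", (0.0,)),
        ],
    )
    def test_invalid_parameters_rejected(self, name, params):
        with pytest.raises(InvalidParameterError):
            make_distribution(name, params)


class TestEvaluationGrid:
    def test_bounded_support_interior_points(self, unit_uniform):
        g = evaluation_grid(unit_uniform, 3)
        assert len(g) == 3
        assert np.all(np.diff(g) > 0)
        assert g[0] > 0 and g[-1] < 1

    def test_unbounded_support_quantile_truncation(self):
        norm = make_distribution("normal", (0.0, 1.0))
        g = evaluation_grid(norm, 101)
        assert g[0] == pytest.approx(stats.norm.ppf(1e-6))
        assert g[-1] == pytest.approx(stats.norm.ppf(1 - 1e-6))

    def test_half_bounded_support_stays_positive(self):
        expo = make_distribution("exponential", (1.0,))
        g = evaluation_grid(expo, 16)
        assert np.all(g > 0)

    def test_too_few_points_rejected(self, unit_uniform):
        with pytest.raises(InvalidParameterError):
            evaluation_grid(unit_uniform, 2)


class TestEmpiricalDistribution:
    def test_ks_distance_to_true_uniform(self, rng):
        draws = rng.uniform(0, 1, size=10_000)
        est = empirical_distribution(draws)
        x = np.linspace(0, 1, 2001)
        ks = np.max(np.abs(est.cdf(x) - x))
        assert ks < 0.02

    def test_ks_distance_decreases_with_sample_size(self, rng):
        distances = []
        for n in (100, 1000, 10_000):
            draws = rng.uniform(0, 1, size=n)
            est = empirical_distribution(draws)
            x = np.linspace(0, 1, 1001)
            distances.append(np.max(np.abs(est.cdf(x) - x)))
        assert distances[0] > distances[1] > distances[2]

    def test_cdf_zero_below_extended_support(self, rng):
        draws = rng.normal(size=50)
        est = empirical_distribution(draws)
        lo, hi = est.support
        assert float(est.cdf(lo - 1.0)) == 0.0
        assert float(est.cdf(hi + 1.0)) == 1.0

    def test_median_of_symmetric_sample(self):
        est = empirical_distribution(np.arange(1.0, 101.0))
        assert est.median == pytest.approx(50.5, abs=1.0)

    def test_pdf_cdf_mutually_consistent(self, rng):
        draws = rng.normal(size=500)
        est = empirical_distribution(draws)
        lo, hi = est.support
        # integral of pdf between two quantiles equals the CDF increment
        a, b = lo + 0.2 * (hi - lo), lo + 0.7 * (hi - lo)
        mass, _ = integrate.quad(lambda t: float(est.pdf(t)), a, b, limit=200)
        assert mass == pytest.approx(float(est.cdf(b)) - float(est.cdf(a)), abs=1e-6)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DegenerateSampleError):
            empirical_distribution([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateSampleError):
            empirical_distribution(np.full(50, 7.0))

    def test_nonfinite_samples_rejected(self):
        bad = np.ones(20)
        bad[3] = np.nan
        with pytest.raises(InvalidInputError):
            empirical_distribution(bad)

    def test_explicit_bandwidth_used(self, rng):
        draws = rng.normal(size=100)
        est = empirical_distribution(draws, bandwidth=0.5)
        assert est.params == (0.5,)
        assert est.support[0] == pytest.approx(draws.min() - 1.5)


class TestReadSamples:
    def test_roundtrip_with_header(self, tmp_path):
        p = tmp_path / "samples.txt"
        p.write_text("amplitude\n1.5\n-2.25\n3e-1\n")
        np.testing.assert_allclose(read_samples(p), [1.5, -2.25, 0.3])

    def test_blank_line_rejected(self, tmp_path):
        p = tmp_path / "samples.txt"
        p.write_text("1.0\n\n2.0\n")
        with pytest.raises(InvalidInputError, match="blank"):
            read_samples(p)

    def test_non_numeric_body_rejected(self, tmp_path):
        p = tmp_path / "samples.txt"
        p.write_text("1.0\nNA\n2.0\n")
        with pytest.raises(InvalidInputError, match="line 2|:2"):
            read_samples(p)
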