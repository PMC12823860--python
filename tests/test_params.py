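"""Parameter loading, validation, round-trip I/O and PSA samplers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecea import (
    MRSDistribution,
    ModelSpec,
    ParamRange,
    ValidationError,
    beta_from_mean_ci,
    dirichlet_from_distribution,
    gamma_from_mean_range,
    load_model_spec,
    write_model_spec,
)
from strokecea.params import FixedSampler, sampler_for


class TestDefaultSpec:
    def test_intervention_mrs_distribution(self, default_spec):
        assert default_spec.intervention.mrs_at_3mo.p == pytest.approx(
            (0.3913, 0.3478, 0.1565, 0.0261, 0.0174, 0.0087, 0.0522), abs=1e-12
        )

    def test_utility_values(self, default_spec):
        assert default_spec.utilities.u_mrs == (0.95, 0.89, 0.67, 0.44, 0.16, 0.10, 0.0)
        assert default_spec.utilities.u_recurrence == 0.42
        assert default_spec.utilities.d_sich == 0.38

    def test_key_scalars(self, default_spec):
        s = default_spec
        assert s.comparator.sich_incidence == 0.0087
        assert s.intervention.sich_incidence == 0.0172
        assert s.mortality.hr_by_mrs == (1.0, 1.0, 1.11, 1.27, 1.71, 2.37)
        assert s.recurrence.case_fatality == 0.21
        assert s.costs.alteplase_base_case == 0.5 * (1700.0 + 3400.0)
        assert s.thresholds.wtp_1x == 95749.0
        assert s.thresholds.wtp_3x == 3 * 95749.0
        assert s.life_table.annual_mortality(64.0) == 0.00760
        assert s.life_table.annual_mortality(93.0) == 0.15120

    def test_round_trip_exact(self, default_spec, tmp_path):
        path = tmp_path / "spec.yaml"
        write_model_spec(default_spec, path)
        reloaded = load_model_spec(path)
        assert reloaded.to_dict() == default_spec.to_dict()
        assert reloaded.uncertainty == default_spec.uncertainty
        assert reloaded.utilities == default_spec.utilities
        assert reloaded.costs == default_spec.costs


class TestValidation:
    def test_mrs_sum_far_from_one_rejected(self):
        with pytest.raises(ValidationError):
            MRSDistribution.from_values([0.2, 0.2, 0.2, 0.1, 0.1, 0.05, 0.05])  # sums to 0.90

    def test_mrs_small_deviation_renormalised(self):
        vals = [0.2565, 0.3504, 0.1197, 0.1197, 0.0342, 0.0342, 0.0855]  # sum 1.0002
        d = MRSDistribution.from_values(vals)
        assert math.isclose(sum(d.p), 1.0, abs_tol=1e-12)

    def test_error_names_offending_field(self, default_spec):
        doc = default_spec.to_dict()
        doc["costs"]["annual_care_mrs25"]["value"] = -5.0
        with pytest.raises(ValidationError, match="annual_care_mrs25"):
            ModelSpec.from_dict(doc)

    def test_non_monotone_utilities_rejected_strict_only(self, default_spec):
        doc = default_spec.to_dict()
        doc["utilities"]["u_mrs"]["values"] = [0.5, 0.89, 0.67, 0.44, 0.16, 0.10, 0.0]
        with pytest.raises(ValidationError, match="u_mrs"):
            ModelSpec.from_dict(doc, strict=True)
        ModelSpec.from_dict(doc, strict=False)  # relaxed path used by OWSA/PSA

    @settings(derandomize=True, max_examples=30)
    @given(idx=st.integers(0, 6), bump=st.floats(0.01, 0.5))
    def test_mrs_sum_violations_always_rejected(self, idx, bump):
        vals = [0.2564, 0.3504, 0.1197, 0.1197, 0.0342, 0.0342, 0.0855]
        vals[idx] += bump
        with pytest.raises(ValidationError):
            MRSDistribution.from_values(vals)

    @settings(derandomize=True, max_examples=30)
    @given(idx=st.integers(0, 6), cost=st.floats(-1e6, -0.01))
    def test_negative_costs_always_rejected(self, default_spec, idx, cost):
        doc = default_spec.to_dict()
        doc["costs"]["acute_hosp_by_mrs"]["values"][idx] = cost
        with pytest.raises(ValidationError):
            ModelSpec.from_dict(doc)


class TestBetaFit:
    def test_mean_is_exact(self):
        s = beta_from_mean_ci(0.0172, ParamRange(0.0, 0.0257))
        assert s.mean == pytest.approx(0.0172, abs=1e-9)

    def test_sd_matches_wald_width(self):
        # independent cross-check through scipy's beta moments
        from scipy import stats

        s = beta_from_mean_ci(0.0172, ParamRange(0.0, 0.0257))
        dist = stats.beta(s.alpha, s.beta)
        assert dist.mean() == pytest.approx(0.0172, abs=1e-9)
        assert dist.std() == pytest.approx(0.0257 / 3.92, rel=1e-6)

    def test_zero_width_interval_degenerates(self):
        s = beta_from_mean_ci(0.5, ParamRange(0.5, 0.5))
        assert isinstance(s, FixedSampler)
        assert s.sample(np.random.default_rng(0)) == 0.5

    def test_mean_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            beta_from_mean_ci(1.2, ParamRange(0.9, 1.5))

    def test_monte_carlo_mean(self):
        s = beta_from_mean_ci(0.0172, ParamRange(0.0, 0.0257))
        draws = s.sample(np.random.default_rng(42), size=100_000)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.0172) < 3 * se


class TestGammaFit:
    def test_mean_is_exact(self):
        s = gamma_from_mean_range(2550.0, ParamRange(1700.0, 3400.0))
        assert s.mean == pytest.approx(2550.0, abs=1e-6)

    def test_scipy_moments_cross_check(self):
        from scipy import stats

        s = gamma_from_mean_range(2550.0, ParamRange(1700.0, 3400.0))
        dist = stats.gamma(s.shape, scale=s.scale)
        assert dist.mean() == pytest.approx(2550.0, abs=1e-6)
        assert dist.std() == pytest.approx((3400.0 - 1700.0) / 3.92, rel=1e-9)

    def test_zero_width_and_domain_error(self):
        assert isinstance(gamma_from_mean_range(100.0, ParamRange(100.0, 100.0)), FixedSampler)
        with pytest.raises(ValidationError):
            gamma_from_mean_range(-1.0, ParamRange(0.0, 1.0))

    def test_monte_carlo_mean(self):
        s = gamma_from_mean_range(2550.0, ParamRange(1700.0, 3400.0))
        draws = s.sample(np.random.default_rng(7), size=100_000)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 2550.0) < 3 * se


class TestDirichlet:
    def test_degenerate_mass_concentrates(self):
        d = MRSDistribution.from_values([1.0, 0, 0, 0, 0, 0, 0])
        s = dirichlet_from_distribution(d, 50.0)
        draws = s.sample(np.random.default_rng(0), size=1000)
        assert draws[:, 0].mean() > 0.999

    def test_simplex_and_mean_recovery(self, default_spec):
        d = default_spec.intervention.mrs_at_3mo
        s = dirichlet_from_distribution(d, 115.0)
        draws = s.sample(np.random.default_rng(3), size=100_000)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)
        se = draws.std(axis=0, ddof=1) / math.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - s.mean) < 3 * se + 1e-12)
        # dirichlet mean approximates the source distribution (1e-6 floor aside)
        np.testing.assert_allclose(s.mean, d.as_array(), atol=1e-5)

    def test_concentration_must_be_positive(self, default_spec):
        with pytest.raises(ValidationError):
            dirichlet_from_distribution(default_spec.intervention.mrs_at_3mo, 0.0)


def test_registry_sampler_means_match_point_estimates(default_spec):
    """Every non-degenerate PSA sampler is centred on its point estimate."""
    rng = np.random.default_rng(11)
    checked = 0
    for path, u in default_spec.uncertainty.items():
        if u.family not in ("beta", "gamma") or u.range is None or u.range.width == 0:
            continue
        s = sampler_for(u)
        draws = s.sample(rng, size=20_000)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - u.value) < 3 * se + 1e-12, path
        checked += 1
    assert checked > 10
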