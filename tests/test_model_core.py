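"""Likelihood, ML fitting, and estimate reporting of the core model."""

import numpy as np
import pytest
from scipy import stats

from icedmri import (
    ICEDModel,
    ReliabilityDataset,
    SyntheticSpec,
    VarianceComponents,
    fit_iced,
    log_likelihood,
    model_covariance,
    simulate_roi_dataset,
)


class TestLogLikelihood:
    def test_matches_multivariate_normal_oracle(self, design, small_dataset):
        """Direct density evaluation via scipy is the independent oracle."""
        vc = VarianceComponents(0.3, 0.1, 0.05, 0.2)
        Sigma = model_covariance(vc, design)
        means = np.array([0.9, 1.0, 1.1, 1.05])
        expected = stats.multivariate_normal(means, Sigma).logpdf(
            small_dataset.values
        ).sum()
        assert log_likelihood(small_dataset, vc, means) == pytest.approx(
            expected, abs=1e-8
        )

    def test_single_person_unit_normal_constant(self, design):
        row = np.array([[0.2, 0.4, 0.6, 0.8]])
        ds = ReliabilityDataset(row, design)
        ll = log_likelihood(ds, VarianceComponents(0, 0, 0, 1), means=row[0])
        assert ll == pytest.approx(-(design.k / 2) * np.log(2 * np.pi), abs=1e-12)

    def test_sample_means_maximize_the_likelihood(self, design, small_dataset):
        vc = VarianceComponents(0.3, 0.1, 0.05, 0.2)
        at_ml = log_likelihood(small_dataset, vc)
        rng = np.random.default_rng(0)
        sample_means = small_dataset.values.mean(axis=0)
        for _ in range(20):
            other = sample_means + rng.normal(0, 0.1, design.k)
            assert at_ml >= log_likelihood(small_dataset, vc, other) - 1e-10

    def test_singular_covariance_raises(self, design, small_dataset):
        with pytest.raises(np.linalg.LinAlgError):
            log_likelihood(small_dataset, VarianceComponents(1, 0, 0, 0))


class TestFit:
    def test_parameter_recovery_large_n(self, design):
        spec = SyntheticSpec(
            2000, design, [0.87] * 4, VarianceComponents(0.6, 0.1, 0.1, 0.2), seed=3
        )
        res = ICEDModel(simulate_roi_dataset(spec)).fit()
        assert res.converged
        np.testing.assert_allclose(
            res.proportions.as_array(), [0.6, 0.1, 0.1, 0.2], atol=0.03
        )

    def test_degenerate_between_person_only(self, design):
        """Identical values within person: error terms collapse to the bound."""
        rng = np.random.default_rng(5)
        person_levels = rng.normal(1.0, 0.3, (10, 1))
        ds = ReliabilityDataset(np.repeat(person_levels, 4, axis=1), design)
        res = ICEDModel(ds).fit()
        lb = res.lower_bound
        assert res.params.var_d <= lb * 1.01
        assert res.params.var_s <= lb * 1.01
        assert res.params.var_e <= lb * 1.01
        between = np.var(person_levels)
        assert res.params.var_t == pytest.approx(between, rel=0.05)

    def test_beats_coarse_grid_on_tiny_data(self, design):
        """Grid-search oracle: no grid point outscores the ML solution."""
        rng = np.random.default_rng(7)
        ds = ReliabilityDataset(rng.normal(1.0, 0.5, (4, 4)), design)
        res = fit_iced(ds)
        scale = ds.values.var()
        # grid over the same bounded region the estimator searches
        grid = np.clip(
            np.array([1e-4, 0.05, 0.15, 0.4, 1.0, 2.5]) * scale, 1e-4, None
        )
        best_grid = -np.inf
        for t in grid:
            for d in grid:
                for s in grid:
                    for e in grid:
                        ll = log_likelihood(
                            ds, VarianceComponents(t, d, s, e)
                        )
                        best_grid = max(best_grid, ll)
        assert res.llf >= best_grid - 1e-9

    def test_too_few_persons_rejected(self, design):
        ds = ReliabilityDataset(np.ones((2, 4)) + np.eye(2, 4), design)
        with pytest.raises(ValueError, match="3 persons"):
            ICEDModel(ds).fit()

    def test_missing_cells_hard_error(self, design):
        values = np.ones((5, 4))
        values[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ReliabilityDataset(values, design)

    def test_listwise_deletion_optional(self, design):
        values = np.tile([1.0, 1.1, 0.9, 1.0], (5, 1))
        values[2, 1] = np.nan
        ds = ReliabilityDataset(values, design, allow_missing=True)
        assert ds.n_persons == 4


class TestReporting:
    def test_proportions_sum_to_one_and_icc_is_var_t_share(self, mixed_dataset):
        res = ICEDModel(mixed_dataset).fit()
        assert res.proportions.total == pytest.approx(1.0, abs=1e-10)
        assert res.icc == pytest.approx(res.proportions.var_t, abs=1e-10)

    def test_bound_pinned_components_reported_as_zero(self, design):
        rng = np.random.default_rng(5)
        person_levels = rng.normal(1.0, 0.3, (10, 1))
        ds = ReliabilityDataset(np.repeat(person_levels, 4, axis=1), design)
        res = ICEDModel(ds).fit()
        reported = res.proportions_reported()
        assert reported.var_d == 0.0
        assert reported.var_s == 0.0
        # raw estimates keep the bound value
        assert res.params.var_d == pytest.approx(res.lower_bound)

    def test_summary_renders(self, mixed_dataset):
        text = ICEDModel(mixed_dataset).fit().summary()
        assert "ICC" in text and "var_t" in text

    def test_standardized_fit_matches_unit_scale_fit(self, mixed_dataset):
        """For unit-scale data (bound inactive) standardization is a no-op
        on proportions, ICC and ICC2."""
        plain = ICEDModel(mixed_dataset).fit()
        std = ICEDModel(mixed_dataset).fit(standardize=True)
        assert std.standardized
        np.testing.assert_allclose(
            plain.proportions.as_array(), std.proportions.as_array(), atol=1e-6
        )
        assert plain.icc2 == pytest.approx(std.icc2, abs=1e-6)

    def test_standardization_frees_small_variance_modalities(self):
        """MT-scale data (total variance ~6.5e-4) hits the 1e-4 bound on the
        raw scale; the standardized fit recovers the structure."""
        from icedmri import default_study_spec

        ds = simulate_roi_dataset(default_study_spec("MT", n_persons=200, seed=2))
        raw = ICEDModel(ds).fit()
        std = ICEDModel(ds).fit(standardize=True)
        assert np.all(raw.at_bound[1:])  # all error components pinned on the raw scale
        assert std.proportions.var_t == pytest.approx(0.883, abs=0.1)

    def test_icc_between_icc_and_one_when_residual_only(self, design):
        spec = SyntheticSpec(
            500, design, [1.0] * 4, VarianceComponents(0.6, 0, 0, 0.4), seed=21
        )
        res = ICEDModel(simulate_roi_dataset(spec)).fit()
        assert 0 <= res.icc <= res.icc2 <= 1
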