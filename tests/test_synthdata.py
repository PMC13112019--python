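"""Ground-truth cohort generation: planted structure and bookkeeping."""

import numpy as np
import pytest

import connkit as ck
from connkit.synthdata import (
    CohortSpec,
    SyntheticCohort,
    UnsupportedOperationError,
    generate_behavior,
    generate_hematology,
    generate_matrix_cohort,
    generate_timeseries_cohort,
    planted_component,
)


class TestCohortSpec:
    def test_validation_rejects_bad_edges_and_counts(self):
        with pytest.raises(ValueError, match="behavior_edges"):
            CohortSpec(n_regions=5, behavior_edges=(50,))
        with pytest.raises(ValueError, match="n_patients"):
            CohortSpec(n_patients=0)
        with pytest.raises(ValueError, match="noise_sd_behavior"):
            CohortSpec(noise_sd_behavior=-1)

    def test_yaml_round_trip_is_byte_identical(self):
        spec = CohortSpec(n_regions=20, disrupted_edges=(1, 5, 9), seed=3)
        text = spec.to_yaml()
        again = CohortSpec.from_yaml(text)
        assert again == spec
        assert again.to_yaml() == text

    def test_aal_default_edge_count(self):
        assert CohortSpec().n_edges == 6670


class TestPlantedComponent:
    def test_component_is_connected_with_requested_size(self):
        for m in (5, 15, 30):
            comp = planted_component(40, m)
            iu, ju = ck.edge_index(40)
            pairs = [(int(iu[e]), int(ju[e])) for e in comp]
            comps, sizes = ck.connected_components(pairs, 40)
            assert len(comps) == 1 and sizes[0] == m


class TestMatrixRoute:
    def test_matrices_symmetric_zero_diagonal(self, small_cohort):
        Z = small_cohort.z_matrices
        assert np.array_equal(Z, np.transpose(Z, (0, 2, 1)))
        assert np.all(Z[:, np.arange(30), np.arange(30)] == 0)
        assert len(small_cohort.manifest) == 30

    def test_aal_cohort_vectorizes_to_6670(self):
        spec = CohortSpec(n_patients=3, n_controls=3, seed=0)
        c = generate_matrix_cohort(spec)
        assert c.edge_matrix().shape == (6, 6670)
        v = ck.vectorize(ck.ConnectivityMatrix(c.z_matrices[0]))
        assert len(v.values) == 6670

    def test_null_spec_groups_identically_distributed(self):
        spec = CohortSpec(n_regions=20, n_patients=100, n_controls=100,
                          disruption_delta=0.0, seed=1)
        c = generate_matrix_cohort(spec)
        X = c.edge_matrix()
        diff = X[c.is_patient].mean(0) - X[~c.is_patient].mean(0)
        # same mean profile; differences are pure sampling noise ~ sd*sqrt(2/n)
        assert np.max(np.abs(diff)) < 5 * spec.subject_sd * np.sqrt(2 / 100)

    def test_planted_delta_recovered_in_sample_means(self):
        comp = planted_component(20, 8)
        deltas = []
        for s in range(50):
            spec = CohortSpec(n_regions=20, n_patients=200, n_controls=200,
                              disrupted_edges=comp, disruption_delta=0.6, seed=s)
            c = generate_matrix_cohort(spec)
            X = c.edge_matrix()
            d = X[~c.is_patient][:, comp].mean() - X[c.is_patient][:, comp].mean()
            deltas.append(d)
        assert np.mean(deltas) == pytest.approx(0.6, abs=0.02)


class TestTimeseriesRoute:
    def test_planted_single_edge_delta_within_tolerance(self):
        # Monte-Carlo over replicates: mean Fisher-z difference near planted 0.6
        deltas = []
        for s in range(50):
            spec = CohortSpec(n_regions=12, n_patients=200, n_controls=200,
                              disrupted_edges=(3,), disruption_delta=0.6, seed=s)
            c = generate_timeseries_cohort(spec)
            X = c.edge_matrix()
            deltas.append(X[~c.is_patient, 3].mean() - X[c.is_patient, 3].mean())
        assert abs(np.mean(deltas) - 0.6) < 0.1

    def test_series_shape_and_autocorrelation(self):
        spec = CohortSpec(n_regions=10, n_patients=4, n_controls=4,
                          n_timepoints=120, seed=2)
        c = generate_timeseries_cohort(spec)
        assert c.timeseries.shape == (8, 120, 10)
        x = c.timeseries[0]
        lag1 = np.mean([np.corrcoef(x[:-1, j], x[1:, j])[0, 1] for j in range(10)])
        assert 0.1 < lag1 < 0.5  # AR(1) rho = 0.3 by construction

    def test_infeasible_edits_rejected_with_edge_diagnostic(self):
        # an extreme delta on a dense clique cannot stay positive semidefinite
        comp = planted_component(10, 30)
        spec = CohortSpec(n_regions=10, n_patients=3, n_controls=3,
                          disrupted_edges=comp, disruption_delta=4.0, seed=0)
        with pytest.raises(ValueError, match="offending edges"):
            generate_timeseries_cohort(spec)

    def test_edge_z_moments_match_conventions(self):
        spec = CohortSpec(n_regions=30, n_patients=30, n_controls=30, seed=4)
        c = generate_timeseries_cohort(spec)
        X = c.edge_matrix()
        assert abs(X.mean() - spec.control_mean_z) < 0.08


class TestBehavior:
    def test_noiseless_behavior_exactly_linear_in_strength(self, rng):
        spec = CohortSpec(n_regions=15, behavior_edges=planted_component(15, 8),
                          noise_sd_behavior=0.0, seed=5)
        c = generate_matrix_cohort(spec)
        generate_behavior(spec, c)
        strength = c.edge_matrix()[:, list(spec.behavior_edges)].sum(1)
        expected = spec.behavior_intercept + spec.behavior_slope * strength
        assert np.allclose(c.manifest["wis"].to_numpy(), expected)

    def test_empty_behavior_edges_gives_pure_noise(self):
        spec = CohortSpec(n_regions=15, seed=6)
        c = generate_matrix_cohort(spec)
        generate_behavior(spec, c)
        wis = c.manifest["wis"].to_numpy()
        assert np.isfinite(wis).all()
        assert abs(wis.mean() - spec.behavior_intercept) < 3 * spec.noise_sd_behavior

    def test_positive_slope_gives_positive_edge_correlations(self):
        spec = CohortSpec(n_regions=20, behavior_edges=planted_component(20, 10),
                          seed=7)
        c = generate_matrix_cohort(spec)
        generate_behavior(spec, c)
        X = c.edge_matrix()
        y = c.manifest["wis"].to_numpy()
        rs = [np.corrcoef(X[:, e], y)[0, 1] for e in spec.behavior_edges]
        assert np.mean(rs) > 0.3
        assert min(rs) > 0


class TestHematology:
    def test_controls_request_rejected(self, small_cohort):
        with pytest.raises(UnsupportedOperationError):
            generate_hematology(small_cohort.ground_truth, small_cohort,
                                group="control")

    def test_requires_behavior_first(self):
        spec = CohortSpec(n_regions=15, behavior_edges=planted_component(15, 6),
                          seed=8)
        c = generate_matrix_cohort(spec)
        with pytest.raises(ValueError, match="generate_behavior"):
            generate_hematology(spec, c)

    def test_hemoglobin_moments_near_reference(self):
        means = []
        for s in range(20):
            spec = CohortSpec(n_regions=15,
                              behavior_edges=planted_component(15, 6), seed=100 + s)
            c = ck.generate_cohort(spec)
            means.append(c.manifest.loc[c.is_patient, "hemoglobin"].mean())
        # single-cohort mean within 2 SE of 104.28; replicate mean much tighter
        se = 13.31 / np.sqrt(25)
        assert abs(means[0] - 104.28) < 2 * se
        assert abs(np.mean(means) - 104.28) < 2 * se / np.sqrt(20) * 3

    def test_controls_have_no_hematology(self, small_cohort):
        assert small_cohort.manifest.loc[~small_cohort.is_patient, "hemoglobin"] \
            .isna().all()
        assert small_cohort.manifest.loc[small_cohort.is_patient, "hemoglobin"] \
            .notna().all()

    def test_null_a_path_ci_covers_zero(self):
        from connkit.mediation import Mediation
        cover = 0
        n_rep = 60
        for s in range(n_rep):
            spec = CohortSpec(n_regions=15,
                              behavior_edges=planted_component(15, 6),
                              mediation_a=0.0, seed=300 + s)
            c = ck.generate_cohort(spec)
            pat = c.manifest[c.is_patient]
            m = c.edge_matrix()[c.is_patient][:, list(spec.behavior_edges)].mean(1)
            res = Mediation(pat["hemoglobin"], m, pat["wis"],
                            n_boot=300, seed=s).fit()
            lo, hi = res.ci
            cover += int(lo <= 0 <= hi)
        assert cover / n_rep >= 0.85  # nominal 95%, binomial slack at 60 reps


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, small_cohort):
        out = small_cohort.save(tmp_path / "cohort")
        again = SyntheticCohort.load(out)
        assert again.ground_truth == small_cohort.ground_truth
        assert np.allclose(again.z_matrices, small_cohort.z_matrices)
        assert again.manifest["wis"].round(6).equals(
            small_cohort.manifest["wis"].round(6))
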