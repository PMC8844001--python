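"""Synthetic cohort generator: centroids, sequences, BOLD, cortisol, cohorts."""
import numpy as np
import pytest

from stressdfc import (
    CohortSpec,
    RoiTimeSeries,
    generate_bold_run,
    generate_centroids,
    generate_cohort,
    generate_cortisol_series,
    generate_state_sequence,
    window_labels,
)


class TestCentroids:
    def test_single_state_minimal_size(self):
        cs = generate_centroids(k=1, n_roi=4, seed=0)
        mat = cs.matrices[0]
        assert np.allclose(np.diag(mat), 1.0)
        assert np.array_equal(mat, mat.T)

    def test_default_scale_is_positive_semidefinite(self):
        cs = generate_centroids(k=5, n_roi=114, seed=7)
        assert cs.matrices.shape == (5, 114, 114)
        for mat in cs.matrices:
            assert np.linalg.eigvalsh(mat).min() >= -1e-8
            assert np.abs(mat[~np.eye(114, dtype=bool)]).max() <= 1.0 + 1e-12

    def test_deterministic_under_fixed_seed(self):
        a = generate_centroids(k=2, n_roi=10, seed=3)
        b = generate_centroids(k=2, n_roi=10, seed=3)
        assert np.array_equal(a.matrices, b.matrices)

    def test_patterns_pairwise_distinct(self):
        cs = generate_centroids(k=5, n_roi=30, seed=1)
        rho = cs.pairwise_spearman()
        off = rho[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.95

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_centroids(k=0, n_roi=10, seed=0)
        with pytest.raises(ValueError):
            generate_centroids(k=2, n_roi=3, seed=0)


class TestStateSequence:
    def test_degenerate_single_state(self):
        seq = generate_state_sequence(100, [1.0], mean_dwell=5, seed=1)
        assert np.all(seq.labels == 1)

    def test_long_sequence_tracks_target_occupancy(self):
        seq = generate_state_sequence(20000, [0.5, 0.5], mean_dwell=10, seed=2)
        frac = np.mean(seq.labels == 1)
        assert 0.48 <= frac <= 0.52

    def test_short_sequence_support(self):
        seq = generate_state_sequence(10, [0.3, 0.7], mean_dwell=3, seed=4)
        assert len(seq.labels) == 10
        assert set(seq.labels) <= {1, 2}

    def test_dwell_lengths_partition_sequence(self):
        seq = generate_state_sequence(500, [0.25, 0.25, 0.5], mean_dwell=8, seed=9)
        assert seq.dwell_lengths.sum() == 500
        assert seq.dwell_lengths.min() >= 1

    def test_bad_occupancy_rejected(self):
        with pytest.raises(ValueError):
            generate_state_sequence(100, [0.6, 0.6], mean_dwell=5, seed=0)

    def test_occupancy_within_two_percent_at_scale(self):
        target = np.array([0.3, 0.2, 0.2, 0.15, 0.15])
        seq = generate_state_sequence(10000, target, mean_dwell=10, seed=5)
        assert np.abs(seq.empirical_occupancy() - target).max() <= 0.02


class TestBoldRun:
    def test_identity_centroid_gives_uncorrelated_samples(self):
        from stressdfc.synthetic import CentroidSet

        centroids = CentroidSet(matrices=np.eye(4)[None].repeat(1, axis=0))
        seq = generate_state_sequence(5000, [1.0], mean_dwell=50, seed=1)
        ts = generate_bold_run(seq, centroids, noise_sd=0.1, seed=5)
        corr = np.corrcoef(ts.values.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_strong_pair_correlation_recovered(self):
        from stressdfc.synthetic import CentroidSet

        mat = np.eye(4)
        mat[0, 1] = mat[1, 0] = 0.8
        centroids = CentroidSet(matrices=mat[None])
        seq = generate_state_sequence(5000, [1.0], mean_dwell=50, seed=2)
        ts = generate_bold_run(seq, centroids, noise_sd=0.1, seed=6)
        r = np.corrcoef(ts.values[:, 0], ts.values[:, 1])[0, 1]
        assert 0.70 <= r <= 0.88

    def test_output_shape_matches_design(self):
        centroids = generate_centroids(k=2, n_roi=114, seed=0)
        seq = generate_state_sequence(300, [0.5, 0.5], mean_dwell=20, seed=3)
        ts = generate_bold_run(seq, centroids, noise_sd=0.5, seed=7)
        assert ts.values.shape == (300, 114)

    def test_non_psd_centroid_rejected(self):
        from stressdfc.synthetic import CentroidSet

        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues (3, -1)
        seq = generate_state_sequence(10, [1.0], mean_dwell=3, seed=0)
        with pytest.raises(ValueError, match="positive semidefinite"):
            generate_bold_run(seq, CentroidSet(matrices=bad[None]), noise_sd=0.1, seed=0)


class TestWindowLabels:
    def test_constant_sequence_passes_through(self):
        assert np.all(window_labels(np.full(20, 3), w=7) == 3)

    def test_majority_vote_at_transition(self):
        vol = np.array([1] * 10 + [2] * 10)
        wl = window_labels(vol, w=7)
        assert len(wl) == 12
        assert wl[0] == 1 and wl[-1] == 2
        # windows are ordered: once the majority flips it stays flipped
        assert np.all(np.diff(wl) >= 0)


class TestCortisol:
    def test_flat_response_without_noise(self):
        s = generate_cortisol_series(5.0, 0.0, noise_sd=0.0, seed=1)
        assert np.allclose(s.concentrations, 5.0)

    def test_peak_occurs_after_onset(self):
        s = generate_cortisol_series(5.0, 10.0, noise_sd=0.0, seed=1)
        peak_idx = int(np.argmax(s.concentrations))
        assert s.timepoints[peak_idx] > 0

    def test_deterministic_under_fixed_seed(self):
        a = generate_cortisol_series(0.2, 0.3, noise_sd=0.1, seed=11)
        b = generate_cortisol_series(0.2, 0.3, noise_sd=0.1, seed=11)
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_cortisol_series(0.0, 0.1)
        with pytest.raises(ValueError):
            generate_cortisol_series(1.0, 0.1, timepoints=[0.0, 0.0, 10.0])


class TestCohort:
    def test_cardinality(self):
        spec = CohortSpec(n_subjects=2, n_roi=10, volumes_per_run=60, seed=0)
        cohort = generate_cohort(spec)
        assert len(cohort.subjects) == 2
        assert len(cohort.bold) == 6
        assert len(cohort.sequences) == 6
        assert all(isinstance(ts, RoiTimeSeries) for ts in cohort.bold.values())

    def test_injected_trait_correlation_in_ground_truth(self):
        spec = CohortSpec(n_subjects=200, r_trait_delta=0.6, seed=7)
        cohort = generate_cohort(spec, generate_bold=False)
        gt = cohort.ground_truth
        r = np.corrcoef(gt["trait_z"], gt["latent_delta"])[0, 1]
        assert 0.5 <= r <= 0.7

    def test_null_construction_centres_deltas_on_zero(self):
        spec = CohortSpec(
            n_subjects=150,
            occupancy_post=(0.30, 0.20, 0.20, 0.15, 0.15),
            r_trait_delta=0.0,
            r_cortisol_delta=0.0,
            r_trait_stress=0.0,
            seed=3,
        )
        cohort = generate_cohort(spec, generate_bold=False)
        assert abs(cohort.ground_truth["latent_delta"].mean()) < 0.02

    def test_generator_is_pure_function_of_seed(self):
        spec = CohortSpec(n_subjects=2, n_roi=8, volumes_per_run=50, seed=21)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        key = ("sub-002", "RS2")
        assert np.array_equal(a.bold[key].values, b.bold[key].values)
        assert np.array_equal(a.motion[key], b.motion[key])
        assert a.ground_truth.equals(b.ground_truth)

    def test_latent_structure_identical_with_and_without_bold(self):
        spec = CohortSpec(n_subjects=3, n_roi=8, volumes_per_run=50, seed=5)
        with_bold = generate_cohort(spec, generate_bold=True)
        without = generate_cohort(spec, generate_bold=False)
        assert with_bold.ground_truth.equals(without.ground_truth)
        assert all(
            np.array_equal(with_bold.sequences[k].labels, without.sequences[k].labels)
            for k in with_bold.sequences
        )

    def test_subject_table_has_auc_columns(self):
        spec = CohortSpec(n_subjects=3, n_roi=8, volumes_per_run=50, seed=6)
        table = generate_cohort(spec, generate_bold=False).subject_table()
        assert {"subject", "ffmq_total", "aucg", "auci"} <= set(table.columns)
        assert len(table) == 3
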