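"""Ground-truth generators: rating counts, model representations, patterns."""

import numpy as np
import pytest

from socialrsa import geometry
from socialrsa.rdm import rdm_vector, spearman_rsa
from socialrsa.synthetic import (
    InfeasibleTargetsError,
    MixtureSpec,
    _measured_pairwise,
    gen_frame_stack,
    gen_model_representations,
    gen_pattern_dataset,
    gen_rating_counts,
    gen_windowed_dataset,
)


class TestRatingCounts:
    def test_degenerate_profile(self):
        df = gen_rating_counts(5, profiles=np.tile([1.0, 0, 0], (5, 1)),
                               n_raters=10, seed=0)
        assert (df["friendly"] == 10).all()
        assert (df[["neutral", "adversarial"]] == 0).all().all()

    def test_expected_counts_for_worked_profile(self):
        df = gen_rating_counts(2000, profiles=np.tile([0.8, 0, 0.2], (2000, 1)),
                               n_raters=10, seed=1)
        assert df["friendly"].mean() == pytest.approx(8.0, abs=0.1)
        assert df["adversarial"].mean() == pytest.approx(2.0, abs=0.1)
        assert (df["neutral"] == 0).all()

    def test_law_of_large_numbers(self):
        profile = np.array([0.5, 0.3, 0.2])
        df = gen_rating_counts(5000, profiles=np.tile(profile, (5000, 1)),
                               n_raters=10, seed=2)
        freqs = df[["friendly", "neutral", "adversarial"]].sum().to_numpy()
        freqs = freqs / freqs.sum()
        se = np.sqrt(profile * (1 - profile) / (5000 * 10))
        assert np.all(np.abs(freqs - profile) < 3 * se)

    def test_reproducible(self):
        a = gen_rating_counts(20, seed=5)
        b = gen_rating_counts(20, seed=5)
        assert a.equals(b)


class TestModelRepresentations:
    def test_published_targets_within_tolerance(self, model_reps):
        measured = _measured_pairwise(model_reps)
        assert measured[("modelA", "modelB")] == pytest.approx(0.27, abs=0.05)
        assert measured[("modelA", "behavior")] == pytest.approx(0.50, abs=0.05)
        assert measured[("modelB", "behavior")] == pytest.approx(0.46, abs=0.05)

    def test_unit_targets_duplicate(self):
        sets = gen_model_representations(
            n_conditions=12, targets=(1.0, 1.0, 1.0), seed=0
        )
        measured = _measured_pairwise(sets)
        assert all(v == pytest.approx(1.0) for v in measured.values())

    def test_zero_targets_independent(self):
        sets = gen_model_representations(
            n_conditions=40, targets=(0.0, 0.0, 0.0), seed=4, tolerance=0.3
        )
        measured = _measured_pairwise(sets)
        assert all(abs(v) <= 0.3 for v in measured.values())

    def test_mixed_unit_targets_unsupported(self):
        with pytest.raises(InfeasibleTargetsError):
            gen_model_representations(targets=(1.0, 0.3, 0.3), seed=0)


class TestPatternDataset:
    def test_pure_component_geometry_recovered_noiselessly(self, model_rdms,
                                                           small_grid, cube_roi):
        comps = {"A": model_rdms["modelA"], "B": model_rdms["modelB"]}
        spec = MixtureSpec(components=comps,
                           regions={"r": (cube_roi, {"A": 1.0, "B": 0.0})},
                           sigma=0.0, n_subjects=2, n_repeats=1,
                           subject_jitter=0.0)
        data = gen_pattern_dataset(spec, small_grid, seed=3,
                                   analysis_mask=cube_roi)
        for subj in data.dataset.subject_ids:
            nv = rdm_vector(geometry.neural_rdm(data.dataset.subjects[subj][0]))
            rho = spearman_rsa(nv, rdm_vector(comps["A"])).rho
            assert rho >= 0.95

    def test_pure_noise_region_statistics_centered(self, model_rdms, small_grid,
                                                   cube_roi):
        comps = {"A": model_rdms["modelA"], "B": model_rdms["modelB"]}
        spec = MixtureSpec(components=comps, regions={"r": (cube_roi, {})},
                           sigma=1.0, n_subjects=40, n_repeats=2)
        data = gen_pattern_dataset(spec, small_grid, seed=5,
                                   analysis_mask=cube_roi)
        rhos = []
        for subj in data.dataset.subject_ids:
            avg = geometry.normalize_and_average(data.dataset.subjects[subj])
            nv = rdm_vector(geometry.neural_rdm(avg))
            rhos.append(spearman_rsa(nv, rdm_vector(comps["A"])).rho)
        rhos = np.array(rhos)
        assert abs(rhos.mean()) < 3 * rhos.std() / np.sqrt(len(rhos)) + 0.01

    def test_bit_identical_under_seed(self, model_rdms, small_grid, cube_roi):
        comps = {"A": model_rdms["modelA"], "B": model_rdms["modelB"]}
        spec = MixtureSpec(components=comps,
                           regions={"r": (cube_roi, {"A": 1.0, "B": 1.0})},
                           n_subjects=2, n_repeats=2)
        d1 = gen_pattern_dataset(spec, small_grid, seed=9)
        d2 = gen_pattern_dataset(spec, small_grid, seed=9)
        for subj in d1.dataset.subject_ids:
            for r1, r2 in zip(d1.dataset.subjects[subj],
                              d2.dataset.subjects[subj]):
                np.testing.assert_array_equal(r1, r2)

    def test_region_outside_mask_rejected(self, model_rdms, small_grid):
        comps = {"A": model_rdms["modelA"]}
        outside = geometry.VoxelMask.from_indices(small_grid, [(7, 7, 7)])
        inside = geometry.VoxelMask.from_indices(small_grid, [(1, 1, 1)])
        spec = MixtureSpec(components=comps, regions={"r": (outside, {"A": 1.0})},
                           n_subjects=1, n_repeats=1)
        with pytest.raises(ValueError, match="outside"):
            gen_pattern_dataset(spec, small_grid, seed=0, analysis_mask=inside)

    def test_noise_ceiling_decreases_with_sigma(self, model_rdms, small_grid,
                                                cube_roi):
        comps = {"A": model_rdms["modelA"]}
        ceilings = []
        for sigma in (1.0, 3.0, 6.0, 12.0):
            spec = MixtureSpec(components=comps,
                               regions={"r": (cube_roi, {"A": 1.0})},
                               sigma=sigma, n_subjects=8, n_repeats=4)
            data = gen_pattern_dataset(spec, small_grid, seed=21,
                                       analysis_mask=cube_roi)
            vals = [
                geometry.split_half_rsa_reliability(data.dataset.subjects[s])
                for s in data.dataset.subject_ids
            ]
            ceilings.append(np.nanmean(vals))
        assert all(a > b for a, b in zip(ceilings, ceilings[1:]))


class TestWindowedDataset:
    def test_schedules_required_and_checked(self, model_rdms, small_grid,
                                            cube_roi):
        comps = {"A": model_rdms["modelA"], "B": model_rdms["modelB"]}
        spec = MixtureSpec(components=comps,
                           regions={"r": (cube_roi, {"A": 1.0, "B": 1.0})},
                           n_subjects=1, n_repeats=1)
        with pytest.raises(ValueError, match="window_schedules"):
            gen_windowed_dataset(spec, small_grid, seed=0)
        with pytest.raises(ValueError, match="5 windows"):
            MixtureSpec(components=comps,
                        regions={"r": (cube_roi, {"A": 1.0})},
                        window_schedules={"A": (1.0, 1.0)})

    def test_five_windows_share_subjects(self, model_rdms, small_grid, cube_roi):
        comps = {"A": model_rdms["modelA"], "B": model_rdms["modelB"]}
        spec = MixtureSpec(components=comps,
                           regions={"r": (cube_roi, {"A": 1.0, "B": 1.0})},
                           n_subjects=3, n_repeats=2,
                           window_schedules={"A": (0.3, 0.9, 1.2, 0.9, 0.3),
                                             "B": (0.1, 0.4, 0.7, 1.0, 1.3)})
        windows = gen_windowed_dataset(spec, small_grid, seed=2,
                                       analysis_mask=cube_roi)
        assert len(windows) == 5
        ids = {w.dataset.subject_ids for w in windows}
        assert len(ids) == 1

    def test_scheduled_amplitude_tracks_weights(self, model_rdms, small_grid,
                                                cube_roi):
        # component A absent in window 0, dominant in window 2
        comps = {"A": model_rdms["modelA"], "B": model_rdms["modelB"]}
        spec = MixtureSpec(components=comps,
                           regions={"r": (cube_roi, {"A": 1.0, "B": 1.0})},
                           sigma=2.0, n_subjects=6, n_repeats=2,
                           window_schedules={"A": (0.0, 0.5, 2.0, 0.5, 0.0),
                                             "B": (0.5, 0.5, 0.5, 0.5, 0.5)})
        windows = gen_windowed_dataset(spec, small_grid, seed=4,
                                       analysis_mask=cube_roi)
        corr_by_window = []
        for w in windows:
            rhos = []
            for subj in w.dataset.subject_ids:
                avg = geometry.normalize_and_average(w.dataset.subjects[subj])
                nv = rdm_vector(geometry.neural_rdm(avg))
                rhos.append(spearman_rsa(nv, rdm_vector(comps["A"])).rho)
            corr_by_window.append(np.mean(rhos))
        assert corr_by_window[2] > corr_by_window[0] + 0.1


class TestFrameStack:
    def test_zero_velocity_gives_static_stack(self):
        stack = gen_frame_stack((10, 10), (0.0, 0.0), size=(24, 24), n_frames=8)
        for frame in stack.frames[1:]:
            np.testing.assert_array_equal(frame, stack.frames[0])

    def test_trajectory_bounds_checked(self):
        with pytest.raises(ValueError, match="leaves the frame"):
            gen_frame_stack((10, 20), (0.0, 2.0), size=(24, 24), n_frames=10)

    def test_deterministic(self):
        a = gen_frame_stack((8, 4), (0.5, 1.0), n_frames=10, seed=1)
        b = gen_frame_stack((8, 4), (0.5, 1.0), n_frames=10, seed=1)
        np.testing.assert_array_equal(a.frames, b.frames)
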