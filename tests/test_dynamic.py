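"""Gaze simulation, dynamic greedy encoding, and scene assembly."""

import numpy as np
import pytest
import scipy.stats

from dither.dynamic import (SpatioTemporalFilter, assemble_scene,
                            dynamic_greedy, dynamic_stimulus, error_vs_saccades,
                            exponential_kernel, generate_gaze,
                            jitter_benefit_ratio, saccades_to_reach)
from dither.greedy import run_greedy
from dither.synthetic import ReconstructionFilter
from tests.test_greedy import replay_refractory_audit, toy_dictionary


PATCH = (4, 6)


def tiny_scene(rng, shape=(40, 60)):
    return rng.uniform(-1, 1, size=shape)


class TestGaze:
    def test_periodic_without_variability(self, rng):
        scene = tiny_scene(rng)
        gaze = generate_gaze(scene, 5, mean_ms=50.0, sd_ms=0.0,
                             jitter_sd_px=0.0, frame_rate=120.0, seed=0,
                             patch_shape=PATCH)
        frames_per = np.bincount(gaze.fixation_of_frame)
        assert np.all(frames_per == round(50.0 / (1000 / 120)))
        for i in range(5):
            pos = gaze.frame_positions[gaze.fixation_of_frame == i]
            assert np.allclose(pos, gaze.fixation_centers[i])

    def test_jitter_increment_sd(self, rng):
        """Brownian per-frame increments recover the nominal 3 px SD."""
        scene = tiny_scene(rng, shape=(600, 600))
        gaze = generate_gaze(scene, 1, mean_ms=500 * (1000 / 120), sd_ms=0.0,
                             jitter_sd_px=3.0, seed=1, patch_shape=PATCH)
        assert gaze.n_frames == 500
        inc = np.diff(gaze.frame_positions, axis=0).ravel()
        se = 3.0 / np.sqrt(2 * inc.size)
        assert abs(inc.std(ddof=1) - 3.0) < 3 * se
        assert gaze.n_clamped == 0

    def test_flat_scene_uniform_fixations(self):
        """On a featureless scene the fixation sampler is uniform (chi-square)."""
        scene = np.zeros((14, 16))
        gaze = generate_gaze(scene, 10_000, mean_ms=10.0, sd_ms=0.0,
                             jitter_sd_px=0.0, seed=2, patch_shape=(4, 4))
        rows = gaze.fixation_centers[:, 0] - 2
        cols = gaze.fixation_centers[:, 1] - 2
        n_r, n_c = 11, 13
        counts = np.bincount((rows * n_c + cols).astype(int), minlength=n_r * n_c)
        chi = scipy.stats.chisquare(counts)
        assert chi.pvalue > 1e-3

    def test_scene_too_small(self, rng):
        with pytest.raises(ValueError):
            generate_gaze(np.zeros((3, 3)), 1, seed=0, patch_shape=PATCH)


class TestDynamicStimulus:
    def test_static_gaze_repeats_crop(self, rng):
        scene = tiny_scene(rng)
        gaze = generate_gaze(scene, 3, mean_ms=50.0, sd_ms=0.0,
                             jitter_sd_px=0.0, seed=3, patch_shape=PATCH)
        frames = dynamic_stimulus(scene, gaze, PATCH)
        for i in range(3):
            sel = frames[gaze.fixation_of_frame == i]
            assert np.all(sel == sel[0])

    def test_translation_equivariance(self, rng):
        scene = tiny_scene(rng)
        gaze = generate_gaze(scene, 1, mean_ms=10.0, sd_ms=0.0,
                             jitter_sd_px=0.0, seed=4, patch_shape=PATCH)
        f0 = dynamic_stimulus(scene, gaze, PATCH)[0]
        shifted = gaze.frame_positions + np.array([0.0, 1.0])
        object.__setattr__(gaze, "frame_positions", shifted)
        f1 = dynamic_stimulus(scene, gaze, PATCH)[0]
        assert np.array_equal(f0[:, 1:], f1[:, :-1])


class TestDynamicGreedy:
    def make_instance(self, rng, n_cells=4, n_el=6):
        filt = ReconstructionFilter(
            A=rng.normal(size=(PATCH[0] * PATCH[1], n_cells)) * 0.5,
            grid_shape=PATCH, pixel_pitch_um=44.0)
        D = rng.uniform(0, 1, size=(n_cells, n_el)) * (rng.random((n_cells, n_el)) < 0.7)
        return filt, toy_dictionary(D, filters=filt)

    def test_impulse_kernel_equals_static_greedy(self, rng):
        """With a single-frame kernel the dynamic encoder is the static one."""
        filt, dic = self.make_instance(rng)
        target = rng.uniform(-1, 1, size=PATCH)
        st = SpatioTemporalFilter(spatial=filt, kernel=np.array([1.0]))
        T = 30
        dyn = dynamic_greedy(target[None, :, :], st, dic, choices_per_frame=T,
                             refractory_params=(1.1, 100))  # no masking
        static = run_greedy(target, filt, dic, T_max=T,
                            refractory_params=(1.1, 100))
        assert dyn.picks.element_id.tolist() == static.element_ids.tolist()
        final = dyn.recon_frames[0]
        from dither.reconstruction import reconstruct

        assert np.allclose(final,
                           reconstruct(filt, static.cumulative_expected))

    def test_matches_windowed_objective_oracle(self, rng):
        """Brute-force evaluation of the lookahead objective at every choice."""
        filt, dic = self.make_instance(rng, n_cells=3, n_el=4)
        frames = rng.uniform(-1, 1, size=(2, *PATCH))
        kern = np.array([1.0, 0.5])
        st = SpatioTemporalFilter(spatial=filt, kernel=kern)
        theta, window = 0.1, 3
        res = dynamic_greedy(frames, st, dic, choices_per_frame=3,
                             refractory_params=(theta, window))

        # oracle: rebuild reconstructions from scratch at every choice
        G = filt.A @ dic.D
        kmass, ksq = kern.sum(), np.sum(kern**2)
        picks = {(int(r.frame), int(r.slot_in_frame)): int(r.element_id)
                 for r in res.picks.itertuples()}
        history = []                      # (step, frame, element)
        step = 1
        for f in range(2):
            for slot in range(3):
                recon_f = np.zeros(PATCH[0] * PATCH[1])
                for (s_, f_, e_) in history:
                    lag = f - f_
                    if 0 <= lag < kern.size:
                        recon_f += kern[lag] * G[:, e_]
                resid = frames[f].ravel() - recon_f
                best, best_val = dic.null_index, 0.0
                for c in range(dic.n_elements):
                    blocked = False
                    for (s_, f_, e_) in history:
                        if step - s_ <= window and np.any(
                                (dic.D[:, c] > theta) & (dic.D[:, e_] > theta)):
                            blocked = True
                    if blocked or c == dic.null_index:
                        continue
                    val = (-2 * kmass * (resid @ G[:, c])
                           + ksq * (G[:, c] @ G[:, c] + dic.v[c]))
                    if val < best_val - 1e-12:
                        best, best_val = c, val
                chosen = picks.get((f, slot))
                if best == dic.null_index:
                    assert chosen is None
                else:
                    assert chosen == best
                    history.append((step, f, best))
                step += 1

    def test_refractory_audit_across_frames(self, rng):
        filt, dic = self.make_instance(rng)
        frames = rng.uniform(-1, 1, size=(6, *PATCH))
        st = SpatioTemporalFilter(spatial=filt, kernel=exponential_kernel(3, 1.5))
        res = dynamic_greedy(frames, st, dic, choices_per_frame=4,
                             refractory_params=(0.1, 7))
        assert len(res.picks) > 0
        assert replay_refractory_audit(res.picks, dic, 0.1, 7) == 0

    def test_empty_stream(self, rng):
        filt, dic = self.make_instance(rng)
        st = SpatioTemporalFilter(spatial=filt, kernel=np.array([1.0]))
        res = dynamic_greedy(np.zeros((0, *PATCH)), st, dic)
        assert len(res.picks) == 0
        assert res.recon_frames.shape == (0, *PATCH)

    def test_empty_kernel_rejected(self, rng):
        filt, _ = self.make_instance(rng)
        with pytest.raises(ValueError):
            SpatioTemporalFilter(spatial=filt, kernel=np.array([]))


class TestAssembly:
    def make_gaze(self, positions, scene_shape, patch):
        positions = np.asarray(positions, dtype=float)
        from dither.dynamic import GazeTrace

        return GazeTrace(fixation_centers=positions,
                         onset_times_ms=np.zeros(len(positions)),
                         frame_positions=positions,
                         fixation_of_frame=np.arange(len(positions)),
                         frame_rate=120.0)

    def test_single_fixation_identity(self, rng):
        patch = rng.normal(size=PATCH)
        gaze = self.make_gaze([[10, 10]], (30, 30), PATCH)
        out = assemble_scene(patch[None], gaze, (30, 30))
        r, c = 10 - PATCH[0] // 2, 10 - PATCH[1] // 2
        assert np.allclose(out.image[r:r + PATCH[0], c:c + PATCH[1]], patch)
        assert np.isnan(out.image[0, 0])
        assert out.coverage.sum() == PATCH[0] * PATCH[1]

    def test_disjoint_and_overlapping_averaging(self):
        ph, pw = PATCH
        zeros, ones = np.zeros(PATCH), np.ones(PATCH)
        gaze = self.make_gaze([[10, 10], [10, 13]], (30, 40), PATCH)
        out = assemble_scene(np.stack([zeros, ones]), gaze, (30, 40))
        r = 10 - ph // 2
        c0, c1 = 10 - pw // 2, 13 - pw // 2
        overlap = out.image[r:r + ph, c1:c0 + pw]
        assert np.allclose(overlap, 0.5)
        assert np.allclose(out.image[r:r + ph, c0:c1], 0.0)
        assert np.allclose(out.image[r:r + ph, c0 + pw:c1 + pw], 1.0)

    def test_coverage_conservation(self, rng):
        frames = rng.normal(size=(5, *PATCH))
        centers = [[8 + i, 10 + 2 * i] for i in range(5)]
        gaze = self.make_gaze(centers, (40, 50), PATCH)
        out = assemble_scene(frames, gaze, (40, 50))
        assert out.coverage.sum() == 5 * PATCH[0] * PATCH[1]


class TestSaccadeCurves:
    def test_error_decreases_with_coverage(self, rng):
        scene = tiny_scene(rng, (20, 30))
        centers = [[5, 5], [12, 20], [8, 12], [14, 8]]
        gaze = TestAssembly().make_gaze(centers, (20, 30), PATCH)
        frames = dynamic_stimulus(scene, gaze, PATCH)   # perfect reconstruction
        curve = error_vs_saccades(frames, gaze, scene)
        assert np.all(np.diff(curve.relative_mse) <= 1e-12)
        assert curve.relative_mse_covered.iloc[-1] == pytest.approx(0.0)

    def test_saccade_ratio_helpers(self):
        without = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        with_j = np.array([0.8, 0.5, 0.45, 0.42, 0.40])
        assert saccades_to_reach(without, 0.7) == 3
        assert saccades_to_reach(with_j, 10.0) == 1
        assert saccades_to_reach(with_j, 0.1) is None
        # matched level is the worse run's final error (0.5)
        assert jitter_benefit_ratio(without, with_j) == pytest.approx(5 / 2)
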