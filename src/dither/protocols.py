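"""Frozen study protocols on synthetic fixtures.

The functions here pin the study conditions used throughout the test-suite,
the examples, and the reproduction script: a scaled-down checkerboard fixture
(quarter array, ~100 cells) for the bound-gap and subsampling analyses, a
full-array fixture for dictionary-size checks, and a sparse wide-field
fixture for the naturalistic-viewing study.  All randomness flows from the
single ``seed`` argument via numpy's SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_rng
from .bounds import fractional_gap, perfect_control, relaxed_joint
from .dynamic import (SpatioTemporalFilter, dynamic_greedy, dynamic_stimulus,
                      error_vs_saccades, exponential_kernel, filter_support_mask,
                      generate_gaze, jitter_benefit_ratio)
from .greedy import GreedyWorkspace, run_greedy
from .hardware import subsampling_curve
from .synthetic import (CellPopulation, ElectrodeArray, ReconstructionFilter,
                        StimDictionary, VisualTarget, make_checkerboard_targets,
                        make_dictionary, make_retina)

__all__ = ["Fixture", "default_fixture", "paper_scale_fixture",
           "dynamic_fixture", "make_natural_scene", "checkerboard_bounds_study",
           "subsampling_study", "dynamic_jitter_study"]


@dataclass(frozen=True)
class Fixture:
    """A complete synthetic preparation: array, cells, filters, dictionary."""

    array: ElectrodeArray
    population: CellPopulation
    filters: ReconstructionFilter
    dictionary: StimDictionary


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def default_fixture(seed: int = 0) -> Fixture:
    """Quarter-array checkerboard fixture: 8x16 electrodes, ~50 ON + ~50 OFF.

    The pixel grid (8 x 16 at 60 um) matches the electrode span and keeps the
    target dimensionality comparable to the cell count, mirroring the regime
    of the ex vivo analyses where the checkerboard squares are coarse enough
    for the parasol mosaics to resolve them.
    """
    s1, s2 = _seeds(seed, 2)
    array, pop, filt = make_retina(
        rows=8, cols=16, pitch_um=60.0, n_on=50, n_off=50, rf_radius_um=45.0,
        gain=0.2, seed=s1, pixel_pitch_um=60.0, grid_shape=(8, 16))
    dictionary = make_dictionary(array, pop, filt, seed=s2)
    return Fixture(array, pop, filt, dictionary)


def paper_scale_fixture(seed: int = 0, n_on: int = 350, n_off: int = 350) -> Fixture:
    """Full 16x32 array with ~700 parasol-like cells on the standard 40x80 grid."""
    s1, s2 = _seeds(seed, 2)
    array, pop, filt = make_retina(
        rows=16, cols=32, pitch_um=60.0, n_on=n_on, n_off=n_off,
        rf_radius_um=45.0, gain=0.2, seed=s1, pixel_pitch_um=44.0,
        grid_shape=(40, 80))
    dictionary = make_dictionary(array, pop, filt, seed=s2)
    return Fixture(array, pop, filt, dictionary)


def dynamic_fixture(seed: int = 0) -> Fixture:
    """Sparse wide-field fixture for the naturalistic-viewing study.

    Full 16x32 array under the standard 40 x 80 (44 um) stimulus grid, with a
    deliberately sparse population (60 ON + 60 OFF, 130 um filters, unit
    gain): the per-window stimulation budget of the scaled-down dynamic runs
    (12 choices per frame instead of 83) supports proportionally fewer cells,
    and unit gain keeps a cell's full contribution reachable from the spikes
    evoked within one visual-integration window.
    """
    s1, s2 = _seeds(seed, 2)
    array, pop, filt = make_retina(
        rows=16, cols=32, pitch_um=60.0, n_on=60, n_off=60, rf_radius_um=130.0,
        gain=1.0, seed=s1, pixel_pitch_um=44.0, grid_shape=(40, 80))
    dictionary = make_dictionary(array, pop, filt, seed=s2)
    return Fixture(array, pop, filt, dictionary)


def make_natural_scene(shape: tuple[int, int] = (160, 320), seed: int = 0,
                       spectral_slope: float = 1.0) -> np.ndarray:
    """Seeded naturalistic grayscale scene with a 1/f amplitude spectrum.

    Natural images have approximately power-law spatial spectra; a random
    phase field with 1/f^slope amplitude reproduces that second-order
    structure.  Intensities are scaled to [-1, 1].
    """
    rng = as_rng(seed)
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    amp = 1.0 / f**spectral_slope
    amp[0, 0] = 0.0
    phase = rng.uniform(0, 2 * np.pi, size=shape)
    spectrum = amp * np.exp(1j * phase)
    img = np.real(np.fft.ifft2(spectrum))
    img -= img.mean()
    return img / np.abs(img).max()


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

def checkerboard_bounds_study(seed: int = 0, n_targets: int = 20,
                              T_max: int = 10_000,
                              refractory_params: tuple[float, int] = (0.1, 100),
                              fixture: Fixture | None = None) -> pd.DataFrame:
    """Greedy vs relaxed-joint vs perfect-control errors on checkerboard targets.

    Per target: the greedy expected error (bias + variance of the produced
    sequence), the convex usage-relaxation lower bound, and the
    perfect-control error floor, all as relative (objective / ||s||^2)
    values, plus the two fractional gaps
        gap_greedy     = (greedy - relaxed) / greedy
        gap_dictionary = (relaxed - perfect) / relaxed.
    """
    s_fix, s_targ = _seeds(seed, 2)
    fix = fixture if fixture is not None else default_fixture(s_fix)
    targets = make_checkerboard_targets(n_targets, fix.filters.grid_shape, s_targ)
    ws = GreedyWorkspace(fix.filters, fix.dictionary)
    rows = []
    for i, t in enumerate(targets):
        seq = run_greedy(t, fix.filters, fix.dictionary, T_max=T_max,
                         refractory_params=refractory_params, workspace=ws)
        err_g = seq.error.relative_mse
        relax = relaxed_joint(t, fix.filters, fix.dictionary)
        err_r = relax.relative_objective
        err_p = perfect_control(t, fix.filters).relative_mse
        rows.append((i, err_g, err_r, err_p,
                     fractional_gap(err_g, err_r), fractional_gap(err_r, err_p),
                     seq.n_stimulations))
    return pd.DataFrame(rows, columns=["target", "err_greedy", "err_relaxed",
                                       "err_perfect", "gap_greedy",
                                       "gap_dictionary", "n_stimulations"])


def subsampling_study(seed: int = 0, n_targets: int = 20, T_max: int = 10_000,
                      fractions=(0.5, 1.0),
                      fixture: Fixture | None = None) -> pd.DataFrame:
    """Held-out greedy error with the dictionary restricted to top electrodes.

    Disjoint 20-target train/eval checkerboard sets: the training runs rank
    electrodes by stimulation frequency, evaluation reruns greedy with the
    restricted and full dictionaries.
    """
    s_fix, s_train, s_eval = _seeds(seed, 3)
    fix = fixture if fixture is not None else default_fixture(s_fix)
    shape = fix.filters.grid_shape
    train = make_checkerboard_targets(n_targets, shape, s_train)
    evals = make_checkerboard_targets(n_targets, shape, s_eval)
    return subsampling_curve(fix.filters, fix.dictionary, train, evals,
                             fractions=fractions, T_max=T_max)


def fractional_error_increase(curve: pd.DataFrame, fraction: float = 0.5) -> float:
    """(mean error at the given fraction - full-dictionary error) / full error."""
    full = float(curve.loc[curve.fraction == 1.0, "greedy_error"].iloc[0])
    sub = float(curve.loc[curve.fraction == fraction, "greedy_error"].iloc[0])
    return (sub - full) / full


def dynamic_jitter_study(seed: int = 0, n_fixations: int = 100,
                         choices_per_frame: int = 12, n_replicates: int = 5,
                         scene_shape: tuple[int, int] = (160, 320),
                         jitter_sd_px: float = 3.0,
                         fixture: Fixture | None = None) -> pd.DataFrame:
    """Saccade-count benefit of fixational jitter at matched final error.

    For each replicate, the same scene and fixture are encoded with and
    without Brownian fixational jitter; the assembled-scene error curve is
    recorded after each saccade and the saccade-count ratio at the matched
    attained error level is reported (column ``ratio``).
    """
    s_fix, s_scene, *reps = _seeds(seed, 2 + n_replicates)
    fix = fixture if fixture is not None else dynamic_fixture(s_fix)
    scene = make_natural_scene(scene_shape, s_scene)
    patch_shape = fix.filters.grid_shape
    st = SpatioTemporalFilter(spatial=fix.filters, kernel=exponential_kernel())
    sup = filter_support_mask(fix.filters)
    ws = GreedyWorkspace(fix.filters, fix.dictionary)
    rows = []
    for k, rep_seed in enumerate(reps):
        curves = {}
        for label, jit in (("with", jitter_sd_px), ("without", 0.0)):
            gaze = generate_gaze(scene, n_fixations, jitter_sd_px=jit,
                                 seed=rep_seed, patch_shape=patch_shape)
            frames = dynamic_stimulus(scene, gaze, patch_shape)
            result = dynamic_greedy(frames, st, fix.dictionary,
                                    choices_per_frame=choices_per_frame,
                                    workspace=ws)
            curve = error_vs_saccades(result.recon_frames, gaze, scene, sup)
            curves[label] = curve["relative_mse"].to_numpy()
        ratio = jitter_benefit_ratio(curves["without"], curves["with"])
        rows.append((k, curves["with"][-1], curves["without"][-1], ratio))
    return pd.DataFrame(rows, columns=["replicate", "final_err_with",
                                       "final_err_without", "ratio"])
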