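"""Synthetic retina fixtures: electrode arrays, ON/OFF mosaics, dictionaries, targets.

This module replaces the ex vivo calibration products of a lab-prototype
epiretinal interface with seeded synthetic equivalents:

* a triangular-lattice multi-electrode array (default 16 x 32 at 60 um pitch),
* mosaics of ON and OFF cells with signed Gaussian reconstruction filters,
* a single-electrode stimulation dictionary whose per-cell activation
  probabilities follow sigmoids in log current amplitude, with activation
  thresholds growing with cell-electrode distance (so low amplitudes are
  selective and high amplitudes co-activate several cells),
* random black/white checkerboard targets.

All geometry is in micrometers with the array centered at the origin; pixel
indexing is 0-based row-major with pixel (0, 0) at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng

__all__ = [
    "ElectrodeArray",
    "CellPopulation",
    "ReconstructionFilter",
    "StimDictionary",
    "VisualTarget",
    "make_electrode_array",
    "make_retina",
    "make_dictionary",
    "make_checkerboard_targets",
    "sample_responses",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeArray:
    """Planar multi-electrode array on a triangular lattice.

    positions : (n_electrodes, 2) float array, um, array center at origin.
    """

    positions: np.ndarray
    rows: int
    cols: int
    pitch_um: float

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)


@dataclass(frozen=True)
class CellPopulation:
    """ON/OFF cell mosaics with receptive-field geometry.

    types are +1 (ON) or -1 (OFF); rf_center_um are (n, 2) receptive-field
    centers; rf_radius_um is the Gaussian sigma of each filter; soma_um are
    positions on the array used for electrical activation distances; gain is
    the peak filter amplitude in expected-spike-count units.
    """

    ids: np.ndarray
    types: np.ndarray
    rf_center_um: np.ndarray
    rf_radius_um: np.ndarray
    soma_um: np.ndarray
    gain: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.ids.shape[0]

    @property
    def on_mask(self) -> np.ndarray:
        return self.types > 0


@dataclass(frozen=True)
class ReconstructionFilter:
    """Linear decoding filters A (pixels x cells) on a fixed pixel grid."""

    A: np.ndarray
    grid_shape: tuple[int, int]
    pixel_pitch_um: float

    @property
    def n_pixels(self) -> int:
        return self.A.shape[0]

    @property
    def n_cells(self) -> int:
        return self.A.shape[1]

    def pixel_centers(self) -> np.ndarray:
        """(n_pixels, 2) physical centers (x, y) in um, row-major order.

        Row 0 is the top of the image (largest y).
        """
        h, w = self.grid_shape
        xs = (np.arange(w) - (w - 1) / 2.0) * self.pixel_pitch_um
        ys = ((h - 1) / 2.0 - np.arange(h)) * self.pixel_pitch_um
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def column_image(self, n: int) -> np.ndarray:
        return self.A[:, n].reshape(self.grid_shape)

    def column_sq_norms(self) -> np.ndarray:
        """||a_n||^2 for every cell, used in the variance penalty."""
        return np.einsum("ij,ij->j", self.A, self.A)


@dataclass(frozen=True)
class VisualTarget:
    """A target stimulus: signed pixel intensities in [-1, +1]."""

    pixels: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def ravel(self) -> np.ndarray:
        return self.pixels.ravel().astype(float)

    def sq_norm(self) -> float:
        return float(np.sum(self.pixels.astype(float) ** 2))


@dataclass
class StimDictionary:
    """Calibrated single-electrode stimulation dictionary.

    Retained (usable) elements only are stored in the matrix view ``D``
    (cells x elements); the final column is the null element (all-zero
    probabilities) which lets the encoder skip stimulation.  ``candidates``
    keeps the metadata of every generated element, including the ones dropped
    by the axon-bundle flag or the p >= 0.01 retention rule.
    """

    D: np.ndarray                      # (n_cells, n_elements) activation probabilities
    v: np.ndarray                      # (n_elements,) per-element decoding variance
    electrode: np.ndarray              # (n_elements,) electrode id, -1 for null
    amplitude_uA: np.ndarray           # (n_elements,) current amplitude, 0 for null
    electrode_positions: np.ndarray    # (n_electrodes, 2) um
    amplitudes_uA: np.ndarray          # the calibration amplitude grid
    candidates: pd.DataFrame = field(repr=False)

    @property
    def n_elements(self) -> int:
        return self.D.shape[1]

    @property
    def n_cells(self) -> int:
        return self.D.shape[0]

    @property
    def null_index(self) -> int:
        return self.n_elements - 1

    def element_probabilities(self, element_id: int) -> np.ndarray:
        if not 0 <= element_id < self.n_elements:
            raise KeyError(f"unknown dictionary element {element_id}")
        return self.D[:, element_id]

    def element_positions(self) -> np.ndarray:
        """(n_elements, 2) electrode position per element; null sits at +inf."""
        pos = np.full((self.n_elements, 2), np.inf)
        real = self.electrode >= 0
        pos[real] = self.electrode_positions[self.electrode[real]]
        return pos

    def restrict_to_electrodes(self, electrodes) -> "StimDictionary":
        """Sub-dictionary with elements on the given electrodes plus the null."""
        keep = np.isin(self.electrode, np.asarray(list(electrodes), dtype=int))
        keep[self.null_index] = True
        if keep.sum() <= 1:
            raise ValueError("restriction removed every stimulating element")
        return StimDictionary(
            D=self.D[:, keep],
            v=self.v[keep],
            electrode=self.electrode[keep],
            amplitude_uA=self.amplitude_uA[keep],
            electrode_positions=self.electrode_positions,
            amplitudes_uA=self.amplitudes_uA,
            candidates=self.candidates,
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_electrode_array(rows: int, cols: int, pitch_um: float) -> ElectrodeArray:
    """Triangular (offset-row) lattice; interior nearest-neighbor distance = pitch."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if pitch_um <= 0:
        raise ValueError("electrode pitch must be positive")
    row_spacing = pitch_um * np.sqrt(3.0) / 2.0
    xs = []
    for r in range(rows):
        offset = 0.25 * pitch_um if r % 2 == 0 else -0.25 * pitch_um
        x = np.arange(cols) * pitch_um + offset
        y = np.full(cols, r * row_spacing)
        xs.append(np.column_stack([x, y]))
    pos = np.concatenate(xs, axis=0)
    pos -= pos.mean(axis=0)
    return ElectrodeArray(positions=pos, rows=rows, cols=cols, pitch_um=pitch_um)


def _sample_mosaic(n: int, bounds: tuple[float, float, float, float],
                   min_dist: float, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing mosaic sampler: n points with pairwise distance > min_dist."""
    x0, x1, y0, y1 = bounds
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20000 * max(n, 1)
    while len(pts) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                "could not place mosaic: exclusion distance too large for the "
                f"requested density ({len(pts)}/{n} placed)"
            )
        attempts += 1
        cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        if all(np.linalg.norm(cand - p) > min_dist for p in pts):
            pts.append(cand)
    return np.array(pts).reshape(n, 2)


def make_retina(rows: int = 16, cols: int = 32, pitch_um: float = 60.0,
                n_on: int = 0, n_off: int = 0, rf_radius_um: float = 45.0,
                gain: float = 0.2, seed=None, *,
                pixel_pitch_um: float = 44.0,
                grid_shape: tuple[int, int] | None = None,
                truncation_sigmas: float = 3.0,
                exclusion_fraction: float = 0.5,
                soma_jitter_um: float = 10.0,
                ) -> tuple[ElectrodeArray, CellPopulation, ReconstructionFilter]:
    """Generate an electrode array, ON/OFF mosaics, and reconstruction filters.

    Filters are signed 2-D Gaussians (positive for ON, negative for OFF) with
    sigma ``rf_radius_um``, truncated at ``truncation_sigmas`` sigma, and peak
    amplitude ``gain`` (the expected-spike-count scale of the linear decoder).
    Same-type receptive-field centers form a mosaic: pairwise distances exceed
    ``exclusion_fraction`` times the RF diameter (2 sigma).

    If ``grid_shape`` is None the pixel grid is sized to cover the electrode
    array plus one pitch of margin at ``pixel_pitch_um`` per pixel.
    """
    if rf_radius_um <= 0:
        raise ValueError("rf_radius_um must be positive")
    if n_on < 0 or n_off < 0:
        raise ValueError("cell counts must be non-negative")
    rng = as_rng(seed)
    array = make_electrode_array(rows, cols, pitch_um)

    pad = pitch_um
    x0, y0 = array.positions.min(axis=0) - pad
    x1, y1 = array.positions.max(axis=0) + pad
    if grid_shape is None:
        h = max(1, int(np.ceil((y1 - y0) / pixel_pitch_um)))
        w = max(1, int(np.ceil((x1 - x0) / pixel_pitch_um)))
        grid_shape = (h, w)

    min_dist = exclusion_fraction * 2.0 * rf_radius_um
    centers_on = _sample_mosaic(n_on, (x0, x1, y0, y1), min_dist, rng)
    centers_off = _sample_mosaic(n_off, (x0, x1, y0, y1), min_dist, rng)
    centers = np.vstack([centers_on, centers_off])
    types = np.concatenate([np.ones(n_on, dtype=int), -np.ones(n_off, dtype=int)])
    n_cells = n_on + n_off
    soma = centers + rng.normal(0.0, soma_jitter_um, size=(n_cells, 2))

    population = CellPopulation(
        ids=np.arange(n_cells),
        types=types,
        rf_center_um=centers,
        rf_radius_um=np.full(n_cells, float(rf_radius_um)),
        soma_um=soma,
        gain=np.full(n_cells, float(gain)),
    )

    filters = _build_filters(population, grid_shape, pixel_pitch_um, truncation_sigmas)
    return array, population, filters


def _build_filters(population: CellPopulation, grid_shape: tuple[int, int],
                   pixel_pitch_um: float, truncation_sigmas: float) -> ReconstructionFilter:
    filt = ReconstructionFilter(
        A=np.zeros((grid_shape[0] * grid_shape[1], max(population.n_cells, 0))),
        grid_shape=tuple(grid_shape), pixel_pitch_um=float(pixel_pitch_um))
    if population.n_cells == 0:
        return filt
    px = filt.pixel_centers()
    A = np.zeros((px.shape[0], population.n_cells))
    for n in range(population.n_cells):
        d2 = np.sum((px - population.rf_center_um[n]) ** 2, axis=1)
        sigma = population.rf_radius_um[n]
        col = population.gain[n] * np.exp(-d2 / (2.0 * sigma**2))
        col[d2 > (truncation_sigmas * sigma) ** 2] = 0.0
        A[:, n] = population.types[n] * col
    return ReconstructionFilter(A=A, grid_shape=tuple(grid_shape),
                                pixel_pitch_um=float(pixel_pitch_um))


# dictionary generation ------------------------------------------------------

#: minimum activation probability for an element to be retained
RETENTION_P = 0.01


def activation_probability(amplitude_uA, distance_um, *, threshold0_uA: float = 2.0,
                           lambda_um: float = 40.0, slope: float = 6.0) -> np.ndarray:
    """Sigmoidal activation probability in log amplitude.

    The half-activation threshold grows exponentially with soma-electrode
    distance, t(d) = t0 * exp(d / lambda_um); the response probability is
    logistic in log amplitude with the given slope.  Probabilities below 1e-4
    are clamped to zero (thresholds far beyond the amplitude range).
    """
    a = np.asarray(amplitude_uA, dtype=float)
    t = threshold0_uA * np.exp(np.asarray(distance_um, dtype=float) / lambda_um)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-slope * (np.log(a) - np.log(t))))
    p = np.where(p < 1e-4, 0.0, p)
    return p


def make_dictionary(array: ElectrodeArray, population: CellPopulation,
                    filters: ReconstructionFilter, n_amplitudes: int = 40,
                    amp_range_uA: tuple[float, float] = (0.1, 4.0),
                    selectivity: float = 40.0, axon_fraction: float = 0.1,
                    seed=None, *, threshold0_uA: float = 2.0,
                    slope: float = 6.0) -> StimDictionary:
    """Build a calibrated-like single-electrode stimulation dictionary.

    Every (electrode, amplitude) pair on a logarithmic amplitude grid is a
    candidate element.  ``selectivity`` is the distance constant (um) of the
    activation thresholds: larger values recruit more distant cells, making
    elements less selective.  A fraction ``axon_fraction`` of high-amplitude
    elements is flagged as axon-bundle activation and excluded.  Elements are
    retained only if they activate at least one cell with probability >= 0.01,
    and a single null element (zero probability for every cell) is appended.
    """
    if population.n_cells != filters.n_cells:
        raise ValueError("population and filters disagree on the number of cells")
    if n_amplitudes < 1:
        raise ValueError("need at least one amplitude")
    lo, hi = amp_range_uA
    if not (0 < lo < hi):
        raise ValueError("amplitude range must satisfy 0 < lo < hi")
    rng = as_rng(seed)
    amps = np.geomspace(lo, hi, n_amplitudes)

    n_e = array.n_electrodes
    n_c = population.n_cells
    if n_c:
        dist = np.linalg.norm(
            array.positions[:, None, :] - population.soma_um[None, :, :], axis=-1)
        # (electrodes, amplitudes, cells)
        probs = activation_probability(
            amps[None, :, None], dist[:, None, :],
            threshold0_uA=threshold0_uA, lambda_um=selectivity, slope=slope)
    else:
        probs = np.zeros((n_e, n_amplitudes, 0))

    elec_idx = np.repeat(np.arange(n_e), n_amplitudes)
    amp_idx = np.tile(np.arange(n_amplitudes), n_e)
    flat_p = probs.reshape(n_e * n_amplitudes, n_c)

    # axon-bundle emulation: high-amplitude elements (top half of the grid)
    # are flagged at random so that the overall flagged fraction ~ axon_fraction
    high = amp_idx >= n_amplitudes // 2
    axon = np.zeros(flat_p.shape[0], dtype=bool)
    if axon_fraction > 0 and high.any():
        p_flag = min(1.0, axon_fraction * flat_p.shape[0] / high.sum())
        axon[high] = rng.random(high.sum()) < p_flag

    max_p = flat_p.max(axis=1) if n_c else np.zeros(flat_p.shape[0])
    retained = (max_p >= RETENTION_P) & ~axon

    candidates = pd.DataFrame({
        "element_id": np.arange(flat_p.shape[0]),
        "electrode_id": elec_idx,
        "amplitude_uA": amps[amp_idx],
        "axon_bundle": axon,
        "retained": retained,
    })

    D = flat_p[retained].T                      # (cells, retained elements)
    a_sq = filters.column_sq_norms()
    v = (a_sq[:, None] * D * (1.0 - D)).sum(axis=0) if n_c else np.zeros(D.shape[1])

    # append the null element
    D = np.concatenate([D, np.zeros((n_c, 1))], axis=1)
    v = np.concatenate([v, [0.0]])
    electrode = np.concatenate([elec_idx[retained], [-1]])
    amplitude = np.concatenate([amps[amp_idx[retained]], [0.0]])

    return StimDictionary(
        D=D, v=v, electrode=electrode.astype(int), amplitude_uA=amplitude,
        electrode_positions=array.positions.copy(), amplitudes_uA=amps,
        candidates=candidates,
    )


def make_checkerboard_targets(n_targets: int, grid_shape: tuple[int, int],
                              seed=None) -> list[VisualTarget]:
    """i.i.d. equiprobable +/-1 black/white checkerboard targets."""
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = as_rng(seed)
    out = []
    for _ in range(n_targets):
        pix = rng.integers(0, 2, size=grid_shape) * 2 - 1
        out.append(VisualTarget(pixels=pix.astype(float)))
    return out


def sample_responses(dictionary: StimDictionary, element_id: int,
                     n_trials: int, seed=None) -> np.ndarray:
    """Bernoulli spike draws for one dictionary element: (trials x cells) 0/1."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    p = dictionary.element_probabilities(element_id)
    rng = as_rng(seed)
    return (rng.random((n_trials, p.size)) < p[None, :]).astype(np.int64)
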