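"""Greedy temporal dithering: per-step element selection with refractory masking
and optional spatial multiplexing.

At each time step the encoder picks the dictionary element that minimizes

    || s - A (P + p_c) ||^2  +  sum_n ||a_n||^2 p_{n,c} (1 - p_{n,c})

over the currently *valid* elements, where P is the cumulative expected
response of the sequence so far.  Validity implements refractoriness: an
element is masked if any cell it activates with probability > theta was
targeted with probability > theta within the last ``window`` steps.  The null
element (all-zero probabilities) is always valid, so the per-step objective is
non-increasing and the run stops early once no stimulation can reduce it.

With spatial multiplexing enabled, several elements are chosen greedily within
one time step; after each pick, elements on electrodes within the exclusion
radius of an already-picked electrode are disabled for the rest of the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng
from .reconstruction import ErrorReport
from .synthetic import ReconstructionFilter, StimDictionary, VisualTarget

__all__ = ["RefractoryState", "StimulationSequence", "valid_mask",
           "greedy_step", "run_greedy"]


@dataclass
class RefractoryState:
    """Tracks which cells were recently targeted (probability > theta).

    ``blocked_until[n]`` is the last step index at which cell n is still
    off-limits; an element targeting cell n is invalid at steps t with
    t <= blocked_until[n].  A cell targeted at step t is blocked for the next
    ``window`` steps, i.e. until step t + window inclusive.
    """

    n_cells: int
    theta: float = 0.1
    window: int = 100
    step: int = 1
    blocked_until: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.blocked_until is None:
            self.blocked_until = np.zeros(self.n_cells, dtype=np.int64)

    def blocked_cells(self) -> np.ndarray:
        return self.blocked_until >= self.step

    def register_choice(self, p_c: np.ndarray) -> None:
        """Mark cells targeted by a chosen element (p > theta) as refractory."""
        targeted = np.asarray(p_c) > self.theta
        if targeted.any():
            self.blocked_until[targeted] = self.step + self.window

    def advance(self) -> None:
        self.step += 1


def valid_mask(dictionary: StimDictionary, state: RefractoryState) -> np.ndarray:
    """Boolean vector over elements: the per-step valid set D_t."""
    blocked = state.blocked_cells()
    if not blocked.any():
        return np.ones(dictionary.n_elements, dtype=bool)
    hits = (dictionary.D[blocked, :] > state.theta).any(axis=0)
    mask = ~hits
    mask[dictionary.null_index] = True
    return mask


def greedy_step(target, filters: ReconstructionFilter,
                cumulative_expected_response: np.ndarray,
                dictionary: StimDictionary,
                mask: np.ndarray) -> tuple[int, float]:
    """One greedy choice by direct evaluation of the objective.

    Returns (element id, objective value after the choice).  Ties break toward
    the lowest element id.  This direct form is the reference for the faster
    incremental update used by :func:`run_greedy`.
    """
    s = target.ravel() if isinstance(target, VisualTarget) else np.asarray(target, float).ravel()
    P = np.asarray(cumulative_expected_response, dtype=float)
    resid = s - filters.A @ P
    G = filters.A @ dictionary.D                      # (pixels, elements)
    bias = np.sum(resid**2) - 2.0 * (G.T @ resid) + np.einsum("ij,ij->j", G, G)
    obj = bias + dictionary.v
    obj = np.where(mask, obj, np.inf)
    choice = int(np.argmin(obj))                      # argmin takes the first tie
    return choice, float(obj[choice])


@dataclass
class StimulationSequence:
    """Ordered record of a greedy run.

    ``picks`` has one row per chosen (non-null) element with columns
    step, slot, element_id, electrode_id, amplitude_uA, objective (the running
    objective value after that pick).  ``objective_trace`` holds the objective
    after every completed step, starting from ||s||^2 before any stimulation.
    """

    picks: pd.DataFrame
    objective_trace: np.ndarray
    cumulative_expected: np.ndarray
    n_steps: int
    target_sq_norm: float
    error: ErrorReport
    theta: float
    window: int
    exclusion_radius_um: float
    max_per_step: int
    sampled_responses: np.ndarray | None = None
    sample_seed: int | None = None

    @property
    def element_ids(self) -> np.ndarray:
        return self.picks["element_id"].to_numpy()

    @property
    def n_stimulations(self) -> int:
        return len(self.picks)

    def steps(self) -> list[list[int]]:
        """Element ids grouped by time step (non-null picks only)."""
        out: list[list[int]] = [[] for _ in range(self.n_steps)]
        for step, elem in zip(self.picks["step"], self.picks["element_id"]):
            out[int(step) - 1].append(int(elem))
        return out


def run_greedy(target, filters: ReconstructionFilter, dictionary: StimDictionary,
               T_max: int = 10_000, refractory_params: tuple[float, int] = (0.1, 100),
               exclusion_radius_um: float = 0.0, max_per_step: int = 1,
               seed=None, *, sample: bool = False,
               workspace: "GreedyWorkspace | None" = None) -> StimulationSequence:
    """Run greedy temporal dithering for one target.

    Stops early when a whole step selects only the null element.  With
    ``max_per_step > 1`` and a positive exclusion radius, multiple elements are
    picked greedily within each step, re-evaluating the shared objective after
    each pick and disabling electrodes inside the exclusion radius of the
    picks already made in that step.  If ``sample`` is true, Bernoulli spike
    responses are drawn for every pick (selection itself stays open-loop).
    """
    if T_max < 1:
        raise ValueError("T_max must be >= 1")
    if exclusion_radius_um < 0:
        raise ValueError("exclusion radius must be >= 0")
    if dictionary.D[:, dictionary.null_index].any():
        raise ValueError("dictionary lacks a null element in the last column")
    theta, window = refractory_params
    ws = workspace if workspace is not None else GreedyWorkspace(filters, dictionary)
    s = target.ravel() if isinstance(target, VisualTarget) else np.asarray(target, float).ravel()
    if s.size != filters.n_pixels:
        raise ValueError("target does not match the filter pixel grid")

    multiplex = exclusion_radius_um > 0 and max_per_step > 1
    state = RefractoryState(n_cells=dictionary.n_cells, theta=theta, window=int(window))
    d = ws.G.T @ s                       # per-element <resid, g_c>, updated incrementally
    obj = float(np.sum(s**2))
    null = dictionary.null_index
    delta = ws.sq + dictionary.v         # objective change of each element: -2 d + sq + v

    counts = np.zeros(dictionary.n_elements, dtype=np.int64)
    rows: list[tuple[int, int, int, float]] = []
    trace = [obj]
    elem_pos = dictionary.element_positions()

    for t in range(1, T_max + 1):
        mask = valid_mask(dictionary, state)
        step_targeted: list[np.ndarray] = []
        picked_pos: list[np.ndarray] = []
        step_mask = mask.copy()
        for slot in range(max_per_step if multiplex else 1):
            gain = delta - 2.0 * d
            gain[~step_mask] = np.inf
            gain[null] = 0.0
            choice = int(np.argmin(gain))
            if choice == null or gain[choice] >= 0.0:
                break
            obj += float(gain[choice])
            d -= ws.gram_column(choice)
            counts[choice] += 1
            rows.append((t, slot, choice, obj))
            step_targeted.append(dictionary.D[:, choice] > theta)
            if multiplex:
                picked_pos.append(elem_pos[choice])
                near = (np.linalg.norm(elem_pos - picked_pos[-1], axis=1)
                        <= exclusion_radius_um)
                step_mask &= ~near
                step_mask[null] = True
        trace.append(obj)
        # refractory bookkeeping takes effect from the next step onward
        for tg in step_targeted:
            if tg.any():
                state.blocked_until[tg] = state.step + state.window
        state.advance()
        if not step_targeted:          # a whole step chose only the null element
            break

    picks = pd.DataFrame(rows, columns=["step", "slot", "element_id", "objective"])
    picks["electrode_id"] = dictionary.electrode[picks["element_id"]] if len(picks) else []
    picks["amplitude_uA"] = dictionary.amplitude_uA[picks["element_id"]] if len(picks) else []
    picks = picks[["step", "slot", "element_id", "electrode_id", "amplitude_uA",
                   "objective"]]

    cum_p = dictionary.D @ counts
    bias = float(np.sum((s - filters.A @ cum_p) ** 2))
    variance = float(np.dot(dictionary.v, counts))
    report = ErrorReport(bias=bias, variance=variance, _target_sq=float(np.sum(s**2)))

    sampled = None
    sample_seed = None
    if sample:
        rng = as_rng(seed)
        sample_seed = seed if isinstance(seed, (int, np.integer)) else None
        if len(picks):
            p_mat = dictionary.D[:, picks["element_id"].to_numpy()].T
            sampled = (rng.random(p_mat.shape) < p_mat).astype(np.int64)
        else:
            sampled = np.zeros((0, dictionary.n_cells), dtype=np.int64)

    return StimulationSequence(
        picks=picks, objective_trace=np.asarray(trace), cumulative_expected=cum_p,
        n_steps=len(trace) - 1, target_sq_norm=float(np.sum(s**2)), error=report,
        theta=theta, window=int(window), exclusion_radius_um=exclusion_radius_um,
        max_per_step=max_per_step, sampled_responses=sampled, sample_seed=sample_seed)


class GreedyWorkspace:
    """Cached per-(filters, dictionary) quantities for fast greedy runs.

    Keeps G = A D and the per-element squared norms; Gram-matrix columns
    G^T g_c (needed once per distinct chosen element) are precomputed in full
    for small problems and cached lazily otherwise, so each pick costs
    O(elements) after the first use of an element.
    """

    #: precompute the full Gram matrix only below this flop budget
    GRAM_FLOP_LIMIT = 5e8

    def __init__(self, filters: ReconstructionFilter, dictionary: StimDictionary):
        self.G = filters.A @ dictionary.D
        self.sq = np.einsum("ij,ij->j", self.G, self.G)
        n_pix, n_el = self.G.shape
        if n_el * n_el * n_pix <= self.GRAM_FLOP_LIMIT:
            self.M = self.G.T @ self.G
        else:
            self.M = None
        self._columns: dict[int, np.ndarray] = {}

    def gram_column(self, j: int) -> np.ndarray:
        if self.M is not None:
            return self.M[:, j]
        col = self._columns.get(j)
        if col is None:
            col = self.G.T @ self.G[:, j]
            self._columns[j] = col
        return col
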