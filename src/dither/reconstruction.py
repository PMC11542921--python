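"""Linear stimulus reconstruction and the bias-variance expected error.

The encoder's objective is the expected squared error between a target image
``s`` and the linear reconstruction ``A (r_1 + ... + r_T)`` from Bernoulli
spike responses.  Because responses at different time steps are independent,
the expectation decomposes exactly into

    bias     = || s - A (p_1 + ... + p_T) ||^2
    variance = sum_i  sum_n ||a_n||^2 p_{n,i} (1 - p_{n,i})

where p_i is the activation-probability vector of the element chosen at step
i and a_n the reconstruction filter of cell n.  Both terms are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._util import check_probabilities
from .synthetic import ReconstructionFilter, VisualTarget

__all__ = ["ErrorReport", "reconstruct", "relative_mse", "element_variance",
           "expected_error", "sampled_errors"]


@dataclass(frozen=True)
class ErrorReport:
    """Expected reconstruction error split into bias and variance terms."""

    bias: float
    variance: float

    @property
    def squared_error(self) -> float:
        return self.bias + self.variance

    @property
    def target_sq_norm(self) -> float:
        return self._target_sq

    _target_sq: float = 0.0

    @property
    def relative_mse(self) -> float:
        if self._target_sq <= 0:
            raise ValueError("relative MSE undefined for a zero target")
        return self.squared_error / self._target_sq


def _as_pixels(target) -> np.ndarray:
    if isinstance(target, VisualTarget):
        return target.pixels.astype(float)
    return np.asarray(target, dtype=float)


def reconstruct(filters: ReconstructionFilter, response: np.ndarray) -> np.ndarray:
    """Linear reconstruction A @ r, reshaped to the pixel grid."""
    r = np.asarray(response, dtype=float).ravel()
    if r.size != filters.n_cells:
        raise ValueError(
            f"response has {r.size} entries for {filters.n_cells} cells")
    return (filters.A @ r).reshape(filters.grid_shape)


def relative_mse(target, reconstruction) -> float:
    """||s - s_hat||^2 / ||s||^2 over pixels."""
    s = _as_pixels(target)
    s_hat = _as_pixels(reconstruction)
    if s.shape != s_hat.shape:
        raise ValueError("target and reconstruction shapes differ")
    denom = float(np.sum(s**2))
    if denom <= 0:
        raise ValueError("relative MSE undefined for a zero target")
    return float(np.sum((s - s_hat) ** 2)) / denom


def element_variance(filters: ReconstructionFilter, p_c: np.ndarray) -> float:
    """Decoding variance of one element: sum_n ||a_n||^2 p_n (1 - p_n)."""
    p = check_probabilities(np.asarray(p_c, dtype=float).ravel())
    if p.size != filters.n_cells:
        raise ValueError("probability vector length does not match cell count")
    return float(np.dot(filters.column_sq_norms(), p * (1.0 - p)))


def expected_error(target, filters: ReconstructionFilter,
                   probability_sequence: Iterable[np.ndarray]) -> ErrorReport:
    """Expected squared error of a stimulation sequence given per-step probabilities.

    ``probability_sequence`` holds one activation-probability vector per chosen
    element (in any order; the expectation is order-free).
    """
    s = _as_pixels(target).ravel()
    if s.size != filters.n_pixels:
        raise ValueError("target does not match the filter pixel grid")
    total_p = np.zeros(filters.n_cells)
    variance = 0.0
    for p in probability_sequence:
        p = check_probabilities(np.asarray(p, dtype=float).ravel())
        if p.size != filters.n_cells:
            raise ValueError("probability vector length does not match cell count")
        total_p += p
        variance += float(np.dot(filters.column_sq_norms(), p * (1.0 - p)))
    bias = float(np.sum((s - filters.A @ total_p) ** 2))
    return ErrorReport(bias=bias, variance=variance, _target_sq=float(np.sum(s**2)))


def sampled_errors(target, filters: ReconstructionFilter,
                   trial_responses: np.ndarray) -> dict[str, float]:
    """Both error conventions for sampled (per-trial) total responses.

    ``trial_responses`` is (trials x cells) summed spike counts per trial.
    Returns the mean of per-trial relative MSE ('single_trial') and the
    relative MSE of the trial-averaged reconstruction ('trial_averaged');
    the latter is smaller whenever response noise partially averages out.
    """
    r = np.asarray(trial_responses, dtype=float)
    if r.ndim != 2 or r.shape[1] != filters.n_cells:
        raise ValueError("trial_responses must be (trials x cells)")
    s = _as_pixels(target)
    per_trial = [relative_mse(s, reconstruct(filters, row)) for row in r]
    averaged = relative_mse(s, reconstruct(filters, r.mean(axis=0)))
    return {"single_trial": float(np.mean(per_trial)),
            "trial_averaged": averaged}
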