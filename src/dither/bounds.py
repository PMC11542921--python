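"""Optimality bounds and the static pixel-wise baseline.

Three order-free comparison methods bracket the greedy encoder:

* ``relaxed_joint`` — the continuous relaxation of the joint element-usage
  program  min_{w >= 0} ||s - A D w||^2 + v^T w,  a lower bound on any
  integer stimulation sequence drawn from the same dictionary;
* ``perfect_control`` — non-negative least squares on the cells directly,
  min_{r >= 0} ||s - A r||^2, the error floor of an ideal interface that can
  set every cell's spike count;
* the static pixel-wise baseline, which maps local image intensity through a
  per-electrode sigmoid to a current amplitude, emulating existing implants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .reconstruction import ErrorReport
from .synthetic import (ElectrodeArray, ReconstructionFilter, StimDictionary,
                        VisualTarget)

__all__ = ["RelaxedResult", "PerfectControlResult", "PixelwiseMapping",
           "relaxed_joint", "perfect_control", "fit_pixelwise_mapping",
           "apply_pixelwise", "fractional_gap"]


def _ravel(target) -> np.ndarray:
    if isinstance(target, VisualTarget):
        return target.ravel()
    return np.asarray(target, dtype=float).ravel()


def fractional_gap(err_hi: float, err_lo: float) -> float:
    """(err_hi - err_lo) / err_hi: the fraction of error the better method removes."""
    if err_hi <= 0:
        raise ValueError("gap undefined for non-positive reference error")
    return (err_hi - err_lo) / err_hi


# ---------------------------------------------------------------------------
# relaxed joint optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxedResult:
    """Solution of min_{w>=0} ||s - ADw||^2 + v^T w."""

    w: np.ndarray
    objective: float          # bias + linear variance penalty at the optimum
    bias: float               # ||s - ADw*||^2
    variance: float           # v^T w*
    relative_mse: float       # bias / ||s||^2 of the expected reconstruction
    relative_objective: float # objective / ||s||^2
    kkt_residual: float


def relaxed_joint(target, filters: ReconstructionFilter,
                  dictionary: StimDictionary, *, tol: float = 1e-10,
                  kkt_tol: float = 1e-5, max_iter: int = 5000) -> RelaxedResult:
    """Solve the convex usage relaxation with a projected quasi-Newton method.

    The KKT residual (stationarity on the active/inactive sets) is checked at
    the returned point; non-convergence raises with the residual attached.
    """
    s = _ravel(target)
    B = filters.A @ dictionary.D
    v = dictionary.v
    s_sq = float(np.sum(s**2))
    if s_sq == 0.0:
        w = np.zeros(dictionary.n_elements)
        return RelaxedResult(w, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    w = _nnls_linear_penalty(B, s, v, max_iter=max_iter, tol=tol)
    g = 2.0 * (B.T @ (B @ w - s)) + v
    # KKT: g ~ 0 where w > 0, g >= 0 where w = 0 (scaled by the problem size)
    scale = max(1.0, s_sq)
    kkt = float(np.max(np.where(w > 1e-12, np.abs(g), np.maximum(0.0, -g))))
    if kkt / scale > kkt_tol:
        raise RuntimeError(
            f"relaxed joint optimization did not converge (KKT residual {kkt:.3g})")
    bias = float(np.sum((s - B @ w) ** 2))
    var = float(v @ w)
    return RelaxedResult(w=w, objective=bias + var, bias=bias, variance=var,
                         relative_mse=bias / s_sq,
                         relative_objective=(bias + var) / s_sq,
                         kkt_residual=kkt)


def _nnls_linear_penalty(B: np.ndarray, s: np.ndarray, v: np.ndarray, *,
                         max_iter: int = 5000, tol: float = 1e-10) -> np.ndarray:
    """Active-set solver for min_{w>=0} ||s - Bw||^2 + v^T w.

    Lawson-Hanson non-negative least squares extended with the linear
    penalty: the unconstrained solve on the passive set uses the shifted
    normal equations 2 B_P^T B_P z = 2 B_P^T s - v_P.  Exact at termination
    (KKT holds to the numerical tolerance of the inner least-squares solves).
    """
    n = B.shape[1]
    w = np.zeros(n)
    passive: list[int] = []
    BtB = None                      # lazily maintained Gram of passive columns
    scale = max(float(np.sum(s**2)), 1.0)
    for _ in range(max_iter):
        grad = 2.0 * (B.T @ (B @ w - s)) + v
        candidates = np.setdiff1d(np.arange(n), passive, assume_unique=False)
        if candidates.size == 0:
            break
        j = candidates[np.argmin(grad[candidates])]
        if grad[j] >= -1e-12 * scale:
            break
        passive.append(int(j))
        for _inner in range(max_iter):
            P = np.array(passive)
            Bp = B[:, P]
            rhs = 2.0 * (Bp.T @ s) - v[P]
            z, *_ = np.linalg.lstsq(2.0 * (Bp.T @ Bp), rhs, rcond=None)
            if np.all(z > 0):
                w[:] = 0.0
                w[P] = z
                break
            # step toward z until the first passive coordinate hits zero
            wp = w[P]
            neg = z <= 0
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = wp[neg] / (wp[neg] - z[neg])
            alpha = float(np.nanmin(alphas)) if alphas.size else 0.0
            wp = wp + alpha * (z - wp)
            wp[neg & (wp <= 1e-14)] = 0.0
            w[:] = 0.0
            w[P] = np.maximum(wp, 0.0)
            passive = [int(p) for p, val in zip(P, w[P]) if val > 0.0]
            if not passive:
                break
    return w


# ---------------------------------------------------------------------------
# perfect control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerfectControlResult:
    """Non-negative least-squares spike counts and the resulting error floor."""

    r: np.ndarray
    objective: float          # ||s - Ar*||^2
    relative_mse: float


def perfect_control(target, filters: ReconstructionFilter) -> PerfectControlResult:
    """Error floor with direct, non-negative control of every cell's spike count."""
    if filters.n_cells == 0:
        raise ValueError("perfect control needs at least one cell")
    s = _ravel(target)
    r, rnorm = scipy.optimize.nnls(filters.A, s)
    obj = float(rnorm**2)
    s_sq = float(np.sum(s**2))
    rel = obj / s_sq if s_sq > 0 else 0.0
    return PerfectControlResult(r=r, objective=obj, relative_mse=rel)


# ---------------------------------------------------------------------------
# static pixel-wise baseline
# ---------------------------------------------------------------------------

@dataclass
class PixelwiseMapping:
    """Per-electrode sigmoidal intensity-to-current mapping with repeat counts.

    For electrode e with parameters (a, b, c, d, n), local mean intensity
    s_bar maps to current  i = a + b / (1 + exp(c * s_bar + d)),  delivered n
    times after snapping i to the nearest calibrated amplitude (in log scale)
    that has a retained element on that electrode.  n = 0 disables the
    electrode (also used when it has no retained elements).
    """

    params: pd.DataFrame          # columns: electrode_id, a, b, c, d, n
    window_um: float
    training_error: float | None = None

    def current_for(self, electrode_id: int, intensity: float) -> float:
        row = self.params.loc[self.params.electrode_id == electrode_id]
        if row.empty or int(row.n.iloc[0]) == 0:
            return 0.0
        a, b, c, d = (float(row[k].iloc[0]) for k in "abcd")
        return a + b / (1.0 + np.exp(c * intensity + d))


def electrode_window_intensity(target, filters: ReconstructionFilter,
                               array: ElectrodeArray,
                               window_um: float = 130.0) -> np.ndarray:
    """Mean target intensity in a window_um x window_um box around each electrode."""
    s = _ravel(target)
    px = filters.pixel_centers()
    out = np.zeros(array.n_electrodes)
    half = window_um / 2.0
    for e in range(array.n_electrodes):
        ex, ey = array.positions[e]
        inside = (np.abs(px[:, 0] - ex) <= half) & (np.abs(px[:, 1] - ey) <= half)
        out[e] = s[inside].mean() if inside.any() else 0.0
    return out


def _electrode_elements(dictionary: StimDictionary) -> dict[int, np.ndarray]:
    """Retained element ids per electrode (null excluded), sorted by amplitude."""
    out: dict[int, np.ndarray] = {}
    for e in np.unique(dictionary.electrode):
        if e < 0:
            continue
        idx = np.where(dictionary.electrode == e)[0]
        out[int(e)] = idx[np.argsort(dictionary.amplitude_uA[idx])]
    return out


def snap_to_amplitude(dictionary: StimDictionary, electrode_id: int,
                      current_uA: float) -> int | None:
    """Nearest retained element on the electrode in log-amplitude distance."""
    elems = _electrode_elements(dictionary).get(int(electrode_id))
    if elems is None or current_uA <= 0:
        return None
    amps = dictionary.amplitude_uA[elems]
    j = int(np.argmin(np.abs(np.log(amps) - np.log(current_uA))))
    return int(elems[j])


def fit_pixelwise_mapping(training_targets, filters: ReconstructionFilter,
                          dictionary: StimDictionary, array: ElectrodeArray, *,
                          window_um: float = 130.0, n_max: int = 30,
                          n_sweeps: int = 2) -> PixelwiseMapping:
    """Fit the per-electrode sigmoid parameters by derivative-free search.

    Expected reconstruction error (bias + variance) over the training set is
    minimized by cyclic coordinate descent over electrodes; each electrode's
    (a, b, c, d, n) is chosen from a structured candidate grid of sigmoid
    shapes spanning the calibrated amplitude range, holding the other
    electrodes fixed.  Electrodes with no retained elements are excluded.
    """
    targets = [_ravel(t) for t in training_targets]
    if not targets:
        raise ValueError("need at least one training target")
    per_elec = _electrode_elements(dictionary)
    n_t = len(targets)
    G = filters.A @ dictionary.D                       # (pixels, elements)
    intens = np.stack([
        electrode_window_intensity(t, filters, array, window_um) for t in targets
    ])                                                 # (targets, electrodes)

    amps = dictionary.amplitudes_uA
    a_lo, a_hi = float(amps.min()), float(amps.max())
    # candidate sigmoids: i = a + b/(1+exp(c*s+d)); c<0 makes current increase
    # with intensity (drive ON cells in bright areas), c>0 the reverse
    cand = [(a_lo, a_hi - a_lo, c, d)
            for c in (-8.0, -4.0, 4.0, 8.0) for d in (-2.0, 0.0, 2.0)]
    cand += [(a, 0.0, 0.0, 0.0) for a in np.geomspace(a_lo, a_hi, 5)]  # constant current

    electrodes = sorted(per_elec)
    choice: dict[int, tuple[float, float, float, float, int]] = {
        e: (0.0, 0.0, 0.0, 0.0, 0) for e in electrodes}

    # expected contribution of electrode e under params theta for target k
    def contribution(e, theta, k):
        a, b, c, d, n = theta
        if n == 0:
            return None
        i = a + b / (1.0 + np.exp(c * intens[k, e] + d))
        elem = snap_to_amplitude(dictionary, e, i)
        if elem is None:
            return None
        return elem, n

    resid = [t.copy() for t in targets]                # s - sum of contributions
    total_var = 0.0

    def apply_choice(e, theta, sign):
        nonlocal total_var
        for k in range(n_t):
            contrib = contribution(e, theta, k)
            if contrib is None:
                continue
            elem, n = contrib
            resid[k] -= sign * n * G[:, elem]
            total_var += sign * n * dictionary.v[elem]

    for _ in range(n_sweeps):
        for e in electrodes:
            apply_choice(e, choice[e], -1)             # remove current contribution
            best = (0.0, 0.0, 0.0, 0.0, 0)
            best_err = sum(float(r @ r) for r in resid) + total_var
            for (a, b, c, d) in cand:
                for n in _candidate_counts(n_max):
                    theta = (a, b, c, d, n)
                    err = total_var
                    for k in range(n_t):
                        contrib = contribution(e, theta, k)
                        if contrib is None:
                            err += float(resid[k] @ resid[k])
                            continue
                        elem, nn = contrib
                        rk = resid[k] - nn * G[:, elem]
                        err += float(rk @ rk) + nn * dictionary.v[elem]
                    if err < best_err - 1e-12:
                        best_err, best = err, theta
            choice[e] = best
            apply_choice(e, choice[e], +1)

    train_err = sum(float(r @ r) for r in resid) + total_var
    rows = [(e, *choice[e]) for e in electrodes]
    params = pd.DataFrame(rows, columns=["electrode_id", "a", "b", "c", "d", "n"])
    return PixelwiseMapping(params=params, window_um=window_um,
                            training_error=train_err / n_t)


def _candidate_counts(n_max: int) -> list[int]:
    counts = [0, 1, 2, 3, 5, 8, 12, 20, 30]
    return sorted({c for c in counts if c <= n_max})


def apply_pixelwise(target, mapping: PixelwiseMapping,
                    dictionary: StimDictionary, filters: ReconstructionFilter,
                    array: ElectrodeArray) -> tuple[pd.DataFrame, ErrorReport]:
    """Emit the baseline stimulation schedule for one target and score it.

    Returns the schedule (electrode-major parameters, repeats interleaved
    round-robin as delivery order) and the bias-variance error report.
    """
    s = _ravel(target)
    intens = electrode_window_intensity(target, filters, array, mapping.window_um)
    per_target: list[tuple[int, int]] = []             # (element, repeats)
    for _, row in mapping.params.iterrows():
        e, n = int(row.electrode_id), int(row.n)
        if n == 0:
            continue
        i = row.a + row.b / (1.0 + np.exp(row.c * intens[e] + row.d))
        elem = snap_to_amplitude(dictionary, e, i)
        if elem is not None:
            per_target.append((elem, n))

    # round-robin delivery order across electrodes
    order: list[int] = []
    remaining = [[elem, n] for elem, n in per_target]
    while any(n > 0 for _, n in remaining):
        for item in remaining:
            if item[1] > 0:
                order.append(item[0])
                item[1] -= 1

    total_p = np.zeros(dictionary.n_cells)
    variance = 0.0
    for elem in order:
        p = dictionary.D[:, elem]
        total_p += p
        variance += float(dictionary.v[elem])
    bias = float(np.sum((s - filters.A @ total_p) ** 2))
    report = ErrorReport(bias=bias, variance=variance,
                         _target_sq=float(np.sum(s**2)))
    schedule = pd.DataFrame({
        "order": np.arange(len(order)),
        "element_id": order,
        "electrode_id": dictionary.electrode[order] if order else [],
        "amplitude_uA": dictionary.amplitude_uA[order] if order else [],
    })
    return schedule, report
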