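"""Activation-curve fitting and the bi-electrode exclusion-radius analysis.

Single-electrode calibration scans are summarized by a sigmoid fitted across
current levels; the activation threshold is the amplitude at 50% spike
probability.  The spatial-multiplexing analysis compares thresholds measured
with and without a simultaneously driven secondary electrode and summarizes
the fractional threshold change versus electrode separation with inverse-
variance-weighted bin means and bootstrap standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import expit

from ._util import as_rng

__all__ = ["ActivationCurve", "fit_sigmoid_activation",
           "fractional_threshold_change", "exclusion_radius_summary",
           "analyze_pair_scan", "default_amplitude_grid"]


def default_amplitude_grid(n: int = 40, lo: float = 0.1, hi: float = 4.0) -> np.ndarray:
    """The standard calibration grid: 40 log-spaced amplitudes, 0.1-4 uA."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class ActivationCurve:
    """Fitted sigmoidal activation curve in log amplitude.

    threshold is the amplitude (uA) at fitted probability 0.5; threshold_var
    is its variance from the observed-information (curvature) approximation.
    Non-identifiable fits (all-zero or all-saturated responses) carry
    ``identifiable = False`` and an undefined (NaN) threshold.
    """

    amplitudes_uA: np.ndarray
    probabilities: np.ndarray         # fitted probability at each amplitude
    log_threshold: float
    slope: float
    threshold_var: float
    identifiable: bool

    @property
    def threshold_uA(self) -> float:
        return float(np.exp(self.log_threshold)) if self.identifiable else float("nan")

    def probability_at(self, amplitude_uA) -> np.ndarray:
        x = np.log(np.asarray(amplitude_uA, dtype=float))
        return expit(self.slope * (x - self.log_threshold))


def fit_sigmoid_activation(amplitudes, trial_counts, success_counts) -> ActivationCurve:
    """Maximum-likelihood logistic fit of spike probability vs log amplitude.

    Model: p(a) = expit(k * (log a - m)); threshold = exp(m).  The threshold
    variance comes from the expected (Fisher) information of the binomial
    likelihood at the MLE, via the delta method for t = exp(m).
    """
    a = np.asarray(amplitudes, dtype=float)
    n = np.asarray(trial_counts, dtype=float)
    y = np.asarray(success_counts, dtype=float)
    if a.size < 4:
        raise ValueError("need at least 4 amplitude levels")
    if np.any(y < 0) or np.any(n < 0) or np.any(y > n):
        raise ValueError("invalid counts")
    x = np.log(a)

    tot_n, tot_y = n.sum(), y.sum()
    if tot_y == 0 or tot_y == tot_n:
        return ActivationCurve(a, np.full(a.size, np.nan), np.nan, np.nan,
                               np.nan, identifiable=False)

    def nll(theta):
        m, logk = theta
        k = np.exp(logk)
        eta = k * (x - m)
        # -sum [ y*eta - n*log(1+exp(eta)) ]
        return -float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))

    # moment-based start: threshold near the amplitude where p crosses 0.5
    frac = np.where(n > 0, y / np.maximum(n, 1), 0.0)
    m0 = x[np.argmin(np.abs(frac - 0.5))]
    best = None
    for logk0 in (0.0, 1.0, 2.0):
        res = scipy.optimize.minimize(nll, np.array([m0, logk0]), method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12,
                                               "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    m, logk = best.x
    k = float(np.exp(logk))
    p_fit = expit(k * (x - m))

    # expected information for (m, k); var(m) from the inverse
    w = n * p_fit * (1.0 - p_fit)
    J = np.empty((2, 2))
    J[0, 0] = np.sum(w * k**2)
    J[0, 1] = J[1, 0] = -np.sum(w * k * (x - m))
    J[1, 1] = np.sum(w * (x - m) ** 2)
    det = J[0, 0] * J[1, 1] - J[0, 1] ** 2
    var_m = J[1, 1] / det if det > 0 else np.inf
    thr = float(np.exp(m))
    thr_var = float(thr**2 * var_m)

    identifiable = np.isfinite(thr_var) and x.min() - 2.0 <= m <= x.max() + 2.0
    return ActivationCurve(a, p_fit, float(m), k, thr_var, identifiable=identifiable)


def fractional_threshold_change(single_curve: ActivationCurve,
                                paired_curve: ActivationCurve) -> float:
    """|t_paired - t_single| / t_single between two fitted curves."""
    if not (single_curve.identifiable and paired_curve.identifiable):
        raise ValueError("fractional change undefined: non-identifiable threshold")
    t_s, t_p = single_curve.threshold_uA, paired_curve.threshold_uA
    return abs(t_p - t_s) / t_s


def exclusion_radius_summary(pair_results, distance_bins, *, n_boot: int = 1000,
                             seed=None) -> pd.DataFrame:
    """Inverse-variance-weighted mean fractional threshold change per distance bin.

    ``pair_results`` is a DataFrame (or records) with columns distance_um,
    frac_change and threshold_var; weights are proportional to
    1 / threshold_var.  The standard error is a seeded bootstrap over pairs
    within each bin.  Empty bins are omitted.
    """
    df = pd.DataFrame(pair_results)
    for col in ("distance_um", "frac_change", "threshold_var"):
        if col not in df:
            raise ValueError(f"pair results lack column {col!r}")
    edges = np.asarray(distance_bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("distance_bins must be a 1-D array of bin edges")
    rng = as_rng(seed)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = df[(df.distance_um >= lo) & (df.distance_um < hi)]
        if sel.empty:
            continue
        w = 1.0 / np.maximum(sel.threshold_var.to_numpy(), 1e-300)
        x = sel.frac_change.to_numpy()
        mean = float(np.sum(w * x) / np.sum(w))
        if len(sel) > 1:
            idx = rng.integers(0, len(sel), size=(n_boot, len(sel)))
            bw, bx = w[idx], x[idx]
            boots = np.sum(bw * bx, axis=1) / np.sum(bw, axis=1)
            se = float(np.std(boots, ddof=1))
        else:
            se = 0.0
        rows.append((lo, hi, len(sel), mean, se))
    return pd.DataFrame(rows, columns=["bin_lo_um", "bin_hi_um", "n_pairs",
                                       "weighted_mean", "bootstrap_se"])


def analyze_pair_scan(scan: pd.DataFrame, n_bins: int = 8,
                      max_distance_um: float = 400.0, *, n_boot: int = 1000,
                      seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full bi-electrode analysis from a long-format activation scan.

    ``scan`` columns: pair_id, distance_um, condition ('single' or 'paired'),
    amplitude_uA, n_trials, n_spikes.  Each pair's two activation curves are
    fitted, the fractional threshold change computed, and the per-distance-bin
    weighted summary returned alongside the per-pair table.  Pairs with a
    non-identifiable threshold in either condition are dropped.
    """
    rows = []
    for pair_id, grp in scan.groupby("pair_id"):
        curves = {}
        for cond, sub in grp.groupby("condition"):
            sub = sub.sort_values("amplitude_uA")
            curves[cond] = fit_sigmoid_activation(
                sub.amplitude_uA.to_numpy(), sub.n_trials.to_numpy(),
                sub.n_spikes.to_numpy())
        if not {"single", "paired"} <= curves.keys():
            raise ValueError(f"pair {pair_id} lacks a single or paired scan")
        single, paired = curves["single"], curves["paired"]
        if not (single.identifiable and paired.identifiable):
            continue
        rows.append((pair_id, float(grp.distance_um.iloc[0]),
                     fractional_threshold_change(single, paired),
                     single.threshold_var))
    pairs = pd.DataFrame(rows, columns=["pair_id", "distance_um",
                                        "frac_change", "threshold_var"])
    edges = np.linspace(0.0, max_distance_um, n_bins + 1)
    summary = exclusion_radius_summary(pairs, edges, n_boot=n_boot, seed=seed)
    return pairs, summary
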