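"""Perceptually weighted joint optimization: SSIM (or MSE) with an L1 budget.

The stimulation budget extension drops the greedy/stochastic machinery and
jointly optimizes, over all fixation patches at once, how often each
dictionary element is used per patch:

    min_{w_i >= 0}  d(s, G({A D w_i}))  +  lambda * sum_i ||w_i||_1

where G averages the per-patch expected reconstructions over their scene
footprints (a uniform fixation distribution) and d is either relative MSE or
1 - SSIM.  Larger lambda buys fewer stimulations; sweeping it traces the
budget-quality curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.optimize

from .synthetic import ReconstructionFilter, StimDictionary

__all__ = ["ssim", "ssim_and_gradient", "PatchUsageSet", "patch_grid",
           "joint_patch_optimize"]


# ---------------------------------------------------------------------------
# SSIM (standard reference parameterization)
# ---------------------------------------------------------------------------

def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_fields(a, b, window, k1, k2, dynamic_range, sigma):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must share a 2-D shape")
    if window > min(a.shape):
        raise ValueError("window larger than image")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    kern = _gaussian_window(window, sigma)
    m = window // 2

    def corr(img):
        return scipy.ndimage.correlate(img, kern, mode="constant")

    def crop(img):
        return img[m:img.shape[0] - m, m:img.shape[1] - m]

    mu_a, mu_b = crop(corr(a)), crop(corr(b))
    s_aa = crop(corr(a * a)) - mu_a**2
    s_bb = crop(corr(b * b)) - mu_b**2
    s_ab = crop(corr(a * b)) - mu_a * mu_b
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    a1 = 2.0 * mu_a * mu_b + c1
    a2 = 2.0 * s_ab + c2
    b1 = mu_a**2 + mu_b**2 + c1
    b2 = s_aa + s_bb + c2
    S = (a1 * a2) / (b1 * b2)
    return S, (kern, m, mu_a, mu_b, s_aa, s_bb, s_ab, a1, a2, b1, b2)


def ssim(image_a, image_b, window: int = 11, k1: float = 0.01, k2: float = 0.03,
         dynamic_range: float = 2.0, *, sigma: float = 1.5) -> float:
    """Mean structural similarity over Gaussian-weighted sliding windows.

    Only windows fully inside the image contribute.  The defaults are the
    reference parameterization (11-pixel window, Gaussian weights with
    sigma 1.5, k1 = 0.01, k2 = 0.03); ``dynamic_range`` defaults to 2 for
    signed intensities in [-1, +1].
    """
    S, _ = _ssim_fields(image_a, image_b, window, k1, k2, dynamic_range, sigma)
    return float(S.mean())


def ssim_and_gradient(target, x, window: int = 11, k1: float = 0.01,
                      k2: float = 0.03, dynamic_range: float = 2.0, *,
                      sigma: float = 1.5) -> tuple[float, np.ndarray]:
    """Mean SSIM(target, x) and its analytic gradient with respect to ``x``."""
    target = np.asarray(target, dtype=float)
    x = np.asarray(x, dtype=float)
    S, (kern, m, mu_t, mu_x, s_tt, s_xx, s_tx, a1, a2, b1, b2) = _ssim_fields(
        target, x, window, k1, k2, dynamic_range, sigma)
    n_win = S.size

    # per-window partials of S with respect to mu_x, sigma_x^2, sigma_tx
    dS_dmu = (2.0 * mu_t * b1 - a1 * 2.0 * mu_x) / b1**2 * (a2 / b2)
    dS_dsxx = (a1 / b1) * (-a2 / b2**2)
    dS_dstx = (a1 / b1) * (2.0 / b2)

    H, W = x.shape

    def spread(field):
        full = np.zeros((H, W))
        full[m:H - m, m:W - m] = field
        return scipy.ndimage.correlate(full, kern, mode="constant")

    grad = (spread(dS_dmu)
            + 2.0 * x * spread(dS_dsxx) - 2.0 * spread(dS_dsxx * mu_x)
            + target * spread(dS_dstx) - spread(dS_dstx * mu_t))
    return float(S.mean()), grad / n_win


# ---------------------------------------------------------------------------
# joint patch optimization
# ---------------------------------------------------------------------------

def patch_grid(scene_shape: tuple[int, int], patch_shape: tuple[int, int],
               stride: tuple[int, int] | None = None) -> np.ndarray:
    """Top-left corners of a stride grid of fixation patches covering the scene.

    The default stride is half the patch in each dimension; the last row and
    column of patches are shifted to touch the scene border so every pixel is
    covered.
    """
    H, W = scene_shape
    ph, pw = patch_shape
    if ph > H or pw > W:
        raise ValueError("patch larger than scene")
    if stride is None:
        stride = (max(1, ph // 2), max(1, pw // 2))

    def axis_positions(extent, size, step):
        pos = list(range(0, extent - size + 1, step))
        if pos[-1] != extent - size:
            pos.append(extent - size)
        return pos

    rows = axis_positions(H, ph, stride[0])
    cols = axis_positions(W, pw, stride[1])
    return np.array([(r, c) for r in rows for c in cols], dtype=int)


@dataclass
class PatchUsageSet:
    """Per-patch element-usage vectors and the assembled reconstruction."""

    W: np.ndarray                     # (n_patches, n_elements), all >= 0
    patch_corners: np.ndarray         # (n_patches, 2) top-left scene coords
    lambda_: float
    metric: str
    metric_value: float               # d(s, assembly) at the solution
    assembled: np.ndarray
    converged: bool
    grad_norm: float

    @property
    def total_usage(self) -> float:
        return float(self.W.sum())


def joint_patch_optimize(scene, filters: ReconstructionFilter,
                         dictionary: StimDictionary, metric: str = "mse",
                         lambda_: float = 0.0, *,
                         stride: tuple[int, int] | None = None,
                         patch_corners: np.ndarray | None = None,
                         max_iter: int = 800, gtol: float = 1e-8,
                         ssim_params: dict | None = None) -> PatchUsageSet:
    """Jointly optimize element usage across fixation patches.

    Uses expected responses only (the formulation has no inter-trial
    variability term) and projected quasi-Newton descent with non-negativity
    bounds.  ``metric`` is 'mse' (relative MSE) or 'ssim' (d = 1 - SSIM).
    """
    if metric not in ("mse", "ssim"):
        raise ValueError("metric must be 'mse' or 'ssim'")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    scene = np.asarray(scene, dtype=float)
    ph, pw = filters.grid_shape
    corners = (np.asarray(patch_corners, dtype=int) if patch_corners is not None
               else patch_grid(scene.shape, (ph, pw), stride))
    n_patch = corners.shape[0]
    G = filters.A @ dictionary.D
    n_elem = dictionary.n_elements
    s_sq = float(np.sum(scene**2))
    sp = ssim_params or {}

    count = np.zeros(scene.shape)
    for r, c in corners:
        count[r:r + ph, c:c + pw] += 1.0
    if (count == 0).any():
        raise ValueError("patch grid leaves scene pixels uncovered")

    def assemble(Wmat):
        total = np.zeros(scene.shape)
        recon = (G @ Wmat.T).T                      # (patches, pixels)
        for i, (r, c) in enumerate(corners):
            total[r:r + ph, c:c + pw] += recon[i].reshape(ph, pw)
        return total / count

    def distance_and_grad(s_hat):
        if metric == "mse":
            d = float(np.sum((scene - s_hat) ** 2)) / s_sq
            return d, -2.0 * (scene - s_hat) / s_sq
        val, g = ssim_and_gradient(scene, s_hat, **sp)
        return 1.0 - val, -g

    def fun_grad(wflat):
        Wmat = wflat.reshape(n_patch, n_elem)
        s_hat = assemble(Wmat)
        d, g_img = distance_and_grad(s_hat)
        g_img = g_img / count
        gW = np.empty_like(Wmat)
        for i, (r, c) in enumerate(corners):
            gW[i] = G.T @ g_img[r:r + ph, c:c + pw].ravel()
        gW += lambda_
        return d + lambda_ * float(Wmat.sum()), gW.ravel()

    w0 = np.zeros(n_patch * n_elem)
    res = scipy.optimize.minimize(
        fun_grad, w0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * w0.size,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol})
    Wmat = np.maximum(res.x.reshape(n_patch, n_elem), 0.0)
    s_hat = assemble(Wmat)
    d, _ = distance_and_grad(s_hat)
    _, g = fun_grad(Wmat.ravel())
    g = g.reshape(n_patch, n_elem)
    proj_grad = np.where(Wmat > 1e-12, np.abs(g), np.maximum(0.0, -g))
    return PatchUsageSet(W=Wmat, patch_corners=corners, lambda_=lambda_,
                         metric=metric, metric_value=d, assembled=s_hat,
                         converged=bool(res.success), grad_norm=float(proj_grad.max()))
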