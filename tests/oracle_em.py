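"""Independent brute-force local-EM reference implementation.

Everything here is written directly from the estimator's definition with
dense matrices and explicit Python loops — no code shared with the package
beyond numpy — so that agreement with the production fixed point is a real
check of the E-step/M-step machinery and of the FFT-based smoothing path.
"""

from __future__ import annotations

import numpy as np


def dense_kernel(nx: int, ny: int, sigma_cells: float, truncation_sd: float = 4.0,
                 mask=None) -> np.ndarray:
    """Doubly stochastic truncated-Gaussian operator as an explicit matrix
    over flattened (row-major) cells, Sinkhorn-normalized on the mask."""
    n = nx * ny
    if mask is None:
        mask = np.ones(n, bool)
    else:
        mask = np.asarray(mask, bool).ravel()
    r = max(int(np.ceil(truncation_sd * sigma_cells)), 1)
    d1 = np.arange(-r, r + 1)
    w1 = np.exp(-0.5 * (d1 / sigma_cells) ** 2)
    w1 = w1 / w1.sum()

    K = np.zeros((n, n))
    for a in range(n):
        ya, xa = divmod(a, nx)
        for b in range(n):
            yb, xb = divmod(b, nx)
            dx, dy = xb - xa, yb - ya
            if abs(dx) <= r and abs(dy) <= r and mask[a] and mask[b]:
                K[a, b] = w1[dx + r] * w1[dy + r]
    # symmetric Sinkhorn scaling to doubly stochastic on the mask
    d = mask.astype(float)
    for _ in range(10_000):
        kd = K @ d
        err = np.max(np.abs(np.where(mask, d * kd, 1.0) - 1.0))
        d = np.where(mask, np.sqrt(d / np.where(kd > 0, kd, 1.0)), 0.0)
        if err < 1e-13:
            break
    return np.diag(d) @ K @ np.diag(d)


def brute_force_em(case_cells: list[np.ndarray], mu: np.ndarray, S: np.ndarray,
                   tol: float = 1e-4, max_iter: int = 200) -> np.ndarray:
    """Reference fixed point.

    case_cells: per case, the flat indices of its candidate cells;
    mu: flat expected counts per cell; S: dense smoothing matrix.
    Iterates  E: w_jg = lam_g mu_g / sum over the candidate set;
              M: lam = (S m) / (S mu), rescaled so sum(lam mu) = n.
    """
    n_cells = mu.size
    lam = np.ones(n_cells)
    s_mu = S @ mu
    n = len(case_cells)
    for _ in range(max_iter):
        m = np.zeros(n_cells)
        for cells in case_cells:
            w = np.array([lam[g] * mu[g] for g in cells])
            m_case = w / w.sum()
            for g, wg in zip(cells, m_case):
                m[g] += wg
        new = np.zeros(n_cells)
        for g in range(n_cells):
            if s_mu[g] > 0:
                new[g] = (S @ m)[g] / s_mu[g]
        tot = sum(new[g] * mu[g] for g in range(n_cells))
        if tot > 0:
            new = new * (n / tot)
        change = np.max(np.abs(new - lam)) / max(lam.max(), 1e-300)
        lam = new
        if change < tol:
            break
    return lam
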