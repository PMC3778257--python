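"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np
from scipy import optimize, stats


def svm_dual_objective_oracle(X, y, C):
    """Optimal soft-margin SVM objective by direct dual QP (SLSQP).

    Maximizes sum(a) - 1/2 a^T Q a over the box [0, C]^n intersected with
    a . y = 0, where Q_ij = y_i y_j x_i . x_j. By strong duality the
    optimum equals the primal objective 1/2||w||^2 + C sum xi.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_dual_grad(a):
        return -(np.ones(n) - Q @ a)

    best = None
    for start in (np.zeros(n), np.full(n, min(C, 1.0) / 2), np.full(n, C * 0.99)):
        res = optimize.minimize(
            neg_dual, start, jac=neg_dual_grad, method="SLSQP",
            bounds=[(0.0, C)] * n,
            constraints=[{"type": "eq", "fun": lambda a: a @ y,
                          "jac": lambda a: y}],
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        if best is None or res.fun < best:
            best = res.fun
    return -best


def dense_gaussian_convolution_oracle(data, fwhm_mm, voxel_size_mm, truncate=4.0):
    """Direct dense convolution with a normalized truncated Gaussian kernel."""
    sigma = np.asarray(fwhm_mm, float) / np.asarray(voxel_size_mm, float) \
        / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    axes = []
    for s in sigma:
        radius = int(truncate * s + 0.5)
        x = np.arange(-radius, radius + 1)
        axes.append(np.exp(-0.5 * (x / s) ** 2))
    kernel = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    kernel /= kernel.sum()
    out = np.zeros_like(data, dtype=float)
    rx, ry, rz = [(len(a) - 1) // 2 for a in axes]
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                v = data[i, j, k]
                if v == 0:
                    continue
                for di in range(-rx, rx + 1):
                    if not 0 <= i + di < nx:
                        continue
                    for dj in range(-ry, ry + 1):
                        if not 0 <= j + dj < ny:
                            continue
                        for dk in range(-rz, rz + 1):
                            if not 0 <= k + dk < nz:
                                continue
                            out[i + di, j + dj, k + dk] += \
                                v * kernel[di + rx, dj + ry, dk + rz]
    return out


def fisher_exact_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over tables with fixed margins,
    minimum-likelihood rule with relative tolerance 1e-7."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    pmfs = {x: stats.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    p_obs = pmfs[a]
    return float(sum(p for p in pmfs.values() if p <= p_obs * (1 + 1e-7)))


def auc_trapezoid_oracle(actual, decision):
    """Trapezoidal area under the empirical ROC curve."""
    actual = np.asarray(actual)
    decision = np.asarray(decision, float)
    pos = decision[actual == 1]
    neg = decision[actual == -1]
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(decision))[::-1]])
    fpr = [np.mean(neg >= t) for t in thresholds]
    tpr = [np.mean(pos >= t) for t in thresholds]
    return float(np.trapezoid(tpr, fpr))


def precision_recall_threshold_oracle(actual, decision):
    """Precision/recall by explicit thresholding at each distinct value."""
    actual = np.asarray(actual)
    decision = np.asarray(decision, float)
    n_pos = np.sum(actual == 1)
    out = []
    for t in sorted(set(decision), reverse=True):
        called = decision >= t
        tp = np.sum(called & (actual == 1))
        out.append((tp / n_pos, tp / called.sum()))
    return out
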