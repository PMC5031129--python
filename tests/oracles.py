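"""Independent reference implementations used only to cross-check results.

These deliberately avoid the code paths they verify: brute-force scans for
density peaks/valleys, a multi-restart scikit-learn mixture fit for EM, and
closed forms for Poisson occupancy.
"""

import math

import numpy as np


def brute_force_peaks(grid, density, min_prominence):
    """All local maxima of the sampled density with prominence >= threshold.

    Prominence of a maximum is its height minus the higher of the two
    minima separating it from taller terrain (textbook definition, found
    by explicit scanning).
    """
    n = len(density)
    maxima = [
        i for i in range(1, n - 1) if density[i] > density[i - 1] and density[i] >= density[i + 1]
    ]
    peaks = []
    for i in maxima:
        left_min = density[i]
        j = i
        while j > 0 and density[j] <= density[i]:
            left_min = min(left_min, density[j])
            j -= 1
        if j == 0 and density[0] <= density[i]:
            left_min = min(left_min, density[0])
        right_min = density[i]
        j = i
        while j < n - 1 and density[j] <= density[i]:
            right_min = min(right_min, density[j])
            j += 1
        if j == n - 1 and density[n - 1] <= density[i]:
            right_min = min(right_min, density[n - 1])
        prominence = density[i] - max(left_min, right_min)
        if prominence >= min_prominence:
            peaks.append(i)
    return [grid[i] for i in peaks]


def brute_force_valleys(grid, density, peak_positions):
    """Minimum-density grid point between each consecutive pair of peaks."""
    idx = [int(np.argmin(np.abs(grid - p))) for p in peak_positions]
    out = []
    for a, b in zip(idx[:-1], idx[1:]):
        out.append(grid[a + int(np.argmin(density[a : b + 1]))])
    return out


def reference_mixture_loglik(values, n_restarts=50, seed=0):
    """Best total log-likelihood over random-restart scikit-learn fits of a
    two-component univariate Gaussian mixture."""
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    best = -math.inf
    for r in range(n_restarts):
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            init_params="random",
            n_init=1,
            max_iter=500,
            tol=1e-7,
            reg_covar=1e-10,
            random_state=seed + r,
        ).fit(x)
        best = max(best, float(gm.score(x)) * len(x))
    return best


def poisson_concentration_closed_form(n_positive, n_total, volume_nl=0.85):
    p = n_positive / n_total
    return -math.log(1.0 - p) / (volume_nl * 1e-3)
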