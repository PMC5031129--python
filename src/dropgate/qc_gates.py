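"""Quality-control gates: failed wells, outlier droplets, empty droplets.

These are the first three stages of the analysis pipeline. A well either
fails outright (too few droplets, or no discernible empty/filled structure
in the positive channel), or its droplets are screened for readout
outliers and then split into empty and template-containing populations at
the first valley of a kernel density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .errors import InsufficientDataError, InternalContradictionError

__all__ = [
    "DensityCurve",
    "GateParams",
    "density_peaks",
    "detect_failed_well",
    "flag_outliers",
    "flag_empty",
]


@dataclass(frozen=True)
class DensityCurve:
    """A 1-D kernel density estimate evaluated on a regular grid.

    The density integrates to ~1 over the grid (trapezoid rule); the grid
    extends three bandwidths beyond the data range so essentially no mass
    is clipped.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class GateParams:
    """Tunable thresholds for the QC stages.

    min_total_droplets:
        A well with fewer droplets than this is a failed reaction; the
        instrument nominally produces ~15-20k droplets per well.
    min_empty_fraction:
        Minimum fraction of droplets below the empty/filled valley for the
        well to count as a plausible digital experiment; 0.15 admits loads
        up to roughly lambda = 1.9 while still failing saturated wells.
    outlier_top_quantile, outlier_k:
        Tukey-style tail fence: amplitudes above
        Q(outlier_top_quantile) + outlier_k * IQR in either channel are
        readout outliers.
    peak_min_prominence:
        Prominence, as a fraction of the density maximum, below which a
        local density maximum is not reported as a peak; 0.02 keeps the
        filled peak visible at occupancies down to lambda ~ 0.05.
    kde_grid_points:
        Resolution of the density grid.
    """

    min_total_droplets: int = 5000
    min_empty_fraction: float = 0.15
    outlier_top_quantile: float = 0.99
    outlier_k: float = 5.0
    peak_min_prominence: float = 0.02
    kde_grid_points: int = 512

    def __post_init__(self) -> None:
        for name in ("min_empty_fraction", "outlier_top_quantile", "peak_min_prominence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if self.min_total_droplets < 0 or self.kde_grid_points < 8:
            raise ValueError("invalid count parameter")


def _silverman_bandwidth(values: np.ndarray) -> float:
    """Robust Silverman rule: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * values.size ** (-1 / 5)


def density_peaks(
    values: np.ndarray, params: GateParams | None = None
) -> tuple[DensityCurve, np.ndarray, np.ndarray]:
    """Estimate the amplitude density and locate its peaks and valleys.

    Peaks are local maxima of the kernel density estimate with prominence
    at least ``peak_min_prominence`` times the density maximum, reported in
    ascending position order. Valleys are the minimum-density grid points
    between consecutive reported peaks (one fewer than the peaks).

    Raises
    ------
    InsufficientDataError
        If fewer than 10 finite values are supplied.
    """
    params = params or GateParams()
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise InsufficientDataError(
            f"need at least 10 finite values for a density estimate, got {values.size}"
        )

    h = _silverman_bandwidth(values)
    if h <= 0 or np.ptp(values) == 0:
        # Degenerate spread: report a single peak at the (near-)constant value.
        c = float(np.median(values))
        grid = np.array([c - 1.0, c, c + 1.0])
        curve = DensityCurve(grid=grid, density=np.array([0.0, 1.0, 0.0]), bandwidth=0.0)
        return curve, np.array([c]), np.array([])

    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, params.kde_grid_points)
    kde = stats.gaussian_kde(values, bw_method=h / values.std(ddof=1))
    density = kde(grid)
    curve = DensityCurve(grid=grid, density=density, bandwidth=h)

    idx, _ = signal.find_peaks(density, prominence=params.peak_min_prominence * density.max())
    idx = np.sort(idx)
    peaks = grid[idx]

    valleys = np.empty(max(len(idx) - 1, 0))
    for i in range(len(idx) - 1):
        lo, hi = idx[i], idx[i + 1]
        valleys[i] = grid[lo + int(np.argmin(density[lo : hi + 1]))]
    return curve, peaks, valleys


def detect_failed_well(
    ch1: np.ndarray,
    ch2: np.ndarray,
    positive_channel: int | None,
    params: GateParams | None = None,
) -> tuple[bool, str | None]:
    """Decide whether a well's reaction failed.

    A well fails if it has too few droplets, if the positive-channel
    amplitude density shows no empty/filled valley, or if too small a
    fraction of droplets sits below the first valley (no credible empty
    population). For assays without a designated positive channel the
    check runs on channel 1.

    Returns ``(success, reason)``; failure is a result, not an exception.
    """
    params = params or GateParams()
    n = len(ch1)
    if n < params.min_total_droplets:
        return False, f"too few droplets ({n} < {params.min_total_droplets})"
    amps = np.asarray(ch1 if positive_channel in (1, None) else ch2, dtype=float)
    try:
        _, peaks, valleys = density_peaks(amps, params)
    except InsufficientDataError:
        return False, "too few finite amplitudes"
    if len(valleys) == 0:
        return False, "no empty/filled separation"
    empty_frac = float(np.mean(amps < valleys[0]))
    if empty_frac < params.min_empty_fraction:
        return False, (
            f"empty fraction {empty_frac:.3f} below minimum {params.min_empty_fraction}"
        )
    return True, None


def flag_outliers(
    ch1: np.ndarray, ch2: np.ndarray, params: GateParams | None = None
) -> np.ndarray:
    """Mark droplets whose amplitude exceeds a per-channel tail fence.

    The fence for a channel is ``Q(outlier_top_quantile) + outlier_k * IQR``
    of that channel's amplitudes; a droplet is an outlier iff either channel
    strictly exceeds its fence. With zero spread nothing strictly exceeds
    the fence, so constant wells yield no outliers.
    """
    params = params or GateParams()
    mask = np.zeros(len(ch1), dtype=bool)
    for amps in (np.asarray(ch1, dtype=float), np.asarray(ch2, dtype=float)):
        q75, q25 = np.percentile(amps, [75, 25])
        cutoff = np.quantile(amps, params.outlier_top_quantile) + params.outlier_k * (q75 - q25)
        mask |= amps > cutoff
    return mask


def flag_empty(
    ch1: np.ndarray,
    ch2: np.ndarray,
    positive_channel: int | None,
    params: GateParams | None = None,
) -> tuple[np.ndarray, dict[int, float]]:
    """Identify empty droplets by thresholding at the first density valley.

    For PN/PP assays (``positive_channel`` 1 or 2) every template-containing
    droplet is positive in that channel, so the cutoff is the first valley
    of the positive-channel density and droplets strictly below it are
    empty. For generic assays the rule is applied per channel and a droplet
    is empty only if it is below the cutoff in both channels; a channel with
    no valley (no positive population) places no constraint.

    Parameters are the amplitudes of droplets still in play (outliers and
    failed wells already excluded). Returns the empty mask and the cutoff
    per channel.

    Raises
    ------
    InternalContradictionError
        If the positive channel of a PN/PP well that passed QC no longer
        shows a valley.
    """
    params = params or GateParams()
    channels = {1: np.asarray(ch1, dtype=float), 2: np.asarray(ch2, dtype=float)}
    cutoffs: dict[int, float] = {}
    if positive_channel in (1, 2):
        _, _, valleys = density_peaks(channels[positive_channel], params)
        if len(valleys) == 0:
            raise InternalContradictionError(
                "well passed QC but the empty/filled valley disappeared after outlier removal"
            )
        cutoffs[positive_channel] = float(valleys[0])
        mask = channels[positive_channel] < cutoffs[positive_channel]
        return mask, cutoffs

    mask = np.ones(len(ch1), dtype=bool)
    for c, amps in channels.items():
        _, _, valleys = density_peaks(amps, params)
        if len(valleys) == 0:
            cutoffs[c] = float("inf")
        else:
            cutoffs[c] = float(valleys[0])
        mask &= amps < cutoffs[c]
    return mask, cutoffs
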