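"""Mixture-model gating of template-containing droplets in PN/PP assays.

A PN/PP assay produces two non-empty populations: singly-positive droplets
(mutant allele only) and double-positive droplets (wild-type present).
Both are positive in the assay's constitutive channel, so the gate acts on
the *variable* channel, where the two populations separate. The gate is a
two-component univariate Gaussian mixture fitted by EM with deterministic
initialization; droplets far from their assigned component (beyond
``rain_sd_multiplier`` standard deviations) are rain. Wells whose minor
population is too small to fit reliably borrow a consensus gate from the
confident wells of the same plate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InsufficientDataError
from .wells import ClusterLabel

__all__ = [
    "MixtureFit",
    "PnppGateParams",
    "WellGate",
    "fit_two_gaussian_em",
    "detect_significant_minor",
    "gate_pnpp_well",
    "reclassify_pnpp",
    "manual_gate",
    "variable_channel",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: labels a gate may (re)assign — the template-containing droplets
FILLED_LABELS = (
    ClusterLabel.UNDEFINED.value,
    ClusterLabel.RAIN.value,
    ClusterLabel.SINGLE_POS.value,
    ClusterLabel.DOUBLE_POS.value,
)


def variable_channel(positive_channel: int) -> int:
    """The channel on which PN and PP populations separate."""
    if positive_channel not in (1, 2):
        raise ValueError(f"positive_channel must be 1 or 2, got {positive_channel!r}")
    return 2 if positive_channel == 1 else 1


@dataclass(frozen=True)
class MixtureFit:
    """A converged (or iteration-capped) two-component Gaussian mixture.

    Components are reported in ascending-mean order; weights sum to one.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class PnppGateParams:
    """Gating parameters.

    rain_sd_multiplier:
        Half-width, in component standard deviations, of the band around
        each component mean outside of which a droplet is rain.
    em_max_iter / em_tol:
        EM stopping rule (iteration cap / log-likelihood change).
    min_minor_weight / min_minor_count / max_minor_sd_ratio / min_separation_sds:
        A fitted minor component lighter than min_minor_weight, with an
        expected droplet count below min_minor_count, with a standard
        deviation more than max_minor_sd_ratio times the major
        component's (a rain shelf masquerading as a cluster), or whose
        mean sits within min_separation_sds standard deviations of the
        other component's (one population split in two, not two
        populations) is not trusted; such wells are re-gated from the
        plate consensus.
    borrow_gate_quantile:
        Quantile of the confident wells' gate geometry (boundary, band
        centers and scales) used as the consensus gate (0.5 = median).
    """

    rain_sd_multiplier: float = 3.0
    em_max_iter: int = 200
    em_tol: float = 1e-6
    min_minor_weight: float = 0.01
    min_minor_count: int = 4
    max_minor_sd_ratio: float = 4.0
    min_separation_sds: float = 3.0
    borrow_gate_quantile: float = 0.5

    def __post_init__(self) -> None:
        if self.rain_sd_multiplier <= 0 or self.em_tol <= 0 or self.em_max_iter <= 0:
            raise ValueError("rain_sd_multiplier, em_tol, em_max_iter must be positive")
        if self.max_minor_sd_ratio <= 0:
            raise ValueError("max_minor_sd_ratio must be positive")
        for name in ("min_minor_weight", "borrow_gate_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")


@dataclass
class WellGate:
    """Gate description for one well: the fit, the boundary, and its status."""

    means: tuple[float, float] | None = None
    sds: tuple[float, float] | None = None
    weights: tuple[float, float] | None = None
    boundary: float = math.nan  # variable-channel cutoff between PN and PP
    confident: bool = False
    gate_failed: bool = False
    borrowed: bool = False


def _log_resp(v: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (v[:, None] - mu[None, :]) / sd[None, :]
    return np.log(w)[None, :] - np.log(sd)[None, :] - 0.5 * (z * z + _LOG_2PI)


def fit_two_gaussian_em(
    values: np.ndarray, params: PnppGateParams | None = None
) -> MixtureFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    Initialization is deterministic: the sample is split at its median and
    each half supplies one component's starting moments, so the fit is
    reproducible without a random seed. Standard deviations are floored at
    1e-6 times the data range to prevent collapse onto a point. The
    log-likelihood is non-decreasing across iterations (asserted); the loop
    stops when it changes by less than ``em_tol`` or after ``em_max_iter``
    iterations.

    Raises
    ------
    DegenerateFitError
        If the input has zero spread.
    InsufficientDataError
        If fewer than ``2 * min_minor_count`` values are supplied.
    """
    params = params or PnppGateParams()
    v = np.asarray(values, dtype=float)
    if v.size < 2 * params.min_minor_count:
        raise InsufficientDataError(
            f"need at least {2 * params.min_minor_count} values, got {v.size}"
        )
    span = float(np.ptp(v))
    if span == 0.0:
        raise DegenerateFitError("all values identical: mixture fit is degenerate")
    floor = 1e-6 * span

    order = np.sort(v)
    half = v.size // 2
    lo, hi = order[:half], order[half:]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum([lo.std(), hi.std()], floor)
    w = np.array([lo.size, hi.size], dtype=float) / v.size

    prev_ll = -np.inf
    ll = prev_ll
    converged = False
    it = 0
    for it in range(1, params.em_max_iter + 1):
        lr = _log_resp(v, w, mu, sd)
        m = lr.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(lr - m).sum(axis=1))
        ll = float(lse.sum())
        assert ll >= prev_ll - 1e-8 * (1.0 + abs(ll)), "EM log-likelihood decreased"
        if abs(ll - prev_ll) < params.em_tol:
            converged = True
            break
        prev_ll = ll

        resp = np.exp(lr - lse[:, None])
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        w = nk / v.size
        mu = (resp * v[:, None]).sum(axis=0) / nk
        var = (resp * (v[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), floor)

    if mu[0] > mu[1]:
        mu, sd, w = mu[::-1], sd[::-1], w[::-1]
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        loglik=ll,
        iterations=it,
        converged=converged,
    )


def detect_significant_minor(
    fit: MixtureFit, n_filled: int, params: PnppGateParams | None = None
) -> bool:
    """Is the lighter mixture component a real droplet population?

    True iff its weight reaches ``min_minor_weight``, its expected droplet
    count (weight x n_filled) reaches ``min_minor_count`` (both thresholds
    inclusive), its standard deviation is at most ``max_minor_sd_ratio``
    times the other component's, and the component means are at least
    ``min_separation_sds`` standard deviations apart. The sd guard rejects
    fits where the "cluster" is really the diffuse rain shelf between
    populations; the separation guard rejects fits that split one
    population into two overlapping halves. A False verdict means the
    well is treated as single-population and deferred to the
    plate-consensus re-gate.
    """
    params = params or PnppGateParams()
    i_minor = 0 if fit.weights[0] <= fit.weights[1] else 1
    w_minor = fit.weights[i_minor]
    sd_ok = fit.sds[i_minor] <= params.max_minor_sd_ratio * fit.sds[1 - i_minor]
    separated = (fit.means[1] - fit.means[0]) >= params.min_separation_sds * max(fit.sds)
    return (
        w_minor >= params.min_minor_weight
        and w_minor * n_filled >= params.min_minor_count
        and sd_ok
        and separated
    )


def gate_pnpp_well(
    ch1: np.ndarray,
    ch2: np.ndarray,
    positive_channel: int,
    params: PnppGateParams | None = None,
) -> tuple[np.ndarray | None, WellGate]:
    """Gate the template-containing droplets of one well.

    ``ch1``/``ch2`` are the amplitudes of filled droplets only (QC passed,
    outliers and empties excluded). The mixture is fitted on the variable
    channel; the lower-mean component is SINGLE_POS (mutant), the higher
    DOUBLE_POS (wild-type). Each droplet goes to its maximum-posterior
    component (ties to the lower mean), then becomes RAIN if it lies more
    than ``rain_sd_multiplier`` band scales from its component's band
    center. Band centers and scales are the median and 1.4826*MAD of each
    component's assigned droplets — the EM standard deviations themselves
    are biased upward by the rain shelf, while the robust scales track the
    underlying cluster.

    Returns ``(labels, gate)``. ``labels`` is None — and the gate is marked
    failed — when the well cannot support a fit (too few droplets, zero
    spread); wells whose minor component is insignificant are labeled
    single-population and left unconfident. Both kinds are resolved by
    :func:`reclassify_pnpp`.
    """
    params = params or PnppGateParams()
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    v = ch2 if variable_channel(positive_channel) == 2 else ch1
    vpos = ch1 if positive_channel == 1 else ch2
    try:
        fit = fit_two_gaussian_em(v, params)
    except (DegenerateFitError, InsufficientDataError):
        return None, WellGate(gate_failed=True)

    lr = _log_resp(v, np.array(fit.weights), np.array(fit.means), np.array(fit.sds))
    comp = np.where(lr[:, 0] >= lr[:, 1], 0, 1)  # tie -> lower mean
    centers, scales = _robust_bands(v, comp, fit)
    pos_centers, pos_scales = _robust_bands(vpos, comp, fit, fallback_sds=None)

    # Significance is judged on the robust scales: the EM sds themselves
    # are inflated by the rain shelf between the clusters.
    robust_fit = MixtureFit(
        weights=fit.weights,
        means=(float(centers[0]), float(centers[1])),
        sds=(float(scales[0]), float(scales[1])),
        loglik=fit.loglik,
        iterations=fit.iterations,
        converged=fit.converged,
    )
    if not detect_significant_minor(robust_fit, v.size, params):
        # Single-population well: everything filled is wild-type for now;
        # the cross-well re-gate gets the final word.
        gate = WellGate(
            means=robust_fit.means,
            sds=robust_fit.sds,
            weights=fit.weights,
            boundary=0.5 * (robust_fit.means[0] + robust_fit.means[1]),
            confident=False,
        )
        labels = np.full(v.size, ClusterLabel.DOUBLE_POS.value, dtype=object)
        return labels, gate

    gate = WellGate(
        means=robust_fit.means,
        sds=robust_fit.sds,
        weights=fit.weights,
        boundary=0.5 * float(centers[0] + centers[1]),
        confident=True,
    )
    labels = np.where(
        comp == 0, ClusterLabel.SINGLE_POS.value, ClusterLabel.DOUBLE_POS.value
    ).astype(object)
    k = params.rain_sd_multiplier
    rain = np.abs(v - centers[comp]) > k * scales[comp]
    if pos_centers is not None:
        # Partially amplified droplets sag below the cluster in the
        # constitutive channel even when their variable-channel amplitude
        # looks normal (mutant-derived rain does exactly this).
        rain |= np.abs(vpos - pos_centers[comp]) > k * pos_scales[comp]
    labels[rain] = ClusterLabel.RAIN.value
    return labels, gate


def _robust_bands(
    x: np.ndarray, comp: np.ndarray, fit: MixtureFit, fallback_sds=True
):
    """Median and 1.4826*MAD of each component's assigned members."""
    centers = np.empty(2)
    scales = np.empty(2)
    for j in (0, 1):
        member = x[comp == j]
        if member.size == 0:
            if fallback_sds is None:
                return None, None
            centers[j], scales[j] = fit.means[j], fit.sds[j]
            continue
        centers[j] = np.median(member)
        mad = np.median(np.abs(member - centers[j]))
        if mad > 0:
            scales[j] = 1.4826 * mad
        elif fallback_sds is None:
            return None, None
        else:
            scales[j] = fit.sds[j]
    return centers, scales


def _threshold_labels(v: np.ndarray, boundary: float) -> np.ndarray:
    return np.where(
        v < boundary, ClusterLabel.SINGLE_POS.value, ClusterLabel.DOUBLE_POS.value
    ).astype(object)


def _band_labels(
    v: np.ndarray, centers: np.ndarray, scales: np.ndarray, boundary: float, k: float
) -> np.ndarray:
    labels = _threshold_labels(v, boundary)
    comp = (v >= boundary).astype(int)
    labels[np.abs(v - centers[comp]) > k * scales[comp]] = ClusterLabel.RAIN.value
    return labels


def reclassify_pnpp(plate, params: PnppGateParams | None = None):
    """Re-gate low-signal wells with the plate's consensus gate.

    Confident wells are those whose own mixture fit had a significant
    minor component. Their gate geometry — boundary, band centers and
    band scales in the variable channel — is pooled per-quantile
    (``borrow_gate_quantile``; the median by default) into a consensus
    gate, which is legitimate because wells of one plate share the assay
    chemistry and instrument scaling. Wells that are gate-failed or not
    confident have their filled droplets re-gated with it: split at the
    consensus boundary, then the usual rain band around the consensus
    centers. With zero confident wells the plate is returned unchanged
    with a warning.
    """
    from .plate_model import refresh_summaries  # deferred: avoids import cycle

    params = params or PnppGateParams()
    plate = plate.copy()
    gates: dict[str, WellGate] = plate.well_gates()
    trusted = [
        g
        for g in gates.values()
        if g.confident and not g.gate_failed and g.means is not None
    ]
    if not trusted:
        warnings.warn(
            "no confident wells on this plate: consensus re-gate skipped", stacklevel=2
        )
        return plate
    q = params.borrow_gate_quantile
    consensus_boundary = float(np.quantile([g.boundary for g in trusted], q))
    centers = np.array(
        [np.quantile([g.means[j] for g in trusted], q) for j in (0, 1)]
    )
    scales = np.array([np.quantile([g.sds[j] for g in trusted], q) for j in (0, 1)])

    vch = variable_channel(plate.positive_channel)
    data = plate.plate_data
    for well, gate in gates.items():
        if gate.confident and not gate.gate_failed:
            continue
        sel = (data["well"] == well) & data["label"].isin(FILLED_LABELS)
        if not sel.any():
            continue
        v = data.loc[sel, f"ch{vch}"].to_numpy(dtype=float)
        data.loc[sel, "label"] = _band_labels(
            v, centers, scales, consensus_boundary, params.rain_sd_multiplier
        )
        gate.means = (float(centers[0]), float(centers[1]))
        gate.sds = (float(scales[0]), float(scales[1]))
        gate.boundary = consensus_boundary
        gate.borrowed = True
        gate.gate_failed = False
        plate.set_well_gate(well, gate)
    refresh_summaries(plate)
    return plate


def manual_gate(plate, selector, boundary: float):
    """Manually re-gate selected wells at a fixed variable-channel cutoff.

    Filled droplets of the selected wells are relabeled by a simple
    threshold rule (below ``boundary`` -> SINGLE_POS, otherwise
    DOUBLE_POS); any rain assignment is discarded and summaries are
    recomputed. Intended for secondary verification of the automated gate.
    """
    from .plate_model import refresh_summaries
    from .wells import parse_selector

    if not math.isfinite(boundary):
        raise ValueError("boundary must be finite")
    plate = plate.copy()
    wells = [w for w in parse_selector(selector) if w in plate.wells()]
    if not wells:
        from .errors import SelectionError

        raise SelectionError(f"selector {selector!r} matches no wells on this plate")

    vch = variable_channel(plate.positive_channel)
    data = plate.plate_data
    for well in wells:
        sel = (data["well"] == well) & data["label"].isin(FILLED_LABELS)
        v = data.loc[sel, f"ch{vch}"].to_numpy(dtype=float)
        data.loc[sel, "label"] = _threshold_labels(v, boundary)
        gate = plate.well_gates().get(well, WellGate())
        gate.boundary = float(boundary)
        gate.confident = True
        gate.gate_failed = False
        plate.set_well_gate(well, gate)
    refresh_summaries(plate)
    return plate
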