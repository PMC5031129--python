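"""Poisson occupancy quantification and mutant allele frequency.

Droplets partition the sample at random, so the number of templates per
droplet is Poisson. With p the fraction of template-positive droplets,
the mean occupancy is lambda = -ln(1 - p) and the template concentration
is lambda divided by the droplet volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import SaturationError

__all__ = ["QuantParams", "poisson_concentration", "mutant_frequency"]


@dataclass(frozen=True)
class QuantParams:
    """Quantification settings.

    droplet_volume_nl:
        Volume of one droplet in nanolitres; 0.85 nL is the nominal
        Bio-Rad droplet volume. Concentrations are reported in copies
        per microlitre of input.
    poisson_correct_frequency:
        Whether the mutant frequency uses Poisson-corrected per-allele
        loads (lambda ratios) or raw droplet-count ratios. The two agree
        in the low-occupancy limit.
    """

    droplet_volume_nl: float = 0.85
    poisson_correct_frequency: bool = True

    def __post_init__(self) -> None:
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")


def _lambda(n_positive: int, n_total: int) -> float:
    if not 0 <= n_positive <= n_total:
        raise ValueError(f"need 0 <= n_positive <= n_total, got {n_positive}/{n_total}")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_positive == n_total:
        raise SaturationError(
            "every droplet is positive: occupancy -ln(1-p) is undefined at p=1"
        )
    return -math.log1p(-n_positive / n_total) + 0.0  # normalize -0.0


def poisson_concentration(
    n_positive: int, n_total: int, quant: QuantParams | None = None
) -> float:
    """Template concentration in copies per microlitre.

    lambda = -ln(1 - n_positive/n_total); concentration = lambda / V with
    V the droplet volume in microlitres (droplet_volume_nl * 1e-3).

    Raises
    ------
    SaturationError
        If every droplet is positive (lambda unbounded).
    """
    quant = quant or QuantParams()
    return _lambda(n_positive, n_total) / (quant.droplet_volume_nl * 1e-3)


def mutant_frequency(
    n_single_pos: int,
    n_double_pos: int,
    n_total: int,
    quant: QuantParams | None = None,
) -> float:
    """Mutant allele frequency in percent.

    In a PN/PP assay the singly-positive droplets carry only the mutant
    allele while double-positive droplets carry wild-type. With Poisson
    correction on, each allele's load is estimated as
    lambda = -ln(1 - n/n_total) and the frequency is
    100 * lambda_mut / (lambda_mut + lambda_wt); with correction off it is
    the raw droplet-count ratio. Returns NaN when both positive counts are
    zero (frequency undefined).

    Raises
    ------
    SaturationError
        If either positive count saturates the well.
    """
    quant = quant or QuantParams()
    if n_single_pos + n_double_pos > n_total:
        raise ValueError("positive counts exceed total droplets")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_single_pos == 0 and n_double_pos == 0:
        return math.nan
    if quant.poisson_correct_frequency:
        lam_mut = _lambda(n_single_pos, n_total)
        lam_wt = _lambda(n_double_pos, n_total)
        return 100.0 * lam_mut / (lam_mut + lam_wt)
    return 100.0 * n_single_pos / (n_single_pos + n_double_pos)
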