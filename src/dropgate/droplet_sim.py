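"""Synthetic droplet-cloud generator with known ground truth.

Emulates a two-channel PN/PP experiment: template molecules partition
into droplets at random (Poisson occupancy per allele), empty droplets
fluoresce at baseline in both channels, mutant-only droplets light up the
constitutive (FAM) channel, and wild-type-containing droplets light up
both. A fraction of template-containing droplets is converted to rain
(partial amplification: intermediate amplitudes between a cluster and the
empty cloud) and a small fraction to high-amplitude readout outliers.

Every draw is reproducible from the seed, and the writer emits the same
CSV bundle layout the amplitude importer consumes, so the whole pipeline
is testable without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .wells import ClusterLabel, WellId

__all__ = ["SimParams", "simulate_well", "simulate_plate_bundle", "TRUTH_SUFFIX"]

TRUTH_SUFFIX = "_truth.csv"

#: per-population (ch1, ch2) amplitude means for a FAM-positive PN/PP assay
DEFAULT_CENTERS = {
    ClusterLabel.EMPTY.value: (1800.0, 1700.0),
    ClusterLabel.SINGLE_POS.value: (8200.0, 2800.0),
    ClusterLabel.DOUBLE_POS.value: (8400.0, 8200.0),
}
DEFAULT_SDS = {
    ClusterLabel.EMPTY.value: (150.0, 150.0),
    ClusterLabel.SINGLE_POS.value: (200.0, 200.0),
    ClusterLabel.DOUBLE_POS.value: (250.0, 250.0),
}


@dataclass(frozen=True)
class SimParams:
    """Generative description of one synthetic well.

    lambda_wt / lambda_mut:
        Mean wild-type / mutant templates per droplet. Droplets with any
        wild-type template are double-positive (the wild-type probe fires
        both dyes in this assay design); droplets with only mutant
        template are singly-positive; droplets with neither are empty.
    centers / sds:
        Per-population (ch1, ch2) amplitude means and spreads.
    rain_fraction:
        Fraction of template-containing droplets repositioned as rain
        along the segment from the empty-cluster center toward their own
        cluster center, uniformly within ``rain_span`` (fraction of the
        distance from empty toward the cluster). The span starts at 0.5
        because droplets nearer the empty cloud are indistinguishable
        from empties — real rain sits between the empty/filled threshold
        and the positive cluster.
    outlier_fraction / outlier_scale:
        Fraction of droplets turned into readout spikes by scaling the
        channel-1 amplitude of a template-containing droplet.
    """

    n_droplets: int = 15000
    lambda_wt: float = 0.5
    lambda_mut: float = 0.05
    centers: dict = field(default_factory=lambda: dict(DEFAULT_CENTERS))
    sds: dict = field(default_factory=lambda: dict(DEFAULT_SDS))
    rain_fraction: float = 0.02
    rain_span: tuple[float, float] = (0.5, 0.9)
    outlier_fraction: float = 0.0005
    outlier_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.lambda_wt < 0 or self.lambda_mut < 0:
            raise ValueError("lambda values must be non-negative")
        for name in ("rain_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v!r}")
        e, s, d = (
            self.centers[ClusterLabel.EMPTY.value],
            self.centers[ClusterLabel.SINGLE_POS.value],
            self.centers[ClusterLabel.DOUBLE_POS.value],
        )
        if not (e[0] < s[0] and e[0] < d[0]):
            raise ValueError("EMPTY center must sit below the positive populations in ch1")


def simulate_well(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one well: returns ``(droplets, truth)``.

    ``droplets`` has columns ch1, ch2; ``truth`` has the generative class
    per droplet (EMPTY / SINGLE_POS / DOUBLE_POS / RAIN / OUTLIER) and the
    template counts k_wt, k_mut. Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_droplets
    k_wt = rng.poisson(params.lambda_wt, n)
    k_mut = rng.poisson(params.lambda_mut, n)

    cls = np.full(n, ClusterLabel.EMPTY.value, dtype=object)
    cls[k_mut > 0] = ClusterLabel.SINGLE_POS.value
    cls[k_wt > 0] = ClusterLabel.DOUBLE_POS.value  # wild-type dominates

    ch = np.empty((n, 2))
    for label in (
        ClusterLabel.EMPTY.value,
        ClusterLabel.SINGLE_POS.value,
        ClusterLabel.DOUBLE_POS.value,
    ):
        idx = np.flatnonzero(cls == label)
        for c in (0, 1):
            ch[idx, c] = rng.normal(
                params.centers[label][c], params.sds[label][c], idx.size
            )

    truth_cls = cls.copy()
    filled = np.flatnonzero(cls != ClusterLabel.EMPTY.value)

    n_outlier = int(round(params.outlier_fraction * n))
    outlier_idx = np.array([], dtype=int)
    if n_outlier > 0 and filled.size > 0:
        outlier_idx = rng.choice(filled, size=min(n_outlier, filled.size), replace=False)
        ch[outlier_idx, 0] *= params.outlier_scale
        truth_cls[outlier_idx] = ClusterLabel.OUTLIER.value

    remaining = np.setdiff1d(filled, outlier_idx, assume_unique=True)
    n_rain = int(round(params.rain_fraction * filled.size))
    if n_rain > 0 and remaining.size > 0:
        rain_idx = rng.choice(remaining, size=min(n_rain, remaining.size), replace=False)
        t = rng.uniform(params.rain_span[0], params.rain_span[1], rain_idx.size)
        empty = np.array(params.centers[ClusterLabel.EMPTY.value])
        for j, i in enumerate(rain_idx):
            center = np.array(params.centers[cls[i]])
            ch[i] = empty + t[j] * (center - empty)
        truth_cls[rain_idx] = ClusterLabel.RAIN.value

    droplets = pd.DataFrame({"ch1": ch[:, 0], "ch2": ch[:, 1]})
    truth = pd.DataFrame({"class": truth_cls, "k_wt": k_wt, "k_mut": k_mut})
    return droplets, truth


def simulate_plate_bundle(
    well_specs: dict[str, SimParams],
    directory,
    prefix: str = "SIM",
    sample_names: dict[str, str] | None = None,
) -> Path:
    """Write a QuantaSoft-style CSV bundle for the given wells.

    Emits one ``<prefix>_<WELL>_Amplitude.csv`` per well (amplitudes
    rendered with four decimals, which fixes the text form across
    platforms), one metadata CSV with one row per well and channel target
    (as the instrument software does), and a ``<prefix>_truth.csv``
    ground-truth table for test use. Identical specs produce
    byte-identical bundles.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wells = [str(WellId.parse(w)) for w in well_specs]
    if len(set(wells)) != len(wells):
        raise InputError(f"duplicate wells in simulation spec: {sorted(well_specs)}")
    if len(wells) > 96:
        raise InputError("a plate has at most 96 wells")

    truth_rows = []
    meta_rows = []
    for raw_well, params in well_specs.items():
        well = str(WellId.parse(raw_well))
        droplets, truth = simulate_well(params)
        out = directory / f"{prefix}_{well}_Amplitude.csv"
        with open(out, "w", newline="") as fh:
            fh.write("Ch1 Amplitude,Ch2 Amplitude\n")
            for a, b in droplets.itertuples(index=False):
                fh.write(f"{a:.4f},{b:.4f}\n")
        truth = truth.copy()
        truth.insert(0, "well", well)
        truth_rows.append(truth)
        sample = (sample_names or {}).get(raw_well, f"sample_{well}")
        meta_rows.append({"Well": well, "Sample": sample, "Target": "MUT"})
        meta_rows.append({"Well": well, "Sample": sample, "Target": "WT"})

    pd.DataFrame(meta_rows).to_csv(directory / f"{prefix}_metadata.csv", index=False)
    pd.concat(truth_rows, ignore_index=True).to_csv(
        directory / f"{prefix}{TRUTH_SUFFIX}", index=False
    )
    return directory


def load_truth(directory, prefix: str = "SIM") -> pd.DataFrame:
    """Read back the ground-truth table written by simulate_plate_bundle."""
    return pd.read_csv(Path(directory) / f"{prefix}{TRUTH_SUFFIX}")
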