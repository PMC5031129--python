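"""Well coordinates, cluster labels, and per-well summaries for a 96-well plate."""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum

from .errors import SelectionError

__all__ = ["WellId", "ClusterLabel", "WellSummary", "ROWS", "COLUMNS", "parse_selector"]

ROWS = "ABCDEFGH"
COLUMNS = range(1, 13)

_WELL_RE = re.compile(r"^([A-Ha-h])(0?[1-9]|1[0-2])$")


@dataclass(frozen=True, order=True)
class WellId:
    """One well of a 96-well plate, e.g. row 'A', column 1 -> "A01".

    Ordering is row-major (A01 ... A12, B01 ...), the plate's reading order.
    """

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS or self.column not in COLUMNS:
            raise SelectionError(f"invalid well coordinates {self.row}{self.column}")

    @classmethod
    def parse(cls, text: str) -> "WellId":
        m = _WELL_RE.match(text.strip())
        if not m:
            raise SelectionError(f"not a well id: {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column:02d}"


def parse_selector(selector: str | list[str]) -> list[str]:
    """Expand a well selector into canonical well names.

    A selector is a well ("F05"), a rectangular range ("A01:C05" = rows A-C
    crossed with columns 1-5, inclusive), or a comma-separated union of
    either. Lists of selectors union as well. Output is row-major ordered
    and deduplicated.
    """
    terms: list[str] = []
    if isinstance(selector, str):
        terms = [t for t in selector.split(",") if t.strip()]
    else:
        for s in selector:
            terms.extend(t for t in str(s).split(",") if t.strip())
    if not terms:
        raise SelectionError("empty selector")

    wells: set[WellId] = set()
    for term in terms:
        term = term.strip()
        if ":" in term:
            a, _, b = term.partition(":")
            lo, hi = WellId.parse(a), WellId.parse(b)
            r0, r1 = sorted((lo.row, hi.row))
            c0, c1 = sorted((lo.column, hi.column))
            for r in ROWS[ROWS.index(r0) : ROWS.index(r1) + 1]:
                for c in range(c0, c1 + 1):
                    wells.add(WellId(r, c))
        else:
            wells.add(WellId.parse(term))
    return [str(w) for w in sorted(wells)]


class ClusterLabel(str, Enum):
    """Droplet assignment vocabulary.

    UNDEFINED is the pre-analysis state; every pipeline stage only refines
    it. FAILED marks all droplets of a failed well; OUTLIER marks readout
    errors; EMPTY marks template-free droplets; SINGLE_POS (mutant,
    singly-positive), DOUBLE_POS (wild-type, double-positive) and RAIN
    (ambiguous, between clusters) partition the template-containing
    droplets of a gated PN/PP well.
    """

    UNDEFINED = "UNDEFINED"
    FAILED = "FAILED"
    OUTLIER = "OUTLIER"
    EMPTY = "EMPTY"
    RAIN = "RAIN"
    SINGLE_POS = "SINGLE_POS"
    DOUBLE_POS = "DOUBLE_POS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class WellSummary:
    """Per-well QC verdict, cluster counts, concentrations and mutant frequency.

    Concentrations are copies per microlitre; mutant_freq is percent.
    gate_ch1/gate_ch2 are the per-channel cutoffs used (empty-droplet
    cutoff in the positive channel, mixture gate in the variable channel);
    NaN where no gate applies. Failed wells carry counts only.
    """

    well: str
    success: bool = True
    failure_reason: str | None = None
    n_total: int = 0
    n_outlier: int = 0
    n_empty: int = 0
    n_rain: int = 0
    n_single_pos: int = 0
    n_double_pos: int = 0
    conc_total: float = math.nan
    conc_single: float = math.nan
    conc_double: float = math.nan
    mutant_freq: float = math.nan
    gate_ch1: float = math.nan
    gate_ch2: float = math.nan

    FIELDS = (
        "well",
        "success",
        "failure_reason",
        "n_total",
        "n_outlier",
        "n_empty",
        "n_rain",
        "n_single_pos",
        "n_double_pos",
        "conc_total",
        "conc_single",
        "conc_double",
        "mutant_freq",
        "gate_ch1",
        "gate_ch2",
    )
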