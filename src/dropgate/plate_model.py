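"""Plate state model, assay-type registry, and pipeline orchestration.

A :class:`Plate` bundles the complete analysis state of one 96-well run:
the droplet table, per-well metadata, the resolved parameters, and the
pipeline cursor. Assay types form a single-inheritance registry: each
type names a parent, inherits its step list and parameters transitively
from the root ``generic`` type, and may override either. ``generic``
plates run QC and empty-droplet removal only; PN/PP plates add mixture
gating and the cross-well re-gate.
"""

from __future__ import annotations

import copy as _copy
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pnpp_gating, qc_gates, quantify
from .errors import InputError, RegistryError, SaturationError, SelectionError
from .pnpp_gating import PnppGateParams, WellGate
from .qc_gates import GateParams
from .quantify import QuantParams
from .wells import ClusterLabel, WellId, WellSummary, parse_selector

__all__ = [
    "AssayType",
    "PipelineStatus",
    "Plate",
    "PLATE_FORMAT_VERSION",
    "register_assay",
    "registered_assays",
    "resolve_assay",
    "new_plate",
    "plate_from_tables",
    "subset_plate",
    "analyze",
    "next_step",
    "set_params",
    "well_table",
    "refresh_summaries",
    "plates_equal",
]

PLATE_FORMAT_VERSION = "1.0"

STEP_INITIALIZE = "initialize"
STEP_REMOVE_FAILURES = "remove_failures"
STEP_REMOVE_OUTLIERS = "remove_outliers"
STEP_REMOVE_EMPTY = "remove_empty"
STEP_CLASSIFY_PNPP = "classify_pnpp"
STEP_RECLASSIFY_PNPP = "reclassify_pnpp"

#: labels each step may assign; used to roll state back when params change
STEP_LABELS: dict[str, tuple[str, ...]] = {
    STEP_INITIALIZE: (),
    STEP_REMOVE_FAILURES: (ClusterLabel.FAILED.value,),
    STEP_REMOVE_OUTLIERS: (ClusterLabel.OUTLIER.value,),
    STEP_REMOVE_EMPTY: (ClusterLabel.EMPTY.value,),
    STEP_CLASSIFY_PNPP: (
        ClusterLabel.SINGLE_POS.value,
        ClusterLabel.DOUBLE_POS.value,
        ClusterLabel.RAIN.value,
    ),
    STEP_RECLASSIFY_PNPP: (
        ClusterLabel.SINGLE_POS.value,
        ClusterLabel.DOUBLE_POS.value,
        ClusterLabel.RAIN.value,
    ),
}

#: earliest pipeline step re-run when a parameter section is edited
_SECTION_STEP: dict[str, str | None] = {
    "general": STEP_REMOVE_FAILURES,
    "gate": STEP_REMOVE_FAILURES,
    "pnpp": STEP_CLASSIFY_PNPP,
    "quant": None,  # affects summaries only
}

_GATE_COLUMNS = (
    "gate_mean_lo",
    "gate_mean_hi",
    "gate_sd_lo",
    "gate_sd_hi",
    "gate_weight_lo",
    "gate_boundary",
    "gate_confident",
    "gate_failed",
    "gate_borrowed",
)
_SUMMARY_COLUMNS = tuple(f for f in WellSummary.FIELDS if f != "well")


# ---------------------------------------------------------------------------
# Assay-type registry


@dataclass(frozen=True)
class AssayType:
    """One node of the assay registry.

    ``steps`` of None inherits the parent's step list; ``param_overrides``
    is deep-merged over the ancestors' parameters; ``positive_channel``
    (1=FAM, 2=HEX, None=generic) says which channel is constitutively
    positive in template-containing droplets.
    """

    name: str
    parent: str | None
    steps: tuple[str, ...] | None = None
    param_overrides: dict = field(default_factory=dict)
    positive_channel: int | None = None


def _dataclass_defaults(cls) -> dict:
    return {f: getattr(cls(), f) for f in cls.__dataclass_fields__}


_REGISTRY: dict[str, AssayType] = {}


def register_assay(assay: AssayType) -> None:
    """Add an assay type to the registry (single inheritance only)."""
    if assay.name in _REGISTRY:
        raise RegistryError(f"assay type {assay.name!r} already registered")
    if assay.parent is None and any(a.parent is None for a in _REGISTRY.values()):
        raise RegistryError("only one root assay type is allowed")
    _REGISTRY[assay.name] = assay


def registered_assays() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def _deep_merge(base: dict, override: dict) -> dict:
    out = _copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = _copy.deepcopy(v)
    return out


def _ancestry(name: str, registry: dict[str, AssayType]) -> list[AssayType]:
    chain: list[AssayType] = []
    seen: set[str] = set()
    cur: str | None = name
    while cur is not None:
        if cur in seen:
            raise RegistryError(f"cycle in assay-type ancestry at {cur!r}")
        if cur not in registry:
            raise RegistryError(f"unknown assay type {cur!r}")
        seen.add(cur)
        chain.append(registry[cur])
        cur = registry[cur].parent
    return chain[::-1]  # root first


def resolve_assay(
    assay_type: str, registry: dict[str, AssayType] | None = None
) -> tuple[tuple[str, ...], dict, int | None]:
    """Resolve a type to its (steps, params, positive_channel) via inheritance."""
    registry = registry if registry is not None else _REGISTRY
    chain = _ancestry(assay_type, registry)
    steps: tuple[str, ...] = ()
    params: dict = {}
    positive_channel: int | None = None
    for node in chain:
        if node.steps is not None:
            steps = tuple(node.steps)
        params = _deep_merge(params, node.param_overrides)
        if node.positive_channel is not None:
            positive_channel = node.positive_channel
    params.setdefault("general", {})
    params["general"]["assay_type"] = assay_type
    params["general"]["positive_channel"] = positive_channel
    return steps, params, positive_channel


_GENERIC_STEPS = (
    STEP_INITIALIZE,
    STEP_REMOVE_FAILURES,
    STEP_REMOVE_OUTLIERS,
    STEP_REMOVE_EMPTY,
)
_PNPP_STEPS = _GENERIC_STEPS + (STEP_CLASSIFY_PNPP, STEP_RECLASSIFY_PNPP)

register_assay(
    AssayType(
        name="generic",
        parent=None,
        steps=_GENERIC_STEPS,
        param_overrides={
            "general": {},
            "gate": _dataclass_defaults(GateParams),
            "quant": _dataclass_defaults(QuantParams),
        },
    )
)
register_assay(
    AssayType(
        name="pnpp",
        parent="generic",
        steps=_PNPP_STEPS,
        param_overrides={"pnpp": _dataclass_defaults(PnppGateParams)},
    )
)
register_assay(AssayType(name="fam_positive_pnpp", parent="pnpp", positive_channel=1))
register_assay(AssayType(name="hex_positive_pnpp", parent="pnpp", positive_channel=2))


# ---------------------------------------------------------------------------
# Plate


@dataclass
class PipelineStatus:
    """Pipeline cursor: index of the last completed step.

    ``restart_from`` is set when parameters change after a step has run;
    the next analyze() rolls labels back and re-runs from that index.
    """

    cursor: int = 0
    restart_from: int | None = None


@dataclass
class Plate:
    """Complete analysis state of one plate: nine components, sufficient
    to reproduce the analysis (see persistence round-trip)."""

    plate_data: pd.DataFrame  # columns well, ch1, ch2, label
    plate_meta: pd.DataFrame  # indexed by well
    name: str
    params: dict
    status: PipelineStatus
    clusters: tuple[str, ...]
    steps: tuple[str, ...]
    dirty: bool
    version: str

    # -- convenience accessors -------------------------------------------
    @property
    def assay_type(self) -> str:
        return self.params["general"]["assay_type"]

    @property
    def positive_channel(self) -> int | None:
        return self.params["general"]["positive_channel"]

    @property
    def is_pnpp(self) -> bool:
        return STEP_CLASSIFY_PNPP in self.steps

    def gate_params(self) -> GateParams:
        return GateParams(**self.params["gate"])

    def quant_params(self) -> QuantParams:
        return QuantParams(**self.params["quant"])

    def pnpp_params(self) -> PnppGateParams:
        return PnppGateParams(**self.params["pnpp"])

    def wells(self) -> list[str]:
        return list(self.plate_meta.index)

    def used_wells(self) -> list[str]:
        return list(self.plate_meta.index[self.plate_meta["used"].astype(bool)])

    def copy(self) -> "Plate":
        return Plate(
            plate_data=self.plate_data.copy(),
            plate_meta=self.plate_meta.copy(),
            name=self.name,
            params=_copy.deepcopy(self.params),
            status=replace(self.status),
            clusters=tuple(self.clusters),
            steps=tuple(self.steps),
            dirty=self.dirty,
            version=self.version,
        )

    # -- per-well gate records (stored in plate_meta so they persist) ----
    def well_gates(self) -> dict[str, WellGate]:
        gates: dict[str, WellGate] = {}
        for well, row in self.plate_meta.iterrows():
            if not row.get("used", True) or not row.get("success", True):
                continue
            failed = bool(row.get("gate_failed", False))
            boundary = row.get("gate_boundary", math.nan)
            if not failed and (boundary is None or pd.isna(boundary)):
                continue  # gating never attempted on this well
            means = (row.get("gate_mean_lo"), row.get("gate_mean_hi"))
            sds = (row.get("gate_sd_lo"), row.get("gate_sd_hi"))
            w_lo = row.get("gate_weight_lo")
            gates[well] = WellGate(
                means=None if pd.isna(means[0]) else (float(means[0]), float(means[1])),
                sds=None if pd.isna(sds[0]) else (float(sds[0]), float(sds[1])),
                weights=None if pd.isna(w_lo) else (float(w_lo), 1.0 - float(w_lo)),
                boundary=math.nan if pd.isna(boundary) else float(boundary),
                confident=bool(row.get("gate_confident", False)),
                gate_failed=failed,
                borrowed=bool(row.get("gate_borrowed", False)),
            )
        return gates

    def set_well_gate(self, well: str, gate: WellGate) -> None:
        m = self.plate_meta
        if gate.means is not None:
            m.loc[well, ["gate_mean_lo", "gate_mean_hi"]] = gate.means
            m.loc[well, ["gate_sd_lo", "gate_sd_hi"]] = gate.sds
            m.loc[well, "gate_weight_lo"] = gate.weights[0]
        m.loc[well, "gate_boundary"] = gate.boundary
        m.loc[well, "gate_confident"] = bool(gate.confident)
        m.loc[well, "gate_failed"] = bool(gate.gate_failed)
        m.loc[well, "gate_borrowed"] = bool(gate.borrowed)


def _empty_meta(wells: list[str]) -> pd.DataFrame:
    meta = pd.DataFrame(index=pd.Index(wells, name="well"))
    meta["sample"] = None
    meta["target_ch1"] = None
    meta["target_ch2"] = None
    meta["used"] = True
    for c in ("success",):
        meta[c] = True
    meta["failure_reason"] = None
    for c in ("empty_cutoff_ch1", "empty_cutoff_ch2"):
        meta[c] = math.nan
    for c in _GATE_COLUMNS:
        meta[c] = False if c in ("gate_confident", "gate_failed", "gate_borrowed") else math.nan
    for c in _SUMMARY_COLUMNS:
        if c not in meta.columns:
            meta[c] = math.nan
    meta["n_total"] = 0
    for c in ("n_outlier", "n_empty", "n_rain", "n_single_pos", "n_double_pos"):
        meta[c] = 0
    return meta


def plate_from_tables(
    droplets: pd.DataFrame,
    meta: pd.DataFrame | None,
    assay_type: str,
    name: str = "plate",
) -> Plate:
    """Assemble a Plate from a droplet table (well, ch1, ch2) and optional
    per-well metadata (indexed by well: sample/target columns).

    Wells appearing only in the metadata are retained but marked unused;
    droplets start UNDEFINED with the cursor on the initialize step.
    """
    if droplets.empty:
        raise InputError("no droplets: cannot build a plate")
    droplets = droplets.copy()
    droplets["well"] = [str(WellId.parse(w)) for w in droplets["well"]]
    data_wells = sorted({WellId.parse(w) for w in droplets["well"]})
    all_wells = [str(w) for w in data_wells]

    extra_meta = None
    if meta is not None:
        extra_meta = meta.copy()
        extra_meta.index = [str(WellId.parse(w)) for w in extra_meta.index]
        all_wells = [str(w) for w in sorted({WellId.parse(w) for w in
                                             set(all_wells) | set(extra_meta.index)})]

    table = _empty_meta(all_wells)
    with_data = set(str(w) for w in data_wells)
    table["used"] = [w in with_data for w in table.index]
    if extra_meta is not None:
        for col in extra_meta.columns:
            dest = col if col in ("sample", "target_ch1", "target_ch2") else f"meta_{col}"
            for w in extra_meta.index:
                table.loc[w, dest] = extra_meta.loc[w, col]

    steps, params, _ = resolve_assay(assay_type)
    droplets = droplets.sort_values("well", kind="stable").reset_index(drop=True)
    droplets["label"] = ClusterLabel.UNDEFINED.value
    droplets = droplets[["well", "ch1", "ch2", "label"]]
    plate = Plate(
        plate_data=droplets,
        plate_meta=table,
        name=name,
        params=params,
        status=PipelineStatus(cursor=0),
        clusters=tuple(l.value for l in ClusterLabel),
        steps=steps,
        dirty=False,
        version=PLATE_FORMAT_VERSION,
    )
    refresh_summaries(plate)
    return plate


def new_plate(source, assay_type: str = "generic", name: str | None = None) -> Plate:
    """Load a QuantaSoft-style amplitude CSV bundle into a new Plate.

    ``source`` is a directory containing ``<prefix>_<WELL>_Amplitude.csv``
    files and, optionally, one plate metadata CSV. All droplets start
    UNDEFINED and the cursor sits on the initialize step.
    """
    from . import quantasoft_io  # deferred: io imports the plate model

    resolve_assay(assay_type)  # fail fast on unknown types
    bundle = quantasoft_io.load_plate_bundle(source)
    droplets, meta = quantasoft_io.read_bundle_tables(bundle)
    return plate_from_tables(
        droplets, meta, assay_type, name=name or bundle.prefix
    )


# ---------------------------------------------------------------------------
# Subsetting


def subset_plate(plate: Plate, selector) -> Plate:
    """Retain only the selected wells (droplets and metadata); all other
    state is copied. Selector syntax: wells, rectangular ranges
    ("A01:C05"), comma-separated unions."""
    wanted = parse_selector(selector)
    present = [w for w in wanted if w in plate.plate_meta.index]
    if not present:
        raise SelectionError(f"selector {selector!r} matches no wells on this plate")
    out = plate.copy()
    out.plate_data = (
        out.plate_data[out.plate_data["well"].isin(present)].reset_index(drop=True)
    )
    out.plate_meta = out.plate_meta.loc[[w for w in out.plate_meta.index if w in present]]
    out.name = f"{plate.name}[{','.join(present)}]"
    return out


# ---------------------------------------------------------------------------
# Pipeline steps


def _analysis_wells(plate: Plate) -> list[str]:
    """Used wells that have not failed QC."""
    m = plate.plate_meta
    return [
        w
        for w in plate.used_wells()
        if bool(m.loc[w, "success"]) or pd.isna(m.loc[w, "success"])
    ]


def _well_mask(plate: Plate, well: str) -> pd.Series:
    return plate.plate_data["well"] == well


def _step_initialize(plate: Plate) -> None:
    # Droplets are already UNDEFINED at construction; nothing to do.
    pass


def _step_remove_failures(plate: Plate) -> None:
    gp = plate.gate_params()
    for well in plate.used_wells():
        mask = _well_mask(plate, well)
        sub = plate.plate_data.loc[mask]
        ok, reason = qc_gates.detect_failed_well(
            sub["ch1"].to_numpy(), sub["ch2"].to_numpy(), plate.positive_channel, gp
        )
        plate.plate_meta.loc[well, "success"] = ok
        plate.plate_meta.loc[well, "failure_reason"] = reason
        if not ok:
            plate.plate_data.loc[mask, "label"] = ClusterLabel.FAILED.value


def _step_remove_outliers(plate: Plate) -> None:
    gp = plate.gate_params()
    for well in _analysis_wells(plate):
        mask = _well_mask(plate, well) & (
            plate.plate_data["label"] == ClusterLabel.UNDEFINED.value
        )
        sub = plate.plate_data.loc[mask]
        if sub.empty:
            continue
        out = qc_gates.flag_outliers(sub["ch1"].to_numpy(), sub["ch2"].to_numpy(), gp)
        plate.plate_data.loc[sub.index[out], "label"] = ClusterLabel.OUTLIER.value


def _step_remove_empty(plate: Plate) -> None:
    gp = plate.gate_params()
    for well in _analysis_wells(plate):
        mask = _well_mask(plate, well) & (
            plate.plate_data["label"] == ClusterLabel.UNDEFINED.value
        )
        sub = plate.plate_data.loc[mask]
        if sub.empty:
            continue
        empty, cutoffs = qc_gates.flag_empty(
            sub["ch1"].to_numpy(), sub["ch2"].to_numpy(), plate.positive_channel, gp
        )
        plate.plate_data.loc[sub.index[empty], "label"] = ClusterLabel.EMPTY.value
        for c, cut in cutoffs.items():
            plate.plate_meta.loc[well, f"empty_cutoff_ch{c}"] = cut


def _step_classify_pnpp(plate: Plate) -> None:
    pp = plate.pnpp_params()
    for well in _analysis_wells(plate):
        mask = _well_mask(plate, well) & (
            plate.plate_data["label"] == ClusterLabel.UNDEFINED.value
        )
        sub = plate.plate_data.loc[mask]
        if sub.empty:
            plate.set_well_gate(well, WellGate(gate_failed=True))
            continue
        labels, gate = pnpp_gating.gate_pnpp_well(
            sub["ch1"].to_numpy(), sub["ch2"].to_numpy(), plate.positive_channel, pp
        )
        if labels is not None:
            plate.plate_data.loc[sub.index, "label"] = labels
        plate.set_well_gate(well, gate)


def _step_reclassify_pnpp(plate: Plate) -> None:
    regated = pnpp_gating.reclassify_pnpp(plate, plate.pnpp_params())
    plate.plate_data = regated.plate_data
    plate.plate_meta = regated.plate_meta


STEP_FUNCTIONS = {
    STEP_INITIALIZE: _step_initialize,
    STEP_REMOVE_FAILURES: _step_remove_failures,
    STEP_REMOVE_OUTLIERS: _step_remove_outliers,
    STEP_REMOVE_EMPTY: _step_remove_empty,
    STEP_CLASSIFY_PNPP: _step_classify_pnpp,
    STEP_RECLASSIFY_PNPP: _step_reclassify_pnpp,
}


def _assert_partition(plate: Plate) -> None:
    labels = plate.plate_data["label"]
    assert labels.isin(plate.clusters).all(), "droplet with label outside vocabulary"


def _run_one(plate: Plate) -> None:
    idx = plate.status.cursor + 1
    step = plate.steps[idx]
    STEP_FUNCTIONS[step](plate)
    plate.status.cursor = idx
    _assert_partition(plate)


def _reset_from(plate: Plate, restart: int) -> None:
    labels_to_clear: set[str] = set()
    for step in plate.steps[restart:]:
        labels_to_clear.update(STEP_LABELS[step])
    if labels_to_clear:
        mask = plate.plate_data["label"].isin(labels_to_clear)
        plate.plate_data.loc[mask, "label"] = ClusterLabel.UNDEFINED.value
    if restart <= plate.steps.index(STEP_REMOVE_FAILURES):
        plate.plate_meta["success"] = True
        plate.plate_meta["failure_reason"] = None
    if STEP_CLASSIFY_PNPP in plate.steps and restart <= plate.steps.index(
        STEP_CLASSIFY_PNPP
    ):
        for c in _GATE_COLUMNS:
            plate.plate_meta[c] = (
                False if c in ("gate_confident", "gate_failed", "gate_borrowed") else math.nan
            )
    plate.status.cursor = min(plate.status.cursor, restart - 1)


def analyze(plate: Plate) -> Plate:
    """Run all remaining pipeline steps and populate the well summaries.

    Re-running a fully analyzed plate is the identity. On a dirty plate
    (parameters edited after a step had run) labels are rolled back and
    the pipeline restarts from the earliest affected step.
    """
    out = plate.copy()
    if out.dirty and out.status.restart_from is not None:
        _reset_from(out, out.status.restart_from)
    out.dirty = False
    out.status.restart_from = None
    while out.status.cursor < len(out.steps) - 1:
        _run_one(out)
    refresh_summaries(out)
    return out


def next_step(plate: Plate) -> Plate:
    """Advance the pipeline by exactly one step (no-op with a warning when
    already complete)."""
    out = plate.copy()
    if out.status.cursor >= len(out.steps) - 1:
        warnings.warn("pipeline already complete; next_step is a no-op", stacklevel=2)
        return out
    _run_one(out)
    refresh_summaries(out)
    return out


def set_params(plate: Plate, section: str, **updates) -> Plate:
    """Override parameters; marks the plate dirty if an affected step
    already ran, so the next analyze() recomputes from there."""
    if section not in plate.params:
        raise KeyError(f"unknown parameter section {section!r}")
    out = plate.copy()
    for k, v in updates.items():
        if k not in out.params[section]:
            raise KeyError(f"unknown parameter {section}.{k}")
        out.params[section][k] = v
    step = _SECTION_STEP.get(section, STEP_REMOVE_FAILURES)
    restart = len(out.steps) if step is None or step not in out.steps else out.steps.index(step)
    if out.status.cursor >= restart or step is None:
        out.dirty = True
        prev = out.status.restart_from
        out.status.restart_from = restart if prev is None else min(prev, restart)
    return out


# ---------------------------------------------------------------------------
# Summaries


def _safe_conc(n_pos: int, n_total: int, qp: QuantParams) -> float:
    if n_total <= 0:
        return math.nan
    try:
        return quantify.poisson_concentration(n_pos, n_total, qp)
    except SaturationError:
        return math.inf


def summarize_well(labels: pd.Series, well: str, plate: Plate) -> WellSummary:
    """Per-well cluster counts, concentrations and mutant frequency from
    the droplet labels (step 6 of the pipeline)."""
    qp = plate.quant_params()
    counts = labels.value_counts()

    def c(label: ClusterLabel) -> int:
        return int(counts.get(label.value, 0))

    row = plate.plate_meta.loc[well]
    s = WellSummary(
        well=well,
        success=bool(row["success"]) if not pd.isna(row["success"]) else True,
        failure_reason=None if pd.isna(row["failure_reason"]) else str(row["failure_reason"]),
        n_total=int(len(labels)),
        n_outlier=c(ClusterLabel.OUTLIER),
        n_empty=c(ClusterLabel.EMPTY),
        n_rain=c(ClusterLabel.RAIN),
        n_single_pos=c(ClusterLabel.SINGLE_POS),
        n_double_pos=c(ClusterLabel.DOUBLE_POS),
    )
    if not s.success:
        return s

    accepted = s.n_total - s.n_outlier
    gated = s.n_single_pos + s.n_double_pos > 0 or (
        plate.is_pnpp and plate.status.cursor >= plate.steps.index(STEP_CLASSIFY_PNPP)
    )
    if plate.is_pnpp and gated and accepted > 0:
        s.conc_single = _safe_conc(s.n_single_pos, accepted, qp)
        s.conc_double = _safe_conc(s.n_double_pos, accepted, qp)
        s.conc_total = _safe_conc(s.n_single_pos + s.n_double_pos, accepted, qp)
        try:
            s.mutant_freq = quantify.mutant_frequency(
                s.n_single_pos, s.n_double_pos, accepted, qp
            )
        except SaturationError:
            s.mutant_freq = math.nan
    elif not plate.is_pnpp and plate.status.cursor >= plate.steps.index(STEP_REMOVE_EMPTY):
        # Generic assay: every non-empty accepted droplet is template-positive.
        n_pos = accepted - s.n_empty
        s.conc_total = _safe_conc(n_pos, accepted, qp)

    pos = plate.positive_channel
    cut1 = row.get("empty_cutoff_ch1", math.nan)
    cut2 = row.get("empty_cutoff_ch2", math.nan)
    boundary = row.get("gate_boundary", math.nan)
    if pos == 1:
        s.gate_ch1, s.gate_ch2 = cut1, boundary
    elif pos == 2:
        s.gate_ch1, s.gate_ch2 = boundary, cut2
    else:
        s.gate_ch1, s.gate_ch2 = cut1, cut2
    return s


def refresh_summaries(plate: Plate) -> None:
    """Recompute all WellSummary columns of plate_meta from the labels."""
    for well in plate.used_wells():
        labels = plate.plate_data.loc[_well_mask(plate, well), "label"]
        s = summarize_well(labels, well, plate)
        for f in _SUMMARY_COLUMNS:
            plate.plate_meta.loc[well, f] = getattr(s, f)


def well_table(plate: Plate) -> pd.DataFrame:
    """One row per used well, row-major order, WellSummary columns."""
    wells = sorted(plate.used_wells(), key=WellId.parse)
    cols = list(WellSummary.FIELDS)
    out = plate.plate_meta.loc[wells].reset_index().rename(columns={"index": "well"})
    return out[cols]


# ---------------------------------------------------------------------------
# Equality (used by persistence round-trip guarantees)


def plates_equal(a: Plate, b: Plate) -> bool:
    """Exact equality on all nine state components (bit-exact labels and
    text, value-exact floats)."""
    if (a.name, a.version, a.dirty, tuple(a.steps), tuple(a.clusters)) != (
        b.name,
        b.version,
        b.dirty,
        tuple(b.steps),
        tuple(b.clusters),
    ):
        return False
    if (a.status.cursor, a.status.restart_from) != (b.status.cursor, b.status.restart_from):
        return False
    if a.params != b.params:
        return False
    try:
        pd.testing.assert_frame_equal(
            a.plate_data.reset_index(drop=True),
            b.plate_data.reset_index(drop=True),
            check_dtype=False,
            check_exact=True,
        )
        am = a.plate_meta.sort_index()
        bm = b.plate_meta.sort_index()
        if list(am.columns) != list(bm.columns):
            return False
        pd.testing.assert_frame_equal(am, bm, check_dtype=False, check_exact=True)
    except AssertionError:
        return False
    return True
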