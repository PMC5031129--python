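"""Reading QuantaSoft CSV exports and persisting plate state.

The instrument software exports one droplet amplitude CSV per well, named
``<prefix>_<WELL>_Amplitude.csv`` with columns "Ch1 Amplitude" and
"Ch2 Amplitude", plus an optional plate metadata CSV keyed by well (one
row per well and channel target). Plate state is saved as a single zip
archive holding a version manifest, the droplet table as CSV, and the
remaining state as JSON — open and diffable, and a lossless round trip.
"""

from __future__ import annotations

import json
import math
import re
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AmbiguityError,
    InputError,
    ParseError,
    SchemaError,
    VersionError,
)
from .wells import SelectionError, WellId

__all__ = [
    "AmplitudeFile",
    "PlateBundle",
    "read_amplitude_csv",
    "read_plate_metadata",
    "load_plate_bundle",
    "read_bundle_tables",
    "persist_plate",
    "restore_plate",
    "export_well_table",
]

_AMPLITUDE_RE = re.compile(
    r"^(?P<prefix>.+)_(?P<well>[A-Ha-h](?:0?[1-9]|1[0-2]))_Amplitude\.csv$",
    re.IGNORECASE,
)
_SUPPORTED_MAJOR = 1
_TRUTH_SUFFIX = "_truth.csv"  # simulator ground truth; never plate metadata


@dataclass(frozen=True)
class AmplitudeFile:
    """One well's parsed droplet amplitudes."""

    path: Path
    assay_prefix: str
    well: str
    rows: pd.DataFrame  # columns ch1, ch2


@dataclass(frozen=True)
class PlateBundle:
    """A directory of amplitude CSVs sharing one prefix, plus optional metadata."""

    directory: Path
    prefix: str
    amplitude_files: dict[str, Path]  # canonical well -> path
    metadata_path: Path | None


def _find_channel_columns(columns) -> tuple[str, str]:
    ch: dict[int, str] = {}
    for col in columns:
        low = str(col).lower()
        if "amplitude" in low:
            for c in (1, 2):
                if f"ch{c}" in low.replace(" ", ""):
                    ch[c] = col
    if 1 not in ch or 2 not in ch:
        raise SchemaError(
            f"amplitude CSV must contain 'Ch1 Amplitude' and 'Ch2 Amplitude' columns, got {list(columns)}"
        )
    return ch[1], ch[2]


def read_amplitude_csv(path) -> AmplitudeFile:
    """Parse one ``<prefix>_<WELL>_Amplitude.csv`` file.

    The well id comes from the filename; column names are matched
    case-insensitively and any extra columns (e.g. a pre-assigned cluster
    column) are ignored.

    Raises
    ------
    ParseError
        Malformed filename, or a non-numeric/non-finite amplitude cell
        (reported with its data row number).
    """
    path = Path(path)
    m = _AMPLITUDE_RE.match(path.name)
    if not m:
        raise ParseError(
            f"filename {path.name!r} does not match '<prefix>_<WELL>_Amplitude.csv'"
        )
    well = str(WellId.parse(m.group("well")))
    df = pd.read_csv(path)
    c1, c2 = _find_channel_columns(df.columns)
    out = pd.DataFrame(
        {
            "ch1": pd.to_numeric(df[c1], errors="coerce"),
            "ch2": pd.to_numeric(df[c2], errors="coerce"),
        }
    )
    bad = ~np.isfinite(out.to_numpy()).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1  # 1-based data row
        raise ParseError(f"non-numeric amplitude in {path.name}, data row {row}")
    return AmplitudeFile(
        path=path, assay_prefix=m.group("prefix"), well=well, rows=out
    )


def read_plate_metadata(path) -> pd.DataFrame:
    """Read a plate metadata/results CSV into per-well annotations.

    Returns a frame indexed by canonical well with columns ``sample``,
    ``target_ch1``, ``target_ch2`` plus any other columns preserved
    verbatim (first value per well). QuantaSoft emits one row per well and
    channel target; duplicate well rows are merged, their target names
    collected in row order.

    Raises
    ------
    SchemaError
        If no well identifier column is present.
    """
    df = pd.read_csv(Path(path))
    well_col = next((c for c in df.columns if str(c).strip().lower() == "well"), None)
    if well_col is None:
        raise SchemaError(f"metadata CSV has no 'Well' column: {list(df.columns)}")
    sample_col = next((c for c in df.columns if "sample" in str(c).lower()), None)
    target_col = next((c for c in df.columns if "target" in str(c).lower()), None)
    extra_cols = [c for c in df.columns if c not in (well_col, sample_col, target_col)]

    records = {}
    for _, row in df.iterrows():
        try:
            well = str(WellId.parse(str(row[well_col])))
        except SelectionError as exc:
            raise ParseError(f"bad well id in metadata: {row[well_col]!r}") from exc
        rec = records.setdefault(well, {"sample": None, "targets": []})
        if sample_col is not None and rec["sample"] is None and not pd.isna(row[sample_col]):
            rec["sample"] = str(row[sample_col])
        if target_col is not None and not pd.isna(row[target_col]):
            rec["targets"].append(str(row[target_col]))
        for c in extra_cols:
            rec.setdefault(c, row[c])

    out = pd.DataFrame(
        {
            "sample": [records[w]["sample"] for w in records],
            "target_ch1": [
                records[w]["targets"][0] if records[w]["targets"] else None for w in records
            ],
            "target_ch2": [
                records[w]["targets"][1] if len(records[w]["targets"]) > 1 else None
                for w in records
            ],
        },
        index=pd.Index(list(records), name="well"),
    )
    for c in extra_cols:
        out[c] = [records[w].get(c) for w in records]
    return out


def load_plate_bundle(directory) -> PlateBundle:
    """Discover a bundle's amplitude files and (optional) metadata CSV.

    All amplitude files must share one prefix; a metadata file is paired
    only when exactly one non-amplitude CSV candidate exists (simulator
    truth tables are excluded from candidacy).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    amplitude: dict[str, Path] = {}
    prefixes: set[str] = set()
    candidates: list[Path] = []
    for path in sorted(directory.glob("*.csv")):
        m = _AMPLITUDE_RE.match(path.name)
        if m:
            well = str(WellId.parse(m.group("well")))
            if well in amplitude:
                raise InputError(f"two amplitude files for well {well}")
            amplitude[well] = path
            prefixes.add(m.group("prefix"))
        elif not path.name.endswith(_TRUTH_SUFFIX):
            candidates.append(path)
    if not amplitude:
        raise InputError(f"no amplitude CSV files found in {directory}")
    if len(prefixes) > 1:
        raise AmbiguityError(
            f"mixed amplitude prefixes in {directory}: {sorted(prefixes)}"
        )
    return PlateBundle(
        directory=directory,
        prefix=prefixes.pop(),
        amplitude_files=amplitude,
        metadata_path=candidates[0] if len(candidates) == 1 else None,
    )


def read_bundle_tables(bundle: PlateBundle) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read all of a bundle's droplets into one table (well, ch1, ch2)."""
    frames = []
    for well in sorted(bundle.amplitude_files):
        amp = read_amplitude_csv(bundle.amplitude_files[well])
        frame = amp.rows.copy()
        frame.insert(0, "well", amp.well)
        frames.append(frame)
    droplets = pd.concat(frames, ignore_index=True)
    meta = (
        read_plate_metadata(bundle.metadata_path)
        if bundle.metadata_path is not None
        else None
    )
    return droplets, meta


# ---------------------------------------------------------------------------
# Plate-state persistence


def _json_cell(v):
    if v is None:
        return None
    if isinstance(v, (np.floating, float)):
        f = float(v)
        return {"__nan__": True} if math.isnan(f) else f
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, (np.bool_, bool)):
        return bool(v)
    if isinstance(v, (str, int)):
        return v
    if pd.isna(v):
        return None
    return str(v)


def _from_json_cell(v):
    if isinstance(v, dict) and v.get("__nan__"):
        return math.nan
    return v


def persist_plate(plate, path) -> Path:
    """Save the full plate state to a zip archive (version manifest, the
    droplet table as CSV, everything else as JSON)."""
    path = Path(path)
    meta = plate.plate_meta
    meta_doc = {
        "wells": list(meta.index),
        "columns": list(meta.columns),
        "rows": [[_json_cell(v) for v in meta.loc[w]] for w in meta.index],
    }
    state = {
        "name": plate.name,
        "params": plate.params,
        "status": {
            "cursor": plate.status.cursor,
            "restart_from": plate.status.restart_from,
        },
        "clusters": list(plate.clusters),
        "steps": list(plate.steps),
        "dirty": bool(plate.dirty),
        "version": plate.version,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(
            "manifest.json",
            json.dumps({"format": "dropgate-plate", "version": plate.version}),
        )
        zf.writestr("plate_data.csv", plate.plate_data.to_csv(index=False))
        zf.writestr("plate_meta.json", json.dumps(meta_doc))
        zf.writestr("state.json", json.dumps(state))
    return path


def restore_plate(path):
    """Load a plate archive saved by :func:`persist_plate`.

    Raises
    ------
    VersionError
        If the archive's format version is newer than this package
        supports.
    """
    from .plate_model import PipelineStatus, Plate  # deferred import cycle

    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        try:
            major = int(str(manifest.get("version", "0")).split(".")[0])
        except ValueError as exc:
            raise VersionError(f"unparsable archive version {manifest.get('version')!r}") from exc
        if manifest.get("format") != "dropgate-plate":
            raise InputError(f"{path} is not a plate archive")
        if major > _SUPPORTED_MAJOR:
            raise VersionError(
                f"archive version {manifest['version']} is newer than supported ({_SUPPORTED_MAJOR}.x)"
            )
        with zf.open("plate_data.csv") as fh:
            data = pd.read_csv(
                fh, dtype={"well": str, "ch1": float, "ch2": float, "label": str}
            )
        meta_doc = json.loads(zf.read("plate_meta.json"))
        state = json.loads(zf.read("state.json"))

    meta = pd.DataFrame(
        [[_from_json_cell(v) for v in row] for row in meta_doc["rows"]],
        index=pd.Index(meta_doc["wells"], name="well"),
        columns=meta_doc["columns"],
    )
    meta = meta.infer_objects()
    return Plate(
        plate_data=data,
        plate_meta=meta,
        name=state["name"],
        params=state["params"],
        status=PipelineStatus(
            cursor=state["status"]["cursor"],
            restart_from=state["status"]["restart_from"],
        ),
        clusters=tuple(state["clusters"]),
        steps=tuple(state["steps"]),
        dirty=bool(state["dirty"]),
        version=state["version"],
    )


def export_well_table(plate, path) -> Path:
    """Write the per-well summary table as CSV (full float precision, so
    re-exporting an unchanged plate is byte-identical)."""
    from .plate_model import well_table

    path = Path(path)
    well_table(plate).to_csv(path, index=False)
    return path
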