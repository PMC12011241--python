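"""Reading and writing marker trajectories and long-format parameter tables.

Marker data travel as :class:`MarkerTrajectorySet`: a named collection of
(n_frames, 3) position tracks in millimetres with per-frame validity flags,
a sampling rate in Hz, and an explicit axis convention mapping the three
coordinates onto mediolateral (ML), anteroposterior (AP) and vertical (VT).
Supported on-disk dialects are TRC (tab-delimited, standard header) and wide
CSV with a configurable column schema.

Statistics-only runs ingest a long-format parameter table with one row per
(participant, step-width level, speed level, body segment, parameter).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MocapFormatError, ValidationError

#: Markers every full pipeline run must provide.
REQUIRED_MARKERS = ("head", "T4", "PSIS_L", "PSIS_R", "heel_L", "heel_R")

#: Segments analysed for mediolateral displacement.
SEGMENTS = ("head", "T4", "pelvis")

#: Fixed factor vocabularies (step width, gait speed).
SW_LEVELS = ("NB", "WB")
SP_LEVELS = ("Normal", "Slow")

_MM_PER_UNIT = {"mm": 1.0, "m": 1000.0, "cm": 10.0}


@dataclass(frozen=True)
class AxisMap:
    """Which coordinate index is mediolateral / anteroposterior / vertical.

    Defaults to X=ML, Y=AP, Z=VT; must be a bijection onto {0, 1, 2}.
    """

    ml: int = 0
    ap: int = 1
    vt: int = 2

    def __post_init__(self) -> None:
        if sorted((self.ml, self.ap, self.vt)) != [0, 1, 2]:
            raise ValidationError(
                f"axis_map must be a bijection onto axes 0..2, got "
                f"ml={self.ml}, ap={self.ap}, vt={self.vt}"
            )


@dataclass
class MarkerTrajectorySet:
    """Time-aligned named 3D marker tracks.

    Parameters
    ----------
    sampling_rate : float
        Frames per second, > 0.
    markers : dict
        Marker name -> float array of shape (n_frames, 3), millimetres.
        Invalid samples hold NaN.
    valid : dict
        Marker name -> boolean array of shape (n_frames,). Filled in from
        NaN patterns when omitted.
    axis_map : AxisMap
        Coordinate convention.
    meta : dict
        Participant id, condition labels, free-text notes.
    """

    sampling_rate: float
    markers: dict[str, np.ndarray]
    valid: dict[str, np.ndarray] = field(default_factory=dict)
    axis_map: AxisMap = field(default_factory=AxisMap)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        lengths = {name: len(arr) for name, arr in self.markers.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(f"marker tracks differ in length: {lengths}")
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"marker {name!r} must be (n, 3), got {arr.shape}")
            self.markers[name] = arr
            if name not in self.valid:
                self.valid[name] = ~np.isnan(arr).any(axis=1)

    @property
    def duration_frames(self) -> int:
        if not self.markers:
            return 0
        return len(next(iter(self.markers.values())))

    def require_markers(self, names: Sequence[str] = REQUIRED_MARKERS) -> None:
        missing = [m for m in names if m not in self.markers]
        if missing:
            raise ValidationError(f"required markers missing: {missing}")

    def component(self, marker: str, axis: str) -> np.ndarray:
        """1D series of one marker along 'ml', 'ap' or 'vt'."""
        idx = getattr(self.axis_map, axis)
        return self.markers[marker][:, idx]

    def pelvis_ml(self, definition: str = "midpoint") -> np.ndarray:
        """Pelvis mediolateral series: PSIS midpoint (default) or one PSIS."""
        if definition == "midpoint":
            return 0.5 * (self.component("PSIS_L", "ml") + self.component("PSIS_R", "ml"))
        if definition in ("PSIS_L", "PSIS_R"):
            return self.component(definition, "ml")
        raise ValidationError(f"unknown pelvis definition {definition!r}")

    def segment_ml(self, segment: str, pelvis_definition: str = "midpoint") -> np.ndarray:
        if segment == "pelvis":
            return self.pelvis_ml(pelvis_definition)
        return self.component(segment, "ml")


# ---------------------------------------------------------------------------
# TRC dialect
# ---------------------------------------------------------------------------

def write_trc(mts: MarkerTrajectorySet, path: str | Path, units: str = "mm") -> None:
    """Write a standard TRC file (tab-delimited, two-line marker header)."""
    path = Path(path)
    factor = _MM_PER_UNIT.get(units)
    if factor is None:
        raise ValidationError(f"unsupported TRC units {units!r}")
    names = list(mts.markers)
    n = mts.duration_frames
    fs = mts.sampling_rate
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{fs:g}\t{fs:g}\t{n}\t{len(names)}\t{units}\t{fs:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names))),
        "",
    ]
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for f in range(n):
            cells = [str(f + 1), repr(float(f / fs))]
            for name in names:
                row = mts.markers[name][f]
                if mts.valid[name][f]:
                    cells.extend(repr(float(v) / factor) for v in row)
                else:
                    cells.extend(["", "", ""])
            fh.write("\t".join(cells) + "\n")


def read_trc(path: str | Path, units_override: str | None = None) -> MarkerTrajectorySet:
    """Read a TRC file into a :class:`MarkerTrajectorySet` (positions in mm).

    Missing samples (empty cells) are flagged invalid, never zero-filled.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 5:
        raise MocapFormatError(f"{path}: too short to be a TRC file")
    header_idx = None
    for i, line in enumerate(lines[:6]):
        if line.startswith("DataRate"):
            header_idx = i
            break
    if header_idx is None:
        raise MocapFormatError(f"{path}: no 'DataRate' header line found (line 2 expected)")
    keys = lines[header_idx].rstrip("\n").split("\t")
    vals = lines[header_idx + 1].rstrip("\n").split("\t")
    header = dict(zip(keys, vals))
    try:
        fs = float(header["DataRate"])
    except (KeyError, ValueError) as exc:
        raise MocapFormatError(
            f"{path}: malformed DataRate on line {header_idx + 2}: {lines[header_idx + 1]!r}"
        ) from exc
    units = header.get("Units", "").strip() or units_override
    if not units:
        raise MocapFormatError(
            f"{path}: Units field absent; pass units_override='mm'|'m' explicitly"
        )
    factor = _MM_PER_UNIT.get(units)
    if factor is None:
        raise MocapFormatError(f"{path}: unsupported units {units!r}")

    name_line = lines[header_idx + 2].rstrip("\n").split("\t")
    names = [c for c in name_line[2:] if c.strip()]
    if not names:
        raise MocapFormatError(f"{path}: no marker names on line {header_idx + 3}")

    data_rows: list[list[str]] = []
    for line in lines[header_idx + 3 :]:
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        try:
            int(cells[0])
        except ValueError:
            continue  # the X1/Y1/Z1 axis-label row
        data_rows.append(cells)
    n = len(data_rows)
    ncols = max(len(r) for r in data_rows) - 2 if data_rows else 0
    if data_rows and (ncols % 3 != 0 or ncols < 3 * len(names)):
        raise MocapFormatError(
            f"{path}: marker column count {ncols} not 3 x {len(names)} markers"
        )
    markers = {name: np.full((n, 3), np.nan) for name in names}
    for f, row in enumerate(data_rows):
        for j, name in enumerate(names):
            cells = row[2 + 3 * j : 5 + 3 * j]
            if len(cells) == 3 and all(c.strip() for c in cells):
                try:
                    markers[name][f] = [float(c) * factor for c in cells]
                except ValueError as exc:
                    raise MocapFormatError(
                        f"{path}: non-numeric sample in data row {f + 1}"
                    ) from exc
    return MarkerTrajectorySet(sampling_rate=fs, markers=markers,
                               meta={"source": str(path), "units": units})


# ---------------------------------------------------------------------------
# Wide-CSV dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerCsvSchema:
    """Column mapping for wide marker CSV: one row per frame.

    ``pattern`` names columns per marker/axis, e.g. ``"{marker}_{axis}"``
    yields head_x, head_y, head_z. ``sampling_rate`` is mandatory because
    wide CSV carries no rate metadata. ``unit`` declares the file's length
    unit (converted to mm on read).
    """

    sampling_rate: float | None = None
    pattern: str = "{marker}_{axis}"
    markers: tuple[str, ...] = REQUIRED_MARKERS
    unit: str = "mm"


def write_marker_csv(mts: MarkerTrajectorySet, path: str | Path,
                     schema: MarkerCsvSchema | None = None) -> None:
    schema = schema or MarkerCsvSchema(sampling_rate=mts.sampling_rate,
                                       markers=tuple(mts.markers))
    factor = _MM_PER_UNIT[schema.unit]
    cols = {}
    for name in schema.markers:
        for k, axis in enumerate("xyz"):
            col = schema.pattern.format(marker=name, axis=axis)
            vals = mts.markers[name][:, k] / factor
            cols[col] = np.where(mts.valid[name], vals, np.nan)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_marker_csv(path: str | Path, schema: MarkerCsvSchema) -> MarkerTrajectorySet:
    """Read a wide marker CSV per the supplied schema (positions -> mm)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise MocapFormatError(f"{path}: empty file") from exc
    if df.empty:
        raise MocapFormatError(f"{path}: no data rows")
    if schema.sampling_rate is None:
        raise MocapFormatError(
            f"{path}: schema must supply sampling_rate (wide CSV has no rate metadata)"
        )
    factor = _MM_PER_UNIT.get(schema.unit)
    if factor is None:
        raise MocapFormatError(f"{path}: unsupported unit {schema.unit!r}")
    markers = {}
    missing: list[str] = []
    for name in schema.markers:
        cols = [schema.pattern.format(marker=name, axis=a) for a in "xyz"]
        absent = [c for c in cols if c not in df.columns]
        if absent:
            missing.extend(absent)
            continue
        markers[name] = df[cols].to_numpy(dtype=float) * factor
    if missing:
        raise MocapFormatError(f"{path}: missing mapped columns: {missing}")
    return MarkerTrajectorySet(sampling_rate=schema.sampling_rate, markers=markers,
                               meta={"source": str(path), "units": schema.unit})


# ---------------------------------------------------------------------------
# Long-format parameter tables
# ---------------------------------------------------------------------------

_COLUMN_SYNONYMS = {
    "participant": {"participant", "subject", "id", "participant_id", "subj"},
    "sw": {"sw", "step_width_level", "base", "stepwidth", "width_level"},
    "sp": {"sp", "speed", "gait_speed", "speed_level"},
    "segment": {"segment", "bs", "body_segment", "region"},
    "parameter": {"parameter", "param", "measure", "variable"},
    "value": {"value", "val", "y"},
}

_LEVEL_SYNONYMS = {
    "sw": {"nb": "NB", "narrow": "NB", "wb": "WB", "wide": "WB"},
    "sp": {"normal": "Normal", "4.5": "Normal", "fast": "Normal",
           "slow": "Slow", "2.2": "Slow"},
    "segment": {"head": "head", "t4": "T4", "thorax": "T4", "pelvis": "pelvis",
                "-": "-", "": "-"},
}


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for canon, syns in _COLUMN_SYNONYMS.items():
        for syn in syns:
            if syn in lower:
                rename[lower[syn]] = canon
                break
    df = df.rename(columns=rename)
    missing = [c for c in ("participant", "sw", "sp", "parameter", "value")
               if c not in df.columns]
    if missing:
        raise ValidationError(f"parameter table lacks columns {missing}; "
                              f"found {list(df.columns)}")
    if "segment" not in df.columns:
        df["segment"] = "-"
    return df


def _normalize_levels(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("sw", "sp", "segment"):
        syns = _LEVEL_SYNONYMS[col]
        def fix(v, syns=syns, col=col):
            key = str(v).strip().lower()
            if key in syns:
                return syns[key]
            raise ValidationError(f"unrecognised {col} level {v!r}")
        df[col] = df[col].fillna("-").map(fix) if col == "segment" else df[col].map(fix)
    df["value"] = pd.to_numeric(df["value"])
    return df


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format parameter table (CSV/TSV/XLSX) into canonical form.

    Output columns: participant, sw, sp, segment, parameter, value.
    Raises on duplicate keys. Whole-body parameters carry segment '-'.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    df = _normalize_levels(_normalize_columns(df))
    key = ["participant", "sw", "sp", "segment", "parameter"]
    dup = df.duplicated(subset=key)
    if dup.any():
        rows = df.loc[dup, key].head(5).to_dict("records")
        raise ValidationError(f"duplicate parameter-table keys, e.g. {rows}")
    return df[key + ["value"]].reset_index(drop=True)


def check_complete_design(table: pd.DataFrame, parameters: Sequence[str] | None = None) -> None:
    """Every participant must hold every SW x SP cell for every parameter.

    Required for a fully within-subject ANOVA; names the first offending
    participant/condition on failure.
    """
    params = parameters or sorted(table["parameter"].unique())
    participants = sorted(table["participant"].unique())
    for param in params:
        sub = table[table["parameter"] == param]
        segs = sorted(sub["segment"].unique())
        for p in participants:
            mine = sub[sub["participant"] == p]
            for sw in SW_LEVELS:
                for sp in SP_LEVELS:
                    for seg in segs:
                        cell = mine[(mine.sw == sw) & (mine.sp == sp)
                                    & (mine.segment == seg)]
                        if cell.empty:
                            raise ValidationError(
                                f"participant {p!r} is missing cell "
                                f"(sw={sw}, sp={sp}, segment={seg}) for "
                                f"parameter {param!r}"
                            )


def write_parameter_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def write_reports(report, out_dir: str | Path, cycle_table: pd.DataFrame | None = None,
                  ensembles: pd.DataFrame | None = None, prefix: str = "") -> list[Path]:
    """Write one analysis report as a CSV file set plus a JSON summary.

    ``report`` is an :class:`gaitlat.rm_stats.AnovaReport`. Emits
    anova.csv, simple_interactions.csv, simple_simple.csv, pairwise.csv
    (header-only when a tier is empty), optional cycles.csv and
    ensembles.csv, and summary.json with the decision trace.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(df: pd.DataFrame, name: str) -> None:
        p = out_dir / f"{prefix}{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)

    emit(report.omnibus, "anova")
    emit(report.simple_interactions, "simple_interactions")
    emit(report.simple_simple, "simple_simple")
    emit(report.pairwise, "pairwise")
    if cycle_table is not None:
        emit(cycle_table, "cycles")
    if ensembles is not None:
        emit(ensembles, "ensembles")
    summary = {
        "response": report.response,
        "design": report.design,
        "alpha": report.alpha,
        "trace": report.trace,
        "n_participants": report.n_participants,
    }
    p = out_dir / f"{prefix}summary.json"
    p.write_text(json.dumps(summary, indent=2))
    written.append(p)
    return written


def dataclass_to_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(obj), indent=2, default=str))
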