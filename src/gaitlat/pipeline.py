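"""End-to-end orchestration: trials -> parameters -> statistics -> reports.

Three input modes share one statistics backend:

* ``trials``  — marker files listed in a manifest are filtered, segmented
  and reduced to condition summaries before the ANOVA ladder runs;
* ``parameter_table`` — a long-format table (e.g. an exported workbook of
  per-participant representative values) drives the statistics directly;
* ``synthetic`` — a generated cohort is pushed through the full trial
  path, so every stage is exercised without external data.

Whole-body parameters (stride time, step width) get the two-way
step-width x speed ANOVA with simple main effects; segment parameters
(mean DIS, mean %DIS, CV-%DIS) get the three-way ladder with body segment
as the third factor.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mocap_io, rm_stats
from .errors import GaitlatError, ValidationError
from .gait_events import (EventParams, GaitEventTable, StartPolicy,
                          detect_heel_contacts, segment_cycles, time_normalize)
from .gait_parameters import (compute_cycle_parameters, summaries_to_long_table,
                              summarize_condition)
from .mocap_io import SEGMENTS, SP_LEVELS, SW_LEVELS, MarkerTrajectorySet
from .preprocessing import FilterSpec, butterworth_lowpass, interpolate_gaps
from .rm_stats import (AnovaReport, WithinAnova, decompose_interactions,
                       decompose_two_way)
from .synthetic_gait import SyntheticConfig, generate_cohort

log = logging.getLogger("gaitlat")

#: Parameters analysed with the two-way (whole body) vs three-way design.
TWO_WAY_PARAMS = ("stride_time", "step_width")
THREE_WAY_PARAMS = ("dis", "pct_dis", "cv_pct_dis")


@dataclass
class RunConfig:
    mode: str = "synthetic"              # trials | parameter_table | synthetic
    manifest: str | None = None          # trials mode: CSV with path,participant,sw,sp
    table: str | None = None             # parameter_table mode
    out_dir: str = "gaitlat_out"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    event_params: EventParams = field(default_factory=EventParams)
    start_policy: StartPolicy = field(default_factory=StartPolicy)
    n_cycles: int = 7
    max_gap: int = 10
    alpha: float = 0.05
    followup_alpha: float = 0.10
    d_variant: str = "av"
    cycle_width: str = "mean"
    pelvis_definition: str = "midpoint"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("trials", "parameter_table", "synthetic"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.n_cycles < 2:
            raise ValidationError("n_cycles must be >= 2")


@dataclass
class PipelineResult:
    reports: dict[str, AnovaReport]
    parameter_table: pd.DataFrame
    cycle_table: pd.DataFrame | None
    ensembles: pd.DataFrame | None
    qc: pd.DataFrame | None
    manifest: dict


# ---------------------------------------------------------------------------
# single-trial processing
# ---------------------------------------------------------------------------

def process_trial(mts: MarkerTrajectorySet, config: RunConfig):
    """Filter, detect events, segment and parameterise one trial.

    Returns (cycle_table, condition_summary, events, filtered_trial).
    """
    mts.require_markers()
    clean = interpolate_gaps(mts, max_gap=config.max_gap)
    filt = butterworth_lowpass(clean, config.filter_spec)
    params = config.event_params
    sp = mts.meta.get("sp")
    if params.min_separation_s is None and sp in ("Normal", "Slow"):
        params = EventParams(prominence_mm=params.prominence_mm, speed_level=sp)
    left = detect_heel_contacts(filt.component("heel_L", "vt"),
                                filt.sampling_rate, params)
    right = detect_heel_contacts(filt.component("heel_R", "vt"),
                                 filt.sampling_rate, params)
    events = GaitEventTable(left_contacts=left, right_contacts=right, params=params)
    cycles = segment_cycles(events, filt.sampling_rate, n_cycles=config.n_cycles,
                            start_policy=config.start_policy)
    cycle_table = compute_cycle_parameters(
        filt, cycles, cycle_width=config.cycle_width,
        pelvis_definition=config.pelvis_definition)
    summary = summarize_condition(
        cycle_table, participant=mts.meta.get("participant", "?"),
        sw=mts.meta.get("sw", "?"), sp=mts.meta.get("sp", "?"),
        n_cycles=config.n_cycles)
    return cycle_table, summary, events, cycles, filt


def ensemble_curves(filt: MarkerTrajectorySet, cycles, pelvis_definition="midpoint",
                    n_points: int = 101) -> pd.DataFrame:
    """Mean +- SD mediolateral curves per segment over 0-100% gait cycle."""
    rows = []
    for seg in SEGMENTS:
        series = filt.segment_ml(seg, pelvis_definition)
        curves = np.array([time_normalize(series, c, n_points)
                           for c in cycles.cycles])
        for i, phase in enumerate(np.linspace(0, 100, n_points)):
            rows.append({"participant": filt.meta.get("participant", "?"),
                         "sw": filt.meta.get("sw", "?"),
                         "sp": filt.meta.get("sp", "?"),
                         "segment": seg, "phase_pct": phase,
                         "mean": curves[:, i].mean(),
                         "sd": curves[:, i].std(ddof=1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics backend
# ---------------------------------------------------------------------------

def analyze_table(table: pd.DataFrame, alpha: float = 0.05,
                  followup_alpha: float = 0.10,
                  d_variant: str = "av") -> dict[str, AnovaReport]:
    """Run the appropriate ANOVA ladder for every parameter in the table."""
    mocap_io.check_complete_design(table)
    reports: dict[str, AnovaReport] = {}
    for param in sorted(table["parameter"].unique()):
        sub = table[table["parameter"] == param]
        segs = [s for s in sub["segment"].unique() if s != "-"]
        if segs:
            wa = WithinAnova.from_table(
                sub, within=["sw", "sp", "segment"],
                levels={"sw": SW_LEVELS, "sp": SP_LEVELS, "segment": SEGMENTS},
                response=param)
            reports[param] = decompose_interactions(
                wa, alpha=alpha, followup_alpha=followup_alpha,
                d_variant=d_variant)
        else:
            wa = WithinAnova.from_table(
                sub, within=["sw", "sp"],
                levels={"sw": SW_LEVELS, "sp": SP_LEVELS}, response=param)
            reports[param] = decompose_two_way(wa, alpha=alpha)
    return reports


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_report(trials: list[tuple[str, str, str, MarkerTrajectorySet]],
              config: RunConfig) -> pd.DataFrame:
    """Per-trial QC: events per side, gaps, cycles extracted, rejects."""
    rows = []
    for pid, sw, sp, mts in trials:
        row = {"participant": pid, "sw": sw, "sp": sp,
               "n_frames": mts.duration_frames,
               "status": "ok", "reason": ""}
        gaps = []
        for name, ok in mts.valid.items():
            if not ok.all():
                from .preprocessing import _invalid_runs
                gaps.extend(b - a for a, b in _invalid_runs(ok))
        row["max_gap"] = max(gaps) if gaps else 0
        try:
            cycle_table, _, events, cycles, _ = process_trial(mts, config)
            row["n_left"] = len(events.left_contacts)
            row["n_right"] = len(events.right_contacts)
            row["cycles_extracted"] = cycles.count
        except GaitlatError as exc:
            row.update(status="rejected", reason=f"{type(exc).__name__}: {exc}",
                       n_left=np.nan, n_right=np.nan, cycles_extracted=0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def _config_hash(config: RunConfig) -> str:
    text = repr(config).encode()
    return hashlib.sha256(text).hexdigest()[:16]


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute a full run per the config; deterministic given inputs + seed."""
    log.info("run start: mode=%s out=%s", config.mode, config.out_dir)
    cycle_tables = []
    ensembles = []
    qc = None
    if config.mode == "parameter_table":
        table = mocap_io.read_parameter_table(config.table)
        trials = None
    else:
        if config.mode == "synthetic":
            from dataclasses import replace as _rep
            syn = _rep(config.synthetic, master_seed=config.seed,
                       n_cycles=config.n_cycles)
            cohort = generate_cohort(syn)
            trials = cohort.trials
        else:
            trials = _load_trials(config)
        summaries = []
        for pid, sw, sp, mts in trials:
            log.info("trial %s %s/%s: %d frames", pid, sw, sp, mts.duration_frames)
            cycle_table, summary, events, cycles, filt = process_trial(mts, config)
            cycle_table = cycle_table.assign(participant=pid, sw=sw, sp=sp)
            cycle_tables.append(cycle_table)
            summaries.append(summary)
            ensembles.append(ensemble_curves(filt, cycles,
                                             config.pelvis_definition))
        table = summaries_to_long_table(summaries)
        qc = qc_report(trials, config)
    reports = analyze_table(table, alpha=config.alpha,
                            followup_alpha=config.followup_alpha,
                            d_variant=config.d_variant)
    cycle_df = pd.concat(cycle_tables, ignore_index=True) if cycle_tables else None
    ens_df = pd.concat(ensembles, ignore_index=True) if ensembles else None
    manifest = {"mode": config.mode, "seed": config.seed,
                "config_hash": _config_hash(config),
                "n_parameters": len(reports),
                "alpha": config.alpha}
    result = PipelineResult(reports=reports, parameter_table=table,
                            cycle_table=cycle_df, ensembles=ens_df, qc=qc,
                            manifest=manifest)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "parameters.csv", index=False)
        if cycle_df is not None:
            cycle_df.to_csv(out / "cycles.csv", index=False)
        if ens_df is not None:
            grp = ens_df.groupby(["sw", "sp", "segment", "phase_pct"])["mean"] \
                .agg(["mean", "std"]).reset_index()
            grp.to_csv(out / "ensembles.csv", index=False)
        if qc is not None:
            qc.to_csv(out / "qc.csv", index=False)
        for param, report in reports.items():
            mocap_io.write_reports(report, out, prefix=f"{param}_")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %d parameters analysed", len(reports))
    return result


def _load_trials(config: RunConfig):
    manifest = pd.read_csv(config.manifest)
    needed = {"path", "participant", "sw", "sp"}
    if not needed <= set(manifest.columns):
        raise ValidationError(
            f"trial manifest must have columns {sorted(needed)}")
    trials = []
    base = Path(config.manifest).parent
    for _, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        if path.suffix.lower() == ".trc":
            mts = mocap_io.read_trc(path)
        else:
            schema = mocap_io.MarkerCsvSchema(sampling_rate=120.0)
            mts = mocap_io.read_marker_csv(path, schema)
        mts.meta.update(participant=row["participant"], sw=row["sw"], sp=row["sp"])
        trials.append((row["participant"], row["sw"], row["sp"], mts))
    return trials


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
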