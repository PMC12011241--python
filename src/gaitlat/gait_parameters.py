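"""Per-cycle and per-condition gait parameters.

General parameters: stride time (left contact to next left contact, s),
step length (AP heel separation at each contact, mm) and step width (ML
heel separation at each contact, mm).

Segment-control parameters: DIS is the mediolateral amplitude (max - min)
of a segment's ML trajectory within one cycle; %DIS divides DIS by the
cycle's step width (stored as a mm/mm ratio, rendered x100); CV-%DIS is
the coefficient of variation of %DIS across the extracted cycles (sample
SD over mean, x100) — the repeatability index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .gait_events import GaitCycle, GaitCycleSet
from .mocap_io import SEGMENTS, MarkerTrajectorySet


def stride_time(cycle: GaitCycle, fs: float) -> float:
    """Cycle duration in seconds: (end - start) / fs."""
    if fs <= 0:
        raise ParameterError(f"fs must be > 0, got {fs}")
    return (cycle.end - cycle.start) / fs


def step_metrics(cycle: GaitCycle, heel_l_ml: np.ndarray, heel_r_ml: np.ndarray,
                 heel_l_ap: np.ndarray, heel_r_ap: np.ndarray,
                 cycle_width: str = "mean") -> dict[str, float]:
    """Step lengths/widths for the two steps of one cycle.

    The L->R step is evaluated at the right contact (right heel leads);
    the R->L step at the closing left contact. Width is the absolute ML
    separation of the two heels at the lead-contact frame, length the
    absolute AP separation. ``step_width_cycle`` (the %DIS denominator)
    aggregates the two widths per ``cycle_width``: mean (default), first
    or min.
    """
    n = len(heel_l_ml)
    for f in (cycle.start, cycle.right_contact, cycle.end):
        if not 0 <= f < n:
            raise ParameterError(f"contact frame {f} outside trial of {n} frames")
    w_lr = abs(heel_r_ml[cycle.right_contact] - heel_l_ml[cycle.right_contact])
    w_rl = abs(heel_l_ml[cycle.end] - heel_r_ml[cycle.end])
    l_lr = abs(heel_r_ap[cycle.right_contact] - heel_l_ap[cycle.right_contact])
    l_rl = abs(heel_l_ap[cycle.end] - heel_r_ap[cycle.end])
    if cycle_width == "mean":
        w_cycle = 0.5 * (w_lr + w_rl)
    elif cycle_width == "first":
        w_cycle = w_lr
    elif cycle_width == "min":
        w_cycle = min(w_lr, w_rl)
    else:
        raise ParameterError(f"cycle_width must be mean|first|min, got {cycle_width!r}")
    return {"step_width_lr": float(w_lr), "step_width_rl": float(w_rl),
            "step_length_lr": float(l_lr), "step_length_rl": float(l_rl),
            "step_width_cycle": float(w_cycle)}


def dis(segment_ml: np.ndarray, cycle: GaitCycle) -> float:
    """Mediolateral amplitude (max - min) over the half-open cycle slice.

    The slice [start, end) avoids double-counting the contact frame shared
    by contiguous cycles.
    """
    seg = np.asarray(segment_ml, dtype=float)[cycle.start: cycle.end]
    if seg.size == 0:
        raise ParameterError(f"empty cycle slice [{cycle.start}, {cycle.end})")
    return float(seg.max() - seg.min())


def pct_dis(dis_mm: float, step_width_cycle_mm: float) -> float:
    """DIS / step width per cycle: a dimensionless mm/mm ratio (may exceed 1)."""
    if step_width_cycle_mm <= 0:
        raise ParameterError(
            f"step_width_cycle must be > 0, got {step_width_cycle_mm}")
    return dis_mm / step_width_cycle_mm


def cv_pct_dis(values, ddof: int = 1) -> float:
    """Coefficient of variation of per-cycle %DIS, in percent.

    Sample SD (n-1) over the mean, x100. ``ddof=0`` selects the population
    SD instead.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError(f"CV needs >= 2 cycles, got {v.size}")
    m = v.mean()
    if m == 0:
        raise ParameterError("CV undefined: mean of %DIS is zero")
    return float(v.std(ddof=ddof) / m * 100.0)


def compute_cycle_parameters(mts: MarkerTrajectorySet, cycles: GaitCycleSet,
                             cycle_width: str = "mean",
                             pelvis_definition: str = "midpoint") -> pd.DataFrame:
    """Per-cycle parameter table for one (filtered) trial.

    One row per cycle: stride time, the two step lengths/widths, the cycle
    width, and DIS / %DIS for head, T4 and pelvis.
    """
    fs = mts.sampling_rate
    heel_l_ml = mts.component("heel_L", "ml")
    heel_r_ml = mts.component("heel_R", "ml")
    heel_l_ap = mts.component("heel_L", "ap")
    heel_r_ap = mts.component("heel_R", "ap")
    seg_ml = {s: mts.segment_ml(s, pelvis_definition) for s in SEGMENTS}
    rows = []
    for i, cyc in enumerate(cycles.cycles):
        row: dict[str, float] = {"cycle": i}
        row["stride_time"] = stride_time(cyc, fs)
        row.update(step_metrics(cyc, heel_l_ml, heel_r_ml, heel_l_ap, heel_r_ap,
                                cycle_width=cycle_width))
        for s in SEGMENTS:
            d = dis(seg_ml[s], cyc)
            row[f"dis_{s}"] = d
            row[f"pct_dis_{s}"] = pct_dis(d, row["step_width_cycle"])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ConditionSummary:
    """Representative values for one participant x condition."""

    participant: str
    sw: str
    sp: str
    stride_time: float
    step_length: float
    step_width: float
    dis: dict[str, float]
    pct_dis: dict[str, float]
    cv_pct_dis: dict[str, float]
    n_cycles: int


def summarize_condition(cycle_table: pd.DataFrame, participant: str, sw: str, sp: str,
                        n_cycles: int = 7, ddof: int = 1) -> ConditionSummary:
    """Arithmetic means over exactly ``n_cycles`` cycles plus CV-%DIS.

    Step length/width representative values average the two steps of every
    cycle.
    """
    if len(cycle_table) != n_cycles:
        raise ValidationError(
            f"expected {n_cycles} cycles, got {len(cycle_table)}")
    t = cycle_table
    mean_len = float(np.mean(np.r_[t.step_length_lr, t.step_length_rl]))
    mean_wid = float(np.mean(np.r_[t.step_width_lr, t.step_width_rl]))
    return ConditionSummary(
        participant=participant, sw=sw, sp=sp,
        stride_time=float(t.stride_time.mean()),
        step_length=mean_len,
        step_width=mean_wid,
        dis={s: float(t[f"dis_{s}"].mean()) for s in SEGMENTS},
        pct_dis={s: float(t[f"pct_dis_{s}"].mean()) for s in SEGMENTS},
        cv_pct_dis={s: cv_pct_dis(t[f"pct_dis_{s}"], ddof=ddof) for s in SEGMENTS},
        n_cycles=n_cycles,
    )


def summaries_to_long_table(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Flatten condition summaries into the canonical long parameter table.

    Whole-body parameters (stride_time, step_length, step_width) carry
    segment '-'; segment parameters (dis, pct_dis, cv_pct_dis) expand over
    head/T4/pelvis.
    """
    rows = []
    for s in summaries:
        base = {"participant": s.participant, "sw": s.sw, "sp": s.sp}
        for name in ("stride_time", "step_length", "step_width"):
            rows.append({**base, "segment": "-", "parameter": name,
                         "value": getattr(s, name)})
        for param in ("dis", "pct_dis", "cv_pct_dis"):
            for seg, v in getattr(s, param).items():
                rows.append({**base, "segment": seg, "parameter": param, "value": v})
    return pd.DataFrame(rows)
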