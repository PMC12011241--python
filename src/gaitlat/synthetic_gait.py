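"""Synthetic treadmill-gait cohorts with known ground truth.

The generator emulates the study conditions end to end: a 2x2 grid of
step width (narrow/wide base) by belt speed (4.5 vs 2.2 km/h), n
participants, ~30 s trials at 120 Hz with the six-marker set (head top,
T4, left/right PSIS, left/right heel).

Per trial it synthesises
  * a left/right heel-contact schedule with jittered stride times,
  * vertical heel oscillation with exactly one minimum per stride at the
    scheduled contacts,
  * alternating heel placements at a commanded step width plus placement
    noise, and anteroposterior sawtooth motion at belt speed so step
    length is physical,
  * near-sinusoidal mediolateral sway of head/T4/pelvis whose per-cycle
    amplitude is the commanded displacement with multiplicative lognormal
    jitter (CV maps directly onto the jitter parameter), AR(1) measurement
    noise on top.

Participant-level lognormal amplitude multipliers (shared across
conditions) give the within-subject correlation structure a repeated
measures ANOVA needs. Every drawn quantity is recorded as ground truth so
pipeline recovery can be scored.

A parameter-level fast path (:func:`simulate_parameter_cohort`) draws the
same per-cycle quantities without synthesising frames; it is what makes
thousand-replicate null simulations affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import mocap_io
from .errors import ParameterError
from .mocap_io import (SEGMENTS, SP_LEVELS, SW_LEVELS, AxisMap,
                       MarkerTrajectorySet)

#: Belt speed in mm/s per speed level (4.5 and 2.2 km/h).
BELT_SPEED_MM_S = {"Normal": 4.5e6 / 3600.0, "Slow": 2.2e6 / 3600.0}

#: Default commanded mediolateral displacement (DIS, mm) per segment and
#: condition. Chosen once to mirror the qualitative ordering reported for
#: treadmill walking: T4 largest, narrow < wide base, normal < slow speed.
DEFAULT_SWAY_DIS = {
    "head":   {("NB", "Normal"): 35.0, ("NB", "Slow"): 40.0,
               ("WB", "Normal"): 70.0, ("WB", "Slow"): 95.0},
    "T4":     {("NB", "Normal"): 40.0, ("NB", "Slow"): 52.0,
               ("WB", "Normal"): 82.0, ("WB", "Slow"): 112.0},
    "pelvis": {("NB", "Normal"): 37.0, ("NB", "Slow"): 46.0,
               ("WB", "Normal"): 78.0, ("WB", "Slow"): 100.0},
}

_MARKER_HEIGHT = {"head": 1600.0, "T4": 1400.0, "pelvis": 1000.0}
_HIP_HALF_WIDTH = 60.0  # PSIS markers sit this far either side of the midline


@dataclass(frozen=True)
class SyntheticConfig:
    n_participants: int = 17
    fs: float = 120.0
    trial_s: float = 30.0
    n_cycles: int = 7
    stride_time_mean: dict = field(default_factory=lambda: {"Normal": 1.05, "Slow": 1.63})
    stride_time_sd: float = 0.02
    step_width_mean: dict = field(default_factory=lambda: {"NB": 80.0, "WB": 280.0})
    placement_sd: float = 10.0
    sway_dis: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_SWAY_DIS.items()})
    amplitude_cv: float = 0.10
    participant_cv: float = 0.15
    participant_segment_cv: float = 0.05
    segment_phase: dict = field(default_factory=lambda: {
        "head": 0.0, "T4": 0.2, "pelvis": 0.4})
    heel_lift_mm: float = 40.0
    noise_sd: float = 1.0
    noise_ar1: float = 0.9
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.stride_time_mean.values()) <= 0:
            raise ParameterError("stride times must be > 0")
        if self.step_width_mean["NB"] >= self.step_width_mean["WB"]:
            raise ParameterError("NB mean width must be below WB mean width")
        for sd in (self.stride_time_sd, self.placement_sd, self.amplitude_cv,
                   self.participant_cv, self.noise_sd):
            if sd < 0:
                raise ParameterError("all SDs must be >= 0")

    def null(self) -> "SyntheticConfig":
        """A copy with identical conditions and segments (every effect null)."""
        flat = {s: {key: 60.0 for key in v} for s, v in self.sway_dis.items()}
        widths = {"NB": 150.0, "WB": 150.000001}
        strides = {k: 1.2 for k in self.stride_time_mean}
        return replace(self, sway_dis=flat, step_width_mean=widths,
                       stride_time_mean=strides)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-mean lognormal multiplier with the requested CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def participant_effects(config: SyntheticConfig,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-participant, per-segment amplitude multipliers (condition-shared).

    A common whole-body multiplier (CV ``participant_cv``) is modulated by
    a smaller segment-specific one (CV ``participant_segment_cv``): people
    who sway more do so at every segment, which is what gives the
    within-subject design its correlation across segments.
    """
    common = _lognormal_factor(rng, config.participant_cv, config.n_participants)
    return {s: common * _lognormal_factor(rng, config.participant_segment_cv,
                                          config.n_participants)
            for s in SEGMENTS}


# ---------------------------------------------------------------------------
# frame-level trial synthesis
# ---------------------------------------------------------------------------

def generate_trial(config: SyntheticConfig, participant: int, sw: str, sp: str,
                   seed: int, segment_mult: dict[str, float] | None = None
                   ) -> tuple[MarkerTrajectorySet, pd.DataFrame]:
    """One trial plus its per-cycle ground truth.

    Returns the marker set and a truth frame with one row per full gait
    cycle: scheduled contact frames, stride time, realised step widths and
    the commanded per-segment DIS (2 x the drawn amplitude).
    """
    rng = np.random.default_rng(seed)
    segment_mult = segment_mult or {s: 1.0 for s in SEGMENTS}
    fs, n = config.fs, int(round(config.trial_s * config.fs))
    t = np.arange(n) / fs

    # --- contact schedule -------------------------------------------------
    stride_mu = config.stride_time_mean[sp]
    lefts = [0.55]
    while lefts[-1] < config.trial_s + stride_mu:
        stride = max(0.4, rng.normal(stride_mu, config.stride_time_sd))
        lefts.append(lefts[-1] + stride)
    lefts = np.array(lefts)
    rights = lefts[:-1] + 0.5 * np.diff(lefts) + rng.normal(
        0.0, 0.01, len(lefts) - 1)
    n_full = np.sum(lefts[1:] <= config.trial_s - 1.0 / fs)
    if n_full < config.n_cycles + 1:
        raise ParameterError(
            f"trial of {config.trial_s} s holds only {n_full} full cycles; "
            f"need >= {config.n_cycles + 1}")

    # --- per-cycle draws --------------------------------------------------
    n_cyc = len(lefts) - 1
    width_mu = config.step_width_mean[sw]
    left_ml = width_mu / 2 + rng.normal(0, config.placement_sd, len(lefts))
    right_ml = -width_mu / 2 + rng.normal(0, config.placement_sd, len(rights))
    amp = {s: 0.5 * config.sway_dis[s][(sw, sp)] * segment_mult[s]
           * _lognormal_factor(rng, config.amplitude_cv, n_cyc)
           for s in SEGMENTS}

    # --- heel kinematics --------------------------------------------------
    def foot_phase(contacts: np.ndarray) -> np.ndarray:
        # piecewise-linear stride phase, one full turn between own contacts;
        # extrapolated at the edges so the first/last contacts are true minima
        phase = np.interp(t, contacts, np.arange(len(contacts)))
        head = t < contacts[0]
        phase[head] = (t[head] - contacts[0]) / (contacts[1] - contacts[0])
        tail = t > contacts[-1]
        phase[tail] = (len(contacts) - 1) + (t[tail] - contacts[-1]) \
            / (contacts[-1] - contacts[-2])
        return phase

    phase_l = foot_phase(lefts)
    phase_r = foot_phase(rights)
    heel_z_l = 25.0 + 0.5 * config.heel_lift_mm * (1 - np.cos(2 * np.pi * phase_l))
    heel_z_r = 25.0 + 0.5 * config.heel_lift_mm * (1 - np.cos(2 * np.pi * phase_r))

    def held(contacts: np.ndarray, values: np.ndarray) -> np.ndarray:
        # the swing foot settles on its landing position mid-swing, a
        # quarter interval before contact, so filtered placements are
        # stable at every contact instant
        trans = contacts - 0.25 * np.diff(contacts,
                                          prepend=contacts[0] - stride_mu)
        idx = np.clip(np.searchsorted(trans, t, side="right") - 1,
                      0, len(values) - 1)
        return values[idx]

    heel_ml_l = held(lefts, left_ml)
    heel_ml_r = held(rights, right_ml)

    belt = BELT_SPEED_MM_S[sp]

    def sawtooth_ap(contacts: np.ndarray) -> np.ndarray:
        steps = np.diff(contacts, prepend=contacts[0] - stride_mu)
        land = 0.5 * belt * np.minimum(steps, 2.0)
        idx = np.clip(np.searchsorted(contacts, t, side="right") - 1,
                      0, len(contacts) - 1)
        return land[idx] - belt * (t - contacts[idx])

    heel_ap_l = sawtooth_ap(lefts)
    heel_ap_r = sawtooth_ap(rights)

    # --- segment sway -----------------------------------------------------
    cyc_idx = np.clip(np.searchsorted(lefts, t, side="right") - 1, 0, n_cyc - 1)
    cyc_phase = np.clip(phase_l - np.floor(phase_l), 0, 1)
    # before the first contact, run the first cycle's phase backwards
    pre = t < lefts[0]
    cyc_phase[pre] = ((t[pre] - lefts[0]) / (lefts[1] - lefts[0])) % 1.0

    def ar1(rng: np.random.Generator) -> np.ndarray:
        if config.noise_sd == 0:
            return np.zeros(n)
        phi = config.noise_ar1
        innov_sd = config.noise_sd * np.sqrt(1 - phi * phi)
        e = rng.normal(0, innov_sd, n)
        x0 = rng.normal(0, config.noise_sd)
        out, _ = signal.lfilter([1.0], [1.0, -phi], e, zi=[phi * x0])
        return out

    seg_ml = {}
    for s in SEGMENTS:
        a = amp[s][cyc_idx]
        seg_ml[s] = a * np.sin(2 * np.pi * cyc_phase + config.segment_phase[s]) \
            + ar1(rng)

    pelvis = seg_ml["pelvis"]
    zeros = np.zeros(n)
    markers = {
        "head": np.column_stack([seg_ml["head"], zeros,
                                 np.full(n, _MARKER_HEIGHT["head"])]),
        "T4": np.column_stack([seg_ml["T4"], zeros,
                               np.full(n, _MARKER_HEIGHT["T4"])]),
        "PSIS_L": np.column_stack([pelvis + _HIP_HALF_WIDTH, zeros,
                                   np.full(n, _MARKER_HEIGHT["pelvis"])]),
        "PSIS_R": np.column_stack([pelvis - _HIP_HALF_WIDTH, zeros,
                                   np.full(n, _MARKER_HEIGHT["pelvis"])]),
        "heel_L": np.column_stack([heel_ml_l, heel_ap_l, heel_z_l]),
        "heel_R": np.column_stack([heel_ml_r, heel_ap_r, heel_z_r]),
    }
    mts = MarkerTrajectorySet(
        sampling_rate=fs, markers=markers, axis_map=AxisMap(),
        meta={"participant": f"P{participant:02d}", "sw": sw, "sp": sp,
              "seed": seed, "synthetic": True})

    # --- ground truth -----------------------------------------------------
    rows = []
    for k in range(n_cyc):
        end_frame = lefts[k + 1] * fs
        if end_frame > n - 1:
            break
        # rights[k] lies inside cycle k by construction
        w_lr = abs(right_ml[k] - left_ml[k])
        w_rl = abs(left_ml[k + 1] - right_ml[k])
        row = {
            "participant": f"P{participant:02d}", "sw": sw, "sp": sp, "cycle": k,
            "start_frame": int(round(lefts[k] * fs)),
            "end_frame": int(round(lefts[k + 1] * fs)),
            "stride_time": lefts[k + 1] - lefts[k],
            "step_width_lr": w_lr, "step_width_rl": w_rl,
            "step_width_cycle": 0.5 * (w_lr + w_rl),
        }
        for s in SEGMENTS:
            row[f"dis_{s}"] = 2.0 * amp[s][k]
            row[f"pct_dis_{s}"] = 2.0 * amp[s][k] / row["step_width_cycle"]
        rows.append(row)
    return mts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    trials: list[tuple[str, str, str, MarkerTrajectorySet]]
    truth_cycles: pd.DataFrame
    truth_table: pd.DataFrame
    manifest: dict


def _trial_seed(master: int, participant: int, sw: str, sp: str) -> int:
    return (master * 10007 + participant * 101
            + SW_LEVELS.index(sw) * 11 + SP_LEVELS.index(sp) * 3) % (2 ** 31 - 1)


def generate_cohort(config: SyntheticConfig,
                    out_dir: str | Path | None = None,
                    file_format: str = "trc") -> Cohort:
    """n_participants x 4 condition trials with shared participant effects.

    When ``out_dir`` is given, trials are written as TRC or wide CSV files
    and the manifest records paths and seeds. The truth table summarises,
    per participant x condition, the same cycles the pipeline's default
    start policy selects (first left contact after 2 s, then
    ``config.n_cycles`` cycles).
    """
    rng = np.random.default_rng(config.master_seed)
    mult = participant_effects(config, rng)
    trials = []
    truth_frames = []
    manifest = {"master_seed": config.master_seed, "trials": []}
    for p in range(config.n_participants):
        for sw in SW_LEVELS:
            for sp in SP_LEVELS:
                seed = _trial_seed(config.master_seed, p, sw, sp)
                seg_mult = {s: float(mult[s][p]) for s in SEGMENTS}
                mts, truth = generate_trial(config, p, sw, sp, seed, seg_mult)
                pid = f"P{p:02d}"
                trials.append((pid, sw, sp, mts))
                truth_frames.append(truth)
                entry = {"participant": pid, "sw": sw, "sp": sp, "seed": seed}
                if out_dir is not None:
                    out = Path(out_dir)
                    out.mkdir(parents=True, exist_ok=True)
                    name = f"{pid}_{sw}_{sp}.{'trc' if file_format == 'trc' else 'csv'}"
                    path = out / name
                    if file_format == "trc":
                        mocap_io.write_trc(mts, path)
                    else:
                        mocap_io.write_marker_csv(mts, path)
                    entry["path"] = str(path)
                manifest["trials"].append(entry)
    truth_cycles = pd.concat(truth_frames, ignore_index=True)
    truth_table = truth_to_parameter_table(truth_cycles, config)
    return Cohort(trials=trials, truth_cycles=truth_cycles,
                  truth_table=truth_table, manifest=manifest)


def truth_to_parameter_table(truth_cycles: pd.DataFrame,
                             config: SyntheticConfig) -> pd.DataFrame:
    """Condition summaries of the ground truth over the pipeline's cycles.

    Applies the same selection the event stage uses: the first cycle
    starting at or after 2 s, then n_cycles consecutive cycles.
    """
    skip_frame = 2.0 * config.fs
    rows = []
    for (pid, sw, sp), g in truth_cycles.groupby(["participant", "sw", "sp"]):
        g = g.sort_values("cycle")
        g = g[g.start_frame >= skip_frame].head(config.n_cycles)
        if len(g) < config.n_cycles:
            raise ParameterError(
                f"{pid} {sw}/{sp}: only {len(g)} truth cycles after settling")
        base = {"participant": pid, "sw": sw, "sp": sp}
        rows.append({**base, "segment": "-", "parameter": "stride_time",
                     "value": g.stride_time.mean()})
        rows.append({**base, "segment": "-", "parameter": "step_width",
                     "value": float(np.mean(np.r_[g.step_width_lr,
                                                  g.step_width_rl]))})
        for s in SEGMENTS:
            pct = g[f"pct_dis_{s}"]
            rows.append({**base, "segment": s, "parameter": "dis",
                         "value": g[f"dis_{s}"].mean()})
            rows.append({**base, "segment": s, "parameter": "pct_dis",
                         "value": pct.mean()})
            rows.append({**base, "segment": s, "parameter": "cv_pct_dis",
                         "value": float(pct.std(ddof=1) / pct.mean() * 100.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter-level fast path (no frame synthesis)
# ---------------------------------------------------------------------------

def simulate_parameter_cohort(config: SyntheticConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Draw condition summaries directly from the generative model.

    Same distributional assumptions as the frame-level path (lognormal
    per-cycle amplitudes, participant multipliers, noisy placements) but
    skipping trajectory synthesis; used for large replication studies of
    the statistics ladder.
    """
    n, c = config.n_participants, config.n_cycles
    mult = participant_effects(config, rng)
    rows = []
    for p in range(n):
        pid = f"P{p:02d}"
        for sw in SW_LEVELS:
            for sp in SP_LEVELS:
                base = {"participant": pid, "sw": sw, "sp": sp}
                strides = rng.normal(config.stride_time_mean[sp],
                                     config.stride_time_sd, c)
                wl = config.step_width_mean[sw] / 2 + rng.normal(
                    0, config.placement_sd, c)
                wr = -config.step_width_mean[sw] / 2 + rng.normal(
                    0, config.placement_sd, c)
                widths = np.abs(wl - wr)
                rows.append({**base, "segment": "-", "parameter": "stride_time",
                             "value": strides.mean()})
                rows.append({**base, "segment": "-", "parameter": "step_width",
                             "value": widths.mean()})
                for s in SEGMENTS:
                    a = 0.5 * config.sway_dis[s][(sw, sp)] * mult[s][p] \
                        * _lognormal_factor(rng, config.amplitude_cv, c)
                    d = 2.0 * a
                    pct = d / widths
                    rows.append({**base, "segment": s, "parameter": "dis",
                                 "value": d.mean()})
                    rows.append({**base, "segment": s, "parameter": "pct_dis",
                                 "value": pct.mean()})
                    rows.append({**base, "segment": s, "parameter": "cv_pct_dis",
                                 "value": pct.std(ddof=1) / pct.mean() * 100.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

#: Registered recovery tolerances (relative unless noted).
RECOVERY_TOLERANCES = {
    "stride_time": 0.02,
    "step_width": 0.05,
    "dis": 0.05,
    "pct_dis": 0.07,
    "cv_pct_dis": 0.15,
}


def truth_compare(pipeline_table: pd.DataFrame, truth_table: pd.DataFrame,
                  tolerances: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-parameter bias/RMSE of pipeline estimates against ground truth.

    Joins on (participant, sw, sp, segment, parameter); raises on key
    mismatch. ``passed`` compares |bias| / mean truth against the
    registered tolerance.
    """
    tolerances = tolerances or RECOVERY_TOLERANCES
    key = ["participant", "sw", "sp", "segment", "parameter"]
    merged = pipeline_table.merge(truth_table, on=key, how="outer",
                                  suffixes=("_est", "_true"), indicator=True)
    bad = merged[merged._merge != "both"]
    if len(bad):
        raise ParameterError(
            f"key mismatch between pipeline and truth tables: "
            f"{bad[key].head(5).to_dict('records')}")
    out = []
    for param, g in merged.groupby("parameter"):
        err = g.value_est - g.value_true
        scale = abs(g.value_true.mean())
        bias = float(err.mean())
        rel = abs(bias) / scale if scale else np.inf
        tol = tolerances.get(param)
        out.append({"parameter": param, "n": len(g), "bias": bias,
                    "rmse": float(np.sqrt(np.mean(err ** 2))),
                    "rel_bias": rel, "tolerance": tol,
                    "passed": bool(rel <= tol) if tol is not None else None})
    return pd.DataFrame(out)
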