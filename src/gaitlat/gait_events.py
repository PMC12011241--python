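"""Heel-contact detection and gait-cycle segmentation.

Heel contact is the frame at which the heel marker's vertical coordinate
is lowest within a stride. On a treadmill this recurs once per stride per
side, so contacts are extracted as local minima of the (filtered) vertical
heel series guarded by a prominence floor and a minimum separation; ties
on flat minima resolve to the earliest frame.

A gait cycle runs from one left heel contact to the next and must contain
exactly one right contact. Seven consecutive cycles are extracted by
default, starting at the first left contact after a settling interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import AlternationError, InsufficientEventsError, ParameterError

#: Expected stride time per speed level (s); used only to default the
#: minimum event separation.
STRIDE_TIME_PRESETS = {"Normal": 1.05, "Slow": 1.63}


@dataclass(frozen=True)
class EventParams:
    """Detection guards for heel-contact minima.

    prominence_mm : required prominence of each minimum (default 2 mm).
    min_separation_s : minimum spacing between same-side contacts; when
        None it defaults to 0.4 x the expected stride time for
        ``speed_level`` (Normal preset if unspecified).
    """

    prominence_mm: float = 2.0
    min_separation_s: float | None = None
    speed_level: str = "Normal"

    def separation_s(self) -> float:
        if self.min_separation_s is not None:
            return self.min_separation_s
        try:
            expected = STRIDE_TIME_PRESETS[self.speed_level]
        except KeyError:
            raise ParameterError(f"unknown speed level {self.speed_level!r}")
        return 0.4 * expected


@dataclass
class GaitEventTable:
    """Strictly increasing heel-contact frame indices per side."""

    left_contacts: np.ndarray
    right_contacts: np.ndarray
    params: EventParams = field(default_factory=EventParams)

    def __post_init__(self) -> None:
        self.left_contacts = np.asarray(self.left_contacts, dtype=int)
        self.right_contacts = np.asarray(self.right_contacts, dtype=int)
        for side, arr in (("left", self.left_contacts), ("right", self.right_contacts)):
            if len(arr) > 1 and not (np.diff(arr) > 0).all():
                raise ParameterError(f"{side} contacts not strictly increasing")


@dataclass
class GaitCycle:
    start: int                  # left heel contact frame
    end: int                    # next left heel contact frame
    right_contact: int          # the single right contact inside


@dataclass
class GaitCycleSet:
    cycles: list[GaitCycle]

    @property
    def count(self) -> int:
        return len(self.cycles)


def detect_heel_contacts(heel_vertical: np.ndarray, fs: float,
                         params: EventParams | None = None) -> np.ndarray:
    """Frame indices of heel contacts (local minima of the vertical series).

    Ties across flat minima resolve to the earliest frame of the plateau.
    Raises :class:`InsufficientEventsError` when fewer than two minima pass
    the guards.
    """
    if fs <= 0:
        raise ParameterError(f"fs must be > 0, got {fs}")
    params = params or EventParams()
    z = np.asarray(heel_vertical, dtype=float)
    distance = max(1, int(round(params.separation_s() * fs)))
    peaks, props = signal.find_peaks(-z, prominence=params.prominence_mm,
                                     distance=distance,
                                     plateau_size=(None, None))
    # earliest frame of each plateau, not its midpoint
    frames = props["left_edges"] if "left_edges" in props else peaks
    if len(frames) < 2:
        raise InsufficientEventsError(
            f"found {len(frames)} heel-contact minima (need >= 2); "
            f"prominence>={params.prominence_mm} mm, "
            f"separation>={params.separation_s():.3f} s")
    return np.asarray(frames, dtype=int)


@dataclass(frozen=True)
class StartPolicy:
    """Which left contact begins the extracted span.

    Default skips the first ``skip_s`` seconds of the trial so treadmill
    settling does not contaminate the cycles.
    """

    skip_s: float = 2.0


def segment_cycles(events: GaitEventTable, fs: float, n_cycles: int = 7,
                   start_policy: StartPolicy | None = None) -> GaitCycleSet:
    """Extract ``n_cycles`` contiguous left-anchored cycles.

    Each cycle must contain exactly one right contact; violations raise
    :class:`AlternationError` naming the offending frames rather than
    repairing the trial.
    """
    start_policy = start_policy or StartPolicy()
    left = events.left_contacts
    right = events.right_contacts
    skip_frame = start_policy.skip_s * fs
    eligible = np.flatnonzero(left >= skip_frame)
    if len(eligible) == 0:
        raise InsufficientEventsError(
            f"no left contact after {start_policy.skip_s} s settling interval")
    k0 = eligible[0]
    if len(left) - k0 < n_cycles + 1:
        raise InsufficientEventsError(
            f"need {n_cycles + 1} left contacts from frame {left[k0]}, "
            f"have {len(left) - k0} (of {len(left)} total)")
    cycles = []
    for k in range(k0, k0 + n_cycles):
        a, b = left[k], left[k + 1]
        inside = right[(right > a) & (right < b)]
        if len(inside) != 1:
            raise AlternationError(
                f"cycle [{a}, {b}) contains {len(inside)} right contacts "
                f"(frames {inside.tolist()}); expected exactly 1")
        cycles.append(GaitCycle(start=int(a), end=int(b), right_contact=int(inside[0])))
    return GaitCycleSet(cycles=cycles)


def time_normalize(series: np.ndarray, cycle: GaitCycle, n_points: int = 101) -> np.ndarray:
    """Resample one cycle of a series onto 0-100% gait-cycle phase.

    Linear interpolation over the inclusive span [start, end]; the first
    point equals the value at the starting contact, the last the value at
    the closing contact.
    """
    length = cycle.end - cycle.start
    if length <= 0:
        raise ParameterError(f"degenerate cycle [{cycle.start}, {cycle.end}]")
    if length < 4:
        raise ParameterError(f"cycle of {length} frames too short to resample")
    seg = np.asarray(series, dtype=float)[cycle.start: cycle.end + 1]
    phase = np.linspace(0.0, 1.0, n_points)
    return np.interp(phase * length, np.arange(length + 1), seg)
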