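"""Low-pass filtering of marker trajectories.

The processing step mirrors standard treadmill-kinematics practice: a
fourth-order Butterworth low-pass at 6 Hz applied to every coordinate of
every marker. The default is zero-phase (forward-backward) filtering so
heel-contact timing is not lagged; "order" refers to the design order of
the single-pass prototype (the two-pass magnitude response is then
effectively 8th order). Set ``order_interpretation='effective'`` to halve
the prototype order instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ParameterError, ValidationError
from .mocap_io import MarkerTrajectorySet


@dataclass(frozen=True)
class FilterSpec:
    order: int = 4
    cutoff_hz: float = 6.0
    mode: str = "zero_phase"          # or "causal"
    order_interpretation: str = "design"  # or "effective"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if self.mode not in ("zero_phase", "causal"):
            raise ParameterError(f"unknown filter mode {self.mode!r}")
        if self.order_interpretation not in ("design", "effective"):
            raise ParameterError(
                f"order_interpretation must be design|effective, got "
                f"{self.order_interpretation!r}")

    def design_order(self) -> int:
        if self.order_interpretation == "effective" and self.mode == "zero_phase":
            if self.order % 2:
                raise ParameterError("effective order must be even for zero-phase")
            return self.order // 2
        return self.order

    def padlen(self) -> int:
        # odd-reflection padding, 3 x (order + 1) samples per edge
        return 3 * (self.design_order() + 1)


def interpolate_gaps(mts: MarkerTrajectorySet, max_gap: int = 10) -> MarkerTrajectorySet:
    """Linearly interpolate invalid runs of <= max_gap frames.

    Longer gaps (or invalid trial edges) raise: range-based statistics and
    minimum detection cannot be trusted across long occlusions.
    """
    markers: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for name, arr in mts.markers.items():
        ok = mts.valid[name].copy()
        out = arr.copy()
        if not ok.all():
            if not ok[0] or not ok[-1]:
                raise ValidationError(
                    f"marker {name!r}: trial starts or ends with invalid frames")
            runs = _invalid_runs(ok)
            worst = max((b - a) for a, b in runs)
            if worst > max_gap:
                raise ValidationError(
                    f"marker {name!r}: gap of {worst} frames exceeds "
                    f"max_gap={max_gap}; trial rejected")
            idx = np.arange(len(ok))
            for k in range(3):
                out[:, k] = np.interp(idx, idx[ok], arr[ok, k])
        markers[name] = out
        valid[name] = np.ones_like(ok, dtype=bool)
    return MarkerTrajectorySet(sampling_rate=mts.sampling_rate, markers=markers,
                               valid=valid, axis_map=mts.axis_map,
                               meta=dict(mts.meta))


def _invalid_runs(ok: np.ndarray) -> list[tuple[int, int]]:
    bad = ~ok
    edges = np.flatnonzero(np.diff(bad.astype(int)))
    starts = [i + 1 for i in edges if bad[i + 1]]
    ends = [i + 1 for i in edges if not bad[i + 1]]
    return list(zip(starts, ends))


def lowpass_series(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Butterworth low-pass of a 1D series (used by both pipeline and tests)."""
    spec = spec or FilterSpec()
    nyq = fs / 2.0
    if not 0 < spec.cutoff_hz < nyq:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    b, a = signal.butter(spec.design_order(), spec.cutoff_hz / nyq, btype="low")
    if spec.mode == "causal":
        return signal.lfilter(b, a, x)
    padlen = spec.padlen()
    if len(x) <= 3 * padlen:
        raise ParameterError(
            f"trial of {len(x)} frames is shorter than 3 x pad length "
            f"({3 * padlen}); cannot zero-phase filter")
    return signal.filtfilt(b, a, x, padtype="odd", padlen=padlen)


def butterworth_lowpass(mts: MarkerTrajectorySet,
                        spec: FilterSpec | None = None) -> MarkerTrajectorySet:
    """Filter every coordinate of every marker independently.

    Requires all frames valid (run :func:`interpolate_gaps` first); output
    length equals input length and the spec is recorded in ``meta``.
    """
    spec = spec or FilterSpec()
    for name, ok in mts.valid.items():
        if not ok.all():
            raise ValidationError(
                f"marker {name!r} still has invalid frames; interpolate first")
    markers = {}
    for name, arr in mts.markers.items():
        out = np.empty_like(arr)
        for k in range(3):
            out[:, k] = lowpass_series(arr[:, k], mts.sampling_rate, spec)
        markers[name] = out
    meta = dict(mts.meta)
    meta["filter"] = {"order": spec.order, "cutoff_hz": spec.cutoff_hz,
                      "mode": spec.mode,
                      "order_interpretation": spec.order_interpretation}
    return MarkerTrajectorySet(sampling_rate=mts.sampling_rate, markers=markers,
                               valid={k: v.copy() for k, v in mts.valid.items()},
                               axis_map=mts.axis_map, meta=meta)


def magnitude_response(f_hz: float, fs: float, spec: FilterSpec | None = None) -> float:
    """Gain of the configured digital filter at one frequency.

    Evaluated from the realised transfer function (bilinear-transformed
    Butterworth); for zero-phase mode the single-pass magnitude is squared
    (two passes).
    """
    spec = spec or FilterSpec()
    nyq = fs / 2.0
    b, a = signal.butter(spec.design_order(), spec.cutoff_hz / nyq, btype="low")
    _, h = signal.freqz(b, a, worN=[2 * np.pi * f_hz / fs])
    g = float(np.abs(h[0]))
    return g * g if spec.mode == "zero_phase" else g
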