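"""Quantitative rules for the clinical myotonia instruments.

Three deterministic measures are implemented:

* Streib needle-EMG grading of myotonic discharges over 10 insertions
  (0 / 1+ / 2+ / 3+);
* quantitative grip-relaxation time: time for force to fall from 90% to 5%
  of the maximal voluntary isometric contraction (MVIC) peak;
* transient paresis: percent decline of the peak force within the MVIC
  window (3 s by default).

Threshold crossings on force traces are located with linear interpolation
between samples, giving sub-sample timing precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class InvalidTraceError(ValueError):
    """Force trace unusable (too short, flat, or non-positive peak)."""


class NotRelaxedError(ValueError):
    """Force never falls to 5% of peak within the trace."""


#: Streib grade by number of insertions (out of 10) showing discharges.
_GRADE_BOUNDS = ((0, 2, "0"), (3, 5, "1+"), (6, 9, "2+"), (10, 10, "3+"))


def grade_myotonic_discharges(n_detections: int) -> str:
    """Streib grade from the number of positive insertions out of 10.

    0-2 insertions -> "0"; 3-5 -> "1+"; 6-9 -> "2+"; 10 -> "3+".
    """
    if int(n_detections) != n_detections or not 0 <= n_detections <= 10:
        raise ValueError(f"detections must be an integer in [0, 10], got {n_detections!r}")
    for lo, hi, grade in _GRADE_BOUNDS:
        if lo <= n_detections <= hi:
            return grade
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly or explicitly timed grip-force trace.

    ``onset_time`` marks the start of the MVIC (event marker); times are in
    seconds, force in arbitrary units (results are scale-invariant).
    """

    time: np.ndarray
    force: np.ndarray
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if t.ndim != 1 or f.shape != t.shape or t.size < 2:
            raise InvalidTraceError("trace needs matching 1-d time/force with >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidTraceError("time must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise InvalidTraceError("force contains non-finite values")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)

    @classmethod
    def from_sampling(cls, force, fs: float, onset_time: float = 0.0) -> "ForceTrace":
        """Build from a sampling rate (Hz) and ordered samples."""
        if fs <= 0:
            raise InvalidTraceError("sampling rate must be positive")
        force = np.asarray(force, dtype=float)
        t = np.arange(force.size) / fs
        return cls(time=t, force=force, onset_time=onset_time)

    @classmethod
    def from_csv(cls, path) -> "ForceTrace":
        """Read a two-column (time, force) CSV."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise InvalidTraceError("trace CSV needs two columns (time, force)")
        return cls(time=df.iloc[:, 0].to_numpy(), force=df.iloc[:, 1].to_numpy())


def _cross_down(t: np.ndarray, f: np.ndarray, level: float, i0: int, i1: int):
    """(time, index) of down-crossings of `level` in samples [i0, i1]."""
    hits = []
    for i in range(max(i0, 1), i1 + 1):
        if f[i - 1] > level >= f[i]:
            # linear interpolation between samples i-1 and i
            frac = (f[i - 1] - level) / (f[i - 1] - f[i])
            hits.append((t[i - 1] + frac * (t[i] - t[i - 1]), i))
    return hits


def relaxation_time(trace: ForceTrace) -> float:
    """Grip-myotonia relaxation time: 90% -> 5% of the MVIC peak, seconds.

    The 5% point is the first crossing after the peak; the 90% point is the
    last down-crossing of 90% of peak before that 5% crossing (so transient
    re-rises above 90% restart the clock).
    """
    t, f = trace.time, trace.force
    peak = float(f.max())
    if peak <= 0 or np.allclose(f, f[0]):
        raise InvalidTraceError("flat or non-positive trace has no relaxation phase")
    ipk = int(np.argmax(f))
    lo_hits = _cross_down(t, f, 0.05 * peak, ipk + 1, len(f) - 1)
    if not lo_hits:
        raise NotRelaxedError("force never falls to 5% of peak")
    t5, i5 = lo_hits[0]
    hi_hits = _cross_down(t, f, 0.90 * peak, ipk, i5)
    if not hi_hits:
        raise InvalidTraceError("no 90%-of-peak crossing precedes the 5% point")
    t90 = hi_hits[-1][0]
    return float(t5 - t90)


def transient_paresis_decline(trace: ForceTrace, window: float = 3.0) -> float:
    """Percent force decline from peak within the MVIC window.

    The peak force (PF) is located within ``window`` seconds from
    ``onset_time``; the decline is ``100 * (PF - min force after the peak
    within the window) / PF``.  A peak at the window end yields 0% with a
    warning (no post-peak samples to assess).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t, f = trace.time, trace.force
    t_end = trace.onset_time + window
    if t_end > t[-1] + 1e-12:
        raise ValueError("window extends beyond the trace duration")
    mask = (t >= trace.onset_time) & (t <= t_end + 1e-12)
    tw, fw = t[mask], f[mask]
    if tw.size < 2:
        raise InvalidTraceError("window contains fewer than two samples")
    peak = float(fw.max())
    if peak <= 0:
        raise InvalidTraceError("non-positive peak force")
    ipk = int(np.argmax(fw))
    if ipk == tw.size - 1:
        warnings.warn(
            "peak force occurs at the window end; no post-peak decline observable",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    trough = float(fw[ipk:].min())
    return float(100.0 * (peak - trough) / peak)
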