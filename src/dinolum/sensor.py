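"""Decoding of the pillar-array living force sensor.

A DLP-printed sensor carries a tall stabilising pillar p0 and shorter
indicator pillars p1..pn of decreasing height. Under a flat puncher the
pillars luminesce sequentially: a pillar is considered actuated when its
ROI intensity exceeds five standard deviations of the background noise.
Because the embedded dinoflagellates need a minimum strain of 2% to
fire, the onset of p0's luminescence anchors the video to the force
record at displacement 0.02 * h_p0; all other onsets then map through
the record to displacement and force. The set of lit indicator pillars
finally decodes the applied force into a calibrated interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import ActuationEvent, ForceRecord, FrameStack, PillarSensor
from .flashcount import blue_channel

__all__ = [
    "pillar_traces",
    "detect_actuation",
    "sync_displacement",
    "decode_force",
    "ACTUATION_SIGMA",
]

ACTUATION_SIGMA = 5.0  # actuation threshold in baseline SDs


def pillar_traces(stack: FrameStack, sensor: PillarSensor,
                  roi_radius_px: float) -> np.ndarray:
    """Mean blue-channel intensity inside each pillar's circular ROI per frame.

    Returns an ``(n_pillars, n_frames)`` array. ROIs must be pairwise
    disjoint and fully inside the frame.
    """
    if sensor.roi_centers is None:
        raise ValueError("sensor.roi_centers must be set for trace extraction")
    centers = sensor.roi_centers
    h, w = stack.frames.shape[1:3]
    for i, (r, c) in enumerate(centers):
        if (r - roi_radius_px < 0 or r + roi_radius_px > h - 1
                or c - roi_radius_px < 0 or c + roi_radius_px > w - 1):
            raise ValueError(f"ROI of pillar {i} extends outside the frame")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.hypot(*(centers[i] - centers[j])) < 2 * roi_radius_px:
                raise ValueError(f"ROIs of pillars {i} and {j} overlap")

    blue = blue_channel(stack).astype(float)
    rr, cc = np.mgrid[0:h, 0:w]
    traces = np.empty((len(centers), stack.n_frames))
    for i, (r0, c0) in enumerate(centers):
        roi = (rr - r0) ** 2 + (cc - c0) ** 2 <= roi_radius_px ** 2
        traces[i] = blue[:, roi].mean(axis=1)
    return traces


def detect_actuation(trace: np.ndarray, baseline_window: int,
                     n_sigma: float = ACTUATION_SIGMA) -> Optional[int]:
    """First frame where intensity exceeds baseline mean + n_sigma * baseline SD.

    ``baseline_window`` frames at the start of the trace (before any
    stimulus) estimate the background statistics. A zero baseline SD is
    replaced by a floor of 1 intensity unit. Returns None when the trace
    never crosses the threshold.
    """
    trace = np.asarray(trace, dtype=float)
    if baseline_window < 2 or baseline_window >= len(trace):
        raise ValueError("baseline_window must cover >= 2 frames before stimulus")
    base = trace[:baseline_window]
    mean, sd = float(base.mean()), float(base.std())
    if sd == 0.0:
        sd = 1.0  # SD floor for a noiseless baseline
    above = np.nonzero(trace - mean > n_sigma * sd)[0]
    if len(above) == 0:
        return None
    return int(above[0])


@dataclass
class SensorReadout:
    """Synchronised actuation events plus the pillars that never fired."""

    events: list[ActuationEvent]
    non_actuated: list[int]
    time_offset_s: float  # video time minus record time


def sync_displacement(onsets: Sequence[Optional[int]], stack: FrameStack,
                      record: ForceRecord, sensor: PillarSensor) -> SensorReadout:
    """Map per-pillar onset frames to displacement and force.

    The time offset between video and force record is fixed by the
    physiological anchor: p0's onset frame corresponds to the instant the
    record's displacement reaches ``actuation_strain * h_p0`` (2% strain
    by default). Pillars without a detected onset are listed as
    non-actuated.
    """
    if onsets[0] is None:
        raise ValueError("p0 onset undetected; synchronization impossible")
    d_anchor = sensor.actuation_strain * sensor.heights[0]
    # loading branch of the record
    peak = int(np.argmax(record.displacement))
    t_load = record.time[: peak + 1]
    x_load = record.displacement[: peak + 1]
    if d_anchor > x_load.max():
        raise ValueError("record never reaches the p0 anchor displacement")
    t_anchor = float(np.interp(d_anchor, x_load, t_load))
    offset = float(stack.timestamps[onsets[0]]) - t_anchor

    events: list[ActuationEvent] = []
    non_actuated: list[int] = []
    for pid, frame in enumerate(onsets):
        if frame is None:
            non_actuated.append(pid)
            continue
        t_rec = float(stack.timestamps[frame]) - offset
        d = float(np.interp(t_rec, record.time, record.displacement))
        f = float(np.interp(t_rec, record.time, record.force)) * 1000.0  # N->mN
        events.append(ActuationEvent(pillar_id=pid, onset_time=t_rec,
                                     onset_displacement=d, onset_force=f))
    return SensorReadout(events=events, non_actuated=non_actuated,
                         time_offset_s=offset)


def decode_force(actuated: set[int] | Sequence[int],
                 calibration: Mapping[int, float]) -> tuple[float, float]:
    """Force interval (mN) implied by the set of lit indicator pillars.

    ``calibration`` maps indicator pillar ids (1, 2, ...) to their onset
    forces, strictly increasing with pillar index. With the printed
    calibration {p1: 214, p2: 333, p3: 569} mN, a lit {p1} decodes to
    [214, 333) mN and {p1, p2} to [333, 569) mN; an empty set decodes to
    [0, first onset) and lighting every calibrated pillar leaves the
    interval open above (upper bound +inf).
    """
    actuated = set(actuated)
    pillars = sorted(calibration)
    forces = [calibration[p] for p in pillars]
    if any(f2 <= f1 for f1, f2 in zip(forces, forces[1:])):
        raise ValueError("calibration forces must be strictly increasing")
    unknown = actuated - set(pillars)
    if unknown:
        raise ValueError(f"actuated pillars {sorted(unknown)} not in calibration")
    # consistency: lit pillars must be a prefix of the height ordering
    lit = [p in actuated for p in pillars]
    if any(later and not earlier for earlier, later in zip(lit, lit[1:])):
        raise ValueError(
            f"inconsistent readout: actuated set {sorted(actuated)} "
            "skips a taller pillar"
        )
    k = sum(lit)  # number of lit indicators, a prefix
    lower = 0.0 if k == 0 else forces[k - 1]
    upper = float("inf") if k == len(pillars) else forces[k]
    return (float(lower), float(upper))
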