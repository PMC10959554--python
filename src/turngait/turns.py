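"""Turn segmentation from pelvis yaw rate.

The turning period is the longest contiguous run where the absolute pelvis
yaw rate exceeds a threshold (30 deg/s by default); the analysis window
extends it to the last toe-off before onset and the first heel strike after
offset.  The internal leg is the one on the inside of the turn circle
(left turn -> left leg internal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._signal import DEFAULT_CUTOFF_HZ, central_diff, lowpass
from .events import (GaitEventSeries, HEEL_STRIKE, TOE_OFF, PelvisFrame,
                     Side, pelvis_frame)
from .io import TrialRecording

#: Angular-speed threshold defining the turning period (deg/s).
TURN_RATE_THRESHOLD = 30.0

#: Supra-threshold runs shorter than this are treated as noise (s).
MIN_RUN_DURATION = 0.1


class NoTurnDetectedError(ValueError):
    """Raised when no supra-threshold yaw-rate run is found."""


@dataclass
class TurnSegment:
    yaw_onset_time: float
    yaw_offset_time: float
    window_start_time: float   # last toe-off before onset
    window_end_time: float     # first heel strike after offset
    direction: Literal["left", "right"]
    internal_side: Side
    external_side: Side
    amplitude_measured: float  # |yaw(offset) - yaw(onset)|, degrees

    def __post_init__(self) -> None:
        if not (self.window_start_time <= self.yaw_onset_time
                < self.yaw_offset_time <= self.window_end_time):
            raise ValueError("turn segment times out of order")
        if self.internal_side == self.external_side:
            raise ValueError("internal and external side must differ")


def pelvis_yaw_rate(recording: TrialRecording,
                    frame: PelvisFrame | None = None,
                    cutoff: float = DEFAULT_CUTOFF_HZ) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped pelvis yaw angle (deg) and yaw rate (deg/s) per frame.

    Yaw is the heading of the pelvis forward axis in the ground plane,
    unwrapped so full turns accumulate without +-180 deg jumps; the rate is
    the central difference of the low-pass-filtered unwrapped angle.
    """
    if frame is None:
        frame = pelvis_frame(recording)
    yaw = np.degrees(np.unwrap(np.arctan2(frame.forward[:, 1], frame.forward[:, 0])))
    yaw_f = lowpass(yaw, recording.sampling_rate, cutoff)
    rate = central_diff(yaw_f, recording.sampling_rate)
    return yaw, rate


def _supra_threshold_runs(rate: np.ndarray, threshold: float,
                          fs: float) -> list[tuple[int, int]]:
    """Contiguous index runs with |rate| > threshold, longer than the
    hysteresis minimum; [(start, stop)) pairs."""
    above = np.abs(rate) > threshold
    runs: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(rate))
    min_len = int(round(MIN_RUN_DURATION * fs))
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_len]


def detect_turn(recording: TrialRecording, events: GaitEventSeries,
                threshold: float = TURN_RATE_THRESHOLD,
                frame: PelvisFrame | None = None,
                cutoff: float = DEFAULT_CUTOFF_HZ) -> TurnSegment:
    """Segment the turn of one trial by the angular-speed rule.

    Onset/offset are the first/last frame of the longest contiguous run with
    |yaw rate| > ``threshold`` (runs shorter than 0.1 s are ignored);
    direction is the sign of the net yaw change over the run (left =
    counterclockwise); the analysis window is extended to the last toe-off
    before onset and the first heel strike after offset.
    """
    fs = recording.sampling_rate
    yaw, rate = pelvis_yaw_rate(recording, frame, cutoff)
    runs = _supra_threshold_runs(rate, threshold, fs)
    if not runs:
        raise NoTurnDetectedError(
            f"no turn detected: pelvis yaw rate never exceeds {threshold:g} deg/s")
    onset_i, offset_i = max(runs, key=lambda ab: ab[1] - ab[0])
    offset_i -= 1  # last frame of the run
    net_yaw = yaw[offset_i] - yaw[onset_i]
    direction: Side = "left" if net_yaw > 0 else "right"
    internal, external = (("left", "right") if direction == "left"
                          else ("right", "left"))
    onset_t, offset_t = onset_i / fs, offset_i / fs

    to_before = [e for e in events.of(kind=TOE_OFF) if e.time <= onset_t]
    hs_after = [e for e in events.of(kind=HEEL_STRIKE) if e.time >= offset_t]
    if not to_before:
        raise ValueError("no toe-off precedes the turn onset; window undefined")
    if not hs_after:
        raise ValueError("no heel strike follows the turn offset; window undefined")
    return TurnSegment(
        yaw_onset_time=onset_t,
        yaw_offset_time=offset_t,
        window_start_time=to_before[-1].time,
        window_end_time=hs_after[0].time,
        direction=direction,
        internal_side=internal,
        external_side=external,
        amplitude_measured=abs(float(net_yaw)),
    )
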