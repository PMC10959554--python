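"""Gait-event detection from marker kinematics.

Heel strikes follow the foot-velocity principle (minimum of the foot-centre
vertical velocity, gated to phases where the foot is not progressing
forward relative to the pelvis); toe-offs follow the coordinate principle
(minimum of the toe's forward coordinate expressed in a pelvis-fixed
frame).  Both are computed in a pelvis-local progression frame so the same
rules stay valid through 90-360 degree turns, where lab-fixed axes are
meaningless.

Candidate extrema are located on 6 Hz zero-phase-filtered signals for
robustness and then refined on the raw signals for frame-exact timing:
a heel strike is the frame where the foot-centre height returns to its
stance baseline, a toe-off is the raw minimum of the relative forward
coordinate near the filtered candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import signal as sps

from ._signal import DEFAULT_CUTOFF_HZ, central_diff, lowpass
from .io import TrialRecording

log = logging.getLogger(__name__)

Side = Literal["left", "right"]
EventKind = Literal["heel_strike", "toe_off"]

HEEL_STRIKE: EventKind = "heel_strike"
TOE_OFF: EventKind = "toe_off"


class InsufficientGaitError(ValueError):
    """Raised when a recording contains too few gait events to analyze."""


class DegeneratePelvisError(ValueError):
    """Raised when the pelvis markers do not define a usable frame."""


@dataclass(frozen=True)
class GaitEvent:
    time: float
    frame: int
    side: Side
    kind: EventKind

    def __lt__(self, other: "GaitEvent") -> bool:
        return (self.time, self.side, self.kind) < (other.time, other.side, other.kind)


@dataclass
class GaitEventSeries:
    """Ordered, sided heel-strike / toe-off events of one trial."""

    events: list[GaitEvent] = field(default_factory=list)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of(self, side: Side | None = None, kind: EventKind | None = None) -> list[GaitEvent]:
        return [e for e in self.events
                if (side is None or e.side == side)
                and (kind is None or e.kind == kind)]

    def times(self, side: Side | None = None, kind: EventKind | None = None) -> np.ndarray:
        return np.array([e.time for e in self.of(side, kind)])

    def to_table(self):
        """Events as a pandas DataFrame (time, frame, side, type), ready
        for CSV/JSON export."""
        import pandas as pd
        return pd.DataFrame([{"time": e.time, "frame": e.frame,
                              "side": e.side, "type": e.kind}
                             for e in self.events])

    def validate(self) -> None:
        """Check strictly increasing times and per-side HS/TO alternation."""
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times are not strictly increasing")
        for side in ("left", "right"):
            kinds = [e.kind for e in self.of(side)]
            for a, b in zip(kinds, kinds[1:]):
                if a == b:
                    raise ValueError(f"{side} events do not alternate HS/TO")


@dataclass
class PelvisFrame:
    """Per-frame pelvis origin and horizontal progression axes.

    ``forward``/``lateral`` are unit, orthogonal, horizontal; lateral points
    to the subject's left (RASI towards LASI), forward = vertical x lateral.
    """

    origin: np.ndarray    # (n, 3)
    forward: np.ndarray   # (n, 3), unit, horizontal
    lateral: np.ndarray   # (n, 3), unit, horizontal


def pelvis_frame(recording: TrialRecording) -> PelvisFrame:
    """Build the pelvis-local progression frame from the four iliac markers."""
    recording.require("LASI", "RASI", "LPSI", "RPSI")
    m = recording.markers
    origin = (m["LASI"] + m["RASI"] + m["LPSI"] + m["RPSI"]) / 4.0
    lat = m["LASI"] - m["RASI"]
    lat = lat.copy()
    lat[:, 2] = 0.0  # project to ground plane
    norms = np.linalg.norm(lat, axis=1)
    if np.any(norms < 1e-9):
        raise DegeneratePelvisError(
            "ASIS markers coincide in the horizontal plane; pelvis axes undefined")
    lat /= norms[:, None]
    up = np.array([0.0, 0.0, 1.0])
    fwd = np.cross(lat, up[None, :] * np.ones_like(lat))
    # lateral x up points forward for a left-positive lateral axis
    fwd /= np.linalg.norm(fwd, axis=1)[:, None]
    return PelvisFrame(origin=origin, forward=fwd, lateral=lat)


# ---------------------------------------------------------------------------
# candidate finding
# ---------------------------------------------------------------------------

def _candidate_minima(signal: np.ndarray, fs: float,
                      prominence_frac: float = 0.10,
                      abs_floor: float = 0.0) -> np.ndarray:
    """Local minima of ``signal`` with prominence above a fraction of its
    interquartile range (and an absolute floor)."""
    iqr = np.subtract(*np.percentile(signal, [75, 25]))
    prominence = max(prominence_frac * iqr, abs_floor)
    peaks, _ = sps.find_peaks(-signal, prominence=prominence)
    return peaks


def _refractory_thin(frames: np.ndarray, refractory_frac: float = 0.4) -> np.ndarray:
    """Thin event frames by a refractory interval of ``refractory_frac`` x
    the median inter-event spacing; the earlier frame wins."""
    frames = np.sort(np.asarray(frames, dtype=int))
    if len(frames) <= 2:
        return frames
    min_gap = refractory_frac * float(np.median(np.diff(frames)))
    kept: list[int] = []
    for f in frames:
        if not kept or f - kept[-1] >= min_gap:
            kept.append(f)
    return np.asarray(kept)


def _noise_scale(x: np.ndarray) -> float:
    """Robust per-sample noise estimate from successive differences."""
    d = np.abs(np.diff(x))
    return 1.4826 * float(np.median(d)) / np.sqrt(2.0) if len(d) else 0.0


def _foot_signals(recording: TrialRecording, frame: PelvisFrame, side: Side,
                  cutoff: float):
    heel = recording.markers[f"{'L' if side == 'left' else 'R'}_HEEL"]
    toe = recording.markers[f"{'L' if side == 'left' else 'R'}_TOE"]
    center = 0.5 * (heel + toe)
    rel = center - frame.origin
    fwd_coord = np.einsum("ij,ij->i", rel, frame.forward)
    toe_fwd = np.einsum("ij,ij->i", toe - frame.origin, frame.forward)
    return center, fwd_coord, toe_fwd


def detect_heel_strikes(recording: TrialRecording, frame: PelvisFrame | None = None,
                        cutoff: float = DEFAULT_CUTOFF_HZ,
                        sides: Sequence[Side] = ("left", "right")) -> list[GaitEvent]:
    """Heel strikes per side: minima of the filtered foot-centre vertical
    velocity, restricted to phases where the foot is not advancing relative
    to the pelvis, refined to the frame where the raw foot height returns to
    the stance baseline."""
    recording.require()
    if frame is None:
        frame = pelvis_frame(recording)
    fs = recording.sampling_rate
    events: list[GaitEvent] = []
    for side in sides:
        center, fwd_coord, _ = _foot_signals(recording, frame, side, cutoff)
        z_raw = center[:, 2]
        z_f = lowpass(z_raw, fs, cutoff)
        vz = central_diff(z_f, fs)
        v_fwd = central_diff(lowpass(fwd_coord, fs, cutoff), fs)
        if np.ptp(z_raw) < 5e-3:  # no foot lift anywhere: standing still
            continue
        cands = _candidate_minima(vz, fs, abs_floor=0.02)
        if len(cands) == 0:
            continue
        # depth gate: true landings share the trial's steepest descent rate;
        # filter ripple and noise produce only shallow minima.  The third-
        # deepest candidate is the reference so an edge transient cannot
        # shift the gate.
        depths = np.sort(vz[cands])
        deepest = float(depths[min(2, len(depths) - 1)])
        cands = _refractory_thin(cands[vz[cands] < 0.45 * deepest])
        baseline = float(np.percentile(z_raw, 5))
        thr = baseline + max(2e-3, 4 * _noise_scale(z_raw))
        win = max(3, int(round(0.15 * fs)))
        ahead = max(2, int(round(0.10 * fs)))
        n = len(z_raw)
        contacts: list[int] = []
        for c in cands:
            lo, hi = max(0, c - win), min(n, c + win + 1)
            seg = z_raw[lo:hi]
            airborne = np.nonzero(seg > thr)[0]
            if len(airborne) == 0:
                continue
            contact = lo + airborne[-1] + 1
            if contact >= n or contact in contacts:
                continue
            # forward gate: once in stance the foot recedes relative to the
            # advancing pelvis (forward velocity below the zero threshold)
            post = v_fwd[contact + 1:contact + 1 + ahead]
            if len(post) == 0 or post.mean() >= 0.0:
                continue
            contacts.append(contact)
            events.append(GaitEvent(time=contact / fs, frame=int(contact),
                                    side=side, kind=HEEL_STRIKE))
    return sorted(events)


def detect_toe_offs(recording: TrialRecording, frame: PelvisFrame | None = None,
                    cutoff: float = DEFAULT_CUTOFF_HZ,
                    sides: Sequence[Side] = ("left", "right")) -> list[GaitEvent]:
    """Toe-offs per side: minima (most negative) of the toe marker's forward
    coordinate in the pelvis frame, refined to the raw-coordinate minimum
    near the filtered candidate."""
    recording.require()
    if frame is None:
        frame = pelvis_frame(recording)
    fs = recording.sampling_rate
    events: list[GaitEvent] = []
    for side in sides:
        _, _, toe_fwd = _foot_signals(recording, frame, side, cutoff)
        filt = lowpass(toe_fwd, fs, cutoff)
        if np.ptp(toe_fwd) < 5e-3:
            continue
        cands = _refractory_thin(_candidate_minima(filt, fs, abs_floor=1e-3))
        win = max(3, int(round(0.12 * fs)))
        n = len(toe_fwd)
        for c in cands:
            lo, hi = max(0, c - win), min(n, c + win + 1)
            refined = lo + int(np.argmin(toe_fwd[lo:hi]))
            if refined in (0, n - 1):  # boundary, not a true local minimum
                continue
            events.append(GaitEvent(time=refined / fs, frame=int(refined),
                                    side=side, kind=TOE_OFF))
    return sorted(events)


def merge_and_validate(hs_events: Iterable[GaitEvent],
                       to_events: Iterable[GaitEvent]) -> GaitEventSeries:
    """Merge heel strikes and toe-offs into a validated series.

    Per side, types must alternate; when two consecutive events of one side
    share a type, the later one is dropped and logged.  Fewer than two heel
    strikes overall is an error ("insufficient gait").
    """
    merged = sorted(list(hs_events) + list(to_events))
    kept: list[GaitEvent] = []
    last_kind: dict[Side, EventKind] = {}
    for ev in merged:
        if last_kind.get(ev.side) == ev.kind:
            log.warning("dropping duplicated %s %s at t=%.3fs", ev.side, ev.kind, ev.time)
            continue
        last_kind[ev.side] = ev.kind
        kept.append(ev)
    series = GaitEventSeries(kept)
    if len(series.of(kind=HEEL_STRIKE)) < 2:
        raise InsufficientGaitError("insufficient gait: fewer than 2 heel strikes")
    series.validate()
    return series


def detect_events(recording: TrialRecording,
                  cutoff: float = DEFAULT_CUTOFF_HZ) -> GaitEventSeries:
    """Convenience: pelvis frame + both detectors + merge."""
    frame = pelvis_frame(recording)
    return merge_and_validate(
        detect_heel_strikes(recording, frame, cutoff),
        detect_toe_offs(recording, frame, cutoff),
    )
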