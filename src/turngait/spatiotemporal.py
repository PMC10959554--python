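"""Whole-turn and per-leg spatiotemporal parameters, and trial aggregation.

Conventions
-----------
* The analysis window (last toe-off before turn onset to first heel strike
  after turn offset) selects which events and gait cycles are analyzed.
* Whole-turn duration is measured from the first to the last heel strike
  inside that window; number of steps counts the heel strikes in the closed
  window; cadence = 60*(n_steps - 1)/duration.  These three therefore
  satisfy cadence*duration/60 + 1 = n_steps identically, the internal
  consistency normative turning tables exhibit.
* Walking speed is the pelvis-centroid horizontal path arc length over the
  same first-to-last-heel-strike span divided by the duration (arc length,
  not displacement: over a 360-degree turn net displacement is ~0 while the
  subject keeps walking).
* Step length / stride width of a footfall are the components of the vector
  from the preceding contralateral footfall, taken along and perpendicular
  to the chord through the two contralateral footfalls bracketing the step.
  Width is signed: positive when the foot lands on its own anatomical side
  of the contralateral progression line, negative for a crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import GaitEvent, GaitEventSeries, HEEL_STRIKE, TOE_OFF, Side
from .io import TrialRecording
from .turns import TurnSegment

#: Per-leg per-cycle parameter names.
LEG_PARAMETERS = (
    "stride_length", "step_length", "stride_width",
    "gait_cycle", "stance", "stance_cycle_ratio", "initial_double_support",
)


@dataclass(frozen=True)
class Footfall:
    """One foot contact: the heel position at (and shortly after) a heel strike."""
    time: float
    side: Side
    x: float
    y: float

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class TurnParameters:
    """Spatiotemporal parameters of one analyzed turn.

    ``legs`` maps "internal"/"external" to per-cycle arrays for each name in
    :data:`LEG_PARAMETERS`; ``scalars()`` flattens everything into the
    canonical parameter->value mapping with per-cycle series averaged.
    """

    speed: float
    duration: float
    n_steps: int
    cadence: float
    legs: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def scalars(self) -> dict[str, float]:
        out = {"speed": self.speed, "duration": self.duration,
               "n_steps": float(self.n_steps), "cadence": self.cadence}
        for role, params in self.legs.items():
            for name, values in params.items():
                values = np.asarray(values, float)
                out[f"{name}_{role}"] = float(np.mean(values)) if values.size else np.nan
        return out


def footfall_position(recording: TrialRecording, event: GaitEvent,
                      n_average: int = 5) -> tuple[float, float]:
    """Horizontal heel position for a heel-strike event, averaged over the
    ``n_average`` frames starting at the event (the foot is stationary in
    early stance, so averaging suppresses marker noise)."""
    if event.kind != HEEL_STRIKE:
        raise ValueError("footfall_position expects a heel-strike event")
    if not (0 <= event.frame < recording.n_frames):
        raise ValueError(f"event frame {event.frame} outside recording")
    heel = recording.markers[f"{'L' if event.side == 'left' else 'R'}_HEEL"]
    # frames strictly after the event: the detected frame itself may still
    # be the last airborne sample under quantization
    start = min(event.frame + 1, recording.n_frames - 1)
    stop = min(start + n_average, recording.n_frames)
    window = heel[start:stop, :2]
    x, y = window.mean(axis=0)
    return float(x), float(y)


def footfalls_from_recording(recording: TrialRecording,
                             events: GaitEventSeries) -> list[Footfall]:
    out = []
    for ev in events.of(kind=HEEL_STRIKE):
        x, y = footfall_position(recording, ev)
        out.append(Footfall(time=ev.time, side=ev.side, x=x, y=y))
    return out


# ---------------------------------------------------------------------------
# whole-turn parameters
# ---------------------------------------------------------------------------

def path_arc_length(xy: np.ndarray) -> float:
    """Cumulative horizontal chord length of a sampled path (n, 2)."""
    if len(xy) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def whole_turn_from_events(hs_times: Sequence[float],
                           path_length: float) -> tuple[float, float, int, float]:
    """Core whole-turn computation from the heel-strike times inside the
    window and the pelvis path length spanned between the first and last of
    them.  Returns (speed, duration, n_steps, cadence)."""
    hs_times = np.sort(np.asarray(hs_times, float))
    n = len(hs_times)
    if n < 2:
        raise ValueError("analysis window contains fewer than 2 heel strikes")
    duration = float(hs_times[-1] - hs_times[0])
    cadence = 60.0 * (n - 1) / duration
    speed = path_length / duration
    return speed, duration, n, cadence


def whole_turn_parameters(recording: TrialRecording, events: GaitEventSeries,
                          segment: TurnSegment) -> tuple[float, float, int, float]:
    """(speed, duration, n_steps, cadence) for the analysis window."""
    hs = [e for e in events.of(kind=HEEL_STRIKE)
          if segment.window_start_time <= e.time <= segment.window_end_time]
    if len(hs) < 2:
        raise ValueError("analysis window contains fewer than 2 heel strikes")
    t0, t1 = hs[0].time, hs[-1].time
    f0, f1 = recording.time_to_frame(t0), recording.time_to_frame(t1)
    m = recording.markers
    centroid = (m["LASI"] + m["RASI"] + m["LPSI"] + m["RPSI"]) / 4.0
    arc = path_arc_length(centroid[f0:f1 + 1, :2])
    return whole_turn_from_events([e.time for e in hs], arc)


# ---------------------------------------------------------------------------
# per-leg parameters
# ---------------------------------------------------------------------------

def _signed_step_components(foot: Footfall, prev_contra: Footfall,
                            next_contra: Footfall) -> tuple[float, float]:
    """Step length (along the contralateral chord) and signed stride width
    (perpendicular; positive towards the foot's own anatomical side)."""
    chord = next_contra.xy - prev_contra.xy
    norm = np.linalg.norm(chord)
    if norm < 1e-9:
        raise ValueError("contralateral footfalls coincide; chord undefined")
    d = chord / norm
    r = foot.xy - prev_contra.xy
    step_length = float(r @ d)
    cross_z = float(d[0] * r[1] - d[1] * r[0])  # + = left of the chord
    side_sign = 1.0 if foot.side == "left" else -1.0
    return step_length, side_sign * cross_z


def per_leg_from_events(events: GaitEventSeries, footfalls: Sequence[Footfall],
                        segment: TurnSegment,
                        time_tol: float = 0.05) -> dict[str, dict[str, np.ndarray]]:
    """Per-cycle parameter series for the internal and external leg.

    Works from events + footfall positions only, so the same formulas apply
    to detected data and to generator ground truth.  Cycles are pairs of
    consecutive same-side heel strikes that both fall inside the analysis
    window; footfalls outside the window still serve as step brackets.
    """

    def match_footfall(side: Side, time: float) -> Footfall | None:
        best = None
        for ff in footfalls:
            if ff.side == side and abs(ff.time - time) <= time_tol:
                if best is None or abs(ff.time - time) < abs(best.time - time):
                    best = ff
        return best

    out: dict[str, dict[str, np.ndarray]] = {}
    for role in ("internal", "external"):
        side: Side = getattr(segment, f"{role}_side")
        contra: Side = "left" if side == "right" else "right"
        hs_all = events.of(side, HEEL_STRIKE)
        to_own = events.times(side, TOE_OFF)
        to_contra = events.times(contra, TOE_OFF)
        ff_contra = sorted([f for f in footfalls if f.side == contra],
                           key=lambda f: f.time)
        series: dict[str, list[float]] = {name: [] for name in LEG_PARAMETERS}
        in_win = [e for e in hs_all
                  if segment.window_start_time <= e.time <= segment.window_end_time]
        for hs_a, hs_b in zip(in_win, in_win[1:]):
            cycle = hs_b.time - hs_a.time
            own_to = to_own[(to_own > hs_a.time) & (to_own < hs_b.time)]
            contra_to = to_contra[(to_contra > hs_a.time) & (to_contra < hs_b.time)]
            if len(own_to) == 0 or len(contra_to) == 0:
                continue
            stance = float(own_to[0] - hs_a.time)
            idbs = float(contra_to[0] - hs_a.time)
            fa = match_footfall(side, hs_a.time)
            fb = match_footfall(side, hs_b.time)
            prev_c = max((f for f in ff_contra if f.time < hs_a.time),
                         key=lambda f: f.time, default=None)
            next_c = min((f for f in ff_contra if f.time > hs_a.time),
                         key=lambda f: f.time, default=None)
            series["gait_cycle"].append(cycle)
            series["stance"].append(stance)
            series["stance_cycle_ratio"].append(100.0 * stance / cycle)
            series["initial_double_support"].append(idbs)
            if fa is not None and fb is not None:
                series["stride_length"].append(
                    float(np.linalg.norm(fb.xy - fa.xy)))
            if fa is not None and prev_c is not None and next_c is not None:
                sl, sw = _signed_step_components(fa, prev_c, next_c)
                series["step_length"].append(sl)
                series["stride_width"].append(sw)
        out[role] = {name: np.asarray(vals) for name, vals in series.items()}
    return out


def per_leg_parameters(recording: TrialRecording, events: GaitEventSeries,
                       segment: TurnSegment) -> dict[str, dict[str, np.ndarray]]:
    """Per-cycle series for the internal and external leg of one trial."""
    footfalls = footfalls_from_recording(recording, events)
    return per_leg_from_events(events, footfalls, segment)


def turn_parameters(recording: TrialRecording, events: GaitEventSeries,
                    segment: TurnSegment) -> TurnParameters:
    """All spatiotemporal parameters of one analyzed turn."""
    speed, duration, n, cadence = whole_turn_parameters(recording, events, segment)
    legs = per_leg_parameters(recording, events, segment)
    return TurnParameters(speed=speed, duration=duration, n_steps=n,
                          cadence=cadence, legs=legs)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class SubjectConditionSummary:
    """Across-trial mean and within-subject SD per parameter for one
    subject x condition cell."""
    n_trials: int
    mean: dict[str, float]
    sd: dict[str, float]


def summarize_trials(trial_parameters: Sequence[TurnParameters]) -> SubjectConditionSummary:
    """Aggregate one subject's trials of one condition.

    Per-cycle series are averaged within each trial first; the mean and the
    within-subject SD (sample SD, n-1 denominator) are then taken across
    trials.  With a single trial the SD is reported as NaN.
    """
    if not trial_parameters:
        raise ValueError("no trials to summarize")
    rows = [tp.scalars() for tp in trial_parameters]
    keys = sorted({k for row in rows for k in row})
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for key in keys:
        vals = np.array([row[key] for row in rows if key in row and np.isfinite(row[key])])
        mean[key] = float(np.mean(vals)) if vals.size else np.nan
        sd[key] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
    return SubjectConditionSummary(n_trials=len(rows), mean=mean, sd=sd)


def bootstrap_ci(values: Sequence[float], level: float = 0.95,
                 n_boot: int = 10_000, seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("bootstrap CI needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
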