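"""Synthetic walk-turn-walk trials with exact ground truth.

The generator lays out a walking path (straight approach, circular turn
arc, straight exit), places alternating footfalls at equal arc length along
it, and builds marker trajectories around them:

* each foot is exactly stationary while in stance (flat, rigid heel-toe
  pair) and translates along the path during swing with a smooth arc-length
  profile and a sinusoidal vertical lift;
* the pelvis centroid moves along the path at the constant speed
  step_length / step_interval, its yaw locked to the path tangent, so the
  total yaw change equals the turn amplitude;
* the four iliac markers form a rigid rectangle around the centroid.

Because contact and lift times are knots of the construction, the ground
truth (event times, footfall positions, and the turn parameters they imply)
is exact, which makes every downstream stage testable without recorded
data.  The swing progression keeps a small forward speed at its endpoints
(1.2x the pelvis speed) so the coordinate-based toe-off extremum and the
velocity-based heel-strike extremum coincide with the true lift/contact
instants instead of lagging them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .events import GaitEvent, GaitEventSeries, HEEL_STRIKE, TOE_OFF, Side
from .io import TrialRecording
from .spatiotemporal import (Footfall, TurnParameters, per_leg_from_events,
                             whole_turn_from_events)
from .turns import TURN_RATE_THRESHOLD, TurnSegment

FOOT_LENGTH = 0.20        # heel-to-toe marker distance, m
PELVIS_WIDTH = 0.24       # ASIS-ASIS, m
PELVIS_DEPTH = 0.10       # anteroposterior, m
PELVIS_HEIGHT = 0.95      # marker height above ground, m
SWING_ENDPOINT_SPEED_RATIO = 1.2  # foot arc speed at toe-off/contact, x pelvis speed


@dataclass(frozen=True)
class GaitScenario:
    """Parameters of one synthetic walk-turn-walk trial.

    ``step_interval`` is the time between successive heel strikes of
    opposite feet; ``stance_fraction`` the stance share of the gait cycle;
    ``step_length`` the arc-length progression per step; a negative
    ``step_width_offset`` places each foot across the midline (crossover).
    """

    turn_amplitude: float = 90.0          # degrees; 0 = straight walk
    turn_direction: Literal["left", "right"] = "left"
    step_interval: float = 60.0 / 113.0   # s
    stance_fraction: float = 0.60
    step_length: float = 0.60             # m
    step_width_offset: float = 0.10       # m, signed
    turn_radius: float = 0.8              # m
    approach_length: float = 5.0          # m
    exit_length: float = 3.0              # m
    sampling_rate: float = 120.0          # Hz
    noise_sd: float = 0.0                 # m, i.i.d. Gaussian per coordinate
    swing_lift: float = 0.05              # m, peak vertical foot lift
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.step_interval <= 0:
            raise ValueError("step_interval must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.stance_fraction <= 0.5:
            raise ValueError("stance_fraction <= 0.5 implies flight phases (running), "
                             "which the generator does not model")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.turn_radius <= 0:
            raise ValueError("turn_radius must be positive")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.turn_amplitude < 0:
            raise ValueError("turn_amplitude must be >= 0")
        if self.turn_direction not in ("left", "right"):
            raise ValueError("turn_direction must be 'left' or 'right'")
        arc = self.turn_radius * math.radians(self.turn_amplitude)
        if self.turn_amplitude > 0 and arc < 2 * self.step_length:
            raise ValueError(
                f"turn arc ({arc:.2f} m) shorter than two steps "
                f"({2 * self.step_length:.2f} m); increase turn_radius")

    @property
    def pelvis_speed(self) -> float:
        return self.step_length / self.step_interval

    @property
    def cycle_duration(self) -> float:
        return 2.0 * self.step_interval

    @property
    def cadence(self) -> float:
        return 60.0 / self.step_interval


@dataclass
class GroundTruth:
    """Exact construction record of one synthetic trial."""

    events: GaitEventSeries
    footfalls: list[Footfall]
    segment: TurnSegment | None           # analytic turn window, None for straight walks
    nominal_parameters: TurnParameters | None
    scenario: GaitScenario

    def event_frames(self, fs: float) -> dict[tuple[str, str], np.ndarray]:
        out: dict[tuple[str, str], np.ndarray] = {}
        for side in ("left", "right"):
            for kind in (HEEL_STRIKE, TOE_OFF):
                out[(side, kind)] = np.round(self.events.times(side, kind) * fs)
        return out


# ---------------------------------------------------------------------------
# path geometry
# ---------------------------------------------------------------------------

class _WalkPath:
    """Straight-arc-straight path parameterized by arc length; the first and
    last straights extrapolate beyond their ends so feet can be pre-placed
    before the recording starts."""

    def __init__(self, scenario: GaitScenario):
        A = scenario.approach_length
        R = scenario.turn_radius
        amp = math.radians(scenario.turn_amplitude)
        d = 1.0 if scenario.turn_direction == "left" else -1.0
        self.s_arc0 = A
        self.arc_len = R * amp
        self.s_arc1 = A + self.arc_len
        self.total = self.s_arc1 + scenario.exit_length
        self.R, self.d, self.amp = R, d, amp
        # approach along +x from the origin
        self.center = np.array([A, d * R])
        self.exit_heading = d * amp
        phi1 = -d * math.pi / 2 + d * amp
        self.arc_end = self.center + R * np.array([math.cos(phi1), math.sin(phi1)])

    def heading(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, float)
        h = np.zeros_like(s)
        on_arc = (s >= self.s_arc0) & (s <= self.s_arc1)
        after = s > self.s_arc1
        h[on_arc] = self.d * (s[on_arc] - self.s_arc0) / self.R
        h[after] = self.exit_heading
        return h

    def point(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, float))
        xy = np.empty((len(s), 2))
        before = s < self.s_arc0
        on_arc = (s >= self.s_arc0) & (s <= self.s_arc1)
        after = s > self.s_arc1
        xy[before] = np.stack([s[before], np.zeros(before.sum())], axis=1)
        phi = -self.d * math.pi / 2 + self.d * (s[on_arc] - self.s_arc0) / self.R
        xy[on_arc] = self.center + self.R * np.stack([np.cos(phi), np.sin(phi)], axis=1)
        ds = s[after] - self.s_arc1
        ca, sa = math.cos(self.exit_heading), math.sin(self.exit_heading)
        xy[after] = self.arc_end + np.stack([ds * ca, ds * sa], axis=1)
        return xy

    def normal(self, s: np.ndarray) -> np.ndarray:
        """Left-pointing unit normal."""
        h = self.heading(np.atleast_1d(s))
        return np.stack([-np.sin(h), np.cos(h)], axis=1)

    def tangent(self, s: np.ndarray) -> np.ndarray:
        h = self.heading(np.atleast_1d(s))
        return np.stack([np.cos(h), np.sin(h)], axis=1)


def _side_of(k: int) -> Side:
    return "right" if k % 2 == 0 else "left"


def _lateral_offset(scenario: GaitScenario, side: Side) -> float:
    half = scenario.step_width_offset / 2.0
    return half if side == "left" else -half


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _swing_progress(u: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Normalized arc-length progress through swing, 0 -> 1.

    Linear + cosine blend whose endpoint slope gives the foot
    SWING_ENDPOINT_SPEED_RATIO x the pelvis speed at toe-off and contact.
    """
    a = SWING_ENDPOINT_SPEED_RATIO * (1.0 - stance_fraction)
    return a * u + (1.0 - a) * 0.5 * (1.0 - np.cos(np.pi * u))


def _foot_marker_tracks(scenario: GaitScenario, path: _WalkPath,
                        times: np.ndarray, contacts: dict[int, float],
                        s_of_k: dict[int, float], side: Side
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Heel and toe tracks (n, 3) for one foot."""
    tau, sf = scenario.step_interval, scenario.stance_fraction
    stance_dur = sf * scenario.cycle_duration
    ks = sorted(k for k in contacts if _side_of(k) == side)
    lat = _lateral_offset(scenario, side)

    heel = np.empty((len(times), 3))
    toe = np.empty((len(times), 3))

    def place(mask: np.ndarray, s: np.ndarray, z: np.ndarray,
              heading_s: np.ndarray) -> None:
        pts = path.point(s) + path.normal(s) * lat
        heel[mask, :2] = pts
        heel[mask, 2] = z
        t_hat = np.stack([np.cos(heading_s), np.sin(heading_s)], axis=1)
        toe[mask, :2] = pts + FOOT_LENGTH * t_hat
        toe[mask, 2] = z

    for i, k in enumerate(ks):
        t_on = contacts[k]
        next_k = ks[i + 1] if i + 1 < len(ks) else None
        t_off = t_on + stance_dur if next_k is not None else np.inf
        t_next = contacts[next_k] if next_k is not None else np.inf
        # stance: include everything from this contact up to lift
        mask = (times >= t_on) & (times < min(t_off, t_next))
        if i == 0:
            mask |= times < t_on  # pre-placed before first recorded contact
        if mask.any():
            s_k = np.full(mask.sum(), s_of_k[k])
            place(mask, s_k, np.zeros(mask.sum()),
                  path.heading(np.full(mask.sum(), s_of_k[k])))
        if next_k is None:
            continue  # final stance holds to the end of the recording
        # swing
        mask = (times >= t_off) & (times < t_next)
        if mask.any():
            u = (times[mask] - t_off) / (t_next - t_off)
            rho = _swing_progress(u, sf)
            s = s_of_k[k] + (s_of_k[next_k] - s_of_k[k]) * rho
            z = scenario.swing_lift * np.sin(np.pi * u)
            place(mask, s, z, path.heading(s))
    return heel, toe


def generate_trial(scenario: GaitScenario) -> tuple[TrialRecording, GroundTruth]:
    """Generate one synthetic trial and its exact ground truth."""
    path = _WalkPath(scenario)
    L, tau = scenario.step_length, scenario.step_interval
    sf, fs = scenario.stance_fraction, scenario.sampling_rate
    v = scenario.pelvis_speed
    stance_dur = sf * scenario.cycle_duration

    K = int(math.floor((path.total - L) / L))
    if K < 3:
        raise ValueError("path too short for a gait trial; "
                         "increase approach/exit length or reduce step_length")
    # contacts: s_k = (k+1) L at t_k = k tau; k = -2, -1 pre-place the feet
    contacts = {k: k * tau for k in range(-2, K + 1)}
    s_of_k = {k: (k + 1) * L for k in contacts}
    t_end = K * tau + tau / 2.0
    n_frames = int(math.floor(t_end * fs)) + 1
    times = np.arange(n_frames) / fs

    markers: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        heel, toe = _foot_marker_tracks(scenario, path, times, contacts, s_of_k, side)
        prefix = "L" if side == "left" else "R"
        markers[f"{prefix}_HEEL"] = heel
        markers[f"{prefix}_TOE"] = toe

    s_p = L / 2.0 + v * times
    centroid = path.point(s_p)
    psi = path.heading(s_p)
    f_hat = np.stack([np.cos(psi), np.sin(psi)], axis=1)
    l_hat = np.stack([-np.sin(psi), np.cos(psi)], axis=1)
    hw, hd = PELVIS_WIDTH / 2.0, PELVIS_DEPTH / 2.0
    for name, (af, al) in {"LASI": (hd, hw), "RASI": (hd, -hw),
                           "LPSI": (-hd, hw), "RPSI": (-hd, -hw)}.items():
        xy = centroid + af * f_hat + al * l_hat
        markers[name] = np.column_stack([xy, np.full(n_frames, PELVIS_HEIGHT)])

    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, scenario.noise_sd, markers[name].shape)

    recording = TrialRecording(
        sampling_rate=fs, markers=markers,
        metadata={"turn_amplitude": scenario.turn_amplitude,
                  "turn_direction": scenario.turn_direction,
                  "synthetic": True})

    # --- ground truth ----------------------------------------------------
    events: list[GaitEvent] = []
    for k in range(1, K + 1):  # contact 0 happens at frame 0, descent unrecorded
        t = contacts[k]
        events.append(GaitEvent(time=t, frame=int(round(t * fs)),
                                side=_side_of(k), kind=HEEL_STRIKE))
    for k in range(-1, K - 1):  # toe-off requires a following same-side contact
        t = contacts[k] + stance_dur
        if t <= 2.0 / fs:
            continue
        events.append(GaitEvent(time=t, frame=int(round(t * fs)),
                                side=_side_of(k), kind=TOE_OFF))
    truth_events = GaitEventSeries(sorted(events))

    footfalls = []
    for k in range(-1, K + 1):
        s_k = s_of_k[k]
        xy = (path.point(np.array([s_k]))
              + path.normal(np.array([s_k])) * _lateral_offset(scenario, _side_of(k)))[0]
        footfalls.append(Footfall(time=contacts[k], side=_side_of(k),
                                  x=float(xy[0]), y=float(xy[1])))

    segment = nominal = None
    if scenario.turn_amplitude > 0:
        t_on = (path.s_arc0 - L / 2.0) / v
        t_off = (path.s_arc1 - L / 2.0) / v
        to_before = [e for e in truth_events.of(kind=TOE_OFF) if e.time <= t_on]
        hs_after = [e for e in truth_events.of(kind=HEEL_STRIKE) if e.time >= t_off]
        yaw_rate = math.degrees(v / scenario.turn_radius)
        if to_before and hs_after and yaw_rate > TURN_RATE_THRESHOLD:
            direction = scenario.turn_direction
            segment = TurnSegment(
                yaw_onset_time=t_on, yaw_offset_time=t_off,
                window_start_time=to_before[-1].time,
                window_end_time=hs_after[0].time,
                direction=direction,
                internal_side=direction,
                external_side="right" if direction == "left" else "left",
                amplitude_measured=scenario.turn_amplitude)
            hs_in = [e.time for e in truth_events.of(kind=HEEL_STRIKE)
                     if segment.window_start_time <= e.time <= segment.window_end_time]
            speed, duration, n, cadence = whole_turn_from_events(
                hs_in, v * (max(hs_in) - min(hs_in)))
            legs = per_leg_from_events(truth_events, footfalls, segment)
            nominal = TurnParameters(speed=speed, duration=duration,
                                     n_steps=n, cadence=cadence, legs=legs)

    truth = GroundTruth(events=truth_events, footfalls=footfalls,
                        segment=segment, nominal_parameters=nominal,
                        scenario=scenario)
    return recording, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Condition means of the scenario-level parameters for a young-adult cohort
#: turning at self-selected normal vs volitionally reduced speed.  Cadence in
#: steps/min; step length in m (walking speed x step time); stance fraction
#: dimensionless.  Keys: (speed_condition, amplitude).
DEFAULT_CONDITION_MEANS: dict[str, dict[tuple[str, int], float]] = {
    "cadence": {("normal", 90): 113.0, ("normal", 180): 111.0, ("normal", 360): 112.0,
                ("slow", 90): 93.0, ("slow", 180): 92.0, ("slow", 360): 94.0},
    "step_length": {("normal", 90): 0.600, ("normal", 180): 0.535, ("normal", 360): 0.471,
                    ("slow", 90): 0.568, ("slow", 180): 0.509, ("slow", 360): 0.460},
    "stance_fraction": {("normal", 90): 0.6031, ("normal", 180): 0.6179,
                        ("normal", 360): 0.6248, ("slow", 90): 0.6247,
                        ("slow", 180): 0.6391, ("slow", 360): 0.6439},
}

#: Between-subject and trial-to-trial SDs of the same parameters.
DEFAULT_SUBJECT_SD = {"cadence": 2.5, "step_length": 0.025, "stance_fraction": 0.005}
DEFAULT_TRIAL_SD = {"cadence": 2.9, "step_length": 0.030, "stance_fraction": 0.008}


@dataclass
class CohortDesign:
    """Cohort structure: subjects x (speed condition, amplitude) x trials.

    Per-parameter trial values are condition mean + a subject effect (drawn
    once per subject) + trial noise, and scenarios are built to realize
    them, mirroring a repeated-measures design with a subject random effect.
    """

    n_subjects: int = 10
    n_trials: int = 9
    conditions: Sequence[tuple[str, int]] = (
        ("normal", 90), ("normal", 180), ("normal", 360),
        ("slow", 90), ("slow", 180), ("slow", 360),
    )
    condition_means: dict[str, dict[tuple[str, int], float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONDITION_MEANS.items()})
    subject_effect_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBJECT_SD))
    trial_effect_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRIAL_SD))
    noise_sd: float = 0.0
    turn_radius: float = 1.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for table in (self.subject_effect_sd, self.trial_effect_sd):
            if any(v < 0 for v in table.values()):
                raise ValueError("effect SDs must be >= 0")


@dataclass
class CohortTrial:
    subject: int
    speed_condition: str
    amplitude: int
    trial: int
    scenario: GaitScenario
    recording: TrialRecording
    ground_truth: GroundTruth
    realized: dict[str, float]


def generate_cohort(design: CohortDesign) -> list[CohortTrial]:
    """Generate every trial of a cohort; bit-reproducible given the seed."""
    root = np.random.SeedSequence(design.seed)
    subj_seqs = root.spawn(design.n_subjects)
    out: list[CohortTrial] = []
    params = list(design.condition_means)
    for s, seq in enumerate(subj_seqs):
        rng = np.random.default_rng(seq)
        direction = "left" if rng.integers(2) else "right"  # fixed per subject
        subject_effect = {p: rng.normal(0.0, design.subject_effect_sd.get(p, 0.0))
                          for p in params}
        for speed_cond, amplitude in design.conditions:
            for trial in range(design.n_trials):
                value = {}
                for p in params:
                    mean = design.condition_means[p][(speed_cond, amplitude)]
                    value[p] = (mean + subject_effect[p]
                                + rng.normal(0.0, design.trial_effect_sd.get(p, 0.0)))
                noise_seed = int(rng.integers(2 ** 31))
                if design.noise_sd == 0:
                    noise_seed = None  # noise stream unused; keep trials comparable
                # keep the realized step length compatible with the
                # turn-arc >= 2 steps constraint
                max_step = min(0.9, 0.45 * design.turn_radius
                               * math.radians(amplitude)) if amplitude else 0.9
                scenario = GaitScenario(
                    turn_amplitude=float(amplitude),
                    turn_direction=direction,
                    step_interval=60.0 / value["cadence"],
                    step_length=float(np.clip(value["step_length"], 0.3, max_step)),
                    stance_fraction=float(np.clip(value["stance_fraction"], 0.52, 0.78)),
                    turn_radius=design.turn_radius,
                    noise_sd=design.noise_sd,
                    seed=noise_seed,
                )
                recording, truth = generate_trial(scenario)
                recording.metadata.update(subject=s, speed_condition=speed_cond,
                                          amplitude=amplitude, trial=trial)
                out.append(CohortTrial(subject=s, speed_condition=speed_cond,
                                       amplitude=amplitude, trial=trial,
                                       scenario=scenario, recording=recording,
                                       ground_truth=truth, realized=value))
    return out
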