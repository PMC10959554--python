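"""Spatiotemporal parameters: closed-form geometry, quantization bounds,
frame invariance, aggregation."""

import numpy as np
import pytest

from tests.conftest import rotate_recording
from turngait.events import detect_events
from turngait.spatiotemporal import (SubjectConditionSummary, TurnParameters,
                                     bootstrap_ci, footfall_position,
                                     per_leg_from_events, summarize_trials,
                                     turn_parameters, whole_turn_from_events,
                                     whole_turn_parameters)
from turngait.synthetic import GaitScenario, generate_trial
from turngait.turns import TurnSegment, detect_turn


def analyzed(scenario):
    rec, truth = generate_trial(scenario)
    events = detect_events(rec)
    seg = detect_turn(rec, events)
    return rec, truth, events, seg


# ---------------------------------------------------------------------------
# footfall localization
# ---------------------------------------------------------------------------

def test_footfall_matches_ground_truth_within_1mm(turn90_analyzed):
    _, rec, truth, events, _ = turn90_analyzed
    fs = rec.sampling_rate
    for ev in events.of(kind="heel_strike"):
        x, y = footfall_position(rec, ev)
        best = min((f for f in truth.footfalls if f.side == ev.side),
                   key=lambda f: abs(f.time - ev.time))
        assert np.hypot(x - best.x, y - best.y) < 1e-3


def test_footfall_requires_heel_strike_and_valid_frame(turn90_analyzed):
    _, rec, _, events, _ = turn90_analyzed
    to = events.of(kind="toe_off")[0]
    with pytest.raises(ValueError, match="heel-strike"):
        footfall_position(rec, to)
    from turngait.events import GaitEvent
    with pytest.raises(ValueError, match="outside"):
        footfall_position(rec, GaitEvent(1e6, 10**8, "left", "heel_strike"))


def test_footfall_averaging_reduces_noise_variance():
    """5-frame averaging on a stationary noisy heel has lower read variance
    than a single-frame read (Monte-Carlo)."""
    rng = np.random.default_rng(3)
    n_rep, sd = 400, 0.002
    single = rng.normal(0, sd, n_rep)
    averaged = rng.normal(0, sd, (n_rep, 5)).mean(axis=1)
    assert averaged.var() < single.var() * 0.5


# ---------------------------------------------------------------------------
# whole-turn parameters
# ---------------------------------------------------------------------------

def test_cadence_identity_on_reference_turning_means():
    """The (n-1)/T cadence convention reproduces the published normative
    cadences from their own printed step counts and durations."""
    assert abs(60 * (3.75 - 1) / 1.46 - 113.0) <= 1.0   # normal 90 deg
    assert abs(60 * (7.71 - 1) / 3.58 - 112.0) <= 1.0   # normal 360 deg


def test_uniform_gait_cadence_equals_step_rate(turn90_analyzed):
    sc, rec, _, events, seg = turn90_analyzed
    speed, duration, n, cadence = whole_turn_parameters(rec, events, seg)
    assert abs(cadence - sc.cadence) < 1.0  # frame quantization only


def test_cadence_duration_step_identity(turn90_analyzed):
    _, rec, _, events, seg = turn90_analyzed
    _, duration, n, cadence = whole_turn_parameters(rec, events, seg)
    assert cadence * duration / 60.0 + 1 == pytest.approx(n, abs=1e-9)


def test_whole_turn_requires_two_heel_strikes():
    with pytest.raises(ValueError, match="2 heel strikes"):
        whole_turn_from_events([1.0], 1.0)


# ---------------------------------------------------------------------------
# per-leg parameters
# ---------------------------------------------------------------------------

def test_straight_gait_closed_form_geometry():
    """Uniform straight gait with step length s and lateral offset w:
    step length = s, stride length = 2s, stride width = w for both legs."""
    s, w = 0.62, 0.11
    sc = GaitScenario(turn_amplitude=0.0, step_length=s, step_width_offset=w)
    rec, truth = generate_trial(sc)
    events = detect_events(rec)
    seg = TurnSegment(yaw_onset_time=2.0, yaw_offset_time=4.0,
                      window_start_time=1.5, window_end_time=5.0,
                      direction="left", internal_side="left",
                      external_side="right", amplitude_measured=0.0)
    from turngait.spatiotemporal import per_leg_parameters
    legs = per_leg_parameters(rec, events, seg)
    for role in ("internal", "external"):
        np.testing.assert_allclose(legs[role]["step_length"], s, atol=5e-3)
        np.testing.assert_allclose(legs[role]["stride_length"], 2 * s, atol=5e-3)
        np.testing.assert_allclose(legs[role]["stride_width"], w, atol=5e-3)


def test_crossover_gives_negative_external_stride_width():
    sc = GaitScenario(turn_amplitude=90, turn_radius=1.6, step_length=0.45,
                      step_interval=0.48, step_width_offset=-0.07)
    rec, _, events, seg = (lambda r: (r[0], r[1], r[2], r[3]))(analyzed(sc))
    from turngait.spatiotemporal import per_leg_parameters
    legs = per_leg_parameters(rec, events, seg)
    assert np.mean(legs["external"]["stride_width"]) < 0


def test_stance_ratio_recovers_configured_fraction():
    """stance fraction 0.6031 at cycle 1.0 s: stance 0.603 s and ratio
    60.31% within frame quantization."""
    sc = GaitScenario(turn_amplitude=90, turn_radius=1.2,
                      step_interval=0.5, stance_fraction=0.6031)
    rec, _, events, seg = analyzed(sc)
    tp = turn_parameters(rec, events, seg)
    got = tp.scalars()
    assert got["stance_cycle_ratio_internal"] == pytest.approx(60.31, abs=0.9)
    assert got["stance_internal"] == pytest.approx(0.6031, abs=2.5 / 120)
    assert got["gait_cycle_internal"] == pytest.approx(1.0, abs=2.0 / 120)


def test_spatial_parameters_frame_invariant(turn90_analyzed):
    """Rigid rotation + translation of the lab frame leaves every
    spatiotemporal parameter unchanged."""
    _, rec, _, _, _ = turn90_analyzed
    rot = rotate_recording(rec, 37.0, offset=(3.0, -5.0, 0.0))
    ev0, ev1 = detect_events(rec), detect_events(rot)
    s0, s1 = detect_turn(rec, ev0), detect_turn(rot, ev1)
    p0 = turn_parameters(rec, ev0, s0).scalars()
    p1 = turn_parameters(rot, ev1, s1).scalars()
    for key, v0 in p0.items():
        if np.isnan(v0):
            assert np.isnan(p1[key])
        else:
            assert p1[key] == pytest.approx(v0, abs=1e-9), key


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _tp(value):
    return TurnParameters(speed=value, duration=1.0, n_steps=3, cadence=value,
                          legs={})


def test_summarize_trials_mean_and_sd():
    out = summarize_trials([_tp(1.0), _tp(2.0), _tp(3.0)])
    assert out.mean["cadence"] == pytest.approx(2.0)
    assert out.sd["cadence"] == pytest.approx(1.0)
    same = summarize_trials([_tp(5.0)] * 4)
    assert same.sd["cadence"] == 0.0


def test_within_subject_sd_matches_c4_expectation():
    """Across many subjects the mean sample SD of n=9 trials approaches
    c4(9) * sigma (the small-sample bias of the SD)."""
    rng = np.random.default_rng(11)
    sigma, n_trials, n_subj = 2.9, 9, 400
    sds = []
    for _ in range(n_subj):
        trials = [_tp(113 + rng.normal(0, sigma)) for _ in range(n_trials)]
        sds.append(summarize_trials(trials).sd["cadence"])
    from scipy.special import gamma
    c4 = np.sqrt(2 / (n_trials - 1)) * gamma(n_trials / 2) / gamma((n_trials - 1) / 2)
    expected = c4 * sigma
    assert np.mean(sds) == pytest.approx(expected, rel=0.05)


def test_bootstrap_ci():
    lo, hi = bootstrap_ci([2.0, 2.0, 2.0], seed=0)
    assert lo == hi == 2.0
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 100)
    lo, hi = bootstrap_ci(x, seed=1)
    half = (hi - lo) / 2
    assert half == pytest.approx(1.96 / 10, rel=0.25)
    assert bootstrap_ci(x, seed=7) == bootstrap_ci(x, seed=7)
    with pytest.raises(ValueError):
        bootstrap_ci([1.0])
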