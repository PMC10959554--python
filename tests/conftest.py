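"""Shared fixtures: small synthetic trials generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from turngait.events import detect_events
from turngait.synthetic import GaitScenario, generate_trial
from turngait.turns import detect_turn


@pytest.fixture(scope="session")
def turn90():
    """Noise-free left 90-degree turn with a radius large enough that the
    analysis window holds full gait cycles for both legs."""
    scenario = GaitScenario(turn_amplitude=90, turn_radius=1.2)
    recording, truth = generate_trial(scenario)
    return scenario, recording, truth


@pytest.fixture(scope="session")
def turn90_analyzed(turn90):
    scenario, recording, truth = turn90
    events = detect_events(recording)
    segment = detect_turn(recording, events)
    return scenario, recording, truth, events, segment


@pytest.fixture(scope="session")
def turn180():
    scenario = GaitScenario(turn_amplitude=180, turn_direction="right",
                            turn_radius=1.0)
    recording, truth = generate_trial(scenario)
    return scenario, recording, truth


def rotate_recording(recording, angle_deg: float, offset=(0.0, 0.0, 0.0)):
    """Rigidly rotate (about z) and translate all markers of a recording."""
    th = np.radians(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th), 0.0],
                  [np.sin(th), np.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    from turngait.io import TrialRecording
    markers = {k: v @ R.T + np.asarray(offset) for k, v in recording.markers.items()}
    return TrialRecording(sampling_rate=recording.sampling_rate,
                          markers=markers, metadata=dict(recording.metadata))
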