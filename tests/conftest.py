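"""Shared fixtures: presets and cached noise-free synthetic trials."""

from __future__ import annotations

import numpy as np
import pytest

import spinegait as sg


@pytest.fixture(scope="session")
def presets():
    return sg.builtin_presets()


def _clean_trial(preset, n_strides):
    spec = sg.TrialSpec(
        n_strides=n_strides,
        frame_rate=100.0,
        seed=7,
        noise_enabled=False,
        jitter_enabled=False,
    )
    chain, events = sg.generate_trial(preset, spec)
    relative = sg.chain_to_relative(chain)
    segments = sg.segment_strides(events)
    duty = sg.duty_factor(events)
    return {
        "chain": chain,
        "events": events,
        "relative": relative,
        "segments": segments,
        "duty": duty,
        "preset": preset,
    }


@pytest.fixture(scope="session")
def walk_trial(presets):
    """Noise-free, jitter-free walk trial: 6 strides at 100 Hz."""
    return _clean_trial(presets["walk"], 6)


@pytest.fixture(scope="session")
def trot_trial(presets):
    """Noise-free, jitter-free trot trial: 9 strides at 100 Hz."""
    return _clean_trial(presets["trot"], 9)


def trial_mean_curve(trial, bone, dof):
    """Across-stride mean curve of one DOF of a trial fixture."""
    df = trial["relative"][bone]
    curves = [
        sg.normalize_stride(
            df["time_s"].to_numpy(), df[dof].to_numpy(), seg, trial["duty"]
        )
        for seg in trial["segments"]
    ]
    return sg.mean_curve(curves)


@pytest.fixture(scope="session")
def mean_curve_of():
    return trial_mean_curve


@pytest.fixture()
def rng():
    return np.random.default_rng(20240911)
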