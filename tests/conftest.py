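import numpy as np
import pytest

from piezokit import (
    ChannelSimSpec,
    CurrentTrace,
    MembraneSpec,
    ParticleFrame,
    StimulusEpoch,
    Trajectory,
    generate_dome_bilayer,
    generate_flat_bilayer,
)


def make_frame(positions, names=None, box=None, ids=None, frame_index=0):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return ParticleFrame(
        frame_index=frame_index,
        particle_ids=np.arange(n) if ids is None else np.asarray(ids),
        names=np.full(n, "PO4", dtype=object) if names is None else np.asarray(names, dtype=object),
        positions=positions,
        box=box,
    )


@pytest.fixture
def flat_bilayer():
    """Noise-free flat bilayer, separation 4 nm, 200 particles/leaflet."""
    spec = MembraneSpec(
        particles_per_leaflet=200, box_xy=(15.0, 15.0), leaflet_separation=4.0,
        dome_amplitude=0.0, noise_sd=0.0, seed=11,
    )
    return generate_flat_bilayer(spec)


@pytest.fixture
def dome_bilayer():
    """Noise-free dome bilayer, A = 6 nm, sigma = 5 nm."""
    spec = MembraneSpec(
        particles_per_leaflet=2000, box_xy=(40.0, 40.0), leaflet_separation=4.0,
        dome_amplitude=6.0, dome_sigma=5.0, noise_sd=0.0, seed=11,
    )
    return generate_dome_bilayer(spec)


def step_trace(amplitude=-100.0, rate=None, residual=0.0, noise_sd=0.0,
               baseline_s=0.05, pulse_s=0.2, fs=20_000.0, seed=0):
    """Trace that steps instantly to `amplitude` at onset, then optionally
    decays exponentially toward residual*amplitude."""
    n_base = round(baseline_s * fs)
    n_pulse = round(pulse_s * fs)
    t = np.arange(n_pulse) / fs
    pulse = np.full(n_pulse, float(amplitude))
    if rate is not None:
        pulse = amplitude * (residual + (1 - residual) * np.exp(-rate * t))
    current = np.concatenate([np.zeros(n_base), pulse, np.zeros(n_base)])
    if noise_sd > 0:
        current = current + np.random.default_rng(seed).normal(0, noise_sd, current.size)
    onset = n_base / fs
    return CurrentTrace(
        current=current, sampling_rate=fs,
        stimulus_epochs=[StimulusEpoch(onset, onset + pulse_s, "pulse", -20.0)],
    )


@pytest.fixture
def sim_spec():
    return ChannelSimSpec(n_channels=50, activation_tau=0.0, noise_sd=0.0, seed=0)
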