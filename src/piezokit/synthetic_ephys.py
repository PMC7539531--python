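"""Synthetic patch-current generator with exact kinetic ground truth.

Emulates multi-channel stretch-activated currents recorded in cell-attached
or excised patches: a square pressure pulse (default 0.2 s at 20 kHz) evokes
an inward current that activates with time constant ``activation_tau`` to a
peak of ``n_channels * unitary_pA * p_open(pressure)``, optionally inactivates
exponentially toward a residual plateau, and carries additive white Gaussian
noise.  Open probability follows a Boltzmann dependence on pressure-step
magnitude.  For amplitude-histogram work a two-state telegraph trace of a
single channel is generated instead, since that analysis needs level
structure rather than ensemble kinetics.

Kinetics traces are simulated at the mean-current level (the ensemble
average), so the recorded ground truth — peak, decay rate, time for 20%
decay, end/peak ratio — is exact and closed-form.  The decay clock starts at
the peak: with instantaneous activation (``activation_tau = 0``) the current
steps to the peak at pulse onset and the post-peak segment is a pure
exponential; with a finite activation time constant the rise is counted
complete once it reaches 99.9% and the inactivation envelope starts there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ephys_kinetics import (
    DEFAULT_SAMPLING_RATE_HZ,
    CurrentTrace,
    StimulusEpoch,
)

__all__ = [
    "Inactivation",
    "ChannelSimSpec",
    "PatchGroundTruth",
    "generate_patch_current",
    "generate_two_level_trace",
    "boltzmann_open_probability",
]

#: activation is treated as complete (and the inactivation clock started)
#: once the rising exponential reaches this fraction of its asymptote
ACTIVATION_COMPLETE_FRACTION = 0.999


@dataclass(frozen=True)
class Inactivation:
    """Exponential inactivation: rate (1/s) toward a residual plateau."""

    rate: float  # 1/s
    residual: float = 0.0  # fraction of peak remaining at t -> inf

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("inactivation rate must be positive")
        if not 0.0 <= self.residual <= 1.0:
            raise ValueError("residual fraction must lie in [0, 1]")


@dataclass
class ChannelSimSpec:
    """Parameters of the synthetic patch-current ensemble."""

    n_channels: int = 50
    unitary_pA: float = 1.95
    activation_tau: float = 5.0  # ms; 0 = instantaneous activation
    inactivation: Inactivation | None = None
    boltzmann: tuple[float, float] = (20.0, 5.0)  # (P_half, slope), mmHg magnitudes
    pressures: tuple[float, ...] = (-5.0, -10.0, -15.0, -20.0, -25.0, -30.0, -35.0, -40.0)
    pulse_duration: float = 0.2  # s
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    noise_sd: float = 0.0  # pA
    baseline_duration: float = 0.05  # s of pre-pulse baseline
    tail_duration: float = 0.05  # s after the pulse
    holding_potential: float = -80.0  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.unitary_pA <= 0:
            raise ValueError("unitary_pA must be positive")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.activation_tau < 0:
            raise ValueError("activation_tau must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class PatchGroundTruth:
    """Exact generated kinetics of the noise-free mean current."""

    pressure: float  # mmHg as applied (negative)
    p_open: float
    peak_pA: float  # signed, inward negative
    time_to_peak_ms: float
    decay_rate: float | None  # 1/s; None when non-inactivating
    t20_ms: float | None  # time from peak for 20% decay; None = censored
    end_over_peak: float


def boltzmann_open_probability(
    pressure_mmHg: float, p_half: float, slope: float
) -> float:
    """Open probability 1/(1+exp((P_half - |P|)/s)) on pressure magnitude."""
    return 1.0 / (1.0 + math.exp((p_half - abs(pressure_mmHg)) / slope))


def _envelope(spec: ChannelSimSpec, t_pulse: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Normalized activation/inactivation envelope over pulse-relative times.

    Returns (envelope, peak_fraction, t_peak_s): the envelope peaks at
    ``peak_fraction`` (of the asymptotic open level) at time ``t_peak_s``.
    """
    tau_s = spec.activation_tau / 1e3
    if tau_s <= 0:
        t_peak = 0.0
        rise = np.ones_like(t_pulse)
        peak_frac = 1.0
    else:
        t_peak = -tau_s * math.log(1.0 - ACTIVATION_COMPLETE_FRACTION)
        t_peak = min(t_peak, spec.pulse_duration)
        rise = 1.0 - np.exp(-t_pulse / tau_s)
        peak_frac = 1.0 - math.exp(-t_peak / tau_s)
    env = rise.copy()
    if spec.inactivation is not None:
        k, r = spec.inactivation.rate, spec.inactivation.residual
        post = t_pulse >= t_peak
        env[post] = peak_frac * (r + (1.0 - r) * np.exp(-k * (t_pulse[post] - t_peak)))
    return env, peak_frac, t_peak


def generate_patch_current(
    spec: ChannelSimSpec, pressure: float
) -> tuple[CurrentTrace, PatchGroundTruth]:
    """Generate one pressure-step trace plus its exact kinetic ground truth.

    The noise-free mean current during the pulse is
    ``-n_channels * unitary_pA * p_open(pressure) * envelope(t)`` and zero
    outside it; white Gaussian noise of sd ``noise_sd`` is added throughout.
    """
    if not math.isfinite(pressure):
        raise ValueError("pressure must be finite")
    p_half, slope = spec.boltzmann
    p_open = boltzmann_open_probability(pressure, p_half, slope)
    amp = spec.n_channels * spec.unitary_pA * p_open

    n_base = round(spec.baseline_duration * spec.sampling_rate)
    n_pulse = round(spec.pulse_duration * spec.sampling_rate)
    n_tail = round(spec.tail_duration * spec.sampling_rate)
    t_pulse = np.arange(n_pulse) / spec.sampling_rate
    env, peak_frac, t_peak = _envelope(spec, t_pulse)

    current = np.zeros(n_base + n_pulse + n_tail)
    current[n_base:n_base + n_pulse] = -amp * env
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        current += rng.normal(0.0, spec.noise_sd, size=current.size)

    onset = n_base / spec.sampling_rate
    trace = CurrentTrace(
        current=current,
        sampling_rate=spec.sampling_rate,
        stimulus_epochs=[
            StimulusEpoch(onset, onset + n_pulse / spec.sampling_rate,
                          "pulse", pressure)
        ],
        holding_potential=spec.holding_potential,
    )

    t_end = spec.pulse_duration
    if spec.inactivation is None:
        # without inactivation the envelope rises monotonically, so the true
        # peak sits at the pulse end and the trace never decays
        decay = None
        t20 = None
        eop = 1.0
        tau_s = spec.activation_tau / 1e3
        if tau_s > 0:
            t_peak = t_end
            peak_frac = 1.0 - math.exp(-t_end / tau_s)
    else:
        k, r = spec.inactivation.rate, spec.inactivation.residual
        decay = k
        if r < 0.8:
            t20_s = math.log((1.0 - r) / (0.8 - r)) / k
            t20 = t20_s * 1e3 if t_peak + t20_s <= t_end else None
        else:
            t20 = None  # plateau above 80% of peak: censored
        eop = r + (1.0 - r) * math.exp(-k * (t_end - t_peak))
    truth = PatchGroundTruth(
        pressure=pressure,
        p_open=p_open,
        peak_pA=-amp * peak_frac,
        time_to_peak_ms=t_peak * 1e3,
        decay_rate=decay,
        t20_ms=t20,
        end_over_peak=eop,
    )
    return trace, truth


def generate_two_level_trace(
    spec: ChannelSimSpec,
    open_probability: float = 0.5,
    duration_s: float = 1.0,
    mean_open_time_ms: float = 5.0,
) -> CurrentTrace:
    """Two-state telegraph trace of a single channel for histogram analysis.

    The channel switches between closed (0 pA) and open (``-unitary_pA``)
    as a discrete-time Markov chain whose stationary open probability and
    mean open dwell are as requested; Gaussian noise of sd ``noise_sd`` is
    superimposed.  Deterministic for a fixed seed.
    """
    if spec.n_channels != 1:
        raise ValueError("two-level traces model a single channel")
    if not 0.0 <= open_probability <= 1.0:
        raise ValueError("open_probability must lie in [0, 1]")
    n = round(duration_s * spec.sampling_rate)
    rng = np.random.default_rng(spec.seed)
    if open_probability in (0.0, 1.0):
        states = np.full(n, open_probability)
    else:
        dt_ms = 1e3 / spec.sampling_rate
        p_close = min(dt_ms / mean_open_time_ms, 1.0)  # open -> closed
        p_openp = p_close * open_probability / (1.0 - open_probability)
        p_openp = min(p_openp, 1.0)  # closed -> open
        u = rng.random(n)
        states = np.empty(n)
        state = 1.0 if u[0] < open_probability else 0.0
        for i in range(n):
            if state == 1.0:
                if u[i] < p_close:
                    state = 0.0
            else:
                if u[i] < p_openp:
                    state = 1.0
            states[i] = state
    current = -spec.unitary_pA * states
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, size=n)
    return CurrentTrace(
        current=current,
        sampling_rate=spec.sampling_rate,
        stimulus_epochs=[],
        holding_potential=spec.holding_potential,
    )
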