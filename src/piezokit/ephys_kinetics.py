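"""Patch-clamp current quantification for mechanically activated channels.

Metrics follow standard stretch-activated-channel analysis practice: inward
current is negative; all amplitudes are deviations from a pre-stimulus
baseline (mean of a configurable window, default 50 ms, before epoch onset).

* peak amplitude and time to peak within a stimulus epoch;
* time for the current to decay by a given fraction (default 20%) after the
  peak, linearly interpolated between samples and explicitly censored when
  the threshold is never crossed within the epoch;
* inactivation decay rate as the rate constant of a single-exponential-plus-
  offset least-squares fit to the post-peak segment, flagged absent when the
  fitted decaying amplitude is below 5% of the peak;
* end-of-recording current normalized to peak;
* all-point amplitude histograms at fixed 0.05 pA bins anchored at 0, with
  closed/open level amplitudes from a two-component Gaussian fit and the
  unitary current as the separation of the two means;
* unitary conductance from unitary current and holding potential;
* Boltzmann (sigmoid) fits of normalized peak current against pressure-step
  magnitude, yielding the half-maximal pressure P_1/2 and the slope factor
  (smaller slope = steeper curve = higher force sensitivity).

Stimulus pressures are suctions reported as negative mmHg; fitting is done
on pressure magnitudes and P_1/2 is reported as a magnitude in mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StimulusEpoch",
    "CurrentTrace",
    "KineticsResult",
    "DecayRateResult",
    "AmplitudeHistogram",
    "PressureResponse",
    "BoltzmannFitError",
    "DEFAULT_SAMPLING_RATE_HZ",
    "DEFAULT_BIN_WIDTH_PA",
    "DEFAULT_BASELINE_WINDOW_S",
    "peak_current",
    "time_to_fraction_decay",
    "decay_rate",
    "end_over_peak",
    "amplitude_histogram",
    "unitary_conductance",
    "pressure_response",
    "boltzmann_fit",
    "analyze_epoch",
]

DEFAULT_SAMPLING_RATE_HZ = 20_000.0
DEFAULT_BIN_WIDTH_PA = 0.05
DEFAULT_BASELINE_WINDOW_S = 0.05

#: fitted decaying amplitude below this fraction of the peak counts as
#: effectively non-decaying
NON_DECAYING_AMPLITUDE_FRACTION = 0.05


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus application: [onset, offset) in seconds from trace start."""

    onset: float
    offset: float
    label: str = "pulse"
    pressure_mmHg: float | None = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("epoch offset must exceed onset")


@dataclass
class CurrentTrace:
    """Uniformly sampled current series with stimulus-epoch annotations.

    ``current`` is in pA with inward current negative; ``sampling_rate`` in
    Hz (acquisition default 20 kHz); ``holding_potential`` in mV.
    """

    current: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    stimulus_epochs: list[StimulusEpoch] = field(default_factory=list)
    holding_potential: float | None = None

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1 or self.current.size == 0:
            raise ValueError("current must be a nonempty 1D series")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration
        last_end = -math.inf
        for ep in self.stimulus_epochs:
            if ep.onset < last_end:
                raise ValueError("stimulus epochs must be ordered, non-overlapping")
            if ep.offset > dur + 1e-12:
                raise ValueError(f"epoch {ep.label!r} extends past the trace end")
            last_end = ep.offset

    @property
    def duration(self) -> float:
        return self.current.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.current.size) / self.sampling_rate

    def epoch(self, label: str) -> StimulusEpoch:
        for ep in self.stimulus_epochs:
            if ep.label == label:
                return ep
        raise KeyError(f"no stimulus epoch labelled {label!r}")

    def _slice(self, t0: float, t1: float) -> slice:
        i0 = int(np.ceil(t0 * self.sampling_rate - 1e-9))
        i1 = int(np.floor(t1 * self.sampling_rate - 1e-9)) + 1
        return slice(max(i0, 0), min(i1, self.current.size))


@dataclass
class KineticsResult:
    """Peak/decay metrics for one stimulus epoch."""

    peak_amplitude: float  # pA, signed deviation from baseline (inward < 0)
    time_to_peak: float  # ms from epoch onset
    baseline: float  # pA
    low_signal: bool = False
    decay_rate: float | None = None  # 1/s
    t20: float | None = None  # ms from peak; None when censored
    t20_censored: bool = False
    end_over_peak: float | None = None


@dataclass
class DecayRateResult:
    """Single-exponential-plus-offset fit of the post-peak segment."""

    rate: float | None  # 1/s; None when non-decaying or fit failed
    amplitude: float  # pA of the decaying component (|value|)
    offset: float  # pA residual plateau (|deviation|)
    non_decaying: bool
    fit_failed: bool = False


@dataclass
class AmplitudeHistogram:
    """All-point histogram with fitted current levels."""

    bin_edges: np.ndarray  # pA, exact multiples of the bin width
    counts: np.ndarray
    levels: tuple[float, ...]  # fitted level means, ascending (pA)
    unitary_amplitude: float | None  # |separation of the two means|, pA


@dataclass
class PressureResponse:
    """Per-pressure normalized peak currents, optionally with a sigmoid fit."""

    pressures: np.ndarray  # mmHg, signed as applied (suction negative)
    normalized_current: np.ndarray  # anchor pressure == 1
    anchor_pressure: float
    P_half: float | None = None  # mmHg magnitude
    slope: float | None = None  # mmHg
    fit_residual: float | None = None  # rms


class BoltzmannFitError(RuntimeError):
    """Sigmoid fit could not be determined (saturated data, no convergence)."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


# ---------------------------------------------------------------------------
# Baseline & peak
# ---------------------------------------------------------------------------

def _baseline(trace: CurrentTrace, epoch: StimulusEpoch,
              window_s: float = DEFAULT_BASELINE_WINDOW_S) -> tuple[float, float]:
    """(mean, sd) of the pre-onset baseline window."""
    sl = trace._slice(max(0.0, epoch.onset - window_s), epoch.onset)
    seg = trace.current[sl]
    if seg.size == 0:
        raise ValueError("no baseline samples before epoch onset")
    return float(seg.mean()), float(seg.std())


def peak_current(
    trace: CurrentTrace,
    epoch: str | StimulusEpoch,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> KineticsResult:
    """Peak inward current amplitude and time to peak within an epoch.

    The peak is the most negative deviation from the pre-onset baseline;
    ``time_to_peak`` is measured in ms from epoch onset.  A trace whose peak
    does not exceed 3 baseline standard deviations is flagged ``low_signal``.
    """
    ep = trace.epoch(epoch) if isinstance(epoch, str) else epoch
    sl = trace._slice(ep.onset, ep.offset)
    if sl.stop - sl.start < 2:
        raise ValueError("epoch shorter than 2 samples")
    base, base_sd = _baseline(trace, ep, baseline_window_s)
    dev = trace.current[sl] - base
    idx = int(np.argmin(dev))
    peak = float(dev[idx])
    t_peak_ms = ((sl.start + idx) / trace.sampling_rate - ep.onset) * 1e3
    low = abs(peak) <= 3.0 * base_sd + 1e-12
    return KineticsResult(
        peak_amplitude=peak,
        time_to_peak=t_peak_ms,
        baseline=base,
        low_signal=low,
    )


# ---------------------------------------------------------------------------
# Decay metrics
# ---------------------------------------------------------------------------

def time_to_fraction_decay(
    trace: CurrentTrace,
    epoch: str | StimulusEpoch,
    fraction: float = 0.2,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> tuple[float | None, bool]:
    """Time (ms after the peak) for the current to decay by ``fraction``.

    Returns ``(t_ms, censored)``: the first time after the peak at which
    |current - baseline| <= (1 - fraction)*|peak|, linearly interpolated
    between samples; ``(None, True)`` when the threshold is never reached
    within the epoch.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    ep = trace.epoch(epoch) if isinstance(epoch, str) else epoch
    kin = peak_current(trace, ep, baseline_window_s)
    sl = trace._slice(ep.onset, ep.offset)
    dev = np.abs(trace.current[sl] - kin.baseline)
    peak_idx = int(np.argmax(-(trace.current[sl] - kin.baseline)))
    threshold = (1.0 - fraction) * abs(kin.peak_amplitude)
    post = dev[peak_idx:]
    below = np.nonzero(post <= threshold)[0]
    if below.size == 0:
        return None, True
    j = int(below[0])
    dt_samples = float(j)
    if j > 0:
        y0, y1 = post[j - 1], post[j]
        if y0 > threshold >= y1 and y0 != y1:
            dt_samples = (j - 1) + (y0 - threshold) / (y0 - y1)
    return dt_samples / trace.sampling_rate * 1e3, False


def decay_rate(
    trace: CurrentTrace,
    epoch: str | StimulusEpoch,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> DecayRateResult:
    """Rate constant (1/s) of the post-peak single-exponential decay.

    Fits |deviation|(t) = offset + amplitude * exp(-rate * t) from the peak
    to the epoch end.  The result is flagged ``non_decaying`` (rate ``None``)
    when the fitted amplitude is below 5% of the peak, and ``fit_failed``
    (never raising) when the optimizer does not converge.
    """
    ep = trace.epoch(epoch) if isinstance(epoch, str) else epoch
    kin = peak_current(trace, ep, baseline_window_s)
    sl = trace._slice(ep.onset, ep.offset)
    dev = np.abs(trace.current[sl] - kin.baseline)
    peak_idx = int(np.argmax(dev))
    y = dev[peak_idx:]
    if y.size < 10:
        raise ValueError("need >= 10 samples between peak and epoch offset")
    t = np.arange(y.size) / trace.sampling_rate
    peak_abs = abs(kin.peak_amplitude)

    def model(tt, offset, amplitude, rate):
        return offset + amplitude * np.exp(-rate * tt)

    # initial guesses: plateau from the tail, rate from the half-drop time
    offset0 = float(y[-max(1, y.size // 10):].mean())
    amp0 = max(peak_abs - offset0, 1e-6)
    half_level = offset0 + amp0 / 2.0
    below = np.nonzero(y <= half_level)[0]
    rate0 = math.log(2.0) / max(t[below[0]], t[1]) if below.size else 1.0 / max(t[-1], 1e-6)
    try:
        popt, _ = curve_fit(
            model, t, y,
            p0=[offset0, amp0, rate0],
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return DecayRateResult(
            rate=None, amplitude=0.0, offset=offset0,
            non_decaying=False, fit_failed=True,
        )
    offset, amplitude, rate = (float(v) for v in popt)
    if amplitude < NON_DECAYING_AMPLITUDE_FRACTION * peak_abs:
        return DecayRateResult(
            rate=None, amplitude=amplitude, offset=offset, non_decaying=True
        )
    return DecayRateResult(
        rate=rate, amplitude=amplitude, offset=offset, non_decaying=False
    )


def end_over_peak(
    trace: CurrentTrace,
    epoch: str | StimulusEpoch,
    end_window: tuple[float, float],
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> float:
    """Mean |current - baseline| over ``end_window`` divided by |peak|.

    ``end_window`` is (start_s, end_s) in trace time, inside the epoch and
    after the peak; quantifies the residual (non-inactivated) current.
    """
    ep = trace.epoch(epoch) if isinstance(epoch, str) else epoch
    kin = peak_current(trace, ep, baseline_window_s)
    t_peak_s = ep.onset + kin.time_to_peak / 1e3
    w0, w1 = end_window
    if not (ep.onset <= w0 < w1 <= ep.offset + 1e-12) or w0 < t_peak_s - 1e-12:
        raise ValueError("end_window must lie inside the epoch, after the peak")
    sl = trace._slice(w0, w1)
    seg = np.abs(trace.current[sl] - kin.baseline)
    if seg.size == 0:
        raise ValueError("end_window holds no samples")
    if kin.peak_amplitude == 0:
        raise ValueError("peak amplitude is zero; ratio undefined")
    return float(seg.mean() / abs(kin.peak_amplitude))


def analyze_epoch(
    trace: CurrentTrace,
    epoch: str | StimulusEpoch,
    fraction: float = 0.2,
    end_window: tuple[float, float] | None = None,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> KineticsResult:
    """Convenience bundle: peak, t20, decay rate and (optionally) end/peak."""
    ep = trace.epoch(epoch) if isinstance(epoch, str) else epoch
    kin = peak_current(trace, ep, baseline_window_s)
    kin.t20, kin.t20_censored = time_to_fraction_decay(
        trace, ep, fraction, baseline_window_s
    )
    dr = decay_rate(trace, ep, baseline_window_s)
    kin.decay_rate = dr.rate
    if end_window is None:
        end_window = (max(ep.offset - 0.02, ep.onset + kin.time_to_peak / 1e3), ep.offset)
    kin.end_over_peak = end_over_peak(trace, ep, end_window, baseline_window_s)
    return kin


# ---------------------------------------------------------------------------
# Amplitude histogram & unitary conductance
# ---------------------------------------------------------------------------

def amplitude_histogram(
    trace: CurrentTrace | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH_PA,
    random_state: int = 0,
) -> AmplitudeHistogram:
    """All-point amplitude histogram with two-component Gaussian level fit.

    Bins are left-closed, width ``bin_width`` (default 0.05 pA), with edges
    at exact multiples of the bin width anchored at 0.  Level amplitudes are
    the means of a two-component Gaussian mixture fitted to the raw samples
    (closed + open channel); the unitary amplitude is the separation of the
    two means.  When the distribution is effectively unimodal (one-component
    fit preferred by BIC, or a degenerate second component) a single level is
    returned and the open level is absent.
    """
    values = trace.current if isinstance(trace, CurrentTrace) else np.asarray(trace, float)
    if values.size < 1000:
        raise ValueError("amplitude histogram needs >= 1000 samples")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = math.floor(values.min() / bin_width)
    hi = math.ceil(values.max() / bin_width)
    if hi == lo:
        hi = lo + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)

    if float(values.std()) < 1e-12:
        level = float(values.mean())
        return AmplitudeHistogram(edges, counts, (level,), None)

    from sklearn.mixture import GaussianMixture

    x = values.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=random_state).fit(x)
    gm2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(x)
    means2 = np.sort(gm2.means_.ravel())
    weights2 = gm2.weights_.ravel()
    unimodal = (
        gm1.bic(x) <= gm2.bic(x)
        or weights2.min() < 0.02
        or abs(means2[1] - means2[0]) < bin_width
    )
    if unimodal:
        return AmplitudeHistogram(edges, counts, (float(gm1.means_[0, 0]),), None)
    return AmplitudeHistogram(
        edges, counts,
        tuple(float(m) for m in means2),
        float(means2[1] - means2[0]),
    )


def unitary_conductance(amplitude_pA: float, holding_mV: float) -> float:
    """Unitary conductance in pS from unitary current and holding potential.

    gamma = 1000 * |i| / |V| with i in pA and V in mV, e.g. 1.95 pA at
    -80 mV gives 24.375 pS (the ~25 pS signature of PIEZO1 channels).
    """
    if holding_mV == 0:
        raise ValueError("holding potential must be nonzero")
    return 1000.0 * abs(amplitude_pA) / abs(holding_mV)


# ---------------------------------------------------------------------------
# Pressure-response curve & Boltzmann fit
# ---------------------------------------------------------------------------

def pressure_response(
    peaks_by_pressure: dict[float, float],
    anchor_pressure: float = -40.0,
) -> PressureResponse:
    """Normalize per-pressure peak amplitudes to the anchor pressure's peak.

    ``peaks_by_pressure`` maps applied pressure (mmHg, suction negative) to
    the peak current amplitude (pA, sign ignored).  Requires >= 4 distinct
    pressures including the anchor (the maximal-magnitude step, by protocol
    the saturating -40 mmHg).
    """
    if len(peaks_by_pressure) < 4:
        raise ValueError("need >= 4 distinct pressures")
    if anchor_pressure not in peaks_by_pressure:
        raise ValueError(f"anchor pressure {anchor_pressure} mmHg missing")
    anchor_amp = abs(peaks_by_pressure[anchor_pressure])
    if anchor_amp == 0:
        raise ValueError("anchor peak amplitude is zero")
    pressures = np.array(sorted(peaks_by_pressure, key=abs))
    normalized = np.array([abs(peaks_by_pressure[p]) / anchor_amp for p in pressures])
    return PressureResponse(
        pressures=pressures,
        normalized_current=normalized,
        anchor_pressure=float(anchor_pressure),
    )


def _boltzmann(p_mag: np.ndarray, p_half: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((p_half - p_mag) / slope))


def boltzmann_fit(pr: PressureResponse) -> PressureResponse:
    """Fit f(P) = 1 / (1 + exp((P_1/2 - P)/s)) on pressure magnitudes.

    Returns a copy of ``pr`` with ``P_half`` (mmHg magnitude), ``slope`` s
    (mmHg; smaller = steeper = more force-sensitive) and the rms residual
    filled in.  Raises :class:`BoltzmannFitError` on saturated data (all
    points near one level, midpoint undetermined) or non-convergence, with
    the residuals attached.
    """
    p_mag = np.abs(pr.pressures)
    y = np.asarray(pr.normalized_current, dtype=float)
    if p_mag.size < 4:
        raise ValueError("need >= 4 points for a sigmoid fit")
    if y.max() - y.min() < 0.1:
        raise BoltzmannFitError(
            "response range too small to determine a midpoint (saturated data)",
            residuals=y - y.mean(),
        )
    # initial midpoint: pressure where the response crosses half its range
    half = (y.max() + y.min()) / 2.0
    order = np.argsort(p_mag)
    p_half0 = float(np.interp(half, y[order], p_mag[order]))
    slope0 = max((p_mag.max() - p_mag.min()) / 8.0, 0.5)
    try:
        popt, _ = curve_fit(
            _boltzmann, p_mag, y,
            p0=[p_half0, slope0],
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise BoltzmannFitError(
            f"sigmoid fit did not converge: {exc}",
            residuals=y - _boltzmann(p_mag, p_half0, slope0),
        ) from exc
    resid = y - _boltzmann(p_mag, *popt)
    return PressureResponse(
        pressures=pr.pressures,
        normalized_current=pr.normalized_current,
        anchor_pressure=pr.anchor_pressure,
        P_half=float(popt[0]),
        slope=float(popt[1]),
        fit_residual=float(np.sqrt(np.mean(resid**2))),
    )
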