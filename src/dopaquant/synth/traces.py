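"""Synthetic stimulus-locked dopamine transients with known ground truth.

The release transient is modeled as a difference of exponentials,

    c(t) = A * k * (exp(-t/tau_decay) - exp(-t/tau_rise)),   t >= 0,

with k chosen so the peak equals A. This is a generic kinetic form for a
fast-rising, exponentially clearing transient; the quantification pipeline
makes no use of it, which keeps generated traces a fair test of metric
recovery. Uptake block (e.g. nomifensine at the dopamine transporter) is
emulated by scaling tau_decay by ``clearance_scale``. Stimulus artefacts are
single-sample rectangular spikes at each onset; noise is additive Gaussian in
the concentration domain and propagates through the calibration map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .._rng import substream
from ..traces import Trace

__all__ = ["TraceSpec", "TraceTruth", "generate_trace", "transient_kinetics"]


def transient_kinetics(
    t_s: np.ndarray, amplitude_um: float, tau_rise_s: float, tau_decay_s: float
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials transient evaluated at t (s)."""
    if not 0 < tau_rise_s < tau_decay_s:
        raise ValueError("require 0 < tau_rise < tau_decay")
    t = np.asarray(t_s, dtype=float)
    # peak time and normalization of the difference of exponentials
    t_peak = (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)) * math.log(
        tau_decay_s / tau_rise_s
    )
    k = 1.0 / (math.exp(-t_peak / tau_decay_s) - math.exp(-t_peak / tau_rise_s))
    out = np.where(
        t >= 0,
        amplitude_um * k * (np.exp(-np.clip(t, 0, None) / tau_decay_s)
                            - np.exp(-np.clip(t, 0, None) / tau_rise_s)),
        0.0,
    )
    return out


def transient_auc_analytic(
    amplitude_um: float, tau_rise_s: float, tau_decay_s: float, duration_s: float
) -> float:
    """Closed-form integral of the transient from 0 to duration (µM·s)."""
    t_peak = (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)) * math.log(
        tau_decay_s / tau_rise_s
    )
    k = 1.0 / (math.exp(-t_peak / tau_decay_s) - math.exp(-t_peak / tau_rise_s))
    T = duration_s
    return amplitude_um * k * (
        tau_decay_s * (1 - math.exp(-T / tau_decay_s))
        - tau_rise_s * (1 - math.exp(-T / tau_rise_s))
    )


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a synthetic amperometric recording.

    Defaults reflect the recording conditions the analysis targets: 10 kHz
    sampling, millisecond-scale rise, tens-of-ms clearance, µM-scale peaks.
    """

    sampling_rate_hz: float = 10_000.0
    duration_s: float = 2.0
    stimulus_times_s: tuple[float, ...] = (0.5,)
    amplitude_um: tuple[float, ...] = (1.0,)
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 40.0
    clearance_scale: float = 1.0
    artefact_amplitude: float = 0.0  # nA, single-sample spike at each onset
    noise_sd_um: float = 0.0
    calibration_slope_na_per_um: float = 2.0
    calibration_intercept_na: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0 < self.tau_rise_ms < self.tau_decay_ms * self.clearance_scale:
            raise ValueError("require 0 < tau_rise < effective tau_decay")
        if len(self.amplitude_um) != len(self.stimulus_times_s):
            raise ValueError("one amplitude per stimulus required")
        if any(a < 0 for a in self.amplitude_um):
            raise ValueError("amplitudes must be non-negative")
        if any(t < 0 or t > self.duration_s for t in self.stimulus_times_s):
            raise ValueError("stimulus times must lie within [0, duration]")
        if self.noise_sd_um < 0:
            raise ValueError("noise sd must be non-negative")
        dt = 1.0 / self.sampling_rate_hz
        stims = sorted(self.stimulus_times_s)
        if any(b - a < dt for a, b in zip(stims, stims[1:])):
            raise ValueError(
                "stimulus/artefact windows closer than one sample period would alias"
            )

    @property
    def effective_tau_decay_ms(self) -> float:
        return self.tau_decay_ms * self.clearance_scale


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth computed from the noiseless concentration trace.

    Rise times and peaks come from dense numerical evaluation of the kinetic
    form (25x oversampled relative to acquisition), independent of the
    analysis code path.
    """

    true_peak_um: tuple[float, ...]
    true_rise_time_20_80_ms: tuple[float, ...]
    true_auc_um_s: float
    auc_window_s: tuple[float, float]
    noiseless_trace: Trace = field(repr=False)


def _dense_transient_truth(spec: TraceSpec, oversample: int = 25):
    """Per-stimulus peak and 20-80% rise time on a dense grid (noise-free).

    Evaluated on the full superposed trace so summation during trains is
    reflected; local baseline is the superposed level just before each onset.
    """
    tau_r = spec.tau_rise_ms / 1e3
    tau_d = spec.effective_tau_decay_ms / 1e3
    dt = 1.0 / (spec.sampling_rate_hz * oversample)
    t = np.arange(0.0, spec.duration_s + dt / 2, dt)
    dense = np.zeros_like(t)
    for onset, amp in zip(spec.stimulus_times_s, spec.amplitude_um):
        dense += transient_kinetics(t - onset, amp, tau_r, tau_d)
    peaks, rises = [], []
    onsets = sorted(spec.stimulus_times_s)
    for i, onset in enumerate(onsets):
        w_end = onsets[i + 1] if i + 1 < len(onsets) else spec.duration_s
        sel = (t >= onset) & (t <= w_end)
        seg, tseg = dense[sel], t[sel]
        local_base = dense[np.searchsorted(t, onset) - 1] if onset > 0 else 0.0
        rel = seg - local_base
        peak = float(np.max(rel))
        peaks.append(peak)
        if peak > 0:
            i20 = int(np.argmax(rel >= 0.2 * peak))
            i80 = int(np.argmax(rel >= 0.8 * peak))
            rises.append(float((tseg[i80] - tseg[i20]) * 1e3))
        else:
            rises.append(float("nan"))
    return tuple(peaks), tuple(rises), t, dense


def generate_trace(spec: TraceSpec) -> tuple[Trace, Trace, TraceTruth]:
    """Render a synthetic recording.

    Returns
    -------
    current : Trace in nA
        slope * (concentration + noise) + intercept + artefact spikes.
    concentration : Trace in µM, noiseless
        The clean concentration signal the metrics should recover.
    truth : TraceTruth
        Per-stimulus peak and rise time, and AUC over the train window
        (from the first stimulus, 2.935 s or to the end of the trace).
    """
    rng = substream(spec.seed, "synth.trace")
    n = int(round(spec.duration_s * spec.sampling_rate_hz)) + 1
    t = np.arange(n) / spec.sampling_rate_hz
    tau_r = spec.tau_rise_ms / 1e3
    tau_d = spec.effective_tau_decay_ms / 1e3

    conc = np.zeros(n)
    for onset, amp in zip(spec.stimulus_times_s, spec.amplitude_um):
        conc += transient_kinetics(t - onset, amp, tau_r, tau_d)

    noisy = conc + (rng.normal(0.0, spec.noise_sd_um, n) if spec.noise_sd_um > 0 else 0.0)
    current = spec.calibration_slope_na_per_um * noisy + spec.calibration_intercept_na
    if spec.artefact_amplitude != 0.0:
        for onset in spec.stimulus_times_s:
            idx = int(round(onset * spec.sampling_rate_hz))
            current[idx] += spec.artefact_amplitude

    peaks, rises, t_dense, dense = _dense_transient_truth(spec)
    if spec.stimulus_times_s:
        auc_start = min(spec.stimulus_times_s)
        auc_end = min(auc_start + 2.935, spec.duration_s)
        sel = (t_dense >= auc_start) & (t_dense <= auc_end)
        true_auc = float(np.trapezoid(dense[sel], t_dense[sel]))
    else:
        auc_start, auc_end, true_auc = 0.0, spec.duration_s, 0.0

    truth = TraceTruth(
        true_peak_um=peaks,
        true_rise_time_20_80_ms=rises,
        true_auc_um_s=true_auc,
        auc_window_s=(auc_start, auc_end),
        noiseless_trace=Trace(conc, spec.sampling_rate_hz, 0.0, "uM"),
    )
    current_trace = Trace(current, spec.sampling_rate_hz, 0.0, "nA",
                          meta={"seed": spec.seed})
    conc_trace = Trace(conc, spec.sampling_rate_hz, 0.0, "uM", meta={"seed": spec.seed})
    return current_trace, conc_trace, truth
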