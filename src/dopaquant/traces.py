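"""Quantification of amperometric and microdialysis time series.

Carbon-fiber amperometry reports local dopamine concentration as an oxidation
current. The operations here cover the full measurement chain used on such
recordings: electrode calibration against a dopamine concentration ladder,
current-to-concentration conversion, sweep averaging, stimulus-artefact
blanking, peak amplitude, 20-80% rise time, windowed area under the curve,
per-stimulus train amplitudes, uptake-blocker (DAT block) comparisons, KCl-puff
responses, and microdialysis normalization.

Conventions
-----------
* Traces are uniformly sampled; times are seconds, currents nA, dopamine
  concentrations µM, areas µM·s.
* Peak and AUC are baseline-corrected by default against the mean of a
  pre-stimulus window (50 ms ending 1 ms before onset unless overridden);
  the raw (non-subtracted) mode is available via ``baseline_window=None``.
* Window endpoints that fall between samples are handled by linear
  interpolation so that AUC is exactly additive over adjacent windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

__all__ = [
    "Trace",
    "Calibration",
    "StimulusTrain",
    "TrainResponse",
    "DatBlockResult",
    "fit_calibration",
    "current_to_concentration",
    "concentration_to_current",
    "average_sweeps",
    "remove_stimulus_artefacts",
    "lowpass_filter",
    "peak_amplitude",
    "rise_time_20_80",
    "area_under_curve",
    "train_amplitudes",
    "dat_block_comparison",
    "kcl_response",
    "normalize_microdialysis",
]

DEFAULT_SAMPLING_RATE_HZ = 10_000.0
DEFAULT_AUC_DURATION_S = 2.935  # train AUC window: from the 1st stimulus
DEFAULT_BASELINE_WINDOW_S = (-0.051, -0.001)  # relative to onset
KCL_WINDOW_AFTER_PUFF_S = 200.0


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled time series.

    Parameters
    ----------
    values : array of amplitudes
    sampling_rate_hz : samples per second (amperometry: 10 kHz)
    start_time_s : time of the first sample
    units : "nA" for current, "uM" for dopamine concentration
    meta : free-form provenance (e.g. the calibration used)
    """

    values: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    start_time_s: float = 0.0
    units: str = "uM"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return (self.n - 1) * self.dt

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n) * self.dt

    def value_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated value at arbitrary time(s) within the trace."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.start_time_s - 1e-12) or np.any(t > self.end_time_s + 1e-12):
            raise ValueError("time outside trace extent")
        x = (t - self.start_time_s) * self.sampling_rate_hz
        x = np.clip(x, 0, self.n - 1)
        i0 = np.floor(x).astype(int)
        i0 = np.minimum(i0, self.n - 2)
        frac = x - i0
        return self.values[i0] * (1 - frac) + self.values[i0 + 1] * frac

    def _index_range(self, t0: float, t1: float) -> tuple[int, int]:
        """Indices of samples strictly inside (t0, t1)."""
        i0 = int(math.ceil((t0 - self.start_time_s) * self.sampling_rate_hz - 1e-9))
        i1 = int(math.floor((t1 - self.start_time_s) * self.sampling_rate_hz + 1e-9))
        return max(i0, 0), min(i1, self.n - 1)

    def slice_values(self, t0: float, t1: float) -> np.ndarray:
        if t1 <= t0:
            raise ValueError("empty window")
        if t0 < self.start_time_s - 1e-12 or t1 > self.end_time_s + 1e-12:
            raise ValueError(
                f"window [{t0}, {t1}] s outside trace "
                f"[{self.start_time_s}, {self.end_time_s}] s"
            )
        i0, i1 = self._index_range(t0, t1)
        if i1 < i0:
            raise ValueError("window contains no samples")
        return self.values[i0 : i1 + 1]


@dataclass(frozen=True)
class Calibration:
    """Linear current-concentration map for a carbon-fiber electrode.

    Electrodes are calibrated by puffing dopamine standards (typically 0, 1,
    5, 10, 20 µM) and fitting plateau current against concentration; only
    electrodes with a linear relationship (high r²) are usable.
    """

    points: tuple[tuple[float, float], ...]
    slope_na_per_um: float
    intercept_na: float
    r_squared: float
    usable: bool
    r_squared_threshold: float = 0.98

    def concentration(self, current_na: np.ndarray) -> np.ndarray:
        if self.slope_na_per_um <= 0:
            raise ValueError("calibration slope must be positive to invert")
        return (np.asarray(current_na, dtype=float) - self.intercept_na) / self.slope_na_per_um

    def current(self, concentration_um: np.ndarray) -> np.ndarray:
        return self.slope_na_per_um * np.asarray(concentration_um, dtype=float) + self.intercept_na


@dataclass(frozen=True)
class StimulusTrain:
    """Ordered stimulus onsets (e.g. ten 1 ms light pulses at 10 Hz)."""

    onset_times_s: tuple[float, ...]
    pulse_duration_ms: float = 1.0

    def __post_init__(self):
        onsets = tuple(float(t) for t in self.onset_times_s)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        if self.pulse_duration_ms <= 0:
            raise ValueError("pulse duration must be positive")
        object.__setattr__(self, "onset_times_s", onsets)

    @classmethod
    def regular(cls, n: int, rate_hz: float, start_s: float = 0.0,
                pulse_duration_ms: float = 1.0) -> "StimulusTrain":
        return cls(tuple(start_s + i / rate_hz for i in range(n)), pulse_duration_ms)


@dataclass(frozen=True)
class TrainResponse:
    """Per-stimulus amplitudes of a train, raw and normalized."""

    amplitudes_um: tuple[float, ...]
    normalized: tuple[float, ...]
    reference_first_amplitude_um: float


@dataclass(frozen=True)
class DatBlockResult:
    """Windowed-area comparison before vs after DAT block (nomifensine)."""

    area_baseline_um_s: float
    area_drug_um_s: float
    subtracted_area_um_s: float
    fold_increase: float | None  # None when baseline area is not positive


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def fit_calibration(
    points: Sequence[tuple[float, float]],
    r_squared_threshold: float = 0.98,
) -> Calibration:
    """Ordinary least-squares line through (concentration µM, plateau nA) points.

    Flags the electrode unusable when the fit is not linear enough
    (r² below ``r_squared_threshold``) or the slope is not positive.
    """
    pts = [(float(c), float(i)) for c, i in points]
    conc = np.array([p[0] for p in pts])
    curr = np.array([p[1] for p in pts])
    if np.unique(conc).size < 2:
        raise ValueError("calibration needs at least 2 distinct concentrations")
    res = _stats.linregress(conc, curr)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    slope = float(res.slope)
    usable = bool(slope > 0 and r2 >= r_squared_threshold)
    return Calibration(
        points=tuple(pts),
        slope_na_per_um=slope,
        intercept_na=float(res.intercept),
        r_squared=r2,
        usable=usable,
        r_squared_threshold=r_squared_threshold,
    )


def current_to_concentration(trace: Trace, cal: Calibration) -> Trace:
    """Convert a current trace (nA) to dopamine concentration (µM)."""
    if trace.units != "nA":
        raise ValueError(f"expected a current trace in nA, got units={trace.units!r}")
    if cal.slope_na_per_um <= 0:
        raise ValueError("calibration slope must be positive")
    meta = dict(trace.meta)
    meta["calibration"] = {
        "slope_na_per_um": cal.slope_na_per_um,
        "intercept_na": cal.intercept_na,
        "r_squared": cal.r_squared,
    }
    return replace(trace, values=cal.concentration(trace.values), units="uM", meta=meta)


def concentration_to_current(trace: Trace, cal: Calibration) -> Trace:
    if trace.units != "uM":
        raise ValueError(f"expected a concentration trace in uM, got units={trace.units!r}")
    return replace(trace, values=cal.current(trace.values), units="nA")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def average_sweeps(traces: Sequence[Trace]) -> Trace:
    """Pointwise mean of repeated sweeps (equal length, rate and units)."""
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for t in traces[1:]:
        if t.n != first.n:
            raise ValueError("sweeps differ in length")
        if t.sampling_rate_hz != first.sampling_rate_hz:
            raise ValueError("sweeps differ in sampling rate")
        if t.units != first.units:
            raise ValueError("sweeps differ in units")
    mean = np.mean([t.values for t in traces], axis=0)
    return replace(first, values=mean, meta={**first.meta, "n_sweeps_averaged": len(traces)})


def remove_stimulus_artefacts(
    trace: Trace, stims: StimulusTrain, blank_window_ms: float = 1.0
) -> Trace:
    """Blank the stimulus artefact window after each onset.

    Samples in [onset, onset + blank_window] are replaced by linear
    interpolation between the nearest retained samples on either side.
    """
    if blank_window_ms < 1e3 / trace.sampling_rate_hz:
        raise ValueError("blank window must cover at least one sample period")
    out = trace.values.copy()
    win_s = blank_window_ms / 1e3
    for onset in stims.onset_times_s:
        if onset + win_s > trace.end_time_s or onset < trace.start_time_s:
            raise ValueError("blank window extends beyond the trace")
        i0, i1 = trace._index_range(onset, onset + win_s)
        if i1 < i0:
            continue
        lo = max(i0 - 1, 0)
        hi = min(i1 + 1, trace.n - 1)
        # interpolate across the blanked samples
        out[i0 : i1 + 1] = np.interp(np.arange(i0, i1 + 1), [lo, hi], [out[lo], out[hi]])
    return replace(trace, values=out, meta={**trace.meta, "artefact_blank_ms": blank_window_ms})


def lowpass_filter(trace: Trace, cutoff_hz: float = 400.0, order: int = 4) -> Trace:
    """Optional zero-phase Butterworth low-pass (acquisition uses a 400 Hz filter).

    Not applied by default during analysis; provided for conditioning
    synthetic data so it resembles the filtered recordings.
    """
    nyq = trace.sampling_rate_hz / 2
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = _signal.butter(order, cutoff_hz / nyq, output="sos")
    filtered = _signal.sosfiltfilt(sos, trace.values)
    return replace(trace, values=filtered, meta={**trace.meta, "lowpass_hz": cutoff_hz})


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _baseline_level(trace: Trace, baseline_window: tuple[float, float] | None) -> float:
    if baseline_window is None:
        return 0.0
    b0, b1 = baseline_window
    return float(np.mean(trace.slice_values(b0, b1)))


def peak_amplitude(
    trace: Trace,
    search_window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
) -> float:
    """max over the search window minus the baseline-window mean.

    May be negative for flat or noisy traces; reported as-is.
    """
    s0, s1 = search_window
    if baseline_window is not None and baseline_window[1] > s0 + 1e-12:
        raise ValueError("baseline window must precede the search window")
    base = _baseline_level(trace, baseline_window)
    return float(np.max(trace.slice_values(s0, s1))) - base


def rise_time_20_80(
    trace: Trace,
    onset_s: float,
    baseline_window: tuple[float, float] | None = None,
    search_end_s: float | None = None,
) -> float:
    """20-80% rise time in ms of the first transient after ``onset_s``.

    The baseline-corrected signal's peak after onset defines 100%; the rise
    time is the interval between the first upward crossings of 20% and 80%
    of that peak, located with linear interpolation between the bracketing
    samples (sub-sample resolution). Invariant to amplitude scaling and to a
    constant baseline offset of the trace.
    """
    base = _baseline_level(trace, baseline_window)
    end = trace.end_time_s if search_end_s is None else search_end_s
    seg = trace.slice_values(onset_s, end) - base
    i0, _ = trace._index_range(onset_s, end)
    peak = float(np.max(seg))
    if peak <= 0:
        raise ValueError("no positive peak after onset")
    t_of = lambda idx: trace.start_time_s + idx * trace.dt  # noqa: E731

    def first_crossing(level: float) -> float:
        above = seg >= level
        if not above.any():
            raise ValueError(f"signal never reaches {level:.3g}")
        k = int(np.argmax(above))
        if k == 0:
            return t_of(i0)
        # linear interpolation between samples k-1 and k
        frac = (level - seg[k - 1]) / (seg[k] - seg[k - 1])
        return t_of(i0 + k - 1 + frac)

    t20 = first_crossing(0.2 * peak)
    t80 = first_crossing(0.8 * peak)
    return (t80 - t20) * 1e3


def area_under_curve(
    trace: Trace,
    start_s: float,
    duration_s: float = DEFAULT_AUC_DURATION_S,
    baseline_window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal integral (µM·s) of the baseline-corrected trace over a window.

    Window endpoints between samples are interpolated, so the integral is
    exactly additive over adjacent windows and exactly linear in amplitude.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    t0, t1 = start_s, start_s + duration_s
    if t0 < trace.start_time_s - 1e-12 or t1 > trace.end_time_s + 1e-12:
        raise ValueError("AUC window exceeds the trace")
    base = _baseline_level(trace, baseline_window)
    i0 = int(math.ceil((t0 - trace.start_time_s) * trace.sampling_rate_hz - 1e-9))
    i1 = int(math.floor((t1 - trace.start_time_s) * trace.sampling_rate_hz + 1e-9))
    inner_t = trace.start_time_s + np.arange(i0, i1 + 1) * trace.dt
    ts = np.concatenate([[t0], inner_t, [t1]])
    vs = np.concatenate([[trace.value_at(t0)], trace.values[i0 : i1 + 1], [trace.value_at(t1)]])
    # de-duplicate endpoints landing exactly on samples
    keep = np.concatenate([[True], np.diff(ts) > 1e-12])
    return float(np.trapezoid(vs[keep] - base, ts[keep]))


def train_amplitudes(
    trace: Trace,
    stims: StimulusTrain,
    reference_first_amplitude_um: float,
) -> TrainResponse:
    """Per-stimulus peak amplitudes in a train, local-baseline corrected.

    Each stimulus' amplitude is the maximum within its inter-stimulus window
    minus the trace value immediately preceding that stimulus, so summating
    responses are not double-counted. Normalized values divide by a reference
    first amplitude (e.g. the control-group mean first response).
    """
    if reference_first_amplitude_um <= 0:
        raise ValueError("reference first amplitude must be positive")
    onsets = list(stims.onset_times_s)
    if len(onsets) >= 2:
        interval = onsets[1] - onsets[0]
    else:
        interval = trace.end_time_s - onsets[0]
    amps = []
    for i, onset in enumerate(onsets):
        w_end = onsets[i + 1] if i + 1 < len(onsets) else min(onset + interval, trace.end_time_s)
        # level immediately preceding the stimulus (one sample before onset)
        local_base = float(trace.value_at(max(onset - trace.dt, trace.start_time_s)))
        amps.append(float(np.max(trace.slice_values(onset, w_end))) - local_base)
    normalized = tuple(a / reference_first_amplitude_um for a in amps)
    return TrainResponse(
        amplitudes_um=tuple(amps),
        normalized=normalized,
        reference_first_amplitude_um=reference_first_amplitude_um,
    )


def dat_block_comparison(
    baseline: Trace,
    drug: Trace,
    window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
) -> DatBlockResult:
    """Compare windowed dopamine areas before vs after DAT block.

    subtracted = area_drug - area_baseline; fold = area_drug / area_baseline
    (undefined, reported as None, when the baseline area is not positive).
    """
    t0, t1 = window
    a_base = area_under_curve(baseline, t0, t1 - t0, baseline_window)
    a_drug = area_under_curve(drug, t0, t1 - t0, baseline_window)
    fold = a_drug / a_base if a_base > 0 else None
    return DatBlockResult(
        area_baseline_um_s=a_base,
        area_drug_um_s=a_drug,
        subtracted_area_um_s=a_drug - a_base,
        fold_increase=fold,
    )


def kcl_response(
    trace: Trace,
    puff_start_s: float,
    puff_duration_s: float = 10.0,
    baseline_window: tuple[float, float] | None = None,
    window_after_puff_s: float = KCL_WINDOW_AFTER_PUFF_S,
) -> tuple[float, float]:
    """Peak (µM) and AUC (µM·s) of a KCl-puff response.

    Quantified from the start of KCl application to ``window_after_puff_s``
    (default 200 s) after the end of the puff; baseline from a pre-puff window.
    """
    t_end = puff_start_s + puff_duration_s + window_after_puff_s
    if t_end > trace.end_time_s + 1e-12:
        raise ValueError("trace too short to cover the KCl quantification window")
    peak = peak_amplitude(trace, (puff_start_s, t_end), baseline_window)
    auc = area_under_curve(trace, puff_start_s, t_end - puff_start_s, baseline_window)
    return peak, auc


def normalize_microdialysis(
    series: Sequence[tuple[float, float]],
    reference_window_min: tuple[float, float] = (76.0, 120.0),
    reference_series: Sequence[tuple[float, float]] | None = None,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Normalize a microdialysis concentration series to a reference window mean.

    Each value is divided by the mean concentration of ``reference_series``
    (default: the series itself, e.g. the control group) over the reference
    window (inclusive; default the 76th-120th minute). Returns the normalized
    series and its natural-log copy. The log copy is refused when any
    normalized value is non-positive.
    """
    ref = list(reference_series) if reference_series is not None else list(series)
    lo, hi = reference_window_min
    in_window = [c for t, c in ref if lo <= t <= hi]
    if not in_window:
        raise ValueError("no samples in the reference window")
    ref_mean = float(np.mean(in_window))
    if ref_mean == 0:
        raise ValueError("reference window mean is zero")
    normalized = [(float(t), float(c) / ref_mean) for t, c in series]
    if any(v <= 0 for _, v in normalized):
        raise ValueError("log copy refused: non-positive normalized values")
    log_copy = [(t, math.log(v)) for t, v in normalized]
    return normalized, log_copy
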