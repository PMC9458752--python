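"""Whole-cell recording analysis: passive membrane properties, spike
detection and intrinsic-excitability metrics, spike-frequency adaptation,
and miniature-PSC detection and statistics.

All sweeps are uniformly sampled; currents are in pA, voltages in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class EstimationError(RuntimeError):
    """A model fit (e.g. the membrane time constant) did not converge."""


class InsufficientSpikesError(ValueError):
    """Too few spikes for the requested metric."""


class DegenerateThresholdError(ValueError):
    """Event threshold is zero on a zero-noise trace: nothing separates
    signal from baseline."""


@dataclass
class TraceSweep:
    """One uniformly sampled current or voltage sweep.

    ``annotations`` carries protocol metadata such as ``step_mv``/
    ``step_pa`` with ``onset_s``/``offset_s``, or ``laser_onset_s`` for
    photostimulation sweeps.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    units: str = "pA"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.duration_s
        for key in ("onset_s", "offset_s", "laser_onset_s"):
            if key in self.annotations and not (
                    0 <= self.annotations[key] <= dur):
                raise ValueError(f"annotation {key} outside sweep")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz

    def index_at(self, t: float) -> int:
        return int(round(t * self.sampling_rate_hz))


@dataclass
class PassiveProps:
    input_resistance_mohm: float
    capacitance_pf: float
    time_constant_ms: float


@dataclass
class SpikeMetrics:
    times_s: np.ndarray
    thresholds_mv: np.ndarray
    half_widths_ms: np.ndarray

    @property
    def count(self) -> int:
        return self.times_s.size


@dataclass
class MiniEventTable:
    times_s: np.ndarray
    amplitudes_pa: np.ndarray
    polarity: str
    duration_s: float
    threshold_pa: float

    @property
    def inter_event_intervals_s(self) -> np.ndarray:
        return np.diff(self.times_s)

    @property
    def frequency_hz(self) -> float:
        return self.times_s.size / self.duration_s


@dataclass
class MiniStats:
    bin_edges_pa: np.ndarray
    histogram: np.ndarray
    ecdf_x: np.ndarray
    ecdf_y: np.ndarray
    mean_amplitude_pa: float
    frequency_hz: float


# ---------------------------------------------------------------------------
# passive properties

def passive_properties(step_sweep: TraceSweep,
                       step_mv: float | None = None,
                       steady_fraction: float = 0.2) -> PassiveProps:
    """Passive membrane properties from a hyperpolarising voltage step.

    The sweep is the clamp *current* response (pA) to a small voltage step
    (default -5 mV).  Rin = step / steady-state current change, with the
    steady state taken as the mean over the final ``steady_fraction`` of
    the step.  The membrane time constant comes from a single-exponential
    fit of the capacitive transient decay, and Cm = tau / Rin.
    """
    ann = step_sweep.annotations
    step = step_mv if step_mv is not None else ann.get("step_mv")
    if step is None or step == 0:
        raise ValueError("voltage step amplitude required")
    on = step_sweep.index_at(ann["onset_s"])
    off = step_sweep.index_at(ann["offset_s"])
    x = step_sweep.samples
    baseline = x[:on].mean()
    n_ss = max(1, int(steady_fraction * (off - on)))
    steady = x[off - n_ss:off].mean()
    delta_i = steady - baseline
    if delta_i == 0 or np.sign(delta_i) != np.sign(step):
        raise EstimationError("no resolvable steady-state current change")
    rin_mohm = (step / delta_i) * 1000.0  # mV/pA = GOhm

    # transient: from the post-onset extremum down to the steady state
    seg_end = min(off, on + max(3, (off - on) // 2))
    seg = x[on:seg_end]
    peak_rel = int(np.argmax(np.abs(seg - steady)))
    t = (np.arange(seg.size - peak_rel)) / step_sweep.sampling_rate_hz
    y = seg[peak_rel:]
    a0 = y[0] - steady
    tau0 = max(t[-1] / 5, 1e-4)
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: steady + a * np.exp(-tt / tau),
            t, y, p0=(a0, tau0), maxfev=5000)
    except (RuntimeError, ValueError) as exc:
        raise EstimationError(
            f"transient fit failed (n={t.size}, a0={a0:.3g}): {exc}") from exc
    tau_ms = abs(popt[1]) * 1000.0
    if not np.isfinite(tau_ms) or tau_ms <= 0:
        raise EstimationError(f"non-physical time constant {tau_ms}")
    cm_pf = tau_ms / rin_mohm * 1000.0  # ms/MOhm = nF
    return PassiveProps(input_resistance_mohm=float(rin_mohm),
                        capacitance_pf=float(cm_pf),
                        time_constant_ms=float(tau_ms))


# ---------------------------------------------------------------------------
# spikes

def detect_spikes(voltage_sweep: TraceSweep,
                  dvdt_threshold_v_per_s: float = 20.0,
                  crossing_mv: float = 0.0,
                  refractory_ms: float = 2.0) -> SpikeMetrics:
    """Detect action potentials in a current-clamp sweep.

    A spike is an upward crossing of ``crossing_mv`` (crossings within the
    refractory window are merged).  The spike threshold is the voltage at
    the start of the depolarising run where dV/dt first stays at or above
    the criterion before the peak; the half-width is measured at half of
    (peak - threshold) with linear interpolation at the crossings.
    """
    v = voltage_sweep.samples
    fs = voltage_sweep.sampling_rate_hz
    above = v >= crossing_mv
    starts = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if starts.size == 0:
        return SpikeMetrics(np.array([]), np.array([]), np.array([]))
    refr = int(round(refractory_ms * 1e-3 * fs))
    merged = [starts[0]]
    for s in starts[1:]:
        if s - merged[-1] > refr:
            merged.append(s)
    dvdt = np.diff(v) * fs / 1000.0  # mV/sample -> V/s

    times, thresholds, widths = [], [], []
    for s in merged:
        # peak: maximum until v falls back below the crossing level
        e = s
        while e < v.size and v[e] >= crossing_mv:
            e += 1
        peak_idx = s + int(np.argmax(v[s:e])) if e > s else s
        peak = v[peak_idx]
        # walk back from the peak while the depolarisation rate criterion holds
        i = peak_idx - 1
        while i > 0 and dvdt[i - 1] >= dvdt_threshold_v_per_s:
            i -= 1
        thr = v[i]
        half = thr + 0.5 * (peak - thr)
        widths.append(_width_at_level(v, fs, peak_idx, half))
        times.append(peak_idx / fs)
        thresholds.append(thr)
    return SpikeMetrics(times_s=np.array(times),
                        thresholds_mv=np.array(thresholds),
                        half_widths_ms=np.array(widths))


def _width_at_level(v, fs, peak_idx, level) -> float:
    i = peak_idx
    while i > 0 and v[i] > level:
        i -= 1
    if v[i] == level or i == peak_idx:
        left = float(i)
    else:
        left = i + (level - v[i]) / (v[i + 1] - v[i])
    j = peak_idx
    while j < v.size - 1 and v[j] > level:
        j += 1
    if v[j] == level or j == peak_idx:
        right = float(j)
    else:
        right = j - 1 + (level - v[j - 1]) / (v[j] - v[j - 1])
    return (right - left) / fs * 1000.0


def fi_curve(session, dvdt_threshold_v_per_s: float = 20.0):
    """Spike count per current step over the step window.

    ``session`` is a :class:`~ephyskit.synth.CurrentClampSession`-like
    object with ``steps_pa`` and one voltage ``TraceSweep`` per step.
    Returns ``(steps_pa, counts)`` as arrays sorted by step amplitude.
    """
    steps = np.asarray(session.steps_pa, dtype=float)
    counts = np.empty(steps.size, dtype=int)
    for i, sweep in enumerate(session.sweeps):
        m = detect_spikes(sweep, dvdt_threshold_v_per_s)
        on = sweep.annotations.get("onset_s", 0.0)
        off = sweep.annotations.get("offset_s", sweep.duration_s)
        counts[i] = int(np.sum((m.times_s >= on) & (m.times_s < off)))
    order = np.argsort(steps)
    return steps[order], counts[order]


def sfa_index(spike_times) -> float:
    """Spike-frequency adaptation as the ratio ISI3 / ISI5.

    Requires at least 7 spikes so that the 5th inter-spike interval exists;
    values below 1 indicate lengthening intervals (adaptation).
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 7:
        raise InsufficientSpikesError(
            f"need >= 7 spikes for ISI3/ISI5, got {t.size}")
    isi = np.diff(t)
    return float(isi[2] / isi[4])


def select_sfa_step(session, min_spikes: int = 8,
                    dvdt_threshold_v_per_s: float = 20.0):
    """Smallest current step evoking at least ``min_spikes`` spikes
    (about 10 Hz over a 1-s step); returns ``(step_pa, spike_times)``."""
    steps, counts = fi_curve(session, dvdt_threshold_v_per_s)
    ok = np.flatnonzero(counts >= min_spikes)
    if ok.size == 0:
        raise InsufficientSpikesError(
            f"no step evoked >= {min_spikes} spikes")
    step = steps[ok[0]]
    idx = list(np.asarray(session.steps_pa, dtype=float)).index(step)
    m = detect_spikes(session.sweeps[idx], dvdt_threshold_v_per_s)
    return float(step), m.times_s


# ---------------------------------------------------------------------------
# miniature PSCs

def _boxcar(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD estimate as 1.4826 x median absolute deviation; robust to
    sparse events riding on the baseline."""
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def detect_minis(sweep: TraceSweep, polarity: str,
                 threshold_sd: float = 3.0,
                 min_interval_ms: float = 5.0,
                 smooth_ms: float = 1.0,
                 threshold_pa: float | None = None) -> MiniEventTable:
    """Threshold-crossing miniature-PSC detection.

    The signal is baseline-subtracted (median), rectified by polarity
    (``inward`` events are negative deflections), and lightly smoothed for
    onset detection; the detection threshold defaults to ``threshold_sd``
    times a robust noise-SD estimate of the raw rectified trace.
    Above-threshold runs closer together than ``min_interval_ms`` are
    merged into one event; the amplitude is the raw extremum of the event.
    """
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    x = sweep.samples
    fs = sweep.sampling_rate_hz
    sign = -1.0 if polarity == "inward" else 1.0
    r = sign * (x - np.median(x))
    if threshold_pa is None:
        sigma = robust_noise_sd(r)
        if sigma == 0 and threshold_sd == 0:
            raise DegenerateThresholdError(
                "zero noise with zero threshold multiplier")
        threshold = threshold_sd * sigma
    else:
        threshold = threshold_pa
    smooth_n = max(1, int(round(smooth_ms * 1e-3 * fs)))
    det = _boxcar(r, smooth_n)
    above = det > threshold
    if not above.any():
        return MiniEventTable(np.array([]), np.array([]), polarity,
                              sweep.duration_s, float(threshold))
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    # merge runs separated by less than the minimum interval
    gap = int(round(min_interval_ms * 1e-3 * fs))
    runs = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - runs[-1][1] < gap:
            runs[-1][1] = e
        else:
            runs.append([s, e])
    pad = smooth_n  # re-measure the raw extremum slightly beyond the run
    times, amps = [], []
    for s, e in runs:
        lo, hi = max(0, s - pad), min(r.size, e + pad)
        k = lo + int(np.argmax(r[lo:hi]))
        times.append(k / fs)
        amps.append(r[k])
    return MiniEventTable(np.array(times), np.array(amps), polarity,
                          sweep.duration_s, float(threshold))


def mini_stats(events: MiniEventTable,
               duration_s: float | None = None) -> MiniStats:
    """Summary statistics: 1-pA amplitude histogram, ECDF, mean amplitude
    and event frequency (count / analysed duration)."""
    dur = duration_s if duration_s is not None else events.duration_s
    if dur <= 0:
        raise ValueError("duration must be positive")
    amps = np.asarray(events.amplitudes_pa, dtype=float)
    if amps.size == 0:
        return MiniStats(np.array([0.0]), np.array([], dtype=int),
                         np.array([]), np.array([]), float("nan"), 0.0)
    edges = np.arange(0.0, np.ceil(amps.max()) + 1.0)
    hist, _ = np.histogram(amps, bins=edges)
    xs = np.sort(amps)
    ys = np.arange(1, xs.size + 1) / xs.size
    return MiniStats(bin_edges_pa=edges, histogram=hist, ecdf_x=xs,
                     ecdf_y=ys, mean_amplitude_pa=float(amps.mean()),
                     frequency_hz=amps.size / dur)
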