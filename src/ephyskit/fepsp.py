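"""Field-potential scoring: fiber volley, initial fEPSP slope,
input-output curves, paired-pulse ratios, theta-burst induction timing and
LTP magnitude.

The fEPSP slope is a least-squares line over the first 1 ms of the
response after the fiber volley; LTP magnitude is the mean
baseline-normalised slope over the final 10 minutes after induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intracellular import TraceSweep, robust_noise_sd


@dataclass
class FepspMeasure:
    fiber_volley_mv: float
    slope_mv_per_ms: float
    stimulus_intensity_ua: float = float("nan")
    sweep_time_s: float = float("nan")

    @property
    def is_null(self) -> bool:
        return np.isnan(self.slope_mv_per_ms)


NULL_MEASURE = FepspMeasure(float("nan"), float("nan"))


@dataclass(frozen=True)
class InductionProtocol:
    """Theta-burst stimulation: 2-s trains of 4-pulse 100-Hz bursts at
    5 Hz, repeated 5 times at a 10-s inter-train interval."""

    burst_freq_hz: float = 100.0
    pulses_per_burst: int = 4
    burst_rate_hz: float = 5.0
    train_duration_s: float = 2.0
    train_count: int = 5
    inter_train_interval_s: float = 10.0

    @property
    def bursts_per_train(self) -> int:
        return int(round(self.train_duration_s * self.burst_rate_hz))

    @property
    def total_pulses(self) -> int:
        return self.pulses_per_burst * self.bursts_per_train * self.train_count


@dataclass
class LTPTimecourse:
    times_s: np.ndarray
    slopes: np.ndarray            # raw slopes, mV/ms (or already normalized %)
    induction_time_s: float
    baseline_window_min: float = 10.0
    magnitude_window_min: float = 10.0
    normalized: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class MeasureConfig:
    """Timing conventions for fEPSP scoring (stimulus-artifact blanking,
    fiber-volley search window, slope-window anchor)."""

    blank_ms: float = 1.0
    volley_search_ms: tuple = (1.0, 4.0)
    slope_offset_ms: float = 0.5
    slope_window_ms: float = 1.0
    detect_sd: float = 3.0


def measure_fepsp(sweep: TraceSweep, stim_onset_s: float | None = None,
                  config: MeasureConfig | None = None) -> FepspMeasure:
    """Fiber-volley amplitude and initial fEPSP slope for one sweep.

    The artifact is blanked for ``blank_ms`` after the stimulus; the fiber
    volley is the first fast negative trough in the search window, and the
    slope is fitted over the 1-ms window starting ``slope_offset_ms`` after
    the volley trough.  Returns a null measure (NaN fields) when no
    deflection rises above the baseline noise.
    """
    config = config or MeasureConfig()
    fs = sweep.sampling_rate_hz
    onset = stim_onset_s if stim_onset_s is not None else \
        sweep.annotations.get("stim_onset_s")
    if onset is None:
        raise ValueError("stimulus onset not annotated")
    x = sweep.samples
    i_on = sweep.index_at(onset)
    baseline = x[:i_on].mean() if i_on > 0 else 0.0
    noise = robust_noise_sd(x[:i_on] - baseline) if i_on > 1 else 0.0

    v0 = i_on + int(round(config.volley_search_ms[0] * 1e-3 * fs))
    v1 = i_on + int(round(config.volley_search_ms[1] * 1e-3 * fs))
    v1 = min(v1, x.size)
    if v1 <= v0:
        return NULL_MEASURE
    seg = x[v0:v1] - baseline
    thr = config.detect_sd * noise
    # first local minimum that dips below the noise floor (the volley is a
    # brief trough that recovers before the slower fEPSP descends)
    local = np.flatnonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:])
                           & (-seg[1:-1] > thr)) + 1
    trough_rel = int(local[0]) if local.size else int(np.argmin(seg))
    volley_amp = -seg[trough_rel]  # positive magnitude of the negative dip
    if volley_amp <= thr:
        return NULL_MEASURE

    s0 = v0 + trough_rel + int(round(config.slope_offset_ms * 1e-3 * fs))
    s1 = s0 + int(round(config.slope_window_ms * 1e-3 * fs))
    if s1 > x.size or s1 - s0 < 2:
        return NULL_MEASURE
    t_ms = np.arange(s1 - s0) / fs * 1e3
    slope = float(np.polyfit(t_ms, x[s0:s1], 1)[0])
    return FepspMeasure(fiber_volley_mv=float(volley_amp),
                        slope_mv_per_ms=slope,
                        stimulus_intensity_ua=sweep.annotations.get(
                            "stim_intensity_ua", float("nan")),
                        sweep_time_s=sweep.annotations.get(
                            "sweep_time_s", float("nan")))


def input_output_curve(measures):
    """Stimulus-response curve: sorted (fiber volley, slope) pairs plus a
    linear-fit gain.

    Returns ``(volley, slope, fit)`` where ``fit`` is a dict with
    ``gain`` (slope per mV of volley), ``intercept`` and ``r_squared``, or
    None when the abscissa is degenerate.
    """
    pairs = [(m.fiber_volley_mv, m.slope_mv_per_ms) for m in measures
             if not m.is_null]
    if len(pairs) < 2:
        raise ValueError("need at least two non-null measures")
    pairs.sort()
    fv = np.array([p[0] for p in pairs])
    sl = np.array([p[1] for p in pairs])
    fit = None
    if np.unique(fv).size >= 2:
        coef = np.polyfit(fv, sl, 1)
        pred = np.polyval(coef, fv)
        ss_res = float(((sl - pred) ** 2).sum())
        ss_tot = float(((sl - sl.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        fit = {"gain": float(coef[0]), "intercept": float(coef[1]),
               "r_squared": r2}
    return fv, sl, fit


def paired_pulse_ratio(sweep: TraceSweep, onsets_s: tuple,
                       config: MeasureConfig | None = None) -> float:
    """Paired-pulse ratio slope2/slope1 for one two-stimulus sweep."""
    m1 = measure_fepsp(sweep, onsets_s[0], config)
    m2 = measure_fepsp(sweep, onsets_s[1], config)
    if m1.is_null or m1.slope_mv_per_ms == 0:
        return float("nan")
    if m2.is_null:
        return float("nan")
    return m2.slope_mv_per_ms / m1.slope_mv_per_ms


def paired_pulse_curve(sweeps_by_interval: dict,
                       config: MeasureConfig | None = None) -> dict:
    """Paired-pulse ratio per inter-pulse interval (ms).

    ``sweeps_by_interval`` maps interval_ms -> (sweep, (onset1_s, onset2_s)).
    """
    return {float(iv): paired_pulse_ratio(sweep, onsets, config)
            for iv, (sweep, onsets) in sorted(sweeps_by_interval.items())}


def theta_burst_times(protocol: InductionProtocol | None = None) -> np.ndarray:
    """Timestamps (s) of every pulse of the theta-burst induction.

    Default protocol: 5 trains starting every 10 s, each a 2-s 5-Hz series
    of 10 bursts, each burst 4 pulses at 100 Hz -> 200 pulses, the last at
    41.83 s.
    """
    p = protocol or InductionProtocol()
    train_starts = np.arange(p.train_count) * p.inter_train_interval_s
    burst_starts = np.arange(p.bursts_per_train) / p.burst_rate_hz
    pulse_offsets = np.arange(p.pulses_per_burst) / p.burst_freq_hz
    t = (train_starts[:, None, None] + burst_starts[None, :, None]
         + pulse_offsets[None, None, :])
    return np.sort(t.ravel())


def normalize_timecourse(tc: LTPTimecourse) -> LTPTimecourse:
    """Express slopes as % of the pre-induction baseline-window mean.

    Idempotent: normalising an already-normalised time course changes
    nothing (the baseline mean of a normalised series is 100).
    """
    t0 = tc.induction_time_s - tc.baseline_window_min * 60.0
    base = (tc.times_s >= t0) & (tc.times_s < tc.induction_time_s)
    if not base.any():
        raise ValueError("no baseline sweeps in the baseline window")
    base_mean = tc.slopes[base].mean()
    if base_mean <= 0 and not tc.normalized:
        raise ValueError("non-positive baseline mean slope")
    return LTPTimecourse(times_s=tc.times_s,
                         slopes=tc.slopes / base_mean * 100.0,
                         induction_time_s=tc.induction_time_s,
                         baseline_window_min=tc.baseline_window_min,
                         magnitude_window_min=tc.magnitude_window_min,
                         normalized=True, meta=dict(tc.meta))


def ltp_magnitude(tc: LTPTimecourse) -> float:
    """LTP magnitude: mean normalised slope (% of baseline) over the final
    ``magnitude_window_min`` minutes of the post-induction recording."""
    norm = tc if tc.normalized else normalize_timecourse(tc)
    t_end = norm.times_s.max()
    lo = t_end - norm.magnitude_window_min * 60.0
    if lo < norm.induction_time_s:
        raise ValueError("insufficient post-induction data "
                         f"(need {norm.magnitude_window_min} min)")
    win = norm.times_s > lo
    return float(norm.slopes[win].mean())
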