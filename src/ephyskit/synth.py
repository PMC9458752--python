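"""Seeded synthetic-data generators for every recording modality.

Each generator is a pure function of its arguments and a seed and returns
the ground truth alongside the data, so that every analysis routine in the
package can be validated by parameter recovery.  The emulated designs are:

* drifting-grating single-unit sessions: Poisson spiking units with
  circular-Gaussian orientation tuning and eye-specific drive (2-s stimuli
  in 4-s trials, 12 orientations x 3 repeats per eye, plus blank trials);
  monocular deprivation is a multiplicative reduction of deprived-eye drive;
* adaptive leaky integrate-and-fire responses to 1-s current steps
  (-100..+500 pA in 50-pA increments), forward-Euler at 0.05 ms;
* miniature-PSC sweeps: Poisson event times, right-skewed (gamma)
  amplitudes, biexponential kernels, Gaussian noise;
* 16 x 16 LSPS maps with layer-structured connectivity and near-soma
  direct responses;
* baseline / post-induction fEPSP slope series for LTP scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .intracellular import TraceSweep
from .lsps import (DEFAULT_LAYER_BOUNDS, HOLDING_FOR_MODE, LSPSGrid,
                   LSPSRecording, SITE_DIRECT, SITE_NONE, SITE_SYNAPTIC)
from .fepsp import LTPTimecourse


# ---------------------------------------------------------------------------
# visual stimulation / ocular dominance

@dataclass(frozen=True)
class StimProtocol:
    """Drifting-grating protocol: 0.1 cpd, 95% contrast gratings at twelve
    equally spaced orientations, 2 s of stimulus per 4-s trial, three
    repeats per orientation and eye, with blank trials for baseline."""

    n_orientations: int = 12
    stim_duration: float = 2.0
    trial_duration: float = 4.0
    repeats_per_condition: int = 3
    spatial_frequency_cpd: float = 0.1
    contrast: float = 0.95
    eyes: tuple = ("contra", "ipsi")
    includes_blank: bool = True

    def __post_init__(self) -> None:
        if self.stim_duration >= self.trial_duration:
            raise ValueError("stimulus must be shorter than the trial")
        if self.n_orientations < 1 or self.repeats_per_condition < 1:
            raise ValueError("need >= 1 orientation and repeat")

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.arange(self.n_orientations) * (180.0 / self.n_orientations)


@dataclass
class ODPopulation:
    """Population-level spiking model for simulated binocular units.

    Per-unit eye drives are drawn log-normally around the population means
    (independently per eye), giving a spread of ocular-dominance indices;
    ``md_shift`` in [0, 1] is the fractional reduction of the deprived
    (contralateral) eye's drive, so 0 is the non-deprived control.
    """

    contra_drive_hz: float = 8.0
    ipsi_drive_hz: float = 4.0
    baseline_hz: float = 2.0
    tuning_kappa: float = 1.5
    drive_sigma: float = 0.6     # log-normal sd of per-unit drive
    md_shift: float = 0.0
    deprived_eye: str = "contra"

    def __post_init__(self) -> None:
        if not 0.0 <= self.md_shift <= 1.0:
            raise ValueError("md_shift must lie in [0, 1]")
        if min(self.contra_drive_hz, self.ipsi_drive_hz,
               self.baseline_hz) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class ODGroundTruth:
    """Realised per-unit ground truth returned with a generated dataset."""

    mouse_id: np.ndarray
    unit_id: np.ndarray
    contra_drive_hz: np.ndarray   # effective (post-MD) drives
    ipsi_drive_hz: np.ndarray
    baseline_hz: float
    tuning_kappa: float
    preferred_deg: np.ndarray
    md_shift: float

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ODGroundTruth":
        return cls(mouse_id=np.asarray(d["mouse_id"]),
                   unit_id=np.asarray(d["unit_id"]),
                   contra_drive_hz=np.asarray(d["contra_drive_hz"], float),
                   ipsi_drive_hz=np.asarray(d["ipsi_drive_hz"], float),
                   baseline_hz=float(d["baseline_hz"]),
                   tuning_kappa=float(d["tuning_kappa"]),
                   preferred_deg=np.asarray(d["preferred_deg"], float),
                   md_shift=float(d["md_shift"]))


def orientation_gain(theta_deg, pref_deg, kappa) -> np.ndarray:
    """Circular-Gaussian (von Mises-shaped) orientation gain, peak 1 at the
    preferred orientation, period 180 degrees."""
    d = np.deg2rad(2.0 * (np.asarray(theta_deg, float) - pref_deg))
    return np.exp(kappa * (np.cos(d) - 1.0))


def gen_od_dataset(protocol: StimProtocol, pop: ODPopulation,
                   n_units: int, n_mice: int, seed: int,
                   mouse_prefix: str = "m"):
    """Simulate per-trial spike-count tables for ``n_mice`` mice.

    Spike counts are Poisson over the stimulus window with rate
    baseline + eye drive x orientation gain; one blank trial precedes each
    stimulus trial.  Returns ``(trial_table, truth)``; the table is tidy
    with one row per unit x eye x orientation x repeat plus blank rows.
    """
    if n_units < 1 or n_mice < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_total = n_units * n_mice
    ori = protocol.orientations_deg
    K, R = ori.size, protocol.repeats_per_condition

    sigma = pop.drive_sigma
    lognorm = lambda mean: mean * rng.lognormal(-sigma**2 / 2, sigma, n_total)
    contra = lognorm(pop.contra_drive_hz)
    ipsi = lognorm(pop.ipsi_drive_hz)
    if pop.deprived_eye == "contra":
        contra = contra * (1.0 - pop.md_shift)
    else:
        ipsi = ipsi * (1.0 - pop.md_shift)
    pref = rng.uniform(0.0, 180.0, n_total)

    gain = orientation_gain(ori[None, :], pref[:, None], pop.tuning_kappa)
    drives = np.stack([contra, ipsi], axis=1)              # (N, 2)
    rate = pop.baseline_hz + drives[:, :, None] * gain[:, None, :]  # (N,2,K)
    lam = rate[:, :, :, None] * protocol.stim_duration
    counts = rng.poisson(np.broadcast_to(lam, (n_total, 2, K, R)))
    n_blank = 2 * K * R  # one blank preceding every stimulus trial
    blanks = rng.poisson(pop.baseline_hz * protocol.stim_duration,
                         (n_total, n_blank))

    mouse_ids = np.array([f"{mouse_prefix}{i}" for i in range(n_mice)])
    unit_ids = np.array([f"u{i}" for i in range(n_units)])
    mouse_col = np.repeat(mouse_ids, n_units)
    unit_col = np.array([f"{m}_{u}" for m in mouse_ids for u in unit_ids])

    stim = pd.DataFrame({
        "mouse_id": np.repeat(mouse_col, 2 * K * R),
        "unit_id": np.repeat(unit_col, 2 * K * R),
        "eye": np.tile(np.repeat(np.array(protocol.eyes), K * R), n_total),
        "orientation_deg": np.tile(np.repeat(ori, R), n_total * 2),
        "repeat": np.tile(np.arange(1, R + 1), n_total * 2 * K),
        "spike_count": counts.ravel(),
    })
    blank = pd.DataFrame({
        "mouse_id": np.repeat(mouse_col, n_blank),
        "unit_id": np.repeat(unit_col, n_blank),
        "eye": "blank",
        "orientation_deg": np.nan,
        "repeat": np.tile(np.arange(1, n_blank + 1), n_total),
        "spike_count": blanks.ravel(),
    })
    table = pd.concat([stim, blank], ignore_index=True)
    table["stim_s"] = protocol.stim_duration
    table["trial_s"] = protocol.trial_duration

    truth = ODGroundTruth(
        mouse_id=mouse_col.copy(), unit_id=unit_col.copy(),
        contra_drive_hz=contra, ipsi_drive_hz=ipsi,
        baseline_hz=pop.baseline_hz, tuning_kappa=pop.tuning_kappa,
        preferred_deg=pref, md_shift=pop.md_shift)
    return table, truth


# ---------------------------------------------------------------------------
# adaptive integrate-and-fire current-step sessions

@dataclass(frozen=True)
class IFParams:
    """Adaptive leaky integrate-and-fire parameters.

    Spikes are threshold crossings; the voltage is painted to
    ``spike_peak_mv`` for one sample (a stereotyped spike marker) and reset.
    The adaptation current increments at each spike and decays
    exponentially, producing lengthening inter-spike intervals.
    """

    resistance_mohm: float = 200.0
    capacitance_pf: float = 100.0
    rest_mv: float = -70.0
    threshold_mv: float = -40.0
    reset_mv: float = -55.0
    refractory_ms: float = 2.0
    adapt_increment_pa: float = 20.0
    adapt_tau_ms: float = 120.0
    noise_sd_mv: float = 0.0
    spike_peak_mv: float = 30.0

    def __post_init__(self) -> None:
        if min(self.resistance_mohm, self.capacitance_pf,
               self.adapt_tau_ms) <= 0:
            raise ValueError("resistance, capacitance, taus must be positive")
        if self.threshold_mv <= self.reset_mv:
            raise ValueError("threshold must exceed reset")

    @property
    def tau_m_ms(self) -> float:
        return self.resistance_mohm * self.capacitance_pf / 1000.0

    @property
    def rheobase_pa(self) -> float:
        """Minimal sustained current whose steady state reaches threshold:
        (threshold - rest) / R."""
        return (self.threshold_mv - self.rest_mv) / self.resistance_mohm * 1e3


@dataclass
class CurrentClampSession:
    steps_pa: np.ndarray
    sweeps: list                  # TraceSweep (mV) per step
    spike_times: list             # ground-truth spike times (s) per step
    params: IFParams


DEFAULT_STEPS_PA = tuple(range(-100, 501, 50))


def gen_current_step_session(params: IFParams | None = None,
                             steps_pa=DEFAULT_STEPS_PA,
                             step_duration_s: float = 1.0,
                             dt_ms: float = 0.05,
                             pre_s: float = 0.1, post_s: float = 0.1,
                             seed: int = 0) -> CurrentClampSession:
    """Simulate one voltage sweep per current step (forward Euler).

    ``dt_ms`` must divide the step duration exactly.  Ground-truth spike
    times per step are returned in the session.
    """
    params = params or IFParams()
    steps = np.asarray(steps_pa, dtype=float)
    if steps.size == 0:
        raise ValueError("steps must be non-empty")
    if step_duration_s <= 0:
        raise ValueError("step duration must be positive")
    n_step = step_duration_s * 1000.0 / dt_ms
    if abs(n_step - round(n_step)) > 1e-9:
        raise ValueError(f"dt {dt_ms} ms does not divide the step duration")
    rng = np.random.default_rng(seed)
    fs = 1000.0 / dt_ms
    n_pre = int(round(pre_s * fs))
    n_on = int(round(n_step))
    n_post = int(round(post_s * fs))
    n_total = n_pre + n_on + n_post

    tau_m = params.tau_m_ms
    r = params.resistance_mohm
    v = np.full(steps.size, params.rest_mv)
    w = np.zeros(steps.size)
    refr = np.zeros(steps.size, dtype=int)
    refr_n = int(round(params.refractory_ms / dt_ms))
    out = np.empty((steps.size, n_total))
    spikes: list[list[float]] = [[] for _ in steps]
    i_ext = np.zeros(steps.size)
    noise_scale = params.noise_sd_mv * np.sqrt(dt_ms / tau_m)

    for k in range(n_total):
        i_ext[:] = steps if n_pre <= k < n_pre + n_on else 0.0
        dv = (-(v - params.rest_mv) + r * (i_ext - w) / 1000.0) * dt_ms / tau_m
        if noise_scale > 0:
            dv = dv + noise_scale * rng.standard_normal(steps.size)
        active = refr == 0
        v[active] += dv[active]
        refr[~active] -= 1
        fired = active & (v >= params.threshold_mv)
        out[:, k] = v
        if fired.any():
            out[fired, k] = params.spike_peak_mv
            v[fired] = params.reset_mv
            w[fired] += params.adapt_increment_pa
            refr[fired] = refr_n
            t = k / fs
            for idx in np.flatnonzero(fired):
                spikes[idx].append(t)
        w *= 1.0 - dt_ms / params.adapt_tau_ms

    sweeps = [TraceSweep(out[i], fs, units="mV",
                         annotations={"step_pa": float(steps[i]),
                                      "onset_s": n_pre / fs,
                                      "offset_s": (n_pre + n_on) / fs})
              for i in range(steps.size)]
    return CurrentClampSession(steps_pa=steps, sweeps=sweeps,
                               spike_times=[np.array(s) for s in spikes],
                               params=params)


def gen_rc_step_sweep(r_mohm: float = 200.0, cm_pf: float = 65.0,
                      step_mv: float = -5.0, fs: float = 20000.0,
                      pre_s: float = 0.05, step_s: float = 0.2,
                      post_s: float = 0.05, peak_factor: float = 20.0,
                      noise_sd_pa: float = 0.0, seed: int = 0) -> TraceSweep:
    """Ideal-RC voltage-clamp current response to a small voltage step.

    The current jumps to ``peak_factor`` times the steady state and decays
    single-exponentially with the membrane time constant tau = R*C toward
    I_ss = step/R; the passive-property estimator recovers R, tau and
    C = tau/R from this sweep.
    """
    rng = np.random.default_rng(seed)
    tau_s = r_mohm * cm_pf / 1000.0 * 1e-3
    i_ss = step_mv / r_mohm * 1000.0   # pA
    n_pre, n_on = int(pre_s * fs), int(step_s * fs)
    n_post = int(post_s * fs)
    t_on = np.arange(n_on) / fs
    x = np.concatenate([
        np.zeros(n_pre),
        i_ss + (peak_factor - 1.0) * i_ss * np.exp(-t_on / tau_s),
        -(peak_factor - 1.0) * i_ss * np.exp(-np.arange(n_post) / fs / tau_s),
    ])
    if noise_sd_pa > 0:
        x = x + rng.normal(0.0, noise_sd_pa, x.size)
    return TraceSweep(x, fs, units="pA",
                      annotations={"step_mv": step_mv, "onset_s": pre_s,
                                   "offset_s": pre_s + step_s})


# ---------------------------------------------------------------------------
# miniature PSCs

@dataclass
class MiniGroundTruth:
    event_times_s: np.ndarray
    event_amplitudes_pa: np.ndarray
    rise_tau_ms: float = 1.0
    decay_tau_ms: float = 6.0
    noise_sd_pa: float = 0.0
    polarity: str = "inward"

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.event_amplitudes_pa = np.asarray(self.event_amplitudes_pa,
                                              dtype=float)
        if np.any(self.event_amplitudes_pa <= 0):
            raise ValueError("amplitudes must be positive magnitudes")
        if self.decay_tau_ms <= self.rise_tau_ms:
            raise ValueError("decay tau must exceed rise tau")
        if np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("event times must be strictly increasing")

    def to_dict(self) -> dict:
        return {"event_times_s": self.event_times_s.tolist(),
                "event_amplitudes_pa": self.event_amplitudes_pa.tolist(),
                "rise_tau_ms": self.rise_tau_ms,
                "decay_tau_ms": self.decay_tau_ms,
                "noise_sd_pa": self.noise_sd_pa, "polarity": self.polarity}

    @classmethod
    def from_dict(cls, d: dict) -> "MiniGroundTruth":
        return cls(np.asarray(d["event_times_s"], float),
                   np.asarray(d["event_amplitudes_pa"], float),
                   d["rise_tau_ms"], d["decay_tau_ms"],
                   d["noise_sd_pa"], d["polarity"])


def gen_mini_truth(rate_hz: float, duration_s: float,
                   mean_amp_pa: float = 20.0, amp_shape: float = 4.0,
                   rise_tau_ms: float = 1.0, decay_tau_ms: float = 6.0,
                   noise_sd_pa: float = 0.0, polarity: str = "inward",
                   seed: int = 0) -> MiniGroundTruth:
    """Draw Poisson event times and right-skewed gamma amplitudes."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, n))
    times = np.unique(times)
    amps = rng.gamma(amp_shape, mean_amp_pa / amp_shape, times.size)
    amps = np.maximum(amps, 1e-6)
    return MiniGroundTruth(times, amps, rise_tau_ms, decay_tau_ms,
                           noise_sd_pa, polarity)


def biexp_kernel(t_s, rise_tau_ms: float, decay_tau_ms: float) -> np.ndarray:
    """Unit-peak biexponential: (e^{-t/tau_d} - e^{-t/tau_r}) normalised so
    the maximum is exactly 1 (closed-form peak time)."""
    tr, td = rise_tau_ms * 1e-3, decay_tau_ms * 1e-3
    t = np.asarray(t_s, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / td) - np.exp(-t / tr), 0.0)
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return raw / peak


def gen_mini_sweep(truth: MiniGroundTruth, duration_s: float,
                   sampling_rate_hz: float, seed: int = 0):
    """Render a mini-PSC sweep: biexponential events at the truth times and
    amplitudes plus Gaussian noise, signed by polarity.  Returns
    ``(TraceSweep, truth)``."""
    if duration_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if truth.event_times_s.size and truth.event_times_s.max() >= duration_s:
        raise ValueError("event time beyond sweep duration")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    x = np.zeros(n)
    k_len = int(round((truth.rise_tau_ms + 8 * truth.decay_tau_ms) * 1e-3
                      * sampling_rate_hz))
    kernel = biexp_kernel(np.arange(k_len) / sampling_rate_hz,
                          truth.rise_tau_ms, truth.decay_tau_ms)
    for t, a in zip(truth.event_times_s, truth.event_amplitudes_pa):
        i = int(round(t * sampling_rate_hz))
        j = min(n, i + k_len)
        x[i:j] += a * kernel[:j - i]
    sign = -1.0 if truth.polarity == "inward" else 1.0
    x = sign * x
    if truth.noise_sd_pa > 0:
        x = x + rng.normal(0.0, truth.noise_sd_pa, n)
    sweep = TraceSweep(x, sampling_rate_hz, units="pA",
                       annotations={"polarity": truth.polarity})
    return sweep, truth


# ---------------------------------------------------------------------------
# LSPS grid datasets

@dataclass
class LSPSCellTruth:
    site_class: np.ndarray      # (rows, cols) codes
    amplitude_pa: np.ndarray    # signed window-mean strength


@dataclass
class LSPSTruth:
    cells: list                  # LSPSCellTruth per cell
    layer_profile: dict
    mode: str


def gen_lsps_dataset(grid: LSPSGrid | None = None,
                     layer_profile: dict | None = None,
                     direct_radius_um: float = 100.0,
                     n_cells: int = 1, seed: int = 0,
                     mode: str = "excitatory",
                     noise_sd_pa: float = 2.0,
                     site_jitter_frac: float = 0.1,
                     layer_bounds: dict | None = None,
                     sampling_rate_hz: float = 10000.0,
                     pre_s: float = 0.05, post_s: float = 0.1,
                     synaptic_latency_s: tuple = (0.009, 0.025),
                     direct_amp_pa: float = 400.0,
                     direct_latency_s: float = 0.002):
    """Simulate per-site LSPS recordings with layer-structured connectivity.

    ``layer_profile`` maps layer name -> mean site strength in pA (signed;
    inward negative for excitatory).  Site strengths are parameterised on
    the analysis scale: each synaptic event is scaled so its mean current
    over the synaptic analysis window equals the planted strength, which is
    what the map estimator measures.  Sites within ``direct_radius_um`` of
    the soma receive an additional large short-latency direct response and
    are classified direct in the truth.  Returns
    ``(recordings, LSPSTruth)``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if mode not in HOLDING_FOR_MODE:
        raise ValueError(f"unknown mode {mode!r}")
    grid = grid or LSPSGrid()
    bounds = layer_bounds or DEFAULT_LAYER_BOUNDS
    profile = dict(layer_profile or {})
    missing = [n for n in profile if n not in bounds]
    if missing:
        raise ValueError(f"profile names unknown layers: {missing}")
    rng = np.random.default_rng(seed)
    fs = sampling_rate_hz
    n_samp = int(round((pre_s + post_s) * fs))
    syn_w = (0.007, 0.050)  # analysis window used for amplitude scaling
    j0 = int(round((pre_s + syn_w[0]) * fs))
    j1 = int(round((pre_s + syn_w[1]) * fs))
    k_len = n_samp
    t_axis = np.arange(k_len) / fs
    sign = -1.0 if mode == "excitatory" else 1.0

    depths = grid.depth_um(np.arange(grid.rows))
    layer_of_row = np.full(grid.rows, "", dtype=object)
    for name, (lo, hi) in bounds.items():
        layer_of_row[(depths >= lo) & (depths < hi)] = name

    recordings, cell_truths = [], []
    for ci in range(n_cells):
        cls = np.zeros((grid.rows, grid.cols), dtype=int)
        amp = np.zeros((grid.rows, grid.cols))
        sweeps = []
        for rr in range(grid.rows):
            for cc in range(grid.cols):
                mag = np.zeros(n_samp)  # deflection magnitude, signed later
                dist = float(grid.distance_um(rr, cc))
                is_direct = dist <= direct_radius_um and direct_radius_um > 0
                layer = layer_of_row[rr]
                target = abs(profile.get(layer, 0.0))
                if target != 0.0 and not is_direct:
                    m = rng.normal(target, site_jitter_frac * target)
                    m = max(m, 0.1 * target)
                    lat = rng.uniform(*synaptic_latency_s)
                    kern = biexp_kernel(t_axis - pre_s - lat, 1.0, 15.0)
                    wmean = kern[j0:j1].mean()
                    mag += (m / wmean) * kern
                    cls[rr, cc] = SITE_SYNAPTIC
                    amp[rr, cc] = sign * m
                if is_direct:
                    kern = biexp_kernel(t_axis - pre_s - direct_latency_s,
                                        0.3, 5.0)
                    mag += direct_amp_pa * kern
                    cls[rr, cc] = SITE_DIRECT
                    amp[rr, cc] = sign * float(
                        direct_amp_pa * kern[j0:j1].mean())
                x = sign * mag
                if noise_sd_pa > 0:
                    x = x + rng.normal(0.0, noise_sd_pa, n_samp)
                sweeps.append(TraceSweep(
                    x, fs, units="pA",
                    annotations={"laser_onset_s": pre_s,
                                 "site_rc": (rr, cc)}))
        recordings.append(LSPSRecording(
            grid=grid, sweeps=sweeps, holding_mv=HOLDING_FOR_MODE[mode],
            cell_id=f"cell{ci}", group="synthetic"))
        cell_truths.append(LSPSCellTruth(site_class=cls, amplitude_pa=amp))
    return recordings, LSPSTruth(cells=cell_truths, layer_profile=profile,
                                 mode=mode)


# ---------------------------------------------------------------------------
# LTP slope series

def gen_ltp_session(baseline_slope: float = 0.15,
                    potentiation_factor: float = 1.5,
                    noise_cv: float = 0.05,
                    interval_s: float = 20.0,
                    pre_minutes: float = 10.0,
                    post_minutes: float = 60.0,
                    seed: int = 0) -> LTPTimecourse:
    """Baseline / post-induction fEPSP slope-magnitude series.

    Sweeps every ``interval_s`` (0.05 Hz); slopes sit at the baseline value
    before induction and at baseline x factor after, with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.
    """
    if baseline_slope <= 0 or potentiation_factor <= 0:
        raise ValueError("slope and factor must be positive")
    rng = np.random.default_rng(seed)
    induction = pre_minutes * 60.0
    times = np.arange(0.0, (pre_minutes + post_minutes) * 60.0, interval_s)
    slopes = np.where(times < induction, baseline_slope,
                      baseline_slope * potentiation_factor)
    if noise_cv > 0:
        slopes = slopes * (1.0 + noise_cv * rng.standard_normal(times.size))
    return LTPTimecourse(times_s=times, slopes=slopes,
                         induction_time_s=induction,
                         meta={"potentiation_factor": potentiation_factor,
                               "noise_cv": noise_cv})


# ---------------------------------------------------------------------------
# synthetic field sweeps (volley + fEPSP templates)

def gen_fepsp_sweep(slope_mv_per_ms: float = -0.5,
                    volley_amp_mv: float = 0.2,
                    stim_onset_s: float = 0.01,
                    sampling_rate_hz: float = 20000.0,
                    duration_s: float = 0.05,
                    noise_sd_mv: float = 0.0, seed: int = 0,
                    second_onset_s: float | None = None,
                    second_factor: float = 1.0) -> TraceSweep:
    """Constructed field sweep: stimulus artifact, a sharp fiber-volley
    trough 2 ms later, then a linear fEPSP segment of the requested slope.

    With ``second_onset_s`` a second stimulus/response pair (scaled by
    ``second_factor``) is added for paired-pulse measurements.
    """
    fs = sampling_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    def template(onset, scale):
        y = np.zeros(n)
        # brief biphasic artifact
        y += 2.0 * np.exp(-0.5 * ((t - onset) / 1e-4) ** 2)
        # sharp volley trough at onset + 2 ms (sigma 0.1 ms)
        y -= scale * volley_amp_mv * np.exp(
            -0.5 * ((t - onset - 0.002) / 1e-4) ** 2)
        # linear fEPSP from onset+2.3 ms for 1.5 ms, then linear recovery
        t0, ramp, rec = onset + 0.0023, 0.0015, 0.006
        depth = scale * slope_mv_per_ms * ramp * 1e3   # mV at ramp end
        seg = (t >= t0) & (t < t0 + ramp)
        y[seg] += depth * (t[seg] - t0) / ramp
        seg2 = (t >= t0 + ramp) & (t < t0 + ramp + rec)
        y[seg2] += depth * (1.0 - (t[seg2] - t0 - ramp) / rec)
        return y

    x = template(stim_onset_s, 1.0)
    onsets = {"stim_onset_s": stim_onset_s}
    if second_onset_s is not None:
        x += template(second_onset_s, second_factor)
        onsets["stim2_onset_s"] = second_onset_s
    if noise_sd_mv > 0:
        x = x + rng.normal(0.0, noise_sd_mv, n)
    return TraceSweep(x, fs, units="mV", annotations=onsets)
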