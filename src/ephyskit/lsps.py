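"""Laser-scanning photostimulation (LSPS) input-map analysis.

Builds excitatory/inhibitory synaptic input maps onto a recorded neuron
from per-site photostimulation sweeps on a stimulation grid (16 x 16 sites
at 75 um spacing by default, top row aligned with the pia).  Each site is
classified as a direct somatodendritic response (short latency), a synaptic
response, no response, or excluded (clipped sweep); direct sites are
removed from all synaptic statistics.  Site strength is the
baseline-subtracted mean current over the synaptic analysis window.

Sign convention: excitatory maps (cell held at -70 mV) are inward currents
and non-positive; inhibitory maps (held at 0 mV) are outward and
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intracellular import TraceSweep, _boxcar, robust_noise_sd

SITE_NONE = 0
SITE_SYNAPTIC = 1
SITE_DIRECT = 2
SITE_EXCLUDED = 3
SITE_CLASS_NAMES = {SITE_NONE: "none", SITE_SYNAPTIC: "synaptic",
                    SITE_DIRECT: "direct", SITE_EXCLUDED: "excluded"}

#: approximate mouse V1 laminar boundaries, um below the pia (configurable;
#: rows beyond the last bound are treated as white matter and unbinned)
DEFAULT_LAYER_BOUNDS = {
    "L1": (0.0, 100.0),
    "L2/3": (100.0, 350.0),
    "L4": (350.0, 450.0),
    "L5": (450.0, 650.0),
    "L6": (650.0, 900.0),
}

HOLDING_FOR_MODE = {"excitatory": -70.0, "inhibitory": 0.0}


@dataclass(frozen=True)
class LSPSGrid:
    rows: int = 16
    cols: int = 16
    spacing_um: float = 75.0
    pia_row: int = 0
    soma_rc: tuple = (7.0, 7.5)

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        r, c = self.soma_rc
        if not (0 <= r <= self.rows - 1 and 0 <= c <= self.cols - 1):
            raise ValueError("soma location outside grid")

    def depth_um(self, row) -> np.ndarray:
        """Depth below the pia of a grid row (top row = pia surface)."""
        return (np.asarray(row, dtype=float) - self.pia_row) * self.spacing_um

    def distance_um(self, row, col) -> np.ndarray:
        dr = (np.asarray(row, dtype=float) - self.soma_rc[0])
        dc = (np.asarray(col, dtype=float) - self.soma_rc[1])
        return np.hypot(dr, dc) * self.spacing_um


@dataclass
class LSPSRecording:
    grid: LSPSGrid
    sweeps: list          # row-major, one TraceSweep per site
    holding_mv: float
    cell_id: str = "cell"
    group: str = ""

    def __post_init__(self) -> None:
        n = self.grid.rows * self.grid.cols
        if len(self.sweeps) != n:
            raise ValueError(f"expected {n} sweeps, got {len(self.sweeps)}")
        rates = {s.sampling_rate_hz for s in self.sweeps}
        if len(rates) != 1:
            raise ValueError("all sweeps must share one sampling rate")


@dataclass
class InputMap:
    grid: LSPSGrid
    site_class: np.ndarray   # (rows, cols) int codes
    amplitude_pa: np.ndarray  # signed; 0 where class is none
    mode: str
    cell_id: str = "cell"


@dataclass
class LaminarProfile:
    layer_names: list
    bounds_um: list          # (lo, hi) per layer
    mean_pa: np.ndarray      # NaN where a bin has no sites
    n_sites: np.ndarray
    combined: dict = field(default_factory=dict)


@dataclass
class ClassifyConfig:
    """Windows and threshold for per-site response classification.

    Latency windows are relative to laser onset: deflections beginning in
    the direct window are direct somatodendritic responses, those starting
    in the synaptic window are synaptic.  The detection threshold defaults
    to ``threshold_sd`` times a robust noise SD of the raw pre-stimulus
    baseline; onset detection runs on a boxcar-smoothed trace.
    """

    direct_window_s: tuple = (0.0, 0.007)
    synaptic_window_s: tuple = (0.007, 0.050)
    threshold_sd: float = 3.0
    threshold_pa: float | None = None
    smooth_ms: float = 1.0
    saturation_pa: float | None = None
    estimator: str = "mean"  # or "peak"


def classify_site(sweep: TraceSweep, mode: str,
                  config: ClassifyConfig | None = None):
    """Classify one site's sweep and measure its input strength.

    Returns ``(site_class, amplitude_pa)``.  The amplitude is the
    baseline-subtracted mean (or peak) current over the synaptic window,
    signed by mode (inward negative), and 0 for unresponsive sites.
    """
    config = config or ClassifyConfig()
    if mode not in HOLDING_FOR_MODE:
        raise ValueError(f"unknown mode {mode!r}")
    onset = sweep.annotations.get("laser_onset_s")
    if onset is None:
        raise ValueError("sweep lacks a laser-onset marker")
    d0, d1 = config.direct_window_s
    s0, s1 = config.synaptic_window_s
    if not (d0 <= d1 <= s0 <= s1):
        raise ValueError("windows must be ordered: direct before synaptic")

    x = sweep.samples
    fs = sweep.sampling_rate_hz
    if (config.saturation_pa is not None
            and np.abs(x).max() >= config.saturation_pa):
        return SITE_EXCLUDED, 0.0

    i_on = sweep.index_at(onset)
    baseline = x[:i_on].mean() if i_on > 0 else 0.0
    sign = -1.0 if mode == "excitatory" else 1.0
    r = sign * (x - baseline)  # rectified: responses positive

    if config.threshold_pa is not None:
        threshold = config.threshold_pa
    else:
        threshold = config.threshold_sd * robust_noise_sd(r[:i_on]) if i_on \
            else 0.0
    det = _boxcar(r, max(1, int(round(config.smooth_ms * 1e-3 * fs))))

    i_end = min(x.size, i_on + int(round(s1 * fs)))
    seg = det[i_on:i_end]
    above = np.flatnonzero(seg > threshold)
    if above.size == 0:
        return SITE_NONE, 0.0
    latency = above[0] / fs

    j0 = i_on + int(round(s0 * fs))
    j1 = min(x.size, i_on + int(round(s1 * fs)))
    if config.estimator == "mean":
        strength = float(r[j0:j1].mean())
    elif config.estimator == "peak":
        strength = float(r[j0:j1].max())
    else:
        raise ValueError(f"unknown estimator {config.estimator!r}")
    amplitude = sign * max(strength, 0.0)

    if d0 <= latency < d1:
        return SITE_DIRECT, amplitude
    return SITE_SYNAPTIC, amplitude


def build_input_map(rec: LSPSRecording, mode: str,
                    config: ClassifyConfig | None = None) -> InputMap:
    """Classify all grid sites of one recording into an input map.

    The holding potential must match the mode (-70 mV excitatory, 0 mV
    inhibitory).  Direct-class sites are flagged and carry no weight in
    synaptic statistics downstream.
    """
    if mode not in HOLDING_FOR_MODE:
        raise ValueError(f"unknown mode {mode!r}")
    if not np.isclose(rec.holding_mv, HOLDING_FOR_MODE[mode], atol=5.0):
        raise ValueError(
            f"holding {rec.holding_mv} mV inconsistent with mode {mode!r}")
    g = rec.grid
    cls = np.empty((g.rows, g.cols), dtype=int)
    amp = np.zeros((g.rows, g.cols))
    for i, sweep in enumerate(rec.sweeps):
        r, c = divmod(i, g.cols)
        cls[r, c], amp[r, c] = classify_site(sweep, mode, config)
    amp[(cls == SITE_NONE) | (cls == SITE_EXCLUDED)] = 0.0
    return InputMap(grid=g, site_class=cls, amplitude_pa=amp, mode=mode,
                    cell_id=rec.cell_id)


def _synaptic_mask(m: InputMap) -> np.ndarray:
    """Sites contributing to synaptic statistics: synaptic or none."""
    return (m.site_class == SITE_SYNAPTIC) | (m.site_class == SITE_NONE)


def average_maps(maps: list, alignment: str = "pia-row"):
    """Average maps across cells; direct/excluded sites are dropped from
    each site's n.  Returns ``(mean_amplitude, per_site_n)`` arrays.

    ``alignment='pia-row'`` averages sites in register (all grids share the
    pia-aligned top row); ``'soma-centered'`` shifts each map by its
    integer-rounded soma offset before averaging.
    """
    if not maps:
        raise ValueError("need at least one map")
    modes = {m.mode for m in maps}
    if len(modes) != 1:
        raise ValueError("cannot average maps of mixed modes")
    shapes = {m.amplitude_pa.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("maps must share grid geometry")
    shape = shapes.pop()

    total = np.zeros(shape)
    n = np.zeros(shape, dtype=int)
    if alignment == "pia-row":
        for m in maps:
            mask = _synaptic_mask(m)
            total[mask] += m.amplitude_pa[mask]
            n[mask] += 1
    elif alignment == "soma-centered":
        ref = maps[0].grid.soma_rc
        for m in maps:
            dr = int(round(ref[0] - m.grid.soma_rc[0]))
            dc = int(round(ref[1] - m.grid.soma_rc[1]))
            mask = _synaptic_mask(m)
            rr, cc = np.nonzero(mask)
            r2, c2 = rr + dr, cc + dc
            keep = (r2 >= 0) & (r2 < shape[0]) & (c2 >= 0) & (c2 < shape[1])
            total[r2[keep], c2[keep]] += m.amplitude_pa[rr[keep], cc[keep]]
            n[r2[keep], c2[keep]] += 1
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return mean, n


def laminar_profile(input_map: InputMap,
                    layer_bounds: dict | None = None,
                    combine: tuple = ("L2/3",)) -> LaminarProfile:
    """Mean input strength per cortical-layer depth bin.

    Each grid row is assigned to the layer whose half-open depth interval
    [lo, hi) contains it; the per-layer value is the mean amplitude over
    that layer's contributing (synaptic or none) sites.  ``combine`` lists
    layers whose pooled mean is reported as a combined strength (e.g.
    ``("L2/3", "L5")`` for combined excitatory+inhibitory source layers).
    """
    bounds = layer_bounds or DEFAULT_LAYER_BOUNDS
    g = input_map.grid
    depths = g.depth_um(np.arange(g.rows))
    mask = _synaptic_mask(input_map)
    names, lohi, means, ns = [], [], [], []
    layer_rows = {}
    for name, (lo, hi) in bounds.items():
        rows = np.flatnonzero((depths >= lo) & (depths < hi))
        layer_rows[name] = rows
        sel = mask[rows, :]
        vals = input_map.amplitude_pa[rows, :][sel]
        names.append(name)
        lohi.append((lo, hi))
        ns.append(vals.size)
        means.append(vals.mean() if vals.size else np.nan)
    combined = {}
    member_rows = [layer_rows[n] for n in combine if n in layer_rows]
    if member_rows:
        rows = np.concatenate(member_rows)
        sel = mask[rows, :]
        vals = input_map.amplitude_pa[rows, :][sel]
        combined["+".join(combine)] = float(vals.mean()) if vals.size else np.nan
    return LaminarProfile(layer_names=names, bounds_um=lohi,
                          mean_pa=np.array(means), n_sites=np.array(ns),
                          combined=combined)


def mean_map_profile(maps: list, layer_bounds: dict | None = None,
                     combine: tuple = ("L2/3",)) -> LaminarProfile:
    """Laminar profile of the across-cell average map (pia-row aligned)."""
    mean, n = average_maps(maps)
    g = maps[0].grid
    # wrap the averaged map as an InputMap: sites with n=0 become excluded
    cls = np.where(n > 0, SITE_SYNAPTIC, SITE_EXCLUDED)
    avg = InputMap(grid=g, site_class=cls,
                   amplitude_pa=np.nan_to_num(mean), mode=maps[0].mode,
                   cell_id="average")
    return laminar_profile(avg, layer_bounds, combine)
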