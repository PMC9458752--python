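"""Single-unit ocular-dominance scoring.

Implements the in-vivo ocular-dominance pipeline for binocular V1 units
recorded under monocular deprivation experiments: orientation tuning from
per-trial spike counts, the 50%-above-blank inclusion rule, the ocular
dominance index ODI = (IE - CE)/(IE + CE), the seven-category scheme, the
per-mouse contralateral bias index (CBI) and the ND-vs-MD group comparison.

Sign convention: ODI = -1 is purely contralateral-driven, +1 purely
ipsilateral; CBI = 1 means a fully contralateral-dominated mouse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as ek_stats
from .synth import StimProtocol

EYES = ("contra", "ipsi")

#: category bin edges on ODI; bins are half-open [lower, upper), the last
#: bin closed at +1, so -0.75 falls in category 2 and 0.15 in category 5.
CATEGORY_EDGES = np.array([-0.75, -0.45, -0.15, 0.15, 0.45, 0.75])

#: per-category CBI weights; CBI = 0.5 + sum(n_k * w_k) / (2 N)
CBI_WEIGHTS = np.array([1.0, 2 / 3, 1 / 3, 0.0, -1 / 3, -2 / 3, -1.0])


@dataclass
class ODConfig:
    """Analysis conventions for the OD pipeline.

    response_mode
        ``"global_pref"`` (default): CE and IE are each eye's
        baseline-subtracted response at the single orientation that
        maximises the evoked rate over both eyes.  ``"per_eye_pref"``:
        each eye's response at its own preferred orientation.
    inclusion_factor
        Units are included when the raw (not baseline-subtracted) rate at
        the preferred orientation of the better eye is at least this
        multiple of the blank rate (1.5 = "50% greater").
    """

    response_mode: str = "global_pref"
    inclusion_factor: float = 1.5


@dataclass
class OrientationTuning:
    unit_id: str
    orientations_deg: np.ndarray
    evoked_hz: np.ndarray        # (2, K) baseline-subtracted, eyes x orientations
    raw_hz: np.ndarray           # (2, K) raw stimulus-window rates
    blank_hz: float
    preferred_deg: dict          # per eye
    preferred_evoked_hz: dict    # per eye


@dataclass
class ODUnitResult:
    unit_id: str
    ce: float
    ie: float
    odi: float
    category: int
    included: bool


@dataclass
class MouseODSummary:
    mouse_id: str
    condition: str
    counts: np.ndarray  # n1..n7
    n: int
    cbi: float


@dataclass
class ODGroupResult:
    nd_odi: np.ndarray
    md_odi: np.ndarray
    nd_cbi: np.ndarray
    md_cbi: np.ndarray
    nd_counts: np.ndarray
    md_counts: np.ndarray
    ks: ek_stats.TestResult
    cbi_t: ek_stats.TestResult
    dropped_mice: list = field(default_factory=list)


def compute_odi(ce: float, ie: float) -> float:
    """ODI = (IE - CE)/(IE + CE); requires non-negative rates, ce+ie > 0."""
    if ce < 0 or ie < 0:
        raise ValueError("CE and IE must be non-negative")
    total = ce + ie
    if total <= 0:
        raise ValueError("undefined ODI: CE + IE = 0 (unit should be excluded)")
    return (ie - ce) / total


def odi_to_category(odi: float) -> int:
    """Map an ODI in [-1, 1] to the seven-category scheme (1..7)."""
    if not -1.0 <= odi <= 1.0:
        raise ValueError(f"ODI {odi} outside [-1, 1]")
    return int(np.digitize(odi, CATEGORY_EDGES)) + 1


def compute_cbi(counts) -> float:
    """Contralateral bias index from seven-category counts n1..n7.

    CBI = [(n1-n7) + (2/3)(n2-n6) + (1/3)(n3-n5) + N] / (2N); 1 = fully
    contralateral (all units category 1), 0 = fully ipsilateral.
    """
    n = np.asarray(counts, dtype=float)
    if n.shape != (7,):
        raise ValueError("expected 7 category counts")
    if np.any(n < 0):
        raise ValueError("category counts must be non-negative")
    total = n.sum()
    if total == 0:
        raise ValueError("empty summary: no included units")
    return float(((n[0] - n[6]) + (2 / 3) * (n[1] - n[5])
                  + (1 / 3) * (n[2] - n[4]) + total) / (2 * total))


# ---------------------------------------------------------------------------
# trial-table handling

def _counts_from_trials(trials: pd.DataFrame, protocol: StimProtocol):
    """Pivot one unit's tidy trial rows into (2, K, R) counts + blank counts."""
    ori = np.asarray(protocol.orientations_deg)
    stim = trials[trials["eye"].isin(EYES)]
    blank = trials[trials["eye"] == "blank"]
    if blank.empty:
        raise ValueError("missing blank trials: baseline rate undefined")
    counts = np.full((2, ori.size, protocol.repeats_per_condition), np.nan)
    for ei, eye in enumerate(EYES):
        sub = stim[stim["eye"] == eye]
        for ki, o in enumerate(ori):
            vals = sub.loc[sub["orientation_deg"] == o, "spike_count"].to_numpy()
            if vals.size != protocol.repeats_per_condition:
                raise ValueError(
                    f"unit is missing trials for eye={eye}, orientation={o}")
            counts[ei, ki, :] = vals
    return counts, blank["spike_count"].to_numpy(dtype=float)


def tuning_from_trials(trials: pd.DataFrame, protocol: StimProtocol,
                       unit_id: str | None = None) -> OrientationTuning:
    """Orientation tuning for a single unit from its trial rows.

    Evoked rate = mean stimulus-window rate minus mean blank rate, per eye
    and orientation; the preferred orientation is the argmax per eye, ties
    broken toward the lowest orientation value.
    """
    counts, blank_counts = _counts_from_trials(trials, protocol)
    stim_s = protocol.stim_duration
    raw = counts.mean(axis=2) / stim_s
    blank_hz = float(blank_counts.mean() / stim_s)
    evoked = raw - blank_hz
    ori = np.asarray(protocol.orientations_deg)
    pref_idx = evoked.argmax(axis=1)  # argmax takes the first (lowest) on ties
    uid = unit_id if unit_id is not None else str(trials["unit_id"].iloc[0])
    return OrientationTuning(
        unit_id=uid, orientations_deg=ori, evoked_hz=evoked, raw_hz=raw,
        blank_hz=blank_hz,
        preferred_deg={e: float(ori[pref_idx[i]]) for i, e in enumerate(EYES)},
        preferred_evoked_hz={e: float(evoked[i, pref_idx[i]])
                             for i, e in enumerate(EYES)},
    )


def passes_inclusion(tuning: OrientationTuning,
                     factor: float = 1.5) -> bool:
    """Inclusion rule: raw preferred-orientation rate >= factor x blank rate.

    Uses raw (not baseline-subtracted) rates of the better eye; with a zero
    blank rate any positive response passes.
    """
    raw_pref = float(tuning.raw_hz.max())
    if tuning.blank_hz <= 0:
        return raw_pref > 0
    return raw_pref >= factor * tuning.blank_hz


def score_unit(tuning: OrientationTuning,
               config: ODConfig | None = None) -> ODUnitResult:
    """ODI and category for one unit; negative evoked rates are clipped to 0."""
    config = config or ODConfig()
    included = passes_inclusion(tuning, config.inclusion_factor)
    if config.response_mode == "global_pref":
        k = int(tuning.evoked_hz.max(axis=0).argmax())
        ce, ie = tuning.evoked_hz[0, k], tuning.evoked_hz[1, k]
    elif config.response_mode == "per_eye_pref":
        ce = tuning.preferred_evoked_hz["contra"]
        ie = tuning.preferred_evoked_hz["ipsi"]
    else:
        raise ValueError(f"unknown response_mode {config.response_mode!r}")
    ce, ie = max(ce, 0.0), max(ie, 0.0)
    if ce + ie <= 0:
        included = False
        odi, category = np.nan, 0
    else:
        odi = compute_odi(ce, ie)
        category = odi_to_category(odi)
    return ODUnitResult(unit_id=tuning.unit_id, ce=float(ce), ie=float(ie),
                        odi=float(odi), category=category, included=included)


# ---------------------------------------------------------------------------
# vectorised batch pipeline (used by group analysis and power simulations)

def _score_units_arrays(counts: np.ndarray, blanks: np.ndarray,
                        stim_s: float, config: ODConfig):
    """Vectorised scoring of many units.

    counts: (U, 2, K, R) spike counts; blanks: (U, B) blank counts.
    Returns (odi, category, included) arrays; odi is NaN for units with no
    response after rectification.
    """
    raw = counts.mean(axis=3) / stim_s            # (U, 2, K)
    blank = blanks.mean(axis=1) / stim_s          # (U,)
    evoked = raw - blank[:, None, None]
    raw_pref = raw.max(axis=(1, 2))
    included = np.where(blank > 0,
                        raw_pref >= config.inclusion_factor * blank,
                        raw_pref > 0)
    if config.response_mode == "global_pref":
        k = evoked.max(axis=1).argmax(axis=1)     # (U,)
        idx = np.arange(counts.shape[0])
        ce = evoked[idx, 0, k]
        ie = evoked[idx, 1, k]
    else:
        ce = evoked[:, 0, :].max(axis=1)
        ie = evoked[:, 1, :].max(axis=1)
    ce, ie = np.maximum(ce, 0.0), np.maximum(ie, 0.0)
    total = ce + ie
    responsive = total > 0
    included = included & responsive
    odi = np.full(counts.shape[0], np.nan)
    odi[responsive] = (ie[responsive] - ce[responsive]) / total[responsive]
    category = np.zeros(counts.shape[0], dtype=int)
    category[responsive] = np.digitize(odi[responsive], CATEGORY_EDGES) + 1
    return odi, category, included


def _pivot_mouse(trials: pd.DataFrame, protocol: StimProtocol):
    """Pivot a full mouse trial table into batch count arrays."""
    ori = list(protocol.orientations_deg)
    stim = trials[trials["eye"].isin(EYES)]
    units = stim["unit_id"].drop_duplicates().to_numpy()
    u_idx = {u: i for i, u in enumerate(units)}
    e_idx = {e: i for i, e in enumerate(EYES)}
    k_idx = {o: i for i, o in enumerate(ori)}
    counts = np.full((units.size, 2, len(ori),
                      protocol.repeats_per_condition), np.nan)
    counts[stim["unit_id"].map(u_idx).to_numpy(),
           stim["eye"].map(e_idx).to_numpy(),
           stim["orientation_deg"].map(k_idx).to_numpy(),
           stim["repeat"].to_numpy() - 1] = stim["spike_count"].to_numpy()
    if np.isnan(counts).any():
        raise ValueError("incomplete trial table: missing conditions")
    blank = trials[trials["eye"] == "blank"]
    if blank.empty:
        raise ValueError("missing blank trials")
    blanks = (blank.pivot_table(index="unit_id", columns="repeat",
                                values="spike_count", observed=True)
              .reindex(units).to_numpy(dtype=float))
    return units, counts, blanks


def analyze_mouse(trials: pd.DataFrame, protocol: StimProtocol,
                  condition: str = "ND", config: ODConfig | None = None,
                  mouse_id: str | None = None):
    """Score every unit of one mouse and summarise to category counts + CBI.

    Returns ``(unit_df, MouseODSummary | None)``; the summary is None when
    every unit is excluded.
    """
    config = config or ODConfig()
    units, counts, blanks = _pivot_mouse(trials, protocol)
    odi, category, included = _score_units_arrays(
        counts, blanks, protocol.stim_duration, config)
    mid = mouse_id if mouse_id is not None else str(trials["mouse_id"].iloc[0])
    unit_df = pd.DataFrame({"mouse_id": mid, "unit_id": units, "odi": odi,
                            "category": category, "included": included})
    if not included.any():
        return unit_df, None
    cat_counts = np.bincount(category[included], minlength=8)[1:8]
    summary = MouseODSummary(mouse_id=mid, condition=condition,
                             counts=cat_counts, n=int(included.sum()),
                             cbi=compute_cbi(cat_counts))
    return unit_df, summary


def od_group_analysis(nd_mice, md_mice, protocol: StimProtocol,
                      config: ODConfig | None = None) -> ODGroupResult:
    """Full ND-vs-MD comparison over lists of per-mouse trial tables.

    Pools included-unit ODI values per condition for the K-S comparison and
    compares per-mouse CBI values with a pooled-variance two-sample t test.
    Mice with no included units are dropped with a record in the result.
    """
    if not nd_mice or not md_mice:
        raise ValueError("need at least one mouse per condition")
    config = config or ODConfig()

    def _run(tables, label):
        odis, cbis, counts, dropped = [], [], np.zeros(7), []
        for i, tab in enumerate(tables):
            unit_df, summary = analyze_mouse(tab, protocol, condition=label,
                                             config=config)
            if summary is None:
                dropped.append((label, unit_df["mouse_id"].iloc[0]))
                continue
            odis.append(unit_df.loc[unit_df["included"], "odi"].to_numpy())
            cbis.append(summary.cbi)
            counts += summary.counts
        return (np.concatenate(odis) if odis else np.array([]),
                np.array(cbis), counts, dropped)

    nd_odi, nd_cbi, nd_counts, nd_drop = _run(nd_mice, "ND")
    md_odi, md_cbi, md_counts, md_drop = _run(md_mice, "MD")
    ks = ek_stats.ks_two_sample(nd_odi, md_odi)
    cbi_t = ek_stats.t_test(nd_cbi, md_cbi, method="pooled")
    return ODGroupResult(nd_odi=nd_odi, md_odi=md_odi, nd_cbi=nd_cbi,
                         md_cbi=md_cbi, nd_counts=nd_counts,
                         md_counts=md_counts, ks=ks, cbi_t=cbi_t,
                         dropped_mice=nd_drop + md_drop)
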