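# Methods

`ephyskit` quantifies cortical-circuit plasticity experiments of the kind
used to characterise early circuit phenotypes in transgenic mouse models:
in-vivo ocular-dominance (OD) plasticity scoring in binocular V1,
laser-scanning photostimulation (LSPS) input mapping onto L5 pyramidal
neurons, whole-cell intrinsic-excitability and miniature-PSC analysis, and
field-potential LTP scoring in slices. No raw recordings from such studies
are publicly deposited, so the package pairs every estimator with a seeded
synthetic-data generator that reproduces the statistical structure the
analysis assumes, and validates the estimators by parameter recovery.

## Ocular-dominance scoring

Units are scored from per-trial spike counts recorded under drifting
gratings (0.1 cpd, 95% contrast, twelve equally spaced orientations, 2-s
stimulus in 4-s trials, three repeats per orientation per eye, blank
trials interleaved for baseline).

* **Tuning.** Per eye and orientation, the evoked rate is the mean
  stimulus-window rate minus the mean blank rate; the preferred
  orientation is the argmax, ties broken toward the lowest orientation
  value (a deterministic convention; ties are measure-zero under the
  Poisson model).
* **Inclusion.** A unit is analysed only if its *raw* (not
  baseline-subtracted) rate at the preferred orientation of the better eye
  is at least 1.5× the blank rate. Raw rates are used because a
  baseline-subtracted version of a "50% above blank" rule is degenerate;
  with a zero blank rate any positive response passes.
* **ODI.** ODI = (IE − CE)/(IE + CE) with CE/IE the contralateral/
  ipsilateral evoked responses; −1 is purely contralateral. By default CE
  and IE are taken at the single orientation maximising the evoked rate
  over both eyes ("global preferred"); a per-eye-preferred convention is
  available (`ODConfig.response_mode`) because the underlying experimental
  convention is not uniquely determined. Negative evoked rates are clipped
  to zero before the ratio so ODI stays in [−1, 1]; units with CE+IE = 0
  after clipping are excluded and counted.
* **Categories and CBI.** ODI maps onto the classic seven-category scheme
  with edges −0.75, −0.45, −0.15, 0.15, 0.45, 0.75. Bins are half-open
  [lower, upper) with the last bin closed at 1 — the published edge lists
  overlap at the boundaries, so a closure convention must be chosen; this
  one is deterministic and order-preserving. The per-mouse contralateral
  bias index is CBI = [(n1−n7) + (2/3)(n2−n6) + (1/3)(n3−n5) + N]/2N,
  equivalently 0.5 plus half the mean per-unit weight
  (1, 2/3, 1/3, 0, −1/3, −2/3, −1), which is the independent oracle used
  in the tests.
* **Group comparison.** Included-unit ODIs are pooled within condition and
  compared by a two-sample K-S test; per-mouse CBIs are compared with a
  pooled-variance Student t test (integer df, matching the convention of
  printed df values). Mice with no included units are dropped and
  reported.

The generator draws per-unit eye drives log-normally (median-preserving,
sd 0.6 log units) around population means of 8 Hz (contra) and 4 Hz
(ipsi) on a 2-Hz baseline, with a shared circular-Gaussian
(von Mises-shaped, κ = 1.5) orientation profile per unit and Poisson spike
counts. These defaults give non-deprived CBIs near 0.65–0.70 and a broad
seven-category spread, the regime reported for mouse bV1.  Monocular
deprivation is a single parameter: the deprived (contralateral) eye's
drive is multiplied by (1 − `md_shift`). It does not model deprivation
kinetics, open-eye potentiation, or changes in tuning width — so recovery
tests demonstrate that the scoring pipeline detects a contra-to-ipsi shift
of the planted size, not that real deprivation produces one.

## LSPS input maps

Recordings are one sweep per site of a 16×16 stimulation grid (75 μm
spacing, top row on the pia), cells held at −70 mV (excitatory maps,
inward currents) or 0 mV (inhibitory, outward). Per site:

* The trace is baseline-subtracted (pre-stimulus mean) and rectified by
  mode. Onset detection runs on a 1-ms boxcar-smoothed copy against a
  threshold of 3× a robust noise SD (1.4826×MAD) of the *raw* pre-stimulus
  baseline; smoothing is needed because a per-sample 3-SD rule at 10 kHz
  would fire constantly on noise alone.
* Deflections starting within 0–7 ms of the laser are **direct**
  somatodendritic responses; 7–50 ms are **synaptic**; otherwise the site
  is **none**. The latency cutoffs are the standard choice for
  glutamate-uncaging maps and are configurable — they are a declared
  convention, not a reproduced one. Clipped sweeps are **excluded**.
* Site strength is the baseline-subtracted *mean* current over the
  synaptic window (a peak estimator is available). Direct and excluded
  sites carry no weight in any synaptic statistic.

Maps are averaged across cells in pia-aligned register (soma-centered
alignment available), each site's n counting only cells where that site
was synaptic or none. Laminar profiles bin sites by depth below the pia
using configurable boundaries defaulting to mouse V1 approximations
(L1 0–100, L2/3 100–350, L4 350–450, L5 450–650, L6 650–900 μm); combined
layer strengths (e.g. L2/3, or L2/3+L5 for inhibitory maps) are means over
the member sites.

The generator plants per-site strengths **on the analysis scale**: each
biexponential event is scaled so its mean over the synaptic window equals
the planted value. This makes "recover the planted laminar means" a
well-posed check of the mapping chain rather than of an arbitrary
peak-to-mean conversion factor. Near-soma sites (within 100 μm by
default) receive a large 2-ms-latency direct response instead.

## Intrinsic excitability and minis

* **Passive properties** come from a −5 mV voltage step: Rin =
  step / steady-state current change (steady state = final 20% of the
  step), τ from a single-exponential fit of the capacitive transient
  decay, and Cm = τ/Rin. The estimator assumes the transient decays with
  the membrane time constant (an idealisation of a well-compensated
  recording); a charge-integral estimator was considered and rejected as
  more sensitive to the blanked artifact region.
* **Spikes** are upward 0-mV crossings (2-ms refractory merging). The
  spike threshold is the voltage where dV/dt first sustains ≥ 20 V/s
  before the peak (criterion configurable); half-width is measured at half
  of (peak − threshold) with linear interpolation.
* **F-I curves** count spikes per 1-s step over the −100..+500 pA ladder.
  The shipped adaptive integrate-and-fire simulator (forward Euler,
  dt = 0.05 ms, spikes painted as one-sample markers at +30 mV) has a
  closed-form rheobase (threshold − rest)/R; at exactly rheobase the
  asymptote only reaches threshold, so the predicted first spiking step is
  the smallest ladder step strictly above it. Inter-spike intervals under
  constant drive are non-decreasing up to one integration step of jitter.
* **SFA** is ISI3/ISI5 within one step, computed at the smallest step
  evoking ≥ 8 spikes/s (≈10 Hz); requires ≥ 7 spikes.
* **Minis** are detected by threshold crossing: the rectified,
  median-baseline-subtracted trace is smoothed (1-ms boxcar) and compared
  against `threshold_sd` (default 3) times the robust raw-trace noise SD;
  above-threshold runs closer than 5 ms merge into one event, and the
  amplitude is the raw extremum. As with LSPS, the noise SD is estimated
  on the raw trace and detection runs on the smoothed one — chosen so the
  3-SD default is usable at 10–20 kHz. This detector is a deliberately
  simple, fully specified stand-in validated against planted ground truth
  (recall/precision ≥ 0.9 at a per-event SNR of 5); it is not a
  reproduction of any commercial template-matching package, and events
  below ~3 noise SDs are undetectable by construction. Statistics are the
  1-pA amplitude histogram, the empirical CDF, mean amplitude, and
  frequency = count/duration.

## fEPSP and LTP scoring

The stimulus artifact is blanked for 1 ms; the fiber volley is the first
local minimum dipping below 3× baseline noise within 1–4 ms of the
stimulus; the fEPSP slope is a least-squares line over the 1-ms window
starting 0.5 ms after the volley trough. The anchor offset is a declared
convention — "after the fiber volley" does not define the volley endpoint
— and is configurable. Input–output curves are sorted (volley amplitude,
slope) pairs with a linear-fit gain; paired-pulse ratios are slope₂/slope₁
per inter-pulse interval (20–200 ms).

Theta-burst induction is 5 trains at a 10-s interval, each a 2-s 5-Hz
series of 10 bursts of 4 pulses at 100 Hz: 200 pulses, last at 41.83 s.
LTP time courses store slope magnitudes sampled every 20 s (0.05 Hz);
slopes are normalised to the mean of the 10 min preceding induction
(×100), and the LTP magnitude is the mean normalised slope over the final
10 min of the post-induction hour. Normalisation is idempotent and the
magnitude is invariant to uniform rescaling of the raw slopes.

## Statistics

Two-sample t tests work from raw values or (mean, SEM, n) summaries
(sd = sem·√n); both modes share one code path so they agree exactly when
the summary derives from the raw data. The default is the pooled-variance
Student t (df = n1+n2−2); Welch is available; all p values are two-sided.
The repeated-measures two-way ANOVA is the balanced split-plot
decomposition (between effect tested against subjects-within-groups) and
is hand-implemented because the common repeated-measures helpers do not
accept a between-subjects factor; a zero error term at double precision
reports an infinite F with p = 0. K-S and Mann-Whitney tests wrap scipy
(exact Mann-Whitney p for combined n ≤ 10 without ties). Sidak adjustment
is 1−(1−p)^m. The outlier rule removes values with |z| > 2.5 in a single
pass using the full-sample mean and SD — a fixed a-priori criterion, not
an iterative one.

## Problem sizes and numerical choices

The recovery suites use the study-scale designs throughout: 7 mice × 30
units per condition for the OD power simulation (200 replicate
experiments; 1000 null replicates for the type-I check), 10 cells for
LSPS laminar recovery at 2-pA trace noise, 100-s mini sweeps at 10 kHz,
and the full 13-step current ladder at dt = 0.05 ms. Generators draw all
randomness from one `numpy` Generator per call seeded by the caller; no
global state is touched, and every generator is byte-reproducible for a
fixed seed.

Known limitations: the spike model is inhomogeneous-Poisson with
trial-independent rates (no adaptation, bursting or correlations); LSPS
truth assigns every site of a connected layer an input (no connection
sparsity); mini amplitudes below the detection threshold are invisible to
the detector, so measured amplitude distributions are truncated; and the
fEPSP measurement assumes the volley and EPSP are temporally separable,
which constructed test waveforms guarantee but real recordings may not.
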