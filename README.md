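# ephyskit

Quantification toolkit for cortical-circuit plasticity experiments:
ocular-dominance (OD) plasticity scoring from in-vivo single-unit
recordings, laser-scanning photostimulation (LSPS) synaptic input maps,
whole-cell intrinsic-excitability and miniature-PSC analysis, and
fEPSP/LTP scoring in slices — plus seeded synthetic-data generators for
every modality so each estimator can be validated by parameter recovery.
It is aimed at slice and in-vivo electrophysiologists who need these
standard quantifications as tested, scriptable building blocks rather
than one-off analysis scripts.

## The quantities it computes

* **Ocular dominance.** Per unit, from per-trial spike counts under
  drifting gratings: baseline-subtracted orientation tuning, the
  50%-above-blank inclusion rule, the ocular dominance index
  ODI = (IE − CE)/(IE + CE) (−1 = purely contralateral), and the classic
  seven-category assignment with edges ±0.75, ±0.45, ±0.15. Per mouse,
  the contralateral bias index
  CBI = [(n1 − n7) + ⅔(n2 − n6) + ⅓(n3 − n5) + N] / 2N,
  and the group comparison (K-S on pooled ODIs, pooled t on CBIs).
* **LSPS input maps.** Per-site classification (direct / synaptic / none /
  excluded) from latency windows, site strength as the window-mean
  current, across-cell map averaging, and laminar input profiles binned
  by cortical depth.
* **Intracellular metrics.** Rin and Cm from −5 mV steps (Cm = τ/Rin),
  spike threshold/half-width, F-I curves over −100..+500 pA steps,
  spike-frequency adaptation SFA = ISI3/ISI5, and threshold-crossing
  mini-PSC detection with 1-pA amplitude histograms and ECDFs.
* **LTP.** Fiber-volley anchored 1-ms fEPSP slope, input–output curves,
  paired-pulse ratios (20–200 ms), theta-burst induction timing
  (4 pulses @ 100 Hz × 10 bursts @ 5 Hz × 5 trains), and LTP magnitude as
  the last-10-min mean of baseline-normalised slope.
* **Statistics.** Pooled/Welch t tests from raw data *or* printed
  mean ± SEM summaries, two-sample K-S, Mann-Whitney U, split-plot
  repeated-measures two-way ANOVA, Sidak adjustment, and a fixed 2.5-SD
  outlier rule.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```bash
python examples/od_plasticity.py
```

simulates a 7-mouse non-deprived (ND) cohort and a 7-mouse monocularly
deprived (MD) cohort (30 units each, deprived-eye drive halved) and runs
the full scoring chain:

```
ND mean CBI: 0.696   MD mean CBI: 0.494
CBI t test: t(12) = 6.46, p = 3.1e-05
pooled-ODI K-S test: D = 0.367, p = 6e-13
ND category counts (1..7): [22 77 60 26 19  4  2]
MD category counts (1..7): [14 29 42 31 50 32 12]
```

The ND cohort is contralaterally biased (CBI ≈ 0.7, categories piled at
the low end); deprivation of the contralateral eye shifts units toward
the ipsilateral categories and drops the CBI toward 0.5 — the
plasticity effect the pipeline is built to detect. The other scripts in
`examples/` demonstrate LSPS mapping, intrinsic excitability, mini
detection, LTP scoring and the summary statistics, one capability each.

A thin CLI mirrors the library (`ephyskit simulate-od`, `od-analyze`,
`simulate-lsps`, `lsps-map`, `intrinsic`, `minis`, `ltp`, `summary-t`,
`report`); run `ephyskit --help`.

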