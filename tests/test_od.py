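"""Ocular-dominance pipeline: tuning, inclusion, ODI, categories, CBI."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ephyskit import od, synth
from ephyskit.od import (CBI_WEIGHTS, ODConfig, OrientationTuning,
                         compute_cbi, compute_odi, odi_to_category,
                         passes_inclusion, tuning_from_trials)

from conftest import make_unit_trials


def _tuning(raw_contra, raw_ipsi, blank, ori=None):
    ori = np.asarray(ori if ori is not None
                     else synth.StimProtocol().orientations_deg, float)
    raw = np.stack([np.asarray(raw_contra, float),
                    np.asarray(raw_ipsi, float)])
    evoked = raw - blank
    pref = evoked.argmax(axis=1)
    return OrientationTuning(
        unit_id="u", orientations_deg=ori, evoked_hz=evoked, raw_hz=raw,
        blank_hz=blank,
        preferred_deg={e: float(ori[pref[i]])
                       for i, e in enumerate(("contra", "ipsi"))},
        preferred_evoked_hz={e: float(evoked[i, pref[i]])
                             for i, e in enumerate(("contra", "ipsi"))})


class TestTuning:
    def test_flat_counts_give_zero_evoked_rates(self, protocol):
        counts = np.full((2, 12, 3), 4)
        trials = make_unit_trials(counts, np.full(72, 4), protocol)
        t = tuning_from_trials(trials, protocol)
        assert np.allclose(t.evoked_hz, 0.0)
        assert t.blank_hz == pytest.approx(2.0)

    def test_doubled_count_at_90_sets_contra_preferred(self, protocol):
        counts = np.full((2, 12, 3), 4)
        k90 = list(protocol.orientations_deg).index(90.0)
        counts[0, k90, :] = 8
        trials = make_unit_trials(counts, np.full(72, 4), protocol)
        t = tuning_from_trials(trials, protocol)
        assert t.preferred_deg["contra"] == 90.0

    def test_missing_blank_trials_raise(self, protocol):
        counts = np.full((2, 12, 3), 4)
        trials = make_unit_trials(counts, np.full(72, 4), protocol)
        with pytest.raises(ValueError, match="blank"):
            tuning_from_trials(trials[trials["eye"] != "blank"], protocol)

    def test_planted_preferred_orientation_recovered(self, protocol):
        # Sharply tuned Poisson unit (kappa = 6, so neighbouring
        # orientations are well separated) with drive/baseline = 3 and
        # preferred 150 degrees; the argmax tuning estimate should recover
        # 150 nearly always.
        rng = np.random.default_rng(42)
        n_sim, hits = 500, 0
        ori = protocol.orientations_deg
        gain = synth.orientation_gain(ori, 150.0, 6.0)
        rate = 2.0 + 6.0 * gain  # baseline 2 Hz, drive 6 Hz (SNR 3)
        for _ in range(n_sim):
            counts = rng.poisson(rate * 2.0, size=(3, ori.size)).mean(axis=0)
            if ori[np.argmax(counts)] == 150.0:
                hits += 1
        assert hits / n_sim >= 0.95


class TestInclusion:
    @pytest.mark.parametrize("raw_pref, blank, expected", [
        (3.1, 2.0, True),    # 1.55x blank: 50% greater criterion met
        (2.9, 2.0, False),   # 1.45x blank: below criterion
        (0.0, 0.0, False),   # no response at all
        (0.5, 0.0, True),    # zero blank: any positive response passes
    ])
    def test_fifty_percent_rule(self, raw_pref, blank, expected):
        raw = np.full(12, min(raw_pref, blank))
        raw[3] = raw_pref
        t = _tuning(raw, np.full(12, 0.0), blank)
        assert passes_inclusion(t) is expected


class TestODI:
    @pytest.mark.parametrize("ce, ie, expected", [
        (10.0, 0.0, -1.0), (5.0, 5.0, 0.0), (3.0, 7.0, 0.4)])
    def test_odi_values(self, ce, ie, expected):
        assert compute_odi(ce, ie) == pytest.approx(expected)

    def test_no_response_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_odi(0.0, 0.0)

    @pytest.mark.parametrize("odi, cat", [
        (-1.0, 1), (0.4, 5), (-0.75, 2), (1.0, 7), (0.15, 5), (-0.149, 4)])
    def test_category_bins(self, odi, cat):
        assert odi_to_category(odi) == cat

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            odi_to_category(1.01)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_every_odi_maps_to_exactly_one_category(self, odi):
        assert odi_to_category(odi) in range(1, 8)

    @given(st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))
    def test_category_non_decreasing_in_odi(self, a, b):
        lo, hi = sorted((a, b))
        assert odi_to_category(lo) <= odi_to_category(hi)


counts7 = st.lists(st.integers(0, 50), min_size=7, max_size=7).filter(
    lambda c: sum(c) > 0)


class TestCBI:
    @pytest.mark.parametrize("counts, expected", [
        ((20, 0, 0, 0, 0, 0, 0), 1.0),
        ((0, 0, 0, 20, 0, 0, 0), 0.5),
        ((0, 0, 0, 0, 0, 0, 20), 0.0)])
    def test_anchors(self, counts, expected):
        assert compute_cbi(counts) == pytest.approx(expected)

    def test_empty_counts_error(self):
        with pytest.raises(ValueError, match="empty"):
            compute_cbi([0] * 7)

    @given(counts7)
    def test_bounds_and_mirror_symmetry(self, counts):
        cbi = compute_cbi(counts)
        assert 0.0 <= cbi <= 1.0
        assert compute_cbi(counts[::-1]) == pytest.approx(1.0 - cbi)

    @given(counts7)
    def test_matches_per_unit_weighted_sum_oracle(self, counts):
        # independent oracle: CBI = 0.5 + mean per-unit weight / 2
        n = np.asarray(counts, float)
        per_unit = np.repeat(CBI_WEIGHTS, counts)
        oracle = 0.5 + per_unit.mean() / 2.0
        assert compute_cbi(counts) == pytest.approx(oracle, abs=1e-12)

    @given(counts7, st.integers(0, 5))
    def test_moving_a_unit_up_a_category_never_raises_cbi(self, counts, k):
        counts = list(counts)
        if counts[k] == 0:
            counts[k] = 1
        moved = list(counts)
        moved[k] -= 1
        moved[k + 1] += 1
        assert compute_cbi(moved) <= compute_cbi(counts) + 1e-12


class TestGroupAnalysis:
    def test_identical_groups_give_null_statistics(self, protocol):
        tab, _ = synth.gen_od_dataset(protocol, synth.ODPopulation(), 20, 3,
                                      seed=7)
        mice = [g for _, g in tab.groupby("mouse_id", sort=True)]
        res = od.od_group_analysis(mice, mice, protocol)
        assert res.ks.statistic == 0.0
        assert res.cbi_t.statistic == pytest.approx(0.0, abs=1e-12)

    def test_unit_relabeling_leaves_outputs_unchanged(self, protocol):
        tab, _ = synth.gen_od_dataset(protocol, synth.ODPopulation(), 15, 2,
                                      seed=8)
        relabeled = tab.copy()
        relabeled["unit_id"] = relabeled["unit_id"].map(
            lambda u: f"renamed_{u}")
        mice = [g for _, g in tab.groupby("mouse_id", sort=True)]
        mice2 = [g for _, g in relabeled.groupby("mouse_id", sort=True)]
        r1 = od.od_group_analysis(mice, mice, protocol)
        r2 = od.od_group_analysis(mice2, mice2, protocol)
        np.testing.assert_allclose(np.sort(r1.nd_odi), np.sort(r2.nd_odi))
        np.testing.assert_allclose(r1.nd_cbi, r2.nd_cbi)

    def test_response_mode_option_changes_only_the_convention(self, protocol):
        tab, _ = synth.gen_od_dataset(protocol, synth.ODPopulation(), 20, 2,
                                      seed=9)
        mice = [g for _, g in tab.groupby("mouse_id", sort=True)]
        for mode in ("global_pref", "per_eye_pref"):
            res = od.od_group_analysis(mice, mice, protocol,
                                       od.ODConfig(response_mode=mode))
            assert np.all(np.abs(res.nd_odi) <= 1.0)

    def test_zero_drive_units_fail_inclusion_at_chance_level(self, protocol):
        # With no evoked drive the inclusion rule passes only on Poisson
        # fluctuation; compare against an independent Monte-Carlo estimate
        # of the same exceedance probability.
        pop = synth.ODPopulation(contra_drive_hz=0.0, ipsi_drive_hz=0.0,
                                 baseline_hz=2.0)
        tab, _ = synth.gen_od_dataset(protocol, pop, 1000, 1, seed=10)
        unit_df, _ = od.analyze_mouse(tab, protocol)
        frac = unit_df["included"].mean()

        rng = np.random.default_rng(123)
        lam = 2.0 * protocol.stim_duration
        n_mc = 4000
        stim = rng.poisson(lam, (n_mc, 24, 3)).mean(axis=2)
        blank = rng.poisson(lam, (n_mc, 72)).mean(axis=1)
        chance = np.mean(stim.max(axis=1) >= 1.5 * blank)
        assert frac == pytest.approx(chance, abs=0.05)

    def test_increasing_ipsi_drive_shifts_mean_odi_toward_ipsi(self, protocol):
        means = []
        for i, drive in enumerate((2.0, 4.0, 8.0)):
            pop = synth.ODPopulation(contra_drive_hz=4.0,
                                     ipsi_drive_hz=drive, drive_sigma=0.3)
            tab, _ = synth.gen_od_dataset(protocol, pop, 150, 1, seed=20)
            unit_df, _ = od.analyze_mouse(tab, protocol)
            means.append(unit_df.loc[unit_df["included"], "odi"].mean())
        assert means[0] < means[1] < means[2]
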