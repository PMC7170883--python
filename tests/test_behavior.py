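"""Attenuation scoring, group comparison and USV syllable filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hearvar.behavior import (
    attenuation_scores,
    group_compare,
    usv_filter,
    usv_summaries,
)
from hearvar.simulate import sim_ppi_usv


def trial_table(rows):
    return pd.DataFrame(
        rows,
        columns=["subject", "genotype", "task", "day", "cue_level", "condition", "asr_amplitude"],
    )


def syllable(onset_s, duration_ms=50.0, freq=60.0, vol=60.0, cat="Flat"):
    return {
        "onset_s": onset_s,
        "duration_ms": duration_ms,
        "mean_freq_khz": freq,
        "volume_db": vol,
        "category": cat,
    }


class TestAttenuation:
    def test_equal_means_give_100(self):
        t = trial_table(
            [
                ("m1", "WT", "NST", 1, 1.0, "cued", 50.0),
                ("m1", "WT", "NST", 1, 1.0, "cued", 150.0),
                ("m1", "WT", "NST", 1, 1.0, "uncued", 100.0),
            ]
        )
        assert attenuation_scores(t)["att"].iloc[0] == pytest.approx(100.0)

    def test_half_suppression_gives_50(self):
        t = trial_table(
            [
                ("m1", "WT", "NST", 1, 1.0, "cued", 50.0),
                ("m1", "WT", "NST", 1, 1.0, "uncued", 100.0),
            ]
        )
        assert attenuation_scores(t)["att"].iloc[0] == pytest.approx(50.0)

    def test_missing_uncued_trials_error_names_cell(self):
        t = trial_table([("m7", "WT", "EBT", 2, 1.0, "cued", 50.0)])
        with pytest.raises(ValueError, match="m7.*EBT.*2"):
            attenuation_scores(t)

    def test_zero_uncued_mean_flagged_undefined(self):
        t = trial_table(
            [
                ("m1", "WT", "NST", 1, 1.0, "cued", 50.0),
                ("m1", "WT", "NST", 1, 1.0, "uncued", 0.0),
            ]
        )
        out = attenuation_scores(t)
        assert np.isnan(out["att"].iloc[0]) and out["undefined"].iloc[0]

    @given(
        amps=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=10),
        k=st.floats(0.01, 100.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, amps, k):
        """Multiplying every amplitude in a cell by k > 0 leaves ATT unchanged."""
        half = max(1, len(amps) // 2)
        rows = [("m", "WT", "T", 1, 1.0, "cued", a) for a in amps[:half]]
        rows += [("m", "WT", "T", 1, 1.0, "uncued", a) for a in amps[half:] or [amps[0]]]
        t1 = trial_table(rows)
        t2 = t1.assign(asr_amplitude=t1["asr_amplitude"] * k)
        a1 = attenuation_scores(t1)["att"].iloc[0]
        a2 = attenuation_scores(t2)["att"].iloc[0]
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_negative_amplitude_rejected(self):
        t = trial_table([("m1", "WT", "NST", 1, 1.0, "cued", -1.0)])
        with pytest.raises(ValueError, match=">= 0"):
            attenuation_scores(t)


class TestGroupCompare:
    @staticmethod
    def scores(values_by_group):
        rows = []
        for g, vals in values_by_group.items():
            for i, v in enumerate(vals):
                rows.append({"subject": f"{g}{i}", "genotype": g, "att": float(v)})
        return pd.DataFrame(rows)

    def test_identical_groups_f_zero(self):
        df = self.scores({"WT": [50, 60, 70], "KO": [50, 60, 70]})
        res = group_compare(df)
        assert res.f_stat == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_textbook_anova_arithmetic(self):
        # groups (1,2,3), (2,3,4), (6,7,8): SSB = 42 (df 2), SSW = 6 (df 6)
        # F = (42/2) / (6/6) = 21
        df = self.scores({"A": [1, 2, 3], "B": [2, 3, 4], "C": [6, 7, 8]})
        res = group_compare(df)
        assert res.f_stat == pytest.approx(21.0)
        assert (res.df_between, res.df_resid) == (2, 6)

    def test_covariate_adjustment_recovers_group_effect(self):
        rng = np.random.default_rng(21)
        rows = []
        cov = {}
        for g, shift in (("WT", 0.0), ("HT", 15.0)):
            for i in range(12):
                subj = f"{g}{i}"
                c = rng.normal(50, 10)
                cov[subj] = c
                rows.append(
                    {"subject": subj, "genotype": g, "att": 40 + 0.5 * c + shift + rng.normal(0, 3)}
                )
        df = pd.DataFrame(rows)
        res = group_compare(df, covariate=pd.Series(cov))
        assert res.p < 1e-4
        assert res.group_means["HT"] - res.group_means["WT"] == pytest.approx(15.0, abs=4.0)

    def test_zero_variance_covariate_rejected(self):
        df = self.scores({"WT": [1, 2, 3], "KO": [4, 5, 6]})
        cov = pd.Series({s: 7.0 for s in df["subject"]})
        with pytest.raises(ValueError, match="singular"):
            group_compare(df, covariate=cov)

    def test_group_collinear_covariate_rejected(self):
        df = self.scores({"WT": [1, 2, 3], "KO": [4, 5, 6]})
        cov = pd.Series({s: (0.0 if s.startswith("WT") else 1.0) for s in df["subject"]})
        with pytest.raises(ValueError, match="singular"):
            group_compare(df, covariate=cov)

    def test_single_group_rejected(self):
        df = self.scores({"WT": [1, 2, 3]})
        with pytest.raises(ValueError, match=">=2 groups"):
            group_compare(df)


class TestUsvFilter:
    @pytest.mark.parametrize(
        "freq,kept",
        [(34.0, False), (35.0, True), (110.0, True), (111.0, False)],
    )
    def test_frequency_bounds_inclusive(self, freq, kept):
        df = pd.DataFrame([syllable(1.0, freq=freq)])
        assert (len(usv_filter(df)) == 1) is kept

    @pytest.mark.parametrize(
        "dur,kept",
        [(7.0, False), (8.0, True), (200.0, True), (201.0, False)],
    )
    def test_duration_bounds_inclusive(self, dur, kept):
        df = pd.DataFrame([syllable(1.0, duration_ms=dur)])
        assert (len(usv_filter(df)) == 1) is kept

    def test_close_pair_both_removed(self):
        # second syllable starts 3 ms after the first ends
        df = pd.DataFrame([syllable(1.0, duration_ms=50), syllable(1.053, duration_ms=50)])
        assert len(usv_filter(df)) == 0

    def test_gap_of_exactly_5_ms_kept(self):
        df = pd.DataFrame([syllable(1.0, duration_ms=50), syllable(1.055, duration_ms=50)])
        assert len(usv_filter(df)) == 2

    def test_drop_later_policy(self):
        df = pd.DataFrame([syllable(1.0, duration_ms=50), syllable(1.053, duration_ms=50)])
        out = usv_filter(df, drop="later")
        assert len(out) == 1 and out["onset_s"].iloc[0] == 1.0

    def test_subset_and_idempotent(self):
        sim = sim_ppi_usv(3, n_per_genotype=4)
        once = usv_filter(sim.syllables)
        assert len(once) <= len(sim.syllables)
        twice = usv_filter(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_isolated_in_band_syllable_kept(self):
        df = pd.DataFrame([syllable(2.0, duration_ms=50.0, freq=60.0)])
        assert len(usv_filter(df)) == 1


class TestUsvSummaries:
    def test_single_syllable_group(self):
        df = pd.DataFrame([{**syllable(1.0, 40.0, 70.0, 55.0), "genotype": "WT"}])
        out = usv_summaries(df)
        assert out.loc[0, "mean_freq_khz"] == 70.0
        assert np.isnan(out.loc[0, "sem_freq_khz"])
        assert not out.loc[0, "sem_defined"]

    def test_planted_frequency_shift_recovered(self):
        sim = sim_ppi_usv(11, n_per_genotype=12)
        filt = usv_filter(sim.syllables)
        out = usv_summaries(filt).set_index("group")
        shift = sim.truth.usv_shifts["HT"]["freq_khz"]
        diff = out.loc["HT", "mean_freq_khz"] - out.loc["WT", "mean_freq_khz"]
        sem = np.hypot(out.loc["HT", "sem_freq_khz"], out.loc["WT", "sem_freq_khz"])
        assert abs(diff - shift) <= 2 * sem + 0.5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match=">=1 syllable"):
            usv_summaries(pd.DataFrame(columns=["genotype", "mean_freq_khz"]))


class TestPlantedPpiEffect:
    def test_low_band_flagged_not_high_band(self):
        # planted HT deficit at the low frequency only
        detection = {
            "WT": {"NST_15k": 0.6, "NST_40k": 0.6},
            "HT": {"NST_15k": 0.35, "NST_40k": 0.6},
            "KO": {"NST_15k": 0.6, "NST_40k": 0.6},
        }
        flagged_low = 0
        flagged_high = 0
        reps = 30
        for seed in range(reps):
            sim = sim_ppi_usv(seed, n_per_genotype=12, detection=detection)
            att = attenuation_scores(sim.trials)
            p_low = group_compare(att[att["task"] == "NST_15k"]).p
            p_high = group_compare(att[att["task"] == "NST_40k"]).p
            flagged_low += p_low < 0.05
            flagged_high += p_high < 0.05
        assert flagged_low / reps >= 0.8
        assert flagged_high / reps <= 0.3
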