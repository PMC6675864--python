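"""Percent time, bout counts, count/duration regressions and PK decline."""

import numpy as np
import pandas as pd
import pytest

import sleepbouts as sb

from conftest import random_hypnogram


def hyp(states, **kw):
    return sb.Hypnogram("r1", "VEH", tuple(states), **kw)


class TestPercentTime:
    def test_even_split(self):
        pct = sb.percent_time(hyp(["AW"] * 1350 + ["S2"] * 1350))
        assert pct["AW"] == 50.0 and pct["S2"] == 50.0
        assert all(pct[s] == 0.0 for s in pct if s not in ("AW", "S2"))

    def test_all_rem_combined_vs_split(self):
        h = hyp(["REMS"] * 2700)
        assert sb.percent_time(h)["REMS"] == 100.0
        split = sb.percent_time(h, rems_split=True)
        # one 2700-epoch bout: long REM by the 4-epoch cutoff
        assert split["REMS_L"] == 100.0 and split["REMS_S"] == 0.0

    def test_rem_split_attributes_epochs_by_bout_class(self):
        h = hyp(["REMS"] * 3 + ["AW"] * 2 + ["REMS"] * 5)
        pct = sb.percent_time(h, window_epochs=10, rems_split=True)
        assert pct["REMS_S"] == 30.0 and pct["REMS_L"] == 50.0

    @pytest.mark.parametrize("rems_split", [False, True])
    def test_conservation(self, rng, rems_split):
        for _ in range(20):
            h = random_hypnogram(rng, 300)
            pct = sb.percent_time(h, window_epochs=250, rems_split=rems_split)
            assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_window_exceeding_recording_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            sb.percent_time(hyp(["AW"] * 10), window_epochs=11)

    def test_window_starts_at_treatment_epoch(self):
        h = hyp(["AW"] * 5 + ["S2"] * 5, treatment_epoch=5)
        assert sb.percent_time(h, window_epochs=5)["S2"] == 100.0


class TestCountBouts:
    def test_worked_example(self):
        table = pd.DataFrame(
            {
                "subject_id": ["r1"] * 3,
                "treatment": ["VEH"] * 3,
                "state": ["AW", "PW", "AW"],
                "onset_epoch": [0, 2, 5],
                "n_epochs": [2, 3, 1],
                "duration_s": [8.0, 12.0, 4.0],
                "bin": [0, 0, 0],
            }
        )
        counts = sb.count_bouts(table)
        key = counts.set_index(["state", "bin"])["count"]
        assert key.loc[("AW", 0)] == 2 and key.loc[("PW", 0)] == 1
        # zero-filling: IS present with count 0 in every bin
        assert (counts[counts["state"] == "IS"]["count"] == 0).all()
        assert len(counts) == len(sb.SPLIT_STATES) * 3

    def test_total_matches_in_window_bouts(self, study_table):
        counts = sb.count_bouts(study_table)
        inside = study_table[study_table["bin"] != sb.OUTSIDE]
        assert counts["count"].sum() == len(inside)
        # exhaustive zero-filled grid: 18 pairs x 7 states x 3 bins
        assert len(counts) == 18 * 7 * 3


def planted_counts(rng, fold=2.0, n_subjects=6, n_bins=3, mean=8.0):
    """Poisson counts with subject/bin structure; dose means scaled by `fold`."""
    rows = []
    base = mean * rng.uniform(0.6, 1.4, size=(n_subjects, n_bins))
    for tr, f in (("VEH", 1.0), ("DOSE", fold)):
        for s in range(n_subjects):
            for b in range(n_bins):
                rows.append(
                    {
                        "subject_id": f"r{s}",
                        "treatment": tr,
                        "state": "AW",
                        "bin": b,
                        "count": rng.poisson(f * base[s, b]),
                    }
                )
    return pd.DataFrame(rows)


class TestFrequencyRatios:
    def test_identical_groups_give_ratio_one(self, rng):
        df = planted_counts(rng, fold=1.0)
        df["count"] = np.tile(df["count"][:18].to_numpy(), 2)  # dose == vehicle
        (est,) = sb.estimate_frequency_ratios(df, "AW", reference="VEH")
        assert est.ratio == pytest.approx(1.0, abs=1e-6)
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_planted_fold_change_recovered(self, rng):
        df = planted_counts(rng, fold=2.0, n_subjects=10)
        (est,) = sb.estimate_frequency_ratios(df, "AW", reference="VEH")
        assert 1.8 <= est.ratio <= 2.2
        assert est.ci_low <= 2.0 <= est.ci_high

    def test_all_zero_dose_not_estimable(self, rng):
        df = planted_counts(rng)
        df.loc[df["treatment"] == "DOSE", "count"] = 0
        (est,) = sb.estimate_frequency_ratios(df, "AW", reference="VEH")
        assert not est.estimable and np.isnan(est.ratio)

    def test_all_zero_state_is_error(self, rng):
        df = planted_counts(rng)
        df["count"] = 0
        with pytest.raises(ValueError, match="zero"):
            sb.estimate_frequency_ratios(df, "AW", reference="VEH")

    def test_missing_reference_is_error(self, rng):
        with pytest.raises(ValueError, match="reference"):
            sb.estimate_frequency_ratios(planted_counts(rng), "AW", reference="X")


def planted_durations(rng, shift_cell=None, shift=np.e, n_per_cell=50,
                      n_subjects=6, sigma=0.5):
    rows = []
    for tr in ("VEH", "DOSE"):
        for b in range(3):
            mult = shift if (tr, b) == shift_cell else 1.0
            for k in range(n_per_cell):
                rows.append(
                    {
                        "subject_id": f"r{k % n_subjects}",
                        "treatment": tr,
                        "state": "PW",
                        "bin": b,
                        "duration_s": float(
                            mult * np.exp(rng.normal(np.log(20), sigma))
                        ),
                    }
                )
    return pd.DataFrame(rows)


class TestDurationModel:
    def test_constant_durations(self):
        rows = [
            {"subject_id": f"r{k}", "treatment": tr, "state": "PW",
             "bin": b, "duration_s": 8.0}
            for tr in ("VEH", "DOSE") for b in range(3) for k in range(4)
        ]
        fit = sb.fit_duration_model(pd.DataFrame(rows), "PW")
        assert fit.f_stat == 0.0 and fit.p_value == 1.0
        assert np.allclose(fit.cells["mean_log"], np.log(8.0))

    def test_shifted_cell_detected(self, rng):
        df = planted_durations(rng, shift_cell=("DOSE", 2))
        fit = sb.fit_duration_model(df, "PW")
        assert fit.p_value < 0.05
        cell = fit.cells.query("treatment == 'DOSE' and bin == 2").iloc[0]
        grand = np.log(20)
        assert cell.ci_low > grand  # shifted by e: CI excludes the null mean

    def test_rescaling_invariance(self, rng):
        """Scaling durations shifts log-means by log(c), F unchanged."""
        df = planted_durations(rng)
        fit1 = sb.fit_duration_model(df, "PW")
        df2 = df.assign(duration_s=df["duration_s"] * 3.0)
        fit2 = sb.fit_duration_model(df2, "PW")
        assert fit2.f_stat == pytest.approx(fit1.f_stat, rel=1e-8)
        assert np.allclose(
            fit2.cells["mean_log"] - fit1.cells["mean_log"], np.log(3.0)
        )

    def test_empty_cell_reported_missing(self, rng):
        df = planted_durations(rng, n_per_cell=10)
        df = df[~((df["treatment"] == "DOSE") & (df["bin"] == 1))]
        fit = sb.fit_duration_model(df, "PW")
        assert len(fit.cells) == 5
        assert fit.cells.query("treatment == 'DOSE' and bin == 1").empty

    def test_type_one_error_calibration(self, rng):
        """Without a planted interaction the F p-value is ~uniform."""
        pvals = []
        for _ in range(60):
            fit = sb.fit_duration_model(planted_durations(rng, n_per_cell=15), "PW")
            pvals.append(fit.p_value)
        assert 0.25 < np.mean(pvals) < 0.75
        assert (np.array(pvals) < 0.05).mean() < 0.2


class TestPkDecline:
    def test_reported_three_hour_decline(self):
        assert sb.pk_decline_percent(22, 3) == pytest.approx(9.01, abs=0.05)

    def test_half_life_definition(self):
        assert sb.pk_decline_percent(22, 22) == pytest.approx(50.0)

    def test_zero_duration(self):
        assert sb.pk_decline_percent(22, 0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sb.pk_decline_percent(0, 3)
        with pytest.raises(ValueError):
            sb.pk_decline_percent(22, -1)
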