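"""Behavioral scoring: ranking, refractory period, drive, vulva and
insertion metrics, sustained transfer, binning, potency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiculate.behavior import (
    bin_refractory,
    classify_sustained_transfer,
    drive_metrics,
    insertion_metrics,
    potency,
    rank_sperm_transfer,
    refractory_period,
    vulva_metrics,
)
from spiculate.datatypes import MatingTrial
from spiculate.synthetic import TrialSpec, simulate_trials, trials_from_frame


def trial(**kwargs):
    defaults = dict(male_id="m0", outcome="neither")
    defaults.update(kwargs)
    return MatingTrial(**defaults)


def uterine(insert_s, release=(160.0, 180.0), retract=None, **kwargs):
    retract = retract if retract is not None else insert_s + 94.0
    return trial(
        insertions=[(insert_s, retract)],
        sperm_release=release,
        outcome="uterine_ejaculation",
        **kwargs,
    )


class TestRanking:
    def test_uterine_ejaculation_at_150s_scores_half(self):
        assert rank_sperm_transfer(uterine(150.0)) == pytest.approx(0.5)

    def test_insert_at_cap_without_ejaculation_scores_two(self):
        t = trial(insertions=[(300.0, 340.0)], outcome="insert_no_ejaculation")
        assert rank_sperm_transfer(t) == pytest.approx(2.0)

    def test_neither_scores_four(self):
        assert rank_sperm_transfer(trial()) == pytest.approx(4.0)

    def test_ectopic_without_insert_scores_three(self):
        t = trial(outcome="ectopic_ejaculation")
        assert rank_sperm_transfer(t) == pytest.approx(3.0)

    def test_inconsistent_outcome_rejected(self):
        with pytest.raises(ValueError):
            trial(outcome="uterine_ejaculation")  # no insertion, no release

    @given(
        t1=st.floats(1.0, 299.0),
        t2=st.floats(1.0, 299.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_insertion_time(self, t1, t2):
        if t1 == t2:
            return
        early, late = sorted([t1, t2])
        s_early = rank_sperm_transfer(uterine(early))
        s_late = rank_sperm_transfer(uterine(late))
        assert s_early < s_late

    def test_category_order_dominates_at_cap(self):
        # a category-k male at the cap scores below any category-(k+1) male
        cat0 = rank_sperm_transfer(uterine(300.0))
        cat1 = rank_sperm_transfer(
            trial(insertions=[(300.0, 320.0)], outcome="insert_no_ejaculation")
        )
        cat2 = rank_sperm_transfer(trial(outcome="ectopic_ejaculation"))
        cat3 = rank_sperm_transfer(trial())
        assert cat0 < cat1 < cat2 <= cat3


class TestRefractory:
    def test_interval_between_first_two_insertions(self):
        t = trial(
            insertions=[(100.0, 150.0), (820.0, 860.0)],
            outcome="insert_no_ejaculation",
        )
        assert refractory_period(t) == pytest.approx(720.0)

    def test_single_insertion_undefined(self):
        t = trial(insertions=[(100.0, 150.0)], outcome="insert_no_ejaculation")
        assert refractory_period(t) is None

    def test_simulated_cohort_median_matches_generator(self):
        spec = TrialSpec(n_males=200, p_insert=1.0, seed=6)
        trials = trials_from_frame(simulate_trials(spec))
        rps = np.array([refractory_period(t) for t in trials], dtype=float)
        # moment-matched lognormal(720, 390): median = mean / sqrt(1 + cv^2)
        gen_median = 720.0 / math.sqrt(1.0 + (390.0 / 720.0) ** 2)
        assert abs(np.median(rps) - gen_median) / gen_median < 0.10


class TestDriveMetrics:
    def test_first_commencement(self):
        t = trial(placed_s=0.0, commence_s=[34.0])
        assert drive_metrics(t)["first_commencement_s"] == pytest.approx(34.0)

    def test_second_commencement_from_retraction(self):
        t = trial(
            commence_s=[30.0, 500.0],
            insertions=[(100.0, 200.0)],
            outcome="insert_no_ejaculation",
        )
        assert drive_metrics(t)["second_commencement_s"] == pytest.approx(300.0)

    def test_missing_second_commencement_undefined(self):
        t = trial(
            commence_s=[30.0],
            insertions=[(100.0, 200.0)],
            outcome="insert_no_ejaculation",
        )
        assert drive_metrics(t)["second_commencement_s"] is None


class TestVulvaMetrics:
    def test_contact_durations_sum(self):
        t = trial(vulva_contacts=[(10.0, 20.0), (30.0, 45.0)], vulva_passes=3)
        out = vulva_metrics(t)
        assert out["total_time_at_vulva_s"] == pytest.approx(25.0)
        assert out["passes"] == 3

    def test_no_contacts_zero(self):
        assert vulva_metrics(trial())["total_time_at_vulva_s"] == 0.0

    def test_contact_spanning_insertion_truncated(self):
        t = trial(
            vulva_contacts=[(90.0, 130.0)],
            insertions=[(100.0, 160.0)],
            outcome="insert_no_ejaculation",
        )
        assert vulva_metrics(t)["total_time_at_vulva_s"] == pytest.approx(10.0)

    def test_overlapping_contacts_rejected(self):
        t = trial(vulva_contacts=[(10.0, 30.0), (20.0, 40.0)])
        with pytest.raises(ValueError, match="overlap"):
            vulva_metrics(t)


class TestInsertionMetrics:
    def test_first_insertion_duration(self):
        t = trial(insertions=[(100.0, 194.0)], outcome="insert_no_ejaculation")
        assert insertion_metrics(t)["first_total_s"] == pytest.approx(94.0)

    def test_repeated_short_insertions_in_thirty_second_window(self):
        ins = [(0.0, 50.0), (100.0, 105.0), (110.0, 115.0), (120.0, 125.0)]
        t = trial(insertions=ins, outcome="insert_no_ejaculation")
        assert insertion_metrics(t)["second_window_total_s"] == pytest.approx(15.0)

    def test_continuous_insertion_clipped_to_window(self):
        t = trial(
            insertions=[(0.0, 50.0), (100.0, 300.0)],
            outcome="insert_no_ejaculation",
        )
        assert insertion_metrics(t)["second_window_total_s"] == pytest.approx(30.0)

    def test_insert_and_retract_counts_in_sixty_seconds(self):
        ins = [(0.0, 50.0), (100.0, 105.0), (110.0, 115.0), (150.0, 158.0)]
        t = trial(insertions=ins, outcome="insert_no_ejaculation")
        out = insertion_metrics(t)
        assert out["inserts_in_60s"] == 2  # at 110 and 150 (100 is the anchor)
        assert out["retracts_in_60s"] == 3  # at 105, 115, 158

    def test_no_insertions_rejected(self):
        with pytest.raises(ValueError):
            insertion_metrics(trial())


class TestSustainedTransfer:
    def test_seventeen_second_release_is_wild_type(self):
        assert classify_sustained_transfer(uterine(100.0, release=(160.0, 177.0)))

    def test_just_under_ten_seconds_is_not(self):
        assert not classify_sustained_transfer(uterine(100.0, release=(160.0, 169.9)))

    def test_no_release_is_not(self):
        t = trial(insertions=[(100.0, 160.0)], outcome="insert_no_ejaculation")
        assert not classify_sustained_transfer(t)


class TestBinRefractory:
    def _with_refractory(self, rp):
        return trial(
            insertions=[(100.0, 150.0), (100.0 + rp, 120.0 + rp)],
            outcome="insert_no_ejaculation",
        )

    def test_539_seconds_is_short_group(self):
        out = bin_refractory([self._with_refractory(539.0)])
        assert len(out["short"]) == 1

    def test_540_seconds_is_long_group(self):
        out = bin_refractory([self._with_refractory(540.0)])
        assert len(out["long"]) == 1

    def test_out_of_range_flagged(self):
        out = bin_refractory([self._with_refractory(2000.0)])
        assert len(out["out_of_range"]) == 1

    def test_longer_refractory_group_sires_more_at_second_mating(self):
        # binning applied to simulated populations must reproduce the
        # sperm-reserve effect: long-refractory males succeed more often at
        # the 2nd mating
        short_success, long_success = [], []
        for seed in range(50):
            spec = TrialSpec(n_males=40, p_insert=1.0, seed=seed)
            groups = bin_refractory(trials_from_frame(simulate_trials(spec)))
            for key, acc in (("short", short_success), ("long", long_success)):
                acc.extend(
                    1 if t.progeny and len(t.progeny) > 1 and t.progeny[1] > 0 else 0
                    for t in groups[key]
                )
        assert np.mean(long_success) > np.mean(short_success)


class TestPotency:
    def test_eight_of_twelve_fraction(self):
        trials = [
            uterine(100.0, progeny=[25 if i < 8 else 0]) for i in range(12)
        ]
        assert potency(trials)[0] == pytest.approx(8 / 12)

    def test_all_zero_progeny(self):
        trials = [uterine(100.0, progeny=[0]) for _ in range(5)]
        assert potency(trials)[0] == 0.0

    def test_missing_progeny_excluded_with_warning(self):
        trials = [uterine(100.0, progeny=[10]), uterine(120.0)]
        with pytest.warns(UserWarning, match="excluded"):
            out = potency(trials)
        assert out[0] == 1.0

    def test_no_scorable_trials_rejected(self):
        with pytest.raises(ValueError):
            potency([uterine(100.0)])


class TestTimeShiftInvariance:
    @given(shift=st.floats(0.0, 1000.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_interval_metrics_shift_invariant(self, shift):
        base = trial(
            placed_s=0.0,
            commence_s=[30.0, 400.0],
            vulva_contacts=[(50.0, 70.0)],
            insertions=[(100.0, 150.0), (800.0, 830.0)],
            outcome="insert_no_ejaculation",
        )
        shifted = trial(
            placed_s=shift,
            commence_s=[30.0 + shift, 400.0 + shift],
            vulva_contacts=[(50.0 + shift, 70.0 + shift)],
            insertions=[(100.0 + shift, 150.0 + shift), (800.0 + shift, 830.0 + shift)],
            outcome="insert_no_ejaculation",
        )
        assert refractory_period(base) == pytest.approx(refractory_period(shifted))
        assert drive_metrics(base) == pytest.approx(drive_metrics(shifted))
        assert vulva_metrics(base)["total_time_at_vulva_s"] == pytest.approx(
            vulva_metrics(shifted)["total_time_at_vulva_s"]
        )
        assert rank_sperm_transfer(base) == pytest.approx(rank_sperm_transfer(shifted))
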