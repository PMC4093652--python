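"""Tests for the six task-environment generators."""

import numpy as np
import pytest

from prosim.tasks import (
    gen_cued_stroop,
    gen_expect_reward,
    gen_flanker_frequency,
    gen_item_stroop,
    gen_mmn,
    gen_stop_signal,
    schedule_to_frame,
)

GENERATORS = {
    "flanker": lambda seed=0, n=100: gen_flanker_frequency(
        "frequent-congruent", n, seed
    ),
    "stroop": lambda seed=0, n=100: gen_item_stroop(1, n, seed),
    "mmn": lambda seed=0, n=50: gen_mmn(n_repetitions=n, seed=seed),
    "cued": lambda seed=0, n=100: gen_cued_stroop(n, seed),
    "stop": lambda seed=0, n=100: gen_stop_signal(n, seed),
    "reward": lambda seed=0, n=100: gen_expect_reward(n, seed),
}


def binomial_band(p: float, n: int, z: float = 3.0) -> tuple[float, float]:
    se = np.sqrt(p * (1 - p) / n)
    return p - z * se, p + z * se


class TestCatalogs:
    @pytest.mark.parametrize(
        "name, size",
        [("flanker", 8), ("stroop", 12), ("mmn", 1), ("cued", 10), ("stop", 7),
         ("reward", 10)],
    )
    def test_catalog_sizes(self, name, size):
        assert len(GENERATORS[name]().catalog) == size

    def test_conjunction_subsets_marked(self):
        sched = gen_flanker_frequency("frequent-congruent", 10, 0)
        assert sched.catalog.conjunctions == {
            "left_correct", "left_error", "right_correct", "right_error"
        }

    def test_unknown_event_lookup_raises(self):
        sched = gen_stop_signal(5, 0)
        with pytest.raises(KeyError):
            sched.catalog.index("nonexistent")


class TestReproducibility:
    @pytest.mark.parametrize("name", sorted(GENERATORS))
    def test_same_seed_same_schedule(self, name):
        a = schedule_to_frame(GENERATORS[name](seed=42))
        b = schedule_to_frame(GENERATORS[name](seed=42))
        assert a.equals(b)

    def test_different_seed_different_schedule(self):
        a = schedule_to_frame(gen_flanker_frequency("frequent-congruent", 200, 1))
        b = schedule_to_frame(gen_flanker_frequency("frequent-congruent", 200, 2))
        assert not a.equals(b)


class TestTimingTemplate:
    @pytest.mark.parametrize("name", sorted(GENERATORS))
    def test_within_trial_onsets_identical_across_trials(self, name):
        sched = GENERATORS[name]()
        onsets_by_event: dict[str, set[int]] = {}
        for trial in sched.trials:
            for ev, onset in trial.onsets.items():
                onsets_by_event.setdefault(ev, set()).add(onset)
        assert all(len(v) == 1 for v in onsets_by_event.values())

    def test_trial_count(self):
        assert gen_flanker_frequency("frequent-congruent", 300, 0).n_trials == 300


class TestFlankerFrequency:
    def test_frequent_fraction_near_three_quarters(self):
        sched = gen_flanker_frequency("frequent-congruent", 10_000, 7)
        frac = np.mean([t.meta["congruent"] for t in sched.trials])
        lo, hi = binomial_band(0.75, 10_000)
        assert lo < frac < hi

    def test_frequency_condition_swaps_trial_types(self):
        sched = gen_flanker_frequency("frequent-incongruent", 10_000, 7)
        frac = np.mean([not t.meta["congruent"] for t in sched.trials])
        lo, hi = binomial_band(0.75, 10_000)
        assert lo < frac < hi

    def test_stimuli_fire_simultaneously_at_onset(self):
        sched = gen_flanker_frequency("frequent-congruent", 20, 0)
        assert all(set(t.onsets.values()) == {0} for t in sched.trials)

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValueError):
            gen_flanker_frequency("mostly-neutral", 10, 0)


class TestItemStroop:
    def test_experiment2_incongruent_half_in_both_classes(self):
        sched = gen_item_stroop(2, 10_000, 3)
        for cls in "AB":
            sub = [t for t in sched.trials if t.meta["stimulus_class"] == cls]
            frac = np.mean([t.condition == "incongruent" for t in sub])
            lo, hi = binomial_band(0.5, len(sub))
            assert lo < frac < hi

    def test_experiment1_low_class_rate(self):
        sched = gen_item_stroop(1, 10_000, 3)
        sub = [t for t in sched.trials if t.meta["item_rate"] == 0.1]
        frac = np.mean([t.condition == "incongruent" for t in sub])
        lo, hi = binomial_band(0.1, len(sub))
        assert lo < frac < hi

    def test_classes_balanced(self):
        sched = gen_item_stroop(1, 10_000, 3)
        frac = np.mean([t.meta["stimulus_class"] == "A" for t in sched.trials])
        lo, hi = binomial_band(0.5, 10_000)
        assert lo < frac < hi

    def test_invalid_experiment_rejected(self):
        with pytest.raises(ValueError):
            gen_item_stroop(4, 10, 0)


class TestMMN:
    def test_onset_to_onset_interval_thirty(self):
        sched = gen_mmn(n_repetitions=50, seed=0)
        starts = sched.trial_starts
        tone_onsets = [
            starts[i] + t.onsets["tone"]
            for i, t in enumerate(sched.trials)
            if "tone" in t.onsets
        ]
        # consecutive standards are exactly 30 iterations apart
        gaps = np.diff(tone_onsets[:50])
        assert (gaps == 30).all()

    def test_training_repetition_count(self):
        sched = gen_mmn(n_repetitions=200, seed=0)
        train = [t for t in sched.trials if t.meta.get("phase") == "train"]
        assert len(train) == 200

    def test_omission_trials_have_no_stimulus(self):
        sched = gen_mmn(n_repetitions=10, seed=0)
        omissions = [t for t in sched.trials if t.condition == "omission"]
        assert omissions and all(not t.onsets for t in omissions)

    def test_omissions_follow_one_to_seven_repetitions(self):
        sched = gen_mmn(n_repetitions=10, n_test_cycles=2, seed=1)
        reps = [
            t.meta["after_repetitions"]
            for t in sched.trials
            if t.condition == "omission"
        ]
        assert sorted(set(reps)) == [1, 2, 3, 4, 5, 6, 7]

    def test_lesioned(self):
        assert gen_mmn(n_repetitions=5, seed=0).lesioned

    def test_invalid_omission_counts_rejected(self):
        with pytest.raises(ValueError):
            gen_mmn(n_repetitions=10, omission_after=(0, 3), seed=0)


class TestCuedStroop:
    def test_cue_types_each_about_a_third(self):
        sched = gen_cued_stroop(9_999, 5)
        cues = [t.meta["cue"] for t in sched.trials]
        for cue in ("informed-congruent", "informed-incongruent", "uninformative"):
            frac = cues.count(cue) / len(cues)
            lo, hi = binomial_band(1 / 3, len(cues))
            assert lo < frac < hi

    def test_informative_cues_always_valid(self):
        sched = gen_cued_stroop(3_000, 5)
        for t in sched.trials:
            if t.meta["cue"] == "informed-incongruent":
                assert t.condition == "incongruent"
            elif t.meta["cue"] == "informed-congruent":
                assert t.condition == "congruent"

    def test_uninformative_cues_split_evenly(self):
        sched = gen_cued_stroop(10_000, 5)
        sub = [t for t in sched.trials if t.meta["cue"] == "uninformative"]
        frac = np.mean([t.condition == "incongruent" for t in sub])
        lo, hi = binomial_band(0.5, len(sub))
        assert lo < frac < hi

    def test_cue_precedes_stimulus_by_fifty(self):
        sched = gen_cued_stroop(10, 5)
        for t in sched.trials:
            assert t.onsets["target"] == 50
            cue_onset = [v for k, v in t.onsets.items() if k.startswith("cue_")]
            assert cue_onset == [0]


class TestStopSignal:
    def test_stop_fraction_near_quarter(self):
        sched = gen_stop_signal(10_000, 9)
        frac = np.mean([t.meta["stop"] for t in sched.trials])
        lo, hi = binomial_band(0.25, 10_000)
        assert lo < frac < hi

    def test_every_trial_begins_with_fixation(self):
        sched = gen_stop_signal(500, 9)
        assert all(t.onsets.get("fixation") == 0 for t in sched.trials)

    def test_stop_signal_delay_constant(self):
        sched = gen_stop_signal(500, 9)
        delays = {
            t.onsets["stop"] - t.onsets["go"]
            for t in sched.trials
            if "stop" in t.onsets
        }
        assert delays == {15}

    def test_conjunction_maps_by_trial_type(self):
        sched = gen_stop_signal(200, 9)
        for t in sched.trials:
            if t.meta["stop"]:
                assert t.conjunction_map == {"go": "stop_error", None: "stop_correct"}
            else:
                assert t.conjunction_map == {"go": "go_correct", None: "go_error"}


class TestExpectReward:
    def test_switch_rate_among_small_large(self):
        sched = gen_expect_reward(10_000, 13)
        sub = [t for t in sched.trials if t.meta["magnitude"] != "medium"]
        frac = np.mean([t.meta["switch"] for t in sub])
        lo, hi = binomial_band(0.25, len(sub))
        assert lo < frac < hi

    def test_medium_never_switches(self):
        sched = gen_expect_reward(10_000, 13)
        assert all(
            not t.meta["switch"]
            for t in sched.trials
            if t.meta["magnitude"] == "medium"
        )

    def test_switches_swap_small_and_large(self):
        sched = gen_expect_reward(5_000, 13)
        for t in sched.trials:
            if t.meta["switch"]:
                assert {t.meta["magnitude"], t.meta["go_magnitude"]} == {
                    "small", "large"
                }

    def test_reward_identity_matches_go_cue(self):
        sched = gen_expect_reward(2_000, 13)
        for t in sched.trials:
            go = t.meta["go_magnitude"]
            assert t.onsets[f"go_{go}"] == 100
            assert t.onsets[f"reward_{go}"] == 150

    def test_lesioned(self):
        assert gen_expect_reward(5, 0).lesioned
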