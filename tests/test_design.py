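"""Experiment design: stimuli, timelines, target schedules, scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamfmri.design import (CONDITIONS, DesignError, ExperimentParams,
                            LoomingSoundSpec, LoomingVisualSpec, ResponseLog,
                            RunDesign, auditory_looming_trajectories,
                            build_run_design, events_table, schedule_targets,
                            score_responses, visual_annulus_trajectories)


class TestLoomingStimuli:
    def test_annulus_count_and_radii(self):
        trajs = visual_annulus_trajectories()
        assert len(trajs) == 4                       # 1 to 4 annuli on screen
        assert [t.onset_ms for t in trajs] == [0.0, 125.0, 250.0, 375.0]
        for t in trajs:
            assert t.radius(0.0) == pytest.approx(0.25)

    def test_annulus_lifetime_solves_expansion_equation(self):
        # start + speed * t == max  =>  t = (3.88 - 0.25) / 15.52
        t = visual_annulus_trajectories()[0]
        assert t.lifetime_s == pytest.approx((3.88 - 0.25) / 15.52)
        assert t.lifetime_s == pytest.approx(0.2339, abs=1e-4)
        assert t.radius(t.lifetime_s) == pytest.approx(3.88)
        assert np.isnan(t.radius(t.lifetime_s + 1e-6))  # removed at max radius

    def test_invalid_visual_spec_rejected(self):
        with pytest.raises(DesignError):
            LoomingVisualSpec(speed_deg_per_s=-1.0)
        with pytest.raises(DesignError):
            LoomingVisualSpec(start_radius_deg=4.0)   # above max radius

    def test_tone_frequency_ramp_is_two_thirds(self):
        tones = auditory_looming_trajectories()
        t440 = next(t for t in tones if t.base_hz == 440.0)
        assert t440.frequency(0.0) == pytest.approx(440.0)
        assert t440.frequency(0.5) == pytest.approx(440.0 * 5.0 / 3.0)

    def test_tone_amplitude_exponential_growth(self):
        spec = LoomingSoundSpec(base_amplitude=2.0)
        amp = auditory_looming_trajectories(spec)[0].amplitude
        assert amp(0.0) == pytest.approx(2.0 - 1.0)           # A0*e^0 - 1
        assert amp(0.5) == pytest.approx(2.0 * math.exp(0.34) - 1.0)

    def test_invalid_sound_spec_rejected(self):
        with pytest.raises(DesignError):
            LoomingSoundSpec(duration_ms=-5.0)
        with pytest.raises(DesignError):
            LoomingSoundSpec(base_frequencies_hz=(440.0, 220.0))  # unsorted


class TestRunDesign:
    def test_block_and_stimulus_counts(self, default_design):
        params = default_design.params
        assert len(default_design.run_blocks(1)) == 18
        assert params.stimuli_per_block == 50
        per_cond = sum(1 for b in default_design.blocks if b.condition == CONDITIONS[0])
        assert per_cond == 12     # 3 blocks x 4 runs per condition

    def test_stimulus_onsets_exactly_soa_spaced(self, default_design):
        block = default_design.run_blocks(2)[5]
        onsets = default_design.stimulus_onsets(block)
        assert len(onsets) == 50
        assert np.allclose(np.diff(onsets), 0.66)
        assert onsets[-1] < block.onset_s + block.duration_s

    def test_timeline_layout(self, default_design):
        p = default_design.params
        blocks = default_design.run_blocks(1)
        assert blocks[0].onset_s == p.fixation_s
        gaps = np.diff([b.onset_s for b in blocks])
        assert np.allclose(gaps, p.fixation_s + p.block_duration_s)
        assert p.run_duration_s == 18 * (16 + 33) + 20

    def test_determinism_and_seed_sensitivity(self):
        a = build_run_design(rng_seed=5)
        b = build_run_design(rng_seed=5)
        c = build_run_design(rng_seed=6)
        assert a == b
        assert [x.condition for x in a.blocks] != [x.condition for x in c.blocks]

    def test_overlapping_blocks_rejected(self, default_design):
        bad = list(default_design.blocks)
        bad[1] = type(bad[1])(condition=bad[1].condition, run=bad[1].run,
                              index_in_run=bad[1].index_in_run,
                              occurrence=bad[1].occurrence,
                              onset_s=bad[0].onset_s + 1.0,
                              duration_s=bad[1].duration_s)
        with pytest.raises(DesignError, match="overlap"):
            RunDesign(params=default_design.params, blocks=tuple(bad),
                      seed=default_design.seed)


class TestTargetSchedule:
    def test_sixteen_targets_per_condition_per_modality(self, default_schedule):
        totals = default_schedule.per_condition_totals()
        assert (totals == 16).all().all()

    def test_two_thirds_single_target_split(self, default_design, default_schedule):
        df = default_schedule.to_frame()
        counts = (df.groupby(["condition", "run", "block", "modality"]).size()
                  .unstack("modality"))
        # within each block both modalities have the same count
        assert (counts["A"] == counts["V"]).all()
        per_block = counts["A"].groupby("condition").value_counts().unstack()
        assert (per_block[1] == 8).all() and (per_block[2] == 4).all()

    def test_targets_in_final_half_and_separated(self, default_design,
                                                 default_schedule):
        blocks = {(b.run, b.index_in_run): b for b in default_design.blocks}
        df = default_schedule.to_frame()
        for (run, blk), grp in df.groupby(["run", "block"]):
            b = blocks[(run, blk)]
            assert (grp["onset_s"] >= b.onset_s + b.duration_s / 2).all()
            assert (grp["onset_s"] <= b.onset_s + b.duration_s).all()
            onsets = np.sort(grp["onset_s"].to_numpy())
            if len(onsets) > 1:
                assert np.min(np.diff(onsets)) >= 1.0

    def test_deterministic_given_seed(self, default_design):
        assert (schedule_targets(default_design, rng_seed=3)
                == schedule_targets(default_design, rng_seed=3))


class TestScoring:
    def _single_target_setup(self, default_design, onset=None):
        from lamfmri.design import Target, TargetSchedule
        block = default_design.run_blocks(1)[0]
        t = Target(modality="A", onset_s=onset or block.onset_s + 20.0,
                   run=1, block_index_in_run=block.index_in_run,
                   condition=block.condition)
        return TargetSchedule(targets=(t,), seed=0), t

    def test_press_within_window_is_a_hit(self, default_design):
        sched, t = self._single_target_setup(default_design)
        log = ResponseLog(presses=((1, t.onset_s + 1.0),))
        score = score_responses(sched, log, default_design)
        assert score.n_hits == 1 and score.n_extra == 0
        assert score.table["pct_responded"].iloc[0] == 100.0

    def test_press_after_window_is_extra(self, default_design):
        sched, t = self._single_target_setup(default_design)
        log = ResponseLog(presses=((1, t.onset_s + 3.0),))   # > 2.5 s window
        score = score_responses(sched, log, default_design)
        assert score.n_hits == 0 and score.n_extra == 1
        assert score.table["pct_responded"].iloc[0] == 0.0

    def test_window_truncated_by_next_target(self, default_design):
        from lamfmri.design import Target, TargetSchedule
        block = default_design.run_blocks(1)[0]
        t1 = Target("A", block.onset_s + 10.0, 1, block.index_in_run, block.condition)
        t2 = Target("A", block.onset_s + 11.0, 1, block.index_in_run, block.condition)
        sched = TargetSchedule(targets=(t1, t2), seed=0)
        log = ResponseLog(presses=((1, block.onset_s + 11.2),))
        score = score_responses(sched, log, default_design)
        row = score.table.iloc[0]
        assert score.n_hits == 1
        assert row["n_responded"] == 1 and row["n_targets"] == 2  # only 2nd hit

    def test_press_before_first_target_is_extra(self, default_design):
        sched, t = self._single_target_setup(default_design)
        log = ResponseLog(presses=((1, 0.5),))
        score = score_responses(sched, log, default_design)
        assert score.n_hits == 0 and score.n_extra == 1

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=900.0), max_size=30))
    def test_presses_partition_into_hits_and_extras(self, press_times):
        design = build_run_design(rng_seed=11)
        schedule = schedule_targets(design, rng_seed=12)
        log = ResponseLog(presses=tuple((1, t) for t in sorted(press_times)))
        score = score_responses(schedule, log, design)
        assert score.n_hits + score.n_extra == len(press_times)
        assert (score.table["pct_responded"].between(0, 100)).all()


def test_events_table_is_bids_like(default_design, default_schedule):
    ev = events_table(default_design, run=1, schedule=default_schedule)
    assert list(ev.columns) == ["onset", "duration", "trial_type"]
    assert (ev["onset"].diff().dropna() >= 0).all()
    assert ev["trial_type"].str.startswith(("cue_", "Target")).sum() > 0
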