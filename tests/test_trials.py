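"""Trial ingest, scoring, error rates, exclusion rule, and RT coding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_scored, make_trial
from workcap.trials import (
    CONDITIONS,
    TARGET_CONDITIONS,
    ConditionRTs,
    ParticipantSummary,
    EmptyConditionError,
    SchemaError,
    UndefinedRateError,
    apply_exclusions,
    condition_rts,
    load_trials,
    participant_error_rates,
    redundancy_gain,
    score_trial,
    score_trials,
    write_exclusion_report,
    write_trial_log,
)

HEADER = "participant_id,task_load,interval,onset_ms,condition,rt_left_ms,rt_right_ms,responded\n"


def write_log(tmp_path, rows, header=HEADER, name="log.csv"):
    path = tmp_path / name
    path.write_text(header + "".join(r + "\n" for r in rows))
    return path


class TestLoadTrials:
    def test_well_formed_rows_parse(self, tmp_path):
        path = write_log(
            tmp_path,
            [
                "P01,single,1,1200,TT,500,530,True",
                "P01,single,1,4800,LL,,,False",
                "P01,single,2,900.5,TL,612,,True",
            ],
        )
        result = load_trials(path)
        assert len(result) == 3 and not result.rejected
        assert result.records[1].responded is False
        assert result.records[2].rt_right_ms is None
        assert result.records[2].rt_left_ms == 612.0

    def test_missing_condition_column_is_schema_error(self, tmp_path):
        header = HEADER.replace("condition,", "")
        path = write_log(tmp_path, ["P01,single,1,1200,500,530,True"], header)
        with pytest.raises(SchemaError, match="condition"):
            load_trials(path)

    def test_rt_beyond_timeout_rejected_with_line_number(self, tmp_path):
        path = write_log(
            tmp_path,
            [
                "P01,single,1,1200,TT,500,530,True",
                "P01,single,1,4800,TL,2500,,True",
            ],
        )
        result = load_trials(path)
        assert len(result) == 1
        assert len(result.rejected) == 1
        assert "line 2" in result.rejected[0].reason
        assert "timeout" in result.rejected[0].reason

    def test_non_numeric_rt_rejected(self, tmp_path):
        path = write_log(tmp_path, ["P01,single,1,1200,TT,fast,530,True"])
        result = load_trials(path)
        assert not result.records and result.rejected[0].line == 1

    def test_seconds_scale_input_rejected(self, tmp_path):
        rows = [f"P01,single,1,{i},TT,0.{5+i},0.{6+i},True" for i in range(1, 3)]
        rows += [f"P01,single,2,{i},TL,0.{4+i},,True" for i in range(1, 4)]
        path = write_log(tmp_path, rows)
        with pytest.raises(ValueError, match="seconds"):
            load_trials(path)

    def test_round_trip_through_writer(self, tmp_path):
        records = [
            make_trial("TT", rt=500.0, rt_right=530.0),
            make_trial("LL"),
            make_trial("TL", rt=612.0, interval=2),
        ]
        path = tmp_path / "out.csv"
        write_trial_log(records, path)
        back = load_trials(path)
        assert not back.rejected
        assert [r.condition for r in back.records] == ["TT", "LL", "TL"]
        assert back.records[0].rt_left_ms == 500.0


class TestScoring:
    def test_faster_button_press_is_analysis_rt(self):
        s = score_trial(make_trial("TL", rt=600.0, rt_right=640.0))
        assert s.rt_ms == 600.0 and s.outcome == "hit"

    def test_response_on_redundant_distractors_is_false_alarm(self):
        s = score_trial(make_trial("LL", rt=700.0))
        assert s.outcome == "false_alarm"

    def test_no_response_to_targets_is_miss(self):
        s = score_trial(make_trial("TT"))
        assert s.outcome == "miss" and s.rt_ms is None

    def test_no_response_on_ll_is_correct_rejection(self):
        assert score_trial(make_trial("LL")).outcome == "correct_rejection"

    def test_fast_response_flagged_anticipatory_but_kept(self):
        s = score_trial(make_trial("TT", rt=80.0))
        assert s.anticipatory and s.outcome == "hit"
        kept = score_trials([make_trial("TT", rt=80.0)])
        assert len(kept) == 1
        dropped = score_trials([make_trial("TT", rt=80.0)], drop_anticipatory=True)
        assert not dropped

    @given(
        rt_left=st.one_of(st.none(), st.floats(1.0, 2000.0)),
        rt_right=st.one_of(st.none(), st.floats(1.0, 2000.0)),
        condition=st.sampled_from(CONDITIONS),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_min_rule_and_outcome_consistency(self, rt_left, rt_right, condition):
        s = score_trial(make_trial(condition, rt=rt_left, rt_right=rt_right))
        present = [r for r in (rt_left, rt_right) if r is not None]
        if present:
            assert s.rt_ms == min(present)
            assert s.outcome == ("hit" if condition != "LL" else "false_alarm")
        else:
            assert s.rt_ms is None
            assert s.outcome == ("miss" if condition != "LL" else "correct_rejection")


def _mixed_block(rng, participant="P01", n_ll=10, n_fa=1):
    """Trials with known outcome composition, shuffled."""
    trials = []
    comp = {"TT": (72, 0), "TL": (70, 3), "LT": (69, 2)}  # (hits, misses)
    for cond, (hits, misses) in comp.items():
        for _ in range(hits):
            trials.append(make_trial(cond, rt=float(rng.uniform(300, 900)),
                                     participant=participant))
        for _ in range(misses):
            trials.append(make_trial(cond, participant=participant))
    for i in range(n_ll):
        rt = float(rng.uniform(300, 900)) if i < n_fa else None
        trials.append(make_trial("LL", rt=rt, participant=participant))
    rng.shuffle(trials)
    return trials, comp


class TestErrorRates:
    def test_false_alarm_rate_is_ratio(self, rng):
        trials = [make_trial("LL", rt=500.0 if i == 0 else None) for i in range(10)]
        trials += [make_trial(c, rt=400.0) for c in TARGET_CONDITIONS]
        s = participant_error_rates(score_trials(trials))
        assert s.false_alarm_rate == pytest.approx(0.10)

    def test_zero_misses_gives_zero_rate(self):
        trials = [make_trial("TT", rt=400.0) for _ in range(72)]
        trials += [make_trial(c, rt=400.0) for c in ("TL", "LT")]
        trials += [make_trial("LL")]
        s = participant_error_rates(score_trials(trials))
        assert s.miss_rates["TT"] == 0.0

    def test_rates_match_hand_tally_on_mixed_block(self, rng):
        trials, comp = _mixed_block(rng)
        s = participant_error_rates(score_trials(trials))
        for cond, (hits, misses) in comp.items():
            assert s.hits[cond] == hits
            assert s.miss_rates[cond] == pytest.approx(misses / (hits + misses))
        assert s.false_alarm_rate == pytest.approx(0.1)
        # conservation: outcomes partition the trials
        total = (sum(s.hits.values()) + sum(s.misses.values())
                 + s.false_alarms + s.correct_rejections)
        assert total == len(trials)

    def test_empty_condition_raises_naming_it(self):
        trials = [make_trial(c, rt=400.0) for c in ("TT", "TL", "LL")]
        with pytest.raises(UndefinedRateError, match="LT"):
            participant_error_rates(score_trials(trials))


def _summary(pid, fa=0.0, misses=(0.0, 0.0, 0.0), load="single"):
    return ParticipantSummary(
        participant_id=pid, task_load=load,
        n_trials={c: 72 for c in CONDITIONS},
        hits={c: 72 for c in TARGET_CONDITIONS},
        misses={c: 0 for c in TARGET_CONDITIONS},
        false_alarms=0, correct_rejections=72,
        miss_rates=dict(zip(TARGET_CONDITIONS, misses)),
        false_alarm_rate=fa,
        rts={c: np.full(72, 500.0) for c in TARGET_CONDITIONS},
    )


class TestExclusions:
    def test_cohort_with_high_fa_and_miss_rates(self):
        # 29 participants: 25 clean, three with FA 0.35/0.41/0.67, one with a
        # 0.79 miss rate in the right single-target condition
        summaries = [_summary(f"C{i:02d}", fa=0.22 * i / 25) for i in range(25)]
        summaries += [_summary("F1", fa=0.35), _summary("F2", fa=0.41),
                      _summary("F3", fa=0.67),
                      _summary("M1", misses=(0.0, 0.0, 0.79))]
        retained, excluded = apply_exclusions(summaries)
        assert len(retained) == 25 and len(excluded) == 4
        assert all(s.exclusion_reason for s in excluded)

    def test_boundary_rate_is_retained(self):
        retained, excluded = apply_exclusions([_summary("P", fa=0.30)])
        assert retained and not excluded

    def test_all_zero_rates_retained(self):
        retained, excluded = apply_exclusions([_summary(f"P{i}") for i in range(5)])
        assert len(retained) == 5 and not excluded

    def test_idempotent_and_order_independent(self):
        summaries = [_summary("A", fa=0.5), _summary("B"), _summary("C", fa=0.1)]
        r1, e1 = apply_exclusions(summaries)
        r2, e2 = apply_exclusions(list(reversed(summaries)))
        assert {s.participant_id for s in r1} == {s.participant_id for s in r2}
        r3, e3 = apply_exclusions(r1 + e1)
        assert {s.participant_id for s in r3} == {s.participant_id for s in r1}

    def test_failing_either_block_excludes_participant(self):
        summaries = [_summary("A", load="single"),
                     _summary("A", fa=0.5, load="dual"), _summary("B")]
        retained, excluded = apply_exclusions(summaries)
        assert {s.participant_id for s in excluded} == {"A"}
        assert len(excluded) == 2  # both of A's blocks leave the analysis

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            apply_exclusions([_summary("P")], threshold=0.0)

    def test_report_file(self, tmp_path):
        import pandas as pd

        summaries = [_summary("A", fa=0.5), _summary("B")]
        apply_exclusions(summaries)
        path = tmp_path / "excl.csv"
        write_exclusion_report(summaries, path)
        df = pd.read_csv(path)
        assert set(df["participant_id"]) == {"A", "B"}
        assert bool(df.set_index("participant_id").loc["A", "excluded"])


def _coded_trials(left_rts, right_rts, red_rts, participant="P01"):
    trials = [make_trial("TL", rt=float(r), participant=participant) for r in left_rts]
    trials += [make_trial("LT", rt=float(r), participant=participant) for r in right_rts]
    trials += [make_trial("TT", rt=float(r), participant=participant) for r in red_rts]
    trials += [make_trial("LL", participant=participant)]
    return score_trials(trials)


class TestConditionCoding:
    def test_fast_side_by_mean(self):
        # left mean 577, right mean 568 -> the right single target is faster
        coded = condition_rts(_coded_trials([577, 577], [568, 568], [523, 523]))
        assert coded.fast_side == "right"
        assert coded.fast_single.mean() == pytest.approx(568)
        assert coded.slow_single.mean() == pytest.approx(577)

    def test_tie_breaks_to_left(self):
        coded = condition_rts(_coded_trials([600, 600], [600, 600], [500, 500]))
        assert coded.fast_side == "left"

    def test_order_invariance(self, rng):
        trials = _coded_trials([610, 590], [640, 660], [520, 540])
        shuffled = list(trials)
        rng.shuffle(shuffled)
        a, b = condition_rts(trials), condition_rts(shuffled)
        assert a.fast_side == b.fast_side
        assert np.array_equal(np.sort(a.left), np.sort(b.left))
        assert np.array_equal(np.sort(a.redundant), np.sort(b.redundant))

    def test_fast_mean_never_exceeds_slow_mean(self, rng):
        for _ in range(20):
            left = rng.uniform(300, 900, 8)
            right = rng.uniform(300, 900, 8)
            coded = condition_rts(_coded_trials(left, right, rng.uniform(300, 900, 8)))
            assert coded.fast_single.mean() <= coded.slow_single.mean()

    def test_empty_condition_raises(self):
        trials = [make_trial("TL", rt=500.0), make_trial("LT", rt=500.0),
                  make_trial("TT"), make_trial("LL")]
        with pytest.raises((EmptyConditionError, UndefinedRateError)):
            condition_rts(score_trials(trials))

    def test_only_correct_trials_enter(self):
        trials = _coded_trials([600], [620], [520]) + score_trials(
            [make_trial("TT"), make_trial("LL", rt=400.0)]
        )
        coded = condition_rts(trials)
        assert coded.redundant.size == 1  # the missed TT and the FA are excluded


class TestRedundancyGain:
    def test_printed_mean_arithmetic(self):
        coded = condition_rts(_coded_trials([560, 560], [590, 590], [523, 523]))
        assert redundancy_gain(coded) == pytest.approx(37.0)
        coded = condition_rts(_coded_trials([610, 610], [620, 620], [574, 574]))
        assert redundancy_gain(coded) == pytest.approx(36.0)

    def test_identical_samples_give_zero(self):
        coded = condition_rts(_coded_trials([500, 600], [500, 600], [500, 600]))
        assert redundancy_gain(coded) == pytest.approx(0.0)

    def test_fast_single_convention_is_conservative(self, rng):
        for _ in range(20):
            left = rng.uniform(400, 800, 10)
            right = rng.uniform(400, 800, 10) + 20
            coded = condition_rts(_coded_trials(left, right, rng.uniform(350, 700, 10)))
            if not np.isclose(coded.left.mean(), coded.right.mean()):
                assert redundancy_gain(coded, "fast_single") <= redundancy_gain(
                    coded, "mean_single"
                )

    def test_unknown_convention(self):
        coded = condition_rts(_coded_trials([500], [510], [450]))
        with pytest.raises(ValueError):
            redundancy_gain(coded, "median")
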