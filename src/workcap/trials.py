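"""Ingest, scoring, and exclusion of per-trial logs from the dual-task
redundant-target paradigm.

A trial presents a letter pair in the left and right periphery drawn from four
equiprobable conditions: redundant targets (``TT``), a single target on the
left (``TL``), a single target on the right (``LT``), or redundant distractors
(``LL``).  The participant presses both joystick buttons as fast as possible
when at least one target is present and withholds a response on ``LL`` trials.
Both button response times are logged; analysis uses the faster of the two
presses.  Stimuli time out after 2000 ms.

This module parses delimited trial logs, scores each trial
(hit / miss / false alarm / correct rejection), tallies per-participant error
rates, applies the 0.30 strict-exclusion rule, and produces the per-condition
RT samples — coded both as left/right/redundant and as fast/slow single
target — that feed the hazard-based capacity analysis.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("TT", "TL", "LT", "LL")
TARGET_CONDITIONS = ("TT", "TL", "LT")
TASK_LOADS = ("single", "dual")

#: canonical column order of a trial log
TRIAL_LOG_COLUMNS = (
    "participant_id",
    "task_load",
    "interval",
    "onset_ms",
    "condition",
    "rt_left_ms",
    "rt_right_ms",
    "responded",
)

DEFAULT_TIMEOUT_MS = 2000.0
DEFAULT_EXCLUSION_THRESHOLD = 0.30
DEFAULT_ANTICIPATORY_FLOOR_MS = 100.0


class SchemaError(ValueError):
    """The trial log is missing required columns."""


class UndefinedRateError(ValueError):
    """An error rate is undefined because a condition has no trials."""


class EmptyConditionError(ValueError):
    """A condition required for RT coding has no correct response times."""


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus event as logged by the experiment."""

    participant_id: str
    task_load: str
    interval_index: int
    onset_ms: float
    condition: str
    rt_left_ms: float | None
    rt_right_ms: float | None
    responded: bool

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.task_load not in TASK_LOADS:
            raise ValueError(f"unknown task load {self.task_load!r}")
        if self.interval_index < 1:
            raise ValueError("interval_index must be >= 1")
        has_rt = self.rt_left_ms is not None or self.rt_right_ms is not None
        if self.responded != has_rt:
            raise ValueError("responded must be true iff at least one RT is present")
        for rt in (self.rt_left_ms, self.rt_right_ms):
            if rt is not None and rt <= 0:
                raise ValueError("RTs must be positive")

    @property
    def target_present(self) -> bool:
        return self.condition in TARGET_CONDITIONS


@dataclass(frozen=True)
class ScoredTrial:
    """A trial with the analysis RT (faster button press) and outcome attached."""

    trial: TrialRecord
    rt_ms: float | None
    outcome: str  # hit | miss | false_alarm | correct_rejection
    anticipatory: bool = False

    @property
    def participant_id(self) -> str:
        return self.trial.participant_id

    @property
    def condition(self) -> str:
        return self.trial.condition

    @property
    def task_load(self) -> str:
        return self.trial.task_load


@dataclass
class RowError:
    line: int
    reason: str


@dataclass
class TrialLoadResult:
    """Parsed trial records plus row-level rejection diagnostics."""

    records: list[TrialRecord]
    rejected: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in {"true", "1", "t", "yes"}:
        return True
    if v in {"false", "0", "f", "no"}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _parse_rt(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"nan", "na", "none"}:
        return None
    return float(s)


def load_trials(
    path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
    timeout_ms: float = DEFAULT_TIMEOUT_MS,
) -> TrialLoadResult:
    """Read a delimited trial log into validated :class:`TrialRecord` objects.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row.
    schema : mapping, optional
        Maps canonical column names (``participant_id``, ``task_load``,
        ``interval``, ``onset_ms``, ``condition``, ``rt_left_ms``,
        ``rt_right_ms``, ``responded``) to the file's column names.  Defaults
        to the identity mapping.
    delimiter : str
        Field separator (comma by default).
    timeout_ms : float
        Upper bound on valid RTs; rows with RTs above it are rejected.

    Returns
    -------
    TrialLoadResult
        ``records`` holds parsed trials; ``rejected`` lists per-row
        diagnostics (1-based data line numbers) for rows that failed
        validation.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValueError
        If RT magnitudes suggest the log is in seconds rather than ms.
    """
    schema = dict(schema or {})
    colmap = {name: schema.get(name, name) for name in TRIAL_LOG_COLUMNS}
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"trial log is missing required column(s): {missing}")

    records: list[TrialRecord] = []
    rejected: list[RowError] = []
    all_rts: list[float] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            rt_left = _parse_rt(rowd[colmap["rt_left_ms"]])
            rt_right = _parse_rt(rowd[colmap["rt_right_ms"]])
            for rt in (rt_left, rt_right):
                if rt is not None and rt > timeout_ms:
                    raise ValueError(
                        f"RT {rt:g} ms exceeds the {timeout_ms:g} ms timeout bound"
                    )
            rec = TrialRecord(
                participant_id=str(rowd[colmap["participant_id"]]),
                task_load=str(rowd[colmap["task_load"]]).strip().lower(),
                interval_index=int(rowd[colmap["interval"]]),
                onset_ms=float(rowd[colmap["onset_ms"]]),
                condition=str(rowd[colmap["condition"]]).strip().upper(),
                rt_left_ms=rt_left,
                rt_right_ms=rt_right,
                responded=_parse_bool(rowd[colmap["responded"]]),
            )
        except (ValueError, KeyError) as exc:
            rejected.append(RowError(line=i, reason=f"line {i}: {exc}"))
            continue
        records.append(rec)
        all_rts.extend(rt for rt in (rt_left, rt_right) if rt is not None)

    # magnitude heuristic: RTs recorded in seconds would all sit below ~20
    if len(all_rts) >= 5 and max(all_rts) < 20.0:
        raise ValueError(
            "all RTs are below 20; the log appears to be in seconds, "
            "but times must be in milliseconds"
        )
    if rejected:
        logger.info("load_trials: rejected %d row(s)", len(rejected))
    return TrialLoadResult(records=records, rejected=rejected)


def score_trial(
    trial: TrialRecord,
    anticipatory_floor_ms: float = DEFAULT_ANTICIPATORY_FLOOR_MS,
) -> ScoredTrial:
    """Score one trial: analysis RT = faster button press; outcome from
    (condition, responded).

    ``LL`` trials with a response are false alarms; target-present trials
    without a response are misses.  Responses faster than
    ``anticipatory_floor_ms`` are flagged anticipatory but kept.
    """
    rts = [rt for rt in (trial.rt_left_ms, trial.rt_right_ms) if rt is not None]
    rt_ms = min(rts) if rts else None
    if trial.target_present:
        outcome = "hit" if trial.responded else "miss"
    else:
        outcome = "false_alarm" if trial.responded else "correct_rejection"
    anticipatory = rt_ms is not None and rt_ms < anticipatory_floor_ms
    return ScoredTrial(trial=trial, rt_ms=rt_ms, outcome=outcome, anticipatory=anticipatory)


def score_trials(
    trials: Iterable[TrialRecord],
    anticipatory_floor_ms: float = DEFAULT_ANTICIPATORY_FLOOR_MS,
    drop_anticipatory: bool = False,
) -> list[ScoredTrial]:
    scored = [score_trial(t, anticipatory_floor_ms) for t in trials]
    if drop_anticipatory:
        n0 = len(scored)
        scored = [s for s in scored if not s.anticipatory]
        if len(scored) != n0:
            logger.info("dropped %d anticipatory trial(s)", n0 - len(scored))
    return scored


@dataclass
class ParticipantSummary:
    """Per-participant (and task-load) accuracy tallies and correct-RT samples."""

    participant_id: str
    task_load: str
    n_trials: dict[str, int]
    hits: dict[str, int]
    misses: dict[str, int]
    false_alarms: int
    correct_rejections: int
    miss_rates: dict[str, float]
    false_alarm_rate: float
    rts: dict[str, np.ndarray]
    excluded: bool = False
    exclusion_reason: str | None = None


def participant_error_rates(
    trials: Sequence[ScoredTrial],
    participant_id: str | None = None,
    task_load: str | None = None,
) -> ParticipantSummary:
    """Tally hit/miss/false-alarm counts and rates for one participant.

    Miss rate per target condition = misses / target trials in that
    condition; false-alarm rate = false alarms / ``LL`` trials.  Correct-RT
    samples keep hits only.

    Raises
    ------
    UndefinedRateError
        If any condition has zero trials (the rate is undefined).
    """
    trials = list(trials)
    if participant_id is None:
        ids = {t.participant_id for t in trials}
        if len(ids) != 1:
            raise ValueError(
                f"expected trials from exactly one participant, got {sorted(ids)}"
            )
        participant_id = ids.pop()
    if task_load is None:
        loads = {t.task_load for t in trials}
        task_load = loads.pop() if len(loads) == 1 else "mixed"

    n = {c: 0 for c in CONDITIONS}
    hits = {c: 0 for c in TARGET_CONDITIONS}
    misses = {c: 0 for c in TARGET_CONDITIONS}
    fa = cr = 0
    rts: dict[str, list[float]] = {c: [] for c in TARGET_CONDITIONS}
    for s in trials:
        n[s.condition] += 1
        if s.outcome == "hit":
            hits[s.condition] += 1
            rts[s.condition].append(s.rt_ms)
        elif s.outcome == "miss":
            misses[s.condition] += 1
        elif s.outcome == "false_alarm":
            fa += 1
        else:
            cr += 1
    for c in CONDITIONS:
        if n[c] == 0:
            raise UndefinedRateError(
                f"participant {participant_id}: no trials in condition {c}; "
                "error rate undefined"
            )
    miss_rates = {c: misses[c] / n[c] for c in TARGET_CONDITIONS}
    fa_rate = fa / n["LL"]
    return ParticipantSummary(
        participant_id=participant_id,
        task_load=task_load,
        n_trials=n,
        hits=hits,
        misses=misses,
        false_alarms=fa,
        correct_rejections=cr,
        miss_rates=miss_rates,
        false_alarm_rate=fa_rate,
        rts={c: np.asarray(v, dtype=float) for c, v in rts.items()},
    )


def apply_exclusions(
    summaries: Sequence[ParticipantSummary],
    threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[list[ParticipantSummary], list[ParticipantSummary]]:
    """Partition participants into (retained, excluded) by the error-rate rule.

    A participant is excluded iff their false-alarm rate or any per-condition
    miss rate is *strictly greater* than ``threshold`` (default 0.30) in any
    of their summaries (so a participant failing in either task-load block is
    excluded from both).  Boundary cases (rate exactly equal to the
    threshold) are retained.  The decision is order-independent and
    idempotent; reasons are recorded on the excluded summaries.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    reasons: dict[str, list[str]] = defaultdict(list)
    for s in summaries:
        if s.false_alarm_rate > threshold:
            reasons[s.participant_id].append(
                f"false alarm rate {s.false_alarm_rate:.3f} > {threshold:g}"
                f" ({s.task_load})"
            )
        for c, r in s.miss_rates.items():
            if r > threshold:
                reasons[s.participant_id].append(
                    f"miss rate {r:.3f} > {threshold:g} in {c} ({s.task_load})"
                )
    retained, excluded = [], []
    for s in summaries:
        if s.participant_id in reasons:
            s.excluded = True
            s.exclusion_reason = "; ".join(reasons[s.participant_id])
            excluded.append(s)
            logger.info("excluding %s: %s", s.participant_id, s.exclusion_reason)
        else:
            s.excluded = False
            s.exclusion_reason = None
            retained.append(s)
    return retained, excluded


def write_exclusion_report(summaries: Sequence[ParticipantSummary], path) -> None:
    """Write one row per participant summary with rates and the decision."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "participant_id": s.participant_id,
                "task_load": s.task_load,
                "false_alarm_rate": s.false_alarm_rate,
                **{f"miss_rate_{c}": s.miss_rates[c] for c in TARGET_CONDITIONS},
                "excluded": s.excluded,
                "reason": s.exclusion_reason or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ConditionRTs:
    """Correct-RT samples keyed both by side and by fast/slow single target.

    ``left`` holds RTs from single-target-left trials (``TL``), ``right``
    from single-target-right trials (``LT``), ``redundant`` from ``TT``.
    ``fast_side`` names the single-target condition with the shorter mean RT
    for this participant (ties go to the left, deterministically).
    """

    participant_id: str
    task_load: str
    left: np.ndarray
    right: np.ndarray
    redundant: np.ndarray
    fast_side: str  # "left" | "right"

    @property
    def fast_single(self) -> np.ndarray:
        return self.left if self.fast_side == "left" else self.right

    @property
    def slow_single(self) -> np.ndarray:
        return self.right if self.fast_side == "left" else self.left


def condition_rts(trials: Sequence[ScoredTrial]) -> ConditionRTs:
    """Collect correct target-present RTs per condition and code fast/slow.

    Only hits enter (the paradigm analyzes correct target-present trials
    only).  The faster single-target condition is the one with the smaller
    mean RT; ties break to the left, and the choice is logged.
    """
    summary = participant_error_rates(trials)
    for cond, label in (("TL", "left single target"), ("LT", "right single target"),
                        ("TT", "redundant target")):
        if summary.rts[cond].size == 0:
            raise EmptyConditionError(
                f"participant {summary.participant_id}: no correct RTs in "
                f"{label} condition ({cond})"
            )
    left, right, redundant = summary.rts["TL"], summary.rts["LT"], summary.rts["TT"]
    fast_side = "left" if left.mean() <= right.mean() else "right"
    logger.debug(
        "participant %s: fast single-target side = %s (means L=%.1f R=%.1f)",
        summary.participant_id, fast_side, left.mean(), right.mean(),
    )
    return ConditionRTs(
        participant_id=summary.participant_id,
        task_load=summary.task_load,
        left=left,
        right=right,
        redundant=redundant,
        fast_side=fast_side,
    )


def redundancy_gain(coded: ConditionRTs, convention: str = "fast_single") -> float:
    """Redundancy gain in ms; positive means redundant targets were faster.

    ``fast_single`` (default, conservative): mean RT of the faster
    single-target condition minus mean redundant-target RT.  ``mean_single``:
    the average of the two single-target means minus the redundant mean,
    which can only be larger whenever the single-target means differ.
    """
    if coded.fast_single.size == 0 or coded.redundant.size == 0:
        raise EmptyConditionError("fast_single and redundant samples must be non-empty")
    if convention == "fast_single":
        baseline = coded.fast_single.mean()
    elif convention == "mean_single":
        baseline = 0.5 * (coded.left.mean() + coded.right.mean())
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(baseline - coded.redundant.mean())


def trials_to_frame(scored: Sequence[ScoredTrial]) -> pd.DataFrame:
    """Flatten scored trials into a DataFrame (one row per trial)."""
    rows = []
    for s in scored:
        t = s.trial
        rows.append(
            {
                "participant_id": t.participant_id,
                "task_load": t.task_load,
                "interval": t.interval_index,
                "onset_ms": t.onset_ms,
                "condition": t.condition,
                "rt_left_ms": t.rt_left_ms,
                "rt_right_ms": t.rt_right_ms,
                "responded": t.responded,
                "rt_ms": s.rt_ms,
                "outcome": s.outcome,
                "anticipatory": s.anticipatory,
            }
        )
    return pd.DataFrame(rows)


def write_trial_log(records: Iterable[TrialRecord], path) -> None:
    """Write trial records in the canonical trial-log schema (empty = absent)."""
    rows = []
    for t in records:
        rows.append(
            {
                "participant_id": t.participant_id,
                "task_load": t.task_load,
                "interval": t.interval_index,
                "onset_ms": t.onset_ms,
                "condition": t.condition,
                "rt_left_ms": "" if t.rt_left_ms is None else t.rt_left_ms,
                "rt_right_ms": "" if t.rt_right_ms is None else t.rt_right_ms,
                "responded": t.responded,
            }
        )
    pd.DataFrame(rows, columns=list(TRIAL_LOG_COLUMNS)).to_csv(path, index=False)
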