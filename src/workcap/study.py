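"""End-to-end study analysis: ingest -> score -> exclude -> capacity/resilience
-> hierarchical Bayesian group models -> report.

A study is either a set of trial logs on disk or a simulation specification;
the analysis chain is identical from scoring onward, mirroring the paradigm's
workflow: per-participant hazard-based resilience scores are computed
individually, then passed to group-level Bayesian estimation (no pooling
across participants before hazard estimation).
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes, capacity, simulate, trials

REPORT_FILENAME = "report.json"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: cohort size, generative architecture, task loads."""

    n_participants: int = 25
    architecture: simulate.ArchitectureSpec = field(
        default_factory=simulate.ArchitectureSpec
    )
    dual_task: bool = True
    dual_base_shift_ms: float = 30.0
    dual_kappa_scale: float = 1.0
    session: simulate.SessionConfig = field(default_factory=simulate.SessionConfig)
    tracking: simulate.TrackingConfig = field(default_factory=simulate.TrackingConfig)
    include_tracking: bool = True


@dataclass(frozen=True)
class StudyConfig:
    """Exactly one of ``input_paths`` (trial logs) or ``simulation`` must be set."""

    input_paths: tuple[str, ...] | None = None
    simulation: SimulationSpec | None = None
    tracking_dir: str | None = None  # optional traces named <pid>_<load>*.csv
    exclusion_threshold: float = trials.DEFAULT_EXCLUSION_THRESHOLD
    grid_quantiles: tuple[float, float] = capacity.DEFAULT_GRID_QUANTILES
    mcmc: bayes.McmcConfig = field(default_factory=bayes.McmcConfig)
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_paths or simulation must be provided"
            )


@dataclass
class StudyReport:
    """Machine-readable study results; every entry traces to an upstream
    operation output (all values JSON-native for lossless round-trips)."""

    seed: int | None
    n_participants_total: int
    n_retained: int
    exclusion_log: list
    observed_correct_counts: dict
    participants: list  # one dict per participant x load
    posterior: dict  # nested {section: {name: {mean, lower, upper, ...}}}
    notes: list


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _summary_dict(s) -> dict:
    out = {"mean": float(s.mean), "lower": float(s.lower), "upper": float(s.upper)}
    es = getattr(s, "effect_size", None)
    if es is not None:
        out["d"] = float(es)
    return out


def _acquire_records(cfg: StudyConfig) -> list[trials.TrialRecord]:
    if cfg.simulation is not None:
        spec = cfg.simulation
        session = dataclasses.replace(spec.session, seed=cfg.seed)
        arch_dual = (
            spec.architecture.with_dual_task_cost(
                spec.dual_base_shift_ms, spec.dual_kappa_scale
            )
            if spec.dual_task
            else None
        )
        return simulate.simulate_cohort(
            spec.architecture, spec.n_participants, session, arch_dual=arch_dual
        )
    records: list[trials.TrialRecord] = []
    for path in cfg.input_paths:
        result = trials.load_trials(path)
        records.extend(result.records)
    return records


def _tracking_rmse(cfg: StudyConfig, pids_loads) -> dict[tuple[str, str], float]:
    """RMSE per (participant, load): simulated traces for simulation studies
    (idle cursor under single-task load, active pursuit under dual), or
    traces read from ``tracking_dir`` for log-based studies."""
    rmse: dict[tuple[str, str], float] = {}
    if cfg.simulation is not None and cfg.simulation.include_tracking:
        spec = cfg.simulation
        ss = np.random.SeedSequence([0 if cfg.seed is None else cfg.seed, 7])
        children = ss.spawn(len(pids_loads))
        for (pid, load), child in zip(sorted(pids_loads), children):
            rng = np.random.default_rng(child)
            errs = [
                simulate.rmse_angular(
                    simulate.simulate_tracking(
                        spec.tracking, spec.session.interval_s, rng,
                        active=(load == "dual"),
                    )
                )
                for _ in range(spec.session.n_intervals)
            ]
            rmse[(pid, load)] = float(np.mean(errs))
    elif cfg.tracking_dir is not None:
        for pid, load in sorted(pids_loads):
            paths = sorted(glob.glob(os.path.join(cfg.tracking_dir, f"{pid}_{load}*.csv")))
            if not paths:
                continue
            errs = []
            for p in paths:
                df = pd.read_csv(p)
                errs.append(
                    simulate.rmse_angular(df["target_deg"].to_numpy(),
                                          df["cursor_deg"].to_numpy())
                )
            rmse[(pid, load)] = float(np.mean(errs))
    return rmse


def run_study_analysis(cfg: StudyConfig) -> StudyReport:
    """Execute the full analysis chain and assemble a :class:`StudyReport`.

    Stages: acquire (load or simulate) -> score -> error rates & exclusions
    -> per-participant RT coding, redundancy gains, and standardized
    resilience -> group-level Bayesian models (RTs under both the left/right
    and fast/slow codings, Rz, RMSE, and the Rz-RMSE correlation).  Any
    stage failure aborts with a stage-named diagnostic.
    """
    notes: list[str] = []
    with _stage("acquire"):
        records = _acquire_records(cfg)
        if not records:
            raise ValueError("no trial records acquired")
    with _stage("score"):
        scored = trials.score_trials(records)
        by_pid_load: dict[tuple[str, str], list] = {}
        for s in scored:
            by_pid_load.setdefault((s.participant_id, s.task_load), []).append(s)
    with _stage("error_rates"):
        summaries = [
            trials.participant_error_rates(v, pid, load)
            for (pid, load), v in sorted(by_pid_load.items())
        ]
        retained, excluded = trials.apply_exclusions(summaries, cfg.exclusion_threshold)
        exclusion_log = [
            f"{s.participant_id} ({s.task_load}): {s.exclusion_reason}"
            for s in excluded
        ]
        counts = {
            load: {
                c: float(np.mean([s.hits[c] for s in retained if s.task_load == load]))
                for c in trials.TARGET_CONDITIONS
            }
            for load in sorted({s.task_load for s in retained})
        }
    with _stage("capacity"):
        participant_rows = []
        coded_by_key: dict[tuple[str, str], trials.ConditionRTs] = {}
        retained_ids = sorted({s.participant_id for s in retained})
        loads = sorted({s.task_load for s in retained})
        rmse_map = _tracking_rmse(cfg, [(p, l) for p in retained_ids for l in loads])
        for pid in retained_ids:
            for load in loads:
                key = (pid, load)
                if key not in by_pid_load:
                    continue
                coded = trials.condition_rts(by_pid_load[key])
                coded_by_key[key] = coded
                rz = capacity.standardized_ucip_z(
                    coded.redundant, coded.left, coded.right
                )
                participant_rows.append(
                    {
                        "participant_id": pid,
                        "task_load": load,
                        "mean_left_ms": float(coded.left.mean()),
                        "mean_right_ms": float(coded.right.mean()),
                        "mean_redundant_ms": float(coded.redundant.mean()),
                        "fast_side": coded.fast_side,
                        "gain_fast_single_ms": trials.redundancy_gain(coded),
                        "gain_mean_single_ms": trials.redundancy_gain(
                            coded, "mean_single"
                        ),
                        "rz": rz.z,
                        "rmse_deg": rmse_map.get(key),
                    }
                )
        if not participant_rows:
            raise ValueError("no participants survived exclusion")
    with _stage("bayes_rt"):
        posterior: dict = {}
        mcmc = cfg.mcmc
        ptable = pd.DataFrame(participant_rows)
        two_way = len(loads) > 1
        # trial-level RT table under both codings
        rt_rows = []
        for (pid, load), coded in coded_by_key.items():
            for cond_side, cond_speed, sample in (
                ("left", "fast" if coded.fast_side == "left" else "slow", coded.left),
                ("right", "fast" if coded.fast_side == "right" else "slow", coded.right),
                ("redundant", "redundant", coded.redundant),
            ):
                for rt in sample:
                    rt_rows.append(
                        {"participant_id": pid, "task_load": load,
                         "side_condition": cond_side, "speed_condition": cond_speed,
                         "rt_ms": float(rt)}
                    )
        rt_df = pd.DataFrame(rt_rows)
        for coding, col in (("side", "side_condition"), ("speed", "speed_condition")):
            model = bayes.HierarchicalRTModel(
                rt_df, response="rt_ms", condition=col,
                task_load="task_load" if two_way else None,
            )
            res = model.fit(mcmc)
            sec: dict = {"max_rhat": res.max_rhat}
            for cond in res.labels["a_condition"]:
                sec[f"mean_rt[{cond}]"] = _summary_dict(
                    res.level_mean("a_condition", cond)
                )
            if coding == "side":
                c = res.contrast("a_condition", "left", "right")
                sec["left_minus_right"] = _summary_dict(c)
            else:
                c = res.contrast("a_condition", "fast", "redundant")
                sec["redundancy_gain"] = _summary_dict(c)
            if two_way:
                lc = res.contrast("a_task_load", "single", "dual")
                sec["single_minus_dual"] = _summary_dict(lc)
                if coding == "speed":
                    # load difference in the redundancy gain, from the
                    # interaction draws: (fast - redundant | single) minus
                    # (fast - redundant | dual)
                    li = {l: res.labels["a_task_load"].index(l) for l in loads}
                    ci_ = {c_: res.labels["a_condition"].index(c_)
                           for c_ in ("fast", "redundant")}
                    inter = res.draws["a_interaction"]
                    gain = {
                        l: (inter[:, :, li[l], ci_["fast"]]
                            - inter[:, :, li[l], ci_["redundant"]])
                        for l in ("single", "dual")
                    }
                    diff = gain["single"] - gain["dual"]
                    s = bayes.summarize_draws(diff)
                    sec["gain_single_minus_dual"] = _summary_dict(s)
            posterior[f"rt_{coding}"] = sec
        # Rz and RMSE group models
        for measure, colname in (("rz", "rz"), ("rmse", "rmse_deg")):
            sub = ptable.dropna(subset=[colname])
            if sub.empty:
                continue
            sec = {}
            if two_way and sub["task_load"].nunique() > 1:
                model = bayes.HierarchicalRTModel(
                    sub, response=colname, condition="task_load"
                )
                res = model.fit(mcmc)
                for load in loads:
                    sec[f"mean[{load}]"] = _summary_dict(
                        res.level_mean("a_condition", load)
                    )
                sec["single_minus_dual"] = _summary_dict(
                    res.contrast("a_condition", "single", "dual")
                )
                sec["max_rhat"] = res.max_rhat
            else:
                for load in sub["task_load"].unique():
                    vals = sub.loc[sub["task_load"] == load, colname]
                    res = bayes.fit_one_sample(vals, mcmc)
                    sec[f"mean[{load}]"] = _summary_dict(res.mean_summary())
                    sec["max_rhat"] = res.max_rhat
            posterior[measure] = sec
        # Rz-RMSE correlation (dual-task load where available)
        corr_load = "dual" if "dual" in loads else loads[0]
        sub = ptable[(ptable["task_load"] == corr_load)].dropna(subset=["rmse_deg"])
        if len(sub) >= 3:
            corr = bayes.BayesianCorrelation(sub["rz"], sub["rmse_deg"]).fit(mcmc)
            posterior["rz_rmse_correlation"] = {
                "r": corr.r, "lower": corr.lower, "upper": corr.upper,
                "n": corr.n, "task_load": corr_load,
            }
        else:
            notes.append("Rz-RMSE correlation skipped: no tracking error available")
    return StudyReport(
        seed=cfg.seed,
        n_participants_total=len({s.participant_id for s in summaries}),
        n_retained=len(retained_ids),
        exclusion_log=exclusion_log,
        observed_correct_counts=_jsonify(counts),
        participants=_jsonify(participant_rows),
        posterior=_jsonify(posterior),
        notes=notes,
    )


def write_report(report: StudyReport, outdir, fmt: str = "json") -> list[str]:
    """Write the report: report.json (lossless), participants.csv, summary.txt."""
    if not report.participants:
        raise ValueError("cannot write a report with no participants")
    os.makedirs(outdir, exist_ok=True)
    written = []
    path = os.path.join(outdir, REPORT_FILENAME)
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
    written.append(path)
    csv_path = os.path.join(outdir, "participants.csv")
    pd.DataFrame(report.participants).to_csv(csv_path, index=False)
    written.append(csv_path)
    txt_path = os.path.join(outdir, "summary.txt")
    with open(txt_path, "w") as fh:
        fh.write(format_report(report))
    written.append(txt_path)
    return written


def read_report(outdir) -> StudyReport:
    with open(os.path.join(outdir, REPORT_FILENAME)) as fh:
        payload = json.load(fh)
    return StudyReport(**payload)


def format_report(report: StudyReport) -> str:
    lines = [
        "Redundant-target study report",
        "=============================",
        f"participants: {report.n_retained} retained of "
        f"{report.n_participants_total} (seed={report.seed})",
    ]
    for entry in report.exclusion_log:
        lines.append(f"  excluded: {entry}")
    lines.append("")
    lines.append("mean correct trials per condition:")
    for load, counts in report.observed_correct_counts.items():
        pretty = ", ".join(f"{c}={v:.1f}" for c, v in counts.items())
        lines.append(f"  {load}: {pretty}")
    lines.append("")
    for section, entries in report.posterior.items():
        lines.append(f"[{section}]")
        for name, val in entries.items():
            if isinstance(val, dict) and "mean" in val:
                d = f", d={val['d']:.2f}" if "d" in val else ""
                lines.append(
                    f"  {name}: {val['mean']:.2f} "
                    f"[{val['lower']:.2f}, {val['upper']:.2f}]{d}"
                )
            elif isinstance(val, dict) and "r" in val:
                lines.append(
                    f"  {name}: r={val['r']:.2f} "
                    f"[{val['lower']:.2f}, {val['upper']:.2f}] (n={val['n']})"
                )
            else:
                lines.append(f"  {name}: {val}")
        lines.append("")
    for note in report.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
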