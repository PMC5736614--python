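"""End-to-end driver: simulate -> classify -> cohort -> fit -> link.

One YAML config specifies the task, the behavioural agent profile, the
synthetic cohort, and the analysis settings; :func:`run_pipeline` executes
the whole chain deterministically from a seed and writes a structured report
plus the intermediate tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import brain_behavior as bb
from . import phase_classifier as pc
from . import synthetic_cohort as sc
from . import task_engine as te
from . import trajectory_models as tm
from .agents import DevelopmentalProfile, OmniscientSession, make_policy


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs, loadable from a single YAML file."""

    seed: int = 0
    profile: DevelopmentalProfile = field(default_factory=DevelopmentalProfile)
    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    n_behavioral_subjects: int = 24
    selection_rule: str = "forward_stop"
    mc_k: int = 6
    mc_r_bar: float = 0.66
    mc_alpha: float = 0.05
    lagged_pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 3))
    peak_bootstrap: int = 1000

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "profile" in d:
            pd_ = dict(d["profile"])
            if "valid_age_range" in pd_:
                pd_["valid_age_range"] = tuple(pd_["valid_age_range"])
            d["profile"] = DevelopmentalProfile(**pd_)
        if "cohort" in d:
            cd = dict(d["cohort"])
            if "coupling" in cd and cd["coupling"] is not None:
                cd["coupling"] = {
                    tuple(k.split(":")): float(v) for k, v in cd["coupling"].items()
                }
            for tup_key in ("rois", "contrasts", "age_range_tp1"):
                if tup_key in cd:
                    cd[tup_key] = tuple(cd[tup_key])
            if "performance_coef" in cd and isinstance(cd["performance_coef"], dict):
                cd["performance_coef"] = sc.TrajectoryCoef(**cd["performance_coef"])
            if "ceiling_rate" in cd and isinstance(cd["ceiling_rate"], dict):
                cd["ceiling_rate"] = {int(k): float(v) for k, v in cd["ceiling_rate"].items()}
            d["cohort"] = sc.CohortConfig(**cd)
        if "lagged_pairs" in d:
            d["lagged_pairs"] = tuple(tuple(p) for p in d["lagged_pairs"])
        return PipelineConfig(**d)

    @staticmethod
    def from_yaml(path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        cohort = d["cohort"]
        cohort.pop("activity_coef", None)  # built-in defaults; not YAML-serializable
        coupling = cohort.get("coupling")
        if coupling is not None:
            cohort["coupling"] = {f"{r}:{c}": v for (r, c), v in coupling.items()}
        d["lagged_pairs"] = [list(p) for p in self.lagged_pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(
    config: Union[PipelineConfig, str, Path],
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
) -> dict:
    """Run the full chain and return (and write) the report dictionary."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if seed is None:
        seed = config.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(4) % (2**31)]
    report: dict = {"seed": seed}

    # 1. task arithmetic: trial-count ceilings and floors under the two
    #    session layouts, exercised by rules-aware degenerate policies
    never = OmniscientSession("incorrect")
    always = OmniscientSession("correct")
    report["task"] = {
        "tp1_trials_never_correct": len(never.run(te.TaskConfig.tp1(), np.random.default_rng(seeds[0]))),
        "tp3_trials_never_correct": len(never.run(te.TaskConfig.tp3(), np.random.default_rng(seeds[0]))),
        "tp1_trials_always_correct": len(always.run(te.TaskConfig.tp1(), np.random.default_rng(seeds[0]))),
    }

    # 2. behavioural sample: simulate and classify a small agent cohort
    rng = np.random.default_rng(seeds[1])
    sessions, ids = [], []
    first_trials = None
    ages = np.linspace(*config.profile.valid_age_range, config.n_behavioral_subjects)
    for i, age in enumerate(ages):
        params = config.profile.params_at(age, config.profile.draw_subject_offset(rng))
        trials = te.run_session(make_policy(params), te.TaskConfig.tp1(), rng)
        if first_trials is None:
            first_trials = trials
        sessions.append(pc.classify_session(trials))
        ids.append(f"sim{i:03d}")
    summary = pc.count_summary(sessions, ids)
    summary.to_csv(out / "behavioral_summary.csv", index=False)
    events = te.write_events(first_trials, [lb.category for lb in sessions[0].labels])
    events.to_csv(out / "example_events.tsv", sep="\t", index=False)
    report["behavior"] = {
        "n_sessions": len(sessions),
        "mean_performance": float(summary["learning_performance"].mean()),
        "sd_performance": float(summary["learning_performance"].std(ddof=1)),
        "mean_learning_trials": float(summary["learning"].mean()),
        "mean_total_trials": float(summary["total"].mean()),
    }

    # 3. synthetic cohort (linear mode: closed-form ground truth)
    long_df, truth = sc.generate_cohort(config.cohort, seed=seeds[2])
    long_df.to_csv(out / "cohort_long.csv", index=False)
    with open(out / "cohort_ground_truth.json", "w") as fh:
        json.dump(_jsonable(truth), fh, indent=2)
    report["cohort"] = {
        "n_rows": len(long_df),
        "n_subject_waves": int(long_df[["subject_id", "wave"]].drop_duplicates().shape[0]),
        "waves": {int(w): int(n) for w, n in
                  long_df[["subject_id", "wave"]].drop_duplicates().groupby("wave").size().items()},
    }

    # 4. trajectory ladder per stratum + behaviour, peaks and ICCs
    ladders = tm.fit_ladder_by(long_df, "activity", rule=config.selection_rule)
    perf_rows = long_df[["subject_id", "wave", "age", "performance"]].drop_duplicates(
        ["subject_id", "wave"]
    )
    perf_ladder = tm.compare_ladder(perf_rows, "performance", rule=config.selection_rule)
    rng_boot = np.random.default_rng(seeds[3])
    traj_report = {}
    for (roi, contrast), comp in ladders.items():
        entry = comp.summary()
        if comp.selected_degree == 2:
            pk = tm.peak_age(comp.selected, n_boot=config.peak_bootstrap, rng=rng_boot)
            entry["peak_age"] = pk.peak_age
            entry["peak_ci"] = [pk.ci_low, pk.ci_high]
        entry["icc"] = tm.icc(long_df[(long_df["roi"] == roi) & (long_df["contrast"] == contrast)],
                              "activity")
        traj_report[f"{roi}:{contrast}"] = entry
    perf_entry = perf_ladder.summary()
    if perf_ladder.selected_degree == 2:
        pk = tm.peak_age(perf_ladder.selected, n_boot=config.peak_bootstrap, rng=rng_boot)
        perf_entry["peak_age"] = pk.peak_age
        perf_entry["peak_ci"] = [pk.ci_low, pk.ci_high]
    perf_entry["icc"] = tm.icc(perf_rows, "performance")
    report["trajectories"] = traj_report
    report["performance_trajectory"] = perf_entry

    # 5. brain-behaviour linking with multiplicity correction
    correction = bb.mc_adjust(config.mc_k, config.mc_r_bar, config.mc_alpha)
    measured_r = bb.mean_pairwise_correlation(long_df)
    resid = bb.residualize(long_df, ladders)
    battery = bb.run_hierarchical_battery(resid, correction)
    filtered, removed = bb.ceiling_filter(resid)
    battery_noceiling = bb.run_hierarchical_battery(filtered, correction)
    lagged = []
    for pw, ow in config.lagged_pairs:
        for roi, contrast in resid[["roi", "contrast"]].drop_duplicates().itertuples(index=False):
            try:
                lr = bb.lagged_prediction(long_df, pw, ow, roi, contrast)
            except bb.SampleSizeError:
                continue
            lagged.append(dataclasses.asdict(lr))
    report["mc_correction"] = {
        **dataclasses.asdict(correction),
        "alpha_adjusted_rounded": correction.alpha_adjusted_rounded,
        "measured_mean_pairwise_correlation": measured_r,
    }
    report["hierarchical"] = [dataclasses.asdict(r) for r in battery]
    report["ceiling_sensitivity"] = {
        "removed_per_wave": removed,
        "results": [dataclasses.asdict(r) for r in battery_noceiling],
    }
    report["lagged"] = lagged

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report
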