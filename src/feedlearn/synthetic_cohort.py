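"""Synthetic accelerated-longitudinal cohorts with known ground truth.

Emulates the study design the analysis machinery targets: subjects enter at
ages 8-25, are measured at up to three biannual waves, and contribute one
ROI-contrast activity value and one learning-performance value per retained
wave.  Activity follows a quadratic age trajectory with subject random
intercepts and cross-ROI correlated noise; performance follows its own
quadratic trajectory plus a configurable coupling to the activity residuals,
with truncation at 100 and a wave-specific fraction of exact ceiling scores.

Every generated dataset is accompanied by its ground-truth parameters so
downstream fits can be scored against the generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

Stratum = tuple[str, str]  # (roi, contrast)

DEFAULT_ROIS = ("dorsal_caudate", "ventral_caudate", "nucleus_accumbens")
CORTICAL_ROIS = ("mfg", "sma", "spl", "acc")
DEFAULT_CONTRASTS = ("informative_value", "valence")


class CohortConfigError(ValueError):
    """Configuration implies an invalid (e.g. non-PSD) generative model."""


@dataclass(frozen=True)
class TrajectoryCoef:
    """Quadratic fixed-effect trajectory b0 + b1*c + b2*c^2 on centered age c."""

    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0

    def mean_at(self, centered_age: np.ndarray) -> np.ndarray:
        return self.b0 + self.b1 * centered_age + self.b2 * centered_age**2

    def peak_age(self, center: float) -> Optional[float]:
        """Vertex of the trajectory on the raw age scale (None unless concave)."""
        if self.b2 >= 0:
            return None
        return center - self.b1 / (2.0 * self.b2)


def _as_stratum_map(value, strata: Sequence[Stratum], default) -> dict[Stratum, TrajectoryCoef]:
    if value is None:
        return {s: default for s in strata}
    out = {}
    for s in strata:
        out[s] = value.get(s, default) if isinstance(value, Mapping) else value
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth generative parameters for one synthetic cohort.

    Defaults mirror the target design: 271 subjects entering at ages 8-25,
    three waves two years apart, ~86% retention at the follow-up waves,
    striatal activity peaking in late adolescence, performance peaking around
    age 20.5 in the mid-90s, average inter-variable correlation 0.66 and
    wave-specific ceiling rates rising with age.
    """

    n_subjects: int = 271
    age_range_tp1: tuple[float, float] = (8.0, 25.0)
    n_waves: int = 3
    wave_gap: float = 2.0
    retention_per_wave: float = 0.86
    rois: tuple[str, ...] = DEFAULT_ROIS
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    age_center: float = 18.5  # midpoint of the observable 8-29 span
    # per-(roi, contrast) fixed-effect trajectories; None -> built-in defaults
    activity_coef: Optional[Mapping[Stratum, TrajectoryCoef]] = None
    random_intercept_sd: float = 1.0
    residual_sd: float = 1.0
    inter_roi_corr: float = 0.66
    performance_coef: TrajectoryCoef = TrajectoryCoef(b0=94.84, b1=0.16, b2=-0.04)
    performance_intercept_sd: float = 4.0
    performance_residual_sd: float = 3.0
    # coupling: performance points per unit of activity residual, per stratum
    coupling: Optional[Mapping[Stratum, float]] = None
    # injected exact-100 fraction per wave; observed ceiling also includes
    # scores truncated at 100, so these sit below the emulated observed rates
    ceiling_rate: Union[float, Mapping[int, float]] = field(
        default_factory=lambda: {1: 0.02, 2: 0.05, 3: 0.15}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention_per_wave <= 1.0:
            raise CohortConfigError("retention_per_wave must be in [0, 1]")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise CohortConfigError("SDs must be non-negative")
        if not -1.0 <= self.inter_roi_corr <= 1.0:
            raise CohortConfigError("inter_roi_corr must be in [-1, 1]")
        for rate in self._ceiling_rates().values():
            if not 0.0 <= rate <= 1.0:
                raise CohortConfigError("ceiling rates must be in [0, 1]")

    # -- resolved views -----------------------------------------------------

    @property
    def strata(self) -> list[Stratum]:
        return [(r, c) for r in self.rois for c in self.contrasts]

    def _default_activity(self) -> dict[Stratum, TrajectoryCoef]:
        """Built-in trajectories: informative-value sensitivity peaks in late
        adolescence in every ROI; valence sensitivity is flat, linearly
        decreasing, or shallowly convex depending on ROI."""
        peaks = {"dorsal_caudate": 18.5, "ventral_caudate": 18.0, "nucleus_accumbens": 17.5}
        out: dict[Stratum, TrajectoryCoef] = {}
        for roi in self.rois:
            peak = peaks.get(roi, 18.0)
            b2 = -0.025
            b1 = 2.0 * (-b2) * (peak - self.age_center)
            out[(roi, "informative_value")] = TrajectoryCoef(b0=2.0, b1=b1, b2=b2)
            if roi == "dorsal_caudate":
                out[(roi, "valence")] = TrajectoryCoef(b0=-0.5)
            elif roi == "ventral_caudate":
                out[(roi, "valence")] = TrajectoryCoef(b0=0.0, b1=-0.08)
            else:
                out[(roi, "valence")] = TrajectoryCoef(b0=0.3, b1=-0.06, b2=0.008)
        return {s: out.get(s, TrajectoryCoef(b0=1.0)) for s in self.strata}

    def activity_coefficients(self) -> dict[Stratum, TrajectoryCoef]:
        return _as_stratum_map(self.activity_coef, self.strata, TrajectoryCoef(b0=1.0)) \
            if self.activity_coef is not None else self._default_activity()

    def coupling_map(self) -> dict[Stratum, float]:
        if self.coupling is None:
            return {
                s: {("dorsal_caudate", "informative_value"): 0.5,
                    ("ventral_caudate", "informative_value"): 0.45}.get(s, 0.0)
                for s in self.strata
            }
        return {s: float(self.coupling.get(s, 0.0)) for s in self.strata}

    def _ceiling_rates(self) -> dict[int, float]:
        if isinstance(self.ceiling_rate, Mapping):
            return {w: float(self.ceiling_rate.get(w, 0.0)) for w in range(1, self.n_waves + 1)}
        return {w: float(self.ceiling_rate) for w in range(1, self.n_waves + 1)}

    def ground_truth(self) -> dict:
        """Generating parameters in plain-python form (sidecar metadata)."""
        act = {f"{r}:{c}": asdict(v) for (r, c), v in self.activity_coefficients().items()}
        peaks = {
            f"{r}:{c}": v.peak_age(self.age_center)
            for (r, c), v in self.activity_coefficients().items()
        }
        tot_perf = self.performance_intercept_sd**2 + self.performance_residual_sd**2
        tot_act = self.random_intercept_sd**2 + self.residual_sd**2
        return {
            "age_center": self.age_center,
            "activity_coef": act,
            "activity_peak_age": peaks,
            "performance_coef": asdict(self.performance_coef),
            "performance_peak_age": self.performance_coef.peak_age(self.age_center),
            "coupling": {f"{r}:{c}": v for (r, c), v in self.coupling_map().items()},
            "random_intercept_sd": self.random_intercept_sd,
            "residual_sd": self.residual_sd,
            "performance_intercept_sd": self.performance_intercept_sd,
            "performance_residual_sd": self.performance_residual_sd,
            "icc_activity": self.random_intercept_sd**2 / tot_act if tot_act > 0 else float("nan"),
            "icc_performance": self.performance_intercept_sd**2 / tot_perf if tot_perf > 0 else float("nan"),
            "inter_roi_corr": self.inter_roi_corr,
            "ceiling_rate": self._ceiling_rates(),
            "retention_per_wave": self.retention_per_wave,
        }


# ---------------------------------------------------------------------------
# generation


def sample_design(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject/wave/age frame for the accelerated-longitudinal design.

    Wave 1 is enrollment and always observed; each later wave is retained
    independently with probability ``retention_per_wave`` (attrition need not
    be monotone).  Age at wave w is age_tp1 + wave_gap * (w - 1).
    """
    if config.n_subjects == 0:
        import warnings

        warnings.warn("n_subjects = 0: returning an empty design frame")
        return pd.DataFrame(columns=["subject_id", "wave", "age_tp1", "age"])
    lo, hi = config.age_range_tp1
    age_tp1 = rng.uniform(lo, hi, size=config.n_subjects)
    rows = []
    for s in range(config.n_subjects):
        for w in range(1, config.n_waves + 1):
            if w > 1 and rng.random() > config.retention_per_wave:
                continue
            rows.append(
                {
                    "subject_id": s,
                    "wave": w,
                    "age_tp1": age_tp1[s],
                    "age": age_tp1[s] + config.wave_gap * (w - 1),
                }
            )
    return pd.DataFrame(rows)


def _equicorrelated(rng: np.random.Generator, n: int, k: int, corr: float) -> np.ndarray:
    """n draws of a k-variate standard normal with common pairwise correlation."""
    if k == 1:
        return rng.standard_normal((n, 1))
    if corr < -1.0 / (k - 1) or corr > 1.0:
        raise CohortConfigError(
            f"equicorrelation {corr} with {k} variables is not positive semi-definite"
        )
    if corr >= 0:
        common = rng.standard_normal((n, 1))
        unique = rng.standard_normal((n, k))
        return np.sqrt(corr) * common + np.sqrt(1.0 - corr) * unique
    cov = np.full((k, k), corr) + np.eye(k) * (1.0 - corr)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise CohortConfigError("implied covariance is not positive definite") from exc
    return rng.standard_normal((n, k)) @ chol.T


def generate_activity(
    design: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Long-format activity rows: one per subject-wave-ROI-contrast.

    activity = b0 + b1*c + b2*c^2 + u_subject + e, with c the centered age;
    both the subject intercepts u and the observation noise e are drawn
    equicorrelated across the ROI-contrast variables with correlation
    ``inter_roi_corr`` so the observed inter-variable correlation matches.
    """
    strata = config.strata
    k = len(strata)
    coefs = config.activity_coefficients()
    subjects = design["subject_id"].unique()
    u = config.random_intercept_sd * _equicorrelated(rng, len(subjects), k, config.inter_roi_corr)
    u_map = {s: u[i] for i, s in enumerate(subjects)}
    e = config.residual_sd * _equicorrelated(rng, len(design), k, config.inter_roi_corr)

    c = (design["age"].to_numpy() - config.age_center)
    base = design[["subject_id", "wave", "age"]].reset_index(drop=True)
    frames = []
    for j, (roi, contrast) in enumerate(strata):
        sub = base.copy()
        sub["roi"] = roi
        sub["contrast"] = contrast
        fixed = coefs[(roi, contrast)].mean_at(c)
        u_j = np.array([u_map[s][j] for s in design["subject_id"]])
        sub["activity"] = fixed + u_j + e[:, j]
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def generate_performance(
    design: pd.DataFrame,
    activity: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Subject-wave performance rows, coupled to activity residuals.

    performance = quadratic(age) + sum_r coupling_r * residual_r + u + e,
    truncated to [0, 100]; then a wave-specific fraction of subject-waves is
    set to exactly 100 to emulate ceiling scorers.
    """
    coefs = config.activity_coefficients()
    coupling = config.coupling_map()
    c_act = activity["age"].to_numpy() - config.age_center
    resid = np.zeros(len(activity))
    for (roi, contrast), coef in coefs.items():
        m = (activity["roi"] == roi) & (activity["contrast"] == contrast)
        resid[m.to_numpy()] = activity.loc[m, "activity"].to_numpy() - coef.mean_at(c_act[m.to_numpy()])
    act = activity.assign(_resid=resid, _w=[coupling[(r, c)] for r, c in zip(activity["roi"], activity["contrast"])])
    contrib = (
        act.assign(_wr=act["_resid"] * act["_w"])
        .groupby(["subject_id", "wave"], sort=False)["_wr"]
        .sum()
    )

    perf = design[["subject_id", "wave", "age"]].drop_duplicates().reset_index(drop=True)
    c = perf["age"].to_numpy() - config.age_center
    subjects = perf["subject_id"].unique()
    u = rng.normal(0.0, config.performance_intercept_sd, size=len(subjects))
    u_map = dict(zip(subjects, u))
    e = rng.normal(0.0, config.performance_residual_sd, size=len(perf))
    keyed = contrib.reindex(list(zip(perf["subject_id"], perf["wave"])), fill_value=0.0).to_numpy()
    raw = (
        config.performance_coef.mean_at(c)
        + keyed
        + np.array([u_map[s] for s in perf["subject_id"]])
        + e
    )
    perf["performance"] = np.clip(raw, 0.0, 100.0)

    rates = config._ceiling_rates()
    ceiling = np.array([rng.random() < rates[w] for w in perf["wave"]])
    perf.loc[ceiling, "performance"] = 100.0
    return perf


def generate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, dict]:
    """Full linear-mode cohort: long ROI table joined with performance.

    Returns ``(long_df, ground_truth)`` where ``long_df`` has one row per
    subject-wave-ROI-contrast with columns subject_id, wave, age, roi,
    contrast, activity, performance.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    design = sample_design(config, rng)
    if design.empty:
        return (
            pd.DataFrame(
                columns=["subject_id", "wave", "age", "roi", "contrast", "activity", "performance"]
            ),
            config.ground_truth(),
        )
    activity = generate_activity(design, config, rng)
    perf = generate_performance(design, activity, config, rng)
    long_df = activity.merge(perf[["subject_id", "wave", "performance"]], on=["subject_id", "wave"])
    return long_df, config.ground_truth()


def generate_behavioral_cohort(
    config: CohortConfig,
    profile=None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Behavioural-mode cohort: performance produced by simulated agents.

    Each retained subject-wave runs a full session through the task engine
    with an age-mapped stay/switch agent (wave 3 uses the shorter 10-sequence
    session) and is scored by the phase classifier.  Used for end-to-end
    integration; the linear mode remains the default because its ground truth
    is closed-form.
    """
    from .agents import DevelopmentalProfile, make_policy
    from .phase_classifier import classify_session
    from .task_engine import TaskConfig, run_session

    if profile is None:
        profile = DevelopmentalProfile()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    design = sample_design(config, rng)
    rows = []
    offsets = {s: profile.draw_subject_offset(rng) for s in design["subject_id"].unique()}
    for row in design.itertuples(index=False):
        task_cfg = TaskConfig.tp3() if row.wave == 3 else TaskConfig.tp1()
        params = profile.params_at(min(row.age, profile.valid_age_range[1]), offsets[row.subject_id])
        trials = run_session(make_policy(params), task_cfg, rng)
        cs = classify_session(trials)
        rows.append(
            {
                "subject_id": row.subject_id,
                "wave": row.wave,
                "age": row.age,
                "performance": cs.learning_performance,
                "n_learning": cs.n_learning_evaluable,
                "n_trials": cs.n_trials,
            }
        )
    return pd.DataFrame(rows)
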