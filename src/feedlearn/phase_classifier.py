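"""Trial-by-trial classification of feedback events and the learning-performance statistic.

Each feedback event is assigned to exactly one of five categories, per
stimulus and in presentation order:

* ``learning_pos`` / ``learning_neg`` — the stimulus had not yet been sorted
  correctly (feedback still carried informative value) and the feedback was
  used on the next presentation: stay after positive, switch after negative.
* ``excluded_nonlearning`` — learning-phase feedback that was *not* used on
  the next presentation (stayed on a disconfirmed square, or abandoned a
  confirmed one).
* ``application`` — the stimulus had already been sorted correctly, was
  sorted correctly again, and continued to be sorted correctly on the next
  presentation (or had no further presentation); feedback carries no new
  information.
* ``no_interest`` — everything else: too-late trials, learning-phase trials
  with no later responded presentation (feedback use undecidable), correct
  trials whose next presentation relapsed to an error, and the relapse
  trials themselves.

Learning performance is the percentage of evaluable learning-phase trials on
which feedback was used:

    100 * (learning_pos + learning_neg)
        / (learning_pos + learning_neg + excluded_nonlearning)

"Next presentation" always means the next presentation of the same stimulus
*with a response*; too-late presentations are skipped.  "Switch" after
negative feedback counts as feedback use even when the switch lands on the
other wrong square — use is stay/switch, not success.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .task_engine import NEGATIVE, POSITIVE, TrialRecord

LEARNING_POS = "learning_pos"
LEARNING_NEG = "learning_neg"
APPLICATION = "application"
EXCLUDED_NONLEARNING = "excluded_nonlearning"
NO_INTEREST = "no_interest"
CATEGORIES = (LEARNING_POS, LEARNING_NEG, APPLICATION, EXCLUDED_NONLEARNING, NO_INTEREST)


class UnorderedTrialsError(ValueError):
    """Session trials were not ordered by onset."""


class UndefinedPerformanceError(ValueError):
    """No evaluable learning-phase trial exists; performance is undefined."""


@dataclass(frozen=True)
class TrialLabel:
    category: str
    used_next: Optional[bool] = None  # defined only for evaluable learning trials

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in (LEARNING_POS, LEARNING_NEG) and self.used_next is not True:
            raise ValueError("learning labels imply used_next=True")
        if self.category == EXCLUDED_NONLEARNING and self.used_next is not False:
            raise ValueError("excluded_nonlearning implies used_next=False")


@dataclass
class ClassifiedSession:
    """Per-trial labels plus category counts and the performance statistic."""

    labels: list[TrialLabel]
    counts: dict[str, int]
    n_learning_evaluable: int
    n_unevaluable_learning: int  # final learning-phase trials with no later response
    learning_performance: Optional[float]  # percent; None when undefined
    flagged: bool  # True when performance is undefined (zero evaluable trials)

    @property
    def n_trials(self) -> int:
        return len(self.labels)


def classify_session(
    trials: Sequence[TrialRecord],
    include_unevaluable_final: bool = False,
) -> ClassifiedSession:
    """Label every trial of one session.

    ``include_unevaluable_final`` adds final learning-phase trials without a
    later responded presentation to the performance denominator (as unused
    feedback) instead of dropping them; the default excludes them because
    "used on the next trial" is undecidable there.
    """
    onsets = [t.onset_s for t in trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise UnorderedTrialsError("trials must be strictly ordered by onset within one session")

    labels: list[Optional[TrialLabel]] = [None] * len(trials)

    # group presentation indices per stimulus (stimuli are unique per sequence,
    # but key on the pair to be safe with external logs)
    groups: dict[tuple[int, str], list[int]] = {}
    for i, t in enumerate(trials):
        groups.setdefault((t.sequence_id, t.stimulus_id), []).append(i)

    n_unevaluable = 0
    for idxs in groups.values():
        responded = [i for i in idxs if not trials[i].too_late]
        next_responded: dict[int, Optional[int]] = {}
        for pos, i in enumerate(idxs):
            later = [j for j in responded if j > i]
            next_responded[i] = later[0] if later else None
        prior_correct = False
        for i in idxs:
            t = trials[i]
            if t.too_late:
                labels[i] = TrialLabel(NO_INTEREST)
                continue
            nxt = next_responded[i]
            if not prior_correct:
                # learning phase: feedback still informative
                if nxt is None:
                    labels[i] = TrialLabel(NO_INTEREST)  # unevaluable final trial
                    n_unevaluable += 1
                else:
                    nxt_choice = trials[nxt].chosen_square
                    if t.feedback == POSITIVE:
                        used = nxt_choice == t.chosen_square
                        cat = LEARNING_POS
                    else:
                        used = nxt_choice != t.chosen_square
                        cat = LEARNING_NEG
                    if used:
                        labels[i] = TrialLabel(cat, used_next=True)
                    else:
                        labels[i] = TrialLabel(EXCLUDED_NONLEARNING, used_next=False)
            else:
                if t.accuracy:
                    # application requires continued correct sorting
                    if nxt is None or trials[nxt].accuracy:
                        labels[i] = TrialLabel(APPLICATION)
                    else:
                        labels[i] = TrialLabel(NO_INTEREST)
                else:
                    # relapse after a prior correct: no return to learning phase
                    labels[i] = TrialLabel(NO_INTEREST)
            prior_correct = prior_correct or t.accuracy

    final_labels = [lb for lb in labels]
    assert all(lb is not None for lb in final_labels)
    counts = {c: 0 for c in CATEGORIES}
    for lb in final_labels:
        counts[lb.category] += 1

    n_used = counts[LEARNING_POS] + counts[LEARNING_NEG]
    denom = n_used + counts[EXCLUDED_NONLEARNING]
    if include_unevaluable_final:
        denom += n_unevaluable
    performance = 100.0 * n_used / denom if denom > 0 else None
    return ClassifiedSession(
        labels=final_labels,
        counts=counts,
        n_learning_evaluable=n_used + counts[EXCLUDED_NONLEARNING],
        n_unevaluable_learning=n_unevaluable,
        learning_performance=performance,
        flagged=performance is None,
    )


def learning_performance(classified: ClassifiedSession) -> float:
    """Percent of evaluable learning-phase feedback used on the next trial."""
    if classified.learning_performance is None:
        raise UndefinedPerformanceError("no evaluable learning-phase trials in this session")
    return classified.learning_performance


def labels_frame(trials: Sequence[TrialRecord], classified: ClassifiedSession) -> pd.DataFrame:
    """Trial log with ``category`` and ``used_next`` columns appended."""
    from .task_engine import trials_to_frame

    df = trials_to_frame(trials)
    df["category"] = [lb.category for lb in classified.labels]
    df["used_next"] = pd.array([lb.used_next for lb in classified.labels], dtype="boolean")
    return df


def count_summary(
    sessions: Iterable[ClassifiedSession],
    session_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-session category counts and performance, for calibration reports.

    ``learning`` counts evaluable learning-phase trials (used + not used);
    ``total`` is the session length.
    """
    rows = []
    for k, cs in enumerate(sessions):
        rows.append(
            {
                "session": session_ids[k] if session_ids is not None else k,
                "total": cs.n_trials,
                "learning": cs.n_learning_evaluable,
                "learning_pos": cs.counts[LEARNING_POS],
                "learning_neg": cs.counts[LEARNING_NEG],
                "application": cs.counts[APPLICATION],
                "excluded_nonlearning": cs.counts[EXCLUDED_NONLEARNING],
                "no_interest": cs.counts[NO_INTEREST],
                "learning_performance": cs.learning_performance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "session",
            "total",
            "learning",
            "learning_pos",
            "learning_neg",
            "application",
            "excluded_nonlearning",
            "no_interest",
            "learning_performance",
        ],
    )


def flag_outliers(
    performance: pd.DataFrame,
    value_col: str = "performance",
    wave_col: str = "wave",
    sd_threshold: float = 3.0,
) -> pd.Series:
    """Wave-wise extreme-low-performance flag.

    A session is flagged when its performance lies more than ``sd_threshold``
    SDs below its wave's mean (the direction of interest: participants who
    did not understand the task).  Returns a boolean Series aligned to the
    input index.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    flags = pd.Series(False, index=performance.index)
    for _, grp in performance.groupby(wave_col):
        m, s = grp[value_col].mean(), grp[value_col].std(ddof=1)
        if not np.isfinite(s) or s == 0:
            continue
        flags.loc[grp.index] = grp[value_col] < m - sd_threshold * s
    return flags
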