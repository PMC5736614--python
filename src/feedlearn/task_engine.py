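"""Deterministic engine for the three-stimulus feedback-sorting task.

On every trial the participant sees three squares and one of three stimuli,
and must sort the stimulus into its square.  Feedback is a plus sign after a
correct sort and a minus sign after an incorrect one.  A sequence of three
novel stimuli ends after 12 trials, or earlier once every stimulus has been
sorted correctly at least twice (the learning criterion); a session is a
fixed number of such sequences (15 at the first two measurement waves, 10 at
the third).  Trial timing is fixation 500 ms, stimulus + response 2500 ms,
feedback 1000 ms, with a jittered inter-trial interval.

The engine is policy-agnostic: any callable mapping the per-stimulus
feedback history to a square choice (or a too-late omission) can drive it,
which makes the same code usable for simulated agents and for replaying
recorded choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

SQUARES = (0, 1, 2)
#: feedback codes carried on :class:`TrialRecord`
POSITIVE = "positive"
NEGATIVE = "negative"
NO_FEEDBACK = "none"

#: signature: policy(stimulus_id, history, rng) -> square index or None
#: where ``history`` is the list of prior (chosen_square, feedback) pairs for
#: the presented stimulus (responded trials only).
Policy = Callable[[str, Sequence[tuple[int, str]], np.random.Generator], Optional[int]]


class InvalidChoiceError(ValueError):
    """A policy returned a square outside the task's three squares."""


class MissingLabelError(ValueError):
    """Labels were requested for an events table but not supplied for all trials."""


@dataclass(frozen=True)
class RuleSet:
    """Bijective stimulus -> square assignment for one sequence."""

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.assignment) != 3:
            raise ValueError("a rule set maps exactly 3 stimuli")
        squares = sorted(self.assignment.values())
        if squares != sorted(SQUARES):
            raise ValueError("each of the 3 squares must be used exactly once")

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    @staticmethod
    def random(stimuli: Sequence[str], rng: np.random.Generator) -> "RuleSet":
        if len(stimuli) != 3:
            raise ValueError("need exactly 3 stimuli")
        squares = rng.permutation(len(SQUARES))
        return RuleSet({s: int(q) for s, q in zip(stimuli, squares)})


@dataclass(frozen=True)
class TaskConfig:
    """Session parameters.

    Defaults are the wave-1/wave-2 session: 15 sequences of at most 12
    trials each (180-trial ceiling), criterion of 2 correct placements per
    stimulus, and the stated event timings with 0-6 s jittered intervals.
    """

    n_sequences: int = 15
    max_trials_per_sequence: int = 12
    criterion_correct_per_stimulus: int = 2
    fixation_ms: float = 500.0
    stim_response_ms: float = 2500.0
    feedback_ms: float = 1000.0
    jitter_range_s: tuple[float, float] = (0.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sequences", "max_trials_per_sequence", "criterion_correct_per_stimulus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.jitter_range_s
        if lo < 0 or hi < lo:
            raise ValueError("jitter bounds must be non-negative and ordered")

    @property
    def trial_duration_s(self) -> float:
        return (self.fixation_ms + self.stim_response_ms + self.feedback_ms) / 1000.0

    @property
    def feedback_offset_s(self) -> float:
        """Feedback onset relative to trial (fixation) onset."""
        return (self.fixation_ms + self.stim_response_ms) / 1000.0

    @staticmethod
    def tp1() -> "TaskConfig":
        return TaskConfig(n_sequences=15)

    @staticmethod
    def tp3() -> "TaskConfig":
        """Wave-3 session: 10 sequences (120-trial ceiling)."""
        return TaskConfig(n_sequences=10)


@dataclass(frozen=True)
class TrialRecord:
    """One task trial as logged by the engine."""

    sequence_id: int
    trial_index: int  # 0-based within sequence
    stimulus_id: str
    chosen_square: Optional[int]
    correct_square: int
    accuracy: bool
    feedback: str  # positive | negative | none
    too_late: bool
    onset_s: float  # trial (fixation) onset from session start
    feedback_onset_s: float

    def __post_init__(self) -> None:
        if (self.feedback == NO_FEEDBACK) != self.too_late:
            raise ValueError("feedback is 'none' iff the trial was too late")


@dataclass
class SequenceState:
    """Criterion counters for one running sequence."""

    correct_counts: dict[str, int]
    trials_elapsed: int = 0

    @staticmethod
    def fresh(stimuli: Iterable[str]) -> "SequenceState":
        return SequenceState({s: 0 for s in stimuli})


def is_criterion_met(state: SequenceState, config: TaskConfig) -> bool:
    """True once every stimulus has been sorted correctly at least
    ``criterion_correct_per_stimulus`` times."""
    c = config.criterion_correct_per_stimulus
    return all(n >= c for n in state.correct_counts.values())


def _block_schedule(stimuli: Sequence[str], n_trials: int, rng: np.random.Generator) -> list[str]:
    """Permuted-block presentation order: within each block of 3 trials every
    stimulus appears exactly once, block order freshly permuted."""
    order: list[str] = []
    while len(order) < n_trials:
        order.extend(np.array(stimuli)[rng.permutation(len(stimuli))].tolist())
    return order[:n_trials]


def run_sequence(
    rules: RuleSet,
    policy: Policy,
    config: TaskConfig,
    rng: np.random.Generator,
    sequence_id: int = 0,
    start_time_s: float = 0.0,
    schedule: Optional[Sequence[str]] = None,
) -> tuple[list[TrialRecord], float]:
    """Run one sequence; returns (trials, end time).

    The sequence stops after the first trial on which the criterion holds,
    or after ``max_trials_per_sequence`` trials, whichever comes first.
    ``schedule`` overrides the seeded permuted-block presentation order
    (used for replay and for hand-enumerated tests).
    """
    if schedule is None:
        schedule = _block_schedule(rules.stimuli, config.max_trials_per_sequence, rng)
    state = SequenceState.fresh(rules.stimuli)
    history: dict[str, list[tuple[int, str]]] = {s: [] for s in rules.stimuli}
    trials: list[TrialRecord] = []
    t = start_time_s
    for trial_index in range(config.max_trials_per_sequence):
        stim = schedule[trial_index]
        choice = policy(stim, history[stim], rng)
        if choice is None:
            accuracy, feedback, too_late = False, NO_FEEDBACK, True
        else:
            if choice not in SQUARES:
                raise InvalidChoiceError(f"policy chose square {choice!r}; valid squares are {SQUARES}")
            choice = int(choice)
            accuracy = choice == rules.assignment[stim]
            feedback = POSITIVE if accuracy else NEGATIVE
            too_late = False
            history[stim].append((choice, feedback))
            if accuracy:
                state.correct_counts[stim] += 1
        trials.append(
            TrialRecord(
                sequence_id=sequence_id,
                trial_index=trial_index,
                stimulus_id=stim,
                chosen_square=choice,
                correct_square=rules.assignment[stim],
                accuracy=accuracy,
                feedback=feedback,
                too_late=too_late,
                onset_s=t,
                feedback_onset_s=t + config.feedback_offset_s,
            )
        )
        state.trials_elapsed += 1
        t += config.trial_duration_s + rng.uniform(*config.jitter_range_s)
        if is_criterion_met(state, config):
            break
    return trials, t


def run_session(
    policy: Policy,
    config: TaskConfig,
    rng: Optional[np.random.Generator] = None,
    rules_per_sequence: Optional[Sequence[RuleSet]] = None,
) -> list[TrialRecord]:
    """Run a full session of ``n_sequences`` sequences with fresh stimuli.

    With a fixed seed (``config.seed`` or a caller-supplied generator) and a
    deterministic policy the output is bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if rules_per_sequence is not None and len(rules_per_sequence) != config.n_sequences:
        raise ValueError("rules_per_sequence length must equal n_sequences")
    trials: list[TrialRecord] = []
    t = 0.0
    for seq in range(config.n_sequences):
        if rules_per_sequence is None:
            stimuli = [f"seq{seq:02d}_stim{k}" for k in range(3)]
            rules = RuleSet.random(stimuli, rng)
        else:
            rules = rules_per_sequence[seq]
        seq_trials, t = run_sequence(rules, policy, config, rng, sequence_id=seq, start_time_s=t)
        trials.extend(seq_trials)
    return trials


# ---------------------------------------------------------------------------
# tabular I/O

TRIAL_COLUMNS = [
    "sequence_id",
    "trial_index",
    "stimulus_id",
    "chosen_square",
    "correct_square",
    "accuracy",
    "feedback",
    "too_late",
    "onset_s",
    "feedback_onset_s",
]


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(t) for t in trials], columns=TRIAL_COLUMNS)
    df["chosen_square"] = df["chosen_square"].astype("Int64")
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for row in df.itertuples(index=False):
        chosen = row.chosen_square
        chosen = None if pd.isna(chosen) else int(chosen)
        trials.append(
            TrialRecord(
                sequence_id=int(row.sequence_id),
                trial_index=int(row.trial_index),
                stimulus_id=str(row.stimulus_id),
                chosen_square=chosen,
                correct_square=int(row.correct_square),
                accuracy=bool(row.accuracy),
                feedback=str(row.feedback),
                too_late=bool(row.too_late),
                onset_s=float(row.onset_s),
                feedback_onset_s=float(row.feedback_onset_s),
            )
        )
    return trials


def write_events(
    trials: Sequence[TrialRecord],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """BIDS-style events table, one row per feedback event.

    Feedback events are modelled time-locked with duration 0 to feedback
    presentation.  ``trial_type`` is the feedback valence, or the supplied
    classifier label when ``labels`` is given (one per trial).
    """
    if labels is not None and len(labels) != len(trials):
        raise MissingLabelError(
            f"{len(trials)} trials but {len(labels)} labels; every trial needs a label"
        )
    rows = []
    for i, tr in enumerate(trials):
        trial_type = labels[i] if labels is not None else tr.feedback
        rows.append({"onset": tr.feedback_onset_s, "duration": 0.0, "trial_type": trial_type})
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
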