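"""Generative models of participant behaviour on the sorting task.

The agent family is a stochastic win-stay/lose-shift learner with optional
elimination memory: after positive feedback it repeats the confirmed square
with probability ``p_use_positive``; after negative feedback it switches
with probability ``p_use_negative``, and when its elimination memory fires
it avoids squares already disconfirmed for that stimulus.  The summary
statistic of this policy family is exactly the task's learning-performance
measure (fraction of learning-phase feedback used on the next presentation),
which is why it is the minimal behavioural generator for this analysis.

A :class:`DevelopmentalProfile` maps age to agent parameters through a
quadratic on the logit scale, producing the inverted-U performance
trajectory (rising through childhood, peaking around age 20-21) with
optional subject-level heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .task_engine import SQUARES, NEGATIVE, POSITIVE, Policy, TaskConfig, TrialRecord, run_session


@dataclass(frozen=True)
class AgentParams:
    """Stochastic stay/switch tendencies of one simulated participant."""

    p_use_positive: float = 0.95
    p_use_negative: float = 0.95
    p_elim_memory: float = 0.5
    p_too_late: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_use_positive", "p_use_negative", "p_elim_memory", "p_too_late"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def make_policy(params: AgentParams) -> Policy:
    """Policy closure implementing the stay/switch agent.

    ``history`` holds prior (choice, feedback) pairs for the presented
    stimulus; disconfirmed squares are recovered from negative-feedback
    entries, so the policy itself is stateless.
    """

    def policy(stimulus_id: str, history: Sequence[tuple[int, str]], rng: np.random.Generator):
        if params.p_too_late > 0 and rng.random() < params.p_too_late:
            return None
        if not history:
            return int(rng.integers(len(SQUARES)))
        last_choice, last_feedback = history[-1]
        others = [q for q in SQUARES if q != last_choice]
        if last_feedback == POSITIVE:
            if rng.random() < params.p_use_positive:
                return last_choice
            return int(others[rng.integers(2)])
        # negative feedback: use = switch, failure to use = stay
        if rng.random() >= params.p_use_negative:
            return last_choice
        candidates = others
        if rng.random() < params.p_elim_memory:
            disconfirmed = {c for c, fb in history if fb == NEGATIVE}
            remembered = [q for q in others if q not in disconfirmed]
            if remembered:  # empty -> fall back to plain switch
                candidates = remembered
        return int(candidates[rng.integers(len(candidates))])

    return policy


@dataclass(frozen=True)
class DevelopmentalProfile:
    """Age -> AgentParams map, quadratic on the logit scale.

    logit(p_use_*) = peak_logit_* - curvature_* * (age - peak_age)^2, so the
    stay/switch tendencies (hence learning performance) peak at ``peak_age``
    and fall off symmetrically; the logistic link keeps every probability in
    [0, 1] over the whole age range.  ``subject_logit_sd`` adds a shared
    subject-level offset on the logit scale to create stable individual
    differences.  Defaults put wave-level mean performance in the low-to-mid
    90s with an SD of a few points, peaking around age 20.5.
    """

    peak_age: float = 20.5
    peak_logit_positive: float = 3.2
    peak_logit_negative: float = 2.9
    curvature_positive: float = 0.007
    curvature_negative: float = 0.007
    p_elim_memory: float = 0.5
    p_too_late: float = 0.02
    subject_logit_sd: float = 0.35
    valid_age_range: tuple[float, float] = (8.0, 29.0)

    def params_at(self, age: float, subject_offset: float = 0.0) -> AgentParams:
        lo, hi = self.valid_age_range
        if not lo <= age <= hi:
            raise ValueError(f"age {age} outside profile's valid range [{lo}, {hi}]")
        d2 = (age - self.peak_age) ** 2
        return AgentParams(
            p_use_positive=float(expit(self.peak_logit_positive - self.curvature_positive * d2 + subject_offset)),
            p_use_negative=float(expit(self.peak_logit_negative - self.curvature_negative * d2 + subject_offset)),
            p_elim_memory=self.p_elim_memory,
            p_too_late=self.p_too_late,
        )

    def draw_subject_offset(self, rng: np.random.Generator) -> float:
        return float(rng.normal(0.0, self.subject_logit_sd))


def simulate_participant(
    age: float,
    profile: DevelopmentalProfile,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_offset: Optional[float] = None,
) -> list[TrialRecord]:
    """Simulate one full session for a participant of the given age."""
    if subject_offset is None:
        subject_offset = 0.0
    params = profile.params_at(age, subject_offset)
    return run_session(make_policy(params), config, rng)


# degenerate reference policies used throughout the tests and drivers


class AlwaysCorrectPolicy:
    """Callable policy that knows the rules and always sorts correctly."""

    def __init__(self, rules_by_stimulus: dict[str, int]):
        self.rules = rules_by_stimulus

    def __call__(self, stimulus_id, history, rng):
        return self.rules[stimulus_id]


class NeverCorrectPolicy:
    """Callable policy that knows the rules and always sorts incorrectly
    (exercises the per-sequence trial cap)."""

    def __init__(self, rules_by_stimulus: dict[str, int]):
        self.rules = rules_by_stimulus

    def __call__(self, stimulus_id, history, rng):
        wrong = [q for q in SQUARES if q != self.rules[stimulus_id]]
        return wrong[0]


class OmniscientSession:
    """Helper that runs a session with a rules-aware degenerate policy.

    ``mode='correct'`` always sorts correctly; ``mode='incorrect'`` never
    does.  Rules are generated inside and shared with the policy.
    """

    def __init__(self, mode: str):
        if mode not in ("correct", "incorrect"):
            raise ValueError("mode must be 'correct' or 'incorrect'")
        self.mode = mode

    def run(self, config: TaskConfig, rng: Optional[np.random.Generator] = None):
        from .task_engine import RuleSet

        if rng is None:
            rng = np.random.default_rng(config.seed)
        rules = []
        merged: dict[str, int] = {}
        for seq in range(config.n_sequences):
            stimuli = [f"seq{seq:02d}_stim{k}" for k in range(3)]
            rs = RuleSet.random(stimuli, rng)
            rules.append(rs)
            merged.update(rs.assignment)
        policy = AlwaysCorrectPolicy(merged) if self.mode == "correct" else NeverCorrectPolicy(merged)
        return run_session(policy, config, rng, rules_per_sequence=rules)
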