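"""Independent brute-force reference for the feedback classifier.

Written as a literal walk of the classification rules, deliberately
structured differently from the package implementation: for every trial it
re-scans the whole session to find same-stimulus presentations, prior
correct responses, and the next responded presentation.  No state is carried
between trials.
"""

from feedlearn.task_engine import POSITIVE, TrialRecord


def _same_stimulus(trials, i):
    t = trials[i]
    return [
        j
        for j, u in enumerate(trials)
        if u.sequence_id == t.sequence_id and u.stimulus_id == t.stimulus_id
    ]


def brute_force_labels(trials: list[TrialRecord]) -> list[str]:
    labels = []
    for i, t in enumerate(trials):
        if t.too_late:
            labels.append("no_interest")
            continue
        same = _same_stimulus(trials, i)
        prior_correct = any(
            trials[j].accuracy and not trials[j].too_late for j in same if j < i
        )
        nxt = None
        for j in same:
            if j > i and not trials[j].too_late:
                nxt = j
                break
        if not prior_correct:
            if nxt is None:
                labels.append("no_interest")
            else:
                if t.feedback == POSITIVE:
                    used = trials[nxt].chosen_square == t.chosen_square
                    labels.append("learning_pos" if used else "excluded_nonlearning")
                else:
                    used = trials[nxt].chosen_square != t.chosen_square
                    labels.append("learning_neg" if used else "excluded_nonlearning")
        else:
            if not t.accuracy:
                labels.append("no_interest")
            elif nxt is None or trials[nxt].accuracy:
                labels.append("application")
            else:
                labels.append("no_interest")
    return labels


def brute_force_performance(trials: list[TrialRecord]):
    """Percent of learning-phase feedback used on the next trial, or None."""
    labels = brute_force_labels(trials)
    used = sum(lb in ("learning_pos", "learning_neg") for lb in labels)
    not_used = sum(lb == "excluded_nonlearning" for lb in labels)
    if used + not_used == 0:
        return None
    return 100.0 * used / (used + not_used)
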