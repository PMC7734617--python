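"""Navigation-strategy classification and learning onset.

Test trials (start alley 4, rewards in alleys 1 and 3) reveal the
spontaneous strategy: reaching alley 3 directly means the participant used
the landmarks learnt in training (allocentric, AS); reaching alley 1
directly means they replayed the trained body-relative motor sequence
(egocentric, ES); anything else — failure, or more than two alleys visited
— is no efficient strategy.  Five test-trial labels then classify the
participant as Allocentric, Egocentric, Shifter or Lacking an efficient
strategy.  Compelled trials (Task 2) count as successful only with a
direct two-alley route to the reward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .maze import TrialSpec
from .metrics import TrialMetrics

__all__ = [
    "AS",
    "ES",
    "NO_EFFICIENT",
    "ParticipantStrategy",
    "classify_test_trial",
    "classify_participant",
    "compelled_success",
    "compelled_success_rate",
    "learning_onset",
    "DEFAULT_ONSET_BINS",
]

AS = "AS"
ES = "ES"
NO_EFFICIENT = "NoEfficient"

ALLOCENTRIC = "Allocentric"
EGOCENTRIC = "Egocentric"
SHIFTER = "Shifter"
LACKING = "Lacking"

#: Test-trial goal alleys: alley 3 is reached by landmark use (AS), alley 1
#: by replaying the start-relative motor sequence (ES).
AS_GOAL_ALLEY = 3
ES_GOAL_ALLEY = 1


@dataclass(frozen=True)
class ParticipantStrategy:
    label: str  # Allocentric | Egocentric | Shifter | Lacking
    trial_labels: Tuple[str, ...]


def classify_test_trial(metrics: TrialMetrics, spec: TrialSpec) -> str:
    """AS / ES / NoEfficient label of a single test trial."""
    if spec.trial_type != "test":
        raise ValueError(f"trial {spec.trial_index} is {spec.trial_type!r}, not a test trial")
    if metrics.success and metrics.visited_n == 2:
        if metrics.reached_alley == AS_GOAL_ALLEY:
            return AS
        if metrics.reached_alley == ES_GOAL_ALLEY:
            return ES
    return NO_EFFICIENT


def _longest_run(labels: Sequence[str], target: str) -> int:
    best = run = 0
    for lab in labels:
        run = run + 1 if lab == target else 0
        best = max(best, run)
    return best


def classify_participant(
    trial_labels: Sequence[str],
    consecutive_threshold: int = 4,
    noeff_threshold: int = 4,
) -> ParticipantStrategy:
    """Overall strategy from the five test-trial labels.

    Precedence: Allocentric (≥ ``consecutive_threshold`` consecutive AS,
    all other trials NoEfficient) and the symmetric Egocentric rule come
    first; then Shifter (both AS and ES appear); then Lacking
    (≥ ``noeff_threshold`` NoEfficient).  Residual patterns fall back to
    Lacking.  The default threshold 4 reads "more than three" as ≥ 4 of
    the five trials; pass 3 for the laxer reading.
    """
    labels = tuple(trial_labels)
    if len(labels) != 5:
        raise ValueError(f"expected exactly 5 test-trial labels, got {len(labels)}")
    bad = set(labels) - {AS, ES, NO_EFFICIENT}
    if bad:
        raise ValueError(f"unknown trial labels: {sorted(bad)}")
    has_as, has_es = AS in labels, ES in labels
    if _longest_run(labels, AS) >= consecutive_threshold and not has_es:
        return ParticipantStrategy(ALLOCENTRIC, labels)
    if _longest_run(labels, ES) >= consecutive_threshold and not has_as:
        return ParticipantStrategy(EGOCENTRIC, labels)
    if has_as and has_es:
        return ParticipantStrategy(SHIFTER, labels)
    if labels.count(NO_EFFICIENT) >= noeff_threshold:
        return ParticipantStrategy(LACKING, labels)
    return ParticipantStrategy(LACKING, labels)  # documented residual fallback


def compelled_success(metrics: TrialMetrics, spec: TrialSpec) -> bool:
    """A compelled trial succeeds only with a direct two-alley route."""
    if spec.trial_type not in ("compelled_AS", "compelled_ES"):
        raise ValueError(f"trial {spec.trial_index} is {spec.trial_type!r}, not a compelled trial")
    return bool(metrics.success and metrics.visited_n == 2)


def compelled_success_rate(
    records: Sequence[Tuple[TrialSpec, Optional[TrialMetrics]]],
) -> Tuple[Optional[float], Optional[float]]:
    """Percent success over compelled-AS and compelled-ES trials.

    ``records`` pairs each Task 2 spec with its metrics (None = missing
    trial, excluded from the denominator).  Returns (as_pct, es_pct); a
    type with zero observed trials yields None.
    """
    counts = {"compelled_AS": [0, 0], "compelled_ES": [0, 0]}
    for spec, metrics in records:
        if spec.trial_type not in counts:
            continue
        if metrics is None:
            continue
        n_succ, n_tot = counts[spec.trial_type]
        counts[spec.trial_type] = [n_succ + int(compelled_success(metrics, spec)), n_tot + 1]
    out = []
    for kind in ("compelled_AS", "compelled_ES"):
        n_succ, n_tot = counts[kind]
        out.append(100.0 * n_succ / n_tot if n_tot else None)
    return out[0], out[1]


#: (upper onset edge, label) pairs; onsets above the last edge get "late",
#: no stable onset gets "never_stable".
DEFAULT_ONSET_BINS: Tuple[Tuple[int, str], ...] = (
    (1, "first_trial"),
    (3, "by_third_trial"),
    (7, "by_seventh_trial"),
    (16, "late"),
)


def learning_onset(
    training_success: Sequence[Optional[bool]],
    bins: Sequence[Tuple[int, str]] = DEFAULT_ONSET_BINS,
) -> Tuple[Optional[int], str]:
    """Stable-success onset over the 16 training trials.

    The onset is the smallest training trial *t* with success at every
    trial t..16; missing trials count as failures.  Returns ``(onset,
    bin_label)``; ``(None, "never_stable")`` when success never becomes
    stable.
    """
    flags = [bool(s) for s in training_success]
    if len(flags) == 0:
        return None, "never_stable"
    onset: Optional[int] = None
    for t in range(len(flags), 0, -1):
        if not flags[t - 1]:
            break
        onset = t
    if onset is None:
        return None, "never_stable"
    for edge, label in bins:
        if onset <= edge:
            return onset, label
    return onset, "late"
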