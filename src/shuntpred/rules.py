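"""Clinical classification rules.

Tap-test positivity (any of three improvement criteria after CSF removal),
the Krauss-index responder rule grading shunt outcome, dichotomization of
the callosal angle at a cutoff, and the two rules used to combine imaging
signs with the tap test:

* OR rule ("believe the positive"): a negative tap upgraded to positive by
  a positive imaging sign.
* Majority rule: start from the tap result; override to negative when both
  imaging signs disagree with a positive tap, to positive when both
  disagree with a negative tap.  Equivalent to a 2-of-3 majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .cohort import TapAssessment

__all__ = [
    "RuleDomainError",
    "TapCriteria",
    "KraussRule",
    "DichotomizedTests",
    "TapResult",
    "classify_tap_response",
    "krauss_responder",
    "dichotomize_ca",
    "combine_or",
    "combine_majority",
]


class RuleDomainError(ValueError):
    """An input outside the rule's domain (e.g. non-positive baseline)."""


@dataclass
class TapCriteria:
    """Improvement thresholds defining tap-test positivity.

    Defaults: >= 20% improvement in 10 m walk time or steps, >= 10%
    improvement in MMSE, or a decrease of >= 1 point in the 0-10 urinary
    incontinence score.  All boundaries inclusive.
    """

    gait_improvement_threshold: float = 0.20
    mmse_improvement_threshold: float = 0.10
    urinary_improvement_points: int = 1

    def __post_init__(self):
        if (
            self.gait_improvement_threshold <= 0
            or self.mmse_improvement_threshold <= 0
            or self.urinary_improvement_points <= 0
        ):
            raise RuleDomainError("tap criteria thresholds must be positive")


@dataclass
class KraussRule:
    """Responder rule on the relative improvement of a symptom-severity score.

    index = (preop - postop)/preop; responder iff index >= threshold
    (inclusive).  The scoring hook allows alternative improvement indices.
    """

    responder_threshold: float = 0.5
    scoring: Optional[Callable[[float, float], float]] = None

    def __post_init__(self):
        if not (0 < self.responder_threshold <= 1):
            raise RuleDomainError("responder threshold must lie in (0, 1]")


@dataclass(frozen=True)
class DichotomizedTests:
    """Binary results of the three predictors for one subject."""

    tap_positive: bool
    desh_positive: bool
    ca_positive: bool


@dataclass
class TapResult:
    positive: bool
    criteria_met: frozenset  # subset of {"gait", "cognition", "urinary"}
    flags: tuple = ()  # e.g. ("mmse_baseline_zero",)


def classify_tap_response(tap: TapAssessment, criteria: TapCriteria = None) -> TapResult:
    """Apply the three improvement criteria; positive iff at least one is met.

    Improvement conventions: walk time and steps improve by *decreasing*
    (relative change (pre - post)/pre, either measure sufficing); MMSE
    improves by *increasing* ((post - pre)/pre); urinary improves by a
    *decrease* of at least 1 point.  A zero MMSE baseline makes the relative
    change undefined: the cognition criterion is treated as not met and the
    record is flagged.
    """
    criteria = criteria or TapCriteria()
    if tap.pre_walk_time <= 0 or tap.pre_walk_steps <= 0:
        raise RuleDomainError("pre-tap walk time and steps must be positive")
    met = set()
    flags = []

    time_gain = (tap.pre_walk_time - tap.post_walk_time) / tap.pre_walk_time
    steps_gain = (tap.pre_walk_steps - tap.post_walk_steps) / tap.pre_walk_steps
    if max(time_gain, steps_gain) >= criteria.gait_improvement_threshold:
        met.add("gait")

    if tap.pre_mmse == 0:
        if tap.post_mmse != tap.pre_mmse:
            flags.append("mmse_baseline_zero")
    elif (tap.post_mmse - tap.pre_mmse) / tap.pre_mmse >= criteria.mmse_improvement_threshold:
        met.add("cognition")

    if tap.pre_urinary - tap.post_urinary >= criteria.urinary_improvement_points:
        met.add("urinary")

    return TapResult(positive=bool(met), criteria_met=frozenset(met), flags=tuple(flags))


def krauss_responder(
    preop_severity: float, postop_severity: float, rule: KraussRule = None
) -> tuple[float, bool]:
    """Krauss improvement index and responder call.

    Returns ``(index, responder)`` with index = (pre - post)/pre and
    responder iff index >= rule.responder_threshold (boundary inclusive).
    """
    rule = rule or KraussRule()
    if preop_severity <= 0:
        raise RuleDomainError("preoperative severity must be positive to define improvement")
    if postop_severity < 0:
        raise RuleDomainError("postoperative severity must be non-negative")
    scoring = rule.scoring or (lambda pre, post: (pre - post) / pre)
    index = scoring(preop_severity, postop_severity)
    return index, index >= rule.responder_threshold


def dichotomize_ca(ca: float, cutoff: float, inclusive: bool = True) -> bool:
    """Callosal-angle positivity: a *smaller* angle predicts shunt response.

    Positive iff ca <= cutoff (inclusive boundary by default, so the cutoff
    itself falls with the group it was selected to capture; configurable).
    """
    if not (0 < ca < 180):
        raise RuleDomainError("callosal angle must lie in (0, 180) degrees")
    if not (0 < cutoff < 180):
        raise RuleDomainError("cutoff must lie in (0, 180) degrees")
    return ca <= cutoff if inclusive else ca < cutoff


def combine_or(tap_positive: bool, imaging_positive: bool) -> bool:
    """OR combination: a positive imaging sign upgrades a negative tap."""
    return bool(tap_positive) or bool(imaging_positive)


def combine_majority(tests: DichotomizedTests) -> bool:
    """Tap-anchored override rule, identical to a 2-of-3 majority vote.

    Start from the tap result; flip to negative when tap+/DESH-/CA-, flip
    to positive when tap-/DESH+/CA+.
    """
    result = bool(tests.tap_positive)
    if tests.tap_positive and not tests.desh_positive and not tests.ca_positive:
        result = False
    elif not tests.tap_positive and tests.desh_positive and tests.ca_positive:
        result = True
    return result
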