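"""Diagnostic accuracy: confusion counts, sensitivity/specificity/PPV/NPV,
ROC curves, binary-test AUC, and Youden-index cutoff selection.

A dichotomous (single-operating-point) test has the three-point ROC
(0,0) - (1-specificity, sensitivity) - (1,1), whose trapezoidal area is
exactly (sensitivity + specificity)/2; that identity is how the AUC of a
binary rule is computed and reported here.

For a continuous marker, candidate thresholds are the midpoints between
adjacent distinct observed values plus -inf/+inf sentinels (so (0,0) and
(1,1) always lie on the curve); AUC is the trapezoid over all operating
points, which with tied values equals the Mann-Whitney U statistic over
n1*n2 with half credit for ties.  The Youden-optimal cutoff maximizes
J = sensitivity + specificity - 1; among tied maxima the threshold with
the higher specificity is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MetricsError",
    "ConfusionCounts",
    "DiagnosticPerformance",
    "RocResult",
    "confusion_counts",
    "diagnostic_performance",
    "binary_auc",
    "roc_and_youden",
    "round_half_away",
]


class MetricsError(ValueError):
    pass


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.595 -> 0.60 at 2 dp), as report tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 cross-tabulation of a binary prediction against responder status."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0  # subjects dropped for missing predictions

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DiagnosticPerformance:
    """Accuracy summary of a binary test; auc = (sens + spec)/2."""

    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    auc: float
    flags: tuple = ()

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for k in ("sensitivity", "specificity", "ppv", "npv", "auc"):
            val = getattr(self, k)
            out[k] = None if val is None else round_half_away(val, ndigits)
        return out


@dataclass
class RocResult:
    """Full ROC of a continuous marker with the Youden-optimal operating point.

    Operating points are stored as parallel arrays sorted by threshold;
    sentinel thresholds are -inf/+inf, so (0,0) and (1,1) always lie on
    the curve.  ``points`` materializes them as (threshold, sensitivity,
    1 - specificity) tuples.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    fprs: np.ndarray
    auc: float
    youden_j_max: float
    optimal_cutoff: Optional[float]
    direction: str
    flags: tuple = ()

    @property
    def points(self) -> list:
        return [
            (float(t), float(s), float(f))
            for t, s, f in zip(self.thresholds, self.sensitivities, self.fprs)
        ]


def confusion_counts(
    predicted: Sequence[Optional[bool]], truth: Sequence[bool]
) -> ConfusionCounts:
    """Cross-tabulate predictions against truth (truth=True means responder).

    ``None`` predictions are excluded and tallied in ``n_excluded``.
    """
    if len(predicted) != len(truth):
        raise MetricsError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    tp = fp = fn = tn = excluded = 0
    for p, t in zip(predicted, truth):
        if p is None:
            excluded += 1
        elif p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn, n_excluded=excluded)


def binary_auc(sensitivity: float, specificity: float) -> float:
    """Trapezoidal ROC area of a single-operating-point test: (sens+spec)/2."""
    if not (0 <= sensitivity <= 1) or not (0 <= specificity <= 1):
        raise MetricsError("sensitivity and specificity must lie in [0, 1]")
    return (sensitivity + specificity) / 2.0


def diagnostic_performance(counts: ConfusionCounts) -> DiagnosticPerformance:
    """Sensitivity/specificity/PPV/NPV/AUC from a 2x2 table.

    Requires at least one subject in each truth class.  PPV (NPV) is None
    and flagged when no positive (negative) call was made.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if tp + fn == 0:
        raise MetricsError("no subjects in the positive (responder) class")
    if tn + fp == 0:
        raise MetricsError("no subjects in the negative (non-responder) class")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    flags = []
    if tp + fp == 0:
        ppv, f = None, "ppv_undefined_no_positive_calls"
        flags.append(f)
    else:
        ppv = tp / (tp + fp)
    if tn + fn == 0:
        npv = None
        flags.append("npv_undefined_no_negative_calls")
    else:
        npv = tn / (tn + fn)
    return DiagnosticPerformance(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        auc=binary_auc(sens, spec),
        flags=tuple(flags),
    )


def roc_and_youden(
    marker_values: Sequence[float],
    truth: Sequence[bool],
    direction: str = "lower_is_positive",
) -> RocResult:
    """ROC over midpoint thresholds and the Youden-optimal cutoff.

    direction="lower_is_positive": call positive when value <= threshold
    (the callosal-angle convention: smaller angles predict response);
    "higher_is_positive" calls positive when value >= threshold.
    """
    if direction not in ("lower_is_positive", "higher_is_positive"):
        raise MetricsError(f"unknown direction {direction!r}")
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if x.shape != y.shape:
        raise MetricsError("marker and truth lengths differ")

    if direction == "higher_is_positive":
        # x >= t is x' <= t' for x' = -x, t' = -t: reuse the ascending path
        res = roc_and_youden(-x, y, "lower_is_positive")
        order = np.argsort(-res.thresholds, kind="stable")
        return RocResult(
            thresholds=-res.thresholds[order],
            sensitivities=res.sensitivities[order],
            fprs=res.fprs[order],
            auc=res.auc,
            youden_j_max=res.youden_j_max,
            optimal_cutoff=None if res.optimal_cutoff is None else -res.optimal_cutoff,
            direction=direction,
            flags=res.flags,
        )

    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise MetricsError("need at least 2 subjects per truth class")

    order = np.argsort(x, kind="mergesort")
    ys = y[order]
    distinct, first_idx = np.unique(x[order], return_index=True)
    flags = []

    # cut positions: how many of the smallest values are called positive at
    # each threshold (sentinels = none / all)
    cuts = np.concatenate(([0], first_idx[1:], [x.size]))
    thresholds = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    cum_pos = np.concatenate(([0], np.cumsum(ys)))
    tp = cum_pos[cuts]
    fp = cuts - tp
    sens = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(sens, fpr))

    if distinct.size == 1:
        flags.append("constant_marker_cutoff_undefined")
        return RocResult(
            thresholds=thresholds, sensitivities=sens, fprs=fpr, auc=0.5,
            youden_j_max=0.0, optimal_cutoff=None, direction=direction,
            flags=tuple(flags),
        )

    j = sens - fpr
    j_max = float(j.max())
    # tie-break among max-J thresholds: highest specificity (lowest FPR),
    # then lowest threshold, for determinism
    tied = np.flatnonzero(j >= j_max - 1e-15)
    best = tied[np.lexsort((thresholds[tied], fpr[tied]))[0]]
    cutoff = float(thresholds[best])
    if not np.isfinite(cutoff):
        flags.append("degenerate_cutoff_at_sentinel")
        cutoff = None
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        fprs=fpr,
        auc=auc,
        youden_j_max=j_max,
        optimal_cutoff=cutoff,
        direction=direction,
        flags=tuple(flags),
    )
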