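"""Group comparison tests and forward likelihood-ratio logistic regression.

Continuous variables go through a dispatch cascade: Shapiro-Wilk normality
in each group and a two-sample variance-ratio F test; only when both groups
look normal AND variances look homogeneous is the pooled-variance t-test
used, otherwise the Mann-Whitney U test.  Categorical variables use the
Pearson chi-square test without continuity correction.

The multivariable model is a logistic regression with forward stepwise
selection by likelihood-ratio tests: at each step the candidate with the
smallest LR p-value below ``entry_alpha`` enters; any included variable
whose LR p-value (dropping it from the current model) exceeds
``removal_alpha`` is removed.  Per-variable Wald chi-square, odds ratios
and 95% CIs are reported for the final model.  Because the outcome coding
(which class is 1) flips every odds ratio to its reciprocal, the result
records the coding and reports both directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning as SMConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "StatsError",
    "SeparationError",
    "ConvergenceError",
    "GroupComparison",
    "LogisticModelResult",
    "compare_continuous",
    "chi_square_test",
    "fit_logistic_forward_lr",
]


class StatsError(ValueError):
    pass


class SeparationError(RuntimeError):
    """A covariate (quasi-)perfectly separates the outcome classes."""


class ConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to converge; carries the fit trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class GroupComparison:
    """One row of a univariate comparison table."""

    variable: str
    test_used: str  # "t_test" | "mann_whitney" | "chi_square"
    statistic: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)


@dataclass
class LogisticModelResult:
    """Final forward-LR logistic model with its selection trace.

    ``outcome_coding`` states which class was coded 1; odds ratios for the
    opposite coding are the reciprocals, reported in
    ``odds_ratios_inverse``.
    """

    selected_variables: list
    coefficients: dict
    std_errors: dict
    odds_ratios: dict
    odds_ratios_inverse: dict
    ci95: dict  # variable -> (low, high) on the OR scale
    wald_chi_square: dict
    p_values: dict
    intercept: float
    log_likelihood: float
    outcome_coding: str
    selection_trace: list  # (step, action, variable, lr_statistic, p)
    n_obs: int


def _shapiro_p(x: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def compare_continuous(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    variable: str = "",
) -> GroupComparison:
    """Normality/homogeneity-gated two-sample comparison.

    Pooled t-test when both Shapiro-Wilk tests and the variance-ratio
    F test are non-significant at ``alpha``; Mann-Whitney U otherwise
    (exact below n=8 without ties, normal approximation with tie
    correction and no continuity correction otherwise, so identical
    groups give p = 1 exactly).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise StatsError("each group needs n >= 3 for the normality gate")

    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0  # Shapiro undefined on constants
    normal = (not degenerate) and _shapiro_p(a) > alpha and _shapiro_p(b) > alpha
    homogeneous = False
    if normal:
        f_stat = float(np.var(a, ddof=1) / np.var(b, ddof=1))
        fdist = sps.f(a.size - 1, b.size - 1)
        p_f = 2.0 * min(fdist.cdf(f_stat), fdist.sf(f_stat))
        homogeneous = p_f > alpha

    summaries = {
        "group_a": {"n": int(a.size), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
        "group_b": {"n": int(b.size), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
    }
    if normal and homogeneous:
        res = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison(variable, "t_test", float(res.statistic), float(res.pvalue), summaries)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) < 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return GroupComparison(variable, "mann_whitney", float(res.statistic), float(res.pvalue), summaries)


def chi_square_test(table, variable: str = "") -> GroupComparison:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError("chi_square_test expects a 2x2 count table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("chi-square undefined: a row or column marginal is zero")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    summaries = {"table": t.astype(int).tolist()}
    return GroupComparison(variable, "chi_square", float(chi2), float(p), summaries)


_MAX_ABS_COEF = 25.0
_MAX_SE = 1e3


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Single ML logistic fit with separation and convergence checks."""
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", SMConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=50, method="newton", tol=1e-10)
        except PerfectSeparationError as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
    # separation shows as diverging coefficients / exploding SEs; test for it
    # before the convergence check so it is reported as what it is
    slopes = res.params.drop("const", errors="ignore")
    ses = res.bse.drop("const", errors="ignore")
    if (slopes.abs() > _MAX_ABS_COEF).any() or (ses > _MAX_SE).any():
        raise SeparationError(
            "diverging coefficient or exploding standard error indicates separation"
        )
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge within 50 iterations",
                               trace=res.mle_retvals)
    return res


def fit_logistic_forward_lr(
    design: pd.DataFrame,
    outcome: Sequence[bool],
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
    outcome_coding: str = "1=responder",
) -> LogisticModelResult:
    """Forward stepwise logistic regression with LR entry/removal tests.

    ``design`` holds one column per candidate covariate; ``outcome`` is the
    boolean class coded 1.  LR statistic = 2 * (loglik gain), df = 1.
    """
    X = pd.DataFrame(design).astype(float)
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise StatsError("design and outcome lengths differ")
    if len(np.unique(y)) < 2:
        raise StatsError("outcome must contain both classes")

    candidates = list(X.columns)
    included: list[str] = []
    trace: list[tuple] = []
    current = _fit_logit(y, X[[]])
    step = 0

    while True:
        step += 1
        best = None
        for var in candidates:
            if var in included:
                continue
            trial = _fit_logit(y, X[included + [var]])
            lr = 2.0 * (trial.llf - current.llf)
            p = float(sps.chi2.sf(max(lr, 0.0), 1))
            if p < entry_alpha and (best is None or p < best[1]):
                best = (var, p, lr, trial)
        if best is None:
            break
        var, p, lr, fit = best
        included.append(var)
        current = fit
        trace.append((step, "enter", var, float(lr), p))

        # backward pass: drop anything whose LR p now exceeds removal_alpha
        removed = True
        while removed and len(included) > 1:
            removed = False
            worst = None
            for var in included:
                reduced = _fit_logit(y, X[[v for v in included if v != var]])
                lr_drop = 2.0 * (current.llf - reduced.llf)
                p_drop = float(sps.chi2.sf(max(lr_drop, 0.0), 1))
                if p_drop > removal_alpha and (worst is None or p_drop > worst[1]):
                    worst = (var, p_drop, lr_drop)
            if worst is not None:
                var, p_drop, lr_drop = worst
                included.remove(var)
                current = _fit_logit(y, X[included])
                trace.append((step, "remove", var, float(lr_drop), p_drop))
                removed = True

    params = current.params
    bse = current.bse
    coefs = {v: float(params[v]) for v in included}
    ses = {v: float(bse[v]) for v in included}
    ors = {v: float(np.exp(c)) for v, c in coefs.items()}
    ci = {
        v: (float(np.exp(coefs[v] - 1.96 * ses[v])), float(np.exp(coefs[v] + 1.96 * ses[v])))
        for v in included
    }
    wald = {v: float((coefs[v] / ses[v]) ** 2) for v in included}
    pvals = {v: float(sps.chi2.sf(wald[v], 1)) for v in included}
    return LogisticModelResult(
        selected_variables=list(included),
        coefficients=coefs,
        std_errors=ses,
        odds_ratios=ors,
        odds_ratios_inverse={v: 1.0 / o for v, o in ors.items()},
        ci95=ci,
        wald_chi_square=wald,
        p_values=pvals,
        intercept=float(params["const"]),
        log_likelihood=float(current.llf),
        outcome_coding=outcome_coding,
        selection_trace=trace,
        n_obs=int(y.shape[0]),
    )
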