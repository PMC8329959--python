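"""Survival inference chain for cutoff-dichotomized texture biomarkers.

The chain mirrors the standard exploratory-radiomics workflow: compare a
feature between survivors and non-survivors (Levene for variance equality,
Mann-Whitney U for location), pick an optimal cutoff on the ROC curve
(Youden's J), dichotomize, compare the two groups' survival (Kaplan-Meier
curves, log-rank test), and estimate hazard ratios with Cox
proportional-hazards models (univariate, and bivariate feature + M stage).
Spearman rank correlations screen the features for collinearity.

Kaplan-Meier, log-rank and Cox fitting are delegated to ``lifelines``
(Efron tie correction, Wald confidence intervals and p-values); the cutoff
search, the exact small-sample Mann-Whitney p-value and the orientation
conventions are implemented here.

Direction convention: throughout, *lower* feature values are the adverse
phenotype -- the low group is ``value < cutoff`` (strict), and ROC AUC is
computed for the rule "lower value predicts death".
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import ConvergenceWarning
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger("texsurv")

__all__ = [
    "MWUResult",
    "CutoffResult",
    "DichotomyResult",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "CorrEntry",
    "levene_test",
    "mann_whitney",
    "roc_auc",
    "optimal_cutoff",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "spearman_corr",
    "spearman_matrix",
]

#: largest pooled sample size for which the Mann-Whitney p is computed by
#: full enumeration of the permutation distribution
_MWU_EXACT_MAX_N = 12


# ---------------------------------------------------------------------------
# group comparison


def levene_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classic Levene test (deviations from the group mean) for >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Levene's test needs at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least two observations")
    stat, p = stats.levene(*groups, center="mean")
    return float(stat), float(p)


@dataclass(frozen=True)
class MWUResult:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    exact: bool
    degenerate: bool = False


def _u_from_ranks(pooled_ranks: np.ndarray, idx_a: np.ndarray, n_a: int) -> float:
    r_a = pooled_ranks[idx_a].sum()
    return float(r_a - n_a * (n_a + 1) / 2.0)


def mann_whitney(group_a, group_b) -> MWUResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    The p-value is exact (full enumeration of all label assignments) when
    the pooled sample size is at most 12; otherwise the normal approximation
    with tie correction (and continuity correction) is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])

    if np.ptp(pooled) == 0:
        return MWUResult(
            u_statistic=n1 * n2 / 2.0,
            p_value=1.0,
            median_a=float(np.median(a)),
            median_b=float(np.median(b)),
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            exact=True,
            degenerate=True,
        )

    ranks = stats.rankdata(pooled)
    u_obs = _u_from_ranks(ranks, np.arange(n1), n1)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= _MWU_EXACT_MAX_N:
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = _u_from_ranks(ranks, np.asarray(idx), n1)
            hits += abs(u - mu) >= dev_obs - 1e-12
            total += 1
        p = hits / total
        exact = True
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        exact = False

    return MWUResult(
        u_statistic=u_obs,
        p_value=float(p),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        exact=exact,
    )


# ---------------------------------------------------------------------------
# ROC cutoff selection


def roc_auc(values, labels, direction: str = "lower") -> float:
    """AUC for predicting death from a feature; ties count one half.

    ``direction="lower"`` scores the rule "lower value predicts death"
    (labels: 1 = death).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both label classes must be present for ROC analysis")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    score = -values if direction == "lower" else values
    return float(roc_auc_score(labels, score))


@dataclass(frozen=True)
class CutoffResult:
    feature: str
    cutoff: float
    auc: float
    direction: str
    youden_j: float


def optimal_cutoff(values, labels, feature: str = "", criterion: str = "youden") -> CutoffResult:
    """Observed feature value maximizing Youden's J for "value < cutoff => death".

    Ties on J are broken toward the larger cutoff (the more inclusive low
    group).  The returned cutoff is always an observed value.
    """
    if criterion != "youden":
        raise ValueError(f"unsupported cutoff criterion: {criterion!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc(values, labels, direction="lower")

    candidates = np.unique(values)
    pred_death = values[:, None] < candidates[None, :]  # n x m
    deaths = labels == 1
    sens = pred_death[deaths].mean(axis=0)
    spec = (~pred_death[~deaths]).mean(axis=0)
    j = sens + spec - 1.0
    best = j.max()
    # candidates ascend, so the last argmax is the largest tied cutoff
    idx = np.flatnonzero(j >= best - 1e-12)[-1]
    return CutoffResult(
        feature=feature,
        cutoff=float(candidates[idx]),
        auc=auc,
        direction="lower",
        youden_j=float(best),
    )


@dataclass(frozen=True)
class DichotomyResult:
    labels: np.ndarray  # object array of "low" / "high" / None
    n_low: int
    n_high: int
    n_missing: int

    @property
    def has_empty_group(self) -> bool:
        return self.n_low == 0 or self.n_high == 0


def dichotomize(values, cutoff: float, feature: str = "") -> DichotomyResult:
    """Label subjects "low" (value < cutoff, strict) or "high" (otherwise).

    Subjects with missing values are excluded (label ``None``) with a logged
    warning.  An empty group is flagged so downstream KM/Cox can refuse.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    values = np.asarray(values, dtype=float)
    labels = np.empty(values.shape, dtype=object)
    missing = ~np.isfinite(values)
    labels[missing] = None
    labels[~missing & (values < cutoff)] = "low"
    labels[~missing & (values >= cutoff)] = "high"
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning(
            "dichotomize(%s): excluded %d subject(s) with missing values",
            feature or "<feature>",
            n_missing,
        )
    res = DichotomyResult(
        labels=labels,
        n_low=int(np.sum(labels == "low")),
        n_high=int(np.sum(labels == "high")),
        n_missing=n_missing,
    )
    if res.has_empty_group:
        logger.warning("dichotomize(%s): one group is empty at cutoff %g", feature, cutoff)
    return res


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival probability after each event time."""

    timeline: np.ndarray  # includes t = 0
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    median: float  # np.inf when the curve never crosses 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects leave the risk set after their time; a subject
    censored exactly at an event time is counted at risk for that event
    (the standard convention, as in ``lifelines``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("at least one record required")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    return KMCurve(
        timeline=timeline,
        survival=survival,
        at_risk=at_risk,
        censor_times=np.sort(times[events == 0]),
        median=median,
    )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sample log-rank test (O-E chi-square, hypergeometric variance, df=1)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    res = _ll_logrank(
        times_a, times_b, event_observed_A=events_a, event_observed_B=events_b
    )
    return LogRankResult(
        chi_square=float(res.test_statistic), p_value=float(res.p_value)
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    summary: pd.DataFrame  # index: covariate; columns: beta, se, hr, ci_low, ci_high, p
    log_likelihood: float
    converged: bool
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "os_months",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit via partial likelihood (Efron ties).

    Covariates must be numeric columns of ``df`` (binary indicators for the
    dichotomized feature and M-stage analyses).  Non-convergence is raised;
    monotone-likelihood / separation warnings are captured and surfaced in
    ``CoxFit.warnings`` instead of silently discarded.
    """
    for c in covariates:
        col = df[c]
        if col.nunique(dropna=True) < 2:
            raise ValueError(f"covariate {c!r} is constant; model unidentifiable")
    if df[event_col].sum() < 1:
        raise ValueError("at least one event is required")

    data = df[[duration_col, event_col, *covariates]].astype(float)
    cph = CoxPHFitter()
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
        caught = [str(w.message).strip() for w in wlist]
    for msg in caught:
        logger.warning("cox_fit: %s", msg.splitlines()[0])

    s = cph.summary
    summary = pd.DataFrame(
        {
            "beta": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
        warnings=tuple(caught),
    )


# ---------------------------------------------------------------------------
# collinearity screening


@dataclass(frozen=True)
class CorrEntry:
    feature_a: str
    feature_b: str
    rho: float | None  # None when undefined (constant feature)
    p_value: float | None


def spearman_corr(x, y, name_a: str = "a", name_b: str = "b") -> CorrEntry:
    """Spearman rank correlation (midrank ties, two-sided t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman_corr(%s, %s): constant input, rho undefined", name_a, name_b)
        return CorrEntry(name_a, name_b, None, None)
    rho, p = stats.spearmanr(x, y)
    return CorrEntry(name_a, name_b, float(rho), float(p))


def spearman_matrix(features: pd.DataFrame) -> list[CorrEntry]:
    """All unordered pairwise Spearman correlations among feature columns."""
    if len(features) < 3:
        raise ValueError("need >= 3 subjects")
    cols = list(features.columns)
    out = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            out.append(spearman_corr(features[a], features[b], a, b))
    return out
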