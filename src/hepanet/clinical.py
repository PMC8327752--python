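"""Clinicopathological association tests, IHC scoring, and survival analysis.

Covers the clinical arm of the study design: Pearson chi-square (no
continuity correction) on 2x2 contingency tables of covariate level vs
expression class, Remmele-style immunohistochemistry percent-positive
binning, Kaplan-Meier estimation, the two-group log-rank test, and
univariate/multivariate Cox proportional-hazards fits (partial likelihood
with Efron's tie correction; equivalent to Breslow on tie-free data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2_contingency

__all__ = [
    "IHCScore",
    "CoxResult",
    "chisq_2x2",
    "bin_ihc_score",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "dichotomize_expression",
    "association_table",
]


@dataclass(frozen=True)
class IHCScore:
    """Remmele-style ordinal score from percent of positively stained cells.

    Score 1: < 25 %, score 2: [25, 50), score 3: [50, 75), score 4: >= 75 %
    (boundary percentages go to the higher score).  Scores 1-2 are the low
    expression class, 3-4 the high class.
    """

    percent: float
    score: int
    expression_class: str


@dataclass(frozen=True)
class CoxResult:
    """Per-covariate proportional-hazards summary."""

    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    log_likelihood: float
    n: int
    n_events: int
    converged: bool = True


def chisq_2x2(table: np.ndarray | list[list[int]], correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction by default."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = chi2_contingency(t, correction=correction)
    return float(chi2), float(p)


def bin_ihc_score(percent: float, boundary_up: bool = True) -> IHCScore:
    """Bin a percent-positive value into the 4-level score and low/high class.

    ``boundary_up`` assigns boundary percentages (25/50/75) to the higher
    score; set False for the lower-score convention.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent {percent} outside [0, 100]")
    cuts = (25.0, 50.0, 75.0)
    if boundary_up:
        score = 1 + sum(percent >= c for c in cuts)
    else:
        score = 1 + sum(percent > c for c in cuts)
    return IHCScore(percent, score, "low" if score <= 2 else "high")


def km_estimate(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival curve: (time, survival, at-risk count) per event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame({"time": surv.index.to_numpy(),
                         "survival": surv.to_numpy(),
                         "at_risk": at_risk.to_numpy()})


def logrank_test(
    time: np.ndarray,
    event: np.ndarray,
    groups: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test (observed minus expected, hypergeometric variance).

    Returns (chi-square statistic, p) on 1 df; two identical groups give
    statistic 0 and p = 1.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    mask = groups == labels[0]
    if mask.all() or (~mask).all():
        raise ValueError("one group is empty")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events observed")
    res = _ll_logrank(time[mask], time[~mask], event[mask], event[~mask])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    mode: str = "univariate",
    time_col: str = "time",
    event_col: str = "event",
) -> list[CoxResult]:
    """Cox proportional-hazards fits (partial likelihood, Efron ties).

    ``univariate`` fits one single-covariate model per covariate;
    ``multivariate`` fits one joint model.  Covariate columns must be
    numeric (dichotomize or dummy-code categorical covariates first) and
    non-constant.  HR = exp(beta), 95 % CI = exp(beta +- 1.96 SE), Wald p.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    for cov in covariates:
        col = df[cov].astype(float)
        if col.nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    groups = [[c] for c in covariates] if mode == "univariate" else [list(covariates)]
    results: list[CoxResult] = []
    for covs in groups:
        sub = df[[time_col, event_col, *covs]].astype(float)
        cph = CoxPHFitter()
        converged = True
        try:
            cph.fit(sub, duration_col=time_col, event_col=event_col)
        except Exception as exc:  # non-convergence / separation
            raise RuntimeError(f"Cox fit failed for {covs}: {exc}") from exc
        summ = cph.summary
        for cov in covs:
            row = summ.loc[cov]
            results.append(
                CoxResult(
                    covariate=cov,
                    hr=float(row["exp(coef)"]),
                    ci_low=float(row["exp(coef) lower 95%"]),
                    ci_high=float(row["exp(coef) upper 95%"]),
                    p=float(row["p"]),
                    coef=float(row["coef"]),
                    se=float(row["se(coef)"]),
                    log_likelihood=float(cph.log_likelihood_),
                    n=len(sub),
                    n_events=int(sub[event_col].sum()),
                    converged=converged,
                )
            )
    return results


def dichotomize_expression(
    values: np.ndarray | pd.Series,
    rule: str = "median",
    threshold: float | None = None,
) -> np.ndarray:
    """Two-level low/high labeling of a continuous expression vector.

    ``median``: values <= median go to "low" (ties at the median are low);
    ``threshold``: explicit cut, values <= threshold are low;
    ``ihc_score``: values are percent-positive, classed via the score rule.
    """
    v = np.asarray(values, dtype=float)
    if rule == "median":
        if np.all(v == v[0]):
            raise ValueError("constant values cannot be median-split")
        cut = np.median(v)
        return np.where(v <= cut, "low", "high")
    if rule == "threshold":
        if threshold is None:
            raise ValueError("explicit rule needs a threshold")
        return np.where(v <= threshold, "low", "high")
    if rule == "ihc_score":
        return np.asarray([bin_ihc_score(x).expression_class for x in v])
    raise ValueError(f"unknown rule {rule!r}")


def association_table(
    clinical: pd.DataFrame,
    covariates: list[str],
    class_col: str = "expression",
) -> pd.DataFrame:
    """Covariate-by-expression-class association summary (one chi-square per covariate).

    For each binary covariate, builds the 2x2 table of covariate level vs
    low/high class and reports cell counts and the Pearson chi-square p.
    """
    rows = []
    cls = clinical[class_col]
    for cov in covariates:
        levels = sorted(clinical[cov].dropna().unique().tolist())
        if len(levels) != 2:
            raise ValueError(f"covariate {cov!r} is not binary (levels {levels})")
        t = np.array(
            [
                [((clinical[cov] == lev) & (cls == "low")).sum(),
                 ((clinical[cov] == lev) & (cls == "high")).sum()]
                for lev in levels
            ]
        )
        chi2, p = chisq_2x2(t)
        for i, lev in enumerate(levels):
            rows.append(
                {
                    "covariate": cov,
                    "level": lev,
                    "n": int(t[i].sum()),
                    "n_low": int(t[i, 0]),
                    "n_high": int(t[i, 1]),
                    "chi2": chi2,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
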