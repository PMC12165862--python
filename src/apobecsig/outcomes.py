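"""Survival comparisons for signature-defined groups.

Kaplan-Meier product-limit estimates, the log-rank test (two or more
groups) and Cox proportional-hazards models (Efron tie handling, optional
stratification by treatment covariates such as endocrine-therapy partner or
line) — thin wrappers over lifelines returning plain result objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMResult:
    """Kaplan-Meier estimate: step function and median survival."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # NaN when S never reaches 0.5

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMResult:
    """Product-limit survival estimate.

    The median is the earliest time at which the estimate drops to 0.5 or
    below; NaN when that never happens.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    med = kmf.median_survival_time_
    return KMResult(times=sf.index.to_numpy(dtype=float),
                    survival=sf.iloc[:, 0].to_numpy(dtype=float),
                    median=float("nan") if np.isinf(med) else float(med))


def logrank_test(times: Sequence[float], events: Sequence[int],
                 groups: Sequence) -> tuple[float, float]:
    """Log-rank chi-square statistic and p across two or more groups."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if len(set(g.tolist())) < 2:
        raise ValueError("need at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """One Cox coefficient: hazard ratio, CI, Wald p, convergence flag."""

    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    converged: bool = True


def cox_fit(data: pd.DataFrame, duration_col: str = "time_months",
            event_col: str = "event",
            covariates: Optional[Sequence[str]] = None,
            strata: Optional[Sequence[str]] = None) -> list[CoxResult]:
    """Cox proportional-hazards fit with Efron ties and optional strata.

    Stratification fits separate baseline hazards per stratum while sharing
    coefficients.  Non-convergence (including monotone likelihood from
    complete separation) is returned as a flagged result rather than raised.
    """
    covariates = list(covariates or
                      [c for c in data.columns
                       if c not in (duration_col, event_col, *(strata or []))])
    cols = [duration_col, event_col, *covariates, *(strata or [])]
    df = data[cols].copy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col,
                strata=list(strata) if strata else None)
    except (ConvergenceError, ValueError) as exc:
        return [CoxResult(covariate=c, hr=float("nan"), ci_low=float("nan"),
                          ci_high=float("nan"), p=float("nan"),
                          coef=float("nan"), se=float("nan"),
                          converged=False)
                for c in covariates]
    out = []
    summary = cph.summary
    for c in covariates:
        row = summary.loc[c]
        out.append(CoxResult(
            covariate=c, hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]), coef=float(row["coef"]),
            se=float(row["se(coef)"])))
    return out


def biopsy_window_filter(clinical: pd.DataFrame,
                         biopsy_to_treatment_days: str = "biopsy_to_treatment_days",
                         window_days: float = 30.0) -> pd.DataFrame:
    """Restrict to samples biopsied within a window of treatment start."""
    if biopsy_to_treatment_days not in clinical.columns:
        return clinical
    d = clinical[biopsy_to_treatment_days].abs()
    return clinical[d <= window_days]
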