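"""Score-stratified survival analysis.

Samples are split at the median HER2 metagene score into HER2-low /
HER2-high, follow-up is administratively right-censored at 20 years
(240 months), and the groups are compared by Kaplan-Meier curves with the
log-rank test and by Cox proportional-hazards models (univariate screen at
p < 0.1, then a multivariate fit; Efron tie handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

CENSOR_HORIZON_MONTHS = 240.0


@dataclass
class KmResult:
    curves: pd.DataFrame  # columns: group, time, survival
    logrank_p: float
    medians: dict[str, float]  # group -> median survival (nan if not reached)


@dataclass
class CoxResult:
    univariate: pd.DataFrame  # index term: hr, ci_low, ci_high, p
    multivariate: pd.DataFrame
    screened_terms: list[str]


def censor_at(time, event, horizon: float = CENSOR_HORIZON_MONTHS,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Administrative right-censoring: observations past ``horizon`` become
    censored at ``horizon``. Idempotent."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    over = t > horizon
    return np.where(over, horizon, t), np.where(over, 0, e)


def median_split(scores) -> np.ndarray:
    """Binary high/low labels at the median; ties at the median go low."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least two samples")
    return np.where(s > np.median(s), "high", "low")


def km_logrank(time, event, groups,
               horizon: float = CENSOR_HORIZON_MONTHS) -> KmResult:
    """Kaplan-Meier curves per group with the log-rank test.

    Median survival per group is the first time the product-limit estimate
    drops to <= 0.5 (NaN when never reached).
    """
    t, e = censor_at(time, event, horizon)
    g = np.asarray(groups)
    if e.sum() == 0:
        pass  # curves are still defined; log-rank is not informative
    uniq = np.unique(g)
    if any((g == u).sum() == 0 for u in uniq) or len(uniq) < 2:
        raise ValueError("need at least two non-empty groups")
    frames, medians = [], {}
    for u in uniq:
        kmf = KaplanMeierFitter()
        kmf.fit(t[g == u], e[g == u], label=str(u))
        sf = kmf.survival_function_
        frames.append(pd.DataFrame({
            "group": str(u),
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }))
        med = float(kmf.median_survival_time_)
        medians[str(u)] = med if np.isfinite(med) else float("nan")
    res = multivariate_logrank_test(t, g, e)
    return KmResult(curves=pd.concat(frames, ignore_index=True),
                    logrank_p=float(res.p_value), medians=medians)


def _encode(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """One-hot encode non-numeric covariates, dropping the first level."""
    parts = []
    for c in covariates:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(c))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def cox_model(df: pd.DataFrame, covariates: list[str],
              time_col: str = "time_months", event_col: str = "event",
              screen_p: float = 0.1,
              horizon: float = CENSOR_HORIZON_MONTHS) -> CoxResult:
    """Univariate Cox screen followed by a multivariate fit.

    Each covariate is first fitted alone; covariates with any term at
    p < ``screen_p`` enter the multivariate model. Hazard ratios are
    exp(coef) with 95% CIs; ties use the Efron approximation (lifelines
    default).
    """
    t, e = censor_at(df[time_col], df[event_col], horizon)
    if e.sum() == 0:
        raise ValueError("no events: Cox model undefined")

    def _fit(cov_list: list[str]) -> pd.DataFrame:
        x = _encode(df, cov_list)
        const = [c for c in x.columns if x[c].nunique() <= 1]
        if const:
            raise ValueError(f"constant covariate(s): {const}")
        data = x.copy()
        data["_time"], data["_event"] = t, e
        cph = CoxPHFitter()
        cph.fit(data, duration_col="_time", event_col="_event")
        s = cph.summary
        return pd.DataFrame({
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        })

    uni_frames = []
    screened = []
    for c in covariates:
        res = _fit([c])
        uni_frames.append(res)
        if (res["p"] < screen_p).any():
            screened.append(c)
    univariate = pd.concat(uni_frames)
    if not screened:
        raise ValueError(f"no covariate passed the p < {screen_p} screen")
    multivariate = _fit(screened)
    return CoxResult(univariate=univariate, multivariate=multivariate,
                     screened_terms=screened)
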