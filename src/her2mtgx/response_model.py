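"""Neoadjuvant-response modelling on metagene scores.

Logistic regression of pCR on the HER2/Basal/Luminal scores with study
strata entered as fixed-effect indicators (reference = largest stratum),
likelihood-ratio comparison of nested models, ROC analysis with the
Youden-J operating point, and responder triage: predicted individual pCR
probabilities are compared against the cohort-level Wald band — above the
upper bound is a "good" responder, below the lower bound "bad", inside
"regular" — with PPV/NPV computed from the observed outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clinical_stats import WaldInterval, wald_interval


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


@dataclass
class LogisticFit:
    terms: list[str]
    coefficients: pd.Series
    se: pd.Series
    odds_ratios: pd.DataFrame  # columns: or, ci_low, ci_high, p
    loglik: float
    n: int
    result: object = field(repr=False, default=None)

    def predict(self) -> np.ndarray:
        return np.asarray(self.result.predict())


@dataclass
class RocResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class ResponderSummary:
    interval: WaldInterval
    counts: dict[str, int]
    ppv: float | None
    npv: float | None
    regular_rate: float | None


def _design(scores: pd.DataFrame, strata: pd.Series | None) -> pd.DataFrame:
    x = scores.copy()
    x.columns = [str(c) for c in x.columns]
    if strata is not None:
        s = pd.Series(strata, index=scores.index).astype(str)
        levels = s.value_counts()
        ref = levels.index[0]  # largest stratum is the reference
        for lev in sorted(levels.index):
            if lev != ref:
                x[f"stratum[{lev}]"] = (s == lev).astype(float)
    return sm.add_constant(x, has_constant="add")


def fit_logistic(scores: pd.DataFrame, outcome,
                 strata: pd.Series | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on the scores.

    ``scores``: samples x score columns. Stratum indicators (if given) use
    the largest stratum as reference, so score odds ratios are adjusted for
    study membership. Raises :class:`SeparationError` on perfect separation
    and ValueError on a singular design.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two outcomes of each class")
    x = _design(scores, strata)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("singular design matrix")
    import warnings as _warnings
    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.filterwarnings(
                "error", message=".*[Pp]erfect separation.*")
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # error or promoted PerfectSeparationWarning
        if "separat" in str(exc).lower() or \
                "separat" in type(exc).__name__.lower():
            raise SeparationError(str(exc)) from exc
        raise
    if not np.all(np.isfinite(res.bse)):
        bad = [t for t, b in zip(x.columns, res.bse) if not np.isfinite(b)]
        raise SeparationError(f"non-finite standard error for term(s) {bad}")
    ci = res.conf_int()
    ors = pd.DataFrame({
        "or": np.exp(res.params),
        "ci_low": np.exp(ci[0]),
        "ci_high": np.exp(ci[1]),
        "p": res.pvalues,
    })
    return LogisticFit(terms=list(x.columns),
                       coefficients=res.params, se=res.bse,
                       odds_ratios=ors, loglik=float(res.llf),
                       n=len(y), result=res)


def compare_models(fit_reduced: LogisticFit, fit_full: LogisticFit) -> float:
    """Likelihood-ratio chi-squared test of nested logistic models."""
    if fit_reduced.n != fit_full.n:
        raise ValueError("models were fitted on different sample sizes")
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ValueError("models are not nested")
    df = len(fit_full.terms) - len(fit_reduced.terms)
    lr = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(lr, df))


def roc_analysis(probs, outcome) -> RocResult:
    """ROC over all observed probability thresholds.

    AUC by the trapezoidal rule; the operating point maximizes Youden's
    J = sensitivity + specificity - 1, ties broken toward the lower
    threshold.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcome, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    thresholds = np.unique(p)
    sens = np.array([(p[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(p[y == 0] < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # lowest threshold
    # trapezoidal AUC over the full (FPR, TPR) path
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(-np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, threshold=float(thresholds[best]),
                     sensitivity=float(sens[best]),
                     specificity=float(spec[best]),
                     youden_j=float(j[best]))


def classify_responders(probs, outcome=None, cohort_successes: int | None = None,
                        n: int | None = None, alpha: float = 0.01,
                        ) -> tuple[pd.DataFrame, ResponderSummary]:
    """Triage samples into good/regular/bad responders.

    The cohort pCR rate (``cohort_successes``/``n``, defaulting to the
    observed outcome) defines a Wald band at level ``alpha``; predicted
    probabilities strictly above the upper bound are "good", strictly below
    the lower bound "bad", boundary values "regular". PPV is the observed
    pCR rate among good responders, NPV the observed non-pCR rate among bad
    responders (None when a class is empty or outcomes are unavailable).
    """
    p = np.asarray(probs, dtype=float)
    y = None if outcome is None else np.asarray(outcome, dtype=int)
    if cohort_successes is None or n is None:
        if y is None:
            raise ValueError("need either outcome or explicit cohort counts")
        cohort_successes, n = int(y.sum()), len(y)
    interval = wald_interval(cohort_successes / n, n, alpha)
    if interval.degenerate:
        raise ValueError("degenerate Wald interval (rate 0 or 1)")
    cls = np.where(p > interval.upper, "good",
                   np.where(p < interval.lower, "bad", "regular"))
    idx = probs.index if isinstance(probs, pd.Series) else pd.RangeIndex(len(p))
    calls = pd.DataFrame({"probability": p, "responder_class": cls}, index=idx)
    counts = {c: int((cls == c).sum()) for c in ("good", "regular", "bad")}

    def _rate(mask, val):
        if y is None or mask.sum() == 0:
            return None
        return float((y[mask] == val).mean())

    summary = ResponderSummary(
        interval=interval, counts=counts,
        ppv=_rate(cls == "good", 1),
        npv=_rate(cls == "bad", 0),
        regular_rate=_rate(cls == "regular", 1),
    )
    return calls, summary


def compare_classifiers(calls_a, calls_b, truth,
                        restrict_to_responders: bool = True,
                        ) -> tuple[float, dict]:
    """Exact McNemar comparison of two binary classifiers on paired samples.

    By default the contrast is restricted to true responders (truth == 1),
    i.e. a paired test of sensitivity. Returns ``(p, info)`` with the
    discordant-pair counts; zero discordant pairs gives p = 1 with a flag.
    """
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    t = np.asarray(truth, dtype=int)
    if not (len(a) == len(b) == len(t)):
        raise ValueError("classifier calls and truth must be the same length")
    mask = (t == 1) if restrict_to_responders else np.ones(len(t), bool)
    n10 = int(((a == 1) & (b == 0) & mask).sum())
    n01 = int(((a == 0) & (b == 1) & mask).sum())
    info = {"n10": n10, "n01": n01, "no_discordant": n10 + n01 == 0}
    if n10 + n01 == 0:
        return 1.0, info
    p = stats.binomtest(n10, n10 + n01, 0.5).pvalue
    return float(min(1.0, p)), info
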