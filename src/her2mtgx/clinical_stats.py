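"""HER2 clinical reclassification and basic cohort statistics.

Implements the ASCO-CAP HER2 decision rule (IHC gate, ISH confirmation for
equivocal 2+ tumors), contingency-table association tests, and the Wald
normal-approximation confidence interval for a proportion, which downstream
defines the good/regular/bad responder bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

IHC_CATEGORIES = ("0", "1+", "2+", "3+")


@dataclass
class Her2Call:
    sample_id: str
    ihc: str
    ish_ratio: float | None
    ish_copies: float | None
    status: str  # positive | negative | indeterminate


@dataclass
class WaldInterval:
    p_hat: float
    n: int
    se: float
    z: float
    lower: float
    upper: float
    degenerate: bool = False


def classify_her2(ihc: str, ratio: float | None = None,
                  copies: float | None = None,
                  sample_id: str = "") -> Her2Call:
    """ASCO-CAP HER2 status from IHC and (for 2+) ISH.

    3+ -> positive; 0/1+ -> negative; 2+ -> positive iff
    (ratio >= 2.0 and copies >= 4.0) or (ratio < 2.0 and copies >= 6.0),
    negative otherwise, indeterminate when ISH is missing.
    """
    ihc = str(ihc).strip()
    if ihc not in IHC_CATEGORIES:
        raise ValueError(f"malformed IHC category {ihc!r}; "
                         f"expected one of {IHC_CATEGORIES}")

    def _num(v):
        if v is None:
            return None
        v = float(v)
        return None if np.isnan(v) else v

    ratio, copies = _num(ratio), _num(copies)
    if ihc == "3+":
        status = "positive"
    elif ihc in ("0", "1+"):
        status = "negative"
    else:  # 2+ needs ISH confirmation
        if ratio is None or copies is None:
            status = "indeterminate"
        elif (ratio >= 2.0 and copies >= 4.0) or (ratio < 2.0 and copies >= 6.0):
            status = "positive"
        else:
            status = "negative"
    return Her2Call(sample_id=sample_id, ihc=ihc, ish_ratio=ratio,
                    ish_copies=copies, status=status)


def reclassify_table(clinical: pd.DataFrame,
                     ihc_col: str = "ihc_score",
                     ratio_col: str = "ish_ratio",
                     copies_col: str = "ish_copies") -> pd.Series:
    """Vector version of :func:`classify_her2` over a clinical table."""
    return pd.Series(
        [classify_her2(row[ihc_col], row.get(ratio_col), row.get(copies_col),
                       sample_id=str(idx)).status
         for idx, row in clinical.iterrows()],
        index=clinical.index, name="her2_status")


def contingency_test(table, n_mc: int = 20000, seed: int = 0,
                     ) -> tuple[float, str]:
    """Association test for a two-way count table.

    Pearson chi-squared without continuity correction when every expected
    count is >= 5; otherwise Fisher's exact test (2x2) or a Monte-Carlo
    permutation version of the chi-squared test for larger sparse tables.
    Returns ``(p_value, test_tag)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero-margin row or column")
    expected = stats.contingency.expected_freq(t)
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(t, correction=False)
        return float(p), "chi2"
    if t.shape == (2, 2):
        _, p = stats.fisher_exact(t)
        return float(p), "fisher"
    # r x c with small expected counts: permutation null of the chi2 statistic
    rng = np.random.default_rng(seed)
    chi_obs = stats.chi2_contingency(t, correction=False)[0]
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0).astype(int))
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, perm), 1.0)
        if stats.chi2_contingency(sim, correction=False)[0] >= chi_obs - 1e-12:
            hits += 1
    return float((hits + 1) / (n_mc + 1)), "fisher-simulated"


def proportion_rate(successes: int, n: int) -> float:
    """Percentage rate 100*s/n, rounded to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    return round(100.0 * successes / n, 1)


def wald_interval(p_hat: float, n: int, alpha: float = 0.01) -> WaldInterval:
    """Wald interval p_hat +/- z_alpha * sqrt(p_hat(1-p_hat)/n).

    ``z_alpha`` is the one-tailed normal quantile Phi^-1(1-alpha)
    (~2.326 at alpha=0.01). Bounds are clipped to [0, 1]; a degenerate
    p_hat of exactly 0 or 1 is flagged.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    z = float(stats.norm.ppf(1.0 - alpha))
    degenerate = p_hat in (0.0, 1.0)
    return WaldInterval(
        p_hat=float(p_hat), n=int(n), se=se, z=z,
        lower=max(0.0, p_hat - z * se),
        upper=min(1.0, p_hat + z * se),
        degenerate=degenerate,
    )
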