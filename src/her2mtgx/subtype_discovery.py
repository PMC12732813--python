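"""Molecular-subtype discovery by hierarchical clustering.

Ward-linkage agglomerative clustering on Euclidean distances, with the
number of clusters chosen from the Calinski-Harabasz (CH) curve: local
maxima of CH(k) are candidate solutions and the candidate with the largest
Dunn index wins (ties go to the smaller k, for parsimony).

Also characterizes clusters against the 17q12 core-amplicon copy-number
signal: per-sample mean log2 ratio over the core genes, one-way ANOVA
across clusters, and a post hoc Dunn rank-sum test with Bonferroni
adjustment for the pairwise contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score

# 17q12 core-amplicon gene set: ERBB2 plus the co-amplified neighbours
# consistently elevated in the HER2-amplified cluster.  The upstream report
# of this region counts "nine genes besides ERBB2" yet prints thirteen
# symbols; the full printed list is carried here and can be overridden.
CORE_AMPLICON_GENES: tuple[str, ...] = (
    "ERBB2", "CDK12", "NEUROD2", "PPP1R1B", "STARD3", "TCAP", "PNMT",
    "PGAP3", "MIR4728", "MIEN1", "GRB7", "IKZF3", "ZPBP2", "GSDMB",
)


@dataclass
class ClusterSolution:
    """A hierarchical-clustering solution with its selection diagnostics."""

    k: int
    labels: pd.Series  # sample -> 1..k
    ch_values: dict[int, float]
    dunn_values: dict[int, float]
    linkage_method: str = "ward"

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "labels": {s: int(l) for s, l in self.labels.items()},
            "ch_values": {int(k): float(v) for k, v in self.ch_values.items()},
            "dunn_values": {int(k): float(v) for k, v in self.dunn_values.items()},
            "linkage_method": self.linkage_method,
        }


@dataclass
class AmpliconReport:
    """ANOVA + post hoc Dunn comparison of a score across clusters."""

    f_statistic: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p, p_adjusted
    group_means: dict = field(default_factory=dict)


def _sample_matrix(expr: pd.DataFrame) -> np.ndarray:
    # expression matrices are genes x samples; cluster the samples
    return np.asarray(expr.T, dtype=float)


def hierarchical_cluster(expr: pd.DataFrame, k: int,
                         method: str = "ward") -> pd.Series:
    """Cut the Ward dendrogram of the samples into ``k`` clusters.

    Returns labels in 1..k indexed by sample, renumbered in order of first
    appearance so the labelling is deterministic.
    """
    x = _sample_matrix(expr)
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} samples")
    z = linkage(x, method=method, metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    # renumber by first appearance for determinism
    seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return pd.Series(out, index=expr.columns, name="cluster")


def ch_curve(expr: pd.DataFrame, k_range: range | list[int],
             method: str = "ward") -> dict[int, float]:
    """Calinski-Harabasz index of the dendrogram cut at each candidate k.

    CH(k) = [B(k)/(k-1)] / [W(k)/(n-k)], between- over within-cluster
    dispersion normalized by degrees of freedom.
    """
    x = _sample_matrix(expr)
    n = x.shape[0]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate data: all samples identical")
    out: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k < n:
            raise ValueError(f"k={k} must satisfy 2 <= k < n_samples={n}")
        labels = hierarchical_cluster(expr, k, method=method)
        out[k] = float(calinski_harabasz_score(x, labels.to_numpy()))
    return out


def dunn_index(expr: pd.DataFrame, labels: pd.Series | np.ndarray) -> float:
    """Minimum inter-cluster distance over maximum intra-cluster diameter."""
    x = _sample_matrix(expr)
    lab = np.asarray(labels)
    if len(lab) != x.shape[0]:
        raise ValueError("labels length does not match number of samples")
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    d = squareform(pdist(x, metric="euclidean"))
    max_diam = 0.0
    for c in uniq:
        idx = np.flatnonzero(lab == c)
        if len(idx) > 1:
            max_diam = max(max_diam, d[np.ix_(idx, idx)].max())
    if max_diam == 0.0:
        raise ZeroDivisionError("all clusters are singletons or duplicates "
                                "(zero maximum diameter)")
    min_inter = np.inf
    for a, b in combinations(uniq, 2):
        ia, ib = np.flatnonzero(lab == a), np.flatnonzero(lab == b)
        min_inter = min(min_inter, d[np.ix_(ia, ib)].min())
    return float(min_inter / max_diam)


def _local_maxima(ch: dict[int, float]) -> list[int]:
    ks = sorted(ch)
    vals = [ch[k] for k in ks]
    cand = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or vals[i] >= vals[i - 1]
        right_ok = i == len(ks) - 1 or vals[i] >= vals[i + 1]
        if left_ok and right_ok:
            cand.append(k)
    return cand


def select_k(ch: dict[int, float], expr: pd.DataFrame,
             method: str = "ward") -> int:
    """Pick the cluster count: CH local maxima arbitrated by the Dunn index.

    Candidates are local maxima of the CH curve (endpoints included when
    maximal); among candidates the one with the largest Dunn index of its
    dendrogram cut wins; ties break toward smaller k.
    """
    if not ch:
        raise ValueError("empty CH curve")
    candidates = _local_maxima(ch)
    if len(candidates) == 1:
        return candidates[0]
    best_k, best_dunn = None, -np.inf
    for k in sorted(candidates):
        labels = hierarchical_cluster(expr, k, method=method)
        try:
            d = dunn_index(expr, labels)
        except ZeroDivisionError:
            d = -np.inf
        if d > best_dunn + 1e-12:
            best_k, best_dunn = k, d
    return int(best_k)


def cluster_solution(expr: pd.DataFrame, k_range: range | list[int],
                     method: str = "ward") -> ClusterSolution:
    """Full model selection: CH curve, Dunn arbitration, final labels."""
    ch = ch_curve(expr, k_range, method=method)
    dunn = {}
    for k in ch:
        labels = hierarchical_cluster(expr, k, method=method)
        try:
            dunn[k] = dunn_index(expr, labels)
        except ZeroDivisionError:
            dunn[k] = float("nan")
    k = select_k(ch, expr, method=method)
    return ClusterSolution(k=k, labels=hierarchical_cluster(expr, k, method),
                           ch_values=ch, dunn_values=dunn, linkage_method=method)


def amplicon_core_score(cnv: pd.DataFrame,
                        core_genes: list[str] | tuple[str, ...] = CORE_AMPLICON_GENES,
                        ) -> tuple[pd.Series, list[str]]:
    """Per-sample mean copy-number log2 ratio over the core-amplicon genes.

    Returns ``(scores, missing_genes)``; genes absent from the matrix are
    dropped with a warning and recorded in ``missing_genes``.
    """
    present = [g for g in core_genes if g in cnv.index]
    missing = [g for g in core_genes if g not in cnv.index]
    if not present:
        raise ValueError("none of the core amplicon genes are in the CNV matrix")
    if missing:
        warnings.warn(f"core amplicon genes missing from CNV matrix: {missing}")
    return cnv.loc[present].mean(axis=0), missing


def _dunn_posthoc(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Post hoc Dunn test: pairwise rank-sum z statistics on pooled ranks,
    tie-corrected, with Bonferroni adjustment."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    uniq = np.unique(labels)
    m = len(uniq) * (len(uniq) - 1) // 2
    rows = []
    for a, b in combinations(uniq, 2):
        ia, ib = labels == a, labels == b
        na, nb = ia.sum(), ib.sum()
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (ranks[ia].mean() - ranks[ib].mean()) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p,
                     "p_adjusted": min(1.0, p * m)})
    return pd.DataFrame(rows)


def compare_groups(values: pd.Series | np.ndarray,
                   labels: pd.Series | np.ndarray) -> AmpliconReport:
    """One-way ANOVA across clusters plus post hoc Dunn pairwise test."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise ValueError(f"groups with fewer than two values: {list(small)}")
    groups = [v[lab == g] for g in uniq]
    if np.ptp(v) == 0.0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
    return AmpliconReport(
        f_statistic=float(f_stat),
        anova_p=float(p),
        pairwise=_dunn_posthoc(v, lab),
        group_means={(g.item() if hasattr(g, "item") else g):
                     float(np.mean(v[lab == g])) for g in uniq},
    )
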