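"""Exclusive-module gene selection and metagene scoring.

The core of the package. Each gene is modelled by a one-way ANOVA across
the three molecular groups (HER2, Basal, Luminal) on log2(TPM + 1); the
group coefficients (group-mean deviations from the mean of group means,
sum-to-zero coding) are squashed through a bounded sigmoid

    g(beta) = 3 * tanh(beta / 3)        # odd, monotone, |g| < 3

and a gene joins module k only when its evidence is strong (FDR q < 0.01,
R^2 > 0.3), its clipped coefficient in k is high (> 2.7), and its clipped
coefficients in BOTH other groups are non-positive. Each module's metagene
score is the weighted mean of its genes' cohort-standardized expression,
with the clipped coefficients as weights; standardizing per cohort is what
lets the score transfer across expression platforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MODULES = ("HER2", "Basal", "Luminal")

DEFAULT_Q_MAX = 0.01
DEFAULT_R2_MIN = 0.3
DEFAULT_W_MIN = 2.7


@dataclass
class GeneModel:
    """Per-gene three-group ANOVA summary."""

    gene: str
    coefficients: dict[str, float]  # group -> beta (sum-to-zero)
    clipped: dict[str, float]       # group -> 3*tanh(beta/3)
    r2: float
    f_statistic: float
    pvalue: float
    qvalue: float | None = None


@dataclass
class SignatureModel:
    """Three exclusive gene modules with per-gene weights."""

    modules: dict[str, list[tuple[str, float]]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [set(g for g, _ in self.modules.get(m, [])) for m in MODULES]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"modules overlap: {sorted(overlap)}")

    def genes(self, module: str | None = None) -> list[str]:
        if module is not None:
            return [g for g, _ in self.modules[module]]
        return [g for m in MODULES for g, _ in self.modules.get(m, [])]

    def to_json(self) -> str:
        return json.dumps({
            "modules": {m: [[g, w] for g, w in v]
                        for m, v in self.modules.items()},
            "metadata": self.metadata,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        return cls(modules={m: [(g, float(w)) for g, w in v]
                            for m, v in d["modules"].items()},
                   metadata=d.get("metadata", {}))


@dataclass
class MetageneScores:
    """Per-sample HER2/Basal/Luminal scores and the argmax profile."""

    scores: pd.DataFrame  # samples x (HER2, Basal, Luminal)
    profile: pd.Series    # samples -> module name
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)


def clip_coefficient(beta: float | np.ndarray) -> float | np.ndarray:
    """Bounded sigmoid g(beta) = 3*tanh(beta/3), mapping R onto (-3, 3)."""
    return 3.0 * np.tanh(np.asarray(beta, dtype=float) / 3.0)


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _anova_arrays(x: np.ndarray, groups: np.ndarray,
                  group_order: tuple[str, ...] = MODULES):
    """Vectorized one-way ANOVA over the rows of ``x`` (genes x samples).

    Returns (betas [genes x 3], F, p, R2). Coefficients are group-mean
    deviations from the unweighted mean of the group means, so they sum to
    zero per gene regardless of group sizes.
    """
    n = x.shape[1]
    uniq = list(group_order)
    unknown = set(np.unique(groups)) - set(uniq)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    counts = np.array([(groups == g).sum() for g in uniq])
    if (counts < 2).any():
        bad = [g for g, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with fewer than two samples: {bad}")
    means = np.stack([x[:, groups == g].mean(axis=1) for g in uniq], axis=1)
    grand = x.mean(axis=1)
    ss_total = ((x - grand[:, None]) ** 2).sum(axis=1)
    ss_between = (counts[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = ss_total - ss_between
    df_b, df_w = len(uniq) - 1, n - len(uniq)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
        r2 = np.where(ss_total > 0, ss_between / ss_total, np.nan)
    f = np.where(ss_within == 0, np.inf, f)
    p = stats.f.sf(f, df_b, df_w)
    p = np.where(np.isinf(f), 0.0, p)
    betas = means - means.mean(axis=1, keepdims=True)
    return betas, f, p, r2, ss_total


def fit_gene_anova(expr_row: pd.Series | np.ndarray,
                   groups: pd.Series | np.ndarray,
                   gene: str = "") -> GeneModel:
    """One-way ANOVA of a single gene across the three molecular groups."""
    x = np.asarray(expr_row, dtype=float)[None, :]
    g = np.asarray(groups)
    betas, f, p, r2, ss_total = _anova_arrays(x, g)
    if ss_total[0] == 0:
        raise ValueError("zero total variance: R^2 undefined")
    name = gene or (expr_row.name if isinstance(expr_row, pd.Series) else "")
    coef = dict(zip(MODULES, betas[0]))
    return GeneModel(
        gene=str(name),
        coefficients={k: float(v) for k, v in coef.items()},
        clipped={k: float(clip_coefficient(v)) for k, v in coef.items()},
        r2=float(r2[0]),
        f_statistic=float(f[0]),
        pvalue=float(p[0]),
    )


def fit_all_genes(expr: pd.DataFrame, groups: pd.Series | np.ndarray,
                  ) -> list[GeneModel]:
    """Vectorized per-gene ANOVA over a genes x samples matrix.

    Genes with zero total variance are dropped (they carry no group signal
    and have undefined R^2).
    """
    g = np.asarray(groups.loc[expr.columns] if isinstance(groups, pd.Series)
                   else groups)
    x = expr.to_numpy(dtype=float)
    betas, f, p, r2, ss_total = _anova_arrays(x, g)
    models = []
    for i, gene in enumerate(expr.index):
        if ss_total[i] == 0:
            continue
        coef = dict(zip(MODULES, betas[i]))
        models.append(GeneModel(
            gene=str(gene),
            coefficients={k: float(v) for k, v in coef.items()},
            clipped={k: float(clip_coefficient(v)) for k, v in coef.items()},
            r2=float(r2[i]),
            f_statistic=float(f[i]),
            pvalue=float(p[i]),
        ))
    return models


def select_informative_genes(models: list[GeneModel],
                             q_max: float = DEFAULT_Q_MAX,
                             r2_min: float = DEFAULT_R2_MIN,
                             w_min: float = DEFAULT_W_MIN,
                             metadata: dict | None = None) -> SignatureModel:
    """Exclusive-module selection.

    A gene joins module k iff q < q_max, R^2 > r2_min, its clipped
    coefficient in k exceeds ``w_min`` and its clipped coefficients in the
    other two groups are <= 0; its weight is the clipped coefficient.
    Modules are sorted by weight, descending. Empty modules are allowed.
    """
    q = adjust_fdr([m.pvalue for m in models])
    for m, qv in zip(models, q):
        m.qvalue = float(qv)
    modules: dict[str, list[tuple[str, float]]] = {m: [] for m in MODULES}
    for m in models:
        if m.qvalue >= q_max or m.r2 <= r2_min:
            continue
        for k in MODULES:
            others = [j for j in MODULES if j != k]
            if m.clipped[k] > w_min and all(m.clipped[j] <= 0 for j in others):
                modules[k].append((m.gene, m.clipped[k]))
                break
    for k in MODULES:
        modules[k].sort(key=lambda gw: (-gw[1], gw[0]))
    meta = {"q_max": q_max, "r2_min": r2_min, "w_min": w_min,
            "n_genes_tested": len(models)}
    meta.update(metadata or {})
    return SignatureModel(modules=modules, metadata=meta)


def build_signature(tpm: pd.DataFrame, groups: pd.Series,
                    q_max: float = DEFAULT_Q_MAX,
                    r2_min: float = DEFAULT_R2_MIN,
                    w_min: float = DEFAULT_W_MIN) -> SignatureModel:
    """ANOVA on log2(TPM+1) for every gene, then exclusive-module selection."""
    models = fit_all_genes(np.log2(tpm + 1.0), groups)
    return select_informative_genes(models, q_max, r2_min, w_min)


def score_samples(expr: pd.DataFrame, sig: SignatureModel) -> MetageneScores:
    """Weighted-mean metagene scores on cohort-standardized expression.

    Per module: score = sum_g w_g * z_g / sum_g w_g, where z_g is the
    gene's expression standardized across the scored cohort. Module genes
    absent from ``expr`` (or constant across the cohort) are dropped with a
    warning; a module with no usable gene raises.
    Profile = argmax score, ties broken HER2 > Basal > Luminal.
    """
    dropped: dict[str, list[str]] = {}
    per_module = {}
    for mod in MODULES:
        entries = sig.modules.get(mod, [])
        usable, weights = [], []
        drop = []
        for gene, w in entries:
            if gene not in expr.index:
                drop.append(gene)
                continue
            row = expr.loc[gene].astype(float)
            sd = row.std(ddof=0)
            if sd == 0 or not np.isfinite(sd):
                drop.append(gene)
                continue
            usable.append((row - row.mean()) / sd)
            weights.append(w)
        if drop:
            dropped[mod] = drop
            warnings.warn(f"{mod} module: dropped unusable gene(s) {drop}")
        if not usable:
            raise ValueError(f"{mod} module has no usable gene in the matrix")
        z = pd.concat(usable, axis=1).to_numpy()
        w = np.asarray(weights, dtype=float)
        per_module[mod] = pd.Series(z @ w / w.sum(), index=expr.columns)
    scores = pd.DataFrame(per_module)[list(MODULES)]
    # argmax with tie priority HER2 > Basal > Luminal (column order)
    profile = pd.Series(
        [MODULES[int(np.argmax(r))] for r in scores.to_numpy()],
        index=scores.index, name="profile")
    return MetageneScores(scores=scores, profile=profile, dropped_genes=dropped)


def bundle_published_signature() -> SignatureModel:
    """The published 31-gene signature with unit weights.

    The trained per-gene coefficients are confidential, so this fixture
    carries the printed module memberships with every weight set to 1.0
    (making each score a plain mean of standardized expression). Note the
    printed Basal list places FOXA1 — a canonical luminal marker — in the
    Basal module; the membership is reproduced verbatim.
    """
    her2 = ["ERBB2", "PGAP3", "GRB7", "STARD3", "CREB3L1", "TMEM86A",
            "CBX2", "SOX11"]
    basal = ["FOXA1", "ROPN1", "SCRG1", "DSG1", "PRSS33", "GDF5", "CCKBR"]
    luminal = ["SLC39A6", "TFF1", "AGR3", "GFRA1", "ESR1", "SCUBE2", "RERG",
               "THSD4", "KIF12", "CCDC74A", "AFF3", "CLSTN2", "BCL2", "MAPT",
               "KCNK15", "WNK4"]
    return SignatureModel(
        modules={"HER2": [(g, 1.0) for g in her2],
                 "Basal": [(g, 1.0) for g in basal],
                 "Luminal": [(g, 1.0) for g in luminal]},
        metadata={"source": "published 31-gene assay", "weights": "unit"},
    )
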