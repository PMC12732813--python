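"""Expression normalization for clustering and gene selection.

Two routes out of the raw count matrix:

* TPM (transcripts per million) for per-gene ANOVA modelling, and
* a per-sample standardization + asymmetric winsorization transform for
  hierarchical clustering: log2(count+1) is z-scored within each sample,
  then extreme z-values are smoothly capped so that a handful of highly
  expressed genes cannot dominate the Euclidean sample distances.

The winsorization smoother used here is piecewise linear: identity between
``tau_low`` and ``tau_high`` and flat outside (defaults -2 / +2 on the
z-scale). It is monotone non-decreasing and idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import CountsMatrix

DEFAULT_TAU_LOW = -2.0
DEFAULT_TAU_HIGH = 2.0
DEFAULT_MIN_SPREAD = 0.2


def _as_frame(counts: CountsMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountsMatrix) else counts


def compute_tpm(counts: CountsMatrix | pd.DataFrame,
                gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts-per-million normalization.

    Per sample: rate_g = count_g / length_kb(g); TPM_g = 1e6 * rate_g / sum(rates).
    Every output column sums to 1e6.
    """
    mat = _as_frame(counts)
    if gene_lengths is None:
        if not isinstance(counts, CountsMatrix):
            raise ValueError("gene_lengths required when counts is a bare DataFrame")
        gene_lengths = counts.gene_annotation["length_bp"]
    missing = mat.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"no length for gene(s): {list(missing[:5])}")
    lengths = gene_lengths.loc[mat.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rate = mat.div(lengths / 1000.0, axis=0)
    col_sums = rate.sum(axis=0)
    if (col_sums == 0).any():
        bad = col_sums.index[col_sums == 0][0]
        raise ValueError(f"all-zero sample {bad!r}: TPM undefined")
    return rate.div(col_sums, axis=1) * 1e6


def sample_standardize(counts: CountsMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-sample z-scores of log2(count + 1).

    Each column of the result has mean 0 and SD 1 (ddof=0). A sample whose
    log-counts are constant has no defined z-score and raises.
    """
    mat = _as_frame(counts)
    logx = np.log2(mat.astype(float) + 1.0)
    sd = logx.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"constant sample {bad!r}: SD is zero")
    return (logx - logx.mean(axis=0)) / sd


def asymmetric_winsorize(z: pd.DataFrame,
                         tau_low: float = DEFAULT_TAU_LOW,
                         tau_high: float = DEFAULT_TAU_HIGH) -> pd.DataFrame:
    """Smoothly cap z-values outside [tau_low, tau_high].

    Identity in between, constant outside; monotone non-decreasing and
    idempotent. Asymmetric caps (|tau_low| != tau_high) shrink one tail
    harder than the other.
    """
    if not tau_low < tau_high:
        raise ValueError(f"tau_low={tau_low} must be < tau_high={tau_high}")
    return z.clip(lower=tau_low, upper=tau_high)


def transform_for_clustering(counts: CountsMatrix | pd.DataFrame,
                             tau_low: float = DEFAULT_TAU_LOW,
                             tau_high: float = DEFAULT_TAU_HIGH) -> pd.DataFrame:
    """Per-sample standardization followed by winsorization."""
    return asymmetric_winsorize(sample_standardize(counts), tau_low, tau_high)


def filter_genes(transformed: pd.DataFrame,
                 min_spread: float = DEFAULT_MIN_SPREAD) -> list[str]:
    """Keep genes whose across-sample spread (MAD) exceeds ``min_spread``.

    Returns the retained gene ids sorted lexicographically; may be empty.
    """
    med = transformed.median(axis=1)
    mad = (transformed.sub(med, axis=0)).abs().median(axis=1)
    return sorted(transformed.index[mad > min_spread])
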