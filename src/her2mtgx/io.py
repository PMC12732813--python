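"""File I/O: expression matrices (TSV / MatrixMarket), clinical tables,
gene annotation and YAML/JSON configuration.

MatrixMarket expression files use sidecar id lists: ``<stem>.mtx`` with
``<stem>.genes.txt`` and ``<stem>.samples.txt`` (one id per line).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .synthetic_data import CountsMatrix


def _check_matrix(df: pd.DataFrame, raw: bool) -> pd.DataFrame:
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicated gene id(s): {list(dup[:5])}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    if raw:
        vals = df.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("raw counts must be integers")
        df = df.round().astype(np.int64)
    return df


def read_expression(path: str | Path, fmt: str | None = None,
                    raw: bool = True) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV or MatrixMarket."""
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "mtx":
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        mat = spio.mmread(path)
        df = pd.DataFrame(np.asarray(mat.todense() if sparse.issparse(mat)
                                     else mat),
                          index=genes, columns=samples)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    df.index.name = "gene_id"
    return _check_matrix(df, raw)


def write_expression(df: pd.DataFrame, path: str | Path,
                     fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        df.to_csv(path, sep="\t")
    elif fmt == "mtx":
        stem = path.with_suffix("")
        spio.mmwrite(str(path), sparse.coo_matrix(df.to_numpy()))
        Path(f"{stem}.genes.txt").write_text("\n".join(map(str, df.index)) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(map(str, df.columns)) + "\n")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"gene_id", "length_bp"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    return ann.set_index("gene_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_counts_bundle(counts: CountsMatrix, out_dir: str | Path,
                        mtx: bool = False) -> dict[str, Path]:
    """Write counts (TSV and optionally MTX) plus gene annotation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"counts_tsv": out / "counts.tsv",
             "annotation": out / "gene_annotation.tsv"}
    write_expression(counts.counts, paths["counts_tsv"])
    counts.gene_annotation.to_csv(paths["annotation"], sep="\t")
    if mtx:
        paths["counts_mtx"] = out / "counts.mtx"
        write_expression(counts.counts, paths["counts_mtx"], fmt="mtx")
    return paths


def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
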