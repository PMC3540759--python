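"""Reading and writing the package's tab-separated file formats.

Input is a plain TSV expression matrix: header row of sample ids, first
column of gene ids, numeric body (genes x samples).  Processed GEO series
matrices export to this shape directly.  All output files begin with a
provenance comment line (``# lepnet <version> | config=<hash> | seed=...``)
so a run can be traced to its configuration; comment lines are skipped on
read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import ExpressionMatrix
from .evaluate import EvaluationResult
from .network import EdgeList, PartialCorrelationMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "write_adjacency_tsv",
    "read_adjacency_tsv",
    "write_edge_list_tsv",
    "write_degree_table_tsv",
    "write_metrics_tsv",
    "write_frequency_matrix_tsv",
    "provenance_header",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a resolved configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_header(config: dict | None = None, seed=None) -> str:
    h = config_hash(config or {})
    return f"# lepnet {__version__} | config={h} | seed={seed}"


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV expression matrix.

    First column holds gene ids, header row holds sample ids.  Rows with
    non-numeric entries and cells with missing values are rejected with
    their locations; duplicate gene ids are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 genes x 2 samples, got {df.shape}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene id(s): {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        rows = sorted({df.index.get_loc(i) + 2 for i in df.index[bad.any(axis=1)]})
        raise ValueError(
            f"{path}: non-numeric values in data rows (file line numbers "
            f"{rows[:10]}{'...' if len(rows) > 10 else ''})"
        )
    if numeric.isna().to_numpy().any():
        coords = [
            (str(numeric.index[i]), str(numeric.columns[j]))
            for i, j in zip(*np.where(numeric.isna().to_numpy()))
        ]
        raise ValueError(
            f"{path}: missing values at (gene, sample) "
            f"{coords[:10]}{'...' if len(coords) > 10 else ''}"
        )
    return ExpressionMatrix.from_dataframe(numeric)


def _write_with_header(df: pd.DataFrame, path, header: str, index_label=None, float_fmt="%.10g"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format=float_fmt)


def write_expression_tsv(X: ExpressionMatrix, path, config=None, seed=None) -> None:
    _write_with_header(
        X.to_dataframe(), path, provenance_header(config, seed), index_label="gene_id",
        float_fmt="%.12g",
    )


def write_adjacency_tsv(pcm: PartialCorrelationMatrix, path, config=None, seed=None) -> None:
    """Partial-correlation matrix as TSV with gene ids as header row/column."""
    df = pd.DataFrame(pcm.rho, index=pcm.gene_ids, columns=pcm.gene_ids)
    _write_with_header(df, path, provenance_header(config, seed), index_label="gene_id")


def read_adjacency_tsv(path) -> PartialCorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    rho = df.to_numpy(dtype=float)
    rho = (rho + rho.T) / 2.0  # tolerate decimal-rounding asymmetry
    np.fill_diagonal(rho, 1.0)
    return PartialCorrelationMatrix(rho, list(df.index))


def write_edge_list_tsv(edges: EdgeList, path, config=None, seed=None) -> None:
    """Edges as TSV (gene_a, gene_b, rho), sorted by |rho| descending."""
    df = pd.DataFrame(edges.edges, columns=["gene_a", "gene_b", "rho"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_degree_table_tsv(edges: EdgeList, gene_ids, path, config=None, seed=None) -> None:
    """Per-gene edge counts, in input gene order."""
    df = pd.DataFrame(
        {"gene_id": list(gene_ids), "n_edges": [edges.degree[g] for g in gene_ids]}
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_metrics_tsv(per_rep: pd.DataFrame, path, config=None, seed=None, scenario=None) -> None:
    """Per-repetition metrics table (scenario, family, rep, sensitivity, ppv, f1)."""
    df = per_rep.copy()
    if scenario is not None and "scenario" not in df.columns:
        df.insert(0, "scenario", scenario)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_frequency_matrix_tsv(freq: np.ndarray, gene_ids, path, config=None, seed=None) -> None:
    df = pd.DataFrame(np.asarray(freq), index=list(gene_ids), columns=list(gene_ids))
    _write_with_header(df, path, provenance_header(config, seed), index_label="gene_id",
                       float_fmt="%.4g")


def read_keep_genes(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if not out:
        raise ValueError(f"{path}: no gene ids found")
    return out
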