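"""Plain-text readers/writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .prep import CountMatrix, ExpressionMatrix, IdMap, NodeWeights

__all__ = [
    "read_counts", "read_node_list", "read_idmap",
    "write_weights", "read_weights", "read_r2_matrix",
    "read_snp_table", "read_bed", "read_phenotypes",
]


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Counts TSV (genes in column 1, samples in header) + metadata TSV
    (sample, condition, batch)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, meta=meta)


def read_node_list(path: str | Path) -> list[str]:
    """One node ID per line; blank lines and ``#`` comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_idmap(path: str | Path) -> IdMap:
    """Two-column TSV (source ID, target ID), header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping table needs two columns")
    src, tgt = df.columns[:2]
    return IdMap(pairs=dict(zip(df[src], df[tgt])))


def write_weights(w: NodeWeights, path: str | Path) -> None:
    df = pd.DataFrame({"node": sorted(w.weights),
                       "weight": [w.weights[k] for k in sorted(w.weights)]})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_weights(path: str | Path, condition: str) -> NodeWeights:
    df = pd.read_csv(path, sep="\t")
    return NodeWeights(condition=condition,
                       weights=dict(zip(df["node"], df["weight"])))


def read_snp_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open); first three columns used, name kept if present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = cols[:df.shape[1]]
    if "col3" in df.columns:
        df = df.rename(columns={"col3": "name"})
    return df


def read_r2_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(e: ExpressionMatrix, path: str | Path) -> None:
    e.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
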