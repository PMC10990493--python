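"""Expression preprocessing: from raw counts to per-condition node weights.

The pipeline is: filter low-count genes, compute median-of-ratios size
factors, apply a log2 variance-stabilizing transform, residualize batch
effects while protecting the condition contrast, map gene IDs one-to-one
onto network node IDs, and average per condition. A ``2^-ddCt`` helper for
relative qPCR expression lives here too.

All matrix operations work on a ``CountMatrix`` / ``ExpressionMatrix`` pair
of thin containers around pandas DataFrames (genes in rows, samples in
columns) plus a per-sample metadata table with ``condition`` and ``batch``
labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "NodeWeights",
    "IdMap",
    "filter_low_counts",
    "size_factors",
    "vst",
    "remove_batch",
    "map_ids",
    "condition_means",
    "ddct_relative_expression",
    "prepare_condition_weights",
]


def _check_meta(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dup}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dup}")
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    for col in ("condition", "batch"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample counts with sample metadata."""

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_meta(self.counts, self.meta)
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be nonnegative")
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        # align metadata rows to the column order of the matrix
        self.meta = self.meta.loc[self.counts.columns]

    @property
    def genes(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def conditions(self) -> pd.Series:
        return self.meta["condition"]

    @property
    def batches(self) -> pd.Series:
        return self.meta["batch"]


@dataclass
class ExpressionMatrix:
    """Real-valued (log scale) gene x sample matrix with sample metadata."""

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_meta(self.values, self.meta)
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        self.meta = self.meta.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class NodeWeights:
    """Per-node scalar weights for one condition (mean log expression)."""

    condition: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.weights.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite weights for: {bad}")

    def __getitem__(self, node: str) -> float:
        return self.weights[node]

    def __contains__(self, node: str) -> bool:
        return node in self.weights

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class IdMap:
    """Injective source -> target gene ID mapping (e.g. mouse -> human).

    A strict one-to-one correspondence between genes (and their protein
    products) is assumed; many-to-one maps are rejected rather than
    silently aggregated.
    """

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        targets: dict[str, str] = {}
        colliding = set()
        for src, tgt in self.pairs.items():
            if tgt in targets:
                colliding.add(tgt)
            targets[tgt] = src
        if colliding:
            raise ValueError(f"colliding targets: {sorted(colliding)}")


def filter_low_counts(m: CountMatrix, min_count: int = 5) -> CountMatrix:
    """Drop genes whose count falls below ``min_count`` in ANY sample.

    Keeps exactly the genes with count >= min_count in every sample; the
    literal reading of remove-if-low-anywhere filtering. Gene order is
    preserved. An empty result is allowed (with a warning).
    """
    keep = (m.counts >= min_count).all(axis=1)
    out = m.counts.loc[keep]
    n_dropped = len(m.counts) - len(out)
    logger.info("filter_low_counts: dropped %d/%d genes (min_count=%d)",
                n_dropped, len(m.counts), min_count)
    if out.empty and len(m.counts):
        warnings.warn("all genes removed by low-count filter", stacklevel=2)
    return CountMatrix(counts=out.copy(), meta=m.meta.copy())


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one positive factor per sample.

    For each gene with all-positive counts (the reference set) compute the
    geometric mean across samples; the factor of sample j is the median
    over reference genes of count_gj / geomean_g.
    """
    counts = m.counts.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no reference genes: every gene has a zero count "
                         "in some sample")
    log_counts = np.log(counts[ref])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    ratios = np.exp(log_counts - log_geomean)
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("nonpositive size factor computed")
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def vst(m: CountMatrix, factors: pd.Series | np.ndarray,
        pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount) variance-stabilizing transform.

    A simple monotone stand-in for shrinkage-based regularized-log
    transforms; downstream use is only mean-based path scoring, which
    depends on the transformed scale, not on shrinkage details.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (m.counts.shape[1],):
        raise ValueError("factors length must equal the number of samples")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = np.log2(m.counts.to_numpy(dtype=float) / factors + pseudocount)
    df = pd.DataFrame(values, index=m.counts.index, columns=m.counts.columns)
    return ExpressionMatrix(values=df, meta=m.meta.copy())


def _design(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicator columns, first level dropped."""
    levels = sorted(pd.unique(labels))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((labels == lev).to_numpy(dtype=float))
        names.append(str(lev))
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(labels), 0)), names


def remove_batch(e: ExpressionMatrix,
                 condition_labels: pd.Series | None = None,
                 batch_labels: pd.Series | None = None) -> ExpressionMatrix:
    """Subtract the batch component of a per-gene OLS fit.

    Per gene, fit value ~ intercept + condition indicators + batch
    indicators by least squares and subtract only the fitted batch part,
    leaving condition-associated signal untouched (the residualization
    contract of limma-style batch removal with protected covariates).
    With a single batch this is the identity. A batch perfectly confounded
    with condition makes the design rank-deficient and raises.
    """
    cond = e.meta["condition"] if condition_labels is None else pd.Series(
        condition_labels, index=e.values.columns)
    batch = e.meta["batch"] if batch_labels is None else pd.Series(
        batch_labels, index=e.values.columns)
    X_cond, _ = _design(cond)
    X_batch, batch_names = _design(batch)
    if X_batch.shape[1] == 0:
        return ExpressionMatrix(values=e.values.copy(), meta=e.meta.copy())
    n = len(e.values.columns)
    X = np.column_stack([np.ones(n), X_cond, X_batch])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "confounded design: batch indicators "
            f"{batch_names} are collinear with intercept/condition columns")
    Y = e.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_part = X[:, -X_batch.shape[1]:] @ beta[-X_batch.shape[1]:]
    corrected = (Y - batch_part).T
    df = pd.DataFrame(corrected, index=e.values.index, columns=e.values.columns)
    return ExpressionMatrix(values=df, meta=e.meta.copy())


def map_ids(e: ExpressionMatrix, idmap: IdMap,
            on_unmapped: str = "drop") -> ExpressionMatrix:
    """Rename gene IDs through an injective map.

    Unmapped genes are dropped (default) or raise with ``on_unmapped=
    'error'``. Injectivity of the map guarantees no duplicate output IDs.
    """
    if on_unmapped not in ("drop", "error"):
        raise ValueError("on_unmapped must be 'drop' or 'error'")
    mapped = [g for g in e.values.index if g in idmap.pairs]
    unmapped = [g for g in e.values.index if g not in idmap.pairs]
    if unmapped and on_unmapped == "error":
        raise ValueError(f"unmapped gene IDs: {unmapped[:10]}"
                         + ("..." if len(unmapped) > 10 else ""))
    if unmapped:
        logger.info("map_ids: dropping %d unmapped genes", len(unmapped))
    if not mapped:
        warnings.warn("no genes could be mapped; result is empty",
                      stacklevel=2)
    out = e.values.loc[mapped].rename(index=idmap.pairs)
    return ExpressionMatrix(values=out, meta=e.meta.copy())


def condition_means(e: ExpressionMatrix,
                    condition_labels: pd.Series | None = None,
                    condition: str = "") -> NodeWeights:
    """Arithmetic per-gene mean over the samples of one condition."""
    cond = e.meta["condition"] if condition_labels is None else pd.Series(
        condition_labels, index=e.values.columns)
    mask = (cond == condition).to_numpy()
    if not mask.any():
        raise ValueError(f"unknown condition {condition!r}; "
                         f"available: {sorted(pd.unique(cond))}")
    means = e.values.loc[:, e.values.columns[mask]].mean(axis=1)
    return NodeWeights(condition=condition, weights=means.to_dict())


def ddct_relative_expression(ct_target_sample: float,
                             ct_housekeeping_sample: float,
                             ct_target_ref: float,
                             ct_housekeeping_ref: float) -> float:
    """Relative expression by the 2^-ddCt method.

    Normalizes the target gene's Ct to a housekeeping gene (e.g. ribosomal
    L32) in both the sample and the reference condition, and returns the
    fold change 2 ** -((Ct_t,s - Ct_h,s) - (Ct_t,r - Ct_h,r)).
    """
    for v in (ct_target_sample, ct_housekeeping_sample,
              ct_target_ref, ct_housekeeping_ref):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = ((ct_target_sample - ct_housekeeping_sample)
            - (ct_target_ref - ct_housekeeping_ref))
    return float(2.0 ** (-ddct))


def prepare_condition_weights(m: CountMatrix, *, min_count: int = 5,
                              pseudocount: float = 1.0,
                              idmap: IdMap | None = None,
                              ) -> dict[str, NodeWeights]:
    """Full preprocessing chain: filter, normalize, VST, de-batch, map, average.

    Returns one ``NodeWeights`` per condition present in the metadata.
    """
    filtered = filter_low_counts(m, min_count=min_count)
    factors = size_factors(filtered)
    expr = vst(filtered, factors, pseudocount=pseudocount)
    if expr.meta["batch"].nunique() > 1:
        expr = remove_batch(expr)
    if idmap is not None:
        expr = map_ids(expr, idmap)
    return {c: condition_means(expr, condition=c)
            for c in sorted(pd.unique(expr.meta["condition"]))}
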