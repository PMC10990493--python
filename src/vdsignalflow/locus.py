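"""Locus-side statistics: GWAS-catalog filtering, binding-site overlap,
LD-block clustering, and the gene-by-vitamin-D interaction logistic model.

Conventions: SNP positions are 1-based (VCF style); interval tracks are
0-based half-open (BED style). A SNP at 1-based position p therefore
overlaps [start, end) iff start <= p-1 < end. LD blocks are single-linkage
clusters at an r-squared threshold (default 0.8, the usual convention for
"high LD"). Vitamin D levels in ng/ml are binarized at 30 ng/ml, with the
boundary assigned to sufficiency (>= 30 -> 1).

The interaction model is a logistic regression of disease status (e.g.
asthma) on IKZF1 and IKZF3 expression, their product, the IKZF3 x
vitamin-D interaction, and adjustment covariates; it is fit by
Newton-Raphson IRLS with Wald inference from the inverse observed
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "GlmFit",
    "PerfectSeparationError",
    "filter_significant",
    "overlap_counts",
    "ld_blocks",
    "binarize_vitd",
    "interaction_logistic",
    "build_interaction_design",
]

SNP_COLUMNS = ["id", "chrom", "pos", "pvalue", "trait"]
INTERVAL_COLUMNS = ["chrom", "start", "end"]


class PerfectSeparationError(RuntimeError):
    """Raised when a predictor perfectly separates the binary outcome."""


def validate_snp_table(t: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("id", "chrom", "pos", "pvalue") if c not in t.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    if t["id"].duplicated().any():
        raise ValueError("SNP table has duplicate IDs")
    if (t["pos"] <= 0).any():
        raise ValueError("SNP positions must be positive (1-based)")
    p = t["pvalue"]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return t


def filter_significant(t: pd.DataFrame, alpha: float = 1e-5) -> pd.DataFrame:
    """Rows with association p-value strictly below ``alpha``, order kept."""
    validate_snp_table(t)
    return t.loc[t["pvalue"] < alpha].copy()


def _point_in(regions: pd.DataFrame, chrom: str, pos_1based: int) -> pd.Series:
    """Boolean mask over region rows containing the point."""
    idx = pos_1based - 1  # 0-based index of the base
    return ((regions["chrom"] == chrom)
            & (regions["start"] <= idx) & (idx < regions["end"]))


def overlap_counts(query: pd.DataFrame, regions: pd.DataFrame,
                   ) -> tuple[pd.Series, int]:
    """Count query records overlapping each region.

    ``query`` is either a SNP table (point queries at 1-based ``pos``) or
    an interval track (half-open ``start``/``end``); ``regions`` is an
    interval track. Returns (per-region counts aligned to ``regions``'
    index, number of distinct query records overlapping any region).
    """
    for c in INTERVAL_COLUMNS:
        if c not in regions.columns:
            raise ValueError(f"regions track missing column {c!r}")
    if (regions["start"] >= regions["end"]).any():
        raise ValueError("regions must satisfy start < end (half-open)")
    is_points = "pos" in query.columns
    if not is_points:
        for c in INTERVAL_COLUMNS:
            if c not in query.columns:
                raise ValueError("query must have either 'pos' or "
                                 "'start'/'end' columns")
    if set(query["chrom"]).isdisjoint(set(regions["chrom"])):
        logger.warning("overlap_counts: query and regions share no "
                       "chromosome names; zero overlap is guaranteed")
    counts = pd.Series(0, index=regions.index, dtype=int)
    hit_any = pd.Series(False, index=query.index)
    for ridx, region in regions.iterrows():
        if is_points:
            mask = ((query["chrom"] == region["chrom"])
                    & (region["start"] <= query["pos"] - 1)
                    & (query["pos"] - 1 < region["end"]))
        else:
            mask = ((query["chrom"] == region["chrom"])
                    & (query["start"] < region["end"])
                    & (region["start"] < query["end"]))
        counts.loc[ridx] = int(mask.sum())
        hit_any |= mask
    return counts, int(hit_any.sum())


def ld_blocks(r2: pd.DataFrame, threshold: float = 0.8,
              atol: float = 1e-12) -> list[set[str]]:
    """Single-linkage LD blocks: chain-connected sets at r^2 >= threshold.

    The input is a symmetric r-squared matrix with SNP IDs as both index
    and columns and a unit diagonal. Two SNPs share a block iff they are
    connected by a chain of pairs each with r^2 >= threshold; SNPs linked
    to nothing form singleton blocks. Blocks are returned sorted by their
    smallest member.
    """
    ids = list(r2.index)
    if list(r2.columns) != ids:
        raise ValueError("r2 matrix index and columns must match")
    m = r2.to_numpy(dtype=float)
    if m.size and np.abs(m - m.T).max() > atol:
        raise ValueError("r2 matrix is asymmetric beyond tolerance")
    if m.size and ((m < 0).any() or (m > 1 + atol).any()):
        raise ValueError("r2 values must lie in [0, 1]")
    # union-find over thresholded pairs
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if m[i, j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    blocks: dict[int, set[str]] = {}
    for i, snp in enumerate(ids):
        blocks.setdefault(find(i), set()).add(snp)
    return sorted(blocks.values(), key=min)


def binarize_vitd(values: np.ndarray | pd.Series | list[float],
                  threshold: float = 30.0) -> np.ndarray:
    """1 iff 25-hydroxyvitamin D (ng/ml) is at or above the threshold.

    30 ng/ml is the clinical sufficiency cutoff; the boundary value counts
    as sufficient.
    """
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("vitamin D values must be finite")
    return (arr >= threshold).astype(int)


@dataclass
class GlmFit:
    """Logistic-regression fit: estimates, Wald inference, convergence."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    converged: bool
    n_iter: int
    loglike: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "std_err": self.bse,
                             "z": self.zvalues, "p": self.pvalues},
                            index=self.names)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that add no rank (QR with column pivoting via numpy)."""
    rank = np.linalg.matrix_rank(X)
    aliased: list[str] = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            aliased.append(names[j])
        if len(kept) == rank:
            aliased.extend(names[j + 1:])
            break
    return aliased


def interaction_logistic(y: np.ndarray | pd.Series,
                         X: pd.DataFrame,
                         add_intercept: bool = True,
                         max_iter: int = 100,
                         score_tol: float = 1e-8,
                         ll_rtol: float = 1e-10) -> GlmFit:
    """Fit a logistic regression by Newton-Raphson IRLS.

    ``y`` is a 0/1 outcome; ``X`` holds the design columns (expression
    main effects, interaction products, covariate dummies — use
    ``build_interaction_design`` for the canonical asthma model).
    Convergence is declared when the maximum absolute score drops below
    ``score_tol`` or the relative log-likelihood change below ``ll_rtol``.
    Standard errors come from the inverse observed information; p-values
    are two-sided Wald. Rank-deficient designs raise listing the aliased
    columns; perfect separation raises naming the runaway predictor.
    """
    yv = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    if add_intercept:
        Xm = np.column_stack([np.ones(len(yv)), Xm])
        names = ["intercept"] + names
    if len(yv) != Xm.shape[0]:
        raise ValueError("outcome and design have different lengths")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("rank-deficient design; aliased columns: "
                         f"{_aliased_columns(Xm, names)}")

    beta = np.zeros(Xm.shape[1])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        p = expit(eta)
        # log-likelihood via log1p for numerical stability
        ll = float(yv @ eta - np.logaddexp(0.0, eta).sum())
        score = Xm.T @ (yv - p)
        w = p * (1.0 - p)
        if np.max(w) < 1e-10 or np.max(np.abs(beta)) > 30.0:
            j = int(np.argmax(np.abs(beta)))
            raise PerfectSeparationError(
                f"perfect separation detected; predictor {names[j]!r} "
                "drives fitted probabilities to 0/1")
        info = (Xm * w[:, None]).T @ Xm
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        if np.isfinite(ll_old) and abs(ll - ll_old) <= ll_rtol * (abs(ll_old) + 1e-300):
            converged = True
            break
        ll_old = ll
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise PerfectSeparationError(
                "singular information matrix during IRLS (quasi-complete "
                f"separation): {exc}") from exc
        beta = beta + step
    eta = Xm @ beta
    p = expit(eta)
    ll = float(yv @ eta - np.logaddexp(0.0, eta).sum())
    info = (Xm * (p * (1 - p))[:, None]).T @ Xm
    cov = np.linalg.inv(info)
    bse = np.sqrt(np.diag(cov))
    z = beta / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    if not converged:
        logger.warning("interaction_logistic: IRLS did not converge in %d "
                       "iterations", max_iter)
    return GlmFit(names=names, params=beta, bse=bse, zvalues=z, pvalues=pvals,
                  converged=converged, n_iter=it, loglike=ll)


def build_interaction_design(pheno: pd.DataFrame,
                             vitd_threshold: float = 30.0,
                             covariates: list[str] | None = None,
                             ) -> tuple[np.ndarray, pd.DataFrame]:
    """Design for: outcome ~ IKZF1 + IKZF3 + vitD + IKZF1:IKZF3 + IKZF3:vitD
    (+ covariates), with vitamin D binarized at ``vitd_threshold`` ng/ml.

    ``pheno`` needs columns ``outcome``, ``IKZF1``, ``IKZF3`` and
    ``vitd_ngml``; categorical covariates are dummy-coded dropping the
    first level. Returns (outcome vector, design DataFrame without
    intercept).
    """
    required = ["outcome", "IKZF1", "IKZF3", "vitd_ngml"]
    missing = [c for c in required if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    vitd = binarize_vitd(pheno["vitd_ngml"], threshold=vitd_threshold)
    design = pd.DataFrame({
        "IKZF1": pheno["IKZF1"].to_numpy(dtype=float),
        "IKZF3": pheno["IKZF3"].to_numpy(dtype=float),
        "vitd": vitd.astype(float),
    }, index=pheno.index)
    design["IKZF1:IKZF3"] = design["IKZF1"] * design["IKZF3"]
    design["IKZF3:vitd"] = design["IKZF3"] * design["vitd"]
    for cov in covariates or []:
        if cov not in pheno.columns:
            raise ValueError(f"covariate {cov!r} not in phenotype table")
        col = pheno[cov]
        if col.dtype.kind in "ifb" and col.nunique() <= 2:
            design[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov,
                                     drop_first=True)
            for dcol in dummies.columns:
                design[dcol] = dummies[dcol].astype(float)
    return np.asarray(pheno["outcome"], dtype=float), design
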