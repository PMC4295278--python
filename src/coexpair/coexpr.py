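"""Per-class coexpression: correlations, p-values, and the base network.

For each class, every gene pair's Pearson r (or Spearman rho) is computed
on that class's samples. The significance of a single correlation is the
two-sided tail probability of t = r*sqrt((n-2)/(1-r^2)) under Student's t
with n-2 degrees of freedom. Pairs with |r| strictly above the base
threshold (0.6 by default) form the class's base coexpression network.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedCorrelationError
from .ingest import ClassMap, ExpressionMatrix

logger = logging.getLogger(__name__)

#: Default |r| cutoff for constructing the base coexpression network
#: (strict inequality: a pair with |r| exactly at the cutoff is excluded).
BASE_R = 0.6

#: Correlations are clamped to +/-(1 - R_CLAMP_EPS) before the t statistic
#: and the Fisher z-transform; at any realistic sample size this changes
#: no threshold or significance decision, it only avoids division by zero
#: for numerically perfect correlations.
R_CLAMP_EPS = 1e-12

EDGE_COLUMNS = ["gene_a", "gene_b", "r", "n", "t", "p"]


@dataclass(frozen=True)
class CorrelationRecord:
    """One gene pair's correlation in one class (canonical order gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    class_label: str
    r: float
    n: int
    t: float
    p: float
    method: str = "pearson"

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise ValueError("pair must be in canonical order gene_a < gene_b")


@dataclass
class CoexpressionNetwork:
    """Edges (a pair table) surviving the active |r| threshold in one class.

    ``edges`` has columns gene_a, gene_b, r, n, t, p with gene_a < gene_b
    and rows sorted by (gene_a, gene_b). ``skipped_genes`` lists rows with
    zero variance within the class, whose pairs are undefined.
    """

    edges: pd.DataFrame
    threshold: float
    class_label: str
    method: str
    n: int
    skipped_genes: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        if self.edges.empty:
            return set()
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def __len__(self) -> int:
        return len(self.edges)


def clamp_r(r):
    """Clamp correlations into the open interval (-1, 1)."""
    return np.clip(r, -1.0 + R_CLAMP_EPS, 1.0 - R_CLAMP_EPS)


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    return float(stats.spearmanr(x, y).statistic)


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise InputError("correlation requires at least 4 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in an input vector")


def correlation_pvalue(r: float, n: int):
    """t statistic and two-sided p-value for a single correlation.

    t = r*sqrt(d/(1-r^2)) with d = n-2 degrees of freedom; p is the
    two-sided tail probability under Student's t. p decreases
    monotonically in |r| at fixed n.
    """
    if n < 4:
        raise InputError("correlation p-value requires n >= 4")
    r = float(clamp_r(r))
    d = n - 2
    t = r * math.sqrt(d / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), d)
    return t, p


def correlation_pvalues(r: np.ndarray, n: int):
    """Vectorised ``correlation_pvalue``."""
    if n < 4:
        raise InputError("correlation p-value requires n >= 4")
    r = clamp_r(np.asarray(r, dtype=float))
    d = n - 2
    t = r * np.sqrt(d / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), d)
    return t, p


def pairwise_correlation(
    values: np.ndarray, method: str = "pearson", n_workers: int = 1
) -> np.ndarray:
    """All-pairs correlation matrix over rows of ``values``.

    Rows are standardised and the Gram matrix computed in fixed row blocks,
    optionally across a thread pool. The block decomposition is identical
    for any worker count, so the result does not depend on ``n_workers``.

    Rows with zero variance yield NaN against every other row.
    """
    if method not in ("pearson", "spearman"):
        raise InputError(f"method must be 'pearson' or 'spearman', got {method!r}")
    values = np.asarray(values, dtype=float)
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    scale = np.where(constant, np.nan, norms)
    z = centered / scale[:, None]
    m = z.shape[0]
    block = 256
    starts = list(range(0, m, block))
    out = np.empty((m, m), dtype=float)

    def fill(start: int) -> None:
        stop = min(start + block, m)
        out[start:stop] = z[start:stop] @ z.T

    if n_workers > 1 and len(starts) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            list(pool.map(fill, starts))
    else:
        for start in starts:
            fill(start)
    np.clip(out, -1.0, 1.0, out=out)
    np.fill_diagonal(out, 1.0)
    out[constant, :] = np.nan
    out[:, constant] = np.nan
    return out


def build_base_network(
    expr: ExpressionMatrix,
    cls: ClassMap,
    class_label: str,
    method: str = "pearson",
    base_r: float = BASE_R,
    n_workers: int = 1,
) -> CoexpressionNetwork:
    """Base coexpression network of one class: all pairs with |r| > base_r.

    Genes with zero variance within the class are skipped (their
    correlations are undefined) and recorded on the returned network.
    Edges are canonical (gene_a < gene_b) and sorted, so the result is
    independent of gene input order.
    """
    samples = cls.samples(class_label)
    n = len(samples)
    sub = expr.data[samples]
    values = sub.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    skipped = [g for g, c in zip(sub.index, constant) if c]
    if skipped:
        logger.info(
            "class %s: %d zero-variance genes skipped: %s",
            class_label, len(skipped), skipped[:10],
        )
    keep_ids = np.asarray(sub.index)[~constant]
    corr = pairwise_correlation(values[~constant], method=method, n_workers=n_workers)
    iu, ju = np.triu_indices(len(keep_ids), k=1)
    r = corr[iu, ju]
    mask = np.abs(r) > base_r
    r = r[mask]
    ga = keep_ids[iu[mask]].astype(str)
    gb = keep_ids[ju[mask]].astype(str)
    swap = ga > gb
    ga[swap], gb[swap] = gb[swap], ga[swap].copy()
    t, p = correlation_pvalues(r, n) if len(r) else (np.array([]), np.array([]))
    edges = pd.DataFrame(
        {"gene_a": ga, "gene_b": gb, "r": r, "n": n, "t": t, "p": p}
    ).sort_values(["gene_a", "gene_b"], kind="mergesort", ignore_index=True)
    if edges.empty:
        logger.warning("class %s: no edges survive |r| > %g", class_label, base_r)
    return CoexpressionNetwork(
        edges=edges,
        threshold=base_r,
        class_label=class_label,
        method=method,
        n=n,
        skipped_genes=skipped,
    )


class CorrelationLookup:
    """(r, n) lookup for ANY gene pair in one class.

    Backed by the full correlation matrix; returns None for pairs
    involving a zero-variance (skipped) gene.
    """

    def __init__(self, gene_ids, corr: np.ndarray, n: int):
        self._index = {g: i for i, g in enumerate(gene_ids)}
        self._corr = corr
        self.n = n

    def get(self, gene_a: str, gene_b: str):
        i = self._index.get(gene_a)
        j = self._index.get(gene_b)
        if i is None or j is None:
            return None
        r = self._corr[i, j]
        if np.isnan(r):
            return None
        return float(r)


def class_correlation_lookup(
    expr: ExpressionMatrix,
    cls: ClassMap,
    class_label: str,
    method: str = "pearson",
    n_workers: int = 1,
) -> CorrelationLookup:
    """Full correlation lookup for one class (used by pair classification)."""
    samples = cls.samples(class_label)
    values = expr.data[samples].to_numpy(dtype=float)
    corr = pairwise_correlation(values, method=method, n_workers=n_workers)
    return CorrelationLookup(expr.row_ids, corr, len(samples))
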