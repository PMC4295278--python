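"""Network-density threshold scan and pair filtering.

Scanning |r| cutoffs over a grid, the density of the network retained at
each cutoff is D = 2E / (K(K-1)), with E the number of surviving edges
and K the number of non-singleton nodes (degree >= 1). The biologically
significant cutoff r_bs is the grid value at which D is minimal: raising
the cutoff past r_bs prunes weak, likely spurious edges faster than it
prunes nodes, so the density minimum separates the noise-dominated from
the structure-dominated regime. Pairs are then filtered to |r| > r_bs,
and optionally to the top fraction ranked by correlation p-value.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: Threshold scan grid: 0.60 to 0.99 inclusive, step 0.01.
DEFAULT_GRID = np.round(0.60 + 0.01 * np.arange(40), 2)

#: Allowed top-fraction levels for the p-value filter (1.0 keeps all).
TOP_FRACTIONS = (0.01, 0.05, 0.10, 0.50, 1.0)


@dataclass
class DensityProfile:
    """Per-threshold (E, K, D) curve.

    ``table`` has columns threshold, E, K, D; D is NaN where fewer than
    two non-singleton nodes remain. ``r_bs`` is filled by ``select_rbs``.
    """

    table: pd.DataFrame
    r_bs: float | None = None

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold"].to_numpy()


def density_profile(edges: pd.DataFrame, grid=DEFAULT_GRID) -> DensityProfile:
    """Compute E, K and D = 2E/(K(K-1)) at each threshold of ``grid``.

    E counts edges with |r| strictly above the threshold; K counts nodes
    incident to at least one surviving edge. Both are non-increasing in
    the threshold. D is undefined (NaN) when K < 2.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise InputError("threshold grid must be non-empty and strictly ascending")
    if edges.empty:
        warnings.warn("empty edge set: density profile has no defined D", stacklevel=2)
    rows = []
    abs_r = edges["r"].abs().to_numpy() if len(edges) else np.array([])
    for tau in grid:
        mask = abs_r > tau
        e = int(mask.sum())
        if e:
            sub = edges.loc[mask]
            k = len(set(sub["gene_a"]) | set(sub["gene_b"]))
        else:
            k = 0
        d = 2.0 * e / (k * (k - 1)) if k >= 2 else np.nan
        rows.append((tau, e, k, d))
    table = pd.DataFrame(rows, columns=["threshold", "E", "K", "D"])
    return DensityProfile(table)


def select_rbs(profile: DensityProfile) -> float:
    """Threshold attaining the minimum defined density (ties: smallest)."""
    d = profile.table["D"].to_numpy()
    defined = ~np.isnan(d)
    if not defined.any():
        raise InputError("no non-singleton network at any threshold")
    idx = int(np.nanargmin(d))  # first minimum -> smallest threshold on ties
    r_bs = float(profile.table["threshold"].iloc[idx])
    profile.r_bs = r_bs
    logger.info("selected r_bs = %.2f (D = %.4g)", r_bs, d[idx])
    return r_bs


def filter_by_rbs(edges: pd.DataFrame, r_bs: float) -> pd.DataFrame:
    """Keep pairs with |r| strictly above r_bs."""
    return edges.loc[edges["r"].abs() > r_bs].reset_index(drop=True)


def filter_top_fraction(edges: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Keep the ceil(fraction * #pairs) most significant pairs.

    Ranked by ascending p, ties broken by larger |r|, then canonical pair
    order. ``fraction`` must be one of 1%, 5%, 10%, 50% or all (1.0);
    1.0 returns the input unchanged.
    """
    if not any(math.isclose(fraction, f) for f in TOP_FRACTIONS):
        raise InputError(f"fraction must be one of {TOP_FRACTIONS}, got {fraction}")
    if fraction >= 1.0 or edges.empty:
        return edges
    k = math.ceil(fraction * len(edges))
    ranked = edges.assign(_abs_r=edges["r"].abs()).sort_values(
        ["p", "_abs_r", "gene_a", "gene_b"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    kept = ranked.head(k).drop(columns="_abs_r")
    return kept.sort_values(["gene_a", "gene_b"], kind="mergesort", ignore_index=True)
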