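"""Fisher z-test for correlation differences and pair classification.

A gene pair coexpressed (|r| above the active cutoff) in both classes
with the same sign is conserved: PCCGP if positive, NCCGP if negative.
A pair coexpressed in only one class is a differentially coexpressed
non-conserved pair (DCNCGP); one coexpressed in both classes with
opposite signs is a contra-coexpressed non-conserved pair (CCNCGP).

For the two non-conserved categories, the between-class difference must
be significant under Fisher's z-test: with Z_i = arctanh(r_i), the
statistic Z = (Z1 - Z2) / sqrt(1/(n1-3) + 1/(n2-3)) is approximately
standard normal under the null hypothesis of equal population
correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .coexpr import CorrelationLookup, clamp_r, correlation_pvalues
from .errors import InputError

logger = logging.getLogger(__name__)

CATEGORIES = ("PCCGP", "NCCGP", "DCNCGP", "CCNCGP")

#: Allowed significance levels for the non-conserved gate (1.0 = report all).
DIFF_ALPHAS = (0.01, 0.05, 1.0)

CLASSIFICATION_COLUMNS = [
    "gene_a", "gene_b", "r1", "p1", "r2", "p2",
    "Z1", "Z2", "Z", "p_diff", "category", "coexpressed_in",
]


@dataclass(frozen=True)
class DiffTestResult:
    """Fisher z-test of r1 (n1 samples) against r2 (n2 samples)."""

    r1: float
    r2: float
    n1: int
    n2: int
    Z1: float
    Z2: float
    Z: float
    p_diff: float


def fisher_z_transform(r):
    """Variance-stabilising transform Z = 0.5*ln((1+r)/(1-r)) = arctanh(r)."""
    return np.arctanh(clamp_r(r))


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> DiffTestResult:
    """Two-sided test of equality of two independent correlations."""
    if n1 <= 3 or n2 <= 3:
        raise InputError("Fisher z-test requires n > 3 in both classes")
    z1 = float(fisher_z_transform(r1))
    z2 = float(fisher_z_transform(r2))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = float(2.0 * special.ndtr(-abs(z)))
    return DiffTestResult(r1=r1, r2=r2, n1=n1, n2=n2, Z1=z1, Z2=z2, Z=z, p_diff=p)


def fisher_z_test_arrays(r1, n1: int, r2, n2: int):
    """Vectorised (Z1, Z2, Z, p_diff) for arrays of correlations."""
    if n1 <= 3 or n2 <= 3:
        raise InputError("Fisher z-test requires n > 3 in both classes")
    z1 = fisher_z_transform(np.asarray(r1, dtype=float))
    z2 = fisher_z_transform(np.asarray(r2, dtype=float))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * special.ndtr(-np.abs(z))
    return z1, z2, z, p


def classify_pairs(
    pairs1: pd.DataFrame,
    pairs2: pd.DataFrame,
    lookup1: CorrelationLookup,
    lookup2: CorrelationLookup,
    alpha: float = 0.05,
    gate_all: bool = False,
) -> pd.DataFrame:
    """Assign every surviving pair to one of the four categories.

    ``pairs1``/``pairs2`` are the per-class filtered pair tables;
    ``lookup1``/``lookup2`` provide r for any pair (needed for the class
    in which a DCNCGP candidate did not survive). The Fisher significance
    gate (p_diff < alpha) applies to DCNCGP and CCNCGP; with
    ``gate_all=True`` it is applied to the conserved categories as well.
    alpha = 1.0 reports all candidates.

    Returns a frame with one row per reported pair, sorted canonically;
    the four category sets are disjoint by construction.
    """
    if not any(np.isclose(alpha, a) for a in DIFF_ALPHAS):
        raise InputError(f"alpha must be one of {DIFF_ALPHAS}, got {alpha}")
    set1 = {(a, b) for a, b in zip(pairs1["gene_a"], pairs1["gene_b"])}
    set2 = {(a, b) for a, b in zip(pairs2["gene_a"], pairs2["gene_b"])}
    all_pairs = sorted(set1 | set2)
    n1, n2 = lookup1.n, lookup2.n

    kept: list[tuple] = []
    skipped = 0
    for pair in all_pairs:
        r1 = lookup1.get(*pair)
        r2 = lookup2.get(*pair)
        if r1 is None or r2 is None:
            skipped += 1
            logger.warning(
                "pair %s skipped: correlation undefined in one class", pair
            )
            continue
        kept.append((pair, pair in set1, pair in set2, r1, r2))
    if skipped:
        logger.info("classification skipped %d pairs with undefined correlation", skipped)
    if not kept:
        return pd.DataFrame(columns=CLASSIFICATION_COLUMNS)

    r1 = np.array([k[3] for k in kept])
    r2 = np.array([k[4] for k in kept])
    c1 = np.array([k[1] for k in kept])
    c2 = np.array([k[2] for k in kept])
    z1, z2, z, p_diff = fisher_z_test_arrays(r1, n1, r2, n2)
    _, p1 = correlation_pvalues(r1, n1)
    _, p2 = correlation_pvalues(r2, n2)

    # surviving correlations are bounded away from 0 (|r| > r_bs >= base),
    # so sign() is never 0 for a coexpressed class
    assert not np.any((c1 & (r1 == 0)) | (c2 & (r2 == 0)))

    both = c1 & c2
    same_sign = np.sign(r1) == np.sign(r2)
    category = np.full(len(kept), "", dtype=object)
    category[both & same_sign & (r1 > 0)] = "PCCGP"
    category[both & same_sign & (r1 < 0)] = "NCCGP"
    category[both & ~same_sign] = "CCNCGP"
    category[c1 ^ c2] = "DCNCGP"

    significant = p_diff < alpha if alpha < 1.0 else np.ones(len(kept), dtype=bool)
    gated = np.isin(category, ["DCNCGP", "CCNCGP"]) if not gate_all else np.ones(len(kept), dtype=bool)
    report = ~gated | significant

    coexpressed_in = [
        ",".join(
            lbl for lbl, flag in (("class1", a), ("class2", b)) if flag
        )
        for a, b in zip(c1, c2)
    ]
    frame = pd.DataFrame(
        {
            "gene_a": [k[0][0] for k in kept],
            "gene_b": [k[0][1] for k in kept],
            "r1": r1, "p1": p1, "r2": r2, "p2": p2,
            "Z1": z1, "Z2": z2, "Z": z, "p_diff": p_diff,
            "category": category,
            "coexpressed_in": coexpressed_in,
        }
    )
    dropped = int((~report).sum())
    if dropped:
        logger.info(
            "significance gate (alpha=%g) removed %d non-conserved candidates",
            alpha, dropped,
        )
    return frame.loc[report].reset_index(drop=True)
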