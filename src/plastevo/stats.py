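"""Shared statistical kernel.

Small wrappers around the standard tests the pipeline uses repeatedly:
Benjamini-Hochberg adjustment, proportion tests, hypergeometric gene-set
enrichment, and the 2^-ddCt relative-expression transform for qPCR data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bh_adjust",
    "two_proportion_chisq",
    "one_proportion_ztest",
    "hypergeometric_enrichment",
    "ddct",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p: float
    df: float | None = None
    adjusted_p: float | None = None


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]

    Returns
    -------
    ndarray of adjusted p-values, same order as the input, clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed in bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def two_proportion_chisq(
    k1: int, n1: int, k2: int, n2: int, yates: bool = False
) -> TestResult:
    """Pearson chi-square test comparing two proportions k1/n1 vs k2/n2.

    The 2x2 table is [[k1, n1-k1], [k2, n2-k2]]; df = 1. No continuity
    correction by default.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n for each group")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: empty margin in the 2x2 table")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=yates)
    return TestResult(statistic=float(chi2), p=float(p), df=float(df))


def one_proportion_ztest(k: int, n: int, p0: float) -> TestResult:
    """One-sample proportion Z-test: z = (k/n - p0) / sqrt(p0 (1-p0) / n).

    Two-sided normal p-value, no continuity correction.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = (k / n - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic=float(z), p=float(p))


def hypergeometric_enrichment(
    hits, categories: dict, universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``hits`` in each category set.

    Parameters
    ----------
    hits : iterable of gene ids (must be a subset of ``universe``)
    categories : mapping of category name -> iterable of gene ids
    universe : iterable of all gene ids the draw was made from

    Returns
    -------
    DataFrame with one row per category: overlap k, category size K,
    hit-set size n, universe size N, gene_ratio k/n, p and BH q across
    the tested categories. Categories reduce to their in-universe members;
    out-of-universe members are dropped with a warning. An empty hit set
    yields an empty frame.
    """
    universe = set(universe)
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hit set must be a subset of the universe")
    if not hits:
        return pd.DataFrame(
            columns=["category", "k", "K", "n", "N", "gene_ratio", "p", "q"]
        )
    rows = []
    N, n = len(universe), len(hits)
    for name, members in categories.items():
        members = set(members)
        extra = members - universe
        if extra:
            warnings.warn(
                f"category {name!r}: {len(extra)} members outside the universe ignored"
            )
            members &= universe
        K = len(members)
        k = len(hits & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, k / n, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["category", "k", "K", "n", "N", "gene_ratio", "p"]
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def ddct(
    target_ct: float,
    reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt is target minus reference (housekeeping) Ct within each sample;
    ddCt is the sample dCt minus the calibrator dCt.
    """
    vals = (target_ct, reference_ct, calibrator_target_ct, calibrator_reference_ct)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    dct_sample = target_ct - reference_ct
    dct_cal = calibrator_target_ct - calibrator_reference_ct
    return float(2.0 ** -(dct_sample - dct_cal))
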