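"""Count-matrix handling: I/O, low-expression filtering, TMM normalization, PCA.

Count matrices are plain pandas DataFrames with genes as rows and samples as
columns (nonnegative integers); sample metadata is a DataFrame indexed by
sample id with at least ``tissue``, ``region`` (S/N), ``acclimation``
(Cold/CK/Warm) and ``replicate`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_table",
    "cpm",
    "filter_low_expression",
    "NormalizationFactors",
    "tmm_factors",
    "normalize",
    "pca",
]


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_counts(df)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample metadata TSV (first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on raw (or supplied effective) library sizes."""
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts / lib * 1e6


def filter_low_expression(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Drop weakly expressed genes.

    A gene is kept iff the number of samples with CPM >= ``cpm_threshold``
    is strictly greater than ``min_fraction`` of the samples; equivalently a
    gene with sub-threshold CPM in at least half of the samples (default) is
    removed, the boundary case (exactly half) included. CPM is computed on
    raw library sizes because filtering precedes normalization.
    """
    _validate_counts(counts)
    if counts.shape[1] == 0:
        raise ValueError("count matrix has no samples")
    n_ok = (cpm(counts) >= cpm_threshold).sum(axis=1)
    keep = n_ok > min_fraction * counts.shape[1]
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    return counts.loc[keep]


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors (geometric mean 1)."""

    factors: pd.Series
    library_sizes: pd.Series
    reference: str
    effective_library_sizes: pd.Series = field(init=False)

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        self.effective_library_sizes = self.library_sizes * self.factors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_size": self.library_sizes,
                "tmm_factor": self.factors,
                "effective_library_size": self.effective_library_sizes,
            }
        )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed-mean-of-M-values factor of one sample against the reference.

    M = log2 expression ratio, A = average log2 abundance, both on genes
    positive in both samples; double trim (30% on M, 5% on A) and
    precision-weight the retained M by the inverse asymptotic (delta-method)
    variance of a log ratio of binomial counts.
    """
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        raise ValueError("sample shares no positive genes with the reference")
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    # degenerate: all ratios (near) identical
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps_rank(m)
    rank_a = sps_rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def sps_rank(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), matching R's rank()."""
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def tmm_factors(counts: pd.DataFrame, ref: str | None = None) -> NormalizationFactors:
    """TMM normalization factors for every sample of a count matrix.

    The reference (when not given) is the sample whose upper-quartile CPM is
    closest to the mean upper-quartile across samples. Factors are rescaled
    to geometric mean 1 so effective library sizes stay on the raw scale.
    """
    _validate_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if ref is None:
        uq = counts.quantile(0.75, axis=0) / lib
        ref = (uq - uq.mean()).abs().idxmin()
    elif ref not in counts.columns:
        raise KeyError(f"reference sample {ref!r} not in count matrix")
    if lib[ref] <= 0:
        raise ValueError("reference sample has zero library size")
    refcol = counts[ref].to_numpy()
    raw = pd.Series(
        {
            s: 1.0
            if s == ref
            else _tmm_pair(counts[s].to_numpy(), refcol, lib[s], lib[ref])
            for s in counts.columns
        }
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(factors=factors, library_sizes=lib, reference=ref)


def normalize(
    counts: pd.DataFrame,
    factors: NormalizationFactors | None = None,
    log: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """CPM on TMM-effective library sizes, optionally log2(x + pseudocount)."""
    _validate_counts(counts)
    if factors is None:
        eff = counts.sum(axis=0).astype(float)
    else:
        missing = set(counts.columns) - set(factors.factors.index)
        if missing:
            raise KeyError(f"normalization factors missing for samples: {sorted(missing)}")
        eff = factors.effective_library_sizes[counts.columns]
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    out = counts / eff * 1e6
    if log:
        out = np.log2(out + pseudocount)
    return out


def pca(
    em: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Sample-level PCA of an expression matrix (genes x samples).

    Centered SVD over samples; returns (scores: samples x PCs,
    loadings: genes x PCs, variance_explained). The sign of each component
    is fixed so its largest-magnitude gene loading is positive.
    """
    if n_components > min(em.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    x = em.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("constant expression matrix: PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    for i in range(n_components):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = pd.DataFrame(
        u * s, index=em.columns, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    loadings = pd.DataFrame(
        vt.T, index=em.index, columns=scores.columns
    )
    total_var = (x**2).sum()
    variance_explained = s**2 / total_var
    return scores, loadings, variance_explained
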