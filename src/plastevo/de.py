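"""Negative-binomial GLM differential expression with a Region x Acclimation
interaction design.

The model for gene g in sample s is

    count_gs ~ NB(mu_gs, alpha_g),   Var = mu + alpha mu^2
    log mu_gs = offset_s + x_s' beta_g

with the design ~ Region + Acclimation + Region:Acclimation (reference cell
S_CK) and offsets equal to log effective library sizes. Dispersions alpha_g
are method-of-moments estimates shrunk halfway toward a mean-dispersion
trend; coefficients are fit by IRLS (Fisher scoring) vectorized across
genes; hypotheses are tested with Wald contrasts and BH adjustment within
each contrast. The seven pairwise comparisons of the study design plus the
two interaction contrasts are predefined in ``CONTRASTS``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression import NormalizationFactors, tmm_factors
from .stats import bh_adjust

__all__ = [
    "REGIONS",
    "ACCLIMATIONS",
    "CONTRASTS",
    "design_matrix",
    "estimate_dispersion",
    "NBFit",
    "fit_nb_glm",
    "wald_contrast",
    "run_de",
    "call_degs",
]

REGIONS = ("S", "N")
ACCLIMATIONS = ("Cold", "CK", "Warm")

#: design columns, in order
_COEFS = ("Intercept", "regionN", "accCold", "accWarm", "regionN:accCold", "regionN:accWarm")

#: contrast vectors on the coefficient scale (natural log of cell-mean ratios)
CONTRASTS: dict[str, np.ndarray] = {
    # seven pairwise comparisons
    "S_Cold_vs_S_CK": np.array([0, 0, 1, 0, 0, 0], float),
    "N_Cold_vs_N_CK": np.array([0, 0, 1, 0, 1, 0], float),
    "S_Warm_vs_S_CK": np.array([0, 0, 0, 1, 0, 0], float),
    "N_Warm_vs_N_CK": np.array([0, 0, 0, 1, 0, 1], float),
    "N_Cold_vs_S_Cold": np.array([0, 1, 0, 0, 1, 0], float),
    "N_Warm_vs_S_Warm": np.array([0, 1, 0, 0, 0, 1], float),
    "N_CK_vs_S_CK": np.array([0, 1, 0, 0, 0, 0], float),
    # interaction contrasts per acclimation arm
    "interaction_cold": np.array([0, 0, 0, 0, 1, 0], float),
    "interaction_warm": np.array([0, 0, 0, 0, 0, 1], float),
}


def design_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded design ~ Region + Acclimation + Region:Acclimation.

    Reference levels are region S and acclimation CK. Every sample must map
    to one of the six design cells and all six cells must be populated.
    """
    region = meta["region"].astype(str)
    acc = meta["acclimation"].astype(str)
    bad = set(region) - set(REGIONS) | set(acc) - set(ACCLIMATIONS)
    if bad:
        raise ValueError(f"unknown region/acclimation levels: {sorted(bad)}")
    cells = region + "_" + acc
    expected = {f"{r}_{a}" for r in REGIONS for a in ACCLIMATIONS}
    missing = expected - set(cells)
    if missing:
        raise ValueError(f"empty design cells: {sorted(missing)}")
    n = (region == "N").astype(float)
    cold = (acc == "Cold").astype(float)
    warm = (acc == "Warm").astype(float)
    x = pd.DataFrame(
        {
            "Intercept": 1.0,
            "regionN": n,
            "accCold": cold,
            "accWarm": warm,
            "regionN:accCold": n * cold,
            "regionN:accWarm": n * warm,
        },
        index=meta.index,
    )
    return x


def estimate_dispersion(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factors: NormalizationFactors | None = None,
    trend_weight: float = 0.5,
    alpha_min: float = 1e-8,
    alpha_max: float = 10.0,
) -> pd.Series:
    """Per-gene NB dispersion by pooled method of moments plus trend shrinkage.

    Counts are scaled to a common depth; within each design cell with >= 2
    replicates the excess of the sample variance over the (depth-corrected)
    Poisson expectation is converted to a raw alpha estimate, pooled across
    cells with df weights, then averaged (weight ``trend_weight``) with a
    running-median mean-dispersion trend and capped to [alpha_min, alpha_max].
    """
    if factors is None:
        eff = counts.sum(axis=0).astype(float)
    else:
        eff = factors.effective_library_sizes[counts.columns]
    depth = eff / np.exp(np.mean(np.log(eff)))  # geometric-mean-1 depth factors
    y = counts.to_numpy(dtype=float) / depth.to_numpy()  # depth-normalized counts
    cells = (meta["region"].astype(str) + "_" + meta["acclimation"].astype(str)).to_numpy()
    inv_depth = 1.0 / depth.to_numpy()

    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for cell in np.unique(cells):
        idx = cells == cell
        n_c = int(idx.sum())
        if n_c < 2:
            continue
        yc = y[:, idx]
        mu = yc.mean(axis=1)
        s2 = yc.var(axis=1, ddof=1)
        h = inv_depth[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu * h) / mu**2
        a = np.where(np.isfinite(a), a, 0.0)
        num += (n_c - 1) * a
        den += n_c - 1
    if not den.any():
        raise ValueError("no design cell has >= 2 replicates")
    raw = np.clip(num / den, 0.0, alpha_max)

    # mean-dispersion trend: running median of raw alpha over genes ordered
    # by mean normalized count
    mean_expr = y.mean(axis=1)
    order = np.argsort(mean_expr)
    window = max(11, (counts.shape[0] // 20) | 1)
    half = window // 2
    sorted_raw = raw[order]
    trend_sorted = np.array(
        [
            np.median(sorted_raw[max(0, i - half) : i + half + 1])
            for i in range(len(sorted_raw))
        ]
    )
    trend = np.empty_like(trend_sorted)
    trend[order] = trend_sorted

    alpha = (1.0 - trend_weight) * raw + trend_weight * trend
    alpha = np.clip(alpha, alpha_min, alpha_max)
    return pd.Series(alpha, index=counts.index, name="alpha")


@dataclass
class NBFit:
    """Per-gene NB GLM fit: coefficients (natural-log scale), covariances."""

    beta: pd.DataFrame  # genes x coefficients
    cov: np.ndarray  # genes x p x p
    alpha: pd.Series
    converged: pd.Series
    mu: np.ndarray  # genes x samples fitted means
    base_mean: pd.Series

    @property
    def coef_names(self) -> tuple[str, ...]:
        return tuple(self.beta.columns)


def fit_nb_glm(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    alpha: pd.Series,
    offset: pd.Series | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NBFit:
    """Fit the NB log-link GLM to every gene by vectorized IRLS.

    ``offset`` is the per-sample log effective library size (zero if omitted).
    Convergence is a relative deviance change below ``tol``; genes that do
    not converge within ``max_iter`` iterations are flagged, not fatal.
    """
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is not full rank")
    y = counts.to_numpy(dtype=float)
    g = y.shape[0]
    a = alpha.loc[counts.index].to_numpy(dtype=float)[:, None]  # g x 1
    off = np.zeros(n) if offset is None else offset[design.index].to_numpy(dtype=float)

    # initialize every sample at the gene's mean count
    mu = np.broadcast_to(
        np.clip(y.mean(axis=1, keepdims=True), 0.1, None), y.shape
    ).copy()
    eta = np.log(mu)
    dev = _nb_deviance(y, mu, a)
    converged = np.zeros(g, dtype=bool)
    beta = np.zeros((g, p))
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + a * mu)  # Fisher weights for log link
        z = (eta - off) + (y - mu) / mu
        xtwx = np.einsum("sp,gs,sq->gpq", x, w[active], x, optimize=True)
        xtwz = np.einsum("sp,gs->gp", x, (w * z)[active], optimize=True)
        # ridge jitter keeps degenerate genes (all-zero rows) solvable
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        beta[active] = beta_new
        eta_new = np.clip(beta @ x.T + off, -30.0, 30.0)
        mu_new = np.exp(eta_new)
        dev_new = _nb_deviance(y, mu_new, a)
        rel = np.abs(dev_new - dev) / (np.abs(dev) + 0.1)
        converged = converged | (rel < tol)
        eta, mu, dev = eta_new, mu_new, dev_new

    w = mu / (1.0 + a * mu)
    xtwx = np.einsum("sp,gs,sq->gpq", x, w, x, optimize=True)
    xtwx += 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(xtwx)
    return NBFit(
        beta=pd.DataFrame(beta, index=counts.index, columns=design.columns),
        cov=cov,
        alpha=alpha.loc[counts.index],
        converged=pd.Series(converged, index=counts.index),
        mu=mu,
        base_mean=pd.Series(
            (y / np.exp(off - off.mean())).mean(axis=1),
            index=counts.index,
            name="baseMean",
        ),
    )


def _nb_deviance(y: np.ndarray, mu: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Per-gene NB2 deviance (alpha held fixed); Poisson limit at alpha ~ 0."""
    mu = np.clip(mu, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        small = a < 1e-10
        az = np.where(small, 1.0, a)  # placeholder to avoid div-by-zero
        term2_nb = (y + 1.0 / az) * np.log((1.0 + az * y) / (1.0 + az * mu))
        term2_pois = y - mu
        term2 = np.where(small, term2_pois, term2_nb)
    return 2.0 * np.sum(term1 - term2, axis=1)


def wald_contrast(fit: NBFit, contrast, name: str | None = None) -> pd.DataFrame:
    """Wald test of a single contrast c'beta = 0 for every gene.

    Returns a DataFrame with baseMean, log2FoldChange, lfcSE (log2 scale),
    stat (z), pvalue and BH-adjusted padj. Genes with zero contrast variance
    get NaN statistics and are flagged in ``zero_variance``.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.beta.shape[1],):
        raise ValueError("contrast length does not match the design")
    if not c.any():
        raise ValueError("zero contrast vector is invalid")
    est = fit.beta.to_numpy() @ c  # natural log
    var = np.einsum("p,gpq,q->g", c, fit.cov, c)
    zero_var = var <= 0
    se = np.sqrt(np.where(zero_var, np.nan, var))
    z = est / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    padj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        padj[ok] = bh_adjust(p[ok])
    ln2 = np.log(2.0)
    out = pd.DataFrame(
        {
            "baseMean": fit.base_mean,
            "log2FoldChange": est / ln2,
            "lfcSE": se / ln2,
            "stat": z,
            "pvalue": p,
            "padj": padj,
            "zero_variance": zero_var,
        },
        index=fit.beta.index,
    )
    if name is not None:
        out.attrs["contrast"] = name
    return out


def run_de(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factors: NormalizationFactors | None = None,
    contrasts: dict[str, np.ndarray] | None = None,
) -> dict[str, pd.DataFrame]:
    """Full DE pipeline: TMM offsets, dispersion, GLM fit, all Wald contrasts."""
    meta = meta.loc[counts.columns]
    if factors is None:
        factors = tmm_factors(counts)
    design = design_matrix(meta)
    alpha = estimate_dispersion(counts, meta, factors)
    offset = np.log(factors.effective_library_sizes[counts.columns])
    fit = fit_nb_glm(counts, design, alpha, offset=offset)
    contrasts = CONTRASTS if contrasts is None else contrasts
    results = {
        cname: wald_contrast(fit, cvec, name=cname) for cname, cvec in contrasts.items()
    }
    results["_fit"] = fit  # type: ignore[assignment]
    return results


def call_degs(
    de: pd.DataFrame,
    lfc_min: float | None = 1.0,
    alpha: float = 0.05,
    direction: str = "both",
) -> pd.Index:
    """Differentially expressed genes: |log2FC| > lfc_min and padj < alpha.

    Both inequalities are strict. ``lfc_min=None`` drops the fold-change gate
    (the rule used for miRNAs, where significance alone defines DE).
    ``direction`` restricts to 'up' or 'down' fold changes when requested.
    """
    sig = de["padj"] < alpha
    lfc = de["log2FoldChange"]
    if lfc_min is not None:
        if direction == "both":
            sig &= lfc.abs() > lfc_min
        elif direction == "up":
            sig &= lfc > lfc_min
        elif direction == "down":
            sig &= lfc < -lfc_min
        else:
            raise ValueError("direction must be 'both', 'up' or 'down'")
    elif direction == "up":
        sig &= lfc > 0
    elif direction == "down":
        sig &= lfc < 0
    return de.index[sig.fillna(False)]
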