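"""Compact signed-free co-expression workflow.

Implements the standard weighted co-expression recipe on an expression
matrix (genes x samples, typically log2 TMM-CPM): soft-threshold power
selection against the scale-free topology criterion, unsigned adjacency
a_ij = |cor(x_i, x_j)|^beta, the topological overlap measure

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij = sum_u a_iu a_uj,

average-linkage clustering of 1 - TOM with a static tree cut, module
eigengenes (first principal component of the standardized module
expression, sign-anchored to the module mean profile), eigengene merging,
module-trait correlation, gene significance (GS) / module membership (MM),
and hub-gene extraction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "pick_soft_threshold",
    "compute_tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_stats",
    "hub_genes",
    "export_network",
    "make_trait_table",
]

#: color-style module labels in assignment order; "grey" is reserved for
#: unassigned genes
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
)


def _drop_constant(em: pd.DataFrame) -> pd.DataFrame:
    sd = em.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} constant genes from the network")
        em = em.loc[~bad]
    return em


def _adjacency(em: pd.DataFrame, beta: float) -> np.ndarray:
    r = np.corrcoef(em.to_numpy(dtype=float))
    if not np.isfinite(r).all():
        raise ValueError("non-finite correlations; drop constant genes first")
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def pick_soft_threshold(
    em: pd.DataFrame,
    powers=tuple(range(1, 21)),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power the connectivity k_i = sum_j a_ij is binned
    (``n_bins`` bins); the fit index is the signed R^2 of log10 bin frequency
    against log10 bin connectivity (positive when the degree distribution
    decays, as scale-free topology requires). The smallest power with signed
    R^2 >= ``r2_target`` wins; if none reaches the target the power with the
    best signed R^2 is returned.
    """
    powers = list(powers)
    if len(powers) < 3:
        raise ValueError("need at least 3 candidate powers")
    em = _drop_constant(em)
    rows = []
    for beta in powers:
        a = _adjacency(em, beta)
        k = a.sum(axis=1)
        rows.append((beta, _scale_free_r2(k, n_bins), float(k.mean()), float(k.max())))
    table = pd.DataFrame(rows, columns=["power", "sft_r2", "mean_k", "max_k"])
    ok = table[table["sft_r2"] >= r2_target]
    power = int(ok["power"].iloc[0]) if len(ok) else int(table.loc[table["sft_r2"].idxmax(), "power"])
    return power, table


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 freq(k) vs log10 k over equal-width k bins."""
    k = k[k > 0]
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 2:
        raise ValueError("fewer than 2 nonempty connectivity bins")
    slope, _, r, _, _ = sps.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def compute_tom(em: pd.DataFrame, beta: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Topological overlap matrix and its dissimilarity 1 - TOM.

    The TOM is symmetric with unit diagonal and entries in [0, 1]; both
    invariants are asserted on every call.
    """
    if beta < 1:
        raise ValueError("soft-threshold power must be >= 1")
    em = _drop_constant(em)
    a = _adjacency(em, beta)
    k = a.sum(axis=1)
    l_mat = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l_mat + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = 0.5 * (tom + tom.T)  # remove float asymmetry
    assert np.allclose(tom, tom.T)
    assert (tom >= -1e-12).all() and (tom <= 1 + 1e-12).all()
    tom = np.clip(tom, 0.0, 1.0)
    tom_df = pd.DataFrame(tom, index=em.index, columns=em.index)
    return tom_df, 1.0 - tom_df


def module_eigengene(em: pd.DataFrame, genes) -> pd.Series:
    """First principal component of the standardized module expression.

    Returns one score per sample, scaled to unit norm and sign-anchored to
    correlate positively with the module's mean standardized expression.
    """
    x = em.loc[genes].to_numpy(dtype=float)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    me = vt[0]
    mean_profile = x.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return pd.Series(me, index=em.columns)


def detect_modules(
    tom: pd.DataFrame,
    em: pd.DataFrame,
    min_size: int = 30,
    merge_threshold: float = 0.25,
    cut_height: float = 0.95,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster the TOM dissimilarity into modules and merge similar ones.

    Average-linkage hierarchical clustering of 1 - TOM is cut at
    ``cut_height``; clusters smaller than ``min_size`` become "grey"
    (unassigned). Module pairs whose eigengene dissimilarity
    1 - cor(ME_a, ME_b) falls below ``merge_threshold`` are merged
    iteratively. Returns (labels per gene, eigengene matrix samples x module).
    """
    genes = tom.index
    em = em.loc[genes]
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    raw = hierarchy.fcluster(z, t=cut_height, criterion="distance")

    labels = pd.Series("grey", index=genes, name="module")
    # assign colors largest cluster first, the field's labeling convention
    sizes = pd.Series(raw).value_counts()
    color_iter = iter(MODULE_COLORS)
    for cluster_id, size in sizes.items():
        if size < min_size:
            continue
        try:
            color = next(color_iter)
        except StopIteration:
            color = f"module{cluster_id}"
        labels[raw == cluster_id] = color
    modules = [m for m in labels.unique() if m != "grey"]
    if not modules:
        warnings.warn("no module reached the minimum size; all genes are grey")
        return labels, pd.DataFrame(index=em.columns)

    mes = {m: module_eigengene(em, labels.index[labels == m]) for m in modules}
    # iterative eigengene merging
    while len(mes) > 1:
        names = list(mes)
        me_mat = np.corrcoef(np.array([mes[m].to_numpy() for m in names]))
        np.fill_diagonal(me_mat, -np.inf)
        i, j = np.unravel_index(np.argmax(me_mat), me_mat.shape)
        if 1.0 - me_mat[i, j] >= merge_threshold:
            break
        keep, drop = names[i], names[j]
        if (labels == drop).sum() > (labels == keep).sum():
            keep, drop = drop, keep
        labels[labels == drop] = keep
        del mes[drop]
        mes[keep] = module_eigengene(em, labels.index[labels == keep])

    eigengenes = pd.DataFrame(mes)
    return labels, eigengenes


def module_trait_stats(
    em: pd.DataFrame,
    labels: pd.Series,
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    ctmin_trait: str = "CT_min",
    ctmax_trait: str = "CT_max",
) -> dict:
    """Module-trait correlations with GS/MM tables and trait-rule flags.

    Returns a dict with ``module_trait_r`` / ``module_trait_p`` (modules x
    traits, Pearson with t-distributed p at df = n - 2), ``GS`` (genes x
    traits, absolute correlation with each trait), ``MM`` (genes x modules,
    absolute correlation with each eigengene), and ``selected`` flags for the
    cold-tolerance rule (p < 0.05 and r < -0.5 against CT_min) and the heat
    rule (p < 0.05 and r > 0.5 against CT_max).
    """
    traits = traits.loc[em.columns]
    if (traits.std(axis=0) == 0).any():
        bad = traits.columns[traits.std(axis=0) == 0].tolist()
        raise ValueError(f"zero-variance traits: {bad}")
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for m in eigengenes.columns:
        for t in traits.columns:
            rr, pp = sps.pearsonr(eigengenes[m], traits[t])
            r.loc[m, t], p.loc[m, t] = rr, pp
    x = em.to_numpy(dtype=float)
    gs = pd.DataFrame(
        {t: np.abs(_row_cor(x, traits[t].to_numpy())) for t in traits.columns},
        index=em.index,
    )
    mm = pd.DataFrame(
        {m: np.abs(_row_cor(x, eigengenes[m].to_numpy())) for m in eigengenes.columns},
        index=em.index,
    )
    selected = pd.DataFrame(index=eigengenes.columns)
    if ctmin_trait in traits.columns:
        selected["cold_tolerance"] = (p[ctmin_trait] < 0.05) & (r[ctmin_trait] < -0.5)
    if ctmax_trait in traits.columns:
        selected["heat_tolerance"] = (p[ctmax_trait] < 0.05) & (r[ctmax_trait] > 0.5)
    return {
        "module_trait_r": r,
        "module_trait_p": p,
        "GS": gs,
        "MM": mm,
        "selected": selected,
        "labels": labels,
    }


def _row_cor(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with vector v."""
    xc = x - x.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc @ vc) / denom


def hub_genes(
    stats: dict,
    module: str,
    trait: str = "CT_min",
    gs_min: float = 0.8,
    mm_min: float = 0.8,
) -> pd.Index:
    """Hub genes of a module: MM > mm_min and GS > gs_min (strict)."""
    labels: pd.Series = stats["labels"]
    members = labels.index[labels == module]
    if len(members) == 0:
        return pd.Index([])
    mm = stats["MM"].loc[members, module]
    gs = stats["GS"].loc[members, trait]
    return members[(mm > mm_min) & (gs > gs_min)]


def export_network(
    tom: pd.DataFrame, genes, tom_cut: float = 0.08
) -> pd.DataFrame:
    """Edge list (source, target, tom_weight) among ``genes`` above a TOM cut."""
    genes = [g for g in genes if g in tom.index]
    sub = tom.loc[genes, genes].to_numpy()
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if sub[i, j] > tom_cut:
                rows.append((genes[i], genes[j], float(sub[i, j])))
    return pd.DataFrame(rows, columns=["source", "target", "tom_weight"])


def make_trait_table(meta: pd.DataFrame, traits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Binary design indicators plus quantitative traits, aligned to samples.

    Region is coded 1 for the northern edge and 0 for the southern edge;
    Normal/Warm/Cold are one-hot indicators of the acclimation condition.
    """
    out = pd.DataFrame(
        {
            "Region": (meta["region"].astype(str) == "N").astype(float),
            "Normal": (meta["acclimation"].astype(str) == "CK").astype(float),
            "Warm": (meta["acclimation"].astype(str) == "Warm").astype(float),
            "Cold": (meta["acclimation"].astype(str) == "Cold").astype(float),
        },
        index=meta.index,
    )
    if traits is not None:
        out = out.join(traits.loc[meta.index])
    return out
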