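"""Classification of the evolution of expression plasticity.

Genes with a significant Region x Acclimation interaction are sorted into
reaction-norm categories by comparing the within-region acclimation response
of the ancestral (southern, S) and derived (northern, N) populations:

* ``assimilated``    - the ancestral response is significant, the derived one
  is not: plasticity has been lost in the derived population.
* ``evolved_plastic`` - the derived response is significant, the ancestral one
  is not: plasticity has newly emerged.
* ``accommodated``   - both responses are significant in the same direction;
  the significant interaction certifies the change in magnitude.
* ``reversed``       - both responses are significant with opposite signs.
* ``unclassified``   - interaction significant but neither within-region
  response is.

Frontloaded genes are detected separately as the intersection of genes with
elevated derived baseline (up in N vs S under control conditions) and genes
induced by acclimation within a region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import call_degs
from .stats import TestResult, one_proportion_ztest

__all__ = [
    "CATEGORIES",
    "classify_plasticity",
    "category_ztest",
    "FrontloadReport",
    "detect_frontloaded",
    "venn_summary",
]

CATEGORIES = ("assimilated", "accommodated", "evolved_plastic", "reversed")

_ARMS = {"cold": "Cold", "warm": "Warm"}


def _arm_contrasts(arm: str) -> tuple[str, str, str]:
    arm = arm.lower()
    if arm not in _ARMS:
        raise ValueError("arm must be 'cold' or 'warm'")
    a = _ARMS[arm]
    return (f"S_{a}_vs_S_CK", f"N_{a}_vs_N_CK", f"interaction_{arm}")


def classify_plasticity(
    de: dict[str, pd.DataFrame],
    arm: str = "cold",
    alpha: float = 0.05,
    posthoc_alpha: float = 0.05,
    use_adjusted_posthoc: bool = False,
) -> pd.DataFrame:
    """Assign each interaction-significant gene one reaction-norm category.

    Parameters
    ----------
    de : mapping of contrast name -> DE table (``run_de`` output)
    arm : 'cold' or 'warm' acclimation arm
    alpha : interaction significance level on BH-adjusted p
    posthoc_alpha : within-region significance level; applied to raw p by
        default (``use_adjusted_posthoc`` switches to adjusted p)

    Returns
    -------
    DataFrame indexed by gene with the within-region effects, significance
    flags/directions and the assigned ``category``.
    """
    s_name, n_name, i_name = _arm_contrasts(arm)
    for needed in (s_name, n_name, i_name):
        if needed not in de:
            raise KeyError(f"missing contrast {needed!r} in DE results")
    s_tab, n_tab, i_tab = de[s_name], de[n_name], de[i_name]

    sig_int = i_tab["padj"] < alpha
    genes = i_tab.index[sig_int.fillna(False)]
    pcol = "padj" if use_adjusted_posthoc else "pvalue"
    s_p = s_tab.loc[genes, pcol]
    n_p = n_tab.loc[genes, pcol]
    s_lfc = s_tab.loc[genes, "log2FoldChange"]
    n_lfc = n_tab.loc[genes, "log2FoldChange"]
    s_sig = (s_p < posthoc_alpha).fillna(False)
    n_sig = (n_p < posthoc_alpha).fillna(False)

    category = pd.Series("unclassified", index=genes, name="category")
    category[s_sig & ~n_sig] = "assimilated"
    category[~s_sig & n_sig] = "evolved_plastic"
    same_sign = np.sign(s_lfc) == np.sign(n_lfc)
    category[s_sig & n_sig & same_sign] = "accommodated"
    category[s_sig & n_sig & ~same_sign] = "reversed"

    return pd.DataFrame(
        {
            "arm": arm.lower(),
            "S_lfc": s_lfc,
            "S_p": s_p,
            "N_lfc": n_lfc,
            "N_p": n_p,
            "ancestral_plastic": s_sig,
            "ancestral_direction": np.sign(s_lfc).astype(int),
            "derived_plastic": n_sig,
            "derived_direction": np.sign(n_lfc).astype(int),
            "interaction_padj": i_tab.loc[genes, "padj"],
            "category": category,
        }
    )


def category_ztest(calls: pd.DataFrame, p0: float = 0.25) -> pd.DataFrame:
    """One-proportion Z-test of each category's share among classified genes.

    The null proportion defaults to an equal split (0.25) across the four
    named categories, with unclassified genes excluded from the total.
    """
    classified = calls[calls["category"] != "unclassified"]
    n = len(classified)
    if n == 0:
        raise ValueError("no classified genes to test")
    rows = []
    for cat in CATEGORIES:
        k = int((classified["category"] == cat).sum())
        res: TestResult = one_proportion_ztest(k, n, p0)
        rows.append((cat, k, n, k / n, p0, res.statistic, res.p))
    return pd.DataFrame(
        rows, columns=["category", "k", "n", "proportion", "p0", "z", "p"]
    ).set_index("category")


@dataclass
class FrontloadReport:
    """Baseline-elevated genes and their overlap with induced gene sets."""

    arm: str
    baseline: set = field(default_factory=set)  # up in N vs S at CK
    induced_S: set = field(default_factory=set)  # up in S_arm vs S_CK
    induced_N: set = field(default_factory=set)  # up in N_arm vs N_CK
    baseline_empty: bool = False

    @property
    def frontloaded(self) -> set:
        return self.baseline & self.induced_S

    @property
    def pct_induced_S(self) -> float:
        return 100.0 * len(self.baseline & self.induced_S) / len(self.baseline) if self.baseline else 0.0

    @property
    def pct_induced_N(self) -> float:
        return 100.0 * len(self.baseline & self.induced_N) / len(self.baseline) if self.baseline else 0.0


def detect_frontloaded(
    de: dict[str, pd.DataFrame],
    arm: str = "cold",
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> FrontloadReport:
    """Frontloaded genes: higher derived baseline plus ancestral induction.

    B = genes up in N vs S under control conditions; I_S and I_N = genes
    upregulated by the acclimation arm within each region. All three sets use
    the full DEG rule (log2FC > lfc_min and padj < alpha, strict). Frontloaded
    genes are B intersected with I_S; the report also carries the share of B
    still induced in the derived population (expected to be small when the
    baseline elevation has become constitutive).
    """
    s_name, n_name, _ = _arm_contrasts(arm)
    if "N_CK_vs_S_CK" not in de:
        raise KeyError("missing contrast 'N_CK_vs_S_CK' in DE results")
    b = set(call_degs(de["N_CK_vs_S_CK"], lfc_min=lfc_min, alpha=alpha, direction="up"))
    i_s = set(call_degs(de[s_name], lfc_min=lfc_min, alpha=alpha, direction="up"))
    i_n = set(call_degs(de[n_name], lfc_min=lfc_min, alpha=alpha, direction="up"))
    return FrontloadReport(
        arm=arm.lower(),
        baseline=b,
        induced_S=i_s,
        induced_N=i_n,
        baseline_empty=not b,
    )


def venn_summary(sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise overlap summary of DEG sets.

    For each pair reports |A|, |B|, the intersection and union sizes and the
    shared fraction |A & B| / |A | B| (in percent).
    """
    names = list(sets)
    rows = []
    for i, a_name in enumerate(names):
        for b_name in names[i + 1 :]:
            a, b = set(sets[a_name]), set(sets[b_name])
            inter, union = len(a & b), len(a | b)
            shared = 100.0 * inter / union if union else 0.0
            rows.append((a_name, b_name, len(a), len(b), inter, union, shared))
    return pd.DataFrame(
        rows,
        columns=["set_a", "set_b", "size_a", "size_b", "intersection", "union", "shared_pct"],
    )
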