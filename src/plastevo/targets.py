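"""miRNA target consensus, negative-correlation filtering and network reports.

Target predictions from multiple tools are intersected (a pair must be
called by all sources by default), then screened for repressive expression
signatures: a consensus miRNA-gene pair is kept only when the Pearson
correlation of their expression across matched samples is strictly below
-0.4, the signature expected of a post-transcriptional repressor. A simple
canonical seed matcher (sites complementary to miRNA positions 2-8 in a
3' UTR) is included as a built-in prediction source for testing pipelines
end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SEED_RULES",
    "seed_match_predict",
    "read_predictions",
    "intersect_predictions",
    "correlation_filter",
    "network_report",
]

SEED_RULES = ("6mer", "7mer-m8", "7mer-A1", "8mer")

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def seed_match_predict(
    mirna_id: str,
    mirna_seq: str,
    utrs: dict[str, str],
    rule: str = "7mer-m8",
    source: str = "seedmatch",
) -> pd.DataFrame:
    """Scan 3' UTRs for canonical seed-match sites of one miRNA.

    The seed is miRNA positions 2-8 (1-based). Site definitions follow the
    canonical classes: ``6mer`` matches the reverse complement of positions
    2-7; ``7mer-m8`` of positions 2-8; ``7mer-A1`` is a 6mer followed by an
    adenosine opposite miRNA position 1; ``8mer`` is a 7mer-m8 followed by
    that adenosine. Coordinates are 0-based half-open on the UTR.
    """
    if rule not in SEED_RULES:
        raise ValueError(f"rule must be one of {SEED_RULES}")
    m = _rna(mirna_seq)
    if len(m) < 8:
        raise ValueError("miRNA shorter than 8 nt: seed undefined")
    seed27 = m[1:7]
    seed28 = m[1:8]
    if rule == "6mer":
        site = _revcomp(seed27)
    elif rule == "7mer-m8":
        site = _revcomp(seed28)
    elif rule == "7mer-A1":
        site = _revcomp(seed27) + "A"
    else:  # 8mer
        site = _revcomp(seed28) + "A"
    rows = []
    for gene, utr in utrs.items():
        u = _rna(utr)
        start = u.find(site)
        while start != -1:
            rows.append((mirna_id, gene, source, rule, start, start + len(site)))
            start = u.find(site, start + 1)
    return pd.DataFrame(
        rows, columns=["mirna", "gene", "source", "rule", "start", "end"]
    )


def read_predictions(path, source: str) -> pd.DataFrame:
    """Read an external predictor's (miRNA, gene) table from TSV."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=str.lower)[["mirna", "gene"]]
    df["source"] = source
    return df


def intersect_predictions(
    predictions: pd.DataFrame, min_sources: int = 3
) -> pd.DataFrame:
    """Consensus (miRNA, gene) pairs predicted by >= ``min_sources`` sources."""
    req = {"mirna", "gene", "source"}
    if not req <= set(predictions.columns):
        raise ValueError(f"prediction table needs columns {sorted(req)}")
    n_distinct = predictions["source"].nunique()
    if min_sources > n_distinct:
        warnings.warn(
            f"min_sources={min_sources} exceeds the {n_distinct} distinct sources; "
            "no pair can qualify"
        )
        return pd.DataFrame(columns=["mirna", "gene", "n_sources", "sources"])
    grouped = (
        predictions.drop_duplicates(["mirna", "gene", "source"])
        .groupby(["mirna", "gene"])["source"]
        .agg(["nunique", lambda s: ",".join(sorted(set(s)))])
        .reset_index()
    )
    grouped.columns = ["mirna", "gene", "n_sources", "sources"]
    return grouped[grouped["n_sources"] >= min_sources].reset_index(drop=True)


def correlation_filter(
    pairs: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_max: float = -0.4,
) -> pd.DataFrame:
    """Keep consensus pairs with Pearson r strictly below ``r_max``.

    Expression matrices are feature x sample (log2 normalized abundance);
    correlations use the samples shared by both matrices. Pairs involving a
    zero-variance series are dropped with a recorded reason; the output is
    deduplicated on (miRNA, gene) and carries r and its two-sided t-test p.
    """
    shared = mirna_expr.columns.intersection(gene_expr.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 matched samples for correlation")
    me = mirna_expr[shared]
    ge = gene_expr[shared]
    rows = []
    for mirna, gene in pairs[["mirna", "gene"]].drop_duplicates().itertuples(index=False):
        if mirna not in me.index or gene not in ge.index:
            continue
        x = me.loc[mirna].to_numpy(dtype=float)
        y = ge.loc[gene].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rows.append((mirna, gene, np.nan, np.nan, "zero_variance"))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((mirna, gene, float(r), float(p), ""))
    out = pd.DataFrame(rows, columns=["mirna", "gene", "r", "p", "drop_reason"])
    kept = out[(out["drop_reason"] == "") & (out["r"] < r_max)].copy()
    kept = kept.drop(columns="drop_reason").reset_index(drop=True)
    if "n_sources" in pairs.columns:
        kept = kept.merge(
            pairs[["mirna", "gene", "n_sources", "sources"]].drop_duplicates(["mirna", "gene"]),
            on=["mirna", "gene"],
            how="left",
        )
    return kept


def network_report(
    edges: pd.DataFrame,
    deg_sets: dict[str, set] | None = None,
    annotations: dict[str, set] | None = None,
) -> dict:
    """Coverage statistics of a miRNA-target edge list.

    Reports per-miRNA target counts and their mean, the fraction of each DEG
    set covered by at least one edge (percent), per-annotation overlap counts
    (e.g. frontloaded or hub gene sets), and node/edge tables ready for
    export to graph tools.
    """
    edges = edges.drop_duplicates(["mirna", "gene"])
    targets = set(edges["gene"])
    per_mirna = edges.groupby("mirna")["gene"].nunique()
    report: dict = {
        "n_edges": int(len(edges)),
        "n_mirnas": int(edges["mirna"].nunique()),
        "n_target_genes": len(targets),
        "targets_per_mirna": per_mirna,
        "mean_targets_per_mirna": float(per_mirna.mean()) if len(per_mirna) else 0.0,
    }
    if deg_sets:
        report["deg_coverage_pct"] = {
            name: (100.0 * len(targets & set(s)) / len(s) if s else 0.0)
            for name, s in deg_sets.items()
        }
    if annotations:
        report["annotation_overlap"] = {
            name: len(targets & set(s)) for name, s in annotations.items()
        }
        for name, s in annotations.items():
            edges[name] = edges["gene"].isin(set(s))
    nodes = pd.concat(
        [
            pd.DataFrame({"id": sorted(set(edges["mirna"])), "kind": "mirna"}),
            pd.DataFrame({"id": sorted(targets), "kind": "gene"}),
        ],
        ignore_index=True,
    )
    report["nodes"] = nodes
    report["edges"] = edges.reset_index(drop=True)
    return report
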