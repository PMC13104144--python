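"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates a two-region (southern ancestral S, northern derived
N) x three-acclimation (Cold, CK control, Warm) expression study with
negative-binomial replicate counts. Each gene is planted with one
reaction-norm class realized as additive log2 shifts of the cell means on
the cold-acclimation arm:

* ``assimilated``     - the ancestral region responds to cold, the derived
  region carries the induced level constitutively (elevated in every N cell).
* ``accommodated``    - both regions respond in the same direction, the
  derived one with a third of the magnitude.
* ``evolved_plastic`` - only the derived region responds.
* ``reversed``        - the regions respond in opposite directions.
* ``frontloaded``     - constructed like an assimilated gene but always
  upward, so the set-intersection frontloading detector can be scored; its
  expected reaction-norm category is ``assimilated``.
* ``null``            - no regional or acclimation effect.

Co-expression modules are planted on null genes as shared latent factors;
the first module's latent tracks cold acclimation and drives the simulated
CT_min trait downward, giving a cold-tolerance-associated module. miRNA
profiles can be coupled negatively to planted target genes, and hairpin
construction produces structures that pass, or fail exactly one of, the
structural miRNA filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mirna import Hairpin, FilterDecision

__all__ = [
    "DEFAULT_CLASS_FRACTIONS",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_mirna_coupling",
    "generate_target_predictions",
    "generate_hairpins",
    "FILTER_CRITERIA",
]

DEFAULT_CLASS_FRACTIONS = {
    "null": 0.70,
    "assimilated": 0.08,
    "accommodated": 0.06,
    "evolved_plastic": 0.06,
    "reversed": 0.05,
    "frontloaded": 0.05,
}

_ALL_GROUPS = tuple((r, a) for r in ("S", "N") for a in ("Cold", "CK", "Warm"))

#: reaction-norm category each planted class should be assigned by the
#: classifier (null genes have no expected category)
EXPECTED_CATEGORY = {
    "assimilated": "assimilated",
    "accommodated": "accommodated",
    "evolved_plastic": "evolved_plastic",
    "reversed": "reversed",
    "frontloaded": "assimilated",
    "null": "",
}


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the simulation.

    Defaults mirror the emulated design: six region x acclimation cells with
    six replicates each (two pooled populations of three replicates per
    region), log-normally distributed baseline means around ~180 counts,
    gene-wise NB dispersions around 0.05, planted |log2 fold change| of 3,
    and log-normal library-depth heterogeneity (sdlog 0.3) for the TMM step
    to correct.
    """

    n_genes: int = 2000
    n_mirnas: int = 30
    replicates_per_group: int = 6
    groups: tuple = _ALL_GROUPS
    baseline_log2_mean: float = 7.5
    baseline_log2_sd: float = 1.0
    dispersion_meanlog: float = float(np.log(0.05))
    dispersion_sdlog: float = 0.5
    effect_log2fc: float = 3.0
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    n_modules: int = 2
    module_size: int = 50
    module_amplitude: float = 1.5
    module_loading_range: tuple = (0.5, 1.2)
    trait_noise_sd: float = 0.5
    depth_sdlog: float = 0.3
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        unknown = set(self.class_fractions) - set(EXPECTED_CATEGORY)
        if unknown:
            raise ValueError(f"unknown classes in class_fractions: {sorted(unknown)}")
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.baseline_log2_mean <= 0:
            raise ValueError("baseline mean must be positive")
        if np.exp(self.dispersion_meanlog) < 0:
            raise ValueError("dispersion must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground-truth labels recorded by the generators."""

    seed: int
    gene_class: pd.Series = None
    expected_category: pd.Series = None
    gene_module: pd.Series = None
    module_trait_sign: dict = field(default_factory=dict)
    mirna_targets: dict = field(default_factory=dict)
    hairpin_truth: dict = field(default_factory=dict)
    traits: pd.DataFrame = None
    # generator internals needed to couple miRNAs to targets afterwards
    log2_mu: pd.DataFrame = None
    depth: pd.Series = None
    alpha: pd.Series = None


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) counts, Var = mu + alpha mu^2; Poisson limit for tiny alpha."""
    alpha = np.broadcast_to(np.asarray(alpha, float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        a = alpha[~tiny]
        m = mu[~tiny]
        out[~tiny] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * m))
    return out


def generate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a count matrix, sample table, traits and truth labels.

    Identical config and seed give bitwise-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    # sample table
    rows = []
    for region, acc in config.groups:
        for rep in range(1, config.replicates_per_group + 1):
            rows.append((f"{region}_{acc}_{rep}", "muscle", region, acc, rep))
    samples = pd.DataFrame(
        rows, columns=["sample", "tissue", "region", "acclimation", "replicate"]
    ).set_index("sample")
    n_samples = len(samples)
    genes = pd.Index([f"gene_{i:05d}" for i in range(config.n_genes)], name="gene")

    # gene-level parameters
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    alpha = rng.lognormal(config.dispersion_meanlog, config.dispersion_sdlog, config.n_genes)

    # planted classes: counts by fraction, remainder goes to null
    classes = np.array(["null"] * config.n_genes, dtype=object)
    order = rng.permutation(config.n_genes)
    pos = 0
    for cls, frac in config.class_fractions.items():
        if cls == "null":
            continue
        k = int(round(frac * config.n_genes))
        classes[order[pos : pos + k]] = cls
        pos += k
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)
    signs[classes == "frontloaded"] = 1.0  # frontloading is directional by definition

    is_n = (samples["region"] == "N").to_numpy(dtype=float)
    is_cold = (samples["acclimation"] == "Cold").to_numpy(dtype=float)
    n_cold = is_n * is_cold
    s_cold = (1.0 - is_n) * is_cold

    delta = config.effect_log2fc
    log2_mu = baseline[:, None] + np.zeros((config.n_genes, n_samples))
    eff = {
        "assimilated": (delta, 0.0, delta),  # (S_Cold shift, N_Cold extra shift, N baseline)
        "frontloaded": (delta, 0.0, delta),
        "accommodated": (delta, delta / 3.0, 0.0),
        "evolved_plastic": (0.0, delta, 0.0),
        "reversed": (delta, -delta, 0.0),
    }
    for cls, (s_shift, n_shift, n_base) in eff.items():
        idx = np.flatnonzero(classes == cls)
        if idx.size == 0:
            continue
        sgn = signs[idx][:, None]
        log2_mu[idx] += sgn * (
            s_shift * s_cold[None, :] + n_shift * n_cold[None, :] + n_base * is_n[None, :]
        )

    # planted co-expression modules on null genes; the first module's latent
    # tracks cold acclimation and drives the CT_min trait
    module_of = pd.Series("", index=genes, name="module")
    module_trait_sign: dict[str, int] = {}
    cold_latent = None
    if config.n_modules > 0:
        null_idx = np.flatnonzero(classes == "null")
        needed = config.n_modules * config.module_size
        if null_idx.size < needed:
            raise ValueError("not enough null genes to host the requested modules")
        chosen = rng.choice(null_idx, size=needed, replace=False)
        u = (is_cold - is_cold.mean())
        u = u / (u.std() if u.std() > 0 else 1.0)
        for m in range(config.n_modules):
            members = chosen[m * config.module_size : (m + 1) * config.module_size]
            if m == 0:
                z = u + rng.normal(0.0, 0.3, n_samples)
            else:
                z = rng.normal(0.0, 1.0, n_samples)
            z = (z - z.mean()) / z.std()
            if m == 0:
                cold_latent = z
            w = rng.uniform(*config.module_loading_range, size=members.size)
            log2_mu[members] += config.module_amplitude * np.outer(w, z)
            name = f"M{m + 1}"
            module_of.iloc[members] = name
            module_trait_sign[name] = -1 if m == 0 else 0

    depth = rng.lognormal(0.0, config.depth_sdlog, n_samples)
    mu = (2.0**log2_mu) * depth[None, :]
    counts = _nb_draw(rng, mu, alpha[:, None])
    counts_df = pd.DataFrame(counts, index=genes, columns=samples.index)

    # simulated group-level traits with per-sample noise; higher cold-module
    # activity means lower (better) critical thermal minimum
    z_trait = cold_latent if cold_latent is not None else (is_cold - is_cold.mean()) / max(is_cold.std(), 1e-9)
    ct_min = 6.0 - 1.5 * z_trait + rng.normal(0.0, config.trait_noise_sd, n_samples)
    warm_ind = (samples["acclimation"] == "Warm").to_numpy(dtype=float)
    ct_max = 41.0 + 0.6 * warm_ind + rng.normal(0.0, config.trait_noise_sd, n_samples)
    traits = pd.DataFrame({"CT_min": ct_min, "CT_max": ct_max}, index=samples.index)

    truth = SyntheticTruth(
        seed=config.seed,
        gene_class=pd.Series(classes, index=genes, name="class"),
        expected_category=pd.Series(
            [EXPECTED_CATEGORY[c] for c in classes], index=genes, name="expected_category"
        ),
        gene_module=module_of,
        module_trait_sign=module_trait_sign,
        traits=traits,
        log2_mu=pd.DataFrame(log2_mu, index=genes, columns=samples.index),
        depth=pd.Series(depth, index=samples.index),
        alpha=pd.Series(alpha, index=genes),
    )
    return counts_df, samples, truth


def generate_mirna_coupling(
    config: SimulationConfig,
    truth: SyntheticTruth,
    counts: pd.DataFrame,
    coupling_strength: float = 1.0,
    targets_per_mirna: int = 5,
    n_regulators: int | None = None,
    mirna_dispersion: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate miRNA counts and couple planted targets negatively to them.

    Each regulator miRNA receives a log2 latent profile; its target genes'
    log2 means are shifted by ``-coupling_strength`` times that profile and
    their counts redrawn, so the sample-level Pearson correlation between a
    miRNA and its targets is negative (below -0.4 in expectation at the
    default strength). Non-targets are left untouched. Returns the miRNA
    count matrix, the updated gene count matrix and the updated truth.
    """
    if truth.log2_mu is None:
        raise ValueError("expression truth must be generated first")
    rng = np.random.default_rng(config.seed + 1_000_003)
    samples = truth.log2_mu.columns
    n_samples = len(samples)
    depth = truth.depth.to_numpy()
    mirnas = pd.Index([f"mir_{i:03d}" for i in range(config.n_mirnas)], name="mirna")
    if n_regulators is None:
        n_regulators = min(10, config.n_mirnas)
    if n_regulators > config.n_mirnas:
        raise ValueError("more regulators requested than miRNAs")

    eligible = truth.gene_class.index[
        (truth.gene_class == "null").to_numpy() & (truth.gene_module == "").to_numpy()
    ]
    needed = n_regulators * targets_per_mirna
    if len(eligible) < needed:
        raise ValueError("not enough unplanted null genes to serve as miRNA targets")
    target_pool = rng.choice(np.asarray(eligible), size=needed, replace=False)

    base = rng.normal(7.0, 1.0, config.n_mirnas)
    latent = rng.normal(0.0, 1.0, (config.n_mirnas, n_samples))
    mirna_mu = (2.0 ** (base[:, None] + latent)) * depth[None, :]
    mirna_counts = _nb_draw(rng, mirna_mu, np.full((config.n_mirnas, 1), mirna_dispersion))
    mirna_df = pd.DataFrame(mirna_counts, index=mirnas, columns=samples)

    counts = counts.copy()
    log2_mu = truth.log2_mu.copy()
    mirna_targets: dict[str, set] = {}
    for r in range(n_regulators):
        mir = mirnas[r]
        tg = target_pool[r * targets_per_mirna : (r + 1) * targets_per_mirna]
        mirna_targets[mir] = set(tg)
        if coupling_strength == 0:
            continue
        shift = -coupling_strength * (latent[r] - latent[r].mean())
        log2_mu.loc[tg] = log2_mu.loc[tg].to_numpy() + shift[None, :]
        mu_new = (2.0 ** log2_mu.loc[tg].to_numpy()) * depth[None, :]
        alpha_tg = truth.alpha.loc[tg].to_numpy()[:, None]
        counts.loc[tg] = _nb_draw(rng, mu_new, alpha_tg)

    truth.mirna_targets = mirna_targets
    truth.log2_mu = log2_mu
    return mirna_df, counts, truth


def generate_target_predictions(
    truth: SyntheticTruth,
    genes,
    sources: tuple = ("rnahybrid", "miranda", "targetscan"),
    consensus_decoy_frac: float = 0.2,
    partial_decoys_per_source: float = 2.0,
    seed_offset: int = 2_000_003,
) -> pd.DataFrame:
    """Synthetic multi-source target-prediction tables for the planted edges.

    Every true miRNA-target pair is reported by all sources (predictors
    recognize real sites). False positives are mostly tool-specific, so
    decoy pairs appearing in one or two sources are common
    (``partial_decoys_per_source`` per true edge and source) while decoys
    agreed by every source are rare (``consensus_decoy_frac`` of the true
    edge count) - the premise that makes all-source consensus an effective
    filter. Decoys never coincide with planted edges.
    """
    if not truth.mirna_targets:
        raise ValueError("miRNA coupling truth must be generated first")
    rng = np.random.default_rng(truth.seed + seed_offset)
    genes = np.asarray(list(genes))
    mirnas = np.asarray(sorted(truth.mirna_targets))
    true_edges = {
        (m, g) for m, targets in truth.mirna_targets.items() for g in targets
    }
    rows = [(m, g, s) for (m, g) in sorted(true_edges) for s in sources]

    def _decoy():
        while True:
            pair = (rng.choice(mirnas), rng.choice(genes))
            if pair not in true_edges:
                return pair

    n_true = len(true_edges)
    for _ in range(int(round(consensus_decoy_frac * n_true))):
        m, g = _decoy()
        rows.extend((m, g, s) for s in sources)
    for _ in range(int(round(partial_decoys_per_source * n_true))):
        m, g = _decoy()
        k = int(rng.integers(1, len(sources)))  # appears in 1..n-1 sources
        for s in rng.choice(np.asarray(sources), size=k, replace=False):
            rows.append((m, g, s))
    return pd.DataFrame(rows, columns=["mirna", "gene", "source"])


# ---------------------------------------------------------------------------
# hairpin construction

FILTER_CRITERIA = (
    "score", "mature_len", "star_len", "randfold", "arm_pairing", "loop", "overhang",
)

def _build_hairpin(
    rng: np.random.Generator,
    hid: str,
    qm: int,
    pm: int,
    om: int,
    loop: int,
    ps: int,
    os_: int,
    score: float,
    randfold_p: float,
) -> Hairpin:
    """Assemble a hairpin from its structural layout.

    Layout, 5' to 3': ``qm`` unpaired mature-lead nt, ``pm`` paired mature
    nt, ``om`` unpaired mature 3' nt, ``loop`` loop nt, ``ps`` unpaired star
    5' nt, ``pm`` paired star nt (reverse complement of the paired mature
    block), ``os_`` unpaired star 3' nt. The dot-bracket follows the layout,
    so the pairing is balanced and index-consistent by construction.
    """
    bases = np.array(list("ACGU"))
    mature_seq = "".join(rng.choice(bases, qm + pm + om))
    loop_seq = "".join(rng.choice(bases, loop))
    pad_seq = "".join(rng.choice(bases, ps))
    paired_block = mature_seq[qm : qm + pm]
    rc = {"A": "U", "U": "A", "G": "C", "C": "G"}
    star_paired = "".join(rc[b] for b in reversed(paired_block))
    tail_seq = "".join(rng.choice(bases, os_))
    sequence = mature_seq + loop_seq + pad_seq + star_paired + tail_seq
    structure = "." * qm + "(" * pm + "." * om + "." * loop + "." * ps + ")" * pm + "." * os_
    mature = (0, qm + pm + om)
    star = (mature[1] + loop, mature[1] + loop + ps + pm + os_)
    return Hairpin(
        id=hid,
        sequence=sequence,
        structure=structure,
        mature=mature,
        star=star,
        score=score,
        randfold_p=randfold_p,
    )


# layouts: (qm, pm, om, loop, ps, os_, score, randfold_p)
_PASS_LAYOUTS = (
    (0, 20, 2, 10, 0, 2, 50.0, 0.01),  # canonical 22/22 duplex
    (0, 18, 2, 10, 0, 2, 50.0, 0.01),  # mature exactly 20 nt (boundary pass)
    (0, 20, 2, 8, 0, 2, 50.0, 0.01),   # loop exactly 8 nt (boundary pass)
    (4, 16, 2, 10, 2, 2, 50.0, 0.01),  # exactly 16 paired positions (boundary pass)
    (0, 20, 2, 10, 0, 2, 10.01, 0.01), # score just above the cutoff
)

_FAIL_LAYOUTS = {
    "score": (0, 20, 2, 10, 0, 2, 10.0, 0.01),       # score not strictly > 10
    "mature_len": (0, 17, 2, 10, 3, 2, 50.0, 0.01),  # mature 19 nt
    "star_len": (0, 20, 2, 10, 5, 2, 50.0, 0.01),    # star 27 nt
    "randfold": (0, 20, 2, 10, 0, 2, 50.0, 0.10),    # p not significant
    "arm_pairing": (5, 15, 2, 10, 3, 2, 50.0, 0.01), # 15 paired positions
    "loop": (0, 20, 2, 7, 0, 2, 50.0, 0.01),         # loop 7 nt
    "overhang": (0, 19, 3, 10, 0, 2, 50.0, 0.01),    # 3-nt mature 3' overhang
}


def generate_hairpins(
    n_pass: int, n_fail_per_criterion: int, seed: int = 0
) -> tuple[list[Hairpin], SyntheticTruth]:
    """Construct hairpins that pass all filters or fail exactly one criterion.

    Passing hairpins cycle through canonical and boundary-passing layouts
    (mature 20 nt, loop 8 nt, 16 paired positions, score 10.01); failing
    hairpins violate only the named criterion (mature 19 nt, star 27 nt,
    loop 7 nt, 15 paired positions, score 10.0, randfold p 0.10, 3-nt
    overhang). The truth table records every expected flag.
    """
    if n_pass < 0 or n_fail_per_criterion < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    hairpins: list[Hairpin] = []
    truth = SyntheticTruth(seed=seed)
    flag_names = FilterDecision.FLAGS

    for i in range(n_pass):
        layout = _PASS_LAYOUTS[i % len(_PASS_LAYOUTS)]
        hid = f"hp_pass_{i:03d}"
        hairpins.append(_build_hairpin(rng, hid, *layout))
        truth.hairpin_truth[hid] = {**{f: True for f in flag_names}, "verdict": True}

    for crit in FILTER_CRITERIA:
        for i in range(n_fail_per_criterion):
            hid = f"hp_fail_{crit}_{i:03d}"
            hairpins.append(_build_hairpin(rng, hid, *_FAIL_LAYOUTS[crit]))
            expected = {f: True for f in flag_names}
            expected[f"{crit}_ok"] = False
            expected["verdict"] = False
            truth.hairpin_truth[hid] = expected
    return hairpins, truth
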