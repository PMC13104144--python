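"""Post-discovery miRNA hairpin filtering and small-RNA annotation utilities.

A candidate hairpin consists of a precursor sequence, its Vienna dot-bracket
secondary structure, the mature and star arm spans (0-based, half-open, on
the precursor) and two discovery statistics (a prediction score and a
folding-randomization p-value). ``filter_hairpin`` applies the stringent
structural criteria used to retain high-confidence miRNAs:

* prediction score strictly above 10,
* mature and star lengths within 20-26 nt,
* significant folding-randomization p (< 0.05),
* at least 16 mature positions base-paired into the star arm,
* a loop of at least 8 nt between the two arms,
* an exact 2-nt unpaired 3' overhang on both strands of the duplex.

Genomic context of reads and hairpins is resolved by strict priority over
overlapping annotation classes (for genomic position:
5' UTR > 3' UTR > exon > intron > intergenic; for read categories:
known miRNAs > ncRNA > repeat > exon > intron > unknown).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "parse_dotbracket",
    "Hairpin",
    "HairpinThresholds",
    "FilterDecision",
    "filter_hairpin",
    "GENOMIC_PRIORITY",
    "READ_PRIORITY",
    "FeatureIndex",
    "assign_by_priority",
    "small_rna_summary",
    "write_hairpins",
    "read_hairpins",
]

#: genomic-position priority, highest first; absent overlap falls through to
#: the final class
GENOMIC_PRIORITY = ("five_prime_utr", "three_prime_utr", "exon", "intron", "intergenic")
#: read-category priority, highest first
READ_PRIORITY = ("known_mirna", "ncrna", "repeat", "exon", "intron", "unknown")


def parse_dotbracket(structure: str) -> np.ndarray:
    """Pair map of a dot-bracket string: partner index per position, -1 if unpaired.

    Raises ValueError (naming the offending position) on unbalanced input or
    characters outside ``(``, ``)``, ``.``.
    """
    partner = np.full(len(structure), -1, dtype=int)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return partner


@dataclass
class Hairpin:
    """A predicted pre-miRNA hairpin with discovery statistics."""

    id: str
    sequence: str
    structure: str
    mature: tuple[int, int]  # 0-based half-open span on the precursor
    star: tuple[int, int]
    score: float
    randfold_p: float

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValueError(f"{self.id}: sequence/structure length mismatch")
        for name, (s, e) in (("mature", self.mature), ("star", self.star)):
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.id}: {name} span out of bounds")
        m, s = sorted((self.mature, self.star))
        if m[1] > s[0]:
            raise ValueError(f"{self.id}: mature and star spans overlap")
        self.pairs = parse_dotbracket(self.structure)


@dataclass
class HairpinThresholds:
    """Configurable cutoffs for the structural filters (defaults as used
    for high-confidence miRNA calling)."""

    min_score: float = 10.0  # strict >
    min_arm_len: int = 20
    max_arm_len: int = 26
    randfold_alpha: float = 0.05
    min_arm_pairs: int = 16
    min_loop: int = 8
    overhang: int = 2
    overhang_mode: str = "exact"  # "exact" or "min"


@dataclass
class FilterDecision:
    """Per-criterion flags for one hairpin; verdict is their conjunction."""

    hairpin_id: str
    score_ok: bool
    mature_len_ok: bool
    star_len_ok: bool
    randfold_ok: bool
    arm_pairing_ok: bool
    loop_ok: bool
    overhang_ok: bool

    FLAGS = (
        "score_ok", "mature_len_ok", "star_len_ok", "randfold_ok",
        "arm_pairing_ok", "loop_ok", "overhang_ok",
    )

    @property
    def verdict(self) -> bool:
        v = all(getattr(self, f) for f in self.FLAGS)
        return v

    def as_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.FLAGS}
        d["verdict"] = self.verdict
        return d


def _arm_overhang(pairs: np.ndarray, span: tuple[int, int], other: tuple[int, int]) -> int | None:
    """Unpaired 3' extension of an arm beyond its last position paired into
    the other arm; None when the arms share no pairs."""
    s, e = span
    paired = [i for i in range(s, e) if other[0] <= pairs[i] < other[1]]
    if not paired:
        return None
    return (e - 1) - max(paired)


def filter_hairpin(h: Hairpin, thresholds: HairpinThresholds | None = None) -> FilterDecision:
    """Evaluate all structural criteria for one hairpin.

    Arm complementarity counts mature positions whose dot-bracket partner
    lies in the star span; the loop is the sequence distance between the
    inner ends of the two spans (internal pairing does not reduce it); the
    3' overhang of each strand is measured from its last position paired
    into the partner arm to its span end.
    """
    t = thresholds or HairpinThresholds()
    m_len = h.mature[1] - h.mature[0]
    s_len = h.star[1] - h.star[0]
    first, second = sorted((h.mature, h.star))
    loop = second[0] - first[1]
    n_pairs = sum(
        1 for i in range(h.mature[0], h.mature[1]) if h.star[0] <= h.pairs[i] < h.star[1]
    )
    oh_m = _arm_overhang(h.pairs, h.mature, h.star)
    oh_s = _arm_overhang(h.pairs, h.star, h.mature)
    if t.overhang_mode == "exact":
        overhang_ok = oh_m == t.overhang and oh_s == t.overhang
    elif t.overhang_mode == "min":
        overhang_ok = (
            oh_m is not None and oh_s is not None and oh_m >= t.overhang and oh_s >= t.overhang
        )
    else:
        raise ValueError("overhang_mode must be 'exact' or 'min'")
    return FilterDecision(
        hairpin_id=h.id,
        score_ok=h.score > t.min_score,
        mature_len_ok=t.min_arm_len <= m_len <= t.max_arm_len,
        star_len_ok=t.min_arm_len <= s_len <= t.max_arm_len,
        randfold_ok=h.randfold_p < t.randfold_alpha,
        arm_pairing_ok=n_pairs >= t.min_arm_pairs,
        loop_ok=loop >= t.min_loop,
        overhang_ok=bool(overhang_ok),
    )


class FeatureIndex:
    """Interval index with strict class priority for overlap resolution.

    Intervals are (chrom, start, end, feature_class) with half-open
    coordinates; ``priority`` is the ordered tuple of classes, highest
    first, whose final element is the fallback for queries overlapping
    nothing.
    """

    def __init__(self, intervals, priority=GENOMIC_PRIORITY):
        self.priority = tuple(priority)
        self._rank = {c: i for i, c in enumerate(self.priority)}
        self._trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
        for chrom, start, end, cls in intervals:
            if end <= start:
                raise ValueError(f"malformed interval {chrom}:{start}-{end}")
            if cls not in self._rank:
                raise ValueError(f"feature class {cls!r} not in the priority order")
            self._trees[chrom][start:end] = cls

    def assign(self, chrom: str, start: int, end: int) -> str:
        if end <= start:
            raise ValueError(f"malformed query interval {chrom}:{start}-{end}")
        hits = self._trees[chrom][start:end] if chrom in self._trees else ()
        if not hits:
            return self.priority[-1]
        return min((h.data for h in hits), key=self._rank.__getitem__)


def assign_by_priority(query: tuple[str, int, int], index: FeatureIndex) -> str:
    """Highest-priority feature class overlapping a half-open query interval."""
    return index.assign(*query)


def small_rna_summary(reads: pd.DataFrame) -> dict:
    """Length distribution and 5' base composition of a small-RNA read set.

    ``reads`` needs columns ``length`` and ``first_base`` and optionally
    ``count`` (read multiplicities, default 1). Returns the modal length,
    the full length histogram (fractions summing to 1) and per-base 5'
    fractions.
    """
    if reads.empty:
        raise ValueError("empty read table")
    counts = reads["count"] if "count" in reads else pd.Series(1, index=reads.index)
    total = counts.sum()
    length_hist = counts.groupby(reads["length"]).sum() / total
    base_freq = counts.groupby(reads["first_base"].str.upper().str.replace("T", "U")).sum() / total
    return {
        "peak_length": int(length_hist.idxmax()),
        "length_hist": length_hist,
        "first_base_freq": base_freq,
    }


def write_hairpins(hairpins, fasta_path, table_path) -> None:
    """Write hairpins as FASTA plus a companion structure TSV."""
    with open(fasta_path, "w") as fh:
        for h in hairpins:
            fh.write(f">{h.id}\n{h.sequence}\n")
    pd.DataFrame(
        [
            {
                "id": h.id,
                "structure": h.structure,
                "mature_start": h.mature[0],
                "mature_end": h.mature[1],
                "star_start": h.star[0],
                "star_end": h.star[1],
                "score": h.score,
                "randfold_p": h.randfold_p,
            }
            for h in hairpins
        ]
    ).to_csv(table_path, sep="\t", index=False)


def read_hairpins(fasta_path, table_path) -> list[Hairpin]:
    """Read hairpins written by :func:`write_hairpins`."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(table_path, sep="\t")
    out = []
    for row in table.itertuples(index=False):
        out.append(
            Hairpin(
                id=row.id,
                sequence=seqs[row.id],
                structure=row.structure,
                mature=(int(row.mature_start), int(row.mature_end)),
                star=(int(row.star_start), int(row.star_end)),
                score=float(row.score),
                randfold_p=float(row.randfold_p),
            )
        )
    return out
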