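"""Pairwise Ka/Ks by Nei–Gojobori (1986) counting, selection
classification, chimeric concatenation, and calibrated strict-clock dating.

NG86 in brief: every codon position contributes fractional synonymous (S)
and nonsynonymous (N) *sites* according to which of its one-step changes
preserve the amino acid (changes to stop codons are excluded and the
remaining fractions renormalized, so S + N = 3 x codons).  Observed
*differences* between two codons are split into synonymous (Sd) and
nonsynonymous (Nd) by averaging, with equal weights, over all minimal
mutational pathways between them, excluding pathways through stop codons.
The proportions ps = Sd/S and pn = Nd/N are corrected for multiple hits
with the Jukes–Cantor formula K = -3/4 ln(1 - 4p/3); the ratio Ka/Ks
classifies selection: < 1 purifying (negative), > 1 positive, ~1 neutral.

Dating uses a strict molecular clock: Jukes–Cantor nucleotide distances
between per-organism concatenations of universally retained single-copy
genes, an average-linkage (UPGMA) ultrametric tree, and one calibration
point (the outgroup split, 112 MYA by default) converting relative heights
into absolute ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log

import numpy as np
import scipy.cluster.hierarchy as sch
from Bio.Seq import Seq
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode as SkbioTree

from .genes import OrganismAnnotation
from .orthologs import PresenceMatrix

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: str(Seq(b1 + b2 + b3).translate())
    for b1 in _BASES
    for b2 in _BASES
    for b3 in _BASES
}
STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in _CODON_TABLE if c not in STOP_CODONS))


class SaturationError(ValueError):
    """Raised when a difference proportion reaches the Jukes–Cantor pole."""


@dataclass
class KaKsResult:
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float | None  # None when Ks == 0 (undefined)
    n_codons: int


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Fractional synonymous sites of one sense codon.

    Per position, the fraction of non-stop one-step changes that are
    synonymous; the three positions sum to 3 with the nonsynonymous
    complement.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _CODON_TABLE[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if _CODON_TABLE[alt] == aa:
                syn += 1
        s += syn / valid if valid else 0.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Equal-weight average over all orderings of the differing positions;
    pathways whose intermediate codons are stops are excluded (unless every
    pathway is, in which case all are kept so the difference count is still
    defined).  Symmetric in its arguments.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = codon_a
        steps = []
        blocked = False
        for k, i in enumerate(order):
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if nxt in STOP_CODONS and k < len(order) - 1:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


def _iter_codon_pairs(cds_a: str, cds_b: str):
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be equal length (consensus parts)")
    if len(cds_a) % 3 != 0:
        raise ValueError("length must be a multiple of 3")
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3].upper(), cds_b[i : i + 3].upper()
        if set(ca + cb) - set("ACGT"):
            continue  # skip codons with gaps or undetermined bases in either
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # stops carry no site counts
        yield ca, cb


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction K = -3/4 ln(1 - 4p/3)."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: distance saturated")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei–Gojobori Ka/Ks between two aligned, equal-length CDS.

    Codons containing gaps/N in either sequence and stop codons are skipped
    in both.  Site counts are averaged between the two sequences.  Raises
    :class:`SaturationError` when ps or pn reaches 3/4.  ``ratio`` is None
    when Ks = 0 (explicitly undefined, not infinity).
    """
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in _iter_codon_pairs(cds_a, cds_b):
        n_codons += 1
        sa, sb = synonymous_sites(ca), synonymous_sites(cb)
        S += (sa + sb) / 2.0
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * n_codons - S
    if n_codons == 0:
        raise ValueError("no comparable codons between the sequences")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = jc_correct(ps)
    Ka = jc_correct(pn)
    ratio = Ka / Ks if Ks > 0 else None
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ks=Ks, Ka=Ka, ratio=ratio,
        n_codons=n_codons,
    )


def classify_selection(result: KaKsResult, neutral_tolerance: float = 0.05) -> str:
    """negative / neutral / positive / undefined from a Ka/Ks result."""
    if result.ratio is None:
        return "undefined"
    if abs(result.ratio - 1.0) <= neutral_tolerance:
        return "neutral"
    return "negative" if result.ratio < 1.0 else "positive"


def build_chimeric_alignment(
    annotations: dict[str, OrganismAnnotation],
    matrix: PresenceMatrix,
) -> dict[str, str]:
    """One concatenated ("chimeric") CDS per organism.

    Ortholog groups that are complete in every organism (single-copy by
    matrix construction) qualify; their CDS are concatenated in
    lexicographic group-name order.  Groups whose members differ in length
    are trimmed to the shared prefix so all concatenations stay equal
    length.  Raises if fewer than two groups qualify.
    """
    orgs = matrix.organisms
    qualifying = [
        g
        for g in matrix.groups
        if all(matrix.df.loc[g, o] == "complete" for o in orgs)
    ]
    if len(qualifying) < 2:
        raise ValueError(
            f"only {len(qualifying)} universally complete single-copy groups; "
            "need at least 2 for a chimeric alignment"
        )
    concat = {o: [] for o in orgs}
    for group in sorted(qualifying):
        seqs = {o: annotations[o].by_id(matrix.members[group][o]).cds for o in orgs}
        min_len = min(len(s) for s in seqs.values()) // 3 * 3
        for o in orgs:
            concat[o].append(seqs[o][:min_len])
    return {o: "".join(parts) for o, parts in concat.items()}


@dataclass
class DatedTree:
    """Ultrametric species tree with node ages in MYA."""

    tree: SkbioTree  # branch lengths in MYA
    ages: dict[frozenset, float]  # clade (tip-name set) -> node age
    calibration_clade: frozenset
    calibration_age: float

    def age_of(self, *taxa: str) -> float:
        """Age of the smallest clade containing all ``taxa``."""
        best = None
        for clade, age in self.ages.items():
            if set(taxa) <= clade and (best is None or len(clade) < len(best[0])):
                best = (clade, age)
        if best is None:
            raise KeyError(f"no clade contains {taxa}")
        return best[1]

    def newick(self) -> str:
        return str(self.tree).strip()


def jc_distance_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise Jukes–Cantor nucleotide distances between equal-length seqs."""
    names = sorted(seqs)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[names[i]], seqs[names[j]]
            if len(a) != len(b):
                raise ValueError("concatenations must be equal length")
            xa = np.frombuffer(a.encode(), dtype=np.uint8)
            xb = np.frombuffer(b.encode(), dtype=np.uint8)
            p = float((xa != xb).mean())
            d[i, j] = d[j, i] = jc_correct(p)
    return names, d


def date_divergences(
    concatenations: dict[str, str],
    outgroup_label: str,
    calibration_age: float = 112.0,
) -> DatedTree:
    """Strict-clock divergence dating with one calibration point.

    UPGMA (average linkage) on Jukes–Cantor distances gives an ultrametric
    tree whose node heights are proportional to time under a strict clock;
    all heights are rescaled by one factor so the node where the outgroup
    splits off sits exactly at ``calibration_age`` MYA.
    """
    if outgroup_label not in concatenations:
        raise ValueError(f"outgroup {outgroup_label!r} not among the taxa")
    if len(concatenations) < 3:
        raise ValueError("need at least 3 taxa including the outgroup")
    names, d = jc_distance_matrix(concatenations)
    out_idx = names.index(outgroup_label)
    if np.any(d[out_idx][np.arange(len(names)) != out_idx] <= 0.0):
        raise ValueError("zero distance to the outgroup; cannot calibrate")
    linkage = sch.average(squareform(d, checks=False))
    tree = SkbioTree.from_linkage_matrix(linkage, names)

    heights: dict[int, float] = {}

    def height(node: SkbioTree) -> float:
        if node.is_tip():
            return 0.0
        return max((c.length or 0.0) + height(c) for c in node.children)

    # the outgroup split is the node where the outgroup's tip branches off
    out_tip = next(t for t in tree.tips() if t.name == outgroup_label)
    split_node = out_tip.parent
    split_height = height(split_node)
    if split_height <= 0:
        raise ValueError("outgroup split height is zero; cannot calibrate")
    scale = calibration_age / split_height

    ages: dict[frozenset, float] = {}
    for node in tree.non_tips(include_self=True):
        clade = frozenset(t.name for t in node.tips())
        ages[clade] = height(node) * scale
    for node in tree.traverse():
        if node.length is not None:
            node.length *= scale
    cal_clade = frozenset(t.name for t in split_node.tips())
    ages[cal_clade] = calibration_age  # exact by construction
    return DatedTree(
        tree=tree,
        ages=ages,
        calibration_clade=cal_clade,
        calibration_age=calibration_age,
    )
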