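"""Codon-aware sequence evolution for simulated gene families.

Indel-free Jukes–Cantor-style process: candidate substitutions arrive at
``clock_rate`` per site per MY, uniformly over sites, targets uniform over
the three alternative bases.  A candidate is accepted if synonymous,
accepted with probability min(1, omega) if nonsynonymous, and rejected if it
would create a stop codon (or destroy the start/terminal-stop codon) — so
functional genes keep an intact ORF.  Pseudogenes evolve free of all
constraints and carry one forced internal stop codon from the moment of
pseudogenization.  All homologs of a family therefore stay equal length.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from .birthdeath import EventRecord, SimulationResult
from .species import TreeNode

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: str(Seq(b1 + b2 + b3).translate())
    for b1 in "TCAG"
    for b2 in "TCAG"
    for b3 in "TCAG"
}
SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random valid ORF: ATG + random sense codons + one stop codon."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons (start, one sense, stop)")
    middle = rng.choice(SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(middle) + "TAA"


def mark_pseudogene(seq: str) -> str:
    """Force one internal stop codon (the frameshift-free disruption)."""
    n_codons = len(seq) // 3
    i = n_codons // 2
    return seq[: 3 * i] + "TGA" + seq[3 * (i + 1) :]


def evolve_seq(
    seq: str,
    duration: float,
    clock_rate: float,
    omega: float,
    rng: np.random.Generator,
    pseudo: bool = False,
) -> str:
    """Evolve one CDS for ``duration`` MY."""
    L = len(seq)
    n_cand = rng.poisson(clock_rate * L * duration)
    if n_cand == 0:
        return seq
    s = list(seq)
    last_codon = L // 3 - 1
    for _ in range(n_cand):
        pos = int(rng.integers(L))
        cur = s[pos]
        alt = _BASES[_BASES != cur][rng.integers(3)]
        ci = pos // 3
        codon = s[3 * ci] + s[3 * ci + 1] + s[3 * ci + 2]
        new_codon = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
        if pseudo:
            s[pos] = alt
            continue
        if ci == 0:
            continue  # protect the start codon
        if ci == last_codon:
            if new_codon in _STOPS:
                s[pos] = alt  # stop-to-stop exchanges allowed
            continue
        if new_codon in _STOPS:
            continue
        if _CODON_TABLE[new_codon] != _CODON_TABLE[codon]:
            if rng.random() >= min(1.0, omega):
                continue
        s[pos] = alt
    return "".join(s)


def inject_partial(seq: str, rng: np.random.Generator, n_sites: int = 30) -> str:
    """Replace an internal stretch with Ns, emulating a sequencing gap."""
    L = len(seq)
    n_sites = min(n_sites, max(3, L - 6))
    start = int(rng.integers(3, L - 3 - n_sites + 1))
    return seq[:start] + "N" * n_sites + seq[start + n_sites :]


def evolve_sequences(
    result: SimulationResult,
    seed: int | np.random.SeedSequence,
    partial_prob: float = 0.0,
) -> dict[str, dict[str, str]]:
    """Evolve a CDS for every gene of a simulated family history.

    Returns ``{organism: {gene_id: cds}}`` for the leaf inventories of
    ``result``.  Each branch's duplication / pseudogenization events are
    replayed in time order so a duplicate inherits its parent's sequence at
    the duplication instant.  With ``partial_prob`` > 0, that fraction of
    leaf genes (complete ones) receives an undetermined-nucleotide stretch,
    emulating incomplete gene models.
    """
    rng = np.random.default_rng(seed)
    p = result.params

    by_branch: dict[str, list[EventRecord]] = {}
    for ev in result.event_log:
        if ev.event_kind != "speciation":
            by_branch.setdefault(ev.branch, []).append(ev)
    for evs in by_branch.values():
        evs.sort(key=lambda e: -e.time)

    root_seqs: dict[str, str] = {}
    root_status: dict[str, str] = {}
    for gid in sorted(result.root_inventory.genes):
        gene = result.root_inventory.genes[gid]
        seq = random_cds(rng, p.n_codons)
        if gene.status == "pseudogene":
            seq = mark_pseudogene(seq)
        root_seqs[gid] = seq
        root_status[gid] = gene.status

    out: dict[str, dict[str, str]] = {}

    def evolve_all(seqs, status, dt):
        if dt <= 0:
            return
        for gid in sorted(seqs):
            seqs[gid] = evolve_seq(
                seqs[gid], dt, p.clock_rate, p.omega, rng,
                pseudo=(status[gid] == "pseudogene"),
            )

    def recurse(node: TreeNode, seqs: dict[str, str], status: dict[str, str]) -> None:
        if node.parent is not None:
            t = node.parent.age
            for ev in by_branch.get(node.label, []):
                evolve_all(seqs, status, t - ev.time)
                t = ev.time
                if ev.event_kind == "duplication":
                    seqs[ev.child_gene] = seqs[ev.parent_gene]
                    status[ev.child_gene] = status[ev.parent_gene]
                elif ev.event_kind == "loss":
                    seqs.pop(ev.parent_gene)
                    status.pop(ev.parent_gene)
                elif ev.event_kind == "pseudogenization":
                    status[ev.parent_gene] = "pseudogene"
                    seqs[ev.parent_gene] = mark_pseudogene(seqs[ev.parent_gene])
            evolve_all(seqs, status, t - node.age)
        if node.is_leaf:
            leaf_seqs = dict(seqs)
            if partial_prob > 0:
                for gid in sorted(leaf_seqs):
                    if status[gid] == "complete" and rng.random() < partial_prob:
                        leaf_seqs[gid] = inject_partial(leaf_seqs[gid], rng)
            out[node.label] = leaf_seqs
            return
        for child in node.children:
            recurse(child, dict(seqs), dict(status))

    recurse(result.tree.root, dict(root_seqs), dict(root_status))
    return out
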