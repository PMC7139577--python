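"""Constructed duplication scenarios with known event truth.

The centrepiece is a tandem-ladder-plus-inverted-segment scenario: one
ancestral gene is tandem-duplicated n-1 times at known, successive times to
form an n-gene cluster, after which the whole segment is duplicated and
re-inserted in reverse orientation further along the same chromosome.  The
truth (duplication order, paralog pairing, orientation) is returned with the
annotation so detection code can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..genes import GeneModel, OrganismAnnotation, translate_cds
from .birthdeath import DISPERSED_GAP, TANDEM_GAP
from .seqevo import evolve_seq, random_cds


@dataclass
class LadderTruth:
    ladder_ids: list[str]  # original segment, in chromosomal/creation order
    copy_ids: list[str]  # inverted copy, in chromosomal order
    dup_times: list[float]  # ladder duplication ages, oldest first (MYA)
    paralog_pairs: list[tuple[str, str]]  # (original, copy)
    sd_time: float


def simulate_tandem_ladder(
    n: int = 8,
    first_dup_age: float = 9.0,
    dup_interval: float = 1.0,
    sd_age: float = 1.0,
    clock_rate: float = 0.01,
    n_codons: int = 300,
    family: str = "CIII Prx",
    organism: str = "grandis",
    seed: int | np.random.SeedSequence = 0,
    with_segment_copy: bool = True,
    segment_gap: int = 40_000,
) -> tuple[OrganismAnnotation, LadderTruth]:
    """Simulate the ladder scenario and return annotation + truth.

    Gene i+1 is a copy of gene i made at age ``first_dup_age - i*dup_interval``
    (so the ladder order equals the creation order).  If
    ``with_segment_copy``, at ``sd_age`` the finished segment is copied in
    reverse orientation ``segment_gap`` bp downstream on the same chromosome.
    Sequences evolve neutrally-constrained (omega 0.2) at ``clock_rate``
    between events, giving the distance signal used to reconstruct the
    duplication order.
    """
    if n < 2:
        raise ValueError("need at least two ladder genes")
    rng = np.random.default_rng(seed)
    omega = 0.2
    times = [first_dup_age - i * dup_interval for i in range(n - 1)]
    if times[-1] <= sd_age and with_segment_copy:
        raise ValueError("segment copy must postdate the last tandem duplication")

    seqs: list[str] = [random_cds(rng, n_codons)]
    t_now = first_dup_age + dup_interval  # birth of the ancestral gene
    for t_dup in times:
        dt = t_now - t_dup
        seqs = [evolve_seq(s, dt, clock_rate, omega, rng) for s in seqs]
        seqs.append(seqs[-1])  # the newest gene is duplicated
        t_now = t_dup
    if with_segment_copy:
        dt = t_now - sd_age
        seqs = [evolve_seq(s, dt, clock_rate, omega, rng) for s in seqs]
        copies = list(seqs)
        seqs = seqs + copies[::-1]  # reversed insertion
        t_now = sd_age
    seqs = [evolve_seq(s, t_now, clock_rate, omega, rng) for s in seqs]

    ladder_ids = [f"Prx{i + 1:02d}" for i in range(n)]
    copy_ids = [f"Prx{n + i + 1:02d}" for i in range(n)] if with_segment_copy else []
    genes: list[GeneModel] = []
    pos = 0
    for i, gid in enumerate(ladder_ids):
        gap = DISPERSED_GAP if i == 0 else TANDEM_GAP
        start = pos + gap + 1
        end = start + len(seqs[i]) - 1
        pos = end
        genes.append(
            GeneModel(
                gene_id=gid,
                organism=organism,
                family=family,
                chromosome="chr1",
                start=start,
                end=end,
                strand="+",
                status="complete",
                cds=seqs[i],
                protein=translate_cds(seqs[i]),
            )
        )
    if with_segment_copy:
        pos += segment_gap
        for i, gid in enumerate(copy_ids):
            gap = 0 if i == 0 else TANDEM_GAP
            start = pos + gap + 1
            seq = seqs[n + i]
            end = start + len(seq) - 1
            pos = end
            genes.append(
                GeneModel(
                    gene_id=gid,
                    organism=organism,
                    family=family,
                    chromosome="chr1",
                    start=start,
                    end=end,
                    strand="-",
                    status="complete",
                    cds=seq,
                    protein=translate_cds(seq),
                )
            )

    annotation = OrganismAnnotation(
        organism=organism,
        genes=genes,
        chromosome_sizes={"chr1": pos + DISPERSED_GAP},
    )
    # the reversed insertion pairs original i with copy at mirrored position
    pairs = (
        [(ladder_ids[i], copy_ids[n - 1 - i]) for i in range(n)]
        if with_segment_copy
        else []
    )
    truth = LadderTruth(
        ladder_ids=ladder_ids,
        copy_ids=copy_ids,
        dup_times=[float(t) for t in times],
        paralog_pairs=pairs,
        sd_time=sd_age,
    )
    return annotation, truth
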