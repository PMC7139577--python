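"""Materialize simulated gene families as GFF3 + FASTA + TSV files.

The emitted files round-trip losslessly through
:func:`rosfam.genes.read_annotation` on the shared fields (ids, coordinates,
strand, family, status, source, CDS).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..genes import GeneModel, OrganismAnnotation, classify_gene_status, translate_cds
from .birthdeath import SimulationResult
from .seqevo import mark_pseudogene

_TAIL = 20_000  # bp of chromosome past the last gene


def build_annotations(
    results: list[SimulationResult],
    sequences: list[dict[str, dict[str, str]]],
    seed: int | np.random.SeedSequence = 0,
    pcr_prob: float = 0.0,
) -> dict[str, OrganismAnnotation]:
    """Turn family simulations into coordinate-resolved gene annotations.

    Families are laid out one after another on each chromosome, preserving
    each family's internal order and gaps (so tandem arrays stay adjacent).
    A ``pcr_prob`` fraction of genes is labelled as found by targeted PCR
    rather than present in the genomic database.
    """
    rng = np.random.default_rng(seed)
    organisms = sorted(results[0].inventories)
    annotations: dict[str, OrganismAnnotation] = {}
    for org in organisms:
        genes: list[GeneModel] = []
        positions: dict[str, int] = {}
        chrom_names = sorted(
            {c for res in results for c in res.inventories[org].order}
        )
        for chrom in chrom_names:
            positions[chrom] = 0
        for res, seqs in zip(results, sequences):
            inv = res.inventories[org]
            for chrom in sorted(inv.order):
                for gid in inv.order[chrom]:
                    seq = seqs[org][gid]
                    sim_status = inv.genes[gid].status
                    if sim_status == "pseudogene" and classify_gene_status(seq) != "pseudogene":
                        seq = mark_pseudogene(seq)
                    status = classify_gene_status(seq)
                    start = positions[chrom] + inv.gap_before[gid] + 1
                    end = start + len(seq) - 1
                    positions[chrom] = end
                    genes.append(
                        GeneModel(
                            gene_id=gid,
                            organism=org,
                            family=res.params.family_name,
                            chromosome=chrom,
                            start=start,
                            end=end,
                            strand="+" if rng.random() < 0.5 else "-",
                            status=status,
                            source="pcr" if rng.random() < pcr_prob else "database",
                            cds=seq,
                            protein="" if status == "pseudogene" else translate_cds(seq),
                        )
                    )
        chrom_sizes = {c: positions[c] + _TAIL for c in positions}
        annotations[org] = OrganismAnnotation(
            organism=org, genes=genes, chromosome_sizes=chrom_sizes
        )
    return annotations


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_organism_files(
    annotation: OrganismAnnotation, out_dir: Path, seed: int | np.random.SeedSequence = 0
) -> dict[str, Path]:
    """Write one organism's GFF3, genome, CDS and protein FASTA files."""
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    org = annotation.organism
    paths = {
        "gff3": out_dir / f"{org}.gff3",
        "genome": out_dir / f"{org}_genome.fasta",
        "cds": out_dir / f"{org}_cds.fasta",
        "protein": out_dir / f"{org}_protein.fasta",
    }

    genes = annotation.sorted_genes()
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chromosome_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chromosome_sizes[chrom]}\n")
        for g in genes:
            attrs = (
                f"ID={g.gene_id};family={g.family};organism={org};"
                f"source_kind={g.source}"
            )
            if g.status == "pseudogene":
                attrs += ";pseudo=true;biotype=pseudogene"
            fh.write(
                f"{g.chromosome}\trosfam_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chromosome}\trosfam_sim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.chromosome}\trosfam_sim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.c1;Parent={g.gene_id}.t1\n"
            )

    genome_records = []
    for chrom in sorted(annotation.chromosome_sizes):
        size = annotation.chromosome_sizes[chrom]
        arr = rng.choice(np.array(list("ACGT")), size=size)
        for g in genes:
            if g.chromosome != chrom:
                continue
            insert = g.cds if g.strand == "+" else _revcomp(g.cds)
            arr[g.start - 1 : g.end] = list(insert)
        genome_records.append((chrom, "".join(arr)))
    _write_fasta(paths["genome"], genome_records)
    _write_fasta(paths["cds"], [(g.gene_id, g.cds) for g in genes])
    _write_fasta(
        paths["protein"], [(g.gene_id, g.protein) for g in genes if g.protein]
    )
    return paths


def emit_dataset(
    annotations: dict[str, OrganismAnnotation],
    out_dir,
    counts: dict[str, pd.DataFrame] | None = None,
    results: list[SimulationResult] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> dict:
    """Write the full simulated dataset: per-organism files + truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen: set[tuple[str, str]] = set()
    for org, ann in annotations.items():
        for g in ann.genes:
            key = (org, g.gene_id)
            if key in seen:
                raise ValueError(f"gene id collision: {key}")
            seen.add(key)
    paths: dict = {"organisms": {}}
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    org_seeds = ss.spawn(len(annotations))
    for (org, ann), s in zip(sorted(annotations.items()), org_seeds):
        paths["organisms"][org] = write_organism_files(ann, out_dir, s)

    if counts is not None:
        rows = []
        for org in sorted(counts):
            df = counts[org]
            for gid in df.index:
                for tissue in df.columns:
                    rows.append((org, gid, tissue, int(df.loc[gid, tissue])))
        cdf = pd.DataFrame(rows, columns=["organism", "gene_id", "tissue", "count"])
        paths["counts"] = out_dir / "counts.tsv"
        cdf.to_csv(paths["counts"], sep="\t", index=False)

    if results is not None:
        rows = []
        for res in results:
            for org in sorted(res.inventories):
                inv = res.inventories[org]
                for gid in sorted(inv.genes):
                    rows.append(
                        (res.params.family_name, gid, org, inv.genes[gid].status)
                    )
        pd.DataFrame(
            rows, columns=["family", "gene_id", "organism", "status"]
        ).to_csv(out_dir / "truth_presence.tsv", sep="\t", index=False)
        rows = []
        for res in results:
            for ev in res.event_log:
                rows.append(
                    (
                        res.params.family_name,
                        ev.event_kind,
                        ev.branch,
                        ev.time,
                        ev.parent_gene or "",
                        ev.child_gene or "",
                    )
                )
        pd.DataFrame(
            rows,
            columns=["family", "event_kind", "branch", "time", "parent_gene", "child_gene"],
        ).to_csv(out_dir / "truth_events.tsv", sep="\t", index=False)
        paths["truth_presence"] = out_dir / "truth_presence.tsv"
        paths["truth_events"] = out_dir / "truth_events.tsv"
    return paths
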