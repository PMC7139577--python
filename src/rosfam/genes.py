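"""Gene models: the shared data layer.

A :class:`GeneModel` is one annotated gene — coordinates on a chromosome
(GFF3 convention: 1-based, closed intervals), family membership, completeness
status (``complete`` / ``partial`` / ``pseudogene``), provenance
(``database`` = genomic annotation, ``pcr`` = experimental detection), and its
CDS / protein sequences.  An :class:`OrganismAnnotation` is one organism's
ordered collection of gene models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .families import FAMILY_ABBREV, check_family

STATUSES = ("complete", "partial", "pseudogene")
SOURCES = ("database", "pcr")

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneModel:
    gene_id: str
    organism: str
    family: str
    chromosome: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    strand: str = "+"
    status: str = "complete"
    source: str = "database"
    cds: str = ""
    protein: str = ""
    name: str = ""  # assigned positional name, e.g. EgrPrx01

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        check_family(self.family)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class OrganismAnnotation:
    organism: str
    genes: list[GeneModel] = field(default_factory=list)
    chromosome_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids in {self.organism}: {dupes}")

    def sorted_genes(self) -> list[GeneModel]:
        """Genes in (chromosome, start) order; chromosomes numeric-first."""
        return sorted(
            self.genes, key=lambda g: (chromosome_key(g.chromosome), g.start)
        )

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def by_family(self, family: str) -> list[GeneModel]:
        return [g for g in self.sorted_genes() if g.family == family]


def chromosome_key(label: str):
    """Sort key ordering chromosomes numerically, then lexically.

    'chr2' < 'chr10' < 'chrX' < 'scaffold_1'.
    """
    m = re.search(r"(\d+)$", label)
    prefix = label[: m.start()] if m else label
    return (prefix, int(m.group(1)) if m else -1, label)


def classify_gene_status(cds: str) -> str:
    """Classify a CDS as complete, partial or pseudogene.

    Pseudogene: internal stop codon or a length not divisible by three
    (frameshift).  Partial: undetermined nucleotides (N) or a missing
    start/stop codon.  Otherwise complete.  An N-containing sequence that
    also carries an internal stop is a pseudogene — the stop/frameshift is
    the stronger evidence of non-functionality.
    """
    if not cds:
        raise ValueError("empty CDS cannot be classified")
    cds = cds.upper()
    if len(cds) % 3 != 0:
        return "pseudogene"
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(c in _STOP_CODONS for c in codons[:-1]):
        return "pseudogene"
    if "N" in cds:
        return "partial"
    if codons[0] != "ATG" or codons[-1] not in _STOP_CODONS:
        return "partial"
    return "complete"


def translate_cds(cds: str) -> str:
    """Standard-code translation without the terminal stop."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(trimmed).translate())
    return prot[:-1] if prot.endswith("*") else prot


def read_annotation(
    gff3_path, genome_fasta, cds_fasta, organism: str | None = None
) -> OrganismAnnotation:
    """Read one organism's annotation from GFF3 + FASTA files.

    One :class:`GeneModel` is built per ``gene`` feature.  The CDS comes from
    ``cds_fasta`` (keyed by gene id); ``genome_fasta`` supplies chromosome
    sizes.  The completeness status is recomputed from the CDS with
    :func:`classify_gene_status`; family / source / organism are read from
    the GFF3 attributes ``family``, ``source_kind`` and ``organism``.
    """
    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    chrom_sizes = {
        rec.id: len(rec.seq) for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }

    with open(gff3_path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:  # header-only file: a valid, empty annotation
        return OrganismAnnotation(
            organism=organism or "unknown", genes=[], chromosome_sizes=chrom_sizes
        )
    try:
        db = gffutils.create_db(
            str(gff3_path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:  # gffutils wraps line-level parse errors
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    org = organism
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.id
        if gid not in cds_seqs:
            raise ValueError(f"no CDS sequence for gene feature {gid!r}")
        cds = cds_seqs[gid]
        if org is None:
            org = feat.attributes.get("organism", ["unknown"])[0]
        family = feat.attributes.get("family", ["CIII Prx"])[0]
        source = feat.attributes.get("source_kind", ["database"])[0]
        status = classify_gene_status(cds)
        protein = translate_cds(cds) if status != "pseudogene" else ""
        genes.append(
            GeneModel(
                gene_id=gid,
                organism=org,
                family=family,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                status=status,
                source=source,
                cds=cds,
                protein=protein,
            )
        )
    return OrganismAnnotation(
        organism=org or "unknown", genes=genes, chromosome_sizes=chrom_sizes
    )


def assign_gene_names(
    annotation: OrganismAnnotation,
    prefix: str,
    reference_names: dict[str, str] | None = None,
) -> OrganismAnnotation:
    """Assign positional gene names: prefix + family tag + 2-digit number.

    Within each family genes are numbered 1..n in (chromosome, start) order,
    chromosomes ordered numerically then lexically — the number encodes the
    position order on the chromosomes.  When ``reference_names`` maps this
    organism's gene ids to the name suffix (family tag + number) already
    given to a reference organism's orthologs, those suffixes are reused
    under this organism's prefix — orthologs are named after the reference
    organism — and only the remaining genes receive fresh numbers.
    Naming is independent of input order and injective within a family.
    """
    reference_names = reference_names or {}
    named: dict[str, str] = {}
    by_family: dict[str, list[GeneModel]] = {}
    for g in annotation.sorted_genes():
        by_family.setdefault(g.family, []).append(g)
    for family, members in by_family.items():
        tag = FAMILY_ABBREV[family]
        used = {
            prefix + reference_names[g.gene_id]
            for g in members
            if g.gene_id in reference_names
        }
        counter = 0
        for g in members:
            if g.gene_id in reference_names:
                named[g.gene_id] = prefix + reference_names[g.gene_id]
                continue
            counter += 1
            while f"{prefix}{tag}{counter:02d}" in used:
                counter += 1
            named[g.gene_id] = f"{prefix}{tag}{counter:02d}"
    new_genes = [replace(g, name=named[g.gene_id]) for g in annotation.genes]
    return OrganismAnnotation(
        organism=annotation.organism,
        genes=new_genes,
        chromosome_sizes=dict(annotation.chromosome_sizes),
    )
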