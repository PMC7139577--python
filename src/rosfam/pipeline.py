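"""End-to-end pipeline wiring: configuration, stage order, report bundle.

Stage outputs are plain TSV with documented headers so any stage can be
re-run standalone; every output file carries the run manifest hash in a
``#`` comment header, and the whole bundle is byte-reproducible given
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .duplication import chromosome_stats, detect_tandem_clusters
from .expression import family_expression_level, load_counts_table
from .family_stats import categorize_conservation, summarize_families
from .genes import OrganismAnnotation, read_annotation
from .molevol import (
    SaturationError,
    build_chimeric_alignment,
    classify_selection,
    date_divergences,
    ng86_kaks,
)
from .orthologs import build_presence_matrix, match_orthologs, pairwise_gain_loss, venn_counts


@dataclass
class PipelineConfig:
    organisms: list[str]
    reference: str
    input_dir: str
    out_dir: str
    min_identity: float = 70.0
    max_gap: int = 15_000
    min_block: int = 3
    cv_threshold: float = 0.15
    neutral_tolerance: float = 0.05
    calibration_age: float = 112.0
    outgroup: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference not in self.organisms:
            raise ValueError(
                f"reference {self.reference!r} not among organisms {self.organisms}"
            )
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be a percentage")
        if self.max_gap <= 0 or self.min_block < 2:
            raise ValueError("thresholds out of range")

    def manifest(self) -> dict:
        m = asdict(self)
        m["version"] = __version__
        # the hash identifies the scientific configuration; filesystem
        # locations do not affect results and are excluded
        hashed = {k: v for k, v in asdict(self).items() if k not in ("input_dir", "out_dir")}
        m["hash"] = hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()
        ).hexdigest()[:12]
        return m


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _header(manifest: dict) -> str:
    return f"# rosfam {manifest['version']} seed={manifest['seed']} manifest={manifest['hash']}\n"


def _write_tsv(df: pd.DataFrame, path: Path, manifest: dict, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_header(manifest))
        df.to_csv(fh, sep="\t", **kwargs)


def load_annotations(
    input_dir, organisms: list[str]
) -> dict[str, OrganismAnnotation]:
    """Read {org}.gff3 / {org}_genome.fasta / {org}_cds.fasta per organism."""
    input_dir = Path(input_dir)
    out: dict[str, OrganismAnnotation] = {}
    for org in organisms:
        gff3 = input_dir / f"{org}.gff3"
        if not gff3.exists():
            raise FileNotFoundError(f"no annotation for organism {org!r}: {gff3}")
        out[org] = read_annotation(
            gff3,
            input_dir / f"{org}_genome.fasta",
            input_dir / f"{org}_cds.fasta",
            organism=org,
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute read -> classify -> compare -> dupscan -> stats -> express ->
    kaks (-> date) and write the report bundle.

    Returns the mapping of report names to paths.  Any stage failure aborts
    with the stage name attached.
    """
    manifest = config.manifest()
    manifest["seed"] = config.seed
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(name, exc) from exc

        return deco

    @stage("read")
    def annotations():
        return load_annotations(config.input_dir, config.organisms)

    @stage("summarize")
    def _summary():
        summary = summarize_families(annotations)
        path = out_dir / "family_summary.tsv"
        _write_tsv(summary.table, path, manifest)
        reports["family_summary"] = path
        return summary

    @stage("compare")
    def matrix():
        m = build_presence_matrix(
            annotations, config.reference, min_identity=config.min_identity
        )
        path = out_dir / "presence_matrix.tsv"
        with open(path, "w") as fh:
            fh.write(_header(manifest))
            m.to_tsv(fh)
        reports["presence_matrix"] = path
        return m

    @stage("venn")
    def _venn():
        if len(config.organisms) == 4:
            counts = venn_counts(matrix)
            df = pd.DataFrame(
                [("+".join(k), v) for k, v in sorted(counts.items())],
                columns=["region", "count"],
            )
            path = out_dir / "venn.tsv"
            _write_tsv(df, path, manifest, index=False)
            reports["venn"] = path

    @stage("gain_loss")
    def _gl():
        rows = []
        for x in config.organisms:
            for y in config.organisms:
                if x < y:
                    gl = pairwise_gain_loss(matrix, x, y)
                    rows.append((x, y, gl.gained, gl.lost, gl.common))
        df = pd.DataFrame(rows, columns=["org_x", "org_y", "gained", "lost", "common"])
        path = out_dir / "gain_loss.tsv"
        _write_tsv(df, path, manifest, index=False)
        reports["gain_loss"] = path

    @stage("dupscan")
    def clusters():
        rows = []
        per_org = {}
        for org in config.organisms:
            cl = detect_tandem_clusters(annotations[org], max_gap=config.max_gap)
            per_org[org] = cl
            for c in cl:
                rows.append((org, c.chromosome, len(c), c.span, ",".join(c.members)))
        df = pd.DataFrame(
            rows, columns=["organism", "chromosome", "size", "span_bp", "members"]
        )
        path = out_dir / "tandem_clusters.tsv"
        _write_tsv(df, path, manifest, index=False)
        reports["tandem_clusters"] = path
        return per_org

    @stage("chrom_stats")
    def _cs():
        rows = []
        for org in config.organisms:
            st = chromosome_stats(annotations[org])
            for chrom in st.counts:
                rows.append(
                    (org, chrom, st.counts[chrom], st.percents[chrom], st.densities[chrom])
                )
        df = pd.DataFrame(
            rows, columns=["organism", "chromosome", "genes", "percent", "per_mb"]
        )
        path = out_dir / "chromosome_stats.tsv"
        _write_tsv(df, path, manifest, index=False)
        reports["chromosome_stats"] = path

    @stage("conservation")
    def _cons():
        summary = summarize_families(annotations)
        fams_clustered = {
            annotations[o].by_id(m).family
            for o, cl in clusters.items()
            for c in cl
            for m in c.members
        }
        cats = categorize_conservation(
            summary.family_sizes(), fams_clustered, config.cv_threshold
        )
        df = pd.DataFrame(sorted(cats.items()), columns=["family", "category"])
        path = out_dir / "conservation.tsv"
        _write_tsv(df, path, manifest, index=False)
        reports["conservation"] = path

    @stage("express")
    def _expr():
        counts_path = Path(config.input_dir) / "counts.tsv"
        if not counts_path.exists():
            return
        rows = []
        for org in config.organisms:
            table = load_counts_table(counts_path, organism=org)
            fam_map = {g.gene_id: g.family for g in annotations[org].genes}
            pseudo = {
                g.gene_id for g in annotations[org].genes if g.status == "pseudogene"
            }
            for fam, level in family_expression_level(table, fam_map, pseudo).items():
                rows.append((org, fam, level))
        df = pd.DataFrame(rows, columns=["organism", "family", "level"])
        path = out_dir / "expression_levels.tsv"
        _write_tsv(df, path, manifest, index=False)
        reports["expression_levels"] = path

    @stage("kaks")
    def _kaks():
        rows = []
        ref = annotations[config.reference]
        for org in config.organisms:
            if org == config.reference:
                continue
            for p in match_orthologs(ref, annotations[org], config.min_identity):
                ga, gb = ref.by_id(p.gene_a), annotations[org].by_id(p.gene_b)
                if ga.status != "complete" or gb.status != "complete":
                    continue
                try:
                    r = ng86_kaks(ga.cds, gb.cds)
                except (SaturationError, ValueError):
                    continue
                rows.append(
                    (
                        config.reference, p.gene_a, org, p.gene_b,
                        round(r.S, 2), round(r.N, 2), round(r.Sd, 2), round(r.Nd, 2),
                        round(r.Ks, 4), round(r.Ka, 4),
                        round(r.ratio, 4) if r.ratio is not None else "NA",
                        classify_selection(r, config.neutral_tolerance),
                    )
                )
        df = pd.DataFrame(
            rows,
            columns=[
                "org_a", "gene_a", "org_b", "gene_b", "S", "N", "Sd", "Nd",
                "Ks", "Ka", "ratio", "selection",
            ],
        )
        path = out_dir / "kaks.tsv"
        _write_tsv(df, path, manifest, index=False)
        reports["kaks"] = path

    @stage("date")
    def _date():
        if config.outgroup is None or config.outgroup not in annotations:
            return
        chim = build_chimeric_alignment(annotations, matrix)
        dated = date_divergences(chim, config.outgroup, config.calibration_age)
        path = out_dir / "dated_tree.nwk"
        with open(path, "w") as fh:
            fh.write(_header(manifest))
            fh.write(dated.newick() + "\n")
        reports["dated_tree"] = path

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    reports["manifest"] = out_dir / "manifest.json"
    return reports
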