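"""Survey orchestration: run the pipeline end to end and verify the catalog.

``run_survey`` executes identify -> classify -> name -> properties ->
map/duplications -> promoters -> expression -> qPCR over one run
configuration, writing every result table plus a MANIFEST of completed
stages; ``verify_against_catalog`` recomputes the bundled catalog's summary
statistics and compares them with the published values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import (
    domain_annotation,
    expression_profiles,
    family_pipeline,
    formats_io,
    genome_organization,
    promoter_elements,
    qpcr_analysis,
    sequence_properties,
)
from .domain_annotation import ArchitectureConfig
from .genome_organization import DuplicationCriteria
from .promoter_elements import PromoterConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys are rejected on load."""

    proteome: str = ""
    gff3: str = ""
    genome: str = ""
    domain_hits: str = ""
    promoters: str = ""
    expression: str = ""
    qpcr: str = ""
    segmental_pairs: str = ""
    out_dir: str = "survey_out"
    prefix: str = "DnaJ"
    reference_gene: str = "UBI"
    seed: int = 0
    e_threshold: float = 1e-5
    cov_complete: float = 0.8
    zf_min_repeats: int = 2
    cterm_min: int = 40
    max_distance_bp: int = 100_000
    min_coverage: float = 0.70
    min_identity: float = 0.70
    upstream_bp: int = 1500
    pseudocount: float = 1.0
    expr_min: float = 1.0
    specific_max: int = 2
    up_threshold: float = 2.0
    down_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.cov_complete <= 1:
            raise ValueError("cov_complete must be in (0,1]")
        if self.e_threshold <= 0 or self.upstream_bp <= 0:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def arch_config(self) -> ArchitectureConfig:
        return ArchitectureConfig(
            e_threshold=self.e_threshold,
            cov_complete=self.cov_complete,
            zf_min_repeats=self.zf_min_repeats,
            cterm_min=self.cterm_min,
        )

    def dup_criteria(self) -> DuplicationCriteria:
        return DuplicationCriteria(
            max_distance_bp=self.max_distance_bp,
            min_coverage=self.min_coverage,
            min_identity=self.min_identity,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_members(
    proteome: Sequence[formats_io.SequenceRecord],
    genes: Sequence[formats_io.GeneRecord],
    hits: Sequence[formats_io.DomainHit],
    arch_config: ArchitectureConfig,
    prefix: str = "DnaJ",
):
    """Identify + filter + classify + name in one call.

    Returns (members, removed, architectures) where members are the named
    family survivors and removed the incomplete-J candidates.
    """
    genes_by_protein = {g.protein_id: g for g in genes}
    hits_by_protein: dict[str, list] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    candidates = []
    archs = {}
    for prot in proteome:
        prot_hits = hits_by_protein.get(prot.id, [])
        arch = domain_annotation.assemble_architecture(prot, prot_hits, arch_config)
        archs[prot.id] = arch
        if arch.j_domains:
            gene = genes_by_protein.get(prot.id)
            if gene is None:
                gene = formats_io.GeneRecord(
                    gene_id=prot.id, chromosome="00", start=None, end=None,
                    strand="+", exons=(), protein_id=prot.id,
                )
            candidates.append((gene, arch))
    retained, removed = family_pipeline.filter_complete(candidates)
    members = family_pipeline.assign_names(
        [(g.gene_id, g, a) for g, a in retained], prefix=prefix
    )
    return members, removed, archs


def run_survey(config: RunConfig) -> Path:
    """Execute all configured stages; returns the output directory.

    Optional stages (promoters, expression, qPCR, segmental pairs) are
    marked skipped when their inputs are absent. Any stage error aborts
    with the stage name; MANIFEST lists the stages that completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    skipped: list[str] = []
    manifest = out / "MANIFEST"

    def finish_manifest() -> None:
        lines = [f"completed\t{s}" for s in completed] + [f"skipped\t{s}" for s in skipped]
        manifest.write_text("\n".join(lines) + "\n")

    try:
        stage = "identify"
        proteome = formats_io.read_fasta(config.proteome, "protein")
        genes = formats_io.read_gff3(config.gff3) if config.gff3 else []
        hits = formats_io.read_domain_table(config.domain_hits)
        members, removed, _ = build_members(
            proteome, genes, hits, config.arch_config(), prefix=config.prefix
        )
        seqs = {r.id: r.residues for r in proteome}
        completed.append(stage)

        stage = "catalog"
        rows = []
        for m in members:
            g = m.gene
            seq = seqs[m.locus]
            rows.append(
                {
                    "Gene name": m.gene_name,
                    "Locus": m.locus,
                    "Location": f"{g.start}-{g.end}" if g.placed else "",
                    "Chr.": g.chromosome,
                    "Group": m.group,
                    "Size(aa)": len(seq),
                    "MW(Da)": round(sequence_properties.molecular_weight(seq), 2),
                    "PI": round(sequence_properties.isoelectric_point(seq), 2),
                    "Introns": sequence_properties.intron_count(g),
                }
            )
        catalog = pd.DataFrame(rows)
        formats_io.write_tsv(catalog, out / "catalog.tsv")
        removed_df = pd.DataFrame(
            [{"locus": g.gene_id, "reason": "incomplete J-domain"} for g, _ in removed]
        )
        formats_io.write_tsv(
            removed_df if len(removed_df) else pd.DataFrame(columns=["locus", "reason"]),
            out / "removed_candidates.tsv",
        )
        completed.append(stage)

        stage = "census"
        census = family_pipeline.group_census(members)
        formats_io.write_tsv(
            pd.DataFrame([{"group": g, "count": c} for g, c in census.items()]),
            out / "group_census.tsv",
        )
        dist = genome_organization.chromosome_distribution(members)
        formats_io.write_tsv(
            pd.DataFrame(
                [{"chromosome": c, "count": n} for c, n in sorted(dist.items())]
            ),
            out / "chromosome_distribution.tsv",
        )
        completed.append(stage)

        stage = "duplications"
        name_seqs = {m.gene_name: seqs[m.locus] for m in members}
        calls = genome_organization.call_tandem(
            members, name_seqs, config.dup_criteria()
        )
        if config.segmental_pairs:
            calls += genome_organization.read_segmental_pairs(config.segmental_pairs, members)
        dup_df = pd.DataFrame(
            [
                {
                    "gene_a": c.gene_a, "gene_b": c.gene_b, "kind": c.kind,
                    "distance_bp": c.distance_bp,
                    "coverage": round(c.alignment.coverage_of_longer, 4) if c.alignment else "",
                    "identity": round(c.alignment.identity_of_aligned, 4) if c.alignment else "",
                }
                for c in calls
            ],
            columns=["gene_a", "gene_b", "kind", "distance_bp", "coverage", "identity"],
        )
        formats_io.write_tsv(dup_df, out / "duplications.tsv")
        completed.append(stage)

        stage = "promoters"
        promoter_windows = None
        if config.promoters:
            promoter_windows = formats_io.read_fasta(config.promoters, "nucleotide")
        elif config.genome and genes:
            genome = formats_io.read_fasta(config.genome, "nucleotide")
            locus_by_name = {m.locus for m in members}
            fam_genes = [g for g in genes if g.gene_id in locus_by_name]
            promoter_windows = promoter_elements.extract_promoters(
                genome, fam_genes, PromoterConfig(upstream_bp=config.upstream_bp)
            )
        if promoter_windows is None:
            skipped.append(stage)
        else:
            motifs = promoter_elements.load_default_motifs()
            pconfig = PromoterConfig(upstream_bp=config.upstream_bp)
            all_hits = []
            for window in promoter_windows:
                all_hits.extend(promoter_elements.scan_motifs(window, motifs, pconfig))
            per_motif, per_gene = promoter_elements.element_census(
                all_hits, [w.id for w in promoter_windows]
            )
            formats_io.write_tsv(per_motif, out / "motif_census.tsv")
            formats_io.write_tsv(per_gene, out / "motif_per_gene.tsv")
            formats_io.write_bed(all_hits, out / "motif_hits.bed")
            completed.append(stage)

        stage = "expression"
        if config.expression:
            m = expression_profiles.read_expression_tsv(config.expression)
            m_log = expression_profiles.log_transform(m, config.pseudocount)
            calls_ = expression_profiles.classify_pattern(
                m,
                expression_profiles.PatternThresholds(
                    expr_min=config.expr_min, specific_max=config.specific_max
                ),
            )
            formats_io.write_tsv(
                pd.DataFrame(
                    [
                        {"gene": c.gene, "pattern": c.pattern,
                         "expressed_in": ",".join(c.expressed_in)}
                        for c in calls_
                    ]
                ),
                out / "expression_patterns.tsv",
            )
            _, leaf_order, newick = expression_profiles.cluster_genes(m_log)
            (out / "expression_dendrogram.nwk").write_text(newick + "\n")
            expression_profiles.render_heatmap(
                m_log.sort_index(), leaf_order, out / "expression_heatmap.png"
            )
            completed.append(stage)
        else:
            skipped.append(stage)

        stage = "qpcr"
        if config.qpcr:
            table = qpcr_analysis.read_qpcr_tsv(config.qpcr)
            folds = qpcr_analysis.all_fold_changes(table, config.reference_gene)
            qcalls = qpcr_analysis.call_response(
                folds, config.up_threshold, config.down_threshold
            )
            formats_io.write_tsv(qpcr_analysis.calls_to_table(qcalls), out / "qpcr_calls.tsv")
            completed.append(stage)
        else:
            skipped.append(stage)

        stage = "report"
        _write_report(out, config, members, removed, census, dist, dup_df, completed, skipped)
        completed.append(stage)
    except StageError:
        finish_manifest()
        raise
    except Exception as exc:
        finish_manifest()
        raise StageError(stage, exc) from exc
    finish_manifest()
    return out


def _write_report(out, config, members, removed, census, dist, dup_df, completed, skipped):
    lines = [
        "# Gene family survey report",
        "",
        f"Candidates with J-domain evidence: {len(members) + len(removed)}",
        f"Removed (incomplete J-domain): {len(removed)}",
        f"Family members retained: {len(members)}",
        "",
        "## Group census",
        "",
        *[f"- {g}: {c}" for g, c in census.items()],
        "",
        "## Chromosome distribution",
        "",
        *[f"- {c}: {n}" for c, n in sorted(dist.items())],
        "",
        "## Duplications",
        "",
        f"- calls: {len(dup_df)}",
        "",
        "## Stages",
        "",
        *[f"- {s}: completed" for s in completed],
        *[f"- {s}: skipped" for s in skipped],
        "",
        "## Effective thresholds",
        "",
        f"- e_threshold: {config.e_threshold}",
        f"- cov_complete: {config.cov_complete}",
        f"- zf_min_repeats: {config.zf_min_repeats}",
        f"- cterm_min: {config.cterm_min}",
        f"- max_distance_bp: {config.max_distance_bp}",
        f"- min_coverage/min_identity: {config.min_coverage}/{config.min_identity}",
        f"- upstream_bp: {config.upstream_bp}",
    ]
    (out / "report.md").write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class CheckResult:
    name: str
    expected: Any
    actual: Any

    @property
    def passed(self) -> bool:
        return self.expected == self.actual


def verify_against_catalog(rows=None) -> list[CheckResult]:
    """Recompute the bundled catalog's summary statistics and compare them
    with the published values (group census 9/8/53/1/5, intron histogram,
    chromosome distribution, the single chromosome-7 tandem candidate pair,
    and the length/pI minima)."""
    if rows is None:
        rows = formats_io.load_catalog_fixture()
    members = family_pipeline.members_from_catalog(rows)
    census = family_pipeline.group_census(members)
    stats = sequence_properties.catalog_stats(rows)
    dist = genome_organization.chromosome_distribution(members)
    candidates = genome_organization.tandem_candidates(members)
    pair_names = [(a.gene_name, b.gene_name) for a, b in candidates]
    checks = [
        CheckResult("member count", 76, len(rows)),
        CheckResult("group census", {"A": 9, "B": 8, "C": 53, "D": 1, "E": 5}, census),
        CheckResult("intronless genes", 25, stats.intron_histogram.get(0, 0)),
        CheckResult("single-intron genes", 11, stats.intron_histogram.get(1, 0)),
        CheckResult("max introns", 11, max(stats.intron_histogram)),
        CheckResult("chromosome 8 genes", 11, dist.get("8", 0)),
        CheckResult("chromosome 5 genes", 9, dist.get("5", 0)),
        CheckResult("tandem candidate pairs", [("CaDnaJ41", "CaDnaJ42")], pair_names),
        CheckResult("min protein length (aa)", (130, "CaDnaJ23"), stats.min_size),
        CheckResult("min pI", (4.56, "CaDnaJ74"), stats.min_pi),
    ]
    return checks
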