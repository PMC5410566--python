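"""Candidate filtering, five-group classification and family naming.

Candidates that survive the profile-search e-value screen are kept only if
they carry a complete J-domain. Survivors are classified by domain
architecture into five groups:

    A - J-domain + zinc-finger domain + distinct C-terminal region
    B - J-domain + C-terminal region, no zinc finger
    C - J-domain only
    D - J-domain + zinc finger, no C-terminal region
    E - J-like: J-domain lacking the HPD tripeptide (overrides all others)

and named ``<prefix><rank>`` in chromosome order (chromosome ascending, then
start coordinate; unplaced genes last, ordered by locus id).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .domain_annotation import DomainArchitecture
from .formats_io import GeneRecord

GROUPS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class FamilyMember:
    gene_name: str
    locus: str
    architecture: DomainArchitecture
    gene: GeneRecord
    group: str


def filter_complete(
    candidates: Sequence[tuple[GeneRecord, DomainArchitecture]],
) -> tuple[list[tuple[GeneRecord, DomainArchitecture]], list[tuple[GeneRecord, DomainArchitecture]]]:
    """Split candidates into (retained, removed) on J-domain completeness."""
    retained = [c for c in candidates if c[1].j_complete]
    removed = [c for c in candidates if not c[1].j_complete]
    return retained, removed


def classify_protein(arch: DomainArchitecture) -> str:
    """Assign one of the five groups from an architecture.

    The HPD test comes first: a J-domain without the hallmark tripeptide is
    a J-like protein (group E) regardless of its other domains.
    """
    if not arch.j_domains:
        raise ValueError(f"{arch.protein_id}: no J-domain; classify after filtering")
    if not arch.has_hpd:
        return "E"
    if arch.has_zinc_finger and arch.has_cterm:
        return "A"
    if arch.has_zinc_finger:
        return "D"
    if arch.has_cterm:
        return "B"
    return "C"


def _sort_key(locus: str, gene: GeneRecord) -> tuple:
    if gene.placed:
        try:
            chrom = int(gene.chromosome)
        except ValueError:
            chrom = gene.chromosome
        return (0, chrom, gene.start, locus)
    return (1, locus)


def assign_names(
    members: Sequence[tuple[str, GeneRecord, DomainArchitecture]],
    prefix: str = "CaDnaJ",
) -> list[FamilyMember]:
    """Name members in chromosome order with zero-padded ranks.

    Input items are (locus, gene, architecture). Placed genes sort by
    (numeric chromosome, start); unplaced genes follow, ordered by locus id.
    Padding width is at least two digits.
    """
    seen: dict[tuple, str] = {}
    for locus, gene, _ in members:
        if gene.placed:
            key = (gene.chromosome, gene.start)
            if key in seen and seen[key] == locus:
                raise ValueError(f"duplicate placement for locus {locus} at {key}")
            seen[key] = locus
    ordered = sorted(members, key=lambda m: _sort_key(m[0], m[1]))
    width = max(2, len(str(len(ordered))))
    out = []
    for rank, (locus, gene, arch) in enumerate(ordered, start=1):
        out.append(
            FamilyMember(
                gene_name=f"{prefix}{rank:0{width}d}",
                locus=locus,
                architecture=arch,
                gene=gene,
                group=classify_protein(arch),
            )
        )
    return out


def group_census(members: Iterable) -> dict[str, int]:
    """Count members per group; accepts FamilyMember or anything with .group."""
    counts = Counter(m.group for m in members)
    return {g: counts.get(g, 0) for g in GROUPS}


def members_from_catalog(rows: Sequence) -> list[FamilyMember]:
    """Adapt published catalog rows (no sequences) into member records.

    Architectures are unknown for catalog rows, so ``architecture`` is None
    and ``group`` is taken from the table; coordinate-based analyses
    (distribution, tandem candidates) work unchanged.
    """
    out = []
    for r in rows:
        gene = GeneRecord(
            gene_id=r.locus,
            chromosome=r.chromosome,
            start=r.start,
            end=r.end,
            strand="+",
            exons=(),
            protein_id=r.locus,
        )
        out.append(
            FamilyMember(
                gene_name=r.gene_name,
                locus=r.locus,
                architecture=None,
                gene=gene,
                group=r.group,
            )
        )
    return out


def members_to_table(members: Sequence[FamilyMember]) -> pd.DataFrame:
    """Family catalog in the published table's column layout."""
    rows = []
    for m in members:
        g = m.gene
        location = f"{g.start}-{g.end}" if g.placed else ""
        rows.append(
            {
                "Gene name": m.gene_name,
                "Locus": m.locus,
                "Location": location,
                "Chr.": g.chromosome,
                "Group": m.group,
            }
        )
    return pd.DataFrame(rows)
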