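"""Promoter extraction and cis-element scanning.

Promoters are the 1.5 kb immediately upstream of the transcription start
(the start base itself excluded), reverse-complemented for minus-strand
genes and truncated at contig edges. Scanning matches IUPAC degenerate
motifs on both strands; overlapping occurrences are counted, since element
tallies count occurrences. The bundled element table (heat-shock element
core AAAAAATTTC plus canonical consensi for nine stress/hormone elements)
is replaceable data: counts depend entirely on the motif library used.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .formats_io import FormatError, GeneRecord, SequenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    sequence: str
    category: str  # stress | hormone
    response: str = ""

    def __post_init__(self) -> None:
        for ch in self.sequence:
            if ch not in IUPAC:
                raise ValueError(f"motif {self.name}: illegal IUPAC code {ch!r}")


@dataclass(frozen=True)
class MotifHit:
    gene: str
    motif: str
    start: int  # 1-based inclusive, promoter-forward coordinates
    end: int
    strand: str
    matched_seq: str


@dataclass(frozen=True)
class PromoterConfig:
    upstream_bp: int = 1500
    scan_both_strands: bool = True
    allow_overlaps: bool = True

    def __post_init__(self) -> None:
        if self.upstream_bp <= 0:
            raise ValueError("upstream_bp must be positive")


def load_default_motifs() -> list[MotifDefinition]:
    ref = importlib.resources.files("dnajsurvey").joinpath("data/cis_elements.tsv")
    motifs = []
    with ref.open() as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = dict(zip(header, line.split("\t")))
            motifs.append(MotifDefinition(**vals))
    return motifs


def read_motif_table(path: str | Path) -> list[MotifDefinition]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MotifDefinition(
            name=r["name"], sequence=r["sequence"],
            category=r["category"], response=r.get("response", ""),
        )
        for r in df.to_dict("records")
    ]


def extract_promoters(
    genome: Sequence[SequenceRecord],
    genes: Sequence[GeneRecord],
    config: PromoterConfig = PromoterConfig(),
) -> list[SequenceRecord]:
    """Cut the upstream window of each placed gene out of its contig.

    Plus strand: bases [start - upstream_bp, start - 1]; minus strand: the
    reverse complement of [end + 1, end + upstream_bp]. Windows shorter than
    ``upstream_bp`` (contig edge) are kept and flagged in the description.
    """
    contigs = {c.id: c.residues for c in genome}
    out = []
    for g in genes:
        if g.chromosome not in contigs:
            raise FormatError(f"gene {g.gene_id}: contig {g.chromosome!r} not in genome")
        seq = contigs[g.chromosome]
        if g.strand == "+":
            lo = max(1, g.start - config.upstream_bp)
            hi = g.start - 1
            window = seq[lo - 1 : hi]
        else:
            lo = g.end + 1
            hi = min(len(seq), g.end + config.upstream_bp)
            window = str(Seq(seq[lo - 1 : hi]).reverse_complement())
        desc = "promoter"
        if len(window) < config.upstream_bp:
            desc += f" truncated:{len(window)}bp"
        out.append(SequenceRecord(id=g.gene_id, residues=window, description=desc))
    return out


def _iupac_regex(motif: str) -> re.Pattern:
    body = "".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in motif)
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def scan_motifs(
    promoter: SequenceRecord,
    motifs: Sequence[MotifDefinition],
    config: PromoterConfig = PromoterConfig(),
) -> list[MotifHit]:
    """All occurrences of each motif in one promoter window.

    Reverse-strand hits are found by scanning the reverse complement and
    reported in forward coordinates with strand '-'.
    """
    seq = promoter.residues.upper()
    n = len(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        regex = _iupac_regex(motif.sequence)
        m_len = len(motif.sequence)
        for m in regex.finditer(seq):
            s = m.start() + 1
            hits.append(
                MotifHit(
                    gene=promoter.id, motif=motif.name,
                    start=s, end=s + m_len - 1, strand="+",
                    matched_seq=m.group(1),
                )
            )
        if config.scan_both_strands:
            rc = str(Seq(seq).reverse_complement())
            for m in regex.finditer(rc):
                # position on rc maps back to forward coordinates
                end = n - m.start()
                start = end - m_len + 1
                hits.append(
                    MotifHit(
                        gene=promoter.id, motif=motif.name,
                        start=start, end=end, strand="-",
                        matched_seq=m.group(1),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


def element_census(
    hits: Iterable[MotifHit], genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally hits per motif and per gene.

    Returns (per_motif, per_gene): per_motif has total occurrence counts and
    the number of genes carrying at least one hit; per_gene has the number
    of distinct element types and total element count for every gene
    (zeros included).
    """
    hits = list(hits)
    df = pd.DataFrame(
        [(h.gene, h.motif) for h in hits], columns=["gene", "motif"]
    )
    motif_names = sorted({h.motif for h in hits})
    per_motif_rows = []
    for m in motif_names:
        sub = df[df.motif == m]
        per_motif_rows.append(
            {"motif": m, "total_hits": len(sub), "genes_with_hit": sub.gene.nunique()}
        )
    per_motif = pd.DataFrame(per_motif_rows, columns=["motif", "total_hits", "genes_with_hit"])
    per_gene_rows = []
    for g in genes:
        sub = df[df.gene == g] if len(df) else df
        per_gene_rows.append(
            {"gene": g, "n_types": sub.motif.nunique() if len(sub) else 0,
             "n_elements": len(sub)}
        )
    per_gene = pd.DataFrame(per_gene_rows, columns=["gene", "n_types", "n_elements"])
    return per_motif, per_gene
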