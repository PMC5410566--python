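"""Readers and writers for the external formats the survey touches.

All genomic coordinates are 1-based inclusive internally (the convention of
GFF3 and of the published catalog); conversion to 0-based half-open happens
only when emitting BED. Sequence I/O goes through Biopython, gene models
through gffutils.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NUCLEOTIDE_ALPHABET = set("ACGTN")

Alphabet = Literal["protein", "nucleotide"]


class FormatError(ValueError):
    """Raised on malformed or invariant-violating input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (protein or nucleotide)."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """One gene model: locus span plus the exon chain of its representative mRNA."""

    gene_id: str
    chromosome: str
    start: int | None
    end: int | None
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None:
            if self.start > self.end:
                raise FormatError(f"{self.gene_id}: start {self.start} > end {self.end}")
            prev_end = 0
            for (s, e) in self.exons:
                if s > e:
                    raise FormatError(f"{self.gene_id}: exon {s}-{e} reversed")
                if s < self.start or e > self.end:
                    raise FormatError(
                        f"{self.gene_id}: exon {s}-{e} outside gene span "
                        f"{self.start}-{self.end}"
                    )
                if s <= prev_end:
                    raise FormatError(f"{self.gene_id}: exons overlap or unsorted at {s}-{e}")
                prev_end = e

    @property
    def placed(self) -> bool:
        return self.chromosome != "00" and self.start is not None


@dataclass(frozen=True)
class DomainHit:
    """One profile-vs-protein domain match from a tabular hit file."""

    protein_id: str
    domain_id: str
    ali_start: int
    ali_end: int
    profile_cov: float
    e_value: float

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise FormatError(
                f"{self.protein_id}/{self.domain_id}: ali_start > ali_end"
            )
        if self.e_value <= 0:
            raise FormatError(f"{self.protein_id}: e-value must be positive")
        if not 0.0 <= self.profile_cov <= 1.0:
            raise FormatError(f"{self.protein_id}: profile_cov outside [0,1]")


@dataclass(frozen=True)
class CatalogRow:
    """One row of the published family catalog (name, locus, placement, properties)."""

    gene_name: str
    locus: str
    chromosome: str
    start: int | None
    end: int | None
    group: str
    size_aa: int
    mw_da: float
    pi: float
    introns: int

    def __post_init__(self) -> None:
        if self.group not in set("ABCDE"):
            raise FormatError(f"{self.gene_name}: group {self.group!r} not in A-E")
        if self.size_aa < 1 or self.introns < 0:
            raise FormatError(f"{self.gene_name}: invalid size/introns")


def _validate_residues(rec_id: str, residues: str, alphabet: Alphabet) -> None:
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    for pos, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise FormatError(
                f"record {rec_id!r}: illegal {alphabet} character {ch!r} at position {pos}"
            )


def read_fasta(path: str | Path, alphabet: Alphabet = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Residues are uppercased; record order is preserved. Duplicate ids and
    characters outside the declared alphabet are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise FormatError(f"record {rec.id!r}: empty sequence")
        _validate_residues(rec.id, residues, alphabet)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Load gene models from GFF3, one record per gene.

    When a gene carries several mRNAs the representative isoform is the one
    with the longest summed exon length (ties broken by lexicographic mRNA
    id). Exons must lie inside their gene span and carry a Parent attribute.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    # every exon must name a Parent
    for exon in db.features_of_type("exon"):
        if "Parent" not in exon.attributes:
            raise FormatError(f"exon at {exon.seqid}:{exon.start}-{exon.end} lacks Parent")

    genes: list[GeneRecord] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise FormatError(f"gene {gene.id}: no mRNA children")

        def exon_spans(mrna: gffutils.Feature) -> list[tuple[int, int]]:
            return sorted(
                (ex.start, ex.end) for ex in db.children(mrna, featuretype="exon")
            )

        best = max(
            mrnas,
            key=lambda m: (sum(e - s + 1 for s, e in exon_spans(m)), m.id),
        )
        spans = exon_spans(best)
        for s, e in spans:
            if s < gene.start or e > gene.end:
                raise FormatError(
                    f"gene {gene.id}: exon {s}-{e} outside gene span "
                    f"{gene.start}-{gene.end}"
                )
        protein_id = best.attributes.get("protein_id", [best.id])[0]
        genes.append(
            GeneRecord(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=tuple(spans),
                protein_id=protein_id,
            )
        )
    return genes


#: column order of the tabular per-domain hit format
_HIT_COLUMNS = (
    "target",
    "domain",
    "e_value",
    "hmm_from",
    "hmm_to",
    "ali_from",
    "ali_to",
    "hmm_len",
)


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Read a whitespace-separated per-domain hit table.

    Columns: target id, domain id, i-E-value, hmm from/to, ali from/to and
    profile length. Profile coverage is (hmm_to - hmm_from + 1) / hmm_length.
    Lines starting with '#' are skipped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < len(_HIT_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(_HIT_COLUMNS)} columns")
            target, domain = fields[0], fields[1]
            try:
                e_value = float(fields[2])
                hmm_from, hmm_to = int(fields[3]), int(fields[4])
                ali_from, ali_to = int(fields[5]), int(fields[6])
                hmm_len = int(fields[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            cov = (hmm_to - hmm_from + 1) / hmm_len
            hits.append(
                DomainHit(
                    protein_id=target,
                    domain_id=domain,
                    ali_start=ali_from,
                    ali_end=ali_to,
                    profile_cov=cov,
                    e_value=e_value,
                )
            )
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path, hmm_len: int) -> None:
    """Emit hits in the tabular format read by :func:`read_domain_table`.

    The hmm span is reconstructed from profile coverage against ``hmm_len``.
    """
    with open(path, "w") as fh:
        fh.write("# " + " ".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            hmm_to = max(1, round(h.profile_cov * hmm_len))
            fh.write(
                f"{h.protein_id}\t{h.domain_id}\t{h.e_value:.3g}\t1\t{hmm_to}\t"
                f"{h.ali_start}\t{h.ali_end}\t{hmm_len}\n"
            )


def load_catalog_fixture() -> list[CatalogRow]:
    """Load the bundled 76-member pepper CaDnaJ catalog.

    The table is typed verbatim from the published survey, including its
    internal inconsistencies; it is data, not a corrected dataset. Unplaced
    scaffold genes carry chromosome "00" and null coordinates.
    """
    ref = importlib.resources.files("dnajsurvey").joinpath("data/catalog_cadnaj.tsv")
    rows: list[CatalogRow] = []
    with ref.open() as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = dict(zip(header, line.split("\t")))
            placed = vals["start"] != "."
            rows.append(
                CatalogRow(
                    gene_name=vals["gene_name"],
                    locus=vals["locus"],
                    chromosome=vals["chromosome"],
                    start=int(vals["start"]) if placed else None,
                    end=int(vals["end"]) if placed else None,
                    group=vals["group"],
                    size_aa=int(vals["size_aa"]),
                    mw_da=float(vals["mw_da"]),
                    pi=float(vals["pi"]),
                    introns=int(vals["introns"]),
                )
            )
    return rows


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with a '#'-prefixed header line (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, table.columns)) + "\n")
        table.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line.startswith("#"):
            raise FormatError(f"{path}: missing '#'-prefixed header")
        columns = header_line[1:].split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=columns)
    return df


def write_bed(hits: Sequence, path: str | Path) -> None:
    """Write interval-like objects as BED6 (0-based half-open).

    Objects must expose ``chrom``-like, ``start``, ``end`` 1-based inclusive
    attributes plus ``name``/``score``/``strand`` (defaults used if absent).
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for h in hits:
            chrom = getattr(h, "chrom", None) or getattr(h, "gene", None) or getattr(h, "chromosome")
            name = getattr(h, "name", None) or getattr(h, "motif", ".")
            score = getattr(h, "score", 0)
            strand = getattr(h, "strand", "+")
            fh.write(f"{chrom}\t{h.start - 1}\t{h.end}\t{name}\t{score}\t{strand}\n")
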