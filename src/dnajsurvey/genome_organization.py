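"""Chromosome distribution and gene-duplication analysis.

Tandem duplicates are called by three criteria: the pair lies within
100 kb on one chromosome (gap between the gene intervals), the alignment
covers more than 70% of the longer gene, and the aligned region is more
than 70% identical (both strict, per "more than 70%"). Alignment is global
Needleman-Wunsch with a linear gap penalty. Segmental duplications are not
discovered here; precomputed synteny pairs are ingested as-is.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DuplicationCriteria:
    max_distance_bp: int = 100_000
    min_coverage: float = 0.70  # strict >
    min_identity: float = 0.70  # strict >
    max_intervening_genes: int | None = 1

    def __post_init__(self) -> None:
        if self.max_distance_bp <= 0:
            raise ValueError("max_distance_bp must be positive")
        for f in (self.min_coverage, self.min_identity):
            if not 0 < f <= 1:
                raise ValueError("coverage/identity thresholds must be in (0,1]")


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    substitution: Mapping[tuple[str, str], float] | None = None

    def score(self, a: str, b: str) -> float:
        if self.substitution is not None:
            return self.substitution.get((a, b), self.substitution.get((b, a), self.mismatch))
        return self.match if a == b else self.mismatch


@dataclass(frozen=True)
class AlignmentResult:
    aligned_pairs: int
    identical: int
    coverage_of_longer: float
    identity_of_aligned: float
    score: float

    def __post_init__(self) -> None:
        if self.identical > self.aligned_pairs:
            raise ValueError("identical exceeds aligned pairs")


@dataclass(frozen=True)
class DuplicationCall:
    gene_a: str
    gene_b: str
    kind: str  # tandem | segmental
    distance_bp: int
    alignment: AlignmentResult | None = None

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            raise ValueError("genes must be in canonical (sorted) order")


def chromosome_distribution(members: Iterable) -> dict[str, int]:
    """Per-chromosome member counts; unplaced genes count under "00"."""
    counts = Counter(m.gene.chromosome for m in members)
    return dict(counts)


def _gap_bp(a, b) -> int:
    """Gap between two gene intervals on one chromosome; 0 if they overlap."""
    if a.gene.start > b.gene.start:
        a, b = b, a
    return max(0, b.gene.start - a.gene.end)


def tandem_candidates(
    members: Sequence, criteria: DuplicationCriteria = DuplicationCriteria()
) -> list[tuple]:
    """Same-chromosome pairs within the distance criterion.

    Each unordered pair appears once (sorted by gene name). When
    ``max_intervening_genes`` is set, pairs separated by more than that many
    other family members on the chromosome are dropped; non-family genes
    are invisible to this count.
    """
    placed = sorted(
        (m for m in members if m.gene.placed),
        key=lambda m: (m.gene.chromosome, m.gene.start),
    )
    by_chrom: dict[str, list] = {}
    for m in placed:
        by_chrom.setdefault(m.gene.chromosome, []).append(m)
    pairs = []
    for chrom_members in by_chrom.values():
        for i, a in enumerate(chrom_members):
            for j in range(i + 1, len(chrom_members)):
                b = chrom_members[j]
                if _gap_bp(a, b) > criteria.max_distance_bp:
                    continue
                if (
                    criteria.max_intervening_genes is not None
                    and (j - i - 1) > criteria.max_intervening_genes
                ):
                    continue
                pairs.append(tuple(sorted((a, b), key=lambda m: m.gene_name)))
    return sorted(pairs, key=lambda p: (p[0].gene_name, p[1].gene_name))


def global_align(a: str, b: str, scoring: Scoring = Scoring()) -> AlignmentResult:
    """Needleman-Wunsch global alignment with a linear gap penalty.

    Coverage of the longer sequence counts its residues placed in
    residue-residue columns; identity is computed over those columns only.
    Traceback prefers diagonal, then gap-in-b, then gap-in-a (deterministic).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    n, m = len(a), len(b)
    gap = scoring.gap
    F = np.empty((n + 1, m + 1))
    F[0, :] = np.arange(m + 1) * gap
    F[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            F[i, j] = max(
                F[i - 1, j - 1] + scoring.score(a[i - 1], b[j - 1]),
                F[i - 1, j] + gap,
                F[i, j - 1] + gap,
            )
    # traceback
    i, j = n, m
    aligned = identical = 0
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and F[i, j] == F[i - 1, j - 1] + scoring.score(a[i - 1], b[j - 1])
        ):
            aligned += 1
            identical += a[i - 1] == b[j - 1]
            i -= 1
            j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    longer = max(n, m)
    return AlignmentResult(
        aligned_pairs=aligned,
        identical=identical,
        coverage_of_longer=aligned / longer,
        identity_of_aligned=(identical / aligned) if aligned else 0.0,
        score=float(F[n, m]),
    )


def call_tandem(
    members: Sequence,
    sequences: Mapping[str, str],
    criteria: DuplicationCriteria = DuplicationCriteria(),
    scoring: Scoring = Scoring(),
) -> list[DuplicationCall]:
    """Apply the coverage/identity criteria to distance candidates.

    ``sequences`` maps member gene names to protein (default) or nucleotide
    sequences. Both thresholds are strict: exactly 70% does not qualify.
    """
    calls = []
    for a, b in tandem_candidates(members, criteria):
        for m in (a, b):
            if m.gene_name not in sequences:
                raise KeyError(f"no sequence for candidate gene {m.gene_name}")
        aln = global_align(sequences[a.gene_name], sequences[b.gene_name], scoring)
        if (
            aln.coverage_of_longer > criteria.min_coverage
            and aln.identity_of_aligned > criteria.min_identity
        ):
            calls.append(
                DuplicationCall(
                    gene_a=a.gene_name,
                    gene_b=b.gene_name,
                    kind="tandem",
                    distance_bp=_gap_bp(a, b),
                    alignment=aln,
                )
            )
    return calls


def read_segmental_pairs(path: str | Path, members: Sequence) -> list[DuplicationCall]:
    """Ingest a two-column TSV of synteny locus pairs as segmental calls.

    Lines naming a locus absent from the family are skipped with a warning.
    """
    by_locus = {m.locus: m for m in members}
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                continue
            la, lb = fields[0], fields[1]
            if la not in by_locus or lb not in by_locus:
                logger.warning("%s:%d: unknown locus in pair (%s, %s); skipped", path, lineno, la, lb)
                continue
            names = sorted((by_locus[la].gene_name, by_locus[lb].gene_name))
            calls.append(
                DuplicationCall(gene_a=names[0], gene_b=names[1], kind="segmental", distance_bp=0)
            )
    return calls
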